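"""FHIR transaction bundles for site exports and master-record merge plans.

A site export is a single transaction bundle carrying one conditional update
(PUT keyed on the record's site-local identifier) per study record, so that
re-running an export never duplicates resources.  The merge plan materializes
as a second bundle: conditional PUTs keyed on the master tag plus one of the
master's identifiers, and conditional DELETEs for stale masters.  Both bundles
are byte-stable for identical input: entry order is deterministic and every
fullUrl is a UUID derived from the resource's stable identity.
"""

from __future__ import annotations

import uuid
from urllib.parse import parse_qs, quote, urlparse

from .core_model import MasterStudy, StudyRecord, local_system_uri
from .fhir_mapping import (
    DEFAULT_PROFILE,
    DEFAULT_TABLE,
    IdentifierSystemTable,
    MASTER_TAG_CODE,
    ProfileConfig,
    ResourceSet,
    build_ref_index,
    from_research_study,
    to_research_study,
)
from .merger import ConditionalKey, MergePlan

_UUID_NS = uuid.uuid5(uuid.NAMESPACE_URL, "urn:trialreg:bundle-entry")

#: characters left readable in conditional-update search tokens
_TOKEN_SAFE = ":/|"


def _full_url(resource: dict) -> str:
    return "urn:uuid:" + str(
        uuid.uuid5(_UUID_NS, f"{resource['resourceType']}/{resource['id']}")
    )


def _token(system: str, value: str) -> str:
    return quote(f"{system}|{value}", safe=_TOKEN_SAFE)


def _put_entry(resource: dict, conditional_url: str) -> dict:
    return {
        "fullUrl": _full_url(resource),
        "resource": resource,
        "request": {"method": "PUT", "url": conditional_url},
    }


def _resource_set_entries(rset: ResourceSet, cfg: ProfileConfig, rs_url: str) -> list[dict]:
    entries = [_put_entry(rset.research_study, rs_url)]
    for loc in rset.locations:
        entries.append(
            _put_entry(loc, f"Location?identifier={_token(cfg.site_id_system, loc['identifier'][0]['value'])}")
        )
    if rset.group is not None:
        # Groups carry no business identifier; update by deterministic id
        entries.append(_put_entry(rset.group, f"Group/{rset.group['id']}"))
    return entries


def _dedupe_entries(entries: list[dict]) -> list[dict]:
    seen: set[str] = set()
    out = []
    for e in entries:
        if e["fullUrl"] in seen:
            continue
        seen.add(e["fullUrl"])
        out.append(e)
    return out


def site_export_bundle(
    records: list[StudyRecord],
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> dict:
    """One site's export: a transaction bundle of conditional updates.

    All records must come from the same exporting site.  Each ResearchStudy is
    keyed on its LOCAL identifier; shared Location resources appear once.
    """
    sites = {r.exporting_site for r in records}
    if len(sites) > 1:
        raise ValueError(f"records from multiple exporting sites: {sorted(sites)}")

    entries: list[dict] = []
    not_master = _token(cfg.tag_system, MASTER_TAG_CODE)
    for record in sorted(records, key=lambda r: r.ref()):
        rset = to_research_study(record, cfg, table)
        local_system = local_system_uri(record.exporting_site, cfg.local_system_template)
        # masters carry their members' LOCAL identifiers too, so the
        # conditional must exclude master-tagged resources
        url = (
            f"ResearchStudy?identifier={_token(local_system, record.local_id)}"
            f"&_tag:not={not_master}"
        )
        entries.extend(_resource_set_entries(rset, cfg, url))
    return {
        "resourceType": "Bundle",
        "type": "transaction",
        "entry": _dedupe_entries(entries),
    }


def _conditional_master_url(key: ConditionalKey) -> str:
    tag = _token(key.tag_system, key.tag_code)
    ident = _token(key.identifier_system, key.identifier_value)
    return f"ResearchStudy?_tag={tag}&identifier={ident}"


def master_plan_bundle(
    plan: MergePlan,
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> dict:
    """Materialize a merge plan as a transaction bundle.

    Creates and updates become conditional PUTs keyed on (master tag AND one
    identifier); deletes become conditional DELETEs with the same key shape.
    """
    entries: list[dict] = []
    for entry in [*plan.creates, *plan.updates]:
        if not entry.master.identifiers:
            raise ValueError("master study without identifiers cannot be keyed")
        rset = to_research_study(entry.master, cfg, table)
        entries.extend(
            _resource_set_entries(rset, cfg, _conditional_master_url(entry.conditional))
        )
    for delete in plan.deletes:
        entries.append(
            {"request": {"method": "DELETE", "url": _conditional_master_url(delete.conditional)}}
        )
    return {
        "resourceType": "Bundle",
        "type": "transaction",
        "entry": _dedupe_entries([e for e in entries if "fullUrl" in e]) +
        [e for e in entries if "fullUrl" not in e],
    }


def chunk_bundle(bundle: dict, max_entries: int) -> list[dict]:
    """Split a transaction bundle into chunks of at most ``max_entries``.

    Central servers may time out on very large transactions; chunking trades
    atomicity of the whole export for bounded request sizes.  Entry order is
    preserved, so resources referenced within one study stay adjacent.
    """
    if max_entries < 1:
        raise ValueError("max_entries must be >= 1")
    entries = bundle.get("entry", [])
    if len(entries) <= max_entries:
        return [bundle]
    return [
        {**bundle, "entry": entries[i : i + max_entries]}
        for i in range(0, len(entries), max_entries)
    ]


def master_query(cfg: ProfileConfig = DEFAULT_PROFILE) -> str:
    """Search string retrieving all actively recruiting master studies."""
    tag = _token(cfg.tag_system, MASTER_TAG_CODE)
    return f"ResearchStudy?status=active&_tag={tag}"


def parse_query(query: str) -> dict[str, list[str]]:
    """URL-decode a search string back into its parameters (test/debug aid)."""
    return parse_qs(urlparse(query).query)


def records_from_bundle(
    bundle: dict,
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> list[StudyRecord | MasterStudy]:
    """Ingest a transaction/collection bundle back into study records."""
    resources = [e["resource"] for e in bundle.get("entry", []) if "resource" in e]
    index = build_ref_index(resources)
    for entry in bundle.get("entry", []):
        if "resource" in entry and "fullUrl" in entry:
            index[entry["fullUrl"]] = entry["resource"]
    return [
        from_research_study(res, cfg, table, ref_index=index)
        for res in resources
        if res.get("resourceType") == "ResearchStudy"
    ]
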