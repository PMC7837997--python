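"""Bidirectional mapping between study records and FHIR R4 resources.

Each study record maps to one ResearchStudy resource plus one Location per
participating site (referenced by ``ResearchStudy.site``) and one Group
holding the demographic eligibility criteria (referenced by
``ResearchStudy.enrollment``).  The base ResearchStudy resource cannot express
a per-site recruitment status, per-site contacts, or an acronym, so those
travel in profile extensions at configurable URLs.  Merged ("master") studies
additionally carry a tag in ``meta.tag`` so that a registry query can filter
for them.

The mapping is lossless: ``from_research_study(to_research_study(r)) == r``
for any record that passes :func:`~trialreg.core_model.validate_record`.

FHIR JSON is handled as plain dicts; only the elements of the core data set
are produced, and unknown extensions are ignored (but logged) on ingestion.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict

from .core_model import (
    SYSTEM_URI,
    DEFAULT_LOCAL_SYSTEM_TEMPLATE,
    ConditionCode,
    CodeSystem,
    ContactPoint,
    EligibilityCriteria,
    Gender,
    IdentifierSource,
    Language,
    LocalizedText,
    MasterStudy,
    QueryRole,
    RecruitmentStatus,
    RelatedLink,
    SiteInfo,
    StudyRecord,
    Telecom,
    TelecomKind,
    TrialIdentifier,
    local_system_uri,
    parse_local_system_uri,
    validate_record,
)

logger = logging.getLogger(__name__)

MASTER_TAG_CODE = "master"

_CONDITION_SYSTEM = {
    CodeSystem.ICD10GM: "http://fhir.de/CodeSystem/bfarm/icd-10-gm",
    CodeSystem.SNOMED: "http://snomed.info/sct",
}
_CONDITION_SYSTEM_INV = {v: k for k, v in _CONDITION_SYSTEM.items()}

_GENDER_SYSTEM = "http://hl7.org/fhir/administrative-gender"


class MappingError(ValueError):
    """Raised when a record or resource cannot be mapped; lists the reasons."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class ProfileConfig(BaseModel):
    """URLs that pin down the registry's ResearchStudy profile.

    The published profile lives in an external registry, so every URL is
    configuration with a stable default rather than a hard constant.
    """

    model_config = ConfigDict(frozen=True)

    profile_canonical: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/ResearchStudyRegistry"
    )
    extension_url_acronym: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/StudyAcronym"
    )
    extension_url_site_status: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/SiteRecruitmentStatus"
    )
    extension_url_site_contact: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/SiteContact"
    )
    extension_url_title_translation: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/LocalizedTitle"
    )
    extension_url_description_translation: str = (
        "https://fhir.miracum.org/uc1/StructureDefinition/LocalizedDescription"
    )
    tag_system: str = "https://fhir.miracum.org/uc1/CodeSystem/registryStudyRole"
    site_id_system: str = "https://fhir.miracum.org/uc1/NamingSystem/siteId"
    local_system_template: str = DEFAULT_LOCAL_SYSTEM_TEMPLATE
    #: emit Location/Group as contained resources instead of referenced ones
    contained_resources: bool = False


DEFAULT_PROFILE = ProfileConfig()


@dataclass(frozen=True)
class IdentifierSystemRow:
    system: str
    url_template: str | None  # ``{value}`` placeholder; None = no public URL
    display: str


@dataclass(frozen=True)
class IdentifierSystemTable:
    """Registry-number to FHIR identifier-system and relatedArtifact mapping."""

    rows: Mapping[IdentifierSource, IdentifierSystemRow] = field(
        default_factory=lambda: dict(_DEFAULT_ROWS)
    )

    def system_for(self, source: IdentifierSource) -> str:
        return self.rows[source].system

    def source_for_system(self, system: str) -> IdentifierSource:
        for source, row in self.rows.items():
            if row.system == system:
                return source
        return IdentifierSource.LOCAL

    def related_url(self, source: IdentifierSource, value: str) -> str | None:
        row = self.rows.get(source)
        if row is None or row.url_template is None:
            return None
        return row.url_template.format(value=value)

    def display_for(self, source: IdentifierSource) -> str:
        row = self.rows.get(source)
        return row.display if row else source.value


_DEFAULT_ROWS: dict[IdentifierSource, IdentifierSystemRow] = {
    IdentifierSource.NCT: IdentifierSystemRow(
        SYSTEM_URI[IdentifierSource.NCT],
        "https://clinicaltrials.gov/ct2/show/{value}",
        "ClinicalTrials.gov",
    ),
    IdentifierSource.DRKS: IdentifierSystemRow(
        SYSTEM_URI[IdentifierSource.DRKS],
        "https://www.drks.de/drks_web/navigate.do?navigationId=trial.HTML&TRIAL_ID={value}",
        "DRKS",
    ),
    IdentifierSource.EUDRACT: IdentifierSystemRow(
        SYSTEM_URI[IdentifierSource.EUDRACT],
        "https://www.clinicaltrialsregister.eu/ctr-search/search?query=eudract_number:{value}",
        "EudraCT",
    ),
    IdentifierSource.UTN: IdentifierSystemRow(
        SYSTEM_URI[IdentifierSource.UTN],
        None,  # no directly linkable URL exists for UTNs
        "UTN",
    ),
}

DEFAULT_TABLE = IdentifierSystemTable()


def related_link_for(
    identifier: TrialIdentifier, table: IdentifierSystemTable = DEFAULT_TABLE
) -> RelatedLink | None:
    """Registry web link for an identifier, or ``None`` if no URL exists."""
    url = table.related_url(identifier.source, identifier.value)
    if url is None:
        return None
    return RelatedLink(
        url=url, label=identifier.value, display=table.display_for(identifier.source)
    )


@dataclass
class ResourceSet:
    """One mapped study: the ResearchStudy plus its referenced resources."""

    research_study: dict
    locations: list[dict] = field(default_factory=list)
    group: dict | None = None

    def all_resources(self) -> list[dict]:
        out = [self.research_study, *self.locations]
        if self.group is not None:
            out.append(self.group)
        return out


def resource_id(*parts: str) -> str:
    """Deterministic FHIR resource id derived from stable keys."""
    joined = "/".join(parts)
    slug = re.sub(r"[^A-Za-z0-9]+", "-", joined).strip("-").lower()[:40]
    digest = hashlib.sha1(joined.encode("utf-8")).hexdigest()[:8]
    return f"{slug}-{digest}" if slug else digest


def location_id(site_id: str) -> str:
    return resource_id("loc", site_id)


# ---------------------------------------------------------------------------
# record -> FHIR


def to_research_study(
    record: StudyRecord | MasterStudy,
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> ResourceSet:
    """Map a study record (or merged master) to its FHIR resource set."""
    is_master = isinstance(record, MasterStudy)
    if not is_master:
        problems = validate_record(record)
        if problems:
            raise MappingError([f"invalid record: {problems[0]}"])

    if is_master:
        key = _sorted_identifiers(record.identifiers)[0]
        rid = resource_id("master", key.system, key.value)
    else:
        rid = resource_id("study", record.exporting_site, record.local_id)

    locations = [_make_location(site, cfg) for site in record.sites]
    group = _make_group(rid, record.eligibility)

    rs: dict = {"resourceType": "ResearchStudy", "id": rid}
    meta: dict = {"profile": [cfg.profile_canonical]}
    if is_master:
        meta["tag"] = [{"system": cfg.tag_system, "code": MASTER_TAG_CODE}]
    rs["meta"] = meta

    rs["identifier"] = [{"system": i.system, "value": i.value} for i in record.identifiers]
    rs["status"] = record.overall_status.value

    display_title = _preferred_text(record.titles)
    if display_title is not None:
        rs["title"] = display_title
    display_desc = _preferred_text(record.descriptions)
    if display_desc is not None:
        rs["description"] = display_desc

    extensions: list[dict] = []
    if record.acronym is not None:
        extensions.append({"url": cfg.extension_url_acronym, "valueString": record.acronym})
    for t in record.titles:
        extensions.append(_translation_ext(cfg.extension_url_title_translation, t))
    for t in record.descriptions:
        extensions.append(_translation_ext(cfg.extension_url_description_translation, t))
    for site in record.sites:
        ref = f"Location/{location_id(site.site_id)}"
        extensions.append(
            {
                "url": cfg.extension_url_site_status,
                "extension": [
                    {"url": "site", "valueReference": {"reference": ref}},
                    {"url": "status", "valueCode": site.recruitment_status.value},
                ],
            }
        )
        for contact in site.contacts:
            extensions.append(_site_contact_ext(cfg, ref, contact))
    if extensions:
        rs["extension"] = extensions

    if record.conditions:
        rs["condition"] = [_condition_cc(c) for c in record.conditions]

    contacts_flat = [c for site in record.sites for c in site.contacts]
    if contacts_flat:
        rs["contact"] = [_contact_detail(c) for c in contacts_flat]

    if record.sites:
        rs["site"] = [
            {
                "reference": f"Location/{location_id(site.site_id)}",
                "display": site.display_name,
            }
            for site in record.sites
        ]
    rs["enrollment"] = [{"reference": f"Group/{group['id']}"}]

    artifacts = []
    for i in record.identifiers:
        link = related_link_for(i, table)
        if link is not None:
            artifacts.append(_related_artifact(link))
    artifacts.extend(_related_artifact(link) for link in record.related_links)
    if artifacts:
        rs["relatedArtifact"] = artifacts

    if record.keywords:
        rs["keyword"] = [{"text": kw} for kw in record.keywords]

    if cfg.contained_resources:
        contained = [*locations, group]
        rs["contained"] = contained
        _internalize_references(rs)
        return ResourceSet(research_study=rs, locations=[], group=None)
    return ResourceSet(research_study=rs, locations=locations, group=group)


def _sorted_identifiers(identifiers: list[TrialIdentifier]) -> list[TrialIdentifier]:
    return sorted(
        identifiers,
        key=lambda i: (i.source is IdentifierSource.LOCAL, i.source.value, i.system, i.value),
    )


def _preferred_text(texts: list[LocalizedText]) -> str | None:
    by_lang = {t.language: t.text for t in texts}
    if Language.EN in by_lang:
        return by_lang[Language.EN]
    if Language.DE in by_lang:
        return by_lang[Language.DE]
    return None


def _translation_ext(url: str, t: LocalizedText) -> dict:
    return {
        "url": url,
        "extension": [
            {"url": "language", "valueCode": t.language.value},
            {"url": "content", "valueString": t.text},
        ],
    }


def _site_contact_ext(cfg: ProfileConfig, site_ref: str, contact: ContactPoint) -> dict:
    nested: list[dict] = [{"url": "site", "valueReference": {"reference": site_ref}}]
    if contact.name is not None:
        nested.append({"url": "name", "valueString": contact.name})
    for tel in contact.telecom:
        nested.append(
            {
                "url": "telecom",
                "valueContactPoint": {"system": tel.kind.value, "value": tel.value},
            }
        )
    if contact.query_role is not None:
        nested.append({"url": "role", "valueCode": contact.query_role.value})
    return {"url": cfg.extension_url_site_contact, "extension": nested}


def _condition_cc(c: ConditionCode) -> dict:
    system = _CONDITION_SYSTEM.get(c.code_system)
    if system is None:
        return {"text": c.code}
    return {"coding": [{"system": system, "code": c.code}]}


def _contact_detail(c: ContactPoint) -> dict:
    detail: dict = {}
    if c.name is not None:
        detail["name"] = c.name
    if c.telecom:
        detail["telecom"] = [
            {"system": t.kind.value, "value": t.value} for t in c.telecom
        ]
    return detail


def _related_artifact(link: RelatedLink) -> dict:
    artifact: dict = {"type": "documentation", "url": link.url}
    if link.label:
        artifact["label"] = link.label
    if link.display:
        artifact["display"] = link.display
    return artifact


def _make_location(site: SiteInfo, cfg: ProfileConfig) -> dict:
    return {
        "resourceType": "Location",
        "id": location_id(site.site_id),
        "identifier": [{"system": cfg.site_id_system, "value": site.site_id}],
        "name": site.display_name,
        "status": "active",
    }


def _make_group(rid: str, elig: EligibilityCriteria) -> dict:
    characteristics: list[dict] = [
        {
            "code": {"text": "gender"},
            "valueCodeableConcept": {
                "coding": [{"system": _GENDER_SYSTEM, "code": elig.gender.value}]
            },
            "exclude": False,
        }
    ]
    age_range: dict = {}
    if elig.min_age_years is not None:
        age_range["low"] = _age_quantity(elig.min_age_years)
    if elig.max_age_years is not None:
        age_range["high"] = _age_quantity(elig.max_age_years)
    if age_range:
        characteristics.append(
            {"code": {"text": "age"}, "valueRange": age_range, "exclude": False}
        )
    return {
        "resourceType": "Group",
        "id": f"{rid}-group",
        "type": "person",
        "actual": False,
        "characteristic": characteristics,
    }


def _age_quantity(years: float) -> dict:
    value = int(years) if float(years).is_integer() else years
    return {"value": value, "unit": "years", "system": "http://unitsofmeasure.org", "code": "a"}


def _internalize_references(rs: dict) -> None:
    """Rewrite references to contained resources as local ``#id`` references."""
    ids = {f"{res['resourceType']}/{res['id']}": f"#{res['id']}" for res in rs["contained"]}

    def rewrite(obj):
        if isinstance(obj, dict):
            ref = obj.get("reference")
            if isinstance(ref, str) and ref in ids:
                obj["reference"] = ids[ref]
            for v in obj.values():
                rewrite(v)
        elif isinstance(obj, list):
            for v in obj:
                rewrite(v)

    for key in ("site", "enrollment", "extension"):
        rewrite(rs.get(key))


# ---------------------------------------------------------------------------
# FHIR -> record


def build_ref_index(resources: Iterable[dict]) -> dict[str, dict]:
    index: dict[str, dict] = {}
    for res in resources:
        if "resourceType" in res and "id" in res:
            index[f"{res['resourceType']}/{res['id']}"] = res
    return index


def from_research_study(
    source: ResourceSet | dict,
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
    ref_index: Mapping[str, dict] | None = None,
) -> StudyRecord | MasterStudy:
    """Inverse mapping: rebuild a StudyRecord/MasterStudy from FHIR JSON.

    ``source`` is either a :class:`ResourceSet` or a bare ResearchStudy dict;
    referenced Location/Group resources are resolved through ``ref_index``
    (and through ``contained`` resources).
    """
    if isinstance(source, ResourceSet):
        rs = source.research_study
        index = dict(build_ref_index(source.all_resources()))
    else:
        rs = source
        index = dict(ref_index or {})
    for res in rs.get("contained", []):
        index[f"{res['resourceType']}/{res['id']}"] = res
        index[f"#{res['id']}"] = res
    if ref_index:
        index.update(ref_index)

    problems = []
    if rs.get("resourceType") != "ResearchStudy":
        problems.append("resourceType: expected ResearchStudy")
    if not rs.get("identifier"):
        problems.append("identifier: missing required element")
    if not rs.get("status"):
        problems.append("status: missing required element")
    if problems:
        raise MappingError(problems)

    identifiers = [
        TrialIdentifier(
            source=table.source_for_system(i.get("system", "")),
            system=i.get("system", ""),
            value=i.get("value", ""),
        )
        for i in rs["identifier"]
    ]
    status = RecruitmentStatus(rs["status"])

    acronym: str | None = None
    titles: list[LocalizedText] = []
    descriptions: list[LocalizedText] = []
    status_by_ref: dict[str, RecruitmentStatus] = {}
    contacts_by_ref: dict[str, list[ContactPoint]] = {}
    known_urls = {
        cfg.extension_url_acronym,
        cfg.extension_url_title_translation,
        cfg.extension_url_description_translation,
        cfg.extension_url_site_status,
        cfg.extension_url_site_contact,
    }
    for ext in rs.get("extension", []):
        url = ext.get("url")
        if url == cfg.extension_url_acronym:
            acronym = ext.get("valueString")
        elif url == cfg.extension_url_title_translation:
            titles.append(_parse_translation(ext))
        elif url == cfg.extension_url_description_translation:
            descriptions.append(_parse_translation(ext))
        elif url == cfg.extension_url_site_status:
            ref, code = _parse_site_status(ext)
            status_by_ref[ref] = RecruitmentStatus(code)
        elif url == cfg.extension_url_site_contact:
            ref, contact = _parse_site_contact(ext)
            contacts_by_ref.setdefault(ref, []).append(contact)
        elif url not in known_urls:
            logger.info("ignoring unknown extension %s", url)

    if not titles and "title" in rs:
        # untagged title from a non-profiled source; assume English
        titles.append(LocalizedText(language=Language.EN, text=rs["title"]))

    sites: list[SiteInfo] = []
    for site_entry in rs.get("site", []):
        ref = site_entry.get("reference", "")
        loc = index.get(ref, {})
        site_id = _site_id_from_location(loc, cfg) or ref.rpartition("/")[2]
        sites.append(
            SiteInfo(
                site_id=site_id,
                display_name=site_entry.get("display", loc.get("name", "")),
                recruitment_status=status_by_ref.get(ref, status),
                contacts=tuple(contacts_by_ref.get(ref, [])),
            )
        )

    eligibility = EligibilityCriteria()
    for enr in rs.get("enrollment", []):
        group = index.get(enr.get("reference", ""))
        if group is not None:
            eligibility = _parse_group(group)
            break

    conditions = [_parse_condition(c) for c in rs.get("condition", [])]

    auto = {
        _artifact_key(_related_artifact(link))
        for link in (related_link_for(i, table) for i in identifiers)
        if link is not None
    }
    related_links = [
        RelatedLink(url=a.get("url", ""), label=a.get("label", ""), display=a.get("display", ""))
        for a in rs.get("relatedArtifact", [])
        if _artifact_key(a) not in auto
    ]

    keywords = [k.get("text", "") for k in rs.get("keyword", [])]

    is_master = any(
        t.get("system") == cfg.tag_system and t.get("code") == MASTER_TAG_CODE
        for t in rs.get("meta", {}).get("tag", [])
    )

    common = dict(
        identifiers=identifiers,
        acronym=acronym,
        titles=titles,
        descriptions=descriptions,
        conditions=conditions,
        eligibility=eligibility,
        sites=sites,
        overall_status=status,
        related_links=related_links,
        keywords=keywords,
    )
    if is_master:
        member_refs = []
        for i in identifiers:
            if i.source is IdentifierSource.LOCAL:
                site = parse_local_system_uri(i.system, cfg.local_system_template)
                if site is not None:
                    member_refs.append((site, i.value))
        return MasterStudy(
            **common,
            member_refs=member_refs,
            master_tag=(cfg.tag_system, MASTER_TAG_CODE),
        )

    exporting_site, local_id = "", ""
    for i in identifiers:
        if i.source is IdentifierSource.LOCAL:
            site = parse_local_system_uri(i.system, cfg.local_system_template)
            if site is not None:
                exporting_site, local_id = site, i.value
                break
    return StudyRecord(**common, exporting_site=exporting_site, local_id=local_id)


def _parse_translation(ext: dict) -> LocalizedText:
    lang, text = "en", ""
    for nested in ext.get("extension", []):
        if nested.get("url") == "language":
            lang = nested.get("valueCode", "en")
        elif nested.get("url") == "content":
            text = nested.get("valueString", "")
    return LocalizedText(language=Language(lang), text=text)


def _parse_site_status(ext: dict) -> tuple[str, str]:
    ref, code = "", RecruitmentStatus.ACTIVE.value
    for nested in ext.get("extension", []):
        if nested.get("url") == "site":
            ref = nested.get("valueReference", {}).get("reference", "")
        elif nested.get("url") == "status":
            code = nested.get("valueCode", code)
    return ref, code


def _parse_site_contact(ext: dict) -> tuple[str, ContactPoint]:
    ref = ""
    name: str | None = None
    telecom: list[Telecom] = []
    role: QueryRole | None = None
    for nested in ext.get("extension", []):
        url = nested.get("url")
        if url == "site":
            ref = nested.get("valueReference", {}).get("reference", "")
        elif url == "name":
            name = nested.get("valueString")
        elif url == "telecom":
            cp = nested.get("valueContactPoint", {})
            telecom.append(
                Telecom(kind=TelecomKind(cp.get("system", "email")), value=cp.get("value", ""))
            )
        elif url == "role":
            role = QueryRole(nested.get("valueCode"))
    return ref, ContactPoint(name=name, telecom=tuple(telecom), query_role=role)


def _site_id_from_location(loc: dict, cfg: ProfileConfig) -> str | None:
    for ident in loc.get("identifier", []):
        if ident.get("system") == cfg.site_id_system:
            return ident.get("value")
    return None


def _parse_group(group: dict) -> EligibilityCriteria:
    gender = Gender.UNKNOWN
    min_age = max_age = None
    for ch in group.get("characteristic", []):
        label = ch.get("code", {}).get("text")
        if label == "gender":
            codings = ch.get("valueCodeableConcept", {}).get("coding", [])
            if codings:
                gender = Gender(codings[0].get("code", "unknown"))
        elif label == "age":
            rng = ch.get("valueRange", {})
            if "low" in rng:
                min_age = float(rng["low"]["value"])
            if "high" in rng:
                max_age = float(rng["high"]["value"])
    return EligibilityCriteria(gender=gender, min_age_years=min_age, max_age_years=max_age)


def _parse_condition(cc: dict) -> ConditionCode:
    for coding in cc.get("coding", []):
        system = coding.get("system", "")
        if system in _CONDITION_SYSTEM_INV:
            return ConditionCode(
                code=coding.get("code", ""), code_system=_CONDITION_SYSTEM_INV[system]
            )
    return ConditionCode(code=cc.get("text", ""), code_system=CodeSystem.FREE_TEXT)


def _artifact_key(a: dict) -> tuple[str, str, str]:
    return (a.get("url", ""), a.get("label", ""), a.get("display", ""))


# ---------------------------------------------------------------------------
# profile validation


_STATUS_CODES = {s.value for s in RecruitmentStatus}


def validate_profile(
    rs: dict,
    cfg: ProfileConfig = DEFAULT_PROFILE,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> list[str]:
    """Check a ResearchStudy JSON object against base + profile rules.

    Returns violation descriptions; empty list iff conformant.
    """
    violations: list[str] = []
    if rs.get("resourceType") != "ResearchStudy":
        violations.append("resourceType: must be 'ResearchStudy'")
        return violations

    status = rs.get("status")
    if status is None:
        violations.append("status: required element is missing")
    elif status not in _STATUS_CODES:
        violations.append(f"status: code {status!r} not in the ResearchStudy status value set")

    identifiers = rs.get("identifier")
    if not identifiers:
        violations.append("identifier: at least one identifier is required")
    else:
        for idx, ident in enumerate(identifiers):
            if not ident.get("system") or not ident.get("value"):
                violations.append(f"identifier[{idx}]: system and value are required")

    for idx, tag in enumerate(rs.get("meta", {}).get("tag", [])):
        if tag.get("system") == cfg.tag_system and tag.get("code") != MASTER_TAG_CODE:
            violations.append(
                f"meta.tag[{idx}]: code for system {cfg.tag_system!r} must be"
                f" '{MASTER_TAG_CODE}', got {tag.get('code')!r}"
            )

    for idx, ext in enumerate(rs.get("extension", [])):
        url = ext.get("url")
        if url == cfg.extension_url_acronym:
            if not isinstance(ext.get("valueString"), str):
                violations.append(f"extension[{idx}] (acronym): valueString is required")
        elif url == cfg.extension_url_site_status:
            nested = {n.get("url"): n for n in ext.get("extension", [])}
            if "site" not in nested or not nested["site"].get("valueReference", {}).get(
                "reference"
            ):
                violations.append(f"extension[{idx}] (site status): site reference is required")
            code = nested.get("status", {}).get("valueCode")
            if code not in _STATUS_CODES:
                violations.append(
                    f"extension[{idx}] (site status): code {code!r} not in the status value set"
                )
        elif url == cfg.extension_url_site_contact:
            nested = {n.get("url") for n in ext.get("extension", [])}
            if "site" not in nested:
                violations.append(f"extension[{idx}] (site contact): site reference is required")
            if not ({"name", "telecom"} & nested):
                violations.append(f"extension[{idx}] (site contact): name or telecom is required")
        elif url in (
            cfg.extension_url_title_translation,
            cfg.extension_url_description_translation,
        ):
            nested = {n.get("url"): n for n in ext.get("extension", [])}
            lang = nested.get("language", {}).get("valueCode")
            if lang not in {lang_.value for lang_ in Language}:
                violations.append(
                    f"extension[{idx}] (translation): language {lang!r} is not supported"
                )
        else:
            logger.info("profile check: ignoring unknown extension %s", url)

    for idx, artifact in enumerate(rs.get("relatedArtifact", [])):
        if not artifact.get("url"):
            violations.append(f"relatedArtifact[{idx}]: url is required")
        if not artifact.get("type"):
            violations.append(f"relatedArtifact[{idx}]: type is required")

    return violations
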