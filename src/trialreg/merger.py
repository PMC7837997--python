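"""Multisite study merging via an identifier-sharing graph.

Each site exports its own record for a study it participates in, so a
multicentric study appears once per site.  Records referring to the same study
are found by treating shared primary registry identifiers (NCT, DRKS, EudraCT
by default) as links: records are vertices, a shared normalized primary
identifier is an edge, and each connected component — found by breadth-first
search — is one distinct study.  Every component is merged into a single
tagged "master" record; a merge plan of conditional creates/updates/deletes
reconciles the new masters with a previously materialized master set.

Identifier values arrive with real-world dirt (trailing whitespace, lowercase
registry prefixes) that would silently break the linkage, so everything is
normalized before graph construction.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
from pydantic import BaseModel, Field

from .core_model import (
    PRIMARY_SOURCES,
    STATUS_PRECEDENCE,
    Cluster,
    IdentifierSource,
    MasterStudy,
    RecruitmentStatus,
    StudyRecord,
    TrialIdentifier,
)
from .fhir_mapping import DEFAULT_TABLE, IdentifierSystemTable

RecordRef = tuple[str, str]


class NormalizationError(ValueError):
    pass


def normalize_identifier(
    raw_system: str,
    raw_value: str,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> TrialIdentifier:
    """Canonicalize a raw (system, value) identifier pair.

    Strips surrounding whitespace, removes internal whitespace from the value,
    uppercases NCT/DRKS values (their registry prefixes are case-insensitive
    in the wild), and infers the source registry from the system URI; unknown
    systems are site-local.
    """
    system = raw_system.strip()
    value = "".join(raw_value.split())
    if not value:
        raise NormalizationError(f"identifier value {raw_value!r} is empty after trimming")
    source = table.source_for_system(system)
    if source in (IdentifierSource.NCT, IdentifierSource.DRKS):
        value = value.upper()
    if source is not IdentifierSource.LOCAL:
        system = table.system_for(source)
    return TrialIdentifier(source=source, system=system, value=value)


def normalize_record_identifiers(
    record: StudyRecord, table: IdentifierSystemTable = DEFAULT_TABLE
) -> list[TrialIdentifier]:
    return [normalize_identifier(i.system, i.value, table) for i in record.identifiers]


class IdentifierGraph:
    """Undirected graph of records linked by shared primary identifiers."""

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.records: dict[RecordRef, StudyRecord] = {}

    def vertices(self) -> list[RecordRef]:
        return sorted(self.graph.nodes)

    def edges(self) -> set[frozenset[RecordRef]]:
        return {frozenset(e) for e in self.graph.edges}

    def shared_identifiers(self, u: RecordRef, v: RecordRef) -> set[TrialIdentifier]:
        return self.graph.edges[u, v]["identifiers"]


def build_identifier_graph(
    records: list[StudyRecord],
    primary_sources: frozenset[IdentifierSource] = PRIMARY_SOURCES,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> IdentifierGraph:
    """Vertices are records; an edge joins two records sharing ≥1 normalized
    primary identifier.  Records without primary identifiers stay isolated."""
    ig = IdentifierGraph()
    by_identifier: dict[tuple[str, str], list[RecordRef]] = {}
    for record in records:
        ref = record.ref()
        if ref in ig.records:
            raise ValueError(f"duplicate record key {ref!r}")
        ig.records[ref] = record
        ig.graph.add_node(ref)
        for ident in normalize_record_identifiers(record, table):
            if ident.source in primary_sources:
                by_identifier.setdefault(ident.key(), []).append(ref)

    for key, refs in by_identifier.items():
        ident = TrialIdentifier(
            source=DEFAULT_TABLE.source_for_system(key[0]), system=key[0], value=key[1]
        )
        for i, u in enumerate(refs):
            for v in refs[i + 1 :]:
                if u == v:
                    continue  # a record listing the same identifier twice
                if ig.graph.has_edge(u, v):
                    ig.graph.edges[u, v]["identifiers"].add(ident)
                else:
                    ig.graph.add_edge(u, v, identifiers={ident})
    return ig


def connected_components(
    graph: IdentifierGraph,
    primary_sources: frozenset[IdentifierSource] = PRIMARY_SOURCES,
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> list[Cluster]:
    """Partition the graph into clusters by breadth-first search.

    Output is deterministic: BFS starts from vertices in sorted order, members
    are sorted by (exporting_site, local_id), and clusters are sorted by their
    smallest member key.
    """
    visited: set[RecordRef] = set()
    clusters: list[Cluster] = []
    for start in sorted(graph.graph.nodes):
        if start in visited:
            continue
        component: list[RecordRef] = []
        queue: deque[RecordRef] = deque([start])
        visited.add(start)
        while queue:
            node = queue.popleft()
            component.append(node)
            for neighbor in sorted(graph.graph.neighbors(node)):
                if neighbor not in visited:
                    visited.add(neighbor)
                    queue.append(neighbor)
        members = [graph.records[ref] for ref in sorted(component)]
        shared = {
            ident
            for m in members
            for ident in normalize_record_identifiers(m, table)
            if ident.source in primary_sources
        }
        clusters.append(Cluster(members=members, shared_primary_identifiers=shared))
    clusters.sort(key=lambda c: c.members[0].ref())
    return clusters


def _identifier_sort_key(i: TrialIdentifier) -> tuple:
    return (i.source is IdentifierSource.LOCAL, i.source.value, i.system, i.value)


def _merge_status(statuses: list[RecruitmentStatus]) -> RecruitmentStatus:
    for status in STATUS_PRECEDENCE:
        if status in statuses:
            return status
    return statuses[0]


def merge_cluster(
    cluster: Cluster,
    tag_system: str = MasterStudy.model_fields["master_tag"].default[0],
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> MasterStudy:
    """Merge one cluster into a master study.

    Identifiers (including the members' site-local ones), keywords and
    conditions become deduplicated unions; the per-site lists are concatenated
    (unique by site_id, first occurrence wins); scalar fields are taken from
    the first member — in the deterministic member order — where they are set.
    """
    if not cluster.members:
        raise ValueError("cannot merge an empty cluster")
    members = sorted(cluster.members, key=lambda m: m.ref())

    identifiers: list[TrialIdentifier] = []
    seen_ids: set[tuple[str, str]] = set()
    for m in members:
        for ident in normalize_record_identifiers(m, table):
            if ident.key() not in seen_ids:
                seen_ids.add(ident.key())
                identifiers.append(ident)
    identifiers.sort(key=_identifier_sort_key)

    keywords: list[str] = []
    for m in members:
        for kw in m.keywords:
            if kw not in keywords:
                keywords.append(kw)
    conditions = []
    for m in members:
        for cond in m.conditions:
            if cond not in conditions:
                conditions.append(cond)

    sites = []
    seen_sites: set[str] = set()
    for m in members:
        for site in m.sites:
            if site.site_id not in seen_sites:
                seen_sites.add(site.site_id)
                sites.append(site)

    def first_title(texts_of, language):
        for m in members:
            for t in texts_of(m):
                if t.language == language and t.text:
                    return t
        return None

    titles = [
        t
        for lang in ("de", "en")
        if (t := first_title(lambda m: m.titles, lang)) is not None
    ]
    descriptions = [
        t
        for lang in ("de", "en")
        if (t := first_title(lambda m: m.descriptions, lang)) is not None
    ]
    acronym = next((m.acronym for m in members if m.acronym is not None), None)
    eligibility = members[0].eligibility
    related_links = []
    for m in members:
        for link in m.related_links:
            if link not in related_links:
                related_links.append(link)

    return MasterStudy(
        identifiers=identifiers,
        acronym=acronym,
        titles=titles,
        descriptions=descriptions,
        conditions=conditions,
        eligibility=eligibility,
        sites=sites,
        overall_status=_merge_status([s.recruitment_status for s in sites]),
        related_links=related_links,
        keywords=keywords,
        member_refs=[m.ref() for m in members],
        master_tag=(tag_system, "master"),
    )


class ConditionalKey(BaseModel):
    """Search criteria that uniquely select one master on the target store:
    the master tag plus any one of the master's identifiers."""

    tag_system: str
    tag_code: str = "master"
    identifier_system: str
    identifier_value: str


class PlanEntry(BaseModel):
    conditional: ConditionalKey
    master: MasterStudy


class DeleteEntry(BaseModel):
    conditional: ConditionalKey
    member_refs: list[tuple[str, str]] = Field(default_factory=list)


class MergePlan(BaseModel):
    creates: list[PlanEntry] = Field(default_factory=list)
    updates: list[PlanEntry] = Field(default_factory=list)
    deletes: list[DeleteEntry] = Field(default_factory=list)


def _conditional_for(master: MasterStudy, identifier: TrialIdentifier) -> ConditionalKey:
    return ConditionalKey(
        tag_system=master.master_tag[0],
        tag_code=master.master_tag[1],
        identifier_system=identifier.system,
        identifier_value=identifier.value,
    )


def merge_all(
    records: list[StudyRecord],
    existing_masters: list[MasterStudy] | None = None,
    primary_sources: frozenset[IdentifierSource] = PRIMARY_SOURCES,
    tag_system: str = MasterStudy.model_fields["master_tag"].default[0],
    table: IdentifierSystemTable = DEFAULT_TABLE,
) -> tuple[list[MasterStudy], MergePlan]:
    """Full merge pass: recompute all masters and diff against existing ones.

    Every connected component yields one master (singleton components
    included).  A master sharing any identifier with an existing master is an
    update, conditioned on that shared identifier; otherwise it is a create,
    conditioned on its first identifier.  Existing masters matching no new
    master are scheduled for deletion; so are surplus existing masters when
    previously separate clusters coalesce.
    """
    existing_masters = existing_masters or []
    graph = build_identifier_graph(records, primary_sources, table)
    clusters = connected_components(graph, primary_sources, table)
    masters = [merge_cluster(c, tag_system, table) for c in clusters]

    existing_by_key: dict[tuple[str, str], int] = {}
    for idx, em in enumerate(existing_masters):
        for ident in em.identifiers:
            existing_by_key.setdefault(ident.key(), idx)

    plan = MergePlan()
    matched_existing: set[int] = set()
    for master in masters:
        hits: list[tuple[int, TrialIdentifier]] = []
        seen_idx: set[int] = set()
        for ident in master.identifiers:
            idx = existing_by_key.get(ident.key())
            if idx is not None and idx not in seen_idx:
                seen_idx.add(idx)
                hits.append((idx, ident))
        if hits:
            hits.sort(key=lambda h: h[0])
            first_idx, shared_ident = hits[0]
            matched_existing.update(idx for idx, _ in hits)
            plan.updates.append(
                PlanEntry(conditional=_conditional_for(master, shared_ident), master=master)
            )
            # clusters that coalesced: keep one master, drop the others
            for idx, _ in hits[1:]:
                stale = existing_masters[idx]
                plan.deletes.append(
                    DeleteEntry(
                        conditional=_conditional_for(stale, stale.identifiers[0]),
                        member_refs=stale.member_refs,
                    )
                )
        else:
            plan.creates.append(
                PlanEntry(conditional=_conditional_for(master, master.identifiers[0]), master=master)
            )

    for idx, em in enumerate(existing_masters):
        if idx not in matched_existing:
            plan.deletes.append(
                DeleteEntry(
                    conditional=_conditional_for(em, em.identifiers[0]),
                    member_refs=em.member_refs,
                )
            )
    return masters, plan
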