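import random

import pytest

from trialreg.core_model import IdentifierSource, PRIMARY_SOURCES
from trialreg.io import canonical_dumps
from trialreg.merger import (
    NormalizationError,
    build_identifier_graph,
    connected_components,
    merge_all,
    merge_cluster,
    normalize_identifier,
)

from conftest import make_identifier, make_record

NCT, DRKS, EUD = IdentifierSource.NCT, IdentifierSource.DRKS, IdentifierSource.EUDRACT


class UnionFind:
    """Independent oracle for the connected-components partition."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)

    def partition(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in groups.values()}


def union_find_partition(records, primary_sources=PRIMARY_SOURCES):
    uf = UnionFind([r.ref() for r in records])
    by_identifier = {}
    for r in records:
        for i in r.identifiers:
            norm = normalize_identifier(i.system, i.value)
            if norm.source in primary_sources:
                by_identifier.setdefault(norm.key(), []).append(r.ref())
    for refs in by_identifier.values():
        for other in refs[1:]:
            uf.union(refs[0], other)
    return uf.partition()


def random_records(rng, n_vertices, n_identifiers):
    """Records with identifier subsets drawn at random (collisions intended)."""
    records = []
    for v in range(n_vertices):
        k = rng.randint(0, 3)
        primaries = [
            (NCT, f"NCT{rng.randrange(n_identifiers):08d}") for _ in range(k)
        ]
        records.append(make_record(f"site-{v % 7}", f"rec-{v:04d}", primaries))
    return records


class TestNormalizeIdentifier:
    def test_trims_whitespace_and_keeps_value(self):
        ident = normalize_identifier("http://clinicaltrials.gov", " NCT03521531 ")
        assert ident.source is NCT
        assert ident.value == "NCT03521531"

    def test_uppercases_registry_prefixes(self):
        assert normalize_identifier("http://www.drks.de", "drks00000164").value == "DRKS00000164"
        assert normalize_identifier("http://clinicaltrials.gov", "nct1").value == "NCT1"

    def test_unknown_system_is_local_and_value_unchanged(self):
        ident = normalize_identifier(
            "https://fhir.uk-erlangen.de/studienregister/NamingSystem/id", "rvnoqjmezlew"
        )
        assert ident.source is IdentifierSource.LOCAL
        assert ident.value == "rvnoqjmezlew"

    def test_internal_whitespace_removed(self):
        assert normalize_identifier("http://www.drks.de", "DRKS 0000 0164").value == "DRKS00000164"

    def test_empty_after_trim_is_an_error(self):
        with pytest.raises(NormalizationError):
            normalize_identifier("http://www.drks.de", "   ")


class TestIdentifierGraph:
    def test_two_multicentric_studies_example(self, fig4_records):
        graph = build_identifier_graph(fig4_records)
        refs = {r.local_id: r.ref() for r in fig4_records}
        expected = {
            frozenset({refs["rec-a"], refs["rec-b"]}),
            frozenset({refs["rec-b"], refs["rec-c"]}),
            frozenset({refs["rec-c"], refs["rec-d"]}),
            frozenset({refs["rec-e"], refs["rec-f"]}),
        }
        assert graph.edges() == expected

    def test_empty_input_yields_empty_graph(self):
        graph = build_identifier_graph([])
        assert graph.vertices() == [] and graph.edges() == set()

    def test_shared_local_identifier_creates_no_edge(self):
        shared_local = make_identifier(IdentifierSource.LOCAL, "same-value", "site-x")
        a = make_record("site-a", "a")
        b = make_record("site-b", "b")
        a.identifiers.append(shared_local)
        b.identifiers.append(shared_local)
        assert build_identifier_graph([a, b]).edges() == set()

    def test_dirty_identifiers_still_link(self):
        a = make_record("site-a", "a", [(NCT, "NCT00000001 ")])
        b = make_record("site-b", "b", [(NCT, "nct00000001")])
        assert len(build_identifier_graph([a, b]).edges()) == 1


class TestConnectedComponents:
    def test_fig_two_clusters(self, fig4_records):
        clusters = connected_components(build_identifier_graph(fig4_records))
        member_sets = [frozenset(c.member_refs()) for c in clusters]
        assert member_sets == [
            frozenset({("site-a", "rec-a"), ("site-b", "rec-b"),
                       ("site-c", "rec-c"), ("site-d", "rec-d")}),
            frozenset({("site-e", "rec-e"), ("site-f", "rec-f")}),
        ]

    def test_isolated_vertices_become_singletons(self):
        records = [make_record(f"site-{i}", f"r{i}") for i in range(5)]
        clusters = connected_components(build_identifier_graph(records))
        assert [len(c.members) for c in clusters] == [1] * 5

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = random.Random(2024)
        for _ in range(200):
            records = random_records(rng, rng.randint(0, 60), rng.randint(1, 25))
            clusters = connected_components(build_identifier_graph(records))
            got = {frozenset(c.member_refs()) for c in clusters}
            assert got == union_find_partition(records)

    def test_output_order_is_deterministic(self, fig4_records):
        shuffled = list(reversed(fig4_records))
        a = connected_components(build_identifier_graph(fig4_records))
        b = connected_components(build_identifier_graph(shuffled))
        assert [c.member_refs() for c in a] == [c.member_refs() for c in b]


class TestMergeCluster:
    def test_identifier_union_over_members(self, fig4_records):
        clusters = connected_components(build_identifier_graph(fig4_records))
        master = merge_cluster(clusters[0])
        non_local = {(i.source, i.value) for i in master.identifiers
                     if i.source is not IdentifierSource.LOCAL}
        assert non_local == {
            (NCT, "NCT00000001"), (DRKS, "DRKS00000002"), (EUD, "2020-000003-03"),
        }
        locals_ = [i for i in master.identifiers if i.source is IdentifierSource.LOCAL]
        assert len(locals_) == 4  # every member keeps its site-local id

    def test_singleton_master_mirrors_its_member(self):
        record = make_record("site-a", "solo", [(NCT, "NCT00000009")])
        clusters = connected_components(build_identifier_graph([record]))
        master = merge_cluster(clusters[0])
        assert master.member_refs == [record.ref()]
        assert master.acronym == record.acronym
        assert master.titles == record.titles
        assert master.sites == record.sites
        assert {i.key() for i in master.identifiers} == {i.key() for i in record.identifiers}

    def test_scalar_fields_first_available_policy(self):
        first = make_record("site-a", "a", [(NCT, "NCT00000001")], acronym=None)
        second = make_record("site-b", "b", [(NCT, "NCT00000001")], acronym="BLINA")
        clusters = connected_components(build_identifier_graph([first, second]))
        assert merge_cluster(clusters[0]).acronym == "BLINA"

    def test_empty_cluster_is_an_error(self, fig4_records):
        cluster = connected_components(build_identifier_graph(fig4_records))[0]
        cluster.members = []
        with pytest.raises(ValueError):
            merge_cluster(cluster)


class TestMergeAll:
    def test_fresh_run_creates_all_masters(self, fig4_records):
        masters, plan = merge_all(fig4_records)
        assert len(masters) == 2
        assert len(plan.creates) == 2 and not plan.updates and not plan.deletes

    def test_rerun_is_idempotent_updates(self, fig4_records):
        masters, _ = merge_all(fig4_records)
        masters2, plan = merge_all(fig4_records, existing_masters=masters)
        assert masters2 == masters
        assert len(plan.updates) == 2 and not plan.creates and not plan.deletes

    def test_removed_records_schedule_deletes(self, fig4_records):
        masters, _ = merge_all(fig4_records)
        reduced = fig4_records[:4]  # drop the second study's two records
        _, plan = merge_all(reduced, existing_masters=masters)
        assert len(plan.updates) == 1
        assert len(plan.deletes) == 1
        assert not plan.creates

    def test_identifier_conservation(self, small_corpus):
        _, records, _ = small_corpus
        masters, _ = merge_all(records)
        input_ids = {
            norm.key()
            for r in records
            for i in r.identifiers
            if (norm := normalize_identifier(i.system, i.value)).source in PRIMARY_SOURCES
        }
        master_ids = [
            i.key() for m in masters for i in m.identifiers
            if i.source is not IdentifierSource.LOCAL
        ]
        assert set(master_ids) == input_ids
        assert len(master_ids) == len(set(master_ids)), "identifier appears in two masters"

    def test_component_count_change_is_one_minus_c(self):
        """A new record linking c clusters changes the count by 1 - c."""
        base = [
            make_record("site-a", "a", [(NCT, "NCT00000001")]),
            make_record("site-b", "b", [(DRKS, "DRKS00000002")]),
            make_record("site-c", "c", [(EUD, "2020-000003-03")]),
        ]
        for c, primaries in [
            (0, []),
            (1, [(NCT, "NCT00000001")]),
            (2, [(NCT, "NCT00000001"), (DRKS, "DRKS00000002")]),
            (3, [(NCT, "NCT00000001"), (DRKS, "DRKS00000002"), (EUD, "2020-000003-03")]),
        ]:
            before = len(connected_components(build_identifier_graph(base)))
            extended = base + [make_record("site-x", "x", primaries)]
            after = len(connected_components(build_identifier_graph(extended)))
            assert after - before == 1 - c

    def test_masters_serialize_byte_identically_across_runs(self, small_corpus):
        _, records, _ = small_corpus
        masters_a, _ = merge_all(records)
        masters_b, _ = merge_all(list(reversed(records)))
        dump = lambda ms: [canonical_dumps(m.model_dump(mode="json")) for m in ms]
        assert dump(masters_a) == dump(masters_b)
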