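import pytest

from trialreg.core_model import IdentifierSource, MasterStudy
from trialreg.fhir_mapping import (
    DEFAULT_TABLE,
    MappingError,
    ProfileConfig,
    from_research_study,
    related_link_for,
    to_research_study,
    validate_profile,
)
from trialreg.merger import merge_all

from conftest import make_identifier, make_record

CFG = ProfileConfig()


class TestRelatedLinks:
    """Registry-number to relatedArtifact web-address mapping."""

    @pytest.mark.parametrize(
        "source, value, url, display",
        [
            (
                IdentifierSource.NCT,
                "NCT03521531",
                "https://clinicaltrials.gov/ct2/show/NCT03521531",
                "ClinicalTrials.gov",
            ),
            (
                IdentifierSource.DRKS,
                "DRKS00000164",
                "https://www.drks.de/drks_web/navigate.do?navigationId=trial.HTML&TRIAL_ID=DRKS00000164",
                "DRKS",
            ),
            (
                IdentifierSource.EUDRACT,
                "2012-000620-17",
                "https://www.clinicaltrialsregister.eu/ctr-search/search?query=eudract_number:2012-000620-17",
                "EudraCT",
            ),
        ],
    )
    def test_registry_links(self, source, value, url, display):
        link = related_link_for(make_identifier(source, value))
        assert link is not None
        assert link.url == url
        assert link.label == value
        assert link.display == display

    def test_utn_has_no_linkable_url(self):
        assert related_link_for(make_identifier(IdentifierSource.UTN, "U1111-1220-2928")) is None

    def test_source_system_mapping_is_bijective(self):
        sources = [s for s in IdentifierSource if s is not IdentifierSource.LOCAL]
        systems = {DEFAULT_TABLE.system_for(s) for s in sources}
        assert len(systems) == len(sources)
        for s in sources:
            assert DEFAULT_TABLE.source_for_system(DEFAULT_TABLE.system_for(s)) is s
        assert DEFAULT_TABLE.source_for_system("https://unknown.example") is IdentifierSource.LOCAL


class TestToResearchStudy:
    def test_nct_identifier_and_related_artifact(self):
        record = make_record(
            "site-a", "abc", [(IdentifierSource.NCT, "NCT03521531")], related_links=[]
        )
        rs = to_research_study(record, CFG).research_study
        assert {"system": "http://clinicaltrials.gov", "value": "NCT03521531"} in rs["identifier"]
        urls = [a["url"] for a in rs["relatedArtifact"]]
        assert "https://clinicaltrials.gov/ct2/show/NCT03521531" in urls

    def test_utn_identifier_emitted_without_artifact(self):
        record = make_record(
            "site-a", "abc", [(IdentifierSource.UTN, "U1111-1220-2928")], related_links=[]
        )
        rs = to_research_study(record, CFG).research_study
        assert {"system": DEFAULT_TABLE.system_for(IdentifierSource.UTN),
                "value": "U1111-1220-2928"} in rs["identifier"]
        assert "relatedArtifact" not in rs

    def test_core_elements_land_in_their_targets(self):
        record = make_record("site-a", "abc", [(IdentifierSource.NCT, "NCT00000001")])
        rset = to_research_study(record, CFG)
        rs = rset.research_study
        assert rs["status"] == "active"
        assert rs["title"] == "Trial of Consolidation Therapy"  # English preferred
        assert rs["condition"][0]["coding"][0]["code"] == "C91.0"
        assert rs["keyword"] == [{"text": "leukemia"}, {"text": "consolidation"}]
        assert len(rset.locations) == 1 and rset.locations[0]["resourceType"] == "Location"
        assert rset.group["resourceType"] == "Group"
        assert rs["site"][0]["reference"] == f"Location/{rset.locations[0]['id']}"
        assert rs["enrollment"][0]["reference"] == f"Group/{rset.group['id']}"
        ext_urls = {e["url"] for e in rs["extension"]}
        assert CFG.extension_url_acronym in ext_urls
        assert CFG.extension_url_site_status in ext_urls
        assert CFG.extension_url_site_contact in ext_urls

    def test_invalid_record_raises_naming_first_violation(self):
        record = make_record("site-a", "abc")
        record.identifiers = []
        with pytest.raises(MappingError, match="identifier"):
            to_research_study(record, CFG)

    def test_master_carries_master_tag(self, fig4_records):
        masters, _ = merge_all(fig4_records)
        rs = to_research_study(masters[0], CFG).research_study
        assert {"system": CFG.tag_system, "code": "master"} in rs["meta"]["tag"]

    def test_contained_mode_inlines_references(self):
        record = make_record("site-a", "abc", [(IdentifierSource.NCT, "NCT00000001")])
        cfg = ProfileConfig(contained_resources=True)
        rset = to_research_study(record, cfg)
        assert rset.locations == [] and rset.group is None
        rs = rset.research_study
        assert {r["resourceType"] for r in rs["contained"]} == {"Location", "Group"}
        assert rs["site"][0]["reference"].startswith("#")
        back = from_research_study(rset, cfg)
        assert back == record


class TestFromResearchStudy:
    def test_drks_system_infers_source(self):
        record = make_record("site-a", "abc", [(IdentifierSource.DRKS, "DRKS00000164")])
        back = from_research_study(to_research_study(record, CFG), CFG)
        drks = [i for i in back.identifiers if i.source is IdentifierSource.DRKS]
        assert drks and drks[0].value == "DRKS00000164"

    def test_master_tag_yields_master_study(self, fig4_records):
        masters, _ = merge_all(fig4_records)
        back = from_research_study(to_research_study(masters[0], CFG), CFG)
        assert isinstance(back, MasterStudy)
        assert back.member_refs == masters[0].member_refs

    def test_missing_required_elements_listed(self):
        with pytest.raises(MappingError) as exc:
            from_research_study({"resourceType": "ResearchStudy"}, CFG)
        assert "identifier" in str(exc.value) and "status" in str(exc.value)

    def test_round_trip_identity_on_generated_corpus(self, small_corpus):
        _, records, _ = small_corpus
        for record in records:
            assert from_research_study(to_research_study(record, CFG), CFG) == record

    def test_master_round_trip_identity(self, small_corpus):
        _, records, _ = small_corpus
        masters, _ = merge_all(records)
        for master in masters:
            assert from_research_study(to_research_study(master, CFG), CFG) == master


class TestValidateProfile:
    def _conformant(self):
        record = make_record("site-a", "abc", [(IdentifierSource.NCT, "NCT00000001")])
        return to_research_study(record, CFG).research_study

    def test_conformant_resource_has_no_violations(self):
        assert validate_profile(self._conformant(), CFG) == []

    def test_mapping_output_always_conformant(self, small_corpus):
        _, records, _ = small_corpus
        for record in records[:20]:
            rs = to_research_study(record, CFG).research_study
            assert validate_profile(rs, CFG) == []

    def test_site_status_outside_value_set_is_flagged(self):
        rs = self._conformant()
        for ext in rs["extension"]:
            if ext["url"] == CFG.extension_url_site_status:
                for nested in ext["extension"]:
                    if nested["url"] == "status":
                        nested["valueCode"] = "recruiting-hard"
        violations = validate_profile(rs, CFG)
        assert len(violations) == 1 and "recruiting-hard" in violations[0]

    def test_missing_status_is_flagged(self):
        rs = self._conformant()
        del rs["status"]
        violations = validate_profile(rs, CFG)
        assert len(violations) == 1 and "status" in violations[0]

    def test_wrong_master_tag_code_is_flagged(self):
        rs = self._conformant()
        rs["meta"]["tag"] = [{"system": CFG.tag_system, "code": "primary"}]
        assert any("master" in v for v in validate_profile(rs, CFG))
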