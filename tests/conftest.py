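import pytest

from trialreg.core_model import (
    SYSTEM_URI,
    ConditionCode,
    CodeSystem,
    ContactPoint,
    EligibilityCriteria,
    Gender,
    IdentifierSource,
    Language,
    LocalizedText,
    RecruitmentStatus,
    RelatedLink,
    SiteInfo,
    StudyRecord,
    Telecom,
    TelecomKind,
    TrialIdentifier,
    local_system_uri,
)
from trialreg.synthetic import SimConfig, generate


def make_identifier(source: IdentifierSource, value: str, site: str = "") -> TrialIdentifier:
    if source is IdentifierSource.LOCAL:
        return TrialIdentifier(source=source, system=local_system_uri(site), value=value)
    return TrialIdentifier(source=source, system=SYSTEM_URI[source], value=value)


def make_record(site: str, local_id: str, primaries=(), **overrides) -> StudyRecord:
    """A fully populated, valid single-site study record."""
    identifiers = [make_identifier(src, value) for src, value in primaries]
    identifiers.append(make_identifier(IdentifierSource.LOCAL, local_id, site))
    fields = dict(
        identifiers=identifiers,
        acronym="BLINA",
        titles=[
            LocalizedText(language=Language.DE, text="Studie zur Konsolidierungstherapie"),
            LocalizedText(language=Language.EN, text="Trial of Consolidation Therapy"),
        ],
        descriptions=[
            LocalizedText(language=Language.DE, text="Eine multizentrische Studie."),
            LocalizedText(language=Language.EN, text="A multicentric study."),
        ],
        conditions=[ConditionCode(code="C91.0", code_system=CodeSystem.ICD10GM)],
        eligibility=EligibilityCriteria(gender=Gender.ALL, min_age_years=18, max_age_years=65),
        sites=[
            SiteInfo(
                site_id=site,
                display_name=f"University Hospital {site}",
                recruitment_status=RecruitmentStatus.ACTIVE,
                contacts=(
                    ContactPoint(
                        name="Dr. A. Example",
                        telecom=(Telecom(kind=TelecomKind.EMAIL, value=f"office@{site}"),),
                    ),
                ),
            )
        ],
        overall_status=RecruitmentStatus.ACTIVE,
        related_links=[
            RelatedLink(
                url="https://registry.example.org/studies/demo",
                label="demo",
                display="Consortium registry",
            )
        ],
        keywords=["leukemia", "consolidation"],
        exporting_site=site,
        local_id=local_id,
    )
    fields.update(overrides)
    return StudyRecord(**fields)


@pytest.fixture
def fig4_records() -> list[StudyRecord]:
    """Six records forming two multicentric studies.

    A-D are linked through NCT:1, DRKS:2, EudraCT:3 (no single record carries
    all three identifiers); E-F share NCT:4 and DRKS:5.
    """
    nct, drks, eud = IdentifierSource.NCT, IdentifierSource.DRKS, IdentifierSource.EUDRACT
    return [
        make_record("site-a", "rec-a", [(nct, "NCT00000001")]),
        make_record("site-b", "rec-b", [(nct, "NCT00000001"), (drks, "DRKS00000002")]),
        make_record("site-c", "rec-c", [(drks, "DRKS00000002"), (eud, "2020-000003-03")]),
        make_record("site-d", "rec-d", [(eud, "2020-000003-03")]),
        make_record("site-e", "rec-e", [(nct, "NCT00000004"), (drks, "DRKS00000005")]),
        make_record("site-f", "rec-f", [(drks, "DRKS00000005")]),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A modest synthetic corpus shared across tests (deterministic seed)."""
    config = SimConfig(n_sites=5, n_studies=60, seed=11)
    records, truth = generate(config)
    return config, records, truth
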