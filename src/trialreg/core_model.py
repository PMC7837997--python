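"""Core data model for site-local clinical-study records.

A multisite trial registry collects study metadata exported independently by
each participating hospital.  The common denominator across the heterogeneous
site registries is an 11-element core data set: identifiers, acronym, contact
details, participating sites, title, description, studied conditions,
demographic eligibility (gender and age), recruitment status, further-
information URLs, and keywords.  The types below model those elements plus
export provenance (which site exported the record, under which local id).

Invariants that go beyond plain typing (identifier normalization, eligibility
ordering, presence of a site-local identifier, ...) are *not* enforced at
construction time; they are reported by :func:`validate_record` so that
malformed exports can be inspected rather than rejected at parse time.
"""

from __future__ import annotations

import enum
from urllib.parse import urlparse

from pydantic import BaseModel, ConfigDict, Field


class IdentifierSource(str, enum.Enum):
    """Registry that assigned a trial identifier."""

    NCT = "NCT"          # ClinicalTrials.gov
    DRKS = "DRKS"        # German Clinical Trials Register
    EUDRACT = "EUDRACT"  # EU Drug Regulating Authorities CT Database
    UTN = "UTN"          # WHO Universal Trial Number
    LOCAL = "LOCAL"      # site-specific registry id


#: Identifier sources used for multicentric-study merging by default.  The UTN
#: is a recognized identifier system but is not used as a merge key unless
#: explicitly enabled.
PRIMARY_SOURCES: frozenset[IdentifierSource] = frozenset(
    {IdentifierSource.NCT, IdentifierSource.DRKS, IdentifierSource.EUDRACT}
)

#: Canonical identifier system URIs for the non-local registries.
SYSTEM_URI: dict[IdentifierSource, str] = {
    IdentifierSource.NCT: "http://clinicaltrials.gov",
    IdentifierSource.DRKS: "http://www.drks.de",
    IdentifierSource.EUDRACT: "http://www.clinicaltrialsregister.eu",
    IdentifierSource.UTN: "http://www.who.int/ictrp/unambiguous_identification/utn",
}

#: Per-site system URI template for LOCAL identifiers; ``{site}`` is replaced
#: by the exporting site's stable key.
DEFAULT_LOCAL_SYSTEM_TEMPLATE = "https://fhir.{site}/studienregister/NamingSystem/id"


def local_system_uri(site_id: str, template: str = DEFAULT_LOCAL_SYSTEM_TEMPLATE) -> str:
    return template.format(site=site_id)


def parse_local_system_uri(
    system: str, template: str = DEFAULT_LOCAL_SYSTEM_TEMPLATE
) -> str | None:
    """Extract the site key from a LOCAL identifier system URI, or ``None``."""
    prefix, _, suffix = template.partition("{site}")
    if system.startswith(prefix) and system.endswith(suffix):
        site = system[len(prefix) : len(system) - len(suffix)]
        if site and "/" not in site:
            return site
    return None


class TrialIdentifier(BaseModel):
    """A (registry, system URI, value) triple identifying a study.

    Equality and hashing use the normalized ``(system, value)`` pair only;
    ``source`` is derivable from ``system`` and never disambiguates further.
    """

    model_config = ConfigDict(frozen=True)

    source: IdentifierSource
    system: str = Field(min_length=1)
    value: str = Field(min_length=1)

    def key(self) -> tuple[str, str]:
        return (self.system, self.value)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialIdentifier):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())


class TelecomKind(str, enum.Enum):
    EMAIL = "email"
    PHONE = "phone"


class QueryRole(str, enum.Enum):
    PUBLIC = "public"
    SCIENTIFIC = "scientific"


class Telecom(BaseModel):
    model_config = ConfigDict(frozen=True)
    kind: TelecomKind
    value: str


class ContactPoint(BaseModel):
    """A named person or office reachable for study inquiries."""

    model_config = ConfigDict(frozen=True)

    name: str | None = None
    telecom: tuple[Telecom, ...] = ()
    query_role: QueryRole | None = None


class RecruitmentStatus(str, enum.Enum):
    """FHIR R4 ResearchStudy.status codes (the full value set)."""

    ACTIVE = "active"
    ADMINISTRATIVELY_COMPLETED = "administratively-completed"
    APPROVED = "approved"
    CLOSED_TO_ACCRUAL = "closed-to-accrual"
    CLOSED_TO_ACCRUAL_AND_INTERVENTION = "closed-to-accrual-and-intervention"
    COMPLETED = "completed"
    DISAPPROVED = "disapproved"
    IN_REVIEW = "in-review"
    TEMPORARILY_CLOSED_TO_ACCRUAL = "temporarily-closed-to-accrual"
    TEMPORARILY_CLOSED_TO_ACCRUAL_AND_INTERVENTION = (
        "temporarily-closed-to-accrual-and-intervention"
    )
    WITHDRAWN = "withdrawn"


#: Precedence used to derive a merged study's single overall status from its
#: per-site statuses: a study is "active" if recruiting anywhere; otherwise the
#: earliest entry of this list present among the member statuses wins.
STATUS_PRECEDENCE: tuple[RecruitmentStatus, ...] = (
    RecruitmentStatus.ACTIVE,
    RecruitmentStatus.TEMPORARILY_CLOSED_TO_ACCRUAL,
    RecruitmentStatus.TEMPORARILY_CLOSED_TO_ACCRUAL_AND_INTERVENTION,
    RecruitmentStatus.APPROVED,
    RecruitmentStatus.IN_REVIEW,
    RecruitmentStatus.CLOSED_TO_ACCRUAL,
    RecruitmentStatus.CLOSED_TO_ACCRUAL_AND_INTERVENTION,
    RecruitmentStatus.ADMINISTRATIVELY_COMPLETED,
    RecruitmentStatus.COMPLETED,
    RecruitmentStatus.DISAPPROVED,
    RecruitmentStatus.WITHDRAWN,
)


class SiteInfo(BaseModel):
    """One participating site's view of a study."""

    model_config = ConfigDict(frozen=True)

    site_id: str = Field(min_length=1)
    display_name: str = ""
    recruitment_status: RecruitmentStatus = RecruitmentStatus.ACTIVE
    contacts: tuple[ContactPoint, ...] = ()


class Gender(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    ALL = "all"
    UNKNOWN = "unknown"


class EligibilityCriteria(BaseModel):
    """Demographic inclusion criteria: gender plus an age range in years."""

    model_config = ConfigDict(frozen=True)

    gender: Gender = Gender.UNKNOWN
    min_age_years: float | None = Field(default=None, ge=0)
    max_age_years: float | None = Field(default=None, ge=0)


class Language(str, enum.Enum):
    DE = "de"
    EN = "en"


class LocalizedText(BaseModel):
    model_config = ConfigDict(frozen=True)
    language: Language
    text: str


class RelatedLink(BaseModel):
    """A further-information URL with its label and display text."""

    model_config = ConfigDict(frozen=True)

    url: str
    label: str = ""
    display: str = ""


class CodeSystem(str, enum.Enum):
    ICD10GM = "ICD-10-GM"
    SNOMED = "SNOMED CT"
    FREE_TEXT = "free-text"


class ConditionCode(BaseModel):
    model_config = ConfigDict(frozen=True)
    code: str
    code_system: CodeSystem = CodeSystem.FREE_TEXT


class StudyRecord(BaseModel):
    """One site-local study record: the core data set plus provenance."""

    identifiers: list[TrialIdentifier] = Field(default_factory=list)
    acronym: str | None = None
    titles: list[LocalizedText] = Field(default_factory=list)
    descriptions: list[LocalizedText] = Field(default_factory=list)
    conditions: list[ConditionCode] = Field(default_factory=list)
    eligibility: EligibilityCriteria = Field(default_factory=EligibilityCriteria)
    sites: list[SiteInfo] = Field(default_factory=list)
    overall_status: RecruitmentStatus = RecruitmentStatus.ACTIVE
    related_links: list[RelatedLink] = Field(default_factory=list)
    keywords: list[str] = Field(default_factory=list)
    exporting_site: str = ""
    local_id: str = ""

    def ref(self) -> tuple[str, str]:
        """Globally unique provenance key ``(exporting_site, local_id)``."""
        return (self.exporting_site, self.local_id)

    def primary_identifiers(
        self, primary_sources: frozenset[IdentifierSource] = PRIMARY_SOURCES
    ) -> list[TrialIdentifier]:
        return [i for i in self.identifiers if i.source in primary_sources]


class MasterStudy(BaseModel):
    """Merged representation of one distinct (possibly multicentric) study.

    Identifiers, keywords and conditions are deduplicated unions over the
    member records; sites are concatenated (unique by site_id) so that
    per-site statuses and contacts survive the merge; scalar fields come from
    the first member (in deterministic member order) where they are set.
    """

    identifiers: list[TrialIdentifier] = Field(default_factory=list)
    acronym: str | None = None
    titles: list[LocalizedText] = Field(default_factory=list)
    descriptions: list[LocalizedText] = Field(default_factory=list)
    conditions: list[ConditionCode] = Field(default_factory=list)
    eligibility: EligibilityCriteria = Field(default_factory=EligibilityCriteria)
    sites: list[SiteInfo] = Field(default_factory=list)
    overall_status: RecruitmentStatus = RecruitmentStatus.ACTIVE
    related_links: list[RelatedLink] = Field(default_factory=list)
    keywords: list[str] = Field(default_factory=list)
    member_refs: list[tuple[str, str]] = Field(default_factory=list)
    master_tag: tuple[str, str] = (
        "https://fhir.miracum.org/uc1/CodeSystem/registryStudyRole",
        "master",
    )


class Cluster(BaseModel):
    """A connected component of records sharing primary identifiers."""

    members: list[StudyRecord]
    shared_primary_identifiers: set[TrialIdentifier] = Field(default_factory=set)

    def member_refs(self) -> list[tuple[str, str]]:
        return [m.ref() for m in self.members]

    def exporting_sites(self) -> set[str]:
        return {m.exporting_site for m in self.members}

    def is_multicentric(self) -> bool:
        return len(self.exporting_sites()) >= 2


def _is_absolute_url(url: str) -> bool:
    parsed = urlparse(url)
    return bool(parsed.scheme) and bool(parsed.netloc)


def validate_record(record: StudyRecord) -> list[str]:
    """Check a record against the core-data-set invariants.

    Returns a list of human-readable violation descriptions (empty iff the
    record is valid).  Violations are data, not exceptions: this function is
    total on any well-typed :class:`StudyRecord`.
    """
    violations: list[str] = []

    if not record.identifiers:
        violations.append("identifiers: at least one identifier is required")
    if not any(i.source is IdentifierSource.LOCAL for i in record.identifiers):
        violations.append("identifiers: a LOCAL (site-specific) identifier is required")
    for i in record.identifiers:
        if i.value != i.value.strip():
            violations.append(
                f"identifiers: value {i.value!r} has leading/trailing whitespace"
            )
        if i.source is not IdentifierSource.LOCAL:
            expected = SYSTEM_URI[i.source]
            if i.system != expected:
                violations.append(
                    f"identifiers: {i.source.value} system must be {expected!r},"
                    f" got {i.system!r}"
                )

    elig = record.eligibility
    if (
        elig.min_age_years is not None
        and elig.max_age_years is not None
        and elig.min_age_years > elig.max_age_years
    ):
        violations.append(
            "eligibility: min_age_years must not exceed max_age_years"
            f" ({elig.min_age_years} > {elig.max_age_years})"
        )

    for field_name, texts in (("titles", record.titles), ("descriptions", record.descriptions)):
        for t in texts:
            if not t.text:
                violations.append(f"{field_name}: text must be non-empty when present")
        languages = [t.language for t in texts]
        if len(languages) != len(set(languages)):
            violations.append(f"{field_name}: at most one text per language")

    if not record.sites:
        violations.append("sites: at least one participating site is required")
    site_ids = [s.site_id for s in record.sites]
    if len(site_ids) != len(set(site_ids)):
        violations.append("sites: site_id must be unique within the record")
    for s in record.sites:
        for c in s.contacts:
            if not c.name and not c.telecom:
                violations.append(
                    f"sites[{s.site_id}].contacts: contact needs a name or telecom"
                )

    for link in record.related_links:
        if not _is_absolute_url(link.url):
            violations.append(f"related_links: {link.url!r} is not an absolute URL")

    if not record.exporting_site:
        violations.append("exporting_site: must be set")
    if not record.local_id:
        violations.append("local_id: must be set")

    return violations


def validate_records(records: list[StudyRecord]) -> list[str]:
    """Corpus-level validation: per-record checks plus global uniqueness."""
    violations: list[str] = []
    seen: dict[tuple[str, str], int] = {}
    for idx, record in enumerate(records):
        for v in validate_record(record):
            violations.append(f"record[{idx}] ({record.exporting_site}/{record.local_id}): {v}")
        ref = record.ref()
        if ref in seen:
            violations.append(
                f"record[{idx}]: duplicate (exporting_site, local_id) {ref!r}"
                f" also used by record[{seen[ref]}]"
            )
        else:
            seen[ref] = idx
    return violations


def study_record_json_schema() -> dict:
    """JSON Schema for the flat-record ingestion format (one record/object)."""
    return StudyRecord.model_json_schema()
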