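"""Synthetic multi-site registry corpora with known ground truth.

Emulates a consortium of hospital sites exporting overlapping study records:
each true study is registered under NCT/DRKS/EudraCT-shaped identifiers, a
configurable fraction is multicentric (exported independently by several
sites, each under its own site-local id), primary identifiers are dropped per
site record with a configurable probability (mirroring incomplete source
data), and textual discrepancies are injected both as content-level edits
(an inserted word, the way protocol-document titles differ from registry
titles) and as harmless case/whitespace edits that normalization must absorb.

By default identifier dropout is constrained so each true study's records
remain connected through shared identifiers, keeping cluster recovery exact;
set ``allow_fragmentation`` to study the failure mode instead.

Everything is driven by one seeded RNG: identical configs yield byte-identical
NDJSON output.
"""

from __future__ import annotations

import random
import string

from pydantic import BaseModel, ConfigDict, Field

from .core_model import (
    SYSTEM_URI,
    ConditionCode,
    CodeSystem,
    ContactPoint,
    EligibilityCriteria,
    Gender,
    IdentifierSource,
    Language,
    LocalizedText,
    QueryRole,
    RecruitmentStatus,
    RelatedLink,
    SiteInfo,
    StudyRecord,
    Telecom,
    TelecomKind,
    TrialIdentifier,
    DEFAULT_LOCAL_SYSTEM_TEMPLATE,
    local_system_uri,
)
from .discrepancy import AUDIT_FIELDS

#: Per-field content-discrepancy probabilities; defaults follow the rates
#: observed in a real university-hospital consortium corpus.
DEFAULT_DISCREPANCY_RATES: dict[str, float] = {
    "acronym": 0.125,
    "title_de": 0.0442,
    "title_en": 0.137,
    "description_de": 0.0065,
    "description_en": 0.0663,
}

_WORDS_EN = (
    "randomized open-label controlled phase trial efficacy safety tolerability "
    "antibody consolidation therapy versus conventional chemotherapy pediatric "
    "subjects relapse precursor lymphoblastic leukemia adaptive multicenter "
    "double-blind placebo dose escalation maintenance adjuvant biomarker cohort "
    "outcome survival remission induction inhibitor receptor targeted immune"
).split()

_WORDS_DE = (
    "randomisierte offene kontrollierte Phase Studie Wirksamkeit Sicherheit "
    "Verträglichkeit Antikörper Konsolidierung Therapie gegen konventionelle "
    "Chemotherapie pädiatrische Patienten Rezidiv Vorläufer lymphoblastische "
    "Leukämie adaptive multizentrische doppelblinde Dosis Erhaltung adjuvante "
    "Biomarker Kohorte Überleben Remission Induktion Inhibitor Rezeptor"
).split()

_STATUS_POOL = (
    [RecruitmentStatus.ACTIVE] * 11
    + [RecruitmentStatus.COMPLETED] * 3
    + [RecruitmentStatus.CLOSED_TO_ACCRUAL] * 2
    + [RecruitmentStatus.TEMPORARILY_CLOSED_TO_ACCRUAL] * 2
    + [RecruitmentStatus.APPROVED] * 2
)


class GenerationError(RuntimeError):
    pass


class SimConfig(BaseModel):
    """Study conditions for one synthetic corpus."""

    model_config = ConfigDict(frozen=True)

    n_sites: int = Field(default=10, ge=1)
    n_studies: int = Field(default=500, ge=0)
    multicentric_fraction: float = Field(default=0.3, ge=0, le=1)
    sites_per_multicentric: tuple[int, int] = (2, 4)
    p_identifier_dropout: float = Field(default=0.2, ge=0, le=1)
    p_field_discrepancy: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DISCREPANCY_RATES)
    )
    #: case/whitespace edits are injected at the same per-field rates
    allow_fragmentation: bool = False
    local_system_template: str = DEFAULT_LOCAL_SYSTEM_TEMPLATE
    seed: int = 42


class GroundTruth(BaseModel):
    """True study assignment and injected content-level discrepancies.

    ``assignment`` maps ``"<exporting_site>|<local_id>"`` to the true study
    id; ``injected_discrepancies`` maps each audit field to the study ids that
    received a content-level (normalization-surviving) edit.
    """

    assignment: dict[str, str] = Field(default_factory=dict)
    injected_discrepancies: dict[str, list[str]] = Field(
        default_factory=lambda: {f: [] for f in AUDIT_FIELDS}
    )

    def partition(self) -> dict[str, set[tuple[str, str]]]:
        out: dict[str, set[tuple[str, str]]] = {}
        for key, study in self.assignment.items():
            site, _, local = key.partition("|")
            out.setdefault(study, set()).add((site, local))
        return out


def _title_words(rng: random.Random, pool: list[str] | tuple[str, ...], n: int) -> str:
    return " ".join(w.capitalize() for w in rng.sample(list(pool), n))


def _primary_identifier(source: IdentifierSource, value: str) -> TrialIdentifier:
    return TrialIdentifier(source=source, system=SYSTEM_URI[source], value=value)


def _connected(member_ids: list[set[str]]) -> list[list[int]]:
    """Components of the member mini-graph linked by shared identifier values."""
    n = len(member_ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if member_ids[i] & member_ids[j]:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values())


def _apply_dropout(
    rng: random.Random, full: set[str], k: int, p: float, allow_fragmentation: bool
) -> list[set[str]]:
    kept = [{v for v in full if rng.random() >= p} for _ in range(k)]
    if allow_fragmentation or k == 0:
        return kept
    # restore dropped identifiers until the member mini-graph is connected
    while len(_connected(kept)) > 1:
        comps = _connected(kept)
        target_comp = min(comps[1:], key=len) if len(comps) > 1 else comps[0]
        candidates = [
            (i, v) for i in target_comp for v in sorted(full - kept[i])
        ]
        if not candidates:
            candidates = [
                (i, v) for i in range(k) for v in sorted(full - kept[i])
            ]
        if not candidates:  # everyone already holds the full set
            raise GenerationError("cannot reconnect cluster: no dropped identifiers left")
        i, v = rng.choice(candidates)
        kept[i].add(v)
    return kept


def _content_edit(rng: random.Random, field_name: str, value: str) -> str:
    """An edit that survives normalization (a real conflict)."""
    if field_name == "acronym":
        return value + rng.choice(string.ascii_uppercase)
    words = value.split()
    pool = _WORDS_DE if field_name.endswith("_de") else _WORDS_EN
    pos = rng.randrange(len(words) + 1)
    words.insert(pos, rng.choice(pool).capitalize())
    return " ".join(words)


def _cosmetic_edit(rng: random.Random, value: str) -> str:
    """A display-only edit (case or whitespace) that normalization absorbs."""
    choice = rng.randrange(3)
    if choice == 0:
        return value.swapcase()
    if choice == 1 and " " in value:
        pos = value.index(" ")
        return value[:pos] + "  " + value[pos + 1 :]
    return " " + value + "  "


def _set_field(record: StudyRecord, field_name: str, value: str) -> None:
    if field_name == "acronym":
        record.acronym = value
        return
    attr, _, lang = field_name.partition("_")
    texts = record.titles if attr == "title" else record.descriptions
    for idx, t in enumerate(texts):
        if t.language is Language(lang):
            texts[idx] = LocalizedText(language=t.language, text=value)
            return
    texts.append(LocalizedText(language=Language(lang), text=value))


def generate(config: SimConfig) -> tuple[list[StudyRecord], GroundTruth]:
    """Generate a corpus of site-local records plus its ground truth."""
    rng = random.Random(config.seed)
    sites = [f"site-{i:02d}.example" for i in range(config.n_sites)]
    truth = GroundTruth()

    n = config.n_studies
    nct_values = rng.sample(range(10**8), n)
    drks_values = rng.sample(range(10**8), n)
    eudract_serials = rng.sample(range(10**6), n)

    records: list[StudyRecord] = []
    for s in range(n):
        study_id = f"S{s:04d}"
        primaries = {
            f"NCT{nct_values[s]:08d}": IdentifierSource.NCT,
            f"DRKS{drks_values[s]:08d}": IdentifierSource.DRKS,
            f"{rng.randint(2005, 2023)}-{eudract_serials[s]:06d}-{rng.randrange(100):02d}":
                IdentifierSource.EUDRACT,
        }

        is_multi = config.n_sites >= 2 and rng.random() < config.multicentric_fraction
        if is_multi:
            lo, hi = config.sites_per_multicentric
            k = rng.randint(min(lo, config.n_sites), min(hi, config.n_sites))
            member_sites = sorted(rng.sample(sites, k))
        else:
            member_sites = [rng.choice(sites)]

        title_en = _title_words(rng, _WORDS_EN, rng.randint(5, 9))
        title_de = _title_words(rng, _WORDS_DE, rng.randint(5, 9))
        desc_en = _title_words(rng, _WORDS_EN, rng.randint(10, 16))
        desc_de = _title_words(rng, _WORDS_DE, rng.randint(10, 16))
        acronym = "".join(rng.choices(string.ascii_uppercase, k=rng.randint(3, 6)))
        conditions = [
            ConditionCode(
                code=f"{rng.choice('CDEIJ')}{rng.randrange(100):02d}.{rng.randrange(10)}",
                code_system=CodeSystem.ICD10GM,
            )
            for _ in range(rng.randint(1, 2))
        ]
        keywords = sorted(rng.sample(_WORDS_EN, rng.randint(1, 3)))
        min_age = float(rng.choice([0, 18, 18, 18, 40]))
        max_age = rng.choice([None, 65.0, 75.0, 99.0])
        eligibility = EligibilityCriteria(
            gender=rng.choice(list(Gender)),
            min_age_years=min_age,
            max_age_years=max_age if max_age is None or max_age >= min_age else None,
        )
        link = RelatedLink(
            url=f"https://registry.example.org/studies/{study_id.lower()}",
            label=study_id,
            display="Consortium registry",
        )

        kept_ids = _apply_dropout(
            rng, set(primaries), len(member_sites), config.p_identifier_dropout,
            config.allow_fragmentation,
        )

        member_records: list[StudyRecord] = []
        for m_idx, site in enumerate(member_sites):
            local_id = "".join(rng.choices(string.ascii_lowercase, k=12))
            identifiers = [
                _primary_identifier(primaries[v], v) for v in sorted(kept_ids[m_idx])
            ]
            identifiers.append(
                TrialIdentifier(
                    source=IdentifierSource.LOCAL,
                    system=local_system_uri(site, config.local_system_template),
                    value=local_id,
                )
            )
            contact = ContactPoint(
                name=f"Dr. {rng.choice(string.ascii_uppercase)}. "
                f"{rng.choice(_WORDS_EN).capitalize()}",
                telecom=(
                    Telecom(
                        kind=TelecomKind.EMAIL,
                        value=f"study-office-{s:04d}@{site}",
                    ),
                ),
                query_role=rng.choice([QueryRole.PUBLIC, QueryRole.SCIENTIFIC]),
            )
            site_info = SiteInfo(
                site_id=site,
                display_name=f"University Hospital {site.split('.')[0].title()}",
                recruitment_status=rng.choice(_STATUS_POOL),
                contacts=(contact,),
            )
            record = StudyRecord(
                identifiers=identifiers,
                acronym=acronym,
                titles=[
                    LocalizedText(language=Language.DE, text=title_de),
                    LocalizedText(language=Language.EN, text=title_en),
                ],
                descriptions=[
                    LocalizedText(language=Language.DE, text=desc_de),
                    LocalizedText(language=Language.EN, text=desc_en),
                ],
                conditions=list(conditions),
                eligibility=eligibility,
                sites=[site_info],
                overall_status=site_info.recruitment_status,
                related_links=[link],
                keywords=list(keywords),
                exporting_site=site,
                local_id=local_id,
            )
            member_records.append(record)
            truth.assignment[f"{site}|{local_id}"] = study_id

        if len(member_records) >= 2:
            for field_name in AUDIT_FIELDS:
                p = config.p_field_discrepancy.get(field_name, 0.0)
                if rng.random() < p:
                    victim = rng.choice(member_records)
                    current = _field_value(victim, field_name)
                    _set_field(victim, field_name, _content_edit(rng, field_name, current))
                    truth.injected_discrepancies[field_name].append(study_id)
                if rng.random() < p:  # cosmetic edits at the same rate
                    victim = rng.choice(member_records)
                    current = _field_value(victim, field_name)
                    _set_field(victim, field_name, _cosmetic_edit(rng, current))

        records.extend(member_records)

    for field_name in truth.injected_discrepancies:
        truth.injected_discrepancies[field_name].sort()
    records.sort(key=lambda r: r.ref())
    return records, truth


def _field_value(record: StudyRecord, field_name: str) -> str:
    from .discrepancy import field_value

    value = field_value(record, field_name)
    assert value is not None  # the generator always populates audited fields
    return value
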