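"""Cross-site metadata discrepancy audit.

Sites export their own copy of a multicentric study's metadata, and those
copies drift: a title imported from ClinicalTrials.gov at one site versus the
study-protocol wording at another, an amended description picked up by only
some sites, diverging acronyms.  The audit counts, per field, the multicentric
clusters whose member records disagree *after* display-level normalization
(whitespace collapsing and case folding), so that purely cosmetic differences
never count as conflicts.  Unset values are ignored: one site not exporting a
German title is missing data, not a conflict to resolve.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .core_model import Cluster, Language, StudyRecord

#: Auditable fields: acronym plus the language-tagged titles and descriptions.
AUDIT_FIELDS: tuple[str, ...] = (
    "acronym",
    "title_de",
    "title_en",
    "description_de",
    "description_en",
)


def normalize_text(s: str) -> str:
    """Display-insensitive text form: runs of Unicode whitespace collapse to a
    single space, surrounding whitespace is stripped, and characters are
    case-folded (locale-independent, so German ß/umlauts fold consistently).
    Idempotent."""
    return " ".join(s.split()).casefold()


def field_value(record: StudyRecord, field_name: str) -> str | None:
    """Raw value of an auditable field, or ``None`` when unset."""
    if field_name == "acronym":
        return record.acronym
    attr, _, lang = field_name.partition("_")
    texts = record.titles if attr == "title" else record.descriptions
    if attr not in ("title", "description") or lang not in ("de", "en"):
        raise KeyError(f"unknown audit field {field_name!r}")
    for t in texts:
        if t.language is Language(lang):
            return t.text
    return None


def field_discrepant(cluster: Cluster, field_name: str) -> bool:
    """True iff ≥2 distinct normalized, non-missing values exist in the cluster.

    Only defined for multicentric clusters (members from ≥2 distinct sites);
    single-site clusters have nothing to disagree across.
    """
    if not cluster.is_multicentric():
        raise ValueError("discrepancy is only defined for multicentric clusters")
    values = {
        normalize_text(v)
        for m in cluster.members
        if (v := field_value(m, field_name)) is not None
    }
    return len(values) >= 2


def percent_str(n: int, total: int) -> str:
    """Percentage formatted with two decimals below 10% and one above."""
    if total == 0:
        return "0.00"
    value = n / total * 100
    return f"{value:.2f}" if value < 10 else f"{value:.1f}"


class FieldStat(BaseModel):
    n_discrepant: int
    percent: str


class DiscrepancyReport(BaseModel):
    total_records: int
    multicentric_clusters: int
    per_field: dict[str, FieldStat] = Field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, total_records: int, multicentric_clusters: int, counts: dict[str, int]
    ) -> "DiscrepancyReport":
        return cls(
            total_records=total_records,
            multicentric_clusters=multicentric_clusters,
            per_field={
                f: FieldStat(n_discrepant=n, percent=percent_str(n, multicentric_clusters))
                for f, n in counts.items()
            },
        )

    def to_csv(self) -> str:
        lines = ["field,n_discrepant,percent"]
        for f in AUDIT_FIELDS:
            if f in self.per_field:
                stat = self.per_field[f]
                lines.append(f"{f},{stat.n_discrepant},{stat.percent}")
        return "\n".join(lines) + "\n"


def audit(records: list[StudyRecord], clusters: list[Cluster]) -> DiscrepancyReport:
    """Count, per field, the multicentric clusters with conflicting values.

    ``clusters`` must partition ``records`` (as produced by the merger's
    connected-components step).
    """
    cluster_refs = [ref for c in clusters for ref in c.member_refs()]
    if sorted(cluster_refs) != sorted(r.ref() for r in records):
        raise ValueError("clusters do not partition the record list")

    multicentric = [c for c in clusters if c.is_multicentric()]
    counts = {
        f: sum(1 for c in multicentric if field_discrepant(c, f)) for f in AUDIT_FIELDS
    }
    return DiscrepancyReport.from_counts(len(records), len(multicentric), counts)
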