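"""Intratumor-heterogeneity metrics and two-tier concordance accounting.

Sharing classes over a mutation-by-sector presence matrix:

* truncal  — present in every sampled sector;
* branched — shared by at least two, but not all, sectors;
* private  — unique to one sector.

The headline ITH statistic is the percentage of non-truncal
("heterogeneous") mutations; comparing it between the discovery tier and
the ultra-deep validation tier quantifies how much apparent heterogeneity
was an artifact of limited discovery depth.  Percentages are reported to
one decimal, half-up, to match how such summary tables are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .discovery import MutationRecord
from .io import Site
from .validation import ValidationResult

__all__ = [
    "PresenceMatrix",
    "ConcordanceReport",
    "classify_sharing",
    "pct_heterogeneous",
    "heterogeneity_reduction",
    "concordance",
    "mutation_rate",
    "round1",
]


def round1(x: float) -> float:
    """Round to one decimal, half-up (printed-table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PresenceMatrix:
    """Binary mutation-by-sector presence calls for one tumor at one tier."""

    df: pd.DataFrame
    tier: str = "tier1"

    def __post_init__(self) -> None:
        if self.df.shape[1] < 2:
            raise ValueError("need at least two sectors")
        vals = self.df.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("presence matrix must be binary")
        if (self.df.sum(axis=1) == 0).any():
            empty = list(self.df.index[self.df.sum(axis=1) == 0])
            raise ValueError(f"mutations present in no sector: {empty}")
        self.df = self.df.astype(int)

    @property
    def n_sectors(self) -> int:
        return self.df.shape[1]

    @property
    def mutations(self) -> list[str]:
        return list(self.df.index)


def classify_sharing(matrix: PresenceMatrix | pd.DataFrame) -> pd.Series:
    """Per-mutation sharing label (truncal/branched/private)."""
    if isinstance(matrix, pd.DataFrame):
        matrix = PresenceMatrix(matrix)
    counts = matrix.df.sum(axis=1)
    S = matrix.n_sectors
    labels = pd.Series("branched", index=matrix.df.index, name="sharing")
    labels[counts == S] = "truncal"
    labels[counts == 1] = "private"
    return labels


def pct_heterogeneous(labels: pd.Series | list[str]) -> float:
    """Percentage of non-truncal mutations, to one decimal (half-up)."""
    labels = pd.Series(list(labels))
    if labels.empty:
        raise ValueError("no mutations to summarize")
    return round1(100.0 * (labels != "truncal").sum() / len(labels))


def heterogeneity_reduction(pct_tier1: float, pct_tier2: float) -> float:
    """Drop in heterogeneity after ultra-deep validation (may be negative)."""
    for p in (pct_tier1, pct_tier2):
        if not 0.0 <= p <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    return round1(pct_tier1 - pct_tier2)


@dataclass
class ConcordanceReport:
    """Discovery-vs-validation accounting.

    ``n_new`` counts (mutation, sector) pairs where a confirmed mutation is
    present at the validation tier in a sector where discovery had not
    called it — i.e. per-sector detections missed by the discovery tier.
    """

    n_candidates: int
    n_confirmed: int
    n_rejected_germline: int
    n_rejected_absent: int
    n_not_assessable: int
    n_new: int

    @property
    def tp_rate(self) -> float:
        return self.n_confirmed / self.n_candidates if self.n_candidates else float("nan")

    @property
    def fn_rate(self) -> float:
        denom = self.n_confirmed + self.n_new
        return self.n_new / denom if denom else float("nan")


def concordance(
    records: list[MutationRecord],
    results: dict[Site, ValidationResult],
    granularity: str = "mutation_sector",
) -> ConcordanceReport:
    """Compare tier-1 candidates with their tier-2 adjudication.

    Candidates failing the coverage criterion are excluded from both the
    numerator and denominator of the true-positive rate.  ``granularity``
    controls how missed detections are counted: per (mutation, sector)
    pair (default) or per mutation.
    """
    if granularity not in {"mutation_sector", "mutation"}:
        raise ValueError("granularity must be 'mutation_sector' or 'mutation'")
    by_site = {r.site: r for r in records}
    unknown = [s for s in results if s not in by_site]
    if unknown:
        raise ValueError(f"validation results for unknown candidates: {unknown[:3]}")
    n_confirmed = n_germ = n_absent = n_na = 0
    n_new = 0
    for site, res in results.items():
        if res.status == "not_assessable":
            n_na += 1
            continue
        if res.status == "confirmed":
            n_confirmed += 1
            rec = by_site[site]
            missed = [
                s
                for s, present in res.present.items()
                if present and not rec.sector_called.get(s, False)
            ]
            if granularity == "mutation_sector":
                n_new += len(missed)
            else:
                n_new += 1 if missed else 0
        elif res.status == "germline_like":
            n_germ += 1
        elif res.status == "absent":
            n_absent += 1
    n_candidates = n_confirmed + n_germ + n_absent
    return ConcordanceReport(
        n_candidates=n_candidates,
        n_confirmed=n_confirmed,
        n_rejected_germline=n_germ,
        n_rejected_absent=n_absent,
        n_not_assessable=n_na,
        n_new=n_new,
    )


def mutation_rate(n_mutations: int, footprint_mb: float) -> float:
    """Somatic mutations per megabase of assayed footprint."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    return n_mutations / footprint_mb


def summarize_tumor(
    tier1: PresenceMatrix,
    tier2: PresenceMatrix,
    intermixing: bool | None = None,
    footprint_mb: float | None = None,
) -> pd.Series:
    """One summary row in the two-tier comparison-table shape."""
    lab1 = classify_sharing(tier1)
    lab2 = classify_sharing(tier2)
    p1 = pct_heterogeneous(lab1)
    p2 = pct_heterogeneous(lab2)
    out = {
        "n_heterogeneous_tier1": int((lab1 != "truncal").sum()),
        "n_total_tier1": len(lab1),
        "pct_heterogeneous_tier1": p1,
        "n_heterogeneous_tier2": int((lab2 != "truncal").sum()),
        "n_total_tier2": len(lab2),
        "pct_heterogeneous_tier2": p2,
        "reduction_pct": heterogeneity_reduction(p1, p2),
    }
    if intermixing is not None:
        out["early_intermixing"] = bool(intermixing)
    if footprint_mb is not None:
        out["mutation_rate_per_mb"] = mutation_rate(len(lab2), footprint_mb)
    return pd.Series(out)
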