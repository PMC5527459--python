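"""Purity/copy-number-aware clonality assessment and early-intermixing detection.

A somatic mutation carried by every malignant cell of a sector ("clonal")
has an expected VAF determined by the sector's malignant-cell fraction
(purity) and the local copy state:

    E[VAF] = m * p / (p * C_t + (1 - p) * C_n)

with purity ``p``, total tumor copies ``C_t`` at the locus, mutated-allele
multiplicity ``m`` and normal-cell copies ``C_n`` (2 for autosomes).  With
``m = 1`` this is the *minimum* expected clonal VAF; an observed VAF far
below it marks the mutation as subclonal in that sector.  The second
criterion compares against the other mutations of the same sharing group
(truncal/branched/private) in the same sector, which buffers against a
locally wrong purity or copy-number estimate.

Ubiquitous (truncal) mutations sitting at subclonal levels in one or more
sectors are the signature of early intermixing of ancestral subclones;
``detect_early_intermixing`` surfaces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SectorProfile",
    "ClonalityCall",
    "expected_min_vaf",
    "classify_clonality",
    "estimate_purity_from_truncal",
    "assess_clonality",
    "detect_early_intermixing",
]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    total_copies: int
    major_copies: int

    def __post_init__(self) -> None:
        if self.total_copies < 0 or not 0 <= self.major_copies <= self.total_copies:
            raise ValueError("invalid copy-number segment")
        if self.start > self.end:
            raise ValueError("segment start after end")


@dataclass
class SectorProfile:
    """Externally estimated purity/ploidy/copy-number context for one sector."""

    sector_id: str
    purity: float
    average_ploidy: float = 2.0
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if a.end >= b.start:
                    raise ValueError("overlapping copy-number segments")

    def copy_number_at(self, chrom: str, pos: int) -> tuple[int, int]:
        """(total, major) copies at a locus; diploid het where unannotated."""
        for seg in self.segments:
            if seg.chrom == chrom and seg.start <= pos <= seg.end:
                return seg.total_copies, seg.major_copies
        return 2, 1


@dataclass
class ClonalityCall:
    mutation: str
    sector: str
    observed_vaf: float
    expected_min_vaf: float
    group: str  # truncal | branched | private
    group_median_vaf: float  # nan when no comparator existed
    verdict: str  # clonal | subclonal | indeterminate
    group_supported: bool = True  # False when criterion (b) had no comparator


def expected_min_vaf(
    purity: float, total_copies: int, multiplicity: int = 1, normal_copies: int = 2
) -> float:
    """Expected VAF of a clonal mutation; multiplicity 1 gives the minimum."""
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0, 1]")
    if total_copies == 0:
        raise ValueError("a mutated site cannot reside on zero copies")
    if total_copies < 1 or not 1 <= multiplicity <= total_copies:
        raise ValueError("need 1 <= multiplicity <= total_copies")
    return multiplicity * purity / (purity * total_copies + (1.0 - purity) * normal_copies)


def classify_clonality(
    observed_vaf: float,
    expected_min: float,
    group_vafs: list[float] | None,
    tolerance: float = 0.5,
) -> str:
    """Two-criterion verdict for one mutation in one sector.

    Subclonal iff the observed VAF falls below ``tolerance`` times *both*
    the minimum expected clonal VAF and the same-group median; clonal iff
    it reaches ``tolerance`` times both; indeterminate when the criteria
    disagree.  Without comparators, criterion (b) is skipped and the
    verdict follows criterion (a) alone.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    meets_a = observed_vaf >= tolerance * expected_min
    if not group_vafs:
        return "clonal" if meets_a else "subclonal"
    med = float(np.median(group_vafs))
    meets_b = observed_vaf >= tolerance * med
    if meets_a and meets_b:
        return "clonal"
    if not meets_a and not meets_b:
        return "subclonal"
    return "indeterminate"


def estimate_purity_from_truncal(vafs: list[float]) -> tuple[float, bool]:
    """Fallback purity from truncal VAFs in copy-neutral segments.

    A clonal heterozygous diploid mutation has VAF = purity / 2, so purity
    is estimated as twice the median VAF (capped at 1).  Returns the
    estimate plus a low-confidence flag when the VAFs disagree (IQR > 0.1).
    Use an external copy-number profile instead whenever one exists.
    """
    vafs = [float(v) for v in vafs]
    if len(vafs) < 3:
        raise ValueError(
            "need >= 3 truncal diploid VAFs to estimate purity; supply a SectorProfile instead"
        )
    est = min(1.0, 2.0 * float(np.median(vafs)))
    q1, q3 = np.percentile(vafs, [25, 75])
    return est, bool(q3 - q1 > 0.1)


def assess_clonality(
    presence: pd.DataFrame,
    vaf: pd.DataFrame,
    labels: pd.Series,
    profiles: dict[str, SectorProfile],
    loci: dict[str, tuple[str, int]] | None = None,
    multiplicity: int = 1,
    tolerance: float = 0.5,
) -> list[ClonalityCall]:
    """Per-(mutation, sector) verdicts over a validated presence matrix.

    ``presence`` and ``vaf`` are mutation-by-sector frames; ``labels``
    gives each mutation's sharing group; ``profiles`` supplies purity and
    copy number per sector; ``loci`` (mutation -> (chrom, pos)) looks up
    copy-number segments, defaulting to diploid when omitted.
    """
    calls: list[ClonalityCall] = []
    for sector in presence.columns:
        prof = profiles[sector]
        present_here = presence.index[presence[sector] > 0]
        group_pool: dict[str, list[tuple[str, float]]] = {}
        for m in present_here:
            group_pool.setdefault(labels[m], []).append((m, float(vaf.loc[m, sector])))
        for m in present_here:
            chrom_pos = loci.get(m) if loci else None
            total, major = (
                prof.copy_number_at(*chrom_pos) if chrom_pos else (2, 1)
            )
            mult = min(multiplicity, max(total, 1))
            exp_min = expected_min_vaf(prof.purity, total, mult)
            comparators = [v for (other, v) in group_pool[labels[m]] if other != m]
            verdict = classify_clonality(
                float(vaf.loc[m, sector]), exp_min, comparators or None, tolerance
            )
            calls.append(
                ClonalityCall(
                    mutation=m,
                    sector=sector,
                    observed_vaf=float(vaf.loc[m, sector]),
                    expected_min_vaf=exp_min,
                    group=labels[m],
                    group_median_vaf=float(np.median(comparators)) if comparators else float("nan"),
                    verdict=verdict,
                    group_supported=bool(comparators),
                )
            )
    return calls


def detect_early_intermixing(
    calls: list[ClonalityCall], min_sectors: int = 1
) -> tuple[bool, list[tuple[str, list[str]]]]:
    """Truncal mutations that sit at subclonal levels in >= ``min_sectors``.

    Returns the tumor-level flag and, per flagged mutation, the sectors in
    which it is subclonal.  A non-empty list at the configured threshold is
    the evidence-of-early-intermixing flag.
    """
    by_mut: dict[str, list[str]] = {}
    for c in calls:
        if c.group == "truncal" and c.verdict == "subclonal":
            by_mut.setdefault(c.mutation, []).append(c.sector)
    flagged = [(m, sorted(secs)) for m, secs in sorted(by_mut.items()) if len(secs) >= min_sectors]
    return bool(flagged), flagged


def read_sector_profiles(
    purity_path, segments_path=None
) -> dict[str, "SectorProfile"]:
    """Load per-sector purity/ploidy and optional copy-number segments.

    The purity table needs columns ``sector_id`` and ``purity`` (optional
    ``average_ploidy``); the segments table needs ``sector_id``, ``chrom``,
    ``start``, ``end``, ``total_copies``, ``major_copies`` with 1-based
    inclusive coordinates.
    """
    pur = pd.read_csv(purity_path, sep="\t", dtype={"sector_id": str})
    segs_by_sector: dict[str, list[Segment]] = {}
    if segments_path is not None:
        segs = pd.read_csv(segments_path, sep="\t", dtype={"sector_id": str, "chrom": str})
        for row in segs.itertuples(index=False):
            segs_by_sector.setdefault(row.sector_id, []).append(
                Segment(row.chrom, int(row.start), int(row.end), int(row.total_copies), int(row.major_copies))
            )
    profiles = {}
    for row in pur.itertuples(index=False):
        ploidy = float(getattr(row, "average_ploidy", 2.0))
        profiles[row.sector_id] = SectorProfile(
            row.sector_id,
            purity=float(row.purity),
            average_ploidy=ploidy,
            segments=segs_by_sector.get(row.sector_id, []),
        )
    return profiles


def calls_to_frame(calls: list[ClonalityCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mutation": [c.mutation for c in calls],
            "sector": [c.sector for c in calls],
            "group": [c.group for c in calls],
            "observed_vaf": [c.observed_vaf for c in calls],
            "expected_min_vaf": [c.expected_min_vaf for c in calls],
            "group_median_vaf": [c.group_median_vaf for c in calls],
            "verdict": [c.verdict for c in calls],
            "group_supported": [c.group_supported for c in calls],
        }
    )
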