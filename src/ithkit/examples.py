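"""Worked examples at published-summary scale.

Small, fully synthetic fixtures shaped like the per-patient summary
statistics of a four-patient multiregion colorectal cancer cohort profiled
with two-tier sequencing: per-tier heterogeneous/total mutation counts,
and the cohort-level discovery-vs-validation tallies.  Only the summary
composition is encoded (how many mutations are truncal at each tier, how
many candidates confirm, how many per-sector detections the discovery
tier missed); the per-sector fill-in is arbitrary but deterministic.
These exist so the metric operations can be exercised end-to-end against
hand-checkable integer arithmetic without any external data.
"""

from __future__ import annotations

import pandas as pd

from .discovery import MutationRecord
from .io import Site, SiteCounts
from .metrics import PresenceMatrix

__all__ = [
    "TWO_TIER_SUMMARY_COUNTS",
    "two_tier_presence_example",
    "concordance_example",
]

#: per-tumor (total mutations, heterogeneous at tier 1, heterogeneous at tier 2)
TWO_TIER_SUMMARY_COUNTS: dict[int, tuple[int, int, int]] = {
    1: (13, 7, 2),
    2: (30, 20, 11),
    3: (36, 31, 24),
    4: (25, 13, 12),
}

_SECTORS = ["A", "B", "C", "D", "E"]


def two_tier_presence_example(patient: int) -> tuple[PresenceMatrix, PresenceMatrix]:
    """Tier-1 and tier-2 presence matrices with the given summary composition.

    Tier-2 presence is a superset of tier-1 presence per mutation (the
    validation tier only adds per-sector detections), so some mutations
    heterogeneous at tier 1 become truncal at tier 2.
    """
    total, het1, het2 = TWO_TIER_SUMMARY_COUNTS[patient]
    if not het2 <= het1 <= total:
        raise ValueError("inconsistent composition")
    S = len(_SECTORS)
    rows1, rows2, index = [], [], []
    n_truncal1 = total - het1
    n_truncal2 = total - het2
    for i in range(total):
        index.append(f"p{patient}_m{i + 1:03d}")
        if i < n_truncal1:  # truncal at both tiers
            rows1.append([1] * S)
            rows2.append([1] * S)
        elif i < n_truncal2:  # branched at tier 1, upgraded to truncal at tier 2
            row1 = [1] * S
            row1[i % S] = 0
            rows1.append(row1)
            rows2.append([1] * S)
        else:  # heterogeneous at both tiers: private widened to branched
            row1 = [0] * S
            row1[i % S] = 1
            row2 = list(row1)
            row2[(i + 1) % S] = 1
            rows1.append(row1)
            rows2.append(row2)
    idx = pd.Index(index, name="mutation")
    t1 = PresenceMatrix(pd.DataFrame(rows1, index=idx, columns=_SECTORS), tier="tier1")
    t2 = PresenceMatrix(pd.DataFrame(rows2, index=idx, columns=_SECTORS), tier="tier2")
    return t1, t2


#: cohort-level two-tier concordance composition
CONCORDANCE_COUNTS = {
    "candidates": 307,
    "confirmed": 289,
    "germline_like": 17,
    "absent": 1,
    "new_mutation_sector_detections": 76,
}


def concordance_example():
    """Candidate records plus validation results matching the cohort tallies.

    289 of 307 assayable candidates confirm (17 look germline, 1 is seen
    nowhere at validation depth), and across the confirmed mutations the
    validation tier finds 76 (mutation, sector) detections the discovery
    tier had missed.  Returns ``(records, results)`` ready for
    :func:`ithkit.metrics.concordance`.
    """
    from .validation import ValidationResult

    records: list[MutationRecord] = []
    results = {}
    deep = SiteCounts(50, 10_000, 10_500)
    quiet = SiteCounts(0, 10_000, 10_500)
    normal = SiteCounts(0, 400, 420)
    n_conf = CONCORDANCE_COUNTS["confirmed"]
    n_germ = CONCORDANCE_COUNTS["germline_like"]
    n_abs = CONCORDANCE_COUNTS["absent"]
    n_new = CONCORDANCE_COUNTS["new_mutation_sector_detections"]
    total = n_conf + n_germ + n_abs
    pos = 0
    for i in range(total):
        pos += 10
        site = Site("chr9", pos, "C", "G")
        # discovery: called in sector A only
        rec = MutationRecord(
            site=site,
            sector_counts={s: SiteCounts(12, 400, 420) for s in _SECTORS},
            sector_called={s: (s == "A") for s in _SECTORS},
            sector_p={s: 1e-9 for s in _SECTORS},
            normal_counts=normal,
        )
        records.append(rec)
        if i < n_conf:
            # first ``n_new`` confirmed candidates gain one extra sector each
            extra = "B" if i < n_new else None
            present = {s: (s == "A" or s == extra) for s in _SECTORS}
            results[site] = ValidationResult(
                site,
                "confirmed",
                sector_z={s: (40.0 if present[s] else 0.1) for s in _SECTORS},
                sector_vaf={s: (deep.vaf if present[s] else 0.0) for s in _SECTORS},
                present=present,
                provenance="z_rule",
            )
        elif i < n_conf + n_germ:
            results[site] = ValidationResult(
                site, "germline_like", present={s: False for s in _SECTORS},
                provenance="variant_in_reference:N",
            )
        else:
            results[site] = ValidationResult(
                site, "absent", present={s: False for s in _SECTORS},
                provenance="no_sector_above_null",
            )
    _ = quiet
    return records, results
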