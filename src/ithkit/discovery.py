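"""Tier-1 discovery: a transparent count-based somatic caller.

Discovery-stage sequencing in the emulated design ran at a few hundred
fold coverage and produced candidate somatic mutations per tumor sector.
This module provides a single explicit test per site: a VAF floor (2.5%
by default, matching the observable behaviour of dual-caller discovery
pipelines at that depth), a minimum variant-read count, a one-sided
binomial evidence test against the base error rate, and a matched-normal
contamination gate.  Everything is a plain threshold in ``CallerConfig``;
there is no hidden model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .io import CountsPanel, Site, SiteCounts

logger = logging.getLogger(__name__)

__all__ = ["CallerConfig", "CallResult", "MutationRecord", "call_site", "discover"]


@dataclass(frozen=True)
class CallerConfig:
    min_vaf: float = 0.025
    base_error_rate: float = 1e-3
    max_p: float = 1e-6
    min_var_reads: int = 4
    min_normal_depth: int = 50
    max_normal_vaf: float = 0.01

    def __post_init__(self) -> None:
        for f in (self.min_vaf, self.base_error_rate, self.max_normal_vaf):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.max_p <= 0 or self.min_var_reads <= 0 or self.min_normal_depth <= 0:
            raise ValueError("thresholds must be positive")


class CallResult(NamedTuple):
    called: bool
    p_value: float
    reason: str  # which gate decided, for provenance


@dataclass
class MutationRecord:
    """One candidate somatic mutation with its per-sector tier-1 evidence."""

    site: Site
    sector_counts: dict[str, SiteCounts]
    sector_called: dict[str, bool]
    sector_p: dict[str, float]
    normal_counts: SiteCounts

    @property
    def id(self) -> str:
        return self.site.label()

    @property
    def called_sectors(self) -> list[str]:
        return sorted(s for s, c in self.sector_called.items() if c)


def call_site(tumor: SiteCounts, normal: SiteCounts, config: CallerConfig) -> CallResult:
    """Somatic call for one sector at one site.

    Called iff all of: VAF >= ``min_vaf``; variant reads >=
    ``min_var_reads``; one-sided binomial tail P(X >= var | depth,
    base_error_rate) <= ``max_p``; and the matched normal is deep enough and
    clean enough.  Zero-depth sites are skipped with a warning, not raised.
    """
    if tumor.q30_depth == 0 or normal.q30_depth == 0:
        logger.warning("zero-depth site skipped (tumor %s, normal %s)", tumor, normal)
        return CallResult(False, float("nan"), "zero_depth")
    p_value = float(stats.binom.sf(tumor.var_reads - 1, tumor.q30_depth, config.base_error_rate))
    if normal.q30_depth < config.min_normal_depth:
        return CallResult(False, p_value, "normal_depth")
    if normal.vaf > config.max_normal_vaf:
        return CallResult(False, p_value, "normal_contaminated")
    if tumor.vaf < config.min_vaf:
        return CallResult(False, p_value, "below_vaf_floor")
    if tumor.var_reads < config.min_var_reads:
        return CallResult(False, p_value, "too_few_reads")
    if p_value > config.max_p:
        return CallResult(False, p_value, "insufficient_evidence")
    return CallResult(True, p_value, "called")


def discover(panel: CountsPanel, config: CallerConfig | None = None) -> list[MutationRecord]:
    """Run the caller over a tier-1 panel; one record per site called somewhere.

    Requires a matched normal sample (somatic status is undefined without
    one).  Records come back sorted by locus.
    """
    config = config or CallerConfig()
    tier1 = panel.tier("tier1")
    normal_id = tier1.normal_id
    if normal_id is None:
        raise ValueError("tier-1 panel has no matched normal sample; somatic status undefined")
    sectors = tier1.sectors
    records: list[MutationRecord] = []
    for site, counts in tier1.iter_sites():
        if normal_id not in counts:
            raise ValueError(f"no normal counts at {site.label()}")
        normal = counts[normal_id]
        sector_counts: dict[str, SiteCounts] = {}
        called: dict[str, bool] = {}
        pvals: dict[str, float] = {}
        for s in sectors:
            if s not in counts:
                continue
            res = call_site(counts[s], normal, config)
            sector_counts[s] = counts[s]
            called[s] = res.called
            pvals[s] = res.p_value
        if any(called.values()):
            records.append(MutationRecord(site, sector_counts, called, pvals, normal))
    records.sort(key=lambda r: (r.site.chrom, r.site.pos, r.site.ref, r.site.alt))
    return records


def records_to_frame(records: list[MutationRecord]):
    """Candidate table: locus columns plus per-sector var/depth/called."""
    import pandas as pd

    rows = []
    for r in records:
        row: dict = {
            "chrom": r.site.chrom,
            "pos": r.site.pos,
            "ref": r.site.ref,
            "alt": r.site.alt,
        }
        for s, c in sorted(r.sector_counts.items()):
            row[f"{s}_var"] = c.var_reads
            row[f"{s}_depth"] = c.q30_depth
            row[f"{s}_called"] = int(r.sector_called[s])
        rows.append(row)
    return pd.DataFrame(rows)
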