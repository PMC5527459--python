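"""Ultra-deep validation with a control-anchored Z-score null.

Each candidate site is re-assayed at amplicon depth in every tumor sector,
the matched normal, and a set of negative-control samples (unrelated
individuals sequenced in the same run).  The controls define an empirical
null for the background variant fraction at the site; a sector supports
the mutation when its VAF exceeds that null by more than ``z_threshold``
standard deviations.  Adjudication per mutation:

* ``not_assessable`` — the quality-filtered coverage criterion (>= 100x of
  q30 bases in the normal and every sector) failed, or data are missing;
* ``germline_like`` — the normal or a control itself shows the variant
  above the null built from the remaining reference samples;
* ``confirmed``  — at least one sector passes the Z rule (and the optional
  reporting VAF floor);
* ``absent``     — no sector passes.

With clean controls the empirical standard deviation collapses to zero, so
it is floored at the binomial sampling noise a control would show at its
depth, computed from a pseudocount-smoothed pooled error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CountsPanel, Site, SiteCounts

__all__ = [
    "ControlNull",
    "ValidationConfig",
    "ValidationResult",
    "build_control_null",
    "z_score",
    "depth_filter",
    "adjudicate",
    "validate_panel",
]

STATUSES = ("confirmed", "germline_like", "absent", "not_assessable")


@dataclass(frozen=True)
class ValidationConfig:
    min_q30_depth: int = 100
    z_threshold: float = 3.0
    min_vaf_floor: float = 0.0  # observed validated VAFs bottom out near 0.07%; exposed as a reporting filter
    sd_floor_mode: str = "binomial"  # or "fixed"
    sd_fixed_floor: float = 1e-4
    controls_required: int = 3
    pseudocount: float = 1.0
    z_on_counts: bool = False
    germline_min_var_reads: int = 2

    def __post_init__(self) -> None:
        if self.min_q30_depth <= 0 or self.z_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 <= self.min_vaf_floor <= 1.0:
            raise ValueError("min_vaf_floor must lie in [0, 1]")
        if self.sd_floor_mode not in {"binomial", "fixed"}:
            raise ValueError("sd_floor_mode must be 'binomial' or 'fixed'")
        if self.controls_required < 1:
            raise ValueError("controls_required must be >= 1")


@dataclass(frozen=True)
class ControlNull:
    """Empirical null for one site: background VAF across reference samples."""

    mean_vaf: float
    sd_vaf: float  # already floored
    n_controls: int
    pooled_error: float

    def __post_init__(self) -> None:
        if self.sd_vaf < 0 or self.n_controls < 1:
            raise ValueError("invalid control null")
        if not 0.0 < self.pooled_error < 1.0:
            raise ValueError("pooled_error must lie in (0, 1)")


@dataclass
class ValidationResult:
    site: Site
    status: str
    sector_z: dict[str, float] = field(default_factory=dict)
    sector_vaf: dict[str, float] = field(default_factory=dict)
    present: dict[str, bool] = field(default_factory=dict)
    provenance: str = ""

    @property
    def present_sectors(self) -> list[str]:
        return sorted(s for s, p in self.present.items() if p)


def _null_from_values(
    values: list[SiteCounts], config: ValidationConfig
) -> ControlNull:
    if config.z_on_counts:
        obs = np.array([c.var_reads for c in values], dtype=float)
    else:
        obs = np.array([c.vaf for c in values], dtype=float)
    depths = np.array([c.q30_depth for c in values], dtype=float)
    mean = float(np.mean(obs))
    sd = float(np.std(obs, ddof=1)) if len(obs) > 1 else 0.0
    total_var = sum(c.var_reads for c in values)
    total_depth = sum(c.q30_depth for c in values)
    pooled = (total_var + config.pseudocount) / (total_depth + 2 * config.pseudocount)
    med_depth = float(np.median(depths))
    if config.sd_floor_mode == "binomial":
        # the Z statistic compares an observation against a mean estimated
        # from few reference samples, so the floor carries both the
        # observation's binomial noise and the reference mean's (1 + 1/n)
        n_ref = len(values)
        infl = math.sqrt(1.0 + 1.0 / n_ref) if n_ref > 0 else 1.0
        if config.z_on_counts:
            floor = infl * math.sqrt(max(pooled * (1.0 - pooled) * med_depth, 0.0))
        else:
            floor = infl * math.sqrt(max(pooled * (1.0 - pooled) / max(med_depth, 1.0), 0.0))
    else:
        floor = config.sd_fixed_floor
    return ControlNull(mean, max(sd, floor), len(values) - 1 if len(values) > 1 else 1, pooled)


def build_control_null(
    normal: SiteCounts, controls: list[SiteCounts], config: ValidationConfig | None = None
) -> ControlNull:
    """Null from the matched normal plus the negative controls at one site."""
    config = config or ValidationConfig()
    if len(controls) < config.controls_required:
        raise ValueError(
            f"need >= {config.controls_required} control samples, got {len(controls)}"
        )
    null = _null_from_values([normal] + list(controls), config)
    return ControlNull(null.mean_vaf, null.sd_vaf, len(controls), null.pooled_error)


def z_score(sector: SiteCounts, null: ControlNull, config: ValidationConfig | None = None) -> float:
    """Signed Z of a sector's observation against the control null."""
    config = config or ValidationConfig()
    if sector.q30_depth == 0:
        return float("nan")
    obs = sector.var_reads if config.z_on_counts else sector.vaf
    return (obs - null.mean_vaf) / null.sd_vaf


def depth_filter(
    counts: dict[str, SiteCounts],
    sectors: list[str],
    normal_id: str,
    config: ValidationConfig | None = None,
) -> tuple[bool, str]:
    """Coverage criterion: q30 depth >= threshold in normal and every sector."""
    config = config or ValidationConfig()
    required = [normal_id] + list(sectors)
    for sample in required:
        if sample not in counts:
            return False, "missing_data"
    for sample in required:
        if counts[sample].q30_depth < config.min_q30_depth:
            return False, f"low_coverage:{sample}"
    return True, ""


def adjudicate(
    site: Site,
    counts: dict[str, SiteCounts],
    sectors: list[str],
    normal_id: str,
    control_ids: list[str],
    config: ValidationConfig | None = None,
) -> ValidationResult:
    """Full per-mutation decision; see the module docstring for the rules."""
    config = config or ValidationConfig()
    ok, why = depth_filter(counts, sectors, normal_id, config)
    if not ok:
        return ValidationResult(site, "not_assessable", provenance=why)
    if len(control_ids) < config.controls_required:
        raise ValueError("fewer control samples than required")

    reference_ids = [normal_id] + list(control_ids)
    reference = [counts[i] for i in reference_ids if i in counts]
    if len(reference) < 1 + config.controls_required:
        return ValidationResult(site, "not_assessable", provenance="missing_data")

    null = build_control_null(counts[normal_id], [counts[i] for i in control_ids], config)

    zs: dict[str, float] = {}
    vafs: dict[str, float] = {}
    present: dict[str, bool] = {}
    for s in sectors:
        c = counts[s]
        z = z_score(c, null, config)
        zs[s] = z
        vafs[s] = c.vaf
        present[s] = bool(z > config.z_threshold and c.vaf >= config.min_vaf_floor)

    # germline adjudication: the same Z rule applied to each reference
    # sample against a null built from the remaining reference samples
    for i, rid in enumerate(reference_ids):
        others = [counts[r] for j, r in enumerate(reference_ids) if j != i]
        loo_null = _null_from_values(others, config)
        z_ref = z_score(counts[rid], loo_null, config)
        if z_ref > config.z_threshold and counts[rid].var_reads >= config.germline_min_var_reads:
            return ValidationResult(
                site, "germline_like", zs, vafs, {s: False for s in sectors},
                provenance=f"variant_in_reference:{rid}",
            )

    if any(present.values()):
        return ValidationResult(site, "confirmed", zs, vafs, present, provenance="z_rule")
    return ValidationResult(site, "absent", zs, vafs, present, provenance="no_sector_above_null")


def validate_panel(
    panel: CountsPanel,
    sites: list[Site] | None = None,
    config: ValidationConfig | None = None,
) -> tuple[dict[Site, ValidationResult], list[str]]:
    """Adjudicate every (requested) site of a tier-2 panel.

    Returns results keyed by site plus a run log recording which filter
    removed each failed mutation.
    """
    config = config or ValidationConfig()
    tier2 = panel.tier("tier2")
    normal_id = tier2.normal_id
    if normal_id is None:
        raise ValueError("tier-2 panel has no matched normal sample")
    control_ids = tier2.controls
    sectors = tier2.sectors
    wanted = set(sites) if sites is not None else None
    results: dict[Site, ValidationResult] = {}
    log: list[str] = []
    for site, counts in tier2.iter_sites():
        if wanted is not None and site not in wanted:
            continue
        res = adjudicate(site, counts, sectors, normal_id, control_ids, config)
        results[site] = res
        if res.status == "not_assessable":
            log.append(f"{site.label()}\tnot_assessable\t{res.provenance}")
        elif res.status == "germline_like":
            log.append(f"{site.label()}\tgermline_like\t{res.provenance}")
        elif res.status == "absent":
            log.append(f"{site.label()}\tabsent\t{res.provenance}")
    n = len(results)
    n_drop = sum(1 for r in results.values() if r.status != "confirmed")
    log.append(f"# {n} sites assayed, {n - n_drop} confirmed, {n_drop} removed")
    return results, log


def results_to_frame(results: dict[Site, ValidationResult]):
    """Validation TSV shape: locus, status, per-sector Z / VAF / present."""
    import pandas as pd

    rows = []
    for site, r in results.items():
        row: dict = {
            "chrom": site.chrom,
            "pos": site.pos,
            "ref": site.ref,
            "alt": site.alt,
            "status": r.status,
            "provenance": r.provenance,
        }
        for s in sorted(r.sector_z):
            row[f"{s}_z"] = r.sector_z[s]
            row[f"{s}_vaf"] = r.sector_vaf[s]
            row[f"{s}_present"] = int(r.present[s])
        rows.append(row)
    return pd.DataFrame(rows)
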