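"""End-to-end orchestration: simulate -> discover -> validate -> clonality
-> summarize -> phylogeny.

Glues the stage modules together for the common case of one tumor with a
matched normal and negative controls, either simulated or loaded from
counts TSVs.  Each stage remains usable on its own; this module only
handles the bookkeeping between them (restricting matrices to confirmed
mutations, building VAF matrices, wiring purity profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import clonality as clonality_mod
from . import metrics, phylogeny
from .discovery import CallerConfig, MutationRecord, discover
from .io import CountsPanel, Site
from .simulate import SimConfig, SimTruth, simulate_dataset
from .validation import ValidationConfig, ValidationResult, validate_panel

__all__ = ["PipelineResult", "run_counts_pipeline", "run_simulated_pipeline"]


@dataclass
class PipelineResult:
    records: list[MutationRecord]
    validation: dict[Site, ValidationResult]
    validation_log: list[str]
    presence_tier1: pd.DataFrame  # confirmed mutations x sectors
    presence_tier2: pd.DataFrame
    vaf_tier2: pd.DataFrame
    labels_tier2: pd.Series
    clonality_calls: list
    early_intermixing: bool
    intermixed_mutations: list
    summary: pd.Series | None
    tree: phylogeny.SectorTree | None
    newick: str | None
    truth: SimTruth | None = None
    panel: CountsPanel | None = None


def _confirmed_matrices(
    records: list[MutationRecord],
    results: dict[Site, ValidationResult],
    sectors: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tier-1 calls, tier-2 presence, and tier-2 VAFs over confirmed mutations."""
    rows1, rows2, vafs, index = [], [], [], []
    by_site = {r.site: r for r in records}
    for site, res in results.items():
        if res.status != "confirmed":
            continue
        rec = by_site[site]
        index.append(site.label())
        rows1.append([int(rec.sector_called.get(s, False)) for s in sectors])
        rows2.append([int(res.present.get(s, False)) for s in sectors])
        vafs.append([res.sector_vaf.get(s, float("nan")) for s in sectors])
    idx = pd.Index(index, name="mutation")
    t1 = pd.DataFrame(rows1, index=idx, columns=sectors)
    t2 = pd.DataFrame(rows2, index=idx, columns=sectors)
    vf = pd.DataFrame(vafs, index=idx, columns=sectors)
    order = t1.index.sort_values()
    return t1.loc[order], t2.loc[order], vf.loc[order]


def run_counts_pipeline(
    panel: CountsPanel,
    profiles: dict[str, clonality_mod.SectorProfile] | None = None,
    caller_config: CallerConfig | None = None,
    validation_config: ValidationConfig | None = None,
    tolerance: float = 0.5,
    min_intermix_sectors: int = 2,
    footprint_mb: float | None = None,
    outgroup: str = "N",
    truth: SimTruth | None = None,
) -> PipelineResult:
    """Run discovery through phylogeny on an assembled two-tier counts panel.

    Without explicit ``profiles``, per-sector purity is estimated from the
    truncal mutations' tier-2 VAFs (diploid assumption) — adequate for
    copy-quiet genomes, otherwise supply external profiles.

    The tumor-level early-intermixing flag requires a truncal mutation to
    be subclonal in at least ``min_intermix_sectors`` sectors; the default
    of two matches the multi-sector pattern that defines the phenomenon
    and keeps the flag robust to a single noise-driven presence call.
    """
    records = discover(panel, caller_config)
    sites = [r.site for r in records]
    results, log = validate_panel(panel, sites=sites, config=validation_config)
    sectors = panel.tier("tier2").sectors

    t1, t2, vf = _confirmed_matrices(records, results, sectors)
    empty = t1.empty
    labels = (
        metrics.classify_sharing(metrics.PresenceMatrix(t2, tier="tier2"))
        if not empty
        else pd.Series(dtype=object)
    )

    calls: list = []
    flag, mixed = False, []
    summary = None
    tree = None
    newick = None
    if not empty:
        if profiles is None:
            profiles = {}
            truncal = labels[labels == "truncal"].index
            for s in sectors:
                vafs = [vf.loc[m, s] for m in truncal if t2.loc[m, s]]
                if len(vafs) >= 3:
                    purity, _ = clonality_mod.estimate_purity_from_truncal(vafs)
                else:  # fall back to an uninformative profile
                    purity = 1.0
                profiles[s] = clonality_mod.SectorProfile(s, purity=max(purity, 1e-3))
        calls = clonality_mod.assess_clonality(
            t2, vf, labels, profiles, tolerance=tolerance
        )
        flag, mixed = clonality_mod.detect_early_intermixing(calls, min_intermix_sectors)
        summary = metrics.summarize_tumor(
            metrics.PresenceMatrix(t1, tier="tier1"),
            metrics.PresenceMatrix(t2, tier="tier2"),
            intermixing=flag,
            footprint_mb=footprint_mb,
        )
        if len(sectors) >= 2:
            cm = phylogeny.presence_to_character_matrix(t2, outgroup=outgroup)
            tree = phylogeny.best_tree(cm)
            newick = phylogeny.to_newick(tree)

    return PipelineResult(
        records=records,
        validation=results,
        validation_log=log,
        presence_tier1=t1,
        presence_tier2=t2,
        vaf_tier2=vf,
        labels_tier2=labels,
        clonality_calls=calls,
        early_intermixing=flag,
        intermixed_mutations=mixed,
        summary=summary,
        tree=tree,
        newick=newick,
        truth=truth,
        panel=panel,
    )


def run_simulated_pipeline(
    config: SimConfig,
    use_true_purity: bool = True,
    **kwargs,
) -> PipelineResult:
    """Simulate one tumor and push it through the whole pipeline.

    ``use_true_purity`` wires the generator's per-sector purity into the
    clonality stage (standing in for an external purity/copy-number
    estimate); otherwise purity is re-estimated from truncal VAFs.
    """
    truth, panel = simulate_dataset(config)
    profiles = None
    if use_true_purity:
        profiles = {
            s: clonality_mod.SectorProfile(s, purity=float(truth.sector_purity[s]))
            for s in truth.sector_ids
        }
    return run_counts_pipeline(panel, profiles=profiles, truth=truth, **kwargs)
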