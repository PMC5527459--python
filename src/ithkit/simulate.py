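"""Synthetic multiregion tumor generator.

Emulates the study design the rest of the package analyses: a clone
phylogeny with somatic mutations on its edges, five-ish spatially separated
tumor sectors that each sample a mixture of clones, a matched normal, and a
trio of error-only negative-control samples.  Read counts are drawn at two
sequencing tiers — deep hybrid-capture discovery (~384x) and ultra-deep
amplicon validation (~17 075x) — under a binomial read-sampling model with
a symmetric per-base error rate.

The generator keeps full ground truth (clone tree, mutation placement,
sector clone fractions, per-sector cancer-cell fractions) so every
downstream stage can be scored against what was actually planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import PANEL_COLUMNS, CountsPanel, Site

__all__ = [
    "CloneTree",
    "SimConfig",
    "SimTruth",
    "simulate_clone_tree",
    "assign_mutations",
    "compose_sectors",
    "ccf_from_fractions",
    "simulate_counts",
    "simulate_dataset",
    "simulate_null_panel",
]

# stage tags used to derive independent RNG substreams from the master seed
_STAGES = {"tree": 11, "mutations": 23, "sectors": 37, "tier1": 53, "tier2": 71, "null": 89}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


@dataclass(frozen=True)
class CloneTree:
    """Rooted clone phylogeny; node 0 is the founding (truncal) clone.

    Every non-root clone is identified with the tree edge leading into it,
    so "a mutation on edge c" means it arose on the branch from c's parent
    to c and is carried by clone c and all its descendants.  Mutations on
    the root are truncal: every malignant cell carries them.
    """

    graph: nx.DiGraph
    root: int = 0

    def __post_init__(self) -> None:
        g = self.graph
        if self.root not in g:
            raise ValueError("root missing from clone tree")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("clone tree must be acyclic")
        for n in g.nodes:
            indeg = g.in_degree(n)
            if n == self.root and indeg != 0:
                raise ValueError("root must have no parent")
            if n != self.root and indeg != 1:
                raise ValueError(f"clone {n} must have exactly one parent")
        if g.number_of_nodes() > 1 and not nx.is_weakly_connected(g):
            raise ValueError("clone tree must be connected")

    @property
    def clones(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_clones(self) -> int:
        return self.graph.number_of_nodes()

    def children(self, clone: int) -> list[int]:
        return sorted(self.graph.successors(clone))

    def parent(self, clone: int) -> int | None:
        preds = list(self.graph.predecessors(clone))
        return preds[0] if preds else None

    def subtree(self, clone: int) -> set[int]:
        """Clone plus all of its descendants."""
        return {clone} | nx.descendants(self.graph, clone)

    def path_to_root(self, clone: int) -> list[int]:
        """Clones from the root down to ``clone`` inclusive."""
        path = [clone]
        while (p := self.parent(path[-1])) is not None:
            path.append(p)
        return path[::-1]

    def edges(self) -> list[tuple[int, int]]:
        return sorted(self.graph.edges)

    def to_newick(self) -> str:
        def rec(n: int) -> str:
            ch = self.children(n)
            if not ch:
                return f"c{n}"
            return "(" + ",".join(rec(c) for c in ch) + f")c{n}"

        return rec(self.root) + ";"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic tumor.

    Depth means mirror the two sequencing tiers of the emulated design
    (deep hybrid-capture discovery, ultra-deep amplicon validation).  The
    purity range spans the moderately contaminated resection sectors such a
    study works with.  ``mixing_concentration`` is the Dirichlet
    concentration for non-dominant resident clones of a sector;
    ``dominance_boost`` multiplies it for the sector's dominant clone so
    that each sector has a clear majority lineage.  ``intermix_fraction``
    selects the fraction of sectors seeded with a minor-fraction ancestral
    subclone (at clone fraction ``intermix_ccf``), the generative analogue
    of early subclone intermixing.
    """

    n_sectors: int = 5
    n_clones: int = 6
    n_mutations: int = 100
    truncal_fraction: float = 0.5
    depth_tier1_mean: float = 384.0
    depth_tier2_mean: float = 17075.0
    base_error_rate: float = 1e-3
    purity_range: tuple[float, float] = (0.4, 0.9)
    mixing_concentration: float = 1.5
    dominance_boost: float = 8.0
    intermix_fraction: float = 0.0
    intermix_ccf: float = 0.05
    guaranteed_share: tuple[float, float] = (0.20, 0.35)
    q30_fraction: float = 0.95
    depth_dispersion: float | None = None
    n_controls: int = 3
    cn_overrides: dict[int, tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sectors < 1 or self.n_clones < 1 or self.n_mutations < 0:
            raise ValueError("counts must be >= 1 (mutations >= 0)")
        for r in (self.base_error_rate, self.intermix_fraction, self.truncal_fraction, self.q30_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must be a subinterval of (0, 1]")
        if self.mixing_concentration <= 0 or self.dominance_boost <= 0:
            raise ValueError("concentration parameters must be positive")
        if not 0.0 < self.intermix_ccf < 0.5:
            raise ValueError("intermix_ccf must be a minor fraction in (0, 0.5)")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")


@dataclass
class SimTruth:
    """Generator-side ground truth for one synthetic tumor.

    ``sector_fractions`` rows sum to one: fractions are of *malignant*
    cells, so the cancer-cell fraction (CCF) of a mutation in a sector is
    the summed fraction of clones descending from (and including) the clone
    whose edge carries it.
    """

    clone_tree: CloneTree
    mutation_edge: dict[str, int]
    sector_fractions: pd.DataFrame  # sectors x clones
    sector_purity: pd.Series  # per sector
    ccf: pd.DataFrame  # mutations x sectors
    cn_total: pd.DataFrame  # mutations x sectors, total copies
    multiplicity: pd.DataFrame  # mutations x sectors, mutated-allele copies
    sites: dict[str, Site]  # mutation id -> synthetic locus
    intermix_clone: int | None = None

    @property
    def mutations(self) -> list[str]:
        return list(self.ccf.index)

    @property
    def sector_ids(self) -> list[str]:
        return list(self.ccf.columns)

    def truncal_by_presence(self) -> pd.Series:
        """True where a mutation has CCF > 0 in every sector."""
        return (self.ccf > 0).all(axis=1)

    def expected_vaf(self, base_error_rate: float = 0.0) -> pd.DataFrame:
        """Closed-form expected VAF per mutation and sector.

        VAF = purity * ccf * multiplicity / (purity * cn_total + 2 (1 - purity)),
        then mixed with the symmetric per-base error rate.
        """
        pur = self.sector_purity.reindex(self.ccf.columns)
        denom = self.cn_total.mul(pur, axis=1) + 2.0 * (1.0 - pur)
        p = (self.ccf * self.multiplicity).mul(pur, axis=1) / denom
        e = base_error_rate
        return p * (1.0 - e) + (1.0 - p) * e


def simulate_clone_tree(n_clones: int, seed: int = 0) -> CloneTree:
    """Sample a uniformly random rooted labelled tree over ``n_clones``.

    Uses a random Pruefer sequence (uniform over labelled trees) rooted at
    clone 0.  Deterministic given ``seed``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    g = nx.DiGraph()
    g.add_node(0)
    if n_clones == 1:
        return CloneTree(g)
    if n_clones == 2:
        g.add_edge(0, 1)
        return CloneTree(g)
    rng = _rng(seed, "tree")
    prufer = rng.integers(0, n_clones, size=n_clones - 2)
    undirected = nx.from_prufer_sequence(list(int(x) for x in prufer))
    directed = nx.bfs_tree(undirected, 0)
    return CloneTree(directed)


def assign_mutations(
    tree: CloneTree, n_mutations: int, truncal_fraction: float, seed: int = 0
) -> dict[str, int]:
    """Place mutations on clone-tree edges.

    ``ceil(truncal_fraction * n_mutations)`` mutations go on the root
    (truncal); the remainder are spread uniformly over non-root clones.
    Mutation ids are zero-padded ``m0001``-style strings.
    """
    if not 0.0 <= truncal_fraction <= 1.0:
        raise ValueError("truncal_fraction must lie in [0, 1]")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if n_mutations == 0:
        return {}
    n_truncal = math.ceil(truncal_fraction * n_mutations)
    non_root = [c for c in tree.clones if c != tree.root]
    if n_truncal < n_mutations and not non_root:
        raise ValueError("tree has no non-root edges for non-truncal mutations")
    rng = _rng(seed, "mutations")
    width = max(4, len(str(n_mutations)))
    out: dict[str, int] = {}
    for i in range(n_mutations):
        mid = f"m{i + 1:0{width}d}"
        if i < n_truncal:
            out[mid] = tree.root
        else:
            out[mid] = int(rng.choice(non_root))
    return out


def ccf_from_fractions(
    tree: CloneTree, mutation_edge: dict[str, int], sector_fractions: pd.DataFrame
) -> pd.DataFrame:
    """Cancer-cell fraction of each mutation in each sector.

    The CCF of a mutation carried by clone ``c`` is the summed malignant
    fraction of ``c`` and all of its descendants present in the sector.
    """
    subtree_cols: dict[int, list[int]] = {}
    ccf = {}
    for mid, clone in mutation_edge.items():
        if clone not in subtree_cols:
            subtree_cols[clone] = sorted(tree.subtree(clone) & set(sector_fractions.columns))
        ccf[mid] = sector_fractions[subtree_cols[clone]].sum(axis=1)
    df = pd.DataFrame(ccf).T.clip(lower=0.0, upper=1.0)  # guard float drift
    df.index.name = "mutation"
    return df.reindex(sorted(mutation_edge))


def _synthetic_sites(mutations: list[str]) -> dict[str, Site]:
    # evenly spaced loci on one synthetic contig; alleles are arbitrary SNVs
    return {
        mid: Site("chr1", 10_000 + 100 * i, "A", "T") for i, mid in enumerate(mutations)
    }


def compose_sectors(tree: CloneTree, config: SimConfig) -> SimTruth:
    """Draw sector clone mixtures, purities and copy states; derive CCFs.

    Each sector is anchored by a *dominant* clone and contains the clones on
    the root-to-dominant path, with Dirichlet-distributed fractions in which
    the dominant clone's concentration is boosted.  Dominant clones are
    sampled without replacement so that (when sectors permit) every clone
    lineage is sampled somewhere; clones still left uncovered are patched
    into a sector as a guaranteed-minor resident so no planted mutation is
    unobservable.  When a non-root clone would end up present in every
    sector by accident, one sector is reassigned to pure founder-clone
    composition so that only root-edge mutations are ubiquitous (the
    deliberate exception is the intermixed ancestral subclone).
    """
    rng = _rng(config.seed, "sectors")
    clones = tree.clones
    root = tree.root
    non_root = [c for c in clones if c != root]
    S = config.n_sectors
    sector_ids = [chr(ord("A") + i) if S <= 26 else f"S{i+1}" for i in range(S)]

    mutation_edge = assign_mutations(
        tree, config.n_mutations, config.truncal_fraction, config.seed
    )

    def draw_dominants(reserve_founder_sector: bool) -> list[int]:
        slots = list(range(S))
        doms: list[int] = [root] * S
        if reserve_founder_sector:
            slots = slots[1:]
        perm = list(rng.permutation(non_root)) if non_root else []
        for i, slot in enumerate(slots):
            if i < len(perm):
                doms[slot] = int(perm[i])
            elif non_root:
                doms[slot] = int(rng.choice(non_root))
        return doms

    def build_members(doms: list[int], reserve_founder_sector: bool):
        members = [set(tree.path_to_root(d)) for d in doms]
        covered = set().union(*members)
        uncovered = [c for c in non_root if c not in covered]
        patch_slots = [i for i in range(S) if not (reserve_founder_sector and i == 0)]
        patched: list[list[int]] = [[] for _ in range(S)]
        for j, c in enumerate(uncovered):
            slot = patch_slots[int(rng.integers(len(patch_slots)))] if patch_slots else 0
            members[slot].add(c)
            patched[slot].append(c)
        return members, patched

    def violates(members: list[set[int]]) -> bool:
        # a non-root clone whose lineage touches every sector would fake truncality
        for c in non_root:
            sub = tree.subtree(c)
            if all(sub & m for m in members):
                return True
        return False

    doms = draw_dominants(reserve_founder_sector=False)
    members, patched = build_members(doms, False)
    founder_reserved = False
    if S >= 2 and violates(members):
        founder_reserved = True
        doms = draw_dominants(reserve_founder_sector=True)
        members, patched = build_members(doms, True)

    # intermixing: seed an early subclone at minor fraction into selected
    # sectors where its lineage is not already resident.  The clone chosen
    # is the one natively sampled in the fewest sectors (ties: shallowest,
    # then lowest id), which maximizes the planted truncal-but-subclonal
    # signal.
    intermix_clone: int | None = None
    if config.intermix_fraction > 0 and non_root:
        def native_coverage(c: int) -> int:
            sub = tree.subtree(c)
            return sum(1 for m in members if sub & m)

        intermix_clone = min(
            non_root, key=lambda c: (native_coverage(c), len(tree.path_to_root(c)), c)
        )
    k_intermix = int(round(config.intermix_fraction * S))
    intermix_sectors: list[int] = []
    minor: list[list[int]] = [[] for _ in range(S)]
    if intermix_clone is not None and k_intermix > 0:
        order = list(rng.permutation(S))
        intermix_sectors = sorted(order[:k_intermix])
        sub = tree.subtree(intermix_clone)
        for i in intermix_sectors:
            if not (sub & members[i]):
                members[i].add(intermix_clone)
                minor[i].append(intermix_clone)

    lo_g, hi_g = config.guaranteed_share
    frac = pd.DataFrame(0.0, index=sector_ids, columns=clones)
    for i, sid in enumerate(sector_ids):
        fixed: dict[int, float] = {}
        for c in minor[i]:
            fixed[c] = config.intermix_ccf
        n_patch = len(patched[i])
        if n_patch:
            shares = rng.uniform(lo_g, hi_g, size=n_patch)
            budget = 1.0 - sum(fixed.values())
            # keep guaranteed residents within half the remaining mass
            scale = min(1.0, 0.5 * budget / shares.sum())
            for c, s in zip(patched[i], shares * scale):
                fixed[c] = float(s)
        path_clones = sorted(members[i] - set(fixed))
        alphas = np.array(
            [
                config.mixing_concentration * (config.dominance_boost if c == doms[i] else 1.0)
                for c in path_clones
            ]
        )
        w = rng.dirichlet(alphas) if len(path_clones) > 1 else np.array([1.0])
        remainder = 1.0 - sum(fixed.values())
        for c, wi in zip(path_clones, w):
            frac.loc[sid, c] = remainder * float(wi)
        for c, s in fixed.items():
            frac.loc[sid, c] = s
    frac.index.name = "sector"

    lo_p, hi_p = config.purity_range
    purity = pd.Series(rng.uniform(lo_p, hi_p, size=S), index=sector_ids, name="purity")

    ccf = ccf_from_fractions(tree, mutation_edge, frac) if mutation_edge else pd.DataFrame(
        index=pd.Index([], name="mutation"), columns=sector_ids, dtype=float
    )
    if not mutation_edge:
        ccf = ccf.reindex(columns=sector_ids)

    muts = sorted(mutation_edge)
    cn_total = pd.DataFrame(2, index=muts, columns=sector_ids)
    mult = pd.DataFrame(1, index=muts, columns=sector_ids)
    if config.cn_overrides:
        for idx, (total, m) in config.cn_overrides.items():
            if not 1 <= m <= total:
                raise ValueError("need 1 <= multiplicity <= total copies")
            mid = muts[idx]
            cn_total.loc[mid, :] = total
            mult.loc[mid, :] = m

    return SimTruth(
        clone_tree=tree,
        mutation_edge=mutation_edge,
        sector_fractions=frac,
        sector_purity=purity,
        ccf=ccf,
        cn_total=cn_total,
        multiplicity=mult,
        sites=_synthetic_sites(muts),
        intermix_clone=intermix_clone if intermix_sectors else None,
    )


def _draw_depths(rng: np.random.Generator, mean: float, size: int, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean, size=size)
    # gamma-Poisson (negative binomial) with variance mean * (1 + mean/dispersion)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def simulate_counts(truth: SimTruth, config: SimConfig, tier: str) -> CountsPanel:
    """Draw read counts for every sample at every mutation site at one tier.

    Depths are Poisson around the tier mean (negative binomial when
    ``depth_dispersion`` is set); quality-filtered depth is a fixed fraction
    of the total; variant reads are binomial at the closed-form expected VAF
    mixed with the symmetric error rate.  Normal and control samples draw at
    the error-only fraction.  Controls are sequenced in the validation run
    only, so they appear in the tier-2 panel alone.
    """
    if tier not in {"tier1", "tier2"}:
        raise ValueError(f"tier must be tier1 or tier2, got {tier!r}")
    rng = _rng(config.seed, tier)
    mean_depth = config.depth_tier1_mean if tier == "tier1" else config.depth_tier2_mean
    e = config.base_error_rate

    samples: list[tuple[str, str]] = [(s, "sector") for s in truth.sector_ids]
    samples.append(("N", "normal"))
    if tier == "tier2":
        samples += [(f"CTRL{i+1}", "control") for i in range(config.n_controls)]

    p_true = truth.expected_vaf(base_error_rate=0.0)
    muts = truth.mutations
    rows = []
    for sample_id, role in samples:
        n = len(muts)
        total = _draw_depths(rng, mean_depth, n, config.depth_dispersion)
        q30 = np.round(config.q30_fraction * total).astype(int)
        if role == "sector":
            p = p_true[sample_id].to_numpy(dtype=float)
        else:
            p = np.zeros(n)
        p_eff = p * (1.0 - e) + (1.0 - p) * e
        var = rng.binomial(q30, p_eff)
        for j, mid in enumerate(muts):
            site = truth.sites[mid]
            rows.append(
                (
                    sample_id,
                    role,
                    tier,
                    site.chrom,
                    site.pos,
                    site.ref,
                    site.alt,
                    int(var[j]),
                    int(q30[j]),
                    int(total[j]),
                )
            )
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return CountsPanel(df)


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, CountsPanel]:
    """Full generator: clone tree -> mutations -> sectors -> both count tiers."""
    tree = simulate_clone_tree(config.n_clones, config.seed)
    truth = compose_sectors(tree, config)
    panel1 = simulate_counts(truth, config, "tier1")
    panel2 = simulate_counts(truth, config, "tier2")
    df = pd.concat([panel1.df, panel2.df], ignore_index=True)
    return truth, CountsPanel(df)


def simulate_null_panel(
    n_sites: int,
    config: SimConfig | None = None,
    seed: int = 0,
    tier: str = "tier2",
) -> CountsPanel:
    """Error-only panel: no mutation anywhere, for specificity studies."""
    config = config or SimConfig()
    rng = _rng(seed, "null")
    mean_depth = config.depth_tier1_mean if tier == "tier1" else config.depth_tier2_mean
    e = config.base_error_rate
    sector_ids = [chr(ord("A") + i) for i in range(config.n_sectors)]
    samples = [(s, "sector") for s in sector_ids] + [("N", "normal")]
    samples += [(f"CTRL{i+1}", "control") for i in range(config.n_controls)]
    rows = []
    for sample_id, role in samples:
        total = _draw_depths(rng, mean_depth, n_sites, config.depth_dispersion)
        q30 = np.round(config.q30_fraction * total).astype(int)
        var = rng.binomial(q30, e)
        for j in range(n_sites):
            rows.append(
                (sample_id, role, tier, "chrN", 1_000 + j, "A", "T", int(var[j]), int(q30[j]), int(total[j]))
            )
    return CountsPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))


# ----------------------------------------------------------------------
# truth serialization


def write_truth(truth: SimTruth, outdir) -> None:
    """Write ground truth as Newick + TSV tables under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "clone_tree.nwk").write_text(truth.clone_tree.to_newick() + "\n")
    edge = pd.DataFrame(
        {"mutation": list(truth.mutation_edge), "clone": list(truth.mutation_edge.values())}
    )
    edge.to_csv(outdir / "mutation_edges.tsv", sep="\t", index=False)
    truth.sector_fractions.to_csv(outdir / "sector_fractions.tsv", sep="\t")
    truth.sector_purity.to_frame().to_csv(outdir / "sector_purity.tsv", sep="\t")
    truth.ccf.to_csv(outdir / "ccf.tsv", sep="\t")
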