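"""Tabular input/output for multiregion sequencing data.

The central interchange format is a *counts panel*: a tidy, tab-separated
table with one row per (sample, site, sequencing tier) holding variant and
total read counts.  All pipeline stages consume and produce plain TSV so
that intermediate results stay inspectable with standard shell tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import pandas as pd

#: columns of the counts-panel TSV, in order
PANEL_COLUMNS = [
    "sample_id",
    "sample_role",
    "tier",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_reads",
    "q30_depth",
    "total_depth",
]

ROLES = {"sector", "normal", "control"}
TIERS = {"tier1", "tier2"}


class SiteCounts(NamedTuple):
    """Read counts for one sample at one candidate site.

    ``q30_depth`` is the coverage restricted to bases with quality >= 30;
    the variant-read count is taken from that same high-quality subset, so
    ``0 <= var_reads <= q30_depth <= total_depth`` always holds.
    """

    var_reads: int
    q30_depth: int
    total_depth: int

    @property
    def vaf(self) -> float:
        """Variant allele frequency over quality-filtered depth."""
        if self.q30_depth == 0:
            return float("nan")
        return self.var_reads / self.q30_depth


class Site(NamedTuple):
    """Genomic identity of a candidate mutation (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CountsPanel:
    """Site-by-sample read counts for one tumor at one or both tiers.

    Wraps a tidy DataFrame in the ``PANEL_COLUMNS`` dialect and provides
    role/tier views.  Invariants are checked on construction.
    """

    df: pd.DataFrame
    _role_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"counts panel missing columns: {missing}")
        self.df = self.df[PANEL_COLUMNS].reset_index(drop=True)
        bad_role = set(self.df["sample_role"]) - ROLES
        if bad_role:
            raise ValueError(f"unknown sample roles: {bad_role}")
        bad_tier = set(self.df["tier"]) - TIERS
        if bad_tier:
            raise ValueError(f"unknown tiers: {bad_tier}")
        v, q, t = (self.df[c] for c in ("var_reads", "q30_depth", "total_depth"))
        if ((v < 0) | (v > q) | (q > t)).any():
            raise ValueError("count invariant violated: need 0 <= var <= q30 <= total")

    # -- views ---------------------------------------------------------

    def tier(self, tier: str) -> "CountsPanel":
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r}")
        return CountsPanel(self.df[self.df["tier"] == tier].reset_index(drop=True))

    def samples(self, role: str | None = None) -> list[str]:
        df = self.df
        if role is not None:
            df = df[df["sample_role"] == role]
        return sorted(df["sample_id"].unique())

    @property
    def sectors(self) -> list[str]:
        return self.samples("sector")

    @property
    def normal_id(self) -> str | None:
        ids = self.samples("normal")
        return ids[0] if ids else None

    @property
    def controls(self) -> list[str]:
        return self.samples("control")

    def sites(self) -> list[Site]:
        cols = ["chrom", "pos", "ref", "alt"]
        uniq = self.df[cols].drop_duplicates()
        return sorted(
            (Site(str(c), int(p), str(r), str(a)) for c, p, r, a in uniq.itertuples(index=False)),
            key=lambda s: (s.chrom, s.pos, s.ref, s.alt),
        )

    def iter_sites(self) -> Iterator[tuple[Site, dict[str, SiteCounts]]]:
        """Yield each site with its per-sample counts mapping."""
        for key, sub in self.df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
            site = Site(str(key[0]), int(key[1]), str(key[2]), str(key[3]))
            counts = {
                row.sample_id: SiteCounts(int(row.var_reads), int(row.q30_depth), int(row.total_depth))
                for row in sub.itertuples(index=False)
            }
            yield site, counts

    def counts(self, sample_id: str, site: Site) -> SiteCounts | None:
        sub = self.df[
            (self.df["sample_id"] == sample_id)
            & (self.df["chrom"] == site.chrom)
            & (self.df["pos"] == site.pos)
            & (self.df["ref"] == site.ref)
            & (self.df["alt"] == site.alt)
        ]
        if sub.empty:
            return None
        row = sub.iloc[0]
        return SiteCounts(int(row.var_reads), int(row.q30_depth), int(row.total_depth))


def write_counts_tsv(panel: CountsPanel, path: str | Path) -> None:
    panel.df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> CountsPanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return CountsPanel(df)


def write_presence_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a mutation-by-sector binary presence matrix (rows = mutations)."""
    matrix.astype(int).to_csv(path, sep="\t", index=True, index_label="mutation")


def read_presence_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="mutation")
    return df.astype(int)


def read_vcf_counts(
    path: str | Path,
    role_map: dict[str, str],
    tier: str = "tier1",
    q30_fraction: float = 1.0,
) -> CountsPanel:
    """Build a counts panel from a VCF with per-sample AD/DP FORMAT fields.

    ``role_map`` maps VCF sample names to roles (sector/normal/control).
    VCFs carry no base-quality-stratified depth, so the q30 depth is
    approximated as ``q30_fraction * DP`` (capped below by AD).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading VCF requires the cyvcf2 package (ithkit[vcf])") from exc

    rows = []
    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    unknown = set(sample_names) - set(role_map)
    if unknown:
        raise ValueError(f"VCF samples without a role: {sorted(unknown)}")
    for rec in vcf:
        if not rec.ALT:
            continue
        alt = rec.ALT[0]
        ad = rec.format("AD")
        dp = rec.format("DP")
        if ad is None or dp is None:
            raise ValueError(f"site {rec.CHROM}:{rec.POS} lacks AD/DP fields")
        for i, name in enumerate(sample_names):
            var = int(ad[i][1]) if ad.shape[1] > 1 else 0
            depth = int(dp[i][0]) if dp.ndim > 1 else int(dp[i])
            q30 = max(var, int(round(q30_fraction * depth)))
            q30 = min(q30, depth)
            rows.append(
                {
                    "sample_id": name,
                    "sample_role": role_map[name],
                    "tier": tier,
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "var_reads": var,
                    "q30_depth": q30,
                    "total_depth": depth,
                }
            )
    return CountsPanel(pd.DataFrame(rows, columns=PANEL_COLUMNS))
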