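# ithkit

Analysis toolkit for **multiregion tumor sequencing** with a two-tier
design: deep targeted discovery of somatic mutations in several spatially
separated tumor sectors (~384× coverage), followed by ultra-deep amplicon
re-assay of every candidate in every sector (~17 000× coverage) against a
matched normal and negative-control samples. It is written for cancer
genomicists who want to quantify **intratumor heterogeneity (ITH)** —
which mutations are truncal (in every sector), branched, or private — and
to reconstruct each tumor's spatial history, without stitching together
one-off scripts.

## What it computes

* **Tier-1 discovery** — a transparent count-based somatic caller: a
  sector is called when VAF ≥ 2.5 %, variant reads ≥ 4, the one-sided
  binomial tail P(X ≥ var | depth, e) ≤ 10⁻⁶ against per-base error *e*,
  and the matched normal is deep and clean.
* **Tier-2 validation** — a control-anchored Z rule: the normal plus ≥ 3
  controls define a per-site background null (mean and sd of their VAFs,
  sd floored at binomial sampling noise); a sector supports the mutation
  when *Z* = (VAF − μ₀)/σ₀ > 3. Mutations are adjudicated
  confirmed / germline-like / absent / not-assessable (the latter when
  q30 coverage < 100× anywhere).
* **Clonality** — the expected VAF of a clonal mutation given sector
  purity *p*, local copies *C*ₜ and multiplicity *m*,
  `E[VAF] = m·p / (p·Cₜ + 2(1−p))`; observed VAFs far below both this
  minimum and the same-group median mark a mutation **subclonal** in that
  sector. Truncal-yet-subclonal mutations in ≥ 2 sectors raise the
  **early-intermixing** flag (ancestral subclones spatially mixed before
  later mutations arose).
* **ITH metrics** — percentage of non-truncal mutations per tier, the
  tier-1→tier-2 heterogeneity reduction, and discovery/validation
  concordance (true-positive and false-negative rates, new per-sector
  detections).
* **Phylogeny** — exact Wagner/Fitch parsimony over sector presence
  matrices with the normal as outgroup: exhaustive topology search
  ((2n−5)!! trees, guarded at 9 taxa), strict consensus over ties,
  mutation placement on edges, Newick output.
* **Simulator** — a fully ground-truthed multiregion tumor generator
  (clone tree, per-sector clone mixtures, purity, two sequencing tiers,
  matched normal, error-only controls) used to test every stage.

See `docs/methods.md` for the models and design choices in detail.

## Worked example

Simulate a five-sector tumor with 80 mutations in which an early subclone
was mixed into every sector at 5 % cell fraction, then run the full
analysis:

```python
from ithkit import SimConfig, run_simulated_pipeline

cfg = SimConfig(n_mutations=80, intermix_fraction=1.0, seed=7)
res = run_simulated_pipeline(cfg)
print(res.summary.to_string())
print("early intermixing:", res.early_intermixing)
print("newick:", res.newick)
```

prints

```
n_heterogeneous_tier1        39
n_total_tier1                79
pct_heterogeneous_tier1    49.4
n_heterogeneous_tier2        35
n_total_tier2                79
pct_heterogeneous_tier2    44.3
reduction_pct               5.1
early_intermixing          True
early intermixing: True
newick: ((((A:0,(C:0,D:8):9):7,E:0):11,B:0):44,N:0);
```

Reading it: 79 of 80 planted mutations were discovered and confirmed.
At discovery depth 49.4 % of them looked heterogeneous; ultra-deep
validation showed some were actually present in every sector, dropping
heterogeneity to 44.3 % (a 5.1-point reduction — apparent ITH that was
really limited sensitivity). The intermixing flag fires because truncal
mutations sit at subclonal VAFs in several sectors, e.g.
`chr1:16400:A>T subclonal in A,C,D,E`. The Newick tree roots the sectors
against the normal `N`, with 44 mutations on the trunk.

The same analysis runs from the shell over plain TSVs:

```bash
ithkit sim --seed 7 --outdir run/
ithkit pipeline run/counts.tsv --outdir run/out/
ithkit tree run/out/presence_tier2.tsv --out run/out/sectors.nwk
```

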