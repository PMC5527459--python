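# Methods

`ithkit` analyses multiregion tumor sequencing experiments of a specific
two-tier design: several spatially separated sectors of one tumor plus a
matched normal are first sequenced deeply over a gene panel (discovery,
~384× mean coverage), and every candidate somatic mutation is then
re-assayed by ultra-deep amplicon sequencing (~17 075× mean coverage) in
every sector, the normal, and a set of unrelated negative-control samples.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Data model

All stages operate on per-site, per-sample read counts
(`var_reads`, `q30_depth`, `total_depth`), exchanged as a tidy TSV.
`q30_depth` is coverage restricted to bases of quality ≥ 30; variant reads
are counted within that subset, and every VAF in the package is
`var_reads / q30_depth`. Microindels are treated identically to
substitutions at the counts level.

## Tier-1 discovery caller

The discovery stage is a deliberately transparent count-based test, not a
re-implementation of an alignment-aware somatic caller. A sector is called
at a site iff all of:

* VAF ≥ `min_vaf` (default 0.025 — the observable floor of dual-caller
  discovery pipelines at a few hundred fold coverage);
* `var_reads` ≥ `min_var_reads` (default 4);
* one-sided exact binomial tail `P(X ≥ var | depth, base_error_rate)` ≤
  `max_p` (defaults 10⁻³ and 10⁻⁶);
* the matched normal has depth ≥ 50 and VAF ≤ 0.01.

At a true VAF of 5% and depth 384 the resulting recall is 0.994 (exact
binomial power at the caller's effective threshold of 10 reads), which is
the sensitivity regime the two-tier design assumes: discovery finds every
mutation *somewhere*, and the validation tier settles where else it is.
The thresholds are plain configuration; none is a claim about any
particular external caller.

## Tier-2 validation: control-anchored Z rule

For each candidate site the normal plus `n ≥ 3` control samples define an
empirical null for the background variant fraction: their mean VAF and
standard deviation (ddof = 1). A sector supports the mutation when

    Z = (VAF_sector − mean_null) / sd_null > z_threshold   (default 3)

Adjudication per mutation: `not_assessable` when any of normal/sectors has
q30 depth < 100; `germline_like` when the normal or a control itself
exceeds, by the same Z rule, a null built from the remaining reference
samples (leave-one-out, with a 2-read minimum to ignore singleton flukes);
`confirmed` when ≥ 1 sector passes; otherwise `absent`.

Numerical choices:

* **sd flooring.** With clean controls the empirical sd is zero and Z is
  undefined. The sd is floored at the binomial sampling noise of a
  reference sample at the median reference depth, computed from a
  pseudocount-smoothed pooled error `p̂ = (Σvar + 1)/(Σdepth + 2)`, and
  inflated by `sqrt(1 + 1/n_ref)` because the null mean is itself
  estimated from only `n_ref` (~4) samples. Without that inflation the
  sector-level false-call rate at error-only sites is ≈ 0.006–0.007;
  with it, ≈ 0.003–0.004, inside the ≤ 0.005 design target.
* **Z on VAFs, not raw counts.** Amplicon depths vary several-fold between
  samples, making raw variant-read counts incomparable; `z_on_counts=True`
  preserves the literal counts-based reading.
* **VAF floor.** Presence requires VAF ≥ `min_vaf_floor`, default 0 (no a
  priori threshold); in practice validated VAFs bottom out near 0.07%, and
  that value can be set as a reporting filter.
* A mutation is confirmed if *any* sector passes; per-sector presence is
  gated per sector. (Whether "all variant reads > 3" should mean every
  sector is ambiguous; the any-sector reading is the one under which
  branched-to-truncal upgrades are expressible.)

## Clonality and early intermixing

A clonal mutation's expected VAF given sector purity `p`, local total
copies `C_t`, mutated-allele multiplicity `m`, and normal copies `C_n = 2`
is `m·p / (p·C_t + (1−p)·C_n)`; `m = 1` gives the *minimum* expected
clonal VAF. Per present (mutation, sector) pair the verdict is:

* `subclonal` iff observed VAF < `tolerance` × expected minimum **and**
  < `tolerance` × median VAF of same-group (truncal/branched/private)
  mutations in the sector;
* `clonal` iff it reaches `tolerance` × both references;
* `indeterminate` when the two criteria disagree.

`tolerance` (default 0.5) quantifies "similar to": the original analyses
of this kind judged per mutation by inspection, so the cut is exposed as a
single multiplicative knob applied symmetrically to both criteria. The
group comparator is the median, robust against the very subclonal
mutations being classified; the mutation under test is excluded from its
own comparator pool. Purity and copy number are consumed from an external
profile (an ASCAT-style estimate); a fallback estimates purity as twice
the median truncal VAF in copy-neutral regions (flagged low-confidence
when the truncal VAF IQR exceeds 0.1).

**Early intermixing** is the signature of ancestral subclones spatially
mixed before later mutations arose: mutations present in *every* sector
yet subclonal in several. The per-mutation detector lists truncal
mutations subclonal in ≥ `min_sectors` sectors (function default 1). The
pipeline's tumor-level flag requires ≥ 2 sectors, matching the
multi-sector pattern that defines the phenomenon; a one-sector rule is
measurably fragile, since a single noise-driven presence call can make a
four-sector branched mutation look truncal-and-subclonal in the phantom
sector (~4–6% of intermix-free simulations), while the two-sector rule
shows 0% false flags at unchanged 100% sensitivity on planted CCF-0.05
subclones.

## Heterogeneity metrics

Sharing labels over a binary presence matrix: truncal (all sectors),
private (exactly one), branched (otherwise). The headline statistic is the
percentage of non-truncal mutations, reported to one decimal half-up (the
printed-table convention); the tier-1 minus tier-2 difference of these
rounded percentages is the "reduction in heterogeneity" after ultra-deep
validation. Mutations failing the coverage criterion are excluded from
numerator and denominator alike. Discovery-vs-validation concordance
counts confirmed / germline-like / absent candidates (true-positive rate =
confirmed/assayable) and counts *new* detections at (mutation, sector)
granularity — a confirmed mutation found in two sectors discovery missed
contributes two — with false-negative rate `new/(confirmed + new)`;
per-mutation granularity is available as an option.

## Sector phylogeny

Taxa are sectors plus the matched normal (outgroup, all-ancestral states);
characters are validated mutations coded present/absent (subclonal
presence codes as present; ternary coding is out of scope). For binary
characters the Wagner minimum-changes criterion equals Fitch parsimony,
generalized to polytomies by Hartigan's algorithm (changes at a node =
children count minus the maximum state vote). Because the design uses six
taxa (105 unrooted topologies; (2n−5)!! in general, guarded at nine taxa),
the search is exhaustive and exact rather than heuristic. All
minimum-score topologies are retained; the reported tree is their strict
consensus rooted on the outgroup edge, which is the unique optimum when
there are no ties and an honestly multifurcating summary when there are.
Mutations are placed by a deterministic uppass that keeps the parent state
whenever the child's preferred-state set allows it, after fixing the root
at the ancestral state; for binary characters this yields a unique minimal
reconstruction whose per-edge change counts sum to the tree's parsimony
score, so truncal mutations always land on the trunk (the edge separating
the outgroup from the tumor clade). Scores were cross-checked during
development against an exhaustive internal-state-assignment oracle (kept
in the test suite) and against an independent R implementation.

## Synthetic multiregion generator

The generator emulates the study design so every stage can be scored
against planted truth.

* **Clone tree**: uniform random rooted labelled tree (Prüfer sampling);
  clone 0 is the founder. Mutations are placed on edges:
  `ceil(truncal_fraction × n)` on the root, the rest uniformly on
  non-root clones.
* **Sector composition**: each sector is a Dirichlet mixture over the
  clones on a root-to-dominant path, with the dominant clone's
  concentration boosted (`mixing_concentration` 1.5, `dominance_boost` 8)
  so sectors have a clear majority lineage. Dominant clones are drawn
  without replacement so each lineage is sampled somewhere; still-uncovered
  clones are patched into one sector at a guaranteed 0.20–0.35 share so no
  planted mutation is unobservable. If a non-root lineage would touch all
  sectors by accident, one sector is reassigned pure-founder composition,
  so truth truncality coincides exactly with root-edge placement — the
  deliberate exception being intermixing: with `intermix_fraction > 0`,
  the least-covered early clone is seeded at `intermix_ccf` (default 0.05)
  into the selected sectors, producing ubiquitous-but-subclonal mutations.
* **CCF**: summed fraction of the carrying clone and its descendants in
  the sector; purity per sector is uniform on `purity_range`
  (default 0.4–0.9).
* **Counts**: depth per site and sample is Poisson around the tier mean
  (384 / 17 075; a gamma-Poisson alternative via `depth_dispersion`);
  q30 depth is a fixed fraction (0.95) of total; variant reads are
  binomial at `VAF = purity·ccf·m / (purity·C_t + 2(1−purity))` mixed with
  a symmetric per-base error (default 10⁻³), so normals and controls draw
  at the error rate. Copy number defaults to diploid heterozygous with
  per-mutation overrides. Controls appear at tier 2 only, as they are part
  of the validation run.
* **Seeding**: one master seed; each stage derives an independent
  substream, so identical configurations reproduce bit-identical panels.

What the generator does *not* emulate: read-level artifacts (alignment,
strand bias, context-dependent or overdispersed error beyond the optional
negative binomial), germline variation (germline-like fixtures are
constructed directly in tests), copy-number heterogeneity between sectors
at the same locus, and spatial correlation beyond the path-mixture
structure. Passing recovery tests therefore demonstrate correctness of the
inference under the stated sampling model, not robustness to artifact
modes absent from it.

## Problem sizes and defaults used in the shipped checks

The repository's acceptance checks run the worked examples (13–36 mutation
fixtures, cohort tallies of 307 candidates), 200 random parsimony
instances at ≤ 6 taxa × ≤ 12 characters, closed-form VAF comparisons at
500 replicate sites, 2 × 50 seeded pipeline replicates at 5 sectors ×
100 mutations × 6 clones, and a 2 000-site error-only specificity panel —
sizes chosen to make each stochastic bound comfortably estimable while a
full run stays in the tens of seconds on one core.

## Known limitations

* The discovery caller is a statistical stand-in; its thresholds mimic the
  observable behaviour, not the internals, of production callers.
* Germline adjudication automates what was originally partly visual
  review; it is symmetric and leave-one-out but cannot capture
  alignment-level evidence.
* The clonality tolerance of 0.5 is a declared convention; per-mutation
  expert judgement will disagree near the boundary.
* Copy-number segmentation and purity estimation are consumed, not
  estimated (beyond the diploid truncal-VAF fallback).
* The phylogeny treats characters as independent and unordered; branch
  support is not computed.
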