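# Methods

## The measurement model behind the synthetic study

The generator emulates a paired-platform comparison of two bead-array-like
probe panels run on the same RNA: a dense "1.5K" cancer panel with three
probes per gene and a sparse-per-gene "24K" whole-genome panel whose
probes-per-gene distribution over {1..8} defaults to the observed gene
counts 333:86:64:5:5:5 (genes with 1, 2, 3, 4, 5, 6 probes out of 498
shared genes). Twenty subjects (9 HER2+, 11 HER2− by IHC, where 2+/3+
staining defines positive) each contribute one primary hybridization;
eight subjects add a technical replicate (same RNA extract hybridized
twice) and eight an extract replicate (second RNA extraction from the same
tumor), four subjects having both. Subjects are interleaved across groups
so the replicate subsets span both HER2 classes.

On the log2 scale, probe p of gene g in sample s measures

    x_pgs = μ_g + β_g·1[s ∈ HER2+] + b_s + π_p + δ_panel(μ_g) + η_(s,e,g) + ε

* μ_g ~ N(8.0, 1.5²) — baseline log2 abundance. The defaults put most
  genes in the 5–11 log2-intensity range typical of non-background-
  corrected bead intensities.
* β_g — planted group effect (HER2+ minus HER2−). A fraction
  `de_fraction = 0.05` of genes carry |β| ~ U(0.5, 1.2) with random sign;
  one designated flagship gene (an ERBB2 analogue) carries β = +1.5. The
  upper end of `fc_range` sits below the flagship effect so that the
  flagship is the strongest planted signal, mirroring a study design in
  which the group-defining gene dominates.
* b_s ~ N(0, 0.5²) — between-subject biological deviation. No published
  value anchors this; 0.5 log2 units is a typical tumor-to-tumor spread
  and is an explicit modeling choice.
* π_p ~ N(0, 0.3²), mean-centered within each gene×panel — probe effects
  are contrasts, so gene-level averages are unbiased for μ_g.
* δ_panel — the inter-panel intensity bias, applied to the 1.5K-like panel
  only: δ(μ) = d_max / (1 + exp(−k(μ − A0))) with defaults d_max = 1.0,
  k = 1.5, A0 = 7.5. A logistic in baseline abundance makes the dense
  panel read high for well-expressed genes while the difference attenuates
  at low expression, reproducing the rising Bland–Altman trend seen when
  comparing such panels.
* ε ~ N(0, σ_tech²) per measurement; σ_tech defaults are 0.39 (1.5K) and
  0.15 (24K), i.e. the observed SDs of technical-replicate differences
  (0.551 and 0.214) divided by √2.
* η — an extract-level random effect with variance
  σ_extract² − σ_tech² (σ_extract defaults 0.49 and 0.15), drawn once per
  (subject, extract) *per gene* and shared by all measurements of that
  extract. Technical-replicate differences therefore have SD √2·σ_tech
  and extract-replicate differences √2·σ_extract at the probe level.
  Making η vary by gene rather than being a whole-array offset matters:
  a constant array shift is exactly what intensity-dependent
  normalization removes, and modeling extract variation that way would
  make extract replicates look as tight as technical ones downstream.
  σ_extract ≥ σ_tech is enforced at configuration time.

Emitted intensities are 2^x, strictly positive, as exported by bead-array
software without background correction.

Manifests exercise all three match tiers: tier-2 genes (27/498 by default)
get divergent symbols rescued by a shared version-stripped RefSeq
accession; tier-3 genes (5/498) get divergent symbols and accessions but a
shared Entrez id, with the dense panel's symbol listed among the sparse
panel's aliases. Probe sequences are uniform random over {A,C,G,T}, 22 nt
on the 1.5K-like panel and 50 nt on the 24K-like panel (the two platforms'
probe lengths); for 17 designated gene pairs the 22-mer is embedded
verbatim inside the 50-mer at a random offset. Random 22-mer collisions
elsewhere have probability ≈ 4⁻²² per comparison and are negligible, so
exactly `n_seq_matched` substring matches exist.

The interaction graph connects every planted differentially expressed gene
to every hub (default three hubs) with reciprocal directed edges, so any
two DE genes are joined by a two-edge path through a hub; distractor nodes
with random edges pad the graph. Random effect labels
(activation/inhibition/unspecified) are attached but never weighted.

What the generator does **not** model: bead-level intensity extraction and
detection p-values, RNA-degradation kinetics, probe-position effects along
the transcript (positions are random metadata), correlated gene modules,
or sample-quality covariates. Tests passing on this generator therefore
demonstrate correctness of the analysis machinery and recovery of planted
parameters under the stated noise model — not performance on real FFPE
data, where probe-sequence-dependent efficiency dominates inter-panel
disagreement.

## Normalization

`fastlo_normalize` iterates: compute the per-probe mean profile Â over
arrays; for each array, fit a degree-1 tricube local regression of the
array's deviation from Â against Â (span 0.6 by default, no robustness
iterations, via statsmodels `lowess`); subtract the fit. Iteration stops
when the largest absolute fitted adjustment falls below `tol` (default
1e-3 log2 units) or after `max_iter` (default 5) passes. The scheme is
subtraction-only: no recentering is applied afterwards, so the grand
intensity level may drift by less than `tol`. Because local regression is
linear in the response, the across-array mean of the fitted adjustments is
approximately zero and the mean profile is stable across iterations; a
component of distortion common to *all* arrays is invisible to the method
(and to cyclic loess) and is left in place. Convergence diagnostics
(per-iteration maximum adjustment, converged flag) are returned rather
than asserted.

One numerical caveat: the achievable adjustment floor is set by the
smoother's response to iid noise, roughly σ_noise/√(span·n) in magnitude.
A `tol` below that floor will simply exhaust `max_iter`; the defaults are
appropriate for matrices of several hundred probes with replicate-scale
noise.

`cyclic_loess_reference` implements the classic pairwise scheme — smooth
M = x_i − x_j against A = (x_i + x_j)/2 for every array pair, apply ±fit/2,
cycle to convergence — using a separately written local-linear tricube
smoother (`smoothing.loess_fit`), so the two normalization routes share no
smoothing code. They agree within 0.05 log2 units on smooth planted
distortions (5 arrays × 1000 probes), which is the package's standing
cross-check. Raw intensities are floored at 1 and log2-transformed before
normalization; log-scale smoothing is the MA-plot convention, and an
intensity-scale path is not offered.

## Matching and summarization

Symbols are compared case-insensitively after whitespace stripping; RefSeq
accessions are compared after removing the ".version" suffix. Tiers are
assigned by first applicable rule (symbol, then RefSeq among the
leftovers, then alias/Entrez), each gene appearing at most once. Any
one-to-many candidate set within a tier raises an ambiguity error rather
than being silently resolved — the expected product is a clean 1:1 map.
Gene-level expression is the unweighted mean of all of a gene's probes'
log2 normalized values on that panel, regardless of which annotation field
established the match. Probe-sequence matching is exact substring search
(no mismatches), implemented with a hash index over all fixed-length
windows of the long-probe sequences.

## Agreement

Bland–Altman summaries use differences d = A − B and means m = (A + B)/2;
`sd_diff` uses the n−1 denominator. Pearson and Spearman correlations are
both reported for every pair, since either may be wanted and the two
answer slightly different questions on skewed expression scales; a vector
with zero variance yields an explicit `None` marker instead of NaN. The
trend line is the degree-1 tricube local regression of d on m evaluated at
100 evenly spaced abscissae; it is descriptive only and feeds no statistic.
Replicate pairing is (first extract, first measurement) against either the
repeat hybridization (technical) or the second extract's measurement
(extract); subjects lacking the requested replicate are skipped silently.

## Differential expression and concordance

Only one sample per subject — minimum order index within the first
extract — enters the tests, so replicates never inflate group sizes. Welch
t-statistics are computed vectorized over units; two identical
zero-variance groups return t = 0, p = 1 by convention, and a zero-variance
pair with unequal means returns the smallest positive float rather than 0
so that p stays in (0, 1]. Candidacy thresholds are strict inequalities
(boundary cases are measure-zero on continuous data). No multiple-testing
correction is applied by default, matching the two-group screening usage;
`statsmodels` Benjamini–Hochberg can be layered on the returned p-values
by callers who need it.

Fold-change direction concordance retains, at each threshold τ in a grid
(default 0 to 1 in steps of 0.05), the genes with |log2FC| > τ on at least
one panel; a retained gene is concordant when both panels agree on a
strict sign. sign(0) counts as neither direction, so zero fold changes are
discordant unless `drop_both_zero` is set. The Fisher exact p sums
hypergeometric probabilities over the full support of tables with the
observed margins, including tables whose probability ties the observed one
within a relative 1e-12 tolerance.

## Networks

"Allowing two steps in the path" is read as paths of at most two edges
(one intermediate node); `max_steps` exposes the alternative reading.
Edges have unit weight, so shortest means fewest edges, and *all* tied
shortest paths between each ordered seed pair are retained — this makes
the subnetwork invariant to edge input order, which a single-path
implementation would not be. Seeds absent from the graph are reported as
unplaced rather than raising. Hubs are ranked by total (in + out) degree
within the subnetwork, ties broken lexicographically.

## Problem sizes and determinism

The default end-to-end pipeline (498 genes, 1494 + ~770 probes, 36
hybridizations per panel) runs in well under a minute on one CPU; the
test-suite simulations use 498-gene studies across 20 seeds for
noise-recovery checks, 2000 null genes for type-I error, 200 replicate
studies for flagship power, 10,000 gene pairs for the null concordance
proportion, and exhaustive enumeration for subnetworks (graphs up to 12
nodes) and Fisher tables (totals up to 30). `scripts/acceptance.py`
averages the stochastic headline quantities over six independently seeded
full-study replicates. All randomness flows from
`numpy.random.default_rng` seeded by the user seed combined with a fixed
per-stage stream constant, so identical configurations reproduce
byte-identical outputs.

## Known limitations

* The noise model is Gaussian on the log2 scale with homoscedastic probe
  noise; real bead arrays show intensity-dependent variance that the
  generator does not emulate.
* The panel bias acts through baseline abundance only; real inter-panel
  disagreement is largely probe-sequence specific, which is why
  sequence-matched probes agree better than gene-matched ones in real
  data. The generator reproduces the former mechanism, not the latter.
* Cross-panel correlation magnitudes on synthetic data are higher than the
  published real-data ranges, since the generator shares a single true
  abundance per gene across panels; the package checks agreement
  *machinery*, not real-data effect sizes.
* The interaction graph is a planted construction, not a curated database;
  hub recovery demonstrates the algorithm, not biology.
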