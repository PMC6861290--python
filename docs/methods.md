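# Methods

## The analysis problem

A mixed-cropping experiment crosses two crop varieties (A, W) with two
cropping strategies (mono, mixed), yielding four root treatment groups,
with paired bacterial (16S) and fungal (ITS) amplicon profiles per plant.
The questions the package answers: do the groups differ in community
composition (PERMANOVA on Bray-Curtis, visualised by NMDS); do the two
kingdoms' community structures covary (Mantel tests on Jensen-Shannon and
Jaccard distances); and how does the cross-kingdom co-occurrence network —
genus pairs with significant, strong Spearman correlation within a group —
change between mono- and mixed-cropping.

## Synthetic-data generator

The generator is a log-normal–softmax–multinomial compositional surrogate,
chosen because it is simple, fully seedable, and produces overdispersed,
correlated counts with realistic depth variation.

1. Per genus, a baseline log-abundance `mu0 ~ Normal(m, s^2)` and variety
   offsets `delta_A, delta_W ~ Normal(0, sigma_v^2)`.
2. Group centroids in latent space: mono-V sits at `mu0 + delta_V`; under
   mixed-cropping a kingdom-and-variety-specific mixing coefficient
   `lambda` blends in the other variety:
   `(1 - lambda) (mu0 + delta_V) + lambda (mu0 + delta_other)`.
3. Per sample, the latent vector is the centroid plus correlated Gaussian
   noise (`sd = noise_sd`). The noise correlation matrix is the identity
   with planted blocks of pairwise correlation `r` overlaid, active only
   in chosen groups; blocks may span kingdoms because both kingdoms'
   latents are drawn jointly and split afterwards. If the overlaid matrix
   is not positive definite it is repaired by eigenvalue clipping; a
   repair that moves any entry by more than `pd_repair_tolerance` (0.1)
   aborts with the offending blocks named.
4. Per kingdom, counts are `Multinomial(softmax(latent), depth)` with
   depth uniform on a per-kingdom range.

Defaults (each is a config field, stated here with its rationale):

| parameter | default | why |
|---|---|---|
| samples per group | 16 / 11 / 11 / 16 | 8 mono pots x 2 plants, 11 mixed pots x 1 plant per variety |
| genera | 120 bacteria, 30 fungi | root communities carry many bacterial but few fungal genera |
| `m, s` | 0, 1 | genus baselines spanning ~2 orders of magnitude of relative abundance |
| `sigma_v` | 0.6 | variety effects visible but smaller than between-genus variation |
| `noise_sd` | 1.0 | per-sample overdispersion comparable to the baseline spread |
| `lambda` | bacteria (A: 0.6, W: 0.05); fungi (A: 0.05, W: 0.6) | kingdom-asymmetric response: variety A's bacteria shift under mixed-cropping while W's stay put, mirrored for fungi |
| depth range | bacteria 14020–95216; fungi 2653–13954 | typical per-sample read totals for 16S vs ITS libraries |
| SV expansion | mean 3 SVs/genus, lengths ~253 ± 3 bp clipped to [240, 260], 0.5% outliers in [261, 434], 2 contaminants, 5% rare SVs | matches the length profile and control contamination a 2x250 bp 16S run produces |

Soil samples (off by default) are drawn from the unshifted baseline using
a separate random stream, so adding or removing them never perturbs the
root samples' counts.

What the generator does **not** emulate: read-level error and chimeras
(the pipeline starts after denoising), phylogenetic structure among
genera, genuinely compositional interaction mechanisms (the planted
correlations live in latent log-abundance space), and temporal dynamics.
Passing recovery tests therefore shows the *analysis chain* is correct
and calibrated under a plausible generative model — not that plain
Spearman co-occurrence is robust to compositional artefacts in real data.

A practical consequence of the softmax step: a latent correlation `r`
attenuates at the count level, and more so for features in small
communities (the shared normalisation term is noisier), so cross-kingdom
planted pairs show slightly weaker sample correlation than within-kingdom
pairs planted at the same `r`.

## Preprocessing decisions

- The length window is inclusive on both ends; fungal tables are not
  length-filtered by default (the ITS region varies too much for a
  length rule), expressed as a per-kingdom optional window.
- "Fewer than 100 reads" keeps totals that are exactly 100.
- Negative-control removal runs before the read filter by default; the
  order is configurable and recorded in the run log.
- Taxonomy fill-down writes `Rank_Name` markers and is idempotent
  (markers are recognised and propagated unchanged).
- Rarefaction subsamples without replacement via the multivariate
  hypergeometric distribution; under-depth samples are dropped and
  reported. All-zero features are retained by default so feature axes
  stay comparable across iterations (a flag drops them).

## Distances, ordination, inference

- Jensen-Shannon divergence uses the natural log and is reported as plain
  divergence (bounded by ln 2 ≈ 0.693), computed on per-sample
  proportions. Bray-Curtis operates on counts as given — rarefy first
  when depth bias matters.
- Jaccard defaults to the binary (presence/absence) form, contrasting
  incidence with JSD's abundance view; the quantitative variant
  `2BC/(1+BC)` is available. Note that binary Jaccard is only informative
  on tables with absences (SV-level); at genus level nearly every feature
  occurs in every sample and the metric degenerates.
- PERMANOVA is one-way only (the design has a single four-level factor).
  Permutation p-values use the (count+1)/(permutations+1) correction so
  p is never 0; when the number of distinct label assignments is below
  the permutation budget and exhaustive mode is requested, the exact
  enumeration is used instead. On univariate Euclidean data the pseudo-F
  reduces to the classical one-way ANOVA F, which the tests verify to
  10+ significant digits. Note that the exhaustive p for two groups of
  three well-separated points is 2/20, not 1/20: the pseudo-F depends
  only on the unordered partition, so the label-swapped assignment always
  ties the observed statistic.
- The Mantel test is one-sided for positive association with Pearson r on
  distance vectors (Spearman available), 999 permutations by default.
- NMDS minimises Kruskal stress-1 by alternating pool-adjacent-violators
  monotone regression (over the stable rank order of the input
  dissimilarities; ties are kept in input order) with Guttman-transform
  updates, over one classical-MDS start plus `n_restarts` (20) random
  starts, `tol` 1e-6, `max_iter` 500. Coordinates are centered; stress is
  invariant to rotation/reflection/translation.

## Co-occurrence tiers and networks

- `-0.50 > rho > 0.50` style thresholds are read as |ρ| exceeding the
  threshold — the only reading under which the published tier structure
  nests.
- Tiers are computed within the significant set, so
  `strong positive ⊆ strong ⊆ moderate ⊆ significant` holds by
  construction; percentages are rounded half-up to integers and blank
  when nothing is significant.
- Spearman p-values use the t-approximation with df = n−2 (adequate at
  group sizes of 11–16); exact permutation enumeration is available for
  n ≤ 9. No multiple-testing correction is applied by default (the
  analysis filters at raw p < 0.05); Benjamini-Hochberg is available
  behind a flag and recorded in the run log.
- Zero-variance features are excluded per group (rank correlation is
  undefined for a constant vector) and the exclusion count reported.
- Correlations use each group's root samples only; soil samples never
  enter networks.

## Pipeline and reproducibility

A single master seed drives everything; each stage derives a child seed
as `(seed * 1000003 + crc32(stage_name)) mod 2^31`, so stages can be
re-run in isolation and a re-run of the same config is byte-identical.
The run log records every analysis default (filter thresholds, Jaccard
variant, p-value method, permutation counts) so unstated-choice gaps are
explicit.

## Problem sizes used by the verification suite

The test suite and `scripts/acceptance.py` use deliberately compact study
conditions chosen to give stable statistics at interactive runtimes:
null calibration uses 1000 synthetic PERMANOVA datasets (n=10, two groups,
99 permutations) and two mono-crop groups of the default 150-genus
community (22 350 pairs); planted-structure recovery uses 50 replicates
of a 75-genus community with 2 mono-group vs 6 mixed-group planted blocks
(r = 0.95, 3 members each); centroid geometry uses 200 samples per group;
the rarefaction closed-form check uses 2000 Monte-Carlo draws.

## Known limitations

- Plain Spearman co-occurrence inherits the compositionality caveats of
  the underlying method; compositionality-aware alternatives (SparCC,
  SPIEC-EASI) are out of scope by design.
- Phylogenetic diversity (UniFrac) and evenness indices are not
  implemented; richness is the only alpha-diversity measure.
- The NMDS tie-handling is the simple stable-order variant, which can
  yield marginally higher stress than full tie-group averaging on heavily
  tied dissimilarities.
- Only one-way PERMANOVA is provided; nested or multi-factor designs need
  external tools.
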