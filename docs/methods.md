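# Methods

This note documents the models and procedures implemented in `phosdyn`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmark does and does not demonstrate.

## Quantification and calibration

Raw inputs are nonnegative intensity matrices (sites × samples and proteins ×
samples) with explicit nulls for missing cells. The fixed processing order is:

1. **Zero replacement (protein matrix only).** An exact-zero protein cell is
   replaced by the global minimum non-zero value of the protein matrix. The
   "lowest value" is read as the minimum *strictly positive* value — a literal
   minimum that included zeros would return 0 and defeat the rule's stated
   purpose of avoiding division by zero. Site-matrix zeros are instead treated
   as missing: the zero rule exists to make the protein denominator safe, and
   a zero site intensity carries no usable quantitative signal.
2. **Row-mean normalization.** Each row is divided by its own mean over
   non-null entries, so every normalized row has mean exactly 1 and any global
   scaling of a raw row cancels (scale invariance is property-tested).
3. **Calibration.** Each normalized site row is divided element-wise by the
   normalized row of its parent protein, removing protein-abundance change
   from the site signal. If the protein was not quantified, the site's own
   normalized level is used directly and flagged `site_only`. Division by a
   null protein cell yields null (pairwise missing propagation).

Missing values are never imputed; a site must have ≥ 2 non-null values in
each compared stage to be testable. No column (sample-loading) normalization
or batch correction is applied — the calibration chain is defined purely on
rows, and adding column steps would change its invariances.

## Differential regulation

Stage comparisons (default GVBD vs GV, MII vs GV, MII vs GVBD) use a
two-sided two-sample t test on **log2 calibrated values** (variance
stabilization for multiplicative noise). Student's pooled-variance test is
the default; Welch/Satterthwaite is an option for unequal variances (no
automatic switching rule is applied — the choice is the caller's). Raw p
values are Benjamini–Hochberg adjusted per comparison across the testable
sites. Significance requires both `p_adj < 0.05` and a fold change above 1.5,
where FC is the ratio of arithmetic stage means of calibrated values and the
gate is enforced symmetrically as `|log2 FC| > log2 1.5` so down-regulation
counts equally. A site is **regulated** when significant in at least one
configured comparison (the most inclusive reading; the comparison list is a
parameter). Label-free (DIA) protein contrasts use raw `p < 0.05` with
`FC > 1.2`, matching common practice for that acquisition mode, and no BH.

BH adjustment is backed by `statsmodels.stats.multitest.multipletests`
behind a null-aware wrapper (null p values are skipped and returned null);
the test suite checks it against an independent brute-force step-up
implementation on random vectors to 1e-12.

## Temporal clustering

Regulated sites are summarized as per-stage means of **log2** calibrated
values (i.e. log geometric stage means, the same scale the tests run on),
then standardized per site to mean 0, population SD 1 across stages. On the
raw-ratio scale two of the five canonical "up" archetypes become nearly
indistinguishable after standardization, so the log scale is also the better
separated representation; constant profiles cannot be standardized and are
dropped with diagnostics.

Clustering is fuzzy c-means (alternating minimization of
`J = Σ_ij u_ij^m ||x_i − c_j||²` under `Σ_j u_ij = 1`), implemented as a
scikit-learn-style estimator:

- `n_clusters` default 5, fuzzifier `m` default 2.0, `tol` 1e-6 on the max
  membership change, `max_iter` 1000 — textbook defaults.
- Memberships are initialized from a seeded flat Dirichlet. A single random
  start can collapse two centers onto one group, so `n_init = 10` restarts
  are run and the lowest-objective solution kept; with a fixed seed the fit
  is bit-deterministic.
- Each half-step of the alternating update cannot increase `J`, so the
  recorded objective path is non-increasing (asserted in tests).
- A profile coincident with a center receives membership 1 there; hard
  assignments take the argmax membership with ties to the lowest cluster
  index.
- Distances are Euclidean on the standardized stage profiles, i.e. shape
  similarity of the temporal course, not amplitude.

No cluster-number selection procedure is implemented; `c` is a parameter.

## Conservation and novelty screens

Each site is represented by a 13-mer window — the phospho-residue plus six
flanking residues per side, `_`-padded beyond the termini. Similarity between
windows is counted position-wise on the fixed frames (no alignment, gaps or
shifts); pad characters never match anything, including another pad. The
integer similarity threshold is derived, not assumed: the smallest k with
k/13 > 0.69 is 9. A site is conserved when at least `min_species = 3` species
(counting the reference species itself) carry a similar window. Matching is
all-vs-all within each species' window set — no orthology mapping — and the
center residue participates in the count like any position; a
`require_center_match` flag provides the strict variant requiring identical
phospho-acceptor residues. Downstream manual assessment of functional
conservation is out of scope; the screen is purely sequence-based.

Novelty screening is a set lookup on (protein, position, residue) keys
against any number of reference catalogs; novel = absent from all.

## Kinome analyses

Kinase → site edges are an **input** table (e.g. exported from a
kinase-substrate predictor); no motif-based prediction is performed.

- **Accounting.** An enzyme is detected if present in the proteome or
  carrying a phosphosite, phosphorylated if it carries ≥ 1 site, regulated if
  ≥ 1 of its sites is regulated; the categories nest by construction.
- **Enrichment.** Per kinase, a 2×2 of substrate membership × (significantly
  upregulated vs the rest of the quantified sites) in one comparison
  (default MII vs GV), tested with a two-sided Fisher exact test (p sums the
  hypergeometric probabilities not exceeding the observed table's) and BH
  adjusted across kinases. Kinases without substrates in the site universe
  are excluded. Note the two-sided test also flags substrate *depletion*;
  when ranking activated kinases, restrict to odds ratio > 1.
- **Activity.** Each quantified substrate's stage-mean profile is
  standardized to z across stages (making the score invariant to any positive
  rescaling of a substrate row); the kinase profile is the per-stage mean
  substrate z, optionally weighted by edge scores. Profiles need
  `min_substrates = 3` quantified substrates, else null. Trends are labeled
  from consecutive differences against a 0.25 z threshold: all significant
  moves up → increasing, all down → decreasing, mixed → transient, none →
  flat. The z-mean summary and both thresholds are this package's documented
  choices; substrate-based activity inference is only qualitatively
  constrained by the literature.

## Synthetic-data generator

The generator emulates the statistical structure of a TMT-style three-stage,
five-replicate oocyte maturation study at desk scale:

- **Proteins:** 500 by default, random sequences of 150–400 residues,
  log-normal baseline abundances. A fraction (0.1) drifts 1.5–2× across
  stages along a geometric ramp, in a random direction; 90 % carry proteome
  quantification, the rest exercise the `site_only` fallback.
- **Sites:** a zero-truncated geometric number per protein with mean 3
  (long-tailed multiplicity), residues drawn S/T/Y at 86.5/13.0/0.5 %,
  localization probabilities U(0.76, 1) — all class I, matching the filter
  applied before quantitative analysis.
- **Regulation:** 75 % of sites regulated, each following one of five stage
  templates — monotone decrease (1, 0.7, 0.3), a transient peak (0.6, 1,
  0.3), and three increase shapes with differing onset (0.3, 0.5, 1),
  (0.3, 0.9, 1), (0.5, 0.6, 1). Template magnitudes are generator choices
  sized so minimum effects exceed the 1.5× gate. Unregulated sites are flat
  at the phosphorylation level but still inherit protein drift, so raw site
  intensities confound the two and calibration is genuinely required.
- **Noise:** multiplicative log-normal with sdlog σ = 0.15 on every site and
  protein measurement independently (so calibrated values carry ≈ √2 σ);
  σ = 0 gives exact, noise-free matrices. σ = 0.15 keeps planted 1.5×
  effects recoverable at n = 5.
- **Kinase–substrate structure:** enzymes are drawn from the simulated
  proteins; each kinase prefers one archetype (90 % of its 8–25 substrates).
- **Species windows:** per species and site, a window at a planted Hamming
  distance d ∈ 0..6 from the reference window (substitutions never at the
  center or at pads), so screen output is checkable against exact truth.

All randomness derives from one seed through fixed per-component substreams;
regeneration is bit-identical and components can be regenerated
independently.

**What the benchmark does not show.** The generator has no peptide level (no
missed cleavages, no multiply-phosphorylated peptide ambiguity), no TMT
ratio compression, no missing-value mechanism beyond undetected proteins, no
batch structure, and residue-independent noise. Passing recovery tests
demonstrates the algorithms are correct under the stated statistical model,
not that real acquisitions meet that model.

## Numerical choices and degenerate inputs

- Zero-variance groups with a nonzero mean difference yield p = 0 (the
  noise-free limit); zero difference with zero variance is untestable (null
  p, never significant).
- Fisher p values enumerate the hypergeometric support with a (1 + 1e-7)
  relative guard on probability ties (the conventional float-safe reading of
  "≤ observed probability"); a zero margin gives p = 1. Exhaustive
  comparison against exact integer enumeration for all tables with total
  ≤ 40 agrees to < 1e-15.
- `rounded_percent` rounds half away from zero, matching how such ratios are
  conventionally printed.
- Duplicate (protein, position) rows are rejected at parse time; in-memory
  duplicates are resolved by class priority I > II > III, then higher
  localization probability, then larger total intensity — invariant to input
  order.
- Accession isoform suffixes (`-2`) are kept distinct: site positions are
  isoform-specific.

## Problem sizes used in validation

The test and acceptance runs use the default desk-scale study (≈ 1500 sites
on 500 proteins, 3 stages × 5 replicates), 200 all-null runs of 500 sites
for the false-positive control, 100 × 3 × 100 windows for the conservation
oracle, and all 2×2 tables with total ≤ 40 for the Fisher oracle — sizes at
which every independent oracle is exact and fast while preserving the study's
statistical structure.

## Known limitations

- The union-over-comparisons regulation rule and the MII-vs-GV default for
  enrichment are conventions; both are parameters.
- Kinase "activity" is a substrate-phosphorylation summary, not a rate
  measurement; direction and magnitude enter only through substrate
  z-profiles.
- The conservation screen treats every species window set as one unordered
  pool; with very large window sets the chance-similarity floor rises and
  `min_matches` may need to be raised.
- Multiply-phosphorylated peptides are outside the model: the site table is
  taken at face value as one row per localized site.
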