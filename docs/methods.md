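# Methods

## Scope and data model

The package analyses per-gene ortholog families (protein + in-frame CDS
per species), pre-computed protein alignments, a species tree, and
domain/motif annotations. Dataset curation mirrors standard ortholog
hygiene: proteins must begin with methionine, coding sequences with
ATG, and each species keeps only its longest protein (ties broken by
source priority). Codon alignments are produced by protein-guided
back-translation rather than an independent nucleotide alignment: each
residue column becomes its source codon and gaps become `---`, which
guarantees the codon/protein column correspondence the window analysis
assumes and removes an external aligner dependency without changing
downstream semantics.

Undefined quantities (saturated distances, Ka/Ks beyond the
Jukes–Cantor bound, empty site sets) are represented as NaN and
excluded from every aggregation; they are never silently zero.
Alignment columns are 1-based inclusive in all file formats; codon k
occupies nucleotide columns 3k−2..3k.

## Protein distances and ranking

Six models operate on pairwise-deleted sites (a site is dropped for a
pair when either sequence has a gap or ambiguity code): number of
differences; p-distance p; Poisson −ln(1−p); equal input −b·ln(1−p/b)
with b = 1 − Σπ²; Dayhoff and JTT. The empirical-matrix distances are
defined through expected identity: with the published exchangeability
matrix and stationary frequencies (bundled as plain-text data), the
rate matrix is normalized to one expected replacement per site per unit
time and the reported distance solves E[identity](d) = 1 − p by Brent's
method on [0, 20] (the root reproduces 1 − p to 1e−9; p beyond the
d = 20 identity floor is undefined). Equal-input frequencies default to
the sequence pair's own valid sites, consistent with pairwise deletion;
alignment-wide frequencies are available (`equal_input_scope=
"alignment"`) since either convention is defensible.

Ranking works on species pairs. Each pair's mean distance over genes
(equal-input reference model) is the binning coordinate; borders are
the three deepest interior minima of a Gaussian-KDE density (Silverman
bandwidth) of those means, falling back to quartiles with a warning
when the distribution shows fewer than three troughs. Bins are
half-open (a value equal to a border joins the upper bin) and are
frozen once from the reference model, then reused for all models and
for Ka/Ks statistics. Within a bin, a gene's aggregate is the mean
(distances) or median (Ka, Ks, log-ratio) over that bin's pairs, and
its percentile is 100 · (#genes strictly greater)/(N − 1) with ties
sharing their mean percentile — so the fastest-changing gene scores 0
and the most conserved 100. The tie rule and strict inequality are
choices (both are configurable via the ranking direction); percentiles
are invariant under any strictly monotone transform of the aggregates.

## Ka/Ks (Nei–Gojobori 1986, Jukes–Cantor corrected)

Per sense codon, the synonymous site fraction at each position is the
synonymous share of the non-stop single-nucleotide changes, so
s + n = 3 exactly. Codons containing gaps, ambiguities, or stops in
either sequence are excluded pairwise. Differences in multi-hit codons
average over all minimal mutational pathways with equal weights,
excluding pathways through stop codons (if every pathway is blocked —
unreachable for sense-codon pairs of length ≤ 3 differences in the
standard code — all pathways are used). Site totals average the two
sequences. Proportions are corrected by d = −(3/4)·ln(1 − (4/3)p),
undefined at p ≥ 3/4. Exact zeros in Ka or Ks are replaced by 1e−15
before log10(Ka/Ks), so "no synonymous change" pairs report ±14 rather
than dividing by zero; a fully identical pair reports 0.

Windows are 99 nt stepped by 9 nt; starts 1 + 9k are always ≡ 1 (mod 3)
on the codon alignment, so every window is exactly 33 codons. Per
window the track records the median log10(Ka/Ks) over all defined
pairs. Domain spans map to the first window starting at the feature
start through the last window ending at the feature end, with
wholly-inside windows as the fallback when boundaries don't coincide
with any window; motifs map from the first window whose end covers the
motif through the last window whose start precedes it.

## Statistical coupling analysis

Preprocessing removes gap-heavy sequences (> 0.2 gap fraction), then
gap-heavy columns (> 0.4), then re-applies the sequence filter on the
retained columns (the first and third filters share the 0.2 cutoff; the
first pass is kept for fidelity to the published order even though it
is nearly redundant). Retained columns are mapped to residue numbers of
the first retained sequence, optionally re-indexed through a reference
structure sequence by global alignment.

Frequencies f_ia are counts over the 20 amino acids divided by the
number of sequences; gaps contribute to no residue and there is no 21st
state. The background q defaults to database-derived amino-acid
frequencies (bundled, sums to 1) and can be switched to uniform 0.05.
Conservation is the binary Kullback–Leibler relative entropy; the
weighting φ_i^a = ln[f(1−q)/((1−f)q)] is its derivative in f, evaluated
after clamping f into [1/(2n), 1 − 1/(2n)] so fully conserved or absent
residues receive a large finite weight instead of an infinity. The
coupling matrix is the Frobenius norm over amino-acid pairs of
φφ·(f_ij − f_i f_j), computed as the Gram matrix of the φ-weighted,
frequency-centered one-hot encoding (single-precision matrix product,
double-precision reduction and eigendecomposition). No phylogenetic
sequence reweighting is applied.

Significance of eigenmodes is calibrated by randomization: each of 10
trials permutes every column independently across sequences (exactly
preserving all f_ia while destroying inter-column correlation) and
records the second eigenvalue of the shuffled coupling matrix; the
cutoff is mean + 2 sd of those ten values, and k\* counts true
eigenvalues above it. The second (not first) eigenvalue is used because
the leading mode reflects overall conservation, which shuffling
preserves. The published description of σ ("average standard deviation
over trials") is ambiguous for a single statistic per trial; the sd
across the ten second eigenvalues is used.

ICA is a seeded fixed-point iteration (tanh contrast, symmetric
decorrelation) applied directly to the k\* top eigenvectors without
centering or re-whitening, so the components are an exact orthogonal
rotation of the eigenmodes — the output provably spans the same
subspace (residual at machine precision), which a generic ICA with
centering would not guarantee. k\* = 1 returns the eigenvector
unchanged; non-convergence after 1000 iterations is reported with a
flag. All eigenvectors and components are sign-oriented so the
largest-magnitude loading is positive.

## Sector determination

Per IC, a location-scale t-distribution is fitted to the loadings by
maximum likelihood and positions above the fitted 95th-percentile value
are selected (one-sided). Degenerate fits fall back to the empirical
quantile with ⌈0.05L⌉ positions and index-order tie-breaking. Note that
selecting beyond a fitted 95th percentile admits roughly 5% of the
background by construction; the planted-outlier tests therefore check
"all outliers plus clearly under 5% background", not an absolute purity.

To decide whether two ICs describe the same group of coupled positions,
each selection in turn serves as reference: every selected position's
response is its mean Euclidean distance (in IC-loading space) to the
reference selection's members, and a one-way ANOVA compares the two
selections' responses; the pair's p-value is the minimum over the two
references, and p ≥ 0.10 links the pair. An earlier variant using the
mean distance to *all* selected positions was rejected because it is
symmetric between two equal-size sectors (the two profiles are
permutations of the same values) and provably cannot separate them; the
reference-based response does, while still merging ICs that split one
sector. Sectors are the connected components of the link graph —
pairwise indistinguishability is not transitive, so transitive closure
is the only consistent partition rule. Selections with fewer than two
positions are skipped and become flagged singleton sectors. A position's
IC membership (for reporting and motif profiles) is the argmax of
absolute loadings, ties to the lower IC index.

Motif profiles extract, for each motif position inside the retained
alignment, its coupling-matrix row restricted to the other motif
positions with the self-entry removed; positions truncated during
preprocessing are reported as missing, never silently dropped.

## Tree annotation

Each internal node of the species tree is annotated with the mean of
the defined pairwise distances between leaves of *different* child
subtrees (cross-child mean), which measures divergence at that split; a
within-clade mean over all descendant pairs is available since the
choice of per-node statistic is genuinely open. Species absent from the
distance matrix are pruned and logged. Colors ramp warm→cool with
increasing distance (warm = closely related); undefined nodes get a
gray sentinel and value `NA`.

## Synthetic data: what it emulates and what it does not

`simulate_species_tree` draws Yule (pure-birth) trees, extends all tip
edges by the waiting time to the next uncounted speciation (the raw
simulation otherwise ends on a zero-length cherry), and rescales to a
chosen root-to-tip height in expected neutral substitutions per site,
making divergence directly controllable.

`evolve_family` evolves codon sequences by thinned Gillespie
simulation: candidate single-nucleotide events arrive at 3·n_codons·
max(1, ω_max) per unit branch length, targets are drawn HKY-like
(transitions weighted κ), stop-creating proposals are rejected,
synonymous proposals accepted at the envelope rate, nonsynonymous
proposals at ω of the codon's region — ω > 1 thereby inflates the
nonsynonymous rate, so positive selection is generable. The start codon
is frozen so outputs satisfy the start-Met/ATG filters by construction.
This is a simulator for planting Ka/Ks contrasts, not an inference
model: it has no indels, no rate heterogeneity beyond the regional ω,
no codon-usage bias, and no recombination, so passing tests demonstrate
estimator correctness under the model class, not robustness to real
alignment error.

`generate_sector_msa` plants sectors via hidden per-sequence modes:
each sequence draws one mode per sector; sector positions show the
mode's preferred residue with probability `fidelity` (> 0.5 required —
below that the sectors are information-theoretically unrecoverable) and
a background draw otherwise; other positions are i.i.d. background;
gaps are i.i.d. Real MSAs add phylogenetic correlation between
sequences, which this generator deliberately omits, so null-calibration
results quantify finite-sampling noise only.

## Study conditions used by tests and the acceptance script

Chosen once, as realistic defaults for the validations they serve:

* ω-recovery: 8-species trees at height 0.1 — even the ω = 10 regime
  then stays below Jukes–Cantor saturation for most pairs; families of
  500 codons give median log-ratios within ±0.15 of the truth at ω = 1.
* Window-spike: height 0.2 (windows of 33 codons need enough
  substitutions per pair), 120-codon genes, ω = 2 spike at codons 5–15
  on an ω = 0.1 background, 20 replicate families per tree.
* Ranking panel: 12 genes × 12 species (66 pairs, enough for trough
  detection), 150 codons, ω = 0.3, planted 3× and 0.3× rate genes.
* SCA: 350 × 250 MSAs; planted sectors of 12 positions, 3 modes,
  fidelity 0.9; 10 randomization trials.

## Known limitations

* Window tracks are noisy for shallow trees: with few substitutions per
  33-codon window, the ±14 log-ratios produced by the zero-replacement
  rule dominate window medians, and the track maximum becomes an
  unreliable spike locator (recovery drops from ~95% to ~65–75% when
  the median pairwise divergence falls well below ~0.2). This reflects
  the method, which was designed for deeply diverged panels.
* The t-fit selection admits ~5% background by construction; sector
  position lists should be read as enriched, not pure.
* Dayhoff/JTT distances assume the bundled stationary frequencies;
  strongly biased compositions are better served by equal input.
* The published bin borders (0.2472…, 0.4282…, 0.6997…) depend on the
  original retrieval snapshot and are treated as a regression-config
  default, not a reproducible target; `find_borders` recovers borders
  only to KDE-grid resolution.
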