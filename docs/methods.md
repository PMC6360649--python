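# Methods

## Model

A cell line's *variant profile* is the set of (site, FREQ, DP) triples
called from its RNA-seq reads, with FREQ the altered-allele frequency in
percent and DP the read depth. Identity between samples is measured as the
Pearson correlation of FREQ over the variant set

V = { k : DP ≥ dp_min in both samples, FREQ > freq_min in at least one },

with dp_min = 10 (non-strict) and freq_min = 10 percent (strict) for
panel-vs-panel comparison. Because a gene that is not expressed yields no
usable sites in either sample, expression differences are implicitly folded
into the correlation. The working assumptions are that allele fractions of
expressed variants are stable characteristics of a line (aneuploidy and
treatment shift them only at a minority of sites) and that two unrelated
lines still share enough common (largely germline) variation to produce a
well-defined background correlation rather than zero.

### Null model and significance

Pairwise correlations between unrelated lines are modeled as
N(μ, σ) truncated to (a, b) = (0, 0.8): negative correlations are
implausible under shared germline variation, and values above 0.8 are
replicates or derivative lines, not background. (μ, σ) are fitted by
maximum likelihood (Nelder–Mead from the retained sample's moments,
log-likelihood tolerance 1e-8; the a/b retention filter is applied inside
the fit). A correlation ρ converts to p = 1 − F(ρ) with F the truncated
CDF; p < alpha_related = 1e-3 → possibly related, p < alpha_same = 1e-4 →
same cell origin.

Above b the truncated CDF has no tail mass, yet observed matches land there
routinely (a replicate at ρ = 0.97). For ρ ≥ b the untruncated normal
survival function is used instead; to keep p monotone non-increasing across
the bound, the truncated tail inside (a, b) is floored at the untruncated
tail mass at b. The floor only matters ~7σ into the tail (≈ 4e-13 at the
reference parameters), far beyond both decision thresholds, so every
reported threshold is an exact inversion of the truncated CDF. `threshold`
inverts the tail probability in closed form via the normal quantile
function; `threshold` and `p_value` are mutual inverses to well below 1e-6.

### Two-pass identification

Pass 1 ranks every panel cell by ρ computed over a *permissive* variant set
(DP ≥ 10 in both, FREQ > 0 in at least one): a query should not be punished
for variants it simply failed to call. If two or more cells pass the
relatedness cut — the signature of synonymous or derivative lines — pass 2
recomputes ρ on sites that discriminate the candidates: FREQ spread across
the candidates (max − min, pooled over all of them when more than two)
above 10 percent and DP ≥ 20 in the query and every candidate. Fewer than
10 such sites is reported as inconclusive rather than decided. Ranking ties
break lexicographically by cell id; undefined correlations (constant
vectors, |V| < 2) are flagged, never coerced to 0.

Coverage is asymmetric by design. Panel cells follow the panel's coverage
mode at sites they did not call — `assume_covered` (default; DP sentinel
+∞, appropriate for deep RNA-seq of expressed transcripts), `strict`
(DP 0), or `external` (user-supplied depths). The query's uncalled sites
always count as DP 0: its VCF is the only coverage evidence available, and
a shallowly sequenced query must be compared only at sites it could call —
this is what makes the variant-dropout experiment meaningful.

### Contamination estimation

A mixed sample is y ≈ Σ q_i x_i + e over FREQ vectors with no intercept
(all vectors share the percent scale). The dominant line is the top
identification hit (or supplied). Candidates are screened one at a time:
for each remaining panel line, regression sites are the n_per_direction =
200 most positive and 200 most negative differences between the candidate's
FREQ and the current fitted mixture, and the fit is iteratively reweighted
least squares with Tukey's bisquare (c = 4.685, max 50 iterations,
coefficient tolerance 1e-8). The candidate with the largest contaminant
t-statistic is accepted if its proportion exceeds q_tol = 1e-6, its t-stat
is at least t_min = 3, and Σq ≤ 1.02; the search ends when no candidate
qualifies (labeled by cause: non-positive q, regression failure, or
saturated proportions), or at max_components = 4.

Two choices here deserve their rationale:

* **Site selection uses the candidate contrast, not the query residual.**
  Selecting the most extreme |y − x₁| differences selects extreme
  realizations of the query's own noise, which the regression then
  attributes to the candidate; on simulated mixtures this inflated the
  contaminant proportion by up to +0.07 at FREQ-noise σ = 6, growing with
  the size of the site pool. Selecting on the candidate-vs-mixture contrast
  — noise-free panel quantities — removes the dependence and leaves the
  small (≲ 1 percent on simulations here, ~3 percent reported for robust
  fits on real profiles) regression bias only.
* **A significance floor (t ≥ 3) on new components.** Termination on
  "q becomes non-positive" alone would admit arbitrarily small spurious
  components fitted to residual noise once the true mixture is saturated;
  requiring a minimally significant t-statistic is the package's guard and
  caps the practical detection floor at roughly 1 percent contamination.

The q₁ + q₂ ≤ 1 condition is checked post-fit and flagged when violated
beyond 0.02, never imposed on the solver; a non-negative least squares
fallback is available behind the `nonneg` flag. Exactly collinear designs
raise; exact (zero-residual) systems are solved directly by least squares —
IRLS weights are undefined at scale 0 — and reported with se = 0.

## Synthetic data generator

`generate_panel` emulates the statistical shape of variant profiles from a
large cancer cell-line collection, at desk scale:

* a shared pool of sites (default 30 percent of the universe) carried by
  every cell; each site has a population hom-alt probability drawn from a
  strongly U-shaped Beta(0.055, 0.25) (mean 0.18), each cell draws its
  zygosity from it, and FREQ scatters around 50 (het) or 100 (hom) with SD
  7, scaled per cell by a library-quality factor U(0.5, 1.5) and truncated
  to [5, 100];
* private (line-specific) variants per cell at rate 0.008 of the universe;
* depths from a negative binomial with mean 60 (dispersion 4, floor 1);
* optional related pairs: a child at divergence d keeps (1 − d) of the
  parent's variants at matched FREQ and gains its own private variants at
  d × private_rate (d = 0 is an exact copy).

These defaults were fixed once, by matching the reported data regime rather
than any test outcome: unrelated pairwise correlations center near 0.46
with spread of a few hundredths (the published RNA-seq panel fit is
(0.464, 0.047)), replicate pairs sit above 0.9, FREQ noise of σ = 15–20
destroys identifiability, permuted positions give near-zero best matches,
and 15 percent variant retention still identifies the line.

`simulate_mixture` implements the simulation protocol: per-site proportions
N(q₁, σ_q) and N(1 − q₁, σ_q) normalized so their mean sum is 1, applied to
both FREQ and DP, then Gaussian FREQ noise σ_f and clipping to [0, 100].
Sites uncalled in one component carry FREQ 0 but that component's median
called depth — the profiles emulate deep RNA-seq in which coverage exists
at expressed sites without a variant call; with DP 0 instead, a
low-proportion contaminant's own variants would fall below the depth
threshold and take the strongest deconvolution signal with them.
Read-level subsampling is emulated as variant dropout with DP rescaled by
the retained fraction; the retained-variant fraction is the quantity the
robustness claim is stated in.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage between nearby sites, copy-number
and allele-specific-expression structure, RNA editing, indel/SNV error
profiles, batch effects between sequencing centers, and panel sizes in the
hundreds of lines with tens of thousands of variants each. The synthetic
background correlation is honest about level and spread but not about the
heavy relatedness tail of a real collection (same-patient lines, shared
contamination history).

## Numerical and procedural choices

* Variant keys are (chrom, pos, ref, alt) — stricter than position-only
  keying; multi-allelic VCF rows are split per alternate allele.
* FREQ parsing accepts "45.45%" and "45.45"; the internal unit is always
  percent in [0, 100].
* UPGMA is implemented directly (O(n³), panels of interest are small) with
  a deterministic lowest-index tie-break; heights equal the average-linkage
  distance 1 − ρ, Newick branch lengths use half-heights (ultrametric).
* Pairwise-matrix diagonal is fixed at ρ = 1 by convention.
* fit_null requires ≥ 50 retained correlations (configurable floor).
* Panels serialize as plain TSV matrices plus JSON metadata (freq written
  to 6 decimals, DP exactly, +∞ sentinel as "inf"); lossless round trip.
* Expression correlation keeps genes with RPKM > 0.1 in at least one of the
  two cells and runs on raw RPKM; a log2(x+1) option exists, default off.
* Test and acceptance problem sizes: 30-cell × 4,000-site panels (≈ 1,250
  variants per cell), 20 seeds for stochastic claims, 100 permutations for
  the false-positive property — chosen as the smallest sizes at which the
  studied effects are stable.

## Known limitations

* The depth of uncalled sites is an assumption, not data; `assume_covered`
  is wrong for silenced genes, and `strict` discards genuinely covered
  reference-homozygous sites. Supplying external depths is the accurate
  path when coverage tracks exist.
* The mixture model is linear in FREQ and blind to copy number; proportions
  of components below ~1 percent, or of lines absent from the panel, are
  not recoverable (the nearest panel line will be proposed with a weaker
  t-statistic instead).
* First-pass (FREQ > 0) correlations run slightly above the Eq.-1-fitted
  null on dense synthetic profiles, so borderline unrelated lines can be
  flagged for the second pass; the second pass resolves them. On sparse
  real profiles the two site rules are much closer.
* p-values far beyond the truncation bound rest on the untruncated-tail
  extension; treat them as ordering evidence, not calibrated probabilities.
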