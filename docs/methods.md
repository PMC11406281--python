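# Methods

## Screen scoring model

The screen design compares sgRNA abundances between two growth conditions
(a control arm and a treatment arm, e.g. normal vs low-serine medium, or
standard medium vs medium with amino acids at plasma levels), each grown for
a known number of population doublings `d`. A guide that changes fitness by
`rho` doublings-per-doubling changes its expected relative abundance by a
factor `2^(rho * d)` over the arm; taking the ratio between arms and
normalizing by the doubling difference `dd = d_control - d_treatment`
recovers `rho` on a per-doubling scale that is comparable across screens of
different lengths.

Per sgRNA and replicate pair `r`:

    rho_r = [ log2(RPM_treat,r / RPM_ctrl,r) - median_NTC(log2 ratio) ] / dd_r

where RPM are reads-per-million after adding a pseudocount of 10 to every
raw count. The median over non-targeting control (NTC) sgRNAs removes the
arm-level composition shift, anchoring "no effect" at zero. The final rho is
the mean over replicate pairs, followed by one more subtraction of the NTC
median of the averaged values, so the invariant "passing-NTC median rho is
exactly 0" holds in floating point, not just approximately. Replicates are
paired by index and combined at the phenotype level (averaging rhos, not
counts); with matched within-arm doublings the two choices differ only
through the nonlinearity of log2 on sampling noise.

Filtering precedes everything: an sgRNA is kept iff its raw counts summed
over the replicates of at least one arm reach 100. The pseudocount is added
after filtering, to all counts, before depth normalization.

Gene-level statistics, per gene with 10 library sgRNAs:

* **phenotype** — the mean of the signed values of the 7 strongest rhos by
  absolute magnitude (`top_k = 7`). Ties in |rho| are broken by sgRNA id so
  the statistic is deterministic. Genes with fewer than 7 but at least 3
  passing guides are scored on what they have and flagged `low_support`;
  genes under 3 passing guides are excluded rather than reported on
  meaningless support.
* **p-value** — two-sided Mann-Whitney rank-sum test of all the gene's
  passing rhos against the pool of passing NTC rhos (nominally 730). For
  pooled sizes up to 25 the p-value comes from the exact permutation
  distribution of the midrank sum, computed with the Streitberg-Röhmel shift
  algorithm on doubled midranks — exact under ties and identical to
  exhaustive enumeration of all C(n1+n2, n1) regroupings. Above that, the
  normal approximation with tie and continuity correction (scipy) is used;
  at the screen's 10-vs-730 size the approximation error is far below the
  Monte-Carlo noise of the pseudogene null. P-values are floored at the
  smallest positive double so -log10(p) stays finite.
* **volcano score** — phenotype × (−log10 p), the single ranking statistic.
  The signed product is used; hypersensitive and resistant hits sit on
  opposite flanks.

## Pseudogene null and empirical FDR

Noise is estimated by scoring simulated negative-control genes: groups of 10
NTC sgRNAs drawn without replacement within a group, independently across
groups (489 groups from a 730-guide pool necessarily reuse guides), one
pseudogene per real gene. Each pseudogene's Mann-Whitney reference pool
leaves out the pseudogene's own 10 guides, so real and simulated genes are
tested under the same geometry — a group against NTCs outside it. Testing a
group against a pool containing itself makes its p-values conservative and
measurably breaks real-vs-pseudogene exchangeability on all-null
simulations, so the leave-self-out form is the default.

For a |volcano score| threshold `s`,

    FDR(s) = #pseudogenes(|score| >= s) / max(1, #real genes(|score| >= s))

and the reported q-value at a gene's threshold is the minimum FDR over all
thresholds that still include that gene (step-down), making q monotone
non-increasing in the threshold. With matched pseudogene counts no rescaling
is needed; if `n_pseudogenes` is set differently the FDR should be read as a
ratio of counts, not of rates.

## Synthetic screens

The generator reproduces the statistical structure the scoring assumes,
with ground truth:

* geometry defaults: 489 genes × 10 sgRNAs + 730 NTCs, 2 replicates per
  arm, doublings 8.4 (control) vs 6.4 (treatment), i.e. `dd = 2`;
* library composition is log-normal (sigma 0.5) — realistic plasmid-pool
  skew; per-sample expected depth is `reads_per_sgrna ×` library size
  (default 300 reads per guide);
* counts are negative-binomial via gamma-Poisson mixing with dispersion
  0.05 (variance = mu + 0.05 mu²), a typical overdispersion for pooled
  screens sequenced at a few hundred reads per guide;
* a hit gene with effect `rho` multiplies its guides' treatment-arm weights
  by `2^(rho_guide * dd)`; per-guide `rho_guide` = gene effect × efficacy,
  efficacy ~ Normal(1, 0.2) truncated to [0, 1]. The truncation point at 1
  means zero efficacy noise plants the gene effect exactly on every guide,
  which the closed-form count-ratio checks rely on; the default 0.2 gives
  the guide-to-guide heterogeneity that makes "strongest 7 of 10"
  meaningful.

What the generator does **not** model: PCR jackpotting and other
heavy-tailed amplification artifacts, guide-specific off-target fitness
effects, sequencing error (counting is tested on separately generated FASTQ
fixtures), cell-cycle or density dependence of doublings, and T0 reference
samples (the scored comparisons are end-point condition vs condition).
Passing tests therefore demonstrate correctness of the arithmetic and
calibration under the assumed noise model, not robustness to every failure
mode of real screens.

## Isotope-tracing arithmetic

A measured mass isotopomer distribution (MID) of a fragment with formula F
and `n` tracer-labelable positions is modeled as `m = M x`, where `x` is the
true labeling distribution (fractions of molecules with 0..n tracer atoms)
and column `j` of `M` is the mass-shift distribution of a molecule with `j`
labeled positions: Binomial(j, purity) over the labeled atoms (purity 0.99
for the 13C tracer — each nominally labeled position is heavy with
probability 0.99), convolved with the natural-abundance distribution of the
remaining tracer-element atoms and of every other atom in the formula
(low-resolution mode: all elements fold into one nominal mass axis).
Natural abundances ship as packaged IUPAC values and are overridable.
Correction solves `min ||M x - m||` subject to `x >= 0` (scipy NNLS) on the
fraction-normalized measurement and renormalizes `x` to sum 1, returning the
residual norm as a fit diagnostic. Rows of `M` are truncated to the measured
window (default M+0..M+n); the NNLS inverse is exact for noise-free data at
any window at least n+1 wide because the truncated matrix keeps full column
rank. The forward generator (`simulate_mid`) implements the same physics as
a direct brute-force convolution, independent of the matrix construction, so
forward-then-invert is a genuine round-trip test, with optional
mean-preserving log-normal intensity noise.

Fragment formulas are caller-supplied and treated as authoritative (e.g. a
TBDMS-derivatized serine fragment); no derivatization chemistry or blank
subtraction is computed.

Batch internal normalization: with `u(a,s) = area(a,s) / norvaline(s)` and
`r(a,s) = u(a,s) / mean_s u(a,s)`, the per-sample factor is the mean of
`r(a,s)` over a 20+ analyte library excluding serine, glutamine and
threonine (substrates of the perturbed transporter, hence expected to change
for real biological reasons); target abundances are divided by the factor.
By construction `mean_s r(a,s) = 1` per analyte, so factors are relative to
the batch mean — a sample with all analytes doubled in a 2-sample batch gets
factor 4/3, not 2. The median is available as a robust alternative
aggregate.

Utilities: caliper tumor volume `0.5 × width² × length` (mm³), and percent
reduction in population doublings `100 × (1 − d_condition / d_reference)`,
reported both raw and rounded to the nearest integer (8.4 → 6.4 gives 24%,
6.8 → 1.3 gives 81%).

## Numerical and design choices

* Exact-match protospacer counting only, with a configurable trim window;
  reads match at most one guide because duplicate protospacers are rejected
  at library load. Mismatch-tolerant alignment is out of scope.
* rho requires a nonzero doubling difference; `dd = 0` is a configuration
  error rather than an infinite phenotype.
* The differential-essentiality comparison between two full media is the
  same pipeline with the arms relabeled; no separate code path exists.
* CLI runs fan a single global seed out to stages via CRC32 of the stage
  name, so full pipelines are byte-reproducible from one integer.
* Problem sizes in the test and acceptance suites (20 all-null screens for
  calibration, 10 planted-hit screens, 1000 enumeration cases, 100 MID
  round trips) were chosen to bound Monte-Carlo error well below the asserted
  tolerances while keeping the default suite fast.

## Known limitations

* The Mann-Whitney exact mode costs O(n1 · S) per test (S = total doubled
  rank sum); it is intended for small oracle comparisons, not for pools of
  hundreds where the asymptotic path engages anyway.
* Empirical FDR pools both volcano-score signs; with strongly asymmetric
  hit directions a per-sign FDR would be more powerful.
* The NNLS correction assumes the supplied formula covers the whole measured
  ion; an incorrect fragment formula biases the corrected labeling and shows
  up only partially in the residual.
* Depth normalization is reads-per-million within sample; UMI collapsing,
  copy-number correction and jackpot trimming are not modeled.
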