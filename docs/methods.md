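# Methods

## The statistical model

MeDIP-seq enriches methylated fragments, so the read depth observed at a
CpG dinucleotide is treated as that site's methylation level.  Two groups
(three biological replicates each) are compared site by site on the
normalized depth matrix:

* **Routing gate.** Bartlett's two-group variance-equality statistic
  against χ²(1), passing at *P* > 0.05.  Bartlett's test examines
  homoscedasticity only — it is not a normality test — but it is used
  purely to choose between the parametric and non-parametric site tests,
  which is conventional for this design.  Conventions: both group
  variances zero → *P* = 1 (perfect homoscedasticity); exactly one zero →
  *P* = 0.
* **Site tests.** Parametric route: two-sided pooled-variance *t*-test
  (equal variances justified by passing the gate).  Non-parametric route:
  two-sided Mann–Whitney U, exact by full enumeration of all balanced
  group relabelings when each group has ≤ 8 samples (mid-ranks under ties,
  conditional on the observed values), normal approximation beyond.  With
  3 vs 3 samples the exact two-sided Mann–Whitney *P* cannot go below
  2/20 = 0.1, so the non-parametric route can never reach the 0.01 seeding
  threshold; the caller emits a warning when sites are routed there.  This
  is a property of the published procedure itself at these group sizes,
  not of this implementation.
* **Seed and extend.** CpGs with site *P* < 0.01 seed regions.  A region
  absorbs each next downstream CpG that is itself significant and lies
  within 200 bp of the region edge; a non-significant CpG — whether within
  the 2 kb termination distance or beyond it — or a gap larger than the
  join window ends the region, and overlapping candidates from different
  seeds merge.  Under these rules candidates are exactly the maximal runs
  of consecutive significant CpGs with inter-site spacing ≤ 200 bp, which
  is how they are computed (vectorised run detection); a literal
  brute-force enumeration of the stated rules serves as the test oracle.
  Candidates need ≥ 5 significant CpGs.
* **Permutation FDR.** Region statistic: Σ −log₁₀(site *P*) over members —
  additive, and sensitive to both the number and the strength of
  significant CpGs (the procedure's source does not fix a statistic).
  Null: for each permutation, the site tests are re-run under a balanced
  relabeling of the group labels and the maximum region statistic over the
  re-extended candidate set is recorded (0 when no candidate forms).  The
  observed partition — the identity relabeling and its mirror image, which
  reproduce the observed two-sided statistics exactly — is excluded; the
  `+1` in the empirical *P* `(1 + #{null ≥ obs}) / (n_perm + 1)` plays the
  identity's role.  With 3 vs 3 samples only 18 other relabelings exist;
  they are enumerated first, and the remaining draws (to 1,000) resample
  one of them and additionally shift the site-to-depth assignment
  circularly, which relocates any residual signal onto unrelated CpG
  geometry.  Region *P* values are Benjamini–Hochberg adjusted (step-up,
  authored here and cross-checked against `statsmodels` in the tests) and
  regions pass at *q* < 0.01.  Directions (hyper/hypo in the first group)
  come from the normalized group means over member CpGs.

## Preprocessing conventions

* Read QC: drop iff `count(N) > 5` **or** `frac(Phred < 5) > 0.5` — both
  strict, so a 50 bp read with exactly 5 Ns or exactly half its bases at
  Phred 4 is kept.  Phred encoding is fixed at offset 33.
* Duplicate collapse keeps the coordinate-first alignment (lexicographic
  chromosome, then start); the source procedure states no tie rule.
  `n_hits` is preserved for reporting.  SAM input uses mapped,
  non-secondary records with the NH tag as `n_hits`.
* Depth at a site counts fragments overlapping the 2 bp dinucleotide
  `[pos, pos+2)`, both strands (CpG methylation is strand-symmetric).
* The "less than a 10 read depth" filter is ambiguous between per-sample,
  per-group and pooled depth.  Default: per-group **mean** raw depth ≥ 10
  in both groups, which honours the threshold while keeping power at
  n = 3; a per-sample-minimum mode is available
  (`filter_low_coverage(..., mode="per-sample")`).
* Normalization rescales each sample to its group's mean library size
  (library size = post-collapse aligned fragments).  The group's mean
  library size is invariant under the transform and within-sample ratios
  are preserved exactly.  Note that rescaling one sample's raw depths
  shifts its group's mean library and hence rescales the whole group by a
  common constant — between-sample comparisons are unaffected.

## The synthetic-data generator

The generator emulates the features of the study's data that the analysis
relies on; its defaults are the study conditions.

* **Genome.** Three chromosomes (2 Mb, 1.5 Mb, 0.7 Mb — ≈ 50,000 CpGs),
  10 kb track windows with GC ~ N(0.41, 0.05) clipped to [0, 0.9] and
  CpG_o/e ~ N(0.30, 0.05) clipped to [0, 1.2].  Expected CpG count per
  window is `len · CpG_o/e · (GC/2)²` (counts Poisson, positions uniform,
  ≥ 2 bp apart), so CpG density rises monotonically with GC — the link
  that drives the profile-module correlations.
* **Depths.** NB1 negative binomial: variance `(1 + a)·mean` with
  dispersion `a = 0.2` (gamma–Poisson with shape `mean/a`; `a → 0` is the
  Poisson limit).  The NB1 convention was chosen over NB2
  (`mean + a·mean²`) because, at a mean depth of 30 with n = 3 per group,
  NB2 noise at a = 0.2 makes 3-fold planted effects undetectable at the
  *P* < 0.01 seeding threshold, whereas NB1 matches the regime the
  procedure operates in (per-site power ≈ 0.9 at effect 3).  Baseline
  mean 30 at every CpG; group-1 samples are multiplied by the planted
  effect inside truth regions, group 2 stays at baseline.  An optional
  `density_exponent` modulates the baseline by local CpG density
  (normalized to the genome mean), making the MeDIP enrichment link
  between coverage and CpG density explicit; it is off by default so
  per-site means equal `baseline × effect` exactly.
* **Truth regions.** Planted on runs of `dmr_n_cpg = 10` consecutive CpGs
  with internal spacing ≤ 200 bp and span ≤ 2 kb (the CpG-cluster geometry
  real DMRs occupy — and the geometry the caller can, by definition,
  recover), ≥ 10 kb apart, directions alternating hyper/hypo at effect 3
  and 1/3 (configurable; `hypo` regions push the depressed group's mean to
  baseline/3, which interacts with the depth-10 filter as it would in real
  data).
* **Reads.** 50 bp reads from 100–500 bp fragments.  Fragments are clipped
  so each overlaps exactly its own CpG and no neighbouring one, and decoy
  multi-hit coordinates sort after the primary alignment; both conventions
  make per-site coverage round-trip exactly through duplicate collapse and
  depth counting, which the end-to-end tests exploit.  FASTQ reads mirror
  the fragments with configured fractions violating the N-count and
  low-quality rules.
* **Validation inputs.** Clone matrices are Bernoulli per cell; Ct tables
  follow `Ct = base + loading − log₂(expression) + noise` with the
  loading offset shared by references and targets, so 2^−ΔΔCt recovers
  the configured fold change.

What the generator does **not** emulate: real genome sequence and mapping
artefacts, fragment-boundary correlations between neighbouring CpGs,
copy-number or GC amplification biases, and batch effects.  Passing the
recovery tests therefore shows the caller is correct and well calibrated
for NB1-distributed coverage with independent sites, not that it is robust
to every artefact of real libraries.

## Annotation and profiles

* Promoter = 2 kb upstream of the TSS (strand-aware; the source never
  defines "promoter", 2 kb mirrors its flank convention); downstream =
  2 kb past the TES; introns = gene span minus exons; intergenic = the
  complement.  Flanks clip at chromosome bounds.
* A DMR takes the highest-precedence feature it overlaps by ≥ 1 bp
  (promoter > exon > intron > downstream > intergenic; precedence is
  unstated in the source — promoter-first because promoter DMRs drive the
  downstream analyses).  A DMR overlapping two genes' features counts for
  both genes; the count table counts genes once per (feature, direction)
  and counts DMRs in the intergenic column.
* Window profile: mean of member-CpG normalized depths per window
  (default 1 Mb, non-overlapping; a smaller step gives overlapping
  smoothing).  Empty windows are missing, not zero.  Chromosome
  correlations use one point per chromosome (CpG-count-weighted window
  means) with Pearson r and the two-sided *t*-transform *P*.
* Metaprofile: 2 kb flanks in 100 bp bins, body rescaled to 40 bins,
  5′→3′; bin means are site-weighted across genes; genes shorter than the
  bin count are skipped with a warning.
* Clustering: per-DMR mean depths, distance 1 − Pearson r, average
  linkage.  Pearson distance is location/scale-invariant, so separation
  requires direction-mixed DMRs (shape, not level) — which real DMR sets
  provide.

## Validation computations

* BSP: site % = methylated clones / clones; region mean = average over
  sites; text lollipop (● methylated, ○ unmethylated), ten subclones per
  region in the simulated default.
* 2^−ΔΔCt: references aggregated as the arithmetic mean of their Ct
  (equivalently the geometric mean of their quantities — the aggregation
  is unstated in the source); ΔΔCt is taken against the calibrator group's
  mean ΔCt per gene, so the calibrator's geometric-mean expression is 1.
* Fatty acids: per-sample SFA/MUFA/PUFA sums from percent-of-total species
  (per-sample total 100 ± 2 enforced), PUFA:SFA rounded to two decimals,
  and a two-sided Student *t* per class — unpaired by default (the groups
  are unrelated animals), with a paired option.
* Adipocyte volume: `V = Σ fᵢ·(π/6)·Dᵢ³ / Σ fᵢ` over histogram bins of
  mean diameter Dᵢ (µm) and cell count fᵢ — the count-weighted mean sphere
  volume; the source prints the formula only as a figure, and this is its
  standard reading.  The anthropometric body-density formula is not
  recoverable from the text and is not implemented.

## Problem sizes and numerics

* Acceptance-style recovery runs use the default genome (≈ 50k CpGs), 50
  planted 10-CpG regions at effect 3, 1,000 permutations; the test suite
  averages 20 seeds (≈ 1 min) and the acceptance script 5 recovery + 10
  null seeds.  The package's vectorised test battery (all 20 relabelings
  at once) makes one full run ≈ 2.5 s on one CPU.
* *P*-value floor 1e-300 before −log₁₀; ties in the empirical-P comparison
  broken with a 1e-12 slack toward significance; BH clipped at 1.
* Degenerate inputs: identical values across both groups → site *P* = 1;
  zero library size, empty clone matrix, zero total cell count, < 2
  samples per group, and out-of-range probabilities all raise errors
  rather than propagating NaNs.

## Known limitations

* The permutation null is limited by the 3 vs 3 design: only 9 distinct
  non-trivial group partitions exist, so the circular-shift top-up mostly
  diversifies the *spatial* null, not the labeling null.
* The non-parametric route cannot seed regions at n = 3 (see above).
* Annotation implements the five canonical gene features only, not finer
  element schemes (CpG-island shores, repeat classes), and gene-set
  enrichment is out of scope.
* The caller targets CpG-dense regions by construction (200 bp join rule);
  DMRs in sparse CpG territory are invisible to it, in this implementation
  as in the published procedure.
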