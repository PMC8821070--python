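# Methods

## Model and procedure

Germline DNA methylation is inferred from its mutational footprint rather
than measured directly. Deamination of 5-methylcytosine converts
methylated CpG sites into TpG over evolutionary time, so genes that have
been methylated in the germline are depleted of CpG dinucleotides relative
to their mononucleotide composition. In taxa with gene-body methylation of
a subset of genes, the per-CDS statistic

    O/E_CpG = (CG · l) / (C · G)

(counts taken over the whole CDS, `CG` by overlapping linear scan, `l` the
CDS length) is distributed as a mixture of a depleted and a non-depleted
population. We model the O/E vector of a species with univariate Gaussian
mixtures of one and two components, fitted by expectation–maximization,
and summarize the two-component fit by the ascending component means
(μ_low, μ_high), their distance d = μ_high − μ_low, and the mixture weight
of the low component (pct_low). The species-level call is a hard
threshold: methylation present iff **d ≥ 0.25**.

Assumptions worth keeping in mind: both gene populations are approximately
normal in O/E; depletion is strong and old enough to separate the modes (a
recent methylation loss leaves the depleted mode in place until mutation
re-equilibrates CpG content, producing a false "present"); conversely
weak, sparse or repeat-targeted methylation shifts too few genes to create
a resolvable second mode and yields a false "absent". The statistic reads
germline history only — somatic, tissue-specific methylation leaves no
CpG footprint.

### Negative control

A mononucleotide shuffle of every CDS (uniform permutation of its
characters, composition and length preserved exactly) destroys all
dinucleotide structure. Re-running the identical pipeline on the shuffled
data must yield a near-degenerate mixture with small d; this control is
wired into the CLI (`--shuffle-control`) and the acceptance script. The
shuffle is per-record, preserving the length/composition structure the
mixture fit sees, and each record's permutation stream is derived from the
top-level seed plus the record id, so one seed reproduces a whole species
file.

### Decision rules

* `distance` (default): present iff d ≥ threshold; threshold 0.25 by
  default. 0.25 is conservative — chosen to avoid false positives across a
  wide phylogenetic range; 0.2 buys sensitivity at the cost of occasional
  false positives, 0.3 only adds false negatives. The boundary counts as
  present.
* `provataris` (cross-study comparison): three-way classification —
  *bimodal depleted* if d > 0.25 (strict, as that rule defines it), μ_low
  < 0.7 and the smaller component holds > 10% of the data; otherwise
  *unimodal indicative* if pct_low ≥ 0.36; else *unimodal not indicative*.
  "Smaller component" is read as min(pct_low, 1 − pct_low).

### DNMT classification

Proteins with a DNA_methylase (PF00145) hit at full-sequence e-value
< 0.001 (strict inequality) are candidates; their architecture is the
union of all annotated domains among the eight models, accessory domains
accepted at any reported e-value. With S1 = architecture ∩
{DNMT1-RFD, zf-CXXC, BAH} and S3 = architecture ∩ {PWWP, ADD}:

| condition                         | call            |
|-----------------------------------|-----------------|
| S3 = ∅, |S1| = 3                  | DNMT1 full      |
| S3 = ∅, |S1| ∈ {1, 2}             | DNMT1 partial   |
| S1 = ∅, |S3| = 2                  | DNMT3 full      |
| S1 = ∅, |S3| = 1                  | DNMT3 partial   |
| architecture = {DNA_methylase}    | DNMT2           |
| S1 ≠ ∅ and S3 ≠ ∅                 | ambiguous       |

Two-of-three S1 domains counts as partial DNMT1 (keeping full/partial
exhaustive). DMAP_binding and CH are annotated and reported but are not
diagnostic; a candidate carrying only such extras is reported DNMT2 with
an `extra_domain` flag, and ambiguous calls carry `needs_review` — the
manual curation (alignment, phylogenetic inspection, motif checks) that
would resolve them is out of scope and deliberately not automated.

## Numerical choices

* **EM**: best of `n_init = 10` runs — one deterministic start that splits
  the sorted data into equal blocks, plus nine seeded random restarts
  (component means drawn from the data, pooled variance, uniform weights).
  Stopping when the log-likelihood improves by < 1e-6; max 500 iterations.
  The winning run's log-likelihood trace is stored and is non-decreasing
  (asserted to 1e-8 per step in the tests).
* **Variance floor** 1e-8 prevents singular components. Input with zero
  range returns a flagged degenerate fit instead of iterating.
* **AIC** = 2k − 2 ln L with k = 3c − 1 (c means, c variances, c − 1 free
  weights). Reported for both fits, never used for calling: the criterion
  prefers two components even on shuffled data once n is large.
* **pct_low** is the fitted weight of the low-mean component (the expected
  fraction of transcripts in it); the hard-assignment fraction is exposed
  alongside for comparison.
* **Degenerate CDS** (no C or no G) make O/E undefined; they are excluded
  and counted rather than set to 0, which would distort the low component.
* Components are always reported in ascending-mean order, so d ≥ 0 and all
  descriptors are invariant to label permutations.
* Reports round d to two decimals; JSON output keeps full precision.
* **Sequence normalization**: uppercase, U→T, non-N ambiguity codes → N.
  CpGs across an N are not counted and N contributes to no count except
  `l`, so masking never creates or destroys signal. Filter boundaries are
  literal: a 100-nt CDS and a CDS with exactly 5% N are kept.
* **Skewness** of the O/E distribution is the adjusted Fisher–Pearson
  standardized third moment (bias-corrected g1); sd uses the n − 1
  denominator. Both are descriptive output only.

## Synthetic data

The generator emulates exactly the features the method consumes. CDS are
drawn from a first-order Markov chain over {A,C,G,T}: target stationary
composition π (C and G each gc/2), C→G transition probability t·π_G for
target O/E t, the G column of the other rows set to
π_G(1 − t·π_C)/(1 − π_C) so that π stays exactly stationary, and each
row's remaining mass spread over A/C/T proportional to π. The long-run
dinucleotide frequency then gives f_CG/(f_C·f_G) = t exactly; a spectral
recomputation of the stationary vector double-checks the construction at
run time. Species are two-class mixtures: each CDS joins the depleted
class with probability `frac_low`; lengths are a shifted geometric
(defaults mean 1500 nt, floor 300 nt — a realistic transcript-length
scale; the exact shape is irrelevant to correctness); optional N injection
exercises the filters.

Default study condition (used by tests and the acceptance script): 5000
CDS, frac_low 0.5, O/E 0.6 vs 1.0, GC 0.42 — a clearly methylated
invertebrate-like species with true d = 0.4, well above the 0.25
threshold. What passing on such data shows: the estimator recovers known
mixture structure from realistic sample sizes and the control behaves.
What it does not show: performance on real genomes, where codon usage,
isoform redundancy, GC heterogeneity and assembly artifacts perturb O/E in
ways the chain does not model; borderline species (d near 0.25) remain
genuinely uncertain.

Synthetic `domtblout` tables realize any achievable set of DNMT calls with
plausible scores/coordinates, shuffled row order, sub-threshold catalytic
hits and unknown-model distractor rows; the generation manifest is the
oracle for round-trip tests.

## Design choices where the design was open

* Transcripts are treated independently — no per-gene isoform collapsing.
  The statistic is defined per data point (transcript), and collapsing
  rules would import annotation-specific arbitrariness.
* O/E values are not capped; extreme ratios from short, C- or G-poor CDS
  are left to the mixture fit (they land in the wide component).
* The candidacy e-value cutoff gates the catalytic domain only; accessory
  domains join the architecture at any reported e-value, since they
  describe, not screen, an already-selected candidate.
* The `MethylationDetector` estimator follows the sklearn protocol
  (`fit`/`predict`/`score`, `get_params`, trailing-underscore fitted
  attributes) so it composes with sklearn tooling; `predict` assigns CDS
  to the depleted/non-depleted component like a 1-D `GaussianMixture`.

## Known limitations

* Presence/absence only — d is monotone in, but not a calibrated estimate
  of, methylation level.
* Recent methylation loss or gain is invisible until mutation catches up.
* Repeat- or intergenic-targeted methylation is out of reach of a
  CDS-based statistic.
* The mixture is restricted to one or two Gaussian components; heavier
  tails or three-mode structures are summarized, not modeled.
* DNMT calls are architecture-based homology screening; divergent or
  fragmented proteins escape detection, and ambiguous architectures are
  only flagged, not resolved.
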