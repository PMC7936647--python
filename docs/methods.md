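# Methods

## Category schemes and classification

**SBS96.** A single-base substitution is labeled by its substitution class
(C>A, C>G, C>T, T>A, T>C, T>G) and its 5′/3′ flanking bases, with
purine-reference calls reverse-complemented so every label carries a
pyrimidine reference (`T[C>A]C`). Classification is strand-invariant by
construction; enumerating all 192 raw (ref, alt, 5′, 3′) inputs covers each
of the 96 labels exactly twice (a context and its reverse complement).

**DBS78.** Doublet substitutions — both bases of an adjacent pair changed on
the same haplotype — collapse under reverse complement from 144 valid
(ref, alt) pairs onto 78 classes over the ten canonical reference doublets
(AC, AT, CC, CG, CT, GC, TA, TC, TG, TT). The canonical label list is the
COSMIC catalog order; at import time an exhaustive enumeration verifies it
is a consistent transversal (each equivalence class represented exactly
once). A pair where only one base differs is rejected: that is one SBS seen
twice, not a DBS. Because doublet callers and SNV callers overlap, adjacent
same-sample SNVs are merged into DBS records *before* SBS cataloging, so a
doublet is never double-counted as two SBS; runs of three or more adjacent
SNVs are paired greedily left to right.

**ID83.** Indels (1–50 bp) are reduced to their inserted/deleted unit
(longest shared allele prefix/suffix stripped) and left-aligned against the
reference — shifting the event left while the preceding base equals the
unit's last base — so VCF dialect differences cannot change the label. 1-bp
events are binned by pyrimidine-collapsed base and homopolymer run length
(the run includes the deleted base, so deleting one T from a 7-T run is
`1:Del:T:5`, the 6+ bin); longer events by the number of tandem copies of
the unit adjacent in the reference; deletions whose unit occurs only once by
the longest junction microhomology between the deleted sequence's ends and
the flanks. Labels follow the COSMIC ID83 convention for interoperability
with published matrices. A window too short to resolve a run raises an
explicit error; the catalog builder retries with doubled flanks before
giving up, so only genuine contig-edge cases surface.

## Variant filtering

The cascade applies, in fixed order: quality (keep qual ≥ 40 — a "filtered
for < 40" rule reads as removal of sub-threshold calls), depth (≥ 20× in
both treated and control), alt support (≥ 4 reads), the doublet
allele-balance rule, blacklist-interval overlap, and shared-variant removal
(a (chrom, pos, ref, alt) key must occur in exactly one cohort sample —
removing clonal/germline leftovers). Because the cascade is a conjunction,
order cannot change the surviving set; it only fixes which criterion a
removal is attributed to in the report, making reports reproducible. The
allele-balance rule for doublets is a removal predicate: drop when depth
< 20 OR 0.01 < AB < 0.25 OR AB > 0.75, i.e. keep confident heterozygous
(0.25–0.75) and effectively-reference calls. The raw rule string is kept on
the policy for auditability, since its operator precedence is a
parenthesization choice. A record missing a field the policy tests raises
rather than silently passing. All thresholds are policy fields; the same
policy applies to SNVs and indels (nothing in the calling conventions
suggests separate thresholds).

Coordinates: VCF is 1-based inclusive, BED and all internal interval
arithmetic 0-based half-open; the readers are the only conversion points. A
variant whose 0-based position equals an interval end is *outside* it.

## Signature refitting

Forward selection with full re-optimization — the behavior of the widely
used R refitting tools — is the reference algorithm: starting empty, add the
signature whose optimal weight most reduces the squared reconstruction
error on the catalog's frequency vector; re-optimize all selected weights
under w ≥ 0, Σw ≤ 1 (non-negative least squares, falling back to an SLSQP
solve when the simplex bound binds); stop when the *relative* SSE
improvement drops below 10⁻³. A relative criterion is deliberate: on 96-bin
frequency vectors an absolute 10⁻³ SSE threshold would discard genuine
components of weight ≈ 0.1, whose SSE contribution is only a few 10⁻⁴.
Weights under the 0.06 detection cutoff are then zeroed and the survivors
re-optimized (re-optimization can be disabled). Reported diagnostics:
reconstruction (the raw linear combination, never renormalized), residual
SSE, and unattributed mass 1 − Σw. The refit is scale-invariant in the
catalog and its residual is non-increasing in the signature library.

## Baseline (control) subtraction by MAP attribution

Given treated-catalog weights w and profiles P, the posterior that category
c arose from signature s is wₛPₛ(c)/Σ w_s′P_s′(c) over the actively fitted
signatures. Each category is attributed to its MAP signature (ties broken by
name order and flagged); in the default hard mode, categories attributed to
a baseline signature are zeroed — each context *is attributed* to one
process — with a soft mode that instead subtracts the posterior-weighted
expected baseline count. Categories where every active signature has zero
probability keep their counts and are flagged.

The baseline set is detected from the solvent-only control: signatures with
control refit weight above 0.10. This is intentionally stricter than the
0.06 refit cutoff: control catalogs are small (a solvent control carries a
few hundred mutations at most), and at ~150 mutations a 6% weight is ~9
mutations — within multinomial sampling error of zero. Empirically, pure
noise pushes an absent signature past 0.06 in ~0.1% of control refits but
never past 0.10 (1000 replicates), and a false baseline signature is
catastrophic: if the exposure signature slips into the baseline, hard
subtraction deletes the entire treated spectrum. True baseline weights sit
at 0.4–0.6, far above either threshold. Both thresholds are parameters.

## Context-normalized rates

For each labeled compartment (genomic element, repeat class, replication
timing, chromatin state, nuclear localization), the rate is the mutation
count inside the compartment divided by the compartment's total merged
interval length, reported as log₁₀. A mutation may legitimately count in
several overlapping tracks (a site is exonic *and* early-replicating);
tracks can therefore be grouped as mutually exclusive partitions or as
independent overlays. Zero-count compartments are reported as explicitly
undefined — no pseudocount, no −inf — so downstream consumers must handle
missingness.

## Cohort analytics

The exposure profile is the mean of the treated replicates' SBS96 frequency
vectors (pooled counts available as an option; the mean weights replicates
equally regardless of burden). Tumor samples are scored by cosine
similarity to that profile. PCA of the samples × 96 frequency matrix is
centered but *not* scaled — the categories share units, and correlation-mode
scaling would inflate sparse categories — computed by SVD with the sign
convention that each component's largest-magnitude loading is positive.
Age association is OLS of similarity on age within a cohort with the
two-sided t-test on the slope. Cohort contrasts use the Mann–Whitney U
test: exact two-sided p by enumeration of all group assignments (mid-ranks
for ties, doubled smaller tail capped at 1) when m + n ≤ 12, tie-corrected
normal approximation above. SV class proportions are per-cohort fractions
of DEL/DUP/INV/TRA among all SVs; region-restricted spectra recompute the
catalog inside a BED-defined region set (e.g. cancer-gene loci) and report
substitution-class and named-category fractions beside the genome-wide
values.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *design* of a control/treated exposure
experiment so every stage is testable without sequencing data:

- A random reference (default 100 kb, GC 0.41 — the human genome-wide
  fraction) with planted homopolymer (1–8 bp) and short-tandem-repeat
  tracts (~1/kb), indexed so every SBS96 category has candidate positions.
- Per-sample mutation draws from a known signature mixture (multinomial
  over categories; per-mutation signature of origin kept as ground truth),
  placed without position collisions so VCF → catalog round trips are
  exact. Default burdens mirror a whole-genome exposure experiment: ~400
  SBS per treated clone vs ~150 in the control — the absolute counts a
  ~0.13–0.17 SBS/Mb treated burden and a lower control produce on a
  ~3 Gb genome — with the treated mixture 0.5·baseline + 0.5·exposure.
- Five deterministic synthetic signatures with pairwise cosine < 0.3
  (80% of mass on a private geometrically-decaying block, 20% uniform), so
  mixture recovery is identifiable by construction.
- Caller annotations from simple parametric models (quality ~ N(55, 10),
  so ~7% of calls fail the 40 threshold; Poisson depths; binomial support;
  a 10% uniform-AB doublet fraction) — enough material for filter tests.
- Cohorts whose exposure admixture rises linearly with age (clipped to
  [0, 1] with a warning), plus SV tables drawn from per-cohort class
  proportions.

Everything is a pure function of the seed; identical seeds give
byte-identical FASTA/VCF/TSV.

What it deliberately does **not** model: read-level noise and mapping
artifacts, mutational hotspots and chromatin-dependent rate variation,
clustered mutations, germline contamination, real COSMIC signature shapes
(flat-ish signatures are much harder to deconvolve than the synthetic
block signatures), or inter-patient burden heterogeneity in cohorts.
Passing tests therefore demonstrate the correctness of the algorithms under
clean, identifiable conditions — not that the pipeline's statistical power
on real tumors matches these numbers.

## Numerical choices and degenerate inputs

- Refit stop tolerance 10⁻³ (relative SSE), weight cutoff 0.06, baseline
  detection 0.10 — all configurable.
- NNLS solves the active-set subproblem; SLSQP (ftol 10⁻¹⁴) only when the
  Σw ≤ 1 bound is violated. The test suite cross-checks the final active
  set against an independent projected-gradient solver to 10⁻⁴ in SSE.
- Empty catalogs cannot be refit (error); empty cohort samples are skipped
  with a warning and listed.
- Pearson/cosine comparisons with zero-variance or zero-norm vectors are
  reported as undefined (NaN + warning) or raised, never coerced to 0.
- MAP ties are broken by signature name order and always flagged.
- PCA of identical samples (rank 0) errors informatively rather than
  returning arbitrary axes.
- Problem sizes in tests and the acceptance script — 100 kb genomes,
  10,000-mutation fuzz sets, 200-replicate recovery and 100-replicate
  subtraction experiments, 500-replicate null calibrations — were chosen as
  the smallest sizes at which the measured properties are stable across
  seeds.

## Known limitations

- No de novo signature extraction (NMF): the package only refits against
  provided matrices.
- No transcription-strand (192-context) classification, kataegis detection,
  or enrichment tests between genomic contexts.
- DBS detection from SNV streams merges adjacent pairs greedily; a true
  triplet multi-nucleotide variant is split into a doublet plus a singleton.
- The forward-selection refit is a greedy heuristic, as in the tools it
  mirrors; it is verified against a constrained least-squares oracle on its
  final active set, not guaranteed globally optimal over subsets.
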