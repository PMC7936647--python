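# mutspect

Somatic mutational-spectrum analysis for exposure experiments: build
SBS96/DBS78/ID83 mutation catalogs from filtered variant calls, refit them
against reference signature matrices, subtract the solvent-control baseline
by per-category MAP attribution, normalize mutation rates by genomic
context, and project tumor cohorts onto exposure signatures.

## Who this is for

Groups that expose cultured human cells to a candidate mutagen (a
plasticizer, a drug, an environmental compound), whole-genome sequence
treated clones alongside a solvent-only control, and ask: *what mutational
pattern did the exposure leave, and do human tumors carry it?* The package
covers the dry half of that study: variant filtering, catalog construction,
signature refitting with baseline removal, context-normalized rates, and
cohort-level statistics. It consumes VCF/BED/TSV and a reference FASTA; it
does not align reads or call variants.

## The model

A mutational **signature** is a probability distribution over a mutation
category scheme — the 96 trinucleotide-context single-base substitutions
(pyrimidine-strand collapsed), the 78 canonical doublet substitutions, or
the 83 indel categories (length × homopolymer/repeat context × junction
microhomology). An observed catalog **m** (counts over categories,
normalized to frequencies **f**) is modeled as a non-negative mixture of
known signatures P = [p₁ … p_K]:

```
f ≈ P w,   w ≥ 0,  Σ w ≤ 1
```

**Refitting** estimates w by iterative forward selection: add the signature
whose optimally chosen weight most reduces ‖f − Pw‖², re-optimize all
selected weights under the constraints, stop when the relative error
improvement falls below 10⁻³, then zero weights under the 0.06 detection
cutoff and re-optimize.

**Baseline subtraction** removes the processes already active in the
solvent-only control. Given fitted weights, each category c is attributed to
the signature with the highest posterior probability

```
P(s | c) = w_s p_s(c) / Σ_s' w_s' p_s'(c)
```

and every category whose MAP signature belongs to the control's signature
set is dropped from the treated catalog, leaving the exposure-specific
spectrum. Cohort samples are then scored by cosine similarity between their
SBS96 spectrum and the exposure profile (mean of the treated replicates'
frequency vectors), with OLS age regression, exact/asymptotic Mann–Whitney
cohort contrasts, centered PCA, and SV class proportions on top.

## Worked example

`examples/02_refit_and_baseline_subtraction.py` simulates a control clone
carrying two culture-acquired signatures and one treated clone with a 50%
exposure admixture, then runs the full refit + subtraction:

```
planted treated mixture: {'SYN1': 0.3, 'SYN2': 0.2, 'SYN5': 0.5}
refit weights:         {'SYN1': 0.315, 'SYN2': 0.204, 'SYN5': 0.461} (residual SSE 1.82e-03)
baseline signatures detected in the control: ['SYN1', 'SYN2']
cosine to exposure signature: 0.763 unadjusted -> 0.966 adjusted
```

The refit recovers the planted weights from 400 sampled mutations; the
control fit flags SYN1/SYN2 as baseline; after MAP subtraction the treated
spectrum's cosine similarity to the pure exposure signature rises from 0.76
to 0.97 — the culture background is gone. The other example scripts cover
catalog construction, context-normalized rates, and cohort analytics
(similarity boxplot summaries, age slopes, Mann–Whitney contrasts, PCA, SV
class fractions).

## Command line

Each pipeline stage is a subcommand over the same library:

```bash
mutspect simulate --seed 1 --outdir out            # reference + control/treated VCFs
mutspect filter   --vcf a.vcf --vcf b.vcf --blacklist bl.bed --outdir f
mutspect catalog  --records f/a.filtered.tsv --genome ref.fa --outdir c
mutspect refit    --catalog c/catalog_SBS96.tsv --signatures sigs.tsv --outdir w
mutspect attribute --catalog c/catalog_SBS96.tsv --control-sample control \
                   --signatures sigs.tsv --outdir adj
mutspect context  --records f/a.filtered.tsv --bed exonic=exons.bed --outdir ctx
mutspect cohort   --spectra tumors.tsv --meta meta.tsv --exposure treated.tsv --outdir coh
```

Every run writes a `manifest.json` (parameter hash, inputs, version);
identical config + seed reproduces outputs byte for byte. Exit codes: 0
success, 2 configuration error, 1 runtime error.

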