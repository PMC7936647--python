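"""Synthetic inputs for every pipeline stage.

Emulates the study design the pipeline targets: a solvent-only control sample
sharing a subset of mutational processes with several treated clones; per-
sample mutation catalogs drawn from known signature mixtures at realistic
whole-genome burdens (a few hundred SBS per sample, i.e. ~0.1-0.25 SBS/Mb on
a human-scale genome, here placed on a scaled-down reference); indels planted
in homopolymer and short-tandem-repeat tracts; SV call tables with configured
class proportions; and tumor cohorts whose exposure-signature admixture rises
linearly with patient age.

Every artifact is a pure function of the seed: identical seeds give
byte-identical FASTA/VCF/TSV output. Mutations are placed without position
collisions so a catalog rebuilt from the VCF equals the ground-truth tally
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import (
    DBS78,
    ID83,
    SBS96,
    GenomeAccessor,
    classify_indel,
    window_from_genome,
)
from .cohort import SampleMeta
from .signatures import SignatureMatrix
from .variants_io import SV_CLASSES, MutationRecord, SVRecord

__all__ = [
    "FieldModel",
    "CohortSpec",
    "SampleSpec",
    "SimulationConfig",
    "ReferenceIndex",
    "SimulatedSample",
    "SimulatedPair",
    "SimulatedCohorts",
    "synthetic_signatures",
    "generate_reference",
    "simulate_sample",
    "simulate_pair",
    "simulate_cohorts",
    "write_sv_table",
]

CHROM = "chrS"


# ---------------------------------------------------------------------------
# Config dataclasses
# ---------------------------------------------------------------------------

@dataclass
class FieldModel:
    """Parametric model for the caller annotations written into VCFs.

    Chosen so a realistic minority of calls fails the default filter policy
    (quality ~ N(55, 10) puts ~7% of calls under the QSS 40 threshold).
    """

    qual_mean: float = 55.0
    qual_sd: float = 10.0
    depth_tumor_mean: float = 35.0
    depth_control_mean: float = 28.0
    vaf: float = 0.5
    ab_noise_frac: float = 0.1  # fraction of doublets with uniform (bad) AB


@dataclass
class SampleSpec:
    sample_id: str
    weights: dict  # signature name -> mixture weight, sums to 1
    n_mutations: int
    n_dbs: int = 0
    n_indels: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations <= 0:
            raise ValueError("n_mutations must be > 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"sample {self.sample_id}: weights sum to {total}, not 1")


@dataclass
class CohortSpec:
    label: str
    n_samples: int
    age_range: tuple[float, float] = (45.0, 75.0)
    exposure_slope: float = 0.0  # admixture units per year of age
    baseline_admixture: float = 0.0  # exposure admixture at age_range[0]
    sv_class_props: dict | None = None  # class -> proportion
    n_sv_mean: float = 30.0


@dataclass
class SimulationConfig:
    """Study conditions for a full simulation run; the seed fixes everything."""

    seed: int
    genome_length: int = 100_000
    gc_content: float = 0.41
    indel_tract_density: float = 1.0  # planted tracts per kb
    signature_set: SignatureMatrix | None = None
    sample_specs: list[SampleSpec] | None = None
    cohort_specs: list[CohortSpec] | None = None
    fields: FieldModel = field(default_factory=FieldModel)


# ---------------------------------------------------------------------------
# Signature fixture
# ---------------------------------------------------------------------------

def synthetic_signatures(scheme=SBS96, n_signatures: int = 5) -> SignatureMatrix:
    """Deterministic, well-separated synthetic signatures (pairwise cosine < 0.3).

    Each signature puts 80% of its mass on a private block of categories with
    geometrically decaying weights and 20% uniformly across the scheme, so
    mixtures of them are identifiable in recovery experiments.
    """
    ncat = scheme.size
    block = ncat // n_signatures
    profiles = np.zeros((ncat, n_signatures))
    decay = 0.8
    for i in range(n_signatures):
        prof = np.full(ncat, 0.2 / ncat)
        lo = i * block
        peaks = decay ** np.arange(block)
        prof[lo : lo + block] += 0.8 * peaks / peaks.sum()
        profiles[:, i] = prof / prof.sum()
    names = [f"SYN{i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(scheme, names, profiles)


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

@dataclass
class ReferenceIndex:
    """A synthetic reference plus indexes of plantable mutation sites."""

    sequence: str
    chrom: str
    trinuc_positions: dict  # pyrimidine-centered trinucleotide -> center positions
    doublet_positions: dict  # canonical DBS ref doublet -> start positions
    homopolymers: list  # (start0, base, length)
    str_tracts: list  # (start0, unit, copies)
    fasta_path: Path | None = None

    def genome(self) -> GenomeAccessor:
        return GenomeAccessor({self.chrom: self.sequence})

    def candidates_sbs(self, label: str) -> np.ndarray:
        """Center positions whose plus-strand trinucleotide matches the label."""
        trinuc = label[0] + label[2] + label[6]
        return self.trinuc_positions.get(trinuc, np.empty(0, dtype=int))


_PYR_TRINUCS = [a + c + b for c in "CT" for a in "ACGT" for b in "ACGT"]
_DBS_REFS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")


def generate_reference(
    genome_length: int = 100_000,
    gc_content: float = 0.41,
    indel_tract_density: float = 1.0,
    seed: int = 0,
    outdir=None,
) -> ReferenceIndex:
    """Random reference at the requested GC with planted homopolymer (1-8 bp)
    and short-tandem-repeat tracts, plus candidate-position indexes."""
    if genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=genome_length, p=p)

    n_tracts = int(round(indel_tract_density * genome_length / 1000))
    homopolymers: list[tuple[int, str, int]] = []
    str_tracts: list[tuple[int, str, int]] = []
    # non-overlapping tract slots, 60 bp apart, away from contig edges
    slots = np.sort(
        rng.choice(np.arange(200, genome_length - 200, 60), size=n_tracts, replace=False)
    )
    for k, start in enumerate(slots):
        start = int(start)
        if k % 2 == 0:
            length = int(rng.integers(1, 9))  # homopolymer length 1-8
            base = str(rng.choice(bases))
            seq[start : start + length] = base
            # break up accidental run extension at the borders
            seq[start - 1] = str(rng.choice([b for b in "ACGT" if b != base]))
            seq[start + length] = str(rng.choice([b for b in "ACGT" if b != base]))
            homopolymers.append((start, base, length))
        else:
            unit_len = int(rng.integers(2, 6))
            copies = int(rng.integers(2, 7))
            unit = "".join(rng.choice(bases, size=unit_len))
            tract = unit * copies
            seq[start : start + len(tract)] = list(tract)
            seq[start - 1] = str(rng.choice([b for b in "ACGT" if b != unit[-1]]))
            end = start + len(tract)
            seq[end] = str(rng.choice([b for b in "ACGT" if b != unit[0]]))
            str_tracts.append((start, unit, copies))

    sequence = "".join(seq)
    trinuc_positions: dict[str, list[int]] = {t: [] for t in _PYR_TRINUCS}
    for i in range(1, genome_length - 1):
        if sequence[i] in "CT":
            trinuc_positions[sequence[i - 1 : i + 2]].append(i)
    missing = [t for t, v in trinuc_positions.items() if not v]
    if missing:
        raise ValueError(
            f"trinucleotide contexts {missing} have no candidate positions; "
            "increase genome_length"
        )
    doublet_positions: dict[str, list[int]] = {d: [] for d in _DBS_REFS}
    for i in range(1, genome_length - 2):
        d = sequence[i : i + 2]
        if d in doublet_positions:
            doublet_positions[d].append(i)

    fasta_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta_path = outdir / "reference.fa"
        with open(fasta_path, "w") as fh:
            fh.write(f">{CHROM}\n")
            for i in range(0, genome_length, 60):
                fh.write(sequence[i : i + 60] + "\n")
        import pyfaidx

        pyfaidx.Faidx(str(fasta_path))

    return ReferenceIndex(
        sequence=sequence,
        chrom=CHROM,
        trinuc_positions={t: np.array(v, dtype=int) for t, v in trinuc_positions.items()},
        doublet_positions={d: np.array(v, dtype=int) for d, v in doublet_positions.items()},
        homopolymers=homopolymers,
        str_tracts=str_tracts,
        fasta_path=fasta_path,
    )


# ---------------------------------------------------------------------------
# Sample simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSample:
    sample_id: str
    records: list
    truth: pd.DataFrame  # chrom, pos, ref, alt, category, signature
    vcf_path: Path | None = None
    truth_path: Path | None = None


def _draw_fields(rng: np.random.Generator, fields: FieldModel) -> dict:
    dpt = int(rng.poisson(fields.depth_tumor_mean))
    dpc = int(rng.poisson(fields.depth_control_mean))
    return {
        "qual": round(float(rng.normal(fields.qual_mean, fields.qual_sd)), 1),
        "depth_tumor": dpt,
        "depth_control": dpc,
        "alt_support": int(rng.binomial(max(dpt, 1), fields.vaf)),
    }


_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##INFO=<ID=QSS,Number=1,Type=Float,Description="Somatic quality score">
##INFO=<ID=DPT,Number=1,Type=Integer,Description="Read depth, treated sample">
##INFO=<ID=DPC,Number=1,Type=Integer,Description="Read depth, control sample">
##INFO=<ID=VS,Number=1,Type=Integer,Description="Reads supporting the variant">
##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance (doublet calls)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_vcf(records: Sequence[MutationRecord], path, contig_len: int) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=CHROM, length=contig_len))
        for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            info = [f"QSS={r.qual:.1f}", f"DPT={r.depth_tumor}", f"DPC={r.depth_control}",
                    f"VS={r.alt_support}"]
            if r.allele_balance is not None:
                info.append(f"AB={r.allele_balance:.3f}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.1f}\tPASS\t"
                + ";".join(info)
                + "\n"
            )


def simulate_sample(
    ref: ReferenceIndex,
    sigs: SignatureMatrix,
    spec: SampleSpec,
    seed: int,
    fields: FieldModel | None = None,
    outdir=None,
) -> SimulatedSample:
    """Draw one sample's mutations from its signature mixture and place them.

    Category counts come from a multinomial over the mixture (per-mutation
    signature of origin retained as ground truth); each SBS is placed at a
    uniformly chosen candidate trinucleotide position without collision.
    Optional doublets are placed at canonical reference doublet sites and
    indels inside the planted homopolymer/repeat tracts.
    """
    fields = fields or FieldModel()
    rng = np.random.default_rng(seed)
    genome = ref.genome()
    w_names = sorted(spec.weights)
    w = np.array([spec.weights[n] for n in w_names])
    sig_cols = {n: sigs.column(n) for n in w_names}

    used: set[int] = set()
    records: list[MutationRecord] = []
    truth_rows: list[dict] = []

    # --- SBS ---
    origin = rng.choice(len(w_names), size=spec.n_mutations, p=w)
    labels = list(SBS96.labels)
    for si, name in enumerate(w_names):
        n_s = int((origin == si).sum())
        if n_s == 0:
            continue
        cat_counts = rng.multinomial(n_s, sig_cols[name])
        for ci in np.nonzero(cat_counts)[0]:
            label = labels[ci]
            m = int(cat_counts[ci])
            cands = ref.candidates_sbs(label)
            avail = np.array([c for c in cands if c not in used], dtype=int)
            if avail.size < m:
                raise ValueError(
                    f"category {label}: {m} mutations requested but only "
                    f"{avail.size} candidate positions remain; increase genome_length"
                )
            chosen = rng.choice(avail, size=m, replace=False)
            ref_base, alt_base = label[2], label[4]
            for pos0 in sorted(int(x) for x in chosen):
                used.add(pos0)
                fv = _draw_fields(rng, fields)
                records.append(
                    MutationRecord(
                        chrom=ref.chrom, pos=pos0 + 1, ref=ref_base, alt=alt_base,
                        sample_id=spec.sample_id, **fv,
                    )
                )
                truth_rows.append(
                    {"chrom": ref.chrom, "pos": pos0 + 1, "ref": ref_base,
                     "alt": alt_base, "category": label, "signature": name}
                )

    # --- DBS (uniform over the 78 canonical classes) ---
    if spec.n_dbs:
        dbs_labels = list(DBS78.labels)
        picks = rng.integers(0, len(dbs_labels), size=spec.n_dbs)
        for li in picks:
            label = dbs_labels[int(li)]
            ref_d, alt_d = label.split(">")
            cands = ref.doublet_positions[ref_d]
            avail = [c for c in cands if c not in used and c + 1 not in used]
            if not avail:
                raise ValueError(f"no free site for doublet {label}")
            pos0 = int(rng.choice(np.array(avail)))
            used.update((pos0, pos0 + 1))
            fv = _draw_fields(rng, fields)
            if rng.random() < fields.ab_noise_frac:
                ab = float(rng.uniform(0, 1))
            else:
                ab = float(np.clip(rng.normal(0.5, 0.05), 0.0, 1.0))
            records.append(
                MutationRecord(
                    chrom=ref.chrom, pos=pos0 + 1, ref=ref_d, alt=alt_d,
                    sample_id=spec.sample_id, allele_balance=round(ab, 3), **fv,
                )
            )
            truth_rows.append(
                {"chrom": ref.chrom, "pos": pos0 + 1, "ref": ref_d, "alt": alt_d,
                 "category": label, "signature": "."}
            )

    # --- indels planted in tracts ---
    if spec.n_indels:
        tracts = [("hp",) + t for t in ref.homopolymers] + [
            ("str",) + t for t in ref.str_tracts
        ]
        order = rng.permutation(len(tracts))
        placed = 0
        for ti in order:
            if placed >= spec.n_indels:
                break
            kind, start, unit_or_base, count = tracts[int(ti)]
            unit = unit_or_base if kind == "str" else unit_or_base
            span_len = (len(unit) * count) if kind == "str" else count
            span = range(start - 1, start + span_len + 1)
            if any(s in used for s in span):
                continue
            is_del = bool(rng.integers(0, 2))
            anchor = ref.sequence[start - 1]
            if kind == "hp":
                ins_unit = unit  # single base
            else:
                ins_unit = unit
            if is_del:
                rec_ref = anchor + (ref.sequence[start] if kind == "hp" else unit)
                rec_alt = anchor
                if kind == "str":
                    rec_ref = anchor + ref.sequence[start : start + len(unit)]
            else:
                rec_ref = anchor
                rec_alt = anchor + ins_unit
            fv = _draw_fields(rng, fields)
            rec = MutationRecord(
                chrom=ref.chrom, pos=start, ref=rec_ref, alt=rec_alt,
                sample_id=spec.sample_id, **fv,
            )
            try:
                label = classify_indel(
                    rec, window_from_genome(rec, genome, flank=max(30, 6 * len(rec_ref)))
                )
            except Exception:
                continue  # tract too close to another feature; skip it
            used.update(span)
            records.append(rec)
            truth_rows.append(
                {"chrom": ref.chrom, "pos": start, "ref": rec_ref, "alt": rec_alt,
                 "category": label, "signature": "."}
            )
            placed += 1
        if placed < spec.n_indels:
            raise ValueError(
                f"only {placed}/{spec.n_indels} indels could be planted; "
                "increase genome_length or indel_tract_density"
            )

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "pos", "ref", "alt", "category", "signature"]
    ).sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)

    vcf_path = truth_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vcf_path = outdir / f"{spec.sample_id}.vcf"
        truth_path = outdir / f"{spec.sample_id}.truth.tsv"
        _write_vcf(records, vcf_path, len(ref.sequence))
        truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedSample(spec.sample_id, records, truth, vcf_path, truth_path)


# ---------------------------------------------------------------------------
# Control / treated pairs
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPair:
    control: SimulatedSample
    treated: list
    exposure_signature: str
    baseline_weights: dict
    treated_weights: dict


def simulate_pair(
    ref: ReferenceIndex,
    sigs: SignatureMatrix,
    seed: int,
    baseline_weights: dict | None = None,
    exposure_signature: str = "SYN5",
    exposure_fraction: float = 0.5,
    n_control: int = 150,
    n_treated: int = 400,
    n_treated_samples: int = 3,
    fields: FieldModel | None = None,
    outdir=None,
) -> SimulatedPair:
    """Control sample from the baseline-only mixture plus treated samples from
    baseline + exposure.

    Defaults mirror a whole-genome exposure experiment scaled to this
    package's synthetic reference: ~400 SBS per treated clone vs ~150 in the
    solvent-only control (the ~0.13-0.17 vs lower SBS/Mb contrast on a 3 Gb
    genome), with half of the treated burden exposure-derived. The truth
    tables record which mutations originate from the exposure signature.
    """
    baseline_weights = baseline_weights or {"SYN1": 0.6, "SYN2": 0.4}
    if exposure_signature in baseline_weights:
        raise ValueError("exposure signature must not be part of the baseline")
    treated_weights = {
        n: (1 - exposure_fraction) * w for n, w in baseline_weights.items()
    }
    treated_weights[exposure_signature] = exposure_fraction

    seeds = np.random.SeedSequence(seed).generate_state(n_treated_samples + 1)
    control = simulate_sample(
        ref, sigs,
        SampleSpec("control", dict(baseline_weights), n_control),
        seed=int(seeds[0] % (2**31)), fields=fields, outdir=outdir,
    )
    treated = [
        simulate_sample(
            ref, sigs,
            SampleSpec(f"treated{k + 1}", dict(treated_weights), n_treated),
            seed=int(seeds[k + 1] % (2**31)), fields=fields, outdir=outdir,
        )
        for k in range(n_treated_samples)
    ]
    return SimulatedPair(control, treated, exposure_signature,
                         dict(baseline_weights), treated_weights)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohorts:
    spectra: pd.DataFrame  # samples x categories, counts
    meta: list
    sv_records: list
    truth: pd.DataFrame  # sample_id, cohort, age, admixture
    n_clipped: int


def simulate_cohorts(
    specs: Sequence[CohortSpec],
    sigs: SignatureMatrix,
    seed: int,
    exposure_signature: str = "SYN5",
    background_weights: dict | None = None,
    n_mutations: int = 3000,
) -> SimulatedCohorts:
    """Cohorts whose exposure admixture grows linearly with age, plus SV tables.

    Per sample: admixture = baseline + slope * (age - age_min), clipped to
    [0, 1] (clips counted and warned about); the spectrum is the corresponding
    mixture of the background and the exposure signature, sampled as a
    multinomial of ``n_mutations`` draws. SV tables are drawn from the
    per-cohort class proportions.
    """
    import warnings

    if not specs:
        raise ValueError("cohort_specs must be non-empty")
    rng = np.random.default_rng(seed)
    background_weights = background_weights or {
        n: 0.25 for n in sigs.names if n != exposure_signature
    }
    bg = np.zeros(sigs.scheme.size)
    for n, w in background_weights.items():
        bg += w * sigs.column(n)
    bg = bg / bg.sum()
    expo = sigs.column(exposure_signature)

    spectra = {}
    meta: list[SampleMeta] = []
    truth_rows = []
    sv_records: list[SVRecord] = []
    n_clipped = 0
    for spec in specs:
        lo_age, hi_age = spec.age_range
        props = spec.sv_class_props or {"DEL": 0.4, "DUP": 0.25, "INV": 0.2, "TRA": 0.15}
        classes = list(SV_CLASSES)
        pvec = np.array([props.get(c, 0.0) for c in classes])
        pvec = pvec / pvec.sum()
        for k in range(spec.n_samples):
            sid = f"{spec.label}_{k:03d}"
            age = float(np.round(rng.uniform(lo_age, hi_age), 1))
            a_raw = spec.baseline_admixture + spec.exposure_slope * (age - lo_age)
            a = float(np.clip(a_raw, 0.0, 1.0))
            if a != a_raw:
                n_clipped += 1
            p = (1 - a) * bg + a * expo
            spectra[sid] = rng.multinomial(n_mutations, p)
            meta.append(SampleMeta(sid, spec.label, age))
            truth_rows.append(
                {"sample_id": sid, "cohort": spec.label, "age": age, "admixture": a}
            )
            n_sv = int(rng.poisson(spec.n_sv_mean))
            sv_classes = rng.choice(len(classes), size=n_sv, p=pvec)
            for ci in sv_classes:
                cls = classes[int(ci)]
                pos_a = int(rng.integers(1_000, 50_000_000))
                if cls == "TRA":
                    chrom_b, pos_b = "chrT", int(rng.integers(1_000, 50_000_000))
                else:
                    size = int(10 ** rng.uniform(2, 7))
                    chrom_b, pos_b = CHROM, pos_a + size
                sv_records.append(
                    SVRecord(sid, cls, CHROM, pos_a, chrom_b, pos_b,
                             support=int(rng.integers(2, 40)))
                )
    if n_clipped:
        warnings.warn(f"exposure admixture clipped to [0,1] for {n_clipped} samples")
    spectra_df = pd.DataFrame(spectra, index=list(sigs.scheme.labels)).T
    return SimulatedCohorts(
        spectra=spectra_df,
        meta=meta,
        sv_records=sv_records,
        truth=pd.DataFrame(truth_rows),
        n_clipped=n_clipped,
    )


def write_sv_table(sv_records: Sequence[SVRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id, "class": r.svclass,
                "chromA": r.chrom_a, "posA": r.pos_a,
                "chromB": r.chrom_b, "posB": r.pos_b, "support": r.support,
            }
            for r in sv_records
        ]
    )
    df.to_csv(path, sep="\t", index=False)
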