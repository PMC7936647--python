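"""Mutation category schemes and context classification.

Implements the three canonical category schemes used in somatic mutational
signature analysis:

* **SBS96** — single base substitutions in trinucleotide context, with the
  mutated base reported on the pyrimidine strand (purine-reference calls are
  reverse-complemented, so every label has a C or T reference).
* **DBS78** — doublet base substitutions (two adjacent bases changed on the
  same haplotype), collapsed by reverse complement onto 78 canonical classes
  over the ten canonical reference doublets.
* **ID83** — small insertions/deletions (1–50 bp) stratified by event length,
  pyrimidine base for 1-bp events, homopolymer/tandem-repeat context of the
  inserted/deleted unit, and junction microhomology for non-repetitive
  deletions.

Label strings follow the COSMIC conventions ("T[C>A]C", "TG>CA",
"1:Del:T:5") so catalogs interoperate with published signature matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants_io import MutationRecord

__all__ = [
    "CategoryScheme",
    "MutationCatalog",
    "ReferenceWindow",
    "GenomeAccessor",
    "ClassificationError",
    "InsufficientFlankError",
    "SBS96",
    "DBS78",
    "ID83",
    "classify_sbs",
    "classify_dbs",
    "classify_indel",
    "build_catalog",
    "merge_adjacent_snvs",
    "revcomp",
    "window_from_genome",
    "read_catalog_tsv",
    "write_catalog_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ClassificationError(ValueError):
    """A mutation cannot be assigned to a category (e.g. N in context)."""


class InsufficientFlankError(ClassificationError):
    """The reference window is too short to resolve a repeat/homopolymer run."""


# ---------------------------------------------------------------------------
# Category schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryScheme:
    """An ordered, fixed set of mutation category labels."""

    name: str
    labels: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CategoryScheme({self.name}, {self.size} categories)"


def _sbs96_labels() -> tuple[str, ...]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    return tuple(
        f"{five}[{sub}]{three}"
        for sub in subs
        for five in "ACGT"
        for three in "ACGT"
    )


# Canonical DBS78 catalog (COSMIC order).  The ten canonical reference
# doublets are AC, AT, CC, CG, CT, GC, TA, TC, TG, TT; self-reverse-
# complementary references (AT, CG, GC, TA) carry six alt classes, the
# rest nine.  Consistency (a transversal of the 144/2 reverse-complement
# classes) is checked below by exhaustive enumeration.
_DBS78_LABELS: tuple[str, ...] = (
    "AC>CA", "AC>CG", "AC>CT", "AC>GA", "AC>GG", "AC>GT", "AC>TA", "AC>TG", "AC>TT",
    "AT>CA", "AT>CC", "AT>CG", "AT>GA", "AT>GC", "AT>TA",
    "CC>AA", "CC>AG", "CC>AT", "CC>GA", "CC>GG", "CC>GT", "CC>TA", "CC>TG", "CC>TT",
    "CG>AT", "CG>GC", "CG>GT", "CG>TA", "CG>TC", "CG>TT",
    "CT>AA", "CT>AC", "CT>AG", "CT>GA", "CT>GC", "CT>GG", "CT>TA", "CT>TC", "CT>TG",
    "GC>AA", "GC>AG", "GC>AT", "GC>CA", "GC>CG", "GC>TA",
    "TA>AT", "TA>CG", "TA>CT", "TA>GC", "TA>GG", "TA>GT",
    "TC>AA", "TC>AG", "TC>AT", "TC>CA", "TC>CG", "TC>CT", "TC>GA", "TC>GG", "TC>GT",
    "TG>AA", "TG>AC", "TG>AT", "TG>CA", "TG>CC", "TG>CT", "TG>GA", "TG>GC", "TG>GT",
    "TT>AA", "TT>AC", "TT>AG", "TT>CA", "TT>CC", "TT>CG", "TT>GA", "TT>GC", "TT>GG",
)


def _build_dbs_lookup() -> dict[tuple[str, str], str]:
    """Map every both-base-changed (ref, alt) doublet pair to its canonical label.

    Built by exhaustive enumeration over the 144 valid pairs; raises at import
    time if the canonical list is not a consistent transversal.
    """
    canonical = set(_DBS78_LABELS)
    lookup: dict[tuple[str, str], str] = {}
    for ref in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
        for alt in ("".join(p) for p in itertools.product("ACGT", repeat=2)):
            if ref[0] == alt[0] or ref[1] == alt[1]:
                continue
            fwd = f"{ref}>{alt}"
            rev = f"{revcomp(ref)}>{revcomp(alt)}"
            in_fwd, in_rev = fwd in canonical, rev in canonical
            if in_fwd and in_rev and fwd != rev:
                raise AssertionError(f"DBS78 catalog ambiguous for {fwd} / {rev}")
            if not in_fwd and not in_rev:
                raise AssertionError(f"DBS78 catalog misses {fwd} / {rev}")
            lookup[(ref, alt)] = fwd if in_fwd else rev
    assert len(set(lookup.values())) == 78
    return lookup


_DBS_LOOKUP = _build_dbs_lookup()


def _id83_labels() -> tuple[str, ...]:
    labels: list[str] = []
    for base in "CT":  # 1-bp deletions, homopolymer length 1..6+ encoded 0..5
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in "CT":  # 1-bp insertions, homopolymer length 0..5+
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in range(2, 6):  # >=2 bp deletions at tandem repeats, 1..6+ copies
        labels += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in range(2, 6):  # >=2 bp insertions at tandem repeats, 0..5+ copies
        labels += [f"{size}:Ins:R:{i}" for i in range(6)]
    for size, n_bins in ((2, 1), (3, 2), (4, 3), (5, 5)):  # microhomology deletions
        labels += [f"{size}:Del:M:{i + 1}" for i in range(n_bins)]
    return tuple(labels)


SBS96 = CategoryScheme("SBS96", _sbs96_labels())
DBS78 = CategoryScheme("DBS78", _DBS78_LABELS)
ID83 = CategoryScheme("ID83", _id83_labels())

_SCHEMES = {"SBS96": SBS96, "DBS78": DBS78, "ID83": ID83}


def get_scheme(name: str) -> CategoryScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise KeyError(f"unknown category scheme {name!r}; expected one of {sorted(_SCHEMES)}")


# ---------------------------------------------------------------------------
# Reference access
# ---------------------------------------------------------------------------

class GenomeAccessor:
    """Uniform 0-based half-open access to a reference genome.

    Wraps either a plain ``{chrom: sequence}`` mapping or a ``pyfaidx.Fasta``
    object; everything downstream only needs :meth:`fetch`.
    """

    def __init__(self, source):
        self._source = source
        self._is_mapping = isinstance(source, Mapping)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0:
            raise KeyError(f"negative coordinate {start} on {chrom}")
        if self._is_mapping:
            try:
                seq = self._source[chrom]
            except KeyError:
                raise KeyError(f"chromosome {chrom!r} not in genome")
            if end > len(seq):
                raise KeyError(f"{chrom}:{start}-{end} beyond contig end ({len(seq)} bp)")
            return seq[start:end].upper()
        try:
            return str(self._source[chrom][start:end]).upper()
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome")

    def length(self, chrom: str) -> int:
        try:
            return len(self._source[chrom])
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome")


@dataclass(frozen=True)
class ReferenceWindow:
    """Reference sequence around a variant.

    ``sequence`` covers genome coordinates ``[offset, offset + len(sequence))``
    (0-based half-open) on ``chrom``; ``pos`` is the 1-based position of the
    first reference base of the variant it was extracted for.
    """

    chrom: str
    pos: int
    sequence: str
    offset: int

    def local(self, genome_pos0: int) -> int:
        """Translate a 0-based genome coordinate into an index into sequence."""
        return genome_pos0 - self.offset


def window_from_genome(
    record: MutationRecord, genome: GenomeAccessor, flank: int = 30
) -> ReferenceWindow:
    """Extract a reference window with ``flank`` bp on each side of the variant."""
    start0 = record.pos - 1
    lo = max(0, start0 - flank)
    hi = start0 + len(record.ref) + flank
    try:
        contig_len = genome.length(record.chrom)
        if start0 + len(record.ref) > contig_len:
            raise KeyError(f"{record.key()} extends beyond contig end ({contig_len} bp)")
        seq = genome.fetch(record.chrom, lo, min(hi, contig_len))
    except KeyError as exc:
        raise ClassificationError(f"locus outside genome for {record.key()}: {exc}")
    return ReferenceWindow(record.chrom, record.pos, seq, lo)


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

def classify_sbs(ref_base: str, alt_base: str, five_prime: str, three_prime: str) -> str:
    """SBS96 label for a single-base substitution in its trinucleotide context.

    Purine-reference substitutions are reverse-complemented (the flanks swap
    roles) so the label always carries a pyrimidine reference base.
    """
    for b in (ref_base, alt_base, five_prime, three_prime):
        if b not in "ACGT" or len(b) != 1:
            raise ClassificationError(
                f"cannot classify SBS with base {b!r} (context "
                f"{five_prime}[{ref_base}>{alt_base}]{three_prime})"
            )
    if ref_base == alt_base:
        raise ClassificationError("ref and alt base are identical")
    if ref_base in "AG":
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
        five_prime, three_prime = revcomp(three_prime), revcomp(five_prime)
    return f"{five_prime}[{ref_base}>{alt_base}]{three_prime}"


# ---------------------------------------------------------------------------
# DBS78
# ---------------------------------------------------------------------------

def classify_dbs(ref_doublet: str, alt_doublet: str) -> str:
    """DBS78 label for a doublet substitution where both bases changed."""
    if len(ref_doublet) != 2 or len(alt_doublet) != 2:
        raise ClassificationError("doublet alleles must be 2-mers")
    if any(b not in "ACGT" for b in ref_doublet + alt_doublet):
        raise ClassificationError(f"non-ACGT base in doublet {ref_doublet}>{alt_doublet}")
    if ref_doublet[0] == alt_doublet[0] or ref_doublet[1] == alt_doublet[1]:
        raise ClassificationError(
            f"{ref_doublet}>{alt_doublet} changes only one base; that is an SBS, not a DBS"
        )
    return _DBS_LOOKUP[(ref_doublet, alt_doublet)]


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------

def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip the longest shared prefix and suffix; returns (new_pos, core_ref, core_alt)."""
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    j = 0
    while j < min(len(ref), len(alt)) - i and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]:
        j += 1
    return pos + i, ref[i : len(ref) - j], alt[i : len(alt) - j]


def classify_indel(record: MutationRecord, window: ReferenceWindow) -> str:
    """ID83 label for a small insertion or deletion.

    The event is reduced to its inserted/deleted unit, left-aligned against the
    window, then binned: 1-bp events by pyrimidine base and homopolymer run
    length (the run includes the deleted base for deletions); longer events by
    the number of tandem copies of the unit in the reference; deletions of a
    unit present only once by the longest junction microhomology.
    """
    if record.variant_class() != "indel":
        raise ClassificationError(f"{record.key()} is not an indel")
    pos, core_ref, core_alt = _trim_alleles(record.pos, record.ref, record.alt)
    if core_ref and core_alt:
        raise ClassificationError(
            f"{record.key()} is a complex substitution, not a simple indel"
        )
    is_del = bool(core_ref)
    unit = core_ref or core_alt
    length = len(unit)
    if not 1 <= length <= 50:
        raise ClassificationError(f"indel length {length} outside 1-50 bp")
    if "N" in unit:
        raise ClassificationError(f"N base in indel unit of {record.key()}")

    seq = window.sequence
    if "N" in seq:
        raise ClassificationError(f"N base in reference window of {record.key()}")
    # locus: for deletions, index of the first deleted base; for insertions,
    # index of the first reference base after the insertion point.
    locus = window.local(pos - 1)
    if is_del and seq[locus : locus + length] != unit:
        raise ClassificationError(
            f"window sequence does not match deleted allele for {record.key()}"
        )

    # Left-align: shift the event left while the preceding reference base
    # equals the last base of the unit (rotating the unit).
    while locus > 0 and seq[locus - 1] == unit[-1]:
        unit = unit[-1] + unit[:-1]
        locus -= 1

    needed = 6 if length == 1 else 5 * length
    right_flank_start = locus + (length if is_del else 0)
    if locus < needed or len(seq) - right_flank_start < needed:
        raise InsufficientFlankError(
            f"reference window around {record.key()} too short to resolve the "
            f"repeat context; provide at least {needed} bp of flank"
        )

    if length == 1:
        base = unit
        pyr = "T" if base in "AT" else "C"
        run = 1 if is_del else 0
        k = right_flank_start
        while k < len(seq) and seq[k] == base and run < 6:
            run += 1
            k += 1
        k = locus - 1
        while k >= 0 and seq[k] == base and run < 6:
            run += 1
            k -= 1
        if is_del:
            return f"1:Del:{pyr}:{min(run, 6) - 1}"
        return f"1:Ins:{pyr}:{min(run, 5)}"

    size = min(length, 5)
    copies = 1 if is_del else 0
    cap = 6 if is_del else 5
    k = right_flank_start
    while k + length <= len(seq) and seq[k : k + length] == unit and copies < cap:
        copies += 1
        k += length
    k = locus - length
    while k >= 0 and seq[k : k + length] == unit and copies < cap:
        copies += 1
        k -= length

    if not is_del:
        return f"{size}:Ins:R:{min(copies, 5)}"
    if copies >= 2:
        return f"{size}:Del:R:{min(copies, 6) - 1}"

    # deletion of a unit present exactly once: junction microhomology between
    # the deleted sequence's ends and the flanking reference
    right = seq[locus + length : locus + 2 * length]
    left = seq[locus - length : locus]
    hom_r = 0
    while hom_r < length and hom_r < len(right) and unit[hom_r] == right[hom_r]:
        hom_r += 1
    hom_l = 0
    while hom_l < length and hom_l < len(left) and unit[-1 - hom_l] == left[-1 - hom_l]:
        hom_l += 1
    hom = max(hom_l, hom_r)
    if hom == 0:
        return f"{size}:Del:R:0"
    max_bin = {2: 1, 3: 2, 4: 3, 5: 5}[size]
    return f"{size}:Del:M:{min(hom, max_bin)}"


# ---------------------------------------------------------------------------
# Catalog construction
# ---------------------------------------------------------------------------

@dataclass
class MutationCatalog:
    """Per-sample mutation counts over a fixed category scheme."""

    sample_id: str
    scheme: CategoryScheme
    counts: np.ndarray
    n_unclassified: int = 0
    unclassified: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.scheme.size,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match scheme "
                f"{self.scheme.name} ({self.scheme.size})"
            )
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum 1 (zero vector for an empty catalog)."""
        total = self.counts.sum()
        if total == 0:
            return np.zeros(self.scheme.size)
        return self.counts / total

    def burden_per_mb(self, callable_length_bp: float) -> float:
        """Mutations per megabase of callable genome."""
        if callable_length_bp <= 0:
            raise ValueError("callable genome length must be positive")
        return self.n_total / (callable_length_bp / 1e6)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.scheme.labels), name=self.sample_id)


def merge_adjacent_snvs(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Merge immediately adjacent same-sample SNVs into doublet (DBS) records.

    Mirrors haplotype-aware doublet calling: two SNVs at consecutive positions
    in the same sample become one DBS record (greedy left-to-right pairing),
    so a doublet is never double-counted as two SBS. Non-SNV records pass
    through unchanged.
    """
    out: list[MutationRecord] = [r for r in records if r.variant_class() != "SNV"]
    snvs = sorted(
        (r for r in records if r.variant_class() == "SNV"),
        key=lambda r: (r.sample_id, r.chrom, r.pos),
    )
    i = 0
    while i < len(snvs):
        a = snvs[i]
        if (
            i + 1 < len(snvs)
            and snvs[i + 1].sample_id == a.sample_id
            and snvs[i + 1].chrom == a.chrom
            and snvs[i + 1].pos == a.pos + 1
        ):
            b = snvs[i + 1]

            def _combine(x, y, how=min):
                if x is None or y is None:
                    return None
                return how(x, y)

            out.append(
                MutationRecord(
                    chrom=a.chrom,
                    pos=a.pos,
                    ref=a.ref + b.ref,
                    alt=a.alt + b.alt,
                    sample_id=a.sample_id,
                    qual=_combine(a.qual, b.qual),
                    depth_tumor=_combine(a.depth_tumor, b.depth_tumor),
                    depth_control=_combine(a.depth_control, b.depth_control),
                    alt_support=_combine(a.alt_support, b.alt_support),
                    allele_balance=a.allele_balance,
                )
            )
            i += 2
        else:
            out.append(a)
            i += 1
    return sorted(out, key=lambda r: (r.sample_id, r.chrom, r.pos))


_CLASS_FOR_SCHEME = {"SBS96": "SNV", "DBS78": "DBS", "ID83": "indel"}


def classify_record(
    record: MutationRecord, genome: GenomeAccessor, scheme: CategoryScheme
) -> str:
    """Classify one record under the given scheme, fetching context as needed."""
    cls = record.variant_class()
    if cls != _CLASS_FOR_SCHEME[scheme.name]:
        raise ClassificationError(
            f"{record.key()} is a {cls}, not classifiable under {scheme.name}"
        )
    if scheme.name == "SBS96":
        pos0 = record.pos - 1
        ctx = genome.fetch(record.chrom, pos0 - 1, pos0 + 2)
        if len(ctx) != 3:
            raise ClassificationError(f"no flanking context at {record.key()}")
        if ctx[1] != record.ref:
            raise ClassificationError(
                f"reference mismatch at {record.key()}: genome has {ctx[1]!r}"
            )
        return classify_sbs(ctx[1], record.alt, ctx[0], ctx[2])
    if scheme.name == "DBS78":
        return classify_dbs(record.ref, record.alt)
    # left-alignment through a long repeat tract can consume flank, so retry
    # with doubled windows before giving up
    flank = max(30, 6 * abs(len(record.ref) - len(record.alt)))
    contig_len = genome.length(record.chrom)
    while True:
        try:
            return classify_indel(record, window_from_genome(record, genome, flank=flank))
        except InsufficientFlankError:
            if flank >= contig_len:
                raise
            flank *= 2


def build_catalog(
    records: Sequence[MutationRecord],
    genome,
    scheme: CategoryScheme,
    sample_id: str | None = None,
) -> MutationCatalog:
    """Tally records of the scheme's variant class into a per-sample catalog.

    Records of other variant classes are ignored (an SBS96 catalog built from
    a mixed record list counts only SNVs); records whose context cannot be
    resolved (N bases, missing flank) are reported in ``unclassified``.
    A genuine out-of-genome locus raises, naming the record.
    """
    if not isinstance(genome, GenomeAccessor):
        genome = GenomeAccessor(genome)
    sample_ids = {r.sample_id for r in records}
    if sample_id is None:
        if len(sample_ids) > 1:
            raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
        sample_id = next(iter(sample_ids)) if sample_ids else "sample"
    idx = scheme.index()
    counts = np.zeros(scheme.size, dtype=np.int64)
    unclassified: list[tuple[str, str]] = []
    want = _CLASS_FOR_SCHEME[scheme.name]
    for rec in records:
        if rec.variant_class() != want:
            continue
        try:
            label = classify_record(rec, genome, scheme)
        except KeyError as exc:
            raise ClassificationError(f"locus outside genome: {rec.key()} ({exc})")
        except ClassificationError as exc:
            unclassified.append((rec.key(), str(exc)))
            continue
        counts[idx[label]] += 1
    return MutationCatalog(
        sample_id=sample_id,
        scheme=scheme,
        counts=counts,
        n_unclassified=len(unclassified),
        unclassified=unclassified,
    )


# ---------------------------------------------------------------------------
# Catalog TSV round trip (COSMIC layout: rows = categories, columns = samples)
# ---------------------------------------------------------------------------

def write_catalog_tsv(catalogs: Iterable[MutationCatalog], path) -> None:
    catalogs = list(catalogs)
    if not catalogs:
        raise ValueError("no catalogs to write")
    schemes = {c.scheme.name for c in catalogs}
    if len(schemes) > 1:
        raise ValueError(f"catalogs mix schemes {sorted(schemes)}")
    df = pd.DataFrame(
        {c.sample_id: c.counts for c in catalogs},
        index=list(catalogs[0].scheme.labels),
    )
    df.index.name = "category"
    df.to_csv(path, sep="\t")


def read_catalog_tsv(path, scheme: CategoryScheme) -> list[MutationCatalog]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(scheme.labels):
        raise ValueError(
            f"category rows in {path} do not match scheme {scheme.name} order"
        )
    return [
        MutationCatalog(sample_id=str(col), scheme=scheme, counts=df[col].to_numpy())
        for col in df.columns
    ]
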