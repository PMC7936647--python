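"""Variant and interval IO plus the somatic-variant filtering cascade.

Reads somatic SNV/indel calls from VCF, genomic compartments from BED, and
structural-variant calls from TSV, and applies the quality / depth / support /
allele-balance / blacklist / shared-variant filter cascade used to isolate
treatment-acquired mutations from clonal or germline leftovers.

Coordinate conventions: VCF positions are 1-based inclusive; BED and all
internal interval arithmetic are 0-based half-open. The converters here are
the only place the shift happens.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MutationRecord",
    "LabeledIntervals",
    "FilterPolicy",
    "FilterReport",
    "SVRecord",
    "read_vcf",
    "apply_filters",
    "read_bed",
    "read_sv_table",
    "read_records_tsv",
    "write_records_tsv",
    "SV_CLASSES",
]

SV_CLASSES = ("DEL", "DUP", "INV", "TRA")


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant call (SNV, doublet, or indel).

    Numeric annotations missing from the source VCF are ``None`` ("unknown"),
    never silently zero; a filter that needs an unknown field raises.
    """

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    sample_id: str
    qual: float | None = None
    depth_tumor: int | None = None
    depth_control: int | None = None
    alt_support: int | None = None
    allele_balance: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele != allele.upper():
                raise ValueError(f"alleles must be uppercase: {allele!r}")

    def variant_class(self) -> str:
        """"SNV", "DBS" (both bases of a 2-mer changed), or "indel"."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if (
            len(self.ref) == 2
            and len(self.alt) == 2
            and self.ref[0] != self.alt[0]
            and self.ref[1] != self.alt[1]
        ):
            return "DBS"
        if len(self.ref) != len(self.alt):
            return "indel"
        return "MNV"

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass
class LabeledIntervals:
    """A named genomic compartment as merged half-open 0-based intervals."""

    label: str
    intervals: dict = field(default_factory=dict)  # chrom -> (starts, ends) sorted lists
    total_length: int = 0

    @classmethod
    def from_tuples(cls, label: str, tuples: Iterable[tuple[str, int, int]]) -> "LabeledIntervals":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if end <= start:
                raise ValueError(f"interval end <= start: {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, tuple[list[int], list[int]]] = {}
        total = 0
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in ivs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            merged[chrom] = (starts, ends)
            total += sum(e - s for s, e in zip(starts, ends))
        return cls(label=label, intervals=merged, total_length=total)

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position (half-open: pos0 == end is outside)."""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """Does [start0, end0) intersect any interval?"""
        if chrom not in self.intervals:
            return False
        starts, ends = self.intervals[chrom]
        i = bisect.bisect_left(starts, end0) - 1
        return i >= 0 and ends[i] > start0

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.intervals):
            starts, ends = self.intervals[chrom]
            out.extend((chrom, s, e) for s, e in zip(starts, ends))
        return out


def read_bed(path, label: str | None = None) -> LabeledIntervals:
    """Read a BED3+ file (0-based half-open) into merged labeled intervals."""
    path = Path(path)
    if label is None:
        label = path.stem
    tuples: list[tuple[str, int, int]] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read BED file {path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end <= start:
            raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
        tuples.append((chrom, start, end))
    return LabeledIntervals.from_tuples(label, tuples)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

_SYMBOLIC = ("<", "[", "]", ".")


def _info_number(info, *keys):
    for k in keys:
        v = info.get(k)
        if v is not None:
            if isinstance(v, tuple):
                v = v[0]
            return v
    return None


def read_vcf(path, sample_id: str):
    """Read a VCF 4.x file into MutationRecords.

    One record per ALT allele (multi-allelic sites split); symbolic or
    breakend ALTs are skipped and counted. Quality/depth/support annotations
    are taken from the QUAL column and the QSS/DPT/DPC/VS/AB INFO keys when
    present, and left unknown (None) otherwise.

    Returns ``(records, n_symbolic_skipped)``.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise IOError(f"cannot read VCF {path}: {exc}") from exc
    records: list[MutationRecord] = []
    skipped = 0
    for i, var in enumerate(vcf):
        info = var.INFO
        qual = _info_number(info, "QSS")
        if qual is None:
            qual = var.QUAL
        depth_tumor = _info_number(info, "DPT")
        depth_control = _info_number(info, "DPC")
        alt_support = _info_number(info, "VS")
        ab = _info_number(info, "AB")
        for alt in var.ALT:
            if not alt or any(c in alt for c in _SYMBOLIC) or "N" in alt:
                skipped += 1
                continue
            try:
                records.append(
                    MutationRecord(
                        chrom=var.CHROM,
                        pos=var.POS,
                        ref=var.REF.upper(),
                        alt=alt.upper(),
                        sample_id=sample_id,
                        qual=float(qual) if qual is not None else None,
                        depth_tumor=int(depth_tumor) if depth_tumor is not None else None,
                        depth_control=int(depth_control) if depth_control is not None else None,
                        alt_support=int(alt_support) if alt_support is not None else None,
                        allele_balance=float(ab) if ab is not None else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record #{i + 1}: {exc}") from exc
    return records, skipped


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

@dataclass
class FilterPolicy:
    """Thresholds for the somatic filtering cascade.

    Defaults follow stringent somatic calling practice: quality >= 40, >= 20x
    depth in both treated and control, >= 4 reads supporting the variant, and
    for doublet calls a removal rule ``depth < 20 OR 0.01 < AB < 0.25 OR
    AB > 0.75`` that keeps confident heterozygous/homozygous calls. The raw
    rule string is kept for auditability.
    """

    min_qual: float = 40.0
    min_depth: int = 20
    min_alt_support: int = 4
    ab_rule: tuple[float, float, float] = (0.01, 0.25, 0.75)
    blacklists: list[LabeledIntervals] = field(default_factory=list)
    drop_shared: bool = False
    ab_rule_raw: str = "DP < 20 || AB > 0.01 & AB < 0.25 | AB > 0.75"

    def __post_init__(self) -> None:
        if self.min_qual < 0 or self.min_depth < 0 or self.min_alt_support < 0:
            raise ValueError("filter thresholds must be >= 0")
        lo, het_lo, het_hi = self.ab_rule
        if not (0 <= lo <= het_lo <= het_hi <= 1):
            raise ValueError(f"allele-balance window must be ordered within [0,1]: {self.ab_rule}")


CRITERIA = ("quality", "depth", "support", "allele_balance", "blacklist", "shared")


@dataclass
class FilterReport:
    """Per-criterion removal counts, attributed to the first failing criterion."""

    n_input: int
    n_output: int
    removed: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "removed": self.removed.get(c, 0)} for c in CRITERIA]
        rows.append({"criterion": "total_removed", "removed": self.n_input - self.n_output})
        return pd.DataFrame(rows)


def _require(record: MutationRecord, name: str, value):
    if value is None:
        raise ValueError(
            f"record {record.key()} (sample {record.sample_id}) is missing "
            f"{name!r}, which the filter policy tests"
        )
    return value


def _failing_criterion(
    record: MutationRecord,
    policy: FilterPolicy,
    shared_keys: set | None,
) -> str | None:
    """First criterion the record fails, in the fixed cascade order."""
    if _require(record, "qual", record.qual) < policy.min_qual:
        return "quality"
    if (
        _require(record, "depth_tumor", record.depth_tumor) < policy.min_depth
        or _require(record, "depth_control", record.depth_control) < policy.min_depth
    ):
        return "depth"
    if _require(record, "alt_support", record.alt_support) < policy.min_alt_support:
        return "support"
    if record.variant_class() == "DBS" and record.allele_balance is not None:
        lo, het_lo, het_hi = policy.ab_rule
        ab = record.allele_balance
        # depth component of the doublet rule is already enforced above
        if (lo < ab < het_lo) or ab > het_hi:
            return "allele_balance"
    start0 = record.pos - 1
    end0 = start0 + len(record.ref)
    for bl in policy.blacklists:
        if bl.overlaps(record.chrom, start0, end0):
            return "blacklist"
    if shared_keys is not None and record.key() in shared_keys:
        return "shared"
    return None


def apply_filters(
    records: Sequence[MutationRecord],
    policy: FilterPolicy,
    cohort: Mapping[str, Sequence[MutationRecord]] | None = None,
) -> tuple[list[MutationRecord], FilterReport]:
    """Apply the filtering cascade; returns surviving records and a report.

    The order is fixed (quality -> depth -> support -> allele balance ->
    blacklist -> shared) and each removal is attributed to the first failing
    criterion, so reports are reproducible; since the cascade is a pure
    conjunction the surviving set does not depend on the order. With
    ``drop_shared`` set, a (chrom, pos, ref, alt) key must occur in exactly
    one sample of the cohort map.
    """
    shared_keys: set | None = None
    if policy.drop_shared:
        if cohort is None:
            raise ValueError("drop_shared policy requires the cohort sample map")
        key_samples: dict[tuple, set[str]] = {}
        for sid, recs in cohort.items():
            for r in recs:
                key_samples.setdefault(r.key(), set()).add(sid)
        shared_keys = {k for k, sids in key_samples.items() if len(sids) > 1}

    kept: list[MutationRecord] = []
    removed: Counter = Counter()
    for rec in records:
        crit = _failing_criterion(rec, policy, shared_keys)
        if crit is None:
            kept.append(rec)
        else:
            removed[crit] += 1
    report = FilterReport(n_input=len(records), n_output=len(kept), removed=dict(removed))
    return kept, report


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRecord:
    """A structural variant call with class, breakpoints, and read support."""

    sample_id: str
    svclass: str  # DEL / DUP / INV / TRA
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    support: int

    @property
    def size(self) -> int | None:
        """Event size in bp; undefined (None) for interchromosomal events."""
        if self.svclass == "TRA" or self.chrom_a != self.chrom_b:
            return None
        return abs(self.pos_b - self.pos_a)

    @property
    def size_bin(self) -> str:
        """Log10 size bin on the 10^2-10^7 bp grid; "interchromosomal" for TRA."""
        size = self.size
        if size is None:
            return "interchromosomal"
        if size < 100:
            return "<1e2"
        for exp in range(2, 7):
            if size < 10 ** (exp + 1):
                return f"[1e{exp},1e{exp + 1})"
        return ">=1e7"

    @property
    def below_min_support(self) -> bool:
        """Flags calls under the minimum of four spanning/split reads."""
        return self.support < 4


def read_sv_table(path) -> list[SVRecord]:
    """Read a tab-delimited SV table with header
    ``sample_id class chromA posA chromB posB support``."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "class", "chromA", "posA", "chromB", "posB", "support"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SV table missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        svclass = str(row[df.columns.get_loc("class")])
        if svclass not in SV_CLASSES:
            raise ValueError(f"{path}: unknown SV class {svclass!r}; expected {SV_CLASSES}")
        records.append(
            SVRecord(
                sample_id=str(row.sample_id),
                svclass=svclass,
                chrom_a=str(row.chromA),
                pos_a=int(row.posA),
                chrom_b=str(row.chromB),
                pos_b=int(row.posB),
                support=int(row.support),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Record TSV round trip (pipeline intermediate)
# ---------------------------------------------------------------------------

_REC_COLS = [
    "sample_id", "chrom", "pos", "ref", "alt",
    "qual", "depth_tumor", "depth_control", "alt_support", "allele_balance",
]


def write_records_tsv(records: Sequence[MutationRecord], path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in _REC_COLS} for r in records],
                      columns=_REC_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    out = []
    for row in df.itertuples(index=False):
        def _opt(v, cast):
            return None if pd.isna(v) else cast(v)
        out.append(
            MutationRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                qual=_opt(row.qual, float),
                depth_tumor=_opt(row.depth_tumor, int),
                depth_control=_opt(row.depth_control, int),
                alt_support=_opt(row.alt_support, int),
                allele_balance=_opt(row.allele_balance, float),
            )
        )
    return out
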