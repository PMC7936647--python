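"""Cohort-level analytics: projection of tumor spectra onto exposure
signatures, PCA of SBS96 spectra, age regression of similarity scores,
inter-cohort Mann-Whitney comparison, SV class proportions, and
region-restricted spectra.

The exposure profile of a treatment is the mean of the treated replicates'
SBS96 frequency vectors (pooled counts available as an alternative); each
tumor sample is then scored by the cosine similarity between its spectrum
and that profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import CategoryScheme, GenomeAccessor, MutationCatalog, build_catalog
from .signatures import cosine_similarity
from .variants_io import LabeledIntervals, MutationRecord, SVRecord

__all__ = [
    "SampleMeta",
    "ExposureProfile",
    "similarity_to_exposure",
    "summarize_by_cohort",
    "PCAResult",
    "pca_spectra",
    "RegressionResult",
    "age_regression",
    "compare_cohorts",
    "sv_class_proportions",
    "RegionSpectrum",
    "region_subset_spectrum",
    "read_meta_tsv",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: cohort label and (optional) patient age in years."""

    sample_id: str
    cohort: str
    age: float | None = None

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")


def read_meta_tsv(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    out = []
    for row in df.itertuples(index=False):
        age = None if "age" not in df.columns or pd.isna(row.age) else float(row.age)
        out.append(SampleMeta(row.sample_id, row.cohort, age))
    return out


@dataclass
class ExposureProfile:
    """An exposure's SBS96 spectrum: mean of the treated replicate frequencies."""

    name: str
    spectrum: np.ndarray
    scheme: CategoryScheme

    def __post_init__(self) -> None:
        self.spectrum = np.asarray(self.spectrum, dtype=float)
        if (self.spectrum < 0).any():
            raise ValueError("exposure spectrum must be non-negative")
        total = self.spectrum.sum()
        if total <= 0:
            raise ValueError("exposure spectrum must have positive mass")
        self.spectrum = self.spectrum / total

    @classmethod
    def from_catalogs(
        cls, name: str, catalogs: Sequence[MutationCatalog], method: str = "mean"
    ) -> "ExposureProfile":
        """Build from treated replicates: 'mean' of frequency vectors (default)
        or 'pooled' counts."""
        if not catalogs:
            raise ValueError("need at least one catalog")
        scheme = catalogs[0].scheme
        if method == "mean":
            spec = np.mean([c.frequencies for c in catalogs], axis=0)
        elif method == "pooled":
            spec = np.sum([c.counts for c in catalogs], axis=0).astype(float)
        else:
            raise ValueError(f"method must be 'mean' or 'pooled', got {method!r}")
        return cls(name, spec, scheme)


def similarity_to_exposure(
    catalogs: Iterable[MutationCatalog], profile: ExposureProfile
) -> pd.DataFrame:
    """Cosine similarity of each sample's spectrum to the exposure profile.

    Empty catalogs are skipped with a warning and listed with NaN similarity.
    """
    rows = []
    for cat in catalogs:
        if cat.scheme.name != profile.scheme.name:
            raise ValueError(
                f"scheme mismatch for {cat.sample_id}: {cat.scheme.name} vs "
                f"{profile.scheme.name}"
            )
        if cat.n_total == 0:
            warnings.warn(f"sample {cat.sample_id} has an empty catalog; skipped")
            rows.append({"sample_id": cat.sample_id, "similarity": np.nan, "skipped": True})
            continue
        rows.append(
            {
                "sample_id": cat.sample_id,
                "similarity": cosine_similarity(cat.frequencies, profile.spectrum),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "similarity", "skipped"])


def summarize_by_cohort(scores: pd.DataFrame, meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Per-cohort median and quartiles of similarity scores (boxplot summary)."""
    cohort_of = {m.sample_id: m.cohort for m in meta}
    df = scores.loc[~scores["skipped"]].copy()
    df["cohort"] = df["sample_id"].map(cohort_of)
    g = df.groupby("cohort")["similarity"]
    return pd.DataFrame(
        {
            "n": g.size(),
            "q1": g.quantile(0.25),
            "median": g.median(),
            "q3": g.quantile(0.75),
        }
    ).reset_index()


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # categories x components
    explained_variance_ratio: np.ndarray


def pca_spectra(freqs) -> PCAResult:
    """PCA of a samples x categories frequency matrix.

    Centered but not scaled (the categories share units, so correlation-mode
    scaling would inflate sparse categories); eigen-decomposition via SVD of
    the centered matrix. Sign convention: the largest-magnitude loading of
    each component is positive. Explained-variance fractions sum to 1.
    """
    X = np.asarray(freqs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("PCA needs a 2-D matrix with at least 3 samples")
    Xc = X - X.mean(axis=0)
    total_var = float((Xc ** 2).sum())
    if total_var <= 1e-300:
        raise ValueError("samples are identical (rank-0 matrix); PCA is undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    ratio = (S ** 2) / (S ** 2).sum()
    return PCAResult(scores=scores, loadings=Vt.T, explained_variance_ratio=ratio)


# ---------------------------------------------------------------------------
# Age regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_pvalue: float
    r_squared: float
    n: int


def age_regression(
    scores: pd.DataFrame, meta: Sequence[SampleMeta], cohort: str
) -> RegressionResult:
    """OLS of similarity on patient age within one cohort, with the two-sided
    t-test on the slope."""
    meta_by_id = {m.sample_id: m for m in meta}
    xs, ys = [], []
    for row in scores.itertuples(index=False):
        m = meta_by_id.get(row.sample_id)
        if m is None or m.cohort != cohort or m.age is None or np.isnan(row.similarity):
            continue
        xs.append(m.age)
        ys.append(row.similarity)
    if len(xs) < 3:
        raise ValueError(f"cohort {cohort!r} has fewer than 3 aged samples")
    xs = np.asarray(xs)
    if np.ptp(xs) == 0:
        raise ValueError(f"cohort {cohort!r} has constant age; slope is not identifiable")
    res = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_pvalue=float(res.pvalue),
        r_squared=float(res.rvalue ** 2),
        n=len(xs),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney cohort comparison
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: pairwise wins plus half-ties."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def compare_cohorts(scores_a, scores_b, exact_max_total: int = 12):
    """Mann-Whitney U (for group A) with a two-sided p-value.

    Exact p by enumeration of all group assignments when m+n <= 12 (handles
    ties); tie-corrected normal approximation otherwise. The two-sided exact
    p doubles the smaller tail probability, capped at 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 samples")
    u = _u_statistic(a, b)
    m, n = a.size, b.size
    if m + n <= exact_max_total:
        pooled = np.concatenate([a, b])
        idx = range(m + n)
        n_assign = comb(m + n, m)
        us = np.empty(n_assign)
        for k, pick in enumerate(combinations(idx, m)):
            mask = np.zeros(m + n, dtype=bool)
            mask[list(pick)] = True
            us[k] = _u_statistic(pooled[mask], pooled[~mask])
        lo = float((us <= u + 1e-9).mean())
        hi = float((us >= u - 1e-9).mean())
        p = min(1.0, 2.0 * min(lo, hi))
        return u, p, "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue), "normal"


# ---------------------------------------------------------------------------
# SV class proportions
# ---------------------------------------------------------------------------

def sv_class_proportions(
    sv_records: Sequence[SVRecord], cohort_of: dict[str, str]
) -> pd.DataFrame:
    """Per-cohort count and fraction of each SV class (DEL/DUP/INV/TRA).

    Cohorts with zero SVs are simply absent; samples without a cohort label
    raise. Fractions sum to 1 within each cohort.
    """
    rows = []
    for r in sv_records:
        if r.sample_id not in cohort_of:
            raise KeyError(f"sample {r.sample_id!r} has no cohort label")
        rows.append({"cohort": cohort_of[r.sample_id], "svclass": r.svclass})
    if not rows:
        warnings.warn("no SV records; empty proportions table")
        return pd.DataFrame(columns=["cohort", "svclass", "count", "fraction"])
    df = pd.DataFrame(rows)
    counts = df.groupby(["cohort", "svclass"]).size().rename("count").reset_index()
    full = []
    for cohort, grp in counts.groupby("cohort"):
        total = grp["count"].sum()
        by_class = dict(zip(grp["svclass"], grp["count"]))
        for cls in ("DEL", "DUP", "INV", "TRA"):
            c = int(by_class.get(cls, 0))
            full.append(
                {"cohort": cohort, "svclass": cls, "count": c, "fraction": c / total}
            )
    return pd.DataFrame(full)


# ---------------------------------------------------------------------------
# Region-restricted spectra
# ---------------------------------------------------------------------------

@dataclass
class RegionSpectrum:
    """SBS96 spectrum restricted to a region set, with genome-wide comparison."""

    subset_catalog: MutationCatalog
    full_catalog: MutationCatalog
    subset_class_fractions: pd.Series
    full_class_fractions: pd.Series
    subset_category_fractions: pd.Series
    full_category_fractions: pd.Series
    empty: bool


def _class_fractions(catalog: MutationCatalog) -> pd.Series:
    freq = catalog.frequencies
    out = {}
    for cls in SUBSTITUTION_CLASSES:
        mask = [f"[{cls}]" in lab for lab in catalog.scheme.labels]
        out[cls] = float(freq[mask].sum())
    return pd.Series(out)


def region_subset_spectrum(
    records: Sequence[MutationRecord],
    regions: LabeledIntervals,
    genome,
    scheme: CategoryScheme,
    focus_categories: Sequence[str] = (),
    sample_id: str | None = None,
) -> RegionSpectrum:
    """Catalog of the mutations inside ``regions`` plus substitution-class and
    named-category fractions, next to the genome-wide values for contrast."""
    if regions.total_length <= 0:
        raise ValueError(f"region set {regions.label!r} is empty")
    if not isinstance(genome, GenomeAccessor):
        genome = GenomeAccessor(genome)
    inside = [r for r in records if regions.contains(r.chrom, r.pos - 1)]
    sub = build_catalog(inside, genome, scheme, sample_id=sample_id)
    full = build_catalog(records, genome, scheme, sample_id=sample_id)
    idx = scheme.index()
    for cat in focus_categories:
        if cat not in idx:
            raise KeyError(f"unknown category {cat!r} for scheme {scheme.name}")
    sub_freq, full_freq = sub.frequencies, full.frequencies
    focus_sub = pd.Series({c: float(sub_freq[idx[c]]) for c in focus_categories})
    focus_full = pd.Series({c: float(full_freq[idx[c]]) for c in focus_categories})
    return RegionSpectrum(
        subset_catalog=sub,
        full_catalog=full,
        subset_class_fractions=_class_fractions(sub),
        full_class_fractions=_class_fractions(full),
        subset_category_fractions=focus_sub,
        full_category_fractions=focus_full,
        empty=sub.n_total == 0,
    )
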