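"""Signature refitting, baseline subtraction by MAP attribution, and spectrum
similarity.

A mutational signature is a probability distribution over a category scheme;
"refitting" estimates non-negative mixture weights of known signatures in an
observed catalog. The refit here uses iterative forward selection with full
re-optimization of the active set at every step (the behavior of the widely
used R refitting tools): starting from an empty set, the signature whose
optimally chosen weight most reduces the squared reconstruction error is
added, all selected weights are re-optimized under w >= 0 and sum(w) <= 1,
and the loop stops when the relative error improvement falls below a
tolerance. Weights below a detection cutoff are zeroed and the remainder
re-optimized.

Baseline subtraction follows the per-category maximum a posteriori
attribution scheme: given fitted weights w and signature profiles P, the
posterior that category c arose from signature s is
``w_s P(c|s) / sum_s' w_s' P(c|s')``; every category attributed (MAP) to a
baseline signature — the processes already active in the solvent-only
control — is removed from the treated catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .catalog import CategoryScheme, MutationCatalog

__all__ = [
    "SignatureMatrix",
    "RefitResult",
    "AttributionResult",
    "refit",
    "attribute_and_subtract",
    "baseline_signature_set",
    "compare_to_published",
    "cosine_similarity",
]


@dataclass
class SignatureMatrix:
    """Column-stochastic reference signatures over one category scheme."""

    scheme: CategoryScheme
    names: list[str]
    profiles: np.ndarray  # shape (n_categories, n_signatures)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (self.scheme.size, len(self.names)):
            raise ValueError(
                f"profiles shape {self.profiles.shape} does not match "
                f"({self.scheme.size}, {len(self.names)})"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if (self.profiles < -1e-12).any():
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = [n for n, s in zip(self.names, sums) if abs(s - 1) > 1e-8]
            raise ValueError(f"signature columns must sum to 1: {bad}")

    def column(self, name: str) -> np.ndarray:
        return self.profiles[:, self.names.index(name)]

    def subset(self, names) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(self.scheme, list(names), self.profiles[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=list(self.scheme.labels), columns=self.names)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "category"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, scheme: CategoryScheme) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(scheme.labels):
            raise ValueError(f"{path}: rows do not match {scheme.name} label order")
        return cls(scheme, [str(c) for c in df.columns], df.to_numpy(float))


@dataclass
class RefitResult:
    """Non-negative signature weights and reconstruction diagnostics."""

    weights: pd.Series  # over all signature names, zeros for unselected
    reconstruction: np.ndarray  # raw linear combination profiles @ weights
    residual_error: float  # sum of squared differences
    unattributed: float  # 1 - sum(weights)
    cutoff_applied: float


def _solve_active(P: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, float]:
    """min ||f - P w||^2 s.t. w >= 0, sum(w) <= 1.

    NNLS solves the unconstrained-sum problem; if its solution violates the
    simplex bound, re-solve with SLSQP under the explicit constraint.
    """
    w, _ = nnls(P, f)
    if w.sum() <= 1.0 + 1e-10:
        r = f - P @ w
        return w, float(r @ r)

    def obj(x):
        r = P @ x - f
        return float(r @ r)

    def grad(x):
        return 2.0 * P.T @ (P @ x - f)

    k = P.shape[1]
    x0 = w / w.sum()
    res = minimize(
        obj,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                      "jac": lambda x: -np.ones_like(x)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    x = np.clip(res.x, 0.0, None)
    if x.sum() > 1.0:
        x = x / x.sum()
    r = f - P @ x
    return x, float(r @ r)


def refit(
    catalog: MutationCatalog,
    sigs: SignatureMatrix,
    cutoff: float = 0.06,
    tol: float = 1e-3,
    reoptimize_after_cutoff: bool = True,
) -> RefitResult:
    """Estimate non-negative signature weights for a catalog by forward selection.

    Parameters
    ----------
    cutoff
        Weights below this value are zeroed after convergence (default 0.06,
        the customary refitting detection limit); the surviving set is
        re-optimized unless ``reoptimize_after_cutoff`` is False.
    tol
        Stop when the relative improvement in squared error from adding the
        best next signature falls below this fraction.
    """
    if catalog.scheme.name != sigs.scheme.name:
        raise ValueError(
            f"scheme mismatch: catalog {catalog.scheme.name} vs signatures {sigs.scheme.name}"
        )
    if catalog.n_total == 0:
        raise ValueError(f"cannot refit empty catalog {catalog.sample_id!r}")
    f = catalog.frequencies
    n_sigs = len(sigs.names)
    active: list[int] = []
    best_sse = float(f @ f)
    weights_active = np.zeros(0)

    while len(active) < n_sigs:
        best = None
        for j in range(n_sigs):
            if j in active:
                continue
            P = sigs.profiles[:, active + [j]]
            w, sse = _solve_active(P, f)
            if best is None or sse < best[1]:
                best = (j, sse, w)
        j, sse, w = best
        if best_sse > 0 and (best_sse - sse) / best_sse < tol:
            break
        active.append(j)
        weights_active = w
        best_sse = sse

    full = np.zeros(n_sigs)
    full[active] = weights_active
    if cutoff > 0:
        full[full < cutoff] = 0.0
        surviving = list(np.nonzero(full)[0])
        if reoptimize_after_cutoff and len(surviving) < len(active) and surviving:
            w, _ = _solve_active(sigs.profiles[:, surviving], f)
            full[:] = 0.0
            full[surviving] = w
    recon = sigs.profiles @ full
    resid = f - recon
    return RefitResult(
        weights=pd.Series(full, index=sigs.names),
        reconstruction=recon,
        residual_error=float(resid @ resid),
        unattributed=float(1.0 - full.sum()),
        cutoff_applied=cutoff,
    )


@dataclass
class AttributionResult:
    """Per-category MAP attribution and baseline-subtracted counts."""

    map_signature: pd.Series  # category -> signature name (or None where undefined)
    posterior: pd.DataFrame  # categories x active signatures
    adjusted_counts: np.ndarray
    ties: list[str] = field(default_factory=list)  # categories with MAP ties
    undefined: list[str] = field(default_factory=list)  # zero total probability
    refit_result: RefitResult | None = None


def attribute_and_subtract(
    treated: MutationCatalog,
    sigs: SignatureMatrix,
    baseline_names,
    mode: str = "hard",
    **refit_kwargs,
) -> AttributionResult:
    """Attribute each category to its MAP signature and remove baseline mass.

    In the default "hard" mode a category whose MAP signature is in
    ``baseline_names`` is zeroed entirely (each context *is attributed* to one
    signature); in "soft" mode the posterior-weighted expected baseline count
    is subtracted instead. Categories where every active signature has zero
    probability keep their counts and are flagged as undefined; MAP ties are
    broken by signature name order and flagged.
    """
    baseline_names = list(baseline_names)
    unknown = [n for n in baseline_names if n not in sigs.names]
    if unknown:
        raise ValueError(f"baseline signatures not in matrix: {unknown}")
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")

    rr = refit(treated, sigs, **refit_kwargs)
    w = rr.weights.to_numpy()
    active_idx = np.nonzero(w > 0)[0]
    if active_idx.size == 0:
        raise ValueError("refit selected no signatures; cannot attribute")
    active_names = [sigs.names[i] for i in active_idx]
    P = sigs.profiles[:, active_idx]  # (ncat, nactive)
    num = P * w[active_idx]
    z = num.sum(axis=1)
    ncat = treated.scheme.size
    posterior = np.full((ncat, len(active_idx)), np.nan)
    defined = z > 0
    posterior[defined] = num[defined] / z[defined, None]

    labels = list(treated.scheme.labels)
    map_sig: list[str | None] = []
    ties: list[str] = []
    undefined: list[str] = []
    baseline_mask = np.zeros(ncat, dtype=bool)
    for c in range(ncat):
        if not defined[c]:
            map_sig.append(None)
            undefined.append(labels[c])
            continue
        row = posterior[c]
        top = row.max()
        winners = [active_names[k] for k in np.nonzero(np.isclose(row, top, atol=1e-12))[0]]
        if len(winners) > 1:
            ties.append(labels[c])
        winner = sorted(winners)[0]
        map_sig.append(winner)
        if winner in baseline_names:
            baseline_mask[c] = True

    counts = treated.counts.astype(float)
    if mode == "hard":
        adjusted = counts.copy()
        adjusted[baseline_mask] = 0.0
    else:
        base_cols = [k for k, n in enumerate(active_names) if n in baseline_names]
        frac = np.zeros(ncat)
        if base_cols:
            frac[defined] = posterior[np.ix_(defined, base_cols)].sum(axis=1)
        adjusted = counts * (1.0 - frac)
    adjusted = np.clip(adjusted, 0.0, counts)

    return AttributionResult(
        map_signature=pd.Series(map_sig, index=labels),
        posterior=pd.DataFrame(posterior, index=labels, columns=active_names),
        adjusted_counts=adjusted,
        ties=ties,
        undefined=undefined,
        refit_result=rr,
    )


def baseline_signature_set(
    control: MutationCatalog,
    sigs: SignatureMatrix,
    min_weight: float = 0.10,
    **refit_kwargs,
) -> list[str]:
    """Signatures active in the control (solvent-only) sample.

    A signature joins the baseline set when its control refit weight exceeds
    ``min_weight``. The default (0.10) is stricter than the refit reporting
    cutoff (0.06) on purpose: control catalogs are small (a solvent-only
    sample carries few mutations), and at ~150 mutations a 6% weight is
    ~9 mutations — within multinomial sampling error of zero. Declaring such
    a signature "present in the control" would subtract genuine exposure
    signal from every treated sample.
    """
    rr = refit(control, sigs, **refit_kwargs)
    return [n for n, w in rr.weights.items() if w > min_weight]


def compare_to_published(catalog: MutationCatalog, sigs: SignatureMatrix) -> pd.Series:
    """Pearson correlation of the catalog frequency vector with each signature.

    Zero-variance inputs (uniform spectra) make the correlation undefined;
    such entries are NaN and a warning is emitted.
    """
    if catalog.n_total == 0:
        raise ValueError("cannot correlate an empty catalog")
    if catalog.scheme.name != sigs.scheme.name:
        raise ValueError("scheme mismatch between catalog and signatures")
    f = catalog.frequencies
    out = {}
    fc = f - f.mean()
    fv = float(fc @ fc)
    for k, name in enumerate(sigs.names):
        s = sigs.profiles[:, k]
        sc = s - s.mean()
        sv = float(sc @ sc)
        if fv == 0.0 or sv == 0.0:
            warnings.warn(f"correlation with {name} undefined (zero variance)")
            out[name] = np.nan
        else:
            out[name] = float(fc @ sc) / np.sqrt(fv * sv)
    return pd.Series(out, name=catalog.sample_id)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two spectra: dot(a,b)/(|a||b|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))
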