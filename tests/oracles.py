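"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: classification works by
direct exhaustive scanning of the reference string, the constrained
least-squares oracle is a projected-gradient iteration, and the Mann-Whitney
oracle enumerates rank-sum statistics over explicit index subsets.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(s):
    return "".join(_COMP[b] for b in reversed(s))


# ---------------------------------------------------------------------------
# SBS96: table built by enumeration from the pyrimidine-collapse definition
# ---------------------------------------------------------------------------

def sbs_label_bruteforce(ref, alt, five, three):
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return f"{_COMP[three]}[{_COMP[ref]}>{_COMP[alt]}]{_COMP[five]}"


# ---------------------------------------------------------------------------
# DBS78: reverse-complement equivalence classes of the 144 valid pairs
# ---------------------------------------------------------------------------

def dbs_equivalence_classes():
    """frozenset of {'XY>AB', rc} strings, one per class; must have 78 members."""
    classes = set()
    bases = "ACGT"
    for r0 in bases:
        for r1 in bases:
            for a0 in bases:
                for a1 in bases:
                    if a0 == r0 or a1 == r1:
                        continue
                    fwd = f"{r0}{r1}>{a0}{a1}"
                    rev = f"{rc(r0 + r1)}>{rc(a0 + a1)}"
                    classes.add(frozenset((fwd, rev)))
    return classes


# ---------------------------------------------------------------------------
# ID83: exhaustive-scan classifier on the raw reference string
# ---------------------------------------------------------------------------

def indel_label_bruteforce(seq, pos1, ref, alt):
    """ID83 label by direct scanning of the full reference string.

    seq: whole chromosome string; pos1: 1-based VCF position.
    """
    # strip shared prefix/suffix
    i = 0
    while i < min(len(ref), len(alt)) and ref[i] == alt[i]:
        i += 1
    j = 0
    while j < min(len(ref), len(alt)) - i and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]:
        j += 1
    core_ref = ref[i: len(ref) - j]
    core_alt = alt[i: len(alt) - j]
    assert not (core_ref and core_alt), "not a simple indel"
    is_del = bool(core_ref)
    unit = core_ref or core_alt
    L = len(unit)
    start = pos1 - 1 + i  # 0-based: first deleted base / first base after insertion

    # leftmost equivalent placement: slide while the preceding base equals the
    # unit's last base (rotating the unit)
    u = unit
    s = start
    while s > 0 and seq[s - 1] == u[-1]:
        u = u[-1] + u[:-1]
        s -= 1

    if L == 1:
        b = u
        pyr = "T" if b in "AT" else "C"
        run = 0
        k = s + (1 if is_del else 0)
        while k < len(seq) and seq[k] == b:
            run += 1
            k += 1
        k = s - 1
        while k >= 0 and seq[k] == b:
            run += 1
            k -= 1
        if is_del:
            run += 1  # the deleted base itself
            return f"1:Del:{pyr}:{min(run, 6) - 1}"
        return f"1:Ins:{pyr}:{min(run, 5)}"

    size = min(L, 5)
    # tandem copies of the unit adjacent in the reference
    copies = 1 if is_del else 0
    k = s + (L if is_del else 0)
    while seq[k: k + L] == u and k + L <= len(seq):
        copies += 1
        k += L
    k = s - L
    while k >= 0 and seq[k: k + L] == u:
        copies += 1
        k -= L
    if not is_del:
        return f"{size}:Ins:R:{min(copies, 5)}"
    if copies >= 2:
        return f"{size}:Del:R:{min(copies, 6) - 1}"
    hom = 0
    for k in range(1, L):
        if seq[s + L: s + L + k] == u[:k]:
            hom = max(hom, k)
        if seq[s - k: s] == u[L - k:]:
            hom = max(hom, k)
    if hom == 0:
        return f"{size}:Del:R:0"
    max_bin = {2: 1, 3: 2, 4: 3, 5: 5}[size]
    return f"{size}:Del:M:{min(hom, max_bin)}"


# ---------------------------------------------------------------------------
# Constrained least squares by projected gradient (refit oracle)
# ---------------------------------------------------------------------------

def _project_capped_simplex(v):
    """Euclidean projection onto {w >= 0, sum(w) <= 1}."""
    w = np.clip(v, 0.0, None)
    if w.sum() <= 1.0:
        return w
    # project onto the simplex {w >= 0, sum = 1}
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    ks = np.arange(1, len(v) + 1)
    cond = u - (css - 1.0) / ks > 0
    k = ks[cond][-1]
    tau = (css[k - 1] - 1.0) / k
    return np.clip(v - tau, 0.0, None)


def constrained_ls_oracle(P, f, n_iter=50_000):
    """min ||f - P w||^2 s.t. w >= 0, sum(w) <= 1, by projected gradient."""
    P = np.asarray(P, float)
    f = np.asarray(f, float)
    L = 2.0 * np.linalg.norm(P, 2) ** 2
    w = np.full(P.shape[1], 1.0 / P.shape[1])
    for _ in range(n_iter):
        grad = 2.0 * P.T @ (P @ w - f)
        w = _project_capped_simplex(w - grad / L)
    r = f - P @ w
    return w, float(r @ r)


# ---------------------------------------------------------------------------
# Exact Mann-Whitney by enumeration over rank sums
# ---------------------------------------------------------------------------

def mw_exact_oracle(a, b):
    """(U_A, two-sided exact p) via mid-rank sums over all index subsets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    m, n = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2.0
    us = []
    for pick in combinations(range(m + n), m):
        u = ranks[list(pick)].sum() - m * (m + 1) / 2.0
        us.append(u)
    us = np.array(us)
    lo = (us <= u_obs + 1e-9).mean()
    hi = (us >= u_obs - 1e-9).mean()
    return u_obs, min(1.0, 2.0 * min(lo, hi))
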