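"""Pairwise linkage disequilibrium (r²) from unphased diploid genotypes.

Two-locus haplotype frequencies are estimated by maximum likelihood with an
EM algorithm in which only the double-heterozygote cell has ambiguous
phase.  Because the genotype likelihood can have up to three stationary
points, EM is run from three deterministic starts (the linkage-equilibrium
product and both ends of the feasible D interval) and the fixed point with
the highest log-likelihood is kept, which makes the estimate reproducible
and, in practice, global.

r² = D² / (pA·(1−pA)·pB·(1−pB)) with D = f11 − pA·pB.  Significance is the
upper tail of χ² = n·r² on 1 df; a pair passes the quality filter when the
p-value is below ``alpha`` and the pair was estimated from at least
``min_obs`` individuals with both calls non-missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import GenotypeMatrix, SnpRecord

__all__ = [
    "HaplotypeFreqs",
    "LdEstimate",
    "em_haplotype_freqs",
    "r2_from_hapfreqs",
    "ld_significance",
    "pairwise_ld",
    "ld_matrix",
    "genotype_table",
    "MIN_PANEL_SIZE",
]

#: below this many individuals r² estimates become unreliable; a warning
#: (not an error) is emitted when a smaller panel is analysed.
MIN_PANEL_SIZE = 75

_EPS = 1e-300


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies; allele "1" is the dosage-counted allele.

    f11 = freq(1 at locus A and 1 at locus B), f12 = freq(1 at A, 0 at B),
    f21, f22 analogous.  ``loglik`` is the multinomial log-likelihood of the
    genotype table at these frequencies.
    """

    f11: float
    f12: float
    f21: float
    f22: float
    loglik: float
    converged: bool = True

    @property
    def p_a(self) -> float:
        return self.f11 + self.f12

    @property
    def p_b(self) -> float:
        return self.f11 + self.f21


@dataclass
class LdEstimate:
    snp_a: str
    snp_b: str
    r2: float
    n_obs: int
    p_value: float
    passes_quality: bool
    em_converged: bool = True


class DegenerateLocusError(ValueError):
    """A locus is monomorphic in the shared-called sample; r² undefined."""


def genotype_table(a: np.ndarray, b: np.ndarray, missing_a=None, missing_b=None) -> np.ndarray:
    """3x3 contingency table of dosage pairs over individuals called at both loci."""
    a = np.asarray(a)
    b = np.asarray(b)
    ok = np.ones(a.shape, dtype=bool)
    if missing_a is not None:
        ok &= ~np.asarray(missing_a, dtype=bool)
    if missing_b is not None:
        ok &= ~np.asarray(missing_b, dtype=bool)
    table = np.zeros((3, 3), dtype=np.int64)
    for i in range(3):
        for j in range(3):
            table[i, j] = int(np.sum(ok & (a == i) & (b == j)))
    return table


# ---------------------------------------------------------------------- #
# vectorised EM kernel
# ---------------------------------------------------------------------- #

def _em_kernel(tables: np.ndarray, tol: float = 1e-8, max_iter: int = 1000):
    """EM over a stack of 3x3 genotype tables.

    Parameters
    ----------
    tables : float array (P, 3, 3)
        Counts n[i, j] of individuals with dosage i at locus A and j at B.

    Returns
    -------
    dict of arrays over pairs: pAB, pA, pB, r2, loglik, converged, valid
    (valid is False for empty or monomorphic pairs, whose outputs are NaN).
    """
    t = np.asarray(tables, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    n = t.sum(axis=(1, 2))
    idx = np.arange(3.0)
    cA = np.einsum("pij,i->p", t, idx)
    cB = np.einsum("pij,j->p", t, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = cA / (2.0 * n)
        pB = cB / (2.0 * n)
    valid = (n > 0) & (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)

    # phase-known haplotype count contributions (double-het cell excluded)
    kAB = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    kAb = 2 * t[:, 2, 0] + t[:, 2, 1] + t[:, 1, 0]
    kaB = 2 * t[:, 0, 2] + t[:, 0, 1] + t[:, 1, 2]
    kab = 2 * t[:, 0, 0] + t[:, 0, 1] + t[:, 1, 0]
    ndh = t[:, 1, 1]
    two_n = np.where(n > 0, 2.0 * n, 1.0)

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    span = hi - lo

    def em_run(f0):
        f = np.where(valid, np.clip(f0, lo, hi), 0.0)
        conv = np.zeros(f.shape, dtype=bool)
        # iterate only the not-yet-converged pairs; most settle in a few steps
        idx = np.flatnonzero(valid)
        fi = f[idx]
        pAi, pBi = pA[idx], pB[idx]
        kABi, ndhi, two_ni = kAB[idx], ndh[idx], two_n[idx]
        loi, hii = lo[idx], hi[idx]
        for _ in range(max_iter):
            if idx.size == 0:
                break
            fAb = pAi - fi
            faB = pBi - fi
            fab = 1.0 - pAi - pBi + fi
            num = fi * fab
            den = num + fAb * faB
            w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
            f_new = np.clip((kABi + w * ndhi) / two_ni, loi, hii)
            done = np.abs(f_new - fi) < tol
            f[idx] = f_new
            if done.any():
                conv[idx[done]] = True
                keep = ~done
                idx = idx[keep]
                fi = f_new[keep]
                pAi, pBi = pAi[keep], pBi[keep]
                kABi, ndhi, two_ni = kABi[keep], ndhi[keep], two_ni[keep]
                loi, hii = loi[keep], hii[keep]
            else:
                fi = f_new
        return f, conv

    def loglik_of(fAB):
        fAb = np.maximum(pA - fAB, 0.0)
        faB = np.maximum(pB - fAB, 0.0)
        fab = np.maximum(1.0 - pA - pB + fAB, 0.0)
        probs = np.empty_like(t)
        probs[:, 2, 2] = fAB**2
        probs[:, 2, 1] = 2 * fAB * fAb
        probs[:, 2, 0] = fAb**2
        probs[:, 1, 2] = 2 * fAB * faB
        probs[:, 1, 1] = 2 * (fAB * fab + fAb * faB)
        probs[:, 1, 0] = 2 * fAb * fab
        probs[:, 0, 2] = faB**2
        probs[:, 0, 1] = 2 * faB * fab
        probs[:, 0, 0] = fab**2
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(t > 0, t * np.log(np.maximum(probs, _EPS)), 0.0).sum(axis=(1, 2))
        return ll

    starts = [pA * pB, lo + 1e-3 * span, hi - 1e-3 * span]
    best_f = np.full(n.shape, np.nan)
    best_ll = np.full(n.shape, -np.inf)
    best_conv = np.zeros(n.shape, dtype=bool)
    for f0 in starts:
        f, conv = em_run(f0)
        ll = loglik_of(f)
        better = valid & (ll > best_ll + 1e-12)
        best_f = np.where(better, f, best_f)
        best_conv = np.where(better, conv, best_conv)
        best_ll = np.where(better, ll, best_ll)

    with np.errstate(invalid="ignore", divide="ignore"):
        d = best_f - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(valid, np.clip(d * d / np.where(valid, denom, 1.0), 0.0, 1.0), np.nan)
    best_ll = np.where(valid, best_ll, np.nan)
    return {
        "pAB": best_f,
        "pA": pA,
        "pB": pB,
        "r2": r2,
        "loglik": best_ll,
        "converged": best_conv,
        "valid": valid,
        "n": n,
    }


def _em_scalar_trace(table: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> list[float]:
    """Log-likelihood after each EM step from the linkage-equilibrium start.

    Diagnostic helper: EM guarantees this sequence is non-decreasing.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    idx = np.arange(3.0)
    pA = (t * idx[:, None]).sum() / (2 * n)
    pB = (t * idx[None, :]).sum() / (2 * n)
    kAB = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    ndh = t[1, 1]

    def loglik(f):
        fAb, faB, fab = pA - f, pB - f, 1 - pA - pB + f
        probs = np.array(
            [
                [fab**2, 2 * faB * fab, faB**2],
                [2 * fAb * fab, 2 * (f * fab + fAb * faB), 2 * f * faB],
                [fAb**2, 2 * f * fAb, f**2],
            ]
        )
        return float(np.where(t > 0, t * np.log(np.maximum(probs, _EPS)), 0.0).sum())

    f = pA * pB
    out = [loglik(f)]
    for _ in range(max_iter):
        fAb, faB, fab = pA - f, pB - f, 1 - pA - pB + f
        den = f * fab + fAb * faB
        w = (f * fab / den) if den > 0 else 0.5
        f_new = (kAB + w * ndh) / (2 * n)
        out.append(loglik(f_new))
        if abs(f_new - f) < tol:
            break
        f = f_new
    return out


def em_haplotype_freqs(table: np.ndarray, tol: float = 1e-8, max_iter: int = 1000) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies for one 3x3 genotype table.

    Raises :class:`DegenerateLocusError` when either locus is monomorphic
    (haplotype frequencies degenerate, r² undefined).
    """
    res = _em_kernel(np.asarray(table, dtype=float), tol=tol, max_iter=max_iter)
    if not res["valid"][0]:
        raise DegenerateLocusError("monomorphic locus or empty table: r² undefined")
    f11 = float(res["pAB"][0])
    pA, pB = float(res["pA"][0]), float(res["pB"][0])
    return HaplotypeFreqs(
        f11=f11,
        f12=pA - f11,
        f21=pB - f11,
        f22=1.0 - pA - pB + f11,
        loglik=float(res["loglik"][0]),
        converged=bool(res["converged"][0]),
    )


def r2_from_hapfreqs(h: HaplotypeFreqs) -> float:
    """r² from haplotype frequencies, clipped to [0, 1]."""
    pA, pB = h.p_a, h.p_b
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise DegenerateLocusError("degenerate marginals: r² undefined")
    d = h.f11 - pA * pB
    return float(np.clip(d * d / denom, 0.0, 1.0))


def ld_significance(r2: float, n_obs: int) -> float:
    """Upper-tail p-value of the allelic-association statistic χ² = n·r², 1 df."""
    if n_obs < 2:
        raise ValueError("need at least 2 observations")
    return float(stats.chi2.sf(n_obs * r2, df=1))


# ---------------------------------------------------------------------- #
# panel-level computation
# ---------------------------------------------------------------------- #

def ld_matrix(
    g: GenotypeMatrix,
    query_idx: np.ndarray,
    anchor_idx: np.ndarray,
    alpha: float = 0.01,
    min_obs: int = 100,
    tol: float = 1e-8,
    max_iter: int = 1000,
):
    """All query x anchor LD estimates, vectorised.

    Returns a dict of (n_query, n_anchor) arrays: ``r2``, ``n_obs``,
    ``p_value``, ``passes``, ``valid`` and ``em_converged``.  Pairs with a
    monomorphic locus among the shared-called individuals, or fewer than 2
    shared calls, have ``valid=False`` and NaN statistics.  Non-converged
    pairs fall back to the squared Pearson correlation of dosages.
    """
    query_idx = np.asarray(query_idx, dtype=np.intp)
    anchor_idx = np.asarray(anchor_idx, dtype=np.intp)
    called = ~g.missing
    nq, na = len(query_idx), len(anchor_idx)

    # 9 cross products of dosage-level indicators give all 3x3 tables at once
    tables = np.empty((nq, na, 3, 3), dtype=np.float64)
    qd = g.dosage[:, query_idx]
    ad = g.dosage[:, anchor_idx]
    qc = called[:, query_idx]
    ac = called[:, anchor_idx]
    q_ind = [((qd == v) & qc).astype(np.float32) for v in range(3)]
    a_ind = [((ad == v) & ac).astype(np.float32) for v in range(3)]
    for i in range(3):
        qi = q_ind[i].T
        for j in range(3):
            tables[:, :, i, j] = qi @ a_ind[j]

    flat = tables.reshape(nq * na, 3, 3)
    res = _em_kernel(flat, tol=tol, max_iter=max_iter)

    n = res["n"]
    valid = res["valid"] & (n >= 2)
    r2 = res["r2"].copy()

    # dosage-correlation fallback where EM did not converge
    fb = valid & ~res["converged"]
    if fb.any():
        t = flat[fb]
        idx = np.arange(3.0)
        tot = t.sum(axis=(1, 2))
        sx = np.einsum("pij,i->p", t, idx)
        sy = np.einsum("pij,j->p", t, idx)
        sxx = np.einsum("pij,i->p", t, idx**2)
        syy = np.einsum("pij,j->p", t, idx**2)
        sxy = np.einsum("pij,i,j->p", t, idx, idx)
        num = (tot * sxy - sx * sy) ** 2
        den = (tot * sxx - sx**2) * (tot * syy - sy**2)
        r2[fb] = np.where(den > 0, np.clip(num / np.maximum(den, _EPS), 0.0, 1.0), np.nan)

    with np.errstate(invalid="ignore"):
        p = stats.chi2.sf(np.where(valid, n, 2.0) * np.where(valid, r2, 0.0), df=1)
    p = np.where(valid, p, np.nan)
    passes = valid & (p < alpha) & (n >= min_obs)

    shape = (nq, na)
    return {
        "r2": r2.reshape(shape),
        "n_obs": n.reshape(shape).astype(np.int64),
        "p_value": p.reshape(shape),
        "passes": passes.reshape(shape),
        "valid": valid.reshape(shape),
        "em_converged": res["converged"].reshape(shape),
    }


def _warn_if_small(g: GenotypeMatrix) -> None:
    if g.n_samples < MIN_PANEL_SIZE:
        warnings.warn(
            f"panel has {g.n_samples} individuals; r² estimates are unreliable "
            f"below {MIN_PANEL_SIZE} unrelated individuals",
            UserWarning,
            stacklevel=3,
        )


def pairwise_ld(
    query: SnpRecord,
    anchors: list[SnpRecord],
    g: GenotypeMatrix,
    alpha: float = 0.01,
    min_obs: int = 100,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> list[LdEstimate]:
    """LD of one query SNP with every mapped anchor SNP.

    Pairs that are monomorphic among shared-called individuals or share
    fewer than 2 calls are skipped (not fatal).
    """
    if not anchors:
        raise ValueError("empty anchor list")
    _warn_if_small(g)
    qi = g.indices([query.snp_id])
    ai = g.indices([a.snp_id for a in anchors])
    res = ld_matrix(g, qi, ai, alpha=alpha, min_obs=min_obs, tol=tol, max_iter=max_iter)
    out = []
    for k, anchor in enumerate(anchors):
        if not res["valid"][0, k]:
            continue
        out.append(
            LdEstimate(
                snp_a=query.snp_id,
                snp_b=anchor.snp_id,
                r2=float(res["r2"][0, k]),
                n_obs=int(res["n_obs"][0, k]),
                p_value=float(res["p_value"][0, k]),
                passes_quality=bool(res["passes"][0, k]),
                em_converged=bool(res["em_converged"][0, k]),
            )
        )
    return out
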