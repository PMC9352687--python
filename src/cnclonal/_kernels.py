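"""Low-level grid-search kernels for the pair distance.

Two interchangeable backends: a numba-compiled loop (default when numba is
importable and CNCLONAL_NO_NUMBA is unset) and a chunked numpy fallback.
Both must agree to ~1e-12; a dedicated test pins them together.

Per candidate pair the distance is

    d = (sum_j w_j |q1_ij - q2_kj| / W) / s_ik

where s_ik is the pooled weighted population std of {q1_ij} u {q2_kj}.
Degenerate rule: s < 1e-9 -> d = 0 if the numerator is < 1e-9, else +inf.
"""

from __future__ import annotations

import os

import numpy as np

EPS_STD = 1e-9
TIE_TOL = 1e-12

HAVE_NUMBA = False
if not os.environ.get("CNCLONAL_NO_NUMBA"):
    try:
        from numba import njit

        HAVE_NUMBA = True
    except ImportError:  # pragma: no cover - numba is a declared dependency
        pass


def dist_matrix(Q1, Q2, w, s1, ss1, s2, ss2, total):
    """Full (n1, n2) distance matrix; numpy, intended for small blocks."""
    num = (np.abs(Q1[:, None, :] - Q2[None, :, :]) @ w) / total
    mu = (s1[:, None] + s2[None, :]) / (2.0 * total)
    var = np.maximum((ss1[:, None] + ss2[None, :]) / (2.0 * total) - mu * mu, 0.0)
    s = np.sqrt(var)
    out = np.where(
        s >= EPS_STD,
        num / np.where(s >= EPS_STD, s, 1.0),
        np.where(num < EPS_STD, 0.0, np.inf),
    )
    return out


def _pair_min_numpy(Q1, Q2, w, s1, ss1, s2, ss2, total, ta, aa, tb, ab, block=128):
    best = np.inf
    key = None
    bi = bk = -1
    n1 = Q1.shape[0]
    for lo in range(0, n1, block):
        hi = min(lo + block, n1)
        D = dist_matrix(Q1[lo:hi], Q2, w, s1[lo:hi], ss1[lo:hi], s2, ss2, total)
        block_min = float(D.min())
        if block_min > best + TIE_TOL:
            continue
        strictly_better = block_min < best - TIE_TOL
        best = min(best, block_min)
        ii, kk = np.nonzero(D <= best + TIE_TOL)
        gi = ii + lo
        # lexicographically smallest (tau_a, -alpha_a, tau_b, -alpha_b)
        order = np.lexsort((-ab[kk], tb[kk], -aa[gi], ta[gi]))
        p = order[0]
        cand_key = (ta[gi[p]], -aa[gi[p]], tb[kk[p]], -ab[kk[p]])
        if key is None or strictly_better or cand_key < key:
            key = cand_key
            bi, bk = int(gi[p]), int(kk[p])
    return float(best), bi, bk


if HAVE_NUMBA:

    @njit(cache=False, fastmath=True)
    def _pair_min_nb(Q1, Q2, w, s1, ss1, s2, ss2, total, ta, aa, tb, ab):  # pragma: no cover - exercised via wrapper
        n1, m = Q1.shape
        n2 = Q2.shape[0]
        best = np.inf
        bi = -1
        bk = -1
        kta = 0.0
        kaa = 0.0
        ktb = 0.0
        kab = 0.0
        for i in range(n1):
            for k in range(n2):
                num = 0.0
                for j in range(m):
                    num += w[j] * abs(Q1[i, j] - Q2[k, j])
                num /= total
                mu = (s1[i] + s2[k]) / (2.0 * total)
                var = (ss1[i] + ss2[k]) / (2.0 * total) - mu * mu
                if var < 0.0:
                    var = 0.0
                s = np.sqrt(var)
                if s < EPS_STD:
                    d = 0.0 if num < EPS_STD else np.inf
                else:
                    d = num / s
                if d > best + TIE_TOL:
                    continue
                if d < best - TIE_TOL or bi < 0:
                    best = d
                    bi = i
                    bk = k
                    kta = ta[i]
                    kaa = aa[i]
                    ktb = tb[k]
                    kab = ab[k]
                else:
                    if d < best:
                        best = d
                    better = False
                    if ta[i] < kta:
                        better = True
                    elif ta[i] == kta:
                        if aa[i] > kaa:
                            better = True
                        elif aa[i] == kaa:
                            if tb[k] < ktb:
                                better = True
                            elif tb[k] == ktb and ab[k] > kab:
                                better = True
                    if better:
                        bi = i
                        bk = k
                        kta = ta[i]
                        kaa = aa[i]
                        ktb = tb[k]
                        kab = ab[k]
        return best, bi, bk


def pair_min(Q1, Q2, w, s1, ss1, s2, ss2, total, ta, aa, tb, ab, use_numba=None):
    """Minimum distance over all (row of Q1) x (row of Q2) candidate pairs.

    Returns ``(d_min, i, k)`` where (i, k) is the arg-min under the
    lexicographic tie-break on (tau_a, -alpha_a, tau_b, -alpha_b).
    """
    args = [np.ascontiguousarray(x, dtype=np.float64) for x in
            (Q1, Q2, w, s1, ss1, s2, ss2)]
    keys = [np.ascontiguousarray(x, dtype=np.float64) for x in (ta, aa, tb, ab)]
    if use_numba is None:
        use_numba = HAVE_NUMBA
    if use_numba and HAVE_NUMBA:
        best, bi, bk = _pair_min_nb(*args[:7], float(total), *keys)
        return float(best), int(bi), int(bk)
    return _pair_min_numpy(*args[:7], float(total), *keys)
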