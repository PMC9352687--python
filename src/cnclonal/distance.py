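"""Inter-profile clonality distance.

The distance between two segmented log2 profiles is the weighted mean
absolute difference of their purity/ploidy-corrected copy numbers divided
by the pooled weighted standard deviation of those corrected values,
minimized over the purity x ploidy grid for *both* samples (a 4-D search).
Patient-level results average the distance over all primary x metastasis
sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import EPS_STD, TIE_TOL
from .absolute import PurityPloidy, relative_to_absolute
from .cnh import SearchGrid
from .profiles import HarmonizedPair, SegmentedProfile, harmonize_pair, weighted_mean_std

ROLES = ("primary", "metastasis")


@dataclass(frozen=True)
class GridPointPair:
    """Candidate (purity, ploidy) for each of the two compared samples."""

    pp_a: PurityPloidy
    pp_b: PurityPloidy


@dataclass(frozen=True)
class PairDistanceResult:
    d: float
    best: GridPointPair
    strategy: str
    n_grid_evaluated: int


@dataclass(frozen=True)
class PatientDistanceResult:
    patient_id: str
    n_pairs: int
    mean_d: float
    pairs: tuple[tuple[str, str, PairDistanceResult], ...]


def pair_distance_at(
    h: HarmonizedPair, theta: GridPointPair, *, normalize: bool = True
) -> float:
    """Distance at a single 4-tuple of candidate parameters.

    Scalar reference implementation; the grid minimizers use vectorized
    kernels that must match this function numerically.
    """
    w = h.weights
    total = float(w.sum())
    ra = np.exp2(h.value_a)
    rb = np.exp2(h.value_b)
    if normalize:
        ra = ra / (float(w @ ra) / total)
        rb = rb / (float(w @ rb) / total)
    q1 = relative_to_absolute(ra, theta.pp_a)
    q2 = relative_to_absolute(rb, theta.pp_b)
    num = float(w @ np.abs(q1 - q2)) / total
    _, s = weighted_mean_std(np.concatenate([q1, q2]), np.concatenate([w, w]))
    if s < EPS_STD:
        return 0.0 if num < EPS_STD else float("inf")
    return num / s


class _GridSearch:
    """Shared state for minimizing the pair distance over candidate subsets."""

    def __init__(self, h: HarmonizedPair, grid: SearchGrid, normalize: bool, use_numba):
        self.w = np.asarray(h.weights, dtype=float)
        self.total = float(self.w.sum())
        ra = np.exp2(h.value_a)
        rb = np.exp2(h.value_b)
        if normalize:
            ra = ra / (float(self.w @ ra) / self.total)
            rb = rb / (float(self.w @ rb) / self.total)
        self.ra, self.rb = ra, rb
        self.alphas = grid.alphas
        self.taus = grid.taus
        self.na, self.nt = len(self.alphas), len(self.taus)
        self.cand_alpha = np.repeat(self.alphas, self.nt)
        self.cand_tau = np.tile(self.taus, self.na)
        self.g = 2.0 * (1.0 - self.cand_alpha) / self.cand_alpha
        self.c = self.cand_tau + self.g
        self.use_numba = use_numba
        self.n_evaluated = 0
        self.best_d = np.inf
        self.best_key: tuple | None = None
        self.best_idx: tuple[int, int] | None = None

    def _prepare(self, idx: np.ndarray, r: np.ndarray):
        q = self.c[idx, None] * r[None, :] - self.g[idx, None]
        s = q @ self.w
        ss = (q * q) @ self.w
        return q, s, ss

    def evaluate(self, idx_a: np.ndarray, idx_b: np.ndarray) -> None:
        """Minimize over the product idx_a x idx_b and fold into the running best."""
        q1, s1, ss1 = self._prepare(idx_a, self.ra)
        q2, s2, ss2 = self._prepare(idx_b, self.rb)
        d, i, k = _kernels.pair_min(
            q1, q2, self.w, s1, ss1, s2, ss2, self.total,
            self.cand_tau[idx_a], self.cand_alpha[idx_a],
            self.cand_tau[idx_b], self.cand_alpha[idx_b],
            use_numba=self.use_numba,
        )
        self.n_evaluated += len(idx_a) * len(idx_b)
        ga, gb = int(idx_a[i]), int(idx_b[k])
        key = (
            self.cand_tau[ga], -self.cand_alpha[ga],
            self.cand_tau[gb], -self.cand_alpha[gb],
        )
        if d < self.best_d - TIE_TOL:
            self.best_d, self.best_key, self.best_idx = d, key, (ga, gb)
        elif d <= self.best_d + TIE_TOL:
            self.best_d = min(self.best_d, d)
            if self.best_key is None or key < self.best_key:
                self.best_key, self.best_idx = key, (ga, gb)

    def coarse_matrix(self, idx: np.ndarray) -> np.ndarray:
        """Full distance matrix over idx x idx (used to rank coarse candidates)."""
        q1, s1, ss1 = self._prepare(idx, self.ra)
        q2, s2, ss2 = self._prepare(idx, self.rb)
        self.n_evaluated += len(idx) ** 2
        return _kernels.dist_matrix(q1, q2, self.w, s1, ss1, s2, ss2, self.total)

    def result(self, strategy: str) -> PairDistanceResult:
        assert self.best_idx is not None
        ga, gb = self.best_idx
        best = GridPointPair(
            PurityPloidy(float(self.cand_alpha[ga]), float(self.cand_tau[ga])),
            PurityPloidy(float(self.cand_alpha[gb]), float(self.cand_tau[gb])),
        )
        return PairDistanceResult(float(self.best_d), best, strategy, self.n_evaluated)


def _strided_indices(n: int, stride: int) -> np.ndarray:
    idx = set(range(0, n, stride))
    idx.add(n - 1)
    return np.array(sorted(idx), dtype=np.intp)


def pair_distance_minimize(
    a: SegmentedProfile,
    b: SegmentedProfile,
    grid: SearchGrid | None = None,
    strategy: str = "coarse_to_fine",
    *,
    normalize: bool = True,
    coarse_alpha_stride: int = 5,
    coarse_tau_stride: int = 25,
    top_m: int = 5,
    use_numba=None,
) -> PairDistanceResult:
    """Minimize the pair distance over the 4-D (alpha, tau) x (alpha, tau) grid.

    ``strategy="exhaustive"`` evaluates every pair of grid points and is
    exact.  ``strategy="coarse_to_fine"`` (default) first evaluates a strided
    sub-grid (stride 5 in the purity index, 25 in the ploidy index, endpoints
    always included), then exhaustively refines the fine grid within +/- one
    coarse stride in all four dimensions around each of the ``top_m`` best
    coarse candidates.  Its minimum is an upper bound on the exhaustive one.
    """
    if grid is None:
        grid = SearchGrid()
    if strategy not in ("exhaustive", "coarse_to_fine"):
        raise ValueError(f"unknown strategy {strategy!r}")
    h = harmonize_pair(a, b)
    search = _GridSearch(h, grid, normalize, use_numba)
    na, nt = search.na, search.nt
    all_cand = np.arange(na * nt, dtype=np.intp)

    if strategy == "exhaustive":
        search.evaluate(all_cand, all_cand)
        return search.result("exhaustive")

    ia = _strided_indices(na, coarse_alpha_stride)
    it = _strided_indices(nt, coarse_tau_stride)
    coarse = (ia[:, None] * nt + it[None, :]).ravel()
    D = search.coarse_matrix(coarse)
    flat = D.ravel()
    m = min(top_m, flat.size)
    top = np.argpartition(flat, m - 1)[:m]

    windows: set[tuple[int, int, int, int, int, int, int, int]] = set()
    for t in top:
        i_c, k_c = divmod(int(t), len(coarse))
        ga, gb = int(coarse[i_c]), int(coarse[k_c])
        a_ia, a_it = divmod(ga, nt)
        b_ia, b_it = divmod(gb, nt)
        win = (
            max(0, a_ia - coarse_alpha_stride), min(na, a_ia + coarse_alpha_stride + 1),
            max(0, a_it - coarse_tau_stride), min(nt, a_it + coarse_tau_stride + 1),
            max(0, b_ia - coarse_alpha_stride), min(na, b_ia + coarse_alpha_stride + 1),
            max(0, b_it - coarse_tau_stride), min(nt, b_it + coarse_tau_stride + 1),
        )
        windows.add(win)

    for a0, a1, t0, t1, b0, b1, u0, u1 in sorted(windows):
        idx_a = (
            np.arange(a0, a1, dtype=np.intp)[:, None] * nt
            + np.arange(t0, t1, dtype=np.intp)[None, :]
        ).ravel()
        idx_b = (
            np.arange(b0, b1, dtype=np.intp)[:, None] * nt
            + np.arange(u0, u1, dtype=np.intp)[None, :]
        ).ravel()
        search.evaluate(idx_a, idx_b)
    return search.result("coarse_to_fine")


def patient_distance(
    primaries: Sequence[SegmentedProfile],
    metastases: Sequence[SegmentedProfile],
    grid: SearchGrid | None = None,
    strategy: str = "coarse_to_fine",
    *,
    patient_id: str = "",
    **kwargs,
) -> PatientDistanceResult:
    """Mean pair distance over all primary x metastasis sample pairs."""
    if not primaries or not metastases:
        raise ValueError(f"patient {patient_id!r}: empty primary or metastasis collection")
    pairs: list[tuple[str, str, PairDistanceResult]] = []
    for p in primaries:
        for m in metastases:
            res = pair_distance_minimize(p, m, grid, strategy, **kwargs)
            pairs.append((p.sample_id, m.sample_id, res))
    mean_d = float(np.mean([r.d for _, _, r in pairs]))
    return PatientDistanceResult(patient_id, len(pairs), mean_d, tuple(pairs))


def cohort_distances(
    sample_sheet: pd.DataFrame,
    profiles: Mapping[str, SegmentedProfile],
    grid: SearchGrid | None = None,
    strategy: str = "coarse_to_fine",
    **kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient mean distances for a cohort.

    ``sample_sheet`` needs columns sample_id, patient_id, role (primary or
    metastasis) and group.  Returns (patient table, per-pair detail table),
    both sorted by patient id.
    """
    required = {"sample_id", "patient_id", "role", "group"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    bad_roles = set(sample_sheet["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in sample sheet: {sorted(bad_roles)}")
    for sid in sample_sheet["sample_id"]:
        if sid not in profiles:
            raise ValueError(f"sample sheet references missing sample {sid!r}")

    patient_rows = []
    pair_rows = []
    for pid, sub in sorted(sample_sheet.groupby("patient_id"), key=lambda kv: str(kv[0])):
        groups = sorted(set(sub["group"]))
        if len(groups) != 1:
            raise ValueError(f"patient {pid!r} has conflicting group labels {groups}")
        prim = [profiles[s] for s in sub.loc[sub["role"] == "primary", "sample_id"]]
        met = [profiles[s] for s in sub.loc[sub["role"] == "metastasis", "sample_id"]]
        if not prim:
            raise ValueError(f"patient {pid!r} has no primary sample")
        if not met:
            raise ValueError(f"patient {pid!r} has no metastasis sample")
        res = patient_distance(prim, met, grid, strategy, patient_id=str(pid), **kwargs)
        patient_rows.append(
            {"patient_id": str(pid), "group": groups[0], "n_pairs": res.n_pairs,
             "mean_d": res.mean_d}
        )
        for sa, sb, pres in res.pairs:
            pair_rows.append(
                {
                    "patient_id": str(pid),
                    "sample_primary": sa,
                    "sample_metastasis": sb,
                    "d": pres.d,
                    "alpha1": pres.best.pp_a.purity,
                    "tau1": pres.best.pp_a.ploidy,
                    "alpha2": pres.best.pp_b.purity,
                    "tau2": pres.best.pp_b.ploidy,
                    "strategy": pres.strategy,
                    "n_grid_evaluated": pres.n_grid_evaluated,
                }
            )
    return pd.DataFrame(patient_rows), pd.DataFrame(pair_rows)
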