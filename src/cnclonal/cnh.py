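"""Copy-number heterogeneity (CNH).

CNH of a sample is the weighted mean distance of its purity/ploidy-corrected
segment copy numbers to the nearest integers, minimized over a discrete
purity x ploidy search grid.  A clean clonal profile at the right grid point
has CNH 0; the statistic is bounded by 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .absolute import PurityPloidy, transform_profile
from .profiles import SegmentedProfile

#: Minimizers within this tolerance of the minimum count as ties.
TIE_TOL = 1e-12


@dataclass(frozen=True)
class SearchGrid:
    """The discrete purity x ploidy search space.

    Defaults: purity 0.20..1.00 step 0.01 (81 values) and mean ploidy
    1.50..5.00 step 0.01 (351 values).
    """

    alpha_min: float = 0.20
    alpha_max: float = 1.00
    alpha_step: float = 0.01
    tau_min: float = 1.50
    tau_max: float = 5.00
    tau_step: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha_min < 0.01:
            raise ValueError("alpha_min must be >= 0.01")
        if self.alpha_max > 1.0 + 1e-12:
            raise ValueError("alpha_max must be <= 1")
        if self.alpha_step <= 0 or self.tau_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.alpha_min > self.alpha_max or self.tau_min > self.tau_max:
            raise ValueError("grid min must not exceed max")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return np.round(lo + step * np.arange(n), 12)

    @property
    def alphas(self) -> np.ndarray:
        return self._axis(self.alpha_min, self.alpha_max, self.alpha_step)

    @property
    def taus(self) -> np.ndarray:
        return self._axis(self.tau_min, self.tau_max, self.tau_step)

    @property
    def size(self) -> int:
        return len(self.alphas) * len(self.taus)


@dataclass(frozen=True)
class CNHResult:
    cnh: float
    best: PurityPloidy
    n_ties: int

    def __post_init__(self) -> None:
        if not -TIE_TOL <= self.cnh <= 0.5 + TIE_TOL:
            raise ValueError(f"CNH out of [0, 0.5]: {self.cnh}")
        if self.n_ties < 1:
            raise ValueError("n_ties must be >= 1")


def nearest_integer_distance(q):
    """Distance of ``q`` to the nearest integer, in [0, 0.5]."""
    arr = np.asarray(q, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("copy number must be finite")
    out = np.abs(arr - np.rint(arr))
    return float(out) if np.isscalar(q) or arr.ndim == 0 else out


def cnh_at(
    profile: SegmentedProfile,
    pp: PurityPloidy,
    *,
    normalize: bool = True,
    weight_mode: str = "bp",
) -> float:
    """CNH evaluated at a single (purity, ploidy) candidate."""
    ap = transform_profile(profile, pp, normalize=normalize, weight_mode=weight_mode)
    d = nearest_integer_distance(ap.copy_numbers)
    return float((ap.weights @ d) / ap.weights.sum())


def cnh_minimize(
    profile: SegmentedProfile,
    grid: SearchGrid | None = None,
    *,
    normalize: bool = True,
    weight_mode: str = "bp",
    max_block: int = 4096,
) -> CNHResult:
    """Exhaustive CNH minimization over the search grid.

    Ties (grid points within ``TIE_TOL`` of the minimum, a known ridge of
    equivalent solutions) are counted; the reported arg-min is the tied point
    with smallest ploidy, then largest purity.
    """
    if grid is None:
        grid = SearchGrid()
    w = profile.weights(weight_mode)
    r = np.exp2(profile.log_ratios)
    if normalize:
        r = r / (float(w @ r) / float(w.sum()))
    total = float(w.sum())

    alphas, taus = grid.alphas, grid.taus
    cand_alpha = np.repeat(alphas, len(taus))
    cand_tau = np.tile(taus, len(alphas))
    g = 2.0 * (1.0 - cand_alpha) / cand_alpha
    c = cand_tau + g

    n = len(cand_alpha)
    vals = np.empty(n)
    for lo in range(0, n, max_block):
        hi = min(lo + max_block, n)
        q = np.outer(c[lo:hi], r) - g[lo:hi, None]
        vals[lo:hi] = (np.abs(q - np.rint(q)) @ w) / total

    best_val = float(vals.min())
    ties = np.flatnonzero(vals <= best_val + TIE_TOL)
    order = np.lexsort((-cand_alpha[ties], cand_tau[ties]))
    pick = ties[order[0]]
    return CNHResult(
        cnh=best_val,
        best=PurityPloidy(float(cand_alpha[pick]), float(cand_tau[pick])),
        n_ties=int(len(ties)),
    )
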