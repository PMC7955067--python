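"""Per-screen quantile normalization and screen-quality spline adjustment.

Both steps run before batch correction. Quantile normalization forces every
screen's score distribution onto a common reference (the per-rank mean across
screens). The quality adjustment regresses each screen on the consensus
profile (per-gene average fold change across screens) with a smoothing
spline and removes the difference between the fitted curve and the diagonal
``y = x``, so a screen whose phenotype intensity is inflated or damped
relative to the consensus is pulled back onto it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .data import ScreenMatrix

__all__ = ["QualitySpline", "quantile_normalize_screens", "spline_quality_adjust"]


def quantile_normalize_screens(m: ScreenMatrix) -> ScreenMatrix:
    """Map every screen's non-missing values onto the shared reference
    distribution (mean of per-rank sorted values across screens).

    Rank order within a screen is preserved; tied values receive the mean of
    their tied reference positions. Screens with missing entries are matched
    through their empirical quantile function, so unequal non-missing counts
    are handled. A screen with fewer than two non-missing values is an error.
    """
    if m.n_screens < 2:
        raise ValueError("quantile normalization needs at least 2 screens")
    X, mask = m.values, m.missing_mask
    n_g, n_s = X.shape
    counts = (~mask).sum(axis=0)
    if (counts < 2).any():
        bad = [m.screen_ids[j] for j in np.where(counts < 2)[0]]
        raise ValueError(f"screens with <2 non-missing values: {bad}")
    grid = np.linspace(0.0, 1.0, n_g)
    ref = np.zeros(n_g)
    for j in range(n_s):
        v = np.sort(X[~mask[:, j], j])
        ref += np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    ref /= n_s
    out = X.copy()
    for j in range(n_s):
        obs = ~mask[:, j]
        v = X[obs, j]
        targ = np.interp(np.linspace(0.0, 1.0, v.size), grid, ref)
        assigned = np.empty(v.size)
        assigned[np.argsort(v, kind="mergesort")] = targ
        # ties -> mean of the tied reference positions
        assigned = (
            pd.Series(assigned).groupby(pd.Series(v)).transform("mean").to_numpy()
        )
        out[obs, j] = assigned
    return ScreenMatrix(out, list(m.gene_ids), list(m.screen_ids), mask.copy())


@dataclass
class QualitySpline:
    """Fitted screen-vs-consensus curve for one screen.

    ``f(consensus score) -> screen score``; the adjustment subtracts
    ``f(x) - x``, so ``f = identity`` leaves the screen unchanged.
    """

    screen_id: str
    knots: np.ndarray
    coefficients: np.ndarray
    degree: int
    domain: tuple

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.domain[0], self.domain[1])
        return BSpline(self.knots, self.coefficients, self.degree)(x)


def _fit_spline(x: np.ndarray, y: np.ndarray, df: int, screen_id: str) -> QualitySpline:
    k = 3
    n_interior = max(df - (k + 1), 0)
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        raise ValueError(f"degenerate consensus range for screen {screen_id}")
    if n_interior:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = interior[(interior > lo) & (interior < hi)]
    else:
        interior = np.array([])
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    design = BSpline.design_matrix(np.clip(x, lo, hi), t, k).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return QualitySpline(screen_id, t, coef, k, (lo, hi))


def spline_quality_adjust(
    m: ScreenMatrix, df: int = 5
) -> tuple[ScreenMatrix, list[QualitySpline]]:
    """Remove per-screen phenotype-intensity distortions.

    The consensus profile is the per-gene average fold change across screens.
    For each screen a cubic smoothing spline with ``df`` effective degrees of
    freedom is fitted to (consensus, screen score) pairs; the adjusted score
    is ``score - (f(consensus_g) - consensus_g)``. Missing entries are
    excluded from the fit but still receive the adjustment at their
    consensus value (they stay masked).
    """
    X, mask = m.values, m.missing_mask
    with np.errstate(invalid="ignore"):
        obs_counts = (~mask).sum(axis=1)
        ref = np.where(
            obs_counts > 0,
            np.where(mask, 0.0, X).sum(axis=1) / np.maximum(obs_counts, 1),
            np.nan,
        )
    usable = np.isfinite(ref)
    splines = []
    out = X.copy()
    for j in range(m.n_screens):
        fit_rows = usable & ~mask[:, j]
        if fit_rows.sum() < df + 1:
            raise ValueError(
                f"screen {m.screen_ids[j]!r} has {int(fit_rows.sum())} usable genes; "
                f"need at least {df + 1} for a {df}-df spline"
            )
        spline = _fit_spline(ref[fit_rows], X[fit_rows, j], df, m.screen_ids[j])
        adj = spline(ref[usable]) - ref[usable]
        out[usable, j] = X[usable, j] - adj
        splines.append(spline)
    return ScreenMatrix(out, list(m.gene_ids), list(m.screen_ids), mask.copy()), splines
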