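"""Degradation-curve fitting and t50 extraction.

Each replicate yields a kinetic curve of remaining polymer signal (percent
of the t0 value) versus time.  The curve is summarized by ``t50``, the time
at which the fitted curve first crosses 50% — i.e. half of the initial
polymer has been consumed.  Curves are fitted by ordinary least-squares
polynomial regression; the polynomial degree is chosen by a significance
screen followed by adjusted-R² maximization (see :func:`select_degree`).

The fit is never extrapolated: t50 is searched only inside the observed
time window, and a curve that stays above (or below) the 50% level is
reported as *censored* rather than as a number.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import optimize, stats

__all__ = [
    "KineticCurve",
    "T50Fit",
    "NoSignificantModel",
    "fit_polynomial",
    "select_degree",
    "extract_t50",
    "fit_t50",
]


class NoSignificantModel(ValueError):
    """No polynomial degree produced a significant fit."""


@dataclass
class KineticCurve:
    """A (time, value) degradation series for one replicate.

    ``values`` are percentages: remaining-% for the image pipeline (starts
    at 100 and falls) or degraded-% for NMR kinetics (starts near 0 and
    rises).  Times are hours, strictly increasing.
    """

    times: np.ndarray
    values: np.ndarray
    sample_id: str = ""
    blend_label: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class T50Fit:
    """A selected polynomial model and the t50 derived from it.

    Attributes
    ----------
    degree : int
        Polynomial degree of the fitted model.
    coefficients : ndarray
        Coefficients in ascending order of power, in original time units
        (hours); ``coefficients[0]`` is the fitted value at t = 0.
    r2, adj_r2 : float
        Coefficient of determination and its degrees-of-freedom-adjusted
        version.
    f_pvalue : float
        p-value of the overall F-test of the regression.
    t50 : float or None
        First time (hours) at which the fitted curve crosses the target
        level inside the fit window; None when censored.
    censored : str or None
        ``"> t_max"`` when the fitted curve never reaches the level within
        the window (degradation too slow), ``"< t_min"`` when it starts
        beyond it; None for an ordinary estimate.
    fit_window : tuple of float
        Observed time range (hours) the fit is valid on.
    """

    degree: int
    coefficients: np.ndarray
    r2: float
    adj_r2: float
    f_pvalue: float
    t50: float | None = None
    censored: str | None = None
    fit_window: tuple[float, float] = (0.0, 0.0)
    _poly: Polynomial | None = dataclasses.field(default=None, repr=False, compare=False)

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted polynomial at time ``t`` (hours)."""
        if self._poly is not None:
            return self._poly(t)
        return Polynomial(self.coefficients)(t)

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coefficients": list(map(float, self.coefficients)),
            "r2": float(self.r2),
            "adj_r2": float(self.adj_r2),
            "f_pvalue": float(self.f_pvalue),
            "t50": None if self.t50 is None else float(self.t50),
            "censored": self.censored,
            "fit_window": [float(self.fit_window[0]), float(self.fit_window[1])],
        }


def fit_polynomial(curve: KineticCurve, degree: int) -> T50Fit:
    """Ordinary least-squares polynomial fit of a kinetic curve.

    The regression is computed on a centred/scaled time axis for numerical
    conditioning; reported coefficients are converted back to original
    hours.  The overall F statistic is
    ``[R²/d] / [(1-R²)/(n-d-1)]`` on ``(d, n-d-1)`` degrees of freedom.

    Raises
    ------
    ValueError
        If fewer than ``degree + 2`` points are available (residual df
        would be < 1), or if the curve has no variance.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n = len(curve)
    if n < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}, got {n}")
    sstot = float(np.sum((curve.values - curve.values.mean()) ** 2))
    if sstot == 0:
        raise ValueError("no variance: curve is flat")

    poly = Polynomial.fit(curve.times, curve.values, degree)
    ssres = float(np.sum((curve.values - poly(curve.times)) ** 2))
    r2 = 1.0 - ssres / sstot
    df_res = n - degree - 1
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res
    if r2 >= 1.0:  # perfect fit: F diverges
        r2, adj_r2, f_pvalue = 1.0, 1.0, 0.0
    else:
        f_stat = (r2 / degree) / ((1.0 - r2) / df_res)
        f_pvalue = float(stats.f.sf(f_stat, degree, df_res))

    return T50Fit(
        degree=degree,
        coefficients=poly.convert().coef,
        r2=r2,
        adj_r2=adj_r2,
        f_pvalue=f_pvalue,
        fit_window=(float(curve.times[0]), float(curve.times[-1])),
        _poly=poly,
    )


def select_degree(curve: KineticCurve, max_degree: int = 6, alpha: float = 0.05) -> T50Fit:
    """Choose the polynomial degree by significance then adjusted R².

    Procedure:

    1. *Screen*: the degree-1 regression must be significant at ``alpha``
       (overall F-test).  If the curve shows no linear time trend the whole
       selection stops with :class:`NoSignificantModel`.  Screening on a
       single pre-specified test keeps the false-model rate on trendless
       data at exactly ``alpha``, which a "keep any significant degree"
       rule would inflate roughly three-fold.
    2. Fit degrees ``1..min(max_degree, n-2)`` and keep those whose overall
       F-test has ``p < alpha``.
    3. Among the kept models return the one maximizing adjusted R²,
       breaking ties toward the lowest degree.

    Raises
    ------
    NoSignificantModel
        If the screen fails (no significant model at any degree is then
        reported).
    """
    n = len(curve)
    if n < 4:
        raise ValueError(f"need at least 4 points, got {n}")
    top = min(max_degree, n - 2)

    fits = [fit_polynomial(curve, 1)]
    if fits[0].f_pvalue >= alpha:
        raise NoSignificantModel(
            f"no significant model: degree-1 F-test p = {fits[0].f_pvalue:.3g} >= {alpha}"
        )
    fits.extend(fit_polynomial(curve, d) for d in range(2, top + 1))

    kept = [f for f in fits if f.f_pvalue < alpha]
    best_adj = max(f.adj_r2 for f in kept)
    # exact ties (e.g. several perfect fits) resolve to the lowest degree
    return min((f for f in kept if f.adj_r2 >= best_adj - 1e-9), key=lambda f: f.degree)


def extract_t50(fit: T50Fit, curve: KineticCurve | None = None, level: float = 50.0) -> T50Fit:
    """Locate the first crossing of ``level`` by the fitted curve.

    The fitted polynomial is scanned on a 2000-point grid over the fit
    window; the first sign change of ``f(t) - level`` is refined by root
    bracketing to better than 1e-6 h.  Polynomials can wiggle, so the
    *first* crossing is taken.  No extrapolation: if the curve stays above
    the level throughout the window the result is censored ``"> t_max"``
    (and ``"< t_min"`` if it starts already beyond it).

    Returns a copy of ``fit`` with ``t50`` / ``censored`` filled in.
    Censoring is a value, not an error.
    """
    t_min, t_max = fit.fit_window
    if curve is not None:
        t_min, t_max = float(curve.times[0]), float(curve.times[-1])
    grid = np.linspace(t_min, t_max, 2000)
    resid = np.asarray(fit(grid), dtype=float) - level

    if resid[0] <= 0:
        # already at/below the level at the window start
        if resid[0] == 0:
            return dataclasses.replace(fit, t50=float(grid[0]), censored=None)
        return dataclasses.replace(fit, t50=None, censored="< t_min")

    sign_change = np.nonzero(resid[:-1] * resid[1:] <= 0)[0]
    if sign_change.size == 0:
        return dataclasses.replace(fit, t50=None, censored="> t_max")

    i = int(sign_change[0])
    if resid[i + 1] == 0 and resid[i] > 0:
        root = float(grid[i + 1])
    else:
        root = float(
            optimize.brentq(lambda t: float(fit(t)) - level, grid[i], grid[i + 1], xtol=1e-9)
        )
    return dataclasses.replace(fit, t50=root, censored=None, fit_window=(t_min, t_max))


def fit_t50(
    curve: KineticCurve, max_degree: int = 6, alpha: float = 0.05, level: float = 50.0
) -> T50Fit:
    """Select a model for ``curve`` and extract its t50 in one step."""
    return extract_t50(select_degree(curve, max_degree=max_degree, alpha=alpha), curve, level)
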