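"""Nonlinear growth-pattern fitting, AIC selection, and maturity inference.

Per-year mass-specific growth rates (msGR) of a taxon are regressed
against year of life under ten candidate curve families
(:mod:`cementochron.growthmodels`).  Fit quality is ranked by AIC
(Gaussian-likelihood form, ``n·ln(RSS/n) + 2k`` with ``k = p + 1`` for
the residual variance) with r² breaking near-ties (ΔAIC < 2).  Extant
mammals are expected to select sigmoidal families (rapid juvenile
growth truncated at sexual maturity); flatter declines select
quadratic/exponential shapes.

The "truncation window" — the run of years with the steepest
year-to-year msGR decline — is the growth proxy for attainment of
sexual maturity, and extant calibration offsets convert it into a
maturity age range for fossils.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .growthmodels import FAMILIES, PARAM_SCALES, ModelFamily, get_family
from .increments import TaxonGrowthSeries

__all__ = [
    "GrowthModelFit",
    "TruncationWindow",
    "MaturityEstimate",
    "fit_models",
    "select_best",
    "find_truncation",
    "maturity_range",
]


@dataclass
class GrowthModelFit:
    """One fitted growth-curve family on a per-year series."""

    family: str
    params: np.ndarray
    aic: float
    r2: float
    fitted: np.ndarray
    rss: float
    converged: bool
    n_points: int
    message: str = ""

    def predict(self, t) -> np.ndarray:
        return get_family(self.family)(t, *self.params)


@dataclass
class TruncationWindow:
    """Years of steepest growth-rate decline (min_age..max_age)."""

    min_age: int
    max_age: int
    slope_sequence: np.ndarray  # d[t] = msGR[t+1] - msGR[t], indexed by start year
    uniform: bool = False  # all slopes equal (non-sigmoidal decline)


@dataclass
class MaturityEstimate:
    """Age-at-maturity range from a truncation window plus extant offsets."""

    min_age: float
    max_age: float
    offsets: np.ndarray


def _series_xy(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, TaxonGrowthSeries):
        y = series.msgr if series.msgr is not None else series.mean_width_um
        return np.asarray(series.years, float), np.asarray(y, float)
    x, y = series
    return np.asarray(x, float), np.asarray(y, float)


def _start_points(
    family: ModelFamily, x: np.ndarray, y: np.ndarray, n_starts: int, rng
) -> np.ndarray:
    """Latin-hypercube starts, scaled from normalized ranges to the data."""
    yscale = max(float(np.max(np.abs(y))), 1e-6)
    tscale = max(float(np.max(x)), 1.0)
    scales = PARAM_SCALES[family.name]
    lo = np.empty(family.n_params)
    hi = np.empty(family.n_params)
    for i, ((a, b), tag) in enumerate(zip(family.start_ranges, scales)):
        s = {"y": yscale, "t": tscale, "r": 1.0}[tag]
        lo[i], hi[i] = a * s, b * s
    sampler = qmc.LatinHypercube(d=family.n_params, seed=rng)
    u = sampler.random(n_starts)
    pts = lo + u * (hi - lo)
    blo, bhi = np.asarray(family.bounds[0]), np.asarray(family.bounds[1])
    return np.clip(pts, blo + 1e-9, np.where(np.isfinite(bhi), bhi - 1e-9, np.inf))


def fit_models(
    series,
    families: list[str] | None = None,
    n_starts: int = 20,
    seed: int = 0,
) -> list[GrowthModelFit]:
    """Fit candidate growth families to a per-year series by least squares.

    Parameters
    ----------
    series:
        A :class:`~cementochron.increments.TaxonGrowthSeries` (its msGR
        if present, else mean widths) or an ``(years, values)`` pair.
    families:
        Subset of family names; default all ten.
    n_starts:
        Multi-start count (Latin hypercube over data-scaled ranges);
        the best residual sum of squares wins.

    Families with more parameters than ``n_points - 1`` are skipped with
    a notice; non-convergent families are returned flagged and excluded
    from selection.

    AIC uses the Gaussian-likelihood form ``n·ln(RSS/n) + 2k`` with
    ``k = p + 1`` (residual variance counts as a parameter); no
    small-sample correction is applied.
    """
    x, y = _series_xy(series)
    if x.size < 3:
        raise ValueError("need at least 3 (year, value) points")
    names = families if families is not None else list(FAMILIES)
    tss = float(np.sum((y - y.mean()) ** 2))
    rng = np.random.default_rng(seed)
    fits: list[GrowthModelFit] = []
    for name in names:
        fam = get_family(name)
        if x.size < fam.n_params + 1:
            fits.append(
                GrowthModelFit(
                    family=name,
                    params=np.full(fam.n_params, np.nan),
                    aic=np.inf,
                    r2=np.nan,
                    fitted=np.full_like(y, np.nan),
                    rss=np.inf,
                    converged=False,
                    n_points=x.size,
                    message=f"skipped: {x.size} points < {fam.n_params + 1} required",
                )
            )
            continue

        def resid(p, fam=fam):
            with np.errstate(all="ignore"):
                r = fam(x, *p) - y
            return np.where(np.isfinite(r), r, 1e6)

        best = None
        for p0 in _start_points(fam, x, y, n_starts, rng):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sol = least_squares(
                        resid, p0, bounds=fam.bounds, xtol=1e-9, ftol=1e-9, gtol=1e-9
                    )
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if np.isfinite(rss) and (best is None or rss < best[0]):
                best = (rss, sol)
        if best is None:
            fits.append(
                GrowthModelFit(
                    family=name,
                    params=np.full(fam.n_params, np.nan),
                    aic=np.inf,
                    r2=np.nan,
                    fitted=np.full_like(y, np.nan),
                    rss=np.inf,
                    converged=False,
                    n_points=x.size,
                    message="non-convergent from all starts",
                )
            )
            continue
        rss, sol = best
        fitted = fam(x, *sol.x)
        n = x.size
        k = fam.n_params + 1
        aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
        r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)
        fits.append(
            GrowthModelFit(
                family=name,
                params=sol.x,
                aic=float(aic),
                r2=float(r2),
                fitted=np.asarray(fitted, float),
                rss=rss,
                converged=bool(np.all(np.isfinite(fitted))),
                n_points=n,
            )
        )
    return fits


def select_best(fits: list[GrowthModelFit]) -> GrowthModelFit:
    """Pick the winning family: lowest AIC, r² breaking ΔAIC < 2 ties.

    The selected fit gains ``runner_up`` and ``delta_aic`` attributes
    for reporting.
    """
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fits to select from")
    ok.sort(key=lambda f: f.aic)
    contenders = [f for f in ok if f.aic - ok[0].aic < 2.0]
    winner = max(contenders, key=lambda f: f.r2)
    runner = ok[1] if len(ok) > 1 else None
    winner.runner_up = runner.family if runner is not None else None
    winner.delta_aic = (runner.aic - winner.aic) if runner is not None else np.inf
    return winner


def find_truncation(series, theta: float = 2.0 / 3.0) -> TruncationWindow | None:
    """Locate the window of steepest year-to-year growth decline.

    Consecutive-year differences ``d[t] = msGR[t+1] − msGR[t]`` are
    computed; the window is the maximal contiguous run of years, around
    the most negative difference, whose differences satisfy
    ``d[t] <= theta · min(d)`` (theta in (0, 1]; smaller theta widens
    the window; the 2/3 default counts any drop at least two-thirds as
    steep as the steepest as part of the truncation).  ``min_age`` is
    the run's first year, ``max_age`` the run's last year + 1 (the year
    the decline lands on).

    Returns ``None`` for a monotone non-decreasing series (no decline
    to truncate).  A strictly uniform decline returns the full run
    flagged ``uniform=True`` (non-sigmoidal).
    """
    x, y = _series_xy(series)
    if x.size < 4:
        raise ValueError("need at least 4 years to locate a truncation window")
    if np.any(np.diff(x) != 1):
        raise ValueError("series years must be consecutive")
    d = np.diff(y)
    dmin = d.min()
    if dmin >= 0:
        return None
    qualifies = d <= theta * dmin
    k = int(np.argmin(d))
    i = j = k
    while i > 0 and qualifies[i - 1]:
        i -= 1
    while j < d.size - 1 and qualifies[j + 1]:
        j += 1
    uniform = bool(np.allclose(d, d[0]))
    return TruncationWindow(
        min_age=int(x[i]),
        max_age=int(x[j]) + 1,
        slope_sequence=d,
        uniform=uniform,
    )


def maturity_range(
    window: TruncationWindow,
    calibration_offsets,
) -> MaturityEstimate:
    """Convert a truncation window into an age-at-maturity range.

    ``calibration_offsets`` are, for each extant reference taxon,
    (known maturity age − truncation min_age); the fossil estimate is
    ``[window.min_age + min(offsets), window.max_age + max(offsets)]``,
    floored at 0.
    """
    offsets = np.asarray(list(calibration_offsets), dtype=float)
    if offsets.size == 0:
        raise ValueError("calibration offset table is empty")
    return MaturityEstimate(
        min_age=max(0.0, window.min_age + float(offsets.min())),
        max_age=max(0.0, window.max_age + float(offsets.max())),
        offsets=offsets,
    )
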