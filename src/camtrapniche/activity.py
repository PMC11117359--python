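"""Diel activity estimation and temporal niche overlap.

Detection times on the 24-h circle are smoothed with a von Mises kernel
density estimate; the overlap between two species' activity curves is the
coefficient Δ — the area under the pointwise minimum of the two densities.
Two estimators are provided: Δ1 integrates the gridded densities and is
preferred for small samples, Δ4 averages density ratios at the observed
times and is preferred when both samples have at least 75 detections.
Confidence intervals come from a smoothed bootstrap (resampling from the
fitted density rather than the raw sample).

The kernel concentration follows the plug-in rule of the circular-KDE
overlap methodology: the sample's von Mises concentration κ̂ is estimated by
maximum likelihood from the mean resultant length and transformed to

    ν = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) ]^(2/5),

then divided by a smoothing adjustment (0.8 for Δ1, 1.0 for Δ4 by default;
larger adjustments smooth more).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

TWO_PI = 2.0 * math.pi

DELTA4_MIN_N = 75  # smaller sample below this -> use Δ1
DENSITY_FLOOR = 1e-12
N_GRID = 128

STRONG_THRESHOLD = 0.75
MODERATE_THRESHOLD = 0.5


@dataclass(frozen=True)
class CircularDensity:
    """A fitted circular kernel density on an equally spaced grid.

    ``grid`` covers [0, 2π) (the periodic closure point 2π is implicit);
    ``kappa`` is the von Mises kernel concentration actually used.
    """

    grid: np.ndarray
    values: np.ndarray
    kappa: float
    data: np.ndarray  # the sample the density was fitted to

    @property
    def n(self) -> int:
        return len(self.data)

    def integral(self) -> float:
        """Trapezoidal integral over the full circle (periodic closure)."""
        return _circular_trapz(self.values, self.grid)

    def __call__(self, theta) -> np.ndarray:
        return vm_kde(np.asarray(theta, dtype=float), self.data, self.kappa)


def _circular_trapz(values: np.ndarray, grid: np.ndarray) -> float:
    h = grid[1] - grid[0]
    closed = np.append(values, values[0])
    return float(np.trapezoid(closed, dx=h))


def vm_kernel(theta: np.ndarray, mu: np.ndarray, kappa: float) -> np.ndarray:
    """von Mises kernel, numerically stable for large concentrations."""
    # I0(k) = i0e(k) e^k, so exp(k cos d)/I0(k) = exp(k (cos d - 1))/i0e(k)
    d = theta - mu  # broadcasts; operate in place on the result
    np.cos(d, out=d)
    d -= 1.0
    d *= kappa
    np.exp(d, out=d)
    d /= TWO_PI * special.i0e(kappa)
    return d


def vm_kde(theta: np.ndarray, sample: np.ndarray, kappa: float) -> np.ndarray:
    """Evaluate the von Mises mixture KDE of ``sample`` at angles ``theta``."""
    t = np.atleast_1d(theta)[:, None]
    dens = vm_kernel(t, sample[None, :], kappa).mean(axis=1)
    return dens if np.ndim(theta) else dens


def vonmises_mle_kappa(sample: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant length."""
    n = len(sample)
    rbar = float(np.hypot(np.cos(sample).sum(), np.sin(sample).sum())) / n
    if rbar <= 1e-8:
        return 0.0
    if rbar >= 1.0 - 1e-8:
        rbar = 1.0 - 1e-8

    def a_minus_r(k):
        return special.i1e(k) / special.i0e(k) - rbar

    # A(k) is increasing from 0 to 1; bracket then solve
    hi = 2.0
    while a_minus_r(hi) < 0 and hi < 1e8:
        hi *= 2.0
    return float(optimize.brentq(a_minus_r, 0.0, hi, xtol=1e-10))


def trigmoment_kappa(sample: np.ndarray, kmax: int = 3) -> float:
    """von Mises concentration fitted to the first ``kmax`` trigonometric moments.

    Minimises Σ_k (A_k(κ) − R_k)², where A_k = I_k(κ)/I_0(κ) and R_k is the
    magnitude of the sample's k-th trigonometric moment. Unlike the
    first-moment ML estimate, this remains informative for bimodal
    (dawn/dusk) activity data, whose nearly antipodal modes cancel the mean
    resultant vector.
    """
    best = 0.0
    for k in range(1, kmax + 1):
        rk = float(np.hypot(np.cos(k * sample).mean(), np.sin(k * sample).mean()))
        best = max(best, _invert_ak(k, rk))
    return best


def _invert_ak(order: int, target: float) -> float:
    """Solve I_k(κ)/I_0(κ) = target for κ (A_k is increasing, 0 -> 1)."""
    if target <= 1e-8:
        return 0.0
    if target >= 1.0 - 1e-8:
        target = 1.0 - 1e-8

    def f(kappa):
        return special.ive(order, kappa) / special.i0e(kappa) - target

    hi = 2.0
    while f(hi) < 0 and hi < 1e6:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-9))


def plugin_kappa(sample: np.ndarray, adjust: float = 1.0) -> float:
    """Plug-in kernel concentration for a circular KDE.

    Taylor's rule on the trigonometric-moment concentration estimate,
    divided by the smoothing adjustment (``adjust`` > 1 smooths more).
    """
    n = len(sample)
    k = trigmoment_kappa(sample)
    if k <= 0:
        return 0.0
    # I2(2k)/I0(k)^2 via scaled Bessels: ive(2,2k)e^{2k} / (i0e(k)e^k)^2
    ratio = special.ive(2, 2 * k) / special.i0e(k) ** 2
    nu = (3.0 * n * k**2 * ratio / (4.0 * math.sqrt(math.pi))) ** 0.4
    return float(nu / adjust)


def fit_circular_kde(
    times: np.ndarray, adjust: float = 1.0, n_grid: int = N_GRID
) -> CircularDensity:
    """Fit a von Mises kernel density to detection times (radians).

    Requires at least two distinct times; an all-identical sample has an
    undefined bandwidth (jitter the times, e.g. by the one-minute recording
    resolution, before fitting).
    """
    t = np.asarray(times, dtype=float) % TWO_PI
    if len(t) < 2:
        raise ValueError("need at least 2 detection times")
    if np.ptp(t) == 0:
        raise ValueError(
            "all detection times identical — jitter to the recording resolution"
        )
    kappa = plugin_kappa(t, adjust)
    grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    values = vm_kde(grid, t, kappa)
    return CircularDensity(grid=grid, values=values, kappa=kappa, data=t)


@dataclass(frozen=True)
class OverlapResult:
    delta: float
    estimator: str  # "Dhat1" or "Dhat4"
    n1: int
    n2: int
    strength: str
    ci_low: float = math.nan
    ci_high: float = math.nan
    resamples: int = 0


def classify_overlap(delta: float) -> str:
    """Strength class: strong if Δ > 0.75, moderate if 0.5 ≤ Δ ≤ 0.75, low below."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("Δ must lie in [0, 1]")
    if delta > STRONG_THRESHOLD:
        return "strong"
    if delta >= MODERATE_THRESHOLD:
        return "moderate"
    return "low"


def _delta1(fa: CircularDensity, fb: CircularDensity) -> float:
    return _circular_trapz(np.minimum(fa.values, fb.values), fa.grid)


def _delta4(fa: CircularDensity, fb: CircularDensity) -> float:
    fa_a = np.maximum(fa(fa.data), DENSITY_FLOOR)
    fb_a = np.maximum(fb(fa.data), DENSITY_FLOOR)
    fa_b = np.maximum(fa(fb.data), DENSITY_FLOOR)
    fb_b = np.maximum(fb(fb.data), DENSITY_FLOOR)
    term_a = np.minimum(1.0, fb_a / fa_a).mean()
    term_b = np.minimum(1.0, fa_b / fb_b).mean()
    return 0.5 * (term_a + term_b)


def select_estimator(n1: int, n2: int) -> str:
    """Δ1 when the smaller sample has < 75 observations, else Δ4."""
    return "Dhat4" if min(n1, n2) >= DELTA4_MIN_N else "Dhat1"


def overlap_delta(
    times_a: np.ndarray,
    times_b: np.ndarray,
    estimator: str | None = None,
    n_grid: int = N_GRID,
) -> OverlapResult:
    """Point estimate of the diel activity overlap between two samples.

    The estimator is auto-selected by the small-sample rule unless forced;
    the result is clamped to [0, 1].
    """
    a = np.asarray(times_a, dtype=float) % TWO_PI
    b = np.asarray(times_b, dtype=float) % TWO_PI
    est = estimator or select_estimator(len(a), len(b))
    if est not in ("Dhat1", "Dhat4"):
        raise ValueError(f"unknown estimator {est!r}")
    adjust = 0.8 if est == "Dhat1" else 1.0
    fa = fit_circular_kde(a, adjust=adjust, n_grid=n_grid)
    fb = fit_circular_kde(b, adjust=adjust, n_grid=n_grid)
    d = _delta1(fa, fb) if est == "Dhat1" else _delta4(fa, fb)
    d = min(1.0, max(0.0, d))
    return OverlapResult(
        delta=d, estimator=est, n1=len(a), n2=len(b), strength=classify_overlap(d)
    )


def true_overlap(f, g, n_points: int = 2**14) -> float:
    """Numeric integral of min(f, g) over the circle for known densities.

    Testing oracle: ``f`` and ``g`` are vectorised density functions that
    each integrate to 1 on [0, 2π). Composite trapezoid at high resolution;
    refinement beyond the default changes the value by far less than 1e-6
    for smooth densities.
    """
    grid = np.linspace(0.0, TWO_PI, n_points, endpoint=False)
    h = TWO_PI / n_points
    vals = np.minimum(f(grid), g(grid))
    closed = np.append(vals, vals[0])
    return float(np.trapezoid(closed, dx=h))


def smoothed_resample(
    density: CircularDensity, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` points from the fitted KDE (smoothed bootstrap draw)."""
    centers = rng.choice(density.data, size=n, replace=True)
    if density.kappa <= 0:
        return rng.uniform(0.0, TWO_PI, size=n)
    return (centers + rng.vonmises(0.0, density.kappa, size=n)) % TWO_PI


def _delta_fast(a: np.ndarray, b: np.ndarray, est: str, n_grid: int) -> float:
    """Point estimate without constructing CircularDensity objects.

    Skips the grid evaluation for Δ4 (which only needs densities at the
    observed times) — the bootstrap hot path.
    """
    adjust = 0.8 if est == "Dhat1" else 1.0
    ka = plugin_kappa(a, adjust)
    kb = plugin_kappa(b, adjust)
    if est == "Dhat1":
        grid = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
        fa = vm_kde(grid, a, ka)
        fb = vm_kde(grid, b, kb)
        h = TWO_PI / n_grid
        m = np.minimum(fa, fb)
        d = float(np.trapezoid(np.append(m, m[0]), dx=h))
    else:
        pts = np.concatenate([a, b])
        fa_pts = np.maximum(vm_kde(pts, a, ka), DENSITY_FLOOR)
        fb_pts = np.maximum(vm_kde(pts, b, kb), DENSITY_FLOOR)
        na = len(a)
        d = 0.5 * (np.minimum(1.0, fb_pts[:na] / fa_pts[:na]).mean()
                   + np.minimum(1.0, fa_pts[na:] / fb_pts[na:]).mean())
    return min(1.0, max(0.0, d))


def bootstrap_ci(
    times_a: np.ndarray,
    times_b: np.ndarray,
    resamples: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    estimator: str | None = None,
    n_grid: int = N_GRID,
) -> OverlapResult:
    """Smoothed-bootstrap confidence interval for the overlap coefficient.

    Each resample draws n1 and n2 points from the fitted densities,
    re-estimates Δ with the same estimator (bandwidth refitted per
    resample), and the interval is the percentile interval of the resample
    distribution, clamped to [0, 1] and widened if needed to contain the
    point estimate. (In calibration simulations the percentile interval
    covers a known Δ closer to the nominal 95% than the basic
    2Δ̂ − quantile reflection, which under-covers here because the smoothed
    resamples inherit the estimator's slight upward bias.)
    """
    if resamples < 100:
        raise ValueError("use at least 100 resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = overlap_delta(times_a, times_b, estimator=estimator, n_grid=n_grid)
    est = point.estimator
    adjust = 0.8 if est == "Dhat1" else 1.0
    fa = fit_circular_kde(np.asarray(times_a, dtype=float), adjust=adjust, n_grid=n_grid)
    fb = fit_circular_kde(np.asarray(times_b, dtype=float), adjust=adjust, n_grid=n_grid)
    boot = np.empty(resamples)
    for i in range(resamples):
        ra = smoothed_resample(fa, fa.n, rng)
        rb = smoothed_resample(fb, fb.n, rng)
        boot[i] = _delta_fast(ra, rb, est, n_grid)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
    lo = min(max(float(q_lo), 0.0), point.delta)
    hi = max(min(float(q_hi), 1.0), point.delta)
    return OverlapResult(
        delta=point.delta,
        estimator=est,
        n1=point.n1,
        n2=point.n2,
        strength=point.strength,
        ci_low=float(lo),
        ci_high=float(hi),
        resamples=resamples,
    )
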