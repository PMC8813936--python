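"""Cytometry comparison statistics: stoichiometric expectations, arcsinh
normalization, two-Gaussian population fitting, the separation parameter,
blank-width sensitivity ratios and log-log linearity fits.

The arcsinh scale

    y = arcsinh(a*I - b) / ln(10)

is asymptotically log10 for large ``a*I`` but remains defined for the
negative intensities that honest background subtraction produces.  The
normalization factors ``a`` and ``b`` are chosen independently per dataset
so that the blank population has mean 0 and the brightest stained
population has mean 2 in arcsinh units.

The separation parameter between two fitted populations,

    s = |mu2 - mu1| / sqrt(sigma1**2 + sigma2**2),

quantifies how resolvable they are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateScaleError, InputError

__all__ = [
    "ArcsinhScale",
    "TwoGaussianFit",
    "LinearityFit",
    "expected_labeled_epitopes",
    "fit_arcsinh_scale",
    "arcsinh_transform",
    "fit_two_gaussians",
    "fit_two_gaussians_hist",
    "separation",
    "blank_width_ratio",
    "fit_loglog_linearity",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class ArcsinhScale:
    """Normalization factors of the arcsinh intensity transform."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InputError("scale factor a must be positive")


@dataclass
class TwoGaussianFit:
    """Two-component Gaussian description of a transformed distribution."""

    w1: float
    w2: float
    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    converged: bool
    log_likelihood: float
    degenerate: bool = False

    @property
    def s(self) -> float:
        return separation(self.mu1, self.sigma1, self.mu2, self.sigma2)


@dataclass
class LinearityFit:
    """Log-log least-squares line through per-level mean intensities."""

    slope: float
    intercept: float
    r_squared: float
    levels: np.ndarray
    means: np.ndarray
    sds: np.ndarray


def expected_labeled_epitopes(labeling_percentage: float,
                              copy_number: int = 57_000,
                              round_2sf: bool = False) -> float:
    """Expected labeled epitopes per cell at a stoichiometric labeling level.

    With 57,000 copies per cell, 10% labeling yields 5,700 labeled
    epitopes; ``round_2sf`` reproduces the two-significant-figure style of
    printed titration tables (33% -> 19,000).
    """
    if not 0 <= labeling_percentage <= 100:
        raise InputError("labeling percentage must lie in [0, 100]")
    value = labeling_percentage / 100.0 * copy_number
    if round_2sf and value > 0:
        magnitude = 10.0 ** (np.floor(np.log10(value)) - 1)
        value = round(value / magnitude) * magnitude
    return float(value)


def arcsinh_transform(I: np.ndarray | float, scale: ArcsinhScale) -> np.ndarray:
    """y = arcsinh(a*I - b) / ln(10), elementwise."""
    return np.arcsinh(scale.a * np.asarray(I, dtype=float) - scale.b) / _LN10


def fit_arcsinh_scale(blank: np.ndarray, top: np.ndarray,
                      blank_target: float = 0.0, top_target: float = 2.0,
                      tol: float = 1e-12, max_iter: int = 200) -> ArcsinhScale:
    """Solve for (a, b) so the transformed blank and top means hit their
    targets (0 and 2 arcsinh units by default).

    The two-equation system is solved by a damped Newton iteration with a
    numerically evaluated Jacobian; the initial guess comes from the
    small-argument (blank) and logarithmic (top) limits of arcsinh.
    """
    blank = np.asarray(blank, dtype=float).ravel()
    top = np.asarray(top, dtype=float).ravel()
    if blank.size == 0 or top.size == 0:
        raise InputError("blank and top samples must be nonempty")
    mb, mt = float(np.mean(blank)), float(np.mean(top))
    if mt <= mb:
        raise DegenerateScaleError("top-population mean must exceed blank mean")

    t_top = np.sinh(top_target * _LN10)  # a*mean(top) - b at the target, roughly

    def residual(p):
        a, b = p
        if a <= 0:
            return np.array([np.inf, np.inf])
        yb = np.mean(np.arcsinh(a * blank - b)) / _LN10 - blank_target
        yt = np.mean(np.arcsinh(a * top - b)) / _LN10 - top_target
        return np.array([yb, yt])

    # small-argument limit: a*mb - b ~ sinh(0) = 0; log limit: a*mt - b ~ t_top
    a0 = t_top / (mt - mb)
    p = np.array([a0, a0 * mb - np.sinh(blank_target * _LN10)])
    r = residual(p)
    for _ in range(max_iter):
        if np.max(np.abs(r)) < tol:
            break
        jac = np.empty((2, 2))
        for j in range(2):
            h = 1e-7 * max(abs(p[j]), 1e-12)
            pj = p.copy()
            pj[j] += h
            jac[:, j] = (residual(pj) - r) / h
        try:
            step = np.linalg.solve(jac, -r)
        except np.linalg.LinAlgError as exc:
            raise DegenerateScaleError("singular Jacobian in scale fit") from exc
        lam = 1.0
        for _ in range(60):
            cand = p + lam * step
            rc = residual(cand)
            if np.all(np.isfinite(rc)) and np.max(np.abs(rc)) < np.max(np.abs(r)):
                p, r = cand, rc
                break
            lam *= 0.5
        else:
            raise DegenerateScaleError("arcsinh scale fit failed to converge")
    if np.max(np.abs(r)) >= 1e-9:
        raise DegenerateScaleError(
            f"arcsinh scale residuals {np.abs(r).max():.2e} exceed 1e-9")
    return ArcsinhScale(a=float(p[0]), b=float(p[1]))


def separation(mu1: float, sigma1: float, mu2: float, sigma2: float) -> float:
    """|mu2 - mu1| / sqrt(sigma1^2 + sigma2^2)."""
    if sigma1 <= 0 or sigma2 <= 0:
        raise InputError("standard deviations must be positive")
    return float(abs(mu2 - mu1) / np.hypot(sigma1, sigma2))


def _em_two_gaussians(y, mu1, mu2, sigma1, sigma2, w1, tol, max_iter):
    n = y.size
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        p1 = w1 * stats.norm.pdf(y, mu1, sigma1)
        p2 = (1 - w1) * stats.norm.pdf(y, mu2, sigma2)
        total = p1 + p2
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        ll = float(np.sum(np.log(total)))
        r1 = p1 / total
        n1 = r1.sum()
        n2 = n - n1
        if n1 < 1e-10 or n2 < 1e-10:
            return None, False
        mu1 = float(np.sum(r1 * y) / n1)
        mu2 = float(np.sum((1 - r1) * y) / n2)
        sigma1 = float(np.sqrt(np.sum(r1 * (y - mu1) ** 2) / n1))
        sigma2 = float(np.sqrt(np.sum((1 - r1) * (y - mu2) ** 2) / n2))
        w1 = float(n1 / n)
        scale = max(float(np.std(y)), 1e-12)
        if sigma1 < 1e-8 * scale or sigma2 < 1e-8 * scale:
            return None, False
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return (w1, mu1, mu2, sigma1, sigma2, prev_ll), converged


def fit_two_gaussians(y: np.ndarray, seed: int | None = None,
                      tol: float = 1e-8, max_iter: int = 500,
                      max_restarts: int = 5) -> TwoGaussianFit:
    """Two-component Gaussian mixture by expectation-maximization.

    Initialized at the 25th/75th sample percentiles with equal weights;
    converged when the log-likelihood change drops below ``tol``.  If a
    component collapses (sigma -> 0) the fit restarts from jittered
    initializations up to ``max_restarts`` times before returning a
    degenerate-fit flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 50:
        raise InputError("need at least 50 observations for a mixture fit")
    rng = np.random.default_rng(seed)
    q25, q75 = np.percentile(y, [25, 75])
    spread = max(float(np.std(y)), 1e-12)
    init = (q25, q75, spread / 2, spread / 2, 0.5)
    for attempt in range(max_restarts + 1):
        result, converged = _em_two_gaussians(y, *init, tol=tol,
                                              max_iter=max_iter)
        if result is not None:
            w1, mu1, mu2, sigma1, sigma2, ll = result
            if mu1 > mu2:  # order components by mean
                mu1, mu2 = mu2, mu1
                sigma1, sigma2 = sigma2, sigma1
                w1 = 1 - w1
            return TwoGaussianFit(w1=w1, w2=1 - w1, mu1=mu1, mu2=mu2,
                                  sigma1=sigma1, sigma2=sigma2,
                                  converged=converged, log_likelihood=ll)
        jitter = rng.normal(0, spread / 4, size=2)
        init = (q25 + jitter[0], q75 + jitter[1],
                spread / 2 * rng.uniform(0.5, 2),
                spread / 2 * rng.uniform(0.5, 2),
                0.5)
    mu, sigma = float(np.mean(y)), max(float(np.std(y)), 1e-12)
    return TwoGaussianFit(w1=0.5, w2=0.5, mu1=mu, mu2=mu, sigma1=sigma,
                          sigma2=sigma, converged=False,
                          log_likelihood=float("nan"), degenerate=True)


def fit_two_gaussians_hist(y: np.ndarray, bins: int = 100,
                           seed: int | None = None) -> TwoGaussianFit:
    """Histogram-based alternative: least-squares fit of a two-Gaussian
    density to the binned sample (avoids per-event likelihoods, mirrors
    fitting published histograms)."""
    from scipy.optimize import curve_fit

    y = np.asarray(y, dtype=float).ravel()
    if y.size < 50:
        raise InputError("need at least 50 observations for a mixture fit")
    density, edges = np.histogram(y, bins=bins, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])

    def model(x, w1, mu1, mu2, s1, s2):
        return (w1 * stats.norm.pdf(x, mu1, abs(s1))
                + (1 - w1) * stats.norm.pdf(x, mu2, abs(s2)))

    q25, q75 = np.percentile(y, [25, 75])
    spread = max(float(np.std(y)), 1e-12)
    p0 = [0.5, q25, q75, spread / 2, spread / 2]
    try:
        popt, _ = curve_fit(model, x, density, p0=p0,
                            bounds=([0, -np.inf, -np.inf, 1e-12, 1e-12],
                                    [1, np.inf, np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError:
        return fit_two_gaussians(y, seed=seed)
    w1, mu1, mu2, s1, s2 = popt
    if mu1 > mu2:
        mu1, mu2, s1, s2, w1 = mu2, mu1, s2, s1, 1 - w1
    resid = density - model(x, *popt)
    return TwoGaussianFit(w1=float(w1), w2=float(1 - w1), mu1=float(mu1),
                          mu2=float(mu2), sigma1=float(abs(s1)),
                          sigma2=float(abs(s2)), converged=True,
                          log_likelihood=-float(np.sum(resid**2)))


def blank_width_ratio(blank_a: np.ndarray, blank_b: np.ndarray,
                      width: str = "sd") -> float:
    """Width of blank B over width of blank A (sensitivity ratio).

    A narrower blank means a lower noise floor: if instrument A's blank is
    14.5x narrower than instrument B's, A is 14.5x more sensitive to weak
    signals.  ``width`` is the standard deviation by default, or the
    Gaussian-consistent robust MAD estimate (``"mad"``).
    """
    blank_a = np.asarray(blank_a, dtype=float).ravel()
    blank_b = np.asarray(blank_b, dtype=float).ravel()
    if blank_a.size == 0 or blank_b.size == 0:
        raise InputError("blank samples must be nonempty")
    if width == "sd":
        wa, wb = float(np.std(blank_a)), float(np.std(blank_b))
    elif width == "mad":
        wa = float(stats.median_abs_deviation(blank_a, scale="normal"))
        wb = float(stats.median_abs_deviation(blank_b, scale="normal"))
    else:
        raise InputError(f"unknown width estimator {width!r}")
    if wa == 0 or wb == 0:
        raise InputError("zero-variance blank sample")
    return wb / wa


def fit_loglog_linearity(levels: np.ndarray,
                         samples: list[np.ndarray]) -> LinearityFit:
    """Least-squares line of log10(mean intensity) vs log10(level).

    Levels with nonpositive mean intensity are excluded with a warning; at
    least three usable levels are required.  A slope of 1 over the full
    titration range is the signature of stoichiometric linearity.
    """
    levels = np.asarray(levels, dtype=float)
    if len(levels) != len(samples):
        raise InputError("levels and samples differ in length")
    means = np.array([float(np.mean(s)) for s in samples])
    sds = np.array([float(np.std(s)) for s in samples])
    usable = (levels > 0) & (means > 0)
    if np.any(~usable):
        warnings.warn(f"excluding {int((~usable).sum())} level(s) with "
                      "nonpositive mean from log-log fit", stacklevel=2)
    if usable.sum() < 3:
        raise InputError("need at least 3 levels with positive means")
    lx = np.log10(levels[usable])
    ly = np.log10(means[usable])
    fit = stats.linregress(lx, ly)
    return LinearityFit(slope=float(fit.slope), intercept=float(fit.intercept),
                        r_squared=float(fit.rvalue**2), levels=levels,
                        means=means, sds=sds)
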