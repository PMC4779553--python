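"""Two-class Gaussian-mixture intensity classification by Expectation-Maximization.

Myocardial CE-SSFP intensities are modelled as a mixture of two Gaussians:
normal myocardium and hyperintense myocardium at risk (MaR).  Both classes
are Gaussian — CE-SSFP does not null remote myocardium, so a Rayleigh class
is not appropriate.  The fit is initialized from the a priori maximal-extent
territory of the culprit artery (voxels inside the territory seed the MaR
class) and run to convergence of the mean log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GaussianMixtureFit:
    """Parameters of the two-class intensity mixture (intensity units)."""

    mu_normal: float
    sigma_normal: float
    mu_mar: float
    sigma_mar: float
    w_mar: float

    def __post_init__(self) -> None:
        if self.sigma_normal <= 0 or self.sigma_mar <= 0:
            raise ValueError("class standard deviations must be > 0")
        if not 0.0 < self.w_mar < 1.0:
            raise ValueError("w_mar must lie in (0, 1)")

    def log_densities(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        ln = (-0.5 * ((x - self.mu_normal) / self.sigma_normal) ** 2
              - np.log(self.sigma_normal) - _LOG_SQRT_2PI)
        lm = (-0.5 * ((x - self.mu_mar) / self.sigma_mar) ** 2
              - np.log(self.sigma_mar) - _LOG_SQRT_2PI)
        return ln, lm

    def posterior_mar(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that each intensity belongs to the MaR class."""
        ln, lm = self.log_densities(x)
        a = np.log1p(-self.w_mar) + ln
        b = np.log(self.w_mar) + lm
        m = np.maximum(a, b)
        return np.exp(b - m) / (np.exp(a - m) + np.exp(b - m))

    def mean_log_likelihood(self, x: np.ndarray) -> float:
        ln, lm = self.log_densities(x)
        a = np.log1p(-self.w_mar) + ln
        b = np.log(self.w_mar) + lm
        m = np.maximum(a, b)
        return float(np.mean(m + np.log(np.exp(a - m) + np.exp(b - m))))

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in
                ("mu_normal", "sigma_normal", "mu_mar", "sigma_mar", "w_mar")}


@dataclass(frozen=True)
class EMConfig:
    """EM hyperparameters.

    ``tol`` is the relative change in mean log-likelihood that counts as
    converged; ``sigma_floor_frac`` times the intensity range is the smallest
    admissible class SD (guards against component collapse).
    """

    tol: float = 1e-6
    max_iter: int = 500
    sigma_floor_frac: float = 1e-3

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.sigma_floor_frac <= 0:
            raise ValueError("invalid EM configuration")


@dataclass
class EMResult:
    fit: GaussianMixtureFit
    log_likelihood: np.ndarray  # mean log-likelihood after each iteration
    n_iter: int
    converged: bool
    sigma_clamped: bool


def _sigma_floor(x: np.ndarray, config: EMConfig) -> float:
    rng = float(np.ptp(x))
    if rng == 0.0:
        raise ValueError("degenerate input: all intensities identical")
    return config.sigma_floor_frac * rng


def initialize_from_extent(intensities: np.ndarray,
                           inside_extent: np.ndarray,
                           config: EMConfig = EMConfig()) -> GaussianMixtureFit:
    """Initial mixture from the a priori territory.

    Voxels inside the maximal-extent model seed the MaR class, voxels outside
    seed the normal class; class means/SDs are the sample statistics and the
    MaR weight is the inside fraction.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    inside = np.asarray(inside_extent, dtype=bool).ravel()
    if x.shape != inside.shape:
        raise ValueError("intensities and inside_extent must align")
    if not inside.any() or inside.all():
        raise ValueError("both classes (inside/outside territory) must be non-empty")
    floor = _sigma_floor(x, config)
    stats = []
    for sel in (~inside, inside):
        mu = float(x[sel].mean())
        sd = float(x[sel].std())
        if sd <= 0:
            warnings.warn("zero sample SD in initialization; clamped to sigma floor")
            sd = floor
        stats.append((mu, sd))
    (mu_n, sd_n), (mu_m, sd_m) = stats
    return GaussianMixtureFit(mu_n, sd_n, mu_m, sd_m, w_mar=float(inside.mean()))


def em_fit(intensities: np.ndarray, init: GaussianMixtureFit,
           config: EMConfig = EMConfig()) -> EMResult:
    """Standard two-component Gaussian-mixture EM.

    Iterates responsibilities (E-step) and weighted mean/SD/weight updates
    (M-step) until the relative change in mean log-likelihood falls below
    ``config.tol`` or ``config.max_iter`` is reached.  The returned fit is
    relabelled if needed so that ``mu_mar >= mu_normal`` (MaR is hyperintense).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if np.unique(x).size < 2:
        raise ValueError("degenerate input: need >= 2 distinct intensity values")
    floor = _sigma_floor(x, config)

    mu_n, sd_n = init.mu_normal, max(init.sigma_normal, floor)
    mu_m, sd_m = init.mu_mar, max(init.sigma_mar, floor)
    w = init.w_mar
    clamped = False
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        fit = GaussianMixtureFit(mu_n, sd_n, mu_m, sd_m, w)
        r = fit.posterior_mar(x)  # E-step
        # M-step
        w = float(np.clip(r.mean(), 1e-12, 1 - 1e-12))
        sum_m, sum_n = r.sum(), (1 - r).sum()
        mu_m = float((r * x).sum() / sum_m)
        mu_n = float(((1 - r) * x).sum() / sum_n)
        sd_m = float(np.sqrt((r * (x - mu_m) ** 2).sum() / sum_m))
        sd_n = float(np.sqrt(((1 - r) * (x - mu_n) ** 2).sum() / sum_n))
        if sd_m < floor or sd_n < floor:
            clamped = True
            sd_m, sd_n = max(sd_m, floor), max(sd_n, floor)
        trace.append(GaussianMixtureFit(mu_n, sd_n, mu_m, sd_m, w).mean_log_likelihood(x))
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= config.tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    if mu_m < mu_n:  # enforce label ordering: MaR is the brighter class
        mu_n, sd_n, mu_m, sd_m, w = mu_m, sd_m, mu_n, sd_n, 1.0 - w
    fit = GaussianMixtureFit(mu_n, sd_n, mu_m, sd_m, w)
    if clamped:
        warnings.warn("EM component SD clamped to the sigma floor")
    return EMResult(fit=fit, log_likelihood=np.asarray(trace), n_iter=it,
                    converged=converged, sigma_clamped=clamped)


def mixture_delta_bic(intensities: np.ndarray, fit: GaussianMixtureFit) -> float:
    """BIC improvement of the two-class mixture over a single Gaussian.

    Positive values support the presence of a second (MaR) intensity class;
    values <= 0 mean the intensity histogram carries no evidence of two
    classes (degenerate, e.g. contrast-free input).  The mixture spends 3
    extra parameters (one mean, one SD, one weight).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    n = x.size
    mu, sd = float(x.mean()), float(x.std())
    if sd <= 0:
        raise ValueError("degenerate input: all intensities identical")
    ll_single = float(np.mean(-0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI))
    ll_mix = fit.mean_log_likelihood(x)
    return 2.0 * n * (ll_mix - ll_single) - 3.0 * np.log(n)


def decision_threshold(fit: GaussianMixtureFit) -> float:
    """Intensity at which the MaR posterior crosses 0.5 (equal-posterior point).

    Solves ``w_mar N(x; mu_mar, sigma_mar) = (1 - w_mar) N(x; mu_normal,
    sigma_normal)`` and returns the upward crossing between the class means;
    the posterior at the returned value equals 0.5 to within 1e-6.
    """
    mu_n, sd_n = fit.mu_normal, fit.sigma_normal
    mu_m, sd_m = fit.mu_mar, fit.sigma_mar
    if mu_n == mu_m and sd_n == sd_m:
        raise ValueError("identical components: no separating threshold")
    # g(x) >= 0  <=>  posterior_mar(x) >= 0.5
    a = 0.5 / sd_n**2 - 0.5 / sd_m**2
    b = mu_m / sd_m**2 - mu_n / sd_n**2
    c = (mu_n**2 / (2 * sd_n**2) - mu_m**2 / (2 * sd_m**2)
         + np.log(fit.w_mar * sd_n / ((1 - fit.w_mar) * sd_m)))
    if abs(a) < 1e-300:  # equal variances: linear crossing
        if b == 0:
            raise ValueError("identical components: no separating threshold")
        return float(-c / b)
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("posterior never crosses 0.5: components indistinguishable")
    roots = sorted(((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)))
    for r in roots:  # smallest upward crossing (g' > 0)
        if 2 * a * r + b > 0:
            return float(r)
    raise ValueError("no upward posterior crossing found")
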