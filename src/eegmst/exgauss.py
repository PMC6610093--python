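"""Ex-Gaussian decomposition of reaction-time distributions.

A reaction time is modelled as the sum of a Normal(mu, sigma) component
(typical speed) and an independent Exponential(tau) component (the heavy
right tail, commonly read as attentional lapses). The density is the
Normal * Exponential convolution, available in closed form; fitting is by
maximum likelihood with moment-based initialisation and a small
multi-start, following standard practice for skewed small samples.

Moment identities used throughout: mean = mu + tau, variance =
sigma^2 + tau^2, skewness = 2 tau^3 / (sigma^2 + tau^2)^{3/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import ExGaussianParams

_EPS = 1e-3  # lower bound for sigma and tau, ms


def exgauss_logdensity(x, params: ExGaussianParams) -> np.ndarray:
    """Log-density of the ex-Gaussian at ``x``.

    Evaluated through scipy's exponentially-modified normal
    (``exponnorm`` with shape K = tau/sigma), whose log-space
    exp-times-erfc evaluation stays stable for tau << sigma and
    tau >> sigma.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite evaluation points")
    return stats.exponnorm.logpdf(x, params.tau / params.sigma,
                                  loc=params.mu, scale=params.sigma)


def exgauss_density(x, params: ExGaussianParams) -> np.ndarray:
    """Density of the ex-Gaussian at ``x``."""
    return np.exp(exgauss_logdensity(x, params))


def _moment_start(rts: np.ndarray) -> tuple[float, float, float]:
    """Moment-based starting values (mean, SD, skewness inversion).

    tau0 is the cube root of half the third central moment, clipped away
    from 0; sigma0 absorbs the rest of the variance.
    """
    m = rts.mean()
    s = rts.std(ddof=1)
    skew = stats.skew(rts, bias=False)
    tau0 = s * np.cbrt(max(skew, 1e-3) / 2.0)
    tau0 = float(np.clip(tau0, _EPS, None))
    sigma0 = float(np.sqrt(max(s**2 - tau0**2, (0.1 * s) ** 2)))
    return float(m - tau0), sigma0, tau0


@dataclass
class ExGaussianResults:
    """Fitted ex-Gaussian parameters with fit diagnostics.

    Attributes
    ----------
    params : ExGaussianParams
        Maximum-likelihood (mu, sigma, tau), ms.
    loglik : float
        Maximised log-likelihood.
    converged : bool
        Whether the best optimiser run reported convergence.
    n_obs : int
        Number of reaction times fitted.
    at_bound : bool
        True when sigma or tau sits at its lower bound (e.g. tau for a
        purely Gaussian sample) — the parameter is then unidentified
        rather than estimated.
    """

    params: ExGaussianParams
    loglik: float
    converged: bool
    n_obs: int
    at_bound: bool
    message: str = ""
    model: "ExGaussianModel | None" = None

    @property
    def mu(self) -> float:
        return self.params.mu

    @property
    def sigma(self) -> float:
        return self.params.sigma

    @property
    def tau(self) -> float:
        return self.params.tau

    def summary(self) -> str:
        rows = [
            ("mu (normal mean, ms)", self.mu),
            ("sigma (normal SD, ms)", self.sigma),
            ("tau (exponential mean, ms)", self.tau),
            ("implied mean RT (mu + tau)", self.mu + self.tau),
            ("implied SD (sqrt(sigma^2+tau^2))",
             float(np.hypot(self.sigma, self.tau))),
            ("log-likelihood", self.loglik),
        ]
        lines = ["Ex-Gaussian maximum-likelihood fit",
                 f"n_obs = {self.n_obs}, converged = {self.converged}"
                 + (", parameter at bound" if self.at_bound else "")]
        lines += [f"  {name:<34s} {val:>12.3f}" for name, val in rows]
        return "\n".join(lines)

    def plot(self, ax=None, bins: int = 40):
        """Histogram of the data with the fitted density overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rts = self.model.rts if self.model is not None else None
        if rts is not None:
            ax.hist(rts, bins=bins, density=True, alpha=0.5, label="data")
            grid = np.linspace(rts.min(), rts.max(), 400)
        else:
            lo = self.mu - 4 * self.sigma
            hi = self.mu + self.tau + 6 * np.hypot(self.sigma, self.tau)
            grid = np.linspace(lo, hi, 400)
        ax.plot(grid, exgauss_density(grid, self.params), "r-",
                label="ex-Gaussian fit")
        ax.set_xlabel("reaction time (ms)")
        ax.set_ylabel("density")
        ax.legend()
        return ax


class ExGaussianModel:
    """Maximum-likelihood ex-Gaussian model for one subject's RTs.

    Parameters
    ----------
    rts : array-like
        Reaction times in ms; all finite and positive. No outlier
        trimming is applied by default — the long tail is the object of
        interest — but a symmetric percentile trim is available.
    trim : float, optional
        Fraction (0-0.05) trimmed from each tail before fitting; off by
        default.
    """

    def __init__(self, rts, trim: float = 0.0):
        rts = np.asarray(rts, dtype=float).ravel()
        if rts.size < 10:
            raise ValueError("need at least 10 reaction times (>= 50 advised)")
        if not np.all(np.isfinite(rts)) or np.any(rts <= 0):
            raise ValueError("reaction times must be finite and positive")
        if rts.std(ddof=1) == 0:
            raise ValueError("degenerate sample: zero variance")
        if trim:
            if not 0 < trim <= 0.05:
                raise ValueError("trim must lie in (0, 0.05]")
            lo, hi = np.quantile(rts, [trim, 1 - trim])
            rts = rts[(rts >= lo) & (rts <= hi)]
        self.rts = rts

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rt_col: str = "rt_ms",
                       correct_col: str | None = "correct",
                       **kwargs) -> "ExGaussianModel":
        """Build from a trial table (one row per trial).

        When ``correct_col`` is present, error trials are dropped.
        """
        rts = df[rt_col]
        if correct_col is not None and correct_col in df.columns:
            rts = rts[df[correct_col].astype(bool)]
        return cls(rts.to_numpy(), **kwargs)

    def loglike(self, mu: float, sigma: float, tau: float) -> float:
        return float(np.sum(exgauss_logdensity(
            self.rts, ExGaussianParams(mu, sigma, tau))))

    def fit(self, n_starts: int = 3, seed: int = 0) -> ExGaussianResults:
        """Maximise the likelihood from ``n_starts`` jittered moment starts.

        L-BFGS-B with box constraints sigma, tau >= 1e-3 ms; the best
        converged run wins. Non-convergence of all runs is reported, not
        silenced.
        """
        rts = self.rts
        mu0, sigma0, tau0 = _moment_start(rts)
        rng = np.random.default_rng(seed)
        starts = [(mu0, sigma0, tau0)]
        for _ in range(n_starts - 1):
            jitter = rng.uniform(0.7, 1.3, size=3)
            starts.append((mu0 * jitter[0] if mu0 > 0 else mu0 + rts.std() *
                           (jitter[0] - 1), sigma0 * jitter[1],
                           tau0 * jitter[2]))

        def nll(theta):
            mu, sigma, tau = theta
            return -np.sum(stats.exponnorm.logpdf(
                rts, tau / sigma, loc=mu, scale=sigma))

        span = rts.max() - rts.min() + rts.std(ddof=1)
        bounds = [(rts.min() - span, rts.max() + span),
                  (_EPS, 10 * span), (_EPS, 10 * span)]
        best = None
        any_converged = False
        for x0 in starts:
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            if not np.isfinite(res.fun):
                continue
            any_converged |= bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("ex-Gaussian likelihood could not be evaluated")
        mu, sigma, tau = best.x
        at_bound = bool(sigma <= _EPS * 1.01 or tau <= _EPS * 1.01)
        return ExGaussianResults(
            params=ExGaussianParams(float(mu), float(sigma), float(tau)),
            loglik=float(-best.fun),
            converged=any_converged,
            n_obs=rts.size,
            at_bound=at_bound,
            message=str(best.message),
            model=self,
        )


def fit_exgauss_mle(rts, **kwargs) -> ExGaussianResults:
    """Functional wrapper: ``ExGaussianModel(rts).fit(**kwargs)``."""
    return ExGaussianModel(rts).fit(**kwargs)


def summary_stats(rts, n_stimuli: int | None = None,
                  n_errors: int | None = None) -> dict[str, float]:
    """Conventional speed/variability summaries of one RT sample.

    Returns the arithmetic mean RT, the individual standard deviation
    (iSD, sample SD with n-1 denominator) and pass-through totals.
    """
    rts = np.asarray(rts, dtype=float).ravel()
    if rts.size == 0:
        raise ValueError("empty reaction-time sample")
    if rts.size < 2:
        raise ValueError("iSD needs at least 2 reaction times")
    out = {"rt_mean": float(rts.mean()), "isd": float(rts.std(ddof=1)),
           "n_trials": int(rts.size)}
    if n_stimuli is not None:
        out["n_stimuli"] = int(n_stimuli)
    if n_errors is not None:
        out["n_errors"] = int(n_errors)
    return out
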