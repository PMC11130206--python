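"""Posterior containers, effect-size indices and convergence diagnostics.

Both experiment models report their posteriors the same way: the median of
the draws, the (normal-consistency scaled) median absolute deviation as a
robust spread, an 89% highest-density interval, and the probability of
direction — the posterior probability that the parameter is strictly
positive or strictly negative, whichever is larger.  89% is deliberately
non-conventional so the interval reads as a description of the posterior
rather than a hypothesis test.

Summaries on a transformed scale (e.g. odds ratios) are computed by
transforming the draws first and summarising after, never by transforming a
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.stats import median_abs_deviation

from .hmc import LogDensityModel, hmc_sample

__all__ = [
    "SamplerSettings",
    "PosteriorDraws",
    "EffectSummary",
    "DiagnosticsReport",
    "sample_posterior",
    "hdi",
    "prob_direction",
    "summarize_effect",
    "contrast_draws",
    "diagnostics",
]


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC run configuration.

    ``n_iterations`` and ``n_warmup`` are per chain; the retained posterior
    has ``n_chains * (n_iterations - n_warmup)`` draws.
    """

    n_chains: int = 4
    n_iterations: int = 6000
    n_warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.8
    max_leapfrog: int = 32

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iterations:
            raise ValueError("n_warmup must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws with chain structure.

    ``draws`` has shape (n_chains, n_draws_per_chain, n_parameters).
    """

    names: list[str]
    draws: np.ndarray = field(repr=False)
    n_divergences: int = 0

    def __post_init__(self) -> None:
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, draws, parameters)")
        if not np.isfinite(self.draws).all():
            raise ValueError("posterior draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total post-warmup draws across chains."""
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """All draws stacked to (total draws, parameters)."""
        return self.draws.reshape(-1, len(self.names))

    @property
    def chain_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chains), self.draws.shape[1])

    def get(self, name: str) -> np.ndarray:
        """Flattened draws of one parameter."""
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}; have {self.names}") from None
        return self.draws[:, :, i].reshape(-1)

    def per_chain(self, name: str) -> np.ndarray:
        i = self.names.index(name)
        return self.draws[:, :, i]

    def to_arviz(self) -> az.InferenceData:
        return az.from_dict({n: self.per_chain(n) for n in self.names})


@dataclass(frozen=True)
class EffectSummary:
    """Median / MAD / 89% HDI / probability-of-direction for one quantity."""

    median: float
    mad: float
    hdi_low: float
    hdi_high: float
    pd: float
    mass: float = 0.89

    def __post_init__(self) -> None:
        assert self.hdi_low <= self.hdi_high
        assert 0.5 - 1e-12 <= self.pd <= 1.0


@dataclass
class DiagnosticsReport:
    """Convergence diagnostics per parameter plus sampler-level counters."""

    rhat: dict[str, float]
    ess: dict[str, float]
    n_divergences: int
    max_lag1_autocorr: float

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")

    def converged(self, rhat_limit: float = 1.05) -> bool:
        return bool(self.rhat) and self.max_rhat < rhat_limit and self.n_divergences == 0


def sample_posterior(model: LogDensityModel, settings: SamplerSettings) -> PosteriorDraws:
    """Draw from a model's posterior with the shared HMC engine."""
    draws, div = hmc_sample(
        model,
        n_chains=settings.n_chains,
        n_iterations=settings.n_iterations,
        n_warmup=settings.n_warmup,
        seed=settings.seed,
        target_accept=settings.target_accept,
        max_leapfrog=settings.max_leapfrog,
    )
    return PosteriorDraws(names=list(model.names), draws=draws, n_divergences=int(div.sum()))


def hdi(samples, mass: float = 0.89) -> tuple[float, float]:
    """Shortest interval containing at least ``mass`` of the samples.

    Computed as the minimum-length window of ``ceil(mass * n)`` consecutive
    order statistics.  For a multimodal posterior this still returns a single
    interval (the shortest one), which may bridge modes.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    arr = np.sort(np.asarray(samples, dtype=float))
    n = arr.size
    if n < 2:
        if n == 1:
            return float(arr[0]), float(arr[0])
        raise ValueError("need at least one sample")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(arr[0]), float(arr[-1])
    widths = arr[k:] - arr[: n - k]
    i = int(np.argmin(widths))
    return float(arr[i]), float(arr[i + k])


def prob_direction(samples) -> float:
    """Probability of direction: max share of strictly positive / negative draws.

    Exact zeros are counted toward neither side and the shares are
    renormalised over the nonzero draws (zeros have measure zero for the
    continuous posteriors this is applied to).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one sample")
    pos = np.count_nonzero(arr > 0)
    neg = np.count_nonzero(arr < 0)
    total = pos + neg
    if total == 0:
        return 0.5
    return max(pos, neg) / total


def summarize_effect(samples, mass: float = 0.89) -> EffectSummary:
    """Assemble the standard effect-size indices from posterior draws."""
    arr = np.asarray(samples, dtype=float)
    if arr.size < 50:
        raise ValueError("need at least 50 draws for a stable summary")
    lo, hi = hdi(arr, mass)
    return EffectSummary(
        median=float(np.median(arr)),
        mad=float(median_abs_deviation(arr, scale="normal")),
        hdi_low=lo,
        hdi_high=hi,
        pd=prob_direction(arr),
        mass=mass,
    )


def contrast_draws(draws: PosteriorDraws, weights: dict[str, float]) -> np.ndarray:
    """Per-draw weighted sum of named parameters (for condition contrasts).

    Under +/-1 sum coding the congruent-vs-incongruent contrast of a factor
    is twice its coefficient, i.e. ``weights={"b_congruent": 2.0}``.
    """
    out = np.zeros(draws.n_draws)
    for name, w in weights.items():
        out = out + w * draws.get(name)
    return out


def _max_lag1_autocorr(draws: PosteriorDraws) -> float:
    worst = 0.0
    for i in range(len(draws.names)):
        for chain in draws.draws[:, :, i]:
            c = chain - chain.mean()
            denom = float(np.dot(c, c))
            if denom <= 0.0:
                worst = max(worst, 1.0)  # constant chain: fully autocorrelated
                continue
            worst = max(worst, abs(float(np.dot(c[1:], c[:-1])) / denom))
    return worst


def diagnostics(draws: PosteriorDraws) -> DiagnosticsReport:
    """Split-R-hat, bulk ESS, divergence count and worst lag-1 autocorrelation."""
    if draws.n_chains < 2:
        raise ValueError("R-hat requires at least 2 chains")
    idata = draws.to_arviz()
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {n: float(rhat_ds[n].values) for n in draws.names}
    ess = {n: float(ess_ds[n].values) for n in draws.names}
    return DiagnosticsReport(
        rhat=rhat,
        ess=ess,
        n_divergences=draws.n_divergences,
        max_lag1_autocorr=_max_lag1_autocorr(draws),
    )
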