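"""Beta-Binomial posterior-predictive test for temporal structure in binary choice series.

A session of two-alternative choices is summarised by the switch statistic
``T``: the number of adjacent trial pairs on which the chosen category
changed.  Under independence, choices are exchangeable Bernoulli draws and
``T`` has a known null distribution once the choice probability ``theta`` is
integrated over its Beta posterior.  An observed ``T`` far below the null
indicates temporal clustering (runs of the same category); far above, temporal
dispersion (alternation).

The null is obtained by Monte Carlo: draw ``theta* ~ Beta(a, b)`` from the
posterior, simulate an independent series of the session's length, count its
switches, repeat.  For short series an exact enumeration over all ``2^n``
sequences is provided as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln

__all__ = [
    "SwitchTestResult",
    "count_switches",
    "posterior_theta",
    "simulate_null_T",
    "exact_null_T",
    "discrete_hdi",
    "switch_test",
    "pooled_switch_test",
]


def _as_binary(series) -> np.ndarray:
    arr = np.asarray(series)
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))]
        raise ValueError(f"series must be binary (0/1); found {bad[:5]!r}")
    return arr.astype(np.int64)


def count_switches(series) -> int:
    """Number of adjacent unequal pairs in a binary series."""
    arr = _as_binary(series)
    if arr.size < 1:
        raise ValueError("series must have length >= 1")
    return int(np.sum(arr[1:] != arr[:-1]))


def posterior_theta(series, prior_a: float = 10.0, prior_b: float = 10.0) -> tuple[float, float]:
    """Conjugate Beta update of the choice probability from one session.

    Returns ``(prior_a + #ones, prior_b + #zeros)``.
    """
    arr = _as_binary(series)
    ones = int(arr.sum())
    return (prior_a + ones, prior_b + (arr.size - ones))


def simulate_null_T(a: float, b: float, n: int, n_sims: int = 10_000, seed: int | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of the switch count under independence.

    Each replicate draws ``theta* ~ Beta(a, b)`` and then ``n`` independent
    Bernoulli(theta*) trials; returns the ``n_sims`` switch counts.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be positive")
    if n < 2:
        raise ValueError("need a series of length >= 2 to count switches")
    rng = np.random.default_rng(seed)
    theta = rng.beta(a, b, size=n_sims)
    series = rng.random((n_sims, n)) < theta[:, None]
    return np.sum(series[:, 1:] != series[:, :-1], axis=1)


def exact_null_T(a: float, b: float, n: int) -> np.ndarray:
    """Exact pmf of the switch count by enumeration of all 2^n sequences.

    The marginal probability of a particular sequence with ``k`` ones under
    ``theta ~ Beta(a, b)`` is ``B(a + k, b + n - k) / B(a, b)``; the pmf over
    ``T`` sums these weights.  Guarded to ``n <= 12``.  Returns an array of
    length ``n`` with ``pmf[t] = P(T = t)``.
    """
    if n > 12:
        raise ValueError("exact enumeration is limited to n <= 12")
    if n < 2:
        raise ValueError("need n >= 2")
    codes = np.arange(2**n, dtype=np.uint32)
    bits = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    k = bits.sum(axis=1)
    t = np.sum(bits[:, 1:] != bits[:, :-1], axis=1)
    logw = betaln(a + k, b + n - k) - betaln(a, b)
    pmf = np.zeros(n)
    np.add.at(pmf, t, np.exp(logw))
    return pmf


def null_T_mean(a: float, b: float, n: int) -> float:
    """Closed-form mean of the null switch count: (n-1) * 2ab / ((a+b)(a+b+1))."""
    return (n - 1) * 2.0 * a * b / ((a + b) * (a + b + 1.0))


def discrete_hdi(values: np.ndarray, mass: float = 0.95) -> tuple[int, int]:
    """Highest-density region of an empirical integer distribution.

    Bins are accumulated in order of decreasing probability until at least
    ``mass`` is covered; ties are broken toward the shorter resulting span.
    Returns the (min, max) of the accumulated set.
    """
    vals, counts = np.unique(np.asarray(values, dtype=np.int64), return_counts=True)
    probs = counts / counts.sum()
    # sort by probability desc, then by distance to the mode to shorten ties
    mode = vals[np.argmax(probs)]
    order = np.lexsort((np.abs(vals - mode), -probs))
    acc = 0.0
    chosen: list[int] = []
    for idx in order:
        chosen.append(vals[idx])
        acc += probs[idx]
        if acc >= mass:
            break
    return int(min(chosen)), int(max(chosen))


@dataclass
class SwitchTestResult:
    """Observed switch count for one session against its independence null."""

    n: int
    T_obs: int
    posterior_a: float
    posterior_b: float
    n_sims: int
    hdi95: tuple[int, int]
    p_ge: float
    p_le: float
    verdict: str
    T_null: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        assert 0 <= self.T_obs <= self.n - 1
        assert self.p_ge + self.p_le >= 1.0 - 1e-12


def switch_test(
    series,
    prior_a: float = 10.0,
    prior_b: float = 10.0,
    n_sims: int = 10_000,
    seed: int | None = None,
    hdi_mass: float = 0.95,
) -> SwitchTestResult:
    """Compare a session's observed switch count with its independence null.

    The verdict is ``"clustering"`` when the observed count falls below the
    null's highest-density interval, ``"dispersion"`` when above, and
    ``"consistent"`` otherwise.  ``p_ge``/``p_le`` are the shares of null
    draws at least / at most the observed count (both include equality).
    """
    arr = _as_binary(series)
    if arr.size < 2:
        raise ValueError("need a series of length >= 2")
    t_obs = count_switches(arr)
    a, b = posterior_theta(arr, prior_a, prior_b)
    t_null = simulate_null_T(a, b, arr.size, n_sims=n_sims, seed=seed)
    lo, hi = discrete_hdi(t_null, hdi_mass)
    p_ge = float(np.mean(t_null >= t_obs))
    p_le = float(np.mean(t_null <= t_obs))
    if t_obs < lo:
        verdict = "clustering"
    elif t_obs > hi:
        verdict = "dispersion"
    else:
        verdict = "consistent"
    return SwitchTestResult(
        n=int(arr.size),
        T_obs=t_obs,
        posterior_a=float(a),
        posterior_b=float(b),
        n_sims=int(n_sims),
        hdi95=(lo, hi),
        p_ge=p_ge,
        p_le=p_le,
        verdict=verdict,
        T_null=t_null,
    )


def pooled_switch_test(
    sessions: list,
    prior_a: float = 10.0,
    prior_b: float = 10.0,
    n_sims: int = 10_000,
    seed: int | None = None,
    hdi_mass: float = 0.95,
) -> SwitchTestResult:
    """Subject-level variant pooling a subject's sessions.

    The statistic is the sum of within-session switch counts (session
    boundaries contribute no switches), the posterior for theta pools all
    sessions' choices, and each null replicate shares one theta* across the
    session lengths.  Off by default in the pipeline, which analyses
    sessions independently.
    """
    arrays = [_as_binary(s) for s in sessions]
    if not arrays or any(a.size < 2 for a in arrays):
        raise ValueError("need at least one session, each of length >= 2")
    t_obs = sum(count_switches(a) for a in arrays)
    pooled = np.concatenate(arrays)
    a, b = posterior_theta(pooled, prior_a, prior_b)

    rng = np.random.default_rng(seed)
    theta = rng.beta(a, b, size=n_sims)
    t_null = np.zeros(n_sims, dtype=np.int64)
    for arr in arrays:
        sims = rng.random((n_sims, arr.size)) < theta[:, None]
        t_null += np.sum(sims[:, 1:] != sims[:, :-1], axis=1)

    lo, hi = discrete_hdi(t_null, hdi_mass)
    verdict = "clustering" if t_obs < lo else ("dispersion" if t_obs > hi else "consistent")
    return SwitchTestResult(
        n=int(pooled.size),
        T_obs=int(t_obs),
        posterior_a=float(a),
        posterior_b=float(b),
        n_sims=int(n_sims),
        hdi95=(lo, hi),
        p_ge=float(np.mean(t_null >= t_obs)),
        p_le=float(np.mean(t_null <= t_obs)),
        verdict=verdict,
        T_null=t_null,
    )
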