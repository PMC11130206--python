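"""Per-subject robust regression of dot-probe reaction times.

Each subject is modelled separately: with ~140 retained trials per subject
and only three animals, a within-subject model per individual is more
informative than a pooled fit.  The response is the subject's mean-centred
RT in ms; congruence (probe behind the large-flange / symmetrised face vs.
the other version) and probe side enter as +/-1 sum-coded fixed effects, and
the intercept varies by session.  Residuals are Student-t, which keeps the
occasional slow-but-not-excluded trial from dominating the fit.

Priors: Normal(0, 5) on the intercept, Normal(0, 10) on the coefficients,
Gamma(shape 2, rate 0.1) on the residual degrees of freedom (prior mean 20,
so the fit can range from heavy-tailed to effectively Gaussian), and
half-Student-t(3) on both scale parameters with scale
``max(2.5, sd(response))`` — on a millisecond response a fixed 2.5 would be
absurdly informative, so the scale follows the response spread, mirroring
standard practice for weakly-informative scale priors.

An optional moderator adds the pair's absolute width difference
(mean-centred) and its interaction with congruence, probing whether any
congruence effect is confined to the most distinguishable pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .inference import (
    DiagnosticsReport,
    EffectSummary,
    PosteriorDraws,
    SamplerSettings,
    diagnostics,
    sample_posterior,
    summarize_effect,
)

__all__ = ["StudentTRegression", "SubjectFitResult", "center_rt", "fit_subject", "results_to_frame"]

logger = logging.getLogger(__name__)

_NU_SHAPE = 2.0
_NU_RATE = 0.1
_SCALE_PRIOR_DF = 3.0


def center_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rt_centred`` column: RT minus the subject's mean RT.

    Centring is over the rows given (the subject's final filtered dataset);
    idempotent up to floating-point on already-centred data.
    """
    out = trials.copy()
    out["rt_centred"] = out["rt_ms"] - out["rt_ms"].mean() if len(out) else np.nan
    return out


def _half_t_logpdf_and_grad(s: np.ndarray, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """log density of half-Student-t(3, scale) at s plus d/dlog(s), Jacobian included."""
    q = s**2 / (_SCALE_PRIOR_DF * scale**2)
    logp = -((_SCALE_PRIOR_DF + 1.0) / 2.0) * np.log1p(q) + np.log(s)
    grad = -(_SCALE_PRIOR_DF + 1.0) * q / (1.0 + q) + 1.0
    return logp, grad


class StudentTRegression:
    """Log posterior (with analytic gradient) for one subject's RT model.

    Session intercepts use the non-centred parameterisation
    ``u_s = sigma_session * z_s`` with standard-normal ``z``.  Positive
    parameters are sampled on the log scale.  ``family="normal"`` swaps the
    Student-t likelihood for a Gaussian with the same mean structure (used
    to quantify the robustness the t family buys).
    """

    def __init__(
        self,
        y: np.ndarray,
        congruence: np.ndarray,
        side: np.ndarray,
        session_idx: np.ndarray | None = None,
        n_sessions: int = 0,
        width: np.ndarray | None = None,
        family: str = "student",
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        cols = [np.ones(n), np.asarray(congruence, float), np.asarray(side, float)]
        self.coef_names = ["intercept", "b_congruent", "b_left"]
        prior_sd = [5.0, 10.0, 10.0]
        if width is not None:
            w = np.asarray(width, dtype=float)
            w = w - w.mean() if n else w
            cols += [w, w * np.asarray(congruence, float)]
            self.coef_names += ["b_width", "b_congruent_x_width"]
            prior_sd += [10.0, 10.0]
        self.X = np.column_stack(cols) if n else np.zeros((0, len(cols)))
        self.prior_sd = np.asarray(prior_sd)
        self.k = len(self.coef_names)

        self.has_sessions = n_sessions >= 2
        self.n_sessions = n_sessions if self.has_sessions else 0
        self.session_idx = np.asarray(session_idx, dtype=np.intp) if self.has_sessions else None
        if family not in ("student", "normal"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family

        sd_y = float(np.std(self.y)) if n >= 2 else 0.0
        self.scale_prior = max(2.5, sd_y)

        self.names = list(self.coef_names)
        if self.has_sessions:
            self.names.append("sigma_session")
        self.names.append("sigma")
        if family == "student":
            self.names.append("nu")
        self.dim = self.k + (self.n_sessions + 1 if self.has_sessions else 0) + 1 + (
            1 if family == "student" else 0
        )

    # -- unconstrained layout: [beta, z (S), log_sigma_u, log_sigma, log_nu] --

    def _unpack(self, theta: np.ndarray):
        beta = theta[: self.k]
        pos = self.k
        z = sigma_u = None
        if self.has_sessions:
            z = theta[pos : pos + self.n_sessions]
            pos += self.n_sessions
            sigma_u = np.exp(theta[pos])
            pos += 1
        sigma = np.exp(theta[pos])
        pos += 1
        nu = np.exp(theta[pos]) if self.family == "student" else None
        return beta, z, sigma_u, sigma, nu

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # log-scale parameters wandering past +/-30 only happen on unstable
        # trajectories; reject before exp() overflows
        if np.any(np.abs(theta[self.k + (self.n_sessions if self.has_sessions else 0):]) > 30.0):
            return -np.inf, np.zeros_like(theta)
        beta, z, sigma_u, sigma, nu = self._unpack(theta)
        grad = np.zeros_like(theta)
        n = self.y.size

        mu = self.X @ beta
        if self.has_sessions:
            mu = mu + sigma_u * z[self.session_idx]
        r = self.y - mu

        if self.family == "student":
            A = nu * sigma**2 + r**2
            loglik = n * (
                gammaln((nu + 1.0) / 2.0)
                - gammaln(nu / 2.0)
                - 0.5 * np.log(nu * np.pi)
                - np.log(sigma)
            ) - ((nu + 1.0) / 2.0) * np.sum(np.log1p(r**2 / (nu * sigma**2)))
            g_mu = (nu + 1.0) * r / A
            g_logsigma = np.sum(-1.0 + (nu + 1.0) * r**2 / A)
            df_dnu = (
                0.5 * n * (digamma((nu + 1.0) / 2.0) - digamma(nu / 2.0) - 1.0 / nu)
                - 0.5 * np.sum(np.log1p(r**2 / (nu * sigma**2)))
                + np.sum((nu + 1.0) * r**2 / (2.0 * nu * A))
            )
            g_lognu = nu * df_dnu + (_NU_SHAPE - _NU_RATE * nu)
            logprior_nu = _NU_SHAPE * np.log(nu) - _NU_RATE * nu  # Gamma(2, 0.1) + Jacobian
        else:
            loglik = -n * np.log(sigma) - 0.5 * np.sum(r**2) / sigma**2
            g_mu = r / sigma**2
            g_logsigma = -n + np.sum(r**2) / sigma**2
            g_lognu = logprior_nu = 0.0

        # fixed effects
        grad[: self.k] = self.X.T @ g_mu - beta / self.prior_sd**2
        logp = loglik - 0.5 * np.sum((beta / self.prior_sd) ** 2)

        pos = self.k
        if self.has_sessions:
            gz = np.zeros(self.n_sessions)
            np.add.at(gz, self.session_idx, g_mu)
            grad[pos : pos + self.n_sessions] = sigma_u * gz - z
            logp += -0.5 * np.sum(z**2)
            pos += self.n_sessions
            lp_u, g_u = _half_t_logpdf_and_grad(np.array(sigma_u), self.scale_prior)
            grad[pos] = sigma_u * float(np.sum(gz * z)) + float(g_u)
            logp += float(lp_u)
            pos += 1

        lp_s, g_s = _half_t_logpdf_and_grad(np.array(sigma), self.scale_prior)
        grad[pos] = g_logsigma + float(g_s)
        logp += float(lp_s)
        pos += 1

        if self.family == "student":
            grad[pos] = g_lognu
            logp += logprior_nu

        return float(logp), grad

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        theta = np.zeros(self.dim)
        theta[: self.k] = 0.5 * rng.standard_normal(self.k)
        sd_y = float(np.std(self.y)) if self.y.size >= 2 else 1.0
        sd_y = max(sd_y, 1.0)
        pos = self.k
        if self.has_sessions:
            theta[pos : pos + self.n_sessions] = 0.1 * rng.standard_normal(self.n_sessions)
            pos += self.n_sessions
            theta[pos] = np.log(0.3 * sd_y) + 0.2 * rng.standard_normal()
            pos += 1
        theta[pos] = np.log(0.8 * sd_y) + 0.2 * rng.standard_normal()
        pos += 1
        if self.family == "student":
            theta[pos] = np.log(10.0) + 0.3 * rng.standard_normal()
        return theta

    def transform(self, theta: np.ndarray) -> np.ndarray:
        beta, z, sigma_u, sigma, nu = self._unpack(theta)
        out = list(beta)
        if self.has_sessions:
            out.append(sigma_u)
        out.append(sigma)
        if self.family == "student":
            out.append(nu)
        return np.asarray(out)


@dataclass
class SubjectFitResult:
    """Posterior summaries of one subject's dot-probe fit."""

    subject_id: str
    congruence: EffectSummary
    probe_side: EffectSummary
    diagnostics: DiagnosticsReport
    draws: PosteriorDraws
    interaction: EffectSummary | None = None
    converged: bool = True


def fit_subject(
    trials: pd.DataFrame,
    settings: SamplerSettings,
    moderator: bool = False,
    family: str = "student",
) -> SubjectFitResult:
    """Fit the robust RT model to one subject's filtered trials.

    ``trials`` must come from a single subject and task; RT is centred here
    if an ``rt_centred`` column is not already present.  With fewer than two
    sessions the session term is dropped (logged as a downgrade).  The
    result is flagged non-converged when any split R-hat exceeds 1.05 or the
    sampler reported divergences.
    """
    subjects = trials["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"fit_subject expects exactly one subject, got {list(subjects)}")
    if "task" in trials.columns and trials["task"].nunique() > 1:
        raise ValueError("trials mix tasks; fit one task at a time")
    if "rt_centred" not in trials.columns:
        trials = center_rt(trials)

    sessions, session_idx = np.unique(trials["session_id"].to_numpy(), return_inverse=True)
    if len(sessions) < 2:
        logger.warning(
            "subject %s has %d session(s); session intercepts dropped", subjects[0], len(sessions)
        )
        session_idx, n_sessions = None, 0
    else:
        n_sessions = len(sessions)

    width = None
    if moderator:
        if "width_diff" not in trials.columns or trials["width_diff"].isna().all():
            raise ValueError("moderator fit requires a width_diff column")
        width = trials["width_diff"].to_numpy(dtype=float)

    model = StudentTRegression(
        y=trials["rt_centred"].to_numpy(dtype=float),
        congruence=np.where(trials["congruence"] == "congruent", 1.0, -1.0),
        side=np.where(trials["probe_side"] == "left", 1.0, -1.0),
        session_idx=session_idx,
        n_sessions=n_sessions,
        width=width,
        family=family,
    )
    draws = sample_posterior(model, settings)
    diag = diagnostics(draws)
    return SubjectFitResult(
        subject_id=str(subjects[0]),
        congruence=summarize_effect(draws.get("b_congruent")),
        probe_side=summarize_effect(draws.get("b_left")),
        diagnostics=diag,
        draws=draws,
        interaction=(
            summarize_effect(draws.get("b_congruent_x_width")) if moderator else None
        ),
        converged=diag.max_rhat < 1.05,
    )


def results_to_frame(results: list[SubjectFitResult]) -> pd.DataFrame:
    """Flatten per-subject fits to a tidy CSV-ready table."""
    rows = []
    for res in results:
        terms = {"congruence": res.congruence, "probe_side": res.probe_side}
        if res.interaction is not None:
            terms["congruence_x_width"] = res.interaction
        for term, s in terms.items():
            rows.append(
                {
                    "subject_id": res.subject_id,
                    "term": term,
                    "median": s.median,
                    "mad": s.mad,
                    "hdi_low": s.hdi_low,
                    "hdi_high": s.hdi_high,
                    "pd": s.pd,
                    "rhat_max": res.diagnostics.max_rhat,
                }
            )
    return pd.DataFrame(rows)
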