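"""Bayesian logistic mixed model for the two-alternative preference task.

All subjects' free-choice trials enter one model of the probability of
choosing the flanged-male stimulus.  Fixed effects: the colour coding of the
flanged category within the session (green vs. red, +/-1 sum-coded), the
between-subject block order (red-coded block first vs. green first, +/-1),
and optionally the vertical position of the flanged dot on the screen
(continuous, in screen fractions, positive = lower).  Random effects:
intercept by subject, intercept by session within subject, and a by-subject
colour slope correlated with the subject intercept (the correlation gets a
uniform prior on (-1, 1)).

Priors are Normal(0, 0.5) on the logit scale for the intercept and fixed
coefficients — odds ratios between roughly 1/3 and 3 a priori — and
half-Student-t(3, 2.5) on the random-effect standard deviations.  All
odds-ratio summaries exponentiate the draws first and summarise after.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dotprobe import _half_t_logpdf_and_grad
from .inference import (
    DiagnosticsReport,
    EffectSummary,
    PosteriorDraws,
    SamplerSettings,
    diagnostics,
    sample_posterior,
    summarize_effect,
)

__all__ = ["BernoulliMixedModel", "PreferenceFitResult", "fit_preference", "per_subject_probability"]

logger = logging.getLogger(__name__)

_FIXED_PRIOR_SD = 0.5
_SD_PRIOR_SCALE = 2.5


class BernoulliMixedModel:
    """Log posterior with analytic gradient for the preference model.

    Random effects are non-centred: subject intercept ``a_j = s1 * z1_j``
    and colour slope ``c_j = s2 * (rho * z1_j + sqrt(1 - rho^2) * z2_j)``
    share standard-normal latents through the Cholesky factor of their
    2x2 correlation; session effects are ``s_k = s3 * w_k``.  ``rho`` is
    sampled as ``tanh`` of an unconstrained scalar.
    """

    def __init__(
        self,
        y: np.ndarray,
        colour: np.ndarray,
        order: np.ndarray,
        subject_idx: np.ndarray,
        session_idx: np.ndarray,
        n_subjects: int,
        n_sessions: int,
        subject_labels: list[str],
        height: np.ndarray | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.g = np.asarray(colour, dtype=float)
        cols = [np.ones(n), self.g, np.asarray(order, dtype=float)]
        self.coef_names = ["intercept", "b_green", "b_order"]
        if height is not None:
            cols.append(np.asarray(height, dtype=float))
            self.coef_names.append("b_height")
        self.X = np.column_stack(cols)
        self.k = len(self.coef_names)
        self.subject_idx = np.asarray(subject_idx, dtype=np.intp)
        self.session_idx = np.asarray(session_idx, dtype=np.intp)
        self.n_subjects = n_subjects
        self.n_sessions = n_sessions
        self.subject_labels = list(subject_labels)

        self.names = list(self.coef_names) + [
            "sigma_subject",
            "sigma_session",
            "sigma_slope",
            "rho",
        ] + [f"a[{s}]" for s in self.subject_labels]
        # layout: beta | z1 (J) | z2 (J) | w (K) | log s1, log s3, log s2, zeta
        self.dim = self.k + 2 * n_subjects + n_sessions + 4

    def _unpack(self, theta: np.ndarray):
        J, K = self.n_subjects, self.n_sessions
        pos = self.k
        beta = theta[: self.k]
        z1 = theta[pos : pos + J]; pos += J
        z2 = theta[pos : pos + J]; pos += J
        w = theta[pos : pos + K]; pos += K
        s1, s3, s2 = np.exp(theta[pos : pos + 3])
        zeta = theta[pos + 3]
        rho = np.tanh(zeta)
        return beta, z1, z2, w, s1, s3, s2, rho

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        # reject unstable trajectories before exp/tanh saturate: log sds
        # beyond +/-30 or |atanh(rho)| beyond 6 (|rho| > 0.99999)
        tail = theta[self.dim - 4 :]
        if np.any(np.abs(tail[:3]) > 30.0) or abs(tail[3]) > 6.0:
            return -np.inf, np.zeros_like(theta)
        beta, z1, z2, w, s1, s3, s2, rho = self._unpack(theta)
        J, K = self.n_subjects, self.n_sessions
        root = np.sqrt(1.0 - rho**2)

        a = s1 * z1
        c = s2 * (rho * z1 + root * z2)
        eta = (
            self.X @ beta
            + a[self.subject_idx]
            + s3 * w[self.session_idx]
            + c[self.subject_idx] * self.g
        )
        p = expit(eta)
        # log-lik: y*eta - softplus(eta), written stably
        loglik = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        resid = self.y - p

        grad = np.zeros_like(theta)
        grad[: self.k] = self.X.T @ resid - beta / _FIXED_PRIOR_SD**2
        logp = loglik - 0.5 * float(np.sum((beta / _FIXED_PRIOR_SD) ** 2))

        G1 = np.zeros(J)
        np.add.at(G1, self.subject_idx, resid)
        G2 = np.zeros(J)
        np.add.at(G2, self.subject_idx, resid * self.g)
        Gs = np.zeros(K)
        np.add.at(Gs, self.session_idx, resid)

        pos = self.k
        grad[pos : pos + J] = s1 * G1 + s2 * rho * G2 - z1
        pos += J
        grad[pos : pos + J] = s2 * root * G2 - z2
        pos += J
        grad[pos : pos + K] = s3 * Gs - w
        pos += K
        logp += -0.5 * float(np.sum(z1**2) + np.sum(z2**2) + np.sum(w**2))

        for offset, (s, dlik) in enumerate(
            [
                (s1, float(np.sum(z1 * G1)) * s1),
                (s3, float(np.sum(w * Gs)) * s3),
                (s2, float(np.sum((rho * z1 + root * z2) * G2)) * s2),
            ]
        ):
            lp, gp = _half_t_logpdf_and_grad(np.array(s), _SD_PRIOR_SCALE)
            grad[pos + offset] = dlik + float(gp)
            logp += float(lp)

        # correlation: uniform prior on rho, tanh transform Jacobian log(1 - rho^2)
        dc_drho = s2 * (z1 - (rho / root) * z2) if root > 1e-12 else np.zeros(J)
        grad_rho = float(np.sum(dc_drho * G2))
        grad[pos + 3] = (1.0 - rho**2) * grad_rho - 2.0 * rho
        logp += float(np.log1p(-(rho**2)))

        return logp, grad

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        theta = 0.1 * rng.standard_normal(self.dim)
        theta[self.dim - 4 : self.dim - 1] = np.log(0.3) + 0.2 * rng.standard_normal(3)
        theta[self.dim - 1] = 0.1 * rng.standard_normal()
        return theta

    def transform(self, theta: np.ndarray) -> np.ndarray:
        beta, z1, z2, w, s1, s3, s2, rho = self._unpack(theta)
        return np.concatenate([beta, [s1, s3, s2, rho], s1 * z1])


@dataclass
class PreferenceFitResult:
    """Odds-ratio summaries of the preference model."""

    intercept_or: EffectSummary
    colour_or: EffectSummary
    order_or: EffectSummary
    diagnostics: DiagnosticsReport
    draws: PosteriorDraws
    subject_labels: list[str]
    height_or: EffectSummary | None = None
    per_subject_or: dict[str, EffectSummary] = field(default_factory=dict)
    converged: bool = True

    def subject_intercept_draws(self, subject: str) -> np.ndarray:
        """Per-draw subject-level intercept: fixed intercept + deviation (logit)."""
        if subject not in self.subject_labels:
            raise KeyError(f"unknown subject {subject!r}")
        return self.draws.get("intercept") + self.draws.get(f"a[{subject}]")


def fit_preference(
    trials: pd.DataFrame,
    include_height: bool = False,
    settings: SamplerSettings | None = None,
) -> PreferenceFitResult:
    """Fit the pooled choice model to all subjects' choice-phase trials.

    Forced-phase rows are dropped (they are not choices).  Subjects whose
    choices are all identical are logged but kept — the priors regularise
    the fit.  Odds-ratio summaries are built from exponentiated draws.
    """
    settings = settings or SamplerSettings()
    data = trials.loc[trials["phase"] == "choice"] if "phase" in trials.columns else trials
    if data.empty:
        raise ValueError("no choice-phase trials to fit")
    subjects, subject_idx = np.unique(data["subject_id"].to_numpy(), return_inverse=True)
    if len(subjects) < 2:
        raise ValueError("the pooled model needs choice trials from at least 2 subjects")
    for subj in subjects:
        ch = data.loc[data["subject_id"] == subj, "choice"]
        if ch.nunique() == 1:
            logger.warning("subject %s made all-identical choices (%d)", subj, ch.iloc[0])

    sess_key = (data["subject_id"].astype(str) + "//" + data["session_id"].astype(str)).to_numpy()
    _, session_idx = np.unique(sess_key, return_inverse=True)

    model = BernoulliMixedModel(
        y=data["choice"].to_numpy(dtype=float),
        colour=np.where(data["flanged_colour"] == "green", 1.0, -1.0),
        order=np.where(data["order"] == "red_first", 1.0, -1.0),
        subject_idx=subject_idx,
        session_idx=session_idx,
        n_subjects=len(subjects),
        n_sessions=int(session_idx.max()) + 1,
        subject_labels=[str(s) for s in subjects],
        height=data["flanged_dot_height"].to_numpy(dtype=float) if include_height else None,
    )
    draws = sample_posterior(model, settings)
    diag = diagnostics(draws)

    def or_summary(name: str) -> EffectSummary:
        return summarize_effect(np.exp(draws.get(name)))

    alpha = draws.get("intercept")
    per_subject = {
        str(s): summarize_effect(np.exp(alpha + draws.get(f"a[{s}]"))) for s in subjects
    }
    return PreferenceFitResult(
        intercept_or=or_summary("intercept"),
        colour_or=or_summary("b_green"),
        order_or=or_summary("b_order"),
        height_or=or_summary("b_height") if include_height else None,
        per_subject_or=per_subject,
        diagnostics=diag,
        draws=draws,
        subject_labels=[str(s) for s in subjects],
        converged=diag.max_rhat < 1.05,
    )


def per_subject_probability(result: PreferenceFitResult) -> dict[str, EffectSummary]:
    """Posterior probability of choosing the flanged stimulus, per subject.

    The logistic transform is applied draw-wise to each subject's level
    (fixed intercept + subject deviation) before summarising.
    """
    return {
        s: summarize_effect(expit(result.subject_intercept_draws(s)))
        for s in result.subject_labels
    }


def preference_to_frame(result: PreferenceFitResult) -> pd.DataFrame:
    """Tidy odds-ratio table (one row per model term)."""
    terms = {
        "intercept": result.intercept_or,
        "colour_green": result.colour_or,
        "order_red_first": result.order_or,
    }
    if result.height_or is not None:
        terms["height"] = result.height_or
    rows = [
        {
            "term": term,
            "or_median": s.median,
            "or_mad": s.mad,
            "hdi_low": s.hdi_low,
            "hdi_high": s.hdi_high,
            "pd": s.pd,
        }
        for term, s in terms.items()
    ]
    return pd.DataFrame(rows)


def per_subject_to_frame(result: PreferenceFitResult) -> pd.DataFrame:
    rows = [
        {
            "subject_id": subj,
            "or_median": s.median,
            "or_mad": s.mad,
            "hdi_low": s.hdi_low,
            "hdi_high": s.hdi_high,
            "pd": s.pd,
        }
        for subj, s in result.per_subject_or.items()
    ]
    return pd.DataFrame(rows)
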