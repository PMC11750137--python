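"""Recursively formulated logistic regression (RFLR) of choice.

The model predicts the next choice from an exponentially decaying evidence
trace. With signed choices c in {+1 left, -1 right} and rewards r in {0,1}:

    phi_{t+1} = c_t * r_t + exp(-1/tau) * phi_t        (evidence update)
    psi_{t+1} = alpha * c_t + beta * phi_{t+1}         (choice log-odds)
    P(c_{t+1} = left) = sigmoid(psi_{t+1})

alpha is a perseveration (choice-history) weight, beta weighs the evidence
trace, and tau (in trials) sets how quickly past action-outcome pairs decay.
Parameters are estimated by maximum likelihood via stochastic gradient
descent with analytic gradients (tau through log-parameterization so it
stays positive); an L-BFGS path over the same gradient is available as a
cross-check/refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .task import LEFT, RFLRAgent, SessionTable, TaskConfig, simulate_cohort

_CLAMP = 1e-12


class ParameterError(ValueError):
    pass


class DivergenceError(RuntimeError):
    """SGD produced a non-finite objective (learning rate too large)."""


@dataclass(frozen=True)
class RFLRParams:
    alpha: float
    beta: float
    tau: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.alpha, self.beta, self.tau]).all():
            raise ParameterError("parameters must be finite")
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")

    @property
    def decay(self) -> float:
        """Per-trial evidence retention exp(-1/tau)."""
        return float(np.exp(-1.0 / self.tau))


@dataclass
class RFLRState:
    phi: float = 0.0
    psi: float = 0.0


def rflr_step(state: RFLRState, choice: int, reward: int,
              params: RFLRParams) -> RFLRState:
    """One update of the recursion given a signed choice and reward."""
    phi = choice * reward + params.decay * state.phi
    psi = params.alpha * choice + params.beta * phi
    return RFLRState(phi=phi, psi=psi)


def _forward(c: np.ndarray, r: np.ndarray, params: RFLRParams):
    """Vectorized forward pass.

    Returns (psi, phi_pred, c_prev) for predicted trials t = 1..N-1:
    psi[t-1] is the log-odds for trial t, phi_pred the evidence entering it.
    The linear recursion phi is evaluated with an IIR filter.
    """
    lam = params.decay
    cr = (c * r).astype(float)
    phi_all = signal.lfilter([1.0], [1.0, -lam], cr)  # phi after trial t
    phi_pred = phi_all[:-1]
    c_prev = c[:-1].astype(float)
    psi = params.alpha * c_prev + params.beta * phi_pred
    return psi, phi_pred, c_prev, phi_all


def session_psi(session: SessionTable, params: RFLRParams) -> np.ndarray:
    """Teacher-forced log-odds per trial; NaN for trial 0 (no prediction)."""
    c, r = session.choices_signed, session.rewards
    psi = np.full(len(session), np.nan)
    if len(session) >= 2:
        psi[1:] = _forward(c, r, params)[0]
    return psi


def _nll_and_grad(c: np.ndarray, r: np.ndarray, alpha: float, beta: float,
                  theta: float):
    """Mean NLL of trials 1..N-1 and gradient wrt (alpha, beta, log tau)."""
    tau = np.exp(theta)
    params = RFLRParams(alpha, beta, tau)
    lam = params.decay
    psi, phi_pred, c_prev, phi_all = _forward(c, r, params)
    y = (c[1:] == 1).astype(float)
    p = 1.0 / (1.0 + np.exp(-psi))
    p = np.clip(p, _CLAMP, 1.0 - _CLAMP)
    nll = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    # d phi / d lambda by a second pass of the same filter
    x = np.concatenate(([0.0], phi_all[:-1]))
    dphi_dlam = signal.lfilter([1.0], [1.0, -lam], x)[:-1]
    g_psi = (p - y) / y.size
    g_alpha = float(np.dot(g_psi, c_prev))
    g_beta = float(np.dot(g_psi, phi_pred))
    dlam_dtheta = lam / tau
    g_theta = float(np.dot(g_psi, beta * dphi_dlam) * dlam_dtheta)
    return float(nll), np.array([g_alpha, g_beta, g_theta])


def negative_log_likelihood(session: SessionTable,
                            params: RFLRParams) -> float:
    """Mean negative log-likelihood per predicted trial (trial 0 excluded)."""
    if len(session) < 2:
        raise ValueError("need at least 2 trials")
    c, r = session.choices_signed, session.rewards
    return _nll_and_grad(c, r, params.alpha, params.beta,
                         np.log(params.tau))[0]


def mean_nll(sessions: Sequence[SessionTable], params: RFLRParams) -> float:
    """Trial-weighted mean NLL across sessions."""
    tot, n = 0.0, 0
    for s in sessions:
        k = len(s) - 1
        tot += negative_log_likelihood(s, params) * k
        n += k
    return tot / n


@dataclass
class RFLRFit:
    params: RFLRParams
    nll: float
    n_trials: int
    trace: list[float] = field(default_factory=list)
    method: str = "sgd"

    def to_dict(self) -> dict:
        return {"alpha": self.params.alpha, "beta": self.params.beta,
                "tau": self.params.tau, "nll": self.nll,
                "n_trials": self.n_trials}


def fit_rflr(sessions: Sequence[SessionTable],
             init: RFLRParams = RFLRParams(0.0, 0.0, 1.0),
             learning_rate: float = 0.5, epochs: int = 500,
             seed: int = 0, method: str = "sgd") -> RFLRFit:
    """Maximum-likelihood fit of (alpha, beta, tau) across sessions.

    ``method='sgd'`` (default): stochastic gradient descent, one session per
    mini-batch, learning rate ``learning_rate / sqrt(epoch)``, session order
    reshuffled each epoch from ``seed``. ``method='lbfgs'`` minimizes the
    pooled mean NLL with the same analytic gradient. tau is optimized as
    log(tau).
    """
    data = [(s.choices_signed, s.rewards) for s in sessions if len(s) >= 2]
    if not data:
        raise ValueError("no usable sessions")
    n_trials = sum(c.size - 1 for c, _ in data)
    weights = np.array([c.size - 1 for c, _ in data], dtype=float)
    weights /= weights.sum()

    def pooled(x):
        nll = 0.0
        g = np.zeros(3)
        for (c, r), w in zip(data, weights):
            v, gi = _nll_and_grad(c, r, *x)
            nll += w * v
            g += w * gi
        return nll, g

    x = np.array([init.alpha, init.beta, np.log(init.tau)], dtype=float)
    trace: list[float] = []
    if method == "lbfgs":
        res = optimize.minimize(pooled, x, jac=True, method="L-BFGS-B")
        x = res.x
        trace.append(float(res.fun))
    elif method == "sgd":
        rng = np.random.default_rng(seed)
        order = np.arange(len(data))
        for epoch in range(1, epochs + 1):
            lr = learning_rate / np.sqrt(epoch)
            rng.shuffle(order)
            for i in order:
                c, r = data[i]
                try:
                    nll_i, g = _nll_and_grad(c, r, *x)
                except (ParameterError, FloatingPointError) as exc:
                    raise DivergenceError(
                        "parameters diverged; reduce learning_rate") from exc
                if not np.isfinite(nll_i):
                    raise DivergenceError(
                        "NLL became non-finite; reduce learning_rate")
                x = x - lr * g
                if not np.isfinite(x).all() or np.abs(x).max() > 1e6:
                    raise DivergenceError(
                        "parameters diverged; reduce learning_rate")
            trace.append(pooled(x)[0])
        if not np.isfinite(trace[-1]):
            raise DivergenceError("NLL became non-finite; reduce learning_rate")
    else:
        raise ValueError(f"unknown method {method!r}")
    params = RFLRParams(float(x[0]), float(x[1]), float(np.exp(x[2])))
    return RFLRFit(params=params, nll=pooled(x)[0], n_trials=n_trials,
                   trace=trace, method=method)


def predict_session(params: RFLRParams, session: SessionTable) -> pd.DataFrame:
    """Teacher-forced per-trial predictions from the animal's actual history.

    Returns a frame with psi, p_left, predicted choice (argmax) and the
    actual choice; trial 0 has no prediction (NaN).
    """
    psi = session_psi(session, params)
    p_left = 1.0 / (1.0 + np.exp(-psi))
    pred = np.where(np.isnan(psi), None,
                    np.where(psi > 0, "left", "right"))
    return pd.DataFrame({
        "trial": session.trials["trial"].to_numpy(),
        "psi": psi, "p_left": p_left, "predicted_choice": pred,
        "choice": session.trials["choice"].to_numpy(),
    })


def simulate_forward(params: RFLRParams, config: TaskConfig, n_mice: int,
                     sessions_per_mouse: int, seed: int) -> list[SessionTable]:
    """Generate sessions from the fitted model acting as the task agent.

    Used to reproduce model p(switch)/p(high port) transition curves for
    comparison against empirical curves.
    """
    return simulate_cohort(
        lambda: RFLRAgent(params.alpha, params.beta, params.tau),
        config, n_mice, sessions_per_mouse, seed)


@dataclass
class PsychometricCurve:
    """Observed p(left) vs binned model log-odds, with a logistic fit.

    The fit is p = 1 / (1 + exp(-(psi - midpoint)/slope)); smaller slope
    means a steeper curve.
    """

    bin_centers: np.ndarray
    p_left_observed: np.ndarray
    n_per_bin: np.ndarray
    midpoint: float
    slope: float
    sse: float

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


def _logistic(psi, m, s):
    return 1.0 / (1.0 + np.exp(-(psi - m) / s))


def _fit_logistic(x: np.ndarray, y: np.ndarray,
                  p0=(0.0, 1.0)) -> tuple[float, float, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
    sse = float(np.sum((_logistic(x, *popt) - y) ** 2))
    return float(popt[0]), float(popt[1]), sse


def psychometric(sessions: Sequence[SessionTable], params: RFLRParams,
                 n_bins: int = 13) -> PsychometricCurve:
    """Bin teacher-forced log-odds into ``n_bins`` equal-count bins and fit a
    logistic of variable midpoint and slope by least squares.

    Degenerate (duplicate-edge) bins are merged with a warning.
    """
    psis, lefts = [], []
    for s in sessions:
        psi = session_psi(s, params)
        ok = ~np.isnan(psi)
        psis.append(psi[ok])
        lefts.append((s.trials["choice"].to_numpy() == LEFT)[ok])
    psi = np.concatenate(psis)
    left = np.concatenate(lefts).astype(float)
    if np.unique(psi).size < n_bins:
        raise ValueError("need at least n_bins distinct log-odds values")
    cats, bins = pd.qcut(psi, n_bins, retbins=True, labels=False,
                         duplicates="drop")
    if bins.size - 1 < n_bins:
        warnings.warn("degenerate quantile bins merged", RuntimeWarning)
    df = pd.DataFrame({"bin": cats, "psi": psi, "left": left})
    g = df.groupby("bin")
    centers = g["psi"].mean().to_numpy()
    p_obs = g["left"].mean().to_numpy()
    n = g.size().to_numpy()
    m, s_, sse = _fit_logistic(centers, p_obs)
    return PsychometricCurve(bin_centers=centers, p_left_observed=p_obs,
                             n_per_bin=n, midpoint=m, slope=s_, sse=sse)


def compare_psychometrics(curves: Sequence[PsychometricCurve]):
    """Extra sum-of-squares F-test: one shared logistic vs per-curve fits.

    F = [(SSE_shared - SSE_sep)/(df_shared - df_sep)] / [SSE_sep/df_sep],
    p from the F distribution. Separate-fit SSEs are recomputed here from
    each curve's binned points so both models use the same data.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    xs = np.concatenate([c.bin_centers for c in curves])
    ys = np.concatenate([c.p_left_observed for c in curves])
    n_points = xs.size
    k = len(curves)
    n_params = 2  # midpoint, slope
    df_sep = n_points - n_params * k
    df_shared = n_points - n_params
    if df_sep <= 0:
        raise ValueError("insufficient degrees of freedom for separate fits")
    sse_sep = 0.0
    for c in curves:
        sse_sep += _fit_logistic(c.bin_centers, c.p_left_observed)[2]
    _, _, sse_shared = _fit_logistic(xs, ys)
    num = (sse_shared - sse_sep) / (df_shared - df_sep)
    den = sse_sep / df_sep
    f_stat = num / den if den > 0 else np.inf
    f_stat = max(f_stat, 0.0)
    p_value = float(stats.f.sf(f_stat, df_shared - df_sep, df_sep))
    return float(f_stat), p_value, {"sse_shared": sse_shared,
                                    "sse_separate": sse_sep,
                                    "df": (df_shared - df_sep, df_sep)}
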