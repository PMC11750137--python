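"""End-to-end synthetic cohorts (behavior + photometry) with known truth.

The generator couples the task simulator (an RFLR agent playing the
switching task) with a forward model of the photometry chain: a fluorescence
signal built from known per-event kernels, AR(1) frame-level noise and
exponential bleaching drift, multiplied onto a 167 Hz carrier with a small
fractional modulation depth, plus a static control fluorophore on 223 Hz.
Because every ingredient is recorded in the truth record, each downstream
stage (demodulation, peri-event averaging, RFLR fitting, kernel regression)
can be checked by parameter recovery.

The modulation is multiplicative with a small depth (in vivo
ligand-dependent fluorescence changes are a few percent), so demodulated
band power is linear in the signal to first order; the quadratic residual
O(depth^2) bounds noise-free recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior, glm, photometry, rflr
from .photometry import (CONTROL_CARRIER, FS_DEFAULT, HOP, NWINDOW,
                         RawPhotometry, SIGNAL_CARRIER, DemodSignal)
from .task import LEFT, RFLRAgent, SessionTable, TaskConfig, simulate_session

FRAME_S = HOP / FS_DEFAULT  # 54 ms


@dataclass(frozen=True)
class KernelSpec:
    """A difference-of-exponentials event transient.

    amplitude in z-units (sign included), rise/decay time constants in
    seconds. Support is truncated to ``n_lags`` demodulation frames so the
    lagged regression can represent it exactly.
    """

    amplitude: float
    rise: float = 0.1
    decay: float = 0.4

    def sample(self, dt: float, n: int) -> np.ndarray:
        """Kernel sampled at spacing ``dt`` over n points from t=0, peak
        normalized to ``amplitude``."""
        t = np.arange(n) * dt
        shape = np.exp(-t / self.decay) - np.exp(-t / self.rise)
        peak = shape.max()
        return self.amplitude * shape / peak if peak > 0 else shape


#: Default kernel battery: positive ipsi center-entry transient, negative
#: rewarded outcome, positive unrewarded outcome, moderate port transients.
DEFAULT_KERNELS: dict[str, KernelSpec] = {
    "CE_ipsi": KernelSpec(3.0),
    "CE_contra": KernelSpec(-1.5),
    "CX_ipsi": KernelSpec(1.5),
    "CX_contra": KernelSpec(-1.5),
    "SE_ipsi": KernelSpec(1.5),
    "SE_contra": KernelSpec(1.5),
    "SX_ipsi": KernelSpec(1.5),
    "SX_contra": KernelSpec(2.0),
    "Rew": KernelSpec(-2.0),
    "Unrew": KernelSpec(2.5),
}


@dataclass(frozen=True)
class TruthSpec:
    """Everything the generator needs, and everything recovery is judged
    against."""

    agent_params: rflr.RFLRParams = field(
        default_factory=lambda: rflr.RFLRParams(alpha=1.0, beta=2.0, tau=1.4))
    task: TaskConfig = field(default_factory=lambda: TaskConfig(
        p_high=0.9, p_low=0.1, n_trials=500))
    kernels: dict = field(default_factory=lambda: dict(DEFAULT_KERNELS))
    ar_coef: float = 0.8
    ar_sigma: float = 0.5
    drift_amplitude: float = 0.3
    drift_tau_s: float = 600.0
    mod_depth: float = 0.04
    baseline: float = 1.0
    control_baseline: float = 0.6
    carriers: tuple[float, float] = (SIGNAL_CARRIER, CONTROL_CARRIER)
    fs: float = FS_DEFAULT
    #: causal kernel support in frames; 21 = lags 0..+20, exactly
    #: representable by the default T=20 lagged regression
    kernel_frames: int = 21
    #: snap event-locked transients to frame centers (removes sub-frame
    #: jitter; used for noise-free calibration checks)
    snap_events_to_frames: bool = False
    hemisphere: str = LEFT

    def __post_init__(self) -> None:
        if abs(self.carriers[0] - self.carriers[1]) < 8.0:
            raise ValueError("carrier bands overlap (|f1-f2| < 8 Hz)")
        if self.ar_sigma < 0 or self.drift_tau_s <= 0:
            raise ValueError("noise sigma >= 0 and time constants > 0 required")


def _event_times(session: SessionTable, hemisphere: str,
                 outcome_at: str = "FL") -> dict[str, np.ndarray]:
    """Per-predictor event timestamp arrays for a session.

    Outcome transients are anchored at first lick (where the outcome is
    revealed) by default. Anchoring them at side entry instead would make
    SE_ipsi + SE_contra - Rew - Unrew an exact column collinearity at every
    lag, leaving individual kernels unidentifiable.
    """
    tr = session.trials
    direction = np.where(tr["choice"].to_numpy() == hemisphere,
                         "ipsi", "contra")
    rewarded = tr["rewarded"].to_numpy(bool)
    out: dict[str, list[float]] = {k: [] for k in glm.PREDICTORS}
    for i in range(len(tr)):
        for ev in ("CE", "CX", "SE", "SX"):
            out[f"{ev}_{direction[i]}"].append(float(tr[f"t_{ev}"].iloc[i]))
        t_out = float(tr[f"t_{outcome_at}"].iloc[i])
        if np.isnan(t_out):
            t_out = float(tr["t_SE"].iloc[i])
        out["Rew" if rewarded[i] else "Unrew"].append(t_out)
    return {k: np.asarray(v) for k, v in out.items()}


def render_fluorescence(session: SessionTable, spec: TruthSpec,
                        rng: np.random.Generator,
                        noise: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth fluorescence signal at the acquisition rate.

    Returns (signal, t) where signal is in z-like units: the sum of event
    kernels plus, if ``noise``, AR(1) noise generated on the 54 ms frame
    grid and held per frame.
    """
    dur = float(session.trials["t_SX"].iloc[-1]) + 3.0
    n = int(np.ceil(dur * spec.fs))
    t = np.arange(n) / spec.fs
    sig = np.zeros(n)
    k_len = int(spec.kernel_frames * FRAME_S * spec.fs)
    for name, times in _event_times(session, spec.hemisphere).items():
        kspec = spec.kernels.get(name)
        if kspec is None or kspec.amplitude == 0 or times.size == 0:
            continue
        k = kspec.sample(1.0 / spec.fs, k_len)
        for t_ev in times:
            if spec.snap_events_to_frames:
                frame = round((t_ev - (NWINDOW - 1) / 2.0 / spec.fs)
                              / FRAME_S)
                t_ev = (NWINDOW - 1) / 2.0 / spec.fs + frame * FRAME_S
            i0 = int(round(t_ev * spec.fs))
            i1 = min(i0 + k_len, n)
            if i0 < 0:  # event snapped before recording start: clip support
                sig[0:max(i1, 0)] += k[-i0:max(i1, 0) - i0]
            elif i0 < n:
                sig[i0:i1] += k[:i1 - i0]
    if noise and spec.ar_sigma > 0:
        n_frames = n // HOP + 2
        innov = rng.normal(0.0, spec.ar_sigma, n_frames)
        ar = np.empty(n_frames)
        ar[0] = innov[0] / np.sqrt(max(1.0 - spec.ar_coef ** 2, 1e-12))
        for i in range(1, n_frames):
            ar[i] = spec.ar_coef * ar[i - 1] + innov[i]
        sig += np.repeat(ar, HOP)[:n]
    return sig, t


def modulate(signal_z: np.ndarray, t: np.ndarray, spec: TruthSpec,
             rng: Optional[np.random.Generator] = None,
             drift: bool = True) -> np.ndarray:
    """Compose the raw detector trace from the fluorescence signal.

    Signal channel: amplitude (baseline * bleach * (1 + depth*signal)) on
    the 167 Hz carrier; control channel: constant envelope on 223 Hz. Both
    carriers are summed as on a single detector.
    """
    f_sig, f_ctl = spec.carriers
    bleach = 1.0 + (spec.drift_amplitude * np.exp(-t / spec.drift_tau_s)
                    if drift else 0.0)
    amp = spec.baseline * bleach * (1.0 + spec.mod_depth * signal_z)
    raw = amp * 0.5 * (1.0 + np.sin(2 * np.pi * f_sig * t))
    raw = raw + spec.control_baseline * 0.5 * (1.0 + np.sin(2 * np.pi * f_ctl * t))
    return raw


@dataclass
class SyntheticRecording:
    raw: RawPhotometry
    session: SessionTable
    truth_signal: np.ndarray  # noise-free kernel sum at fs


@dataclass
class Cohort:
    sessions: list[SessionTable]
    recordings: list[SyntheticRecording]
    spec: TruthSpec
    seed: int

    def truth_record(self) -> dict:
        return {
            "agent_params": {"alpha": self.spec.agent_params.alpha,
                             "beta": self.spec.agent_params.beta,
                             "tau": self.spec.agent_params.tau},
            "kernels": {k: {"amplitude": v.amplitude, "rise": v.rise,
                            "decay": v.decay}
                        for k, v in self.spec.kernels.items()},
            "noise": {"ar_coef": self.spec.ar_coef,
                      "ar_sigma": self.spec.ar_sigma},
            "task": {"p_high": self.spec.task.p_high,
                     "p_low": self.spec.task.p_low,
                     "rewards_per_block": self.spec.task.rewards_per_block},
            "seed": self.seed,
        }


def generate_cohort(spec: TruthSpec, n_mice: int = 6,
                    sessions_per_mouse: int = 5, seed: int = 0,
                    photometry_sessions: Optional[int] = None,
                    noise: bool = True) -> Cohort:
    """Simulate a cohort of mice with known ground truth.

    Behavior for every session; raw photometry rendered for the first
    ``photometry_sessions`` sessions (default: all). Byte-identical outputs
    for identical (spec, seed).
    """
    ss = np.random.SeedSequence(seed)
    sessions: list[SessionTable] = []
    recordings: list[SyntheticRecording] = []
    n_photo = (n_mice * sessions_per_mouse if photometry_sessions is None
               else photometry_sessions)
    children = iter(ss.spawn(n_mice * sessions_per_mouse))
    for m in range(n_mice):
        for s in range(sessions_per_mouse):
            child = next(children)
            beh_seed = int(child.generate_state(1)[0] % (2 ** 31))
            agent = RFLRAgent(spec.agent_params.alpha, spec.agent_params.beta,
                              spec.agent_params.tau)
            session = simulate_session(agent, spec.task, beh_seed,
                                       mouse_id=f"m{m}", session_id=f"s{s}")
            sessions.append(session)
            if len(recordings) < n_photo:
                rng = np.random.default_rng(child.spawn(1)[0])
                clean, t = render_fluorescence(session, spec, rng,
                                               noise=False)
                noisy = clean.copy()
                if noise:
                    full, _ = render_fluorescence(session, spec, rng,
                                                  noise=True)
                    noisy = full
                raw = RawPhotometry(
                    samples=modulate(noisy, t, spec),
                    fs=spec.fs, carriers=spec.carriers)
                recordings.append(SyntheticRecording(
                    raw=raw, session=session, truth_signal=clean))
    return Cohort(sessions=sessions, recordings=recordings, spec=spec,
                  seed=seed)


def truth_kernels_on_lags(spec: TruthSpec, T: int = glm.T_DEFAULT,
                          projected: bool = False) -> dict[str, np.ndarray]:
    """Generating kernels sampled on the GLM lag grid (-T..+T frames).

    ``projected=True`` returns the kernels as the measurement chain renders
    them: convolved with the spectral window's envelope response (the
    normalized squared Hamming window, ~108 ms wide, which leaks one to two
    frames acausally) and, unless events are snapped to frame centers, with
    a one-frame box for the uniform sub-frame timing jitter. This is the
    correct comparison target for coefficients fitted on demodulated data.
    """
    out = {}
    if projected:
        n_per_frame = int(round(FRAME_S * spec.fs))
        w2 = np.hamming(NWINDOW) ** 2
        w2 /= w2.sum()
        for name, k in spec.kernels.items():
            fine = k.sample(1.0 / spec.fs, spec.kernel_frames * n_per_frame)
            sm = np.convolve(fine, w2, mode="full")
            # index of event time within the convolved series
            center = (NWINDOW - 1) / 2.0
            if not spec.snap_events_to_frames:
                box = np.ones(n_per_frame) / n_per_frame
                sm = np.convolve(sm, box, mode="full")
                center += (n_per_frame - 1) / 2.0
            idx = np.arange(-T, T + 1) * n_per_frame + center
            out[name] = np.interp(idx, np.arange(sm.size), sm, left=0.0,
                                  right=0.0)
    else:
        for name, k in spec.kernels.items():
            vals = np.zeros(2 * T + 1)
            vals[T:] = k.sample(FRAME_S, min(T + 1, spec.kernel_frames))
            out[name] = vals
    return out


def exact_design_response(session: SessionTable, spec: TruthSpec,
                          T: int = glm.T_DEFAULT, seed: Optional[int] = None,
                          noise: bool = False):
    """Design matrix whose response is built exactly from the truth kernels.

    The response lives on the demodulation frame grid but bypasses the
    modulation/demodulation chain: y = X @ beta_truth (+ optional AR(1)
    frame noise). This isolates the regression from the measurement chain
    and is the reference for exact-recovery checks.

    Returns (design, beta_truth, kernels_truth).
    """
    dur = float(session.trials["t_SX"].iloc[-1]) + 3.0
    n_frames = photometry.frame_count(int(dur * spec.fs))
    grid = DemodSignal(values=np.zeros(n_frames),
                       t0=(NWINDOW - 1) / 2.0 / spec.fs, period=FRAME_S)
    pred = glm.build_predictors(session, grid,
                                hemisphere=spec.hemisphere, outcome_at="FL")
    truth = truth_kernels_on_lags(spec, T=T, projected=False)
    beta = np.concatenate([truth[name] for name in pred.names])
    full_design = glm.build_design(pred, grid, T=T)
    y = full_design.X @ beta
    if noise and spec.ar_sigma > 0:
        rng = np.random.default_rng(seed)
        innov = rng.normal(0.0, spec.ar_sigma, n_frames)
        from scipy.signal import lfilter
        ar = lfilter([1.0], [1.0, -spec.ar_coef], innov)
        y = y + ar[full_design.frame_indices]
    design = glm.DesignMatrix(X=full_design.X, y=y,
                              groups=full_design.groups,
                              predictor_names=full_design.predictor_names,
                              T=T, frame_indices=full_design.frame_indices)
    return design, beta, truth


def fit_cohort_glm(cohort: Cohort, alpha: float = 1.0,
                   T: int = glm.T_DEFAULT,
                   max_recordings: Optional[int] = None,
                   outcome_at: str = "FL"):
    """Demodulate the cohort's recordings, pool their designs, fit ridge.

    Returns (fit, design). Pooling concatenates rows; trial groups are made
    unique across sessions.
    """
    recs = cohort.recordings[:max_recordings]
    Xs, ys, gs, names = [], [], [], None
    offset = 0
    for rec in recs:
        dem = photometry.demodulate(rec.raw, cohort.spec.carriers[0])
        pred = glm.build_predictors(rec.session, dem,
                                    hemisphere=cohort.spec.hemisphere,
                                    outcome_at=outcome_at)
        design = glm.build_design(pred, dem, T=T)
        Xs.append(design.X)
        ys.append(design.y)
        gs.append(design.groups + offset)
        offset += int(design.groups.max()) + 1
        names = design.predictor_names
    pooled = glm.DesignMatrix(
        X=np.vstack(Xs), y=np.concatenate(ys), groups=np.concatenate(gs),
        predictor_names=names, T=T,
        frame_indices=np.arange(sum(x.shape[0] for x in Xs)))
    return glm.fit_ridge(pooled, alpha=alpha), pooled


def kernel_recovery(cohort: Cohort, fit,
                    projected: bool = True) -> pd.DataFrame:
    """Correlation between fitted and generating kernels per predictor.

    By default the truth is projected through the measurement chain's
    linear response (see :func:`truth_kernels_on_lags`).
    """
    truth = truth_kernels_on_lags(cohort.spec, T=fit.kernels.lags.max(),
                                  projected=projected)
    rows = []
    for name, est in fit.kernels.kernels.items():
        tk = truth.get(name)
        if tk is None or np.allclose(tk, 0):
            continue
        r = float(np.corrcoef(tk, est)[0, 1])
        rows.append({"predictor": name, "correlation": r,
                     "truth_peak": float(tk[np.abs(tk).argmax()]),
                     "est_peak": float(est[np.abs(est).argmax()])})
    return pd.DataFrame(rows)


def recovery_report(cohort: Cohort, glm_recordings: int = 1,
                    fit_seed: int = 0) -> pd.DataFrame:
    """Truth-vs-estimate table for the pipeline's headline parameters.

    Fits the RFLR to the cohort's behavior, the exponential recovery time
    constant to its transition curve, and the ridge GLM to the first
    ``glm_recordings`` recordings; tabulates relative errors.
    """
    rows = []
    truth = cohort.spec.agent_params
    fit = rflr.fit_rflr(cohort.sessions, seed=fit_seed)
    for name, t_val, e_val in [("alpha", truth.alpha, fit.params.alpha),
                               ("beta", truth.beta, fit.params.beta),
                               ("tau", truth.tau, fit.params.tau)]:
        rows.append({"quantity": name, "truth": t_val, "estimate": e_val,
                     "rel_error": abs(e_val - t_val) / abs(t_val)})
    curve = behavior.p_high_port_curve(cohort.sessions)
    tau_fit = behavior.fit_tau(curve)
    rows.append({"quantity": "tau_p_high_port", "truth": np.nan,
                 "estimate": tau_fit.tau, "rel_error": np.nan})
    if cohort.recordings:
        gfit, _ = fit_cohort_glm(cohort, max_recordings=glm_recordings)
        for _, r in kernel_recovery(cohort, gfit).iterrows():
            rows.append({"quantity": f"kernel_corr[{r['predictor']}]",
                         "truth": 1.0, "estimate": r["correlation"],
                         "rel_error": 1.0 - r["correlation"]})
    return pd.DataFrame(rows)
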