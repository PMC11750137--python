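"""Trial-history behavioral statistics around block transitions.

Implements the standard descriptive battery for the switching task:
block-transition-aligned p(high port) and p(switch) curves with exponential
time-constant fits, switch probabilities conditioned on two-trial history
words, per-session scalar summaries, and the pre-surgery performance
criteria check.

Averaging convention: curves are computed per mouse first, then mean and SEM
are taken across mice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .task import SessionTable


class EmptyCurveError(ValueError):
    """No block transitions available to align on."""


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass
class TransitionAlignedCurve:
    """Mean +/- SEM of a per-trial probability aligned to block transitions.

    Offset 0 is the first trial after the reward probabilities flip. Negative
    offsets index pre-transition trials.
    """

    trial_offsets: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_mice: int
    per_mouse: pd.DataFrame  # rows: mouse, cols: offsets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.trial_offsets,
                             "mean": self.mean, "sem": self.sem})


@dataclass
class TauFit:
    """Exponential recovery fit p(t) = A - B*exp(-t/tau) over t = 1..window."""

    tau: float
    asymptote: float
    amplitude: float
    sse: float
    fit_window: int = 20
    identifiable: bool = True
    message: str = ""


@dataclass
class HistoryConditionedSwitch:
    """p(switch) conditioned on history words over {A, a, B, b}.

    Letter = same (A/a) or different (B/b) side as the reference choice (the
    most recent trial of the history); upper case = rewarded. The word lists
    the older trial first. ``table`` has columns word, n, p_switch, freq.
    """

    table: pd.DataFrame
    overall_p_switch: float
    depth: int = 2

    def weighted_mean(self) -> float:
        t = self.table
        return float((t["freq"] * t["p_switch"]).sum())


def _per_mouse_aligned(sessions: Iterable[SessionTable], values_fn, pre: int,
                       post: int) -> pd.DataFrame:
    """Average a per-trial series around transitions, per mouse.

    ``values_fn(session)`` returns a float array (NaN = excluded trial).
    Offsets run -pre..post inclusive; transitions near session edges
    contribute the rows they have.
    """
    offsets = np.arange(-pre, post + 1)
    acc: dict[str, list[np.ndarray]] = {}
    for s in sessions:
        v = np.asarray(values_fn(s), dtype=float)
        for idx in s.transition_indices():
            row = np.full(offsets.size, np.nan)
            lo = max(0, idx - pre)
            hi = min(len(v), idx + post + 1)
            row[(lo - idx) + pre:(hi - idx) + pre] = v[lo:hi]
            acc.setdefault(s.mouse_id, []).append(row)
    if not acc:
        raise EmptyCurveError("no completed block transitions in input")
    per_mouse = pd.DataFrame(
        {m: np.nanmean(np.vstack(rows), axis=0) for m, rows in acc.items()}
    ).T
    per_mouse.columns = offsets
    return per_mouse


def _curve_from_per_mouse(per_mouse: pd.DataFrame) -> TransitionAlignedCurve:
    mean = per_mouse.mean(axis=0).to_numpy()
    n = per_mouse.notna().sum(axis=0).to_numpy()
    sd = per_mouse.std(axis=0, ddof=1).to_numpy() if len(per_mouse) > 1 else \
        np.zeros(per_mouse.shape[1])
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return TransitionAlignedCurve(
        trial_offsets=per_mouse.columns.to_numpy(dtype=int),
        mean=mean, sem=sem, n_mice=len(per_mouse), per_mouse=per_mouse)


def p_high_port_curve(sessions: Sequence[SessionTable], pre: int = 10,
                      post: int = 20) -> TransitionAlignedCurve:
    """p(high port) around block transitions (per-mouse then across-mouse)."""
    per_mouse = _per_mouse_aligned(
        sessions, lambda s: s.high_port_chosen.astype(float), pre, post)
    return _curve_from_per_mouse(per_mouse)


def p_switch_curve(sessions: Sequence[SessionTable], pre: int = 10,
                   post: int = 20) -> tuple[TransitionAlignedCurve, float]:
    """p(switch) around block transitions and max p(switch) over the first
    20 post-transition trials (t = 1..20, i.e. offsets 0..19).

    A switch on trial n means choice(n) != choice(n-1); the first trial of a
    session has no switch value and is excluded.
    """
    def switch_series(s: SessionTable) -> np.ndarray:
        v = np.full(len(s), np.nan)
        if len(s) > 1:
            v[1:] = s.switches.astype(float)
        return v

    per_mouse = _per_mouse_aligned(sessions, switch_series, pre, post)
    curve = _curve_from_per_mouse(per_mouse)
    sel = (curve.trial_offsets >= 0) & (curve.trial_offsets < 20)
    max_p_switch = float(np.nanmax(curve.mean[sel])) if sel.any() else float("nan")
    return curve, max_p_switch


def fit_tau(curve: TransitionAlignedCurve, window: int = 20) -> TauFit:
    """Least-squares exponential fit to the first ``window`` post-transition
    trials: p(t) = A - B*exp(-t/tau), t = 1..window (t in trials).

    Initialization from the series endpoints. A flat series (amplitude ~ 0)
    leaves tau unidentifiable; the fit is returned flagged rather than
    raising.
    """
    sel = (curve.trial_offsets >= 0) & (curve.trial_offsets < window)
    if sel.sum() < window:
        raise FitError(f"need {window} post-transition offsets, have {sel.sum()}")
    y = curve.mean[sel]
    t = curve.trial_offsets[sel].astype(float) + 1.0
    if np.isnan(y).any():
        raise FitError("NaN in post-transition curve")

    a0 = float(np.mean(y[-5:]))
    b0 = float(a0 - y[0])
    if abs(b0) < 1e-12:
        b0 = 1e-3
    p0 = (a0, b0, 3.0)

    def model(tt, a, b, tau):
        return a - b * np.exp(-tt / tau)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, t, y, p0=p0,
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
                maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy nonconvergence
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a, b, tau = (float(v) for v in popt)
    sse = float(np.sum((model(t, *popt) - y) ** 2))
    resid_scale = max(float(np.std(y)), 1e-12)
    identifiable = abs(b) > 1e-6 * max(abs(a), 1.0)
    msg = "" if identifiable else "amplitude ~ 0; tau unidentifiable"
    return TauFit(tau=tau, asymptote=a, amplitude=b, sse=sse,
                  fit_window=window, identifiable=identifiable, message=msg)


def conditional_switch(sessions: Sequence[SessionTable],
                       depth: int = 2) -> HistoryConditionedSwitch:
    """p(switch) after each possible ``depth``-trial history word.

    For a reference trial n, the word encodes trials n-depth+1..n (older
    first): each letter is A/a if that trial's choice matched choice(n)
    (B/b otherwise), upper case if rewarded. The switch outcome is whether
    choice(n+1) differs from choice(n). Frequency-weighted p(switch) over
    words equals the overall p(switch) over the same trials exactly.
    """
    counts: dict[str, list[int]] = {}
    n_sw = 0
    n_tot = 0
    for s in sessions:
        c = s.choices_signed
        r = s.rewards
        for n in range(depth - 1, len(s) - 1):
            letters = []
            for m in range(n - depth + 1, n + 1):
                same = c[m] == c[n]
                letters.append(("A" if same else "B") if r[m] else
                               ("a" if same else "b"))
            word = "".join(letters)
            sw = int(c[n + 1] != c[n])
            tot_sw = counts.setdefault(word, [0, 0])
            tot_sw[0] += 1
            tot_sw[1] += sw
            n_tot += 1
            n_sw += sw
    rows = [{"word": w, "n": v[0], "p_switch": v[1] / v[0],
             "freq": v[0] / n_tot} for w, v in sorted(counts.items())]
    table = pd.DataFrame(rows, columns=["word", "n", "p_switch", "freq"])
    overall = n_sw / n_tot if n_tot else float("nan")
    return HistoryConditionedSwitch(table=table, overall_p_switch=overall,
                                    depth=depth)


def session_summaries(sessions: Sequence[SessionTable]) -> pd.DataFrame:
    """Per-session scalar summaries.

    Columns: mouse_id, session_id, n_trials, p_reward, p_high_port, p_left,
    p_switch, mean_trial_duration, mean_iti, n_completed_blocks,
    mean_block_length. Empty sessions produce a row of NaNs with
    n_trials = 0 (explicit empty sentinel).
    """
    rows = []
    for s in sessions:
        if len(s) == 0:
            rows.append({"mouse_id": s.mouse_id, "session_id": s.session_id,
                         "n_trials": 0})
            continue
        t = s.trials
        trial_dur = (t["t_SX"] - t["t_CE"]).to_numpy()
        iti = t["t_CE"].to_numpy()[1:] - t["t_SX"].to_numpy()[:-1]
        blocks = t["block"].to_numpy()
        # completed blocks: all block ids except the (possibly partial) last
        n_completed = int(blocks.max())
        block_lengths = np.bincount(blocks)[:n_completed] if n_completed else \
            np.array([])
        rows.append({
            "mouse_id": s.mouse_id, "session_id": s.session_id,
            "n_trials": len(s),
            "p_reward": float(s.rewards.mean()),
            "p_high_port": float(s.high_port_chosen.mean()),
            "p_left": float((t["choice"] == "left").mean()),
            "p_switch": float(s.switches.mean()) if len(s) > 1 else np.nan,
            "mean_trial_duration": float(trial_dur.mean()),
            "mean_iti": float(iti.mean()) if iti.size else np.nan,
            "n_completed_blocks": n_completed,
            "mean_block_length": float(block_lengths.mean())
            if block_lengths.size else np.nan,
        })
    return pd.DataFrame(rows)


#: (metric, low, high, max_variance) rows of the pre-surgery criteria.
CRITERIA = (
    ("p_high_port", 0.80, 1.00, 0.003),
    ("p_switch", 0.00, 0.15, 0.001),
    ("p_left", 0.45, 0.55, 0.005),
)
MIN_TRIALS = 200


@dataclass
class CriteriaResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    means: dict = field(default_factory=dict)
    variances: dict = field(default_factory=dict)


def criteria_check(sessions: Sequence[SessionTable]) -> CriteriaResult:
    """Apply the stable-performance criteria to 5 consecutive sessions.

    Mean bounds are inclusive; variance bounds are strict. Variance is the
    population variance over the 5 sessions. Every session must have at
    least 200 trials.
    """
    if len(sessions) != 5:
        raise ValueError("criteria are defined over exactly 5 sessions")
    summ = session_summaries(sessions)
    reasons = []
    means, variances = {}, {}
    for metric, lo, hi, max_var in CRITERIA:
        vals = summ[metric].to_numpy(dtype=float)
        mean = float(vals.mean())
        var = float(vals.var(ddof=0))
        means[metric], variances[metric] = mean, var
        if not (lo <= mean <= hi):
            reasons.append(f"{metric}_mean_out_of_range")
        if not (var < max_var):
            reasons.append(f"{metric}_variance_too_high")
    n = summ["n_trials"].to_numpy()
    if (n < MIN_TRIALS).any():
        reasons.append("too_few_trials")
    means["n_trials_min"] = int(n.min())
    return CriteriaResult(passed=not reasons, reasons=reasons,
                          means=means, variances=variances)
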