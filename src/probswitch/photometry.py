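"""Frequency-modulated fiber-photometry demodulation and event alignment.

The acquisition scheme amplitude-modulates two excitation LEDs at distinct
carrier frequencies (signal 167 Hz, static control 223 Hz) and records the
summed detector output at 2000 samples/s. The slow fluorescence envelope on
each carrier is recovered by short-time spectral power: Hamming windows of
216 samples with 108-sample hop (final sampling period 54 ms), spectral
power evaluated at 1 Hz-spaced frequencies in an 8 Hz band centered on the
carrier and averaged, then detrended with a rolling z-score over a 1 min
window. Only relative (z-scored) values are meaningful, which makes the
whole chain invariant to the detector gain.

Frequencies are evaluated by direct complex-exponential projection, not by
FFT-bin rounding: the native resolution 2000/216 Hz is not an integer, so an
FFT grid would miss the 1 Hz spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .task import SessionTable, LEFT

FS_DEFAULT = 2000.0
NWINDOW = 216
HOP = 108
SIGNAL_CARRIER = 167.0
CONTROL_CARRIER = 223.0


@dataclass
class RawPhotometry:
    """Detector voltage series plus behavioral event timestamps.

    ``events`` is a frame with columns (name, t); ``carriers`` lists the
    modulation frequencies present in the trace.
    """

    samples: np.ndarray
    fs: float = FS_DEFAULT
    carriers: tuple[float, ...] = (SIGNAL_CARRIER, CONTROL_CARRIER)
    events: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        nyq = self.fs / 2.0
        for c in self.carriers:
            if c >= nyq:
                raise ValueError(f"carrier {c} Hz >= Nyquist {nyq} Hz")


@dataclass
class DemodSignal:
    """Demodulated, z-scored fluorescence on the 54 ms frame grid.

    ``values`` are z-scored; ``power`` keeps the pre-z-score band power for
    diagnostics. ``t0`` is the center time of the first frame.
    """

    values: np.ndarray
    t0: float
    period: float
    power: Optional[np.ndarray] = None
    carrier: Optional[float] = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.period * np.arange(self.values.size)

    def frame_of(self, t: np.ndarray) -> np.ndarray:
        """Nearest-center frame index for each time; ties toward the earlier
        frame."""
        d = (np.asarray(t, dtype=float) - self.t0) / self.period
        k = np.round(d).astype(int)
        # np.round ties-to-even; force exact half-offsets to the earlier frame
        frac = d - np.floor(d)
        exact_half = np.isclose(frac, 0.5, rtol=0, atol=1e-12)
        k = np.where(exact_half, np.floor(d).astype(int), k)
        return k


def rolling_zscore(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling z-score with truncated windows at the edges.

    The local standard deviation is floored at 1e-12, so a constant input
    maps to zeros rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    if window < 2 or window > x.size:
        raise ValueError("window must be in [2, len(x)]")
    s = pd.Series(x)
    roll = s.rolling(window, center=True, min_periods=1)
    mu = roll.mean().to_numpy()
    sd = roll.std(ddof=0).to_numpy()
    sd = np.maximum(sd, 1e-12)
    return (x - mu) / sd


def frame_count(n_samples: int, nwindow: int = NWINDOW, hop: int = HOP) -> int:
    return (n_samples - nwindow) // hop + 1


def demodulate(raw: RawPhotometry, carrier: float, nwindow: int = NWINDOW,
               hop: int = HOP, band_hz: float = 8.0,
               zscore_window_s: float = 60.0,
               window: str = "hamming",
               predetrend_raw: bool = False) -> DemodSignal:
    """Recover the envelope power on one carrier.

    Per frame (windowed ``nwindow`` samples, ``hop``-sample advance) the DFT
    is evaluated at 1 Hz-spaced frequencies spanning ``band_hz`` centered on
    the carrier (9 frequencies for the default 8 Hz band); the demodulated
    value is the mean squared magnitude over the band, normalized by window
    energy. A rolling z-score over ``zscore_window_s`` (1111 frames for 60 s
    at 54 ms) detrends the result. ``predetrend_raw`` optionally applies a
    1 min rolling z-score to the raw trace first.
    """
    if carrier >= raw.fs / 2.0:
        raise ValueError("carrier at or above Nyquist")
    x = raw.samples
    if x.size < nwindow:
        raise ValueError("need at least one full window of samples")
    if predetrend_raw:
        x = rolling_zscore(x, int(round(zscore_window_s * raw.fs)))
    if window == "hamming":
        w = np.hamming(nwindow)
    elif window == "hann":
        w = np.hanning(nwindow)
    else:
        raise ValueError(f"unknown window {window!r}")
    frames = np.lib.stride_tricks.sliding_window_view(x, nwindow)[::hop]
    half = band_hz / 2.0
    freqs = carrier + np.arange(-half, half + 1.0, 1.0)
    n = np.arange(nwindow)
    basis = (w[:, None]
             * np.exp(-2j * np.pi * freqs[None, :] * n[:, None] / raw.fs))
    coeff = frames @ basis
    power = (np.abs(coeff) ** 2).mean(axis=1) / np.dot(w, w)
    zwin = int(round(zscore_window_s / (hop / raw.fs)))
    zwin = min(max(zwin, 2), power.size)
    values = rolling_zscore(power, zwin)
    t0 = (nwindow - 1) / 2.0 / raw.fs
    return DemodSignal(values=values, t0=t0, period=hop / raw.fs,
                       power=power, carrier=carrier)


@dataclass
class PeriEventTensor:
    """Trials x time matrix of demodulated snippets aligned to one event.

    ``time`` is the frame-center offset from the aligned frame (seconds);
    ``labels`` carries one row per tensor row (trial id, direction,
    rewarded, previous outcome).
    """

    data: np.ndarray
    time: np.ndarray
    labels: pd.DataFrame
    event: str
    n_dropped: int = 0

    def group_mean(self, by: Sequence[str]) -> pd.DataFrame:
        """Mean trace per label group (rows: groups, columns: time)."""
        df = pd.DataFrame(self.data)
        df[list(by)] = self.labels[list(by)].to_numpy()
        return df.groupby(list(by)).mean()


def align_events(sig: DemodSignal, session: SessionTable, event: str,
                 pre: float, post: float,
                 hemisphere: str = LEFT) -> PeriEventTensor:
    """Extract peri-event snippets of the demodulated signal.

    Events are snapped to the nearest frame center (ties toward the earlier
    frame). Trials whose window would run off the recording are dropped and
    counted. Rows are labeled ipsi/contra (choice side relative to the
    recorded ``hemisphere``), rewarded/unrewarded, and by the previous
    trial's outcome.
    """
    col = f"t_{event}"
    if col not in session.trials.columns:
        raise KeyError(f"unknown event {event!r}")
    t_ev = session.trials[col].to_numpy(dtype=float)
    n_pre = int(round(pre / sig.period))
    n_post = int(round(post / sig.period))
    ks = sig.frame_of(t_ev)
    ok = (~np.isnan(t_ev)) & (ks - n_pre >= 0) & (ks + n_post < sig.values.size)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} events outside recording dropped",
                      RuntimeWarning)
    offs = np.arange(-n_pre, n_post + 1)
    rows = sig.values[ks[ok][:, None] + offs[None, :]]
    tr = session.trials.loc[ok]
    choice = tr["choice"].to_numpy()
    rewarded = tr["rewarded"].to_numpy(bool)
    prev = np.full(len(session), False)
    prev[1:] = session.trials["rewarded"].to_numpy(bool)[:-1]
    labels = pd.DataFrame({
        "trial": tr["trial"].to_numpy(),
        "mouse_id": tr["mouse_id"].to_numpy(),
        "choice": choice,
        "direction": np.where(choice == hemisphere, "ipsi", "contra"),
        "rewarded": rewarded,
        "prev_rewarded": prev[ok.to_numpy() if hasattr(ok, "to_numpy") else ok],
    }).reset_index(drop=True)
    return PeriEventTensor(data=rows, time=offs * sig.period, labels=labels,
                           event=event, n_dropped=n_dropped)


def window_mean(tensor: PeriEventTensor, t_start: float = 0.0,
                t_end: float = 0.5) -> pd.DataFrame:
    """Per-trial mean over frames with center offsets in (t_start, t_end].

    For the default 0-500 ms window on the 54 ms grid this averages exactly
    9 frames. Returns the label frame with an added ``mean`` column.
    """
    sel = (tensor.time > t_start + 1e-12) & (tensor.time <= t_end + 1e-12)
    if not sel.any():
        raise ValueError("window not covered by tensor")
    out = tensor.labels.copy()
    out["mean"] = tensor.data[:, sel].mean(axis=1)
    out.attrs["n_frames"] = int(sel.sum())
    return out


def group_window_means(per_trial: pd.DataFrame,
                       by: Sequence[str]) -> pd.DataFrame:
    """Aggregate per-trial window means per mouse, then per group.

    Matches the convention of reporting one value per animal per condition
    and averaging across animals.
    """
    per_mouse = (per_trial.groupby(["mouse_id", *by])["mean"]
                 .mean().reset_index())
    agg = per_mouse.groupby(list(by))["mean"].agg(["mean", "sem", "count"])
    return agg.rename(columns={"count": "n_mice"})
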