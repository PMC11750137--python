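"""Time-shifted kernel regression of the photometry signal on task events.

Ten binary behavioral predictors (CE/CX/SE/SX split by ipsi/contra, plus
Rew and Unrew) are placed on the 54 ms demodulation frame grid. Each
predictor is expanded into 2T+1 time-shifted copies (T = 20 frames forward
and backward), so the full design has 10*(2*20+1) = 410 columns and the
fitted coefficients form per-event kernels spanning -1.08..+1.08 s.

Only the trial period is modeled: frames from shortly before center entry
to shortly after side exit (a margin of T frames by default); frames shared
by consecutive trial windows are included twice, once in each trial's group.
The model is ridge regression, J = ||y - X b||^2 + alpha*||b||^2 with an
unpenalized intercept (alpha = 0 gives OLS), evaluated with group-shuffle
cross-validation that keeps all rows of a trial on the same side of the
train/test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupShuffleSplit

from .photometry import DemodSignal
from .task import LEFT, SessionTable

#: Canonical predictor order of the full model.
PREDICTORS = ["CE_ipsi", "CE_contra", "CX_ipsi", "CX_contra",
              "SE_ipsi", "SE_contra", "SX_ipsi", "SX_contra",
              "Rew", "Unrew"]

T_DEFAULT = 20

#: The omission-model battery: name -> (events removed, collapse direction?)
OMISSION_VARIANTS = ["Full", "-Rew", "-Direction", "-Direction&Rew",
                     "-CE/CX", "-CE", "-CX", "-SE/SX", "-SE", "-SX"]


@dataclass
class PredictorSet:
    """Binary event series on the demodulation frame grid.

    ``matrix`` is (n_frames, n_predictors) in {0,1}; each event occupies the
    single frame nearest its timestamp. ``trial_windows`` records each
    trial's (CE frame, SX frame) for design windowing.
    """

    matrix: np.ndarray
    names: list[str]
    t0: float
    period: float
    trial_windows: np.ndarray  # (n_trials, 2) frame indices
    trial_ids: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def build_predictors(session: SessionTable, sig: DemodSignal,
                     hemisphere: str = LEFT,
                     outcome_at: str = "SE") -> PredictorSet:
    """One-hot event series for the ten behavioral predictors.

    Ipsi/contra is the choice side relative to the recorded ``hemisphere``.
    Rew/Unrew fire once per trial at the side-entry frame by default
    (``outcome_at='FL'`` places them at first lick instead). Events whose
    frame falls off the grid are dropped with a warning.
    """
    n_frames = sig.values.size
    mat = np.zeros((n_frames, len(PREDICTORS)), dtype=np.uint8)
    names = list(PREDICTORS)
    tr = session.trials
    choice = tr["choice"].to_numpy()
    direction = np.where(choice == hemisphere, "ipsi", "contra")
    rewarded = tr["rewarded"].to_numpy(bool)
    dropped = 0

    def put(col: str, t: float) -> None:
        nonlocal dropped
        if np.isnan(t):
            return
        k = int(sig.frame_of(np.array([t]))[0])
        if 0 <= k < n_frames:
            mat[k, names.index(col)] = 1
        else:
            dropped += 1

    for i in range(len(tr)):
        d = direction[i]
        for ev in ("CE", "CX", "SE", "SX"):
            put(f"{ev}_{d}", float(tr[f"t_{ev}"].iloc[i]))
        t_out = float(tr[f"t_{outcome_at}"].iloc[i])
        if np.isnan(t_out):  # missing FL: fall back to side entry
            t_out = float(tr["t_SE"].iloc[i])
        put("Rew" if rewarded[i] else "Unrew", t_out)
    if dropped:
        warnings.warn(f"{dropped} events off the frame grid dropped",
                      RuntimeWarning)
    ce = sig.frame_of(tr["t_CE"].to_numpy(float))
    sx = sig.frame_of(tr["t_SX"].to_numpy(float))
    return PredictorSet(matrix=mat, names=names, t0=sig.t0,
                        period=sig.period,
                        trial_windows=np.column_stack([ce, sx]),
                        trial_ids=tr["trial"].to_numpy())


def collapse_direction(pred: PredictorSet,
                       events: Sequence[str] = ("CE", "CX", "SE", "SX")
                       ) -> PredictorSet:
    """Merge ipsi/contra pairs into direction-free event series.

    Timing is preserved: the merged column is the union (logical or) of the
    pair. Used by the "-Direction" omission variants.
    """
    cols = {}
    for name in pred.names:
        base = name.split("_")[0]
        if base in events and name != base:
            cols.setdefault(base, np.zeros(pred.n_frames, dtype=np.uint8))
            cols[base] |= pred.matrix[:, pred.names.index(name)]
        else:
            cols[name] = pred.matrix[:, pred.names.index(name)]
    names = list(cols)
    mat = np.column_stack([cols[n] for n in names]).astype(np.uint8)
    return PredictorSet(matrix=mat, names=names, t0=pred.t0,
                        period=pred.period, trial_windows=pred.trial_windows,
                        trial_ids=pred.trial_ids)


def drop_predictors(pred: PredictorSet, names: Sequence[str]) -> PredictorSet:
    keep = [i for i, n in enumerate(pred.names) if n not in names]
    return PredictorSet(matrix=pred.matrix[:, keep],
                        names=[pred.names[i] for i in keep], t0=pred.t0,
                        period=pred.period, trial_windows=pred.trial_windows,
                        trial_ids=pred.trial_ids)


@dataclass
class DesignMatrix:
    """Trial-windowed, time-shifted design with per-row trial groups."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    predictor_names: list[str]
    T: int
    frame_indices: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def lags(self) -> np.ndarray:
        return np.arange(-self.T, self.T + 1)


def build_design(pred: PredictorSet, response: DemodSignal, T: int = T_DEFAULT,
                 margin: Optional[int] = None) -> DesignMatrix:
    """Expand predictors into lagged columns and window rows by trial.

    Column block f spans lags -T..+T of predictor f: column (f, l) at frame
    t holds pred_f[t - l], so the coefficient at lag l describes the
    response l frames after the event. Rows kept per trial run from
    ``margin`` frames before the CE frame to ``margin`` after the SX frame
    (default margin = T, covering each kernel's full support); frames shared
    by consecutive trial windows appear once per trial group (duplicated
    rows).
    """
    if margin is None:
        margin = T
    if margin < 0:
        raise ValueError("margin must be >= 0")
    n_frames = pred.n_frames
    n_pred = len(pred.names)
    full = np.zeros((n_frames, n_pred * (2 * T + 1)), dtype=float)
    for f in range(n_pred):
        series = pred.matrix[:, f].astype(float)
        for j, lag in enumerate(range(-T, T + 1)):
            col = f * (2 * T + 1) + j
            if lag >= 0:
                full[lag:, col] = series[:n_frames - lag] if lag else series
            else:
                full[:lag, col] = series[-lag:]
    rows, groups = [], []
    for (a, b), tid in zip(pred.trial_windows, pred.trial_ids):
        lo = max(0, a - margin)
        hi = min(n_frames - 1, b + margin)
        idx = np.arange(lo, hi + 1)
        rows.append(idx)
        groups.append(np.full(idx.size, tid))
    idx = np.concatenate(rows)
    groups = np.concatenate(groups)
    y = response.values[idx]
    return DesignMatrix(X=full[idx], y=y, groups=groups,
                        predictor_names=list(pred.names), T=T,
                        frame_indices=idx)


@dataclass
class KernelSet:
    """Per-predictor coefficient kernels over lags -T..+T frames."""

    kernels: dict[str, np.ndarray]
    lags: np.ndarray
    period: float = 0.054

    @property
    def lag_seconds(self) -> np.ndarray:
        return self.lags * self.period

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.kernels)
        df.insert(0, "lag_s", self.lag_seconds)
        return df


@dataclass
class GLMFit:
    kernels: KernelSet
    intercept: float
    alpha: float
    mse: float
    r2: float
    coef: np.ndarray = field(repr=False, default=None)


def _ridge_solve(X: np.ndarray, y: np.ndarray, alpha: float):
    """Normal-equations ridge with unpenalized intercept.

    Singular systems at alpha = 0 fall back to the pseudo-inverse with a
    warning.
    """
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    A = Xa.T @ Xa
    A[1:, 1:] += alpha * np.eye(p)
    b = Xa.T @ y
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular normal equations; using pseudo-inverse",
                      RuntimeWarning)
        beta = np.linalg.pinv(A) @ b
    return float(beta[0]), beta[1:]


def _score(X, y, intercept, coef):
    pred = X @ coef + intercept
    resid = y - pred
    mse = float(np.mean(resid ** 2))
    denom = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / denom if denom > 0 else float("nan")
    return mse, r2


def fit_ridge(design: DesignMatrix, alpha: float = 1.0) -> GLMFit:
    """Closed-form ridge fit of the design; alpha = 0 gives OLS."""
    n, p = design.X.shape
    if n < p:
        warnings.warn(f"underdetermined system: {n} rows < {p} columns",
                      RuntimeWarning)
    intercept, coef = _ridge_solve(design.X, design.y, alpha)
    mse, r2 = _score(design.X, design.y, intercept, coef)
    width = 2 * design.T + 1
    kernels = {name: coef[f * width:(f + 1) * width].copy()
               for f, name in enumerate(design.predictor_names)}
    ks = KernelSet(kernels=kernels, lags=design.lags)
    return GLMFit(kernels=ks, intercept=intercept, alpha=alpha, mse=mse,
                  r2=r2, coef=coef)


def cross_validate(design: DesignMatrix, alpha: float = 1.0,
                   n_folds: int = 10, test_frac: float = 0.2,
                   seed: int = 0) -> pd.DataFrame:
    """Group-shuffle-split CV by trial: 80/20 train/test per fold.

    No trial's rows straddle the split. Returns per-fold train/test MSE and
    R^2.
    """
    groups = design.groups
    if np.unique(groups).size < n_folds:
        raise ValueError("fewer trial groups than folds")
    gss = GroupShuffleSplit(n_splits=n_folds, test_size=test_frac,
                            random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(gss.split(design.X, design.y, groups)):
        intercept, coef = _ridge_solve(design.X[tr], design.y[tr], alpha)
        tr_mse, tr_r2 = _score(design.X[tr], design.y[tr], intercept, coef)
        te_mse, te_r2 = _score(design.X[te], design.y[te], intercept, coef)
        rows.append({"fold": fold, "train_mse": tr_mse, "test_mse": te_mse,
                     "train_r2": tr_r2, "test_r2": te_r2})
    return pd.DataFrame(rows)


def reconstruct(fit: GLMFit, pred: PredictorSet) -> np.ndarray:
    """Predicted signal: each event series convolved with its kernel, summed,
    plus the intercept."""
    T = (fit.kernels.lags.size - 1) // 2
    out = np.full(pred.n_frames, fit.intercept, dtype=float)
    for name in pred.names:
        k = fit.kernels.kernels[name]
        series = pred.matrix[:, pred.names.index(name)].astype(float)
        conv = np.convolve(series, k, mode="full")
        out += conv[T:T + pred.n_frames]
    return out


def make_variant(pred: PredictorSet, variant: str) -> PredictorSet:
    """Predictor set for one omission-model variant."""
    if variant == "Full":
        return pred
    if variant == "-Rew":
        return drop_predictors(pred, ["Rew", "Unrew"])
    if variant == "-Direction":
        return collapse_direction(pred)
    if variant == "-Direction&Rew":
        return drop_predictors(collapse_direction(pred), ["Rew", "Unrew"])
    if variant == "-CE/CX":
        return drop_predictors(pred, ["CE_ipsi", "CE_contra",
                                      "CX_ipsi", "CX_contra"])
    if variant == "-CE":
        return drop_predictors(pred, ["CE_ipsi", "CE_contra"])
    if variant == "-CX":
        return drop_predictors(pred, ["CX_ipsi", "CX_contra"])
    if variant == "-SE/SX":
        return drop_predictors(pred, ["SE_ipsi", "SE_contra",
                                      "SX_ipsi", "SX_contra"])
    if variant == "-SE":
        return drop_predictors(pred, ["SE_ipsi", "SE_contra"])
    if variant == "-SX":
        return drop_predictors(pred, ["SX_ipsi", "SX_contra"])
    raise ValueError(f"unknown variant {variant!r}")


def omission_analysis(pred: PredictorSet, response: DemodSignal,
                      variants: Optional[Sequence[str]] = None,
                      T: int = T_DEFAULT, alpha: float = 1.0,
                      n_folds: int = 5, test_frac: float = 0.2,
                      seed: int = 0) -> pd.DataFrame:
    """Refit the model with selected predictors omitted.

    Each variant is cross-validated with 5-fold group shuffle split by
    trial; the long-format output carries per-fold train/test MSE and the
    variant's column count, ready for box plots.
    """
    if variants is None:
        variants = OMISSION_VARIANTS
    frames = []
    for v in variants:
        pv = make_variant(pred, v)
        design = build_design(pv, response, T=T)
        cv = cross_validate(design, alpha=alpha, n_folds=n_folds,
                            test_frac=test_frac, seed=seed)
        cv.insert(0, "variant", v)
        cv["n_columns"] = design.n_columns
        frames.append(cv)
    return pd.concat(frames, ignore_index=True)
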