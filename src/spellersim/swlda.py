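"""Stepwise linear discriminant analysis (SWLDA) for target/non-target scoring.

Features are raw signal values at a (channel, time) point within the
0-800 ms epoch, flattened channel-major.  Coded labels (-1 non-target,
+1 target by default) are regressed on the selected features by ordinary
least squares; features enter one at a time when their coefficient
p-value is below ``p_enter`` and any included feature whose p-value rises
above ``p_remove`` is dropped again.  The loop stops when no change
occurs or ``max_features`` are included.  This is classical stepwise
regression (forward inclusion / backward elimination on coefficient
t-tests), the standard P300 decoder configuration: at most 60 features,
p-enter 0.1, p-remove 0.15.

The forward scan is implemented by residualizing all candidate columns
against the included set (Gram-Schmidt updates), which gives each
candidate's add-one t-statistic as a partial correlation; this is
algebraically identical to refitting OLS with the candidate included,
but costs one matrix product per step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .rcp_engine import FlashSchedule, decide_item
from .signal_sim import EpochSet

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class SWLDAConfig:
    max_features: int = 60
    p_enter: float = 0.1
    p_remove: float = 0.15
    label_coding: tuple[float, float] = (-1.0, 1.0)  # (non-target, target)

    def __post_init__(self) -> None:
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if not (0 < self.p_enter < 1 and 0 < self.p_remove < 1):
            raise ValueError("p-values must lie in (0, 1)")
        if self.p_enter >= self.p_remove:
            raise ValueError("p_enter must be < p_remove (stepwise stability)")


@dataclass
class ClassifierModel:
    """Linear scorer: intercept + sum of weights over selected features."""

    selected_features: list[tuple[int, int]]   # (channel, sample) indices
    weights: np.ndarray
    intercept: float
    n_channels: int
    n_samples: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.selected_features) != self.weights.size:
            raise ValueError("one weight per selected feature")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def flat_indices(self) -> np.ndarray:
        return np.array([ch * self.n_samples + s for ch, s in self.selected_features],
                        dtype=int)


def _flatten(epoch_set: EpochSet) -> np.ndarray:
    n = len(epoch_set)
    return epoch_set.epochs.reshape(n, -1)


def _ols_stats(Xc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients and p-values of centered OLS (intercept projected out)."""
    n, k = Xc.shape
    gram = Xc.T @ Xc
    ginv = np.linalg.pinv(gram)
    beta = ginv @ (Xc.T @ yc)
    resid = yc - Xc @ beta
    df = n - k - 1  # intercept consumed one df
    if df <= 0:
        raise ValueError("not enough epochs for the number of features")
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(np.diag(ginv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    rss = float(resid @ resid)
    return beta, p, rss


def fit_swlda(epoch_set: EpochSet, config: SWLDAConfig = SWLDAConfig()) -> ClassifierModel:
    """Fit the stepwise model on labeled epochs.

    Requires at least two epochs of each class.  Candidates whose residual
    against the included set is numerically zero (rank deficiency) are
    skipped and recorded in ``training_meta['skipped_features']``.
    """
    labels = epoch_set.labels
    n_target = int(labels.sum())
    n_nontarget = int((~labels).sum())
    if n_target < 2 or n_nontarget < 2:
        raise ValueError("need at least two epochs of each class")

    X = _flatten(epoch_set)
    n, p = X.shape
    y = np.where(labels, config.label_coding[1], config.label_coding[0]).astype(float)

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    col_norms = np.linalg.norm(Xc, axis=0)

    included: list[int] = []
    skipped: set[int] = set()
    seen_sets: set[frozenset[int]] = set()

    X_res = Xc.copy()
    y_res = yc.copy()
    Q = np.empty((n, 0))

    def rebuild_residuals() -> None:
        nonlocal X_res, y_res, Q
        if included:
            Q, _ = np.linalg.qr(Xc[:, included])
            X_res = Xc - Q @ (Q.T @ Xc)
            y_res = yc - Q @ (Q.T @ yc)
        else:
            Q = np.empty((n, 0))
            X_res = Xc.copy()
            y_res = yc.copy()

    while True:
        changed = False
        k = len(included)
        df = n - k - 2
        if k < config.max_features and df > 0:
            res_norms = np.linalg.norm(X_res, axis=0)
            y_norm = np.linalg.norm(y_res)
            valid = np.ones(p, dtype=bool)
            valid[included] = False
            degenerate = res_norms <= _RANK_TOL * np.maximum(col_norms, 1.0)
            skipped.update(np.nonzero(valid & degenerate)[0].tolist())
            valid &= ~degenerate
            if y_norm > 0 and valid.any():
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = (X_res.T @ y_res) / (res_norms * y_norm)
                r = np.clip(np.nan_to_num(r), -1.0, 1.0)
                denom = np.maximum(1.0 - r**2, 1e-300)
                t = r * np.sqrt(df / denom)
                pvals = 2.0 * stats.t.sf(np.abs(t), df)
                pvals[~valid] = np.inf
                best = int(np.argmin(pvals))  # argmin ties -> lowest index
                if pvals[best] < config.p_enter:
                    included.append(best)
                    q = X_res[:, best] / res_norms[best]
                    X_res = X_res - np.outer(q, q @ X_res)
                    y_res = y_res - q * (q @ y_res)
                    Q = np.column_stack([Q, q])
                    changed = True

        if included:
            _, pvals_in, _ = _ols_stats(Xc[:, included], yc)
            to_remove = [f for f, pv in zip(included, pvals_in) if pv > config.p_remove]
            if to_remove:
                included = [f for f in included if f not in to_remove]
                rebuild_residuals()
                changed = True

        key = frozenset(included)
        if not changed or key in seen_sets:
            break
        seen_sets.add(key)

    if not included:
        raise ValueError("stepwise selection retained no features")

    beta, _, _ = _ols_stats(Xc[:, included], yc)
    intercept = float(y.mean() - X[:, included].mean(axis=0) @ beta)

    n_ch, n_s = epoch_set.epochs.shape[1], epoch_set.epochs.shape[2]
    feats = [(int(f // n_s), int(f % n_s)) for f in included]
    meta = {
        "config": {"max_features": config.max_features, "p_enter": config.p_enter,
                   "p_remove": config.p_remove, "label_coding": list(config.label_coding)},
        "n_epochs": n,
        "n_target": n_target,
        "skipped_features": sorted(skipped),
        "channel_names": list(epoch_set.channel_names),
    }
    return ClassifierModel(feats, beta, intercept, n_ch, n_s, meta)


def score_epoch(model: ClassifierModel, epoch) -> float:
    """Linear score of one channels x samples epoch."""
    x = np.asarray(epoch, dtype=float)
    if x.shape != (model.n_channels, model.n_samples):
        raise ValueError(
            f"epoch shape {x.shape} does not match training shape "
            f"({model.n_channels}, {model.n_samples})"
        )
    return float(model.intercept + x.ravel()[model.flat_indices] @ model.weights)


def score_epochs(model: ClassifierModel, epochs) -> np.ndarray:
    """Vectorized :func:`score_epoch` over an (n, channels, samples) array."""
    x = np.asarray(epochs, dtype=float)
    if x.shape[1:] != (model.n_channels, model.n_samples):
        raise ValueError("epoch shape does not match training shape")
    flat = x.reshape(x.shape[0], -1)
    return model.intercept + flat[:, model.flat_indices] @ model.weights


def accuracy_by_sequences(model: ClassifierModel, run: EpochSet,
                          seq_range) -> dict[int, float]:
    """Re-decide every selection of a labeled run at reduced sequence counts.

    For each k the first k sequences (14k flashes) of every selection are
    scored and decided; the value is the fraction of selections whose
    decided cell equals the attended one.  Truncation reuses the same
    simulated flashes, so curves across k share their randomness.
    """
    if not run.selections:
        raise ValueError("run carries no selection bookkeeping")
    seq_range = list(seq_range)
    max_avail = min(s.schedule.n_sequences for s in run.selections)
    if max(seq_range) > max_avail:
        raise ValueError(f"requested {max(seq_range)} sequences, run has {max_avail}")
    scores = score_epochs(model, run.epochs)
    curve: dict[int, float] = {}
    for k in seq_range:
        correct = 0
        for sel in run.selections:
            n_ev = 14 * k
            s = scores[sel.event_start: sel.event_start + n_ev]
            decided = decide_item(s, sel.schedule.truncated(k))
            correct += decided == sel.attended_item
        curve[k] = correct / len(run.selections)
    return curve


# ---------------------------------------------------------------------------
# JSON serialization (channel name + millisecond offset per feature)

def model_to_json(model: ClassifierModel, sample_rate_hz: float = 250.0) -> str:
    channels = model.training_meta.get(
        "channel_names", [str(i) for i in range(model.n_channels)])
    return json.dumps({
        "features": [
            {"channel": channels[ch], "time_ms": 1000.0 * s / sample_rate_hz,
             "channel_index": ch, "sample_index": s}
            for ch, s in model.selected_features
        ],
        "weights": model.weights.tolist(),
        "intercept": model.intercept,
        "n_channels": model.n_channels,
        "n_samples": model.n_samples,
        "training_meta": model.training_meta,
    }, indent=1)


def model_from_json(text: str) -> ClassifierModel:
    d = json.loads(text)
    feats = [(f["channel_index"], f["sample_index"]) for f in d["features"]]
    return ClassifierModel(feats, np.asarray(d["weights"]), d["intercept"],
                           d["n_channels"], d["n_samples"], d.get("training_meta", {}))
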