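"""Stepwise linear discriminant analysis (SWLDA) epoch scoring.

Each flash yields an epoch: a fixed multichannel window of post-stimulus
samples.  SWLDA selects a sparse set of (channel, sample) features by
forward/backward stepwise ordinary-least-squares regression of the binary
target label on the features, and scores an epoch as the dot product of the
OLS coefficients with the selected feature values.  Scores of target and
non-target epochs are summarized by per-class Gaussians (mu_a, sigma_a^2) and
(mu_n, sigma_n^2), the likelihood model consumed by the particle filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Conventional SWLDA settings for P300 feature selection.
DEFAULT_P_ENTER = 0.10
DEFAULT_P_REMOVE = 0.15
DEFAULT_MAX_FEATURES = 60
DEFAULT_DECIMATION = 12

#: Acquisition constants: 32 channels, 600 ms windows at 256 Hz (154 samples).
N_CHANNELS = 32
SAMPLE_RATE_HZ = 256
EPOCH_MS = 600
EPOCH_SAMPLES = int(round(EPOCH_MS / 1000 * SAMPLE_RATE_HZ))  # 153.6 -> 154


@dataclass
class EpochFeatures:
    """One flash-locked epoch: (channels, samples) matrix plus optional label."""

    values: np.ndarray
    label: int | None = None  # 1 target, 0 non-target

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("epoch values must be a 2-D (channels, samples) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("epoch contains non-finite values")


@dataclass
class FeatureWeights:
    """Selected (channel, sample) features and their regression coefficients."""

    selected_indices: list[tuple[int, int]]
    coefficients: np.ndarray
    epoch_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.selected_indices) != len(self.coefficients):
            raise ValueError("one coefficient per selected feature required")
        if len(set(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("duplicate selected feature indices")

    @property
    def flat_indices(self) -> np.ndarray:
        n_samples = self.epoch_shape[1]
        return np.array(
            [c * n_samples + s for c, s in self.selected_indices], dtype=int
        )


@dataclass
class ScoreModel:
    """Per-class Gaussian parameters of the stimulus scores.

    Zero variances are permitted only as degenerate *generating* parameters
    (noise-free simulation); the decoding likelihood requires both to be
    strictly positive.
    """

    mu_target: float
    var_target: float
    mu_nontarget: float
    var_nontarget: float

    def __post_init__(self) -> None:
        if self.var_target < 0 or self.var_nontarget < 0:
            raise ValueError("score variances must be non-negative")

    @property
    def separation(self) -> float:
        """Class separation (mu_a - mu_n) / pooled sigma."""
        pooled = np.sqrt((self.var_target + self.var_nontarget) / 2.0)
        return (self.mu_target - self.mu_nontarget) / pooled


def preprocess_epoch(
    raw_window: np.ndarray, decimation_factor: int = DEFAULT_DECIMATION
) -> EpochFeatures:
    """Moving-average and decimate each channel of a raw 600 ms window.

    Each channel is reduced to block means over consecutive runs of
    ``decimation_factor`` samples (a trailing partial block is dropped);
    factor 12 takes 256 Hz data to ~21 Hz, keeping the stepwise design matrix
    tractable.  Factor 1 is the identity.
    """
    raw = np.asarray(raw_window, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw window must be 2-D (channels, samples)")
    if decimation_factor < 1:
        raise ValueError("decimation_factor must be >= 1")
    n_blocks = raw.shape[1] // decimation_factor
    if n_blocks == 0:
        raise ValueError("window shorter than one decimation block")
    trimmed = raw[:, : n_blocks * decimation_factor]
    blocks = trimmed.reshape(raw.shape[0], n_blocks, decimation_factor)
    return EpochFeatures(values=blocks.mean(axis=2))


def _design(X: np.ndarray, cols: list[int]) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0])] + [X[:, c] for c in cols])


def _ols_pvalues(X: np.ndarray, y: np.ndarray, cols: list[int]) -> np.ndarray:
    """Two-sided t-test p-values of the non-intercept coefficients."""
    D = _design(X, cols)
    beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    df = len(y) - D.shape[1]
    if df <= 0:
        return np.ones(len(cols))
    sigma2 = resid @ resid / df
    XtX_inv = np.linalg.pinv(D.T @ D)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
    t = beta / se
    return 2.0 * stats.t.sf(np.abs(t[1:]), df)


def _forward_pvalues(
    X: np.ndarray, y: np.ndarray, cols: list[int], candidates: np.ndarray
) -> np.ndarray:
    """Partial p-value for adding each candidate to the current OLS model.

    Computed from the correlation between the residualized response and each
    residualized candidate column, equivalent to the t-test of the added
    coefficient in the enlarged regression.
    """
    D = _design(X, cols)
    Q, _ = np.linalg.qr(D)
    ry = y - Q @ (Q.T @ y)
    C = X[:, candidates]
    rc = C - Q @ (Q.T @ C)
    ss_y = ry @ ry
    ss_c = np.einsum("ij,ij->j", rc, rc)
    df = len(y) - D.shape[1] - 1
    if df <= 0 or ss_y <= 0:
        return np.ones(len(candidates))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc.T @ ry) / np.sqrt(ss_c * ss_y)
        r = np.clip(np.nan_to_num(r), -1.0, 1.0)
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def fit_swlda(
    epochs: list[EpochFeatures],
    p_enter: float = DEFAULT_P_ENTER,
    p_remove: float = DEFAULT_P_REMOVE,
    max_features: int = DEFAULT_MAX_FEATURES,
) -> FeatureWeights:
    """Forward/backward stepwise OLS feature selection on labeled epochs.

    Forward steps add the candidate with the smallest partial p-value when it
    falls below ``p_enter`` (ties broken by lowest feature index); backward
    steps drop included features whose p-value exceeds ``p_remove`` (largest
    first).  Iteration stops at a fixed point or once ``max_features`` are
    held with nothing removable.  Deterministic given the epoch order.
    """
    if not epochs or any(e.label is None for e in epochs):
        raise ValueError("all training epochs must carry labels")
    if not p_enter < p_remove:
        raise ValueError("p_enter must be < p_remove")
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    shape = epochs[0].values.shape
    X = np.stack([e.values.reshape(-1) for e in epochs])
    y = np.array([float(e.label) for e in epochs])
    if len(np.unique(y)) < 2:
        raise ValueError("both target and non-target epochs are required")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("degenerate design: every feature is constant")

    included: list[int] = []
    while True:
        added = False
        if len(included) < max_features:
            candidates = np.array(
                [j for j in range(X.shape[1]) if j not in included], dtype=int
            )
            variable = X[:, candidates].std(axis=0) > 0
            candidates = candidates[variable]
            if candidates.size:
                pvals = _forward_pvalues(X, y, included, candidates)
                best = int(np.argmin(pvals))  # argmin → lowest index on ties
                if pvals[best] < p_enter:
                    included.append(int(candidates[best]))
                    added = True
        removed = False
        while included:
            pvals = _ols_pvalues(X, y, included)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                included.pop(worst)
                removed = True
            else:
                break
        if not (added or removed):
            break  # fixed point
        if len(included) >= max_features and not removed:
            break  # cap reached and stable
    n_samples = shape[1]
    coeffs = np.zeros(len(included))
    if included:
        D = _design(X, included)
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        coeffs = beta[1:]
    return FeatureWeights(
        selected_indices=[(j // n_samples, j % n_samples) for j in included],
        coefficients=coeffs,
        epoch_shape=(shape[0], shape[1]),
    )


def score_epoch(epoch: EpochFeatures, weights: FeatureWeights) -> float:
    """Dot product of the coefficients with the epoch at the selected features."""
    if epoch.values.shape != tuple(weights.epoch_shape):
        raise ValueError(
            f"epoch shape {epoch.values.shape} does not match "
            f"weights shape {tuple(weights.epoch_shape)}"
        )
    if not len(weights.coefficients):
        return 0.0
    flat = epoch.values.reshape(-1)
    return float(flat[weights.flat_indices] @ weights.coefficients)


def score_epochs(epochs: list[EpochFeatures], weights: FeatureWeights) -> np.ndarray:
    return np.array([score_epoch(e, weights) for e in epochs])


def fit_score_model(scores, labels) -> ScoreModel:
    """Per-class sample means and unbiased (n-1) variances of the scores."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    tgt = scores[labels == 1]
    non = scores[labels == 0]
    if len(tgt) < 2 or len(non) < 2:
        raise ValueError("need at least two scores per class")
    var_t = float(np.var(tgt, ddof=1))
    var_n = float(np.var(non, ddof=1))
    if var_t == 0 or var_n == 0:
        raise ValueError("zero score variance: degenerate training data")
    return ScoreModel(
        mu_target=float(np.mean(tgt)),
        var_target=var_t,
        mu_nontarget=float(np.mean(non)),
        var_nontarget=var_n,
    )


# ---------------------------------------------------------------------------
# Tabular training-data format: one file per session, rows = epochs,
# flattened feature columns f<channel>_<sample> plus label / group /
# character_index metadata columns.
# ---------------------------------------------------------------------------

def write_training_data(
    path: str,
    epochs: list[EpochFeatures],
    groups,
    character_indices,
) -> None:
    shape = epochs[0].values.shape
    cols = [f"f{c}_{s}" for c in range(shape[0]) for s in range(shape[1])]
    frame = pd.DataFrame(
        np.stack([e.values.reshape(-1) for e in epochs]), columns=cols
    )
    frame.insert(0, "character_index", np.asarray(character_indices, dtype=int))
    frame.insert(1, "group", np.asarray(groups, dtype=int))
    frame.insert(2, "label", [int(e.label) for e in epochs])
    frame.to_csv(path, sep="\t", index=False)


def read_training_data(path: str):
    """Read a session file; returns (epochs, groups, character_indices)."""
    frame = pd.read_csv(path, sep="\t")
    meta = ["character_index", "group", "label"]
    for col in meta:
        if col not in frame.columns:
            raise ValueError(f"training file missing column {col!r}")
    feat_cols = [c for c in frame.columns if c not in meta]
    chans, samps = zip(*(map(int, c[1:].split("_")) for c in feat_cols))
    shape = (max(chans) + 1, max(samps) + 1)
    if len(feat_cols) != shape[0] * shape[1]:
        raise ValueError("feature columns do not form a full channel x sample grid")
    values = frame[feat_cols].to_numpy(dtype=float)
    epochs = [
        EpochFeatures(values=row.reshape(shape), label=int(lab))
        for row, lab in zip(values, frame["label"])
    ]
    return epochs, frame["group"].to_numpy(int), frame["character_index"].to_numpy(int)
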