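"""Synthetic spelling sessions.

Real sessions require EEG acquisition; the simulator replaces only the signal
chain, not the decoding problem.  Conditioned on a hidden target string it
emits randomized row/column flash schedules and draws each flash's scalar
score from the target-class Gaussian when the flashed group contains the
target character and from the non-target Gaussian otherwise — exactly the
decoder's likelihood model run forwards, with scores conditionally
independent across flashes.

The default class separation of 1.2 pooled standard deviations is a
calibration chosen so that simulated accuracies and selection rates fall in
the range observed for healthy spellers; it is a package choice, not a
measured effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridLayout, TimingModel, make_flash_schedule
from .pfilter import SCORE_STREAM_COLUMNS, ScoreStream
from .swlda import EpochFeatures, FeatureWeights, ScoreModel

#: Calibrated default score model: unit variances, 1.2 sigma separation.
DEFAULT_SCORE_MODEL = ScoreModel(
    mu_target=1.2, var_target=1.0, mu_nontarget=0.0, var_nontarget=1.0
)


@dataclass
class SimulationConfig:
    """Ground truth and generating parameters for one synthetic session."""

    target_text: str
    score_model: ScoreModel = field(default_factory=lambda: DEFAULT_SCORE_MODEL)
    timing: TimingModel = field(default_factory=TimingModel)
    grid: GridLayout = field(default_factory=GridLayout)
    n_sequences_max: int = 10  # 10 sequences x 12 groups = the 120-flash cap
    seed: int = 0

    def __post_init__(self) -> None:
        for ch in self.target_text:
            if ch not in self.grid.characters:
                raise ValueError(f"target character {ch!r} absent from grid")
        if self.n_sequences_max * self.grid.n_groups < 12:
            raise ValueError("schedule shorter than one full sequence")


def simulate_session(config: SimulationConfig) -> ScoreStream:
    """Emit a full flash schedule with Gaussian scores for each target character.

    Every character period contains ``n_sequences_max`` permuted sequences
    (the decoder stops early on its own); exactly two flashes per sequence
    contain the target (its row and its column).  Reproducible per seed.
    """
    rng = np.random.default_rng(config.seed)
    grid, sm = config.grid, config.score_model
    membership = grid.membership_matrix()
    sd_t, sd_n = np.sqrt(sm.var_target), np.sqrt(sm.var_nontarget)
    rows = []
    soa = config.timing.soa_ms
    for char_idx, target in enumerate(config.target_text):
        schedule = make_flash_schedule(
            config.n_sequences_max,
            seed=int(rng.integers(2**31)),
            grid=grid,
        )
        tgt_col = grid.char_index(target)
        for flash_idx, group in enumerate(schedule):
            is_target = membership[group, tgt_col]
            mu, sd = (sm.mu_target, sd_t) if is_target else (sm.mu_nontarget, sd_n)
            rows.append(
                (
                    char_idx,
                    flash_idx,
                    int(group),
                    mu + sd * rng.standard_normal(),
                    (char_idx * len(schedule) + flash_idx) * soa,
                )
            )
    frame = pd.DataFrame(rows, columns=SCORE_STREAM_COLUMNS)
    return ScoreStream(frame=frame, target_text=config.target_text)


@dataclass
class EpochSession:
    """Labeled epochs with flash annotations, as used for classifier training."""

    epochs: list[EpochFeatures]
    groups: np.ndarray
    character_indices: np.ndarray
    target_text: str


def simulate_epoch_features(
    config: SimulationConfig, weights: FeatureWeights
) -> EpochSession:
    """Generate epochs whose projection through ``weights`` has the configured
    score distributions.

    The class-mean signal is injected along the weight direction (scaled by
    1/||w||^2 so the projection hits the class mean exactly) and isotropic
    Gaussian noise is added with a per-class scale of sigma_class/||w||, so
    the projected score variance matches the class variance.
    """
    w = np.zeros(weights.epoch_shape[0] * weights.epoch_shape[1])
    if not len(weights.coefficients):
        raise ValueError("weights select no features")
    w[weights.flat_indices] = weights.coefficients
    norm2 = float(w @ w)
    if norm2 == 0:
        raise ValueError("zero-norm weights cannot carry a score signal")
    norm = np.sqrt(norm2)
    rng = np.random.default_rng(config.seed)
    grid, sm = config.grid, config.score_model
    membership = grid.membership_matrix()
    shape = tuple(weights.epoch_shape)
    epochs: list[EpochFeatures] = []
    groups: list[int] = []
    char_indices: list[int] = []
    for char_idx, target in enumerate(config.target_text):
        schedule = make_flash_schedule(
            config.n_sequences_max, seed=int(rng.integers(2**31)), grid=grid
        )
        tgt_col = grid.char_index(target)
        for group in schedule:
            is_target = bool(membership[group, tgt_col])
            mu = sm.mu_target if is_target else sm.mu_nontarget
            var = sm.var_target if is_target else sm.var_nontarget
            flat = (mu / norm2) * w
            noise_scale = np.sqrt(var) / norm
            if noise_scale > 0:
                flat = flat + noise_scale * rng.standard_normal(w.shape)
            epochs.append(
                EpochFeatures(values=flat.reshape(shape), label=int(is_target))
            )
            groups.append(int(group))
            char_indices.append(char_idx)
    return EpochSession(
        epochs=epochs,
        groups=np.array(groups, dtype=int),
        character_indices=np.array(char_indices, dtype=int),
        target_text=config.target_text,
    )
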