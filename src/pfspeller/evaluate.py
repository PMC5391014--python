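"""Performance metrics, threshold sweeps, cross-validation, and the published
subject tables.

Speller performance is summarized by four session metrics: selection
accuracy (fraction of output characters matching the target, which is cycled
if the subject finished the phrase and started over), selection rate (SR,
selections per minute), correctly-selected characters per minute (CCPM,
which discards wrong selections), and the Wolpaw information transfer rate
ITR = SR * [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))] for N choices at
accuracy P.

The module also ships the per-subject offline (three-fold cross-validated)
and online result tables from the underlying speller study as plain-text
fixtures, with helpers that recompute their column averages, ITRs, and
famous-faces-vs-inverting percent improvements.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridLayout, TimingModel, selection_time_seconds
from .language import LanguageModel
from .pfilter import (
    DecodeResult,
    DecoderConfig,
    ScoreStream,
    decode_sequence,
)
from .simulate import EpochSession
from .swlda import (
    EpochFeatures,
    ScoreModel,
    fit_score_model,
    fit_swlda,
    score_epochs,
)

GRID_CHOICES = 36  # N in the Wolpaw ITR for a 6x6 grid


@dataclass
class SessionMetrics:
    selection_rate: float  # selections/min
    accuracy: float  # fraction in [0, 1]
    ccpm: float  # correct characters/min
    bit_rate: float  # bits/min
    n_selections: int
    total_time: float  # seconds

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def accuracy(output: str, target: str, cycle: bool = True) -> float:
    """Fraction of output positions matching the target string.

    With ``cycle`` (default) position ``i`` is compared to
    ``target[i mod len(target)]``, covering subjects who finished the phrase
    and repeated it.
    """
    if not output:
        raise ValueError("empty output string")
    if not target:
        raise ValueError("empty target string")
    if cycle:
        matches = sum(o == target[i % len(target)] for i, o in enumerate(output))
    else:
        matches = sum(o == t for o, t in zip(output, target))
    return matches / len(output)


def selection_rate(n_selections: int, total_time: float) -> float:
    """Selections per minute."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return 60.0 * n_selections / total_time


def ccpm(n_correct: int, total_time: float) -> float:
    """Correctly selected characters per minute."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    return 60.0 * n_correct / total_time


def wolpaw_bits_per_selection(p: float, n_choices: int = GRID_CHOICES) -> float:
    """Bits per selection at accuracy ``p`` among ``n_choices`` options."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    if n_choices < 2:
        raise ValueError("n_choices must be >= 2")
    bits = np.log2(n_choices)
    if p > 0.0:
        bits += p * np.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * np.log2((1.0 - p) / (n_choices - 1))
    return float(bits)


def wolpaw_bit_rate(
    selection_rate: float, accuracy: float, n_choices: int = GRID_CHOICES
) -> float:
    """Wolpaw ITR in bits/min."""
    return selection_rate * wolpaw_bits_per_selection(accuracy, n_choices)


def session_metrics(
    result: DecodeResult,
    target: str,
    timing: TimingModel | None = None,
    cycle: bool = True,
) -> SessionMetrics:
    """Metrics of one decoded session against its target text."""
    timing = timing or TimingModel()
    total_time = sum(
        selection_time_seconds(n, timing) for n in result.flash_counts
    )
    acc = accuracy(result.output, target, cycle=cycle)
    n_sel = len(result.output)
    n_correct = int(round(acc * n_sel))
    sr = selection_rate(n_sel, total_time)
    return SessionMetrics(
        selection_rate=sr,
        accuracy=acc,
        ccpm=ccpm(n_correct, total_time),
        bit_rate=wolpaw_bit_rate(sr, acc),
        n_selections=n_sel,
        total_time=total_time,
    )


# ---------------------------------------------------------------------------
# Threshold sweep and offline cross-validation
# ---------------------------------------------------------------------------

def default_threshold_grid() -> np.ndarray:
    """Thresholds 0.00, 0.01, ..., 1.00 (101 values)."""
    return np.round(np.linspace(0.0, 1.0, 101), 2)


def threshold_sweep(
    sessions: list[ScoreStream],
    score_model: ScoreModel,
    model: LanguageModel,
    config: DecoderConfig | None = None,
    thresholds: np.ndarray | None = None,
    timing: TimingModel | None = None,
    grid: GridLayout | None = None,
) -> tuple[pd.DataFrame, float]:
    """Replay the sessions at every threshold; pick the CCPM-maximizing one.

    Returns a per-threshold table of averaged metrics and the argmax
    threshold (ties resolved toward the lower threshold).
    """
    config = config or DecoderConfig()
    thresholds = default_threshold_grid() if thresholds is None else np.asarray(
        thresholds, dtype=float
    )
    if np.any(thresholds < 0) or np.any(thresholds > 1):
        raise ValueError("thresholds must lie in [0, 1]")
    records = []
    for thr in thresholds:
        cfg = DecoderConfig(
            threshold=float(thr),
            max_flashes=config.max_flashes,
            min_flashes=config.min_flashes,
            n_particles=config.n_particles,
            seed=config.seed,
            smoothing_floor=config.smoothing_floor,
            hard_commit=config.hard_commit,
        )
        per_session = []
        for session in sessions:
            if session.target_text is None:
                raise ValueError("threshold sweep needs ground-truth targets")
            result = decode_sequence(session, score_model, model, cfg, grid=grid)
            per_session.append(
                session_metrics(result, session.target_text, timing=timing)
            )
        records.append(
            {
                "threshold": float(thr),
                "selection_rate": np.mean([m.selection_rate for m in per_session]),
                "accuracy": np.mean([m.accuracy for m in per_session]),
                "ccpm": np.mean([m.ccpm for m in per_session]),
                "bit_rate": np.mean([m.bit_rate for m in per_session]),
            }
        )
    table = pd.DataFrame.from_records(records)
    best = float(table.loc[table["ccpm"].idxmax(), "threshold"])  # first max
    return table, best


def _epoch_session_to_stream(
    session: EpochSession, weights, timing: TimingModel
) -> ScoreStream:
    scores = score_epochs(session.epochs, weights)
    frame = pd.DataFrame(
        {
            "character_index": session.character_indices,
            "flash_index": np.concatenate(
                [
                    np.arange(np.sum(session.character_indices == c))
                    for c in np.unique(session.character_indices)
                ]
            ),
            "group": session.groups,
            "score": scores,
        }
    )
    frame["timestamp_ms"] = np.arange(len(frame)) * timing.soa_ms
    return ScoreStream(frame=frame, target_text=session.target_text)


def crossfold_offline(
    sessions: list[EpochSession],
    model: LanguageModel,
    config: DecoderConfig | None = None,
    timing: TimingModel | None = None,
    grid: GridLayout | None = None,
    **swlda_kwargs,
) -> tuple[SessionMetrics, list[SessionMetrics]]:
    """Three-fold cross-validation over training sessions.

    Each fold trains the stepwise feature selector and score model on two
    sessions and decodes the held-out one; returns the fold-averaged metrics
    and the per-fold values.
    """
    if len(sessions) != 3:
        raise ValueError("offline cross-validation uses exactly 3 sessions")
    config = config or DecoderConfig()
    timing = timing or TimingModel()
    fold_metrics: list[SessionMetrics] = []
    for held in range(3):
        train = [s for i, s in enumerate(sessions) if i != held]
        train_epochs: list[EpochFeatures] = [e for s in train for e in s.epochs]
        weights = fit_swlda(train_epochs, **swlda_kwargs)
        scores = score_epochs(train_epochs, weights)
        labels = np.array([e.label for e in train_epochs])
        score_model = fit_score_model(scores, labels)
        stream = _epoch_session_to_stream(sessions[held], weights, timing)
        result = decode_sequence(stream, score_model, model, config, grid=grid)
        fold_metrics.append(
            session_metrics(result, sessions[held].target_text, timing=timing)
        )
    avg = SessionMetrics(
        selection_rate=float(np.mean([m.selection_rate for m in fold_metrics])),
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        ccpm=float(np.mean([m.ccpm for m in fold_metrics])),
        bit_rate=float(np.mean([m.bit_rate for m in fold_metrics])),
        n_selections=int(sum(m.n_selections for m in fold_metrics)),
        total_time=float(sum(m.total_time for m in fold_metrics)),
    )
    return avg, fold_metrics


# ---------------------------------------------------------------------------
# Published subject tables
# ---------------------------------------------------------------------------

def _load_fixture(name: str, include_average: bool) -> pd.DataFrame:
    with resources.files("pfspeller.data").joinpath(name).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    if not include_average:
        table = table[table["subject"] != "Average"].reset_index(drop=True)
    return table


def load_offline_table(include_average: bool = False) -> pd.DataFrame:
    """Offline (cross-validated, dynamic stopping) results per subject.

    The fixture mirrors the published table; the printed Average row is
    excluded unless ``include_average`` is set.
    """
    return _load_fixture("table1_offline.tsv", include_average)


def load_online_table(include_average: bool = False) -> pd.DataFrame:
    """Online (0.95 threshold) results per subject; see load_offline_table."""
    return _load_fixture("table2_online.tsv", include_average)


def printed_averages(table: pd.DataFrame) -> pd.Series:
    """The Average row as printed (requires a table loaded with it)."""
    rows = table[table["subject"] == "Average"]
    if len(rows) != 1:
        raise ValueError("table carries no printed Average row")
    return rows.iloc[0].drop("subject").astype(float)


def summarize_table(table: pd.DataFrame) -> pd.Series:
    """Arithmetic column means rounded to 2 decimals, as printed.

    Operates on the subject rows only; any printed Average row is ignored.
    Note that averaging values already rounded to 2 decimals can differ from
    a published mean of unrounded data by one unit in the last digit.
    """
    subjects = table[table["subject"] != "Average"]
    numeric = subjects.select_dtypes("number")
    if numeric.isna().any().any() or numeric.empty:
        raise ValueError("table has missing cells")
    return numeric.mean().round(2)


def percent_change(new: float, old: float, decimals: int = 1) -> float:
    """(new - old) / old x 100, rounded."""
    return round((new - old) / old * 100.0, decimals)


def percent_improvement(
    table: pd.DataFrame,
    new_col: str,
    old_col: str,
    rounded_means: bool = False,
    decimals: int = 1,
) -> float:
    """(new - old) / old x 100 on the column means, to ``decimals`` places.

    With ``rounded_means`` the means are first rounded to the 2-decimal
    precision of the printed Average row.  The published improvements are
    sensitive to this choice at the first decimal (e.g. the selection-rate
    improvement is 32.0% from unrounded means but 32.1% from rounded ones),
    so both conventions are exposed.
    """
    subjects = table[table["subject"] != "Average"]
    new = subjects[new_col].mean()
    old = subjects[old_col].mean()
    if rounded_means:
        new, old = round(new, 2), round(old, 2)
    return round((new - old) / old * 100.0, decimals)


def table_itr(
    table: pd.DataFrame, sr_col: str, acc_col: str, n_choices: int = GRID_CHOICES
) -> tuple[pd.Series, float]:
    """Per-subject Wolpaw ITRs from a (SR, ACC%) column pair, plus the
    2-decimal average."""
    subjects = table[table["subject"] != "Average"]
    rates = pd.Series(
        [
            wolpaw_bit_rate(sr, acc / 100.0, n_choices)
            for sr, acc in zip(subjects[sr_col], subjects[acc_col])
        ],
        index=subjects.index,
        name=f"itr_{sr_col}",
    )
    return rates, round(float(rates.mean()), 2)


def paired_wilcoxon(table: pd.DataFrame, col_a: str, col_b: str) -> float:
    """Wilcoxon signed-rank p-value between two paired subject columns.

    Convenience only: exact p-values depend on tie/zero handling conventions.
    """
    subjects = table[table["subject"] != "Average"]
    return float(stats.wilcoxon(subjects[col_a], subjects[col_b]).pvalue)
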