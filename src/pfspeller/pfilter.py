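"""Particle-filter decoding of stimulus-score streams.

Each particle is one hypothesis of the full typed string.  At the start of a
character period every particle extends its history by one character sampled
from the language model's transition distribution (the proposal).  Each flash
then multiplies a particle's weight by the Gaussian score likelihood — the
target-class density if the flashed row/column contains the particle's
current character, the non-target density otherwise — and the weights are
renormalized.  The posterior probability of a character is the summed weight
of particles ending in it.  Flashing stops as soon as some character's
posterior reaches a threshold (after at least one full sequence) or at the
flash cap; the population is then resampled proportional to weight and the
next character begins.

Weights are accumulated in the log domain: a character period can multiply up
to 120 densities, which underflows in linear space.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

from .grid import GridLayout
from .language import LanguageModel, transition_probabilities, word_fragment
from .swlda import ScoreModel

#: Dynamic-stopping defaults: 0.95 posterior threshold, 120-flash cap,
#: and no decision before one full 12-flash sequence.
DEFAULT_THRESHOLD = 0.95
DEFAULT_MAX_FLASHES = 120
DEFAULT_MIN_FLASHES = 12
DEFAULT_N_PARTICLES = 1000


class StreamExhaustedError(RuntimeError):
    """A flash stream ended before a legal stopping point was reached."""


class WeightUnderflowError(FloatingPointError):
    """All particle weights vanished; the likelihood model is degenerate."""


@dataclass(frozen=True)
class FlashEvent:
    """One stimulus: which of the 12 groups flashed, and its epoch score."""

    group: int
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.group < 12:
            raise ValueError("flash group index must lie in [0, 12)")


@dataclass
class CharacterPosterior:
    """Posterior over grid characters for the current selection."""

    probabilities: np.ndarray
    characters: str

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be a probability distribution")
        self.probabilities = p

    def top_character(self) -> str:
        # np.argmax returns the first maximum: ties break in grid order
        return self.characters[int(np.argmax(self.probabilities))]


class ParticleSet:
    """P weighted string hypotheses plus the decoder's random streams.

    A single master seed fans out to independent proposal and resampling
    generators so runs are reproducible.
    """

    def __init__(self, histories: list[str], log_weights: np.ndarray, seed: int):
        if len(histories) != len(log_weights):
            raise ValueError("one weight per particle required")
        self.histories = histories
        self.log_weights = np.asarray(log_weights, dtype=float)
        master = np.random.SeedSequence(seed)
        prop_seq, res_seq = master.spawn(2)
        self.proposal_rng = np.random.default_rng(prop_seq)
        self.resample_rng = np.random.default_rng(res_seq)
        self.last_idx = np.full(len(histories), -1, dtype=int)

    @property
    def n_particles(self) -> int:
        return len(self.histories)

    def normalized_weights(self) -> np.ndarray:
        total = logsumexp(self.log_weights)
        if not np.isfinite(total):
            raise WeightUnderflowError("all particle weights are zero")
        return np.exp(self.log_weights - total)


def initialize_particles(n_particles: int, seed: int) -> ParticleSet:
    """P particles with empty histories and weight 1/P each."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    return ParticleSet(
        histories=[""] * n_particles,
        log_weights=np.full(n_particles, -np.log(n_particles)),
        seed=seed,
    )


def propose_next_character(
    particles: ParticleSet, model: LanguageModel
) -> ParticleSet:
    """Extend every particle by one character drawn from the language model.

    The proposal conditions on each particle's current word fragment;
    particles sharing a fragment share one transition distribution, so
    sampling is grouped by unique fragment.  Weights are unchanged.
    """
    fragments: dict[str, list[int]] = {}
    for j, hist in enumerate(particles.histories):
        fragments.setdefault(word_fragment(hist), []).append(j)
    vocab = model.vocabulary
    n = len(vocab)
    for fragment, idx in fragments.items():
        probs = transition_probabilities(model, fragment)
        draws = particles.proposal_rng.choice(n, size=len(idx), p=probs)
        for j, d in zip(idx, draws):
            particles.histories[j] += vocab[d]
            particles.last_idx[j] = d
    return particles


def _log_density(score: float, mu: float, var: float) -> float:
    return -0.5 * np.log(2.0 * np.pi * var) - (score - mu) ** 2 / (2.0 * var)


def update_weights(
    particles: ParticleSet,
    flash: FlashEvent,
    score_model: ScoreModel,
    grid: GridLayout,
) -> ParticleSet:
    """Multiply each weight by the flash likelihood and renormalize.

    A particle whose current character lies in the flashed group takes the
    target-class density; all others take the non-target density.
    """
    if np.any(particles.last_idx < 0):
        raise ValueError("particles carry no current-character hypothesis")
    if score_model.var_target <= 0 or score_model.var_nontarget <= 0:
        raise ValueError("decoding requires strictly positive score variances")
    in_group = grid.membership_matrix()[flash.group][particles.last_idx]
    log_fa = _log_density(flash.score, score_model.mu_target, score_model.var_target)
    log_fn = _log_density(
        flash.score, score_model.mu_nontarget, score_model.var_nontarget
    )
    particles.log_weights = particles.log_weights + np.where(in_group, log_fa, log_fn)
    total = logsumexp(particles.log_weights)
    if not np.isfinite(total):
        raise WeightUnderflowError("all particle weights underflowed to zero")
    particles.log_weights -= total
    return particles


def character_posterior(
    particles: ParticleSet, grid: GridLayout
) -> CharacterPosterior:
    """Sum normalized weights of particles ending in each grid character."""
    if np.any(particles.last_idx < 0):
        raise ValueError("particles have empty histories")
    w = particles.normalized_weights()
    probs = np.bincount(
        particles.last_idx, weights=w, minlength=len(grid.characters)
    )
    return CharacterPosterior(probabilities=probs, characters=grid.characters)


def resample(particles: ParticleSet) -> ParticleSet:
    """Systematic resampling proportional to weight; weights reset to 1/P.

    A single uniform offset stratifies the unit interval into P cells, so a
    particle of weight w survives either floor(P*w) or ceil(P*w) times.
    """
    w = particles.normalized_weights()
    P = particles.n_particles
    positions = (np.arange(P) + particles.resample_rng.random()) / P
    idx = np.searchsorted(np.cumsum(w), positions, side="right")
    idx = np.minimum(idx, P - 1)
    particles.histories = [particles.histories[i] for i in idx]
    particles.last_idx = particles.last_idx[idx]
    particles.log_weights = np.full(P, -np.log(P))
    return particles


def decode_character(
    flash_stream: Iterable[FlashEvent],
    particles: ParticleSet,
    score_model: ScoreModel,
    model: LanguageModel,
    grid: GridLayout,
    threshold: float = DEFAULT_THRESHOLD,
    max_flashes: int = DEFAULT_MAX_FLASHES,
    min_flashes: int = DEFAULT_MIN_FLASHES,
    resample_after: bool = True,
) -> tuple[str, int, list[CharacterPosterior]]:
    """Consume flashes until the dynamic-stopping rule fires; select a character.

    Stops at the first flash (no earlier than ``min_flashes``) at which some
    character's posterior reaches ``threshold``, or at ``max_flashes``.
    Returns the argmax character (grid-order ties), the number of flashes
    consumed, and the per-flash posterior trace.  The population is resampled
    after the selection; callers that display a single committed string
    collapse the histories afterwards (see :func:`decode_sequence`).

    Raises
    ------
    StreamExhaustedError
        If the stream ends before a legal stopping point.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if max_flashes < min_flashes:
        raise ValueError("max_flashes must be >= the minimum flash count")
    trace: list[CharacterPosterior] = []
    n_flashes = 0
    stopped = False
    for flash in flash_stream:
        update_weights(particles, flash, score_model, grid)
        posterior = character_posterior(particles, grid)
        trace.append(posterior)
        n_flashes += 1
        if n_flashes >= max_flashes:
            stopped = True
            break
        if n_flashes >= min_flashes and posterior.probabilities.max() >= threshold:
            stopped = True
            break
    if not stopped:
        raise StreamExhaustedError(
            f"flash stream ended after {n_flashes} flashes, before the "
            f"threshold was reached or the {max_flashes}-flash cap was hit"
        )
    selected = trace[-1].top_character()
    if resample_after:
        resample(particles)
    return selected, n_flashes, trace


# ---------------------------------------------------------------------------
# Score streams and decoder configuration
# ---------------------------------------------------------------------------

SCORE_STREAM_COLUMNS = ["character_index", "flash_index", "group", "score",
                        "timestamp_ms"]


@dataclass
class ScoreStream:
    """A session's flash-annotated scores, plus ground truth when simulated."""

    frame: pd.DataFrame
    target_text: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_STREAM_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"score stream missing columns: {missing}")

    @property
    def n_characters(self) -> int:
        return int(self.frame["character_index"].nunique())

    def character_flashes(self, character_index: int) -> Iterator[FlashEvent]:
        sub = self.frame[self.frame["character_index"] == character_index]
        sub = sub.sort_values("flash_index")
        for group, score in zip(sub["group"], sub["score"]):
            yield FlashEvent(group=int(group), score=float(score))


def write_score_stream(stream: ScoreStream, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pfspeller-scores\t1\n")
        if stream.target_text is not None:
            fh.write(f"# target\t{stream.target_text}\n")
        stream.frame.to_csv(fh, sep="\t", index=False)


def read_score_stream(path: str) -> ScoreStream:
    target = None
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        parts = line[1:].strip("\n").strip().split("\t")
        if parts[0] == "target":
            target = parts[1] if len(parts) > 1 else ""
    frame = pd.read_csv(io.StringIO("".join(lines[body_start:])), sep="\t")
    return ScoreStream(frame=frame, target_text=target)


@dataclass
class DecoderConfig:
    """Scalar decoding parameters (see module docstring for semantics)."""

    threshold: float = DEFAULT_THRESHOLD
    max_flashes: int = DEFAULT_MAX_FLASHES
    min_flashes: int = DEFAULT_MIN_FLASHES
    n_particles: int = DEFAULT_N_PARTICLES
    seed: int = 0
    smoothing_floor: float = 0.05
    hard_commit: bool = True

    @classmethod
    def from_file(cls, path: str) -> "DecoderConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown decoder-config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )


@dataclass
class DecodeResult:
    output: str
    flash_counts: list[int]
    traces: list[list[CharacterPosterior]]


def decode_sequence(
    session: ScoreStream,
    score_model: ScoreModel,
    model: LanguageModel,
    config: DecoderConfig | None = None,
    grid: GridLayout | None = None,
) -> DecodeResult:
    """Decode every character period of a session's score stream.

    Loops propose → decode_character → resample over the session's character
    periods.  With ``hard_commit`` (default) the particle histories are
    collapsed onto the displayed output string after each selection, so the
    speller shows a single committed string; otherwise resampling alone
    concentrates the population on high-weight histories.
    """
    config = config or DecoderConfig()
    grid = grid or GridLayout()
    if grid.characters != model.vocabulary:
        raise ValueError("grid characters and language-model vocabulary differ")
    particles = initialize_particles(config.n_particles, config.seed)
    output = ""
    flash_counts: list[int] = []
    traces: list[list[CharacterPosterior]] = []
    for char_idx in sorted(session.frame["character_index"].unique()):
        propose_next_character(particles, model)
        selected, used, trace = decode_character(
            session.character_flashes(int(char_idx)),
            particles,
            score_model,
            model,
            grid,
            threshold=config.threshold,
            max_flashes=config.max_flashes,
            min_flashes=config.min_flashes,
        )
        output += selected
        flash_counts.append(used)
        traces.append(trace)
        if config.hard_commit:
            particles.histories = [output] * particles.n_particles
            particles.last_idx = np.full(
                particles.n_particles, grid.char_index(selected), dtype=int
            )
    return DecodeResult(output=output, flash_counts=flash_counts, traces=traces)
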