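# Methods

## The decoding model

A speller session is a sequence of character periods. Within a period the
6 rows and 6 columns of the character grid flash in random order (one
permutation of the 12 groups per *sequence*), with a stimulus onset
asynchrony of 125 ms (100 ms flash + 25 ms gap). Each flash i yields a
scalar score yᵢ — the dot product of the SWLDA-selected feature weights
with the post-stimulus EEG epoch — modeled as

    yᵢ ~ N(μₐ, σₐ²)   if the flashed group contains the attended character,
    yᵢ ~ N(μₙ, σₙ²)   otherwise,

with scores conditionally independent across flashes given the target.
The typed string x₀:ₜ is given a prior by a word-prefix count language
model, p(xₜ | x₀:ₜ₋₁) = c(x₀…xₜ)/c(x₀…xₜ₋₁), where c(s) counts corpus words
beginning with s. Decoding maintains the posterior over strings with a
particle filter: particles propose their next character from the language
model, are reweighted by each flash's class-conditional density (log-domain
accumulation with normalization after every flash — a character period can
multiply up to 120 densities, which underflows in linear space), and are
systematically resampled after each selection. The posterior of a character
is the summed weight of particles ending in it; flashing stops when that
posterior reaches a threshold or at a flash cap.

## Word-boundary semantics

The prefix counts are defined over words, so the proposal conditions only
on the fragment of the current word: history resets after a separator, and
the separator's own probability after fragment s is the fraction of
s-prefixed words that are exactly s (completed words). Corpus normalization
uppercases the text and treats any non-vocabulary character as a word
boundary. An unseen fragment falls back to the exact uniform distribution.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| grid | A–Z, 1–9, space (row-major 6×6) | the vocabulary must contain the separator, so the 36th cell is the space rather than a zero digit |
| smoothing floor | 0.05 total mass | mixed uniformly over the 36 characters so no character is unreachable regardless of corpus; the count model itself is otherwise unsmoothed |
| SWLDA p-enter / p-remove / max features | 0.10 / 0.15 / 60 | conventional stepwise settings; ties in the forward step break toward the lowest feature index for reproducibility |
| epoch preprocessing | 600 ms, 32 channels, block-mean decimation ×12 | 256 Hz → ~21 Hz; block means equal a decimated moving average and keep the stepwise design tractable |
| score-model variance | unbiased (n−1) estimator | |
| particles P | 1000 (oracle tests use 50 000) | |
| stopping threshold / cap / minimum | 0.95 / 120 flashes / 12 flashes | the minimum of one full sequence prevents a decision driven by the prior alone; threshold 0 therefore stops at exactly 12 flashes |
| resampling | systematic, after each selection | minimizes resampling variance; weights are recomputed after every flash but the population is only resampled per selection |
| history commitment | hard-commit on | after a selection all histories collapse onto the displayed output; without it resampling alone concentrates the population |
| timing | no inter-character pause | configurable; selection time = flashes × 0.125 s + pause |
| simulator separation | (μₐ−μₙ)/σ = 1.2 | calibration so simulated accuracy/SR land in the observed healthy-subject range; not a measured effect size |

Seeds: one master seed fans out (via `SeedSequence.spawn`) to independent
proposal and resampling streams; the simulator uses its own seed. Identical
seeds give identical sessions and decodes.

## What the simulator does and does not emulate

It reproduces the paradigm's structure — randomized 12-group schedules, two
target flashes per sequence, SOA timing, Gaussian class-conditional scores,
and (for classifier training) feature epochs whose projection through a
given weight vector has the configured score distributions (class mean
injected along the weight direction, per-class isotropic noise). It does
not synthesize raw EEG waveforms, ERP component shapes, overlap/refractory
effects between consecutive flashes, artifacts, or non-stationarity; a
stronger stimulus paradigm (e.g. face overlays vs. inversion) appears only
as a larger class separation. Passing simulation tests therefore validate
the decoding mathematics and its implementation, not robustness to real
EEG noise structure.

## Evaluation conventions

- Accuracy compares output position i against target[i mod len(target)],
  covering subjects who finished their phrase and repeated it (configurable).
- ITR uses the Wolpaw formula with N = 36; the p→0 and p→1 limits are
  handled by continuity.
- The threshold sweep replays a session at thresholds 0.00–1.00 in steps of
  0.01 and reports the CCPM-maximizing threshold (ties toward the lower
  threshold).
- Three-fold cross-validation treats each training session as a fold:
  stepwise weights and the score model are fit on two sessions, the third
  is scored and decoded.
- The packaged subject tables mirror the published offline and online
  results including their printed Average rows. Averaging the printed
  (2-decimal) per-subject values reproduces 14 of the 15 printed averages
  exactly; the online inverting CCPM mean comes out 7.34 against a printed
  7.33 because the published mean was taken over unrounded data, and
  rounding ten addends can shift the mean by up to half a printed unit.
  The printed percent improvements mix conventions: the selection-rate
  improvement (32.0%) arises from unrounded column means, the CCPM
  improvement (44.1%) from the printed rounded averages, and the ITR
  improvement (54.4%) from 2-decimal ITR averages; the package exposes both
  conventions (`percent_improvement(..., rounded_means=...)`,
  `printed_averages`) rather than privileging one.

## Numerical and degenerate-input choices

- Argmax ties in character selection break in grid (row-major) order.
- All-zero weights raise a `WeightUnderflowError` rather than renormalizing
  silently; log-domain accumulation makes this unreachable for finite
  scores and positive variances.
- Zero score variances are accepted as *generating* parameters (noise-free
  simulation) but rejected by the decoding likelihood and by the
  score-model fit.
- A flash stream that ends before the threshold or cap is reached raises
  `StreamExhaustedError`; replayed sessions should carry the full schedule.
- Stepwise selection skips constant feature columns and rejects designs in
  which every feature is constant.

## Test problem sizes

The exact-inference check runs on a 2×2 grid with a 4-character vocabulary
and 3-character strings, where the string posterior can be enumerated; with
50 000 particles the total-variation distance to enumeration is required to
be < 0.01 (observed ≈ 2.5×10⁻⁴). Mechanism checks (threshold monotonicity,
language-model benefit) use 20 paired simulation runs of a 20-character
in-corpus text at separation 1.2 with 300 particles — sizes chosen so the
full suite runs in well under a minute of simulation time while keeping
Monte-Carlo error far below the tested effects.

## Known limitations

- The underlying study's corpus is not identified, so absolute language-model
  probabilities (and thus absolute speeds on real data) are not
  reproducible; only the mechanism is. The packaged default corpus is a
  small public-domain English text.
- Subject-level selection rates and accuracies require the original EEG
  recordings, which are not deposited; they enter only as fixture tables.
- No artifact rejection, channel selection, spatial filtering, raw-EEG file
  formats, or alternative classifiers (HMM/POMDP) are provided.
- Whether the original online system enforced a minimum flash count or
  resampled within a character period is not documented; this
  implementation resamples per selection and enforces a one-sequence
  minimum, both configurable.
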