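"""Particle proposal, weighting, resampling, and dynamic-stopping decoding."""

import numpy as np
import pytest

from pfspeller import (
    DecoderConfig,
    FlashEvent,
    ScoreModel,
    StreamExhaustedError,
    build_language_model,
    character_posterior,
    decode_character,
    decode_sequence,
    initialize_particles,
    propose_next_character,
    resample,
    simulate_session,
    uniform_language_model,
    update_weights,
    SimulationConfig,
)


def _informative_model(mu=2.0):
    return ScoreModel(mu_target=mu, var_target=1.0, mu_nontarget=0.0,
                      var_nontarget=1.0)


class TestInitialize:
    def test_uniform_weights(self):
        particles = initialize_particles(4, seed=0)
        np.testing.assert_allclose(particles.normalized_weights(), 0.25)
        assert particles.histories == [""] * 4

    def test_single_particle(self):
        particles = initialize_particles(1, seed=0)
        np.testing.assert_allclose(particles.normalized_weights(), [1.0])

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            initialize_particles(0, seed=0)

    def test_seed_reproducibility(self, tiny_model):
        runs = []
        for _ in range(2):
            particles = initialize_particles(50, seed=123)
            propose_next_character(particles, tiny_model)
            runs.append(list(particles.histories))
        assert runs[0] == runs[1]


class TestPropose:
    def test_deterministic_proposal(self):
        model = build_language_model("A A A", smoothing_floor=0.0)
        particles = initialize_particles(20, seed=0)
        propose_next_character(particles, model)
        assert all(h == "A" for h in particles.histories)

    def test_history_conditioning(self, tiny_model):
        particles = initialize_particles(30, seed=0)
        particles.histories = ["T"] * 30
        propose_next_character(particles, tiny_model)
        assert all(h == "TH" for h in particles.histories)

    def test_uniform_sampling_fractions(self):
        from scipy import stats

        model = uniform_language_model()
        particles = initialize_particles(10000, seed=42)
        propose_next_character(particles, model)
        counts = np.bincount(particles.last_idx, minlength=36)
        # goodness of fit against the uniform proposal (accounts for the
        # 36-way multiple comparison a per-bin z-test would ignore)
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_weights_unchanged(self, tiny_model):
        particles = initialize_particles(10, seed=0)
        before = particles.log_weights.copy()
        propose_next_character(particles, tiny_model)
        np.testing.assert_array_equal(particles.log_weights, before)


class TestUpdateWeights:
    def _particles_on(self, grid, chars, seed=0):
        particles = initialize_particles(len(chars), seed=seed)
        particles.histories = list(chars)
        particles.last_idx = np.array([grid.char_index(c) for c in chars])
        return particles

    def test_uninformative_likelihood_leaves_weights(self, grid):
        particles = self._particles_on(grid, ["A", "B", "C"])
        sm = ScoreModel(0.0, 1.0, 0.0, 1.0)
        update_weights(particles, FlashEvent(group=0, score=0.7), sm, grid)
        np.testing.assert_allclose(particles.normalized_weights(), 1 / 3)

    def test_gaussian_density_ratio(self, grid):
        # A in row 0, B ('B' is index 1) also row 0 — pick chars in different
        # rows: A (row 0) and G (row 1).
        particles = self._particles_on(grid, ["A", "G"])
        sm = ScoreModel(mu_target=2.0, var_target=1.0, mu_nontarget=0.0,
                        var_nontarget=1.0)
        row_a, _ = grid.groups_of("A")
        update_weights(
            particles, FlashEvent(group=row_a, score=2.0), sm, grid
        )
        w = particles.normalized_weights()
        # density ratio N(2;2,1)/N(2;0,1) = exp(2)
        assert w[0] / w[1] == pytest.approx(np.exp(2.0))

    def test_shared_group_factor_cancels(self, grid):
        # A and B share row 0: a row-0 flash multiplies both by the same factor
        particles = self._particles_on(grid, ["A", "B"])
        particles.log_weights = np.log([0.8, 0.2])
        update_weights(
            particles, FlashEvent(group=0, score=1.3), _informative_model(), grid
        )
        np.testing.assert_allclose(
            particles.normalized_weights(), [0.8, 0.2], atol=1e-12
        )

    def test_missing_hypothesis_rejected(self, grid):
        particles = initialize_particles(3, seed=0)
        with pytest.raises(ValueError, match="hypothesis"):
            update_weights(
                particles, FlashEvent(group=0, score=0.0),
                _informative_model(), grid,
            )


class TestCharacterPosterior:
    def test_sums_weights_by_final_character(self, grid):
        particles = initialize_particles(2, seed=0)
        particles.histories = ["XA", "XB"]
        particles.last_idx = np.array(
            [grid.char_index("A"), grid.char_index("B")]
        )
        particles.log_weights = np.log([0.6, 0.4])
        post = character_posterior(particles, grid)
        assert post.probabilities[grid.char_index("A")] == pytest.approx(0.6)
        assert post.probabilities[grid.char_index("B")] == pytest.approx(0.4)
        assert post.top_character() == "A"

    def test_degenerate_population(self, grid):
        particles = initialize_particles(5, seed=0)
        particles.histories = ["Q"] * 5
        particles.last_idx = np.full(5, grid.char_index("Q"))
        post = character_posterior(particles, grid)
        assert post.probabilities[grid.char_index("Q")] == pytest.approx(1.0)

    def test_unnormalized_equal_weights_give_uniform(self, grid):
        particles = initialize_particles(4, seed=0)
        particles.histories = ["A", "B", "C", "D"]
        particles.last_idx = np.arange(4)
        particles.log_weights = np.full(4, 3.7)  # equal but unnormalized
        post = character_posterior(particles, grid)
        np.testing.assert_allclose(post.probabilities[:4], 0.25)

    def test_empty_history_rejected(self, grid):
        with pytest.raises(ValueError, match="empty"):
            character_posterior(initialize_particles(3, seed=0), grid)


class TestResample:
    def test_degenerate_weight_takes_over(self):
        particles = initialize_particles(8, seed=0)
        particles.histories = [f"H{i}" for i in range(8)]
        particles.last_idx = np.arange(8)
        lw = np.full(8, -np.inf)
        lw[3] = 0.0
        particles.log_weights = lw
        resample(particles)
        assert particles.histories == ["H3"] * 8
        np.testing.assert_allclose(particles.normalized_weights(), 1 / 8)

    def test_systematic_multiplicity_bounds(self):
        rng = np.random.default_rng(9)
        particles = initialize_particles(100, seed=1)
        particles.histories = [f"H{i}" for i in range(100)]
        particles.last_idx = np.arange(100) % 36
        w = rng.dirichlet(np.ones(100))
        particles.log_weights = np.log(w)
        resample(particles)
        counts = {}
        for h in particles.histories:
            counts[h] = counts.get(h, 0) + 1
        for i in range(100):
            n = counts.get(f"H{i}", 0)
            assert np.floor(100 * w[i]) <= n <= np.ceil(100 * w[i])

    def test_exact_survivor_fractions(self):
        particles = initialize_particles(10000, seed=2)
        particles.histories = ["A"] * 5000 + ["B"] * 5000
        particles.last_idx = np.array([0] * 5000 + [1] * 5000)
        lw = np.concatenate(
            [np.log(np.full(5000, 0.7 / 5000)), np.log(np.full(5000, 0.3 / 5000))]
        )
        particles.log_weights = lw
        resample(particles)
        assert particles.histories.count("A") == 7000
        assert particles.histories.count("B") == 3000

    def test_all_zero_weights_rejected(self):
        particles = initialize_particles(4, seed=0)
        particles.log_weights = np.full(4, -np.inf)
        with pytest.raises(FloatingPointError):
            resample(particles)


def _session_flashes(target, score_model, seed, n_sequences=10):
    config = SimulationConfig(
        target_text=target, score_model=score_model, seed=seed,
        n_sequences_max=n_sequences,
    )
    return simulate_session(config)


class TestDecodeCharacter:
    def test_high_snr_stops_at_minimum_with_correct_character(
        self, grid, tiny_model
    ):
        sharp = ScoreModel(1.0, 1e-6, 0.0, 1e-6)
        stream = _session_flashes("T", sharp, seed=3)
        particles = initialize_particles(400, seed=0)
        propose_next_character(particles, tiny_model)
        char, used, trace = decode_character(
            stream.character_flashes(0), particles, sharp, tiny_model, grid
        )
        assert char == "T"
        assert used == 12
        assert trace[-1].probabilities.max() >= 0.95

    def test_zero_information_runs_to_flash_cap(self, grid):
        flat = ScoreModel(0.0, 1.0, 0.0, 1.0)
        model = uniform_language_model()
        stream = _session_flashes("A", flat, seed=4)
        particles = initialize_particles(200, seed=1)
        propose_next_character(particles, model)
        char, used, _ = decode_character(
            stream.character_flashes(0), particles, flat, model, grid
        )
        assert used == 120

    def test_threshold_zero_stops_at_minimum(self, grid, tiny_model):
        sm = _informative_model()
        stream = _session_flashes("T", sm, seed=5)
        particles = initialize_particles(200, seed=2)
        propose_next_character(particles, tiny_model)
        _, used, _ = decode_character(
            stream.character_flashes(0), particles, sm, tiny_model, grid,
            threshold=0.0,
        )
        assert used == 12

    def test_exhausted_stream_raises(self, grid, tiny_model):
        sm = ScoreModel(0.0, 1.0, 0.0, 1.0)  # never reaches the threshold
        stream = _session_flashes("T", sm, seed=6, n_sequences=2)
        particles = initialize_particles(100, seed=3)
        propose_next_character(particles, tiny_model)
        with pytest.raises(StreamExhaustedError):
            decode_character(
                stream.character_flashes(0), particles, sm, tiny_model, grid
            )


class TestDecodeSequence:
    def test_high_snr_recovers_target(self, tiny_model):
        sm = _informative_model(3.0)
        stream = _session_flashes("THE CAT", sm, seed=7)
        result = decode_sequence(
            stream, sm, tiny_model, DecoderConfig(n_particles=500, seed=11)
        )
        assert result.output == "THE CAT"
        assert len(result.flash_counts) == 7

    def test_zero_snr_output_has_structural_length(self):
        flat = ScoreModel(0.0, 1.0, 0.0, 1.0)
        model = uniform_language_model()
        stream = _session_flashes("ABC", flat, seed=8)
        result = decode_sequence(
            stream, flat, model, DecoderConfig(n_particles=100, seed=12)
        )
        assert len(result.output) == 3
        assert all(n == 120 for n in result.flash_counts)

    def test_repeat_decode_is_deterministic(self, tiny_model):
        sm = _informative_model(1.0)
        stream = _session_flashes("THE", sm, seed=9)
        cfg = DecoderConfig(n_particles=300, seed=13)
        a = decode_sequence(stream, sm, tiny_model, cfg)
        b = decode_sequence(stream, sm, tiny_model, cfg)
        assert a.output == b.output
        assert a.flash_counts == b.flash_counts

    def test_weight_conservation_along_decode(self, grid, tiny_model):
        sm = _informative_model(1.5)
        stream = _session_flashes("THE", sm, seed=10)
        particles = initialize_particles(250, seed=14)
        for char_idx in range(3):
            propose_next_character(particles, tiny_model)
            for flash in stream.character_flashes(char_idx):
                update_weights(particles, flash, sm, grid)
                assert particles.normalized_weights().sum() == pytest.approx(1.0)
                assert abs(np.exp(particles.log_weights).sum() - 1.0) < 1e-9
            resample(particles)
            assert particles.n_particles == 250


def test_naive_bayes_closed_form_limit(grid):
    """With a uniform language model the posterior after n flashes matches the
    normalized product of per-flash Gaussian likelihoods."""
    model = uniform_language_model()
    sm = _informative_model(1.5)
    stream = _session_flashes("K", sm, seed=21)
    flashes = list(stream.character_flashes(0))[:24]
    particles = initialize_particles(50000, seed=15)
    propose_next_character(particles, model)
    for flash in flashes:
        update_weights(particles, flash, sm, grid)
    post = character_posterior(particles, grid).probabilities

    membership = grid.membership_matrix()
    log_lik = np.zeros(36)
    for flash in flashes:
        la = -0.5 * (flash.score - sm.mu_target) ** 2
        ln = -0.5 * (flash.score - sm.mu_nontarget) ** 2
        log_lik += np.where(membership[flash.group], la, ln)
    exact = np.exp(log_lik - log_lik.max())
    exact /= exact.sum()
    assert 0.5 * np.abs(post - exact).sum() < 0.03
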