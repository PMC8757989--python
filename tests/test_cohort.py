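"""Synthetic cohort generator: copula calibration, moment recovery,
score round-trip, error injection and determinism."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from welsh.cohort import (
    CohortConfig,
    ConfigError,
    ErrorProfile,
    StratumSpec,
    calibrate_rank_rho,
    config_weighted_means,
    generate_cohort,
    generate_stratum,
    inject_errors,
    reference_config,
    _score_decompositions,
)
from welsh.qc import ErrorKind, Status, detect_errors
from welsh.records import Education, Sex
from welsh.scoring import DEFAULT_TABLE, welsh_score


def _spec(**kw):
    base = dict(
        sex=Sex.MALE, education=Education.NONE, n=216,
        mwd_mean=351, mwd_sd=136, score_mean=47, score_sd=24, rho_target=0.576,
    )
    base.update(kw)
    return StratumSpec(**base)


class TestCopulaCalibration:
    def test_independence_maps_to_independence(self):
        assert calibrate_rank_rho(0.0) == 0.0

    def test_approaches_one_in_the_limit(self):
        assert calibrate_rank_rho(1 - 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_value_for_study_strongest_stratum(self):
        assert calibrate_rank_rho(0.576) == pytest.approx(2 * math.sin(math.pi * 0.576 / 6))

    def test_monte_carlo_spearman_hits_target(self):
        """A large bivariate-normal sample at the calibrated Pearson value
        has sample Spearman within +/-0.01 of the requested 0.576."""
        r = calibrate_rank_rho(0.576)
        rng = np.random.default_rng(2024)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=200_000)
        got = sps.spearmanr(z[:, 0], z[:, 1]).statistic
        assert abs(got - 0.576) < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            calibrate_rank_rho(1.0)


class TestScoreDecompositions:
    def test_every_attainable_score_back_solves(self):
        from welsh.scoring import achievable_scores

        decomp = _score_decompositions(DEFAULT_TABLE)
        assert set(decomp) == set(achievable_scores(DEFAULT_TABLE))
        for s, (p1, p2, p3, pace) in decomp.items():
            assert (1 + p1 + p2 + p3) * DEFAULT_TABLE.pace_coefficients[pace] == s
            assert p1 >= p2 >= p3  # turtle-first preference => paradox-free times


class TestGenerateStratum:
    def test_deterministic_under_seed(self):
        a = generate_stratum(_spec(), seed=7)
        b = generate_stratum(_spec(), seed=7)
        assert a == b

    def test_different_seed_differs(self):
        assert generate_stratum(_spec(), seed=7) != generate_stratum(_spec(), seed=8)

    def test_scores_round_trip_through_scoring_engine(self):
        for rec in generate_stratum(_spec(n=150), seed=3):
            assert welsh_score(rec.response).score == rec.score
            assert detect_errors(rec.response) == []

    def test_rank_correlation_recovered(self):
        recs = generate_stratum(_spec(), seed=5)
        s = [r.score for r in recs]
        d = [r.mwd for r in recs]
        got = sps.spearmanr(s, d).statistic
        # Fisher-z sampling envelope at n=216 is about 0.068
        assert abs(got - 0.576) < 0.10

    def test_degenerate_noise_collapses_mwd(self):
        recs = generate_stratum(
            _spec(mwd_sd=1e-6, rho_target=0.0, n=50), seed=1
        )
        assert all(abs(r.mwd - 351) < 1 for r in recs)

    def test_unattainable_score_mean_rejected(self):
        with pytest.raises(ConfigError):
            generate_stratum(_spec(score_mean=200), seed=0)

    def test_demographics_respect_inclusion_floor(self):
        recs = generate_stratum(_spec(n=300), seed=9)
        assert all(r.age >= 20 for r in recs)
        assert all(r.mwd >= 0 for r in recs)


class TestMomentRecovery:
    def test_stratum_means_centred_on_targets(self, ref_config):
        """Across a handful of seeds, each stratum's mean score and MWD sit
        centred on the target: a 3-standard-error band (16 simultaneous
        checks) that is still tighter in absolute terms than a 2-se band on
        a single cohort."""
        n_seeds = 5
        for spec in ref_config.strata:
            s_means, d_means = [], []
            for seed in range(n_seeds):
                recs = generate_stratum(spec, ref_config.score_table, seed=seed)
                s_means.append(np.mean([r.score for r in recs]))
                d_means.append(np.mean([r.mwd for r in recs]))
            se_s = spec.score_sd / math.sqrt(spec.n * n_seeds)
            se_d = spec.mwd_sd / math.sqrt(spec.n * n_seeds)
            assert abs(np.mean(s_means) - spec.score_mean) < 3 * se_s
            assert abs(np.mean(d_means) - spec.mwd_mean) < 3 * se_d


class TestInjectErrors:
    def test_zero_profile_is_identity(self):
        recs = generate_stratum(_spec(n=30), seed=1)
        profile = ErrorProfile(
            error_rate={e: 0.0 for e in Education}, p_round1_given_clean=1.0
        )
        out = inject_errors(recs, profile, seed=0)
        assert all(o.first_attempt is None for o in out)
        assert all(o.outcome.round == 1 and o.outcome.status is Status.CLEAN for o in out)
        assert [o.response for o in out] == [r.response for r in recs]

    def test_injected_flags_are_detectable(self):
        recs = generate_stratum(_spec(n=80), seed=2)
        profile = ErrorProfile(error_rate={e: 1.0 for e in Education})
        out = inject_errors(recs, profile, seed=3)
        for rec in out:
            assert rec.first_attempt is not None
            flags = detect_errors(rec.first_attempt)
            assert len(flags) >= 1
            assert rec.outcome.n_errors_corrected >= 1

    def test_paradox_only_profile_round_trips_through_qc(self):
        recs = generate_stratum(_spec(n=60), seed=4)
        profile = ErrorProfile(
            error_rate={e: 1.0 for e in Education},
            kind_weights=(0.0, 0.0, 1.0),
            # force single-error outcomes so the paradox is not masked
            outcome_probs_given_error=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        )
        out = inject_errors(recs, profile, seed=5)
        for rec in out:
            kinds = {f.kind for f in detect_errors(rec.first_attempt)}
            assert ErrorKind.PARADOXICAL in kinds

    def test_scores_survive_correction(self):
        recs = generate_stratum(_spec(n=40), seed=6)
        profile = ErrorProfile(error_rate={e: 1.0 for e in Education})
        out = inject_errors(recs, profile, seed=7)
        assert [o.score for o in out] == [r.score for r in recs]


class TestCohortConfig:
    def test_reference_structure(self, ref_config):
        assert len(ref_config.strata) == 8
        assert ref_config.n_total == 1723
        low_lit = sum(
            s.n for s in ref_config.strata
            if s.education in (Education.NONE, Education.PRIMARY)
        )
        assert low_lit == 757
        from welsh.qc import percent_half_up

        assert percent_half_up(low_lit, ref_config.n_total) == 43.9

    def test_weighted_means_match_published_pooled_values(self, ref_config):
        mwd, score = config_weighted_means(ref_config)
        assert round(mwd) == 383
        assert round(score) == 53

    def test_serialization_round_trip(self, ref_config):
        assert CohortConfig.from_dict(ref_config.to_dict()) == ref_config
        assert CohortConfig.from_dict(ref_config.to_dict()).content_hash() == (
            ref_config.content_hash()
        )

    def test_duplicate_stratum_rejected(self):
        with pytest.raises(ConfigError):
            CohortConfig(
                strata=(_spec(), _spec()),
                error_profile=ErrorProfile(error_rate={}),
            )

    def test_cohort_generation_deterministic(self, ref_config):
        assert generate_cohort(ref_config, seed=11) == generate_cohort(ref_config, seed=11)

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ConfigError):
            ErrorProfile(error_rate={Education.NONE: 1.5})
        with pytest.raises(ConfigError):
            ErrorProfile(
                error_rate={}, outcome_probs_given_error=(0.5, 0.5, 0.5, 0, 0, 0)
            )
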