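"""Generative model of synthetic cohorts and parameter recovery."""

import io

import numpy as np
import pytest
from scipy import stats

from ned_mcgurk import (
    CohortConfig,
    build_fusion_table,
    congruent_accuracy,
    filter_participants,
    fusion_probability,
    recovery_experiment,
    simulate_cohort,
    simulate_demographics,
    study_cohort_config,
    study_stimulus_specs,
)
from ned_mcgurk.io import write_trials
from ned_mcgurk.scoring import FUSION_SYLLABLES


def _trial_bytes(cfg):
    trials, _, _ = simulate_cohort(cfg)
    buf = io.StringIO()
    write_trials(trials, buf)
    return buf.getvalue().encode()


class TestDeterminism:
    def test_same_seed_byte_identical(self):
        cfg = CohortConfig(n_participants=6, n_stimuli=4, n_reps=5, seed=9)
        assert _trial_bytes(cfg) == _trial_bytes(cfg)

    def test_different_seed_differs(self):
        a = CohortConfig(n_participants=6, n_stimuli=4, n_reps=5, seed=9)
        b = CohortConfig(n_participants=6, n_stimuli=4, n_reps=5, seed=10)
        assert _trial_bytes(a) != _trial_bytes(b)


class TestGenerativeModel:
    def test_near_deterministic_limit(self):
        """Tiny noise with T far above D fuses on essentially every trial."""
        cfg = CohortConfig(
            n_participants=4, n_stimuli=3, n_reps=50,
            d_dist=lambda rng, n: np.full(n, 0.2),
            t_dist=lambda rng, n: np.full(n, 0.7),
            sigma_dist=lambda rng, n: np.full(n, 0.01),
            seed=0,
        )
        trials, truth, specs = simulate_cohort(cfg)
        mc = trials[trials.stimulus_kind == "mcgurk"]
        fused = mc.raw_response.isin([specs[s].fusion_percept for s in truth.stimuli])
        assert fused.mean() == 1.0

    def test_cell_rates_concentrate_on_model_probability(self):
        """Pooled fusion rates approach Phi((T-D)/sigma) at binomial rate."""
        n_reps = 1000
        cfg = CohortConfig(
            n_participants=2, n_stimuli=3, n_reps=n_reps, seed=13
        )
        trials, truth, specs = simulate_cohort(cfg)
        mc = trials[trials.stimulus_kind == "mcgurk"]
        for j, pid in enumerate(truth.participants):
            for i, sid in enumerate(truth.stimuli):
                cell = mc[(mc.participant_id == pid) & (mc.stimulus_id == sid)]
                rate = (cell.raw_response == specs[sid].fusion_percept).mean()
                p = fusion_probability(truth.D[i], truth.T[j], truth.sigma[j])
                tol = 3 * np.sqrt(max(p * (1 - p), 1e-4) / n_reps)
                assert abs(rate - p) <= tol

    def test_cell_counts_pass_chi_square(self):
        """Per-cell fusion counts behave as Bernoulli draws at the model rate."""
        cfg = CohortConfig(n_participants=15, n_stimuli=8, n_reps=10, seed=21)
        trials, truth, specs = simulate_cohort(cfg)
        table = build_fusion_table(
            trials, specs, set(trials.participant_id)
        )
        P = np.array(
            [
                [
                    fusion_probability(truth.D[i], truth.T[j], truth.sigma[j])
                    for i in range(8)
                ]
                for j in range(15)
            ]
        )
        counts = table.fusion_prop * 10
        keep = (P > 0.02) & (P < 0.98)
        chi2 = np.sum(
            (counts[keep] - 10 * P[keep]) ** 2 / (10 * P[keep] * (1 - P[keep]))
        )
        pval = stats.chi2.sf(chi2, df=int(keep.sum()))
        assert pval > 1e-3

    def test_congruent_fusion_tokens_only_when_target(self):
        """A fusion syllable on a congruent trial is always the correct answer."""
        cfg = CohortConfig(
            n_participants=10, n_stimuli=3, n_reps=2,
            congruent_lapse_rate=0.2, seed=3,
        )
        trials, _, specs = simulate_cohort(cfg)
        cong = trials[trials.stimulus_kind == "congruent"]
        fusionish = cong[cong.raw_response.isin(FUSION_SYLLABLES)]
        target = fusionish.stimulus_id.map(lambda s: specs[s].auditory_syllable)
        assert (fusionish.raw_response == target).all()

    def test_lapses_are_wrong_but_never_fusion(self):
        cfg = CohortConfig(
            n_participants=20, n_stimuli=2, n_reps=1,
            congruent_lapse_rate=0.2, seed=5,
        )
        trials, truth, specs = simulate_cohort(cfg)
        cong = trials[trials.stimulus_kind == "congruent"]
        target = cong.stimulus_id.map(lambda s: specs[s].auditory_syllable)
        lapsed = cong[cong.raw_response != target]
        assert len(lapsed) > 0
        assert set(lapsed.raw_response) <= {"ba", "ga", "pa", "ka"}

    def test_zero_lapse_gives_exact_unit_accuracy(self, small_cohort):
        trials, _, specs = small_cohort
        acc = congruent_accuracy(trials, specs)
        assert set(acc.values()) == {1.0}


class TestStudyDesign:
    def test_study_specs_match_design(self):
        specs = study_stimulus_specs()
        assert len(specs) == 15
        voiced = [s for s in specs.values() if s.voicing == "voiced"]
        doubled = [s for s in specs.values() if s.n_syllables == 2]
        native = [s for s in specs.values() if s.talker_native_japanese]
        assert len(voiced) == 12 and len(doubled) == 4
        assert sorted(s.stimulus_id for s in native) == ["s3", "s9"]

    def test_inattentive_participants_filtered(self):
        cfg = study_cohort_config(seed=2)
        trials, truth, specs = simulate_cohort(cfg)
        acc = congruent_accuracy(trials, specs)
        included, excluded = filter_participants(acc)
        assert len(acc) == 101
        assert len(included) == 80
        assert len(excluded) == 21

    def test_default_design_dimensions(self):
        trials, truth, _ = simulate_cohort(CohortConfig(seed=1))
        mc = trials[trials.stimulus_kind == "mcgurk"]
        assert len(truth.participants) == 80 and len(truth.stimuli) == 15
        assert len(mc) == 80 * 15 * 10
        cong = trials[trials.stimulus_kind == "congruent"]
        assert (cong.groupby("participant_id").size() == 90).all()


class TestRecovery:
    def test_small_cohort_recovery(self):
        rep = recovery_experiment(
            CohortConfig(n_participants=25, n_stimuli=10, n_reps=10, seed=17)
        )
        assert rep.spearman_d >= 0.85
        assert rep.spearman_t >= 0.7
        assert rep.pred_mae <= 0.08

    def test_more_repetitions_do_not_hurt_recovery(self):
        """Halving repetitions does not improve disparity recovery."""
        def mean_d(n_reps):
            vals = [
                recovery_experiment(
                    CohortConfig(
                        n_participants=20, n_stimuli=8, n_reps=n_reps, seed=s
                    )
                ).spearman_d
                for s in (31, 32, 33)
            ]
            return np.mean(vals)

        assert mean_d(10) >= mean_d(5) - 0.02


class TestDemographics:
    def test_planted_association_recovered_on_truth(self):
        _, truth, _ = simulate_cohort(CohortConfig(seed=23))
        demo = simulate_demographics(truth, seed=23)
        from ned_mcgurk import single_predictor_report

        rep = single_predictor_report(truth.sigma, demo["age"])
        assert rep.b == pytest.approx(0.003, abs=0.002)
        assert 0.0 < rep.r_squared < 0.25

    def test_frame_shape_and_ranges(self):
        _, truth, _ = simulate_cohort(
            CohortConfig(n_participants=30, n_stimuli=4, seed=2)
        )
        demo = simulate_demographics(truth, seed=2)
        assert len(demo) == 30
        assert demo["age"].between(18, 63).all()
        assert demo["english_proficiency"].between(0, 6).all()
        assert set(demo["gender"]) <= {"male", "female"}


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_participants=0)
    with pytest.raises(ValueError):
        CohortConfig(congruent_lapse_rate=0.5)
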