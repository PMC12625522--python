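"""The semi-Markov cohort generator and its analytic self-consistency oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import actipat as ap
from actipat.clinical import NPI_ITEM_NAMES, score_clinical_table
from actipat.epochs import ActivityLabel, find_valid_segment
from actipat.simulate import (
    DEFAULT_DWELL_SIGMA,
    AssociationTruth,
    GroupActivityParams,
    config_from_dict,
    config_to_dict,
    default_config_from_paper,
    discretized_lognormal_mean,
    lognormal_mu_for_mean,
    null_config,
    simulate_activity_sequence,
    simulate_bout_sequence,
    simulate_summaries,
    summary_from_bouts,
)


def simple_params(**kw):
    return GroupActivityParams(
        dwell_mu=np.log([2.0, 3.0, 20.0, 40.0]),
        dwell_sigma=np.array([0.4, 0.4, 0.8, 0.8]),
        transition=np.array(
            [
                [0.0, 0.6, 0.3, 0.1],
                [0.5, 0.0, 0.4, 0.1],
                [0.2, 0.4, 0.0, 0.4],
                [0.1, 0.2, 0.7, 0.0],
            ]
        ),
        **kw,
    )


class TestDwellDiscretisation:
    def test_mu_solver_hits_discrete_mean(self):
        for target, sigma in [(1.2, 0.55), (3.0, 0.8), (45.0, 1.0)]:
            mu = lognormal_mu_for_mean(target, sigma)
            assert discretized_lognormal_mean(mu, sigma) == pytest.approx(target, abs=1e-6)

    def test_unreachably_small_target_clamps_at_floor(self):
        mu = lognormal_mu_for_mean(0.5, 0.55)
        assert discretized_lognormal_mean(mu, 0.55) >= 1.0

    def test_monte_carlo_dwell_mean_matches_configured(self, rng):
        sigma = 0.6
        mu = lognormal_mu_for_mean(3.0, sigma)
        draws = np.maximum(np.rint(rng.lognormal(mu, sigma, size=4000)), 1.0)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se


class TestSequenceSimulation:
    def test_same_seed_same_sequence(self):
        p = simple_params()
        a = simulate_activity_sequence(p, 24, seed=99)
        b = simulate_activity_sequence(p, 24, seed=99)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert len(a) == 1440

    def test_absorbing_sitting_chain_yields_constant_sequence(self):
        p = GroupActivityParams(
            dwell_mu=np.log([2.0, 2.0, 5.0, 2.0]),
            dwell_sigma=np.full(4, 0.3),
            transition=np.array(
                [
                    [0, 0, 1, 0],
                    [0, 0, 1, 0],
                    [0, 0, 1, 0],  # self-loop: sitting is absorbing
                    [0, 0, 1, 0],
                ],
                dtype=float,
            ),
        )
        series = simulate_activity_sequence(p, 24, seed=1)
        assert set(series.labels) == {int(ActivityLabel.SITTING)}

    def test_minimum_duration_enforced(self):
        with pytest.raises(ValueError, match="24"):
            simulate_activity_sequence(simple_params(), 12, seed=0)

    def test_bout_sequence_covers_horizon_exactly(self, rng):
        states, durs = simulate_bout_sequence(simple_params(), 2880, rng)
        assert durs.sum() == 2880
        assert durs.min() >= 1
        # no self-transitions: consecutive bouts change state
        assert np.all(states[:-1] != states[1:])

    def test_time_fractions_converge_to_analytic_oracle(self):
        """pi_s E[dwell_s] / sum_k pi_k E[dwell_k] — the key generator oracle."""
        p = simple_params()
        rng = np.random.default_rng(5)
        states, durs = simulate_bout_sequence(p, 1440 * 400, rng)
        per_state = np.zeros(4)
        np.add.at(per_state, states, durs.astype(float))
        empirical = per_state / per_state.sum()
        expected = p.expected_time_fractions()
        np.testing.assert_allclose(empirical, expected, atol=0.01)

    def test_transition_rate_matches_analytic_oracle(self):
        p = simple_params()
        rng = np.random.default_rng(6)
        days = 400
        states, durs = simulate_bout_sequence(p, 1440 * days, rng)
        summary = summary_from_bouts(states, durs, days)
        expected = p.expected_transitions_per_day()
        assert summary.transitions.daily_mean_transitions == pytest.approx(
            expected, rel=0.05
        )


class TestFastPathEquivalence:
    def test_bout_summary_equals_pipeline_on_expanded_epochs(self):
        cfg = default_config_from_paper(n_participants=12, wear_days=2, seed=3)
        cohort = ap.simulate_cohort(cfg)
        rows = []
        for s in cohort.series:
            seg = find_valid_segment(ap.remap_labels(s))
            rows.append(ap.summarize_participant(seg).to_row())
        pd.testing.assert_frame_equal(
            pd.DataFrame(rows), cohort.summaries, check_like=True
        )


class TestDefaultConfig:
    def test_group_sizes_and_emitted_participants(self):
        cfg = default_config_from_paper()
        assert [g.n for g in cfg.groups] == [25, 73, 47, 18]
        assert cfg.n_participants == 163
        cohort = ap.simulate_cohort(dataclasses.replace(cfg, seed=1))
        assert len(cohort.series) == 163
        assert len(cohort.clinical) == 163

    def test_analytic_means_match_descriptive_targets(self):
        """The back-solved dwell parameters reproduce the published means."""
        cfg = default_config_from_paper()
        weights = np.array([g.n for g in cfg.groups], dtype=float)
        mins = np.array([g.activity.expected_time_fractions() * 1440 for g in cfg.groups])
        cohort_mins = weights @ mins / weights.sum()
        # walking slightly exceeds its target because the severe group's
        # sub-minute dwell target clamps at the 1-epoch floor
        np.testing.assert_allclose(
            cohort_mins, [17.6, 66.0, 594.0, 762.4], atol=2.5
        )
        trans = np.array([g.activity.expected_transitions_per_day() for g in cfg.groups])
        np.testing.assert_allclose(trans, [22, 27, 21, 10], rtol=0.08)

    def test_scaled_sizes_preserve_proportions(self):
        cfg = default_config_from_paper(n_participants=200)
        sizes = [g.n for g in cfg.groups]
        assert sum(sizes) == 200
        assert sizes[1] == max(sizes)  # mild dementia remains the largest group

    def test_cohort_reproducibility_byte_identical(self, tmp_path):
        cfg = default_config_from_paper(n_participants=10, wear_days=1, seed=21)
        a = ap.simulate_cohort(cfg).write(tmp_path / "a")
        b = ap.simulate_cohort(cfg).write(tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_written_cohort_reingests_cleanly(self, small_cohort_files):
        cohort, paths = small_cohort_files
        series = ap.read_epoch_csv(paths["epochs"])
        assert len(series) == len(cohort.series)
        for s in series:
            find_valid_segment(ap.remap_labels(s))
        scored = score_clinical_table(ap.read_clinical_csv(paths["clinical"]))
        assert len(scored) == len(cohort.clinical)
        assert scored["sppb_total"].between(0, 12).all()

    def test_config_yaml_round_trip(self, tmp_path):
        from actipat.simulate import load_config, save_config

        cfg = default_config_from_paper(n_participants=20, seed=9)
        path = tmp_path / "cohort.yaml"
        save_config(cfg, path)
        back = load_config(path)
        assert config_to_dict(back) == config_to_dict(cfg)
        a = ap.simulate_cohort(cfg)
        b = ap.simulate_cohort(back)
        assert a.summaries.equals(b.summaries)


class TestClinicalGeneration:
    def test_scores_within_instrument_ranges(self, default_cohort):
        clinical = default_cohort.clinical
        for item in NPI_ITEM_NAMES:
            assert clinical[f"npi_{item}"].between(0, 12).all()
        sppb = clinical[["sppb_balance", "sppb_gait", "sppb_chair"]].sum(axis=1)
        assert sppb.between(0, 12).all()
        assert clinical.loc[clinical.dx_dementia, "cdr_sob"].between(0.5, 18).all()

    def test_null_truth_gives_independent_scores(self):
        cfg = null_config(n_participants=1000, seed=17)
        summary, clinical = simulate_summaries(cfg)
        scored = score_clinical_table(clinical)
        df = summary.merge(scored, on="participant_id")
        for metric in ("walking_min", "standing_min", "transitions_per_day"):
            for score in ("sppb_total", "npi_agitation", "npi_total"):
                r = np.corrcoef(df[metric], df[score])[0, 1]
                assert abs(r) < 0.1

    def test_positive_sppb_truth_sign_recovered(self):
        """A configured walking->function loading is recovered by the GLM."""
        truth = AssociationTruth(sppb={"walking_min": 0.9}, npi={})
        base = null_config(n_participants=500, seed=0)
        cfg = dataclasses.replace(base, truth=truth)
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            c = dataclasses.replace(cfg, seed=1000 + rep)
            summary, clinical = simulate_summaries(c)
            res = ap.ActivityAssociationModel.from_tables(
                summary, score_clinical_table(clinical)
            ).fit(outcomes=["walking_min"])
            row = res["walking_min"].table.loc["sppb_total"]
            if row["coef"] > 0 and row["p"] < 0.05:
                hits += 1
        assert hits >= int(0.95 * n_rep)


class TestTruthLedger:
    def test_ledger_records_expectations_and_truth(self, default_cohort):
        truth = default_cohort.truth
        assert set(truth["groups"]) == {"no_mci", "mild", "moderate", "severe"}
        severe = truth["groups"]["severe"]
        mild = truth["groups"]["mild"]
        assert severe["expected_transitions_per_day"] < mild["expected_transitions_per_day"]
        assert truth["association_truth"]["sppb"]["walking_min"] > 0
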