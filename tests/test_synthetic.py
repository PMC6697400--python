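"""Cohort generator: determinism, validation, behavioral statistics of
the generated event streams, planted-cluster structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from rigidlink import behavior as bhv
from rigidlink.behavior import score_cohort
from rigidlink.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_gmv_images,
    generate_percept_timeline,
    generate_spontaneous_session,
    null_spec,
    yoke_instructed_session,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field,value,match",
        [
            ("n_per_group", 0, "n_per_group"),
            ("trait_behavior_corr", 1.5, "trait_behavior_corr"),
            ("lapse_rate", 1.2, "lapse_rate"),
            ("percept_shape", -1.0, "percept_shape"),
            ("measurement_attenuation", 0.0, "measurement_attenuation"),
        ],
    )
    def test_invalid_fields_named(self, field, value, match):
        with pytest.raises(ValueError, match=match):
            dataclasses.replace(CohortSpec(), **{field: value}).validate()

    def test_cluster_outside_volume(self):
        spec = dataclasses.replace(
            CohortSpec(), cluster_center=(1, 1, 1), cluster_radius_mm=30.0
        )
        with pytest.raises(ValueError, match="cluster"):
            spec.validate()


class TestDeterminism:
    def test_same_spec_same_seed_identical(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        pd.testing.assert_frame_equal(a.subjects, b.subjects)
        pd.testing.assert_frame_equal(a.percept_events, b.percept_events)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.images.values, b.images.values)

    def test_different_seed_differs(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(dataclasses.replace(small_spec, seed=small_spec.seed + 1))
        assert not a.percept_events.equals(b.percept_events)


class TestPerceptTimeline:
    def test_onsets_increasing_within_run(self, rng, small_spec):
        tl = generate_percept_timeline(0.5, small_spec, rng)
        onsets = tl["onset_s"].to_numpy()
        assert np.all(np.diff(onsets) > 0)
        assert onsets[0] >= 0 and onsets[-1] < small_spec.run_length_s

    def test_higher_trait_longer_median(self, small_spec):
        """Monte-Carlo monotonicity: median clear duration increases with
        the trait, comparing 1000 runs per trait level."""
        meds = {}
        for trait in (-1.0, 1.5):
            rng = np.random.default_rng(77)
            vals = []
            for _ in range(1000):
                tl = generate_percept_timeline(trait, small_spec, rng)
                d = bhv.percept_durations(tl, small_spec.run_length_s)
                if d:
                    vals.append(np.median(d))
            meds[trait] = np.mean(vals)
        assert meds[1.5] > meds[-1.0]

    def test_zero_mixed_rate(self, rng, small_spec):
        spec = dataclasses.replace(small_spec, mixed_event_prob=0.0)
        for _ in range(50):
            tl = generate_percept_timeline(0.0, spec, rng)
            assert not (tl["label"] == "mixed").any()

    def test_nonfinite_trait_rejected(self, rng, small_spec):
        with pytest.raises(ValueError, match="finite"):
            generate_percept_timeline(np.nan, small_spec, rng)


class TestSpontaneousSession:
    def test_geometric_run_lengths_at_half_persistence(self):
        """With persistence 0.5 and no lapses the run lengths are
        geometric with mean 1/(1-p) = 2 (oracle: closed form)."""
        spec = CohortSpec(
            persistence_map=lambda u: np.full_like(np.asarray(u, float), 0.5),
            lapse_rate=0.0,
            timeout_rate=0.0,
        )
        rng = np.random.default_rng(123)
        runs = []
        total = 0
        while total < 100_000:
            sess = generate_spontaneous_session(0.0, spec, rng)
            labels = list(bhv.classify_trials(sess))
            runs.extend(bhv.repetition_runs(labels))
            total += len(sess)
        mean_run = np.mean(runs)
        assert mean_run == pytest.approx(2.0, rel=0.02)

    def test_zero_lapse_zero_unclassifiable(self, rng):
        spec = CohortSpec(lapse_rate=0.0, timeout_rate=0.0)
        sess = generate_spontaneous_session(0.0, spec, rng)
        labels = bhv.classify_trials(sess)
        assert not (labels == "unclassifiable").any()

    def test_circle_never_brightest(self, rng, small_spec):
        sess = generate_spontaneous_session(0.3, small_spec, rng)
        assert (sess["circle_index"] != sess["bright_index"]).all()

    def test_trial_budget_respected(self, rng, small_spec):
        sess = generate_spontaneous_session(0.0, small_spec, rng)
        total_s = (sess["rt_ms"] / 1000.0 + small_spec.rt_params.iti_s).sum()
        assert total_s <= small_spec.trial_budget_s + 3.5  # last trial may straddle


class TestYoking:
    def test_omission_rule(self):
        # tasks [S,S,B,U,B] -> cue sequence [S,S,B,B]
        circle = np.array([0, 0, 0, 0, 0])
        bright = np.array([1, 1, 1, 1, 1])
        choice = np.array([0, 0, 1, 2, 1])  # third trial chooses neither
        spont = pd.DataFrame(
            {
                "run": 1, "trial": np.arange(5), "mode": "spontaneous",
                "cue": "none", "task": "n/a", "circle_index": circle,
                "bright_index": bright, "choice_index": choice,
                "rt_ms": 700.0, "timeout": False,
            }
        )
        instr = yoke_instructed_session(spont, CohortSpec(), np.random.default_rng(0))
        assert list(instr["cue"]) == ["shape", "shape", "brightness", "brightness"]
        assert len(instr) == 4

    def test_empty_classified_sequence_rejected(self):
        spont = pd.DataFrame(
            {
                "run": 1, "trial": [0], "mode": "spontaneous", "cue": "none",
                "task": "n/a", "circle_index": [0], "bright_index": [1],
                "choice_index": [-1], "rt_ms": [3000.0], "timeout": [True],
            }
        )
        with pytest.raises(ValueError, match="empty"):
            yoke_instructed_session(spont, CohortSpec(), np.random.default_rng(0))


class TestGMVImages:
    def test_degenerate_noise_free_volumes_identical(self, small_spec):
        spec = dataclasses.replace(
            small_spec, noise_sd=0.0, cluster_effect=0.0,
            subject_global_sd=0.0, asd_whole_brain_offset=0.0,
        )
        rng = np.random.default_rng(1)
        stack = generate_gmv_images(np.array([0.2, -1.0, 3.0]), np.array([1, 0, 0], bool), spec, rng)
        assert np.array_equal(stack.values[0], stack.values[1])
        assert np.array_equal(stack.values[0], stack.values[2])

    def test_roi_mean_tracks_trait(self, small_spec):
        rng = np.random.default_rng(2)
        traits = rng.normal(0, 1, 200)
        stack = generate_gmv_images(traits, np.zeros(200, bool), small_spec, rng)
        roi = stack.values[:, stack.planted].mean(axis=1)
        r = np.corrcoef(roi, traits)[0, 1]
        assert r < -0.5  # sign of cluster_effect, strong coupling

    def test_mask_volume_bookkeeping(self, small_spec):
        rng = np.random.default_rng(3)
        stack = generate_gmv_images(np.zeros(2), np.zeros(2, bool), small_spec, rng)
        voxel_vol = small_spec.voxel_size_mm**3
        assert stack.mask.sum() * voxel_vol == pytest.approx(
            np.count_nonzero(stack.mask) * voxel_vol
        )
        assert stack.planted.sum() > 0
        assert np.all(stack.values[0][~stack.mask] == 0)


class TestCohortStructure:
    def test_groups_matched_and_ados_only_asd(self, small_spec):
        c = generate_cohort(small_spec)
        assert (c.subjects["group"] == "ASD").sum() == (c.subjects["group"] == "TD").sum()
        td = c.subjects[c.subjects["group"] == "TD"]
        asd = c.subjects[c.subjects["group"] == "ASD"]
        assert td[["ados_social", "ados_communication", "ados_rrb"]].isna().all().all()
        assert asd[["ados_social", "ados_communication", "ados_rrb"]].notna().all().all()
        assert set(asd["ados_rrb"]).issubset({0.0, 1.0, 2.0})

    def test_right_skewed_distributions(self, small_spec):
        from scipy.stats import skew

        c = generate_cohort(small_spec)
        durs = []
        for (_, _), g in c.percept_events.groupby(["subject", "run"]):
            durs.extend(bhv.percept_durations(g, small_spec.run_length_s))
        runs = []
        spont = c.trials[c.trials["mode"] == "spontaneous"]
        for (_, _), g in spont.groupby(["subject", "run"]):
            labels = [l for l in bhv.classify_trials(g) if l != "unclassifiable"]
            runs.extend(bhv.repetition_runs(labels))
        assert skew(durs) > 0
        assert skew(runs) > 0

    def test_null_spec_decouples_roi_and_behavior(self):
        spec = null_spec(
            CohortSpec(n_per_group=100, volume_shape=(16, 16, 16),
                       voxel_size_mm=6.0, cluster_center=(10, 6, 10),
                       cluster_radius_mm=12.0),
            seed=31,
        )
        c = generate_cohort(spec)
        tab = score_cohort(c)
        order = {s: i for i, s in enumerate(c.subjects["subject"])}
        rows = np.array([order[s] for s in tab["subject"]])
        roi = c.images.values[rows][:, c.images.planted].mean(axis=1)
        for col in ("median_percept_duration_s", "median_repetition_length"):
            r = np.corrcoef(roi, tab[col])[0, 1]
            assert abs(r) < 0.2


class TestBehavioralCorrelationCalibration:
    def test_realized_correlation_near_target(self):
        """At n = 500 per group the correlation of the two scored medians
        lands within +-0.1 of trait_behavior_corr = 0.45 (large-n check
        against the generating model)."""
        spec = CohortSpec(n_per_group=500, include_volumes=False, seed=42)
        c = generate_cohort(spec)
        tab = score_cohort(c)
        for group in ("ASD", "TD"):
            sub = tab[tab["group"] == group]
            r = np.corrcoef(
                sub["median_percept_duration_s"], sub["median_repetition_length"]
            )[0, 1]
            assert abs(r - spec.trait_behavior_corr) < 0.1
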