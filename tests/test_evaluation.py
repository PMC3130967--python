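"""RA evaluation: matching, the four R² features, report aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from groupica.evaluation import (
    build_report,
    evaluate_dataset,
    match_components,
    r_squared,
    ra_features,
    report_to_wide,
)
from groupica.hybrid import HybridGroundTruth
from groupica.pipeline import GroupResult, SubjectComponents


def toy_truth(rng, n_sources=3, q=8, samples=20, trials=10):
    v = samples * trials
    src = rng.laplace(size=(n_sources, v))
    src /= src.std(axis=1, keepdims=True)
    topos = rng.standard_normal((q, n_sources))
    return HybridGroundTruth(
        source_timecourses=src,
        topographies=topos,
        peak_latencies=np.full((n_sources, trials), samples / 2.0),
        mean_latencies=np.full(n_sources, samples / 2.0),
        amplitudes_a1=np.ones((n_sources, trials)),
        amplitudes_a2=np.ones((n_sources, trials)),
    )


def comps_from(truth, timecourses, scalp_maps, samples=20, trials=10):
    return SubjectComponents("s0", timecourses, scalp_maps, samples, trials)


class TestRSquared:
    def test_affine_and_sign_invariance(self, rng):
        a = rng.standard_normal(500)
        assert r_squared(a, 2 * a + 5) == pytest.approx(1.0)
        assert r_squared(a, -a) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        a, b = rng.standard_normal((2, 20000))
        assert r_squared(a, b) < 0.05

    def test_constant_vector_warns_and_returns_zero(self, rng):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert r_squared(np.ones(10), rng.standard_normal(10)) == 0.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.ones(6))


class TestMatching:
    def test_permuted_copies_recover_permutation(self, rng):
        truth = toy_truth(rng)
        perm = [2, 0, 1]
        tc = np.vstack([truth.source_timecourses[perm.index(j)] for j in range(3)])
        comps = comps_from(truth, tc, rng.standard_normal((8, 3)))
        match = match_components(truth, comps)
        assert match.tolist() == perm
        for k in range(3):
            assert r_squared(truth.source_timecourses[k],
                             comps.timecourses[match[k]]) == pytest.approx(1.0)

    def test_injective_even_with_missing_source(self, rng):
        truth = toy_truth(rng)
        tc = np.vstack([truth.source_timecourses[:2],
                        rng.standard_normal((2, 200))])
        comps = comps_from(truth, tc, rng.standard_normal((8, 4)))
        match = match_components(truth, comps)
        assert len(set(match.tolist())) == 3

    def test_matches_bruteforce_assignment(self, rng):
        """Hungarian assignment equals exhaustive search over 3-permutations."""
        truth = toy_truth(rng)
        tc = rng.laplace(size=(20, 200))
        tc[4] = truth.source_timecourses[0] + 0.3 * rng.standard_normal(200)
        tc[11] = truth.source_timecourses[1] + 0.5 * rng.standard_normal(200)
        tc[17] = truth.source_timecourses[2] + 0.8 * rng.standard_normal(200)
        comps = comps_from(truth, tc, rng.standard_normal((8, 20)))
        match = match_components(truth, comps)
        r2 = np.array([[r_squared(truth.source_timecourses[k], tc[j])
                        for j in range(20)] for k in range(3)])
        best, best_sum = None, -1.0
        for combo in itertools.permutations(range(20), 3):
            s = sum(r2[k, combo[k]] for k in range(3))
            if s > best_sum:
                best, best_sum = combo, s
        assert tuple(match) == best

    def test_too_few_components(self, rng):
        truth = toy_truth(rng)
        comps = comps_from(truth, rng.standard_normal((2, 200)),
                           rng.standard_normal((8, 2)))
        with pytest.raises(ValueError, match="cover"):
            match_components(truth, comps)


class TestRaFeatures:
    def test_affine_copy_scores_one_everywhere(self, rng):
        truth = toy_truth(rng)
        tc = 2.0 * truth.source_timecourses + 5.0
        maps = truth.topographies * -3.0
        comps = comps_from(truth, tc, maps)
        for k in range(3):
            feats = ra_features(truth, comps, k, k)
            assert all(v == pytest.approx(1.0) for v in feats.values())

    def test_independent_component_scores_near_zero(self, rng):
        truth = toy_truth(rng, samples=50, trials=100)
        tc = rng.standard_normal((3, 5000))
        comps = comps_from(truth, tc, rng.standard_normal((8, 3)),
                           samples=50, trials=100)
        feats = ra_features(truth, comps, 0, 0)
        assert feats["single_trial"] < 0.05
        assert feats["average"] < 0.1
        assert feats["peak"] < 0.1

    def test_peak_amplitudes_use_centered_window(self, rng):
        """The per-trial amplitude is the mean over the window around the
        source's mean peak latency; verified against a manual computation."""
        truth = toy_truth(rng, samples=40, trials=8)
        truth.mean_latencies[:] = 20.0
        comps = comps_from(truth, truth.source_timecourses.copy(),
                           truth.topographies.copy(), samples=40, trials=8)
        feats = ra_features(truth, comps, 1, 1, peak_window=10)
        img = truth.source_timecourses[1].reshape(8, 40)
        manual = img[:, 15:25].mean(axis=1)
        assert feats["peak"] == pytest.approx(r_squared(manual, manual))

    def test_window_outside_epoch_rejected(self, rng):
        truth = toy_truth(rng)
        truth.mean_latencies[:] = 500.0
        comps = comps_from(truth, truth.source_timecourses,
                           truth.topographies)
        with pytest.raises(ValueError, match="outside"):
            ra_features(truth, comps, 0, 0)


class TestReport:
    def _fake_result(self, truths, algorithm="infomax", n=4):
        subjects = [
            SubjectComponents(f"s{i}", t.source_timecourses[list(range(3)) + [0]],
                              np.column_stack([t.topographies, t.topographies[:, 0]]),
                              20, 10)
            for i, t in enumerate(truths)
        ]
        return GroupResult(
            reduction=None, ica=None, subjects=subjects,
            group_mean_timecourses=np.zeros((n, 20)),
            config_snapshot={"algorithm": algorithm, "N": n},
        )

    def test_aggregation_matches_hand_computation(self, rng):
        truths = [toy_truth(rng), toy_truth(rng)]
        res = self._fake_result(truths)
        ra = build_report([(res, truths)])
        agg = ra.aggregated
        row = agg[(agg.source == "S1") & (agg.feature == "single_trial")].iloc[0]
        per = ra.per_dataset
        vals = per[(per.source == "S1") & (per.feature == "single_trial")]["r2"].values
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["sem"] == pytest.approx(vals.std(ddof=1) / np.sqrt(2))
        assert row["n"] == 2

    def test_single_dataset_sem_zero_and_flagged(self, rng):
        truths = [toy_truth(rng)]
        ra = build_report([(self._fake_result(truths), truths)])
        assert (ra.aggregated["sem"] == 0).all()
        assert (~ra.aggregated["sem_defined"]).all()

    def test_wide_layout_has_twelve_value_columns(self, rng):
        truths = [toy_truth(rng), toy_truth(rng)]
        wide = report_to_wide(build_report([(self._fake_result(truths), truths)]))
        value_cols = [c for c in wide.columns if c not in ("algorithm", "n_components")]
        assert len(value_cols) == 12
        assert value_cols[0] == "single_trial_S1"

    def test_heterogeneous_source_counts_rejected(self, rng):
        t3 = [toy_truth(rng)]
        t2 = [toy_truth(rng, n_sources=2)]
        r3 = self._fake_result(t3)
        subjects2 = [SubjectComponents("s0", t2[0].source_timecourses,
                                       t2[0].topographies, 20, 10)]
        r2 = GroupResult(reduction=None, ica=None, subjects=subjects2,
                         group_mean_timecourses=np.zeros((2, 20)),
                         config_snapshot={"algorithm": "jade", "N": 2})
        with pytest.raises(ValueError, match="heterogeneous"):
            build_report([(r3, t3), (r2, t2)])
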