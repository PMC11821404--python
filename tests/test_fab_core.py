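"""Component filtering, mass recalculation, tolerance calibration, clustering."""

import numpy as np
import pandas as pd
import pytest
from helpers import brute_force_cluster, canonical, partition_from_clones, random_components
from hypothesis import given, settings
from hypothesis import strategies as st

from synofab.errors import CalibrationError, FormatError
from synofab.fab_core import (
    ToleranceModel,
    cluster_clones,
    estimate_tolerances,
    filter_fab_components,
    profile_sample,
    recalculate_mass,
)


class TestRecalculateMass:
    @pytest.mark.parametrize(
        "peaks, expected",
        [
            ([(48_000.0, 1e6)], 48_000.0),
            # both peaks needed to reach 90% of the total
            ([(47_999.0, 5.0), (48_001.0, 5.0)], 48_000.0),
            # prefix {80, 15} reaches 95% >= 90%: (48000*80 + 48010*15)/95
            ([(48_000.0, 80.0), (48_010.0, 15.0), (48_100.0, 5.0)], 4_560_150.0 / 95.0),
        ],
    )
    def test_weighted_mean_over_90pct_prefix(self, peaks, expected):
        assert recalculate_mass(peaks) == pytest.approx(expected)

    def test_matches_brute_force_prefix_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            masses = rng.uniform(47_000, 49_000, n)
            intens = rng.uniform(0.1, 100.0, n)
            # oracle: enumerate intensity-descending prefixes, take the first
            # whose cumulative intensity reaches 90% of the total
            order = np.argsort(-intens, kind="stable")
            total = intens.sum()
            for k in range(1, n + 1):
                prefix = order[:k]
                if intens[prefix].sum() >= 0.9 * total:
                    break
            expected = np.average(masses[prefix], weights=intens[prefix])
            assert recalculate_mass(list(zip(masses, intens))) == pytest.approx(expected)

    def test_accepts_mapping_peaks(self):
        assert recalculate_mass([{"mass": 48_000.0, "intensity": 2.0}]) == 48_000.0

    @pytest.mark.parametrize("peaks", [[], [(48_000.0, 0.0)]])
    def test_invalid_input(self, peaks):
        with pytest.raises(FormatError):
            recalculate_mass(peaks)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(
                st.floats(45_000, 56_000),
                st.floats(0.01, 1e6),
            ),
            min_size=1,
            max_size=10,
        ),
        st.floats(0.1, 100.0),
    )
    def test_bounded_by_peak_range_and_scale_invariant(self, peaks, scale):
        mass = recalculate_mass(peaks)
        masses = [m for m, _ in peaks]
        assert min(masses) - 1e-6 <= mass <= max(masses) + 1e-6
        scaled = [(m, i * scale) for m, i in peaks]
        assert recalculate_mass(scaled) == pytest.approx(mass)


class TestFabFilter:
    def row(self, mass=48_000.0, mz=1_200.0, score=55.0):
        return {"sample_id": "S1", "mass_da": mass, "rt_min": 20.0, "sum_intensity": 1.0,
                "score": score, "top_cs_mz": mz}

    def test_hand_enumerated_survivors(self):
        # one row violating each criterion, three passing
        df = pd.DataFrame(
            [
                self.row(),  # passes
                self.row(mass=44_999.9, score=99.0),  # below mass range
                self.row(mass=56_300.0),  # above mass range
                self.row(mz=1_000.0),  # top charge state must exceed 1000
                self.row(score=39.9),  # score below 40
                self.row(mass=45_000.0, score=40.0),  # boundary values retained
            ]
        )
        kept = filter_fab_components(df)
        assert list(kept.index) == [0, 5]
        df2 = pd.concat([df, pd.DataFrame([self.row(mass=56_200.0)])], ignore_index=True)
        assert len(filter_fab_components(df2)) == 3

    def test_retains_typical_fab(self):
        df = pd.DataFrame([self.row(mass=48_000.0, mz=1_200.0, score=55.0)])
        assert len(filter_fab_components(df)) == 1

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(1)
        df = random_components(rng, 40)
        df["mass_da"] = rng.uniform(40_000, 60_000, 40)
        df["score"] = rng.uniform(0, 100, 40)
        df["top_cs_mz"] = rng.uniform(500, 3_000, 40)
        once = filter_fab_components(df)
        twice = filter_fab_components(once)
        pd.testing.assert_frame_equal(once, twice)
        assert list(once.index) == sorted(once.index)

    def test_empty_in_empty_out(self):
        df = pd.DataFrame(columns=["mass_da", "top_cs_mz", "score"])
        assert filter_fab_components(df).empty


class TestEstimateTolerances:
    def test_hand_computed_rt_sd(self):
        obs = {"mab": [(48_000.0, 10.0), (48_000.0, 10.2), (48_000.0, 10.4)]}
        tol = estimate_tolerances(obs)
        assert tol.sigma_rt_min == pytest.approx(0.2)
        assert tol.window_rt_min == pytest.approx(0.6)
        assert tol.k == 3.0  # three-standard-deviation windows by default

    def test_pooled_over_two_standards(self):
        obs = {
            "a": [(0.0, 10.0), (0.0, 10.2), (0.0, 10.4)],  # sd 0.2, 2 dof
            "b": [(0.0, 5.0), (0.0, 5.1)],  # var 0.005, 1 dof
        }
        tol = estimate_tolerances(obs)
        expected = np.sqrt((2 * 0.04 + 1 * 0.005) / 3)
        assert tol.sigma_rt_min == pytest.approx(expected)
        assert tol.n_observations == 5

    def test_degenerate_calibration_falls_back_to_floors(self):
        obs = {"mab": [(48_000.0, 10.0)] * 3}
        with pytest.warns(UserWarning, match="degenerate"):
            tol = estimate_tolerances(obs)
        assert tol.degenerate
        assert tol.window_mass_da == 0.5
        assert tol.window_rt_min == 0.05

    def test_too_few_observations(self):
        with pytest.raises(CalibrationError, match="mab"):
            estimate_tolerances({"mab": [(48_000.0, 10.0)]})

    def test_extra_observation_groups_are_pooled(self):
        obs = {"mab": [(0.0, 10.0), (0.0, 10.2)]}
        aug = estimate_tolerances(obs, extra_observations=[[(0.0, 7.0), (0.0, 7.6)]])
        base = estimate_tolerances(obs)
        assert aug.n_observations == 4
        assert aug.sigma_rt_min > base.sigma_rt_min


class TestClusterClones:
    def test_single_component_single_clone(self, tol):
        df = pd.DataFrame(
            [{"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 5.0}]
        )
        clones = cluster_clones(df, tol)
        assert len(clones) == 1
        assert clones[0].members["S1"] == (48_000.0, 20.0, 5.0)

    def test_separated_components_stay_apart(self, tol):
        df = pd.DataFrame(
            [
                {"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 5.0},
                {"sample_id": "S2", "mass_da": 48_000.0 + 2 * tol.window_mass_da,
                 "rt_min": 20.0, "sum_intensity": 4.0},
            ]
        )
        assert len(cluster_clones(df, tol)) == 2

    def test_chain_follows_updating_centroid_rule(self, tol):
        w = tol.window_mass_da
        df = pd.DataFrame(
            [
                {"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 100.0},
                {"sample_id": "S2", "mass_da": 48_000.0 + 0.8 * w, "rt_min": 20.0, "sum_intensity": 90.0},
                {"sample_id": "S3", "mass_da": 48_000.0 + 1.6 * w, "rt_min": 20.0, "sum_intensity": 80.0},
            ]
        )
        got = canonical(partition_from_clones(cluster_clones(df, tol), df))
        expected = canonical(brute_force_cluster(df, tol.window_mass_da, tol.window_rt_min))
        assert got == expected
        # A founds, B joins A; consensus moves to 48000 + 0.8w*90/190 = +0.379w,
        # so C at +1.6w is 1.22w away and must found its own clone
        assert got == {(0, 1), (2,)}

    def test_matches_brute_force_oracle_on_random_instances(self, tol):
        rng = np.random.default_rng(11)
        for _ in range(120):
            df = random_components(rng, int(rng.integers(1, 21)))
            got = canonical(partition_from_clones(cluster_clones(df, tol), df))
            expected = canonical(
                brute_force_cluster(df, tol.window_mass_da, tol.window_rt_min)
            )
            assert got == expected

    def test_invariants_on_random_instances(self, tol):
        rng = np.random.default_rng(13)
        for _ in range(30):
            df = random_components(rng, 60, n_samples=4)
            clones = cluster_clones(df, tol)
            total = sum(c.total_intensity for c in clones)
            assert total == pytest.approx(df["sum_intensity"].sum())
            for c in clones:
                assert len(c.members) == len(set(c.members))  # one member per sample
                for mass, rt, _ in c.members.values():
                    assert abs(mass - c.consensus_mass_da) <= tol.window_mass_da + 1e-9
                    assert abs(rt - c.consensus_rt_min) <= tol.window_rt_min + 1e-9

    def test_recovers_well_separated_true_clones(self):
        # true clones on a 20 Da grid (>> 4 sigma); two samples, Gaussian noise
        # small enough that the window floors (0.5 Da / 0.05 min) dominate
        rng = np.random.default_rng(17)
        sigma_m, sigma_r = 0.1, 0.01
        true_m = 47_000.0 + 20.0 * np.arange(100)
        true_r = 15.0 + 0.2 * np.arange(100) % 10
        rows = []
        for sid in ("S1", "S2"):
            for m, r in zip(true_m, true_r):
                rows.append(
                    {"sample_id": sid, "mass_da": m + rng.normal(0, sigma_m),
                     "rt_min": r + rng.normal(0, sigma_r),
                     "sum_intensity": float(rng.uniform(1, 100))}
                )
        tol = ToleranceModel(sigma_mass_da=sigma_m, sigma_rt_min=sigma_r)
        clones = cluster_clones(pd.DataFrame(rows), tol)
        two_member = sum(1 for c in clones if len(c.members) == 2)
        assert two_member >= 99


class TestProfileSample:
    def test_merges_in_window_duplicates(self, tol):
        df = pd.DataFrame(
            [
                {"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0,
                 "sum_intensity": 3.0, "score": 80.0, "top_cs_mz": 1_900.0},
                {"sample_id": "S1", "mass_da": 48_000.5, "rt_min": 20.01,
                 "sum_intensity": 1.0, "score": 70.0, "top_cs_mz": 1_900.0},
            ]
        )
        out = profile_sample(df, tol)
        assert len(out) == 1
        assert out.loc[0, "sum_intensity"] == pytest.approx(4.0)
        # intensity-weighted consensus mass
        assert out.loc[0, "mass_da"] == pytest.approx((48_000.0 * 3 + 48_000.5) / 4)

    def test_distant_components_untouched(self, tol):
        df = pd.DataFrame(
            [
                {"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 3.0},
                {"sample_id": "S1", "mass_da": 48_500.0, "rt_min": 20.0, "sum_intensity": 1.0},
            ]
        )
        assert len(profile_sample(df, tol)) == 2

    def test_total_intensity_conserved(self, tol):
        rng = np.random.default_rng(23)
        for _ in range(20):
            df = random_components(rng, 30, n_samples=1)
            out = profile_sample(df, tol)
            assert out["sum_intensity"].sum() == pytest.approx(df["sum_intensity"].sum())

    def test_rejects_multi_sample_input(self, tol):
        df = pd.DataFrame(
            [
                {"sample_id": "S1", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 3.0},
                {"sample_id": "S2", "mass_da": 48_000.0, "rt_min": 20.0, "sum_intensity": 1.0},
            ]
        )
        with pytest.raises(FormatError):
            profile_sample(df, tol)
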