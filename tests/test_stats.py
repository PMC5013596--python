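"""Merging statistics: hand-worked values, algebraic identities, limits."""

import math

import numpy as np
import pytest

import gamerge as gm
from gamerge.scaling import ScaleResult
from tests.test_merge import make_subset, unit_scales


def hand_stats(observations):
    """Independent reference: plain-Python R_merge / R_meas / multiplicity.

    ``observations`` maps a unique index to its list of intensities.
    """
    num_merge = num_meas = denom = 0.0
    n_obs = sum(len(v) for v in observations.values())
    for vals in observations.values():
        if len(vals) < 2:
            continue
        mean = sum(vals) / len(vals)
        dev = sum(abs(v - mean) for v in vals)
        num_merge += dev
        num_meas += math.sqrt(len(vals) / (len(vals) - 1)) * dev
        denom += sum(vals)
    return {
        "r_merge": 100.0 * num_merge / denom,
        "r_meas": 100.0 * num_meas / denom,
        "multiplicity": n_obs / len(observations),
    }


@pytest.fixture(scope="module")
def micro():
    # 10 unique P1 indices; varying multiplicity 1..4; all in one shell
    obs = {
        (1, 2, 3): [9.0, 11.0],
        (2, 1, 1): [100.0, 104.0, 96.0],
        (3, 1, 2): [50.0],
        (1, 1, 4): [20.0, 22.0, 18.0, 24.0],
        (2, 3, 1): [75.0, 80.0],
        (4, 1, 1): [33.0, 30.0],
        (1, 4, 2): [60.0, 60.0],
        (2, 2, 3): [15.0, 13.0, 17.0],
        (3, 3, 1): [42.0],
        (1, 3, 3): [88.0, 92.0],
    }
    hkl, intensity = [], []
    for key, vals in obs.items():
        for v in vals:
            hkl.append(key)
            intensity.append(v)
    ds = make_subset(hkl, intensity, [1.0] * len(intensity))
    scheme = gm.ShellScheme((25.0, 10.0, 7.0, 3.0))
    mg = gm.merge_group([ds], unit_scales(1), rng_seed=0)
    stats = gm.compute_stats(mg, scheme, 1, with_completeness=False)
    return obs, stats


class TestHandWorkedMicroDataset:
    """Ten unique reflections with known observations, checked to 1e-9."""

    def test_r_factors_match_hand_computation(self, micro):
        obs, stats = micro
        expect = hand_stats(obs)
        assert stats.overall.r_merge == pytest.approx(expect["r_merge"], abs=1e-9)
        assert stats.overall.r_meas == pytest.approx(expect["r_meas"], abs=1e-9)

    def test_multiplicity_and_counts(self, micro):
        obs, stats = micro
        expect = hand_stats(obs)
        assert stats.overall.multiplicity == pytest.approx(expect["multiplicity"], abs=1e-12)
        assert stats.overall.n_unique == 10
        assert stats.overall.n_obs == sum(len(v) for v in obs.values())

    def test_mean_i_over_sigma_both_variants(self, micro):
        obs, stats = micro
        # sigma = 1 for every observation: merged sigma = 1/sqrt(n)
        expect_merged = np.mean(
            [np.mean(v) * math.sqrt(len(v)) for v in obs.values()]
        )
        assert stats.overall.mean_i_over_sigma == pytest.approx(expect_merged, abs=1e-9)
        expect_obs = np.mean([v for vals in obs.values() for v in vals])
        assert stats.overall.mean_i_over_sigma_obs == pytest.approx(expect_obs, abs=1e-9)

    def test_two_observation_example(self):
        # I = {9, 11}: R_merge = 2/20 = 10%; R_meas = sqrt(2)*2/20
        ds = make_subset([[1, 2, 3], [1, 2, 3]], [9.0, 11.0], [1.0, 1.0])
        scheme = gm.ShellScheme((25.0, 10.0, 7.0, 3.0))
        mg = gm.merge_group([ds], unit_scales(1))
        st = gm.compute_stats(mg, scheme, 1, with_completeness=False)
        assert st.overall.r_merge == pytest.approx(10.0, abs=1e-12)
        assert st.overall.r_meas == pytest.approx(100 * math.sqrt(2) * 2 / 20, abs=1e-12)


@pytest.mark.parametrize("n", [2, 3, 10])
def test_r_meas_r_merge_identity_at_uniform_multiplicity(n):
    """R_meas/R_merge = sqrt(n/(n-1)) exactly when every index has n observations."""
    rng = np.random.default_rng(n)
    hkl, intensity = [], []
    for idx in range(30):
        key = (idx % 5 + 1, idx // 5 + 1, 3)
        base = rng.uniform(10, 100)
        for _ in range(n):
            hkl.append(key)
            intensity.append(base * rng.uniform(0.9, 1.1))
    ds = make_subset(hkl, intensity, [1.0] * len(intensity))
    scheme = gm.ShellScheme((25.0, 10.0, 7.0, 2.0))
    mg = gm.merge_group([ds], unit_scales(1))
    st = gm.compute_stats(mg, scheme, 1, with_completeness=False)
    assert st.overall.r_meas / st.overall.r_merge == pytest.approx(math.sqrt(n / (n - 1)), rel=1e-12)


class TestNoiselessLimit:
    def test_zero_spread_gives_zero_r_and_full_cc(self, noiseless_pool, default_shells):
        pool, _ = noiseless_pool
        scales = gm.scale_group(pool)
        mg = gm.merge_group(pool, scales, rng_seed=1)
        st = gm.compute_stats(mg, default_shells, pool[0].space_group_number)
        for shell in st.shells + [st.overall]:
            assert shell.r_meas == pytest.approx(0.0, abs=1e-9)
            assert shell.r_merge == pytest.approx(0.0, abs=1e-9)
            assert shell.cc_half == pytest.approx(100.0, abs=1e-9)

    def test_monotone_degradation_with_noise(self):
        """R_meas rises and CC1/2 falls monotonically over a noise ladder."""
        r_vals, cc_vals = [], []
        for b_noise in [0.0, 25.0, 100.0, 400.0, 1600.0]:
            cfg = gm.SynthConfig(
                n_subsets=6,
                group_spec=((6, 0.0),),
                noise_a=0.0,
                noise_b=b_noise,
                scale_range=(1.0, 1.0),
                seed=17,
            )
            pool, _ = gm.generate_pool(cfg)
            scales = gm.scale_group(pool)
            mg = gm.merge_group(pool, scales, rng_seed=3)
            st = gm.compute_stats(mg, gm.make_shells(36.0, 2.0, 10), cfg.space_group_number)
            r_vals.append(st.overall.r_meas)
            cc_vals.append(st.overall.cc_half)
        assert r_vals == sorted(r_vals)
        assert cc_vals == sorted(cc_vals, reverse=True)


class TestAnomalous:
    def test_sigano_null_calibration(self):
        """No anomalous signal: SigAno ~ E|N(0,1)| = sqrt(2/pi) ~ 0.80."""
        cfg = gm.SynthConfig(
            n_subsets=20,
            group_spec=((20, 0.0),),
            cell=gm.UnitCell(44, 48, 52),
            completeness_per_subset=0.5,
            track_friedel=True,
            seed=2,
        )
        pool, _ = gm.generate_pool(cfg)
        scales = gm.scale_group(pool)
        mg = gm.merge_group(pool, scales, rng_seed=5)
        n_pairs = int(np.count_nonzero(~np.isnan(mg.mean_I_plus) & ~np.isnan(mg.mean_I_minus)))
        assert n_pairs >= 5000
        st = gm.compute_stats(mg, gm.make_shells(52.0, 2.0, 10), cfg.space_group_number)
        assert st.overall.sig_ano == pytest.approx(0.80, abs=0.05)

    def test_planted_signal_raises_inner_sigano(self):
        cfg = gm.SynthConfig(
            n_subsets=10, group_spec=((10, 0.0),), anomalous_frac=0.05, anomalous_index_frac=1.0, seed=2
        )
        pool, _ = gm.generate_pool(cfg)
        scales = gm.scale_group(pool)
        mg = gm.merge_group(pool, scales, rng_seed=5)
        st = gm.compute_stats(mg, gm.make_shells(36.0, 2.0, 10), cfg.space_group_number)
        assert st.inner.sig_ano > 2.0
        assert st.inner.cc_anom > 30.0


class TestShells:
    def test_make_shells_rejects_small_n(self):
        with pytest.raises(ValueError):
            gm.make_shells(10.0, 2.0, 2)

    def test_equal_reciprocal_volume_progression(self):
        scheme = gm.make_shells(20.0, 2.0, 5)
        inv3 = np.array(scheme.edges) ** -3.0
        steps = np.diff(inv3)
        np.testing.assert_allclose(steps, steps[0], rtol=1e-12)

    def test_explicit_edges_pass_through(self):
        scheme = gm.ShellScheme((30.0, 4.0, 3.0, 2.0))
        assert scheme.edges == (30.0, 4.0, 3.0, 2.0)
        assert scheme.n_shells == 3

    def test_assignment_covers_range_and_excludes_beyond(self):
        scheme = gm.make_shells(20.0, 2.0, 4)
        d = np.array([25.0, 20.0, 10.0, 2.0, 1.9])
        shells = gm.assign_shells(d, scheme)
        assert shells[0] == 0  # low-res straggler lands in the inner shell
        assert shells[-1] == -1  # beyond the resolution limit
        assert shells[3] == 3


class TestTheoreticalCount:
    def test_matches_sphere_enumeration_oracle(self):
        """Brute-force count of unique indices inside the resolution sphere."""
        cell = gm.UnitCell(10, 10, 10)
        scheme = gm.ShellScheme((10.0, 7.0, 6.0, 5.0))
        counts = gm.theoretical_count(scheme, cell, 1)
        # oracle: enumerate, keep one of {h, -h} per pair, count per shell
        seen = set()
        oracle = [0] * 3
        for h in range(-3, 4):
            for k in range(-3, 4):
                for l in range(-3, 4):
                    if (h, k, l) == (0, 0, 0):
                        continue
                    d = 10.0 / math.sqrt(h * h + k * k + l * l)
                    if d < 5.0 - 1e-9:
                        continue
                    key = max((h, k, l), (-h, -k, -l))
                    if key in seen:
                        continue
                    seen.add(key)
                    if d > 7.0:
                        oracle[0] += 1
                    elif d > 6.0:
                        oracle[1] += 1
                    else:
                        oracle[2] += 1
        assert counts.tolist() == oracle

    def test_full_coverage_is_complete(self, noiseless_pool):
        # a merged set containing every theoretical index reaches 100%
        cell = gm.UnitCell(10, 10, 10)
        scheme = gm.ShellScheme((11.0, 5.0, 4.0, 3.0))
        hmax = 4
        hkl = [
            (h, k, l)
            for h in range(-hmax, hmax + 1)
            for k in range(-hmax, hmax + 1)
            for l in range(-hmax, hmax + 1)
            if (h, k, l) != (0, 0, 0) and 10.0 / math.sqrt(h * h + k * k + l * l) >= 3.0
        ]
        ds = gm.SubDataset(
            id="full",
            cell=cell,
            space_group_number=1,
            friedel_law=True,
            hkl=np.array(hkl),
            intensity=np.ones(len(hkl)),
            sigma=np.ones(len(hkl)),
        )
        gm.reduce_to_asu(ds)
        mg = gm.merge_group([ds], unit_scales(1))
        st = gm.compute_stats(mg, scheme, 1)
        assert st.overall.completeness == pytest.approx(100.0)

    def test_reciprocal_volume_scaling(self):
        """Halving d_min multiplies the count by ~8."""
        cell = gm.UnitCell(30, 34, 36)
        c5 = gm.theoretical_count(gm.make_shells(40.0, 5.0, 3), cell, 1).sum()
        c25 = gm.theoretical_count(gm.make_shells(40.0, 2.5, 3), cell, 1).sum()
        assert c25 / c5 == pytest.approx(8.0, rel=0.1)

    def test_enumeration_bound_enforced(self):
        with pytest.raises(ResourceWarning):
            gm.theoretical_count(gm.make_shells(500.0, 0.2, 3), gm.UnitCell(500, 500, 500), 1)


def test_undefined_statistics_not_reported_as_zero():
    # 2 reflections in the outer shell: too few for a correlation
    ds = make_subset([[1, 0, 0], [1, 0, 0], [9, 9, 9], [9, 9, 9]], [10.0, 12.0, 5.0, 6.0], [1.0] * 4)
    scheme = gm.ShellScheme((25.0, 10.0, 3.0, 1.2))
    mg = gm.merge_group([ds], unit_scales(1))
    st = gm.compute_stats(mg, scheme, 1, with_completeness=False)
    assert st.outer.cc_half is None
    assert st.shells[1].mean_i_over_sigma is None  # empty middle shell
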