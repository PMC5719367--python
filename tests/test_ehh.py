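import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from sweepdate.ehh import (
    coalescence_interval,
    date_sweep,
    decay_span,
    ehh_profile,
    expected_generations,
)

from conftest import panel_from_strings


def brute_force_ehh(carriers: np.ndarray, core: int, marker: int) -> float:
    """Pairwise enumeration oracle: fraction of carrier pairs identical
    over the whole segment between the core and ``marker`` (inclusive)."""
    lo, hi = sorted((core, marker))
    seg = carriers[:, lo : hi + 1]
    n = seg.shape[0]
    same = sum(
        np.array_equal(seg[i], seg[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return same / (n * (n - 1) / 2)


class TestEHHProfile:
    def test_four_carriers_three_haplotype_classes(self):
        # carriers extend as A, A, B, C -> EHH = (1+0+0)/C(4,2) = 1/6
        haps = ["100", "100", "110", "101", "000", "011"]
        panel = panel_from_strings(haps)
        prof = ehh_profile(panel, 0, 1, threshold=0.0)
        assert prof.n_carriers == 4
        right = dict(zip(prof.marker_indices.tolist(), prof.ehh.tolist()))
        assert right[2] == pytest.approx(1 / 6)

    def test_core_value_is_one(self):
        panel = panel_from_strings(["10", "10", "11", "01"])
        prof = ehh_profile(panel, 0, 1, threshold=0.0)
        core_pos = np.flatnonzero(prof.marker_indices == 0)[0]
        assert prof.ehh[core_pos] == 1.0

    def test_fewer_than_two_carriers_rejected(self):
        panel = panel_from_strings(["10", "00", "00", "00"])
        with pytest.raises(ValueError, match="fewer than two carriers"):
            ehh_profile(panel, 0, 1)

    @given(data=st.data())
    def test_matches_pairwise_enumeration_and_monotone(self, data):
        n_chrom = data.draw(st.integers(4, 40).filter(lambda x: x % 2 == 0))
        m = data.draw(st.integers(3, 12))
        bits = data.draw(
            st.lists(
                st.lists(st.integers(0, 1), min_size=m, max_size=m),
                min_size=n_chrom,
                max_size=n_chrom,
            )
        )
        haps = ["".join(map(str, row)) for row in bits]
        panel = panel_from_strings(haps)
        core = data.draw(st.integers(0, m - 1))
        carriers = panel.haplotypes[panel.haplotypes[:, core] == 1]
        if carriers.shape[0] < 2:
            return
        prof = ehh_profile(panel, core, 1, threshold=0.0)
        for idx, ehh in zip(prof.marker_indices, prof.ehh):
            assert ehh == pytest.approx(brute_force_ehh(carriers, core, int(idx)))
        # non-increasing outward on each flank
        core_pos = int(np.flatnonzero(prof.marker_indices == core)[0])
        left = prof.ehh[: core_pos + 1][::-1]
        right = prof.ehh[core_pos:]
        assert np.all(np.diff(left) <= 1e-12)
        assert np.all(np.diff(right) <= 1e-12)

    def test_invariant_to_sample_relabeling(self, rng):
        haps = ["".join(rng.choice(["0", "1"], 10)) for _ in range(30)]
        panel = panel_from_strings(haps)
        prof1 = ehh_profile(panel, 5, 1, threshold=0.0)
        order = rng.permutation(15)
        permuted = []
        for i in order:
            permuted += [haps[2 * i], haps[2 * i + 1]]
        prof2 = ehh_profile(panel_from_strings(permuted), 5, 1, threshold=0.0)
        np.testing.assert_allclose(prof1.ehh, prof2.ehh)


class TestDecaySpan:
    def _panel_with_decay(self):
        # identical around core, diverging at the outermost markers
        haps = [
            "01100", "01100",
            "01101", "11100",
            "01110", "00100",
        ]
        return panel_from_strings(haps, spacing=1_000_000)

    def test_stop_to_stop_distance(self):
        panel = self._panel_with_decay()
        prof = ehh_profile(panel, 2, 1, threshold=0.45)
        span, censored = decay_span(prof)
        assert not censored
        assert span == int(
            panel.markers.pos[prof.right_stop] - panel.markers.pos[prof.left_stop]
        )

    def test_flat_profile_is_censored(self):
        panel = panel_from_strings(["111", "111", "111", "000"])
        prof = ehh_profile(panel, 1, 1)
        with pytest.raises(ValueError, match="censored"):
            decay_span(prof)
        span, censored = decay_span(prof, allow_censored=True)
        assert censored and span > 0


class TestExpectedGenerations:
    def test_direct_evaluation(self):
        r, e_g = expected_generations(cm_span=10.0, threshold_p=0.05)
        assert r == pytest.approx(0.1)
        assert e_g == pytest.approx(1 + 2.99573 / 0.1, abs=1e-2)

    def test_default_bp_conversion(self):
        r, _ = expected_generations(span_bp=1.23e6)
        assert r == pytest.approx(0.01)  # 1 Mbp at 1.23 Mbp/cM = 1 cM

    def test_inverse_for_printed_age(self):
        # E[g] = 77.2 corresponds to r ~ 0.03931 M ~ 4.84 Mbp
        r, e_g = expected_generations(span_bp=4.84e6)
        assert e_g == pytest.approx(77.2, rel=0.01)

    def test_limit_large_r(self):
        _, e_g = expected_generations(cm_span=1e9)
        assert e_g == pytest.approx(1.0, abs=1e-6)

    def test_classic_form_drops_offset(self):
        _, with_offset = expected_generations(cm_span=10.0)
        _, classic = expected_generations(cm_span=10.0, classic=True)
        assert with_offset == pytest.approx(classic + 1.0)

    def test_strictly_decreasing_in_r(self):
        ages = [expected_generations(cm_span=c)[1] for c in (1, 2, 5, 10, 50)]
        assert all(a > b for a, b in zip(ages, ages[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_generations(span_bp=-1.0)
        with pytest.raises(ValueError):
            expected_generations(span_bp=1e6, threshold_p=1.5)


class TestCoalescenceInterval:
    @pytest.mark.parametrize(
        "lam, expected_ci",
        [
            (13.0, (30.0, 100.0)),  # Nellore-style dating
            (24.2, (75.0, 170.0)),  # Brahman-style dating
        ],
    )
    def test_printed_intervals_at_default_seed(self, lam, expected_ci):
        res = coalescence_interval(lam, 5.0, n_reps=1_000_000, seed=1)
        assert res.ci_years == expected_ci

    def test_nw_european_upper_bound(self):
        res = coalescence_interval(77.2, 5.0, n_reps=1_000_000, seed=1)
        assert res.ci_years[1] == 475.0

    def test_analytic_mode_closed_form(self):
        res = coalescence_interval(77.2, 5.0, mode="analytic")
        assert res.ci_years == (
            stats.poisson.ppf(0.025, 77.2) * 5,
            stats.poisson.ppf(0.975, 77.2) * 5,
        )

    def test_normal_mode_symmetric(self):
        res = coalescence_interval(100.0, 5.0, mode="normal")
        lo, hi = res.ci_years
        assert hi - res.point_years == pytest.approx(res.point_years - lo, rel=1e-9)

    def test_point_estimate(self):
        res = coalescence_interval(77.2, 5.0, n_reps=100, seed=1)
        assert res.point_years == pytest.approx(386.0)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            coalescence_interval(0.0)


def test_date_sweep_pipeline_runs_end_to_end():
    from sweepdate.simulate import SweepSimConfig, simulate_sweep_panel

    cfg = SweepSimConfig(
        n_samples=200, n_markers=300, spacing_bp=20000, ne=200, age=60,
        s=0.3, seed=42, freq_window=(0.1, 1.0), max_restarts=2000,
    )
    panel, truth = simulate_sweep_panel(cfg)
    res = date_sweep(
        panel, truth.params["focal_index"], 1, n_reps=50_000, seed=5,
        allow_censored=True,
    )
    assert res.e_generations >= 1.0
    assert res.ci_years[0] <= res.point_years <= res.ci_years[1]
    assert res.r_morgans > 0
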