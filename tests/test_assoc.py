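import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import statsmodels.api as sm

from sweepdate.assoc import (
    AssocConfig,
    WeightedPhenotypes,
    compute_weights,
    gls_fit,
    load_phenotypes,
    partial_breeding_values,
    scan_windows,
)
from sweepdate.simulate import SweepSimConfig, simulate_phenotypes, simulate_sweep_panel
from sweepdate.windows import call_window_haplotypes, make_windows, score_genotypes

from conftest import panel_from_strings


class TestComputeWeights:
    def test_reference_evaluation(self):
        w = compute_weights(np.array([0.9025]), h2=0.37, c=0.9191)
        assert w[0] == pytest.approx(0.60324, abs=1e-5)

    def test_unit_weight_case(self):
        assert compute_weights(np.array([0.5]), h2=0.5, c=0.0)[0] == pytest.approx(1.0)

    def test_perfect_reliability_without_c_fails(self):
        with pytest.raises(ValueError, match="non-positive weight"):
            compute_weights(np.array([1.0]), h2=0.37, c=0.0)

    def test_invalid_reliability(self):
        with pytest.raises(ValueError, match="reliabilities"):
            compute_weights(np.array([0.0]), h2=0.37, c=0.9)


class TestGLSFit:
    def test_ols_identity_case(self):
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            fit = gls_fit([1, 2, 3], [-1, 0, 1])
        assert fit.mu == pytest.approx(2.0)
        assert fit.alpha == pytest.approx(1.0)
        assert fit.zero_residual and fit.p == 0.0

    def test_four_point_reference(self):
        fit = gls_fit([1, 2, 3, 2], [-1, 0, 0, 1])
        assert fit.alpha == pytest.approx(0.5)
        assert fit.mu == pytest.approx(2.0)
        assert fit.se == pytest.approx(0.6124, abs=2e-4)
        assert fit.t == pytest.approx(0.8165, abs=2e-4)
        assert fit.df == 2

    @given(scale=st.floats(0.01, 100.0))
    def test_weight_scale_invariance(self, scale):
        y = np.array([0.3, -1.2, 2.0, 0.7, -0.4])
        z = np.array([-1.0, 0.0, 1.0, 2.0, -2.0])
        w = np.array([0.5, 1.0, 2.0, 0.8, 1.5])
        a = gls_fit(y, z, w)
        b = gls_fit(y, z, w * scale)
        for field in ("mu", "alpha", "se", "t", "p"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-9)

    def test_matches_statsmodels_wls(self, rng):
        n = 60
        z = rng.normal(size=n)
        y = 0.4 * z + rng.normal(size=n)
        w = rng.uniform(0.3, 3.0, size=n)
        fit = gls_fit(y, z, w)
        ref = sm.WLS(y, sm.add_constant(z), weights=1.0 / w).fit()
        assert fit.mu == pytest.approx(ref.params[0], rel=1e-8)
        assert fit.alpha == pytest.approx(ref.params[1], rel=1e-8)
        assert fit.se == pytest.approx(ref.bse[1], rel=1e-8)
        assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_unit_weights_equal_ols(self, rng):
        z = rng.normal(size=30)
        y = 1.5 - 0.3 * z + rng.normal(size=30)
        a = gls_fit(y, z, None)
        b = gls_fit(y, z, np.full(30, 1.0))
        assert a.alpha == pytest.approx(b.alpha, abs=1e-10)
        coef = np.polyfit(z, y, 1)
        assert a.alpha == pytest.approx(coef[0], rel=1e-10)

    def test_p_invariant_to_phenotype_shift(self, rng):
        z = rng.normal(size=25)
        y = 0.2 * z + rng.normal(size=25)
        w = rng.uniform(0.5, 2.0, size=25)
        assert gls_fit(y, z, w).p == pytest.approx(gls_fit(y + 7.3, z, w).p, rel=1e-9)

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gls_fit([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])


class TestBinaryMode:
    def test_reduces_to_ols_on_coded_trait(self, rng):
        haps = ["".join(rng.choice(["0", "1"], 4)) for _ in range(60)]
        panel = panel_from_strings(haps)
        y = rng.choice([-1.0, 1.0], size=30)
        phenos = WeightedPhenotypes.binary(panel.samples, y)
        result = scan_windows(panel, make_windows(4, 2), phenos, AssocConfig(min_freq=0.05))
        w = call_window_haplotypes(panel, (0, 2))
        g = score_genotypes(panel, w)
        k = w.alleles.index(result.table.iloc[0]["haplotype"])
        ref = np.polyfit(g.z[:, k], y, 1)
        assert result.table.iloc[0]["alpha"] == pytest.approx(ref[0], rel=1e-9)

    def test_label_mapping(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("sample_id\tvalue\ns1\thorned\ns2\tpolled\ns3\thorned\n")
        phenos = load_phenotypes(path, binary=True)
        np.testing.assert_array_equal(phenos.y, [-1.0, 1.0, -1.0])
        np.testing.assert_array_equal(phenos.weights, 1.0)


def test_partial_breeding_values_center_on_zero(rng):
    z = rng.normal(size=50)
    z -= z.mean()
    u = partial_breeding_values(z, 0.311)
    assert u.mean() == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(u, z * 0.311)
    assert np.all(partial_breeding_values(z, 0.0) == 0.0)


class TestScanWindows:
    def test_tag_recovers_planted_effect(self):
        """The scan's tag window must bracket the causal marker."""
        hits = 0
        n_reps = 50
        for rep in range(n_reps):
            cfg = SweepSimConfig(
                n_samples=600, n_markers=40, spacing_bp=500_000, ne=600,
                age=40, s=0.35, seed=300 + rep, freq_window=(0.15, 0.85),
                max_restarts=5000,
            )
            panel, truth = simulate_sweep_panel(cfg)
            focal = truth.params["focal_index"]
            causal = call_window_haplotypes(panel, (focal, focal + 1))
            phenos, _ = simulate_phenotypes(
                panel, causal, "1", alpha=0.5, seed=1000 + rep
            )
            result = scan_windows(
                panel, make_windows(40, 6), phenos, AssocConfig(min_freq=0.05)
            )
            tag = result.tag
            start = result.table.loc[result.table["is_tag"], "window_index"].iloc[0]
            window_span = make_windows(40, 6)[int(start)]
            if window_span[0] - 2 <= focal <= window_span[1] + 1:
                hits += 1
        assert hits / n_reps >= 0.95

    def test_phenotypes_outside_panel_rejected(self, rng):
        panel = panel_from_strings(["01", "10", "11", "00"])
        phenos = WeightedPhenotypes.binary(("s0", "zz"), np.array([-1.0, 1.0]))
        with pytest.raises(ValueError, match="subset"):
            scan_windows(panel, [(0, 2)], phenos)

    def test_exactly_one_tag_flag(self, rng):
        haps = ["".join(rng.choice(["0", "1"], 8)) for _ in range(80)]
        panel = panel_from_strings(haps)
        phenos = WeightedPhenotypes.binary(
            panel.samples, rng.choice([-1.0, 1.0], size=40)
        )
        result = scan_windows(panel, make_windows(8, 3), phenos, AssocConfig(min_freq=0.05))
        assert result.table["is_tag"].sum() == 1
        assert result.tag["p"] == result.table["p"].min()
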