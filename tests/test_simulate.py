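"""Synthetic-data generator: marginals, dependence structure, missingness."""

import numpy as np
import pytest
from scipy.stats import norm

from smdsnet.data import SMDS_ITEM_NAMES
from smdsnet.polychoric import estimate_summary
from smdsnet.simulate import (
    AuxBlockSpec,
    GeneratorSpec,
    GroupDesign,
    default_spec,
    equal_loadings_for_omega,
    impose_missingness,
    simulate_auxiliary,
    simulate_dataset,
    simulate_multigroup,
    simulate_onefactor,
    simulate_residual_dependence,
)


class TestOneFactor:
    def test_independence_case_zero_loadings(self):
        m = simulate_onefactor(np.zeros(9), np.zeros(9), n=100_000, seed=1)
        rates = m.values.mean(axis=0)
        np.testing.assert_allclose(rates, 0.5, atol=0.006)
        s = estimate_summary(m.values, [2] * 9, compute_gamma=False)
        off = s.rho[np.triu_indices(9, 1)]
        assert np.max(np.abs(off)) < 0.02

    def test_equal_loadings_give_constant_tetrachorics(self):
        m = simulate_onefactor(np.full(9, 0.75), np.zeros(9), n=150_000, seed=2)
        s = estimate_summary(m.values, [2] * 9, compute_gamma=False)
        off = s.rho[np.triu_indices(9, 1)]
        np.testing.assert_allclose(off, 0.5625, atol=0.02)

    def test_marginal_endorsement_matches_normal_cdf(self, table_params):
        lam, tau = table_params
        m = simulate_onefactor(n=200_000, seed=3)
        expected = 1.0 - norm.cdf(tau)
        np.testing.assert_allclose(m.values.mean(axis=0), expected, atol=0.006)

    def test_seed_determinism(self):
        a = simulate_onefactor(n=500, seed=9)
        b = simulate_onefactor(n=500, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestResidualDependence:
    def test_zero_structure_reduces_to_onefactor(self, table_params):
        lam, tau = table_params
        a = simulate_residual_dependence(lam, tau, None, 400, seed=5)
        b = simulate_onefactor(lam, tau, 400, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_injected_edge_sign_preserved(self, table_params, sign):
        lam, tau = table_params
        om = np.zeros((9, 9))
        om[5, 8] = om[8, 5] = sign * 0.12
        m = simulate_residual_dependence(lam, tau, om, 60_000, seed=6)
        s = estimate_summary(m.values, [2] * 9, compute_gamma=False)
        resid = s.rho - np.outer(lam, lam)
        np.fill_diagonal(resid, 0.0)
        assert np.sign(resid[5, 8]) == sign
        assert abs(resid[5, 8]) == np.max(np.abs(resid))

    def test_nonpd_structure_rejected(self, table_params):
        lam, tau = table_params
        om = np.full((9, 9), 0.5)
        np.fill_diagonal(om, 0.0)
        with pytest.raises(ValueError, match="positive definite"):
            simulate_residual_dependence(lam, tau, om, 100, seed=0)


class TestMultigroup:
    def test_no_offsets_matches_single_group_distribution(self):
        spec = GeneratorSpec(groups=[GroupDesign("boy", 11, 40_000),
                                     GroupDesign("girl", 11, 40_000)])
        m = simulate_multigroup(spec, seed=7)
        rates_b = m.values[m.gender == "boy"].mean(axis=0)
        rates_g = m.values[m.gender == "girl"].mean(axis=0)
        np.testing.assert_allclose(rates_b, rates_g, atol=0.012)

    def test_negative_offset_raises_endorsement(self):
        # a lower threshold for girls makes the item easier to endorse
        spec = GeneratorSpec(groups=[
            GroupDesign("boy", 11, 50_000, threshold_offsets={"escape": +0.1}),
            GroupDesign("girl", 11, 50_000, threshold_offsets={"escape": -0.1}),
        ])
        m = simulate_multigroup(spec, seed=8)
        j = list(SMDS_ITEM_NAMES).index("escape")
        assert (m.values[m.gender == "girl", j].mean()
                > m.values[m.gender == "boy", j].mean())

    def test_group_mean_ordering_reflected_in_sum_scores(self):
        spec = GeneratorSpec(groups=[
            GroupDesign("boy", 11, 30_000, mean=0.0),
            GroupDesign("boy", 13, 30_000, mean=0.25),
            GroupDesign("boy", 15, 30_000, mean=0.5),
        ])
        m = simulate_multigroup(spec, seed=9)
        means = [m.values[m.age == a].sum(axis=1).mean() for a in (11, 13, 15)]
        assert means[0] < means[1] < means[2]

    def test_unknown_offset_item_rejected(self):
        with pytest.raises(ValueError, match="unknown item"):
            GroupDesign("boy", 11, 10, threshold_offsets={"nope": 0.1})


class TestAuxiliary:
    def test_zero_correlation_blocks_are_independent(self):
        spec = GeneratorSpec(
            aux_blocks=[AuxBlockSpec.from_omega("ocf", 4, 5, 0.72)],
            construct_corr=np.eye(2))
        m = simulate_auxiliary(spec, n=50_000, seed=10)
        r = np.corrcoef(m.values[:, :9].sum(axis=1),
                        m.values[:, 9:].sum(axis=1))[0, 1]
        assert abs(r) < 0.02

    def test_omega_target_loadings_closed_form(self):
        lam = equal_loadings_for_omega(0.72, 4)
        s = lam.sum()
        omega = s * s / (s * s + np.sum(1 - lam ** 2))
        assert omega == pytest.approx(0.72, abs=1e-12)

    def test_category_ranges_respected(self):
        spec = default_spec()
        m = simulate_auxiliary(spec, n=2000, seed=11)
        for col, meta in enumerate(m.items):
            lo, hi = meta.code_range
            assert m.values[:, col].min() >= lo
            assert m.values[:, col].max() <= hi


class TestMissingness:
    def test_zero_rates_identity(self):
        m = simulate_onefactor(n=300, seed=12)
        spec = GeneratorSpec(missing_rates={})
        out = impose_missingness(m, spec, seed=0)
        assert not out.missing_mask.any()
        np.testing.assert_array_equal(out.values, m.values)

    def test_mcar_fraction_matches_rate(self):
        m = simulate_onefactor(n=50_000, seed=13)
        spec = GeneratorSpec(missing_rates={"escape": 0.19})
        out = impose_missingness(m, spec, seed=1)
        j = list(SMDS_ITEM_NAMES).index("escape")
        assert out.missing_mask[:, j].mean() == pytest.approx(0.19, abs=0.006)
        others = [c for c in range(9) if c != j]
        assert not out.missing_mask[:, others].any()

    def test_mar_depends_on_gender_not_value(self):
        spec = GeneratorSpec(
            groups=[GroupDesign("boy", 11, 40_000),
                    GroupDesign("girl", 11, 40_000)],
            missing_rates={"escape": 0.2}, missing_mechanism="MAR_gender")
        m = simulate_multigroup(spec, seed=14)
        out = impose_missingness(m, spec, seed=2)
        j = list(SMDS_ITEM_NAMES).index("escape")
        rate_b = out.missing_mask[out.gender == "boy", j].mean()
        rate_g = out.missing_mask[out.gender == "girl", j].mean()
        assert rate_g > 1.5 * rate_b
        # masking independent of the (generated) value within gender
        for g in ("boy", "girl"):
            sel = out.gender == g
            masked = out.missing_mask[sel, j]
            vals = m.values[sel, j]
            assert abs(vals[masked].mean() - vals[~masked].mean()) < 0.03

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(missing_rates={"escape": 1.0})


class TestFullDataset:
    def test_shapes_and_determinism(self):
        spec = default_spec()
        for g in spec.groups:
            g.n = 300
        a = simulate_dataset(spec, seed=15)
        b = simulate_dataset(spec, seed=15)
        assert a.values.shape == (1800, 31)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.missing_mask, b.missing_mask)
        assert set(np.unique(a.gender)) == {"boy", "girl"}
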