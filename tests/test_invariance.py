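"""Multigroup invariance ladder, decision rules, partial search, group means."""

import numpy as np
import pytest

from smdsnet.data import SMDS_ITEM_NAMES
from smdsnet.invariance import (
    InvarianceCriteria,
    compare_levels,
    decide,
    estimate_group_means,
    fit_multigroup,
    group_summaries,
    modification_indices,
    partial_invariance_search,
)
from smdsnet.simulate import GeneratorSpec, GroupDesign, simulate_multigroup

IDX = {nm: i for i, nm in enumerate(SMDS_ITEM_NAMES)}


def _two_group_data(seed=1, girls_mean=0.0, girls_sd=1.0, offsets_girl=None,
                    offsets_boy=None, n=(6808, 6569)):
    spec = GeneratorSpec(groups=[
        GroupDesign("boy", 11, n[0], 0.0, 1.0, offsets_boy or {}),
        GroupDesign("girl", 11, n[1], girls_mean, girls_sd, offsets_girl or {}),
    ])
    m = simulate_multigroup(spec, seed=seed)
    return group_summaries(m, by=("gender",))


@pytest.fixture(scope="module")
def invariant_fits():
    labels, summ, ns = _two_group_data(seed=77)
    conf = fit_multigroup(summ, ns, "configural", labels=labels)
    met = fit_multigroup(summ, ns, "metric", labels=labels)
    sca = fit_multigroup(summ, ns, "scalar", labels=labels)
    return labels, summ, ns, conf, met, sca


class TestDecisionEngine:
    # printed delta-fit rows of the emulated analysis, with their verdicts
    PRINTED = [
        ("metric", 0.002, -0.003, "accept"),
        ("scalar", -0.020, 0.005, "reject"),
        ("scalar", -0.001, -0.001, "accept"),
        ("latent_means", -0.016, 0.006, "reject"),
        ("metric", 0.003, -0.005, "accept"),
        ("scalar", -0.015, 0.005, "reject"),
        ("scalar", -0.003, 0.000, "accept"),
        ("latent_means", -0.010, 0.005, "reject"),
        ("metric", 0.002, -0.005, "accept"),
        ("scalar", -0.003, -0.001, "accept"),
        ("latent_means", -0.023, 0.011, "reject"),
    ]

    @pytest.mark.parametrize("level, d_cfi, d_rmsea, expected", PRINTED)
    def test_reproduces_published_verdicts(self, level, d_cfi, d_rmsea, expected):
        assert decide(level, d_cfi, d_rmsea) == expected

    def test_boundary_values_accepted(self):
        assert decide("metric", -0.004, 0.05) == "accept"
        assert decide("scalar", -0.004, 0.01) == "accept"
        assert decide("scalar", -0.0041, 0.0) == "reject"

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            decide("configural", 0.0, 0.0)


class TestMultigroupFit:
    def test_df_ladder_matches_constraint_arithmetic(self, invariant_fits):
        _, _, _, conf, met, sca = invariant_fits
        assert conf.dwls.df == 54
        assert met.dwls.df == 62
        assert sca.dwls.df == 70

    def test_identical_populations_accept_all_levels(self, invariant_fits):
        _, _, _, conf, met, sca = invariant_fits
        cm = compare_levels(conf, met, "metric")
        cs = compare_levels(met, sca, "scalar")
        assert cm.verdict == "accept" and cs.verdict == "accept"
        gm = estimate_group_means(sca)
        assert abs(gm.table["mean"].iloc[1]) < 0.06

    def test_nested_objective_ordering(self, invariant_fits):
        _, _, _, conf, met, sca = invariant_fits
        assert conf.dwls.t0 <= met.dwls.t0 + 1e-9 <= sca.dwls.t0 + 1e-8

    def test_identical_fits_give_zero_deltas(self, invariant_fits):
        labels, summ, ns, conf, met, sca = invariant_fits
        sca2 = fit_multigroup(summ, ns, "scalar", labels=labels)
        with pytest.raises(ValueError):
            compare_levels(sca, sca2)  # not nested: equal df
        comp = compare_levels(met, sca, "scalar")
        comp2 = compare_levels(met, sca2, "scalar")
        assert comp.d_cfi == comp2.d_cfi

    def test_empty_group_rejected(self, invariant_fits):
        labels, summ, ns, *_ = invariant_fits
        with pytest.raises(ValueError):
            fit_multigroup(summ, [ns[0], 0], "metric")

    def test_six_group_constraint_check(self):
        spec = GeneratorSpec(groups=[
            GroupDesign(g, a, 1200, m, 1.0)
            for (g, a, m) in [("boy", 11, 0.0), ("girl", 11, -0.01),
                              ("boy", 13, 0.1), ("girl", 13, 0.36),
                              ("boy", 15, 0.1), ("girl", 15, 0.46)]])
        m = simulate_multigroup(spec, seed=5)
        labels, summ, ns = group_summaries(m, by=("gender", "age_class"))
        sca = fit_multigroup(summ, ns, "scalar", labels=labels)
        gm = estimate_group_means(sca, "cohens_d")
        assert gm.table["mean"].mean() == pytest.approx(0.0, abs=1e-10)
        assert (gm.table["sd"] ** 2).mean() == pytest.approx(1.0, abs=1e-10)


class TestModificationIndices:
    def test_detects_injected_threshold_offset(self):
        hits = 0
        for rep in range(20):
            labels, summ, ns = _two_group_data(
                seed=900 + rep, offsets_girl={"withdrawal": 0.2})
            sca = fit_multigroup(summ, ns, "scalar", labels=labels)
            mi = modification_indices(sca)
            if int(mi.iloc[0]["item"]) == IDX["withdrawal"]:
                hits += 1
        assert hits >= 19

    def test_freeing_top_constraint_reduces_chi2_by_mi(self):
        labels, summ, ns = _two_group_data(seed=33,
                                           offsets_girl={"withdrawal": 0.2})
        sca = fit_multigroup(summ, ns, "scalar", labels=labels)
        mi = modification_indices(sca)
        top = mi.iloc[0]
        freed = {int(top["item"]): "all"}
        sca_free = fit_multigroup(summ, ns, "scalar", freed=freed, labels=labels)
        drop = sca.dwls.t0 - sca_free.dwls.t0
        assert drop == pytest.approx(top["mi"], rel=0.35)

    def test_null_false_positive_rate_controlled(self):
        false_frees = 0
        crit = InvarianceCriteria()
        for rep in range(20):
            labels, summ, ns = _two_group_data(seed=1500 + rep)
            met = fit_multigroup(summ, ns, "metric", labels=labels)
            sca = fit_multigroup(summ, ns, "scalar", labels=labels)
            if compare_levels(met, sca, "scalar", crit).verdict == "reject":
                false_frees += 1
        assert false_frees <= 2


class TestPartialSearch:
    def test_recovers_offset_items(self):
        labels, summ, ns = _two_group_data(
            seed=41,
            offsets_boy={"tolerance": 0.03, "persistence": 0.18, "escape": 0.18},
            offsets_girl={"tolerance": 0.15, "persistence": -0.05,
                          "escape": -0.02})
        met = fit_multigroup(summ, ns, "metric", labels=labels)
        res = partial_invariance_search(summ, ns, met, "scalar", labels=labels)
        assert res.succeeded
        target = {IDX["tolerance"], IDX["persistence"], IDX["escape"]}
        assert set(res.freed) <= target
        assert len(res.freed) >= 2

    def test_invariant_data_needs_no_search(self, invariant_fits):
        labels, summ, ns, conf, met, sca = invariant_fits
        comp = compare_levels(met, sca, "scalar")
        assert comp.verdict == "accept"

    def test_widespread_offsets_fail_anchoring(self):
        offs = {nm: (0.4 if i % 2 else -0.4)
                for i, nm in enumerate(SMDS_ITEM_NAMES[:8])}
        labels, summ, ns = _two_group_data(seed=55, offsets_girl=offs,
                                           n=(6000, 6000))
        met = fit_multigroup(summ, ns, "metric", labels=labels)
        with pytest.warns(UserWarning, match="anchor budget"):
            res = partial_invariance_search(summ, ns, met, "scalar",
                                            labels=labels, max_freed=3)
        assert not res.succeeded


class TestGroupMeans:
    def test_reference_and_d_parametrizations_agree(self):
        labels, summ, ns = _two_group_data(seed=60, girls_mean=0.3)
        sca = fit_multigroup(summ, ns, "scalar", labels=labels)
        ref = estimate_group_means(sca, "reference")
        d = estimate_group_means(sca, "cohens_d")
        np.testing.assert_allclose(ref.contrasts["d"], d.contrasts["d"],
                                   atol=1e-6)
        np.testing.assert_allclose(ref.contrasts["se"], d.contrasts["se"],
                                   atol=1e-6)

    def test_configural_model_refuses_means(self, invariant_fits):
        _, _, _, conf, *_ = invariant_fits
        with pytest.raises(ValueError, match="scalar"):
            estimate_group_means(conf)

    def test_null_contrast_near_zero(self, invariant_fits):
        *_, sca = invariant_fits
        gm = estimate_group_means(sca, "cohens_d")
        d = gm.contrasts["d"].iloc[0]
        assert abs(d) < 0.07
        assert gm.contrasts["lo"].iloc[0] < 0 < gm.contrasts["hi"].iloc[0]
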