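"""Relative-risk rescaling, categorical expansion and random-effects pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebwcost import (
    RelativeRiskEstimate,
    StudyEstimate,
    categorical_profile,
    default_schema,
    pool_random_effects,
    rescale_rr,
)


class TestRescale:
    def test_per5_to_per1_published_example(self, endometrium_rr):
        r1 = rescale_rr(endometrium_rr, 1.0)
        assert round(r1.rr, 2) == 1.08
        assert (round(r1.ci_low, 2), round(r1.ci_high, 2)) == (1.07, 1.10)

    def test_null_effect_invariant(self):
        est = RelativeRiskEstimate("x", "F", 5.0, 1.0, 1.0, 1.0)
        assert rescale_rr(est, 1.0).rr == 1.0

    def test_same_increment_is_identity(self, endometrium_rr):
        assert rescale_rr(endometrium_rr, 5.0) == endometrium_rr

    def test_round_trip_recovers_input(self):
        est = RelativeRiskEstimate("esophagus_adenocarcinoma", "M", 5.0, 1.56, 1.39, 1.74)
        r1 = rescale_rr(est, 1.0)
        assert r1.rr == pytest.approx(1.0930, abs=5e-5)
        back = rescale_rr(r1, 5.0)
        assert back.rr == pytest.approx(1.56, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        rr=st.floats(0.5, 3.0),
        width=st.floats(1.001, 1.5),
        x=st.floats(0.5, 10.0),
        target=st.floats(0.5, 10.0),
    )
    def test_round_trip_property(self, rr, width, x, target):
        est = RelativeRiskEstimate("c", "F", x, rr, rr / width, rr * width)
        back = rescale_rr(rescale_rr(est, target), x)
        for a, b in zip((back.rr, back.ci_low, back.ci_high), (est.rr, est.ci_low, est.ci_high)):
            assert a == pytest.approx(b, rel=1e-12)

    def test_rejects_nonpositive_increment(self, endometrium_rr):
        with pytest.raises(ValueError):
            rescale_rr(endometrium_rr, 0.0)

    def test_rejects_nonpositive_rr(self):
        with pytest.raises(ValueError):
            RelativeRiskEstimate("c", "F", 5.0, -1.0, 0.5, 2.0)


class TestCategoricalProfile:
    @pytest.mark.parametrize(
        "rr1, delta, expected",
        [(1.08, 10.0, 2.158925), (1.02, 5.0, 1.104081)],
    )
    def test_power_expansion(self, rr1, delta, expected):
        from ebwcost import BMICategory, BMICategorySchema

        schema = BMICategorySchema(
            (
                BMICategory("ref", 0.0, 25.0, 22.0, reference=True),
                BMICategory("exposed", 25.0, math.inf, 22.0 + delta),
            )
        )
        est = RelativeRiskEstimate("c", "F", 1.0, rr1, rr1, rr1)
        prof = categorical_profile(est, schema)
        assert prof.rr[-1] == pytest.approx(expected, abs=1e-6)

    def test_reference_is_exactly_one(self, schema):
        est = RelativeRiskEstimate("c", "F", 1.0, 1.08, 1.07, 1.10)
        prof = categorical_profile(est, schema)
        assert prof.rr[schema.reference_index] == 1.0

    @pytest.mark.parametrize("rr1", [1.05, 0.95])
    def test_monotone_in_median(self, schema, rr1):
        est = RelativeRiskEstimate("c", "F", 1.0, rr1, rr1, rr1)
        values = np.array(categorical_profile(est, schema).rr)
        diffs = np.diff(values)
        assert np.all(diffs > 0) if rr1 > 1 else np.all(diffs < 0)

    def test_requires_per_unit_input(self, schema, endometrium_rr):
        with pytest.raises(ValueError, match="per 1"):
            categorical_profile(endometrium_rr, schema)

    def test_custom_ref_value_changes_nothing_downstream(self, schema):
        # the profile is normalized by the reference category, so the PIF
        # is unaffected by the choice of ref
        est = RelativeRiskEstimate("c", "F", 1.0, 1.08, 1.07, 1.10)
        a = categorical_profile(est, schema).values
        b = categorical_profile(est, schema, ref_value=25.0).values
        np.testing.assert_allclose(a, b, rtol=1e-12)


def _dl_oracle(y, se):
    """Longhand DerSimonian–Laird: Q, τ², re-weighting, explicitly."""
    w = [1.0 / s**2 for s in se]
    mu_fe = sum(wi * yi for wi, yi in zip(w, y)) / sum(w)
    q = sum(wi * (yi - mu_fe) ** 2 for wi, yi in zip(w, y))
    c = sum(w) - sum(wi**2 for wi in w) / sum(w)
    tau2 = max(0.0, (q - (len(y) - 1)) / c)
    ws = [1.0 / (s**2 + tau2) for s in se]
    mu = sum(wi * yi for wi, yi in zip(ws, y)) / sum(ws)
    return mu, math.sqrt(1.0 / sum(ws)), tau2


class TestPooling:
    STUDIES = [
        StudyEstimate("a", 0.10, 0.05),
        StudyEstimate("b", 0.20, 0.10),
        StudyEstimate("c", 0.00, 0.08),
    ]

    def test_single_study_returned_unchanged(self):
        pooled = pool_random_effects([StudyEstimate("a", 0.10, 0.05)])
        assert math.log(pooled.rr) == pytest.approx(0.10, abs=1e-12)

    def test_identical_effects_give_zero_heterogeneity(self):
        studies = [StudyEstimate(str(i), 0.15, 0.05 + 0.01 * i) for i in range(4)]
        pooled = pool_random_effects(studies)
        assert math.log(pooled.rr) == pytest.approx(0.15, abs=1e-12)

    def test_matches_longhand_oracle(self):
        pooled = pool_random_effects(self.STUDIES)
        mu, se, _ = _dl_oracle([0.10, 0.20, 0.00], [0.05, 0.10, 0.08])
        assert math.log(pooled.rr) == pytest.approx(mu, abs=1e-9)
        assert math.log(pooled.ci_high / pooled.rr) == pytest.approx(1.959964 * se, abs=1e-9)

    def test_matches_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects

        y = np.array([0.10, 0.20, 0.00])
        v = np.array([0.05, 0.10, 0.08]) ** 2
        res = combine_effects(y, v, method_re="dl")
        pooled = pool_random_effects(self.STUDIES)
        assert math.log(pooled.rr) == pytest.approx(res.mean_effect_re, abs=1e-10)

    def test_zero_tau2_reduces_to_inverse_variance(self):
        # homogeneous effects: DL weights equal fixed-effect weights
        studies = [
            StudyEstimate("a", 0.10, 0.05),
            StudyEstimate("b", 0.10, 0.10),
            StudyEstimate("c", 0.10, 0.08),
        ]
        pooled = pool_random_effects(studies)
        w = [1 / 0.05**2, 1 / 0.10**2, 1 / 0.08**2]
        fe_se = math.sqrt(1.0 / sum(w))
        assert math.log(pooled.ci_high / pooled.rr) == pytest.approx(1.959964 * fe_se, rel=1e-9)

    def test_outcome_filter(self):
        studies = self.STUDIES + [StudyEstimate("d", 0.9, 0.1, outcome="mortality")]
        pooled = pool_random_effects(studies, outcome_filter="incidence")
        mu, _, _ = _dl_oracle([0.10, 0.20, 0.00], [0.05, 0.10, 0.08])
        assert math.log(pooled.rr) == pytest.approx(mu, abs=1e-9)

    def test_empty_after_filter_raises(self):
        with pytest.raises(ValueError):
            pool_random_effects(self.STUDIES, outcome_filter="mortality")
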