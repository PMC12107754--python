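"""Sigmoid substituent weighting and wEFV query construction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from fragvec import (
    AnalogueSeries,
    Fragment,
    WeightProfile,
    WeightScheme,
    normalized_weights,
    raw_weight,
    substituent_query,
    weighted_query,
)

FRAG_POOL = [
    "[*]C", "[*]CC", "[*]CCC", "[*]O", "[*]OC", "[*]N", "[*]F", "[*]Cl",
    "[*]Br", "[*]C#N", "[*]c1ccccc1", "[*]S", "[*]I", "[*]CO", "[*]C=C",
    "[*]CN", "[*]NC", "[*]CCO", "[*]CCN", "[*]C(C)C",
]


def make_series(potencies):
    members = [
        (Fragment.from_smiles(FRAG_POOL[i]), float(p))
        for i, p in enumerate(potencies)
    ]
    return AnalogueSeries("t", members)


class TestRawWeight:
    def test_sigmoid_midpoint(self):
        # at x == L/D the sigmoid argument is 0, denominator 1 + e^0 = 2
        assert raw_weight(1.0, 5, 10, 2.0) == pytest.approx(0.5)

    def test_reference_formula_on_fixture_series(self, example_series):
        # independent evaluation of Pot_x / (1 + exp(x - L/D))
        L, D = 10, 2.0
        for x in range(1, L + 1):
            pot = example_series.potency(x)
            expected = pot / (1.0 + math.exp(x - L / D))
            assert raw_weight(pot, x, L, D) == pytest.approx(
                expected, rel=1e-12
            )

    def test_equal_potency_weights_strictly_decrease_with_x(self):
        w = [raw_weight(7.0, x, 12, 3.0) for x in range(1, 13)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_overflow_safe_far_from_midpoint(self):
        assert raw_weight(8.0, 500, 500, 0.5) == pytest.approx(
            8.0 * float(expit(500 / 0.5 - 500))
        )
        assert raw_weight(8.0, 1, 10**6, 1.0) == pytest.approx(8.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            raw_weight(float("nan"), 1, 5, 1.0)
        with pytest.raises(ValueError):
            raw_weight(7.0, 0, 5, 1.0)
        with pytest.raises(ValueError):
            raw_weight(7.0, 1, 5, -1.0)
        with pytest.raises(ValueError):
            raw_weight(-1.0, 1, 5, 1.0)

    def test_zero_potency_warns_and_gives_zero(self):
        with pytest.warns(UserWarning, match="zero potency"):
            assert raw_weight(0.0, 1, 5, 1.0) == 0.0


class TestNormalizedWeights:
    @given(
        st.integers(3, 20),
        st.sampled_from([0.5, 1.0, 2.0, 3.0]),
        st.integers(0, 2**31 - 1),
    )
    def test_sum_to_one_and_nonnegative(self, length, d, seed):
        rng = np.random.default_rng(seed)
        potencies = np.sort(4.0 + 6.0 * rng.random(length))
        series = make_series(potencies)
        profile = normalized_weights(series, WeightScheme("slope", d))
        assert len(profile) == length - 1
        assert abs(math.fsum(profile.normalized) - 1.0) <= 1e-12
        assert all(w >= 0 for w in profile.normalized)

    def test_average_mode_constant_weights(self, example_series):
        profile = normalized_weights(example_series, WeightScheme("average", None))
        assert len(profile) == 10
        assert all(w == pytest.approx(0.1) for w in profile.normalized)

    def test_larger_slope_concentrates_weight_near_terminal(
        self, example_series
    ):
        w1, w2, w3 = (
            normalized_weights(
                example_series, WeightScheme("slope", d)
            ).normalized[0]
            for d in (1.0, 2.0, 3.0)
        )
        assert w3 > w2 > w1

    def test_degenerate_all_zero_weights_rejected(self):
        series = make_series([0.0, 0.0, 0.0])
        with pytest.warns(UserWarning, match="zero potency"):
            with pytest.raises(ValueError, match="degenerate"):
                normalized_weights(series, WeightScheme("slope", 1.0))

    def test_profile_json_roundtrip(self, tmp_path, example_series):
        import json

        profile = normalized_weights(example_series, WeightScheme("slope", 2.0))
        payload = json.loads(profile.to_json(tmp_path / "w.json"))
        assert payload["positions"] == list(range(1, 11))
        assert payload["normalized"] == list(profile.normalized)
        assert payload["scheme"] == {"mode": "slope", "D": 2.0}


class TestQueryVectors:
    @pytest.fixture()
    def series_in_model(self, fixture_model, small_corpus):
        return next(s for s in small_corpus if len(s) >= 6)

    def test_average_mode_equals_mean_of_member_efvs(
        self, fixture_model, series_in_model
    ):
        s = series_in_model
        q = weighted_query(fixture_model, s, WeightScheme("average", None))
        stack = np.stack(
            [
                fixture_model.get_efv(s.substituent(x))
                for x in range(1, len(s))
            ]
        )
        assert np.allclose(q, stack.mean(axis=0), atol=1e-12)

    def test_delta_profile_returns_single_member_efv_exactly(
        self, fixture_model, series_in_model
    ):
        s = series_in_model
        L = len(s) - 1
        delta = WeightProfile(
            (1.0,) + (0.0,) * (L - 1),
            (1.0,) + (0.0,) * (L - 1),
            WeightScheme("average", None),
        )
        q = weighted_query(fixture_model, s, profile=delta)
        assert np.array_equal(q, fixture_model.get_efv(s.substituent(1)))

    def test_wefv_matches_independent_weighted_sum(
        self, fixture_model, series_in_model
    ):
        s = series_in_model
        scheme = WeightScheme("slope", 2.0)
        profile = normalized_weights(s, scheme)
        expected = sum(
            w * fixture_model.get_efv(s.substituent(x))
            for x, w in enumerate(profile.normalized, start=1)
        )
        q = weighted_query(fixture_model, s, scheme)
        assert np.allclose(q, expected, atol=1e-12)

    def test_linearity_in_the_profile(self, fixture_model, series_in_model):
        s = series_in_model
        L = len(s) - 1
        p1 = normalized_weights(s, WeightScheme("slope", 1.0))
        p2 = normalized_weights(s, WeightScheme("average", None))
        alpha = 0.3
        mixed = WeightProfile(
            tuple(
                alpha * a + (1 - alpha) * b
                for a, b in zip(p1.normalized, p2.normalized)
            ),
            tuple(
                alpha * a + (1 - alpha) * b
                for a, b in zip(p1.normalized, p2.normalized)
            ),
            WeightScheme("average", None),
        )
        q_mix = weighted_query(fixture_model, s, profile=mixed)
        q1 = weighted_query(fixture_model, s, profile=p1)
        q2 = weighted_query(fixture_model, s, profile=p2)
        assert np.allclose(q_mix, alpha * q1 + (1 - alpha) * q2, atol=1e-12)

    def test_substituent_query_indexing(self, fixture_model, series_in_model):
        s = series_in_model
        L = len(s) - 1
        assert np.array_equal(
            substituent_query(fixture_model, s, 1),
            fixture_model.get_efv(s.fragments[-2]),
        )
        assert np.array_equal(
            substituent_query(fixture_model, s, L),
            fixture_model.get_efv(s.fragments[0]),
        )
        with pytest.raises(ValueError, match="outside"):
            substituent_query(fixture_model, s, L + 1)
        with pytest.raises(ValueError, match="outside"):
            substituent_query(fixture_model, s, 0)
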