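import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsirisk.slide_inference import (
    ELIMINATED,
    GPConfig,
    RatioVector,
    SlidePrediction,
    UnclassifiableSlideError,
    ValidationError,
    aggregate_patient,
    compute_ratio_vector,
    fit_slide_classifier,
    load_slide_classifier,
    predict_slide,
    resolve_patch_label,
    save_slide_classifier,
)
from wsirisk.synthetic import CLASSES, HIGH_RISK, LOW_RISK


class TestResolvePatchLabel:
    def test_one_hot_resolves(self):
        assert resolve_patch_label((1, 0, 0, 0)) == "punlmp"
        assert resolve_patch_label((0, 0, 1, 0)) == "high_grade"

    def test_all_negative_eliminated(self):
        assert resolve_patch_label((0, 0, 0, 0)) == ELIMINATED

    def test_multiple_positive_eliminated(self):
        assert resolve_patch_label((1, 1, 0, 0)) == ELIMINATED
        assert resolve_patch_label((1, 1, 1, 1)) == ELIMINATED

    def test_exhaustive_16_combinations(self):
        resolved = 0
        for bits in itertools.product((0, 1), repeat=4):
            fate = resolve_patch_label(bits)
            if sum(bits) == 1:
                resolved += 1
                assert fate == CLASSES[bits.index(1)]
            else:
                assert fate == ELIMINATED
        assert resolved == 4

    def test_wrong_arity(self):
        with pytest.raises(ValidationError):
            resolve_patch_label((1, 0, 0))


class TestComputeRatioVector:
    def test_homogeneous_slide(self):
        rv = compute_ratio_vector(["punlmp"] * 10)
        assert rv.ratios["punlmp"] == 1.0
        assert rv.low_risk_ratio == 1.0
        assert rv.high_risk_ratio == 0.0

    def test_mixed_with_eliminated(self):
        fates = ["punlmp"] * 3 + ["low_grade"] * 3 + [ELIMINATED] * 2
        rv = compute_ratio_vector(fates)
        assert rv.low_risk_ratio == 0.75
        assert rv.high_risk_ratio == 0.0
        assert sum(rv.ratios.values()) == 0.75
        assert rv.n_eliminated == 2

    def test_zero_patches_raises(self):
        with pytest.raises(UnclassifiableSlideError):
            compute_ratio_vector([])

    def test_resolved_denominator_mode(self):
        fates = ["invasive"] * 2 + [ELIMINATED] * 2
        rv = compute_ratio_vector(fates, denominator_mode="resolved")
        assert rv.ratios["invasive"] == 1.0

    def test_all_eliminated_resolved_mode_raises(self):
        with pytest.raises(UnclassifiableSlideError):
            compute_ratio_vector([ELIMINATED] * 4, denominator_mode="resolved")

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(
            st.integers(0, 40), min_size=5, max_size=5
        ).filter(lambda c: sum(c) > 0)
    )
    def test_ratio_conservation_exact(self, counts):
        fates = []
        for label, count in zip(list(CLASSES) + [ELIMINATED], counts):
            fates.extend([label] * count)
        rv = compute_ratio_vector(fates)
        total = sum(
            Fraction(f).limit_denominator(10**9) for f in rv.ratios.values()
        ) + Fraction(rv.n_eliminated, rv.n_patches)
        assert total == 1


def separable_fixture(n_per_class=50, jitter=0.02, seed=0):
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for i in range(n_per_class):
        for (low, high), label in (
            ((0.9, 0.05), LOW_RISK),
            ((0.05, 0.9), HIGH_RISK),
        ):
            eps = abs(rng.normal(0, jitter))
            vectors.append(
                RatioVector(
                    slide_id=f"{label}_{i}",
                    ratios={
                        "punlmp": low / 2,
                        "low_grade": max(low / 2 - eps, 0.0),
                        "high_grade": high / 2,
                        "invasive": max(high / 2 - eps, 0.0),
                    },
                    n_patches=100,
                    n_eliminated=0,
                )
            )
            labels.append(label)
    return vectors, labels


class TestSlideClassifier:
    def test_separable_training_accuracy(self):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        predictions = [predict_slide(model, rv) for rv in vectors]
        assert all(p.risk == label for p, label in zip(predictions, labels))

    def test_probability_range_random_vectors(self):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        rng = np.random.default_rng(1)
        for _ in range(1000):
            low, high = rng.dirichlet([1, 1, 1])[:2]
            rv = RatioVector(
                slide_id="q",
                ratios={
                    "punlmp": low / 2,
                    "low_grade": low / 2,
                    "high_grade": high / 2,
                    "invasive": high / 2,
                },
                n_patches=10,
                n_eliminated=0,
            )
            assert 0.0 <= predict_slide(model, rv).probability_high <= 1.0

    def test_feature_swap_symmetry(self):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        swapped = [
            RatioVector(
                rv.slide_id,
                {
                    "punlmp": rv.ratios["high_grade"],
                    "low_grade": rv.ratios["invasive"],
                    "high_grade": rv.ratios["punlmp"],
                    "invasive": rv.ratios["low_grade"],
                },
                rv.n_patches,
                rv.n_eliminated,
            )
            for rv in vectors
        ]
        flipped = [HIGH_RISK if l == LOW_RISK else LOW_RISK for l in labels]
        mirror = fit_slide_classifier(swapped, flipped, GPConfig(seed=0))
        query = np.array([[0.3, 0.6], [0.7, 0.1], [0.5, 0.5]])
        p = model.predict_probability(query)
        q = mirror.predict_probability(query[:, ::-1])
        assert np.abs(p - (1 - q)).max() < 1e-6

    def test_refit_deterministic(self):
        vectors, labels = separable_fixture()
        a = fit_slide_classifier(vectors, labels, GPConfig(seed=3))
        b = fit_slide_classifier(vectors, labels, GPConfig(seed=3))
        query = np.array([[0.2, 0.7], [0.6, 0.3]])
        assert np.array_equal(a.predict_probability(query), b.predict_probability(query))

    def test_order_invariance(self):
        vectors, labels = separable_fixture()
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(vectors))
        shuffled = fit_slide_classifier(
            [vectors[i] for i in perm], [labels[i] for i in perm], GPConfig(seed=0)
        )
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        query = np.array([[0.4, 0.5]])
        assert (
            abs(
                model.predict_probability(query)[0]
                - shuffled.predict_probability(query)[0]
            )
            < 1e-8
        )

    def test_single_class_training_rejected(self):
        vectors, _ = separable_fixture(n_per_class=3)
        with pytest.raises(ValidationError):
            fit_slide_classifier(vectors, [LOW_RISK] * len(vectors), GPConfig())

    def test_midpoint_of_symmetric_training_set(self):
        ratios_low = {"punlmp": 0.45, "low_grade": 0.45, "high_grade": 0.05, "invasive": 0.05}
        ratios_high = {"punlmp": 0.05, "low_grade": 0.05, "high_grade": 0.45, "invasive": 0.45}
        vectors = [
            RatioVector("l1", ratios_low, 10, 0),
            RatioVector("l2", ratios_low, 10, 0),
            RatioVector("h1", ratios_high, 10, 0),
            RatioVector("h2", ratios_high, 10, 0),
        ]
        model = fit_slide_classifier(
            vectors, [LOW_RISK, LOW_RISK, HIGH_RISK, HIGH_RISK], GPConfig(seed=0)
        )
        midpoint = np.array([[0.5, 0.5]])
        assert abs(model.predict_probability(midpoint)[0] - 0.5) < 0.02

    def test_feature_dimension_mismatch(self):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        with pytest.raises(ValidationError):
            model.predict_probability(np.array([[0.1, 0.2, 0.3, 0.4]]))

    def test_per_class_feature_mode(self):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(
            vectors, labels, GPConfig(feature_mode="per_class", seed=0)
        )
        assert model.n_features == 4
        predictions = [predict_slide(model, rv) for rv in vectors]
        accuracy = np.mean([p.risk == l for p, l in zip(predictions, labels)])
        assert accuracy == 1.0

    def test_serialization_round_trip(self, tmp_path):
        vectors, labels = separable_fixture()
        model = fit_slide_classifier(vectors, labels, GPConfig(seed=0))
        save_slide_classifier(model, tmp_path / "gp.pkl")
        loaded = load_slide_classifier(tmp_path / "gp.pkl")
        query = np.array([[0.3, 0.5]])
        assert np.array_equal(
            model.predict_probability(query), loaded.predict_probability(query)
        )
        assert (tmp_path / "gp.pkl.json").exists()


class TestAggregatePatient:
    def test_single_slide_identity(self):
        pred = SlidePrediction("s1", LOW_RISK, 0.2)
        agg = aggregate_patient([pred])
        assert agg.risk == LOW_RISK and agg.probability_high == 0.2

    def test_max_rule(self):
        agg = aggregate_patient(
            [SlidePrediction("a", LOW_RISK, 0.2), SlidePrediction("b", HIGH_RISK, 0.9)]
        )
        assert agg.risk == HIGH_RISK and agg.probability_high == 0.9

    def test_all_low_stays_low(self):
        agg = aggregate_patient(
            [SlidePrediction("a", LOW_RISK, 0.1), SlidePrediction("b", LOW_RISK, 0.3)]
        )
        assert agg.risk == LOW_RISK

    def test_tie_at_half_is_high(self):
        agg = aggregate_patient([SlidePrediction("a", HIGH_RISK, 0.5)])
        assert agg.risk == HIGH_RISK

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_patient([])
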