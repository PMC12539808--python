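import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oracle import oracle_pci
from pcindex import (
    ConstantVariableWarning,
    ProactiveConservationIndex,
    ValidationError,
    VariableSpec,
    VariableTable,
    WeightScheme,
    interaction_products,
    log1p_transform,
    min_max_scale,
    orient_variable,
    pci,
)
from pcindex.simulate import worked_fixture

from conftest import random_table


class TestLog1pTransform:
    def test_closed_form_values(self):
        assert log1p_transform([0.0]) == pytest.approx([0.0])
        assert log1p_transform([math.e - 1]) == pytest.approx([1.0])
        np.testing.assert_allclose(
            log1p_transform([10, 100, 1000]),
            [2.3979, 4.6151, 6.9088],
            atol=5e-4,
        )

    def test_negative_input_names_species(self):
        with pytest.raises(ValidationError, match="sp_bad"):
            log1p_transform([1.0, -0.5], name="mass", species_ids=["sp_ok", "sp_bad"])

    @given(hst.lists(hst.floats(0, 1e9), min_size=2, max_size=20, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_order_preserving(self, xs):
        order = np.argsort(xs)
        np.testing.assert_array_equal(np.argsort(log1p_transform(xs)), order)


class TestMinMaxScale:
    def test_affine_map(self):
        np.testing.assert_allclose(min_max_scale([0, 5, 10]), [0, 0.5, 1])

    def test_hand_evaluated_log_values(self):
        np.testing.assert_allclose(
            min_max_scale([2.3979, 4.6151, 6.9088]), [0, 0.4915, 1], atol=2e-4
        )

    def test_constant_vector_returns_zeros_with_warning(self):
        with pytest.warns(ConstantVariableWarning):
            out = min_max_scale([7.0, 7.0, 7.0])
        np.testing.assert_array_equal(out, [0, 0, 0])

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            min_max_scale([1.0])

    @given(
        hst.lists(
            hst.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_extremes(self, xs):
        out = min_max_scale(xs)
        assert out.min() == 0.0 and out.max() == 1.0
        assert (out >= 0).all() and (out <= 1).all()


class TestOrientVariable:
    def test_inversion_and_identity(self):
        np.testing.assert_allclose(
            orient_variable([0, 0.5, 1], "inverted"), [1, 0.5, 0]
        )
        np.testing.assert_allclose(orient_variable([0.2], "direct"), [0.2])

    def test_double_inversion_is_identity(self):
        x = np.linspace(0, 1, 7)
        np.testing.assert_allclose(
            orient_variable(orient_variable(x, "inverted"), "inverted"), x
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            orient_variable([1.2], "direct")


class TestInteractionProducts:
    def idx(self, n):
        return pd.Index([f"s{i}" for i in range(n)])

    def test_elementwise_product_example(self):
        T = pd.DataFrame({"t": [0, 0.585, 1]}, index=self.idx(3))
        V = pd.DataFrame({"v": [0, 0.639, 1]}, index=self.idx(3))
        R = interaction_products(T, V, {("t", "v"): 1.0})
        np.testing.assert_allclose(R["t"], [0, 0.585 * 0.639, 1])

    def test_threat_without_modifiers_passes_through(self):
        T = pd.DataFrame({"t": [0.1, 0.9]}, index=self.idx(2))
        V = pd.DataFrame(index=self.idx(2))
        R = interaction_products(T, V, {})
        np.testing.assert_array_equal(R["t"], T["t"])

    def test_linear_in_interaction_weights(self):
        rng = np.random.default_rng(0)
        T = pd.DataFrame({"t": rng.uniform(0, 1, 5)}, index=self.idx(5))
        V = pd.DataFrame(
            {"u": rng.uniform(0, 1, 5), "v": rng.uniform(0, 1, 5)}, index=self.idx(5)
        )
        z = {("t", "u"): 0.7, ("t", "v"): 1.3}
        z2 = {k: 2 * v for k, v in z.items()}
        np.testing.assert_allclose(
            interaction_products(T, V, z2)["t"],
            2 * interaction_products(T, V, z)["t"],
        )

    def test_unknown_columns_rejected(self):
        T = pd.DataFrame({"t": [0.1, 0.2]}, index=self.idx(2))
        V = pd.DataFrame({"v": [0.1, 0.2]}, index=self.idx(2))
        with pytest.raises(ValidationError, match="unknown"):
            interaction_products(T, V, {("t", "w"): 1.0})

    def test_power_mode_uses_weight_as_exponent(self):
        T = pd.DataFrame({"t": [1.0, 1.0]}, index=self.idx(2))
        V = pd.DataFrame({"v": [0.25, 0.5]}, index=self.idx(2))
        R = interaction_products(T, V, {("t", "v"): 2.0}, mode="power")
        np.testing.assert_allclose(R["t"], [0.0625, 0.25])


class TestPciAggregation:
    def test_extreme_species_score_exactly_zero_and_one(self):
        R = pd.DataFrame(
            {"a": [0.0, 1.0, 0.4], "b": [0.0, 1.0, 0.7]}, index=["lo", "hi", "mid"]
        )
        p = pci(R, {"a": 1.0, "b": 1.0})
        assert p["lo"] == 0.0 and p["hi"] == 1.0

    def test_identical_columns_equal_single_column(self):
        col = np.array([0.2, 0.9, 0.5])
        R1 = pd.DataFrame({"a": col})
        R3 = pd.DataFrame({"a": col, "b": col, "c": col})
        p1 = pci(R1, {"a": 1.0})
        p3 = pci(R3, {"a": 1.0, "b": 1.0, "c": 1.0})
        np.testing.assert_allclose(p1, p3)

    def test_all_zero_weights_rejected(self):
        R = pd.DataFrame({"a": [0.1, 0.9]})
        with pytest.raises(ValidationError):
            pci(R, {"a": 0.0})


class TestComputePci:
    def test_worked_fixture_matches_hand_oracle(self):
        table, expected, weights = worked_fixture()
        scores = ProactiveConservationIndex(table, weights=weights).fit().scores
        np.testing.assert_allclose(scores.to_numpy(), expected, atol=1e-9)

    def test_matches_brute_force_transcription(self, rng):
        for _ in range(40):
            table, weights = random_table(rng)
            got = (
                ProactiveConservationIndex(table, weights=weights, cohort="global")
                .fit()
                .scores
            )
            expected = oracle_pci(
                {c: table.values[c].tolist() for c in table.values},
                {s.name: (s.role, s.direction, s.transform) for s in table.specs},
                weights.threat_weights,
                weights.interaction_weights,
            )
            np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        table, weights = random_table(rng, n_species=6, n_threats=2, n_modifiers=1)
        perm = rng.permutation(table.n_species)
        shuffled = VariableTable(table.values.iloc[perm], table.specs)
        base = ProactiveConservationIndex(table, weights=weights, cohort="global").fit()
        shuf = ProactiveConservationIndex(shuffled, weights=weights, cohort="global").fit()
        np.testing.assert_allclose(
            shuf.scores.reindex(base.scores.index), base.scores, atol=1e-14
        )

    def test_variable_column_order_is_irrelevant(self, rng):
        table, weights = random_table(rng, n_species=5, n_threats=3, n_modifiers=2)
        reordered = VariableTable(
            table.values[table.values.columns[::-1]], list(reversed(table.specs))
        )
        a = ProactiveConservationIndex(table, weights=weights, cohort="global").fit()
        b = ProactiveConservationIndex(reordered, weights=weights, cohort="global").fit()
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-14)

    def test_threat_weight_scale_invariance(self, rng):
        table, weights = random_table(rng, n_species=6, n_threats=3, n_modifiers=2)
        scaled = WeightScheme(
            {k: 10 * v for k, v in weights.threat_weights.items()},
            dict(weights.interaction_weights),
        )
        a = ProactiveConservationIndex(table, weights=weights, cohort="global").fit()
        b = ProactiveConservationIndex(table, weights=scaled, cohort="global").fit()
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_single_threat_interaction_row_scale_invariance(self, rng):
        table, weights = random_table(rng, n_species=6, n_threats=3, n_modifiers=2)
        one_threat = table.threat_names[0]
        zw = {
            k: (7.3 * v if k[0] == one_threat else v)
            for k, v in weights.interaction_weights.items()
        }
        scaled = WeightScheme(dict(weights.threat_weights), zw)
        a = ProactiveConservationIndex(table, weights=weights, cohort="global").fit()
        b = ProactiveConservationIndex(table, weights=scaled, cohort="global").fit()
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_weak_monotonicity_in_oriented_threat_values(self, rng):
        # raising a direct threat value of one species never lowers its score
        for _ in range(25):
            table, weights = random_table(rng, n_threats=2, n_modifiers=1)
            direct_threats = [
                s.name for s in table.specs
                if s.role == "threat" and s.direction == "direct"
            ]
            if not direct_threats:
                continue
            var = direct_threats[0]
            sp = table.species_ids[int(rng.integers(table.n_species))]
            bumped = table.values.copy()
            bumped.loc[sp, var] += float(rng.uniform(0.1, 5.0))
            t2 = VariableTable(bumped, table.specs)
            before = ProactiveConservationIndex(
                table, weights=weights, cohort="global"
            ).fit().scores[sp]
            after = ProactiveConservationIndex(
                t2, weights=weights, cohort="global"
            ).fit().scores[sp]
            assert after >= before - 1e-12

    def test_log1p_scaling_preserves_within_variable_ranks(self, rng):
        raw = rng.lognormal(3, 2, 12)
        scaled = min_max_scale(log1p_transform(raw))
        np.testing.assert_array_equal(np.argsort(scaled), np.argsort(raw))


class TestCohorts:
    def build(self, rng, classes):
        table, weights = random_table(rng, n_species=len(classes), n_threats=2,
                                      n_modifiers=1)
        labelled = VariableTable(
            table.values,
            table.specs,
            class_labels=pd.Series(classes, index=table.species_ids),
        )
        return labelled, weights

    def test_class_cohorts_scale_independently(self, rng):
        table, weights = self.build(rng, ["A", "A", "A", "B", "B", "B"])
        joint = ProactiveConservationIndex(table, weights=weights, cohort="class").fit()
        for cls in ("A", "B"):
            members = table.species_ids[table.class_labels == cls]
            solo = ProactiveConservationIndex(
                table.subset(members), weights=weights, cohort="global"
            ).fit()
            np.testing.assert_allclose(
                joint.scores[members], solo.scores, atol=1e-14
            )

    def test_small_cohort_skipped_and_reported(self, rng):
        table, weights = self.build(rng, ["A", "A", "A", "A", "A", "B"])
        res = ProactiveConservationIndex(table, weights=weights, cohort="class").fit()
        assert res.skipped_cohorts == ["B"]
        assert len(res.scores) == 5

    def test_every_nondegenerate_cohort_hits_both_bounds(self, community_results):
        for cohort in community_results.cohorts.unique():
            s = community_results.scores[community_results.cohorts == cohort]
            assert s.min() == 0.0 and s.max() == 1.0

    def test_summary_mentions_cohorts(self, community_results):
        text = community_results.summary()
        assert "Proactive Conservation Index" in text
        assert all(c in text for c in community_results.cohorts.unique())


class TestResultsSurface:
    def test_to_frame_with_intermediates(self, community_results):
        df = community_results.to_frame(intermediates=True)
        assert "pci" in df.columns and "cohort" in df.columns
        assert any(c.startswith("r_") for c in df.columns)
        assert any(c.startswith("scaled_") for c in df.columns)

    def test_scores_lie_in_unit_interval(self, community_results):
        s = community_results.scores
        assert (s >= 0).all() and (s <= 1).all()

    def test_constant_variable_warns_but_completes(self):
        ids = pd.Index(["a", "b", "c"])
        df = pd.DataFrame({"t0": [1.0, 1.0, 1.0], "t1": [0.0, 0.5, 1.0]}, index=ids)
        table = VariableTable(df, [VariableSpec("t0"), VariableSpec("t1")])
        model = ProactiveConservationIndex(table, cohort="global")
        with pytest.warns(ConstantVariableWarning):
            res = model.fit()
        np.testing.assert_allclose(res.scores, [0, 0.5849625007211562, 1], atol=1e-9)
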