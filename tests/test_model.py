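"""Unit and property tests of the 2-HT tree structure."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lineup2ht import (
    ConditionParams,
    LineupCounts,
    ModelSpec,
    ValidationError,
    category_probabilities,
    expected_counts,
    export_eqn,
    validate_dataset,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


def params_strategy():
    return st.builds(ConditionParams, dP=probs, b=probs, g=probs, dA=probs)


class TestCategoryProbabilities:
    def test_certain_presence_detection_forces_culprit_id(self):
        p = category_probabilities(ConditionParams(1.0, 0.3, 0.7, 0.2))
        assert p.cp().tolist() == [1.0, 0.0, 0.0]

    def test_pure_guessing_splits_by_lineup_size(self):
        # a random chooser lands on a filler five times as often as on the
        # suspect in a six-person lineup
        p = category_probabilities(
            ConditionParams(0.0, 0.0, 1.0, 0.0), sampling_constant=1 / 6
        )
        assert p.p_cp_culprit == pytest.approx(1 / 6)
        assert p.p_cp_filler == pytest.approx(5 / 6)
        assert p.p_cp_reject == 0.0

    def test_certain_absence_detection_forces_rejection(self):
        p = category_probabilities(ConditionParams(0.5, 0.3, 0.7, 1.0))
        assert p.ca().tolist() == [0.0, 0.0, 1.0]

    def test_branch_formulas_term_by_term(self):
        # independent hand evaluation of each branch product
        dP, b, g, dA, c = 0.2820, 0.04, 0.45, 0.02, 0.16667
        p = category_probabilities(ConditionParams(dP, b, g, dA), c)
        assert p.p_cp_culprit == pytest.approx(
            dP + (1 - dP) * b + (1 - dP) * (1 - b) * g * c, abs=1e-12
        )
        assert p.p_cp_filler == pytest.approx(
            (1 - dP) * (1 - b) * g * (1 - c), abs=1e-12
        )
        assert p.p_cp_reject == pytest.approx(
            (1 - dP) * (1 - b) * (1 - g), abs=1e-12
        )
        assert p.p_ca_suspect == pytest.approx(
            (1 - dA) * b + (1 - dA) * (1 - b) * g * c, abs=1e-12
        )
        assert p.p_ca_filler == pytest.approx(
            (1 - dA) * (1 - b) * g * (1 - c), abs=1e-12
        )
        assert p.p_ca_reject == pytest.approx(
            dA + (1 - dA) * (1 - b) * (1 - g), abs=1e-12
        )

    def test_out_of_range_parameter_names_offending_field(self):
        with pytest.raises(ValidationError, match="dA"):
            ConditionParams(0.5, 0.5, 0.5, 1.2)
        with pytest.raises(ValidationError, match="sampling_constant"):
            category_probabilities(
                ConditionParams(0.5, 0.5, 0.5, 0.5), sampling_constant=0.0
            )

    @given(params_strategy())
    def test_trees_sum_to_one(self, params):
        p = category_probabilities(params)
        assert p.cp().sum() == pytest.approx(1.0, abs=1e-12)
        assert p.ca().sum() == pytest.approx(1.0, abs=1e-12)

    @given(params_strategy(), st.floats(0.0, 0.5))
    def test_detection_monotonicity(self, params, bump):
        # culprit identifications rise with dP; rejections rise with dA
        p0 = category_probabilities(params)
        p1 = category_probabilities(
            ConditionParams(min(params.dP + bump, 1.0), params.b, params.g,
                            min(params.dA + bump, 1.0))
        )
        assert p1.p_cp_culprit >= p0.p_cp_culprit - 1e-12
        assert p1.p_ca_reject >= p0.p_ca_reject - 1e-12

    @given(probs, probs, probs)
    def test_fair_lineup_signature(self, dP, g, dA):
        # with no bias the suspect is picked 1/(n-1) as often as a filler
        c = 1 / 6
        p = category_probabilities(ConditionParams(dP, 0.0, g, dA), c)
        assert p.p_ca_suspect * (1 - c) / c == pytest.approx(
            p.p_ca_filler, abs=1e-12
        )

    @given(probs)
    def test_no_detection_no_bias_makes_trees_identical(self, g):
        p = category_probabilities(ConditionParams(0.0, 0.0, g, 0.0))
        assert p.cp() == pytest.approx(p.ca(), abs=1e-15)


class TestExpectedCounts:
    def test_degenerate_probabilities(self):
        p = category_probabilities(ConditionParams(1.0, 0.0, 0.0, 1.0))
        np.testing.assert_allclose(
            expected_counts(p, 100, 100), [100, 0, 0, 0, 0, 100]
        )

    def test_expected_totals_match_tree_totals(self):
        p = category_probabilities(ConditionParams(0.3, 0.1, 0.6, 0.05))
        e = expected_counts(p, 300, 200)
        assert e[:3].sum() == pytest.approx(300)
        assert e[3:].sum() == pytest.approx(200)

    def test_negative_totals_rejected(self):
        p = category_probabilities(ConditionParams(0.3, 0.1, 0.6, 0.05))
        with pytest.raises(ValidationError):
            expected_counts(p, -1, 10)


class TestValidateDataset:
    def test_study_ordered_by_actual_delay(self, study):
        assert [cond.actual_delay_days for cond in study] == [0, 1, 8, 33]
        assert len(study) == 4

    def test_zero_tree_total_rejected(self):
        bad = LineupCounts("x", "none", 0, 0, 0, 0, 1, 2, 3)
        with pytest.raises(ValidationError, match="'x'"):
            validate_dataset([bad])

    def test_duplicate_condition_rejected(self, study):
        with pytest.raises(ValidationError, match="duplicate"):
            validate_dataset(list(study) + [study[0]])

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="cp_filler"):
            LineupCounts("x", "none", 0, 1, -1, 2, 1, 2, 3)


class TestExportEqn:
    def test_single_condition_has_ten_branches(self):
        text = export_eqn(ModelSpec.saturated(("only",)))
        assert len(text.strip().splitlines()) == 10

    def test_base_model_shares_one_b_symbol(self, base_spec):
        text = export_eqn(base_spec)
        lines = text.strip().splitlines()
        assert len(lines) == 40
        symbols = {tok for line in lines for tok in
                   line.split()[2].replace("(1-", " ").replace(")", " ")
                   .replace("*", " ").split()}
        # one shared b, per-condition dP/g/dA, numeric sampling constant
        assert "b" in symbols
        assert not any(s.startswith("b[") for s in symbols)
        assert sum(s.startswith("dP[") for s in symbols) == 4
        assert "0.16667" in symbols

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValidationError):
            export_eqn(ModelSpec(conditions=()))
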