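"""Propagation engine: closed forms, budgets, and the Monte Carlo oracle."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biorefuq.uncertainty import (
    DuplicateInputError,
    EvaluationError,
    Measurement,
    UncertaintyError,
    mc_oracle,
    propagate,
    rank_contributions,
)


def _product_inputs():
    return [Measurement("k1", 10.0, 0.1), Measurement("k2", 20.0, 0.4)]


class TestPropagateClosedForms:
    @pytest.mark.parametrize(
        "expr,inputs,value,uncertainty",
        [
            # identity passes value and uncertainty through unchanged
            (lambda k1: k1, [("k1", 5.0, 0.1)], 5.0, 0.1),
            # sum: 3-4-5 quadrature
            (lambda k1, k2: k1 + k2, [("k1", 1.0, 3.0), ("k2", 2.0, 4.0)],
             3.0, 5.0),
            # product: relative quadrature
            (lambda k1, k2: k1 * k2, [("k1", 10.0, 0.1), ("k2", 20.0, 0.4)],
             200.0, 200.0 * math.hypot(0.01, 0.02)),
            # quotient: relative quadrature
            (lambda a, b: a / b, [("a", 8.0, 0.16), ("b", 4.0, 0.12)],
             2.0, 2.0 * math.hypot(0.02, 0.03)),
            # power: |n| * relative uncertainty
            (lambda k: k ** 3, [("k", 2.0, 0.04)], 8.0, 8.0 * 3 * 0.02),
        ],
    )
    def test_matches_analytic_quadrature(self, expr, inputs, value,
                                         uncertainty):
        budget = propagate(expr, [Measurement(*i) for i in inputs])
        assert budget.value == pytest.approx(value, rel=1e-9)
        assert budget.combined_uncertainty == pytest.approx(uncertainty,
                                                            rel=1e-6)

    def test_exact_gradient_hook_is_used(self):
        class Expr:
            def __call__(self, k1, k2):
                return k1 * k2

            def gradient(self, values):
                return {"k1": values["k2"], "k2": values["k1"]}

        budget = propagate(Expr(), _product_inputs())
        # partials are exact, not finite-difference approximations
        assert budget.terms[0].partial == 20.0
        assert budget.terms[1].partial == 10.0

    def test_duplicate_input_names_rejected(self):
        with pytest.raises(DuplicateInputError, match="k1"):
            propagate(lambda k1: k1, [Measurement("k1", 1, 0.1),
                                      Measurement("k1", 2, 0.1)])

    def test_nonfinite_evaluation_names_offending_input(self):
        def expr(k1, k2):
            return math.sqrt(k1) + k2

        # base point is evaluable but the central-difference stencil for k1
        # steps into the negative domain
        with pytest.raises((EvaluationError, ValueError)):
            propagate(expr, [Measurement("k1", 1e-14, 0.1),
                             Measurement("k2", 1.0, 0.1)])


class TestBudgetInvariants:
    @settings(deadline=None, max_examples=50)
    @given(
        vals=st.lists(st.floats(0.5, 50.0), min_size=2, max_size=5),
        uncs=st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
    )
    def test_terms_sum_to_variance_and_fractions_to_one(self, vals, uncs):
        inputs = [Measurement(f"k{i}", v, u)
                  for i, (v, u) in enumerate(zip(vals, uncs))]

        def expr(**kw):
            ks = [kw[f"k{i}"] for i in range(len(inputs))]
            return sum(k ** 2 for k in ks) + math.prod(ks)

        budget = propagate(expr, inputs)
        var = budget.combined_uncertainty ** 2
        assert sum(t.term for t in budget.terms) == pytest.approx(var,
                                                                  rel=1e-9,
                                                                  abs=1e-30)
        if budget.combined_uncertainty > 0:
            assert sum(t.fraction for t in budget.terms) == pytest.approx(
                1.0, abs=1e-9)
            assert all(t.fraction >= 0 for t in budget.terms)

    @settings(deadline=None, max_examples=30)
    @given(c=st.floats(0.0, 10.0))
    def test_uncertainty_scales_linearly_with_input_uncertainties(self, c):
        base = [Measurement("a", 3.0, 0.06), Measurement("b", 7.0, 0.21)]
        scaled = [Measurement(m.name, m.value, c * m.std_uncertainty)
                  for m in base]
        expr = lambda a, b: a * b + a / b  # noqa: E731
        u0 = propagate(expr, base).combined_uncertainty
        uc = propagate(expr, scaled).combined_uncertainty
        assert uc == pytest.approx(c * u0, rel=1e-12, abs=1e-15)


class TestRankContributions:
    def test_orders_descending_with_values_intact(self):
        budget = propagate(lambda k1, k2: k1 * k2, _product_inputs())
        ranked = rank_contributions(budget)
        assert [name for name, _ in ranked] == ["k2", "k1"]
        # closed form: fractions are u_r^2 ratios 0.02^2 : 0.01^2
        assert ranked[0][1] == pytest.approx(0.8, rel=1e-9)
        assert ranked[1][1] == pytest.approx(0.2, rel=1e-9)

    def test_single_input_gets_full_contribution(self):
        budget = propagate(lambda k: 2 * k, [Measurement("k", 1.0, 0.5)])
        assert rank_contributions(budget) == [("k", 1.0)]

    def test_ties_break_lexicographically(self):
        budget = propagate(lambda b, a: a + b, [Measurement("b", 1.0, 0.3),
                                                Measurement("a", 1.0, 0.3)])
        assert [n for n, _ in rank_contributions(budget)] == ["a", "b"]


class TestMCOracle:
    def test_zero_uncertainty_gives_exactly_zero_spread(self):
        mean, sd = mc_oracle(lambda k1, k2: k1 * k2,
                             [Measurement("k1", 10, 0.0),
                              Measurement("k2", 20, 0.0)], n=2000, seed=0)
        assert mean == 200.0
        assert sd == 0.0

    def test_rejects_tiny_sample_counts(self):
        with pytest.raises(UncertaintyError):
            mc_oracle(lambda k: k, [Measurement("k", 1, 0.1)], n=10, seed=0)

    def test_deterministic_given_seed(self):
        args = (lambda k1, k2: k1 / k2,
                [Measurement("k1", 10, 0.1), Measurement("k2", 20, 0.4)])
        assert mc_oracle(*args, n=5000, seed=3) == mc_oracle(*args, n=5000,
                                                             seed=3)

    def test_nonvectorizable_expression_falls_back_to_loop(self):
        def expr(k):
            return math.exp(k)  # math.exp rejects arrays

        mean, sd = mc_oracle(expr, [Measurement("k", 0.0, 0.01)], n=2000,
                             seed=1)
        assert mean == pytest.approx(1.0, abs=1e-3)
        assert sd == pytest.approx(0.01, rel=0.1)

    @pytest.mark.parametrize(
        "expr,inputs,analytic",
        [
            (lambda k1, k2: k1 + k2,
             [("k1", 1.0, 3.0), ("k2", 2.0, 4.0)], 5.0),
            (lambda k1, k2: k1 * k2,
             [("k1", 10.0, 0.1), ("k2", 20.0, 0.4)],
             200.0 * math.hypot(0.01, 0.02)),
        ],
    )
    def test_large_sample_sd_matches_closed_form(self, expr, inputs,
                                                 analytic):
        _, sd = mc_oracle(expr, [Measurement(*i) for i in inputs], n=10 ** 6,
                          seed=11)
        assert sd == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize(
        "expr,inputs",
        [
            (lambda a, b: a * b, [("a", 10.0, 0.5), ("b", 20.0, 1.0)]),
            (lambda a, b: a / b, [("a", 10.0, 0.5), ("b", 20.0, 1.0)]),
            (lambda a, b, c: a + b - c,
             [("a", 10.0, 0.5), ("b", 20.0, 1.0), ("c", 5.0, 0.25)]),
        ],
    )
    def test_linearization_agrees_with_sampling_at_small_uncertainty(
            self, expr, inputs):
        # all relative uncertainties <= 5 %: the first-order quadrature and
        # the sampled spread must agree closely
        ms = [Measurement(*i) for i in inputs]
        budget = propagate(expr, ms)
        _, sd = mc_oracle(expr, ms, n=10 ** 6, seed=7)
        assert sd == pytest.approx(budget.combined_uncertainty, rel=0.02)
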