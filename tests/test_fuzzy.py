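"""Mamdani engine: membership shapes, rule evaluation, inference, centroid."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammotriage.fuzzy import (
    FuzzyRule,
    FuzzyValidationError,
    InferenceConfig,
    LinguisticVariable,
    MembershipFunction,
    NoRuleCoverage,
    RuleBase,
    evaluate_rule,
    infer,
    load_rulebase,
    rulebase_from_json,
    rulebase_to_json,
    save_rulebase,
)

tri = lambda a, b, c: MembershipFunction("triangular", (a, b, c))
trap = lambda a, b, c, d: MembershipFunction("trapezoidal", (a, b, c, d))


@pytest.mark.parametrize(
    "mf, x, expected",
    [
        (tri(0, 50, 100), 50, 1.0),        # apex
        (tri(0, 50, 100), 25, 0.5),        # linear midpoint
        (tri(0, 50, 100), -1, 0.0),        # outside support
        (tri(0, 50, 100), 101, 0.0),
        (tri(0, 50, 100), 0, 0.0),         # exact at breakpoints
        (tri(0, 50, 100), 100, 0.0),
        (trap(0, 20, 40, 60), 30, 1.0),    # plateau
        (trap(0, 20, 40, 60), 70, 0.0),    # outside support
        (trap(0, 20, 40, 60), 10, 0.5),
        (trap(0, 20, 40, 60), 50, 0.5),
        (tri(0, 0, 40), 0, 1.0),           # degenerate left shoulder
        (tri(0, 0, 40), 20, 0.5),
        (tri(60, 100, 100), 100, 1.0),     # degenerate right shoulder
        (trap(0, 0, 20, 40), 0, 1.0),
    ],
)
def test_membership_piecewise_values(mf, x, expected):
    assert mf(x) == pytest.approx(expected)


def test_membership_rejects_bad_breakpoints():
    with pytest.raises(FuzzyValidationError):
        MembershipFunction("triangular", (10, 5, 20))
    with pytest.raises(FuzzyValidationError):
        MembershipFunction("triangular", (0, 1))
    with pytest.raises(FuzzyValidationError):
        MembershipFunction("gaussian", (0, 1, 2))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pts=st.lists(st.floats(0, 100), min_size=3, max_size=3),
    x=st.floats(-50, 150),
)
def test_membership_always_in_unit_interval_and_zero_outside_support(pts, x):
    a, b, c = sorted(pts)
    mf = tri(a, b, c)
    mu = mf(x)
    assert 0.0 <= mu <= 1.0
    if x < a or x > c:
        assert mu == 0.0


@pytest.mark.parametrize(
    "connective, degrees, expected",
    [("AND", (0.3, 0.7), 0.3), ("OR", (0.3, 0.7), 0.7), ("AND", (0.42,), 0.42)],
)
def test_rule_evaluation_min_max_semantics(connective, degrees, expected):
    ants = tuple((f"v{i}", "t") for i in range(len(degrees)))
    rule = FuzzyRule(ants, connective, ("out", "t"))
    fuzzified = {f"v{i}": {"t": d} for i, d in enumerate(degrees)}
    assert evaluate_rule(rule, fuzzified) == pytest.approx(expected)


def test_rule_evaluation_rejects_unresolved_names():
    rule = FuzzyRule((("v", "missing"),), "AND", ("out", "t"))
    with pytest.raises(FuzzyValidationError):
        evaluate_rule(rule, {"v": {"t": 0.5}})


def _single_input_rb(consequents_and_terms, rules):
    """Rule base with one input covering [0,100] by one always-on term."""
    inp = LinguisticVariable("x", (0, 100), {"any": trap(0, 0, 100, 100)})
    out = LinguisticVariable("risk", (0, 100), consequents_and_terms)
    return RuleBase("test", "1", (inp,), out, tuple(rules))


def test_infer_symmetric_consequent_returns_apex():
    rb = _single_input_rb(
        {"mid": tri(40, 70, 100), "cover": trap(0, 0, 100, 100)},
        [FuzzyRule((("x", "any"),), "AND", ("risk", "mid"))],
    )
    assert infer(rb, {"x": 50}) == pytest.approx(70, abs=0.05)


def test_infer_two_equal_rules_symmetric_about_midpoint():
    out_terms = {"lo": tri(0, 30, 60), "hi": tri(40, 70, 100), "cover": trap(0, 0, 100, 100)}
    inp = LinguisticVariable(
        "x", (0, 100), {"half": trap(0, 0, 100, 100), "alsohalf": trap(0, 0, 100, 100)}
    )
    out = LinguisticVariable("risk", (0, 100), out_terms)
    # both rules fire at the same activation -> envelope symmetric about 50
    rb = RuleBase("sym", "1", (inp,), out, (
        FuzzyRule((("x", "half"),), "AND", ("risk", "lo")),
        FuzzyRule((("x", "alsohalf"),), "AND", ("risk", "hi")),
    ))
    assert infer(rb, {"x": 10}) == pytest.approx(50, abs=0.05)


def test_infer_matches_closed_form_centroid_of_right_triangle():
    # full-activation consequent tri(0,0,30): centroid of a right triangle
    # descending from (0,1) to (30,0) is at x = 30/3 = 10
    rb = _single_input_rb(
        {"lo": tri(0, 0, 30), "cover": trap(0, 0, 100, 100)},
        [FuzzyRule((("x", "any"),), "AND", ("risk", "lo"))],
    )
    assert infer(rb, {"x": 0}) == pytest.approx(10, abs=0.05)


def test_infer_raises_when_no_rule_fires():
    inp = LinguisticVariable("x", (0, 100), {"low": trap(0, 0, 20, 40), "hi": trap(30, 60, 100, 100)})
    out = LinguisticVariable("risk", (0, 100), {"lo": tri(0, 0, 100), "hi": tri(0, 100, 100)})
    rb = RuleBase("gap", "1", (inp,), out, (
        FuzzyRule((("x", "low"),), "AND", ("risk", "lo")),
    ))
    with pytest.raises(NoRuleCoverage):
        infer(rb, {"x": 90})


def test_infer_validates_missing_and_out_of_universe_inputs():
    rb = _single_input_rb(
        {"lo": tri(0, 0, 30), "cover": trap(0, 0, 100, 100)},
        [FuzzyRule((("x", "any"),), "AND", ("risk", "lo"))],
    )
    with pytest.raises(FuzzyValidationError):
        infer(rb, {})
    with pytest.raises(FuzzyValidationError):
        infer(rb, {"x": 150})


def _brute_force_centroid(rb, crisp, n=100_000):
    """Independent envelope oracle: pointwise max-min at a dense grid."""
    lo, hi = rb.output.universe
    grid = np.linspace(lo, hi, n)
    fuzz = {v.name: v.fuzzify(crisp[v.name]) for v in rb.inputs}
    env = np.zeros_like(grid)
    for rule in rb.rules:
        degs = [fuzz[v][t] for v, t in rule.antecedents]
        act = min(degs) if rule.connective == "AND" else max(degs)
        mf = rb.output.terms[rule.consequent[1]]
        env = np.maximum(env, np.minimum(act, mf(grid)))
    assert env.sum() > 0
    return float((grid * env).sum() / env.sum())


def _random_small_rulebase(rng):
    def rand_tri(lo, hi):
        a, b, c = np.sort(rng.uniform(lo, hi, 3))
        return tri(a, b, c)

    inp = LinguisticVariable("x", (0, 100), {
        "cover": trap(0, 0, 100, 100),
        "t1": rand_tri(0, 100),
        "t2": rand_tri(0, 100),
    })
    out = LinguisticVariable("risk", (0, 100), {
        "cover": trap(0, 0, 100, 100),
        "lo": rand_tri(0, 60),
        "hi": rand_tri(40, 100),
    })
    n_rules = rng.integers(1, 4)
    terms_in = ["cover", "t1", "t2"]
    terms_out = ["cover", "lo", "hi"]
    rules = tuple(
        FuzzyRule(
            ((("x", terms_in[rng.integers(3)])),),
            "AND",
            ("risk", terms_out[rng.integers(3)]),
        )
        for _ in range(n_rules)
    )
    # guarantee coverage so the oracle comparison is always defined
    rules = rules + (FuzzyRule((("x", "cover"),), "AND", ("risk", "lo")),)
    return RuleBase("rand", "1", (inp,), out, rules)


def test_infer_agrees_with_brute_force_envelope_oracle():
    rng = np.random.default_rng(42)
    for _ in range(12):
        rb = _random_small_rulebase(rng)
        for x in rng.uniform(0, 100, 4):
            got = infer(rb, {"x": x})
            want = _brute_force_centroid(rb, {"x": x})
            assert got == pytest.approx(want, abs=0.1)


def test_grid_convergence_of_centroid(cascade_config):
    """Doubling the grid moves the centroid by < 0.1 on [0, 100]."""
    rb = cascade_config.rulebases["es1a"]
    inputs = {"mass_shape": 6.5, "mass_margins": 3.0, "mass_density": 7.0}
    coarse = infer(rb, inputs, InferenceConfig(grid_resolution=1001))
    fine = infer(rb, inputs, InferenceConfig(grid_resolution=2001))
    assert abs(coarse - fine) < 0.1


def test_centroid_invariant_to_common_activation_scaling():
    """Scaling the whole envelope's amplitude leaves the centroid unchanged."""
    out = LinguisticVariable("risk", (0, 100), {"m": tri(20, 50, 90), "cover": trap(0, 0, 100, 100)})
    grid = np.linspace(0, 100, 1001)
    base = np.minimum(1.0, out.terms["m"](grid))
    for scale in (0.9, 0.5, 0.1):
        env = scale * base
        c_base = (grid * base).sum() / base.sum()
        c_scaled = (grid * env).sum() / env.sum()
        assert c_scaled == pytest.approx(c_base, abs=1e-9)


def test_infer_output_within_activated_consequent_support():
    rng = np.random.default_rng(3)
    for _ in range(10):
        rb = _random_small_rulebase(rng)
        x = float(rng.uniform(0, 100))
        grid = np.linspace(0, 100, 100_001)
        fuzz = {"x": rb.inputs[0].fuzzify(x)}
        supports = []
        for rule in rb.rules:
            act = min(fuzz[v][t] for v, t in rule.antecedents)
            if act > 0:
                supports.append(rb.output.terms[rule.consequent[1]].support)
        lo = min(s[0] for s in supports)
        hi = max(s[1] for s in supports)
        assert lo <= infer(rb, {"x": x}) <= hi


def test_grid_resolution_floor_enforced():
    with pytest.raises(FuzzyValidationError):
        InferenceConfig(grid_resolution=100)


def test_rulebase_json_round_trip(cascade_config, tmp_path):
    rb = cascade_config.rulebases["es2"]
    path = tmp_path / "es2.json"
    save_rulebase(rb, path)
    rb2 = load_rulebase(path)
    assert rb2 == rb
    x = {"r1a": 30.0, "r1b": 70.0, "r1c": 10.0, "birads": 5.0}
    assert infer(rb2, x) == pytest.approx(infer(rb, x))


def test_rulebase_json_schema_validation(cascade_config):
    d = rulebase_to_json(cascade_config.rulebases["es1c"])
    missing_version = {k: v for k, v in d.items() if k != "version"}
    with pytest.raises(FuzzyValidationError):
        rulebase_from_json(missing_version)
    dangling = json.loads(json.dumps(d))
    dangling["rules"][0]["if"][0][0] = "no_such_variable"
    with pytest.raises(FuzzyValidationError):
        rulebase_from_json(dangling)


def test_variable_coverage_check_rejects_gaps():
    with pytest.raises(FuzzyValidationError):
        RuleBase(
            "gapvar", "1",
            (LinguisticVariable("x", (0, 100), {"lo": tri(0, 0, 20)}),),
            LinguisticVariable("risk", (0, 100), {"m": trap(0, 0, 100, 100)}),
            (FuzzyRule((("x", "lo"),), "AND", ("risk", "m")),),
        )
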