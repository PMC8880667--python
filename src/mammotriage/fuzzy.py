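"""Mamdani-type fuzzy inference engine.

Implements the seven-stage inference pipeline used by every expert system in
the risk cascade: membership-function definition, fuzzification of crisp
inputs, rule lookup, antecedent evaluation (min for AND, max for OR),
min-implication (truncation of the consequent), max-aggregation of the
truncated consequents into an envelope, and centroid defuzzification of that
envelope into a crisp output.

Only triangular and trapezoidal membership functions are supported:
triangular terms model the pointwise certainty of consequent risks and of
variables read directly from a mammography interpretation, trapezoidal terms
model the plateau of certainty of a risk that re-enters the next cascade
level as an antecedent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FuzzyRule",
    "RuleBase",
    "InferenceConfig",
    "FuzzyValidationError",
    "NoRuleCoverage",
    "evaluate_rule",
    "infer",
    "load_rulebase",
    "save_rulebase",
]


class FuzzyValidationError(ValueError):
    """A rule base, variable or membership function is ill-formed."""


class NoRuleCoverage(RuntimeError):
    """Every rule activation is zero: the rule base does not cover the input.

    Raised as a hard error rather than returning a default risk, because a
    silent fallback value would propagate through the cascade and corrupt
    every downstream risk index.
    """


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership function on the real line.

    Parameters
    ----------
    kind
        ``"triangular"`` with breakpoints ``(a, b, c)`` or ``"trapezoidal"``
        with breakpoints ``(a, b, c, d)``, in the units of the owning
        variable's universe.  Breakpoints must be non-decreasing; ties are
        allowed and evaluate as one-sided ramps (e.g. ``a == b`` gives a
        left shoulder).
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        n = {"triangular": 3, "trapezoidal": 4}.get(self.kind)
        if n is None:
            raise FuzzyValidationError(f"unknown membership kind {self.kind!r}")
        if len(self.params) != n:
            raise FuzzyValidationError(
                f"{self.kind} membership needs {n} breakpoints, got {len(self.params)}"
            )
        p = np.asarray(self.params, dtype=float)
        if not np.all(np.isfinite(p)):
            raise FuzzyValidationError("breakpoints must be finite")
        if np.any(np.diff(p) < 0):
            raise FuzzyValidationError(f"breakpoints must be non-decreasing: {self.params}")
        object.__setattr__(self, "params", tuple(float(v) for v in p))

    def __call__(self, x) -> np.ndarray | float:
        """Degree of membership of ``x``, elementwise, in [0, 1]."""
        scalar = np.isscalar(x)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "triangular":
            a, b, c = self.params
            lo, plateau_lo, plateau_hi, hi = a, b, b, c
        else:
            a, b, c, d = self.params
            lo, plateau_lo, plateau_hi, hi = a, b, c, d
        y = np.zeros_like(x)
        if plateau_lo > lo:
            m = (x >= lo) & (x < plateau_lo)
            y[m] = (x[m] - lo) / (plateau_lo - lo)
        if hi > plateau_hi:
            m = (x > plateau_hi) & (x <= hi)
            y[m] = (hi - x[m]) / (hi - plateau_hi)
        y[(x >= plateau_lo) & (x <= plateau_hi)] = 1.0
        return float(y[0]) if scalar else y

    @property
    def support(self) -> tuple[float, float]:
        return self.params[0], self.params[-1]


@dataclass(frozen=True)
class LinguisticVariable:
    """A named variable with a closed universe of discourse and fuzzy terms."""

    name: str
    universe: tuple[float, float]
    terms: Mapping[str, MembershipFunction]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        if not lo < hi:
            raise FuzzyValidationError(f"{self.name}: universe [{lo}, {hi}] is empty")
        if not self.terms:
            raise FuzzyValidationError(f"{self.name}: variable has no terms")
        for term, mf in self.terms.items():
            a, b = mf.support
            if a < lo - 1e-9 or b > hi + 1e-9:
                raise FuzzyValidationError(
                    f"{self.name}.{term}: breakpoints {mf.params} outside universe [{lo}, {hi}]"
                )
        object.__setattr__(self, "terms", dict(self.terms))

    def check_coverage(self, resolution: int = 1001) -> None:
        """Every point of the universe must belong to at least one term."""
        grid = np.linspace(*self.universe, resolution)
        peak = np.max([mf(grid) for mf in self.terms.values()], axis=0)
        if np.any(peak <= 0):
            x = grid[np.argmin(peak)]
            raise FuzzyValidationError(
                f"{self.name}: no term covers universe point x={x:g}"
            )

    def fuzzify(self, x: float) -> dict[str, float]:
        lo, hi = self.universe
        if not (lo - 1e-9 <= x <= hi + 1e-9):
            raise FuzzyValidationError(
                f"{self.name}: crisp value {x} outside universe [{lo}, {hi}]"
            )
        return {term: float(mf(x)) for term, mf in self.terms.items()}


@dataclass(frozen=True)
class FuzzyRule:
    """IF <antecedents joined by AND/OR> THEN <consequent term>."""

    antecedents: tuple[tuple[str, str], ...]
    connective: str
    consequent: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise FuzzyValidationError("rule must have at least one antecedent")
        if self.connective not in ("AND", "OR"):
            raise FuzzyValidationError(f"connective must be AND or OR, got {self.connective!r}")
        object.__setattr__(
            self, "antecedents", tuple((str(v), str(t)) for v, t in self.antecedents)
        )
        object.__setattr__(self, "consequent", tuple(self.consequent))


def evaluate_rule(rule: FuzzyRule, fuzzified: Mapping[str, Mapping[str, float]]) -> float:
    """Activation of one rule from per-variable, per-term membership degrees.

    AND takes the minimum of antecedent degrees, OR the maximum; a single
    antecedent passes its degree through unchanged.
    """
    degrees = []
    for var, term in rule.antecedents:
        try:
            degrees.append(fuzzified[var][term])
        except KeyError:
            raise FuzzyValidationError(f"unresolved antecedent {var!r}.{term!r}") from None
    return min(degrees) if rule.connective == "AND" else max(degrees)


@dataclass(frozen=True)
class InferenceConfig:
    """Operator choices of the Mamdani scheme plus the defuzzification grid.

    The operators are fixed to the classical Mamdani set (min/max/min/max,
    centroid); only the grid resolution is genuinely tunable.
    """

    and_operator: str = "minimum"
    or_operator: str = "maximum"
    implication: str = "minimum"
    aggregation: str = "maximum"
    defuzzifier: str = "centroid"
    grid_resolution: int = 1001

    def __post_init__(self) -> None:
        if self.grid_resolution < 101:
            raise FuzzyValidationError("grid_resolution must be >= 101")


@dataclass(frozen=True)
class RuleBase:
    """One expert system's knowledge model: variables plus production rules."""

    name: str
    version: str
    inputs: tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        self.validate()

    def validate(self) -> None:
        vars_by_name = {v.name: v for v in self.inputs}
        if len(vars_by_name) != len(self.inputs):
            raise FuzzyValidationError(f"{self.name}: duplicate input variable names")
        if self.output.name in vars_by_name:
            raise FuzzyValidationError(f"{self.name}: output shadows an input variable")
        if not self.rules:
            raise FuzzyValidationError(f"{self.name}: rule base has no rules")
        for i, rule in enumerate(self.rules):
            for var, term in rule.antecedents:
                if var not in vars_by_name:
                    raise FuzzyValidationError(f"{self.name} rule {i}: unknown variable {var!r}")
                if term not in vars_by_name[var].terms:
                    raise FuzzyValidationError(
                        f"{self.name} rule {i}: unknown term {var!r}.{term!r}"
                    )
            cvar, cterm = rule.consequent
            if cvar != self.output.name:
                raise FuzzyValidationError(
                    f"{self.name} rule {i}: consequent targets {cvar!r}, "
                    f"not the output variable {self.output.name!r}"
                )
            if cterm not in self.output.terms:
                raise FuzzyValidationError(
                    f"{self.name} rule {i}: unknown output term {cterm!r}"
                )
        for v in (*self.inputs, self.output):
            v.check_coverage()

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.inputs)


def aggregate_envelope(
    rb: RuleBase, crisp_inputs: Mapping[str, float], grid: np.ndarray
) -> np.ndarray:
    """Max-aggregated, min-truncated consequent envelope sampled on ``grid``."""
    fuzzified = {v.name: v.fuzzify(float(crisp_inputs[v.name])) for v in rb.inputs}
    envelope = np.zeros_like(grid)
    for rule in rb.rules:
        activation = evaluate_rule(rule, fuzzified)
        if activation <= 0.0:
            continue
        mf = rb.output.terms[rule.consequent[1]]
        envelope = np.maximum(envelope, np.minimum(activation, mf(grid)))
    return envelope


def infer(
    rb: RuleBase, crisp_inputs: Mapping[str, float], cfg: InferenceConfig | None = None
) -> float:
    """Run the full Mamdani pipeline and return the centroid-defuzzified output.

    Raises
    ------
    NoRuleCoverage
        If no rule fires for these inputs (the aggregate envelope is
        identically zero), signalling an incomplete rule base.
    FuzzyValidationError
        If an input variable is missing or its value is outside its universe.
    """
    cfg = cfg or InferenceConfig()
    missing = set(rb.input_names) - set(crisp_inputs)
    if missing:
        raise FuzzyValidationError(f"{rb.name}: missing crisp inputs {sorted(missing)}")
    grid = np.linspace(*rb.output.universe, cfg.grid_resolution)
    envelope = aggregate_envelope(rb, crisp_inputs, grid)
    total = envelope.sum()
    if total <= 0.0:
        raise NoRuleCoverage(f"{rb.name}: no rule fires for inputs {dict(crisp_inputs)}")
    return float((grid * envelope).sum() / total)


# ---------------------------------------------------------------------------
# JSON (de)serialization of rule bases
# ---------------------------------------------------------------------------


def _variable_to_json(v: LinguisticVariable) -> dict:
    return {
        "name": v.name,
        "universe": list(v.universe),
        "terms": {t: {"kind": mf.kind, "params": list(mf.params)} for t, mf in v.terms.items()},
    }


def _variable_from_json(d: Mapping) -> LinguisticVariable:
    try:
        terms = {
            t: MembershipFunction(kind=spec["kind"], params=tuple(spec["params"]))
            for t, spec in d["terms"].items()
        }
        return LinguisticVariable(name=d["name"], universe=tuple(d["universe"]), terms=terms)
    except (KeyError, TypeError) as exc:
        raise FuzzyValidationError(f"malformed variable definition: {exc}") from exc


def rulebase_to_json(rb: RuleBase) -> dict:
    return {
        "name": rb.name,
        "version": rb.version,
        "inputs": [_variable_to_json(v) for v in rb.inputs],
        "output": _variable_to_json(rb.output),
        "rules": [
            {
                "if": [list(a) for a in r.antecedents],
                "connective": r.connective,
                "then": list(r.consequent),
            }
            for r in rb.rules
        ],
    }


def rulebase_from_json(d: Mapping) -> RuleBase:
    for key in ("name", "version", "inputs", "output", "rules"):
        if key not in d:
            raise FuzzyValidationError(f"rule base JSON missing required field {key!r}")
    rules = tuple(
        FuzzyRule(
            antecedents=tuple(tuple(a) for a in r["if"]),
            connective=r.get("connective", "AND"),
            consequent=tuple(r["then"]),
        )
        for r in d["rules"]
    )
    return RuleBase(
        name=str(d["name"]),
        version=str(d["version"]),
        inputs=tuple(_variable_from_json(v) for v in d["inputs"]),
        output=_variable_from_json(d["output"]),
        rules=rules,
    )


def load_rulebase(path: str | Path) -> RuleBase:
    with open(path, "r", encoding="utf-8") as fh:
        return rulebase_from_json(json.load(fh))


def save_rulebase(rb: RuleBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rulebase_to_json(rb), fh, indent=1)
        fh.write("\n")
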