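"""Four-level expert-system cascade over structured mammography descriptors.

A patient record (BI-RADS lexicon findings plus history) is encoded to crisp
ordinal values and pushed through six Mamdani expert systems arranged in
four levels:

* Level 1 — three concurrent systems: masses (``r1a``), calcifications
  (``r1b``), asymmetries / architectural distortion (``r1c``).
* Level 2 — the three level-1 risks plus the BI-RADS category (``r2``).
* Level 3 — ``r2`` plus breast composition (``r3``).
* Level 4 — ``r3`` plus age, personal and family history (``r4``).

Each level's output risk re-enters the next level as a fuzzified antecedent,
so information flows strictly downstream: history only affects ``r4``,
breast composition affects ``{r3, r4}``, BI-RADS affects ``{r2, r3, r4}``.
The persisted result of a cascade run contains only the six risk indices and
the optional class label, which anonymizes the patient's descriptors.

The shipped demo rule bases encode the suspicion ordering of the BI-RADS
lexicon and are illustrative: the JSON rule-base format is the extension
point for a clinically validated knowledge base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fuzzy import InferenceConfig, NoRuleCoverage, RuleBase, infer, load_rulebase

__all__ = [
    "PatientRecord",
    "RiskVector",
    "EncodingTable",
    "CascadeConfig",
    "EncodingError",
    "encode_patient",
    "run_cascade",
    "cascade_table",
    "RISK_COLUMNS",
]

RISK_COLUMNS = ("R1a", "R1b", "R1c", "R2", "R3", "R4")

MASS_SHAPES = ("oval", "round", "irregular", "none")
MASS_MARGINS = ("circumscribed", "obscured", "microlobulated", "indistinct", "spiculated", "none")
MASS_DENSITIES = ("fat-containing", "low", "equal", "high", "none")
CALC_PRIMACIES = ("primary", "associated", "none")
CALC_SHAPES = ("typically-benign", "amorphous", "coarse-heterogeneous",
               "fine-pleomorphic", "fine-linear-branching", "none")
CALC_DISTRIBUTIONS = ("diffuse", "regional", "grouped", "linear", "segmental", "none")
ASYM_TYPES = ("global", "focal", "developing", "none")
DISTORTION_PRIMACIES = ("primary", "associated", "none")
BIRADS_CATEGORIES = ("0", "1", "2", "3", "4A", "4B", "4C", "5", "6")
BREAST_DENSITIES = ("fatty", "scattered", "heterogeneously-dense", "extremely-dense")
PATIENT_HISTORIES = ("yes", "no", "unknown")
FAMILY_HISTORIES = ("none", "minor", "major", "unknown")
LABELS = ("cancer", "non-cancer")


class EncodingError(ValueError):
    """A categorical value has no crisp encoding."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient's structured descriptors — the cascade's input.

    Absent findings force their sub-fields to ``"none"``: e.g. if
    ``mass_present`` is False the shape/margins/density must all be
    ``"none"`` (validated at construction).
    """

    mass_present: bool = False
    mass_shape: str = "none"
    mass_margins: str = "none"
    mass_density: str = "none"
    calc_present: bool = False
    calc_primacy: str = "none"
    calc_shape: str = "none"
    calc_distribution: str = "none"
    asym_present: bool = False
    asym_type: str = "none"
    distortion_present: bool = False
    distortion_primacy: str = "none"
    birads: str = "1"
    breast_density: str = "scattered"
    age: float = 50.0
    patient_history: str = "no"
    family_history: str = "none"
    label: str | None = None

    def __post_init__(self) -> None:
        domains = {
            "mass_shape": MASS_SHAPES, "mass_margins": MASS_MARGINS,
            "mass_density": MASS_DENSITIES, "calc_primacy": CALC_PRIMACIES,
            "calc_shape": CALC_SHAPES, "calc_distribution": CALC_DISTRIBUTIONS,
            "asym_type": ASYM_TYPES, "distortion_primacy": DISTORTION_PRIMACIES,
            "birads": BIRADS_CATEGORIES, "breast_density": BREAST_DENSITIES,
            "patient_history": PATIENT_HISTORIES, "family_history": FAMILY_HISTORIES,
        }
        for name, allowed in domains.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(
                    f"{name}={value!r} not in allowed values {allowed}"
                )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label={self.label!r} not in {LABELS}")
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        absent_rules = {
            "mass_present": ("mass_shape", "mass_margins", "mass_density"),
            "calc_present": ("calc_primacy", "calc_shape", "calc_distribution"),
            "asym_present": ("asym_type",),
            "distortion_present": ("distortion_primacy",),
        }
        for flag, subfields in absent_rules.items():
            if not getattr(self, flag):
                for sub in subfields:
                    if getattr(self, sub) != "none":
                        raise ValueError(
                            f"{flag} is False but {sub}={getattr(self, sub)!r} "
                            "(absent findings force sub-fields to 'none')"
                        )


@dataclass(frozen=True)
class RiskVector:
    """Six defuzzified risk indices on the [0, 100] universe."""

    R1a: float
    R1b: float
    R1c: float
    R2: float
    R3: float
    R4: float

    def __post_init__(self) -> None:
        for name in RISK_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside the [0, 100] risk universe")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RISK_COLUMNS}


class EncodingTable:
    """Categorical → crisp ordinal mapping, loaded from a JSON artifact."""

    def __init__(self, fields: Mapping[str, Mapping[str, float]], version: str = "1"):
        self.fields = {k: dict(v) for k, v in fields.items()}
        self.version = version

    @classmethod
    def from_json(cls, d: Mapping) -> "EncodingTable":
        return cls(fields=d["fields"], version=str(d.get("version", "1")))

    @classmethod
    def load(cls, path: str | Path) -> "EncodingTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))

    def encode(self, field_name: str, category: str) -> float:
        try:
            return float(self.fields[field_name][category])
        except KeyError:
            raise EncodingError(
                f"no crisp encoding for {field_name}={category!r}"
            ) from None


def encode_patient(rec: PatientRecord, enc: EncodingTable) -> dict[str, float]:
    """Deterministic lookup of a record's crisp input values for the cascade."""
    return {
        "mass_shape": enc.encode("mass_shape", rec.mass_shape),
        "mass_margins": enc.encode("mass_margins", rec.mass_margins),
        "mass_density": enc.encode("mass_density", rec.mass_density),
        "calc_primacy": enc.encode("calc_primacy", rec.calc_primacy),
        "calc_shape": enc.encode("calc_shape", rec.calc_shape),
        "calc_distribution": enc.encode("calc_distribution", rec.calc_distribution),
        "asym_type": enc.encode("asym_type", rec.asym_type),
        "distortion_primacy": enc.encode("distortion_primacy", rec.distortion_primacy),
        "birads": enc.encode("birads", rec.birads),
        "breast_density": enc.encode("breast_density", rec.breast_density),
        "age": float(rec.age),
        "patient_history": enc.encode("patient_history", rec.patient_history),
        "family_history": enc.encode("family_history", rec.family_history),
    }


@dataclass(frozen=True)
class CascadeConfig:
    """Six rule bases keyed es1a..es4, one inference config, one encoding."""

    rulebases: Mapping[str, RuleBase]
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    encoding: EncodingTable = None  # type: ignore[assignment]

    _KEYS = ("es1a", "es1b", "es1c", "es2", "es3", "es4")

    def __post_init__(self) -> None:
        missing = set(self._KEYS) - set(self.rulebases)
        if missing:
            raise ValueError(f"cascade config missing rule bases: {sorted(missing)}")
        if self.encoding is None:
            raise ValueError("cascade config needs an encoding table")
        object.__setattr__(self, "rulebases", dict(self.rulebases))

    @classmethod
    def load(cls, directory: str | Path, inference: InferenceConfig | None = None) -> "CascadeConfig":
        directory = Path(directory)
        rbs = {key: load_rulebase(directory / f"{key}.json") for key in cls._KEYS}
        enc = EncodingTable.load(directory / "encoding.json")
        return cls(rulebases=rbs, inference=inference or InferenceConfig(), encoding=enc)

    @classmethod
    def default(cls, inference: InferenceConfig | None = None) -> "CascadeConfig":
        """The packaged demo configuration (illustrative rule bases)."""
        data_dir = resources.files("mammotriage") / "data"
        with resources.as_file(data_dir) as p:
            return cls.load(p, inference=inference)


def run_cascade(rec: PatientRecord, cc: CascadeConfig) -> RiskVector:
    """Propagate one record through the four cascade levels.

    Raises :class:`~mammotriage.fuzzy.NoRuleCoverage` with the offending
    level named if any expert system fails to fire.
    """
    crisp = encode_patient(rec, cc.encoding)
    cfg = cc.inference

    def level(key: str, inputs: dict[str, float]) -> float:
        try:
            return infer(cc.rulebases[key], inputs, cfg)
        except NoRuleCoverage as exc:
            raise NoRuleCoverage(f"cascade level {key}: {exc}") from exc

    r1a = level("es1a", {k: crisp[k] for k in ("mass_shape", "mass_margins", "mass_density")})
    r1b = level("es1b", {k: crisp[k] for k in ("calc_primacy", "calc_shape", "calc_distribution")})
    r1c = level("es1c", {k: crisp[k] for k in ("asym_type", "distortion_primacy")})
    r2 = level("es2", {"r1a": r1a, "r1b": r1b, "r1c": r1c, "birads": crisp["birads"]})
    r3 = level("es3", {"r2": r2, "breast_density": crisp["breast_density"]})
    r4 = level("es4", {"r3": r3, "age": crisp["age"],
                       "patient_history": crisp["patient_history"],
                       "family_history": crisp["family_history"]})
    return RiskVector(R1a=r1a, R1b=r1b, R1c=r1c, R2=r2, R3=r3, R4=r4)


def cascade_table(records: Sequence[PatientRecord], cc: CascadeConfig) -> pd.DataFrame:
    """Risk table for a cohort: columns ``R1a..R4`` plus ``label``.

    This is the anonymized intermediate store — no identifying descriptor
    fields survive, only the six risks and the class label.
    """
    rows = []
    for rec in records:
        rv = run_cascade(rec, cc)
        row = rv.as_dict()
        row["label"] = rec.label
        rows.append(row)
    return pd.DataFrame(rows, columns=[*RISK_COLUMNS, "label"])
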