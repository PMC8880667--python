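"""Synthetic cohorts and factor-structured risk tables.

The original 130-patient reference dataset is not publicly deposited, so
this module provides two seeded generators that stand in for it:

* :func:`generate_patients` draws patient records from class-conditional
  categorical frequency tables emulating the reference cohort's schema,
  class imbalance (21/130 cancer prevalence) and age distribution (mean
  55.2 years).  The shipped frequency tables are synthetic defaults
  informed by the BI-RADS suspicion ordering (cancer cases concentrate in
  categories 4B+, spiculated margins, fine pleomorphic calcifications...);
  they are not fitted to any real data.
* :func:`generate_factor_risks` draws standardized risk vectors from an
  explicit three-factor model whose block structure mirrors the latent
  structure recovered from the cascade risks: one factor behind the
  downstream risks {R2, R3, R4}, one behind masses/calcifications
  {R1a, R1b}, one behind asymmetry/distortion {R1c}.  The single-indicator
  third factor carries a 0.35 cross-loading on R2 so its population
  eigenvalue exceeds 1 and the Kaiser rule is well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cascade import RISK_COLUMNS, PatientRecord

__all__ = [
    "CohortSpec",
    "FactorGenSpec",
    "generate_patients",
    "generate_factor_risks",
    "generate_labeled_risks",
    "DEFAULT_FREQUENCIES",
]

# Class-conditional categorical frequencies.  Finding sub-fields are drawn
# conditional on the finding being present; the *_present keys give the
# Bernoulli probability of presence.
DEFAULT_FREQUENCIES: dict[str, dict] = {
    "non-cancer": {
        "mass_present": 0.25,
        "mass_shape": {"oval": 0.50, "round": 0.30, "irregular": 0.20},
        "mass_margins": {"circumscribed": 0.50, "obscured": 0.20,
                         "microlobulated": 0.15, "indistinct": 0.10, "spiculated": 0.05},
        "mass_density": {"fat-containing": 0.20, "low": 0.30, "equal": 0.40, "high": 0.10},
        "calc_present": 0.30,
        "calc_primacy": {"associated": 0.70, "primary": 0.30},
        "calc_shape": {"typically-benign": 0.50, "amorphous": 0.30,
                       "coarse-heterogeneous": 0.15, "fine-pleomorphic": 0.04,
                       "fine-linear-branching": 0.01},
        "calc_distribution": {"diffuse": 0.30, "regional": 0.25, "grouped": 0.35,
                              "linear": 0.07, "segmental": 0.03},
        "asym_present": 0.20,
        "asym_type": {"global": 0.40, "focal": 0.40, "developing": 0.20},
        "distortion_present": 0.10,
        "distortion_primacy": {"associated": 0.70, "primary": 0.30},
        "birads": {"0": 0.02, "1": 0.28, "2": 0.37, "3": 0.22,
                   "4A": 0.08, "4B": 0.02, "4C": 0.01, "5": 0.0, "6": 0.0},
        "breast_density": {"fatty": 0.15, "scattered": 0.40,
                           "heterogeneously-dense": 0.35, "extremely-dense": 0.10},
        "patient_history": {"yes": 0.05, "no": 0.90, "unknown": 0.05},
        "family_history": {"none": 0.70, "minor": 0.20, "major": 0.05, "unknown": 0.05},
    },
    "cancer": {
        "mass_present": 0.60,
        "mass_shape": {"oval": 0.15, "round": 0.25, "irregular": 0.60},
        "mass_margins": {"circumscribed": 0.03, "obscured": 0.07,
                         "microlobulated": 0.15, "indistinct": 0.30, "spiculated": 0.45},
        "mass_density": {"fat-containing": 0.05, "low": 0.10, "equal": 0.35, "high": 0.50},
        "calc_present": 0.55,
        "calc_primacy": {"associated": 0.50, "primary": 0.50},
        "calc_shape": {"typically-benign": 0.05, "amorphous": 0.15,
                       "coarse-heterogeneous": 0.25, "fine-pleomorphic": 0.35,
                       "fine-linear-branching": 0.20},
        "calc_distribution": {"diffuse": 0.05, "regional": 0.10, "grouped": 0.30,
                              "linear": 0.25, "segmental": 0.30},
        "asym_present": 0.35,
        "asym_type": {"global": 0.15, "focal": 0.50, "developing": 0.35},
        "distortion_present": 0.30,
        "distortion_primacy": {"associated": 0.40, "primary": 0.60},
        "birads": {"0": 0.02, "1": 0.01, "2": 0.02, "3": 0.05,
                   "4A": 0.15, "4B": 0.30, "4C": 0.25, "5": 0.20, "6": 0.0},
        "breast_density": {"fatty": 0.10, "scattered": 0.30,
                           "heterogeneously-dense": 0.40, "extremely-dense": 0.20},
        "patient_history": {"yes": 0.20, "no": 0.70, "unknown": 0.10},
        "family_history": {"none": 0.40, "minor": 0.30, "major": 0.25, "unknown": 0.05},
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, prevalence, age model and per-class frequency tables."""

    n: int = 130
    prevalence: float = 21 / 130
    age_mean: float = 55.2
    age_sd: float = 14.0
    age_min: float = 18.0
    age_max: float = 95.0
    frequencies: dict = field(default_factory=lambda: DEFAULT_FREQUENCIES)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for label, table in self.frequencies.items():
            for name, freq in table.items():
                if isinstance(freq, dict):
                    total = sum(freq.values())
                    if abs(total - 1.0) > 1e-9:
                        raise ValueError(
                            f"{label}.{name}: frequencies sum to {total}, not 1"
                        )


def _draw(rng: np.random.Generator, table: dict[str, float]) -> str:
    cats = list(table)
    probs = np.array([table[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def generate_patients(spec: CohortSpec = CohortSpec()) -> list[PatientRecord]:
    """Draw a labeled synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    b = (spec.age_max - spec.age_mean) / spec.age_sd
    ages = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd,
                         size=spec.n, random_state=rng)
    records = []
    for i in range(spec.n):
        label = "cancer" if rng.random() < spec.prevalence else "non-cancer"
        freq = spec.frequencies[label]
        kwargs: dict = {"label": label, "age": float(round(ages[i], 1))}
        for finding, subfields in (
            ("mass", ("mass_shape", "mass_margins", "mass_density")),
            ("calc", ("calc_primacy", "calc_shape", "calc_distribution")),
            ("asym", ("asym_type",)),
            ("distortion", ("distortion_primacy",)),
        ):
            present = bool(rng.random() < freq[f"{finding}_present"])
            kwargs[f"{finding}_present"] = present
            for sub in subfields:
                kwargs[sub] = _draw(rng, freq[sub]) if present else "none"
        for name in ("birads", "breast_density", "patient_history", "family_history"):
            kwargs[name] = _draw(rng, freq[name])
        records.append(PatientRecord(**kwargs))
    return records


# Default loading matrix Lambda (6 risks x 3 factors).  Rows follow
# RISK_COLUMNS = (R1a, R1b, R1c, R2, R3, R4).
DEFAULT_LOADINGS = np.array(
    [
        # F1     F2     F3
        [0.00, 0.80, 0.00],   # R1a
        [0.00, 0.80, 0.00],   # R1b
        [0.00, 0.00, 0.85],   # R1c
        [0.70, 0.00, 0.35],   # R2
        [0.75, 0.00, 0.00],   # R3
        [0.75, 0.00, 0.00],   # R4
    ]
)


@dataclass(frozen=True)
class FactorGenSpec:
    """Three-factor generating model for standardized risk tables."""

    loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        L = np.asarray(self.loadings, dtype=float)
        if L.shape != (len(RISK_COLUMNS), 3):
            raise ValueError(f"loadings must be {len(RISK_COLUMNS)} x 3")
        object.__setattr__(self, "loadings", L)
        pop = self.population_correlation()
        eig = np.linalg.eigvalsh(pop)
        if np.any(eig <= 0):
            raise ValueError("implied correlation matrix is not positive definite")
        if int((eig > 1.0).sum()) != 3:
            raise ValueError(
                f"population matrix must have exactly 3 eigenvalues > 1, "
                f"got {int((eig > 1.0).sum())}"
            )

    def uniquenesses(self) -> np.ndarray:
        psi = 1.0 - (self.loadings**2).sum(axis=1)
        if np.any(psi < 0):
            raise ValueError("row communalities exceed 1")
        return psi

    def population_correlation(self) -> np.ndarray:
        L = self.loadings
        return L @ L.T + np.diag(1.0 - (L**2).sum(axis=1))


def generate_factor_risks(
    spec: FactorGenSpec = FactorGenSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized risk rows x = Lambda f + eps, plus the true factor scores."""
    rng = np.random.default_rng(spec.seed)
    f = rng.standard_normal((spec.n, 3))
    eps = rng.standard_normal((spec.n, len(RISK_COLUMNS))) * np.sqrt(spec.uniquenesses())
    X = f @ spec.loadings.T + eps
    risks = pd.DataFrame(X, columns=list(RISK_COLUMNS))
    scores = pd.DataFrame(f, columns=["F1", "F2", "F3"])
    return risks, scores


def generate_labeled_risks(
    n_cancer: int = 20,
    n_noncancer: int = 109,
    seed: int = 0,
    scale: float = 12.0,
    center: float = 50.0,
    class_shift: float = 12.0,
) -> pd.DataFrame:
    """Labeled risk table on the [0, 100] scale with factor structure.

    Draws factor-structured standardized risks, maps them to the risk
    universe, and shifts the cancer class upward so the two classes carry a
    learnable signal.  Used as the stand-in for a cascade-produced labeled
    risk table wherever one is needed without running the cascade.
    """
    n = n_cancer + n_noncancer
    risks, _ = generate_factor_risks(FactorGenSpec(n=n, seed=seed))
    labels = np.array(["cancer"] * n_cancer + ["non-cancer"] * n_noncancer)
    shift = np.where(labels == "cancer", class_shift, -class_shift * n_cancer / n_noncancer)
    values = center + scale * risks.to_numpy() + shift[:, None]
    df = pd.DataFrame(np.clip(values, 0.0, 100.0), columns=list(RISK_COLUMNS))
    df["label"] = labels
    return df
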