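"""Exploratory factor analysis of the risk table.

Implements the common-factor-analysis stage: an assumption battery
(normality, multicollinearity, outliers, sampling adequacy), Principal Axis
Factoring with the Kaiser extraction rule, Varimax rotation, and
Anderson-Rubin factor scores.

The assumption battery flags rather than blocks: factor analysis of risk
indices is robust to moderate normality violations, so a failed
Shapiro-Wilk test is recorded in the report and the analysis proceeds.
Only a singular correlation matrix (which leaves Bartlett's test and the
KMO index undefined) is a hard error.

Numerical conventions
---------------------
* Kaiser rule counts eigenvalues > 1 of the *full* sample correlation
  matrix (the deterministic, standard reading).
* PAF starts from squared multiple correlations, iterates the reduced
  correlation matrix's eigendecomposition, and stops when the largest
  communality change falls below ``tol`` (default 1e-4, max 10000
  iterations — near-Heywood variables converge geometrically but slowly,
  and an iteration costs one small eigendecomposition).  A communality
  reaching the 0.999 ceiling (Heywood case) is pinned there for the rest
  of the iteration, with a warning; pinning prevents the update from
  cycling across the clip boundary.
* Varimax uses Kaiser's classical pairwise-rotation algorithm with row
  normalization; the closed-form per-pair angle makes it exact even at
  loadings configurations where gradient-projection rotation stalls.
* Anderson-Rubin weights are built so the fitting data's scores have
  exactly zero mean and identity covariance; the weights and the fitting
  column statistics are stored so a new patient is mapped onto the same
  factor space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_prep import ColumnStats

__all__ = [
    "AssumptionReport",
    "FactorModel",
    "EFAError",
    "assumption_report",
    "fit_paf",
    "varimax",
    "fit_efa",
    "anderson_rubin_scores",
    "kaiser_count",
]

# Thresholds recorded in every assumption report (the battery's defaults).
THRESHOLDS = {
    "shapiro_alpha": 0.05,
    "vif_flag": 10.0,
    "kmo_acceptable": 0.5,
    "mahalanobis_quantile": 0.999,
    "rows_per_variable_min": 10.0,
}


class EFAError(RuntimeError):
    """Factor analysis cannot proceed (singular input or non-convergence)."""


def _correlation(X: np.ndarray) -> np.ndarray:
    R = np.corrcoef(X, rowvar=False)
    return np.atleast_2d(R)


def _safe_inverse(R: np.ndarray, what: str) -> np.ndarray:
    if np.linalg.cond(R) > 1e12:
        raise EFAError(f"correlation matrix is singular: {what} undefined")
    return np.linalg.inv(R)


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's chi-square test that the correlation matrix is identity."""
    p = R.shape[0]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise EFAError("correlation matrix is singular: Bartlett test undefined")
    chi2 = max(0.0, -(n - 1 - (2 * p + 5) / 6.0) * logdet)
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def kmo_index(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy on [0, 1]."""
    Rinv = _safe_inverse(R, "KMO")
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


@dataclass(frozen=True)
class AssumptionReport:
    """Pre-factor-analysis battery with pass/fail flags and thresholds."""

    shapiro: pd.DataFrame            # per-column statistic + p-value
    skewness: pd.Series
    vif: pd.Series
    mahalanobis: np.ndarray          # per-row distance
    outlier_flags: np.ndarray        # per-row bool at the chi2 0.999 quantile
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo: float
    rows_per_variable: float
    flags: dict[str, bool]
    thresholds: dict[str, float] = field(default_factory=lambda: dict(THRESHOLDS))

    def to_json(self) -> dict:
        return {
            "shapiro": self.shapiro.to_dict(orient="index"),
            "skewness": self.skewness.to_dict(),
            "vif": self.vif.to_dict(),
            "n_outliers": int(self.outlier_flags.sum()),
            "bartlett": {"chi2": self.bartlett_chi2, "df": self.bartlett_df,
                         "p": self.bartlett_p},
            "kmo": self.kmo,
            "rows_per_variable": self.rows_per_variable,
            "flags": self.flags,
            "thresholds": self.thresholds,
        }

    def summary(self) -> str:
        lines = [
            f"rows/variable ratio: {self.rows_per_variable:.1f} "
            f"(pass: {self.flags['sample_size']})",
            f"Bartlett sphericity: chi2={self.bartlett_chi2:.2f} "
            f"df={self.bartlett_df} p={self.bartlett_p:.3g} "
            f"(pass: {self.flags['sphericity']})",
            f"KMO: {self.kmo:.3f} (pass: {self.flags['kmo']})",
            f"max VIF: {self.vif.max():.2f} (pass: {self.flags['multicollinearity']})",
            f"outliers flagged: {int(self.outlier_flags.sum())}",
            f"normality (all columns Shapiro-Wilk p >= "
            f"{self.thresholds['shapiro_alpha']}): {self.flags['normality']} "
            "(warning only; analysis proceeds)",
        ]
        return "\n".join(lines)


def assumption_report(df: pd.DataFrame, label_col: str | None = "label") -> AssumptionReport:
    """Run the full assumption battery on the numeric columns of ``df``."""
    if label_col is not None and label_col in df.columns:
        df = df.drop(columns=[label_col])
    cols = list(df.columns)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    if p < 3:
        raise ValueError("assumption battery needs at least 3 variables")
    if n <= p:
        raise ValueError("need more rows than variables")

    shapiro = pd.DataFrame(
        {c: dict(zip(("statistic", "p"), sps.shapiro(X[:, i]))) for i, c in enumerate(cols)}
    ).T
    skewness = pd.Series(sps.skew(X, axis=0), index=cols)

    R = _correlation(X)
    Rinv = _safe_inverse(R, "VIF")
    vif = pd.Series(np.diag(Rinv), index=cols)

    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    if np.linalg.cond(cov) > 1e12:
        raise EFAError("covariance matrix is singular: Mahalanobis undefined")
    delta = X - mean
    d2 = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)
    maha = np.sqrt(np.maximum(d2, 0.0))
    cutoff = np.sqrt(sps.chi2.ppf(THRESHOLDS["mahalanobis_quantile"], df=p))
    outliers = maha > cutoff

    chi2, dfree, pval = bartlett_sphericity(R, n)
    kmo = kmo_index(R)
    ratio = n / p

    flags = {
        "normality": bool((shapiro["p"] >= THRESHOLDS["shapiro_alpha"]).all()),
        "multicollinearity": bool((vif <= THRESHOLDS["vif_flag"]).all()),
        "no_outliers": bool(~outliers.any()),
        "sphericity": bool(pval < THRESHOLDS["shapiro_alpha"]),
        "kmo": bool(kmo >= THRESHOLDS["kmo_acceptable"]),
        "sample_size": bool(ratio >= THRESHOLDS["rows_per_variable_min"]),
    }
    return AssumptionReport(
        shapiro=shapiro, skewness=skewness, vif=vif, mahalanobis=maha,
        outlier_flags=outliers, bartlett_chi2=chi2, bartlett_df=dfree,
        bartlett_p=pval, kmo=kmo, rows_per_variable=float(ratio), flags=flags,
    )


def kaiser_count(R: np.ndarray) -> int:
    """Number of correlation-matrix eigenvalues above 1 (at least one)."""
    eig = np.linalg.eigvalsh(R)
    return max(1, int((eig > 1.0).sum()))


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the PAF starting communalities."""
    Rinv = _safe_inverse(R, "squared multiple correlations")
    return 1.0 - 1.0 / np.diag(Rinv)


@dataclass
class FactorModel:
    """Extracted factor structure plus everything needed to score new data."""

    n_factors: int
    eigenvalues: np.ndarray          # full correlation matrix, descending
    loadings: pd.DataFrame           # variables x factors
    communalities: pd.Series         # row sums of squared loadings
    uniquenesses: pd.Series          # 1 - communality
    variance_explained: np.ndarray   # per-factor proportion of total variance
    cumulative_variance: float
    rotation: np.ndarray             # orthogonal, identity if unrotated
    weights: pd.DataFrame            # Anderson-Rubin scoring weights
    stats: ColumnStats               # fitting-data column mean/sd
    correlation: np.ndarray          # fitting-data correlation matrix
    n_iterations: int = 0

    def score(self, df: pd.DataFrame) -> pd.DataFrame:
        """Anderson-Rubin factor scores for raw (unstandardized) data."""
        cols = list(self.loadings.index)
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"data lacks model variables {sorted(missing)}")
        Z = ((df[cols] - self.stats.mean[cols]) / self.stats.std[cols]).to_numpy(float)
        scores = Z @ self.weights.to_numpy(float)
        return pd.DataFrame(scores, index=df.index, columns=self.weights.columns)

    def to_json(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "eigenvalues": self.eigenvalues.tolist(),
            "variables": list(self.loadings.index),
            "factors": list(self.loadings.columns),
            "loadings": self.loadings.to_numpy().tolist(),
            "communalities": self.communalities.to_dict(),
            "variance_explained": self.variance_explained.tolist(),
            "cumulative_variance": self.cumulative_variance,
            "rotation": self.rotation.tolist(),
            "weights": self.weights.to_numpy().tolist(),
            "stats": self.stats.to_json(),
            "correlation": self.correlation.tolist(),
            "n_iterations": self.n_iterations,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, d: dict) -> "FactorModel":
        variables, factors = d["variables"], d["factors"]
        return cls(
            n_factors=int(d["n_factors"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            loadings=pd.DataFrame(d["loadings"], index=variables, columns=factors),
            communalities=pd.Series(d["communalities"]),
            uniquenesses=1.0 - pd.Series(d["communalities"]),
            variance_explained=np.asarray(d["variance_explained"]),
            cumulative_variance=float(d["cumulative_variance"]),
            rotation=np.asarray(d["rotation"]),
            weights=pd.DataFrame(d["weights"], index=variables, columns=factors),
            stats=ColumnStats.from_json(d["stats"]),
            correlation=np.asarray(d["correlation"]),
            n_iterations=int(d["n_iterations"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FactorModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def _paf_loadings(
    R: np.ndarray, m: int, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the reduced correlation matrix until communalities settle."""
    h = _smc(R).copy()
    trace: list[float] = []
    pinned = np.zeros(len(h), dtype=bool)
    for iteration in range(1, max_iter + 1):
        Rr = R.copy()
        np.fill_diagonal(Rr, h)
        eigval, eigvec = np.linalg.eigh(Rr)
        idx = np.argsort(eigval)[::-1][:m]
        lam = np.clip(eigval[idx], 0.0, None)
        L = eigvec[:, idx] * np.sqrt(lam)
        h_new = (L**2).sum(axis=1)
        # boundary (Heywood) treatment: a communality reaching the ceiling
        # is pinned there for all later iterations, which prevents the
        # update from cycling across the clip boundary
        at_ceiling = h_new >= 0.999
        if at_ceiling.any() and not pinned.any():
            warnings.warn(
                "Heywood case: communality >= 0.999 pinned to 0.999", RuntimeWarning
            )
        pinned |= at_ceiling
        h_new = np.where(pinned, 0.999, h_new)
        delta = float(np.max(np.abs(h_new - h)))
        trace.append(delta)
        h = h_new
        if delta < tol:
            # sign convention: dominant loading of each factor positive
            signs = np.sign(L[np.argmax(np.abs(L), axis=0), np.arange(m)])
            signs[signs == 0] = 1.0
            return L * signs, h, iteration
    raise EFAError(
        f"PAF did not converge in {max_iter} iterations; "
        f"last communality deltas: {trace[-5:]}"
    )


def _anderson_rubin_weights(L: np.ndarray, h: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Weights W with Z @ W having exactly identity covariance on the fit data."""
    psi = np.clip(1.0 - h, 1e-3, None)
    Pinv = np.diag(1.0 / psi)
    M = L.T @ Pinv @ R @ Pinv @ L
    eigval, eigvec = np.linalg.eigh(M)
    if np.any(eigval <= 0):
        raise EFAError("Anderson-Rubin weights undefined: degenerate loading matrix")
    M_inv_sqrt = eigvec @ np.diag(1.0 / np.sqrt(eigval)) @ eigvec.T
    return Pinv @ L @ M_inv_sqrt


def varimax(
    loadings: np.ndarray | pd.DataFrame,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray | pd.DataFrame, np.ndarray]:
    """Varimax rotation by Kaiser's pairwise algorithm.

    Rotates pairs of factors by the closed-form angle maximizing the varimax
    criterion, sweeping until no pair moves.  With ``kaiser_normalize`` the
    rows are scaled to unit communality during rotation (and scaled back),
    the common default.  Returns the rotated loadings and the accumulated
    orthogonal rotation matrix.  A single factor is returned unchanged.
    """
    is_frame = isinstance(loadings, pd.DataFrame)
    L0 = loadings.to_numpy(dtype=float) if is_frame else np.asarray(loadings, dtype=float)
    p, m = L0.shape
    T = np.eye(m)
    if m == 1:
        return (loadings.copy() if is_frame else L0.copy()), T

    norms = np.sqrt((L0**2).sum(axis=1))
    if kaiser_normalize:
        safe = np.where(norms > 0, norms, 1.0)
        L = L0 / safe[:, None]
    else:
        L = L0.copy()

    for _ in range(max_iter):
        max_angle = 0.0
        for i in range(m - 1):
            for j in range(i + 1, m):
                x, y = L[:, i], L[:, j]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C = (u**2 - v**2).sum()
                D = (2.0 * u * v).sum()
                num = D - 2.0 * A * B / p
                den = C - (A**2 - B**2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < tol:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s], [s, c]])
                L[:, [i, j]] = L[:, [i, j]] @ G
                T[:, [i, j]] = T[:, [i, j]] @ G
        if max_angle < 1e-8:
            break

    if kaiser_normalize:
        L = L * np.where(norms > 0, norms, 1.0)[:, None]
    if is_frame:
        L = pd.DataFrame(L, index=loadings.index, columns=loadings.columns)
    return L, T


def fit_paf(
    df: pd.DataFrame,
    n_factors: int | str = "kaiser",
    label_col: str | None = "label",
    tol: float = 1e-4,
    max_iter: int = 10000,
) -> FactorModel:
    """Principal Axis Factoring, unrotated.

    ``n_factors="kaiser"`` extracts as many factors as the full sample
    correlation matrix has eigenvalues above 1.
    """
    if label_col is not None and label_col in df.columns:
        df = df.drop(columns=[label_col])
    cols = list(df.columns)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    R = _correlation(X)
    eig_full = np.sort(np.linalg.eigvalsh(R))[::-1]
    m = kaiser_count(R) if n_factors == "kaiser" else int(n_factors)
    if not 1 <= m <= p:
        raise ValueError(f"n_factors must be in [1, {p}], got {m}")

    L, h, iters = _paf_loadings(R, m, tol, max_iter)
    W = _anderson_rubin_weights(L, h, R)
    factors = [f"F{i + 1}" for i in range(m)]
    var_prop = (L**2).sum(axis=0) / p
    mu = pd.Series(X.mean(axis=0), index=cols)
    sd = pd.Series(X.std(axis=0, ddof=1), index=cols)
    return FactorModel(
        n_factors=m,
        eigenvalues=eig_full,
        loadings=pd.DataFrame(L, index=cols, columns=factors),
        communalities=pd.Series(h, index=cols),
        uniquenesses=pd.Series(1.0 - h, index=cols),
        variance_explained=var_prop,
        cumulative_variance=float(var_prop.sum()),
        rotation=np.eye(m),
        weights=pd.DataFrame(W, index=cols, columns=factors),
        stats=ColumnStats(mean=mu, std=sd),
        correlation=R,
        n_iterations=iters,
    )


def fit_efa(
    df: pd.DataFrame,
    n_factors: int | str = "kaiser",
    label_col: str | None = "label",
    rotate: bool = True,
    tol: float = 1e-4,
    max_iter: int = 10000,
) -> FactorModel:
    """PAF extraction followed by Varimax rotation and Anderson-Rubin weights."""
    model = fit_paf(df, n_factors=n_factors, label_col=label_col, tol=tol,
                    max_iter=max_iter)
    if not rotate or model.n_factors == 1:
        return model
    L_rot, T = varimax(model.loadings)
    h = model.communalities.to_numpy()
    W = _anderson_rubin_weights(L_rot.to_numpy(), h, model.correlation)
    model.loadings = L_rot
    model.rotation = T
    model.variance_explained = (L_rot.to_numpy() ** 2).sum(axis=0) / len(L_rot)
    model.weights = pd.DataFrame(W, index=L_rot.index, columns=L_rot.columns)
    return model


def anderson_rubin_scores(model: FactorModel, df: pd.DataFrame) -> pd.DataFrame:
    """Score ``df`` (raw scale) with the model's stored weights and stats."""
    return model.score(df)
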