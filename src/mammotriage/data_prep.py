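"""Normalization and class balancing of labeled risk tables.

Risk tables (columns ``R1a..R4`` plus ``label``) are Z-score normalized
column-wise, z = (x - mu) / sigma with the sample (n-1) standard deviation;
the column statistics are retained so a new patient's risks can be mapped
onto exactly the same scale later.

Class imbalance is then corrected with Safe-Level SMOTE: synthetic rows are
interpolated between a class member p and one of its k nearest same-class
neighbours n, with the interpolation gap biased by the "safe level" of each
endpoint — the number of same-class points among its k nearest neighbours
over the whole table.  Interpolation is pulled toward the safer endpoint,
which avoids synthesizing points inside the opposite class's territory.
Both classes may be augmented; the class being augmented is treated as the
minority for its own safe-level computation, and interpolation neighbours
are always drawn from that same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ColumnStats",
    "AugmentationConfig",
    "DegenerateColumn",
    "AugmentationError",
    "zscore",
    "safe_level_smote",
    "augment_dataset",
]


class DegenerateColumn(ValueError):
    """A column has zero sample standard deviation."""


class AugmentationError(ValueError):
    """The requested augmentation is infeasible."""


@dataclass(frozen=True)
class ColumnStats:
    """Per-column mean and sample standard deviation captured at fit time."""

    mean: pd.Series
    std: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        """Map new data (e.g. one patient's risks) with the stored mu, sigma."""
        out = df.copy()
        out[self.mean.index] = (df[self.mean.index] - self.mean) / self.std
        return out

    def to_json(self) -> dict:
        return {"mean": self.mean.to_dict(), "std": self.std.to_dict()}

    @classmethod
    def from_json(cls, d: dict) -> "ColumnStats":
        return cls(mean=pd.Series(d["mean"]), std=pd.Series(d["std"]))


def _numeric_columns(df: pd.DataFrame, label_col: str) -> list[str]:
    return [c for c in df.columns if c != label_col]


def zscore(df: pd.DataFrame, label_col: str = "label") -> tuple[pd.DataFrame, ColumnStats]:
    """Z-score normalize every non-label column.

    Returns the normalized table and the captured :class:`ColumnStats`.
    Raises :class:`DegenerateColumn` if any column is constant (sigma = 0).
    """
    cols = _numeric_columns(df, label_col)
    if len(df) < 2:
        raise ValueError("need at least 2 rows to normalize")
    mu = df[cols].mean()
    sigma = df[cols].std(ddof=1)
    bad = sigma[~(sigma > 0)].index.tolist()
    if bad:
        raise DegenerateColumn(f"constant column(s) {bad}: sigma = 0")
    stats = ColumnStats(mean=mu, std=sigma)
    return stats.transform(df), stats


@dataclass(frozen=True)
class AugmentationConfig:
    """How many synthetic rows per class, with how many neighbours.

    ``k_neighbors`` defaults to 4, the initial configuration of the
    balancing stage.  A seed is mandatory: all randomness is local.
    """

    counts: dict[str, int] = field(default_factory=dict)
    k_neighbors: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        for label, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative synthetic count for {label!r}")


def _safe_levels(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """sl(i) = number of same-class points among i's k nearest neighbours.

    Neighbours are searched over the whole table, all classes, excluding the
    point itself; distance ties are broken by row index (stable argsort).
    """
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    return (y[order] == y[:, None]).sum(axis=1)


def safe_level_smote(
    df: pd.DataFrame, cfg: AugmentationConfig, label_col: str = "label"
) -> pd.DataFrame:
    """Generate the requested synthetic rows per class.

    For each synthetic row a seed point p is drawn uniformly from the class,
    and a neighbour n uniformly from p's k nearest same-class neighbours.
    With sl the safe level and ratio = sl(p)/sl(n), the gap g of the
    interpolation p + g (n - p) is drawn as:

    * sl(p) = sl(n) = 0      → skip p (unsafe region, no row generated);
    * sl(n) = 0 < sl(p)      → g = 0 (duplicate p);
    * ratio = 1              → g ~ U(0, 1);
    * ratio > 1              → g ~ U(0, 1/ratio)   (stay near the safer p);
    * ratio < 1              → g ~ U(1 - ratio, 1) (move toward the safer n).
    """
    cols = _numeric_columns(df, label_col)
    X = df[cols].to_numpy(dtype=float)
    y = df[label_col].to_numpy()
    k = cfg.k_neighbors
    rng = np.random.default_rng(cfg.seed)
    sl = _safe_levels(X, y, k)

    out_rows: list[np.ndarray] = []
    out_labels: list[str] = []
    for label, n_requested in cfg.counts.items():
        if n_requested == 0:
            continue
        members = np.flatnonzero(y == label)
        if members.size == 0:
            raise AugmentationError(f"class {label!r} has no members")
        if members.size <= k:
            raise AugmentationError(
                f"class {label!r} has {members.size} members, need > k = {k}"
            )
        # k nearest same-class neighbours of each member, for interpolation
        d_in = cdist(X[members], X[members])
        np.fill_diagonal(d_in, np.inf)
        nn_in = np.argsort(d_in, axis=1, kind="stable")[:, :k]

        produced = 0
        attempts = 0
        max_attempts = 200 * n_requested
        while produced < n_requested:
            attempts += 1
            if attempts > max_attempts:
                raise AugmentationError(
                    f"class {label!r}: all candidate seed points are unsafe "
                    f"(produced {produced}/{n_requested})"
                )
            i = rng.integers(members.size)
            p_idx = members[i]
            n_idx = members[nn_in[i, rng.integers(k)]]
            sl_p, sl_n = sl[p_idx], sl[n_idx]
            if sl_p == 0 and sl_n == 0:
                continue  # skip p: nothing safe nearby
            if sl_n == 0:
                gap = 0.0
            else:
                ratio = sl_p / sl_n
                if ratio == 1.0:
                    gap = rng.uniform(0.0, 1.0)
                elif ratio > 1.0:
                    gap = rng.uniform(0.0, 1.0 / ratio)
                else:
                    gap = rng.uniform(1.0 - ratio, 1.0)
            out_rows.append(X[p_idx] + gap * (X[n_idx] - X[p_idx]))
            out_labels.append(label)
            produced += 1

    if not out_rows:
        return pd.DataFrame(columns=[*cols, label_col])
    synth = pd.DataFrame(np.vstack(out_rows), columns=cols)
    synth[label_col] = out_labels
    return synth


def augment_dataset(
    df: pd.DataFrame, cfg: AugmentationConfig, label_col: str = "label"
) -> tuple[pd.DataFrame, dict]:
    """Append Safe-Level-SMOTE rows to the originals.

    Returns the augmented table (originals first, unmodified) and a summary
    with per-class original / synthetic / total counts.
    """
    synth = safe_level_smote(df, cfg, label_col=label_col)
    if len(synth):
        augmented = pd.concat([df, synth], ignore_index=True)
    else:
        augmented = df.reset_index(drop=True).copy()
    orig_counts = df[label_col].value_counts().to_dict()
    synth_counts = synth[label_col].value_counts().to_dict() if len(synth) else {}
    summary = {
        "per_class": {
            str(label): {
                "original": int(orig_counts.get(label, 0)),
                "synthetic": int(synth_counts.get(label, 0)),
                "total": int(orig_counts.get(label, 0) + synth_counts.get(label, 0)),
            }
            for label in sorted(set(orig_counts) | set(synth_counts))
        },
        "total_rows": int(len(augmented)),
    }
    return augmented, summary
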