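"""Supervised (discriminant) PCA on group×session median metric vectors.

The ordination is fitted to the table of per-group, per-session medians of
the seven behavioral variables (8 groups × 5 acquisition sessions = 40
rows in the default design).  Columns are Z-scored with the population
(divide-by-N) variance so that the between-group variance of the row
scores is exactly 1; individual subject-sessions are then projected into
the fitted space as supplementary points using the *model's* centering
and scaling constants.  Row scores are kept in distance-preserving
(principal) coordinates: pairwise Euclidean distances between full-rank
scores equal those between the Z-scored rows.

Axis orientation is fixed deterministically: PC1 is flipped so the
Gallagher-index loading is negative (high PC1 = short distances to
target, i.e. better learning) and PC2 so the speed loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_COLUMNS


class ZeroVarianceError(ValueError):
    pass


def build_group_median_table(
    records: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Group×session medians of the session-mean metric records.

    Returns a DataFrame indexed by (group, session).  Even-sized groups
    use the midpoint-of-central-order-statistics median.  Raises if any
    (group, session) cell is empty.
    """
    columns = columns or METRIC_COLUMNS
    groups = list(pd.unique(records["group"]))
    sessions = sorted(records["session"].unique())
    med = records.groupby(["group", "session"], sort=False)[columns].median()
    full = pd.MultiIndex.from_product([groups, sessions], names=["group", "session"])
    missing = full.difference(med.index)
    if len(missing):
        g, s = missing[0]
        raise ValueError(f"no subjects for group {g!r} in session {s}")
    return med.reindex(full)


def _zscore_fit(values: np.ndarray, columns: list[str]) -> tuple[np.ndarray, np.ndarray]:
    center = values.mean(axis=0)
    scale = values.std(axis=0, ddof=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        names = [columns[i] for i in zero]
        raise ZeroVarianceError(
            f"zero-variance column(s) {names}: remove them or add jitter before fitting"
        )
    return center, scale


def _orient_signs(loadings: np.ndarray, columns: list[str]) -> np.ndarray:
    """Deterministic sign per component: Gallagher negative on PC1, speed
    positive on PC2, largest-|loading| entry positive elsewhere."""
    k = loadings.shape[1]
    signs = np.ones(k)
    gal = columns.index("gallagher") if "gallagher" in columns else None
    spd = columns.index("speed") if "speed" in columns else None
    for p in range(k):
        ref = None
        if p == 0 and gal is not None and loadings[gal, 0] != 0.0:
            ref = -loadings[gal, 0]
        elif p == 1 and spd is not None and loadings[spd, 1] != 0.0:
            ref = loadings[spd, 1]
        else:
            j = int(np.argmax(np.abs(loadings[:, p])))
            ref = loadings[j, p] if loadings[j, p] != 0.0 else 1.0
        signs[p] = 1.0 if ref > 0 else -1.0
    return signs


def _svd_fit(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scores (distance-preserving), eigenvalues (population) and
    orthonormal loadings of a Z-scored matrix."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eigenvalues = s**2 / z.shape[0]
    return u * s, eigenvalues, vt.T


@dataclass
class PCAModel:
    columns: list[str]
    row_labels: list[tuple]  # (group, session) per row
    center: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray  # descending, population convention
    percent_variance: np.ndarray
    loadings: np.ndarray  # (n_vars, k), orthonormal columns
    contributions: np.ndarray  # (n_vars, k), percent, columns sum to 100
    scores: np.ndarray  # (n_rows, k)
    groups: list = field(default_factory=list)
    sessions: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project raw metric vectors (rows) using the model's constants."""
        z = (np.asarray(values, dtype=float) - self.center) / self.scale
        return z @ self.loadings


def fit_supervised_pca(table: pd.DataFrame) -> PCAModel:
    """Fit the ordination to a group×session median table.

    Z-scores every column with the population variance, then takes the
    SVD of the scaled table; eigenvalues follow the population covariance
    convention so they sum to the number of variables.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to fit a PCA")
    columns = list(table.columns)
    values = table.to_numpy(dtype=float)
    center, scale = _zscore_fit(values, columns)
    z = (values - center) / scale
    scores, eigenvalues, loadings = _svd_fit(z)
    signs = _orient_signs(loadings, columns)
    loadings = loadings * signs
    scores = scores * signs
    pct = 100.0 * eigenvalues / eigenvalues.sum()
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    labels = list(table.index)
    groups = list(dict.fromkeys(g for g, _ in labels))
    sessions = sorted({s for _, s in labels})
    return PCAModel(
        columns=columns,
        row_labels=labels,
        center=center,
        scale=scale,
        eigenvalues=eigenvalues,
        percent_variance=pct,
        loadings=loadings,
        contributions=contrib,
        scores=scores,
        groups=groups,
        sessions=sessions,
    )


def project_supplementary(records: pd.DataFrame, model: PCAModel) -> pd.DataFrame:
    """Project individual subject-session records as supplementary points.

    Each record is centered and scaled by the *model's* constants (those
    of the median table) and mapped through the loadings; projecting a
    median-table row reproduces its fitted score exactly.
    """
    missing = [c for c in model.columns if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing variables {missing}")
    coords = model.transform(records[model.columns].to_numpy(dtype=float))
    out = records.drop(columns=model.columns).copy()
    for p in range(coords.shape[1]):
        out[f"PC{p + 1}"] = coords[:, p]
    return out


def group_trajectories(model: PCAModel) -> dict:
    """Per-group ordered session paths in the (PC1, PC2) plane."""
    paths: dict = {}
    idx = pd.MultiIndex.from_tuples(model.row_labels, names=["group", "session"])
    scores = pd.DataFrame(model.scores[:, :2], columns=["PC1", "PC2"], index=idx)
    for g in model.groups:
        sub = scores.loc[g].sort_index()
        paths[g] = sub
    return paths
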