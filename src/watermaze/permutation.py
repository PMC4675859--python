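"""Permutation inference for group separation and pairwise PC1 contrasts.

Subjects are reassigned uniformly at random to groups of the original
sizes; each subject carries all of its session records to the new label
(sessions are never shuffled).  The whole pipeline — group×session median
table, Z-scaling, PCA, supplementary projection, variance decomposition —
is re-derived for every draw, so the null distribution reflects the full
estimation procedure.

Two statistics:

* ``within_session_separation`` — within-session variance as a percentage
  of total variance; large values mean the groups are far apart inside
  sessions relative to individual scatter (upper-tail test).
* ``pc1_pairwise_t`` — Welch two-sample t on the supplementary PC1
  coordinates of two groups' subjects at a chosen session (two-sided);
  all pairs share the same permutation stream, which also yields a
  max-|t| familywise-adjusted p-value.

p-values use the add-one convention (1 + exceedances) / (1 + B), so they
are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .metrics import METRIC_COLUMNS
from .pca import _orient_signs
from .variance import _decompose_arrays


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    session: int | None = None
    groups: tuple | None = None
    extras: dict = field(default_factory=dict)


def permute_group_labels(
    n_subjects: int, group_sizes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random partition of subjects into groups of the given sizes.

    Returns an integer group index per subject; every subject keeps all of
    its session records together under the new label.
    """
    group_sizes = np.asarray(group_sizes, dtype=int)
    if group_sizes.sum() != n_subjects:
        raise ValueError(
            f"group sizes sum to {group_sizes.sum()} but there are {n_subjects} subjects"
        )
    order = rng.permutation(n_subjects)
    assignment = np.empty(n_subjects, dtype=int)
    assignment[order] = np.repeat(np.arange(len(group_sizes)), group_sizes)
    return assignment


def _records_to_arrays(records: pd.DataFrame, columns: list[str] | None = None):
    """Pivot session-mean records to (n_subjects, S, n_vars) with a group
    index per subject."""
    columns = columns or METRIC_COLUMNS
    sessions = sorted(records["session"].unique())
    groups = list(pd.unique(records["group"]))
    wide = records.pivot_table(
        index=["group", "subject_id"], columns="session", values=columns, sort=True
    )
    subj_groups = np.asarray([groups.index(g) for g, _ in wide.index])
    n, S, p = len(wide), len(sessions), len(columns)
    values = np.empty((n, S, p))
    for j, c in enumerate(columns):
        sub = wide[c].reindex(columns=sessions)
        if sub.isna().any().any():
            raise ValueError("every subject needs a record for every session")
        values[:, :, j] = sub.to_numpy()
    return values, subj_groups, groups, sessions


def _median_table(values: np.ndarray, assignment: np.ndarray, n_groups: int) -> np.ndarray:
    """(G·S, n_vars) median table, rows group-major then session."""
    G, S, p = n_groups, values.shape[1], values.shape[2]
    table = np.empty((G, S, p))
    for g in range(G):
        table[g] = np.median(values[assignment == g], axis=0)
    return table.reshape(G * S, p)


def _pipeline_core(
    values: np.ndarray,
    assignment: np.ndarray,
    n_groups: int,
    columns: list[str] | None = None,
):
    """Median table → population Z-scaling → SVD → supplementary scores.

    Returns (row_scores, session_of_row, supp_scores, loadings) in the
    full-rank ordination space.  When ``columns`` is given the axes are
    oriented with the package's deterministic sign convention.
    """
    n, S, p = values.shape
    table = _median_table(values, assignment, n_groups)
    center = table.mean(axis=0)
    scale = table.std(axis=0, ddof=0)
    if np.any(scale == 0.0):
        raise ValueError("zero-variance column in the median table")
    z = (table - center) / scale
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    row_scores = u * s
    if columns is not None:
        signs = _orient_signs(loadings, columns)
        loadings = loadings * signs
        row_scores = row_scores * signs
    supp = (values.reshape(n * S, p) - center) / scale
    supp_scores = supp @ loadings
    session_of_row = np.tile(np.arange(S), n_groups)
    return row_scores, session_of_row, supp_scores, loadings


def _within_session_pct(values: np.ndarray, assignment: np.ndarray, n_groups: int) -> float:
    row_scores, sess, supp_scores, _ = _pipeline_core(values, assignment, n_groups)
    v_b, v_bs, v_t = _decompose_arrays(
        row_scores, sess, supp_scores, values.shape[2], n_groups
    )
    return 100.0 * (v_b - v_bs) / v_t


def separation_test(
    records: pd.DataFrame,
    n_permutations: int = 10_000,
    seed: int = 0,
    columns: list[str] | None = None,
) -> PermutationResult:
    """Overall group-separation test.

    The statistic is the within-session variance as a percentage of total
    variance; the null relabels subjects (keeping group sizes and session
    structure) and re-derives the full median-table → PCA → decomposition
    pipeline at each of ``n_permutations`` draws.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    values, subj_groups, groups, _ = _records_to_arrays(records, columns)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    G = len(groups)
    sizes = np.bincount(subj_groups, minlength=G)
    observed = _within_session_pct(values, subj_groups, G)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = permute_group_labels(len(subj_groups), sizes, rng)
        null[b] = _within_session_pct(values, perm, G)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + n_permutations)
    return PermutationResult(
        statistic="within_session_separation",
        observed=float(observed),
        null=null,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _pairwise_t_all(
    values: np.ndarray,
    assignment: np.ndarray,
    n_groups: int,
    session_idx: int,
    pairs: list[tuple[int, int]],
    columns: list[str] | None = None,
) -> np.ndarray:
    _, _, supp_scores, _ = _pipeline_core(values, assignment, n_groups, columns)
    n, S, p = values.shape
    pc1 = supp_scores[:, 0].reshape(n, S)[:, session_idx]
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = _welch_t(pc1[assignment == i], pc1[assignment == j])
    return out


def pc1_pairwise_test(
    records: pd.DataFrame,
    session: int,
    n_permutations: int = 10_000,
    seed: int = 0,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """All pairwise PC1 group contrasts at one session.

    For each group pair, the observed Welch t compares the two groups'
    supplementary PC1 coordinates at the chosen session; the PCA is refit
    under every relabeling and all pairs are evaluated on the same
    permutation stream.  Returns one row per pair with the observed t,
    the two-sided permutation p and a max-|t| familywise-adjusted p.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    values, subj_groups, groups, sessions = _records_to_arrays(records, columns)
    if session not in sessions:
        raise ValueError(f"session {session} not present (have {sessions})")
    session_idx = sessions.index(session)
    G = len(groups)
    sizes = np.bincount(subj_groups, minlength=G)
    if np.any(sizes < 2):
        raise ValueError("every group needs at least two subjects for a t-statistic")
    pairs = list(combinations(range(G), 2))
    cols = columns or METRIC_COLUMNS
    observed = _pairwise_t_all(values, subj_groups, G, session_idx, pairs, cols)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(pairs)))
    for b in range(n_permutations):
        perm = permute_group_labels(len(subj_groups), sizes, rng)
        null[b] = _pairwise_t_all(values, perm, G, session_idx, pairs, cols)
    abs_null = np.abs(null)
    max_null = abs_null.max(axis=1)
    rows = []
    for k, (i, j) in enumerate(pairs):
        t_obs = observed[k]
        p = (1.0 + np.count_nonzero(abs_null[:, k] >= abs(t_obs))) / (1.0 + n_permutations)
        p_fwe = (1.0 + np.count_nonzero(max_null >= abs(t_obs))) / (1.0 + n_permutations)
        rows.append(
            {
                "group_a": groups[i],
                "group_b": groups[j],
                "session": session,
                "t": t_obs,
                "p_perm": p,
                "p_fwe": p_fwe,
            }
        )
    return pd.DataFrame(rows)
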