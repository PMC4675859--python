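"""Variance decomposition of the ordination coordinates.

All variances use the same scaled-squared-distance form

    V = (1 / (n_vars · N)) Σ_i d_i²

where d_i is the distance of object i from the origin of the full-rank
ordination space and n_vars is the number of metric variables (7).

* Between-group variance V_B: objects are the group×session median rows
  (N = G·S).  Because the PCA is fitted to these rows with population
  Z-scaling, V_B = 1 by construction.
* Total variance V_T: objects are the individual subject-sessions
  projected as supplementary points (N = subjects × sessions).
* Between-session variance V_BS: d_s² is the squared norm of the
  G-group-average coordinate vector of session s, and N = S.
* Within-session variance V_WS = V_B − V_BS: the average separation of
  the groups within sessions.

Percentages are relative to V_T; the within-group share is
100 − V_B/V_T·100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import PCAModel


@dataclass
class VarianceDecomposition:
    v_total: float
    v_between: float
    v_between_session: float
    v_within_session: float
    pct_between: float
    pct_between_session: float
    pct_within_session: float
    pct_within_group: float
    n_vars: int
    n_groups: int
    n_sessions: int
    n_individuals: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _decompose_arrays(
    row_scores: np.ndarray,
    session_of_row: np.ndarray,
    supp_scores: np.ndarray,
    n_vars: int,
    n_groups: int,
) -> tuple[float, float, float]:
    """(V_B, V_BS, V_T) from full-rank coordinates."""
    d2 = (row_scores**2).sum(axis=1)
    v_b = d2.mean() / n_vars
    sessions = np.unique(session_of_row)
    d2s = np.empty(len(sessions))
    for i, s in enumerate(sessions):
        mean_coord = row_scores[session_of_row == s].sum(axis=0) / n_groups
        d2s[i] = (mean_coord**2).sum()
    v_bs = d2s.mean() / n_vars
    v_t = (supp_scores**2).sum(axis=1).mean() / n_vars
    return float(v_b), float(v_bs), float(v_t)


def decompose_variance(
    model: PCAModel, supplementary: pd.DataFrame
) -> VarianceDecomposition:
    """Decompose the total variance using the fitted model's full-rank
    coordinates and the supplementary individual coordinates.

    ``supplementary`` is the output of
    :func:`watermaze.pca.project_supplementary` (PC columns plus labels).
    """
    pc_cols = [f"PC{p + 1}" for p in range(model.n_components)]
    missing = [c for c in pc_cols if c not in supplementary.columns]
    if missing:
        raise ValueError(f"supplementary table lacks coordinates {missing}")
    if "group" in supplementary.columns:
        extra = set(supplementary["group"].unique()) - set(model.groups)
        if extra:
            raise ValueError(f"supplementary groups {sorted(extra)} not in the model")
    supp = supplementary[pc_cols].to_numpy(dtype=float)
    session_of_row = np.asarray([s for _, s in model.row_labels])
    n_vars = len(model.columns)
    n_groups = len(model.groups)
    v_b, v_bs, v_t = _decompose_arrays(
        model.scores, session_of_row, supp, n_vars, n_groups
    )
    v_ws = v_b - v_bs
    return VarianceDecomposition(
        v_total=v_t,
        v_between=v_b,
        v_between_session=v_bs,
        v_within_session=v_ws,
        pct_between=100.0 * v_b / v_t,
        pct_between_session=100.0 * v_bs / v_t,
        pct_within_session=100.0 * v_ws / v_t,
        pct_within_group=100.0 - 100.0 * v_b / v_t,
        n_vars=n_vars,
        n_groups=n_groups,
        n_sessions=len(model.sessions),
        n_individuals=len(supp),
    )
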