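"""Single-variate models: censored random-intercept regression, mixed
repeated-measures ANOVA with Tukey post-hoc tests, and FDR control.

The centerpiece is a Gaussian random-intercept model with a
right-censored response (a mixed-effects Tobit), used for escape latency
on the log scale where the 60 s cutoff censors the response at log 60:

    y*_ij = x_ij' β + u_i + e_ij,   u_i ~ N(0, σ_u²),  e_ij ~ N(0, σ_e²)
    y_ij  = min(y*_ij, c),          censored ⟺ y*_ij ≥ c

with fixed effects for group, session (numeric 1..S) and their
interaction, so each group's session slope can be contrasted against a
reference group.  The subject random intercept is integrated out with
Gauss–Hermite quadrature and the likelihood maximized by quasi-Newton
iterations from several jittered starts.  Setting the threshold to +inf
recovers the ordinary Gaussian mixed model; additionally constraining
σ_u = 0 recovers OLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.numdiff import approx_hess2

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CensoredFit:
    """Maximum-likelihood fit of the (possibly censored) mixed model."""

    params: pd.DataFrame  # term, estimate, se, z, p, p_bh
    sigma_u: float
    sigma_e: float
    loglik: float
    threshold: float
    reference: str
    converged: bool
    n_iter: int
    grad_norm: float
    quad_order: int
    n_obs: int
    n_subjects: int
    term_names: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])


def _design_matrix(
    data: pd.DataFrame,
    reference: str,
    group_col: str,
    session_col: str,
) -> tuple[np.ndarray, list[str]]:
    groups = list(pd.unique(data[group_col]))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    others = [g for g in groups if g != reference]
    sess = data[session_col].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["Intercept"]
    for g in others:
        cols.append((data[group_col] == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    cols.append(sess)
    names.append("session")
    for g in others:
        cols.append(sess * (data[group_col] == g).to_numpy(dtype=float))
        names.append(f"session:group[{g}]")
    return np.column_stack(cols), names


class _CensoredMixedLoglik:
    """Negative log-likelihood with the random intercept integrated by
    adaptive Gauss–Hermite quadrature: nodes are recentered at every
    subject's posterior mode and rescaled by the local curvature, so
    moderate orders (default 16) are accurate.  Parameter vector is
    (β..., log σ_u, log σ_e) — or (β..., log σ_e) without random effects."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        censored: np.ndarray,
        subject_index: np.ndarray,
        threshold: float,
        quad_order: int,
        random_intercept: bool,
    ):
        order = np.argsort(subject_index, kind="stable")
        self.X = X[order]
        self.y = y[order]
        self.cens = censored[order]
        self.subj = subject_index[order]
        self.n_subjects = int(self.subj.max()) + 1
        self.starts = np.searchsorted(self.subj, np.arange(self.n_subjects))
        self.threshold = threshold
        self.random_intercept = random_intercept
        nodes, weights = np.polynomial.hermite.hermgauss(quad_order)
        self.nodes = nodes  # physicists' nodes, weight e^{-x^2}
        self.log_weights = np.log(weights)

    def _row_loglik(self, shifted: np.ndarray, sigma_e: float) -> np.ndarray:
        """log f(y_j | linear predictor) per row for observed rows and
        log P(y* >= c) for censored rows; ``shifted`` is (n,) or (n, K)."""
        ll = np.empty_like(shifted)
        obs = ~self.cens
        r = (self.y[obs, None] if shifted.ndim == 2 else self.y[obs]) - shifted[obs]
        r = r / sigma_e
        ll[obs] = -0.5 * r * r - math.log(sigma_e) - _LOG_SQRT_2PI
        if self.cens.any():
            zc = (shifted[self.cens] - self.threshold) / sigma_e
            ll[self.cens] = special.log_ndtr(zc)
        return ll

    def _posterior_modes(
        self, mu: np.ndarray, sigma_u: float, sigma_e: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject mode and curvature scale of the log integrand
        (Newton iterations; the integrand is log-concave)."""
        m = self.n_subjects
        u = np.zeros(m)
        obs = ~self.cens
        inv_se2 = 1.0 / sigma_e**2
        for _ in range(50):
            shifted = mu + u[self.subj]
            g1 = np.empty_like(mu)
            g2 = np.empty_like(mu)
            g1[obs] = (self.y[obs] - shifted[obs]) * inv_se2
            g2[obs] = -inv_se2
            if self.cens.any():
                z = (shifted[self.cens] - self.threshold) / sigma_e
                # inverse Mills ratio and its derivative, computed stably
                log_r = -0.5 * z * z - _LOG_SQRT_2PI - special.log_ndtr(z)
                r = np.exp(log_r)
                g1[self.cens] = r / sigma_e
                g2[self.cens] = -r * (z + r) * inv_se2
            h1 = np.add.reduceat(g1, self.starts) - u / sigma_u**2
            h2 = np.add.reduceat(g2, self.starts) - 1.0 / sigma_u**2
            step = h1 / h2
            u -= step
            if np.max(np.abs(step)) < 1e-12:
                break
        scale = 1.0 / np.sqrt(-h2)
        return u, scale

    def loglik(self, theta: np.ndarray) -> float:
        if self.random_intercept:
            beta, log_su, log_se = theta[:-2], theta[-2], theta[-1]
            sigma_u = math.exp(log_su)
        else:
            beta, log_se = theta[:-1], theta[-1]
            sigma_u = 0.0
        sigma_e = math.exp(log_se)
        mu = self.X @ beta
        if not self.random_intercept:
            return float(self._row_loglik(mu, sigma_e).sum())
        u_hat, scale = self._posterior_modes(mu, sigma_u, sigma_e)
        # adaptive nodes per subject: u = u_hat + sqrt(2)*scale*x_k
        u_nodes = u_hat[:, None] + math.sqrt(2.0) * scale[:, None] * self.nodes[None, :]
        shifted = mu[:, None] + u_nodes[self.subj]
        row_ll = self._row_loglik(shifted, sigma_e)
        h = np.add.reduceat(row_ll, self.starts, axis=0)
        h += -0.5 * (u_nodes / sigma_u) ** 2 - math.log(sigma_u) - _LOG_SQRT_2PI
        ll = special.logsumexp(
            self.log_weights[None, :] + self.nodes[None, :] ** 2 + h, axis=1
        )
        ll += 0.5 * math.log(2.0) + np.log(scale)
        return float(ll.sum())

    def __call__(self, theta: np.ndarray) -> float:
        val = self.loglik(theta)
        if not np.isfinite(val):
            return 1e12
        return -val


def fit_censored_mixed(
    data: pd.DataFrame,
    response: str,
    threshold: float | None,
    reference: str,
    *,
    group_col: str = "group",
    session_col: str = "session",
    subject_col: str = "subject_id",
    censored_col: str = "censored",
    random_intercept: bool = True,
    quad_order: int = 16,
    n_starts: int = 3,
    seed: int = 0,
) -> CensoredFit:
    """Fit ``response ~ session × group + (1 | subject)`` with right
    censoring at ``threshold`` (None or +inf for no censoring).

    Wald z-tests are reported per fixed-effect term; the session:group
    interaction contrasts (the per-group learning-slope differences vs
    the reference) additionally get Benjamini–Hochberg adjusted p-values.
    """
    data = data.reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    if threshold is None or not np.isfinite(threshold):
        threshold = np.inf
        cens = np.zeros(len(data), dtype=bool)
    else:
        if censored_col in data.columns:
            cens = data[censored_col].to_numpy(dtype=bool)
        else:
            cens = y >= threshold
        if cens.all():
            raise ValueError("all observations censored: model not identifiable")
    X, names = _design_matrix(data, reference, group_col, session_col)
    subj_codes, _ = pd.factorize(data[subject_col])
    per_group = data.groupby(group_col)[subject_col].nunique()
    if (per_group < 2).any():
        raise ValueError("every group needs at least two subjects")
    ll = _CensoredMixedLoglik(
        X, y, cens, subj_codes, threshold, quad_order, random_intercept
    )

    # start values: OLS on all rows (censored rows included as observed)
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s0 = max(resid.std(ddof=X.shape[1]), 1e-3)
    if random_intercept:
        subj_means = pd.Series(resid).groupby(subj_codes).mean()
        su0 = max(float(subj_means.std(ddof=1)), 0.05 * s0)
        theta0 = np.concatenate([beta0, [math.log(su0), math.log(s0)]])
    else:
        theta0 = np.concatenate([beta0, [math.log(s0)]])

    rng = np.random.default_rng(seed)
    best = None
    for k in range(max(1, n_starts)):
        start = theta0 if k == 0 else theta0 + rng.normal(0.0, 0.3, size=len(theta0))
        res = optimize.minimize(ll, start, method="BFGS", jac="3-point",
                                options={"gtol": 1e-8, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("censored mixed model failed to converge")
    grad_norm = float(np.max(np.abs(best.jac)))
    if not best.success and grad_norm > 1e-2:
        raise RuntimeError(
            f"censored mixed model did not converge: grad_norm={grad_norm:.3g}, "
            f"iterations={best.nit}"
        )

    theta = best.x
    n_beta = X.shape[1]
    hess = approx_hess2(theta, ll)
    # a variance component on its boundary leaves a near-null Hessian
    # direction; the pseudo-inverse still yields usable betas' SEs
    with np.errstate(all="ignore"):
        diag = np.diag(np.linalg.pinv(hess))
    se_all = np.where(np.isfinite(diag) & (diag > 0), np.sqrt(np.abs(diag)), np.nan)
    beta = theta[:n_beta]
    se = se_all[:n_beta]
    with np.errstate(all="ignore"):
        z = beta / se
    p = 2.0 * special.ndtr(-np.abs(z))
    params = pd.DataFrame(
        {"term": names, "estimate": beta, "se": se, "z": z, "p": p}
    )
    inter = params["term"].str.startswith("session:group[").to_numpy()
    p_bh = np.full(len(params), np.nan)
    adjustable = inter & np.isfinite(p)
    if adjustable.any():
        p_bh[adjustable] = bh_adjust(params.loc[adjustable, "p"].to_numpy())
    params["p_bh"] = p_bh
    if random_intercept:
        sigma_u, sigma_e = math.exp(theta[-2]), math.exp(theta[-1])
    else:
        sigma_u, sigma_e = 0.0, math.exp(theta[-1])
    return CensoredFit(
        params=params,
        sigma_u=sigma_u,
        sigma_e=sigma_e,
        loglik=-float(best.fun),
        threshold=float(threshold),
        reference=reference,
        converged=bool(best.success or grad_norm <= 1e-2),
        n_iter=int(best.nit),
        grad_norm=grad_norm,
        quad_order=quad_order,
        n_obs=len(data),
        n_subjects=int(subj_codes.max()) + 1,
        term_names=names,
    )


def fit_uncensored_mixed(
    data: pd.DataFrame, response: str, reference: str, **kwargs
) -> CensoredFit:
    """Gaussian random-intercept model without censoring (threshold +inf);
    used for the uncensored metrics (Gallagher index, thigmotaxis, ...)."""
    return fit_censored_mixed(data, response, None, reference, **kwargs)


@dataclass
class AnovaResult:
    f_group: float
    p_group: float
    table: pd.DataFrame  # full mixed-ANOVA table
    tukey: pd.DataFrame  # pairwise group comparisons on subject means


def rm_anova_with_posthoc(
    session_means: pd.DataFrame,
    dv: str,
    *,
    group_col: str = "group",
    session_col: str = "session",
    subject_col: str = "subject_id",
) -> AnovaResult:
    """Repeated-measures (mixed-design) ANOVA over sessions with group as
    the between-subject factor, plus Tukey HSD pairwise group comparisons
    on the per-subject means."""
    import pingouin as pg
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = session_means.groupby(group_col)[subject_col].nunique()
    if (counts < 2).any() or counts.size < 2:
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    table = pg.mixed_anova(
        data=session_means, dv=dv, within=session_col,
        subject=subject_col, between=group_col,
    )
    row = table.loc[table["Source"] == group_col].iloc[0]
    subj = session_means.groupby([subject_col, group_col], as_index=False)[dv].mean()
    tk = pairwise_tukeyhsd(subj[dv], subj[group_col])
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return AnovaResult(
        f_group=float(row["F"]), p_group=float(row["p_unc"]), table=table, tukey=tukey
    )
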