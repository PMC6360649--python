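"""Cross-contamination estimation by robust linear mixture deconvolution.

A contaminated sample's FREQ vector y is modeled as a proportion-weighted
sum of pure cell-line FREQ vectors,

    y ~ q1 x1 + q2 x2 + e,        q1 + q2 <= 1,

with no intercept (all vectors share the percent scale).  The dominant line
x1 is taken from identification (or supplied), the regression runs on the
sites most discriminative between y and the current mixture (top
``n_per_direction`` positive and negative FREQ differences, 400 sites by
default), and candidate contaminants are screened one at a time with
iteratively reweighted least squares using Tukey's bisquare (c = 4.685).
Components are added greedily by contaminant t-statistic until the best new
proportion is non-positive, regression fails, the component cap is reached,
or the proportions saturate (sum ~ 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from . import null_model
from .identification import identify, join_query
from .null_model import TruncatedNormalNull
from .panel_io import Panel, Profile

log = logging.getLogger(__name__)

TERMINATION_REASONS = (
    "negative_q",
    "regression_failed",
    "max_components",
    "proportions_saturated",
)


@dataclass(frozen=True)
class MixtureComponent:
    cell_id: str
    q: float
    t_stat: float
    se: float


@dataclass
class MixtureEstimate:
    """Ordered mixture components (dominant first) with fit diagnostics."""

    query_id: str
    components: list[MixtureComponent]
    n_sites_used: int
    converged: bool
    termination_reason: str
    sum_violation: bool = False

    @property
    def proportions(self) -> dict[str, float]:
        return {c.cell_id: c.q for c in self.components}

    def summary(self) -> str:
        lines = [f"query {self.query_id}: {len(self.components)} component(s), "
                 f"terminated: {self.termination_reason}"]
        for k, c in enumerate(self.components):
            role = "dominant" if k == 0 else "contaminant"
            lines.append(
                f"  {role} {c.cell_id}: proportion q{k + 1} = {100 * c.q:.1f}%, "
                f"t-stat = {c.t_stat:.1f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class MixtureFit:
    q: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    converged: bool
    exact: bool  # zero-residual design, solved directly

    @property
    def sum_q(self) -> float:
        return float(self.q.sum())


def select_discriminative_sites(
    y: np.ndarray, x1: np.ndarray, n_per_direction: int = 200
) -> np.ndarray:
    """Sites with the largest positive and most negative (y - x1) differences.

    Takes ``n_per_direction`` sites from each direction (ties broken by site
    order; the negative direction draws from sites not already taken, so an
    all-tied difference vector degenerates to the first 2n sites in order).
    Returns sorted site indices; takes all sites, with a warning, when fewer
    than 2n are available.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    if y.size == 0:
        raise ValueError("zero common sites")
    diff = y - x1
    n = n_per_direction
    if y.size <= 2 * n:
        log.warning("only %d sites available for %d requested", y.size, 2 * n)
        return np.arange(y.size)
    pos = np.argsort(-diff, kind="stable")[:n]
    taken = np.zeros(y.size, dtype=bool)
    taken[pos] = True
    rest = np.flatnonzero(~taken)
    neg = rest[np.argsort(diff[rest], kind="stable")[:n]]
    if np.all(diff == diff[0]):
        log.warning("degenerate difference vector (all ties); taking first %d sites", 2 * n)
    return np.sort(np.concatenate([pos, neg]))


def robust_mixture_fit(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
    sum_tol: float = 0.02,
    nonneg: bool = False,
) -> MixtureFit:
    """No-intercept robust regression of y on the candidate FREQ columns.

    IRLS with Tukey bisquare weights (c = 4.685), at most ``max_iter``
    iterations, coefficient-change tolerance ``tol``.  An exactly collinear
    design raises; a zero-residual system is solved directly (IRLS weights
    are undefined at scale 0) and reported with se = 0.  A q1 + q2 > 1 +
    ``sum_tol`` violation is flagged by the caller, never constrained; pass
    ``nonneg`` for a non-negative least squares fallback on the coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, k = X.shape
    if n <= k + 5:
        raise ValueError(f"need more than {k + 5} sites for {k} components, got {n}")
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("singular design: collinear candidate columns")

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.max(np.abs(resid)) < 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        inf_t = np.where(coef != 0, np.inf * np.sign(coef), 0.0)
        return MixtureFit(coef, np.zeros(k), inf_t, converged=True, exact=True)

    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    try:
        fit = model.fit(maxiter=max_iter, tol=tol, conv="coefs")
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise np.linalg.LinAlgError(f"robust regression failed: {exc}") from exc
    q = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float)
    if not np.all(np.isfinite(q)):
        raise np.linalg.LinAlgError("robust regression produced non-finite coefficients")
    if nonneg:
        from scipy.optimize import nnls

        q, _ = nnls(X, y)
        q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, q / se, np.inf * np.sign(q))
    return MixtureFit(q, se, t, converged=bool(getattr(fit, "converged", True)), exact=False)


def find_contaminants(
    query: Profile,
    panel: Panel,
    null: TruncatedNormalNull | None = None,
    dominant: str | None = None,
    max_components: int = 4,
    n_per_direction: int = 200,
    dp_min: float = 10,
    q_tol: float = 1e-6,
    sum_tol: float = 0.02,
    saturation: float = 0.99,
    t_min: float = 3.0,
    reselect_sites: bool = True,
) -> MixtureEstimate:
    """Greedy mixture deconvolution of a query against the panel.

    The dominant line is the top identification hit unless supplied.  Each
    round screens every remaining panel cell as the next regression column,
    fitting on the sites where that candidate's FREQ differs most from the
    current fitted mixture (the candidate contrast; ``reselect_sites``
    False keeps the contrast against the dominant alone).  Selecting sites
    on the candidate contrast rather than on the query's own residual keeps
    the selection independent of the query's noise, which would otherwise
    bias the proportions upward (extreme noise realizations get selected
    and then attributed to the candidate).  The candidate with the largest
    contaminant t-statistic among fits with q > q_tol, t >= t_min and
    sum(q) <= 1 + sum_tol is accepted.  The search ends when no candidate
    qualifies: reported as saturated proportions if the accepted components
    already account for (almost) everything, as a regression failure if
    every fit errored, and as a non-positive q otherwise.
    """
    if panel.n_cells < 2:
        raise ValueError("panel must contain at least 2 cells")
    if dominant is None:
        if null is None:
            raise ValueError("need a fitted null to identify the dominant line")
        dominant = identify(query, panel, null).best().cell_id

    sites, p_freq, p_dp, q_freq, q_dp = join_query(panel, query)
    d_idx = panel.cell_index(dominant)
    qualified = np.flatnonzero((q_dp >= dp_min) & (p_dp[d_idx] >= dp_min))
    if qualified.size == 0:
        raise ValueError("no depth-qualified sites shared with the dominant line")
    y = q_freq[qualified]
    cell_cols = {cid: p_freq[panel.cell_index(cid)][qualified] for cid in panel.cell_ids}

    members = [dominant]
    X = cell_cols[dominant][:, None]

    # baseline dominant-only fit on its own discriminative sites
    sel = select_discriminative_sites(y, cell_cols[dominant], n_per_direction)
    base = robust_mixture_fit(y[sel], X[sel], sum_tol=sum_tol)
    components = [MixtureComponent(dominant, float(base.q[0]), float(base.t_stats[0]),
                                   float(base.se[0]))]
    n_sites_used = int(sel.size)
    reason = "max_components"
    converged = True

    while len(members) < max_components:
        current_q = np.array([c.q for c in components])
        target = X @ current_q if (reselect_sites and len(members) > 1) else cell_cols[dominant]
        best = None
        best_q_seen = -np.inf
        n_failed = n_tested = 0
        for cid in panel.cell_ids:
            if cid in members:
                continue
            n_tested += 1
            sel = select_discriminative_sites(cell_cols[cid], target, n_per_direction)
            Xc = np.column_stack([X, cell_cols[cid]])
            try:
                fit = robust_mixture_fit(y[sel], Xc[sel], sum_tol=sum_tol)
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            q_new, t_new = float(fit.q[-1]), float(fit.t_stats[-1])
            best_q_seen = max(best_q_seen, q_new)
            if q_new <= q_tol or t_new < t_min or fit.sum_q > 1.0 + sum_tol:
                continue
            if best is None or t_new > best[1]:
                best = (cid, t_new, fit, sel)
        if n_tested == 0:
            reason = "max_components"
            break
        if best is None:
            if n_failed == n_tested:
                reason = "regression_failed"
                converged = False
            elif best_q_seen <= q_tol:
                reason = "negative_q"
            elif sum(c.q for c in components) >= saturation:
                reason = "proportions_saturated"
            else:
                reason = "negative_q"
            break
        cid, _, fit, sel = best
        members.append(cid)
        X = np.column_stack([X, cell_cols[cid]])
        components = [
            MixtureComponent(m, float(qk), float(tk), float(sk))
            for m, qk, tk, sk in zip(members, fit.q, fit.t_stats, fit.se)
        ]
        n_sites_used = int(sel.size)
        if len(members) >= max_components:
            reason = "max_components"
            break

    est = MixtureEstimate(
        query.cell_id,
        components,
        n_sites_used,
        converged,
        reason,
        sum_violation=sum(c.q for c in components) > 1.0 + sum_tol,
    )
    return est


def write_mixture_report(est: MixtureEstimate, tsv_path=None) -> str:
    """TSV report (component, q, se, t_stat) plus the human summary."""
    lines = ["component\tcell_id\tq\tse\tt_stat"]
    for k, c in enumerate(est.components):
        lines.append(f"{k + 1}\t{c.cell_id}\t{c.q:.6f}\t{c.se:.6g}\t{c.t_stat:.6g}")
    text = "\n".join(lines) + "\n"
    if tsv_path:
        with open(tsv_path, "w") as fh:
            fh.write(text)
    return text
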