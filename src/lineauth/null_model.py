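"""Truncated-normal null model for pairwise correlation coefficients.

Pairwise Pearson correlations between *unrelated* cell lines concentrate
well below 1, and after discarding values below ``a`` (negative
correlations, implausible for shared germline variation) and above ``b``
(replicates/derivatives of the same line), their distribution is modeled as
a normal density renormalized on (a, b):

    f(x; mu, sigma, a, b) = phi((x - mu)/sigma) / sigma
                            / (Phi((b - mu)/sigma) - Phi((a - mu)/sigma))

with phi/Phi the standard normal pdf/cdf.  A query-vs-panel correlation rho
is converted to p = P(rho_null >= rho) = 1 - F(rho), and fixed cut-offs on p
classify the pair as unrelated / possibly related / same cell origin.

Above the truncation bound the truncated CDF carries no tail mass, so for
rho >= b the survival function of the *untruncated* normal is used instead;
to keep p monotone non-increasing across the bound, the truncated tail is
floored at that bound value (the floor only matters many sigmas into the
tail, far beyond any decision threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "TruncatedNormalNull",
    "truncnorm_pdf",
    "truncnorm_cdf",
    "fit_null",
    "p_value",
    "threshold",
    "classify",
    "save_null",
    "load_null",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = ("unrelated", "possibly_related", "same_origin")


@dataclass(frozen=True)
class TruncatedNormalNull:
    """Fitted null distribution of unrelated-pair correlations."""

    mu: float
    sigma: float
    a: float = 0.0
    b: float = 0.8
    n_used: int | None = None
    loglik: float | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not self.a < self.b:
            raise ValueError(f"need a < b, got ({self.a}, {self.b})")

    def _z(self, x):
        return (np.asarray(x, dtype=float) - self.mu) / self.sigma

    @property
    def _mass(self) -> float:
        # probability mass of the untruncated normal inside (a, b)
        za, zb = (self.a - self.mu) / self.sigma, (self.b - self.mu) / self.sigma
        return float(norm.cdf(zb) - norm.cdf(za))

    @property
    def _tail_floor(self) -> float:
        # untruncated upper-tail mass at b; see module docstring
        return float(norm.sf((self.b - self.mu) / self.sigma))


def truncnorm_pdf(x, null: TruncatedNormalNull):
    """Density of the truncated normal; 0 outside (a, b)."""
    x = np.asarray(x, dtype=float)
    inside = (x > null.a) & (x < null.b)
    pdf = norm.pdf(null._z(x)) / null.sigma / null._mass
    out = np.where(inside, pdf, 0.0)
    return float(out) if out.ndim == 0 else out


def truncnorm_cdf(x, null: TruncatedNormalNull):
    """CDF of the truncated normal; 0 below a, 1 above b."""
    x = np.asarray(x, dtype=float)
    za = (null.a - null.mu) / null.sigma
    out = np.clip((norm.cdf(null._z(x)) - norm.cdf(za)) / null._mass, 0.0, 1.0)
    out = np.where(x <= null.a, 0.0, np.where(x >= null.b, 1.0, out))
    return float(out) if out.ndim == 0 else out


def p_value(rho, null: TruncatedNormalNull):
    """Upper-tail probability P(rho_null >= rho), monotone in rho.

    Inside (a, b) this is 1 - F with F the truncated CDF (floored at the
    untruncated tail mass at b); at or below a it is 1; at or above b it is
    the untruncated normal survival function.
    """
    rho = np.asarray(rho, dtype=float)
    trunc_tail = np.maximum(1.0 - truncnorm_cdf(rho, null), null._tail_floor)
    ext_tail = norm.sf(null._z(rho))
    out = np.where(rho <= null.a, 1.0, np.where(rho >= null.b, ext_tail, trunc_tail))
    return float(out) if out.ndim == 0 else out


def threshold(p: float, null: TruncatedNormalNull) -> float:
    """Correlation L with p_value(L) == p (inverse of the tail probability).

    For p above the extension floor this inverts the truncated CDF in closed
    form; smaller p fall in the untruncated extension beyond b.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if p > null._tail_floor:
        za = (null.a - null.mu) / null.sigma
        zb = (null.b - null.mu) / null.sigma
        target = norm.cdf(zb) - p * null._mass
        return float(null.mu + null.sigma * norm.ppf(target))
    return float(null.mu + null.sigma * norm.isf(p))


def fit_null(
    correlations,
    a: float = 0.0,
    b: float = 0.8,
    min_retained: int = 50,
) -> TruncatedNormalNull:
    """Maximum-likelihood fit of (mu, sigma) on correlations retained in [a, b].

    Values below a or above b are discarded before fitting (the latter are
    presumed replicates/derivatives, not the unrelated background).  The
    optimizer is Nelder-Mead from a moment start (mean/SD of the retained
    sample), converged to 1e-8 on the log-likelihood.
    """
    x = np.asarray(correlations, dtype=float)
    x = x[np.isfinite(x)]
    retained = x[(x >= a) & (x <= b)]
    if retained.size < min_retained:
        raise ValueError(
            f"only {retained.size} correlations retained in [{a}, {b}]; "
            f"need >= {min_retained}"
        )

    def nll(theta: np.ndarray) -> float:
        mu, sigma = theta
        if sigma <= 0:
            return np.inf
        z = (retained - mu) / sigma
        za, zb = (a - mu) / sigma, (b - mu) / sigma
        mass = norm.cdf(zb) - norm.cdf(za)
        if mass <= 0:
            return np.inf
        return float(
            retained.size * (np.log(sigma) + np.log(mass)) + 0.5 * np.sum(z**2)
        )

    start = np.array([retained.mean(), max(retained.std(ddof=1), 1e-6)])
    res = optimize.minimize(
        nll,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-8, "maxiter": 2000},
    )
    if not res.success:
        raise RuntimeError(f"truncated-normal MLE did not converge: {res.message}")
    mu_hat, sigma_hat = map(float, res.x)
    return TruncatedNormalNull(
        mu_hat, sigma_hat, a, b, n_used=int(retained.size), loglik=float(-res.fun)
    )


def classify(
    rho: float,
    null: TruncatedNormalNull,
    alpha_related: float = 1e-3,
    alpha_same: float = 1e-4,
) -> str:
    """Call a correlation: same_origin (p < alpha_same), possibly_related
    (p < alpha_related), else unrelated.  Undefined rho is unrelated."""
    if not alpha_same < alpha_related:
        raise ValueError("alpha_same must be < alpha_related")
    if not np.isfinite(rho):
        return "unrelated"
    p = p_value(rho, null)
    if p < alpha_same:
        return "same_origin"
    if p < alpha_related:
        return "possibly_related"
    return "unrelated"


def save_null(null: TruncatedNormalNull, path: str | Path) -> None:
    rec = {
        "mu": null.mu,
        "sigma": null.sigma,
        "a": null.a,
        "b": null.b,
        "n_used": null.n_used,
        "loglik": null.loglik,
    }
    Path(path).write_text(json.dumps(rec, indent=1))


def load_null(path: str | Path) -> TruncatedNormalNull:
    rec = json.loads(Path(path).read_text())
    return TruncatedNormalNull(**rec)
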