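"""REML variance components, GBLUP prediction and parental fixed effects.

Three models operate on adjusted hybrid means:

* a per-family intercept + additive model ``y = 1 mu + A + E`` with
  ``A ~ N(0, K sigma2_A)`` fitted by REML, giving each family's mean and
  additive variance;
* a GBLUP model calibrated on a training set whose kinship is built over
  the union of training and validation individuals, predicting the
  genetic values of unobserved individuals;
* an additive two-way fixed-effects model ``y = mu + donor + recipient``
  fitted by OLS under sum-to-zero constraints, predicting cross means
  from parental effects alone.

The REML fit reduces the two-component model to a one-dimensional
optimisation over the variance ratio via the spectral decomposition of
the kinship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "VarianceComponents",
    "BLUPResult",
    "ParentalEffects",
    "reml_loglik",
    "fit_family_gblup",
    "gblup_predict",
    "fit_parental_fixed_effects",
]

#: variances below this floor are reported as exactly zero
_VAR_FLOOR = 1e-10
#: convergence tolerance on the log variance ratio
_RATIO_TOL = 1e-8


@dataclass
class VarianceComponents:
    """REML estimates of an intercept + additive-variance model."""

    mu: float
    sigma2_A: float
    sigma2_E: float
    loglik_reml: float

    def __post_init__(self):
        if self.sigma2_A < 0 or self.sigma2_E < 0:
            raise ValueError("variance components must be nonnegative")


@dataclass
class BLUPResult:
    """GBLUP predictions over a training + validation subset."""

    predicted_genetic_values: pd.Series  # indexed by individual, all n
    fitted_mu: float
    varcomp: VarianceComponents

    def predicted_phenotypes(self) -> pd.Series:
        return self.fitted_mu + self.predicted_genetic_values


def reml_loglik(y: np.ndarray, k: np.ndarray, sigma2_a: float, sigma2_e: float) -> float:
    """Restricted log-likelihood of ``y = 1 mu + A + E`` at given variances.

    Direct dense evaluation,
    ``-1/2 [log|V| + log|X'V^-1 X| + y'Py]`` plus the constant, with
    ``V = sigma2_a K + sigma2_e I`` and ``X = 1``.  Used for reporting
    and as an independent check of the profiled optimiser.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    v = sigma2_a * np.asarray(k) + sigma2_e * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vinv = np.linalg.inv(v)
    x = np.ones((n, 1))
    xtvx = float((x.T @ vinv @ x).item())
    mu = float((x.T @ vinv @ y).item()) / xtvx
    r = y - mu
    quad = float(r @ vinv @ r)
    return -0.5 * (
        (n - 1) * np.log(2.0 * np.pi) + logdet_v + np.log(xtvx) + quad
    )


def _profiled_reml(y_t, x_t, eigvals, lam):
    """Profiled restricted loglik at variance ratio lam = s2A/s2E.

    Operates in the eigenbasis of K; returns (loglik, mu, s2A, s2E).
    """
    n = y_t.shape[0]
    d = lam * eigvals + 1.0
    w = 1.0 / d
    xtvx = float(np.sum(x_t * x_t * w))
    mu = float(np.sum(x_t * y_t * w)) / xtvx
    r = y_t - mu * x_t
    rss = float(np.sum(r * r * w))
    s2e = rss / (n - 1)
    if s2e <= 0:
        return -np.inf, mu, 0.0, 0.0
    # log|V| + log|X'V^-1X| jointly carry (n-1) log s2e once V = s2e (lam K + I)
    ll = -0.5 * (
        (n - 1) * np.log(2.0 * np.pi * s2e)
        + np.sum(np.log(d))
        + np.log(xtvx)
        + (n - 1)
    )
    return ll, mu, lam * s2e, s2e


def fit_family_gblup(
    y: np.ndarray, k: np.ndarray, max_log_ratio: float = 12.0
) -> VarianceComponents:
    """REML fit of ``y = 1 mu + A + E``, ``A ~ N(0, K sigma2_A)``.

    The kinship matrix is spectrally decomposed once; the restricted
    likelihood is then profiled down to the single variance ratio
    ``sigma2_A / sigma2_E``, maximised by bounded scalar search over its
    logarithm (grid bracketing + Brent).  Variances are constrained
    nonnegative; estimates under the floor are reported as zero.
    """
    y = np.asarray(y, dtype=float)
    k = np.asarray(k, dtype=float)
    n = y.shape[0]
    if k.shape != (n, n):
        raise ValueError("kinship matrix does not match phenotype length")
    if n < 3:
        raise ValueError("need at least 3 individuals for a REML fit")

    if np.ptp(y) == 0.0:
        return VarianceComponents(float(y[0]), 0.0, 0.0, np.inf)

    eigvals, u = np.linalg.eigh(k)
    eigvals = np.clip(eigvals, 0.0, None)  # singular K handled spectrally
    y_t = u.T @ y
    x_t = u.T @ np.ones(n)

    grid = np.concatenate(([-np.inf], np.linspace(-max_log_ratio, max_log_ratio, 49)))
    lls = np.array(
        [_profiled_reml(y_t, x_t, eigvals, np.exp(g) if np.isfinite(g) else 0.0)[0] for g in grid]
    )
    if not np.any(np.isfinite(lls)):
        raise RuntimeError("REML failed: restricted likelihood not finite on grid")
    best = int(np.argmax(lls))

    if best == 0:  # boundary: sigma2_A = 0
        log_ratio = -np.inf
    else:
        lo = grid[max(best - 1, 1)]
        hi = grid[min(best + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda g: -_profiled_reml(y_t, x_t, eigvals, np.exp(g))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _RATIO_TOL},
        )
        if not res.success:
            raise RuntimeError(
                f"REML optimisation did not converge: {res.message}; "
                f"bracket [{lo:.3g}, {hi:.3g}], grid loglik {lls[best]:.6g}"
            )
        log_ratio = res.x
        if -_profiled_reml(y_t, x_t, eigvals, 0.0)[0] < res.fun:
            log_ratio = -np.inf

    lam = 0.0 if log_ratio == -np.inf else float(np.exp(log_ratio))
    ll, mu, s2a, s2e = _profiled_reml(y_t, x_t, eigvals, lam)
    if s2a < _VAR_FLOOR:
        s2a = 0.0
    if s2e < _VAR_FLOOR:
        s2e = 0.0
    return VarianceComponents(mu=mu, sigma2_A=s2a, sigma2_E=s2e, loglik_reml=ll)


def gblup_predict(
    y_ts: pd.Series, k: np.ndarray, ids: pd.Index | list
) -> BLUPResult:
    """GBLUP prediction of every individual in a kinship subset.

    Parameters
    ----------
    y_ts
        Phenotypes of the training individuals, indexed by individual id.
    k
        Kinship over the full subset (training + validation), built on
        that subset's genotype frequencies.
    ids
        Individual ids labelling the rows of ``k``; must contain every
        training id.

    Variance components are estimated on the training block by REML;
    genetic values for all ``n`` individuals follow by the standard BLUP
    back-solution ``A_hat = s2A K[:, TS] V_TS^-1 (y - mu_hat)``.
    """
    ids = pd.Index(ids)
    missing = y_ts.index.difference(ids)
    if len(missing) > 0:
        raise KeyError(f"training individuals absent from kinship subset: {list(missing)[:5]}")
    ts_pos = ids.get_indexer(y_ts.index)
    k = np.asarray(k, dtype=float)
    k_tt = k[np.ix_(ts_pos, ts_pos)]
    y = y_ts.to_numpy(dtype=float)

    vc = fit_family_gblup(y, k_tt)
    if vc.sigma2_A == 0.0:
        a_hat = np.zeros(len(ids))
        return BLUPResult(
            predicted_genetic_values=pd.Series(a_hat, index=ids),
            fitted_mu=vc.mu,
            varcomp=vc,
        )
    v_ts = vc.sigma2_A * k_tt + vc.sigma2_E * np.eye(len(y))
    vinv = np.linalg.pinv(v_ts)
    ones = np.ones(len(y))
    mu = float(ones @ vinv @ y) / float(ones @ vinv @ ones)
    a_hat = vc.sigma2_A * k[:, ts_pos] @ (vinv @ (y - mu))
    vc = VarianceComponents(mu, vc.sigma2_A, vc.sigma2_E, vc.loglik_reml)
    return BLUPResult(
        predicted_genetic_values=pd.Series(a_hat, index=ids),
        fitted_mu=mu,
        varcomp=vc,
    )


@dataclass
class ParentalEffects:
    """Additive donor + recipient OLS decomposition of hybrid means.

    Effects satisfy sum-to-zero constraints within each factor; the
    predicted mean of a cross, ``mu + donor effect + recipient effect``,
    is invariant to the choice of constraint.
    """

    intercept: float
    donor_effects: pd.Series
    recipient_effects: pd.Series
    constraint: str = "sum-to-zero"

    def predict(self, donor_id: str, recipient_id: str) -> float:
        return (
            self.intercept
            + float(self.donor_effects.get(donor_id, 0.0))
            + float(self.recipient_effects.get(recipient_id, 0.0))
        )


def _check_connected(donors: pd.Series, recipients: pd.Series) -> None:
    """The donor/recipient bipartite graph must be connected, else some
    parental contrasts are aliased."""
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    nodes = [("D", d) for d in donors.unique()] + [("R", r) for r in recipients.unique()]
    for node in nodes:
        parent[node] = node
    for d, r in zip(donors, recipients):
        a, b = find(("D", d)), find(("R", r))
        if a != b:
            parent[a] = b
    roots = {find(node) for node in nodes}
    if len(roots) > 1:
        groups = {}
        for node in nodes:
            groups.setdefault(find(node), []).append(node[1])
        raise ValueError(
            "disconnected crossing design: parental effects are aliased "
            f"between groups {sorted(map(sorted, groups.values()))}"
        )


def fit_parental_fixed_effects(
    y: np.ndarray, donor_labels, recipient_labels
) -> ParentalEffects:
    """OLS fit of ``y = mu + donor + recipient`` with sum-to-zero effects.

    Every hybrid must be labelled with its donor and recipient; the
    design must be connected (a disconnected design leaves parental
    contrasts unidentifiable and raises, naming the aliased groups).
    """
    y = np.asarray(y, dtype=float)
    donors = pd.Series(donor_labels).astype(str)
    recipients = pd.Series(recipient_labels).astype(str)
    if not (len(y) == len(donors) == len(recipients)):
        raise ValueError("y, donor and recipient labels must have equal length")
    _check_connected(donors, recipients)

    d_levels = sorted(donors.unique())
    r_levels = sorted(recipients.unique())

    def _sum_coding(labels, levels):
        # sum-to-zero contrasts: last level = -(sum of others)
        z = np.zeros((len(labels), max(len(levels) - 1, 0)))
        for i, lab in enumerate(labels):
            j = levels.index(lab)
            if j < len(levels) - 1:
                z[i, j] = 1.0
            else:
                z[i, :] = -1.0
        return z

    design = np.column_stack(
        [np.ones(len(y)), _sum_coding(donors, d_levels), _sum_coding(recipients, r_levels)]
    )
    coefs, *_ = np.linalg.lstsq(design, y, rcond=None)
    mu = float(coefs[0])
    nd = len(d_levels) - 1
    d_eff = list(coefs[1 : 1 + nd]) + [-float(np.sum(coefs[1 : 1 + nd]))]
    r_coef = coefs[1 + nd :]
    r_eff = list(r_coef) + [-float(np.sum(r_coef))]
    if len(d_levels) == 1:
        d_eff = [0.0]
    if len(r_levels) == 1:
        r_eff = [0.0]
    return ParentalEffects(
        intercept=mu,
        donor_effects=pd.Series(d_eff, index=d_levels, dtype=float),
        recipient_effects=pd.Series(r_eff, index=r_levels, dtype=float),
    )
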