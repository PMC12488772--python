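"""Training-set construction, cross-validation and evaluation metrics.

The experiment layer answers the study's design questions: how well does
a genomic model calibrated on relatives of varying proximity predict (i)
the individuals of a target family and (ii) the mean, variance and
usefulness criterion of an unobserved cross?

Training-set compositions relative to a target family:

* ``F``    - the target family itself (its non-validation third);
* ``OFO``  - one-family-out: all individuals of every other family;
* ``R``    - families sharing the target's recipient (target excluded);
* ``D``    - families sharing the target's donor;
* ``RD``   - union of R and D;
* ``Disc`` - families sharing neither parent.

Any non-F composition can additionally be augmented with the target
family's non-validation third (``with_family_fraction``).

Within-family cross-validation holds out a random two-thirds of a family
as validation set and calibrates on the remaining third; the same
validation draws are reused across training-set types so predictive
abilities are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import kinship_noia
from .mixedmodel import gblup_predict

__all__ = [
    "TS_TYPES",
    "TrainingSetSpec",
    "build_training_set",
    "cv_partitions",
    "predictive_ability",
    "nrmse",
    "within_family_cv",
    "evaluate_ts_types",
    "uc_decomposition",
    "yield_index",
    "evaluate_cross_predictions",
]

TS_TYPES = ("F", "OFO", "R", "D", "RD", "Disc")


@dataclass
class TrainingSetSpec:
    """A resolved training set for one target family."""

    ts_type: str
    target_family: str
    with_family_fraction: bool
    member_ids: list[str]
    families: list[str] = field(default_factory=list)


def _related_families(design: pd.DataFrame, target_family: str, ts_type: str) -> list[str]:
    row = design.loc[design["family_id"] == target_family]
    if row.empty:
        raise KeyError(f"unknown target family: {target_family}")
    rec = row["recipient_id"].iloc[0]
    don = row["donor_id"].iloc[0]
    others = design[design["family_id"] != target_family]
    same_r = others["recipient_id"] == rec
    same_d = others["donor_id"] == don
    if ts_type == "OFO":
        keep = others
    elif ts_type == "R":
        keep = others[same_r]
    elif ts_type == "D":
        keep = others[same_d]
    elif ts_type == "RD":
        keep = others[same_r | same_d]
    elif ts_type == "Disc":
        keep = others[~(same_r | same_d)]
    else:
        raise ValueError(f"unknown TS type: {ts_type!r}")
    return list(keep["family_id"])


def build_training_set(
    design: pd.DataFrame,
    family_of: pd.Series,
    target_family: str,
    ts_type: str,
    vs_ids,
    with_family_fraction: bool = False,
) -> TrainingSetSpec:
    """Resolve a training-set composition into individual ids.

    ``family_of`` maps each individual id to its family.  ``vs_ids`` are
    the validation individuals (always excluded).  ``F`` resolves to the
    target family minus the validation set; other types resolve to the
    members of the families their definition selects, optionally plus
    the target family's non-validation fraction.
    """
    vs = set(vs_ids)
    target_members = [i for i in family_of.index[family_of == target_family]]
    if ts_type == "F":
        members = [i for i in target_members if i not in vs]
        fams = [target_family]
    else:
        fams = _related_families(design, target_family, ts_type)
        members = [i for i in family_of.index[family_of.isin(fams)]]
        if with_family_fraction:
            members += [i for i in target_members if i not in vs]
            fams = fams + [target_family]
    members = [i for i in members if i not in vs]
    if not members:
        raise ValueError(
            f"empty training set: type {ts_type!r} for family {target_family!r} "
            "resolves to no individuals"
        )
    return TrainingSetSpec(
        ts_type=ts_type,
        target_family=target_family,
        with_family_fraction=bool(with_family_fraction and ts_type != "F"),
        member_ids=members,
        families=fams,
    )


def cv_partitions(ids, n_reps: int, vs_fraction: float = 2.0 / 3.0, seed=None):
    """Draw repeated validation subsets of a family.

    Yields ``n_reps`` lists of validation ids, each a uniform random
    sample of ``round(vs_fraction * n)`` individuals without
    stratification.  Drawing them once and reusing them across
    training-set types keeps comparisons paired.
    """
    rng = np.random.default_rng(seed)
    ids = list(ids)
    n_vs = int(round(vs_fraction * len(ids)))
    n_vs = min(max(n_vs, 1), len(ids) - 1)
    return [list(rng.choice(ids, size=n_vs, replace=False)) for _ in range(n_reps)]


def predictive_ability(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("constant input vector: correlation undefined")
    return float(np.corrcoef(obs, pred)[0, 1])


def nrmse(predicted, observed) -> float:
    """Root-mean-square error normalised by the observed range."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    rng_obs = np.ptp(obs)
    if rng_obs == 0:
        raise ValueError("observed values all equal: NRMSE undefined")
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / rng_obs)


def _gblup_pa(
    y: pd.Series, dosages: pd.DataFrame, ts_ids: list, vs_ids: list
) -> float | None:
    """Calibrate GBLUP on ts_ids, return PA on vs_ids (None if degenerate)."""
    subset = list(ts_ids) + [i for i in vs_ids if i not in set(ts_ids)]
    dos = dosages.loc[subset].to_numpy()
    try:
        kin = kinship_noia(dos)
    except ValueError:
        return None
    blup = gblup_predict(y.loc[ts_ids], kin.k, pd.Index(subset))
    pred = blup.predicted_phenotypes().loc[vs_ids]
    obs = y.loc[vs_ids]
    try:
        return predictive_ability(obs.to_numpy(), pred.to_numpy())
    except ValueError:
        return None


def within_family_cv(
    y: pd.Series,
    dosages: pd.DataFrame,
    n_reps: int = 100,
    vs_fraction: float = 2.0 / 3.0,
    seed=None,
) -> pd.DataFrame:
    """Within-family cross-validated predictive ability (composition F).

    Per repetition a random two-thirds of the family forms the
    validation set; the model is calibrated on the remaining third with
    kinship over the whole family.  Returns one row per repetition with
    the PA (NaN when a repetition is degenerate, e.g. constant observed
    values); callers average over the non-missing rows.
    """
    ids = list(y.index)
    if len(ids) < 3:
        raise ValueError("family too small for cross-validation")
    parts = cv_partitions(ids, n_reps, vs_fraction, seed)
    rows = []
    for rep, vs in enumerate(parts):
        ts = [i for i in ids if i not in set(vs)]
        pa = _gblup_pa(y, dosages, ts, vs)
        rows.append({"repetition": rep, "ts_type": "F", "pa": np.nan if pa is None else pa})
    return pd.DataFrame(rows)


def evaluate_ts_types(
    design: pd.DataFrame,
    family_of: pd.Series,
    y: pd.Series,
    dosages: pd.DataFrame,
    target_family: str,
    ts_types=TS_TYPES,
    n_reps: int = 100,
    vs_fraction: float = 2.0 / 3.0,
    with_family_fraction: bool = False,
    seed=None,
) -> pd.DataFrame:
    """Predictive ability of several TS compositions for one target family.

    The validation draws are shared across compositions within each
    repetition.  Returns a long table (repetition, ts_type, pa); a
    composition that resolves to an empty set raises.
    """
    fam_ids = [i for i in family_of.index[family_of == target_family]]
    parts = cv_partitions(fam_ids, n_reps, vs_fraction, seed)
    rows = []
    for rep, vs in enumerate(parts):
        for ts_type in ts_types:
            spec = build_training_set(
                design, family_of, target_family, ts_type, vs, with_family_fraction
            )
            ts = [i for i in spec.member_ids if i in y.index]
            pa = _gblup_pa(y, dosages, ts, vs)
            rows.append(
                {
                    "repetition": rep,
                    "ts_type": ts_type,
                    "pa": np.nan if pa is None else pa,
                }
            )
    return pd.DataFrame(rows)


def uc_decomposition(mu_per_cross, sigma2_per_cross, intensity: float = 2.07) -> float:
    """Fraction of UC variation across crosses attributable to the mean.

    With ``UC = mu + i sigma2`` per cross, the share of the mean is read
    as the covariance decomposition ``cov(mu, UC) / var(UC)`` (the
    variance term's share is the complement).  This is one concrete
    reading of "contribution to the variation"; it is symmetric in the
    two components and sums to one.
    """
    mu = np.asarray(mu_per_cross, dtype=float)
    s2 = np.asarray(sigma2_per_cross, dtype=float)
    if mu.size < 3 or mu.shape != s2.shape:
        raise ValueError("need >= 3 paired crosses")
    uc = mu + intensity * s2
    var_uc = np.var(uc)
    if var_uc == 0:
        raise ValueError("UC constant across crosses: decomposition undefined")
    return float(np.cov(mu, uc, ddof=0)[0, 1] / var_uc)


def yield_index(gy, h2o, h2o_reference) -> float | np.ndarray:
    """Commercial grain-yield index ``YI = GY + 2.5 (H2O_ref - H2O)``.

    GY and YI in 0.1 t/ha, humidities in %; the reference humidity is
    the trial mean of the reference hybrid.
    """
    return np.asarray(gy, dtype=float) + 2.5 * (
        np.asarray(h2o_reference, dtype=float) - np.asarray(h2o, dtype=float)
    )


def evaluate_cross_predictions(
    observed: pd.DataFrame, predicted: pd.DataFrame, intensity: float = 2.07
) -> pd.DataFrame:
    """Compare predicted cross parameters with family-model estimates.

    ``observed`` must carry columns (family_id, mu, sigma2) from the
    per-family mixed-model fits; ``predicted`` columns (family_id,
    ts_type, mu, sigma2).  Returns per (ts_type, parameter in mu /
    sigma2 / uc): Pearson correlation, RMSE and NRMSE over the common
    crosses.
    """
    if observed["family_id"].duplicated().any():
        raise ValueError("one observed row per family expected")
    obs = observed.set_index("family_id")
    rows = []
    for ts_type, sub in predicted.groupby("ts_type", sort=False):
        sub = sub.set_index("family_id")
        common = obs.index.intersection(sub.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 crosses in common for TS type {ts_type!r}")
        o_mu = obs.loc[common, "mu"].to_numpy()
        p_mu = sub.loc[common, "mu"].to_numpy()
        o_s2 = obs.loc[common, "sigma2"].to_numpy()
        p_s2 = sub.loc[common, "sigma2"].to_numpy()
        for param, o, p in [
            ("mu", o_mu, p_mu),
            ("sigma2", o_s2, p_s2),
            ("uc", o_mu + intensity * o_s2, p_mu + intensity * p_s2),
        ]:
            rows.append(
                {
                    "ts_type": ts_type,
                    "parameter": param,
                    "correlation": predictive_ability(o, p),
                    "rmse": float(np.sqrt(np.mean((p - o) ** 2))),
                    "nrmse": nrmse(p, o),
                    "n_crosses": len(common),
                }
            )
    return pd.DataFrame(rows)
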