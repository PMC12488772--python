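"""Configuration and end-to-end pipeline driver.

``run_pipeline`` chains the full analysis on a synthetic bridging study:
simulate the design, fit the per-family mixed model, run within-family
cross-validation and the training-set-composition comparison, fit
Bayesian ridge models per composition, predict cross means, variances
and usefulness criteria, and rank additional donors per recipient with
the H criterion.  Every stage writes plain TSV artifacts plus a JSON
manifest carrying the config hash and all seeds, so any stage can be
re-run reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brr, crosspred, experiment, hcriterion, io, mixedmodel, simdata
from .genetics import kinship_noia

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("ucbridge")


@dataclass
class PipelineConfig:
    """Serialisable configuration of a full pipeline run."""

    # design / simulation
    n_chromosomes: int = 5
    chromosome_length: float = 1.6
    markers_per_chromosome: int = 60
    n_recipients: int = 7
    n_donors: int = 9
    n_families: int = 20
    family_size_min: int = 38
    family_size_max: int = 66
    traits: dict = field(
        default_factory=lambda: {"trait1": {"heritability": 0.5, "effect_sd": 0.1}}
    )
    hidden_qtl_fraction: float = 0.25
    # evaluation
    ts_types: tuple = ("F", "OFO", "R", "D", "RD", "Disc")
    n_cv_reps: int = 20
    vs_fraction: float = 2.0 / 3.0
    # MCMC
    run_mcmc: bool = True
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 5
    # UC
    selection_intensity: float = crosspred.SELECTION_INTENSITY_5PCT
    accuracy: float = 1.0
    uc_scale: str = "variance"
    # haplotype windows
    window_size: int = 100
    window_step: int = 20
    # seeds
    seed: int = 1

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["ts_types"] = list(self.ts_types)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "ts_types" in d:
            d["ts_types"] = tuple(d["ts_types"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _usable_ts_types(study, fam, ts_types):
    """Drop compositions that resolve to no individuals for this family
    (e.g. Disc in a densely connected design), logging the omission."""
    usable = []
    for t in ts_types:
        try:
            experiment.build_training_set(study.design, study.families, fam, t, vs_ids=[])
        except ValueError:
            logger.info("family %s: composition %s empty, skipped", fam, t)
            continue
        usable.append(t)
    return tuple(usable)


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run the full synthetic analysis and write all artifacts.

    Returns the output directory.  Stages fail loudly with their name;
    artifacts written before a failure are left in place.
    """
    out = io.ensure_dir(out_dir)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")
    rng = np.random.default_rng(config.seed)

    t0 = _stage("simulate")
    study = simdata.simulate_study(
        n_chromosomes=config.n_chromosomes,
        chromosome_length=config.chromosome_length,
        markers_per_chromosome=config.markers_per_chromosome,
        n_recipients=config.n_recipients,
        n_donors=config.n_donors,
        n_families=config.n_families,
        family_size_range=(config.family_size_min, config.family_size_max),
        traits=config.traits,
        hidden_qtl_fraction=config.hidden_qtl_fraction,
        seed=int(rng.integers(2**31)),
    )
    io.write_map(study.gmap, out / "map.tsv")
    io.write_genotypes(study.parents, out / "parents.tsv")
    io.write_genotypes(study.progeny, out / "progeny.tsv")
    io.write_phenotypes(study.phenotypes, out / "phenotypes.tsv")
    io.write_design(study.design, out / "design.tsv")
    manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 2)}

    t0 = _stage("family-model")
    m1_rows = []
    for trait in config.traits:
        y_all = study.trait_values(trait)
        for fam in study.design["family_id"]:
            members = study.family_members(fam)
            kin = kinship_noia(study.progeny.loc[members].to_numpy())
            vc = mixedmodel.fit_family_gblup(y_all.loc[members].to_numpy(), kin.k)
            m1_rows.append(
                {
                    "trait": trait,
                    "family_id": fam,
                    "mu": vc.mu,
                    "sigma2_A": vc.sigma2_A,
                    "sigma2_E": vc.sigma2_E,
                    "uc": crosspred.usefulness_criterion(
                        vc.mu,
                        vc.sigma2_A,
                        config.selection_intensity,
                        config.accuracy,
                        config.uc_scale,
                    ),
                }
            )
    m1 = pd.DataFrame(m1_rows)
    m1.to_csv(out / "family_estimates.tsv", sep="\t", index=False)
    manifest["stages"]["family-model"] = {"seconds": round(time.time() - t0, 2)}

    t0 = _stage("ts-evaluation")
    cv_seed = int(rng.integers(2**31))
    cv_rows = []
    for trait in config.traits:
        y_all = study.trait_values(trait)
        for fam in study.design["family_id"]:
            usable = _usable_ts_types(study, fam, config.ts_types)
            tbl = experiment.evaluate_ts_types(
                study.design,
                study.families,
                y_all,
                study.progeny,
                fam,
                ts_types=usable,
                n_reps=config.n_cv_reps,
                vs_fraction=config.vs_fraction,
                seed=cv_seed,
            )
            tbl["trait"] = trait
            tbl["family_id"] = fam
            cv_rows.append(tbl)
    cv = pd.concat(cv_rows, ignore_index=True)
    cv.to_csv(out / "predictive_ability.tsv", sep="\t", index=False)
    cv_mean = (
        cv.dropna(subset=["pa"])
        .groupby(["trait", "family_id", "ts_type"], as_index=False)["pa"]
        .mean()
    )
    cv_mean.to_csv(out / "predictive_ability_mean.tsv", sep="\t", index=False)
    manifest["stages"]["ts-evaluation"] = {
        "seconds": round(time.time() - t0, 2),
        "cv_seed": cv_seed,
        "n_dropped_pa": int(cv["pa"].isna().sum()),
    }

    if config.run_mcmc:
        t0 = _stage("brr-and-cross-prediction")
        mcmc_seed = int(rng.integers(2**31))
        pred_rows = []
        for trait in config.traits:
            y_all = study.trait_values(trait)
            for fam_row in study.design.itertuples(index=False):
                fam = fam_row.family_id
                x_r = study.parents.loc[fam_row.recipient_id].to_numpy()
                x_d = study.parents.loc[fam_row.donor_id].to_numpy()
                for ts_type in _usable_ts_types(study, fam, config.ts_types):
                    spec = experiment.build_training_set(
                        study.design, study.families, fam, ts_type, vs_ids=[]
                    )
                    ts_ids = spec.member_ids
                    post = brr.fit_brr(
                        y_all.loc[ts_ids].to_numpy(),
                        study.progeny.loc[ts_ids].to_numpy(dtype=float),
                        n_iter=config.n_iter,
                        burn_in=config.burn_in,
                        thin=config.thin,
                        seed=mcmc_seed,
                    )
                    cp = crosspred.predict_cross(
                        fam_row.recipient_id,
                        fam_row.donor_id,
                        x_r,
                        x_d,
                        study.gmap,
                        post,
                        intensity=config.selection_intensity,
                        accuracy=config.accuracy,
                        uc_scale=config.uc_scale,
                    )
                    pred_rows.append(
                        {
                            "trait": trait,
                            "family_id": fam,
                            "ts_type": ts_type,
                            "mu": cp.mu_hat,
                            "sigma2_vpm": cp.sigma2_vpm,
                            "sigma2_pmv": cp.sigma2_pmv,
                            "uc_vpm": cp.uc_vpm,
                            "uc_pmv": cp.uc_pmv,
                            "uc_scale": cp.uc_scale,
                        }
                    )
        preds = pd.DataFrame(pred_rows)
        preds.to_csv(out / "cross_predictions.tsv", sep="\t", index=False)

        metrics_rows = []
        for trait in config.traits:
            obs = m1[m1["trait"] == trait][["family_id", "mu", "sigma2_A"]].rename(
                columns={"sigma2_A": "sigma2"}
            )
            for method in ("vpm", "pmv"):
                pred = preds[preds["trait"] == trait][
                    ["family_id", "ts_type", "mu", f"sigma2_{method}"]
                ].rename(columns={f"sigma2_{method}": "sigma2"})
                tbl = experiment.evaluate_cross_predictions(
                    obs, pred, intensity=config.selection_intensity
                )
                tbl["trait"] = trait
                tbl["method"] = method
                metrics_rows.append(tbl)
        pd.concat(metrics_rows, ignore_index=True).to_csv(
            out / "cross_prediction_metrics.tsv", sep="\t", index=False
        )

        t1 = _stage("donor-selection")
        trait = next(iter(config.traits))
        y_all = study.trait_values(trait)
        post_all = brr.fit_brr(
            y_all.to_numpy(),
            study.progeny.to_numpy(dtype=float),
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=mcmc_seed,
        )
        windows = hcriterion.build_windows(
            study.gmap, config.window_size, config.window_step
        )
        hebv_df = hcriterion.hebv(study.parents, post_all.effects_mean, windows)
        sel_rows = []
        for rec in study.design["recipient_id"].unique():
            initial = list(
                study.design.loc[study.design["recipient_id"] == rec, "donor_id"]
            )
            candidates = [
                d for d in study.design["donor_id"].unique() if d not in initial
            ]
            if not candidates:
                continue
            traj = hcriterion.forward_select_donors(
                rec, initial, candidates, hebv_df, windows.lam
            )
            tbl = traj.table.copy()
            tbl["recipient_id"] = rec
            tbl["baseline_h"] = traj.baseline_h
            sel_rows.append(tbl)
        if sel_rows:
            pd.concat(sel_rows, ignore_index=True).to_csv(
                out / "donor_selection.tsv", sep="\t", index=False
            )
        manifest["stages"]["brr-and-cross-prediction"] = {
            "seconds": round(t1 - t0, 2),
            "mcmc_seed": mcmc_seed,
        }
        manifest["stages"]["donor-selection"] = {
            "seconds": round(time.time() - t1, 2)
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
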