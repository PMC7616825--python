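"""End-to-end analysis pipeline: simulate/read -> FPCA -> fit -> infer -> diagnose.

Each stage writes its artifacts into the output directory and records
them in ``provenance.json`` together with the configuration hash and
master seed, so any output file can be traced back to the run that
produced it.  A ``run_log.json`` stores stage timings and versions.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, simdata
from .basis import make_basis, transform_matrix, transform_scores
from .diagnostics import alpha_curves, conditional_F, overid_Q
from .estimation import association_fit, build_ivdata, cue_gmm, reconstruct_effect
from .fpca import fit_fpca
from .io import (
    Provenance,
    RunConfig,
    read_exposure,
    read_genotypes,
    read_outcome,
    write_exposure,
    write_fpca_model,
    write_genotypes,
    write_outcome,
)
from .weakiv import global_null_test, lm_region, region_to_band

logger = logging.getLogger("mpcmr")

__all__ = ["run_pipeline"]


def _stage(log: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            log[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                logger.error("stage %s failed: %s", name, exc)
                return False
            logger.info("stage %s finished in %.2fs", name, log[name])
            return False

    return _Timer()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns a summary dict of the key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = Provenance(config_hash=cfg.config_hash(), seed=cfg.seed)
    timings: dict = {}
    summary: dict = {}

    with _stage(timings, "inputs"):
        if cfg.simulate is not None:
            sim_cfg = simdata.SimConfig(seed=cfg.seed, **cfg.simulate)
            ds = simdata.simulate(sim_cfg)
            exposure = ds.exposure
            subjects = exposure.subjects
            genos = pd.DataFrame(
                ds.genotypes.dosages, columns=list(ds.genotypes.variant_ids)
            )
            genos.index = pd.Index(subjects, name="subject_id")
            y = pd.Series(ds.outcome, index=subjects, name="y")
            write_exposure(exposure, out / "exposure.csv")
            write_genotypes(
                ds.genotypes.dosages, ds.genotypes.variant_ids, subjects,
                out / "genotypes.csv",
            )
            write_outcome(ds.outcome, subjects, out / "outcome.csv")
            with open(out / "truth.json", "w") as fh:
                json.dump(
                    {
                        "exposure_scenario": sim_cfg.exposure_scenario,
                        "outcome_scenario": sim_cfg.outcome_scenario,
                        "grid": ds.paths.grid.points.tolist(),
                        "beta_true": ds.beta_true.tolist(),
                    },
                    fh,
                )
            for name in ("exposure.csv", "genotypes.csv", "outcome.csv", "truth.json"):
                prov.register(out / name, "simulate")
        else:
            exposure = read_exposure(cfg.exposure, t_min=cfg.t_min, t_max=cfg.t_max)
            genos = read_genotypes(cfg.genotypes)
            y = read_outcome(cfg.outcome)
        # align the three blocks on the intersection of subject ids
        common = [s for s in exposure.subjects if s in genos.index and s in y.index]
        dropped = exposure.n_subjects - len(common)
        if dropped:
            logger.warning("dropping %d subjects missing from a block", dropped)
        genos = genos.loc[common]
        y = y.loc[common]

    with _stage(timings, "fpca"):
        model = fit_fpca(
            exposure,
            grid_size=cfg.grid_size,
            fve_threshold=cfg.fve,
            K=cfg.n_components,
            mean_bandwidth=cfg.mean_bandwidth,
            cov_bandwidth=cfg.cov_bandwidth,
        )
        write_fpca_model(model, out / "fpca_model.json")
        score_df = pd.DataFrame(
            model.scores, columns=[f"xi_{k + 1}" for k in range(model.K)]
        )
        score_df.insert(0, "subject_id", model.subjects)
        score_df.to_csv(out / "scores.csv", index=False)
        prov.register(out / "fpca_model.json", "fpca")
        prov.register(out / "scores.csv", "fpca")
        summary["K"] = model.K
        summary["fve"] = float(model.fve[min(model.K, len(model.fve)) - 1])

    with _stage(timings, "fit"):
        basis = (
            make_basis("eigenfunction", model=model)
            if cfg.basis_kind == "eigenfunction"
            else make_basis("polynomial", grid=model.grid, degree=cfg.basis_degree)
        )
        if basis.L > model.K:
            raise ValueError(
                f"basis dimension {basis.L} exceeds the {model.K} retained components"
            )
        B = transform_matrix(model.eigenfunctions, basis, model.grid)
        scores_aligned = score_df.set_index("subject_id").loc[common].to_numpy()
        xi_star = transform_scores(scores_aligned, B)
        data = build_ivdata(genos.to_numpy(dtype=float), xi_star, y.to_numpy())
        if cfg.method == "cue_gmm":
            fit = cue_gmm(data)
        else:
            fit = association_fit(xi_star, y.to_numpy())
        curve = reconstruct_effect(fit, basis)
        with open(out / "fit.json", "w") as fh:
            json.dump(
                {
                    "method": fit.method,
                    "basis": cfg.basis_kind,
                    "gamma": fit.beta_star.tolist(),
                    "Sigma": fit.Sigma.tolist(),
                    "objective": fit.objective_value,
                    "converged": fit.converged,
                },
                fh,
            )
        pd.DataFrame(
            {
                "t": curve.grid.points,
                "beta": curve.beta_t,
                "se": curve.se_t,
                "lo": curve.wald_lo,
                "hi": curve.wald_hi,
            }
        ).to_csv(out / "effect_curve.csv", index=False)
        prov.register(out / "fit.json", "fit")
        prov.register(out / "effect_curve.csv", "fit")
        summary["gamma"] = fit.beta_star.tolist()

    with _stage(timings, "infer"):
        region = lm_region(data, fit, m=cfg.m, width=cfg.width, alpha=cfg.alpha)
        reg_df = pd.DataFrame(
            region.candidates, columns=[f"beta0_{l + 1}" for l in range(data.L)]
        )
        reg_df["lm"] = region.lm_values
        reg_df["accepted"] = region.accepted
        reg_df.to_csv(out / "lm_region.csv", index=False)
        prov.register(out / "lm_region.csv", "infer")
        if not region.is_empty:
            lo, hi = region_to_band(region, basis)
            pd.DataFrame({"t": basis.grid.points, "lo": lo, "hi": hi}).to_csv(
                out / "effect_band.csv", index=False
            )
            prov.register(out / "effect_band.csv", "infer")
        gnull = global_null_test(data)
        summary["global_null_lm"] = gnull.lm_value
        summary["global_null_p"] = gnull.p_value

    with _stage(timings, "diagnose"):
        # instrument strength is reported per principal component (the
        # pseudo-exposures), not per transformed exposure
        F = conditional_F(data.Z, scores_aligned)
        q, df, p = overid_Q(data, fit) if fit.method == "cue_gmm" else (None, None, None)
        diag = {
            "conditional_F": F.tolist(),
            "overid_Q": q,
            "overid_df": df,
            "overid_p": p,
        }
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag, fh)
        curves = alpha_curves(data.Z, model)
        ac = pd.DataFrame(curves.T, columns=list(genos.columns))
        ac.insert(0, "t", model.grid.points)
        ac.to_csv(out / "alpha_curves.csv", index=False)
        prov.register(out / "diagnostics.json", "diagnose")
        prov.register(out / "alpha_curves.csv", "diagnose")
        summary["conditional_F"] = F.tolist()

    with open(out / "run_log.json", "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "version": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "timings_s": timings,
            },
            fh,
            indent=2,
        )
    prov.write(out)
    return summary
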