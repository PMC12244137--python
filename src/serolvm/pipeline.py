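"""End-to-end analysis pipeline.

Reproduces the analysis sequence on a cohort table (read from disk or
generated synthetically): censoring-aware descriptives, the
group-difference latent-variable model with score-test covariance
refinement, the hormone-mediation model (carrying over any refined
covariances), effect decomposition with group contrasts, an HRRT-only
sensitivity re-fit, and the symptom–hormone–binding network on the
MDD subgroup. All artifacts are JSON/CSV; the manifest records config,
seed and versions so a run can be repeated byte-identically (timestamps
live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .censored import censoring_summary, gehan_test, welch_t
from .cohort import GROUP_MDD, SCANNER_HRRT
from .diagnostics import qq_points, refine_covariance
from .effects import effects_table
from .io import read_cohort, write_cohort
from .lvm import build_lvm_spec, fit_lvm, residuals
from .network import centrality, ebic_glasso, hamd_subscales, residualize
from .synthetic import GeneratorParams, default_params, generate_cohort, generate_hamd

__all__ = ["PipelineConfig", "run_pipeline", "dose_reduction_percent"]

log = logging.getLogger("serolvm")


def dose_reduction_percent(reference_mean: float, reduced_mean: float) -> int:
    """Percent reduction of the second mean relative to the first,
    rounded to an integer for report parity with cohort tables."""
    return int(round(100.0 * (reference_mean - reduced_mean) / reference_mean))


@dataclass
class PipelineConfig:
    """Pipeline settings; exactly one of input_path / generator set."""

    input_path: str | None = None
    generator: GeneratorParams | dict | None = None
    censoring_mode: str = "integrate_main_only"
    refinement_alpha: float = 0.05
    network_tuning: float = 0.5
    small_sample_ack: bool = True
    loq: float = 0.09
    outdir: str = "results"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("set exactly one of input_path or generator")
        if isinstance(self.generator, dict):
            self.generator = GeneratorParams(**self.generator)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True)
                    + "\n")


def _fit_json(fit) -> dict:
    return {
        "params": fit.params_table(),
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_dropped": fit.n_dropped,
        "converged": bool(fit.converged),
        "n_iter": fit.n_iter,
        "extra_covariances": [list(p) for p in fit.spec.extra_covariances],
        "censoring_mode": fit.spec.censoring_mode,
    }


def _active_covariates(table: pd.DataFrame) -> tuple:
    """Drop covariates that are constant on the analysis rows."""
    covs = []
    for c in ("age", "dose"):
        covs.append(c)
    sc = table["scanner"]
    if sc.nunique() > 1:
        covs.append("scanner")
    else:
        log.info("scanner column is constant; dropping the scanner covariate")
    return tuple(covs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every analysis stage; returns the result bundle as a dict.

    Stage failures abort with the completed-stage manifest written to
    the output directory.
    """
    logging.basicConfig(level=config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_jsonable(),
        "version": __version__,
        "started_unix": time.time(),
        "stages": [],
    }
    bundle: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        # ---- cohort ---------------------------------------------------
        stage("cohort")
        if config.input_path is not None:
            table = read_cohort(config.input_path)
        else:
            params = config.generator or default_params()
            table = generate_cohort(params, seed=config.seed)
            table = generate_hamd(params, table, seed=config.seed + 1)
            write_cohort(table, outdir / "cohort.csv")
        bundle["cohort"] = table
        mdd = table[table["group"] == GROUP_MDD]

        # ---- descriptives --------------------------------------------
        stage("descriptives")
        welch = welch_t(table["testosterone"], table["group"])
        gehan = gehan_test(table["estradiol"],
                           table["estradiol_censored"].astype(bool),
                           table["group"], inference="permutation",
                           n_perm=10000, seed=config.seed)
        cens = censoring_summary(table["estradiol_censored"].astype(bool),
                                 table["group"])
        dose_means = table.groupby("group")["dose"].mean()
        dose_reduction_pct = dose_reduction_percent(dose_means["HC"],
                                                    dose_means["MDD"])
        descriptives = {
            "welch_testosterone": welch,
            "gehan_estradiol": gehan,
            "censoring": cens,
            "dose_means": dose_means.to_dict(),
            "dose_reduction_pct": dose_reduction_pct,
        }
        bundle["descriptives"] = descriptives
        _write_json(outdir / "descriptives.json", descriptives)

        # ---- group-difference LVM with refinement --------------------
        stage("lvm_group")
        covs = _active_covariates(table)
        spec1 = build_lvm_spec("group_only", covariates=covs, loq=config.loq)
        fit1, refinement = refine_covariance(spec1, table,
                                             alpha=config.refinement_alpha)
        bundle["fit_group"] = fit1
        bundle["refinement"] = refinement
        fit1.params_table().to_csv(outdir / "model1_params.csv", index=False)
        _write_json(outdir / "model1_fit.json", _fit_json(fit1))
        _write_json(outdir / "refinement.json", {
            "added": refinement.to_records(),
            "aborted": refinement.aborted,
        })

        # ---- hormone-mediation LVM -----------------------------------
        stage("lvm_hormones")
        spec2 = build_lvm_spec(
            "hormones", covariates=covs,
            extra_covariances=fit1.spec.extra_covariances,
            censoring_mode=config.censoring_mode, loq=config.loq)
        fit2 = fit_lvm(spec2, table)
        bundle["fit_hormones"] = fit2
        fit2.params_table().to_csv(outdir / "model2_params.csv", index=False)
        _write_json(outdir / "model2_fit.json", _fit_json(fit2))

        # residual normal-quantile coordinates for QQ plotting
        res = residuals(fit2, table)
        qq = qq_points(res)
        qq_frames = []
        for region, d in qq.items():
            qq_frames.append(pd.DataFrame({
                "region": region,
                "theoretical": d["theoretical"],
                "empirical": d["empirical"],
            }))
        pd.concat(qq_frames).to_csv(outdir / "qq_model2.csv", index=False)

        # ---- effects --------------------------------------------------
        stage("effects")
        eff = effects_table(fit2)
        bundle["effects"] = eff
        eff.to_csv(outdir / "effects.csv", index=False)

        # ---- HRRT-only sensitivity ------------------------------------
        stage("sensitivity_hrrt")
        sub = table[table["scanner"] == SCANNER_HRRT]
        covs_h = _active_covariates(sub)
        f1h = fit_lvm(build_lvm_spec("group_only", covariates=covs_h,
                                     extra_covariances=fit1.spec.extra_covariances,
                                     loq=config.loq), sub)
        f2h = fit_lvm(build_lvm_spec("hormones", covariates=covs_h,
                                     extra_covariances=fit1.spec.extra_covariances,
                                     censoring_mode=config.censoring_mode,
                                     loq=config.loq), sub)
        sens = {
            "n": int(len(sub)),
            "gamma_group": f1h.estimates["gamma_group"],
            "gamma_group_se": f1h.se["gamma_group"],
            "effects": effects_table(f2h),
        }
        bundle["sensitivity_hrrt"] = sens
        _write_json(outdir / "sensitivity_hrrt.json", sens)

        # ---- symptom network (MDD only) -------------------------------
        stage("network")
        net_tab = mdd.copy()
        net_tab["estradiol_low"] = net_tab["estradiol_censored"].astype(float)
        hamd6, veg = hamd_subscales(net_tab[[f"hamd_{i}" for i in range(1, 18)]])
        net_tab["hamd6"] = hamd6
        for c in veg.columns:
            net_tab[c] = veg[c]
        net_tab = residualize(net_tab, {
            "bp_neostriatum": ["age", "dose"],
            "testosterone": ["age"],
            "estradiol_low": ["age"],
        })
        node_cols = (["bp_neostriatum", "testosterone", "estradiol_low",
                      "hamd6"] + list(veg.columns))
        net = ebic_glasso(net_tab[node_cols], tuning=config.network_tuning,
                          small_sample_ack=config.small_sample_ack)
        cent = centrality(net)
        bundle["network"] = net
        bundle["centrality"] = cent
        net.adjacency.to_csv(outdir / "network_adjacency.csv")
        cent.to_csv(outdir / "network_centrality.csv", index=False)
        _write_json(outdir / "network.json", {
            "penalty": net.penalty, "ebic": net.ebic,
            "n_edges": net.n_edges, "edges": net.edge_list(),
        })

        manifest["status"] = "complete"
    except Exception as exc:  # stage failure: keep partial manifest
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["finished_unix"] = time.time()
        _write_json(outdir / "manifest.json", manifest)
        raise
    manifest["finished_unix"] = time.time()
    _write_json(outdir / "manifest.json", manifest)
    return bundle
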