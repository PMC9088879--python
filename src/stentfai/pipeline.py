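"""End-to-end orchestration: phantom -> FAI -> cohort -> stats -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .fai import FAIConfig, measure_peristent_fai
from .geometry import extract_centerline
from .stats import (
    DEFAULT_ADJUSTERS,
    fit_adjusted_logistic,
    group_comparison,
    icc_absolute,
    lasso_select,
    pearson_with_ci,
    roc_curve_auc,
    subgroup_roc,
    youden_cutoff,
)
from .synthetic import (
    CohortConfig,
    PhantomConfig,
    generate_cohort,
    generate_phantom,
)

log = logging.getLogger("stentfai")

# Table-4 predictor set: FAI plus the three laboratory markers retained by
# the lambda_min model.
DEFAULT_PREDICTORS = (
    "peri_stent_fai_hu",
    "hs_crp_mg_l",
    "hdl_c_mmol_l",
    "apoa1_g_l",
)


@dataclass
class PipelineConfig:
    """Nested configuration for the full simulation-and-analysis pipeline."""

    seed: int = 0
    n_phantoms_per_group: int = 2
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    fai: dict = field(default_factory=dict)  # FAIConfig overrides
    stats: dict = field(default_factory=dict)  # test, folds, predictors...
    outdir: str = None
    write_volumes: bool = False
    plots: bool = False
    log_level: str = "INFO"

    # ISR- and non-ISR-condition fat attenuation (HU) used for the phantom
    # validation stage; the cohort-level analogues live in CohortConfig.
    phantom_groups: dict = field(
        default_factory=lambda: {
            "isr": {"fat_mean": -78.1, "fat_sd": 6.2},
            "non_isr": {"fat_mean": -87.2, "fat_sd": 7.3},
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = sio.load_yaml(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % 2**31]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _assert_finite(obj, path="report"):
    if isinstance(obj, dict):
        for k, v in obj.items():
            _assert_finite(v, f"{path}.{k}")
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            _assert_finite(v, f"{path}[{i}]")
    elif isinstance(obj, float) and not np.isfinite(obj):
        raise ValueError(f"non-finite value in report at {path}")


def _stage(name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, et, ev, tb):
            dt = time.perf_counter() - self.t0
            if et is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, ev)

    return _Timer()


def run_phantom_stage(config: PipelineConfig) -> dict:
    """Generate seeded phantoms per condition and measure their FAI
    through the full centerline -> shell -> HU-window pipeline."""
    fai_cfg = FAIConfig(**config.fai)
    results = {}
    seeds = _child_seeds(config.seed, 2 * config.n_phantoms_per_group + 1)[1:]
    i = 0
    for group, pars in config.phantom_groups.items():
        measured = []
        for _ in range(config.n_phantoms_per_group):
            pcfg = PhantomConfig(**{**config.phantom, **pars, "seed": seeds[i]})
            i += 1
            vol, truth = generate_phantom(pcfg)
            cl = extract_centerline(truth.lumen_mask, vol.spacing, vol.origin)
            m = measure_peristent_fai(vol, cl, truth.annotation, fai_cfg)
            measured.append(m.fai_hu)
        results[group] = {
            "configured_fat_mean_hu": pars["fat_mean"],
            "measured_fai_hu": measured,
            "mean_measured_fai_hu": float(np.mean(measured)),
        }
    return results


def run_stats_stage(cohort, config: PipelineConfig) -> dict:
    scfg = dict(config.stats)
    method = scfg.get("test", "welch")
    folds = int(scfg.get("folds", 10))
    predictors = list(scfg.get("predictors", DEFAULT_PREDICTORS))
    adjusters = list(scfg.get("adjusters", DEFAULT_ADJUSTERS))
    seed = _child_seeds(config.seed, 5)[4]

    ccfg = CohortConfig(**config.cohort)
    continuous = ["peri_stent_fai_hu"] + list(ccfg.continuous)
    binary = list(ccfg.binary)

    report = {}
    report["group_comparison"] = group_comparison(
        cohort, continuous, binary, method=method
    )

    features = cohort[
        ["peri_stent_fai_hu"] + list(ccfg.continuous) + list(ccfg.binary)
    ]
    lasso = lasso_select(features, cohort["isr"], folds=folds, seed=seed)
    report["lasso"] = {
        "lambda_min": lasso.lambda_min,
        "lambda_1se": lasso.lambda_1se,
        "model1_features": lasso.selected_min,
        "model2_features": lasso.selected_1se,
        "model1_auc": lasso.auc_min,
        "model2_auc": lasso.auc_1se,
        "model1_coefficients": lasso.coef_min,
        "model2_coefficients": lasso.coef_1se,
        "converged": lasso.converged,
    }

    adj = fit_adjusted_logistic(cohort, predictors, adjusters)
    report["adjusted_logistic"] = {
        "odds_ratios": adj.odds_ratios,
        "adjusters": adj.adjusters,
        "converged": adj.converged,
        "separation": adj.separation,
    }

    roc = roc_curve_auc(cohort["peri_stent_fai_hu"], cohort["isr"])
    cutoff, sens, spec = youden_cutoff(roc)
    report["roc"] = {
        "auc": roc.auc,
        "ci": list(roc.ci),
        "youden_cutoff_hu": cutoff,
        "sensitivity": sens,
        "specificity": spec,
    }
    report["subgroup_auc"] = {
        vessel: (None if r is None else r.auc)
        for vessel, r in subgroup_roc(cohort).items()
    }

    isr_grp = cohort[cohort["isr"] == 1]
    if len(isr_grp) >= 4:
        r, ci, p = pearson_with_ci(
            isr_grp["degree_of_isr_pct"], isr_grp["peri_stent_fai_hu"]
        )
        report["degree_fai_pearson"] = {"r": r, "ci": list(ci), "p": p}

    icc = icc_absolute(cohort[["fai_rater1_hu", "fai_rater2_hu"]].to_numpy())
    report["fai_icc"] = {
        "estimate": icc.estimate,
        "ci": list(icc.ci),
        "model": icc.model,
    }

    report["cohort_counts"] = {
        "n_total": int(len(cohort)),
        "n_isr": int(cohort["isr"].sum()),
        "n_nonisr": int((cohort["isr"] == 0).sum()),
    }
    return report


def run_pipeline(config: PipelineConfig = None, outdir=None) -> dict:
    """Run phantom validation, cohort simulation and the statistical chain.

    Deterministic under a fixed seed; returns (and optionally writes) a
    JSON-serialisable report carrying every configured default for
    provenance.
    """
    config = config or PipelineConfig()
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    outdir = Path(outdir or config.outdir) if (outdir or config.outdir) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report = {"config": _jsonable(dataclasses.asdict(config))}

    with _stage("phantom"):
        report["phantom_validation"] = run_phantom_stage(config)

    with _stage("cohort"):
        cseed = _child_seeds(config.seed, 5)[3]
        ccfg = CohortConfig(**{**config.cohort, "seed": cseed})
        cohort = generate_cohort(ccfg)
        if outdir:
            sio.write_cohort(cohort, outdir / "cohort.csv")

    with _stage("stats"):
        report["stats"] = run_stats_stage(cohort, config)

    report = _jsonable(report)
    _assert_finite({k: v for k, v in report.items() if k != "config"})
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if config.plots:
            _write_plots(cohort, outdir)
    return report


def _write_plots(cohort, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roc = roc_curve_auc(cohort["peri_stent_fai_hu"], cohort["isr"])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - roc.specificity, roc.sensitivity, label=f"FAI AUC={roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "roc_fai.png", dpi=120)
    plt.close(fig)
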