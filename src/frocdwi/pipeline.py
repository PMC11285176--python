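"""End-to-end orchestration: simulation → fitting → quality → statistics.

A run is driven by a :class:`RunConfig` (constructable from YAML) and
produces a report bundle under ``output_dir``:

* ``summary.json`` — every headline number of the run;
* ``quality.csv`` — per-b SNR/CNR of the phantom lesion;
* ``cohort.csv`` — the simulated lesion cohort;
* ``group_stats.csv`` — per-parameter group comparison (benign vs malignant);
* ``roc.csv`` — per-marker ROC table (cutoff, AUC, CI, operating point);
* ``nomogram.csv``, ``calibration.csv``, ``dca.csv`` — combined-model outputs;
* parameter maps and the simulated series as NIfTI.

Every stage derives its own sub-seed from the config seed, so a rerun with
the same config is bit-identical; stage boundaries are logged with the
parameters in effect.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostic_model as dm
from . import group_stats as gs
from .fitting import fit_volume, voi_statistics
from .phantom import (LABEL_AIR, LABEL_LESION_START, LABEL_TISSUE, CohortSpec,
                      EllipsoidLesion, PhantomSpec, generate_parameter_maps,
                      simulate_cohort, simulate_dwi_series, write_cohort,
                      write_mask, write_series)
from .quality_metrics import series_quality_table
from .signal_models import AcquisitionProtocol, FrocParams, breast_14b_protocol

__all__ = ["RunConfig", "run_pipeline", "default_demo_config",
            "cohort_statistics", "MARKER_ORIENTATION"]

logger = logging.getLogger(__name__)

#: Direction of each marker that indicates malignancy (D, β, ADC are lower
#: in malignant lesions; µ is higher).
MARKER_ORIENTATION = {"D": "lower", "beta": "lower", "adc": "lower", "mu": "higher"}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    output_dir: Path = Path("froc_run")
    protocol: Optional[AcquisitionProtocol] = None
    phantom_spec: Optional[PhantomSpec] = None
    cohort_spec: Optional[CohortSpec] = None
    run_phantom: bool = True
    run_cohort: bool = True
    n_bootstrap: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = default_demo_config()
        cfg.seed = int(raw.get("seed", cfg.seed))
        cfg.output_dir = Path(raw.get("output_dir", cfg.output_dir))
        if "protocol" in raw and raw["protocol"]:
            cfg.protocol = AcquisitionProtocol.from_yaml(raw["protocol"])
        ph = raw.get("phantom", {})
        cfg.run_phantom = bool(ph.get("enabled", cfg.run_phantom))
        if "noise_sigma" in ph:
            cfg.phantom_spec.noise_sigma = float(ph["noise_sigma"])
        if "grid_shape" in ph:
            cfg.phantom_spec.grid_shape = tuple(ph["grid_shape"])
        co = raw.get("cohort", {})
        cfg.run_cohort = bool(co.get("enabled", cfg.run_cohort))
        if "n_benign" in co:
            cfg.cohort_spec.n_benign = int(co["n_benign"])
        if "n_malignant" in co:
            cfg.cohort_spec.n_malignant = int(co["n_malignant"])
        cfg.n_bootstrap = int(raw.get("n_bootstrap", cfg.n_bootstrap))
        return cfg


def default_demo_config() -> RunConfig:
    """A small self-contained demo: two-lesion phantom + the default cohort."""
    benign = EllipsoidLesion(center=(14, 8, 3), semi_axes=(3.2, 3.2, 1.6),
                             params=FrocParams(D=1.17, beta=0.86, mu=3.06), s0=0.9)
    malignant = EllipsoidLesion(center=(14, 16, 3), semi_axes=(3.2, 3.2, 1.6),
                                params=FrocParams(D=0.73, beta=0.77, mu=3.39), s0=1.1)
    spec = PhantomSpec(grid_shape=(20, 24, 6), lesions=(benign, malignant),
                       air_fraction=0.25, noise_sigma=0.02)
    return RunConfig(phantom_spec=spec, cohort_spec=CohortSpec())


def _stage_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _roc_row(marker, sequence, roc):
    return {
        "marker": marker, "sequence": sequence, "cutoff": roc.cutoff,
        "auc": roc.auc, "auc_ci_low": roc.auc_ci[0], "auc_ci_high": roc.auc_ci[1],
        "sensitivity": roc.sensitivity, "specificity": roc.specificity,
        "accuracy": roc.accuracy, "orientation": roc.orientation,
    }


def cohort_statistics(cohort: pd.DataFrame, n_bootstrap: int = 200,
                      seed: int = 0) -> dict:
    """The full statistics stage on a lesion cohort table.

    Returns a dict with group-comparison, agreement, ROC, logistic-model,
    nomogram, calibration and decision-curve results (DataFrames where
    tabular, plain dicts elsewhere).
    """
    params = ["D", "beta", "mu", "adc"]
    sequences = sorted(cohort["sequence"].unique())
    out = {}

    rows = []
    for seq in sequences:
        sub = cohort[cohort["sequence"] == seq]
        ben = sub[sub["group"] == "benign"]
        mal = sub[sub["group"] == "malignant"]
        for p in params:
            test, stat, pval = gs.compare_groups(ben[p], mal[p])
            rows.append({
                "sequence": seq, "parameter": p,
                "benign_mean": ben[p].mean(), "benign_sd": ben[p].std(ddof=1),
                "malignant_mean": mal[p].mean(), "malignant_sd": mal[p].std(ddof=1),
                "test": test, "statistic": stat, "p": pval,
            })
    out["group_comparison"] = pd.DataFrame(rows)

    # paired agreement between the two sequences, per parameter
    agreement = []
    if len(sequences) == 2:
        wide = cohort.pivot(index="lesion_id", columns="sequence", values=params)
        for p in params:
            a = wide[p][sequences[0]].to_numpy()
            b = wide[p][sequences[1]].to_numpy()
            sp = gs.spearman_with_category(a, b)
            icc = gs.icc_with_category(np.column_stack([a, b]))
            ba = gs.bland_altman(a, b)
            agreement.append({
                "parameter": p,
                "spearman_r": sp.estimate, "spearman_ci_low": sp.ci[0],
                "spearman_ci_high": sp.ci[1], "spearman_category": sp.category,
                "icc": icc.estimate, "icc_ci_low": icc.ci[0],
                "icc_ci_high": icc.ci[1], "icc_category": icc.category,
                "ba_bias": ba.bias, "ba_loa_low": ba.loa_lower,
                "ba_loa_high": ba.loa_upper,
            })
    out["agreement"] = pd.DataFrame(agreement)

    roc_rows, models = [], {}
    delong_rows = []
    calib, dca, nomograms = {}, {}, {}
    for seq in sequences:
        sub = cohort[cohort["sequence"] == seq].reset_index(drop=True)
        y = (sub["group"] == "malignant").to_numpy()
        seq_scores = {}
        for p in params:
            roc = dm.roc_analysis(sub[p], y, orientation=MARKER_ORIENTATION[p])
            roc_rows.append(_roc_row(p, seq, roc))
            seq_scores[p] = sub[p].to_numpy()
        model = dm.fit_logistic_with_selection(sub, y, features=["D", "beta", "mu"])
        models[seq] = model
        probs = model.predict_proba(sub)
        roc_rows.append(_roc_row("+".join(model.retained) or "intercept", seq,
                                 dm.combined_roc(model, sub, y)))
        for p in params:
            _, pd_ = dm.delong_test(probs, seq_scores[p], y,
                                    orientation_a="higher",
                                    orientation_b=MARKER_ORIENTATION[p])
            delong_rows.append({"sequence": seq, "a": "model", "b": p, "p": pd_})
        chi2, hl_p = dm.hosmer_lemeshow(probs, y)
        calib_df = dm.bootstrap_calibration(model, sub, y, n_boot=n_bootstrap,
                                            seed=seed)
        nb = dm.decision_curve(probs, y)
        if model.coef:
            nomograms[seq] = dm.build_nomogram(model, sub)
        calib[seq] = {"hosmer_lemeshow_chi2": chi2, "hosmer_lemeshow_p": hl_p,
                      "curve": calib_df}
        dca[seq] = nb
    out["roc"] = pd.DataFrame(roc_rows)
    out["delong_model_vs_marker"] = pd.DataFrame(delong_rows)
    out["models"] = models
    out["calibration"] = calib
    out["decision_curves"] = dca
    out["nomograms"] = nomograms
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage and write the report bundle.

    Returns the summary dict (also written to ``summary.json``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    summary = {"seed": config.seed}

    if config.run_phantom:
        spec = config.phantom_spec or default_demo_config().phantom_spec
        spec.seed = seeds[0]
        logger.info("stage phantom: grid=%s sigma=%g seed=%d",
                    spec.grid_shape, spec.noise_sigma, spec.seed)
        maps = generate_parameter_maps(spec)
        protocol = config.protocol or breast_14b_protocol()
        series = simulate_dwi_series(maps, protocol, spec.noise_sigma, spec.seed)
        write_series(series, outdir / "phantom_dwi")
        write_mask(maps.labels, outdir / "phantom_labels.nii.gz", maps.voxel_size)

        lesion_mask = maps.labels >= LABEL_LESION_START
        fitted = fit_volume(series, maps.labels >= LABEL_TISSUE)
        phantom_summary = {"noise_sigma": spec.noise_sigma, "lesions": []}
        for k in range(len(spec.lesions)):
            voi = maps.labels == LABEL_LESION_START + k
            les = spec.lesions[k]
            entry = {"truth": {"D": les.params.D, "beta": les.params.beta,
                               "mu": les.params.mu}}
            for name, grid in (("D", fitted.D), ("beta", fitted.beta),
                               ("mu", fitted.mu), ("adc", fitted.adc)):
                mean, sd = voi_statistics(grid, voi, fitted.converged)
                entry[name] = {"mean": mean, "sd": sd}
            phantom_summary["lesions"].append(entry)
        phantom_summary["non_converged_fraction"] = float(
            1.0 - fitted.converged[maps.labels >= LABEL_TISSUE].mean())

        quality = series_quality_table(series, lesion_mask,
                                       maps.labels == LABEL_TISSUE,
                                       maps.labels == LABEL_AIR)
        quality.to_csv(outdir / "quality.csv", index=False)
        phantom_summary["snr_b0"] = float(quality["snr"].iloc[0])
        phantom_summary["snr_bmax"] = float(quality["snr"].iloc[-1])
        summary["phantom"] = phantom_summary

    if config.run_cohort:
        cspec = config.cohort_spec or CohortSpec()
        cspec.seed = seeds[1]
        logger.info("stage cohort: n=%d/%d seed=%d", cspec.n_benign,
                    cspec.n_malignant, cspec.seed)
        cohort = simulate_cohort(cspec)
        write_cohort(cohort, outdir / "cohort.csv")
        stats = cohort_statistics(cohort, n_bootstrap=config.n_bootstrap,
                                  seed=seeds[2])
        stats["group_comparison"].to_csv(outdir / "group_stats.csv", index=False)
        stats["roc"].to_csv(outdir / "roc.csv", index=False)
        if len(stats["agreement"]):
            stats["agreement"].to_csv(outdir / "agreement.csv", index=False)
        for seq, cal in stats["calibration"].items():
            cal["curve"].to_csv(outdir / f"calibration_{seq}.csv", index=False)
        for seq, nb in stats["decision_curves"].items():
            pd.DataFrame({"threshold": nb.thresholds, "net_benefit": nb.net_benefit,
                          "treat_all": nb.treat_all,
                          "treat_none": nb.treat_none}).to_csv(
                outdir / f"dca_{seq}.csv", index=False)
        for seq, nomo in stats["nomograms"].items():
            rows = [{"feature": f, "coef": nomo.coef[f], "ref": nomo.ref[f],
                     "range_low": nomo.value_range[f][0],
                     "range_high": nomo.value_range[f][1],
                     "points_at_range_end": float(
                         max(nomo.feature_points(f, nomo.value_range[f][0]),
                             nomo.feature_points(f, nomo.value_range[f][1])))}
                    for f in nomo.coef]
            pd.DataFrame(rows).to_csv(outdir / f"nomogram_{seq}.csv", index=False)

        summary["cohort"] = {
            "n_benign": cspec.n_benign, "n_malignant": cspec.n_malignant,
            "group_comparison": stats["group_comparison"].to_dict("records"),
            "agreement": stats["agreement"].to_dict("records"),
            "roc": stats["roc"].to_dict("records"),
            "delong_model_vs_marker":
                stats["delong_model_vs_marker"].to_dict("records"),
            "models": {seq: {"intercept": m.intercept, "coef": m.coef,
                             "pvalues": m.pvalues, "retained": m.retained,
                             "penalized": m.penalized}
                       for seq, m in stats["models"].items()},
            "hosmer_lemeshow": {seq: {"chi2": cal["hosmer_lemeshow_chi2"],
                                      "p": cal["hosmer_lemeshow_p"]}
                                for seq, cal in stats["calibration"].items()},
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
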