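"""End-to-end orchestration: simulate -> fit Cole -> develop -> predict -> validate.

``run_pipeline`` reproduces the full analysis flow on one synthetic cohort:
the seven-model development ladder on the derivation split, agreement of the
two final refit equations on the validation split (FFM and derived FM, with
TOST bounds of 0.25 kg and 0.10 kg), and whole-cohort agreement for the
printed published equations and the six mixture-theory schemes.  All outputs
are JSON/CSV files stamped with the seed and a config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementReport, evaluate_agreement
from .cole import aggregate_replicates, derived_quantities
from .development import fit_linear_model, split_cohort
from .equations import (
    EQUATION_CATALOGUE,
    adjusted_weight,
    ffm_ejlerskov,
    ffm_nipper,
    ffm_rush,
)
from .mixture import MIXTURE_METHODS, default_config, predict_mixture
from .replication import FINAL_TERMS, analysis_frame
from .simulate import SynthConfig, generate_cohort, write_cohort

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("bisffm")

#: development ladder: model id -> analysis-frame term names
LADDER_TERMS = {
    "w": ["weight_scale_kg"],
    "w_l": ["weight_scale_kg", "height_cm"],
    "w_l_s": ["weight_scale_kg", "height_cm", "sex"],
    "w_idx": ["weight_scale_kg", "impedance_index"],
    "w_idx_s": ["weight_scale_kg", "impedance_index", "sex"],
    "nipper_anthro": ["weight_scale_kg", "height_cm", "sex", "ethnicity_asian"],
    "nipper_final": FINAL_TERMS,
}


@dataclass
class RunConfig:
    seed: int = 1
    n_children: int = 65
    derivation_fraction: float = 0.7
    equations: tuple = ("ejlerskov", "rush")
    mixture_methods: tuple = MIXTURE_METHODS
    tost_bound_ffm_kg: float = 0.25
    tost_bound_fm_kg: float = 0.10
    output_dir: str = "results"
    synth: SynthConfig | None = None

    def __post_init__(self):
        if self.tost_bound_ffm_kg <= 0 or self.tost_bound_fm_kg <= 0:
            raise ValueError("equivalence bounds must be positive")
        if not 0 < self.derivation_fraction <= 1:
            raise ValueError("derivation_fraction must be in (0, 1]")
        unknown = set(self.equations) - {"ejlerskov", "rush"} - set(EQUATION_CATALOGUE)
        if unknown:
            raise ValueError(f"unknown equation ids: {sorted(unknown)}")
        unknown_m = set(self.mixture_methods) - set(MIXTURE_METHODS)
        if unknown_m:
            raise ValueError(f"unknown mixture methods: {sorted(unknown_m)}")


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o).__name__)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _report_row(method: str, rep: AgreementReport) -> dict:
    return {
        "method": method,
        "n": rep.n,
        "mape_pct": rep.mape_pct,
        "ccc": rep.ccc,
        "ccc_lo": rep.ccc_ci[0],
        "ccc_hi": rep.ccc_ci[1],
        "bias_kg": rep.bias_kg,
        "bias_pct": rep.bias_pct_of_mean,
        "sd_kg": rep.sd_diff_kg,
        "loa_low_kg": rep.loa_low_kg,
        "loa_high_kg": rep.loa_high_kg,
        "p": rep.proportional_bias_p,
    }


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run the full reproduction; returns the summary dict it also writes."""
    config = config or RunConfig()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: seed=%d, n=%d", config.seed, config.n_children)

    synth = config.synth or SynthConfig()
    synth = dataclasses.replace(synth, seed=config.seed, n_children=config.n_children)
    cohort = generate_cohort(synth)
    write_cohort(cohort, outdir / "cohort")
    log.info("simulated %d children (%d resampled draws)", len(cohort.records), cohort.n_resampled)

    # Cole fits per child; fitted parameters replace the generator R50/R0/Rinf
    fitted = {}
    for rec in cohort.records:
        agg = aggregate_replicates(cohort.spectra[rec.child_id])
        r50, zc = derived_quantities(agg.params)
        fitted[rec.child_id] = {
            "r0": agg.params.r0,
            "rinf": agg.params.rinf,
            "fc_khz": agg.params.fc_khz,
            "alpha": agg.params.alpha,
            "r50": r50,
            "zc": zc,
            "fit_rmse": agg.params.fit_rmse,
            "quality_flag": agg.params.quality_flag,
            "r50_cv": agg.r50_cv,
            "params": agg.params,
        }
        rec.r50_ohm = r50
    with open(outdir / "cole_fits.json", "w") as fh:
        json.dump(
            {k: {kk: vv for kk, vv in v.items() if kk != "params"} for k, v in fitted.items()},
            fh,
            indent=1,
        )
    log.info("Cole fits done; median replicate R50 CV = %.4f%%",
             100 * float(np.median([v["r50_cv"] for v in fitted.values()])))

    df = analysis_frame(cohort)
    deriv, valid = split_cohort(df, config.derivation_fraction, seed=config.seed)
    log.info("split: %d derivation / %d validation", len(deriv), len(valid))

    # Development ladder refit on the derivation split
    ladder_rows, models = [], {}
    for model_id, terms in LADDER_TERMS.items():
        m = fit_linear_model(deriv, "ffm_dxa_kg", terms)
        models[model_id] = m
        ladder_rows.append(
            {
                "model": model_id,
                "terms": "+".join(terms),
                "adj_r2": m.adjusted_r2,
                "rmse_kg": m.rmse_kg,
                "intercept": m.intercept,
                **{f"b_{t}": c for t, c in zip(m.term_names, m.coefficients)},
                **{f"std_{t}": c for t, c in zip(m.term_names, m.standardized_coefficients)},
            }
        )
    pd.DataFrame(ladder_rows).to_csv(outdir / "model_ladder.csv", index=False)
    with open(outdir / "models.json", "w") as fh:
        json.dump(
            {
                mid: {
                    "terms": m.term_names,
                    "intercept": m.intercept,
                    "coefficients": m.coefficients.tolist(),
                    "adj_r2": m.adjusted_r2,
                    "rmse_kg": m.rmse_kg,
                    "n_fit": m.n_fit,
                }
                for mid, m in models.items()
            },
            fh,
            indent=1,
        )

    # Validation-split agreement for the two refit final equations
    ffm_ref = valid["ffm_dxa_kg"].to_numpy()
    fm_ref = valid["fm_dxa_kg"].to_numpy()
    wt_adj = np.array([adjusted_weight(w) for w in valid["weight_scale_kg"]])
    validation = {}
    for model_id in ("nipper_anthro", "nipper_final"):
        pred_ffm = models[model_id].predict(valid)
        rep_ffm = evaluate_agreement(pred_ffm, ffm_ref, tost_bound=config.tost_bound_ffm_kg)
        rep_fm = evaluate_agreement(wt_adj - pred_ffm, fm_ref, tost_bound=config.tost_bound_fm_kg)
        validation[model_id] = {"ffm": asdict(rep_ffm), "fm": asdict(rep_fm)}
    with open(outdir / "validation_ffm.json", "w") as fh:
        json.dump(validation, fh, indent=1)

    # Whole-cohort agreement: published equations and mixture methods
    dxa_all = df["ffm_dxa_kg"].to_numpy()
    mean_ffm = float(dxa_all.mean())
    comparison_rows = []
    published = {"ejlerskov": ffm_ejlerskov, "rush": ffm_rush}
    for eq in config.equations:
        fn = published.get(eq, lambda r, eq=eq: ffm_nipper(r, eq))
        preds = np.array([fn(r) for r in cohort.records])
        rep = evaluate_agreement(preds, dxa_all, tost_bound=config.tost_bound_ffm_kg,
                                 mean_reference=mean_ffm)
        comparison_rows.append(_report_row(eq, rep))
    for method in config.mixture_methods:
        mcfg = default_config(method)
        preds = np.array(
            [
                predict_mixture(rec, fitted[rec.child_id]["params"], mcfg).ffm_kg
                for rec in cohort.records
            ]
        )
        rep = evaluate_agreement(preds, dxa_all, tost_bound=config.tost_bound_ffm_kg,
                                 mean_reference=mean_ffm)
        comparison_rows.append(_report_row(method, rep))
    pd.DataFrame(comparison_rows).to_csv(outdir / "method_comparison.csv", index=False)

    summary = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "version": __version__,
        "n_children": len(cohort.records),
        "n_derivation": int(len(deriv)),
        "n_validation": int(len(valid)),
        "final_model": {
            "adj_r2": models["nipper_final"].adjusted_r2,
            "rmse_kg": models["nipper_final"].rmse_kg,
        },
        "validation_mape_pct": validation["nipper_final"]["ffm"]["mape_pct"],
        "validation_bias_kg": validation["nipper_final"]["ffm"]["bias_kg"],
        "method_comparison": comparison_rows,
        "outputs": [
            str(p)
            for p in (
                outdir / "model_ladder.csv",
                outdir / "models.json",
                outdir / "validation_ffm.json",
                outdir / "method_comparison.csv",
            )
        ],
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("pipeline done: final adj R2=%.3f rmse=%.3f kg",
             summary["final_model"]["adj_r2"], summary["final_model"]["rmse_kg"])
    return summary
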