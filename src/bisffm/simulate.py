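"""Synthetic preschool cohort generator.

Emulates the statistical structure the analysis pipeline assumes for a
3.5-year-old cohort measured with bioimpedance spectroscopy and DXA:

1. sex ~ Bernoulli(p_male), ethnicity ~ Bernoulli(p_asian);
2. height ~ Normal with sex-specific mean/SD; weight follows a sex-calibrated
   affine function of height plus noise, reproducing the sex-specific weight
   means/SDs and a configurable weight-height correlation;
3. latent "true" FFM is affine in weight, sex and ethnicity plus a
   physiological residual, with intercept and sex coefficient solved so the
   sex-specific FFM means hit their calibration targets;
4. the impedance index L²/R50 is obtained by inverting the final impedance
   prediction equation at the latent FFM, which defines R50 = height²/index —
   so the final equation is the exact ground truth of the generated cohort;
5. R0 and Rinf follow fixed ratios to R50; fc is solved (once, cohort-wide)
   so the Cole real part at 50 kHz equals R50 exactly;
6. triplicate Cole spectra receive a common per-replicate multiplicative
   scale error (the replicate CV of R50) plus small per-point noise;
7. DXA FFM adds reference-method noise to the latent FFM, DXA weight follows
   the scale-weight adjustment relation, and DXA FM closes the mass balance.

Every child draws from an independent RNG stream keyed by (seed, index), so
per-child reproducibility survives reordering, and the whole cohort is
byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cole import ColeParameters, ImpedanceSpectrum, cole_impedance
from .equations import EQUATION_CATALOGUE, adjusted_weight
from .records import ChildRecord, ReferenceMeasurement

__all__ = ["SynthConfig", "Cohort", "generate_cohort", "write_cohort", "read_cohort", "to_frames"]

_MALE, _FEMALE = 1, 0


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the cohort structure the pipeline is calibrated against:
    65 children with a 25/40 male/female and 14/65 Asian/non-Asian mix,
    sex-specific height and weight distributions, an R50 replicate CV of
    0.17%, DXA FFM noise of 0.39 kg, and a physiological FFM residual of
    1.06 kg around the covariate-driven mean.
    """

    n_children: int = 65
    p_male: float = 25 / 65
    p_asian: float = 14 / 65
    height_mean: dict = field(default_factory=lambda: {_MALE: 100.3, _FEMALE: 98.6})
    height_sd: dict = field(default_factory=lambda: {_MALE: 3.4, _FEMALE: 3.5})
    weight_mean: dict = field(default_factory=lambda: {_MALE: 15.7, _FEMALE: 15.3})
    weight_sd: dict = field(default_factory=lambda: {_MALE: 2.0, _FEMALE: 1.7})
    ffm_mean: dict = field(default_factory=lambda: {_MALE: 12.0, _FEMALE: 11.1})
    weight_height_corr: float = 0.6
    ffm_weight_slope: float = 0.15
    ffm_ethnicity_coef: float = 0.28
    ffm_resid_sd: float = 1.06
    dxa_noise_sd: float = 0.39
    dxa_weight_noise_sd: float = 0.05
    r0_r50_ratio: float = 1.090
    rinf_r50_ratio: float = 0.828
    alpha: float = 0.10
    replicate_cv: float = 0.0017
    point_noise_cv: float = 0.0005
    n_replicates: int = 3
    freq_min_khz: float = 3.0
    freq_max_khz: float = 1000.0
    n_frequencies: int = 256
    age_mean_days: float = 1232.0
    age_sd_days: float = 60.0
    bmc_mean: dict = field(default_factory=lambda: {_MALE: 545.0, _FEMALE: 517.0})
    bmc_sd: dict = field(default_factory=lambda: {_MALE: 65.0, _FEMALE: 56.0})
    kb_mean: float = 4.3
    kb_sd: float = 0.2
    r50_bounds: tuple = (300.0, 1500.0)
    min_dxa_fm_kg: float = 0.2
    max_resamples: int = 100
    generate_spectra: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_male <= 1 or not 0 <= self.p_asian <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for d in (self.height_sd, self.weight_sd):
            if any(v <= 0 for v in d.values()):
                raise ValueError("all SDs must be positive")
        for v in (self.ffm_resid_sd, self.dxa_noise_sd, self.replicate_cv):
            if v < 0:
                raise ValueError("noise levels must be non-negative")
        if not self.rinf_r50_ratio < 1 < self.r0_r50_ratio:
            raise ValueError("require rinf/r50 ratio < 1 < r0/r50 ratio")
        if not -1 < self.weight_height_corr < 1:
            raise ValueError("weight-height correlation must be in (-1, 1)")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")


@dataclass
class Cohort:
    records: list
    references: list
    spectra: dict  # child_id -> list[ImpedanceSpectrum]
    n_resampled: int = 0


def _ffm_intercepts(config: SynthConfig) -> tuple[float, float]:
    """Solve the latent-FFM intercept and sex coefficient from the sex means."""
    b = config.ffm_weight_slope
    d = config.ffm_ethnicity_coef
    a = (
        config.ffm_mean[_FEMALE]
        - b * config.weight_mean[_FEMALE]
        - d * config.p_asian
    )
    c = (
        config.ffm_mean[_MALE]
        - config.ffm_mean[_FEMALE]
        - b * (config.weight_mean[_MALE] - config.weight_mean[_FEMALE])
    )
    return a, c


def _solve_fc_multiplier(config: SynthConfig) -> float:
    """Solve x = 50/fc so that Re Z(50 kHz) equals R50 given the R0/Rinf ratios.

    The normalized dispersion level (R50 - Rinf)/(R0 - Rinf) depends only on
    the ratios, so a single fc multiplier serves the whole cohort.
    """
    target = (1.0 - config.rinf_r50_ratio) / (config.r0_r50_ratio - config.rinf_r50_ratio)
    if not 0 < target < 1:
        raise ValueError("R0/Rinf ratios place R50 outside the dispersion")

    def level(x):
        return (1.0 / (1.0 + (1j * x) ** (1.0 - config.alpha))).real - target

    return brentq(level, 1e-6, 1e6)


def _cole_params_for(r50: float, fc_khz: float, config: SynthConfig) -> ColeParameters:
    return ColeParameters(
        r0=config.r0_r50_ratio * r50,
        rinf=config.rinf_r50_ratio * r50,
        fc_khz=fc_khz,
        alpha=config.alpha,
    )


def generate_cohort(config: SynthConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort (records, DXA references, spectra)."""
    config = config or SynthConfig()
    final = EQUATION_CATALOGUE["nipper_final"]
    a_ffm, c_sex = _ffm_intercepts(config)
    x_mult = _solve_fc_multiplier(config)
    fc_khz = 50.0 / x_mult
    freqs = np.logspace(
        math.log10(config.freq_min_khz),
        math.log10(config.freq_max_khz),
        config.n_frequencies,
    )
    corr = config.weight_height_corr

    records: list[ChildRecord] = []
    references: list[ReferenceMeasurement] = []
    spectra: dict[str, list[ImpedanceSpectrum]] = {}
    n_resampled = 0

    for i in range(config.n_children):
        rng = np.random.default_rng([config.seed, i])
        sex = _MALE if rng.random() < config.p_male else _FEMALE
        eth = 1 if rng.random() < config.p_asian else 0
        mh, sh = config.height_mean[sex], config.height_sd[sex]
        mw, sw = config.weight_mean[sex], config.weight_sd[sex]

        for attempt in range(config.max_resamples):
            height = rng.normal(mh, sh)
            weight = (
                mw
                + corr * sw / sh * (height - mh)
                + rng.normal(0.0, sw * math.sqrt(1.0 - corr**2))
            )
            ffm_true = (
                a_ffm
                + config.ffm_weight_slope * weight
                + c_sex * sex
                + config.ffm_ethnicity_coef * eth
                + rng.normal(0.0, config.ffm_resid_sd)
            )
            idx = (
                ffm_true
                - final["intercept"]
                - final["w"] * weight
                - final["s"] * sex
                - final["e"] * eth
            ) / final["idx"]
            if idx <= 0 or weight <= 5 or height <= 70:
                n_resampled += 1
                continue
            r50 = height**2 / idx
            dxa_ffm = ffm_true + rng.normal(0.0, config.dxa_noise_sd)
            dxa_weight = adjusted_weight(weight) + rng.normal(
                0.0, config.dxa_weight_noise_sd
            )
            dxa_fm = dxa_weight - dxa_ffm
            # non-physiological fat mass (preschool FM% is ~25 +/- 3.5) is
            # rejected along with out-of-band resistances
            if (
                config.r50_bounds[0] < r50 < config.r50_bounds[1]
                and dxa_fm > config.min_dxa_fm_kg
            ):
                break
            n_resampled += 1
        else:
            raise RuntimeError(
                f"child {i}: no admissible draw in {config.max_resamples} attempts"
            )

        age = rng.normal(config.age_mean_days, config.age_sd_days)
        gest = rng.normal(39.5, 1.5)
        bwz = rng.normal(0.33, 1.0)
        meal = int(rng.integers(0, 4))
        void = int(rng.integers(0, 4))
        kb = rng.normal(config.kb_mean, config.kb_sd)
        bmc = rng.normal(config.bmc_mean[sex], config.bmc_sd[sex])

        child_id = f"C{i:05d}"
        records.append(
            ChildRecord(
                child_id=child_id,
                sex=sex,
                ethnicity_asian=eth,
                age_days=float(age),
                weight_scale_kg=float(weight),
                height_cm=float(height),
                r50_ohm=float(r50),
                kb=float(kb),
                gestational_age_wk=float(gest),
                birthweight_z=float(bwz),
                meal_category=meal,
                void_category=void,
            )
        )
        references.append(
            ReferenceMeasurement(
                ffm_dxa_kg=float(dxa_ffm),
                fm_dxa_kg=float(dxa_fm),
                fm_pct=float(100.0 * dxa_fm / dxa_weight),
                lean_kg=float(dxa_ffm - bmc / 1000.0),
                bmc_g=float(bmc),
                weight_dxa_kg=float(dxa_weight),
            )
        )

        if config.generate_spectra:
            params = _cole_params_for(r50, fc_khz, config)
            z = cole_impedance(params, freqs)
            r_clean, x_clean = z.real, -z.imag
            reps = []
            for rep in range(1, config.n_replicates + 1):
                scale = 1.0 + rng.normal(0.0, config.replicate_cv)
                r_noise = 1.0 + rng.normal(0.0, config.point_noise_cv, freqs.size)
                x_noise = 1.0 + rng.normal(0.0, config.point_noise_cv, freqs.size)
                reps.append(
                    ImpedanceSpectrum(
                        frequencies_khz=freqs.copy(),
                        resistance_ohm=r_clean * scale * r_noise,
                        reactance_ohm=x_clean * scale * x_noise,
                        replicate_id=rep,
                    )
                )
            spectra[child_id] = reps

    return Cohort(
        records=records, references=references, spectra=spectra, n_resampled=n_resampled
    )


# ---------------------------------------------------------------------------
# Frames and file round trips


def to_frames(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(cohort, reference, spectra) DataFrames in the on-disk column layout."""
    rec_rows = []
    for r in cohort.records:
        rec_rows.append(
            {
                "child_id": r.child_id,
                "sex": r.sex,
                "ethnicity_asian": r.ethnicity_asian,
                "age_days": r.age_days,
                "weight_scale_kg": r.weight_scale_kg,
                "height_cm": r.height_cm,
                "r50_ohm": r.r50_ohm,
                "kb": r.kb,
                "gestational_age_wk": r.gestational_age_wk,
                "birthweight_z": r.birthweight_z,
                "meal_category": r.meal_category,
                "void_category": r.void_category,
            }
        )
    ref_rows = []
    for r, ref in zip(cohort.records, cohort.references):
        ref_rows.append(
            {
                "child_id": r.child_id,
                "ffm_dxa_kg": ref.ffm_dxa_kg,
                "fm_dxa_kg": ref.fm_dxa_kg,
                "fm_pct": ref.fm_pct,
                "lean_kg": ref.lean_kg,
                "bmc_g": ref.bmc_g,
                "weight_dxa_kg": ref.weight_dxa_kg,
            }
        )
    spectra_rows = []
    for child_id, reps in cohort.spectra.items():
        for sp in reps:
            spectra_rows.append(
                pd.DataFrame(
                    {
                        "child_id": child_id,
                        "replicate": sp.replicate_id,
                        "frequency_khz": sp.frequencies_khz,
                        "resistance_ohm": sp.resistance_ohm,
                        "reactance_ohm": sp.reactance_ohm,
                    }
                )
            )
    spectra_df = (
        pd.concat(spectra_rows, ignore_index=True)
        if spectra_rows
        else pd.DataFrame(
            columns=["child_id", "replicate", "frequency_khz", "resistance_ohm", "reactance_ohm"]
        )
    )
    cols = list(rec_rows[0]) if rec_rows else [
        "child_id", "sex", "ethnicity_asian", "age_days", "weight_scale_kg",
        "height_cm", "r50_ohm", "kb", "gestational_age_wk", "birthweight_z",
        "meal_category", "void_category",
    ]
    ref_cols = list(ref_rows[0]) if ref_rows else [
        "child_id", "ffm_dxa_kg", "fm_dxa_kg", "fm_pct", "lean_kg", "bmc_g", "weight_dxa_kg",
    ]
    return (
        pd.DataFrame(rec_rows, columns=cols),
        pd.DataFrame(ref_rows, columns=ref_cols),
        spectra_df,
    )


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write cohort.csv, reference.csv and spectra.csv; round-trips losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort_df, ref_df, spectra_df = to_frames(cohort)
    paths = {
        "cohort": directory / "cohort.csv",
        "reference": directory / "reference.csv",
        "spectra": directory / "spectra.csv",
    }
    # %.17g guarantees binary-exact float round trips through the CSVs
    cohort_df.to_csv(paths["cohort"], index=False, float_format="%.17g")
    ref_df.to_csv(paths["reference"], index=False, float_format="%.17g")
    spectra_df.to_csv(paths["spectra"], index=False, float_format="%.17g")
    return paths


def _opt(v):
    return None if pd.isna(v) else float(v)


def read_cohort(directory) -> Cohort:
    """Read the three CSVs written by :func:`write_cohort`."""
    directory = Path(directory)
    cohort_df = pd.read_csv(directory / "cohort.csv", float_precision="round_trip")
    ref_df = pd.read_csv(directory / "reference.csv", float_precision="round_trip")
    spectra_path = directory / "spectra.csv"
    records = [
        ChildRecord(
            child_id=str(row.child_id),
            sex=int(row.sex),
            ethnicity_asian=int(row.ethnicity_asian),
            age_days=float(row.age_days),
            weight_scale_kg=float(row.weight_scale_kg),
            height_cm=float(row.height_cm),
            r50_ohm=_opt(row.r50_ohm),
            kb=_opt(row.kb),
            gestational_age_wk=_opt(row.gestational_age_wk),
            birthweight_z=_opt(row.birthweight_z),
            meal_category=None if pd.isna(row.meal_category) else int(row.meal_category),
            void_category=None if pd.isna(row.void_category) else int(row.void_category),
        )
        for row in cohort_df.itertuples()
    ]
    references = [
        ReferenceMeasurement(
            ffm_dxa_kg=float(row.ffm_dxa_kg),
            fm_dxa_kg=float(row.fm_dxa_kg),
            fm_pct=_opt(row.fm_pct),
            lean_kg=_opt(row.lean_kg),
            bmc_g=_opt(row.bmc_g),
            weight_dxa_kg=_opt(row.weight_dxa_kg),
        )
        for row in ref_df.itertuples()
    ]
    spectra: dict[str, list[ImpedanceSpectrum]] = {}
    if spectra_path.exists():
        sdf = pd.read_csv(spectra_path, float_precision="round_trip")
        for (child_id, rep), grp in sdf.groupby(["child_id", "replicate"], sort=True):
            spectra.setdefault(str(child_id), []).append(
                ImpedanceSpectrum(
                    frequencies_khz=grp["frequency_khz"].to_numpy(),
                    resistance_ohm=grp["resistance_ohm"].to_numpy(),
                    reactance_ohm=grp["reactance_ohm"].to_numpy(),
                    replicate_id=int(rep),
                )
            )
    return Cohort(records=records, references=references, spectra=spectra)
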