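"""Cole-model representation and fitting of bioimpedance spectra.

Bioimpedance spectroscopy (BIS) measures the complex impedance of the body
over a wide frequency band (a few kHz to ~1 MHz).  At low frequency the
current is confined to the extracellular water; at high frequency it also
crosses cell membranes.  The locus of resistance versus (capacitive)
reactance is well described by the four-parameter Cole model

    Z(f) = R_inf + (R0 - R_inf) / (1 + (j f / fc)^(1 - alpha))

where ``R0`` and ``R_inf`` are the zero- and infinite-frequency resistances,
``fc`` is the characteristic frequency (the apex of the Cole semicircle) and
``alpha`` in [0, 1) broadens the dispersion (``alpha = 0`` gives an ideal
semicircle).  Everything downstream of the instrument works from the fitted
parameters: the resistance at 50 kHz ``R50`` feeds the empirical prediction
equations, and (R0, R_inf) feed mixture-theory body-water prediction.

Reactance is stored throughout as the *magnitude* of the capacitive
reactance, i.e. ``-Im Z``; instrument exports differ in sign convention and
this removes the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ImpedanceSpectrum",
    "ColeParameters",
    "ReplicateFit",
    "NonIdentifiableModelError",
    "ColeFitError",
    "cole_impedance",
    "fit_cole",
    "derived_quantities",
    "aggregate_replicates",
]

#: fit_rmse above this fraction of R0 raises the poor-fit quality flag
DEFAULT_RMSE_THRESHOLD_FRAC = 0.01


class NonIdentifiableModelError(ValueError):
    """The spectrum carries no dispersion information (e.g. zero reactance)."""


class ColeFitError(RuntimeError):
    """Optimiser failed to converge; ``diagnostics`` carries solver state."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ImpedanceSpectrum:
    """One replicate sweep: frequency (kHz), resistance and reactance (Ohm).

    Reactance is the magnitude of the capacitive reactance (non-negative).
    """

    frequencies_khz: np.ndarray
    resistance_ohm: np.ndarray
    reactance_ohm: np.ndarray
    replicate_id: int = 0
    side: str = "unknown"

    def __post_init__(self):
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.resistance_ohm = np.asarray(self.resistance_ohm, dtype=float)
        self.reactance_ohm = np.asarray(self.reactance_ohm, dtype=float)
        n = self.frequencies_khz.size
        if not (self.resistance_ohm.size == n == self.reactance_ohm.size):
            raise ValueError("frequency, resistance and reactance must have equal length")
        if n < 8:
            raise ValueError(f"need at least 8 frequencies, got {n}")
        if np.any(self.frequencies_khz <= 0):
            raise ValueError("all frequencies must be positive")
        if np.any(np.diff(self.frequencies_khz) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if np.any(self.resistance_ohm <= 0):
            raise ValueError("all resistance values must be positive")
        if np.any(self.reactance_ohm < 0):
            raise ValueError(
                "reactance must be stored as a non-negative capacitive magnitude"
            )
        if self.side not in ("left", "right", "unknown"):
            raise ValueError(f"side must be left|right|unknown, got {self.side!r}")

    def __len__(self) -> int:
        return self.frequencies_khz.size


@dataclass
class ColeParameters:
    """Fitted Cole parameters for one measurement (or replicate aggregate)."""

    r0: float
    rinf: float
    fc_khz: float
    alpha: float
    fit_rmse: float = 0.0
    quality_flag: bool = False

    def __post_init__(self):
        if not (0 < self.rinf < self.r0):
            raise ValueError(f"require 0 < rinf < r0, got rinf={self.rinf}, r0={self.r0}")
        if not (0 <= self.alpha < 1):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.fc_khz <= 0:
            raise ValueError(f"fc_khz must be positive, got {self.fc_khz}")
        if self.fit_rmse < 0:
            raise ValueError("fit_rmse must be non-negative")


@dataclass
class ReplicateFit:
    """Median-aggregated Cole fit over replicate sweeps."""

    params: ColeParameters
    r50_cv: float
    replicate_params: list[ColeParameters] = field(default_factory=list)


def cole_impedance(params: ColeParameters, frequency_khz) -> complex | np.ndarray:
    """Complex impedance of the Cole model at ``frequency_khz``.

    Vectorised over frequency.  The real part decreases monotonically from
    ``r0`` (f = 0) to ``rinf`` (f -> infinity); the imaginary part is
    capacitive (negative), maximal in magnitude at ``fc``.
    """
    f = np.asarray(frequency_khz, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    jw = (1j * f / params.fc_khz) ** (1.0 - params.alpha)
    z = params.rinf + (params.r0 - params.rinf) / (1.0 + jw)
    if np.ndim(frequency_khz) == 0:
        return complex(z)
    return z


def _model_rx(theta: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r0, rinf, fc, alpha = theta
    jw = (1j * f / fc) ** (1.0 - alpha)
    z = rinf + (r0 - rinf) / (1.0 + jw)
    return z.real, -z.imag


def fit_cole(
    spectrum: ImpedanceSpectrum,
    rmse_threshold_frac: float = DEFAULT_RMSE_THRESHOLD_FRAC,
) -> ColeParameters:
    """Least-squares fit of the Cole model to a measured spectrum.

    Minimises the summed squared deviation jointly over the real and
    imaginary parts (equal weights), i.e. the geometric misfit in the Cole
    plot.  ``fit_rmse`` is the root-mean-square modulus of the complex
    residual, in Ohm; fits with ``fit_rmse > rmse_threshold_frac * r0``
    carry ``quality_flag=True``.

    Raises
    ------
    NonIdentifiableModelError
        If the spectrum has (numerically) zero reactance everywhere, or no
        resistance dispersion: the four parameters are then not jointly
        identifiable.
    ColeFitError
        If the optimiser does not converge; diagnostics attached.
    """
    f = spectrum.frequencies_khz
    r = spectrum.resistance_ohm
    x = spectrum.reactance_ohm

    r_scale = float(np.median(r))
    if float(np.max(x)) < 1e-9 * r_scale:
        raise NonIdentifiableModelError(
            "reactance is zero at all frequencies; Cole dispersion not identifiable"
        )
    if float(np.ptp(r)) < 1e-12 * r_scale:
        raise NonIdentifiableModelError(
            "resistance is constant across frequency; R0 and Rinf not identifiable"
        )

    # Robust starting point on a semicircular locus.
    r0_init = float(np.max(r)) * 1.05
    rinf_init = float(np.min(r)) * 0.95
    fc_init = float(f[np.argmax(x)])
    theta0 = np.array([r0_init, rinf_init, fc_init, 0.1])

    def residuals(theta):
        rm, xm = _model_rx(theta, f)
        return np.concatenate([rm - r, xm - x])

    lb = np.array([1e-6, 1e-6, 1e-4, 0.0])
    ub = np.array([np.inf, np.inf, 1e6, 0.95])
    theta0 = np.clip(theta0, lb + 1e-9, None)
    result = least_squares(residuals, theta0, bounds=(lb, ub), method="trf")
    if not result.success:
        raise ColeFitError(
            "Cole fit did not converge",
            diagnostics={
                "status": result.status,
                "message": result.message,
                "cost": float(result.cost),
                "x": result.x.tolist(),
            },
        )
    r0, rinf, fc, alpha = result.x
    if not rinf < r0:
        raise ColeFitError(
            "fit collapsed to rinf >= r0",
            diagnostics={"x": result.x.tolist(), "cost": float(result.cost)},
        )
    res = residuals(result.x)
    n = len(spectrum)
    # RMS modulus of the complex residual: mean over frequencies of dR^2 + dX^2
    rmse = float(np.sqrt(np.sum(res**2) / n))
    return ColeParameters(
        r0=float(r0),
        rinf=float(rinf),
        fc_khz=float(fc),
        alpha=float(alpha),
        fit_rmse=rmse,
        quality_flag=bool(rmse > rmse_threshold_frac * r0),
    )


def derived_quantities(params: ColeParameters) -> tuple[float, float]:
    """(R50, Zc): resistance at 50 kHz and impedance modulus at fc."""
    r50 = cole_impedance(params, 50.0).real
    zc = abs(cole_impedance(params, params.fc_khz))
    return float(r50), float(zc)


def aggregate_replicates(
    spectra: Sequence[ImpedanceSpectrum],
    rmse_threshold_frac: float = DEFAULT_RMSE_THRESHOLD_FRAC,
) -> ReplicateFit:
    """Fit each replicate and combine by the parameter-wise median.

    Also reports the replicate coefficient of variation of R50 (SD/mean,
    n-1 denominator), the instrument-precision summary used for triplicate
    sweeps.  NaN when only one replicate is supplied.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("aggregate_replicates requires at least one spectrum")
    fits = [fit_cole(s, rmse_threshold_frac) for s in spectra]
    r50s = np.array([derived_quantities(p)[0] for p in fits])
    if len(fits) >= 2:
        r50_cv = float(np.std(r50s, ddof=1) / np.mean(r50s))
    else:
        r50_cv = float("nan")
    med = ColeParameters(
        r0=float(np.median([p.r0 for p in fits])),
        rinf=float(np.median([p.rinf for p in fits])),
        fc_khz=float(np.median([p.fc_khz for p in fits])),
        alpha=float(np.median([p.alpha for p in fits])),
        fit_rmse=float(np.median([p.fit_rmse for p in fits])),
    )
    med = replace(med, quality_flag=bool(med.fit_rmse > rmse_threshold_frac * med.r0))
    return ReplicateFit(params=med, r50_cv=r50_cv, replicate_params=fits)
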