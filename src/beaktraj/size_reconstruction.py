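"""Power-law allometry: beak crest/rostrum length -> mantle length -> mass.

Predictions of mantle length (ML) carry an additive bias correction equal
to the mean (observed - predicted) residual on the training pairs; the two
published regional models ship as presets with their printed corrections.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model_io import IndividualTrajectory


@dataclass
class AllometricModel:
    """ML = a * x**b (+ bias_correction_mm), x a beak length in mm."""

    coefficient_a: float
    exponent_b: float
    bias_correction_mm: float = 0.0
    predictor: str = "UCL"
    region_tag: str = ""
    n_fit: int = 0
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0 or self.exponent_b <= 0:
            raise ValueError("power-law coefficients must be positive")
        if not math.isnan(self.r_squared) and not 0 <= self.r_squared <= 1:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class MassModel:
    """mass_g = a_g * ML**b."""

    coefficient_a_g: float
    exponent_b: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.coefficient_a_g <= 0 or self.exponent_b <= 0:
            raise ValueError("mass-model coefficients must be positive")


# Published regional presets (crest-length predictor) with their additive
# mean-residual corrections.
PRESET_WEST_GREENLAND = AllometricModel(
    coefficient_a=3.25, exponent_b=1.40, bias_correction_mm=4.2,
    predictor="UCL", region_tag="West Greenland", n_fit=86, r_squared=0.95,
)
PRESET_ARCTIC = AllometricModel(
    coefficient_a=3.77, exponent_b=1.34, bias_correction_mm=3.3,
    predictor="UCL", region_tag="Arctic", n_fit=142, r_squared=0.93,
)

# Length-mass coefficients calibrated to two anchor points
# (ML 7.3 mm -> 0.033 g, ML 86.9 mm -> 20.8 g); the source equation's
# coefficients are not published, so this default is an approximation and
# is overridable in config.
_B_MASS = math.log(20.8 / 0.033) / math.log(86.9 / 7.3)
_A_MASS = 0.033 / 7.3 ** _B_MASS
DEFAULT_MASS_MODEL = MassModel(
    coefficient_a_g=_A_MASS, exponent_b=_B_MASS,
    source_tag="two-anchor calibration (approximate)",
)

PRESETS = {"west_greenland": PRESET_WEST_GREENLAND, "arctic": PRESET_ARCTIC}


def fit_power_law(
    x, y, method: str = "log-log", predictor: str = "UCL", region_tag: str = "",
) -> AllometricModel:
    """Fit ML = a * x**b by least squares.

    ``method='log-log'`` (default) linearises the power law and fits OLS on
    log-transformed pairs, the conventional allometric choice;
    ``method='nls'`` runs direct nonlinear least squares started from the
    log-log solution.  R^2 is computed on the fitted scale.  The additive
    bias correction is mean(y - y_hat) on the training pairs (raw scale).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power law undefined for non-positive values")

    ly = np.log(y)
    if np.allclose(ly, ly[0]):
        warnings.warn("constant response: slope undefined, R^2 = 0")

    lx = np.log(x)
    slope, intercept = np.polyfit(lx, ly, 1)
    a, b = float(np.exp(intercept)), float(slope)
    if b <= 0:
        raise ValueError(f"fitted exponent {b:.3g} is not positive")

    if method == "log-log":
        resid = ly - (intercept + slope * lx)
        sst = np.sum((ly - ly.mean()) ** 2)
        r2 = 0.0 if sst == 0 else 1.0 - float(np.sum(resid ** 2)) / float(sst)
    elif method == "nls":
        from scipy.optimize import curve_fit
        (a, b), _ = curve_fit(lambda t, a_, b_: a_ * t ** b_, x, y, p0=(a, b))
        a, b = float(a), float(b)
        resid = y - a * x ** b
        sst = np.sum((y - y.mean()) ** 2)
        r2 = 0.0 if sst == 0 else 1.0 - float(np.sum(resid ** 2)) / float(sst)
    else:
        raise ValueError(f"unknown method {method!r}")

    bias = float(np.mean(y - a * x ** b))
    return AllometricModel(
        coefficient_a=a, exponent_b=b, bias_correction_mm=bias,
        predictor=predictor, region_tag=region_tag,
        n_fit=int(x.size), r_squared=max(0.0, min(1.0, r2)),
    )


def predict_ml(model: AllometricModel, beak_length_mm, apply_correction: bool = True):
    """Mantle length (mm) from a beak length (mm); vectorised."""
    x = np.asarray(beak_length_mm, dtype=float)
    if np.any(x <= 0):
        raise ValueError("beak length must be positive")
    ml = model.coefficient_a * x ** model.exponent_b
    if apply_correction:
        ml = ml + model.bias_correction_mm
    return float(ml) if np.isscalar(beak_length_mm) else ml


def predict_mass(model: MassModel, ml_mm):
    """Body mass (g) from mantle length (mm); vectorised."""
    ml = np.asarray(ml_mm, dtype=float)
    if np.any(ml <= 0):
        raise ValueError("mantle length must be positive")
    mass = model.coefficient_a_g * ml ** model.exponent_b
    return float(mass) if np.isscalar(ml_mm) else mass


def size_at_subsections(
    traj: IndividualTrajectory,
    model: AllometricModel = PRESET_WEST_GREENLAND,
    mass_model: MassModel = DEFAULT_MASS_MODEL,
    anchor: str = "posterior_edge",
) -> list[tuple[int, float, float]]:
    """Estimated (subsection index, ML mm, mass g) at each subsection.

    ``anchor`` picks the crest coordinate representing a subsection: the
    posterior edge of the cut (default; newest material at that size) or
    the subsection midpoint for sensitivity analysis.
    """
    out = []
    for sub in traj.subsections:
        if sub.crest_start_mm is None or sub.crest_end_mm is None:
            raise ValueError(
                f"subsection {sub.index} of {traj.individual_id} has no crest "
                "coordinates; run build_subsection_grid/attach_grid first"
            )
        if anchor == "posterior_edge":
            x = sub.crest_end_mm
        elif anchor == "midpoint":
            x = 0.5 * (sub.crest_start_mm + sub.crest_end_mm)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        ml = predict_ml(model, x)
        out.append((sub.index, ml, predict_mass(mass_model, ml)))
    return out
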