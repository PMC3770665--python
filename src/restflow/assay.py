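"""Closed-form models for the wet-lab assays surrounding the flow experiment.

Two small calculations: the maximal wall shear stress generated by orbital
shaking of a culture plate, and relative qPCR quantification by the
2^(-ddCT) method.
"""
from __future__ import annotations

import dataclasses
import math

__all__ = ["ShearParams", "DdctInput", "estimate_max_shear", "ddct_fold_change"]


@dataclasses.dataclass(frozen=True)
class ShearParams:
    """Orbital-shaker parameters in bench units.

    Parameters
    ----------
    orbital_radius_cm : orbital radius ``a`` of the shaker platform, cm.
    dynamic_viscosity_poise : dynamic viscosity ``eta`` of the medium, poise
        (1 P = 0.1 Pa*s; water-like media are ~0.01 P).
    fluid_density_g_ml : fluid density ``rho``, g/ml.
    orbital_frequency_hz : rotation frequency ``f``, Hz.
    """

    orbital_radius_cm: float
    dynamic_viscosity_poise: float
    fluid_density_g_ml: float
    orbital_frequency_hz: float

    def __post_init__(self) -> None:
        for name in (
            "orbital_radius_cm",
            "dynamic_viscosity_poise",
            "fluid_density_g_ml",
            "orbital_frequency_hz",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value!r}")
            if name != "orbital_radius_cm" and value == 0:
                raise ValueError(f"{name} must be positive, got {value!r}")


@dataclasses.dataclass(frozen=True)
class DdctInput:
    """Cycle-threshold quadruple for relative quantification.

    CT values for the target and housekeeping gene under the treated and
    control conditions.  All values are PCR cycle numbers (dimensionless).
    """

    ct_target_treated: float
    ct_housekeeping_treated: float
    ct_target_control: float
    ct_housekeeping_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_treated",
            "ct_housekeeping_treated",
            "ct_target_control",
            "ct_housekeeping_control",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and positive, got {value!r}")


def estimate_max_shear(params: ShearParams) -> float:
    """Maximal wall shear stress for an orbitally shaken well, in Pa.

    Uses the first-order relation ``tau = a * sqrt(rho * eta * (2*pi*f)^3)``
    with all quantities converted to SI before evaluation.  The relation
    ignores fluid height and well radius, so it brackets rather than
    predicts the true peak shear; it is homogeneous of degree one in ``a``
    and scales as ``f**1.5``.
    """
    a_m = params.orbital_radius_cm * 1e-2
    eta_pa_s = params.dynamic_viscosity_poise * 0.1
    rho_kg_m3 = params.fluid_density_g_ml * 1000.0
    omega = 2.0 * math.pi * params.orbital_frequency_hz
    return a_m * math.sqrt(rho_kg_m3 * eta_pa_s * omega**3)


def ddct_fold_change(inputs: DdctInput) -> float:
    """Relative expression fold change by the 2^(-ddCT) method.

    ``dCT`` normalises the target to the housekeeping gene within each
    condition; ``ddCT`` contrasts treated against control.  A one-cycle
    advantage (ddCT = -1) corresponds to a two-fold increase.  Swapping the
    treated and control conditions returns the reciprocal.
    """
    dct_treated = inputs.ct_target_treated - inputs.ct_housekeeping_treated
    dct_control = inputs.ct_target_control - inputs.ct_housekeeping_control
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))
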