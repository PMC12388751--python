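"""Neumann equation-of-state numerics for solid–liquid interfacial energy.

The one-parameter equation of state relates the contact angle θ of a liquid
of surface tension γ_L on a solid of surface energy γ_S:

    cos θ + 1 = 2·sqrt(γ_S/γ_L)·exp(−β·(γ_L − γ_S)²)

with β an empirical constant (default 0.000115 (m²/mJ)², validated for
low-energy non-metallic solids). Used in two directions:

* invert it on a measured deionized-water contact angle to solve the solid
  surface energy γ_S (``solve_solid_surface_energy``);
* evaluate it forward to predict the wettability factor (cos θ + 1) of an
  ATPS phase on the solid (``wettability_factor``), then obtain the
  solid–liquid interfacial energy from Young's equation
  γ_SL = γ_L + γ_S − (cos θ + 1)·γ_L (``interfacial_energy``).

The predicted wettability factor may exceed 2 (cos θ > 1): that is the
equation of state's way of signalling complete wetting. The factor is fed
into Young's equation *unclamped* — the resulting small positive γ_SL is the
quantity the downstream partitioning model uses — and flagged on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby
from typing import Optional, Sequence

from scipy.optimize import brentq

from .data_model import (
    EOSParameters,
    GroupSummary,
    LiquidPhase,
    SolidSurface,
    summarize_group,
)

#: residual tolerance for the surface-energy solver
SOLVER_TOL = 1e-9


@dataclass(frozen=True)
class WettabilityResult:
    """Predicted wettability of a liquid on a solid.

    ``factor`` is cos θ + 1; ``complete_wetting`` is set when the factor
    exceeds 2 (the implied cos θ is unphysical and the liquid is predicted to
    spread completely); ``implied_contact_angle`` (degrees) is defined only
    when the factor is at most 2.
    """

    factor: float
    complete_wetting: bool
    implied_contact_angle: Optional[float]


@dataclass(frozen=True)
class InterfacialEnergyRecord:
    """Solid–liquid interfacial energy for one (solid, phase) pair, mJ/m²."""

    solid_label: str
    phenotype: str
    phase_name: str
    concentration: float
    gamma_sl: float
    complete_wetting: bool


def _check_energies(gamma_s: float, gamma_l: float, beta: float) -> None:
    if gamma_s <= 0:
        raise ValueError(f"solid surface energy must be > 0, got {gamma_s}")
    if gamma_l <= 0:
        raise ValueError(f"liquid surface tension must be > 0, got {gamma_l}")
    if beta <= 0:
        raise ValueError(f"beta must be > 0, got {beta}")


def wettability_factor(gamma_s: float, gamma_l: float, beta: float = 0.000115) -> WettabilityResult:
    """Predict the wettability factor cos θ + 1 of a liquid on a solid.

    Parameters are in mJ/m² (γ) and (m²/mJ)² (β). The factor is not clamped;
    values above 2 set the ``complete_wetting`` flag.
    """
    _check_energies(gamma_s, gamma_l, beta)
    factor = 2.0 * math.sqrt(gamma_s / gamma_l) * math.exp(-beta * (gamma_l - gamma_s) ** 2)
    complete = factor > 2.0
    angle = None
    if not complete:
        angle = math.degrees(math.acos(factor - 1.0))
    return WettabilityResult(factor=factor, complete_wetting=complete, implied_contact_angle=angle)


def interfacial_energy(gamma_s: float, gamma_l: float, beta: float = 0.000115) -> float:
    """Solid–liquid interfacial energy γ_SL in mJ/m² via Young's equation.

    γ_SL = γ_L + γ_S − (cos θ + 1)·γ_L with the equation-of-state wettability
    factor, which collapses to the closed form
    γ_L + γ_S − 2·sqrt(γ_L·γ_S)·exp(−β(γ_L−γ_S)²). Non-negative for all
    positive inputs (AM–GM plus exp ≤ 1), zero iff γ_S = γ_L.
    """
    w = wettability_factor(gamma_s, gamma_l, beta)
    return gamma_l + gamma_s - w.factor * gamma_l


def solve_solid_surface_energy(
    theta_deg: float, gamma_l: float, beta: float = 0.000115
) -> float:
    """Solve the solid surface energy γ_S from a measured contact angle.

    Inverts the equation of state on the monotone branch γ_S ∈ (0, γ_L] by
    bracketed root finding (Brent); a contact angle above 0° forces
    γ_S < γ_L, so roots above γ_L are excluded. Converges the residual on the
    wettability factor below 1e-9.
    """
    if not (0 < theta_deg < 180):
        raise ValueError(f"contact angle must be in (0, 180) degrees, got {theta_deg}")
    if gamma_l <= 0:
        raise ValueError(f"liquid surface tension must be > 0, got {gamma_l}")
    target = math.cos(math.radians(theta_deg)) + 1.0

    def residual(gs: float) -> float:
        return wettability_factor(gs, gamma_l, beta).factor - target

    lo, hi = 0.5, gamma_l
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo * r_hi > 0:
        raise ValueError(
            f"no sign change on bracket [{lo}, {hi}] "
            f"(residuals {r_lo:.3g}, {r_hi:.3g}); contact angle {theta_deg}° "
            f"may be outside the solvable range for gamma_l={gamma_l}"
        )
    return float(brentq(residual, lo, hi, xtol=SOLVER_TOL, rtol=8.9e-16))


def interfacial_energy_table(
    solids: Sequence[SolidSurface],
    phases: Sequence[LiquidPhase],
    params: EOSParameters | None = None,
) -> tuple[list[InterfacialEnergyRecord], list[GroupSummary]]:
    """Interfacial energies for every (solid, phase) pair plus group summaries.

    Solids lacking a surface energy are solved from their deionized-water
    contact angle first; a solid with neither is an error. Group summaries
    aggregate per (phase, phenotype, concentration) with sample SD, matching
    how donor variability is reported.
    """
    params = params or EOSParameters()
    records: list[InterfacialEnergyRecord] = []
    for solid in solids:
        gs = solid.surface_energy
        if gs is None:
            if solid.contact_angle_diw is None:
                raise ValueError(
                    f"solid {solid.label!r} has neither surface_energy nor contact_angle_diw"
                )
            gs = solve_solid_surface_energy(solid.contact_angle_diw, params.gamma_diw, params.beta)
        for phase in phases:
            w = wettability_factor(gs, phase.surface_tension, params.beta)
            gsl = phase.surface_tension + gs - w.factor * phase.surface_tension
            records.append(
                InterfacialEnergyRecord(
                    solid_label=solid.label,
                    phenotype=solid.phenotype.value,
                    phase_name=phase.name,
                    concentration=phase.concentration,
                    gamma_sl=gsl,
                    complete_wetting=w.complete_wetting,
                )
            )

    def group_key(r: InterfacialEnergyRecord) -> tuple[str, str, float]:
        return (r.phase_name, r.phenotype, r.concentration)

    summaries = [
        summarize_group(
            [r.gamma_sl for r in members],
            label=f"{key[0]}—{key[1]} {key[2]:g}%",
        )
        for key, members in (
            (k, list(g)) for k, g in groupby(sorted(records, key=group_key), key=group_key)
        )
    ]
    return records, summaries
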