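"""Energy-balance model of cell translocation across the ATPS interface.

A cell sitting at the PEG–Dex interface is driven into the phase where its
interfacial energy is lower. The driving energy released by moving a cell of
radius R fully into the preferred phase is

    E_driving = 2π·R²·|Δγ|,      Δγ = γ_PEG−cell − γ_Dex−cell,

and is dissipated by Stokes drag over the full translocation distance 2R at a
constant terminal velocity v:

    E_dissipation = 6π·R·μ_avg·v · 2R,    μ_avg = (μ_PEG + μ_Dex)/2.

Balancing the two gives v = |Δγ|/(6·μ_avg) and the partitioning time

    τ_p = 2R/v = 12·μ_avg·R/|Δγ|.

Sign convention: Δγ is kept signed for phase preference (negative → PEG
preferred, positive → Dex preferred); τ_p and the energies use |Δγ| since a
time must be positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .data_model import (
    EOSParameters,
    LiquidPhase,
    Phenotype,
    SolidSurface,
)
from .neumann_eos import interfacial_energy, solve_solid_surface_energy

MJ_PER_M2_TO_J_PER_M2 = 1e-3


@dataclass(frozen=True)
class PartitionResult:
    """Full translocation-dynamics result for one cell in one ATPS pair."""

    delta_gamma: float  # mJ/m², signed (γ_PEG−cell − γ_Dex−cell)
    preferred_phase: str  # "PEG" | "Dex" | "indifferent"
    mu_avg: float  # Pa·s
    terminal_velocity: float  # m/s
    tau_p: float  # s
    driving_energy: float  # J
    dissipation_energy: float  # J


@dataclass(frozen=True)
class TauPSummary:
    """Group statistics of partitioning times, one row per (phenotype, condition)."""

    phenotype: str
    condition: str
    tau_p_values: tuple[float, ...]  # s
    mean: float
    sd: Optional[float]  # absent for n = 1
    sem: Optional[float]  # sd / sqrt(n), absent for n = 1


def phase_preference(gamma_peg_cell: float, gamma_dex_cell: float) -> tuple[float, str]:
    """Signed interfacial-energy difference and the preferred phase.

    The cell partitions into whichever phase minimizes its interfacial
    energy: Δγ < 0 → PEG, Δγ > 0 → Dex, Δγ = 0 → indifferent.
    """
    if gamma_peg_cell < 0 or gamma_dex_cell < 0:
        raise ValueError("interfacial energies must be >= 0")
    delta = gamma_peg_cell - gamma_dex_cell
    if delta < 0:
        return delta, "PEG"
    if delta > 0:
        return delta, "Dex"
    return 0.0, "indifferent"


def driving_energy(radius: float, delta_gamma: float) -> float:
    """Interfacial driving energy 2π·R²·|Δγ| in joules (Δγ given in mJ/m²)."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    return 2.0 * math.pi * radius**2 * abs(delta_gamma) * MJ_PER_M2_TO_J_PER_M2


def dissipation_energy(radius: float, mu_avg: float, velocity: float) -> float:
    """Stokes-drag work 6π·R·μ_avg·v × 2R over the full translocation, in joules."""
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if mu_avg <= 0:
        raise ValueError(f"viscosity must be > 0, got {mu_avg}")
    if velocity < 0:
        raise ValueError(f"velocity must be >= 0, got {velocity}")
    return 6.0 * math.pi * radius * mu_avg * velocity * 2.0 * radius


def terminal_velocity(delta_gamma: float, mu_peg: float, mu_dex: float) -> tuple[float, float]:
    """Average viscosity (μ_PEG + μ_Dex)/2 and terminal velocity |Δγ|/(6·μ_avg).

    Δγ in mJ/m², viscosities in Pa·s; returns (μ_avg in Pa·s, v in m/s).
    """
    if mu_peg <= 0 or mu_dex <= 0:
        raise ValueError("both phase viscosities must be > 0")
    mu_avg = 0.5 * (mu_peg + mu_dex)
    v = abs(delta_gamma) * MJ_PER_M2_TO_J_PER_M2 / (6.0 * mu_avg)
    return mu_avg, v


def partitioning_time(
    radius: float, delta_gamma: float, mu_peg: float, mu_dex: float
) -> PartitionResult:
    """Partitioning time τ_p = 12·μ_avg·R/|Δγ| with the full energy bookkeeping.

    Raises on Δγ = 0: an indifferent cell never leaves the interface, so the
    translocation time is infinite.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if delta_gamma == 0:
        raise ValueError("delta_gamma = 0: cell is indifferent, partitioning time is infinite")
    preferred = "PEG" if delta_gamma < 0 else "Dex"
    mu_avg, v = terminal_velocity(delta_gamma, mu_peg, mu_dex)
    tau = 12.0 * mu_avg * radius / (abs(delta_gamma) * MJ_PER_M2_TO_J_PER_M2)
    e_drive = driving_energy(radius, delta_gamma)
    e_diss = dissipation_energy(radius, mu_avg, v)
    return PartitionResult(
        delta_gamma=delta_gamma,
        preferred_phase=preferred,
        mu_avg=mu_avg,
        terminal_velocity=v,
        tau_p=tau,
        driving_energy=e_drive,
        dissipation_energy=e_diss,
    )


def tau_p_by_group(
    solids: Sequence[SolidSurface],
    atps: tuple[LiquidPhase, LiquidPhase],
    params: EOSParameters | None = None,
) -> list[TauPSummary]:
    """Per-phenotype partitioning-time statistics for one ATPS condition.

    Runs the full chain per solid — surface energy (solved from the contact
    angle if not given) → interfacial energy in each phase → Δγ → τ_p — then
    aggregates mean, sample SD and SEM per phenotype. Solids must carry radii
    and both phases viscosities.
    """
    params = params or EOSParameters()
    peg, dex = atps
    if {peg.name, dex.name} != {"PEG", "Dex"}:
        raise ValueError("atps must be one PEG and one Dex phase")
    if peg.name == "Dex":
        peg, dex = dex, peg
    if peg.viscosity is None or dex.viscosity is None:
        raise ValueError("both phases need a viscosity for partitioning dynamics")

    by_phenotype: dict[str, list[float]] = {}
    for solid in solids:
        if solid.radius is None:
            raise ValueError(f"solid {solid.label!r} lacks a radius")
        gs = solid.surface_energy
        if gs is None:
            if solid.contact_angle_diw is None:
                raise ValueError(
                    f"solid {solid.label!r} has neither surface_energy nor contact_angle_diw"
                )
            gs = solve_solid_surface_energy(solid.contact_angle_diw, params.gamma_diw, params.beta)
        g_peg = interfacial_energy(gs, peg.surface_tension, params.beta)
        g_dex = interfacial_energy(gs, dex.surface_tension, params.beta)
        delta, _ = phase_preference(g_peg, g_dex)
        result = partitioning_time(solid.radius, delta, peg.viscosity, dex.viscosity)
        by_phenotype.setdefault(solid.phenotype.value, []).append(result.tau_p)

    condition = f"{peg.concentration:g}% PEG / {dex.concentration:g}% Dex"
    summaries = []
    for phenotype, taus in by_phenotype.items():
        n = len(taus)
        mean = sum(taus) / n
        sd = sem = None
        if n >= 2:
            sd = math.sqrt(sum((t - mean) ** 2 for t in taus) / (n - 1))
            sem = sd / math.sqrt(n)
        summaries.append(
            TauPSummary(
                phenotype=phenotype,
                condition=condition,
                tau_p_values=tuple(taus),
                mean=mean,
                sd=sd,
                sem=sem,
            )
        )
    return summaries


def propagate_delta_gamma_uncertainty(
    per_donor_peg: Sequence[float],
    per_donor_dex: Sequence[float],
    mode: str = "paired",
) -> tuple[float, float]:
    """Mean and spread of the interfacial-energy difference across donors.

    Default ``paired`` mode computes Δγ per donor (lists paired by position,
    i.e. by donor id) and returns the mean and sample SD of those
    differences. ``quadrature`` instead combines the two groups' SDs as
    sqrt(sd_PEG² + sd_Dex²) around the difference of means.
    """
    if len(per_donor_peg) != len(per_donor_dex):
        raise ValueError(
            f"donor lists must be paired: {len(per_donor_peg)} vs {len(per_donor_dex)}"
        )
    n = len(per_donor_peg)
    if n == 0:
        raise ValueError("donor lists are empty")
    if mode == "paired":
        deltas = [p - d for p, d in zip(per_donor_peg, per_donor_dex)]
        mean = sum(deltas) / n
        sd = 0.0
        if n >= 2:
            sd = math.sqrt(sum((x - mean) ** 2 for x in deltas) / (n - 1))
        return mean, sd
    if mode == "quadrature":
        mean_p = sum(per_donor_peg) / n
        mean_d = sum(per_donor_dex) / n
        if n < 2:
            return mean_p - mean_d, 0.0
        sd_p = math.sqrt(sum((x - mean_p) ** 2 for x in per_donor_peg) / (n - 1))
        sd_d = math.sqrt(sum((x - mean_d) ** 2 for x in per_donor_dex) / (n - 1))
        return mean_p - mean_d, math.hypot(sd_p, sd_d)
    raise ValueError(f"unknown mode {mode!r}; use 'paired' or 'quadrature'")
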