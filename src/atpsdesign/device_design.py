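"""Residence-time design of a continuous-flow microfluidic ATPS channel.

Under plug flow (cells move at the fluid velocity) the residence time of a
cell in a rectangular channel is channel volume over volumetric flow rate:

    t_res ≈ L·A/Q,   A = width·depth.

Separation by partitioning time places t_res between the two populations'
τ_p values: the fast population (τ_p ≤ t_res) fully translocates into its
preferred phase before exiting, the slow one is still bound at the interface.
No laminar velocity profile or interface-position modelling is attempted —
the plug-flow approximation is the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, field_validator

ML_PER_MIN_TO_M3_PER_S = 1e-6 / 60.0


class DeviceGeometry(BaseModel):
    """Rectangular microchannel: length, width, depth in metres."""

    model_config = ConfigDict(frozen=True)

    length: float  # L, m
    width: float  # m
    depth: float  # m

    @field_validator("length", "width", "depth")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"dimension must be > 0, got {v}")
        return v

    @property
    def cross_section_area(self) -> float:
        return self.width * self.depth


@dataclass(frozen=True)
class SeparationPlan:
    """A residence-time window placed between two partitioning times."""

    geometry: DeviceGeometry
    flow_rate: float  # Q, m³/s
    residence_time: float  # s
    tau_fast: float  # s
    tau_slow: float  # s
    outcome_fast: str  # "partitioned_to_preferred_phase"
    outcome_slow: str  # "retained_at_interface"
    margin_fast: float  # residence / tau_fast, > 1
    margin_slow: float  # tau_slow / residence, > 1


def residence_time(geometry: DeviceGeometry, flow_rate: float) -> float:
    """Plug-flow residence time L·A/Q in seconds (Q in m³/s)."""
    if flow_rate <= 0:
        raise ValueError(f"flow rate must be > 0, got {flow_rate}")
    return geometry.length * geometry.cross_section_area / flow_rate


def design_flow_rate(geometry: DeviceGeometry, target_residence: float) -> float:
    """Flow rate (m³/s) that yields the target residence time in this geometry."""
    if target_residence <= 0:
        raise ValueError(f"target residence time must be > 0, got {target_residence}")
    return geometry.length * geometry.cross_section_area / target_residence


def classify(tau_p: float, residence: float) -> str:
    """Outcome of one population: partitioned iff τ_p ≤ residence time.

    The boundary tie τ_p = t_res counts as partitioned (closed on the fast
    side), applied uniformly in all reports.
    """
    return "partitioned_to_preferred_phase" if tau_p <= residence else "retained_at_interface"


def plan_separation(tau_fast: float, tau_slow: float, geometry: DeviceGeometry) -> SeparationPlan:
    """Design a flow rate that separates two populations by partitioning time.

    The target residence time is the geometric mean sqrt(τ_fast·τ_slow),
    which maximizes the smaller of the two relative safety margins. Requires
    0 < τ_fast < τ_slow; equal times leave no separation window.
    """
    if tau_fast <= 0 or tau_slow <= 0:
        raise ValueError("partitioning times must be > 0")
    if tau_fast >= tau_slow:
        raise ValueError(
            f"no separation window: tau_fast ({tau_fast}) must be < tau_slow ({tau_slow})"
        )
    target = math.sqrt(tau_fast * tau_slow)
    q = design_flow_rate(geometry, target)
    t_res = residence_time(geometry, q)
    return SeparationPlan(
        geometry=geometry,
        flow_rate=q,
        residence_time=t_res,
        tau_fast=tau_fast,
        tau_slow=tau_slow,
        outcome_fast=classify(tau_fast, t_res),
        outcome_slow=classify(tau_slow, t_res),
        margin_fast=t_res / tau_fast,
        margin_slow=tau_slow / t_res,
    )
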