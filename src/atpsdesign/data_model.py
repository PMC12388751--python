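"""Validated domain types, unit conventions, built-in fixtures and tabular I/O.

Internal unit convention (conversion happens only at I/O boundaries):

* surface energy / surface tension: mJ/m² (numerically equal to mN/m)
* dynamic viscosity: Pa·s
* length: metres
* time: seconds
* contact angle: degrees

The Neumann empirical constant ``beta`` carries units of (m²/mJ)², which makes
mJ/m² the natural working unit for the equation of state.
"""

from __future__ import annotations

import enum
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Phenotype(str, enum.Enum):
    """Sample phenotype labels used for grouping."""

    HEALTHY_HCH = "healthy_hCh"
    OA_HCH = "OA_hCh"
    PARTICLE = "particle"
    OTHER = "other"


class LiquidPhase(BaseModel):
    """One ATPS phase solution (e.g. PEG or Dex at a given w/v% concentration).

    ``surface_tension`` is γ_L in mJ/m²; ``viscosity`` is μ in Pa·s and may be
    left unset until translocation dynamics are computed.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    concentration: float  # w/v %, e.g. 10.0
    surface_tension: float  # γL, mJ/m²
    viscosity: Optional[float] = None  # μ, Pa·s

    @field_validator("surface_tension")
    @classmethod
    def _positive_tension(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"surface_tension must be > 0, got {v}")
        return v

    @field_validator("viscosity")
    @classmethod
    def _positive_viscosity(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError(f"viscosity must be > 0, got {v}")
        return v

    @field_validator("concentration")
    @classmethod
    def _nonnegative_concentration(cls, v: float) -> float:
        if v < 0:
            raise ValueError(f"concentration must be >= 0, got {v}")
        return v

    @property
    def key(self) -> str:
        return f"{self.name} {self.concentration:g}%"


class SolidSurface(BaseModel):
    """One cell or particle sample (a donor's chondrocyte layer, a bead layer).

    Either a measured deionized-water contact angle or an already-solved
    surface energy may be supplied; the radius is only needed for dynamics.
    """

    label: str
    phenotype: Phenotype = Phenotype.OTHER
    contact_angle_diw: Optional[float] = None  # θ_DIW, degrees
    surface_energy: Optional[float] = None  # γS, mJ/m²
    radius: Optional[float] = None  # R, metres

    @field_validator("contact_angle_diw")
    @classmethod
    def _angle_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0 < v < 180):
            raise ValueError(f"contact_angle_diw must be in (0, 180) degrees, got {v}")
        return v

    @field_validator("surface_energy")
    @classmethod
    def _positive_energy(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError(f"surface_energy must be > 0, got {v}")
        return v

    @field_validator("radius")
    @classmethod
    def _positive_radius(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v <= 0:
            raise ValueError(f"radius must be > 0, got {v}")
        return v


class EOSParameters(BaseModel):
    """Neumann equation-of-state parameters.

    ``beta`` is the universal empirical constant 0.000115 (m²/mJ)² validated
    for low-energy non-metallic solids; ``gamma_diw`` is the probe-liquid
    (deionized water) surface tension in mJ/m².
    """

    model_config = ConfigDict(frozen=True)

    beta: float = 0.000115  # (m²/mJ)²
    gamma_diw: float = 72.0  # mJ/m²

    @field_validator("beta", "gamma_diw")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError(f"parameter must be > 0, got {v}")
        return v


class GroupSummary(BaseModel):
    """Per-group aggregate: mean and sample SD (ddof=1) over member values."""

    label: str
    values: list[float]
    mean: float
    sd: Optional[float] = None  # absent for n = 1
    n: int

    @model_validator(mode="after")
    def _mean_within_range(self) -> "GroupSummary":
        if self.n < 1:
            raise ValueError("group must have at least one member")
        lo, hi = min(self.values), max(self.values)
        if not (lo - 1e-12 <= self.mean <= hi + 1e-12):
            raise ValueError("mean outside [min, max] of members")
        return self


def summarize_group(values: Sequence[float], label: str) -> GroupSummary:
    """Arithmetic mean and sample standard deviation (ddof=1) of a group.

    The SD is absent for single-member groups, matching how donor-to-donor
    variability is reported.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError(f"cannot summarize empty group {label!r}")
    n = len(vals)
    mean = sum(vals) / n
    sd = None
    if n >= 2:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    return GroupSummary(label=label, values=vals, mean=mean, sd=sd, n=n)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

QUANTITY_KINDS = frozenset({"contact_angle", "surface_tension", "viscosity", "radius"})

#: canonical unit per quantity kind
CANONICAL_UNITS = {
    "contact_angle": "deg",
    "surface_tension": "mJ/m^2",
    "viscosity": "Pa.s",
    "radius": "m",
}

#: multiplicative conversion to the canonical unit, keyed (kind, unit alias)
_UNIT_FACTORS = {
    ("contact_angle", "deg"): 1.0,
    ("contact_angle", "degree"): 1.0,
    ("contact_angle", "degrees"): 1.0,
    ("surface_tension", "mJ/m^2"): 1.0,
    ("surface_tension", "mJ/m2"): 1.0,
    ("surface_tension", "mN/m"): 1.0,  # numerically identical
    ("surface_tension", "N/m"): 1e3,
    ("surface_tension", "J/m^2"): 1e3,
    ("viscosity", "Pa.s"): 1.0,
    ("viscosity", "Pa*s"): 1.0,
    ("viscosity", "Pa s"): 1.0,
    ("viscosity", "mPa.s"): 1e-3,
    ("viscosity", "cP"): 1e-3,
    ("radius", "m"): 1.0,
    ("radius", "um"): 1e-6,
    ("radius", "µm"): 1e-6,
    ("radius", "mm"): 1e-3,
    ("radius", "nm"): 1e-9,
}

MEASUREMENT_COLUMNS = ["label", "kind", "value", "unit", "replicate"]


class MeasurementTable:
    """A validated long-format measurement table.

    Rows are (label, kind, value, unit, replicate); values are normalized to
    the internal unit convention on construction. ``provenance`` records where
    the table came from: ``fixture``, ``user`` or ``synthetic``.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "user"):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"measurement table missing column(s): {', '.join(missing)}")
        if provenance not in {"fixture", "user", "synthetic"}:
            raise ValueError(f"unknown provenance {provenance!r}")
        frame = frame[MEASUREMENT_COLUMNS].copy()
        frame["value"] = frame["value"].astype(float)
        bad_kind = set(frame["kind"]) - QUANTITY_KINDS
        if bad_kind:
            raise ValueError(f"unknown quantity kind(s): {sorted(bad_kind)}")
        for i, row in frame.iterrows():
            key = (row["kind"], str(row["unit"]))
            if key not in _UNIT_FACTORS:
                raise ValueError(
                    f"row {i}: unknown unit {row['unit']!r} for kind {row['kind']!r}"
                )
            frame.at[i, "value"] = row["value"] * _UNIT_FACTORS[key]
            frame.at[i, "unit"] = CANONICAL_UNITS[row["kind"]]
        neg = frame[frame["value"] < 0]
        if not neg.empty:
            i = neg.index[0]
            raise ValueError(
                f"row {i}: negative value {neg.at[i, 'value']} for "
                f"kind {neg.at[i, 'kind']!r} (label {neg.at[i, 'label']!r})"
            )
        self.frame = frame.reset_index(drop=True)
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        return self.provenance == other.provenance and self.frame.equals(other.frame)

    def values_for(self, label: str, kind: str) -> list[float]:
        sel = self.frame[(self.frame["label"] == label) & (self.frame["kind"] == kind)]
        return sel["value"].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def load_measurements(path: str | Path, provenance: str = "user") -> MeasurementTable:
    """Read a long-format CSV (label, kind, value, unit, replicate) and validate it.

    Values are converted to the internal units; schema or invariant violations
    raise ``ValueError`` naming the offending column or row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    return MeasurementTable(frame, provenance=provenance)


# ---------------------------------------------------------------------------
# Built-in fixtures: measured ATPS tensions and solved solid surface energies
# ---------------------------------------------------------------------------

#: pendant-drop surface tensions of the ATPS stock solutions, mJ/m²
PEG_SURFACE_TENSIONS = {5.0: 60.00, 10.0: 58.99, 15.0: 58.71, 20.0: 58.12}
DEX_SURFACE_TENSIONS = {5.0: 70.13, 10.0: 70.88, 15.0: 70.20, 20.0: 69.99}

#: solved solid surface energies of the reference cell models, mJ/m²
SOLID_SURFACE_ENERGIES = {
    "Healthy hChs Donor 1": (Phenotype.HEALTHY_HCH, 26.75),
    "Healthy hChs Donor 2": (Phenotype.HEALTHY_HCH, 33.06),
    "Healthy hChs Donor 3": (Phenotype.HEALTHY_HCH, 27.22),
    "OA hChs Donor 1": (Phenotype.OA_HCH, 18.06),
    "OA hChs Donor 2": (Phenotype.OA_HCH, 9.01),
    "OA hChs Donor 3": (Phenotype.OA_HCH, 9.78),
    "Carboxylated PS Microparticles": (Phenotype.PARTICLE, 65.93),
}


def builtin_fixtures() -> tuple[MeasurementTable, list[SolidSurface], EOSParameters]:
    """Built-in reference dataset: ATPS phase tensions, solid surface energies, EOS constants.

    Returns a surface-tension MeasurementTable (labels like ``"PEG 10%"``),
    the list of reference SolidSurface records (three healthy chondrocyte
    donors, three osteoarthritic donors, one carboxylated polystyrene bead
    sample), and the default EOSParameters.
    """
    rows = []
    for name, table in (("PEG", PEG_SURFACE_TENSIONS), ("Dex", DEX_SURFACE_TENSIONS)):
        for conc, gamma in table.items():
            rows.append(
                {
                    "label": f"{name} {conc:g}%",
                    "kind": "surface_tension",
                    "value": gamma,
                    "unit": "mJ/m^2",
                    "replicate": 1,
                }
            )
    tensions = MeasurementTable(pd.DataFrame(rows), provenance="fixture")
    solids = [
        SolidSurface(label=label, phenotype=ph, surface_energy=gs)
        for label, (ph, gs) in SOLID_SURFACE_ENERGIES.items()
    ]
    return tensions, solids, EOSParameters()


def fixture_phases(
    concentrations: Sequence[float] = (10.0, 15.0, 20.0),
    viscosities: Optional[dict[tuple[str, float], float]] = None,
) -> list[LiquidPhase]:
    """LiquidPhase records for the fixture PEG/Dex tensions at the given concentrations.

    ``viscosities`` optionally maps ("PEG", 10.0)-style keys to Pa·s values.
    """
    phases = []
    for name, table in (("PEG", PEG_SURFACE_TENSIONS), ("Dex", DEX_SURFACE_TENSIONS)):
        for conc in concentrations:
            if conc not in table:
                raise KeyError(f"no fixture tension for {name} at {conc:g}%")
            mu = (viscosities or {}).get((name, conc))
            phases.append(
                LiquidPhase(
                    name=name,
                    concentration=conc,
                    surface_tension=table[conc],
                    viscosity=mu,
                )
            )
    return phases


def lookup_phase(name: str, concentration: float) -> LiquidPhase:
    """Fixture phase by name ("PEG"/"Dex") and w/v% concentration."""
    table = {"PEG": PEG_SURFACE_TENSIONS, "Dex": DEX_SURFACE_TENSIONS}.get(name)
    if table is None or concentration not in table:
        raise KeyError(f"no fixture tension for {name!r} at {concentration:g}%")
    return LiquidPhase(name=name, concentration=concentration, surface_tension=table[concentration])


def lookup_solid(label: str) -> SolidSurface:
    """Fixture solid by (possibly partial, case-insensitive) label."""
    for full, (ph, gs) in SOLID_SURFACE_ENERGIES.items():
        if label.lower() in full.lower():
            return SolidSurface(label=full, phenotype=ph, surface_energy=gs)
    raise KeyError(f"no fixture solid matching {label!r}")


def group_summaries_to_json(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([s.model_dump() for s in summaries], fh, indent=2)
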