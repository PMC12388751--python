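"""Energy-balance translocation model: phase preference, terminal velocity,
partitioning time, and donor-level uncertainty propagation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atpsdesign import (
    LiquidPhase,
    SolidSurface,
    dissipation_energy,
    driving_energy,
    partitioning_time,
    phase_preference,
    propagate_delta_gamma_uncertainty,
    tau_p_by_group,
    terminal_velocity,
)
from atpsdesign.data_model import Phenotype

radii = st.floats(1e-7, 1e-4)
gammas = st.floats(0.01, 50.0)
viscs = st.floats(1e-3, 1.0)


class TestPhasePreference:
    @pytest.mark.parametrize(
        "g_peg, g_dex, delta, phase",
        [
            (0.88, 0.48, 0.40, "Dex"),  # hydrophilic beads favour dextran
            (13.48, 25.79, -12.31, "PEG"),  # chondrocytes favour PEG
            (5.0, 5.0, 0.0, "indifferent"),
        ],
    )
    def test_sign_convention(self, g_peg, g_dex, delta, phase):
        d, p = phase_preference(g_peg, g_dex)
        assert d == pytest.approx(delta)
        assert p == phase

    @given(a=st.floats(0, 60), b=st.floats(0, 60))
    @settings(derandomize=True, max_examples=100)
    def test_preference_is_minimum_energy(self, a, b):
        _, p = phase_preference(a, b)
        if a < b:
            assert p == "PEG"
        elif b < a:
            assert p == "Dex"
        else:
            assert p == "indifferent"


class TestEnergies:
    def test_driving_energy_arithmetic(self):
        # 2π·(1e−5)²·0.01231 J/m²
        assert driving_energy(1e-5, 12.31) == pytest.approx(7.734e-12, rel=1e-3)

    def test_dissipation_arithmetic(self):
        assert dissipation_energy(1e-5, 0.045, 0.045583) == pytest.approx(
            7.734e-12, rel=1e-3
        )

    @given(r=radii, dg=gammas)
    @settings(derandomize=True, max_examples=50)
    def test_driving_quadratic_in_radius(self, r, dg):
        assert driving_energy(2 * r, dg) == pytest.approx(4 * driving_energy(r, dg), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            driving_energy(0.0, 1.0)
        with pytest.raises(ValueError):
            dissipation_energy(1e-5, -0.1, 1.0)
        with pytest.raises(ValueError):
            terminal_velocity(1.0, 0.0, 0.05)


class TestTerminalVelocityAndTau:
    def test_velocity_arithmetic(self):
        mu_avg, v = terminal_velocity(12.31, 0.045, 0.045)
        assert mu_avg == pytest.approx(0.045)
        assert v == pytest.approx(0.0456, abs=2e-4)

    def test_tau_arithmetic(self):
        res = partitioning_time(1e-5, -12.31, 0.045, 0.045)
        assert res.tau_p == pytest.approx(4.39e-4, rel=2e-3)
        assert res.preferred_phase == "PEG"

    def test_indifferent_cell_rejected(self):
        with pytest.raises(ValueError, match="indifferent"):
            partitioning_time(1e-5, 0.0, 0.045, 0.02)

    @given(r=radii, dg=gammas, mp=viscs, md=viscs)
    @settings(derandomize=True, max_examples=200)
    def test_energy_balance_and_translocation_identities(self, r, dg, mp, md):
        res = partitioning_time(r, dg, mp, md)
        # driving equals dissipation at terminal velocity
        assert res.dissipation_energy == pytest.approx(res.driving_energy, rel=1e-12)
        # τp · v = 2R identically
        assert res.tau_p * res.terminal_velocity == pytest.approx(2 * r, rel=1e-12)
        # dimensional scalings: τ ∝ μ·R/|Δγ|
        doubled_mu = partitioning_time(r, dg, 2 * mp, 2 * md)
        assert doubled_mu.tau_p == pytest.approx(2 * res.tau_p, rel=1e-12)
        halved_dg = partitioning_time(r, dg / 2, mp, md)
        assert halved_dg.tau_p == pytest.approx(2 * res.tau_p, rel=1e-12)
        doubled_r = partitioning_time(2 * r, dg, mp, md)
        assert doubled_r.tau_p == pytest.approx(2 * res.tau_p, rel=1e-12)


def _phase_pair(mu_peg=0.05, mu_dex=0.025):
    return (
        LiquidPhase(name="PEG", concentration=10, surface_tension=58.99, viscosity=mu_peg),
        LiquidPhase(name="Dex", concentration=10, surface_tension=70.88, viscosity=mu_dex),
    )


def _solids(energies_by_phenotype, radius=1e-5):
    out = []
    for ph, energies in energies_by_phenotype.items():
        for i, gs in enumerate(energies):
            out.append(
                SolidSurface(
                    label=f"{ph.value} {i}", phenotype=ph, surface_energy=gs, radius=radius
                )
            )
    return out


class TestTauPByGroup:
    def test_tau_ratio_is_inverse_delta_gamma_ratio(self):
        """Equal radii and shared viscosities make the group τ_p ratio equal
        the inverse ratio of group |Δγ|."""
        from atpsdesign import interfacial_energy

        solids = _solids(
            {Phenotype.HEALTHY_HCH: [26.75], Phenotype.OA_HCH: [9.01]}
        )
        summaries = {s.phenotype: s for s in tau_p_by_group(solids, _phase_pair())}
        dg = {}
        for ph, gs in [(Phenotype.HEALTHY_HCH, 26.75), (Phenotype.OA_HCH, 9.01)]:
            dg[ph] = abs(
                interfacial_energy(gs, 58.99) - interfacial_energy(gs, 70.88)
            )
        ratio_tau = summaries["healthy_hCh"].mean / summaries["OA_hCh"].mean
        ratio_dg = dg[Phenotype.OA_HCH] / dg[Phenotype.HEALTHY_HCH]
        assert ratio_tau == pytest.approx(ratio_dg, rel=1e-9)

    def test_smaller_driving_force_means_longer_time(self, reference_dataset):
        """With the reference energies, OA donors have the larger |Δγ|, so
        healthy chondrocytes take longer to partition at equal radii."""
        _, solids, params = reference_dataset
        cells = [
            s.model_copy(update={"radius": 1e-5})
            for s in solids
            if s.phenotype != Phenotype.PARTICLE
        ]
        summaries = {s.phenotype: s for s in tau_p_by_group(cells, _phase_pair(), params)}
        assert summaries["healthy_hCh"].mean > summaries["OA_hCh"].mean
        assert summaries["healthy_hCh"].sem is not None

    def test_missing_radius_is_named(self):
        solids = [SolidSurface(label="norad", surface_energy=20.0)]
        with pytest.raises(ValueError, match="norad"):
            tau_p_by_group(solids, _phase_pair())

    def test_missing_viscosity_rejected(self):
        peg, dex = _phase_pair()
        dex = dex.model_copy(update={"viscosity": None})
        with pytest.raises(ValueError, match="viscosity"):
            tau_p_by_group(_solids({Phenotype.OTHER: [20.0]}), (peg, dex))

    def test_single_donor_has_no_sem(self):
        summaries = tau_p_by_group(_solids({Phenotype.OTHER: [20.0]}), _phase_pair())
        assert summaries[0].sd is None and summaries[0].sem is None


class TestDeltaGammaUncertainty:
    def test_identical_lists_give_zero(self):
        mean, sd = propagate_delta_gamma_uncertainty([1.0, 2.0], [1.0, 2.0])
        assert mean == 0.0 and sd == 0.0

    def test_healthy_donor_chain(self, reference_dataset):
        """Per-donor Δγ from the reference chain at 10%: mean ≈ −12.3 mJ/m²."""
        from atpsdesign import interfacial_energy

        _, solids, params = reference_dataset
        healthy = [s for s in solids if s.phenotype == Phenotype.HEALTHY_HCH]
        peg = [interfacial_energy(s.surface_energy, 58.99, params.beta) for s in healthy]
        dex = [interfacial_energy(s.surface_energy, 70.88, params.beta) for s in healthy]
        deltas = [p - d for p, d in zip(peg, dex)]
        assert sorted(-d for d in deltas) == pytest.approx([11.51, 12.69, 12.77], abs=0.01)
        mean, sd = propagate_delta_gamma_uncertainty(peg, dex)
        assert mean == pytest.approx(-12.33, abs=0.02)
        assert sd > 0

    def test_quadrature_mode(self):
        peg, dex = [10.0, 12.0, 14.0], [20.0, 21.0, 22.0]
        mean, sd = propagate_delta_gamma_uncertainty(peg, dex, mode="quadrature")
        assert mean == pytest.approx(-9.0)
        assert sd == pytest.approx(math.hypot(2.0, 1.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            propagate_delta_gamma_uncertainty([1.0], [1.0, 2.0])
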