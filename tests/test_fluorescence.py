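"""Excitation-emission coupling: dose tables, inherited weights, emission
launch statistics, radial spread trends and weight-sweep linearity."""

import math

import numpy as np
import pytest

from mcfocus import (
    DetectorSpec,
    FluorSource,
    collect,
    excitation_efficiency,
    inherited_weight,
    run_emission,
    weight_sweep,
)
from mcfocus.tissue import LayerOpticalProperties, LayerStack
from mcfocus.transport import PencilBeam


class TestExcitationEfficiency:
    def test_vacuum_ballistic_limit(self, vacuum_stack):
        # no interactions, matched indices: every photon crosses on-axis,
        # dose = 1/(pi r^2) per photon and efficiency exactly 1
        tab = excitation_efficiency(vacuum_stack, depths=[0.5],
                                    n_photons=2_000, seed=3)
        assert tab["on_axis_intensity"].iloc[0] == pytest.approx(
            1.0 / (math.pi * 0.005**2), rel=1e-9
        )
        assert tab["relative_to_incident"].iloc[0] == pytest.approx(1.0)

    def test_strictly_decreasing_with_depth(self, s785):
        tab = excitation_efficiency(s785, n_photons=150_000, seed=11)
        inten = tab["on_axis_intensity"].to_numpy()
        assert np.all(np.diff(inten) < 0)
        assert tab["relative_to_shallowest"].iloc[0] == 1.0
        assert np.all(tab["relative_to_incident"] <= 1.0)

    def test_invalid_inputs(self, s785):
        with pytest.raises(ValueError):
            excitation_efficiency(s785, depths=[5.0], n_photons=100, seed=1)
        with pytest.raises(ValueError):
            excitation_efficiency(s785, bin_radius=0.0, n_photons=100, seed=1)


class TestInheritedWeight:
    def test_published_presets(self):
        assert inherited_weight(0.04) == 1.0
        assert inherited_weight(0.08) == 0.011
        assert inherited_weight(0.14) == 0.0015
        assert inherited_weight(0.20) == 0.0005

    def test_unknown_depth_rejected(self):
        with pytest.raises(KeyError):
            inherited_weight(0.1)

    def test_recomputed_matches_preset_at_first_cortex_depth(self, s785):
        tab = excitation_efficiency(s785, n_photons=300_000, seed=13)
        w = inherited_weight(0.08, table=tab, preset=False)
        assert w == pytest.approx(0.011, rel=0.15)

    def test_recomputed_weights_decrease_with_depth(self, s785):
        tab = excitation_efficiency(s785, n_photons=150_000, seed=14)
        ws = [inherited_weight(z, table=tab, preset=False)
              for z in (0.04, 0.08, 0.14, 0.20)]
        assert ws[0] == 1.0  # incident reference caps the cortical surface
        assert all(a > b for a, b in zip(ws, ws[1:]))


class TestEmission:
    def test_vacuum_cap_fraction(self):
        # isotropic source under a transparent matched slab: the accepted
        # fraction equals the 15-degree spherical cap (1 - cos15)/2
        lay = LayerOpticalProperties("void", 1.0, 1e-9, 0.0, 0.0, 1.0)
        stack = LayerStack("custom", (lay,), ambient_above_n=1.0)
        n = 200_000
        em = run_emission(stack, FluorSource(z_qd=0.5, n_emit=n), seed=15,
                          model="isotropic")
        cap = (1.0 - math.cos(math.radians(15.0))) / 2.0
        frac = np.count_nonzero(em.exit_angle_deg <= 15.0) / n
        assert abs(frac - cap) < 3.0 * math.sqrt(cap * (1 - cap) / n)

    def test_weight_budget_ordering(self, emission_runs):
        for em in emission_runs.values():
            launched = em.transport.launched_weight
            exiting = em.exit_w.sum()
            accepted = em.exit_w[em.exit_angle_deg <= 15.0].sum()
            assert 0.0 < accepted <= exiting <= launched

    def test_radial_spread_grows_with_depth(self, emission_runs):
        det = DetectorSpec.published_preset()
        medians = []
        for z in sorted(emission_runs):
            em = emission_runs[z]
            keep = em.exit_angle_deg <= det.half_angle()
            medians.append(np.median(em.exit_r[keep]))
        assert medians == sorted(medians)

    def test_half_maximum_bin_nondecreasing_with_depth(self, emission_runs):
        det = DetectorSpec.published_preset()
        idx = []
        for z in sorted(emission_runs):
            prof = collect(emission_runs[z], det)
            inten = prof["intensity"].to_numpy()
            half = inten.max() / 2.0
            idx.append(int(np.max(np.nonzero(inten >= half)[0])))
        assert idx == sorted(idx)

    def test_source_validation(self, s1100):
        with pytest.raises(ValueError):
            FluorSource(z_qd=0.01)  # above the cortical surface
        with pytest.raises(ValueError):
            FluorSource(z_qd=0.08, w0=0.0)
        with pytest.raises(ValueError):
            FluorSource(z_qd=0.08, r_qd=0.1)
        with pytest.raises(ValueError):
            run_emission(s1100, FluorSource(z_qd=0.08), model="sideways")
        with pytest.raises(ValueError):
            run_emission(s1100, FluorSource(z_qd=5.0, n_emit=10))


class TestWeightSweep:
    def test_linear_scaling_without_roulette(self, s785):
        runs = weight_sweep(s785, [1.0, 0.25], 3_000, seed=21,
                            roulette_threshold=0.0)
        a, b = runs
        assert np.allclose(b.grid.A, 0.25 * a.grid.A, rtol=1e-12, atol=0.0)
        assert b.ledger["escaped_top"] == pytest.approx(
            0.25 * a.ledger["escaped_top"], rel=1e-12
        )

    def test_unit_weight_run_equals_standard_run(self, s785):
        from mcfocus.transport import run_transport

        sweep = weight_sweep(s785, [1.0], 2_000, seed=22)[0]
        std = run_transport(s785, PencilBeam(), 2_000, seed=22)
        assert np.array_equal(sweep.grid.A, std.grid.A)
        assert sweep.ledger == std.ledger

    def test_penetration_grows_with_initial_weight(self, s785):
        """With roulette active, stronger excitation light reaches deeper
        before the low-weight tail is terminated."""
        runs = weight_sweep(s785, [0.05, 1.0], 30_000, seed=23)
        depths = []
        for res in runs:
            nz_any = np.nonzero(res.grid.A.sum(axis=0) > 0)[0]
            depths.append(nz_any.max() if nz_any.size else -1)
        assert depths[1] >= depths[0]
        assert runs[1].grid.A.sum() > runs[0].grid.A.sum()

    def test_rejects_out_of_range_weights(self, s785):
        with pytest.raises(ValueError):
            weight_sweep(s785, [0.0], 100, seed=1)
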