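"""Transport-engine oracles: Beer-Lambert ballistic transmission, weight
conservation, launch/drop/roulette rules, boundary-mode agreement, seed
reproducibility and fluence normalisation."""

import math

import numpy as np
import pytest

from mcfocus.tissue import LayerOpticalProperties, LayerStack
from mcfocus.transport import (
    FluenceGrid,
    ForwardPointSource,
    IsotropicPointSource,
    PencilBeam,
    PhotonState,
    drop_weight,
    launch_pencil_beam,
    roulette,
    run_transport,
)


def slab(mu_a, mu_s, d=0.1, n=1.0, g=0.0):
    lay = LayerOpticalProperties("slab", n, mu_a, mu_s, g, d)
    return LayerStack("custom", (lay,), ambient_above_n=1.0)


class TestBeerLambert:
    def test_absorbing_only_slab_transmits_exp_mua_d(self):
        # mu_a = 10/cm, d = 0.1 cm, matched indices: T = e^-1
        res = run_transport(slab(10.0, 0.0), PencilBeam(), 100_000, seed=5)
        t = res.ledger["transmitted_bottom"] / res.launched_weight
        p = math.exp(-1.0)
        assert abs(t - p) < 3.0 * math.sqrt(p * (1 - p) / 100_000)

    def test_nonabsorbing_matched_stack_conserves_all_weight(self):
        res = run_transport(slab(0.0, 50.0, g=0.5), PencilBeam(), 20_000, seed=6)
        assert res.ledger["absorbed"] == 0.0
        assert res.ledger["overflow"] == 0.0
        escaped = res.ledger["escaped_top"] + res.ledger["transmitted_bottom"]
        assert escaped == pytest.approx(res.launched_weight, rel=1e-12)


class TestWeightConservation:
    @pytest.mark.parametrize("mode", ["fresnel_full", "specular_split"])
    @pytest.mark.parametrize("source_kind", ["pencil", "isotropic", "forward"])
    def test_ledger_closes(self, s785, s1100, mode, source_kind):
        if source_kind == "pencil":
            stack, src = s785, PencilBeam()
        elif source_kind == "isotropic":
            stack, src = s1100, IsotropicPointSource(0.08, 0.011)
        else:
            stack, src = s1100, ForwardPointSource(0.08, 0.011)
        res = run_transport(stack, src, 5_000, seed=7, mode=mode)
        assert res.conservation_error() <= 1e-6

    def test_specular_split_books_boundary_losses(self, s785):
        res = run_transport(s785, PencilBeam(), 5_000, seed=8, mode="specular_split")
        assert res.ledger["boundary_lost"] > 0.0
        assert res.conservation_error() <= 1e-6


class TestLaunch:
    def test_specular_entry_loss(self, s785, rng):
        ph = launch_pencil_beam(rng, s785)
        assert ph.W == pytest.approx(0.9756, abs=1e-4)
        assert (ph.ux, ph.uy, ph.uz) == (0.0, 0.0, 1.0)

    def test_matched_indices_keep_full_weight(self, vacuum_stack, rng):
        assert launch_pencil_beam(rng, vacuum_stack).W == 1.0

    def test_weight_scales_linearly(self, s785, rng):
        ph = launch_pencil_beam(rng, s785, initial_weight=0.05)
        assert ph.W == pytest.approx(0.05 * 0.9756, abs=1e-5)

    def test_invalid_initial_weight_rejected(self, s785):
        with pytest.raises(ValueError):
            run_transport(s785, PencilBeam(initial_weight=0.0), 10, seed=1)
        with pytest.raises(ValueError):
            run_transport(s785, PencilBeam(initial_weight=1.5), 10, seed=1)


class TestDropAndRoulette:
    @pytest.mark.parametrize(
        "mu_a, mu_s, frac",
        [
            (1.62, 238.9, 6.735e-3),  # skin at 785 nm
            (0.5, 71.4, 6.954e-3),    # cortex at 1100 nm (mu_t = 71.9)
            (0.0, 100.0, 0.0),
        ],
    )
    def test_drop_fraction(self, mu_a, mu_s, frac):
        grid = FluenceGrid(nr=4, nz=4)
        ph = PhotonState(z=0.005, W=1.0)
        dw = drop_weight(ph, mu_a, mu_s, grid)
        assert dw == pytest.approx(frac, rel=1e-3)
        assert ph.W == pytest.approx(1.0 - frac, rel=1e-6)

    def test_dead_photons_never_move(self):
        ph = PhotonState(alive=False)
        with pytest.raises(ValueError):
            drop_weight(ph, 1.0, 1.0, FluenceGrid(nr=2, nz=2))

    def test_roulette_rules(self, rng):
        ph = PhotonState(W=0.5)
        assert roulette(ph, rng).W == 0.5  # above threshold: untouched
        survivors = []
        for _ in range(4000):
            p = roulette(PhotonState(W=1e-5), rng)
            if p.alive:
                assert p.W == pytest.approx(1e-4)
                survivors.append(p.W)
        # unbiased: expected weight 4000 * 1e-5, survivors carry 10x weight
        total = sum(survivors)
        assert total == pytest.approx(4000 * 1e-5, rel=0.25)


class TestBoundaryModes:
    def test_modes_agree_at_normal_incidence(self):
        # clear two-layer stack with an index step: the probabilistic
        # Fresnel split must equal the deterministic (1 - R) in expectation
        l1 = LayerOpticalProperties("a", 1.0, 1e-6, 0.0, 0.0, 0.05)
        l2 = LayerOpticalProperties("b", 1.5, 1e-6, 0.0, 0.0, 0.05)
        stack = LayerStack("custom", (l1, l2), ambient_above_n=1.0)
        n = 50_000
        det = run_transport(stack, PencilBeam(), 1_000, seed=9, mode="specular_split")
        sto = run_transport(stack, PencilBeam(), n, seed=10, mode="fresnel_full")
        t_det = det.ledger["transmitted_bottom"] / det.launched_weight
        t_sto = sto.ledger["transmitted_bottom"] / sto.launched_weight
        assert abs(t_sto - t_det) < 3.0 * math.sqrt(t_det * (1 - t_det) / n)

    def test_unknown_mode_rejected(self, s785):
        with pytest.raises(ValueError):
            run_transport(s785, PencilBeam(), 10, seed=1, mode="nope")


class TestReproducibility:
    def test_same_seed_bit_identical(self, s785):
        a = run_transport(s785, PencilBeam(), 3_000, seed=42,
                          planes=[0.04], plane_bin_radius=0.005)
        b = run_transport(s785, PencilBeam(), 3_000, seed=42,
                          planes=[0.04], plane_bin_radius=0.005)
        assert np.array_equal(a.grid.A, b.grid.A)
        assert a.ledger == b.ledger
        assert np.array_equal(a.exit_r, b.exit_r)
        assert np.array_equal(a.plane_weights, b.plane_weights)

    def test_different_seeds_differ(self, s785):
        a = run_transport(s785, PencilBeam(), 3_000, seed=42)
        b = run_transport(s785, PencilBeam(), 3_000, seed=43)
        assert not np.array_equal(a.grid.A, b.grid.A)

    def test_exit_angles_are_valid_cosines(self, excitation_run):
        assert np.all(excitation_run.exit_cos >= -1e-12)
        assert np.all(excitation_run.exit_cos <= 1.0 + 1e-12)


class TestDepthProfile:
    def test_on_axis_dose_strictly_decreases_with_depth(self, excitation_run):
        w = excitation_run.plane_weights
        assert np.all(np.diff(w) < 0)
        assert np.all(w > 0)


class TestFluenceGrid:
    def test_single_deposit_per_area(self):
        grid = FluenceGrid(dr=0.005, dz=0.005, nr=4, nz=4)
        grid.A[0, 0] = 1.0
        grid.n_launched = 1
        f = grid.fluence()
        assert f[0, 0] == pytest.approx(1.0 / (math.pi * 0.005**2))

    def test_per_photon_normalization_is_scale_free(self):
        g1 = FluenceGrid(nr=2, nz=2)
        g1.A[0, 0] = 3.0
        g1.n_launched = 10
        g2 = FluenceGrid(nr=2, nz=2)
        g2.A[0, 0] = 6.0
        g2.n_launched = 20
        assert np.allclose(g1.fluence(), g2.fluence())

    def test_per_volume_mu_a_mode(self):
        grid = FluenceGrid(nr=2, nz=2, normalization_mode="per_volume_mu_a")
        grid.A[1, 1] = 2.0
        grid.n_launched = 4
        mu = np.array([0.5, 2.0])
        f = grid.fluence(mu_a_of_z=mu)
        area = math.pi * (0.01**2 - 0.005**2)
        assert f[1, 1] == pytest.approx(2.0 / (4 * area * 0.005 * 2.0))
        assert f[0, 0] == 0.0

    def test_empty_grid_is_all_zero_not_an_error(self):
        grid = FluenceGrid(nr=2, nz=2)
        assert np.all(grid.fluence() == 0.0)
        assert np.all(np.isnan(grid.log_fluence()))

    def test_log_fluence_masks_empty_cells(self, excitation_run):
        lf = excitation_run.grid.log_fluence()
        f = excitation_run.grid.fluence()
        assert np.isnan(lf[f == 0]).all()
        assert np.isfinite(lf[f > 0]).all()


class TestSpectralContrast:
    def test_high_fluence_skin_region_wider_at_785(self, excitation_run,
                                                   pencil_1100_run):
        """Stronger absorption and scattering at 785 nm widen the
        high-fluence area within the skin relative to 1100 nm."""
        def skin_fluence(res, z_lo, z_hi):
            g = res.grid
            zc = g.z_edges[:-1] + g.dz / 2.0
            cols = (zc >= z_lo) & (zc < z_hi)
            return g.fluence()[:, cols]

        f785 = skin_fluence(excitation_run, 0.0, 0.02)
        f1100 = skin_fluence(pencil_1100_run, 0.0, 0.02)
        thr = np.quantile(f785[f785 > 0], 0.5)
        assert (f785 > thr).sum() > (f1100 > thr).sum()
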