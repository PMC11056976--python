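"""Generators: closed-form ground truth, determinism, planted fixtures."""

import numpy as np
import pytest

from sclipid import (
    BilayerSpec,
    SolventSpec,
    add_solvent,
    bar_delta_g,
    build_bilayer,
    density_profile,
    order_parameters,
    plant_hbond_fixture,
    sample_fep_work,
    solvent_composition,
)
from sclipid.units import GAS_CONSTANT_KJ


@pytest.mark.parametrize("tilt,expected", [
    (0.0, 1.0),
    (30.0, (3 * np.cos(np.radians(30)) ** 2 - 1) / 2),
    (60.0, -0.125),
    (90.0 - 1e-9, -0.5),
])
def test_fixed_tilt_gives_closed_form_order_parameter(tilt, expected):
    """With zero jitter every interior carbon has S_z = (3cos^2(θ0)−1)/2."""
    spec = BilayerSpec(n_lipids_per_leaflet=8, tilt_angle=tilt,
                       tilt_jitter=0.0, chain_length=8,
                       leaflet_separation=4.0, n_frames=2, seed=3)
    profiles = order_parameters(build_bilayer(spec))
    for prof in profiles.values():
        assert np.allclose(prof.s_z, expected, atol=1e-12)


def test_headgroups_sit_on_leaflet_planes():
    spec = BilayerSpec(n_lipids_per_leaflet=10, leaflet_separation=4.0, seed=0)
    traj = build_bilayer(spec)
    z_mid = traj.frames[0].box[2] / 2
    heads = [a.atom_id for a in traj.topology if a.chain_label is None]
    z = traj.frames[0].positions[heads, 2]
    assert np.allclose(np.abs(z - z_mid), 2.0, atol=1e-12)


def test_box_area_matches_apl_target():
    spec = BilayerSpec(n_lipids_per_leaflet=144, apl_target=0.325, seed=0)
    traj = build_bilayer(spec)
    lx, ly, _ = traj.frames[0].box
    assert np.isclose(lx * ly, 144 * 0.325, rtol=1e-12)


def test_overlong_chains_rejected():
    with pytest.raises(ValueError, match="longer than"):
        build_bilayer(BilayerSpec(chain_length=40, leaflet_separation=2.0))


def test_build_bilayer_deterministic_under_seed():
    spec = BilayerSpec(n_lipids_per_leaflet=6, tilt_jitter=5.0, n_frames=2, seed=42)
    a = build_bilayer(spec)
    b = build_bilayer(spec)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.positions, fb.positions)


class TestAddSolvent:
    def test_water_excluded_from_core(self, small_bilayer):
        traj = add_solvent(small_bilayer, SolventSpec(n_water=2000, seed=1))
        z_mid = traj.frames[0].box[2] / 2
        widx = [a.atom_id for a in traj.topology if a.residue_name == "SOL"]
        z = traj.frames[0].positions[widx, 2]
        assert np.all(np.abs(z - z_mid) >= 1.5)

    def test_zero_amplitude_gives_flat_enhancer_profile(self, small_bilayer):
        traj = add_solvent(small_bilayer, SolventSpec(
            n_water=0, n_enhancer=30000, interface_peak_amplitude=0.0, seed=5))
        prof = density_profile(traj, selection="ENHANCER", n_slices=20,
                               centering="none")
        z_mid = traj.frames[0].box[2] / 2
        # bins fully outside the core-exclusion zone must be flat
        bulk = np.abs(prof.bin_centers - z_mid) > 1.5 + prof.bin_width
        occupied = prof.density[bulk]
        assert occupied.std() / occupied.mean() < 0.1

    def test_peak_mode_recovers_headgroup_plane(self, small_bilayer):
        """With strong interface enrichment the histogram mode lands within
        one bin of the headgroup plane at ±d/2."""
        traj = add_solvent(small_bilayer, SolventSpec(
            n_water=0, n_enhancer=100_000, interface_peak_amplitude=3.0,
            interface_peak_width=0.3, seed=9))
        prof = density_profile(traj, selection="ENHANCER", n_slices=50)
        upper = prof.bin_centers > 0
        peak_z = prof.bin_centers[upper][np.argmax(prof.density[upper])]
        assert abs(peak_z - 4.89 / 2) <= prof.bin_width

    def test_no_water_means_zero_water_profile(self, small_bilayer):
        traj = add_solvent(small_bilayer, SolventSpec(n_water=0, n_enhancer=10))
        prof = density_profile(traj, selection="WATER", n_slices=10)
        assert np.all(prof.density == 0)


class TestHBondFixture:
    @pytest.mark.parametrize("n_bonded,n_miss", [(5, 0), (0, 7), (3, 3)])
    def test_expected_count_is_n_bonded(self, n_bonded, n_miss):
        _, _, expected = plant_hbond_fixture(n_bonded, n_miss, seed=2)
        assert expected == n_bonded

    def test_box_too_small_raises(self):
        with pytest.raises(ValueError, match="separated fixture"):
            plant_hbond_fixture(20, 20, box=(3.0, 3.0, 3.0))

    def test_first_bonded_pair_wraps_boundary(self):
        top, frame, _ = plant_hbond_fixture(3, 0, seed=8)
        donor = next(a for a in top if a.hydrogen_ids)
        acceptor = top.atom(2)  # first acceptor follows first donor+H
        naive = np.linalg.norm(frame.positions[acceptor.atom_id]
                               - frame.positions[donor.atom_id])
        assert naive > 0.35  # unwrapped distance looks unbonded
        vec = frame.positions[acceptor.atom_id] - frame.positions[donor.atom_id]
        vec -= frame.box * np.round(vec / frame.box)
        assert np.linalg.norm(vec) < 0.35


class TestFepWork:
    def test_sigma_to_zero_limit_is_deterministic(self):
        w = sample_fep_work(2.0, 1e-12, 100, seed=0)
        kt = GAS_CONSTANT_KJ * 298.15
        assert np.allclose(w.forward / kt, 2.0, atol=1e-9)
        assert np.allclose(w.reverse / kt, -2.0, atol=1e-9)

    def test_zero_dg_distributions_identical(self):
        w = sample_fep_work(0.0, 1.0, 50_000, seed=1)
        # same generative law => matching moments
        assert abs(w.forward.mean() - w.reverse.mean()) < 0.05
        assert abs(w.forward.std() - w.reverse.std()) < 0.05

    def test_bar_recovers_generative_truth(self):
        w = sample_fep_work(2.0, 1.0, 100_000, seed=12)
        res = bar_delta_g(w)
        kt = GAS_CONSTANT_KJ * 298.15
        assert abs(res.dG / kt - 2.0) < 3 * res.stderr / kt

    @pytest.mark.parametrize("n,sigma", [(1, 1.0), (10, 0.0), (10, -1.0)])
    def test_invalid_inputs_rejected(self, n, sigma):
        with pytest.raises(ValueError):
            sample_fep_work(1.0, sigma, n)


class TestSolventComposition:
    @pytest.mark.parametrize("fraction,expected", [
        (0.0, (0, 8640)),
        (1.0, (8640, 0)),
        (0.6, (2264, 6376)),  # rounded root of the mass-balance equation
    ])
    def test_mass_balance(self, fraction, expected):
        assert solvent_composition(fraction, 8640, 76.09, 18.015) == expected

    def test_counts_always_total_n(self):
        for f in np.linspace(0, 1, 23):
            ne, nw = solvent_composition(float(f), 5400)
            assert ne + nw == 5400 and ne >= 0 and nw >= 0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            solvent_composition(1.2, 100)
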