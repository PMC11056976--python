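"""Area per lipid, thickness, and chain order parameters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclipid import (
    BilayerSpec,
    ChainDefinition,
    DensityProfile,
    Frame,
    Topology,
    Trajectory,
    area_per_lipid,
    bilayer_thickness,
    build_bilayer,
    density_profile,
    order_parameters,
)
from sclipid.structure import area_per_lipid_series
from sclipid.topology import Atom, Species


def _chain_trajectory(directions, n_carbons=7, box=20.0):
    """One straight chain per direction vector; returns (traj, chains)."""
    atoms, chains, pos = [], [], []
    for ci, d in enumerate(directions):
        d = np.asarray(d, float)
        d = d / np.linalg.norm(d)
        ids = []
        for k in range(n_carbons):
            aid = len(atoms)
            atoms.append(Atom(aid, f"C{k+1}", ci, "FFA", 12.011,
                              species=Species.FFA))
            pos.append(10.0 + 0.13 * k * d)
            ids.append(aid)
        chains.append(ChainDefinition("free-fatty-acid", tuple(ids)))
    traj = Trajectory(Topology(atoms),
                      [Frame(np.array(pos), np.array([box] * 3))])
    return traj, chains


class TestOrderParameters:
    def test_parallel_chain_gives_one(self):
        traj, chains = _chain_trajectory([(0, 0, 1)])
        prof = order_parameters(traj, chains)["free-fatty-acid"]
        assert np.allclose(prof.s_z, 1.0, atol=1e-14)
        assert list(prof.carbon_index) == [2, 3, 4, 5, 6]

    def test_perpendicular_chain_gives_minus_half(self):
        traj, chains = _chain_trajectory([(1, 0, 0), (0, 1, 0)])
        prof = order_parameters(traj, chains)["free-fatty-acid"]
        assert np.allclose(prof.s_z, -0.5, atol=1e-14)

    def test_magic_angle_gives_zero(self):
        theta = np.radians(54.7356103)
        traj, chains = _chain_trajectory([(np.sin(theta), 0, np.cos(theta))])
        prof = order_parameters(traj, chains)["free-fatty-acid"]
        assert np.allclose(prof.s_z, 0.0, atol=1e-6)

    def test_reflection_symmetry_pools_leaflets(self):
        """cos^2 makes S_z invariant under z -> -z."""
        traj, chains = _chain_trajectory([(0.3, 0.1, 0.9)])
        flipped = Trajectory(
            traj.topology,
            [Frame(traj.frames[0].positions * np.array([1, 1, -1]) + 20.0,
                   traj.frames[0].box)],
        )
        a = order_parameters(traj, chains)["free-fatty-acid"].s_z
        b = order_parameters(flipped, chains)["free-fatty-acid"].s_z
        assert np.allclose(a, b, atol=1e-12)

    def test_wrapped_chain_uses_minimum_image(self):
        traj, chains = _chain_trajectory([(0, 0, 1)], box=20.0)
        wrapped = Trajectory(
            traj.topology,
            [Frame(np.mod(traj.frames[0].positions + np.array([0, 0, 9.6]),
                          20.0), traj.frames[0].box)],
        )
        prof = order_parameters(wrapped, chains)["free-fatty-acid"]
        assert np.allclose(prof.s_z, 1.0, atol=1e-12)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            ChainDefinition("free-fatty-acid", (0, 1))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(*[st.floats(-1, 1).filter(lambda v: abs(v) > 1e-3)] * 3),
                    min_size=1, max_size=5))
    def test_s_z_bounded_for_arbitrary_directions(self, dirs):
        traj, chains = _chain_trajectory(dirs)
        prof = order_parameters(traj, chains)["free-fatty-acid"]
        assert np.all(prof.s_z >= -0.5 - 1e-9)
        assert np.all(prof.s_z <= 1.0 + 1e-9)

    def test_synthetic_bilayer_closed_form_many_tilts(self):
        for tilt in (0.0, 30.0, 60.0):
            traj = build_bilayer(BilayerSpec(
                n_lipids_per_leaflet=6, tilt_angle=tilt, chain_length=6,
                leaflet_separation=4.0, n_frames=2, seed=1))
            expected = (3 * np.cos(np.radians(tilt)) ** 2 - 1) / 2
            for prof in order_parameters(traj).values():
                assert np.allclose(prof.s_z, expected, atol=1e-12)


class TestAreaPerLipid:
    def _const_traj(self, lx, ly, n_frames=4):
        atoms = [Atom(0, "OCER", 0, "CER", 80.0, species=Species.CER)]
        frames = [Frame(np.array([[1.0, 1.0, 1.0]]),
                        np.array([lx, ly, 10.0]), time=float(i))
                  for i in range(n_frames)]
        return Trajectory(Topology(atoms), frames)

    def test_paper_scale_arithmetic(self):
        """6 x 7.8 nm box with 144 lipids/leaflet gives 0.325 nm^2."""
        res = area_per_lipid(self._const_traj(6.0, 7.8), 144, n_blocks=2)
        assert res.mean == pytest.approx(46.8 / 144)
        assert res.mean == pytest.approx(0.325)
        assert res.sem == 0.0

    def test_simple_ratio_and_linearity(self):
        assert area_per_lipid(self._const_traj(5.0, 5.0), 50,
                              n_blocks=2).mean == pytest.approx(0.5)
        doubled = area_per_lipid(self._const_traj(10.0, 5.0), 50,
                                 n_blocks=2).mean
        assert doubled == pytest.approx(1.0)

    def test_zero_lipids_rejected(self):
        with pytest.raises(ValueError):
            area_per_lipid_series(self._const_traj(5.0, 5.0), 0)


class TestThickness:
    def _two_gaussians(self, center, n_bins=200, half_range=5.0):
        z = np.linspace(-half_range, half_range, n_bins)
        rho = (np.exp(-((z - center) ** 2) / 0.02)
               + np.exp(-((z + center) ** 2) / 0.02))
        return DensityProfile(z, rho, "CER head", 1)

    @pytest.mark.parametrize("center,expected", [(2.445, 4.89), (2.355, 4.71)])
    def test_peak_pair_distance(self, center, expected):
        prof = self._two_gaussians(center)
        assert bilayer_thickness(prof) == pytest.approx(expected,
                                                        abs=prof.bin_width)

    def test_single_central_peak_is_error(self):
        z = np.linspace(-5, 5, 100)
        rho = np.exp(-z ** 2 / 0.1)
        rho[z < 0] = 0.0  # no density on one side
        with pytest.raises(ValueError, match="no peak pair"):
            bilayer_thickness(DensityProfile(z, rho, "CER head", 1))

    @pytest.mark.parametrize("d", [3.5, 4.89])
    def test_recovery_from_synthetic_bilayer(self, d):
        traj = build_bilayer(BilayerSpec(
            n_lipids_per_leaflet=24, leaflet_separation=d, chain_length=10,
            n_frames=3, seed=5))
        names = sorted({a.name for a in traj.topology
                        if a.species is Species.CER and a.chain_label is None})
        prof = density_profile(traj, selection="CER", names=names, n_slices=80)
        assert bilayer_thickness(prof) == pytest.approx(d, abs=prof.bin_width)
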