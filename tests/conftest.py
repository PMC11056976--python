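"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from sclipid import BilayerSpec, SolventSpec, add_solvent, build_bilayer
from sclipid.topology import HBondRole


@pytest.fixture
def small_bilayer():
    """Untilted 12-lipid/leaflet bilayer, 3 frames."""
    return build_bilayer(BilayerSpec(n_lipids_per_leaflet=12, n_frames=3, seed=7))


@pytest.fixture
def solvated_bilayer(small_bilayer):
    return add_solvent(
        small_bilayer,
        SolventSpec(n_water=3000, n_enhancer=600,
                    interface_peak_amplitude=2.0, seed=11),
    )


def brute_force_hbonds(frame, topology, d_cut=0.35, angle_cut=30.0):
    """All-pairs H-bond detection with explicit 27-image enumeration.

    Independent oracle for the neighbour-search implementation: for
    every donor/acceptor pair in different residues, the donor–acceptor
    vector is minimised over all 27 periodic images explicitly; the
    angle at the donor uses that minimising image.  Returns a set of
    (donor_id, hydrogen_id, acceptor_id) triples.
    """
    box = frame.box
    pos = np.mod(frame.positions, box)
    shifts = np.array([(i, j, k)
                       for i in (-1, 0, 1)
                       for j in (-1, 0, 1)
                       for k in (-1, 0, 1)], dtype=float) * box

    donors = [a for a in topology if a.hbond_role is HBondRole.DONOR]
    acceptors = [a for a in topology if a.hbond_role is HBondRole.ACCEPTOR]
    if not donors or not acceptors:
        return set()
    d_ids = np.array([a.atom_id for a in donors])
    a_ids = np.array([a.atom_id for a in acceptors])
    # distance over all 27 images for every donor-acceptor pair
    diff = pos[a_ids][None, :, :] - pos[d_ids][:, None, :]
    images = diff[:, :, None, :] + shifts[None, None, :, :]
    norms = np.linalg.norm(images, axis=-1)            # (nd, na, 27)
    k_min = np.argmin(norms, axis=-1)
    dist = np.take_along_axis(norms, k_min[..., None], axis=-1)[..., 0]

    d_res = np.array([a.residue_id for a in donors])
    a_res = np.array([a.residue_id for a in acceptors])
    candidate = (dist < d_cut) \
        & (d_res[:, None] != a_res[None, :]) \
        & (d_ids[:, None] != a_ids[None, :])

    bonds = set()
    for i, j in zip(*np.nonzero(candidate)):
        d = donors[i]
        da = images[i, j, k_min[i, j]]
        for h_id in d.hydrogen_ids:
            dh_images = pos[h_id] + shifts - pos[d.atom_id]
            dh = dh_images[int(np.argmin(np.linalg.norm(dh_images, axis=1)))]
            cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist[i, j])
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang < angle_cut:
                bonds.add((d.atom_id, h_id, acceptors[j].atom_id))
    return bonds
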