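"""Geometric hydrogen-bond detection and species-pair accounting.

A donor–acceptor pair is bonded when the minimum-image donor–acceptor
distance is strictly below ``d_cut`` (default 0.35 nm) and the angle at
the donor between the donor→hydrogen and donor→acceptor directions is
strictly below ``angle_cut`` (default 30°).  The angle vertex sits at
the donor — the H–D···A reading of the criterion; the alternative
convention with the vertex at the hydrogen is deliberately not used
(see the methods note).  Intra-residue pairs are excluded; one
donor–hydrogen may bond several acceptors.

Neighbour search uses a periodic k-d tree (grid-binned, cell edge ≥
d_cut) on the wrapped coordinates; results are identical to an
all-pairs minimum-image search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import BlockSummary, block_average
from .topology import Frame, HBondRole, Topology, Trajectory

__all__ = ["HBond", "HBondCount", "detect_hbonds", "count_by_species"]


@dataclass(frozen=True)
class HBond:
    donor_atom_id: int
    hydrogen_atom_id: int
    acceptor_atom_id: int
    distance: float  # nm, minimum image
    angle: float     # degrees at the donor


@dataclass
class HBondCount:
    """Per-frame H-bond counts keyed by unordered species pair."""

    per_frame: pd.DataFrame     # columns: frame, species_pair, count
    summary: dict[str, BlockSummary]


def _minimum_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
) -> list[HBond]:
    """All hydrogen bonds in one frame under the geometric criterion."""
    donors = [a for a in topology if a.hbond_role is HBondRole.DONOR]
    acceptors = [a for a in topology if a.hbond_role is HBondRole.ACCEPTOR]
    if not donors or not acceptors:
        return []
    box = frame.box
    pos = frame.wrapped()
    acc_ids = np.array([a.atom_id for a in acceptors])
    tree = cKDTree(pos[acc_ids], boxsize=box)

    bonds: list[HBond] = []
    for d_atom in donors:
        d_pos = pos[d_atom.atom_id]
        # inclusive tree query, strict filtering below
        cand = tree.query_ball_point(d_pos, r=d_cut)
        if not cand:
            continue
        for ci in cand:
            a_atom = acceptors[ci]
            if a_atom.atom_id == d_atom.atom_id:
                continue
            if a_atom.residue_id == d_atom.residue_id:
                continue
            da = _minimum_image(pos[a_atom.atom_id] - d_pos, box)
            dist = float(np.linalg.norm(da))
            if not dist < d_cut:
                continue
            for h_id in d_atom.hydrogen_ids:
                dh = _minimum_image(pos[h_id] - d_pos, box)
                cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if angle < angle_cut:
                    bonds.append(HBond(d_atom.atom_id, h_id, a_atom.atom_id,
                                       dist, angle))
    return bonds


def _pair_key(sp_a: str, sp_b: str) -> str:
    return "-".join(sorted((sp_a, sp_b)))


def count_by_species(
    traj: Trajectory,
    d_cut: float = 0.35,
    angle_cut: float = 30.0,
    n_blocks: int = 10,
) -> HBondCount:
    """Count bonds per frame, bucketed by unordered (donor, acceptor) species pair.

    The per-pair totals are block-averaged over frames; with fewer
    frames than blocks every frame becomes its own block.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    rows = []
    keys: set[str] = set()
    for fi, frame in enumerate(traj):
        counts: dict[str, int] = {}
        for b in detect_hbonds(frame, top, d_cut=d_cut, angle_cut=angle_cut):
            key = _pair_key(top.atom(b.donor_atom_id).species.value,
                            top.atom(b.acceptor_atom_id).species.value)
            counts[key] = counts.get(key, 0) + 1
        keys.update(counts)
        rows.append((fi, counts))
    records = [
        {"frame": fi, "species_pair": key, "count": counts.get(key, 0)}
        for fi, counts in rows
        for key in sorted(keys)
    ]
    per_frame = pd.DataFrame(records, columns=["frame", "species_pair", "count"])

    summary: dict[str, BlockSummary] = {}
    for key in sorted(keys):
        series = np.array([counts.get(key, 0) for _, counts in rows], float)
        nb = min(n_blocks, len(series))
        if nb >= 2:
            summary[key] = block_average(series, n_blocks=nb)
        else:
            summary[key] = BlockSummary(float(series.mean()), 0.0, 1, len(series))
    return HBondCount(per_frame=per_frame, summary=summary)
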