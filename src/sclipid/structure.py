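"""Area per lipid, bilayer thickness, and chain order parameters.

The chain order parameter for an interior carbon C_n is

    S_z = (3 <cos^2 theta_z> - 1) / 2,

where theta_z is the angle between the bilayer normal (z) and the
vector from C_{n-1} to C_{n+1}, and the average runs over all lipids of
the chain class and all frames.  S_z is 1 for a chain parallel to the
normal, -0.5 for a perpendicular chain, and 0 for an isotropic
orientation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityProfile
from .stats import BlockSummary, block_average
from .topology import ChainDefinition, Trajectory

__all__ = [
    "OrderProfile",
    "area_per_lipid",
    "area_per_lipid_series",
    "bilayer_thickness",
    "order_parameters",
]


@dataclass
class OrderProfile:
    """Per-carbon order parameters for one chain class.

    ``carbon_index`` is 1-based from the headgroup end; entries cover
    the interior carbons 2 … N-1 (terminal carbons have no
    C_{n-1}→C_{n+1} vector).  ``uncertainty`` is the standard error of
    the per-frame mean across frames (zero for a single frame).
    """

    chain_label: str
    carbon_index: np.ndarray
    s_z: np.ndarray
    uncertainty: np.ndarray

    def __post_init__(self) -> None:
        self.carbon_index = np.asarray(self.carbon_index, dtype=int)
        self.s_z = np.asarray(self.s_z, dtype=float)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        if np.any(self.s_z < -0.5 - 1e-9) or np.any(self.s_z > 1 + 1e-9):
            raise ValueError("S_z out of the physical range [-0.5, 1]")


def area_per_lipid_series(traj: Trajectory, n_lipids_per_leaflet: int) -> np.ndarray:
    """Per-frame lateral box area / lipids per leaflet, in nm^2."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be positive")
    return np.array([f.box[0] * f.box[1] / n_lipids_per_leaflet for f in traj])


def area_per_lipid(
    traj: Trajectory, n_lipids_per_leaflet: int, n_blocks: int = 10
) -> BlockSummary:
    """Block-averaged area per lipid (nm^2)."""
    series = area_per_lipid_series(traj, n_lipids_per_leaflet)
    if len(series) < n_blocks:
        n_blocks = max(2, len(series)) if len(series) >= 2 else 1
    if len(series) == 1:
        return BlockSummary(mean=float(series[0]), sem=0.0, n_blocks=1,
                            block_length=1)
    return block_average(series, n_blocks=n_blocks)


def bilayer_thickness(headgroup_profile: DensityProfile) -> float:
    """Peak-to-peak distance of a midplane-centred headgroup profile (nm).

    Takes the maximum-density bin on each side of z = 0; resolution is
    therefore one bin width.  Raises if either side carries no density.
    """
    z = headgroup_profile.bin_centers
    rho = headgroup_profile.density
    neg = z < 0
    pos = z > 0
    if not (rho[neg] > 0).any() or not (rho[pos] > 0).any():
        raise ValueError(
            "no peak pair: headgroup density must be positive on both sides "
            "of the midplane"
        )
    z_lo = z[neg][np.argmax(rho[neg])]
    z_hi = z[pos][np.argmax(rho[pos])]
    return float(z_hi - z_lo)


def order_parameters(
    traj: Trajectory, chains: list[ChainDefinition] | None = None
) -> dict[str, OrderProfile]:
    """Chain order parameter S_z per interior carbon, per chain class.

    ``chains`` defaults to the chain definitions stored on the
    trajectory's topology.  cos^2(theta) is averaged over all chain
    instances of a class within each frame, then over frames; the
    (3x-1)/2 transform is applied to the ensemble average.  C_{n-1} to
    C_{n+1} vectors are taken with the minimum-image convention so
    chains wrapped across the periodic box are handled.
    """
    if chains is None:
        chains = traj.topology.chain_definitions()
    if not chains:
        raise ValueError("no chain definitions available")
    by_label: dict[str, list[ChainDefinition]] = {}
    n_carbons: dict[str, int] = {}
    for ch in chains:
        by_label.setdefault(ch.chain_label, []).append(ch)
        n_carbons.setdefault(ch.chain_label, len(ch.carbon_ids))
        if len(ch.carbon_ids) != n_carbons[ch.chain_label]:
            raise ValueError(
                f"chains labelled {ch.chain_label!r} have inconsistent lengths"
            )

    out: dict[str, OrderProfile] = {}
    for label, chain_list in by_label.items():
        ids = np.array([ch.carbon_ids for ch in chain_list])  # (n_chains, N)
        n_interior = ids.shape[1] - 2
        per_frame = np.empty((len(traj), n_interior))
        for fi, frame in enumerate(traj):
            p = frame.positions
            vec = p[ids[:, 2:]] - p[ids[:, :-2]]  # (n_chains, N-2, 3)
            # minimum image on orthorhombic box
            vec -= frame.box * np.round(vec / frame.box)
            cos2 = vec[..., 2] ** 2 / np.sum(vec ** 2, axis=-1)
            per_frame[fi] = cos2.mean(axis=0)
        mean_cos2 = per_frame.mean(axis=0)
        s_z = (3.0 * mean_cos2 - 1.0) / 2.0
        if len(traj) > 1:
            sem = 1.5 * per_frame.std(axis=0, ddof=1) / np.sqrt(len(traj))
        else:
            sem = np.zeros(n_interior)
        out[label] = OrderProfile(
            chain_label=label,
            carbon_index=np.arange(2, 2 + n_interior),
            s_z=s_z,
            uncertainty=sem,
        )
    return out
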