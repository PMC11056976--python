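"""Partial mass-density profiles along the bilayer normal (z).

A profile is built by splitting the instantaneous box into ``n_slices``
equal z-slices per frame, summing the mass of the selected atoms whose
(wrapped) z falls in each slice, dividing by the instantaneous slice
volume and averaging over frames.  With midplane centering the frame is
shifted each frame so the lipid centre of mass sits at z = 0 and bin
centres are reported relative to the midplane; with no centering bin
centres run over [0, Lz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .topology import LIPID_SPECIES, Species, Trajectory
from .units import AMU_PER_NM3_TO_KG_M3

__all__ = ["DensityProfile", "density_profile", "bulk_density"]


@dataclass
class DensityProfile:
    """Mass-density profile of one selection along z.

    ``bin_centers`` in nm, ``density`` in kg/m^3 averaged over
    ``n_frames_averaged`` frames.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    selection_label: str
    n_frames_averaged: int

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_centers.shape != self.density.shape:
            raise ValueError("bin_centers and density must have equal length")
        widths = np.diff(self.bin_centers)
        if len(widths) and not np.allclose(widths, widths[0]):
            raise ValueError("bins must be equal-width and ordered")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])


def density_profile(
    traj: Trajectory,
    selection: Species | str | Sequence[Species | str] | None = None,
    names: Sequence[str] | None = None,
    n_slices: int = 50,
    centering: str = "bilayer-midplane",
) -> DensityProfile:
    """Average mass-density profile of a selection along z.

    ``selection`` filters by species, ``names`` by atom name; both
    ``None`` selects all atoms.  ``centering`` is ``"bilayer-midplane"``
    (shift the lipid centre of mass to z = 0 each frame) or ``"none"``.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be at least 2")
    if centering not in ("bilayer-midplane", "none"):
        raise ValueError(f"unknown centering mode {centering!r}")
    if len(traj) == 0:
        raise ValueError("empty trajectory")

    top = traj.topology
    idx = top.select(species=selection, names=names)
    label = _selection_label(selection, names)
    if idx.size == 0:
        warnings.warn(f"selection {label!r} matches no atoms; profile is zero")
    masses = top.masses[idx]

    lipid_idx = top.select(species=list(LIPID_SPECIES))
    lipid_masses = top.masses[lipid_idx]

    acc = np.zeros(n_slices)
    lz_acc = 0.0
    for frame in traj:
        lz = frame.box[2]
        dz = lz / n_slices
        z = frame.positions[:, 2].copy()
        if centering == "bilayer-midplane":
            if lipid_idx.size:
                zc = np.average(np.mod(z[lipid_idx], lz), weights=lipid_masses)
            else:
                zc = lz / 2.0
            z = z - zc + lz / 2.0  # lipid COM to box centre, bins relative to it
        zw = np.mod(z[idx], lz)
        bins = np.minimum((zw / dz).astype(int), n_slices - 1)
        mass_per_bin = np.bincount(bins, weights=masses, minlength=n_slices)
        slice_volume = frame.box[0] * frame.box[1] * dz  # nm^3
        acc += mass_per_bin / slice_volume
        lz_acc += lz

    density = acc / len(traj) * AMU_PER_NM3_TO_KG_M3
    lz_mean = lz_acc / len(traj)
    dz_mean = lz_mean / n_slices
    centers = (np.arange(n_slices) + 0.5) * dz_mean
    if centering == "bilayer-midplane":
        centers = centers - lz_mean / 2.0
    return DensityProfile(centers, density, label, len(traj))


def _selection_label(selection, names) -> str:
    parts = []
    if selection is not None:
        if isinstance(selection, (str, Species)):
            selection = [selection]
        parts.append("+".join(str(Species(s)) for s in selection))
    if names is not None:
        parts.append("name:" + "+".join(names))
    return " ".join(parts) if parts else "all"


def bulk_density(
    profile: DensityProfile,
    bulk_region: tuple[float, float] | Sequence[tuple[float, float]],
) -> float:
    """Mean density over the bins whose centres fall inside the region(s).

    ``bulk_region`` is one (z_lo, z_hi) interval or a sequence of them
    (e.g. a symmetric pair on either side of the bilayer).
    """
    regions = [bulk_region] if np.isscalar(bulk_region[0]) else list(bulk_region)
    mask = np.zeros_like(profile.bin_centers, dtype=bool)
    for lo, hi in regions:
        if hi < lo:
            lo, hi = hi, lo
        mask |= (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    if not mask.any():
        raise ValueError("bulk region covers no profile bins")
    return float(profile.density[mask].mean())
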