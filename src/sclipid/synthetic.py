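"""Synthetic bilayer, solvent, H-bond and free-energy fixtures.

Every generator here produces configurations with *known ground truth*
so that the analysis layer can be validated exactly: straight tilted
chains give a closed-form order parameter, headgroup planes at ±d/2
give a known thickness, planted donor–hydrogen–acceptor triplets give a
known bond count, and Crooks-consistent Gaussian work distributions
give a known free-energy difference.  None of this is a physical model
of a gel-phase membrane — packing, energetics and dynamics are not
emulated — it is a geometric stand-in whose analytical answers are
exact.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import (
    Atom,
    Frame,
    HBondRole,
    Species,
    Topology,
    Trajectory,
)
from .units import GAS_CONSTANT_KJ

__all__ = [
    "BilayerSpec",
    "SolventSpec",
    "build_bilayer",
    "add_solvent",
    "plant_hbond_fixture",
    "sample_fep_work",
    "solvent_composition",
    "CC_STEP_NM",
]

# z-projection step between successive chain carbons for an untilted
# chain; roughly the 0.127 nm per-carbon rise of an all-trans chain.
CC_STEP_NM = 0.127

# Headgroup pseudo-atom masses (amu): CER[NS]24 amide headgroup is the
# heaviest, then the FFA carboxyl, then the CHOL hydroxyl.
_HEAD_MASSES = {Species.CER: 80.0, Species.FFA: 45.0, Species.CHOL: 17.0}
_HEAD_NAMES = {Species.CER: "OCER", Species.FFA: "OFFA", Species.CHOL: "OCHL"}
_RESNAMES = {Species.CER: "CER", Species.FFA: "FFA", Species.CHOL: "CHL"}

M_WATER = 18.015       # g/mol
M_PROPYLENE_GLYCOL = 76.09  # g/mol


@dataclass
class BilayerSpec:
    """Geometry of a synthetic two-leaflet bilayer.

    ``leaflet_separation`` is the headgroup-plane to headgroup-plane
    distance d (nm); headgroup reference atoms sit exactly on the
    planes z_mid ± d/2.  ``tilt_angle`` is the polar angle θ0 (degrees)
    every chain direction makes with the bilayer normal;
    ``tilt_jitter`` is the standard deviation (degrees) of a per-chain
    Gaussian perturbation of that angle.  ``apl_target`` fixes the
    lateral box area via area = n_lipids_per_leaflet × apl_target.
    ``solvent_margin`` is the extra box height above each headgroup
    plane left for solvent.
    """

    n_lipids_per_leaflet: int = 36
    leaflet_separation: float = 4.89   # nm
    chain_length: int = 16             # carbons per chain
    tilt_angle: float = 0.0            # degrees
    tilt_jitter: float = 0.0           # degrees
    apl_target: float = 0.325          # nm^2
    species_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # CER, FFA, CHOL
    n_frames: int = 1
    solvent_margin: float = 2.0        # nm per side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet <= 0:
            raise ValueError("n_lipids_per_leaflet must be positive")
        if self.leaflet_separation <= 0:
            raise ValueError("leaflet_separation must be positive")
        if not (0 <= self.tilt_angle <= 90):
            raise ValueError("tilt_angle must be in [0, 90] degrees")
        if self.tilt_jitter < 0:
            raise ValueError("tilt_jitter must be non-negative")
        if abs(sum(self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species_mix fractions must sum to 1")
        if self.chain_length < 3:
            raise ValueError("chains need at least 3 carbons")


@dataclass
class SolventSpec:
    """Solvent slab with a water-excluded core and interfacial solute peaks.

    Water z-positions are uniform in the solvent region and identically
    zero inside |z − z_mid| < ``core_exclusion_halfwidth``.  Enhancer
    molecules are drawn from a mixture of a bulk-uniform component and
    two Gaussian peaks centred on the headgroup planes (z_mid ± d/2);
    ``interface_peak_amplitude`` is the peak/bulk density ratio minus 1.
    """

    n_water: int = 4000
    n_enhancer: int = 0
    interface_peak_amplitude: float = 0.0
    interface_peak_width: float = 0.3       # nm
    core_exclusion_halfwidth: float = 1.5   # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_water < 0 or self.n_enhancer < 0:
            raise ValueError("solvent counts must be non-negative")
        if self.interface_peak_width <= 0:
            raise ValueError("interface_peak_width must be positive")
        if self.core_exclusion_halfwidth <= 0:
            raise ValueError("core_exclusion_halfwidth must be positive")


def _species_counts(n: int, mix: tuple[float, float, float]) -> list[Species]:
    """Deterministic per-leaflet species assignment honouring the mix."""
    counts = [int(round(f * n)) for f in mix]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        counts[int(np.argmin(counts))] += 1
    order = [Species.CER, Species.FFA, Species.CHOL]
    labels: list[Species] = []
    for sp, c in zip(order, counts):
        labels.extend([sp] * c)
    return labels


def build_bilayer(spec: BilayerSpec) -> Trajectory:
    """Build a two-leaflet synthetic bilayer trajectory.

    Each lipid is a headgroup reference atom on its leaflet plane plus
    straight chains of ``chain_length`` carbons pointing toward the
    midplane; a straight chain makes every C_{n-1}→C_{n+1} vector
    collinear with the chain direction, so the chain order parameter of
    every interior carbon is exactly (3 cos²θ − 1)/2 for the drawn tilt
    θ.  CER lipids carry two chains (sphingosine and fatty-acid), FFA
    one, CHOL none.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.leaflet_separation
    n_leaf = spec.n_lipids_per_leaflet
    area = n_leaf * spec.apl_target
    lx = ly = float(np.sqrt(area))
    lz = d + 2 * spec.solvent_margin
    z_mid = lz / 2.0

    # chain z-extent at the nominal tilt must fit inside the bilayer
    extent = (spec.chain_length - 1) * CC_STEP_NM * np.cos(np.radians(spec.tilt_angle))
    if extent > d:
        raise ValueError(
            f"chains span {extent:.3f} nm along z at tilt {spec.tilt_angle} deg, "
            f"longer than the leaflet separation {d} nm"
        )

    species = _species_counts(n_leaf, spec.species_mix)
    atoms: list[Atom] = []
    lipid_slots: list[tuple[Species, int, float, list[tuple[str, list[int]]]]] = []
    # lay out the topology once; per-frame randomness moves positions only
    resid = 0
    chain_sets = {
        Species.CER: ("sphingosine", "ceramide-fatty-acid"),
        Species.FFA: ("free-fatty-acid",),
        Species.CHOL: (),
    }
    for leaflet_sign in (+1.0, -1.0):
        for sp in species:
            chains: list[tuple[str, list[int]]] = []
            head = Atom(
                len(atoms), _HEAD_NAMES[sp], resid, _RESNAMES[sp],
                _HEAD_MASSES[sp], species=sp,
            )
            atoms.append(head)
            for label in chain_sets[sp]:
                ids = []
                for pos in range(spec.chain_length):
                    a = Atom(
                        len(atoms), f"C{pos + 1}", resid, _RESNAMES[sp],
                        12.011, species=sp, chain_label=label, chain_pos=pos,
                    )
                    atoms.append(a)
                    ids.append(a.atom_id)
                chains.append((label, ids))
            lipid_slots.append((sp, head.atom_id, leaflet_sign, chains))
            resid += 1

    topology = Topology(atoms)
    n_atoms = len(atoms)

    frames = []
    for f in range(spec.n_frames):
        pos = np.zeros((n_atoms, 3))
        for sp, head_id, sign, chains in lipid_slots:
            xy = rng.uniform(0.0, [lx, ly])
            z_head = z_mid + sign * d / 2.0
            pos[head_id] = (xy[0], xy[1], z_head)
            for _, ids in chains:
                theta = np.radians(spec.tilt_angle)
                if spec.tilt_jitter > 0:
                    theta = abs(theta + np.radians(spec.tilt_jitter) * rng.normal())
                    theta = min(theta, np.radians(89.9))
                phi = rng.uniform(0, 2 * np.pi)
                # chain direction: polar angle theta from the inward normal
                direction = np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    -sign * np.cos(theta),
                ])
                start = np.array([xy[0], xy[1], z_head])
                steps = CC_STEP_NM * np.arange(spec.chain_length)[:, None]
                pos[ids] = start + steps * direction
        frames.append(Frame(pos, np.array([lx, ly, lz]), time=float(f)))
    return Trajectory(topology, frames)


def add_solvent(traj: Trajectory, spec: SolventSpec) -> Trajectory:
    """Add single-site water and enhancer particles around the bilayer.

    The bilayer midplane is taken at Lz/2 (where :func:`build_bilayer`
    puts it).  Water is uniform in z outside the core-exclusion zone;
    enhancer density is bulk-uniform plus Gaussian interface peaks at
    the headgroup planes.
    """
    rng = np.random.default_rng(spec.seed)
    box = traj.frames[0].box
    lx, ly, lz = box
    z_mid = lz / 2.0
    h = spec.core_exclusion_halfwidth
    solvent_extent = lz - 2 * h
    if solvent_extent <= 0:
        raise ValueError(
            f"core exclusion (2x{h} nm) leaves no solvent region in a "
            f"{lz:.3f} nm box"
        )

    # infer the headgroup-plane offset from the lipid headgroup atoms
    lipid_heads = [
        a.atom_id for a in traj.topology
        if a.species in _HEAD_MASSES and a.chain_label is None
    ]
    if lipid_heads:
        zh = traj.frames[0].positions[lipid_heads, 2]
        d_half = float(np.mean(np.abs(zh - z_mid)))
    else:
        d_half = lz / 4.0

    def _uniform_outside_core(n: int) -> np.ndarray:
        # sample the two slabs [0, z_mid-h) and (z_mid+h, lz] directly
        u = rng.uniform(0.0, solvent_extent, size=n)
        z = np.where(u < z_mid - h, u, u + 2 * h)
        return z

    new_atoms = [
        Atom(a.atom_id, a.name, a.residue_id, a.residue_name, a.mass,
             species=a.species, hbond_role=a.hbond_role,
             hydrogen_ids=a.hydrogen_ids, chain_label=a.chain_label,
             chain_pos=a.chain_pos)
        for a in traj.topology
    ]
    next_id = len(new_atoms)
    next_resid = 1 + max((a.residue_id for a in new_atoms), default=-1)

    n_sol = spec.n_water + spec.n_enhancer
    for i in range(spec.n_water):
        new_atoms.append(Atom(next_id, "OW", next_resid, "SOL", M_WATER,
                              species=Species.WATER))
        next_id += 1
        next_resid += 1
    for i in range(spec.n_enhancer):
        new_atoms.append(Atom(next_id, "PG", next_resid, "PGOL",
                              M_PROPYLENE_GLYCOL, species=Species.ENHANCER))
        next_id += 1
        next_resid += 1
    topology = Topology(new_atoms)

    # mixture weight for the enhancer interface peaks: with amplitude a
    # (peak/bulk - 1) and width w, each Gaussian carries excess mass
    # a * rho_bulk * sqrt(2*pi) * w relative to the bulk line.
    a_amp = spec.interface_peak_amplitude
    w = spec.interface_peak_width
    peak_mass = 2.0 * a_amp * np.sqrt(2 * np.pi) * w
    p_peak = peak_mass / (solvent_extent + peak_mass) if n_sol else 0.0

    frames = []
    for old in traj.frames:
        pos = np.zeros((len(new_atoms), 3))
        pos[: old.n_atoms] = old.positions
        k = old.n_atoms
        if spec.n_water:
            zw = _uniform_outside_core(spec.n_water)
            xyw = rng.uniform(0.0, [lx, ly], size=(spec.n_water, 2))
            pos[k:k + spec.n_water] = np.column_stack([xyw, zw])
            k += spec.n_water
        if spec.n_enhancer:
            take_peak = rng.uniform(size=spec.n_enhancer) < p_peak
            n_peak = int(take_peak.sum())
            z = np.empty(spec.n_enhancer)
            z[~take_peak] = _uniform_outside_core(spec.n_enhancer - n_peak)
            centers = z_mid + d_half * rng.choice([-1.0, 1.0], size=n_peak)
            z[take_peak] = np.mod(centers + w * rng.normal(size=n_peak), lz)
            xye = rng.uniform(0.0, [lx, ly], size=(spec.n_enhancer, 2))
            pos[k:k + spec.n_enhancer] = np.column_stack([xye, z])
        frames.append(Frame(pos, old.box.copy(), time=old.time))
    return Trajectory(topology, frames)


def plant_hbond_fixture(
    n_bonded: int,
    n_near_miss: int,
    box: tuple[float, float, float] = (4.0, 4.0, 4.0),
    seed: int = 0,
    donor_species: Species = Species.WATER,
    acceptor_species: Species = Species.CER,
) -> tuple[Topology, Frame, int]:
    """Plant donor–hydrogen–acceptor triplets with a known bond count.

    Bonded triplets satisfy both geometric criteria (donor–acceptor
    distance < 0.35 nm, H–D···A angle at the donor < 30°); near misses
    violate exactly one of the two (distance in [0.36, 0.50] nm, or
    angle in [35°, 60°]).  The first bonded triplet is placed across
    the periodic boundary so that only a minimum-image detector finds
    it.  Returns ``(topology, frame, expected_count)`` with
    ``expected_count == n_bonded``.
    """
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    n_total = n_bonded + n_near_miss
    # triplet centres on a cubic grid with >= 1.6 nm spacing so that
    # cross-triplet pairs stay well outside any plausible cutoff
    spacing = 1.6
    n_cells = np.maximum(np.floor(box_arr / spacing).astype(int), 0)
    if n_total > 0 and np.prod(n_cells) < n_total:
        raise ValueError(
            f"box {tuple(box_arr)} nm holds only {int(np.prod(n_cells))} "
            f"separated fixture sites, need {n_total}"
        )
    cells = [(i, j, k)
             for i in range(n_cells[0])
             for j in range(n_cells[1])
             for k in range(n_cells[2])][:n_total]

    atoms: list[Atom] = []
    positions: list[np.ndarray] = []

    def _add(name: str, resid: int, mass: float, species: Species,
             role: HBondRole, pos: np.ndarray,
             hydrogen_ids: tuple[int, ...] = ()) -> int:
        resname = {Species.WATER: "SOL", Species.CER: "CER",
                   Species.FFA: "FFA", Species.CHOL: "CHL",
                   Species.ENHANCER: "PGOL"}[species]
        atoms.append(Atom(len(atoms), name, resid, resname, mass,
                          species=species, hbond_role=role,
                          hydrogen_ids=hydrogen_ids))
        positions.append(pos)
        return len(atoms) - 1

    def _random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    def _rotate_towards(axis: np.ndarray, angle_deg: float) -> np.ndarray:
        """Unit vector at the given angle from ``axis``, random azimuth."""
        axis = axis / np.linalg.norm(axis)
        perp = np.cross(axis, _random_unit())
        while np.linalg.norm(perp) < 1e-8:
            perp = np.cross(axis, _random_unit())
        perp /= np.linalg.norm(perp)
        ang = np.radians(angle_deg)
        return np.cos(ang) * axis + np.sin(ang) * perp

    resid = 0
    for t in range(n_total):
        center = (np.array(cells[t]) + 0.5) * spacing
        bonded = t < n_bonded
        if t == 0 and n_bonded > 0:
            # straddle the x-boundary: donor just inside x=0, acceptor
            # beyond it so wrapping sends it to the far side
            donor_pos = np.array([0.05, center[1], center[2]])
            da_dir = np.array([-1.0, 0.0, 0.0])
        else:
            donor_pos = center
            da_dir = _random_unit()
        if bonded:
            r = rng.uniform(0.26, 0.34)
            ang = rng.uniform(0.0, 25.0)
        else:
            if t % 2 == 0:   # distance violation, angle fine
                r = rng.uniform(0.36, 0.50)
                ang = rng.uniform(0.0, 25.0)
            else:            # angle violation, distance fine
                r = rng.uniform(0.26, 0.34)
                ang = rng.uniform(35.0, 60.0)
        acceptor_pos = donor_pos + r * da_dir
        h_dir = _rotate_towards(da_dir, ang)
        h_pos = donor_pos + 0.1 * h_dir

        d_id = _add("OD", resid, 15.999, donor_species, HBondRole.DONOR,
                    donor_pos)
        h_id = _add("HD", resid, 1.008, donor_species, HBondRole.NONE, h_pos)
        atoms[d_id].hydrogen_ids = (h_id,)
        resid += 1
        _add("OA", resid, 15.999, acceptor_species, HBondRole.ACCEPTOR,
             acceptor_pos)
        resid += 1

    pos = np.mod(np.array(positions).reshape(-1, 3), box_arr) if atoms \
        else np.zeros((0, 3))
    return Topology(atoms), Frame(pos, box_arr), n_bonded


def sample_fep_work(
    dG_true: float,
    sigma: float,
    n: int,
    seed: int = 0,
    temperature: float = 298.15,
    window_index: int = 0,
):
    """Draw Crooks-consistent Gaussian work samples for one λ-window.

    ``dG_true`` and ``sigma`` are in units of kT.  Forward work is
    Normal(dG_true + σ²/2, σ²) and reverse work Normal(−dG_true + σ²/2,
    σ²), the unique Gaussian pair satisfying the Crooks fluctuation
    relation with free-energy difference ``dG_true``.  Samples are
    returned in kJ/mol at the given temperature.
    """
    from .free_energy import FEWindowSamples

    if n < 2:
        raise ValueError("need at least 2 samples per direction")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    kt = GAS_CONSTANT_KJ * temperature  # kJ/mol per kT
    fwd = dG_true + sigma ** 2 / 2.0 + sigma * rng.normal(size=n)
    rev = -dG_true + sigma ** 2 / 2.0 + sigma * rng.normal(size=n)
    return FEWindowSamples(
        window_index=window_index,
        forward=fwd * kt,
        reverse=rev * kt,
        temperature=temperature,
    )


def solvent_composition(
    mass_fraction: float,
    total_molecules: int,
    m_enhancer: float = M_PROPYLENE_GLYCOL,
    m_water: float = M_WATER,
) -> tuple[int, int]:
    """Split a fixed molecule budget into enhancer/water by mass fraction.

    Solves x·M_e / (x·M_e + (N−x)·M_w) = mass_fraction for x and rounds
    to the nearest integer; returns (n_enhancer, n_water).
    """
    if not (0.0 <= mass_fraction <= 1.0):
        raise ValueError("mass_fraction must be in [0, 1]")
    if total_molecules <= 0:
        raise ValueError("total_molecules must be positive")
    if m_enhancer <= 0 or m_water <= 0:
        raise ValueError("molar masses must be positive")
    N = total_molecules
    f = mass_fraction
    # x*M_e*(1-f) = f*(N-x)*M_w  =>  x = f*N*M_w / ((1-f)*M_e + f*M_w)
    denom = (1.0 - f) * m_enhancer + f * m_water
    x = f * N * m_water / denom if denom > 0 else float(N)
    n_enh = int(round(x))
    n_enh = min(max(n_enh, 0), N)
    return n_enh, N - n_enh
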