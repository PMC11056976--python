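"""Shared data model: atoms, topologies, frames, trajectories, chains.

Internal units are fixed throughout the package: lengths in nm, time in
ps, masses in atomic-mass units, energies in kJ/mol, temperature in K.
Atom ids are 0-based internally; file formats (GRO/PDB) use 1-based
serials and the converters at the format boundary handle the shift.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np


class Species(str, enum.Enum):
    """Molecular species classes of a stratum-corneum bilayer system."""

    CER = "CER"          # ceramide (e.g. CER[NS]24)
    FFA = "FFA"          # free fatty acid (e.g. FA24, lignoceric acid)
    CHOL = "CHOL"        # cholesterol
    WATER = "WATER"
    ENHANCER = "ENHANCER"  # penetration enhancer (propylene glycol)
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


LIPID_SPECIES = frozenset({Species.CER, Species.FFA, Species.CHOL})


class HBondRole(str, enum.Enum):
    NONE = "none"
    DONOR = "donor"
    ACCEPTOR = "acceptor"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class Atom:
    """One atom of the topology.

    ``hydrogen_ids`` lists the 0-based ids of hydrogens covalently
    attached to a donor heavy atom; it must be non-empty when
    ``hbond_role`` is DONOR and is ignored otherwise.  ``chain_label``
    and ``chain_pos`` record chain membership for order-parameter
    analysis (position counted from the headgroup end, 0-based).
    """

    atom_id: int
    name: str
    residue_id: int
    residue_name: str
    mass: float
    species: Species = Species.UNKNOWN
    hbond_role: HBondRole = HBondRole.NONE
    hydrogen_ids: tuple[int, ...] = ()
    chain_label: str | None = None
    chain_pos: int | None = None


@dataclass(frozen=True)
class ChainDefinition:
    """Ordered carbon ids of one acyl chain, headgroup end (C1) first.

    ``chain_label`` names the chain class: ``sphingosine`` and
    ``ceramide-fatty-acid`` for the two ceramide tails,
    ``free-fatty-acid`` for the FFA tail.
    """

    chain_label: str
    carbon_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.carbon_ids) < 3:
            raise ValueError(
                f"chain {self.chain_label!r} needs >=3 carbons, "
                f"got {len(self.carbon_ids)}"
            )
        if len(set(self.carbon_ids)) != len(self.carbon_ids):
            raise ValueError(f"chain {self.chain_label!r} has duplicate carbon ids")


class Topology:
    """Atom metadata for one system; validates invariants on construction."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atom ids in topology")
        idset = set(ids)
        for a in self.atoms:
            if a.mass <= 0:
                raise ValueError(f"atom {a.atom_id} has non-positive mass {a.mass}")
            if a.hbond_role is HBondRole.DONOR:
                if not a.hydrogen_ids:
                    raise ValueError(
                        f"donor atom {a.atom_id} ({a.name}) lists no attached hydrogen"
                    )
                missing = [h for h in a.hydrogen_ids if h not in idset]
                if missing:
                    raise ValueError(
                        f"donor atom {a.atom_id} references missing hydrogens {missing}"
                    )
        self._by_id = {a.atom_id: a for a in self.atoms}

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def atom(self, atom_id: int) -> Atom:
        return self._by_id[atom_id]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def species_array(self) -> np.ndarray:
        return np.array([a.species.value for a in self.atoms])

    def select(
        self,
        species: Species | str | Sequence[Species | str] | None = None,
        names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Indices (positional) of atoms matching a species and/or name filter."""
        mask = np.ones(len(self.atoms), dtype=bool)
        if species is not None:
            if isinstance(species, (str, Species)):
                species = [species]
            wanted = {Species(s) for s in species}
            mask &= np.array([a.species in wanted for a in self.atoms])
        if names is not None:
            nameset = set(names)
            mask &= np.array([a.name in nameset for a in self.atoms])
        return np.nonzero(mask)[0]

    def chain_definitions(self) -> list[ChainDefinition]:
        """Rebuild ChainDefinitions from per-atom chain membership.

        Atoms sharing (residue_id, chain_label) form one chain, ordered
        by ``chain_pos``.
        """
        groups: dict[tuple[int, str], list[Atom]] = {}
        for a in self.atoms:
            if a.chain_label is not None:
                groups.setdefault((a.residue_id, a.chain_label), []).append(a)
        chains = []
        for (_, label), atoms in sorted(groups.items()):
            atoms.sort(key=lambda a: a.chain_pos)
            chains.append(
                ChainDefinition(label, tuple(a.atom_id for a in atoms))
            )
        return chains


@dataclass
class Frame:
    """One configuration: positions (n_atoms, 3) in nm, orthorhombic box."""

    positions: np.ndarray
    box: np.ndarray  # (Lx, Ly, Lz) in nm
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.box.shape != (3,):
            raise ValueError("box must be three orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise ValueError(f"box edges must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> np.ndarray:
        """Positions wrapped into the primary box [0, L)."""
        return np.mod(self.positions, self.box)


class Trajectory:
    """Time-ordered frames over one topology."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory must contain at least one frame")
        n = len(topology)
        for f in frames:
            if f.n_atoms != n:
                raise ValueError(
                    f"frame has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in frames]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frames must be time-ordered")
        self.topology = topology
        self.frames = frames

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


def classify_species(
    topology: Topology,
    rules: Mapping[str, Species | str],
    default: Species | str | None = None,
) -> Topology:
    """Populate the species field from residue-name rules.

    Every residue name must be matched by ``rules`` unless ``default``
    is given.  Idempotent: reapplying the same rules is a no-op.
    """
    norm = {k: Species(v) for k, v in rules.items()}
    unmatched = sorted(
        {a.residue_name for a in topology if a.residue_name not in norm}
    )
    if unmatched and default is None:
        raise ValueError(
            "no species rule for residue name(s) "
            + ", ".join(repr(n) for n in unmatched)
            + " and no default provided"
        )
    default_sp = Species(default) if default is not None else None
    atoms = [
        replace(a, species=norm.get(a.residue_name, default_sp))
        for a in topology.atoms
    ]
    return Topology(atoms)
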