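"""Readers and writers at the format boundary.

GRO files store nm, PDB files store ångström; everything is normalised
to nm on the way in.  Both readers accept only orthorhombic boxes (all
systems this package targets are rectangular); triclinic box records
raise :class:`UnsupportedFormatError`.  File serials are 1-based, the
in-memory atom ids are 0-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .topology import Atom, Frame, HBondRole, Species, Topology

__all__ = [
    "ParseError",
    "UnsupportedFormatError",
    "read_coordinates",
    "read_gro",
    "read_pdb",
    "write_gro",
    "write_table",
    "read_table",
    "apply_roles_table",
    "write_roles_table",
    "read_window_samples",
]


class ParseError(ValueError):
    """Malformed record in a coordinate file; carries the line number."""

    def __init__(self, path: str | os.PathLike, lineno: int, message: str):
        super().__init__(f"{path}, line {lineno}: {message}")
        self.lineno = lineno


class UnsupportedFormatError(ValueError):
    pass


# Standard atomic masses (amu) for the elements that occur in these
# systems; used when no explicit mass table accompanies the file.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06,
}


def _guess_mass(atom_name: str) -> float:
    stripped = atom_name.lstrip("0123456789")
    key = stripped[:1].upper()
    if key in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[key]
    raise ValueError(f"cannot infer element/mass from atom name {atom_name!r}")


def read_gro(path: str | os.PathLike) -> tuple[Topology, Frame]:
    """Read a single-frame GRO file (fixed columns, nm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise ParseError(path, len(lines), "file too short for a GRO frame")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(path, 2, f"expected atom count, got {lines[1]!r}") from None
    if len(lines) < n_atoms + 3:
        raise ParseError(
            path, len(lines), f"expected {n_atoms} atom lines plus a box line"
        )
    atoms: list[Atom] = []
    positions = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        lineno = i + 3
        ln = lines[i + 2]
        if len(ln) < 44:
            raise ParseError(path, lineno, "truncated coordinate line")
        try:
            resid = int(ln[0:5])
            resname = ln[5:10].strip()
            name = ln[10:15].strip()
            x = float(ln[20:28])
            y = float(ln[28:36])
            z = float(ln[36:44])
        except ValueError as exc:
            raise ParseError(path, lineno, f"bad fixed-column field: {exc}") from None
        positions[i] = (x, y, z)
        atoms.append(Atom(i, name, resid, resname, _guess_mass(name)))
    box_line = lines[n_atoms + 2].split()
    if len(box_line) not in (3, 9):
        raise ParseError(path, n_atoms + 3, "missing or malformed box line")
    vals = [float(v) for v in box_line]
    if len(vals) == 9 and any(abs(v) > 1e-9 for v in vals[3:]):
        raise UnsupportedFormatError(
            f"{path}: triclinic box not supported (off-diagonal elements present)"
        )
    box = np.array(vals[:3])
    return Topology(atoms), Frame(positions, box)


def read_pdb(path: str | os.PathLike) -> tuple[Topology, Frame]:
    """Read a single-model PDB file; coordinates converted Å -> nm."""
    atoms: list[Atom] = []
    coords: list[tuple[float, float, float]] = []
    box = None
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            rec = ln[:6].strip()
            if rec == "CRYST1":
                try:
                    a, b, c = float(ln[6:15]), float(ln[15:24]), float(ln[24:33])
                    al, be, ga = float(ln[33:40]), float(ln[40:47]), float(ln[47:54])
                except ValueError:
                    raise ParseError(path, lineno, "malformed CRYST1 record") from None
                if any(abs(ang - 90.0) > 1e-6 for ang in (al, be, ga)):
                    raise UnsupportedFormatError(
                        f"{path}: triclinic box not supported (angles {al}, {be}, {ga})"
                    )
                box = np.array([a, b, c]) / 10.0
            elif rec in ("ATOM", "HETATM"):
                if len(ln.rstrip("\n")) < 54:
                    raise ParseError(path, lineno, "truncated ATOM record")
                try:
                    name = ln[12:16].strip()
                    resname = ln[17:21].strip()
                    resid = int(ln[22:26])
                    x, y, z = float(ln[30:38]), float(ln[38:46]), float(ln[46:54])
                except ValueError as exc:
                    raise ParseError(path, lineno, f"bad ATOM field: {exc}") from None
                atoms.append(Atom(len(atoms), name, resid, resname, _guess_mass(name)))
                coords.append((x / 10.0, y / 10.0, z / 10.0))
            elif rec == "ENDMDL":
                break
    if box is None:
        raise ValueError(f"{path}: no CRYST1 box record found")
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return Topology(atoms), Frame(np.array(coords), box)


def read_coordinates(path: str | os.PathLike, format: str | None = None
                     ) -> tuple[Topology, Frame]:
    """Read a coordinate file, dispatching on ``format`` or the extension."""
    if format is None:
        format = os.path.splitext(str(path))[1].lstrip(".").lower()
    if format == "gro":
        return read_gro(path)
    if format == "pdb":
        return read_pdb(path)
    raise UnsupportedFormatError(f"unsupported coordinate format {format!r}")


def write_gro(path: str | os.PathLike, topology: Topology, frame: Frame,
              title: str = "sclipid frame") -> None:
    """Write one frame as GRO fixed columns (nm, %8.3f)."""
    with open(path, "w") as fh:
        fh.write(f"{title}\n{len(topology):5d}\n")
        for a, (x, y, z) in zip(topology, frame.positions):
            fh.write(
                f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}"
                f"{a.name:>5.5s}{(a.atom_id + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


def write_table(records: pd.DataFrame | dict, path: str | os.PathLike,
                float_format: str = "%.6g") -> None:
    """Write labelled numeric columns as TSV with a header row."""
    if isinstance(records, dict):
        lengths = {len(v) for v in records.values()}
        if len(lengths) > 1:
            raise ValueError("columns must have equal length")
    df = pd.DataFrame(records)
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def apply_roles_table(topology: Topology, path: str | os.PathLike) -> Topology:
    """Apply a sidecar TSV of species / H-bond roles / chain membership.

    Columns: ``atom_id`` (0-based), optional ``species``, ``mass``,
    ``hbond_role`` (none|donor|acceptor), ``hydrogen_ids``
    (comma-separated 0-based ids), ``chain_label``, ``chain_pos``.
    """
    df = read_table(path)
    by_id = {a.atom_id: a for a in topology.atoms}
    for _, row in df.iterrows():
        a = by_id[int(row["atom_id"])]
        if "species" in df.columns and not pd.isna(row["species"]):
            a.species = Species(row["species"])
        if "mass" in df.columns and not pd.isna(row["mass"]):
            a.mass = float(row["mass"])
        if "hbond_role" in df.columns and not pd.isna(row["hbond_role"]):
            a.hbond_role = HBondRole(row["hbond_role"])
        if "hydrogen_ids" in df.columns and not pd.isna(row["hydrogen_ids"]):
            a.hydrogen_ids = tuple(
                int(h) for h in str(row["hydrogen_ids"]).split(",") if h != ""
            )
        if "chain_label" in df.columns and not pd.isna(row["chain_label"]):
            a.chain_label = str(row["chain_label"])
        if "chain_pos" in df.columns and not pd.isna(row["chain_pos"]):
            a.chain_pos = int(row["chain_pos"])
    return Topology(topology.atoms)


def write_roles_table(topology: Topology, path: str | os.PathLike) -> None:
    rows = []
    for a in topology:
        rows.append({
            "atom_id": a.atom_id,
            "species": a.species.value,
            "mass": a.mass,
            "hbond_role": a.hbond_role.value,
            "hydrogen_ids": ",".join(str(h) for h in a.hydrogen_ids),
            "chain_label": a.chain_label if a.chain_label is not None else "",
            "chain_pos": a.chain_pos if a.chain_pos is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_window_samples(path: str | os.PathLike, temperature: float):
    """Read per-window forward/reverse energy differences from TSV.

    Expected columns: ``window`` (integer index), ``direction``
    (``fwd``/``rev``), ``dU_kJ_per_mol``.  Returns a list of
    :class:`~sclipid.free_energy.FEWindowSamples` ordered by window.
    """
    from .free_energy import FEWindowSamples

    df = read_table(path)
    required = {"window", "direction", "dU_kJ_per_mol"}
    if not required.issubset(df.columns):
        raise ValueError(f"window-sample table needs columns {sorted(required)}")
    windows = []
    for w, grp in df.groupby("window", sort=True):
        fwd = grp.loc[grp["direction"] == "fwd", "dU_kJ_per_mol"].to_numpy(float)
        rev = grp.loc[grp["direction"] == "rev", "dU_kJ_per_mol"].to_numpy(float)
        windows.append(FEWindowSamples(
            window_index=int(w), forward=fwd, reverse=rev,
            temperature=temperature,
        ))
    return windows
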