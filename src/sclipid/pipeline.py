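"""End-to-end orchestration: config, run manifest, and the full analysis chain.

A run takes a trajectory (either generated synthetically or loaded from
a GRO file plus a sidecar roles table), restricts it to the analysis
window (final 80% of frames by default), and produces density profiles,
area per lipid, bilayer thickness, chain order parameters, H-bond
counts and the water PMF, each as a TSV with units in the header, plus
a machine-readable manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .density import bulk_density, density_profile
from .free_energy import pmf_from_density
from .hbonds import count_by_species
from .io import apply_roles_table, read_coordinates, write_gro, write_roles_table, write_table
from .stats import analysis_window
from .structure import area_per_lipid, area_per_lipid_series, bilayer_thickness, order_parameters
from .synthetic import BilayerSpec, SolventSpec, add_solvent, build_bilayer
from .topology import Species, Trajectory

logger = logging.getLogger("sclipid")

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


@dataclass
class RunConfig:
    output_dir: str = "sclipid_out"
    # input: either synthetic generation or a coordinate file + roles table
    synthetic: bool = True
    coordinates: str | None = None
    roles_table: str | None = None
    bilayer: dict = field(default_factory=dict)
    solvent: dict = field(default_factory=dict)
    # analysis parameters
    n_slices: int = 50
    analysis_window_fraction: float = 0.8
    n_blocks: int = 10
    hbond_distance_cutoff: float = 0.35   # nm
    hbond_angle_cutoff: float = 30.0      # degrees
    temperature: float = 305.0            # K
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic:
            if not self.coordinates:
                raise ConfigError("coordinates path required when synthetic=false")
            for p in (self.coordinates, self.roles_table):
                if p and not os.path.exists(p):
                    raise ConfigError(f"input path does not exist: {p}")
        if self.n_slices < 2:
            raise ConfigError("n_slices must be >= 2")
        if not (0 < self.analysis_window_fraction <= 1):
            raise ConfigError("analysis_window_fraction must be in (0, 1]")
        if self.hbond_distance_cutoff <= 0 or self.hbond_angle_cutoff <= 0:
            raise ConfigError("H-bond cutoffs must be positive")
        if self.temperature <= 0:
            raise ConfigError("temperature must be positive")


def load_config(path: str | os.PathLike, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file; ``overrides`` (e.g. CLI flags) win."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def _load_trajectory(cfg: RunConfig) -> Trajectory:
    if cfg.synthetic:
        bspec = BilayerSpec(**{**cfg.bilayer, "seed": cfg.bilayer.get("seed", cfg.seed)})
        logger.info("building synthetic bilayer: %d lipids/leaflet, %d frames",
                    bspec.n_lipids_per_leaflet, bspec.n_frames)
        traj = build_bilayer(bspec)
        if cfg.solvent:
            sspec = SolventSpec(**{**cfg.solvent,
                                   "seed": cfg.solvent.get("seed", cfg.seed + 1)})
            traj = add_solvent(traj, sspec)
        return traj
    topology, frame = read_coordinates(cfg.coordinates)
    if cfg.roles_table:
        topology = apply_roles_table(topology, cfg.roles_table)
    return Trajectory(topology, [frame])


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every analysis stage; returns a dict of in-memory results."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "package": "sclipid",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "outputs": [],
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        traj = _load_trajectory(cfg)
        win = analysis_window(len(traj), cfg.analysis_window_fraction)
        traj = Trajectory(traj.topology, traj.frames[win])
        manifest["n_frames_analysed"] = len(traj)

        _stage("density")
        profiles = {}
        present = {a.species for a in traj.topology}
        for sp in [Species.CER, Species.FFA, Species.CHOL,
                   Species.WATER, Species.ENHANCER]:
            if sp in present:
                profiles[sp.value] = density_profile(
                    traj, selection=sp, n_slices=cfg.n_slices)
        rows = {
            "bin_center_nm": next(iter(profiles.values())).bin_centers,
        }
        for name, prof in profiles.items():
            rows[f"density_{name}_kg_m3"] = prof.density
        write_table(rows, out / "density_profiles.tsv")
        manifest["outputs"].append("density_profiles.tsv")
        results["profiles"] = profiles

        _stage("area_per_lipid")
        n_leaf = _lipids_per_leaflet(traj)
        if n_leaf:
            series = area_per_lipid_series(traj, n_leaf)
            apl = area_per_lipid(traj, n_leaf,
                                 n_blocks=min(cfg.n_blocks, max(2, len(traj))))
            write_table({"frame": np.arange(len(series)),
                         "apl_nm2": series}, out / "apl_series.tsv")
            manifest["outputs"].append("apl_series.tsv")
            results["apl"] = apl

        _stage("thickness")
        if Species.CER in present:
            head_prof = density_profile(
                traj, selection=Species.CER, names=_headgroup_names(traj),
                n_slices=cfg.n_slices)
            thickness = bilayer_thickness(head_prof)
            write_table({"thickness_nm": [thickness],
                         "bin_width_nm": [head_prof.bin_width]},
                        out / "thickness.tsv")
            manifest["outputs"].append("thickness.tsv")
            results["thickness"] = thickness

        _stage("order_parameters")
        chains = traj.topology.chain_definitions()
        if chains:
            order = order_parameters(traj, chains)
            recs = []
            for label, prof in order.items():
                for n, s, e in zip(prof.carbon_index, prof.s_z, prof.uncertainty):
                    recs.append({"chain": label, "carbon_index": int(n),
                                 "S_z": s, "stderr": e})
            write_table(
                {k: [r[k] for r in recs] for k in ("chain", "carbon_index",
                                                   "S_z", "stderr")},
                out / "order_parameters.tsv")
            manifest["outputs"].append("order_parameters.tsv")
            results["order"] = order

        _stage("hbonds")
        has_donors = any(a.hydrogen_ids for a in traj.topology)
        if has_donors:
            hb = count_by_species(traj, d_cut=cfg.hbond_distance_cutoff,
                                  angle_cut=cfg.hbond_angle_cutoff,
                                  n_blocks=cfg.n_blocks)
            hb.per_frame.to_csv(out / "hbonds_per_frame.tsv", sep="\t", index=False)
            write_table({
                "species_pair": list(hb.summary),
                "mean_count": [s.mean for s in hb.summary.values()],
                "sem": [s.sem for s in hb.summary.values()],
            }, out / "hbonds_summary.tsv")
            manifest["outputs"] += ["hbonds_per_frame.tsv", "hbonds_summary.tsv"]
            results["hbonds"] = hb

        _stage("pmf")
        if Species.WATER in present:
            wprof = profiles[Species.WATER.value]
            lz = traj.frames[0].box[2]
            edge = lz / 2.0
            region = [(-edge, -edge + 1.0), (edge - 1.0, edge)]
            rho_bulk = bulk_density(wprof, region)
            if rho_bulk > 0:
                pmf = pmf_from_density(wprof, rho_bulk, T=cfg.temperature)
                pmf.to_csv(out / "water_pmf.tsv", sep="\t", index=False)
                manifest["outputs"].append("water_pmf.tsv")
                results["pmf"] = pmf

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        results["manifest"] = manifest
        return results
    except Exception:
        logger.exception("pipeline stage failed; partial outputs kept in %s", out)
        raise


def _lipids_per_leaflet(traj: Trajectory) -> int:
    lipid_resids = {a.residue_id for a in traj.topology
                    if a.species in (Species.CER, Species.FFA, Species.CHOL)}
    return len(lipid_resids) // 2


def _headgroup_names(traj: Trajectory) -> list[str]:
    names = {a.name for a in traj.topology
             if a.species is Species.CER and a.chain_label is None}
    return sorted(names)
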