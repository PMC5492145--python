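"""End-to-end analysis runs: config in, TSV/JSON artifacts out.

`run_pipeline` wires the generators, readers and analysis stages together
and writes one artifact per requested stage plus a provenance block
(effective config, package version, seed).  With a fixed seed the whole
run — simulate, detect, conductance, bootstrap, hydration — is
reproducible byte for byte.  Logs go to stderr; results go to files only.
"""
from __future__ import annotations

import logging
import os
import time

import numpy as np

from . import __version__
from .config import RunConfig
from .errors import ConfigError
from .hydration import flux_water_correlation, pore_water_count, windowed_flux
from .io import read_structure, read_trajectory, write_json_summary, write_table
from .model import Trajectory
from .permeation import bootstrap_conductance, cumulative_flux, detect_crossings
from .structure import RegionSelection, region_rmsd
from .coordination import (
    detect_salt_bridges,
    detect_substitutions,
    metal_coordination,
)
from .synthetic import (
    ChannelSimConfig,
    LigaseSimConfig,
    gen_channel_trajectory,
    gen_ligase_trajectory,
)

logger = logging.getLogger(__name__)


def _load_input(config: RunConfig):
    """Return (trajectory, ground_truth_or_None)."""
    if config.simulate is not None:
        kind = config.simulate["kind"]
        kw = dict(config.simulate.get("config", {}))
        kw.setdefault("seed", config.seed)
        if kind == "channel":
            return gen_channel_trajectory(ChannelSimConfig(**kw))
        return gen_ligase_trajectory(LigaseSimConfig(**kw))
    if config.topology is None:
        raise ConfigError("field 'topology': required when reading a trajectory")
    if not os.path.exists(config.topology):
        raise ConfigError(f"missing input: {config.topology}")
    if not os.path.exists(config.trajectory):
        raise ConfigError(f"missing input: {config.trajectory}")
    structure = read_structure(config.topology)
    traj = read_trajectory(config.trajectory, structure.topology, dt=config.dt)
    return traj, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; returns {stage: artifact path(s)}."""
    os.makedirs(config.outdir, exist_ok=True)
    t_start = time.perf_counter()
    traj, truth = _load_input(config)
    logger.info("input ready: %d frames, %d atoms (%.1f s)",
                traj.n_frames, traj.topology.n_atoms,
                time.perf_counter() - t_start)
    artifacts: dict[str, list[str]] = {}
    chan = config.channel_definition() if config.channel else None
    top = traj.topology

    events = None

    def _events():
        nonlocal events
        if events is None:
            if chan is None:
                raise ConfigError("field 'channel': required for permeation stages")
            ions = top.select(residue_names=set(config.ion_species))
            events = detect_crossings(traj, chan, ions)
        return events

    t_total = traj.duration

    for stage in config.stages:
        t0 = time.perf_counter()
        paths: list[str] = []
        if stage == "flux":
            ev = _events()
            flux = cumulative_flux(ev, traj.times)
            rows = {"time_ns": flux.grid}
            for sp in flux.total:
                rows[f"total_{sp}"] = flux.total[sp]
                rows[f"net_{sp}"] = flux.net[sp]
            p = os.path.join(config.outdir, "flux.tsv")
            write_table(_columns_to_records(rows), p)
            paths.append(p)
        elif stage == "conductance":
            ev = _events()
            est = bootstrap_conductance(
                ev, chan, t_total,
                block_length=config.estimator.block_ns,
                n_boot=config.estimator.n_boot,
                seed=config.seed,
            )
            p = os.path.join(config.outdir, "conductance.json")
            write_json_summary(est.as_summary(), p)
            paths.append(p)
        elif stage == "hydration":
            ev = _events()
            waters = top.select(residue_names={config.water_residue})
            series = pore_water_count(traj, chan, waters)
            p = os.path.join(config.outdir, "pore_water.tsv")
            write_table(
                _columns_to_records(
                    {"time_ns": series.times, "n_water": series.counts}
                ), p,
            )
            paths.append(p)
            flux_w = windowed_flux(ev, config.hydration.window_ns, t_total)
            corr = flux_water_correlation(flux_w, series)
            p2 = os.path.join(config.outdir, "hydration_correlation.json")
            write_json_summary(
                {
                    "r": corr.r,
                    "n_windows": corr.n_windows,
                    "window_ns": corr.window,
                    "undefined": corr.undefined,
                    "method": corr.method,
                }, p2,
            )
            paths.append(p2)
        elif stage == "rmsd":
            if not config.regions:
                raise ConfigError("field 'regions': required for the rmsd stage")
            for rdef in config.regions:
                region = RegionSelection(
                    name=rdef["name"],
                    residue_ranges=[tuple(r) for r in rdef["ranges"]],
                )
                series = region_rmsd(traj, region)
                p = os.path.join(config.outdir, f"rmsd_{region.name}.tsv")
                write_table(
                    _columns_to_records(
                        {"time_ns": series.times, "rmsd_A": series.rmsd}
                    ), p,
                )
                paths.append(p)
        elif stage == "coordination":
            metals = top.select(residue_names={"ZN"})
            if len(metals) == 0:
                raise ConfigError("no ZN atoms found for the coordination stage")
            records = metal_coordination(
                traj, metals, cutoff=config.cutoffs.coordination
            )
            subs = detect_substitutions(
                records, persistence=config.cutoffs.persistence
            )
            p = os.path.join(config.outdir, "substitutions.json")
            write_json_summary(
                {
                    "events": [
                        {
                            "metal_index": s.metal_index,
                            "frame": s.frame,
                            "lost": sorted(map(list, s.lost)),
                            "gained": sorted(map(list, s.gained)),
                        }
                        for s in subs
                    ],
                    "persistence_frames": config.cutoffs.persistence,
                    "cutoff_A": config.cutoffs.coordination,
                }, p,
            )
            paths.append(p)
        elif stage == "saltbridges":
            bridges = detect_salt_bridges(
                traj,
                cutoff=config.cutoffs.salt_bridge,
                occupancy_min=config.cutoffs.occupancy_min,
            )
            p = os.path.join(config.outdir, "salt_bridges.tsv")
            write_table(
                [
                    {
                        "basic_resid": b.basic_residue[0],
                        "basic_resname": b.basic_residue[1],
                        "acidic_resid": b.acidic_residue[0],
                        "acidic_resname": b.acidic_residue[1],
                        "occupancy": b.occupancy,
                        "mean_distance_A": float(np.mean(b.distances)),
                    }
                    for b in bridges
                ], p,
            )
            paths.append(p)
        artifacts[stage] = paths
        logger.info("stage %s done in %.2f s", stage, time.perf_counter() - t0)

    prov = {
        "config": config.as_dict(),
        "version": __version__,
        "seed": config.seed,
    }
    prov_path = os.path.join(config.outdir, "provenance.json")
    write_json_summary(prov, prov_path)
    artifacts["provenance"] = [prov_path]
    return artifacts


def _columns_to_records(columns: dict) -> list[dict]:
    keys = list(columns)
    n = len(columns[keys[0]])
    return [{k: columns[k][i] for k in keys} for i in range(n)]
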