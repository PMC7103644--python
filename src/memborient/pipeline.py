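"""Declarative multi-stage pipeline: one config file drives the full
orient → tilt → contacts → cluster → rdf workflow over one or more
replicas.

The config is validated before any computation: every referenced
selection label must be defined and must match atoms of the topology, and
every cutoff carries an explicit unit tag resolved to nm at parse time.
Each stage writes its CSV outputs plus a JSON provenance record; a stage
failure stops the run with the stage name and cause, leaving completed
outputs and a stage-status manifest on disk.
"""

from __future__ import annotations

import json
import os
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .clustering import cluster_timeseries
from .contacts import ContactCriterion, pool_occupancy, protein_protein_contacts, residue_lipid_contacts, threshold_mask
from .geometry import backbone_dihedrals, min_distance_series, rmsd_series, tilt_series
from .orientation import angle_heatmap_table, angle_histogram, orientation_series
from .rdf import compute_rdf
from .synthetic_data import copy_selections
from .traj_model import (
    Selection,
    Trajectory,
    parse_length,
    read_structure,
    read_trajectory,
    select,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = (
    "orient", "tilt", "rmsd", "dihedrals", "mindist",
    "lipid_contacts", "protein_contacts", "cluster", "rdf",
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (all lengths already in nm)."""

    topology: str
    trajectories: list[str]
    out_prefix: str
    selections: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict, base_dir: str = ".") -> "RunConfig":
        def respath(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        missing = [k for k in ("topology", "out_prefix") if k not in cfg]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        stages = dict(cfg.get("stages") or {})
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        # resolve unit-tagged lengths once, here
        for params in stages.values():
            for key in ("cutoff", "bin_width_nm", "rmax"):
                if key in params and params[key] is not None:
                    params[key] = parse_length(params[key])
        return cls(
            topology=respath(cfg["topology"]),
            trajectories=[respath(p) for p in cfg.get("trajectories", [])],
            out_prefix=respath(cfg["out_prefix"]),
            selections=dict(cfg.get("selections") or {}),
            stages=stages,
            seed=int(cfg.get("seed", 0)),
        )


def _validate_selections(config: RunConfig, topology) -> dict[str, Selection]:
    """Resolve every named selection up front; undefined labels fail fast."""
    resolved = {name: select(topology, expr, label=name)
                for name, expr in config.selections.items()}

    def check(label: str) -> None:
        if label not in resolved and label != "by-resid":
            raise ValueError(f"undefined selection label {label!r}")

    for stage, params in config.stages.items():
        for key in ("selection", "protein", "lipids", "group_a", "group_b"):
            if key in params:
                check(params[key])
        for key in ("helices", "lipid_types_selections"):
            for label in params.get(key, []):
                check(label)
        if isinstance(params.get("copies"), list):
            for label in params["copies"]:
                check(label)
    return resolved


def run_pipeline(cfg: dict | RunConfig, config_dir: str | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest (also written to ``<out_prefix>_manifest.json``).
    Raises :class:`PipelineStageError` on the first failing stage; outputs
    of completed stages remain on disk.
    """
    base = os.path.dirname(config_dir) if config_dir else "."
    config = cfg if isinstance(cfg, RunConfig) else RunConfig.from_dict(cfg, base_dir=base)
    os.makedirs(os.path.dirname(config.out_prefix) or ".", exist_ok=True)

    top, frame0 = read_structure(config.topology)
    if config.trajectories:
        trajs = [read_trajectory(p, top) for p in config.trajectories]
    else:
        trajs = [Trajectory(top, [frame0])]
    sels = _validate_selections(config, top)

    manifest = {"version": __version__, "seed": config.seed, "stages": {}}
    manifest_path = config.out_prefix + "_manifest.json"

    def flush() -> None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = config.stages[stage]
        t0 = _time.monotonic()
        try:
            outputs = _STAGE_RUNNERS[stage](config, trajs, sels, params)
            manifest["stages"][stage] = {
                "status": "ok",
                "outputs": outputs,
                "wall_time_s": round(_time.monotonic() - t0, 3),
            }
            prov = {
                "stage": stage, "version": __version__, "seed": config.seed,
                "parameters": params, "inputs": [config.topology, *config.trajectories],
                "outputs": outputs, "wall_time_s": manifest["stages"][stage]["wall_time_s"],
            }
            with open(f"{config.out_prefix}_{stage}_provenance.json", "w") as fh:
                json.dump(prov, fh, indent=2, default=str)
            flush()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "error", "error": str(exc)}
            flush()
            raise PipelineStageError(stage, exc) from exc
    flush()
    return manifest


# ---------------------------------------------------------------------------
# Stage runners (each returns the list of files it wrote)
# ---------------------------------------------------------------------------

def _stage_orient(config, trajs, sels, p):
    sel_label = p.get("selection", "all")
    series = []
    for tr in trajs:
        sel = sels.get(sel_label) or select(tr.topology, sel_label)
        series.append(orientation_series(tr, sel, reference_mode=p.get("reference", "standard_basis")))
    out = []
    angles = pd.concat([s.to_frame(run=i) for i, s in enumerate(series)], ignore_index=True)
    for suffix, obj in (
        ("_angles.csv", angles),
        ("_hist.csv", angle_histogram(series, bin_width=float(p.get("bin_width", 1.0)))),
    ):
        path = config.out_prefix + suffix
        obj.to_csv(path, index=False)
        out.append(path)
    path = config.out_prefix + "_heatmap.csv"
    angle_heatmap_table(series).to_csv(path)
    out.append(path)
    return out


def _stage_tilt(config, trajs, sels, p):
    rows = []
    for run, tr in enumerate(trajs):
        for label in p.get("helices", []):
            ts = tilt_series(tr, sels[label])
            df = ts.to_frame()
            df["run"] = run
            rows.append(df)
    path = config.out_prefix + "_tilt.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_rmsd(config, trajs, sels, p):
    rows = []
    for run, tr in enumerate(trajs):
        df = rmsd_series(tr, sels[p["selection"]], superpose=p.get("superpose", True))
        df["run"] = run
        rows.append(df)
    path = config.out_prefix + "_rmsd.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_dihedrals(config, trajs, sels, p):
    rows = []
    for run, tr in enumerate(trajs):
        df = backbone_dihedrals(tr, sels[p["selection"]])
        df["run"] = run
        rows.append(df)
    path = config.out_prefix + "_dihedrals.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_mindist(config, trajs, sels, p):
    rows = []
    for run, tr in enumerate(trajs):
        ds = min_distance_series(tr, sels[p["group_a"]], sels[p["group_b"]],
                                 mode=p.get("mode", "com"))
        df = ds.to_frame()
        df["run"] = run
        rows.append(df)
    path = config.out_prefix + "_mindist.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_lipid_contacts(config, trajs, sels, p):
    crit = ContactCriterion(
        probe=p.get("probe", "sidechain_com"),
        partner_atom_names=tuple(p.get("partner_atom_names", ())),
        cutoff=float(p.get("cutoff", 0.5)),
    )
    series = [residue_lipid_contacts(tr, sels[p["protein"]], sels[p["lipids"]], crit)
              for tr in trajs]
    occ = pool_occupancy(series)
    occ.threshold = float(p.get("threshold", 0.025))
    out = []
    for suffix, df in (("_occupancy.csv", occ.to_frame()),
                       ("_above_threshold.csv", threshold_mask(occ, occ.threshold))):
        path = config.out_prefix + "_lipid" + suffix
        df.to_csv(path, index=False)
        out.append(path)
    return out


def _stage_protein_contacts(config, trajs, sels, p):
    tr = trajs[0]
    copies = _resolve_copies(tr, sels, p.get("copies", "by-resid"))
    occ, pairs = protein_protein_contacts(
        tr, copies, cutoff=float(p.get("cutoff", 0.65)),
        threshold=float(p.get("threshold", 0.025)),
    )
    out = []
    for suffix, df in (("_pp_occupancy.csv", occ.to_frame()), ("_pp_pairs.csv", pairs)):
        path = config.out_prefix + suffix
        df.to_csv(path, index=False)
        out.append(path)
    return out


def _resolve_copies(tr, sels, spec):
    if spec == "by-resid":
        return copy_selections(tr.topology)
    return [sels[label] for label in spec]


def _stage_cluster(config, trajs, sels, p):
    tr = trajs[0]
    copies = _resolve_copies(tr, sels, p.get("copies", "by-resid"))
    cts = cluster_timeseries(tr, copies, cutoff=float(p.get("cutoff", 0.65)),
                             smoothing_window=int(p.get("window", 1)))
    out = []
    for suffix, df in (("_partitions.csv", cts.assignments_frame()),
                       ("_sizes.csv", cts.size_histogram())):
        path = config.out_prefix + suffix
        df.to_csv(path, index=False)
        out.append(path)
    return out


def _stage_rdf(config, trajs, sels, p):
    tr = trajs[0]
    prot = sels[p["protein"]]
    beads = {}
    for lt in p.get("lipid_types", []):
        try:
            beads[lt] = select(tr.topology, f"resname {lt}", label=lt)
        except Exception:
            continue
    if not beads:
        raise ValueError("rdf stage: no lipid beads found for the requested types")
    profiles = compute_rdf(
        tr, prot, beads,
        mode=p.get("mode", "protein_surface_min"),
        bin_width=float(p.get("bin_width_nm", 0.02)),
        r_max=p.get("rmax"),
        seed=config.seed,
    )
    table = None
    for prof in profiles.values():
        df = prof.to_frame()
        table = df if table is None else table.merge(df, on="r_nm")
    path = config.out_prefix + "_rdf.csv"
    table.to_csv(path, index=False)
    return [path]


_STAGE_RUNNERS = {
    "orient": _stage_orient,
    "tilt": _stage_tilt,
    "rmsd": _stage_rmsd,
    "dihedrals": _stage_dihedrals,
    "mindist": _stage_mindist,
    "lipid_contacts": _stage_lipid_contacts,
    "protein_contacts": _stage_protein_contacts,
    "cluster": _stage_cluster,
    "rdf": _stage_rdf,
}
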