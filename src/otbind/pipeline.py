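"""Config-driven driver chaining the analysis stages into one run.

Stage order mirrors the analysis workflow: align/RMSD → clustering →
hydrogen bonds → π–π contacts → water bridges → RDF → energetics.  Frame
ranges are given in ps with inclusive endpoints, so a 3–30 ns window at a
100 ps stride selects (30000 − 3000)/100 + 1 = 271 frames.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import energetics as _energetics
from . import geometry as _geometry
from . import noncovalent as _nc
from . import rdf as _rdf
from .md_model import (Topology, Trajectory, assign_parameters,
                       load_parameter_table, read_structure, read_trajectory,
                       select)

logger = logging.getLogger("otbind.pipeline")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_pipeline",
           "validate_config", "frame_range_count", "slice_trajectory"]

STAGES = ("rmsd", "cluster", "hbonds", "pipi", "bridges", "rdf", "energetics")

_DEFAULTS: dict[str, Any] = {
    "structure": None,
    "trajectory": None,
    "parameter_table": None,
    "selections": {},
    "stages": list(STAGES),
    "frame_range_ps": None,       # [start, end] inclusive
    "stride_ps": None,
    "hbond": {"d_cut": 2.5, "angle_cut": 120.0,
              "d_cut_h_pi": 3.0, "approach_angle_cut": 30.0},
    "cluster": {"cutoff": 2.0, "selection": "ligand"},
    "rmsd": {"fit_selection": "protein and not element H",
             "measure_selection": "ligand"},
    "pipi": {"pairs": [], "t_theta_min": 60.0, "s_theta_max": 30.0,
             "r_cen_max": 6.0, "d_max": 5.0},
    "hbond_pairs": [],            # [{donor: expr, acceptor: expr}]
    "bridges": [],                # [{ligand_site:..., protein_site:...}]
    "rdf": {"pairs": [], "r_max": 12.0, "dr": 0.05},
    "energetics": {"ligand_selection": "ligand",
                   "receptor_selection": "protein",
                   "temperature": 298.15,
                   "gamma": 0.0227, "beta_const": 3.849},
    "output_dir": None,
    "seed": 0,
    "log_level": "INFO",
}


@dataclass
class AnalysisConfig:
    """Validated, default-filled analysis configuration."""

    options: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "AnalysisConfig":
        merged = json.loads(json.dumps(_DEFAULTS))
        for key, value in raw.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key].update(value)
            else:
                merged[key] = value
        return cls(merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str) -> Any:
        return self.options[key]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.options, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-stage result tables plus a provenance block."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, Any] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump({"provenance": self.provenance,
                       "failures": self.failures,
                       "tables": sorted(self.tables)}, fh, indent=2)


def validate_config(raw: dict[str, Any]) -> list[str]:
    """Non-throwing validation; returns human-readable findings."""
    findings: list[str] = []
    for key in raw:
        if key not in _DEFAULTS:
            findings.append(f"unknown key: {key}")
    stages = raw.get("stages", list(STAGES))
    for stage in stages:
        if stage not in STAGES:
            findings.append(f"unknown stage name: {stage}")
    hb = raw.get("hbond", {})
    for name in ("d_cut", "angle_cut", "d_cut_h_pi", "approach_angle_cut"):
        if name in hb and hb[name] <= 0:
            findings.append(f"hbond.{name} must be positive")
    if raw.get("cluster", {}).get("cutoff", 1.0) < 0:
        findings.append("cluster.cutoff must be non-negative")
    fr = raw.get("frame_range_ps")
    if fr is not None and (len(fr) != 2 or fr[1] < fr[0]):
        findings.append("frame_range_ps must be [start, end] with end >= start")
    if raw.get("stride_ps") is not None and raw["stride_ps"] <= 0:
        findings.append("stride_ps must be positive")
    en = raw.get("energetics", {})
    if "temperature" in en and en["temperature"] <= 0:
        findings.append("energetics.temperature must be positive")
    return findings


def frame_range_count(t_start: float, t_end: float, stride: float) -> int:
    """Inclusive-endpoint frame count: floor((t_end - t_start)/stride) + 1."""
    if stride <= 0:
        raise ValueError("stride must be positive")
    if t_end < t_start:
        raise ValueError("t_end must be >= t_start")
    return int(np.floor((t_end - t_start) / stride + 1e-9)) + 1


def slice_trajectory(trajectory: Trajectory, t_start: float, t_end: float,
                     stride: float | None = None) -> Trajectory:
    """Frames with t_start <= time <= t_end, optionally at a stride (ps).

    With a stride, frames closest to t_start + k*stride are picked; both
    endpoints are inclusive.
    """
    times = trajectory.times
    if stride is None:
        keep = np.flatnonzero((times >= t_start - 1e-9) & (times <= t_end + 1e-9))
    else:
        wanted = t_start + stride * np.arange(frame_range_count(t_start, t_end, stride))
        keep = []
        for t in wanted:
            in_range = np.flatnonzero(np.abs(times - t) < stride / 2 + 1e-9)
            if in_range.size:
                keep.append(in_range[np.argmin(np.abs(times[in_range] - t))])
        keep = np.unique(keep)
    return Trajectory(trajectory.topology, [trajectory.frames[int(k)] for k in keep])


def _load_inputs(config: AnalysisConfig) -> Trajectory:
    top, _ = read_structure(config["structure"])
    traj = read_trajectory(config["trajectory"], topology=top,
                           sampling_interval=config["stride_ps"])
    if config["parameter_table"]:
        assign_parameters(top, load_parameter_table(config["parameter_table"]))
    return traj


def run_pipeline(config: AnalysisConfig,
                 trajectory: Trajectory | None = None) -> AnalysisReport:
    """Execute the enabled stages in dependency order.

    ``trajectory`` may be passed directly (e.g. a synthetic fixture);
    otherwise the configured files are read.  A failing stage is recorded
    in the report and later independent stages still run.
    """
    logging.basicConfig(level=getattr(logging, config["log_level"], logging.INFO))
    if trajectory is None:
        trajectory = _load_inputs(config)
    top = trajectory.topology
    fr = config["frame_range_ps"]
    if fr is not None:
        trajectory = slice_trajectory(trajectory, fr[0], fr[1], config["stride_ps"])
    report = AnalysisReport()
    report.provenance = {
        "config_digest": config.digest(),
        "n_frames": trajectory.n_frames,
        "n_atoms": top.n_atoms,
        "seed": config["seed"],
    }
    crit = _nc.HBondCriteria(**config["hbond"])
    cluster_matrix: np.ndarray | None = None

    def run_stage(name, fn):
        if name not in config["stages"]:
            return
        t0 = _time.perf_counter()
        try:
            report.tables[name] = fn()
            logger.info("stage %s: %.2f s", name, _time.perf_counter() - t0)
        except Exception as exc:
            logger.warning("stage %s failed: %s", name, exc)
            report.failures[name] = str(exc)

    def stage_rmsd():
        fit = select(top, config["rmsd"]["fit_selection"])
        meas = select(top, config["rmsd"]["measure_selection"])
        series = _geometry.rmsd_series(trajectory, trajectory[0], fit, meas)
        return pd.DataFrame({
            "frame": np.arange(trajectory.n_frames),
            "time_ps": trajectory.times,
            "rmsd_A": series,
        }).assign(mean_rmsd_A=series.mean(),
                  rmse_A=_geometry.series_rmse(series))

    def stage_cluster():
        nonlocal cluster_matrix
        sel = select(top, config["cluster"]["selection"])
        result, cluster_matrix = _cluster.cluster_trajectory(
            trajectory, sel, config["cluster"]["cutoff"])
        return pd.DataFrame({
            "frame": np.arange(trajectory.n_frames),
            "time_ps": trajectory.times,
            "cluster_id": result.labels,
            "representative": [result.representatives[c] for c in result.labels],
        })

    def stage_hbonds():
        rows = []
        for pair in config["hbond_pairs"]:
            donors = select(top, pair["donor"])
            acceptors = select(top, pair["acceptor"])
            prob = _nc.bond_forming_probability(trajectory, donors, acceptors, crit)
            rows.append({
                "donor": pair["donor"], "acceptor": pair["acceptor"],
                "probability": prob.probability,
                "mean_distance_A": prob.mean_distance,
                "mean_angle_deg": prob.mean_angle,
                "mean_closest_distance_A": prob.mean_distance_all_frames,
            })
        return pd.DataFrame(rows)

    def stage_pipi():
        rows = []
        for pair in config["pipi"]["pairs"]:
            ra, rb = top.ring(pair[0]), top.ring(pair[1])
            for k, frame in enumerate(trajectory):
                desc = _geometry.pi_pi_descriptor(frame, ra, rb)
                cat = _nc.classify_pipi(
                    desc,
                    t_theta_min=config["pipi"]["t_theta_min"],
                    s_theta_max=config["pipi"]["s_theta_max"],
                    r_cen_max=config["pipi"]["r_cen_max"],
                    d_max=config["pipi"]["d_max"],
                )
                rows.append({
                    "frame": k, "time_ps": frame.time,
                    "pair_label": f"{pair[0]}-{pair[1]}",
                    "r_cen_A": desc.r_cen, "d_A": desc.d,
                    "theta_deg": desc.theta, "category": cat.value,
                })
        return pd.DataFrame(rows)

    def stage_bridges():
        waters = select(top, "water")
        rows = []
        for spec in config["bridges"]:
            stats = _nc.bridge_statistics(
                trajectory, spec["ligand_site"], spec["protein_site"],
                waters, crit, max_waters=spec.get("max_waters", 2))
            rows.append({
                "ligand_site": spec["ligand_site"],
                "protein_site": spec["protein_site"],
                "occupancy": stats.occupancy,
                "exchange_count": stats.exchange_count,
                "frames_present": stats.frames_present,
            })
        return pd.DataFrame(rows)

    def stage_rdf():
        rows = []
        for pair in config["rdf"]["pairs"]:
            refs = pair["reference"]
            refs = [refs] if isinstance(refs, (str, int)) else list(refs)
            tgts = list(select(top, pair["target"])) \
                if isinstance(pair["target"], str) else list(pair["target"])
            result = _rdf.compute_rdf(trajectory, refs, tgts,
                                      r_max=config["rdf"]["r_max"],
                                      dr=config["rdf"]["dr"])
            peak = _rdf.first_peak(result)
            label = pair.get("label", str(refs))
            for r, g, c in zip(result.bin_centers, result.g_of_r,
                               result.coordination_number()):
                rows.append({"pair_label": label, "r_A": r, "g_r": g,
                             "coordination": c,
                             "first_peak_A": peak[0] if peak else np.nan})
        return pd.DataFrame(rows)

    def stage_energetics():
        en = config["energetics"]
        lig = select(top, en["ligand_selection"])
        rec = select(top, en["receptor_selection"])
        series = _energetics.interaction_energy_series(
            trajectory, rec, lig, top, temperature=en["temperature"])
        entropy = _energetics.interaction_entropy(series)
        evdw = ecoul = 0.0
        for frame in trajectory:
            v, c = _energetics.lj_coulomb_energy(frame, rec, lig, top)
            evdw += v
            ecoul += c
        n = trajectory.n_frames
        evdw /= n
        ecoul /= n
        radii = _energetics.element_radii_for(top)
        frame0 = trajectory[0]
        comp = list(rec) + list(lig)
        _, s_c = _energetics.sasa(frame0, comp, [radii[i] for i in comp])
        _, s_r = _energetics.sasa(frame0, rec, [radii[i] for i in rec])
        _, s_l = _energetics.sasa(frame0, lig, [radii[i] for i in lig])
        ddg_sa = _energetics.nonpolar_solvation(
            s_c, s_r, s_l, gamma=en["gamma"], beta_const=en["beta_const"])
        ddg_pb = _energetics.gb_polar_surrogate(
            frame0, comp, rec, lig, top, radii)
        table = _energetics.mmpbsa_totals(evdw, ecoul, ddg_pb, ddg_sa,
                                          entropy.minus_TdS)
        row = table.as_dict()
        row["entropy_converged"] = entropy.converged
        return pd.DataFrame([row])

    run_stage("rmsd", stage_rmsd)
    run_stage("cluster", stage_cluster)
    run_stage("hbonds", stage_hbonds)
    run_stage("pipi", stage_pipi)
    run_stage("bridges", stage_bridges)
    run_stage("rdf", stage_rdf)
    run_stage("energetics", stage_energetics)

    if config["output_dir"]:
        report.write(config["output_dir"])
    return report
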