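"""End-to-end orchestration: simulate -> preprocess -> MPG -> segment ->
measure -> group statistics, with content-hash caching and a run manifest.

Every stage writes its outputs under ``out_dir/vessels/<id>/<stage>/``
together with a hash of its parameters chained to the upstream stage hash
(content-based, not timestamp-based).  A rerun with an unchanged config
performs no recomputation; changing one stage's parameters invalidates only
that stage and everything downstream.  All randomness derives from the
single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .morphometry import compute_morphometry, morphometry_record
from .phase_gradient import mpg_from_offsets
from .preprocess import DerivedImages, preprocess_acquisition
from .segmentation import (
    EditJournal,
    apply_edit_journal,
    segment_vessel,
    segmentation_from_dict,
    segmentation_to_dict,
)
from .stats import compare_by_dr_severity, compare_by_t1d, render_summary_tables
from .synthetic import (
    PhantomNoiseModel,
    export_acquisition,
    inject_mural_edges,
    simulate_vessel_phantom,
    straight_geometry,
)

OFFSET_NAMES = ("offset_up", "offset_down", "offset_left", "offset_right")


class PipelineError(RuntimeError):
    pass


_DEFAULTS = {
    "seed": 0,
    "pixel_scale": 1.0,
    "keep_going": False,
    "simulate": {
        "enabled": True,
        "n_frames": 100,
        "noise": {
            "flow_sigma": 0.10,
            "background_sigma": 0.005,
            "jitter_sigma": 1.0,
            "shot_noise_sigma": 0.01,
            "mural_edge_rate": 0.0,
        },
        "vessels": [],
    },
    "inputs": {"vessels": []},
    "preprocess": {"frames_keep": None, "max_shift_frac": 0.2, "upsample_factor": 20},
    "mpg": {"smooth_sigma": 1.0},
    "segment": {
        "sample_spacing": 2.0,
        "min_length": 50.0,
        "profile_step": 0.25,
        "prominence_frac": 0.2,
        "min_wall_offset": 2.0,
        "stiffness": 2.0,
        "journals": {},
    },
    "measure": {"min_samples": 10},
    "stats": {"enabled": True, "exact_max_n": 10, "omnibus": "kruskal"},
}


def _merge(defaults, override):
    if isinstance(defaults, dict):
        out = {k: _merge(v, (override or {}).get(k)) for k, v in defaults.items()}
        for k, v in (override or {}).items():
            if k not in out:
                out[k] = v
        return out
    return defaults if override is None else override


@dataclass
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    out_dir: str
    data: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        out_dir = d.pop("out_dir", None)
        if not out_dir:
            raise PipelineError("config requires out_dir")
        data = _merge(_DEFAULTS, d)
        if data["pixel_scale"] <= 0:
            raise PipelineError("pixel_scale must be positive")
        return cls(out_dir=str(out_dir), data=data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_yaml(path))

    def to_dict(self) -> dict:
        return {"out_dir": self.out_dir, **self.data}

    def __getitem__(self, key):
        return self.data[key]


@dataclass
class RunManifest:
    """Per-vessel provenance: stage hashes, cache state, outputs, QC."""

    entries: dict = field(default_factory=dict)
    cohort_path: str = ""
    stats_outputs: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "entries": self.entries,
            "cohort_path": self.cohort_path,
            "stats_outputs": self.stats_outputs,
            "errors": self.errors,
        }


def _hash(obj, upstream: str = "") -> str:
    payload = upstream + json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_dir(out: Path, vid: str, stage: str) -> Path:
    d = out / "vessels" / vid / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _cached(stage_dir: Path, h: str) -> bool:
    f = stage_dir / "stage_hash.json"
    return f.exists() and io.read_json(f).get("hash") == h


def _mark(stage_dir: Path, h: str) -> None:
    io.write_json(stage_dir / "stage_hash.json", {"hash": h})


class _EventLog:
    def __init__(self, path: Path):
        path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(path, "a")

    def emit(self, **kv) -> None:
        kv.setdefault("ts", time.time())
        self._fh.write(json.dumps(kv, default=str) + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()


def _vessel_seed(base: int, index: int) -> int:
    return (int(base) * 1_000_003 + 7919 * index) % (2**31 - 1)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all enabled stages for every configured vessel.

    Raises on the first vessel-level hard error unless ``keep_going`` is
    set, in which case errors are collected in the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _EventLog(out / "run.log")
    manifest = RunManifest()
    scale = float(config["pixel_scale"])

    sim_cfg = config["simulate"]
    vessels = []
    if sim_cfg["enabled"]:
        for i, v in enumerate(sim_cfg["vessels"]):
            vessels.append(("simulate", i, dict(v)))
    for i, v in enumerate(config["inputs"]["vessels"]):
        vessels.append(("load", i, dict(v)))
    if not vessels:
        raise PipelineError("no vessels configured (simulate.vessels / inputs.vessels)")

    records = []
    for mode, index, vspec in vessels:
        vid = str(vspec.get("id", f"vessel{index:03d}"))
        try:
            rec = _run_vessel(config, out, log, mode, index, vspec, vid, manifest)
            records.append(rec)
        except Exception as exc:  # noqa: BLE001 - vessel-level policy decision
            log.emit(event="vessel_error", vessel=vid, error=str(exc))
            manifest.errors[vid] = str(exc)
            if not config["keep_going"]:
                log.close()
                raise PipelineError(f"vessel {vid}: {exc}") from exc

    cohort = pd.DataFrame(records)
    cohort_path = out / "cohort.csv"
    io.write_cohort(cohort_path, cohort)
    manifest.cohort_path = str(cohort_path)
    log.emit(event="cohort_written", n=len(records))

    if config["stats"]["enabled"] and len(records) >= 2:
        manifest.stats_outputs = run_stats(cohort, out / "stats", config["stats"])
        log.emit(event="stats_written")

    io.write_json(out / "manifest.json", manifest.to_dict())
    log.close()
    return manifest


def _run_vessel(config, out, log, mode, index, vspec, vid, manifest) -> dict:
    scale = float(config["pixel_scale"])
    entry: dict = {}
    manifest.entries[vid] = entry

    # --- acquire ----------------------------------------------------------
    if mode == "simulate":
        sim_cfg = config["simulate"]
        seed = _vessel_seed(config["seed"], index)
        sim_params = {
            "vessel": vspec,
            "noise": sim_cfg["noise"],
            "n_frames": sim_cfg["n_frames"],
            "seed": seed,
            "pixel_scale": scale,
        }
        h_in = _hash(sim_params)
        d = _stage_dir(out, vid, "simulate")
        if not _cached(d, h_in):
            noise = PhantomNoiseModel(**{**sim_cfg["noise"], "seed": seed})
            geom, shape = straight_geometry(
                float(vspec["ld_um"]),
                float(vspec["wall_um"]),
                pixel_scale=scale,
                orientation_deg=float(vspec.get("orientation_deg", 0.0)),
                usable_length_px=float(vspec.get("usable_length_px", 160.0)),
                bow_px=float(vspec.get("bow_px", 0.0)),
            )
            acq = simulate_vessel_phantom(geom, noise, sim_cfg["n_frames"], shape)
            if noise.mural_edge_rate > 0:
                acq = inject_mural_edges(acq, noise)
            export_acquisition(acq, d)
            _mark(d, h_in)
            log.emit(event="stage", vessel=vid, stage="simulate", cached=False)
        else:
            log.emit(event="stage", vessel=vid, stage="simulate", cached=True)
        entry["simulate"] = {"hash": h_in, "dir": str(d)}
        src_dir = d
        truth = io.read_json(d / "truth.json")
        seed_point = truth["seed_point"]
    else:
        src_dir = Path(vspec["dir"])
        missing = [
            ch for ch in ("confocal", *OFFSET_NAMES) if not (src_dir / f"{ch}.tif").exists()
        ]
        if missing:
            raise PipelineError(f"vessel {vid}: missing channel file(s) {missing}")
        digest = hashlib.sha256()
        for ch in ("confocal", *OFFSET_NAMES):
            digest.update((src_dir / f"{ch}.tif").read_bytes())
        h_in = digest.hexdigest()[:16]
        seed_point = vspec["seed_point"]
        entry["load"] = {"hash": h_in, "dir": str(src_dir)}

    # --- preprocess --------------------------------------------------------
    pre_cfg = config["preprocess"]
    h_pre = _hash(pre_cfg, h_in)
    d_pre = _stage_dir(out, vid, "preprocess")
    if not _cached(d_pre, h_pre):
        channels = {
            ch: io.read_stack(src_dir / f"{ch}.tif", ch, scale)
            for ch in ("confocal", *OFFSET_NAMES)
        }
        derived, reg = preprocess_acquisition(
            channels,
            frames_keep=pre_cfg["frames_keep"],
            upsample_factor=pre_cfg["upsample_factor"],
            max_shift_frac=pre_cfg["max_shift_frac"],
        )
        for ch, der in derived.items():
            io.write_image(d_pre / f"{ch}_mean.tif", der.mean_image)
        io.write_image(d_pre / "confocal_std.tif", derived["confocal"].std_image)
        io.write_json(
            d_pre / "registration.json",
            {
                "kept_frames": reg.kept_frames,
                "shifts": reg.shifts,
                "params": pre_cfg,
            },
        )
        _mark(d_pre, h_pre)
        log.emit(event="stage", vessel=vid, stage="preprocess", cached=False)
    else:
        log.emit(event="stage", vessel=vid, stage="preprocess", cached=True)
    entry["preprocess"] = {"hash": h_pre, "dir": str(d_pre)}

    # --- MPG ---------------------------------------------------------------
    mpg_cfg = config["mpg"]
    h_mpg = _hash(mpg_cfg, h_pre)
    d_mpg = _stage_dir(out, vid, "mpg")
    if not _cached(d_mpg, h_mpg):
        derived = {
            ch: DerivedImages(
                mean_image=io.read_image(d_pre / f"{ch}_mean.tif"),
                std_image=np.zeros((1, 1)),
                pixel_scale=scale,
            )
            for ch in OFFSET_NAMES
        }
        mpg = mpg_from_offsets(derived, smooth_sigma=mpg_cfg["smooth_sigma"])
        io.write_image(d_mpg / "mpg.tif", mpg.pixels)
        io.write_json(d_mpg / "params.json", mpg_cfg)
        _mark(d_mpg, h_mpg)
        log.emit(event="stage", vessel=vid, stage="mpg", cached=False)
    else:
        log.emit(event="stage", vessel=vid, stage="mpg", cached=True)
    entry["mpg"] = {"hash": h_mpg, "dir": str(d_mpg)}

    # --- segment -----------------------------------------------------------
    seg_cfg = dict(config["segment"])
    journals = seg_cfg.pop("journals", {}) or {}
    journal_path = journals.get(vid)
    journal_blob = Path(journal_path).read_text() if journal_path else ""
    h_seg = _hash({**seg_cfg, "journal": journal_blob, "seed_point": seed_point}, h_mpg)
    d_seg = _stage_dir(out, vid, "segment")
    if not _cached(d_seg, h_seg):
        std = io.read_image(d_pre / "confocal_std.tif")
        mpg_img = io.read_image(d_mpg / "mpg.tif")
        seg = segment_vessel(
            std,
            mpg_img,
            seed_point,
            sample_spacing=seg_cfg["sample_spacing"],
            min_length=seg_cfg["min_length"],
            profile_step=seg_cfg["profile_step"],
            prominence_frac=seg_cfg["prominence_frac"],
            min_wall_offset=seg_cfg["min_wall_offset"],
            stiffness=seg_cfg["stiffness"],
        )
        if journal_path:
            seg = apply_edit_journal(seg, EditJournal.from_dict(io.read_yaml(journal_path)))
        io.write_json(d_seg / "segmentation.json", segmentation_to_dict(seg))
        np.savetxt(
            d_seg / "lumen_contour.csv", seg.lumen_contour, delimiter=",",
            header="row,col", comments="",
        )
        np.savetxt(
            d_seg / "external_contour.csv", seg.external_contour, delimiter=",",
            header="row,col", comments="",
        )
        _mark(d_seg, h_seg)
        log.emit(event="stage", vessel=vid, stage="segment", cached=False)
    else:
        log.emit(event="stage", vessel=vid, stage="segment", cached=True)
    entry["segment"] = {"hash": h_seg, "dir": str(d_seg), "journal": journal_path}

    # --- measure -----------------------------------------------------------
    meas_cfg = config["measure"]
    h_meas = _hash({**meas_cfg, "pixel_scale": scale, "labels": vspec.get("group")}, h_seg)
    d_meas = _stage_dir(out, vid, "measure")
    if not _cached(d_meas, h_meas):
        seg = segmentation_from_dict(io.read_json(d_seg / "segmentation.json"))
        morph = compute_morphometry(seg, scale, min_samples=meas_cfg["min_samples"])
        group = str(vspec.get("group", ""))
        if group and group not in ("Control", "NoDR", "MildModNPDR", "SevNPDR_PDR"):
            raise PipelineError(f"vessel {vid}: unknown group label {group!r}")
        record = morphometry_record(
            morph,
            vessel_id=vid,
            eye_id=str(vspec.get("eye_id", "")),
            patient_id=str(vspec.get("patient_id", "")),
            dr_group=group,
            t1d=bool(vspec.get("t1d", group not in ("", "Control"))),
        )
        io.write_json(d_meas / "record.json", record)
        _mark(d_meas, h_meas)
        log.emit(event="stage", vessel=vid, stage="measure", cached=False)
    else:
        log.emit(event="stage", vessel=vid, stage="measure", cached=True)
    entry["measure"] = {"hash": h_meas, "dir": str(d_meas)}
    return io.read_json(d_meas / "record.json")


def run_stats(cohort: pd.DataFrame, out_dir, params: dict) -> dict:
    """Statistics stage: rank-sum tests, summary tables, box-plot data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kwargs = {"exact_max_n": int(params.get("exact_max_n", 10))}
    t1d = compare_by_t1d(cohort, **kwargs)
    dr = compare_by_dr_severity(cohort, omnibus=params.get("omnibus", "kruskal"), **kwargs)
    tables = render_summary_tables(cohort, t1d, dr)

    rows = []
    for metric, res in t1d.items():
        rows.append(
            {"metric": metric, "grouping": "t1d", "statistic": res.statistic,
             "p_value": res.p_value, "method": res.method}
        )
    for metric, block in dr.items():
        rows.append(
            {"metric": metric, "grouping": "dr_omnibus",
             "statistic": block["omnibus"]["statistic"],
             "p_value": block["omnibus"]["p_value"],
             "method": block["omnibus"]["test"]}
        )
        for (gi, gj), res in block["pairwise"].items():
            rows.append(
                {"metric": metric, "grouping": f"{gi}_vs_{gj}",
                 "statistic": res.statistic, "p_value": res.p_value,
                 "method": res.method}
            )
    results = pd.DataFrame(rows)
    results.to_csv(out / "results.csv", index=False)
    tables["t1d_table"].to_csv(out / "t1d_table.csv", index=False)
    tables["dr_table"].to_csv(out / "dr_table.csv", index=False)
    for name in ("t1d_table", "dr_table"):
        _write_markdown(out / f"{name}.md", tables[name])
    io.write_json(out / "boxplot.json", tables["boxplot"])
    return {
        "results": str(out / "results.csv"),
        "t1d_table": str(out / "t1d_table.csv"),
        "dr_table": str(out / "dr_table.csv"),
        "boxplot": str(out / "boxplot.json"),
    }


def _write_markdown(path, df: pd.DataFrame) -> None:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    Path(path).write_text("\n".join(lines) + "\n")
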