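"""Workflow orchestration: configuration, staged execution, run log.

The full desk-scale workflow runs as a chain of stages with explicit file
artifacts::

    phantom -> uct -> segment -> generations -> section -> register
            -> count -> estimate

mirroring the temporal dependency of the physical protocol (everything
that needs the intact specimen — imaging, segmentation, generation
analysis — precedes the destructive sectioning).  Each stage records its
parameters and the content hashes of its inputs in an append-only run
log; a re-run with unchanged configuration and inputs skips stages whose
recorded hash still matches (make-style dependency tracking without an
external build tool).  All randomness is derived from named per-stage
seeds stored in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .core import CLS_ARTERY, LabelVolume
from .generations import assign_generations, generation_volume, skeletonize
from .phantom import TreeSpec, build_tree, rasterize, simulate_uct
from .sectioning import SectionPlan, extract_section, plan_for_volume
from .segmentation import denoise, join_segments, presegment
from .stereology import (build_test_system, count_field, crop_field,
                         estimate_reference_volume, estimate_total_volumes,
                         estimate_volume_fraction, estimate_wall_metrics,
                         results_table, sample_field_origins, write_counts)

STAGES = ["phantom", "uct", "segment", "generations", "section", "register",
          "count", "estimate"]


DEFAULT_CONFIG: dict = {
    "workdir": "genstereo_run",
    "seed": 0,
    "phantom": {"spacing_um": 9.0},            # TreeSpec field overrides live here too
    "uct": {"noise_sd": 4.0, "blur_fwhm_um": 8.0, "parenchyma_texture": 25.0},
    "segment": {"iterations": 4, "conductance": 2.0, "time_step": 0.0625,
                "watershed_level": 0.02, "bright_threshold": 165.0},
    "generations": {"prune_factor": 3.0, "smooth_sigma": 0.8},
    "section": {"thickness_um": 2.0, "n_collected": 20, "n_skipped": 50,
                "normal_axis": "z"},
    "register": {"enabled": True, "metric": "meansquares", "iterations": 60,
                 "substack_index": 0},
    "count": {"field_height_um": 480.0, "field_width_um": 720.0,
              "sections_per_substack": 4, "cycloid_radius_um": 26.0,
              "n_fine": 16, "n_coarse": 2, "n_arcs": 36},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration on top of the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(name: str, params: dict, inputs: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(name.encode())
    h.update(json.dumps(params, sort_keys=True, default=str).encode())
    for p in inputs:
        h.update(_file_hash(p).encode())
    return h.hexdigest()


class RunLog:
    """Append-only record of stage executions (JSON lines on disk)."""

    def __init__(self, path: Path):
        self.path = path
        self.entries: list[dict] = []
        if path.exists():
            with open(path) as fh:
                self.entries = [json.loads(line) for line in fh if line.strip()]

    def latest(self, stage: str) -> dict | None:
        for entry in reversed(self.entries):
            if entry["stage"] == stage:
                return entry
        return None

    def append(self, stage: str, stage_hash: str, params: dict, outputs: list[str],
               seconds: float, skipped: bool = False, warnings: dict | None = None) -> None:
        entry = {"stage": stage, "hash": stage_hash, "params": params,
                 "outputs": outputs, "seconds": round(seconds, 3),
                 "skipped": skipped, "time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        if warnings:
            entry["warnings"] = warnings
        self.entries.append(entry)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")


@dataclasses.dataclass
class PipelineResult:
    workdir: Path
    log: RunLog
    executed: list[str]
    skipped: list[str]

    def artifact(self, name: str) -> Path:
        return self.workdir / name


def _tree_spec_from_config(cfg: dict) -> TreeSpec:
    phantom_cfg = dict(cfg.get("phantom", {}))
    phantom_cfg.pop("spacing_um", None)
    fields = {f.name for f in dataclasses.fields(TreeSpec)}
    unknown = set(phantom_cfg) - fields
    if unknown:
        raise ValueError(f"unknown phantom parameters: {sorted(unknown)}")
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in phantom_cfg.items()}
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return TreeSpec(**kwargs)


def run_pipeline(config: dict, stages: list[str] | None = None) -> PipelineResult:
    """Execute the workflow (or a contiguous sub-chain) defined by a config.

    Stages whose parameters and inputs are unchanged since the last run
    (by content hash) are skipped.  Raises when a requested stage's
    upstream artifact is missing, naming the stage that should have
    produced it.
    """
    cfg = config
    workdir = Path(cfg["workdir"])
    workdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(workdir / "runlog.jsonl")
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    executed, skipped = [], []

    def need(path: Path, producer: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {path.name}; run the {producer!r} stage first")
        return path

    def run_stage(name: str, params: dict, inputs: list[Path], outputs: list[Path], fn):
        h = _stage_hash(name, params, inputs)
        last = log.latest(name)
        if last and last["hash"] == h and all(o.exists() for o in outputs):
            skipped.append(name)
            log.append(name, h, params, [o.name for o in outputs], 0.0, skipped=True)
            return
        t0 = time.time()
        warnings = fn()
        log.append(name, h, params, [o.name for o in outputs], time.time() - t0,
                   warnings=warnings)
        executed.append(name)

    comp_p = workdir / "phantom_compartments.nrrd"
    truth_p = workdir / "phantom_truth.json"
    uct_p = workdir / "uct.nrrd"
    artery_p = workdir / "artery_mask.nrrd"
    genmap_p = workdir / "generation_map.nrrd"
    graph_p = workdir / "skeleton_graph.json"
    plan_p = workdir / "section_plan.json"
    transform_p = workdir / "volume_to_substack.json"
    counts_p = workdir / "counts.csv"
    estimates_p = workdir / "estimates.json"
    table_p = workdir / "estimates_table.csv"

    # ---- phantom ---------------------------------------------------------
    if "phantom" in stages:
        spec = _tree_spec_from_config(cfg)
        spacing = float(cfg["phantom"].get("spacing_um", 9.0))
        params = {"spec": dataclasses.asdict(spec), "spacing_um": spacing}

        def _phantom():
            tree, truth = build_tree(spec)
            ph = rasterize(tree, spacing=spacing)
            gio.write_volume(ph.compartments, comp_p)
            gio.write_volume(ph.generation_map, workdir / "phantom_generations.nrrd")
            truth_payload = json.loads(truth.to_json())
            truth_payload["root_um"] = [float(v) for v in tree.root.start]
            root = tree.root
            seed_pt = root.start + root.direction * min(4.0 * root.lumen_radius,
                                                        0.5 * root.length)
            truth_payload["seed_um"] = [float(v) for v in seed_pt]
            truth_p.write_text(json.dumps(truth_payload, indent=2))
            return None

        run_stage("phantom", params, [], [comp_p, truth_p], _phantom)

    # ---- simulated µCT ---------------------------------------------------
    if "uct" in stages:
        p = cfg["uct"]
        params = dict(p, seed=cfg.get("seed", 0))

        def _uct():
            comp = gio.read_volume(need(comp_p, "phantom"), labels=True)
            vol = simulate_uct(comp, noise_sd=p["noise_sd"], blur_fwhm=p["blur_fwhm_um"],
                               seed=cfg.get("seed", 0),
                               parenchyma_texture=p.get("parenchyma_texture", 0.0))
            gio.write_volume(vol, uct_p)
            return None

        run_stage("uct", params, [comp_p], [uct_p], _uct)

    # ---- segmentation ----------------------------------------------------
    if "segment" in stages:
        p = cfg["segment"]

        def _segment():
            vol = gio.read_volume(need(uct_p, "uct"))
            den = denoise(vol, iterations=p["iterations"], conductance=p["conductance"],
                          time_step=p["time_step"])
            pre = presegment(den, watershed_level=p["watershed_level"])
            truth_meta = json.loads(need(truth_p, "phantom").read_text())
            seed_pt = truth_meta.get("seed_um", truth_meta["root_um"])
            seed_idx = np.round(vol.index_of(seed_pt)).astype(int)
            labels = join_segments(pre, seeds=[(tuple(seed_idx), "artery")],
                                   bright_threshold=p.get("bright_threshold"))
            mask = LabelVolume((labels.data == CLS_ARTERY).astype(np.uint8),
                               spacing=labels.spacing, origin=labels.origin,
                               vertical_axis=labels.vertical_axis)
            gio.write_volume(mask, artery_p)
            return None

        run_stage("segment", dict(p), [uct_p, truth_p], [artery_p], _segment)

    # ---- generation analysis --------------------------------------------
    if "generations" in stages:
        p = cfg["generations"]

        def _generations():
            mask = gio.read_volume(need(artery_p, "segment"), labels=True)
            root = json.loads(need(truth_p, "phantom").read_text())["root_um"]
            skel = skeletonize(mask, prune_factor=p["prune_factor"],
                               smooth_sigma=p["smooth_sigma"], anchors=[root])
            gm = assign_generations(skel, tuple(root))
            gv = generation_volume(skel, gm, mask)
            gio.write_volume(gv.voxel_map, genmap_p)
            graph_p.write_text(skel.to_json(gm.branch_generation))
            return None

        run_stage("generations", dict(p), [artery_p, truth_p], [genmap_p, graph_p],
                  _generations)

    # ---- sectioning plan -------------------------------------------------
    if "section" in stages:
        p = cfg["section"]
        params = dict(p, seed=cfg.get("seed", 0))

        def _section():
            comp = gio.read_volume(need(comp_p, "phantom"), labels=True)
            plan = plan_for_volume(comp, section_thickness=p["thickness_um"],
                                   n_collected=p["n_collected"], n_skipped=p["n_skipped"],
                                   seed=cfg.get("seed", 0), section_normal=p["normal_axis"])
            plan_p.write_text(plan.to_json())
            return None

        run_stage("section", params, [comp_p], [plan_p], _section)

    # ---- volume-to-substack registration ---------------------------------
    if "register" in stages and cfg["register"].get("enabled", True):
        p = cfg["register"]

        def _register():
            from .registration import jacobian_summary, register_volume_to_substack
            from .sectioning import extract_substack
            vol = gio.read_volume(need(uct_p, "uct"))
            plan = SectionPlan.from_json(need(plan_p, "section").read_text())
            sub = extract_substack(vol, plan, p.get("substack_index", 0))
            chain = register_volume_to_substack(vol, sub, metric=p["metric"],
                                                iterations=p["iterations"])
            transform_p.write_text(chain.to_json())
            return {"jacobian": jacobian_summary(chain)}

        run_stage("register", dict(p), [uct_p, plan_p], [transform_p], _register)

    # ---- counting --------------------------------------------------------
    if "count" in stages:
        p = cfg["count"]
        params = dict(p, seed=cfg.get("seed", 0))

        def _count():
            comp = gio.read_volume(need(comp_p, "phantom"), labels=True)
            gen = gio.read_volume(need(genmap_p, "generations"), labels=True)
            plan = SectionPlan.from_json(need(plan_p, "section").read_text())
            rng = np.random.default_rng(cfg.get("seed", 0))
            fs = (p["field_height_um"], p["field_width_um"])
            records = []
            gens = sorted(int(g) for g in np.unique(gen.data) if g > 0)
            for si in range(plan.n_substacks):
                sections = plan.substack_sections(si)
                step = max(len(sections) // p["sections_per_substack"], 1)
                for sec_idx in sections[::step][:p["sections_per_substack"]]:
                    gen_img = extract_section(gen, plan, sec_idx)
                    comp_img = extract_section(comp, plan, sec_idx)
                    # wall pixels carry no spread label (the artery mask is the
                    # plastic-filled lumen); give every artery-profile pixel the
                    # generation of its nearest labelled neighbour
                    profile = comp_img > 0
                    missing = profile & (gen_img == 0)
                    if missing.any() and (gen_img > 0).any():
                        from scipy import ndimage as _ndi
                        _, (ir, ic) = _ndi.distance_transform_edt(
                            gen_img == 0, return_indices=True)
                        gen_img = gen_img.copy()
                        gen_img[missing] = gen_img[ir[missing], ic[missing]]
                    ref = np.ones_like(gen_img, dtype=bool)
                    spacing2 = (comp.spacing[plan.vertical_axis],
                                comp.spacing[3 - plan.section_normal - plan.vertical_axis])
                    origins = sample_field_origins(gen_img.shape, spacing2, fs,
                                                   seed=int(rng.integers(2 ** 31)))
                    # crop with a guard band on the far sides so cycloid
                    # arcs protruding past the field edge still see tissue
                    # (otherwise partially visible arcs contribute
                    # intersections but no end points)
                    guard = math.pi * p["cycloid_radius_um"]
                    window = (fs[0] + guard, fs[1] + guard)
                    for k, org in enumerate(origins):
                        field = crop_field(np.where(profile, gen_img, 0), comp_img,
                                           ref, spacing2, org, window,
                                           field_id=f"s{sec_idx}_f{k}")
                        ts = build_test_system(field_size=fs, n_fine=p["n_fine"],
                                               n_coarse=p["n_coarse"], n_arcs=p["n_arcs"],
                                               cycloid_radius=p["cycloid_radius_um"],
                                               seed=int(rng.integers(2 ** 31)))
                        records.extend(count_field(field, ts, generations=gens))
            write_counts(records, counts_p)
            return None

        run_stage("count", params, [comp_p, genmap_p, plan_p], [counts_p], _count)

    # ---- estimation ------------------------------------------------------
    if "estimate" in stages:

        def _estimate():
            from .stereology import ingest_counts
            records = ingest_counts(need(counts_p, "count"))
            plan = SectionPlan.from_json(need(plan_p, "section").read_text())
            comp = gio.read_volume(need(comp_p, "phantom"), labels=True)
            p = cfg["count"]
            factor = p["n_fine"] // p["n_coarse"]
            vv = estimate_volume_fraction(records, factor=factor)
            # Cavalieri reference volume from full section areas
            ax_r = plan.vertical_axis
            ax_c = 3 - plan.section_normal - plan.vertical_axis
            area = comp.shape[ax_r] * comp.spacing[ax_r] * comp.shape[ax_c] * comp.spacing[ax_c]
            from .sectioning import collected_section_indices
            areas = [area] * len(collected_section_indices(plan))
            v_ref = estimate_reference_volume(plan, areas)
            totals = estimate_total_volumes(vv, v_ref)
            wall = estimate_wall_metrics(records, l_point_um=2 * p["cycloid_radius_um"])
            payload = {
                "reference_volume_mm3": v_ref,
                "per_generation": {
                    str(g): {
                        "vv_percent": 100 * vv.get(g, 0.0),
                        "volume_mm3": totals.get(g, 0.0),
                        "lumen_to_wall": wall[g].lumen_to_wall if g in wall else None,
                        "t_wall_um": wall[g].t_wall_um if g in wall else None,
                    } for g in sorted(set(vv) | set(wall))
                },
            }
            estimates_p.write_text(json.dumps(payload, indent=2))
            results_table(vv, totals, wall).to_csv(table_p)
            return None

        run_stage("estimate", {"factor": cfg["count"]["n_fine"] // cfg["count"]["n_coarse"]},
                  [counts_p, plan_p, comp_p], [estimates_p, table_p], _estimate)

    return PipelineResult(workdir, log, executed, skipped)
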