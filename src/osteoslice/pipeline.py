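"""End-to-end orchestration: align → segment → slice metrics → profiles
→ Tb.E → VOI 3D → group statistics, with reproducible run records.

All tables are CSV; every output carries a ``# config_sha256=...``
header line so results can be traced to the exact configuration, and a
run log records parameters and QC flags.  Given a fixed seed the run is
deterministic (re-running yields byte-identical CSVs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axis_align import align_to_principal_axis, axis_angle_deg, build_frame
from .compartments import SegmentationParams, segment_stack
from .errors import ConfigurationError, OsteosliceError, ValidationError
from .group_stats import normality_screen, ttest_profile
from .phantoms import PhantomSpec, make_phantom, simulate_groups
from .profiles import (DEFAULT_TBE_THRESHOLDS, MorphProfile, build_profile,
                       percent_grid, trabecular_extent)
from .slice_morph import compute_slice_metrics
from .stack_io import read_stack
from .voi_morph3d import VOISpec, cortical_3d, extract_voi, trabecular_3d

log = logging.getLogger("osteoslice")

TRABECULAR_PARAMS = ("ba_ta", "tb_th_2d", "tb_n_2d", "tb_sp_2d")
CORTICAL_PARAMS = ("ct_th_2d", "ct_ar_2d", "tt_ar_2d", "ma_ar_2d",
                   "ct_ar_frac", "ps_pm_2d", "ec_pm_2d", "j_2d")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    output_dir: str = "osteoslice_out"
    seed: int = 0
    specimens: list = field(default_factory=list)   # [{"stack": ..., "manifest": ...}]
    phantom_cohorts: dict | None = None             # {"base": {...}, "n_per_group": ..}
    align: bool = True
    thickness_model: str = "plate"
    segmentation: dict = field(default_factory=dict)
    trabecular_range: tuple = (60.0, 100.0)
    cortical_range: tuple = (40.0, 80.0)
    grid_step: float = 1.0
    tbe_thresholds: tuple = DEFAULT_TBE_THRESHOLDS
    vois: list = field(default_factory=lambda: ["trab_meta", "trab_epi", "cort_dia", "cort_meta"])
    equal_var: bool = True
    holm: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # output_dir is a run location, not an analysis parameter
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def _load_specimens(config: RunConfig):
    """Materialize (stack, meta, name) triples from files and/or phantoms."""
    out = []
    for entry in config.specimens:
        try:
            stack, meta = read_stack(entry["stack"], entry["manifest"])
        except FileNotFoundError as exc:
            raise ConfigurationError(
                f"specimen {entry.get('stack')}: missing input ({exc})"
            ) from exc
        out.append((stack, meta))
    if config.phantom_cohorts:
        pc = dict(config.phantom_cohorts)
        base = PhantomSpec(**pc.get("base", {}))
        if pc.get("n_per_group"):
            cohorts = simulate_groups(
                base,
                effects=pc.get("effects"),
                n_per_group=int(pc["n_per_group"]),
                noise_cv=float(pc.get("noise_cv", 0.05)),
                seed=config.seed,
                level="voxel",
            )
            for cohort in cohorts:
                out.extend((stack, meta) for stack, meta, _ in cohort)
        else:
            stack, meta, _ = make_phantom(base)
            out.append((stack, meta))
    if not out:
        raise ConfigurationError("no specimens configured")
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("osteoslice %s  config_sha256=%s  seed=%d", __version__, chash, config.seed)

    seg_params = SegmentationParams(**config.segmentation)
    all_metrics, all_profiles, all_tbe, all_voi = [], [], [], []
    try:
        specimens = _load_specimens(config)
        for stack, meta in specimens:
            sid = meta.specimen_id
            try:
                if config.align:
                    stack = align_to_principal_axis(stack)
                    log.info("%s: aligned, residual axis angle %.3f deg",
                             sid, axis_angle_deg(stack.voxels))
                frame = build_frame(stack, meta)
                masks = segment_stack(stack, seg_params)
                n_flagged = int((masks.qc["flags"].str.len() > 0).sum())
                log.info("%s: segmented %d slices (%d flagged)",
                         sid, stack.n_slices, n_flagged)
                metrics = compute_slice_metrics(
                    masks, stack.voxel_size_mm, config.thickness_model, frame)
                metrics.insert(0, "specimen_id", sid)
                metrics.insert(1, "group", meta.group)
                all_metrics.append(metrics)

                coverage = (metrics.percent_length.min(), metrics.percent_length.max())
                for params, rng in ((TRABECULAR_PARAMS, config.trabecular_range),
                                    (CORTICAL_PARAMS, config.cortical_range)):
                    lo = max(rng[0], np.ceil(coverage[0]))
                    hi = min(rng[1], np.floor(coverage[1]))
                    if hi - lo < 2:
                        log.warning("%s: range %s not covered (have %.1f-%.1f)",
                                    sid, rng, *coverage)
                        continue
                    grid = percent_grid(lo, hi, config.grid_step)
                    for param in params:
                        prof = build_profile(metrics, frame, param, grid,
                                             specimen_id=sid, group=meta.group)
                        all_profiles.append(prof.to_frame())

                if meta.growth_plate_slice is not None:
                    ref_pct = frame.percent_of_slice(meta.growth_plate_slice)
                    tbe = trabecular_extent(
                        metrics.percent_length.to_numpy(),
                        metrics.ba_ta.to_numpy(),
                        frame, ref_pct, config.tbe_thresholds,
                        range_percent=(max(60.0, coverage[0]), 100.0),
                        specimen_id=sid)
                    tdf = tbe.to_frame()
                    tdf.insert(1, "group", meta.group)
                    all_tbe.append(tdf)

                for name in config.vois:
                    spec = VOISpec.preset(name) if isinstance(name, str) else VOISpec(**name)
                    try:
                        bone, roi = extract_voi(masks, frame, spec)
                    except ValidationError as exc:
                        log.warning("%s: VOI %s skipped: %s", sid, spec.name, exc)
                        continue
                    if spec.compartment == "trabecular":
                        vm = trabecular_3d(bone, roi, stack.voxel_size_mm)
                    else:
                        vm = cortical_3d(bone, roi, stack.voxel_size_mm)
                    row = {"specimen_id": sid, "group": meta.group, "voi": spec.name}
                    row.update({k: getattr(vm, k) for k in vm.field_names()})
                    row["flags"] = vm.flags
                    all_voi.append(row)
            except OsteosliceError as exc:
                raise type(exc)(f"[specimen {sid}] {exc}") from exc

        _write_csv(pd.concat(all_metrics, ignore_index=True),
                   outdir / "slice_metrics.csv", chash)
        profiles_df = pd.concat(all_profiles, ignore_index=True)
        _write_csv(profiles_df, outdir / "profiles.csv", chash)
        if all_tbe:
            _write_csv(pd.concat(all_tbe, ignore_index=True), outdir / "tbe.csv", chash)
        if all_voi:
            _write_csv(pd.DataFrame(all_voi), outdir / "voi3d.csv", chash)

        stats_df = group_statistics(profiles_df, equal_var=config.equal_var,
                                    holm=config.holm)
        if stats_df is not None:
            _write_csv(stats_df, outdir / "group_stats.csv", chash)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir


def group_statistics(profiles_df: pd.DataFrame, *, equal_var: bool = True,
                     holm: bool = False) -> pd.DataFrame | None:
    """Per-parameter, per-grid-point two-group comparison of a profile table."""
    groups = sorted(profiles_df.group.unique())
    if len(groups) != 2:
        return None
    ga, gb = groups
    frames = []
    for param, sub in profiles_df.groupby("parameter"):
        cohorts = {}
        for g in (ga, gb):
            cohorts[g] = [
                MorphProfile(param, s.percent.to_numpy(), s.value.to_numpy(),
                             specimen_id=sid, group=g)
                for sid, s in sub[sub.group == g].groupby("specimen_id")
            ]
        if min(len(cohorts[ga]), len(cohorts[gb])) < 2:
            continue
        res = ttest_profile(cohorts[ga], cohorts[gb], equal_var=equal_var, holm=holm)
        frame = res.to_frame()
        frame.insert(1, "group_a", ga)
        frame.insert(2, "group_b", gb)
        # normality screen at the grid midpoint, as a per-parameter sanity flag
        mid = len(res.grid_percent) // 2
        screen = normality_screen({
            g: np.array([p.values[mid] for p in cohorts[g]]) for g in (ga, gb)})
        flagged = screen[screen.flagged]
        frame["normality_flag"] = ";".join(flagged.group.astype(str)) if len(flagged) else ""
        if len(flagged):
            log.warning("parameter %s: normality flagged at midpoint for %s",
                        param, flagged.group.tolist())
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else None
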