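"""Pipeline orchestration.

Two analysis branches share one configuration:

* PaTCH branch (single-molecule stacks): detect -> track -> stoich, yielding
  per-track stoichiometries, the single-fluorophore calibration and the
  stoichiometry periodicity;
* SIM branch (reconstructed puncta images): binarize -> objects -> ripley,
  yielding per-cell point patterns, H(r) curves, modal clustering gradients
  and nearest-neighbour distances.

`run_pipeline` executes a requested stage list in dependency order over an
artifact dictionary and returns a provenance report (config hash, seed,
package versions, per-stage counts and timings).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .cluster import (MaskRegion, PointPattern, RectRegion, analyze_objects,
                      binarize_puncta, clustering_gradient,
                      nearest_neighbor_distance, ripley_h)
from .config import RunConfig
from .detect import detect_stack
from .errors import CalibrationError, OrchestrationError
from .io import ImageStack
from .stoich import (CalibrationResult, extract_trace, periodicity,
                     postbleach_knee, single_fluorophore_brightness,
                     track_stoichiometry)
from .track import Track, deduplicate_tracks, link_tracks

logger = logging.getLogger("patchstoich")

__all__ = ["CellResult", "analyze_patch_cell", "analyze_patch_condition",
           "analyze_sim_image", "run_pipeline"]


@dataclass
class CellResult:
    """Single-cell outcome of the PaTCH branch."""

    foci_by_frame: list = field(repr=False)
    tracks: list = field(repr=False)
    calibration: CalibrationResult | None
    calibration_steps: CalibrationResult | None
    stoichiometries: np.ndarray
    n_foci: int = 0

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


def analyze_patch_cell(stack: ImageStack, config: RunConfig,
                       calibration: CalibrationResult | None = None
                       ) -> CellResult:
    """Full single-cell PaTCH analysis: foci, tracks, calibration, S.

    If no external calibration is given, I_1 is estimated from this cell's
    own post-bleach foci (modal_postbleach), cross-checked against the
    step-interval estimate from the intensity traces of its tracks.
    """
    t_start = time.perf_counter()
    foci_by_frame = detect_stack(stack, config)
    n_foci = sum(len(f) for f in foci_by_frame)
    tracks = link_tracks(foci_by_frame, config)
    # immobile assemblies: collapse co-located fragments before counting
    tracks = deduplicate_tracks(tracks, 0.5 * config.psf_fwhm_px)

    calib_steps = None
    if calibration is None:
        knee = postbleach_knee(stack, config.postbleach_fraction)
        post = np.array([f.intensity
                         for frame_foci in foci_by_frame[knee:]
                         for f in frame_foci])
        calibration = single_fluorophore_brightness(
            method="modal_postbleach", postbleach_intensities=post)
        # cross-check: modal step interval from photobleaching traces
        traces = []
        for tr in tracks:
            if tr.length >= config.n_extrapolation_frames and \
                    tr.start_frame - stack.t0_frame < config.max_start_frame:
                x, y = tr.mean_position()
                traces.append(extract_trace(stack, x, y,
                                            config.detect_radius_px,
                                            config.bg_box_px))
        try:
            calib_steps = single_fluorophore_brightness(
                method="step_intervals", traces=traces,
                min_step=config.min_step_fraction * calibration.I1,
                ck_window=config.ck_window, ck_exponent=config.ck_exponent)
        except CalibrationError:
            calib_steps = None

    S = []
    for tr in tracks:
        s = track_stoichiometry(tr, calibration, config.max_start_frame,
                                config.n_extrapolation_frames, stack.t0_frame)
        if s is not None:
            S.append(s)
    logger.info("cell: %d foci, %d tracks, %d stoichiometries, %.1f s",
                n_foci, len(tracks), len(S), time.perf_counter() - t_start)
    return CellResult(foci_by_frame, tracks, calibration, calib_steps,
                      np.array(S), n_foci)


def analyze_patch_condition(stacks: list[ImageStack], config: RunConfig
                            ) -> dict:
    """Multi-cell PaTCH analysis for one experimental condition.

    The headline periodicity is estimated from the tracks of all cells pooled
    (pooling sharpens the low-stoichiometry KDE peaks that carry the period);
    per-cell estimates are also reported.
    """
    cells = [analyze_patch_cell(stack, config) for stack in stacks]
    pooled = np.concatenate([c.stoichiometries for c in cells]) \
        if cells else np.empty(0)
    per_cell = []
    for c in cells:
        if c.stoichiometries.size >= 3:
            try:
                res = periodicity(c.stoichiometries, config.stoich_kernel_width,
                                  config.min_interval,
                                  config.n_extrapolation_frames)
                per_cell.append(res)
            except Exception:
                pass
    mean_period = float(np.mean([r.interval for r in per_cell])) \
        if per_cell else float("nan")
    pooled_period = None
    if pooled.size >= 3:
        try:
            pooled_period = periodicity(pooled, config.stoich_kernel_width,
                                        config.min_interval,
                                        config.n_extrapolation_frames)
        except Exception:
            pooled_period = None
    return {
        "cells": cells,
        "stoichiometries": pooled,
        "tracks_per_cell": [sum(1 for t in c.tracks if not t.excluded)
                            for c in cells],
        "periodicity": pooled_period,
        "periodicity_per_cell": per_cell,
        "periodicity_per_cell_mean": mean_period,
    }


def analyze_sim_image(image: np.ndarray, pixel_size_nm: float,
                      config: RunConfig,
                      roi_mask: np.ndarray | None = None) -> dict:
    """Full single-cell SIM branch: binarize, objects, Ripley summaries."""
    mask = binarize_puncta(image, config.otsu_local_radius_px,
                           config.min_object_px)
    if roi_mask is not None:
        mask &= roi_mask
        region: RectRegion | MaskRegion = MaskRegion(roi_mask, pixel_size_nm)
    else:
        h, w = image.shape
        region = RectRegion(w * pixel_size_nm, h * pixel_size_nm)
    objects = analyze_objects(mask, image, pixel_size_nm)
    pts = np.array([[o.x_px * pixel_size_nm, o.y_px * pixel_size_nm]
                    for o in objects])
    if len(pts):
        pts = pts[region.contains(pts)]
    out = {"mask": mask, "objects": objects, "points_nm": pts, "region": region,
           "curve": None, "modal_gradient": None, "nn_distance_nm": None}
    if len(pts) >= 10:
        curve = ripley_h(PointPattern(pts, region),
                         edge_correction=config.edge_correction)
        out["curve"] = curve
        out["modal_gradient"] = clustering_gradient(
            curve, config.gradient_kernel_width)
        out["nn_distance_nm"] = nearest_neighbor_distance(curve)
    return out


# ---------------------------------------------------------------------------
# staged execution
# ---------------------------------------------------------------------------

_PATCH_ORDER = ["simulate", "detect", "track", "stoich"]
_SIM_ORDER = ["binarize", "objects", "ripley"]


def run_pipeline(config: RunConfig, stages: list[str],
                 artifacts: dict | None = None) -> dict:
    """Execute pipeline stages in order over an artifact dictionary.

    PaTCH stages consume/produce: ``stacks`` -> ``foci`` -> ``tracks`` ->
    ``stoichiometries`` (+ ``calibration``); SIM stages: ``image`` ->
    ``mask`` -> ``objects``/``points`` -> ``ripley``.  A stage whose input
    artifact is missing raises :class:`OrchestrationError` naming it.
    Returns a report with config hash, seed, versions and per-stage counts;
    the artifact dict is updated in place.
    """
    artifacts = artifacts if artifacts is not None else {}
    known = _PATCH_ORDER + _SIM_ORDER
    for s in stages:
        if s not in known:
            raise OrchestrationError(f"unknown stage {s!r}")
    ordered = [s for s in known if s in stages]

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"patchstoich": __version__, "numpy": np.__version__},
        "stages": {},
    }

    for s in ordered:
        t0 = time.perf_counter()
        counts: dict = {}
        if s == "simulate":
            from .synthetic import simulate_assembly_stack

            rng = np.random.default_rng(config.seed)
            stoich = 2 * rng.integers(1, 19, size=50)
            stack, truth = simulate_assembly_stack(stoich, seed=rng)
            artifacts["stacks"] = [stack]
            artifacts["truth"] = [truth]
            counts = {"n_stacks": 1, "n_assemblies": len(stoich)}
        elif s == "detect":
            if "stacks" not in artifacts:
                raise OrchestrationError("stage 'detect' needs artifact 'stacks'")
            artifacts["foci"] = [detect_stack(st, config)
                                 for st in artifacts["stacks"]]
            counts = {"n_foci": sum(len(f) for per in artifacts["foci"]
                                    for f in per)}
        elif s == "track":
            if "foci" not in artifacts:
                raise OrchestrationError("stage 'track' needs artifact 'foci'")
            artifacts["tracks"] = [link_tracks(per, config)
                                   for per in artifacts["foci"]]
            counts = {"n_tracks": sum(len(t) for t in artifacts["tracks"])}
        elif s == "stoich":
            if "tracks" not in artifacts or "stacks" not in artifacts:
                raise OrchestrationError(
                    "stage 'stoich' needs artifacts 'tracks' and 'stacks'")
            all_S = []
            for stack, foci, tracks in zip(artifacts["stacks"],
                                           artifacts.get("foci", []),
                                           artifacts["tracks"]):
                knee = postbleach_knee(stack, config.postbleach_fraction)
                post = np.array([f.intensity for per in foci[knee:]
                                 for f in per])
                calib = single_fluorophore_brightness(
                    method="modal_postbleach", postbleach_intensities=post)
                artifacts.setdefault("calibration", []).append(calib)
                for tr in tracks:
                    sval = track_stoichiometry(
                        tr, calib, config.max_start_frame,
                        config.n_extrapolation_frames, stack.t0_frame)
                    if sval is not None:
                        all_S.append(sval)
            artifacts["stoichiometries"] = np.array(all_S)
            counts = {"n_stoichiometries": len(all_S)}
        elif s == "binarize":
            if "image" not in artifacts:
                raise OrchestrationError("stage 'binarize' needs artifact 'image'")
            artifacts["mask"] = binarize_puncta(
                artifacts["image"], config.otsu_local_radius_px,
                config.min_object_px)
            counts = {"n_mask_px": int(artifacts["mask"].sum())}
        elif s == "objects":
            if "mask" not in artifacts:
                raise OrchestrationError("stage 'objects' needs artifact 'mask'")
            objs = analyze_objects(artifacts["mask"],
                                   artifacts.get("image"),
                                   config.pixel_size_nm)
            artifacts["objects"] = objs
            artifacts["points_nm"] = np.array(
                [[o.x_px * config.pixel_size_nm, o.y_px * config.pixel_size_nm]
                 for o in objs])
            counts = {"n_objects": len(objs)}
        elif s == "ripley":
            if "points_nm" not in artifacts:
                raise OrchestrationError("stage 'ripley' needs artifact 'points_nm'")
            region = artifacts.get("region")
            if region is None:
                h, w = artifacts["mask"].shape
                region = RectRegion(w * config.pixel_size_nm,
                                    h * config.pixel_size_nm)
            pts = artifacts["points_nm"]
            pattern = PointPattern(pts[region.contains(pts)], region)
            curve = ripley_h(pattern, edge_correction=config.edge_correction)
            artifacts["ripley"] = curve
            artifacts["modal_gradient"] = clustering_gradient(
                curve, config.gradient_kernel_width)
            artifacts["nn_distance_nm"] = nearest_neighbor_distance(curve)
            counts = {"n_points": pattern.n}
        dt = time.perf_counter() - t0
        report["stages"][s] = {"counts": counts, "seconds": round(dt, 3)}
        logger.info("stage %-9s %s (%.2f s)", s, counts, dt)
    return report
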