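"""Desk-scale end-to-end validation protocols.

These functions run the whole method — simulate a training section and a
separate test section, build labels from the rendered fluorescence, train
the reduced ("tiny") network on reflectance, predict the held-out scene,
segment, and score against the simulator's exact truth — at sizes a single
CPU handles in minutes.  They define the package's *study conditions*: the
scene parameters below are the fixed regimes every report and test refers
to, and both the test-suite and the reproduction script call these same
functions.

The train and test scenes always use different seeds, mirroring the
train-on-one-section / validate-on-another discipline.
"""

from __future__ import annotations

from dataclasses import replace

from lfseg import segmentation as seg
from lfseg import unet as unet_mod
from lfseg.evaluation import (
    IOUReport,
    evaluate_3d_planes,
    extract_plane,
    match_objects,
    per_plane_medians,
)
from lfseg.profiling import GateSpec, control_threshold, extract_features, gate_cells
from lfseg.synthetic import SceneParams, generate_scene, scene_to_training_pairs

#: 2D study conditions: densely packed contacting cells on a 256^2 grid.
SCENE_2D = SceneParams(shape=(256, 256), n_cells=60, seed=0)

#: 3D study conditions: a 64^3 stack with mild depth attenuation.  Nuclei
#: take a slightly larger fraction of the cell than in 2D so that a
#: ~16-voxel-diameter cell still carries a well-resolved nucleus.
SCENE_3D = SceneParams(
    shape=(64, 64, 64),
    n_cells=70,
    mean_cell_diameter=16.0,
    nucleus_fraction=0.55,
    depth_attenuation=0.995,
    seed=0,
)

#: fraction of a cell's area that must be suprathreshold to stay gated
MIN_AREA_FRACTION = 0.25

#: slice indices annotated per plane in the 3D evaluation
PLANE_SLICES = (20, 32, 44)


def _scene_pair(base: SceneParams, seed: int) -> tuple[SceneParams, SceneParams]:
    train_seed = 2 * seed + 1
    return replace(base, seed=train_seed), replace(base, seed=train_seed + 1)


def _watershed_params(scene_params: SceneParams) -> seg.WatershedParams:
    # elevation smoothing tracks the expected cell size (~diameter / 5),
    # like declumping smoothing filters matched to object diameter
    return seg.WatershedParams(
        elevation_smoothing_sigma=scene_params.mean_cell_diameter / 5.0
    )


def run_label_free_2d(seed: int = 0) -> dict:
    """Full 2D protocol; returns the scored report and all intermediates.

    Train the tiny 2D network on one simulated section, predict the class
    probability map of a held-out section from reflectance alone, watershed
    into cells, apply the percentile size filter, and score every interior
    truth cell with the Jaccard index.
    """
    train_params, eval_params = _scene_pair(SCENE_2D, seed)
    train_scene = generate_scene(train_params)
    reflectance, labels = scene_to_training_pairs(train_scene)

    spec, config = unet_mod.tiny(seed=seed)
    model = unet_mod.build_model(spec, seed=seed)
    sampler = unet_mod.sample_patches(reflectance, labels, config)
    model, history = unet_mod.train(model, sampler, config)

    eval_scene = generate_scene(eval_params)
    eval_reflectance, _ = scene_to_training_pairs(eval_scene)
    probs = unet_mod.predict_probability_map(
        model, eval_reflectance, tile_shape=(128, 128), overlap_fraction=0.30
    )
    params = _watershed_params(eval_params)
    objects = seg.filter_by_size(seg.segment(probs, params))
    report = match_objects(objects, eval_scene.truth)
    return {
        "median_iou": report.median_j,
        "n_scored": len(report.comparisons),
        "report": report,
        "model": model,
        "loss_history": history,
        "probs": probs,
        "objects": objects,
        "train_scene": train_scene,
        "eval_scene": eval_scene,
    }


def run_label_free_3d(seed: int = 0) -> dict:
    """Full 3D protocol with per-plane (xy / zy / xz) validation.

    As :func:`run_label_free_2d` but on a 64^3 stack with the tiny 3D
    network; the segmentation is scored on orthogonal cross-sections
    against the matching slices of the truth, pooling objects across
    :data:`PLANE_SLICES` per plane.
    """
    train_params, eval_params = _scene_pair(SCENE_3D, seed)
    train_scene = generate_scene(train_params)
    reflectance, labels = scene_to_training_pairs(train_scene)

    spec, config = unet_mod.tiny3d(seed=seed)
    model = unet_mod.build_model(spec, seed=seed)
    sampler = unet_mod.sample_patches(reflectance, labels, config)
    model, history = unet_mod.train(model, sampler, config)

    eval_scene = generate_scene(eval_params)
    eval_reflectance, _ = scene_to_training_pairs(eval_scene)
    probs = unet_mod.predict_probability_map(model, eval_reflectance)
    params = _watershed_params(eval_params)
    objects = seg.filter_by_size(seg.segment(probs, params))

    annotations = [
        (plane, idx, extract_plane(eval_scene.truth, plane, idx))
        for plane in ("xy", "zy", "xz")
        for idx in PLANE_SLICES
    ]
    reports: list[IOUReport] = evaluate_3d_planes(objects, annotations)
    medians = per_plane_medians(reports)
    return {
        "per_plane_median_iou": medians,
        "reports": reports,
        "model": model,
        "loss_history": history,
        "probs": probs,
        "objects": objects,
        "train_scene": train_scene,
        "eval_scene": eval_scene,
    }


def run_bystander_gating(seed: int = 0) -> dict:
    """Sequential-gate recovery of planted marker-positive cells.

    Simulates a scene whose surface marker spills 2 px into adjacent
    cells, derives the intensity cutoff from the scene's own control
    channel (removing ~95% of control fluorescence), and compares the pure
    intensity gate against the sequential intensity + fluorescence-area
    gate.  Features are measured on the exact truth objects so the
    comparison isolates the gating behaviour.
    """
    params = replace(SCENE_2D, seed=1000 + seed)
    scene = generate_scene(params)
    planted = set(scene.positives)
    cutoff = control_threshold(scene.channels.get("marker_control"), 0.95)
    table = extract_features(scene.truth, scene.channels, {"marker": cutoff})
    intensity_only = gate_cells(
        table, GateSpec("marker", intensity_cutoff=cutoff, min_area_fraction=0.0)
    )
    sequential = gate_cells(
        table,
        GateSpec("marker", intensity_cutoff=cutoff, min_area_fraction=MIN_AREA_FRACTION),
    )
    tp = len(sequential & planted)
    return {
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(sequential) if sequential else float("nan"),
        "false_positives_intensity_gate": len(intensity_only - planted),
        "false_positives_sequential_gate": len(sequential - planted),
        "planted": planted,
        "intensity_only": intensity_only,
        "sequential": sequential,
        "scene": scene,
        "control_cutoff": cutoff,
    }
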