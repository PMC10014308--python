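"""Synthetic tissue scenes with exact instance ground truth.

Lymphoid tissue is almost entirely composed of contacting cells in dense,
layer-upon-layer arrangements — the regime in which label-free segmentation
is hard.  The simulator reproduces that geometry by Voronoi tessellation of
blue-noise (minimum-distance) seed points clipped to an elliptical tissue
mask: every interior cell touches its neighbors.  Each cell carries an
interior nucleus and a thin boundary shell (cytoskeleton).  Rendered
channels:

* ``nuclei_fluor`` / ``structure_fluor`` — the stains a training section
  would carry: the nucleus mask, and the cytoskeleton rendered as a diffuse
  cytoplasmic fill with a brighter cortical shell (how phalloidin/WGA
  staining actually looks), blurred and noised.
* ``reflectance`` — a fixed affine mixture of shell and nucleus masks with
  multiplicative lognormal speckle, then Gaussian blur: a stationary,
  learnable mapping from structure to intensity standing in for the
  back-scattered laser signal.
* ``marker`` — a surface stain on the outer shell of a chosen subset of
  cells, deliberately dilated 2 px so it spills into adjacent cells and
  creates bystander-positive events for the area gate to remove.
* ``marker_control`` — background-level noise only (a secondary-only
  control image).

In 3D, every rendered channel's slice ``z`` is scaled by
``depth_attenuation**z``, mimicking attenuation with imaging depth.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SceneParams.seed``; identical parameters give bit-identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from lfseg.ground_truth import make_class_labels, rescale_unit
from lfseg.types import MultichannelImage, NormalizedImage

# Fixed rendering constants: one "microscope" for every scene, so train and
# test images live on the same intensity frame.
REFLECTANCE_SHELL_GAIN = 0.8
REFLECTANCE_NUCLEUS_GAIN = 0.45
REFLECTANCE_CYTOPLASM_GAIN = 0.2
REFLECTANCE_AMBIENT = 0.05
#: diffuse cytoplasmic intensity of the structural stain relative to the
#: cortical shell (phalloidin stains cytoplasmic actin, enriched cortically)
CYTOPLASM_FLUOR = 0.55
SPECKLE_SIGMA = 0.25
MARKER_SPILL_PX = 2
#: Fixed acquisition intensity range used when normalizing synthetic images.
SCENE_INTENSITY_RANGE = (0.0, 2.0)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic tissue scene.

    ``shape`` is ``(y, x)`` for 2D or ``(z, y, x)`` for 3D.  ``noise_sd`` is
    the additive Gaussian noise scale on unit-intensity channels;
    ``depth_attenuation`` is the per-slice multiplicative decay in 3D
    (1 = none).
    """

    shape: tuple[int, ...] = (256, 256)
    n_cells: int = 60
    mean_cell_diameter: float = 18.0
    nucleus_fraction: float = 0.45
    shell_thickness: float = 2.0
    marker_positive_fraction: float = 0.25
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    depth_attenuation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError("shape must be 2D (y, x) or 3D (z, y, x)")
        if any(s <= 0 for s in shape):
            raise ValueError(f"shape dimensions must be positive, got {shape}")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 < self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        if not 0 <= self.marker_positive_fraction <= 1:
            raise ValueError("marker_positive_fraction must lie in [0, 1]")
        if self.mean_cell_diameter <= 0 or self.shell_thickness <= 0:
            raise ValueError("mean_cell_diameter and shell_thickness must be positive")
        if self.depth_attenuation <= 0 or self.depth_attenuation > 1:
            raise ValueError("depth_attenuation must lie in (0, 1]")

    @property
    def ndim(self) -> int:
        return len(self.shape)


@dataclass
class SyntheticScene:
    """A rendered scene plus its exact ground truth.

    ``truth`` and ``nuclei_truth`` are instance label maps (0 = background,
    positive integers = cell ids; nucleus pixels carry their cell's id).
    ``positives`` is the set of cell ids rendered marker-positive.
    """

    params: SceneParams
    truth: np.ndarray
    nuclei_truth: np.ndarray
    channels: MultichannelImage
    positives: frozenset[int] = field(default_factory=frozenset)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.truth.shape


def _tissue_mask(shape: tuple[int, ...]) -> np.ndarray:
    """Elliptical/ellipsoidal tissue footprint leaving true background."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    centre = [(s - 1) / 2.0 for s in shape]
    semi = [0.52 * s for s in shape]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semi))
    return r2 <= 1.0


def _blue_noise_points(
    mask: np.ndarray, n: int, min_dist: float, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling inside a boolean mask."""
    shape = mask.shape
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 300 * max(n, 1) + 1000
    while len(pts) < n and attempts < max_attempts:
        cand = rng.uniform(0, 1, size=len(shape)) * (np.array(shape) - 1)
        attempts += 1
        idx = tuple(int(round(c)) for c in cand)
        if not mask[idx]:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_dist:
            continue
        pts.append(cand)
    return np.array(pts).reshape(len(pts), len(shape))


def _boundary_pixels(truth: np.ndarray) -> np.ndarray:
    """Pixels whose face neighbor carries a different label (incl. background)."""
    boundary = np.zeros(truth.shape, dtype=bool)
    for axis in range(truth.ndim):
        sl_a = [slice(None)] * truth.ndim
        sl_b = [slice(None)] * truth.ndim
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        diff = truth[tuple(sl_a)] != truth[tuple(sl_b)]
        boundary[tuple(sl_a)] |= diff
        boundary[tuple(sl_b)] |= diff
    return boundary & (truth > 0)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one synthetic tissue scene.

    If the field cannot host ``n_cells`` at the requested spacing, fewer
    cells are placed (never an error).  With ``n_cells == 0`` the truth is
    all zeros and every channel is pure noise.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.shape
    mask = _tissue_mask(shape)

    min_dist = 0.75 * params.mean_cell_diameter
    seeds = (
        _blue_noise_points(mask, params.n_cells, min_dist, rng)
        if params.n_cells > 0
        else np.empty((0, len(shape)))
    )
    n_placed = len(seeds)

    truth = np.zeros(shape, dtype=np.int32)
    nuclei_truth = np.zeros(shape, dtype=np.int32)
    shell = np.zeros(shape, dtype=bool)
    if n_placed:
        coords = np.indices(shape).reshape(len(shape), -1).T
        tree = cKDTree(seeds)
        dist_to_seed, owner = tree.query(coords)
        truth_flat = np.where(mask.ravel(), owner.astype(np.int32) + 1, 0)
        truth = truth_flat.reshape(shape)

        boundary = _boundary_pixels(truth)
        dist_to_boundary = ndimage.distance_transform_edt(~boundary)
        shell = (truth > 0) & (dist_to_boundary < params.shell_thickness)

        r_nuc = params.nucleus_fraction * params.mean_cell_diameter / 2.0
        nucleus = (dist_to_seed.reshape(shape) <= r_nuc) & (truth > 0) & ~shell
        nuclei_truth = np.where(nucleus, truth, 0).astype(np.int32)

    nucleus_mask = nuclei_truth > 0

    # Marker-positive subset, rendered as a 2 px-dilated rim on the outer
    # shell.  The rendered fluorescence (after blur) is clipped to within
    # MARKER_SPILL_PX of the positive cells so that suprathreshold spill
    # into adjacent cells never exceeds the stated 2 px.
    positives: frozenset[int] = frozenset()
    marker_sig = np.zeros(shape, dtype=np.float64)
    marker_zone: np.ndarray | None = None
    if n_placed and params.marker_positive_fraction > 0:
        n_pos = int(round(params.marker_positive_fraction * n_placed))
        if n_pos > 0:
            chosen = rng.choice(np.arange(1, n_placed + 1), size=n_pos, replace=False)
            positives = frozenset(int(c) for c in chosen)
            rim = shell & np.isin(truth, list(positives))
            ball = _ball_structuring_element(len(shape), MARKER_SPILL_PX)
            spill = ndimage.binary_dilation(rim, ball)
            marker_sig[spill] = 1.0
            marker_zone = ndimage.binary_dilation(np.isin(truth, list(positives)), ball)

    # Channel rendering: signal -> speckle (reflectance) -> blur -> depth
    # attenuation -> additive noise.  The structural stain fills the whole
    # cytoplasm (diffuse) with a brighter cortical shell, as phalloidin/WGA
    # staining does; a shells-only stain would leave cell interiors in the
    # background class and make full-cell objects unrecoverable downstream.
    nuclei_sig = nucleus_mask.astype(np.float64)
    cytoplasm = (truth > 0) & ~nucleus_mask
    shell_sig = shell.astype(np.float64)
    struct_sig = CYTOPLASM_FLUOR * (cytoplasm & ~shell) + 1.0 * shell
    if n_placed:
        refl_sig = (
            REFLECTANCE_SHELL_GAIN * shell_sig
            + REFLECTANCE_NUCLEUS_GAIN * nuclei_sig
            + REFLECTANCE_CYTOPLASM_GAIN * (cytoplasm & ~shell)
            + REFLECTANCE_AMBIENT * mask
        )
    else:
        refl_sig = np.zeros(shape, dtype=np.float64)
    speckle = rng.lognormal(mean=0.0, sigma=SPECKLE_SIGMA, size=shape)
    refl_sig = refl_sig * speckle

    def _render(sig: np.ndarray, support: np.ndarray | None = None) -> np.ndarray:
        out = ndimage.gaussian_filter(sig, params.blur_sigma) if params.blur_sigma > 0 else sig
        if support is not None:
            out = out * support
        if len(shape) == 3 and params.depth_attenuation < 1:
            decay = params.depth_attenuation ** np.arange(shape[0], dtype=np.float64)
            out = out * decay[(slice(None),) + (None,) * (len(shape) - 1)]
        if params.noise_sd > 0:
            out = out + rng.normal(0.0, params.noise_sd, size=shape)
        return np.clip(out, 0.0, None)

    channels = MultichannelImage(
        channels={
            "nuclei_fluor": _render(nuclei_sig),
            "structure_fluor": _render(struct_sig),
            "reflectance": _render(refl_sig),
            "marker": _render(marker_sig, support=marker_zone),
            "marker_control": _render(np.zeros(shape, dtype=np.float64)),
        }
    )
    return SyntheticScene(
        params=params,
        truth=truth,
        nuclei_truth=nuclei_truth,
        channels=channels,
        positives=positives,
    )


def _ball_structuring_element(ndim: int, radius: int) -> np.ndarray:
    """Euclidean disc (2D) or ball (3D) footprint of the given radius."""
    grids = np.ogrid[tuple(slice(-radius, radius + 1) for _ in range(ndim))]
    return sum(g**2 for g in grids) <= radius**2


def scene_to_training_pairs(scene: SyntheticScene) -> tuple[NormalizedImage, np.ndarray]:
    """Derive a (reflectance, class-label) training pair from a scene.

    Labels come from thresholding the *rendered* fluorescence channels —
    exactly how training labels are built from a real stained section — so
    the label-noise path of the method is exercised, not bypassed with the
    geometric truth.
    """
    refl = scene.channels.get("reflectance")
    nuc = scene.channels.get("nuclei_fluor")
    cyt = scene.channels.get("structure_fluor")
    lo, hi = SCENE_INTENSITY_RANGE
    reflectance = rescale_unit(refl, lo=lo, hi=hi)
    if nuc.max() == 0 and cyt.max() == 0:
        labels = np.zeros(scene.shape, dtype=np.uint8)
    else:
        labels = make_class_labels(nuc, cyt, method="otsu")
    return reflectance, labels


def noise_free(params: SceneParams) -> SceneParams:
    """The same scene geometry without speckle-independent noise or blur."""
    return replace(params, noise_sd=0.0, blur_sigma=0.0)
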