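"""Shared containers and class conventions.

Pixel-class convention used everywhere in the package:

* 0 — background
* 1 — nuclei
* 2 — cytoskeleton (or cell membrane for FFPE-style training data)

Probability maps carry the class axis first: ``probs[c, ...spatial]`` with
``probs.sum(axis=0) == 1`` per pixel.  Instance label maps are integer arrays
with 0 = background and positive integers = cell ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_BACKGROUND = 0
CLASS_NUCLEI = 1
CLASS_CYTOSKELETON = 2
N_CLASSES = 3

#: Channel roles a scene / acquisition may carry.
CHANNEL_ROLES = (
    "nuclei_fluor",
    "structure_fluor",
    "reflectance",
    "marker",
    "marker_control",
)


class MissingChannelError(KeyError):
    """A required channel role is absent from a multichannel image."""


@dataclass
class MultichannelImage:
    """A 2D or 3D image with named channel roles.

    All channels share one spatial grid, ``(y, x)`` or ``(z, y, x)``.

    Parameters
    ----------
    channels
        Mapping from role name (see :data:`CHANNEL_ROLES`) to pixel array.
    pixel_size
        Optional pixel/voxel edge length in micrometres (metadata only).
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size: float | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        if not self.channels:
            return ()
        return next(iter(self.channels.values())).shape

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def get(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise MissingChannelError(
                f"channel role {role!r} not present; have {sorted(self.channels)}"
            )
        return self.channels[role]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel grids differ in shape: {sorted(shapes)}")


@dataclass
class NormalizedImage:
    """An image rescaled to the closed unit interval.

    ``pixels`` is float with min >= 0 and max <= 1; the rescale is linear
    with no contrast adjustment, so pixel rank order is preserved.
    """

    pixels: np.ndarray
    pixel_size: float | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.size and (p.min() < -1e-9 or p.max() > 1 + 1e-9):
            raise ValueError("NormalizedImage pixels must lie in [0, 1]")
        self.pixels = p.astype(np.float64, copy=False)


def check_same_shape(*arrays: np.ndarray) -> tuple[int, ...]:
    """Raise ValueError unless all arrays share one shape; return it."""
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")
    return shapes.pop()
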