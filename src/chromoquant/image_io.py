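"""Reading confocal stacks and building maximum-intensity projections.

A stack is held as a 4-D array indexed ``(channel, z, row, col)`` with a
mapping from channel *roles* (``dapi``, ``mark``, ``compartment``, ``fish``)
to channel indices.  All downstream quantification runs on 2-D maximum
projections over a contiguous z-range; by default twelve consecutive
sections are projected, matching the depth of signal typically captured for
a wing-nucleus monolayer at 0.13 um z-spacing.

Pixel values are never rescaled at load time: every threshold and every
integrated intensity downstream operates on raw camera counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Channel roles understood by the pipeline.  ``dapi`` is mandatory.
KNOWN_ROLES = ("dapi", "mark", "compartment", "fish")

#: Default z-spacing in micrometres (system-optimised confocal sectioning).
DEFAULT_VOXEL_Z_UM = 0.13

#: Default number of consecutive sections in a maximum projection.
DEFAULT_PROJECTION_DEPTH = 12


@dataclass
class ImageStack:
    """Multi-channel confocal z-stack with voxel geometry.

    Parameters
    ----------
    pixels
        4-D non-negative intensity array indexed ``(channel, z, row, col)``.
    channel_roles
        Mapping role -> channel index.  Roles are drawn from
        :data:`KNOWN_ROLES`; ``dapi`` must be present.
    voxel_z_um
        z-spacing in micrometres.
    pixel_xy_um
        Lateral pixel size in micrometres.  The default of 1.0 means
        distances are reported in pixels.
    """

    pixels: np.ndarray
    channel_roles: dict[str, int]
    voxel_z_um: float = DEFAULT_VOXEL_Z_UM
    pixel_xy_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"stack must be 4-D (channel, z, row, col); got shape {self.pixels.shape}"
            )
        if self.pixels.shape[1] < 1:
            raise ValueError("stack must contain at least one z-section")
        if np.issubdtype(self.pixels.dtype, np.floating) and not np.all(
            np.isfinite(self.pixels)
        ):
            raise ValueError("stack contains non-finite pixel values")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("stack contains negative intensities")
        if "dapi" not in self.channel_roles:
            raise ValueError("dapi role required")
        indices = list(self.channel_roles.values())
        if len(set(indices)) != len(indices):
            raise ValueError(f"channel indices must be distinct: {self.channel_roles}")
        for role, idx in self.channel_roles.items():
            if role not in KNOWN_ROLES:
                raise ValueError(f"unknown channel role {role!r}; known: {KNOWN_ROLES}")
            if not 0 <= idx < self.pixels.shape[0]:
                raise ValueError(
                    f"channel index {idx} for role {role!r} out of range "
                    f"(stack has {self.pixels.shape[0]} channels)"
                )

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of one section."""
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """3-D ``(z, row, col)`` view of the channel serving *role*."""
        if role not in self.channel_roles:
            raise KeyError(f"role {role!r} not declared; have {list(self.channel_roles)}")
        return self.pixels[self.channel_roles[role]]

    def has_role(self, role: str) -> bool:
        return role in self.channel_roles


@dataclass
class Projection2D:
    """2-D projection of one channel over a half-open z-range."""

    pixels: np.ndarray
    source_z_range: tuple[int, int] = (0, 1)
    channel_role: str = "dapi"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"projection must be 2-D; got shape {self.pixels.shape}")
        z0, z1 = self.source_z_range
        if not (0 <= z0 < z1):
            raise ValueError(f"invalid z range {self.source_z_range}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def load_stack(
    path: str | Path,
    channel_roles: dict[str, int],
    voxel_z_um: float = DEFAULT_VOXEL_Z_UM,
    pixel_xy_um: float = 1.0,
    axis_order: str = "CZYX",
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`, bit-exactly.

    The file's pages are mapped onto ``(channel, z)`` according to
    *axis_order* (``CZYX``: pages grouped by channel, z varying fastest;
    ``ZCYX``: pages grouped by z).  Sample values are taken verbatim — no
    rescaling or normalisation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if "dapi" not in channel_roles:
        raise ValueError("dapi role required")
    if axis_order not in ("CZYX", "ZCYX"):
        raise ValueError(f"axis_order must be CZYX or ZCYX, got {axis_order!r}")

    arr = tifffile.imread(path)
    n_channels = max(channel_roles.values()) + 1
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim == 4:
        pass  # already (A, B, Y, X) in file order
    elif arr.ndim == 3:
        n_pages = arr.shape[0]
        if n_pages % n_channels:
            raise ValueError(
                f"axis-order ambiguity: {n_pages} pages not divisible by "
                f"{n_channels} declared channels"
            )
        n_z = n_pages // n_channels
        if axis_order == "CZYX":
            arr = arr.reshape(n_channels, n_z, *arr.shape[1:])
        else:
            arr = arr.reshape(n_z, n_channels, *arr.shape[1:])
    else:
        raise ValueError(f"cannot interpret TIFF with {arr.ndim} dimensions")

    if axis_order == "ZCYX":
        arr = np.swapaxes(arr, 0, 1)
    return ImageStack(
        pixels=arr,
        channel_roles=dict(channel_roles),
        voxel_z_um=voxel_z_um,
        pixel_xy_um=pixel_xy_um,
    )


def write_stack(stack: ImageStack, path: str | Path, axis_order: str = "CZYX") -> None:
    """Write a stack as a multi-page TIFF in the dialect :func:`load_stack` reads."""
    if axis_order not in ("CZYX", "ZCYX"):
        raise ValueError(f"axis_order must be CZYX or ZCYX, got {axis_order!r}")
    arr = stack.pixels
    if axis_order == "ZCYX":
        arr = np.swapaxes(arr, 0, 1)
    pages = arr.reshape(-1, *arr.shape[2:])
    tifffile.imwrite(Path(path), pages)


def max_project(
    stack: ImageStack,
    role: str,
    z_start: int = 0,
    z_count: int | None = None,
) -> Projection2D:
    """Maximum-intensity projection of one channel over a contiguous z-range.

    Output pixel ``(r, c)`` is the maximum over ``z in [z_start,
    z_start + z_count)`` of the channel's voxel ``(z, r, c)``.  When
    *z_count* is omitted, twelve sections are projected if the stack is deep
    enough, otherwise the full stack is used (with a logged warning, since a
    shallow stack departs from the intended twelve-section depth).
    """
    chan = stack.channel(role)
    n_z = chan.shape[0]
    if z_count is None:
        if n_z - z_start >= DEFAULT_PROJECTION_DEPTH:
            z_count = DEFAULT_PROJECTION_DEPTH
        else:
            z_count = n_z - z_start
            logger.warning(
                "stack has only %d sections from z_start=%d; projecting all of them "
                "instead of the default %d",
                z_count, z_start, DEFAULT_PROJECTION_DEPTH,
            )
    if z_count < 1:
        raise ValueError(f"z_count must be >= 1, got {z_count}")
    if z_start < 0 or z_start + z_count > n_z:
        raise ValueError(
            f"z range [{z_start}, {z_start + z_count}) out of bounds for {n_z} sections"
        )
    proj = chan[z_start : z_start + z_count].max(axis=0)
    return Projection2D(
        pixels=proj,
        source_z_range=(z_start, z_start + z_count),
        channel_role=role,
    )
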