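"""Core containers and NIfTI / event-file I/O.

Conventions used throughout the package:

* voxel coordinates are 0-based indices; the time axis is the 4th axis;
* all event times are seconds relative to the first volume's acquisition
  start;
* NIfTI scaling slope/intercept are applied on read, so grid values are
  physical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "Mask3D",
    "EventTrain",
    "read_volume4d",
    "write_volume4d",
    "read_events",
    "write_events",
    "read_mask",
    "write_mask",
]


class ImagingIOError(ValueError):
    """Raised for malformed imaging or event inputs."""


@dataclass
class Volume4D:
    """A 4D fMRI grid (x, y, z, t) with geometry and repetition time.

    Parameters
    ----------
    data
        Real-valued array of shape ``(nx, ny, nz, nt)``.
    tr
        Repetition time in seconds, strictly positive.
    affine
        4x4 voxel-to-world map. Defaults to a scaled identity built from
        ``voxel_size``.
    voxel_size
        Three positive voxel edge lengths in mm.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ImagingIOError(
                f"Volume4D requires a 4D grid, got {self.data.ndim}D"
            )
        if self.data.shape[3] < 2:
            raise ImagingIOError("Volume4D needs at least 2 time points")
        if not self.tr > 0:
            raise ImagingIOError(f"tr must be > 0, got {self.tr}")
        if any(v <= 0 for v in self.voxel_size):
            raise ImagingIOError(f"voxel sizes must be > 0, got {self.voxel_size}")
        if self.affine is None:
            aff = np.eye(4)
            aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
            self.affine = aff
        else:
            self.affine = np.asarray(self.affine, dtype=np.float64)
            if self.affine.shape != (4, 4):
                raise ImagingIOError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def duration(self) -> float:
        """Total acquisition span in seconds (n_volumes * tr)."""
        return self.n_volumes * self.tr


@dataclass
class Mask3D:
    """Binary 3D mask on the spatial grid of a companion :class:`Volume4D`."""

    data: np.ndarray
    kind: str = "brain"

    _KINDS = ("brain", "edge", "csf")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ImagingIOError(f"mask kind must be one of {self._KINDS}")
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ImagingIOError(f"Mask3D requires a 3D grid, got {arr.ndim}D")
        self.data = arr != 0
        if self.kind == "brain" and not self.data.any():
            raise ImagingIOError("brain mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_matches(self, reference_shape: Sequence[int]) -> None:
        if tuple(self.data.shape) != tuple(reference_shape)[:3]:
            raise ImagingIOError(
                f"mask shape {self.data.shape} does not match reference "
                f"grid {tuple(reference_shape)[:3]}"
            )


@dataclass
class EventTrain:
    """Event onset times (seconds) with optional per-event durations."""

    onsets: np.ndarray
    durations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=np.float64).ravel()
        if self.onsets.size and self.onsets.min() < 0:
            raise ImagingIOError("event onsets must be >= 0")
        if np.any(np.diff(self.onsets) < 0):
            self.onsets = np.sort(self.onsets)
        if self.durations is None:
            self.durations = np.zeros_like(self.onsets)
        else:
            self.durations = np.asarray(self.durations, dtype=np.float64).ravel()
            if self.durations.shape != self.onsets.shape:
                raise ImagingIOError("durations must match onsets in length")
            if self.durations.size and self.durations.min() < 0:
                raise ImagingIOError("event durations must be >= 0")

    def __len__(self) -> int:
        return self.onsets.size

    def check_within(self, vol: Volume4D) -> None:
        """Every onset must fall inside the companion series."""
        if len(self) and self.onsets.max() >= vol.duration:
            raise ImagingIOError(
                f"event onset {self.onsets.max():g}s is outside the series "
                f"(duration {vol.duration:g}s)"
            )


def read_volume4d(path: str | os.PathLike, tr: float | None = None) -> Volume4D:
    """Read a 4D NIfTI series.

    ``tr`` overrides the header repetition time (pixdim[4]); without an
    override a non-positive header TR is an error.
    """
    path = Path(path)
    if not path.exists():
        raise ImagingIOError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ImagingIOError(f"{path}: not a 4D series (got {img.ndim}D)")
    # get_fdata applies scl_slope / scl_inter
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ImagingIOError(
                f"{path}: header repetition time is {header_tr:g}; pass tr explicitly"
            )
        tr = header_tr
    zooms = img.header.get_zooms()[:3]
    return Volume4D(
        data=data,
        tr=float(tr),
        affine=np.asarray(img.affine),
        voxel_size=tuple(float(z) for z in zooms),
    )


def write_volume4d(vol: Volume4D, path: str | os.PathLike) -> None:
    """Write a :class:`Volume4D` as NIfTI-1 with TR stored in pixdim[4]."""
    path = Path(path)
    if not path.parent.exists():
        raise ImagingIOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms((*vol.voxel_size, vol.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(
    path: str | os.PathLike,
    kind: str = "brain",
    reference_shape: Sequence[int] | None = None,
) -> Mask3D:
    """Read a 3D NIfTI mask (nonzero = inside) and binarize it."""
    path = Path(path)
    if not path.exists():
        raise ImagingIOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ImagingIOError(f"{path}: mask must be 3D (got {data.ndim}D)")
    mask = Mask3D(data=data != 0, kind=kind)
    if reference_shape is not None:
        mask.check_matches(reference_shape)
    return mask


def write_mask(mask: Mask3D, path: str | os.PathLike, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_events(path: str | os.PathLike, dialect: str = "plain") -> EventTrain:
    """Read event timings.

    dialect ``plain``: one onset (seconds) per line; durations are 0.
    dialect ``fsl3col``: whitespace-separated onset, duration, weight per
    line (the weight column is ignored).
    """
    if dialect not in ("plain", "fsl3col"):
        raise ImagingIOError(f"unknown event dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise ImagingIOError(f"no such file: {path}")
    onsets: list[float] = []
    durations: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "plain":
                    onset, duration = float(fields[0]), 0.0
                    if len(fields) > 1:
                        raise ValueError("expected a single onset column")
                else:
                    if len(fields) < 3:
                        raise ValueError("expected 3 columns: onset duration weight")
                    onset, duration = float(fields[0]), float(fields[1])
            except (ValueError, IndexError) as exc:
                raise ImagingIOError(f"{path}:{lineno}: unparseable line {line!r} ({exc})") from None
            if onset < 0:
                raise ImagingIOError(f"{path}:{lineno}: negative onset {onset:g}")
            if duration < 0:
                raise ImagingIOError(f"{path}:{lineno}: negative duration {duration:g}")
            onsets.append(onset)
            durations.append(duration)
    order = np.argsort(onsets, kind="stable")
    return EventTrain(
        onsets=np.asarray(onsets)[order], durations=np.asarray(durations)[order]
    )


def write_events(events: EventTrain, path: str | os.PathLike, dialect: str = "plain") -> None:
    """Serialize an :class:`EventTrain`; inverse of :func:`read_events`."""
    if dialect not in ("plain", "fsl3col"):
        raise ImagingIOError(f"unknown event dialect {dialect!r}")
    with open(path, "w") as fh:
        for onset, dur in zip(events.onsets, events.durations):
            if dialect == "plain":
                fh.write(f"{onset:.6f}\n")
            else:
                fh.write(f"{onset:.6f} {dur:.6f} 1\n")
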