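"""Artifact removal by aggressive time-course regression.

Per voxel, the demeaned signal is regressed (ordinary least squares) on
the demeaned artifact time courses alone and replaced by the residual
plus the voxel's temporal mean. This is an orthogonal projection:
idempotent, variance non-increasing, and mean-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sockeica.imaging_io import Volume4D

__all__ = ["DenoisedSeries", "regression_filter"]


@dataclass
class DenoisedSeries:
    volume: Volume4D
    removed_indices: list[int]
    variance_removed_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_removed_fraction <= 1.0:
            raise ValueError(
                f"variance_removed_fraction out of [0,1]: {self.variance_removed_fraction}"
            )


def _collinear_pairs(demeaned: np.ndarray, indices: Sequence[int]) -> list[tuple[int, int]]:
    norms = np.linalg.norm(demeaned, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    corr = (demeaned / safe).T @ (demeaned / safe)
    pairs = []
    for a in range(corr.shape[0]):
        if norms[a] == 0:
            pairs.append((indices[a], indices[a]))
        for b in range(a + 1, corr.shape[0]):
            if abs(corr[a, b]) > 1 - 1e-10:
                pairs.append((indices[a], indices[b]))
    return pairs


def regression_filter(
    vol: Volume4D,
    time_courses: np.ndarray,
    artifact_idx: Sequence[int],
    mode: str = "aggressive",
) -> DenoisedSeries:
    """Remove artifact components from a 4D series by OLS regression.

    Parameters
    ----------
    vol
        Input series.
    time_courses
        n_volumes x n_components matrix (all components).
    artifact_idx
        Indices of components to remove. Empty set returns the input
        unchanged.
    mode
        Only ``"aggressive"`` is supported: all variance explainable by
        the artifact time courses alone is removed.
    """
    if mode != "aggressive":
        raise ValueError(f"unsupported filter mode {mode!r}")
    tcs = np.asarray(time_courses, dtype=np.float64)
    if tcs.ndim != 2 or tcs.shape[0] != vol.n_volumes:
        raise ValueError(
            f"time_courses must be n_volumes x n_components with "
            f"n_volumes={vol.n_volumes}, got shape {tcs.shape}"
        )
    artifact_idx = sorted(set(int(i) for i in artifact_idx))
    if any(i < 0 or i >= tcs.shape[1] for i in artifact_idx):
        raise ValueError(f"artifact index out of range 0..{tcs.shape[1] - 1}")

    if not artifact_idx:
        out = Volume4D(
            vol.data.copy(), tr=vol.tr, affine=vol.affine.copy(), voxel_size=vol.voxel_size
        )
        return DenoisedSeries(volume=out, removed_indices=[], variance_removed_fraction=0.0)

    A = tcs[:, artifact_idx]
    Ad = A - A.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(Ad)
    if rank < Ad.shape[1]:
        pairs = _collinear_pairs(Ad, artifact_idx)
        raise ValueError(
            "artifact time courses are rank-deficient after demeaning; "
            f"collinear component pairs: {pairs or 'degenerate columns'}"
        )

    t = vol.n_volumes
    Y = vol.data.reshape(-1, t).T  # t x all voxels
    voxel_mean = Y.mean(axis=0, keepdims=True)
    Yd = Y - voxel_mean
    beta, *_ = np.linalg.lstsq(Ad, Yd, rcond=None)
    resid = Yd - Ad @ beta

    total_var = float((Yd**2).sum())
    removed = 1.0 - float((resid**2).sum()) / total_var if total_var > 0 else 0.0
    removed = min(max(removed, 0.0), 1.0)

    out_data = (resid + voxel_mean).T.reshape(vol.data.shape)
    out = Volume4D(out_data, tr=vol.tr, affine=vol.affine.copy(), voxel_size=vol.voxel_size)
    return DenoisedSeries(
        volume=out,
        removed_indices=artifact_idx,
        variance_removed_fraction=removed,
    )
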