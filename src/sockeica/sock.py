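"""Feature-based artifact classification of spatial ICA components.

Four feature families are computed per component:

* spatial smoothness — high/low spatial-frequency power ratio of axial
  slices, plus the fraction of suprathreshold voxels in very small
  clusters (a "spotty" appearance);
* edge activity — fraction of suprathreshold voxels inside an edge mask;
* ventricular activity — fraction inside a CSF mask;
* temporal frequency noise (TFN) — fraction of time-course power above a
  cutoff frequency (default 0.08 Hz).

Classification runs, per family, 2-cluster k-means on the robust-z-scored
family scalar across components; the cluster with the higher family mean
is artifact-prone only if its mean exceeds an absolute floor. A component
is labeled artifact iff it is artifact-prone in at least one family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from sockeica.imaging_io import Mask3D
from sockeica.spatial_ica import ICADecomposition, power_spectrum

__all__ = [
    "SockConfig",
    "ComponentFeatures",
    "Classification",
    "make_edge_mask",
    "threshold_map",
    "smoothness_features",
    "region_fraction",
    "tfn_fraction",
    "compute_features",
    "classify",
]

ARTIFACT = "artifact"
UNLIKELY = "unlikely_artifact"

# family scalars that participate in classification, with their floors
_FAMILY_SCALARS = {
    "smoothness": ("smoothness", "floor_smoothness"),
    "small_cluster": ("small_cluster_fraction", "floor_small_cluster"),
    "edge": ("edge_fraction", "floor_edge"),
    "csf": ("csf_fraction", "floor_csf"),
    "tfn": ("tfn_fraction", "floor_tfn"),
}


@dataclass
class SockConfig:
    """Tunable thresholds for feature extraction and classification."""

    z_thr: float = 2.3
    s_min: int = 5
    radial_cutoff: float = 0.25
    tfn_cutoff: float = 0.08
    min_slice_voxels: int = 32
    edge_width: int = 1
    floor_edge: float = 0.4
    floor_csf: float = 0.35
    floor_tfn: float = 0.5
    floor_small_cluster: float = 0.5
    floor_smoothness: float = 1.0
    kmeans_seed: int = 0
    kmeans_restarts: int = 10


@dataclass
class ComponentFeatures:
    """Per-component feature vector.

    ``smoothness`` is NaN when no slice qualifies for the spatial
    spectrum; ``empty`` flags components with no suprathreshold voxels
    (all spatial fractions are then defined as 0).
    """

    smoothness: float
    small_cluster_fraction: float
    edge_fraction: float
    csf_fraction: float
    tfn_fraction: float
    empty: bool = False

    def __post_init__(self) -> None:
        for name in ("small_cluster_fraction", "edge_fraction", "csf_fraction", "tfn_fraction"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (np.isnan(self.smoothness) or self.smoothness >= 0):
            raise ValueError(f"smoothness must be >= 0, got {self.smoothness}")


@dataclass
class Classification:
    """Labels and per-component triggering feature families."""

    labels: list[str]
    reasons: list[list[str]]

    def __post_init__(self) -> None:
        for lab, why in zip(self.labels, self.reasons):
            if lab == ARTIFACT and not why:
                raise ValueError("artifact label without a reason")

    @property
    def n_components(self) -> int:
        return len(self.labels)

    @property
    def artifact_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == ARTIFACT]

    @property
    def rejected_fraction(self) -> float:
        if not self.labels:
            return 0.0
        return len(self.artifact_indices) / len(self.labels)

    def save(self, features: list[ComponentFeatures], outdir: str | Path) -> None:
        """Write the report table and the rejected-index list."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "classification.tsv", "w") as fh:
            fh.write(
                "component\tsmoothness\tsmall_cluster_fraction\tedge_fraction"
                "\tcsf_fraction\ttfn_fraction\tlabel\treasons\n"
            )
            for i, (f, lab, why) in enumerate(zip(features, self.labels, self.reasons)):
                fh.write(
                    f"{i}\t{f.smoothness:.6g}\t{f.small_cluster_fraction:.6g}"
                    f"\t{f.edge_fraction:.6g}\t{f.csf_fraction:.6g}"
                    f"\t{f.tfn_fraction:.6g}\t{lab}\t{','.join(why) or '-'}\n"
                )
        with open(outdir / "rejected_components.txt", "w") as fh:
            fh.write("\n".join(str(i) for i in self.artifact_indices))
            if self.artifact_indices:
                fh.write("\n")


def make_edge_mask(brain: Mask3D, width_voxels: int = 1) -> Mask3D:
    """Edge shell: brain minus brain eroded ``width_voxels`` times (6-connected)."""
    if width_voxels < 1:
        raise ValueError("width_voxels must be >= 1")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(
        brain.data, structure=structure, iterations=width_voxels
    )
    if not interior.any():
        raise ValueError(
            f"eroding the brain mask {width_voxels} time(s) empties it; "
            "use a smaller width"
        )
    return Mask3D(data=brain.data & ~interior, kind="edge")


def threshold_map(zmap: np.ndarray, z_thr: float) -> np.ndarray:
    """Binary suprathreshold set: voxels with |z| >= z_thr."""
    return np.abs(np.asarray(zmap)) >= z_thr


def region_fraction(suprathreshold: np.ndarray, region: Mask3D) -> float:
    """Fraction of suprathreshold voxels inside the region; 0 if empty."""
    supra = np.asarray(suprathreshold, dtype=bool)
    total = int(supra.sum())
    if total == 0:
        return 0.0
    return float((supra & region.data).sum()) / total


def _slice_spectrum_ratio(slice_vals: np.ndarray, radial_cutoff: float) -> float:
    """High/low radial spatial-frequency power ratio of one 2D slice."""
    f = np.fft.fft2(slice_vals)
    power = np.abs(f) ** 2
    fx = np.fft.fftfreq(slice_vals.shape[0])
    fy = np.fft.fftfreq(slice_vals.shape[1])
    radius = np.sqrt(fx[:, None] ** 2 + fy[None, :] ** 2)
    cutoff = radial_cutoff * 0.5  # cycles/voxel; Nyquist = 0.5
    high = float(power[radius > cutoff].sum())
    low = float(power[radius <= cutoff].sum())
    if low == 0:
        return np.inf if high > 0 else 0.0
    return high / low


def smoothness_features(
    component_map: np.ndarray,
    mask: Mask3D,
    z_thr: float = 2.3,
    s_min: int = 5,
    radial_cutoff: float = 0.25,
    min_slice_voxels: int = 32,
) -> tuple[float, float]:
    """Spatial smoothness ratio and small-cluster fraction of one map.

    Smoothness is the high/low radial spatial-frequency power ratio of
    axial slices with at least ``min_slice_voxels`` in-mask voxels,
    averaged across qualifying slices (NaN if none qualify). The
    small-cluster fraction counts suprathreshold voxels in 26-connected
    clusters smaller than ``s_min`` relative to all suprathreshold voxels.
    """
    vol = np.asarray(component_map, dtype=np.float64)
    if vol.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    inmask = np.where(mask.data, vol, 0.0)

    ratios = []
    for z in range(vol.shape[2]):
        if int(mask.data[:, :, z].sum()) >= min_slice_voxels:
            ratios.append(_slice_spectrum_ratio(inmask[:, :, z], radial_cutoff))
    smoothness = float(np.mean(ratios)) if ratios else float("nan")

    supra = threshold_map(inmask, z_thr) & mask.data
    n_supra = int(supra.sum())
    if n_supra == 0:
        return smoothness, 0.0
    labels, n_clusters = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    sizes = np.bincount(labels.ravel())[1:]
    small = int(sizes[sizes < s_min].sum())
    return smoothness, small / n_supra


def tfn_fraction(tc: np.ndarray, tr: float, cutoff: float = 0.08) -> float:
    """Fraction of time-course power at frequencies above ``cutoff`` Hz.

    The 0 Hz bin is excluded from both numerator and denominator.
    """
    nyquist = 1.0 / (2.0 * tr)
    if cutoff >= nyquist:
        raise ValueError(
            f"TFN cutoff {cutoff:g} Hz is at or above Nyquist {nyquist:g} Hz"
        )
    freqs, power = power_spectrum(tc, tr)
    denom = float(power[1:].sum())
    if denom == 0:
        return 0.0
    return float(power[freqs > cutoff].sum()) / denom


def compute_features(
    decomposition: ICADecomposition,
    edge: Mask3D,
    csf: Mask3D,
    config: SockConfig | None = None,
) -> list[ComponentFeatures]:
    """Compute the full feature vector for every component."""
    cfg = config or SockConfig()
    mask = decomposition.mask
    edge.check_matches(mask.shape)
    csf.check_matches(mask.shape)
    out = []
    for i in range(decomposition.n_components):
        vol = decomposition.map_volume(i)
        smooth, small_frac = smoothness_features(
            vol, mask, cfg.z_thr, cfg.s_min, cfg.radial_cutoff, cfg.min_slice_voxels
        )
        supra = threshold_map(vol, cfg.z_thr) & mask.data
        empty = not supra.any()
        out.append(
            ComponentFeatures(
                smoothness=smooth,
                small_cluster_fraction=small_frac,
                edge_fraction=region_fraction(supra, edge),
                csf_fraction=region_fraction(supra, csf),
                tfn_fraction=tfn_fraction(
                    decomposition.time_courses[:, i], decomposition.tr, cfg.tfn_cutoff
                ),
                empty=empty,
            )
        )
    return out


def _robust_z(values: np.ndarray) -> np.ndarray:
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = 1.4826 * mad
    if scale == 0:
        # majority of values identical: fall back to std so outliers
        # still separate
        scale = values.std()
    if scale == 0:
        return np.zeros_like(values)
    return (values - med) / scale


def _family_artifact_prone(
    values: np.ndarray, defined: np.ndarray, floor: float, seed: int, restarts: int
) -> np.ndarray:
    """Boolean artifact-prone flags for one family scalar.

    With >= 3 defined values, 2-means on the robust-z scores decides the
    split; the higher-mean cluster is artifact-prone only if its mean (on
    the original scale) exceeds the absolute floor. With fewer defined
    values, fall back to the absolute floor alone.
    """
    prone = np.zeros(values.size, dtype=bool)
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        return prone
    vals = values[idx]
    if idx.size < 3 or np.allclose(vals, vals[0]):
        prone[idx] = vals >= floor
        return prone
    z = _robust_z(vals)
    # fit on sorted values so the split is invariant to component order;
    # optimal 1-D 2-means clusters are contiguous in sorted order, so the
    # split reduces to a cut value
    order = np.argsort(z, kind="stable")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assign = km.fit_predict(z[order, None])
    hi_cluster = assign[order.argsort()][np.argmax(vals)]
    cut = float(vals[assign[order.argsort()] == hi_cluster].min())
    hi = vals >= cut
    if vals[hi].mean() >= floor:
        prone[idx[hi]] = True
    return prone


def classify(
    features: list[ComponentFeatures], config: SockConfig | None = None
) -> Classification:
    """Label each component artifact / unlikely-artifact.

    A component is an artifact iff at least one feature family flags it.
    Families with undefined feature values (NaN) skip those components.
    Labels are invariant to component ordering and to k-means cluster
    relabeling.
    """
    cfg = config or SockConfig()
    n = len(features)
    if n == 0:
        return Classification(labels=[], reasons=[])
    reasons: list[list[str]] = [[] for _ in range(n)]
    for family, (attr, floor_attr) in _FAMILY_SCALARS.items():
        raw = np.array([getattr(f, attr) for f in features], dtype=np.float64)
        defined = ~np.isnan(raw)
        # empty components carry no spatial evidence
        if attr != "tfn_fraction":
            defined &= ~np.array([f.empty for f in features])
        prone = _family_artifact_prone(
            raw, defined, getattr(cfg, floor_attr), cfg.kmeans_seed, cfg.kmeans_restarts
        )
        reason_name = "smoothness" if family in ("smoothness", "small_cluster") else family
        for i in np.flatnonzero(prone):
            if reason_name not in reasons[i]:
                reasons[i].append(reason_name)
    labels = [ARTIFACT if why else UNLIKELY for why in reasons]
    return Classification(labels=labels, reasons=reasons)
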