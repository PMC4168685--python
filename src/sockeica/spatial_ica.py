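"""Spatial ICA of a 4D fMRI series.

The series is masked, demeaned per voxel, reduced by PCA (explicit order
rule — either a fixed count or a retained-variance fraction) and unmixed
with FastICA (tanh contrast, symmetric decorrelation). Components are
returned as z-scaled spatial maps with associated time courses and
one-sided power spectra.

Determinism contract: given (data, seed, n_restarts) the decomposition is
bitwise reproducible; component order is fixed by descending explained
variance and each component's sign is fixed so its spatial map has
non-negative skewness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from sockeica.imaging_io import Mask3D, Volume4D, write_volume4d

__all__ = [
    "PCAReduction",
    "ICADecomposition",
    "pca_reduce",
    "decompose",
    "power_spectrum",
]

_FASTICA_MAX_ITER = 500
_FASTICA_TOL = 1e-5


class DecompositionError(ValueError):
    """Raised for degenerate or ill-specified decompositions."""


def power_spectrum(tc: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a time course.

    Returns ``(freqs, power)`` with frequencies from 0 to the Nyquist
    frequency ``1/(2*tr)`` and Parseval normalization: ``power.sum()``
    equals the time course variance (ddof=0) exactly.
    """
    tc = np.asarray(tc, dtype=np.float64).ravel()
    if tc.size < 4:
        raise DecompositionError("time course must have length >= 4")
    if tr <= 0:
        raise DecompositionError(f"tr must be > 0, got {tr}")
    n = tc.size
    x = tc - tc.mean()
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2 / n**2
    # one-sided doubling: every bin except DC and (even n) Nyquist
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=tr)
    return freqs, power


@dataclass
class PCAReduction:
    """Whitened PCA reduction of a (time x voxel) matrix.

    ``whitened`` has mutually uncorrelated unit-variance rows;
    ``basis @ whitened`` reconstructs the rank-``order`` approximation of
    the input.
    """

    whitened: np.ndarray  # order x n_voxels
    basis: np.ndarray  # n_volumes x order
    order: int
    variance_fraction: float
    singular_values: np.ndarray


def _resolve_order(order_rule, singular_values: np.ndarray, rank: int, n_rows: int) -> int:
    kind, value = order_rule
    if kind == "fixed":
        k = int(value)
        if k < 1:
            raise DecompositionError("order must be >= 1")
        if k > rank:
            raise DecompositionError(
                f"requested order {k} exceeds achievable rank {rank}"
            )
        if k > n_rows - 1:
            raise DecompositionError(
                f"requested order {k} exceeds n_volumes - 1 = {n_rows - 1}"
            )
        return k
    if kind == "variance":
        f = float(value)
        if not 0 < f <= 1:
            raise DecompositionError("variance fraction must be in (0, 1]")
        total = float((singular_values**2).sum())
        cum = np.cumsum(singular_values**2) / total
        k = int(np.searchsorted(cum, f - 1e-12) + 1)
        return min(k, rank)
    raise DecompositionError(f"unknown order rule kind {kind!r}")


def pca_reduce(masked_series: np.ndarray, order_rule) -> PCAReduction:
    """PCA-reduce and whiten a (n_volumes x n_maskvoxels) matrix.

    ``order_rule`` is ``("fixed", k)`` or ``("variance", f)``. Rows of the
    returned whitened matrix are mutually uncorrelated with unit variance
    (assuming the input rows have zero spatial mean). The reported
    variance fraction is the PCA spectrum mass retained.
    """
    X = np.asarray(masked_series, dtype=np.float64)
    if X.ndim != 2:
        raise DecompositionError("masked series must be a 2D matrix")
    t, v = X.shape
    if t < 4:
        raise DecompositionError("need at least 4 time points")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(t, v) * np.finfo(np.float64).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank == 0:
        raise DecompositionError("input matrix is zero — degenerate series")
    k = _resolve_order(order_rule, s[:rank], rank, t)
    var_fraction = float((s[:k] ** 2).sum() / (s**2).sum())
    whitened = np.sqrt(v) * Vt[:k]
    basis = U[:, :k] * s[:k] / np.sqrt(v)
    return PCAReduction(
        whitened=whitened,
        basis=basis,
        order=k,
        variance_fraction=var_fraction,
        singular_values=s[:rank].copy(),
    )


def _logcosh_negentropy(sources: np.ndarray) -> float:
    # negentropy proxy for the tanh contrast; larger = more non-Gaussian
    gauss = 0.3745672075  # E[log cosh(g)] for g ~ N(0,1)
    j = (np.mean(np.log(np.cosh(sources)), axis=1) - gauss) ** 2
    return float(j.sum())


def _run_fastica(whitened: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One FastICA run on pre-whitened rows; returns (sources, unmixing)."""
    ica = FastICA(
        algorithm="parallel",
        whiten=False,
        fun="logcosh",
        max_iter=_FASTICA_MAX_ITER,
        tol=_FASTICA_TOL,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        sources = ica.fit_transform(whitened.T).T  # k x n_voxels
    return sources, ica.components_  # unmixing W with sources = W @ whitened


def derived_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds for restart loops."""
    return np.random.SeedSequence(int(seed)).generate_state(n)


@dataclass
class ICADecomposition:
    """Spatial ICA of a masked 4D series.

    ``spatial_maps`` rows are z-scaled (zero mean, unit variance over mask
    voxels); ``mean_map + time_courses @ spatial_maps`` reconstructs the
    masked input up to the discarded variance, and
    ``retained_variance_fraction`` reports exactly the variance fraction
    the reconstruction explains.
    """

    spatial_maps: np.ndarray  # n_components x n_maskvoxels
    time_courses: np.ndarray  # n_volumes x n_components
    mean_map: np.ndarray  # n_maskvoxels
    n_components: int
    mask: Mask3D
    seed: int
    tr: float
    power_spectra: np.ndarray  # n_freqs x n_components
    frequencies: np.ndarray
    retained_variance_fraction: float
    pca_variance_fraction: float

    def reconstruct(self) -> np.ndarray:
        """Masked reconstruction, (n_volumes x n_maskvoxels)."""
        return self.mean_map[None, :] + self.time_courses @ self.spatial_maps

    def map_volume(self, index: int) -> np.ndarray:
        """Unmask one component's spatial map into the 3D grid."""
        out = np.zeros(self.mask.shape)
        out[self.mask.data] = self.spatial_maps[index]
        return out

    def save(self, outdir: str | Path, affine: np.ndarray | None = None) -> None:
        """Serialize as a directory: maps as 4D NIfTI, tables as TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        maps4d = np.zeros((*self.mask.shape, self.n_components))
        maps4d[self.mask.data, :] = self.spatial_maps.T
        vol = Volume4D(maps4d, tr=self.tr, affine=affine)
        write_volume4d(vol, outdir / "melodic_like_maps.nii")
        header = "\t".join(f"IC{i + 1}" for i in range(self.n_components))
        np.savetxt(
            outdir / "time_courses.tsv", self.time_courses,
            delimiter="\t", header=header, comments="",
        )
        spec = np.column_stack([self.frequencies, self.power_spectra])
        np.savetxt(
            outdir / "power_spectra.tsv", spec,
            delimiter="\t", header="freq_hz\t" + header, comments="",
        )
        np.savetxt(outdir / "mean_map.tsv", self.mean_map[:, None], delimiter="\t")


def decompose(
    vol: Volume4D,
    mask: Mask3D,
    order_rule=("variance", 0.995),
    seed: int = 0,
    n_restarts: int = 1,
) -> ICADecomposition:
    """Decompose a 4D series into spatially independent components.

    Runs ``n_restarts`` FastICA restarts with derived seeds and keeps the
    run with the best final tanh-contrast value.
    """
    mask.check_matches(vol.spatial_shape)
    if n_restarts < 1:
        raise DecompositionError("n_restarts must be >= 1")
    X = vol.data[mask.data].T.astype(np.float64)  # t x v
    t, v = X.shape
    mean_map = X.mean(axis=0)
    Xd = X - mean_map[None, :]
    if not np.any(np.abs(Xd) > 1e-12 * max(1.0, np.abs(mean_map).max())):
        raise DecompositionError("series is constant in time — nothing to decompose")
    # remove the per-timepoint spatial mean so component maps are exactly
    # zero-mean over the mask
    global_tc = Xd.mean(axis=1)
    Xc = Xd - global_tc[:, None]
    red = pca_reduce(Xc, order_rule)
    k = red.order

    best = None
    best_score = -np.inf
    for child in derived_seeds(seed, n_restarts):
        sources, unmixing = _run_fastica(red.whitened, int(child))
        score = _logcosh_negentropy(sources)
        if score > best_score + 1e-12:
            best_score = score
            best = (sources, unmixing)
    sources, unmixing = best

    # z-scale maps exactly; fold scale into the time courses
    mu = sources.mean(axis=1)
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    maps = (sources - mu[:, None]) / sd[:, None]
    tc = red.basis @ np.linalg.pinv(unmixing) * sd[None, :]

    # deterministic order: descending explained variance
    energy = (tc**2).sum(axis=0)
    order = np.argsort(-energy, kind="stable")
    maps = maps[order]
    tc = tc[:, order]
    # deterministic sign: non-negative spatial skewness
    skew = stats.skew(maps, axis=1)
    flip = skew < 0
    maps[flip] *= -1.0
    tc[:, flip] *= -1.0

    recon = tc @ maps
    denom = float((Xd**2).sum())
    retained = 1.0 - float(((Xd - recon) ** 2).sum()) / denom if denom > 0 else 0.0

    freqs = None
    spectra = np.empty((t // 2 + 1, k))
    for i in range(k):
        freqs, p = power_spectrum(tc[:, i], vol.tr)
        spectra[:, i] = p

    return ICADecomposition(
        spatial_maps=maps,
        time_courses=tc,
        mean_map=mean_map,
        n_components=k,
        mask=mask,
        seed=int(seed),
        tr=vol.tr,
        power_spectra=spectra,
        frequencies=freqs,
        retained_variance_fraction=retained,
        pca_variance_fraction=red.variance_fraction,
    )
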