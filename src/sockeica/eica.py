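"""Event-related ICA of FIR-deconvolved peri-event responses.

The stages are:

1. :func:`build_fir_design` — an FIR (finite impulse response) design
   spanning a peri-event window (default 30 s before to 30 s after each
   event onset) with intercept and polynomial drift confounds;
2. :func:`deconvolve` — per-voxel least squares yielding the estimated
   event-related response at each window bin, with no assumed shape
   (pre-onset bins allow responses that begin before the event);
3. :func:`eica_decompose` — FastICA of the response matrix, repeated from
   distinct derived seeds, components clustered across runs by absolute
   spatial correlation; each cluster is summarized by its centrotype and
   a stability index. Group analyses run on temporally concatenated
   per-subject responses and return one common spatial map set with
   subject-specific time-course segments;
4. :func:`mixture_zmap` / :func:`threshold_zmap` — spatial maps rescaled
   against the null component of a two-Gaussian mixture fitted by EM and
   thresholded at a significance level (uncorrected or BH-FDR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from sockeica.imaging_io import EventTrain, Mask3D, Volume4D
from sockeica.spatial_ica import _run_fastica, derived_seeds, pca_reduce

__all__ = [
    "FIRDesign",
    "PeriEventResponse",
    "EICAResult",
    "GroupStack",
    "build_fir_design",
    "deconvolve",
    "stack_group",
    "eica_decompose",
    "mixture_zmap",
    "threshold_zmap",
    "flip_lr",
]


class EicaError(ValueError):
    pass


@dataclass
class FIRDesign:
    """FIR + confound design matrix for peri-event deconvolution."""

    matrix: np.ndarray  # n_volumes x (n_bins + n_confounds)
    n_bins: int
    window: tuple[float, float]
    bin_times: np.ndarray
    n_confounds: int
    events_used: int

    @property
    def fir_columns(self) -> np.ndarray:
        return self.matrix[:, : self.n_bins]

    @property
    def confound_columns(self) -> np.ndarray:
        return self.matrix[:, self.n_bins :]


def build_fir_design(
    events: EventTrain,
    n_volumes: int,
    tr: float,
    window: tuple[float, float] = (-30.0, 30.0),
    drift_order: int = 1,
    overlap_policy: str = "cap",
    allow_partial: bool = True,
) -> FIRDesign:
    """Build the FIR deconvolution design.

    Each FIR column j carries a 1 at volume v iff some event onset o has
    its bin j (at ``o + bin_times[j]``) nearest to volume v. Events at
    sub-TR offsets are assigned to the nearest volume. Overlapping event
    windows either cap each cell at 1 (default) or accumulate hits
    (``overlap_policy="accumulate"``). Window bins falling outside the
    series are left zero; with ``allow_partial=False`` such events are
    dropped entirely.
    """
    w_pre, w_post = window
    if w_post <= w_pre:
        raise EicaError("window end must exceed window start")
    if overlap_policy not in ("cap", "accumulate"):
        raise EicaError(f"unknown overlap policy {overlap_policy!r}")
    span = w_post - w_pre
    n_bins_f = span / tr
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise EicaError("bin grid must align to tr: window span not divisible by tr")
    n_bins = int(round(n_bins_f)) + 1
    bin_times = w_pre + tr * np.arange(n_bins)

    fir = np.zeros((n_volumes, n_bins))
    events_used = 0
    for onset in events.onsets:
        first = int(np.round((onset + bin_times[0]) / tr))
        last = int(np.round((onset + bin_times[-1]) / tr))
        if not allow_partial and (first < 0 or last >= n_volumes):
            continue
        hit_any = False
        for j in range(n_bins):
            v = int(np.round((onset + bin_times[j]) / tr))
            if 0 <= v < n_volumes:
                fir[v, j] += 1.0
                hit_any = True
        if hit_any:
            events_used += 1
    if events_used == 0:
        raise EicaError("no usable events: every event window misses the series")
    if overlap_policy == "cap":
        fir = np.minimum(fir, 1.0)

    if drift_order < 0:
        raise EicaError("drift_order must be >= 0")
    x = np.linspace(-1.0, 1.0, n_volumes)
    confounds = [np.ones(n_volumes)]
    for order in range(1, drift_order + 1):
        coef = np.zeros(order + 1)
        coef[order] = 1.0
        confounds.append(legendre.legval(x, coef))
    conf = np.column_stack(confounds)

    return FIRDesign(
        matrix=np.hstack([fir, conf]),
        n_bins=n_bins,
        window=(float(w_pre), float(w_post)),
        bin_times=bin_times,
        n_confounds=conf.shape[1],
        events_used=events_used,
    )


@dataclass
class PeriEventResponse:
    """Estimated event-related response per mask voxel and window bin."""

    responses: np.ndarray  # n_maskvoxels x n_bins
    bin_times: np.ndarray
    events_used: int
    mask: Mask3D
    tr: float

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.float64)
        self.bin_times = np.asarray(self.bin_times, dtype=np.float64)
        if not np.all(np.isfinite(self.responses)):
            raise EicaError("responses contain non-finite values")
        steps = np.diff(self.bin_times)
        if np.any(steps <= 0) or not np.allclose(steps, self.tr):
            raise EicaError("bin_times must increase strictly in steps of tr")

    @property
    def n_bins(self) -> int:
        return self.bin_times.size

    def to_grid(self) -> np.ndarray:
        """Unmask into an (x, y, z, n_bins) grid (zeros outside mask)."""
        out = np.zeros((*self.mask.shape, self.n_bins))
        out[self.mask.data, :] = self.responses
        return out


def deconvolve(vol: Volume4D, design: FIRDesign, mask: Mask3D) -> PeriEventResponse:
    """Per-voxel least-squares FIR deconvolution (minimum-norm via pinv)."""
    mask.check_matches(vol.spatial_shape)
    if design.matrix.shape[0] != vol.n_volumes:
        raise EicaError(
            f"design has {design.matrix.shape[0]} rows but series has "
            f"{vol.n_volumes} volumes"
        )
    if not design.fir_columns.any():
        raise EicaError("design FIR columns are all zero: no events hit the series")
    Y = vol.data[mask.data].T  # t x v
    beta = np.linalg.pinv(design.matrix) @ Y
    responses = beta[: design.n_bins].T  # v x n_bins, confounds discarded
    return PeriEventResponse(
        responses=responses,
        bin_times=design.bin_times,
        events_used=design.events_used,
        mask=mask,
        tr=vol.tr,
    )


@dataclass
class GroupStack:
    """Temporally concatenated per-subject peri-event responses.

    All subjects share one voxel grid (after optional left-right flips);
    each subject's response matrix is scaled to unit Frobenius norm before
    concatenation so no subject dominates the decomposition.
    """

    subjects: list[PeriEventResponse]
    flip_flags: list[bool]
    concatenated: np.ndarray  # (sum n_bins) x n_common_voxels
    mask: Mask3D
    subject_slices: list[slice]
    tr: float


def stack_group(
    responses: Sequence[PeriEventResponse],
    flip_flags: Sequence[bool] | None = None,
) -> GroupStack:
    """Align, flip, normalize and concatenate per-subject responses."""
    if not responses:
        raise EicaError("group stack needs at least one subject")
    if flip_flags is None:
        flip_flags = [False] * len(responses)
    if len(flip_flags) != len(responses):
        raise EicaError("flip_flags length must match subjects")
    flipped = [
        flip_lr(r) if flag else r for r, flag in zip(responses, flip_flags)
    ]
    shapes = {r.mask.shape for r in flipped}
    if len(shapes) != 1:
        raise EicaError(f"subjects are on different grids: {sorted(shapes)}")
    common = np.logical_and.reduce([r.mask.data for r in flipped])
    if not common.any():
        raise EicaError("no common in-mask voxels across subjects")
    mask = Mask3D(common, kind="brain")

    blocks = []
    slices = []
    row = 0
    for r in flipped:
        block = r.to_grid()[common, :].T  # n_bins x n_common
        norm = np.linalg.norm(block)
        if norm > 0:
            block = block / norm
        blocks.append(block)
        slices.append(slice(row, row + block.shape[0]))
        row += block.shape[0]
    return GroupStack(
        subjects=list(responses),
        flip_flags=list(flip_flags),
        concatenated=np.vstack(blocks),
        mask=mask,
        subject_slices=slices,
        tr=responses[0].tr,
    )


@dataclass
class EICAResult:
    """Stability-clustered event ICA decomposition.

    ``time_courses`` rows span the (possibly concatenated) bin axis;
    ``subject_slices`` splits them into per-subject segments for group
    runs (a single-subject run has one slice covering all rows).
    """

    spatial_maps: np.ndarray  # n_components x n_maskvoxels
    time_courses: np.ndarray  # total_bins x n_components
    z_maps: np.ndarray
    stability_index: np.ndarray
    n_components: int
    mask: Mask3D
    bin_times: np.ndarray
    subject_slices: list[slice]
    zmap_fallback: np.ndarray  # per component: robust-z fallback used?

    def subject_time_courses(self, subject: int) -> np.ndarray:
        return self.time_courses[self.subject_slices[subject]]

    def map_volume(self, index: int, values: np.ndarray | None = None) -> np.ndarray:
        vals = self.spatial_maps[index] if values is None else values
        out = np.zeros(self.mask.shape)
        out[self.mask.data] = vals
        return out

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = "\t".join(f"eIC{i + 1}" for i in range(self.n_components))
        for s, sl in enumerate(self.subject_slices):
            np.savetxt(
                outdir / f"time_courses_subject{s + 1:02d}.tsv",
                np.column_stack([self.bin_times, self.time_courses[sl]]),
                delimiter="\t", header="bin_time_s\t" + header, comments="",
            )
        np.savetxt(
            outdir / "stability_index.tsv", self.stability_index[None, :],
            delimiter="\t", header=header, comments="",
        )


def _cluster_runs(
    all_maps: np.ndarray, run_ids: np.ndarray, n_components: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Average-linkage clustering of pooled run components by 1 - |r|."""
    z = (all_maps - all_maps.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    z /= norms
    sim = np.abs(z @ z.T)
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    assign = fcluster(tree, t=n_components, criterion="maxclust")
    clusters = [np.flatnonzero(assign == c) for c in np.unique(assign)]
    return clusters, sim


def eica_decompose(
    per: PeriEventResponse | GroupStack,
    n_components: int,
    seed: int = 0,
    n_runs: int = 10,
) -> EICAResult:
    """Event-related ICA with stability clustering across restarts.

    Runs FastICA ``n_runs`` times from distinct derived seeds, pools the
    resulting spatial components, clusters them by absolute spatial
    correlation (average linkage cut at ``n_components``), and returns
    each cluster's centrotype. The stability index per component is the
    mean within-cluster |r| minus the mean between-cluster |r|, clipped
    to [0, 1].
    """
    if n_runs < 2:
        raise EicaError("n_runs must be >= 2")
    if isinstance(per, GroupStack):
        data = per.concatenated  # total_bins x v
        mask = per.mask
        subject_slices = per.subject_slices
        bin_times = per.subjects[0].bin_times
    else:
        data = per.responses.T  # n_bins x v
        mask = per.mask
        subject_slices = [slice(0, data.shape[0])]
        bin_times = per.bin_times
    total_bins, v = data.shape
    if n_components > total_bins:
        raise EicaError(
            f"n_components {n_components} exceeds available bins {total_bins}"
        )

    # center like the full-series ICA: per-voxel mean over bins, then the
    # per-bin spatial mean so maps are exactly zero-mean
    Xd = data - data.mean(axis=0, keepdims=True)
    Xc = Xd - Xd.mean(axis=1, keepdims=True)
    red = pca_reduce(Xc, ("fixed", min(n_components, total_bins - 1)))
    if red.order < n_components:
        warnings.warn(
            f"data rank supports only {red.order} components "
            f"(requested {n_components})", stacklevel=2,
        )
        n_components = red.order

    maps_runs = []
    tcs_runs = []
    run_ids = []
    for run, child in enumerate(derived_seeds(seed, n_runs)):
        sources, unmixing = _run_fastica(red.whitened, int(child))
        mu = sources.mean(axis=1)
        sd = sources.std(axis=1)
        sd[sd == 0] = 1.0
        maps = (sources - mu[:, None]) / sd[:, None]
        tc = red.basis @ np.linalg.pinv(unmixing) * sd[None, :]
        maps_runs.append(maps)
        tcs_runs.append(tc)
        run_ids.extend([run] * maps.shape[0])
    all_maps = np.vstack(maps_runs)
    all_tcs = np.hstack(tcs_runs)
    run_ids = np.asarray(run_ids)

    clusters, sim = _cluster_runs(all_maps, run_ids, n_components)

    chosen = []
    stability = []
    for members in clusters:
        sub = sim[np.ix_(members, members)]
        # centrotype: member with maximal summed within-cluster similarity
        centrotype = members[int(np.argmax(sub.sum(axis=1)))]
        within = (
            (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
            if len(members) > 1 else 1.0
        )
        outside = np.setdiff1d(np.arange(all_maps.shape[0]), members)
        between = float(sim[np.ix_(members, outside)].mean()) if outside.size else 0.0
        chosen.append(centrotype)
        stability.append(np.clip(within - between, 0.0, 1.0))

    # deterministic output order: descending time-course energy
    chosen = np.asarray(chosen)
    stability = np.asarray(stability)
    energy = (all_tcs[:, chosen] ** 2).sum(axis=0)
    order = np.argsort(-energy, kind="stable")
    chosen = chosen[order]
    stability = stability[order]

    maps = all_maps[chosen].copy()
    tcs = all_tcs[:, chosen].copy()
    skew = stats.skew(maps, axis=1)
    flip = skew < 0
    maps[flip] *= -1.0
    tcs[:, flip] *= -1.0

    z_maps = np.empty_like(maps)
    fallback = np.zeros(maps.shape[0], dtype=bool)
    for i in range(maps.shape[0]):
        z_maps[i], fallback[i] = mixture_zmap(maps[i], return_fallback=True)

    return EICAResult(
        spatial_maps=maps,
        time_courses=tcs,
        z_maps=z_maps,
        stability_index=stability,
        n_components=maps.shape[0],
        mask=mask,
        bin_times=bin_times,
        subject_slices=subject_slices,
        zmap_fallback=fallback,
    )


def _em_two_gaussian(
    x: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """EM for a 2-component Gaussian mixture with deterministic robust init.

    Returns (weights, means, sds) or None when degenerate.
    """
    med = float(np.median(x))
    mad_sigma = 1.4826 * float(np.median(np.abs(x - med)))
    if mad_sigma <= 0:
        return None
    w = np.array([0.95, 0.05])
    mu = np.array([med, med + 4.0 * mad_sigma])
    sd = np.array([mad_sigma, 2.0 * mad_sigma])
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_pdf = stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        resp = np.exp(log_pdf - lse[:, None])
        ll = float(lse.sum())
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            return None
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if np.any(var < 1e-12 * mad_sigma**2):
            return None
        sd = np.sqrt(var)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            break
        prev_ll = ll
    return w, mu, sd


def mixture_zmap(values: np.ndarray, return_fallback: bool = False):
    """Rescale a spatial map against the fitted null mixture component.

    Fits a two-component Gaussian mixture by EM (deterministic robust
    initialization); the component with the larger weight is the null and
    ``z = (value - mu_null) / sigma_null``. If EM degenerates the robust
    z (median/MAD) is used and flagged.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 100:
        raise EicaError("mixture z-map needs at least 100 in-mask values")
    fit = _em_two_gaussian(x)
    if fit is None:
        med = float(np.median(x))
        mad_sigma = 1.4826 * float(np.median(np.abs(x - med)))
        if mad_sigma <= 0:
            mad_sigma = float(x.std()) or 1.0
        z = (x - med) / mad_sigma
        used_fallback = True
    else:
        w, mu, sd = fit
        null = int(np.argmax(w))
        z = (x - mu[null]) / sd[null]
        used_fallback = False
    z = z.reshape(np.shape(values))
    if return_fallback:
        return z, used_fallback
    return z


def threshold_zmap(
    z: np.ndarray, p: float = 0.05, correction: str = "none"
) -> np.ndarray:
    """Keep signed z at voxels significant at level p (two-sided Gaussian).

    ``correction="fdr"`` applies Benjamini-Hochberg across the supplied
    values; ``"none"`` thresholds each voxel at the uncorrected level.
    """
    if not 0 < p < 1:
        raise EicaError("p must be in (0, 1)")
    z = np.asarray(z, dtype=np.float64)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    if correction == "none":
        # threshold on |z| so the exact quantile boundary survives
        z_thr = stats.norm.isf(p / 2.0)
        keep = np.abs(z) >= z_thr * (1.0 - 1e-12)
    elif correction == "fdr":
        adjusted = stats.false_discovery_control(pvals.ravel(), method="bh")
        keep = adjusted.reshape(z.shape) <= p
    else:
        raise EicaError(f"unknown correction {correction!r}")
    return np.where(keep, z, 0.0)


def flip_lr(obj: Volume4D | PeriEventResponse):
    """Reverse the x (first voxel) axis; an involution."""
    if isinstance(obj, Volume4D):
        return Volume4D(
            obj.data[::-1].copy(), tr=obj.tr, affine=obj.affine.copy(),
            voxel_size=obj.voxel_size,
        )
    if isinstance(obj, PeriEventResponse):
        grid = obj.to_grid()[::-1]
        mask = Mask3D(obj.mask.data[::-1].copy(), kind=obj.mask.kind)
        return PeriEventResponse(
            responses=grid[mask.data, :],
            bin_times=obj.bin_times.copy(),
            events_used=obj.events_used,
            mask=mask,
            tr=obj.tr,
        )
    raise EicaError(f"cannot flip object of type {type(obj).__name__}")
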