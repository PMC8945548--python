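"""Synthetic multi-subject grayordinate BOLD data with known ground truth.

The generator emulates the statistical structure the group analysis assumes:

* a handful of low-rank spatiotemporal networks shared across subjects, each
  a rank-1 term ``lambda_r * c_rs * a_r b_r^T`` with subject-specific
  participation ``c_rs``;
* one dominant, near-uniform positive "global physiological" component
  (largest magnitude) spanning all grayordinates;
* a DMN-like target network with positive weights in designated cortical hubs
  and in subcortical patches centred on the toy CL, VTA and caudate ROIs, and
  negative (anti-correlated) weights in patches centred on the putamen and
  globus pallidus;
* per-subject temporal misalignment by random orthogonal transforms on the
  time axis (spontaneous activity is not synchronized across subjects);
* additive i.i.d. Gaussian noise scaled to a per-subject SNR.

Each subject's matrix is finally row-centred and row-normalized, matching the
preprocessing the synchronization and tensor stages require.  Spatial maps
are smooth compact blobs (Gaussian kernels on the cortical index line and on
the 3-D subcortical grid); temporal courses are band-limited Gaussian noise
orthogonalized across networks; subject loadings are lognormal, normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import ndimage

from .dataset import GrayordinateDataset
from .roistats import ROIAtlas
from .sync import normalize_timeseries

__all__ = [
    "SynthConfig",
    "SyntheticGroundTruth",
    "generate_dataset",
    "generate_toy_atlas",
    "DEFAULT_ROI_SPEC",
]

# Toy subcortical anatomy on the default 10 x 10 x 4 grid, in voxel units:
# (name, center, radius).  Containing regions first; the small nuclei (CL,
# VTA) come last so their labels overwrite the containing region on overlap.
DEFAULT_ROI_SPEC: list[tuple[str, tuple[float, float, float], float]] = [
    ("thalamus", (2.5, 2.5, 1.5), 2.0),
    ("brainstem", (7.0, 2.0, 1.5), 2.0),
    ("caudate", (2.0, 7.0, 1.5), 1.4),
    ("putamen", (6.0, 7.0, 1.5), 1.4),
    ("GP", (8.4, 7.0, 1.5), 1.1),
    ("CL", (2.5, 2.5, 2.5), 1.0),
    ("VTA", (7.0, 2.0, 2.0), 1.0),
]

_DEFAULT_GRID = (10, 10, 4)

# (network index -> list of (fractional grid center, amplitude)); the DMN-like
# network (index 1) mirrors the hypothesized anatomy: positive CL/VTA/caudate,
# negative putamen/GP.
_DMN_SUBCORTICAL_BLOBS = [
    ((2.5, 2.5, 2.5), 1.0),   # CL
    ((7.0, 2.0, 2.0), 1.0),   # VTA
    ((2.0, 7.0, 1.5), 0.6),   # caudate
    ((6.0, 7.0, 1.5), -0.8),  # putamen
    ((8.4, 7.0, 1.5), -0.8),  # GP
]
_OTHER_SUBCORTICAL_BLOBS = {
    2: [((4.5, 4.5, 1.5), 0.4)],
    3: [((0.5, 0.5, 0.5), 0.4)],
    4: [((9.0, 9.0, 2.5), 0.4)],
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the desk-scale conditions the acceptance experiments use:
    2000 grayordinates (1600 cortical vertices + 400 subcortical voxels on a
    10 x 10 x 4 grid), T = 300 frames, S = 40 subjects, 5 networks whose
    magnitudes descend from a dominant global component, SNR 2, per-subject
    temporal misalignment on.
    """

    n_cortical_vertices: int = 1600
    n_subcortical_voxels: int = 400
    grid_dims: tuple[int, int, int] = _DEFAULT_GRID
    n_timepoints: int = 300
    n_subjects: int = 40
    n_networks: int = 5
    network_magnitudes: tuple[float, ...] = (8.0, 5.0, 3.5, 2.5, 2.0)
    snr: float = 2.0
    temporal_band: tuple[float, float] = (0.01, 0.12)  # cycles/frame
    misalign: bool = True
    loading_sigma: float = 0.5  # lognormal spread of subject participation
    seed: int = 0

    def validate(self) -> None:
        mags = np.asarray(self.network_magnitudes, dtype=float)
        if len(mags) != self.n_networks:
            raise ValueError("network_magnitudes length must equal n_networks")
        if (mags <= 0).any():
            raise ValueError("network magnitudes must be strictly positive")
        if (np.diff(mags) >= 0).any():
            raise ValueError("network magnitudes must be sorted descending")
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        v = self.n_cortical_vertices + self.n_subcortical_voxels
        if self.n_networks >= min(v, self.n_timepoints):
            raise ValueError("degenerate rank: n_networks >= min(V, T)")
        if self.n_timepoints < self.n_networks:
            raise ValueError("need n_timepoints >= n_networks")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if int(np.prod(self.grid_dims)) != self.n_subcortical_voxels:
            raise ValueError("grid_dims must multiply to n_subcortical_voxels")
        lo, hi = self.temporal_band
        if not (0 < lo < hi <= 0.5):
            raise ValueError("temporal_band must satisfy 0 < lo < hi <= 0.5")
        n_bins = np.count_nonzero(
            (np.fft.rfftfreq(self.n_timepoints) >= lo)
            & (np.fft.rfftfreq(self.n_timepoints) <= hi)
        )
        if n_bins < self.n_networks:
            raise ValueError("temporal_band too narrow for n_networks courses")

    @property
    def n_vertices(self) -> int:
        return self.n_cortical_vertices + self.n_subcortical_voxels


@dataclass
class SyntheticGroundTruth:
    """Exact generative ingredients of a synthetic dataset.

    Factor arrays are row-stacked per network and unit-norm (magnitudes carry
    the scale).  ``misalignment_transforms[s]`` is the orthogonal time-axis
    transform applied to subject ``s`` (identity when misalignment is off).
    """

    spatial_maps: np.ndarray         # (R, V), unit-norm rows
    temporal_courses: np.ndarray     # (R, T), unit-norm rows
    subject_loadings: np.ndarray     # (R, S), nonnegative unit-norm rows
    magnitudes: np.ndarray           # (R,)
    misalignment_transforms: np.ndarray  # (S, T, T)
    atlas: ROIAtlas
    noise_sigma: np.ndarray          # (S,)
    seed: int
    dmn_index: int = 1
    positive_rois: tuple[str, ...] = ("CL", "VTA", "caudate")
    negative_rois: tuple[str, ...] = ("putamen", "GP")
    cortical_index: np.ndarray | None = None

    def dmn_cortical_template(self) -> np.ndarray:
        """The DMN-like network's cortical map — the selection template."""
        return self.spatial_maps[self.dmn_index][self.cortical_index]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in (
                "spatial_maps", "temporal_courses", "subject_loadings",
                "magnitudes", "misalignment_transforms", "noise_sigma",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["seed"] = self.seed
            f.attrs["dmn_index"] = self.dmn_index


def _scaled_roi_spec(grid_dims) -> list[tuple[str, tuple[float, ...], float]]:
    dims = np.asarray(grid_dims, dtype=float)
    scale = dims / np.asarray(_DEFAULT_GRID)
    r_scale = float(np.prod(scale) ** (1.0 / 3.0))
    spec = []
    for name, center, radius in DEFAULT_ROI_SPEC:
        # pull the centre far enough inside that a voxel-containing sphere
        # (radius ~ sqrt(3)/2) fits, then shrink the radius to the box
        c = np.clip(np.asarray(center) * scale, 0.37, dims - 1.37)
        fit = float(np.min(np.minimum(c + 0.5, dims - 0.5 - c)))
        spec.append((name, tuple(c), float(np.clip(radius * r_scale, 0.87, fit))))
    return spec


def generate_toy_atlas(grid_dims, roi_spec) -> ROIAtlas:
    """Rasterize named spheres into an integer label volume.

    Later entries overwrite earlier ones on overlap (every voxel keeps exactly
    one label).  Each ROI also gets a probabilistic map with Gaussian fall-off
    from its centre, peak-normalized to 1.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    names = [name for name, _, _ in roi_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate ROI names in roi_spec")
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid_dims], indexing="ij"), axis=-1
    ).astype(float)
    labels = np.zeros(grid_dims, dtype=np.int16)
    prob_maps: dict[str, np.ndarray] = {}
    name_map: dict[int, str] = {}
    for lab, (name, center, radius) in enumerate(roi_spec, start=1):
        center = np.asarray(center, dtype=float)
        if radius < 0:
            raise ValueError(f"ROI {name!r}: negative radius")
        lo_ok = (center - radius >= -0.5).all()
        hi_ok = (center + radius <= np.asarray(grid_dims) - 0.5).all()
        if not (lo_ok and hi_ok):
            raise ValueError(f"ROI {name!r} sphere does not fit in the grid")
        dist2 = np.sum((coords - center) ** 2, axis=-1)
        inside = dist2 <= radius**2 + 1e-12
        if not inside.any():
            raise ValueError(f"ROI {name!r} empty after rasterization")
        labels[inside] = lab
        name_map[lab] = name
        sigma = (radius + 0.5) / 2.0
        prob_maps[name] = np.exp(-dist2 / (2.0 * sigma**2))
    # drop names whose every voxel was overwritten? keep them: names maps the
    # label numbering even if a label was fully shadowed
    return ROIAtlas(labels=labels, names=name_map, prob_maps=prob_maps)


# ----------------------------------------------------------------------
# spatial / temporal factor construction

def _gaussian_bump_1d(n: int, center: float, sigma: float) -> np.ndarray:
    x = np.arange(n, dtype=float)
    return np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def _subcortical_blob(grid_dims, center, sigma=1.2) -> np.ndarray:
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid_dims], indexing="ij"), axis=-1
    ).astype(float)
    d2 = np.sum((coords - np.asarray(center, dtype=float)) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _spatial_maps(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    lc, lsub = config.n_cortical_vertices, config.n_subcortical_voxels
    grid = config.grid_dims
    scale = np.asarray(grid, dtype=float) / np.asarray(_DEFAULT_GRID)
    r = config.n_networks
    maps = np.zeros((r, lc + lsub))

    # global physiological component: near-uniform positive everywhere
    jitter_c = ndimage.gaussian_filter1d(rng.standard_normal(lc), max(lc / 50, 1))
    jitter_s = ndimage.gaussian_filter(
        rng.standard_normal(grid), 1.0
    ).ravel()
    for jit, sl in ((jitter_c, slice(0, lc)), (jitter_s, slice(lc, lc + lsub))):
        jit = jit / max(np.abs(jit).max(), 1e-300)
        maps[0, sl] = 1.0 + 0.05 * jit

    # non-global networks: two cortical Gaussian hubs in disjoint blocks
    n_other = r - 1
    block = lc / max(n_other, 1)
    for k in range(1, r):
        start = (k - 1) * block
        sigma = block / 10.0
        maps[k, :lc] += 1.0 * _gaussian_bump_1d(lc, start + 0.30 * block, sigma)
        maps[k, :lc] += 0.8 * _gaussian_bump_1d(lc, start + 0.70 * block, sigma)

    # subcortical structure
    for center, amp in _DMN_SUBCORTICAL_BLOBS:
        if 1 < r:
            maps[1, lc:] += amp * _subcortical_blob(
                grid, np.asarray(center) * scale
            ).ravel()
    for k, blobs in _OTHER_SUBCORTICAL_BLOBS.items():
        if k < r:
            for center, amp in blobs:
                maps[k, lc:] += amp * _subcortical_blob(
                    grid, np.asarray(center) * scale
                ).ravel()

    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return maps


def _temporal_courses(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    t, r = config.n_timepoints, config.n_networks
    lo, hi = config.temporal_band
    raw = rng.standard_normal((t, r))
    freqs = np.fft.rfftfreq(t)
    mask = (freqs >= lo) & (freqs <= hi)
    spec = np.fft.rfft(raw, axis=0)
    spec[~mask] = 0.0
    filtered = np.fft.irfft(spec, n=t, axis=0)
    # orthogonalize across networks so CP factors are identifiable
    q, rm = np.linalg.qr(filtered)
    q = q * np.sign(np.diag(rm))
    return q.T  # (R, T), orthonormal rows, zero-mean (band excludes DC)


def generate_dataset(
    config: SynthConfig, keep_raw: bool = False
):
    """Generate a multi-subject dataset and its exact ground truth.

    Subject ``s`` receives ``(sum_r lambda_r c_rs a_r b_r^T) Q_s + eps`` with
    ``Q_s`` a Haar-random orthogonal time transform (identity when
    ``config.misalign`` is off) and ``eps`` i.i.d. Gaussian scaled so the
    per-subject signal/noise variance ratio equals ``config.snr``; rows are
    then centred and unit-normalized.  Fully deterministic given
    ``config.seed``.

    Returns ``(dataset, truth)``; with ``keep_raw=True`` additionally returns
    a dict with the pre-normalization ``signal`` and ``noise`` arrays per
    subject (for variance accounting).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    v, t, s, r = (
        config.n_vertices, config.n_timepoints,
        config.n_subjects, config.n_networks,
    )
    lc = config.n_cortical_vertices

    spatial = _spatial_maps(config, rng)           # (R, V)
    temporal = _temporal_courses(config, rng)      # (R, T)
    loadings = rng.lognormal(0.0, config.loading_sigma, size=(r, s))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    lam = np.asarray(config.network_magnitudes, dtype=float)

    transforms = np.empty((s, t, t))
    if config.misalign:
        for j in range(s):
            g = rng.standard_normal((t, t))
            q, rm = np.linalg.qr(g)
            transforms[j] = q * np.sign(np.diag(rm))
    else:
        transforms[:] = np.eye(t)

    subjects = []
    noise_sigma = np.empty(s)
    raw_signal, raw_noise = [], []
    for j in range(s):
        weights = lam * loadings[:, j]
        signal = (spatial.T * weights) @ temporal   # (V, T)
        if config.misalign:
            signal = signal @ transforms[j]
        eps_unit = rng.standard_normal((v, t))
        if np.isinf(config.snr):
            sigma = 0.0
        else:
            sigma = float(np.sqrt(signal.var() / config.snr))
        noise = sigma * eps_unit
        noise_sigma[j] = sigma
        data = signal + noise
        if keep_raw:
            raw_signal.append(signal)
            raw_noise.append(noise)
        subjects.append(normalize_timeseries(data))

    atlas = generate_toy_atlas(config.grid_dims, _scaled_roi_spec(config.grid_dims))
    coords = np.stack(
        np.meshgrid(*[np.arange(d) for d in config.grid_dims], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    cortical_index = np.arange(lc)
    dataset = GrayordinateDataset(
        subjects=subjects,
        cortical_index=cortical_index,
        subcortical_index=np.arange(lc, v),
        subcortical_grid_coords=coords,
        grid_dims=config.grid_dims,
    )
    truth = SyntheticGroundTruth(
        spatial_maps=spatial,
        temporal_courses=temporal,
        subject_loadings=loadings,
        magnitudes=lam,
        misalignment_transforms=transforms,
        atlas=atlas,
        noise_sigma=noise_sigma,
        seed=config.seed,
        dmn_index=1 if r > 1 else 0,
        cortical_index=cortical_index,
    )
    if keep_raw:
        return dataset, truth, {"signal": raw_signal, "noise": raw_noise}
    return dataset, truth
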