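"""Seed-based subcortical correlation mapping, with and without global signal
regression (GSR).

The classical alternative to tensor-based network identification: place a
single-vertex cortical seed (e.g. in the posterior cingulate cortex) and
correlate every subcortical voxel's time series with it, per subject; subject
maps are combined by Fisher-z averaging.  GSR removes the mean all-
grayordinate time series from every voxel before correlating — which is well
known to *introduce* negative correlations mathematically, a property the
tests reproduce on synthetic data with an all-nonnegative ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import GrayordinateDataset
from .sync import normalize_timeseries

__all__ = [
    "SeedCorrelationMap",
    "global_signal_regress",
    "seed_correlation_map",
    "compare_maps",
]


def global_signal_regress(data: np.ndarray) -> np.ndarray:
    """Regress the global (mean over rows) signal out of every time series.

    Each row is replaced by its least-squares residual against the global
    signal, then re-centred and renormalized.  Residuals are exactly
    orthogonal to the global signal (within 1e-10), and remain so after
    re-centring because the global signal of zero-mean rows is itself
    zero-mean.

    Raises
    ------
    ValueError
        If the global signal is numerically zero, or a row dies (rows
        proportional to the global signal leave nothing to correlate).
    """
    data = np.asarray(data, dtype=float)
    g = data.mean(axis=0)
    gg = float(g @ g)
    if gg < 1e-24:
        raise ValueError("global signal is numerically zero")
    resid = data - np.outer(data @ g / gg, g)
    orig_norms = np.linalg.norm(data, axis=1)
    dead = np.flatnonzero(
        np.linalg.norm(resid, axis=1) < 1e-8 * np.maximum(orig_norms, 1e-300)
    )
    if dead.size:
        raise ValueError(
            f"row(s) {dead.tolist()[:10]} are fully explained by the global "
            "signal; nothing left to correlate"
        )
    return normalize_timeseries(resid)


@dataclass
class SeedCorrelationMap:
    """Per-subject and group seed-correlation maps over the subcortex."""

    seed_index: int
    gsr: bool
    per_subject_maps: np.ndarray  # (S, n_subcortical)
    group_map: np.ndarray         # (n_subcortical,)
    n_subjects: int


def _pearson_rows(seed_row: np.ndarray, rows: np.ndarray) -> np.ndarray:
    s = seed_row - seed_row.mean()
    sn = np.linalg.norm(s)
    if sn < 1e-300:
        raise ValueError("seed time series is constant")
    r = rows - rows.mean(axis=1, keepdims=True)
    den = np.linalg.norm(r, axis=1) * sn
    den[den < 1e-300] = np.inf
    return (r @ s) / den


def seed_correlation_map(
    dataset: GrayordinateDataset, seed_index: int, gsr: bool = False
) -> SeedCorrelationMap:
    """Correlate a cortical seed with every subcortical voxel, per subject.

    The group map is the inverse-Fisher transform of the mean Fisher-z across
    subjects (correlations clipped away from +/-1 before the transform).
    Invariant to subject ordering.
    """
    if seed_index not in set(dataset.cortical_index.tolist()):
        raise ValueError(f"seed index {seed_index} is not a cortical grayordinate")
    sub_idx = dataset.subcortical_index
    maps = np.empty((dataset.n_subjects, sub_idx.size))
    for j, x in enumerate(dataset.subjects):
        if gsr:
            x = global_signal_regress(x)
        maps[j] = _pearson_rows(x[seed_index], x[sub_idx])
    z = np.arctanh(np.clip(maps, -1 + 1e-12, 1 - 1e-12))
    group = np.tanh(z.mean(axis=0))
    return SeedCorrelationMap(
        seed_index=int(seed_index),
        gsr=bool(gsr),
        per_subject_maps=maps,
        group_map=group,
        n_subjects=dataset.n_subjects,
    )


def compare_maps(
    map_a: np.ndarray, map_b: np.ndarray
) -> tuple[float, float, float]:
    """Pearson r, Spearman rho and sign-agreement fraction of two maps,
    computed over the common finite support (>= 3 entries required)."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 common finite entries")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance input")
    pear = float(stats.pearsonr(a, b).statistic)
    rho = float(stats.spearmanr(a, b).statistic)
    sign_agree = float(np.mean(np.sign(a) == np.sign(b)))
    return pear, rho, sign_agree
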