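"""Temporal synchronization of subjects by orthogonal transforms (BrainSync).

Spontaneous BOLD fluctuations are not temporally aligned across subjects, yet
a shared low-rank spatiotemporal model requires a common temporal frame.  For
row-normalized data (zero-mean, unit-norm time series) the alignment that
maximizes the correlation of homologous time series between two subjects is an
orthogonal transform on the time axis — the classic orthogonal Procrustes
problem, solved in closed form from an SVD.  Because the transform is
orthogonal and applied on the right, it leaves all within-subject inner
products (hence full-window connectivity) untouched.

The group variant builds a *virtual reference subject*: an alternating scheme
that synchronizes every subject to the current reference and re-estimates the
reference as the row-renormalized mean of the synchronized data.  The
row-renormalized mean is the exact minimizer of the summed squared distance
over references constrained to unit-norm rows, so the group objective is
monotone non-increasing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .dataset import GrayordinateDataset

__all__ = [
    "SyncResult",
    "normalize_timeseries",
    "pairwise_brainsync",
    "group_brainsync",
    "connectivity_preservation_check",
    "homologous_row_correlation",
]


class ConstantRowError(ValueError):
    """A time series is constant (dead voxel) and cannot be normalized."""


def normalize_timeseries(data: np.ndarray) -> np.ndarray:
    """Return a copy with every row zero-mean and unit Euclidean norm.

    Raises
    ------
    ConstantRowError
        If any row is constant; the message names the offending row indices,
        which in practice signal dead voxels.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("expected a (V, T) matrix with T >= 2")
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    dead = np.flatnonzero(norms < 1e-300)
    if dead.size:
        raise ConstantRowError(
            f"constant time series at row(s) {dead.tolist()[:10]}"
            f"{'...' if dead.size > 10 else ''} (dead voxels?)"
        )
    return centered / norms[:, None]


def _check_normalized(data: np.ndarray, what: str, atol: float = 1e-6) -> None:
    norms = np.linalg.norm(data, axis=1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError(f"{what} rows are not unit-norm; normalize first")


def pairwise_brainsync(
    reference: np.ndarray, moving: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimally align ``moving`` to ``reference`` by a temporal orthogonal map.

    Finds the orthogonal ``O`` minimizing ``||reference - moving @ O||_F``
    (closed form: ``O = U @ Vt`` from the SVD of ``moving.T @ reference``).

    Returns
    -------
    synced : ndarray
        ``moving @ O``.
    transform : ndarray
        The ``(T, T)`` orthogonal matrix ``O``.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError(
            f"shape mismatch: reference {reference.shape} vs moving {moving.shape}"
        )
    _check_normalized(reference, "reference")
    _check_normalized(moving, "moving")
    u, _, vt = np.linalg.svd(moving.T @ reference, full_matrices=False)
    transform = u @ vt
    return moving @ transform, transform


@dataclass
class SyncResult:
    """Output of group synchronization.

    ``transforms[s]`` is the orthogonal map for subject ``s`` such that
    ``synced.subjects[s] = dataset.subjects[s] @ transforms[s]``.
    ``objective_history[k]`` logs the constrained group objective
    ``sum_s ||X_s O_s - ref||_F^2`` after iteration ``k``.
    """

    transforms: list[np.ndarray]
    synced: GrayordinateDataset
    reference: np.ndarray
    n_iterations: int
    converged: bool
    objective_history: list[float]


def _most_central_subject(subjects: list[np.ndarray]) -> int:
    """Index of the subject with the largest summed squared homologous-row
    correlation to all others (cheap centrality; used only to initialize)."""
    s = len(subjects)
    scores = np.zeros(s)
    for i in range(s):
        for j in range(i + 1, s):
            c = np.einsum("vt,vt->v", subjects[i], subjects[j])
            val = float(np.sum(c**2))
            scores[i] += val
            scores[j] += val
    return int(np.argmax(scores))


def group_brainsync(
    dataset: GrayordinateDataset,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> SyncResult:
    """Build a virtual reference subject and align all subjects to it.

    The reference is initialized at the most central subject (largest summed
    squared correlation to all others, avoiding arbitrary first-subject bias),
    then refined by alternating Procrustes alignment and row-renormalized
    averaging until the reference moves less than ``tol`` (Frobenius) or
    ``max_iter`` is reached.  Non-convergence is reported via
    ``converged=False``, not an exception.
    """
    if dataset.n_subjects < 2:
        raise ValueError("group synchronization needs at least 2 subjects")
    subjects = dataset.subjects
    for i, x in enumerate(subjects):
        _check_normalized(x, f"subject {i}")

    ref = subjects[_most_central_subject(subjects)].copy()
    transforms = [np.eye(dataset.n_timepoints) for _ in subjects]
    synced = [x.copy() for x in subjects]
    history: list[float] = []
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for s, x in enumerate(subjects):
            synced[s], transforms[s] = pairwise_brainsync(ref, x)
        mean = np.mean(synced, axis=0)
        norms = np.linalg.norm(mean, axis=1, keepdims=True)
        norms[norms < 1e-300] = 1.0
        new_ref = mean / norms
        history.append(float(sum(np.sum((y - new_ref) ** 2) for y in synced)))
        delta = float(np.linalg.norm(new_ref - ref))
        ref = new_ref
        if delta < tol:
            converged = True
            break

    synced_ds = dataclasses.replace(dataset, subjects=synced)
    return SyncResult(
        transforms=transforms,
        synced=synced_ds,
        reference=ref,
        n_iterations=n_it,
        converged=converged,
        objective_history=history,
    )


def connectivity_preservation_check(
    original: np.ndarray, synced: np.ndarray
) -> float:
    """Max absolute change in the full-window correlation matrix.

    Connectivity here is the inner product of unit-norm rows, which equals the
    Pearson correlation on the original (zero-mean) data; right-multiplication
    by an orthogonal matrix preserves it exactly, so the returned deviation is
    numerical noise (< 1e-8) whenever ``synced = original @ O``.
    """
    c0 = original @ original.T
    c1 = synced @ synced.T
    return float(np.max(np.abs(c0 - c1)))


def homologous_row_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Mean Pearson correlation between corresponding rows of two matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("vt,vt->v", a, b)
    den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    return float(np.mean(num / den))
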