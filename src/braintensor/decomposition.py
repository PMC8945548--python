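"""Low-rank CP decomposition of the space x time x subject tensor (NASCAR).

Synchronized multi-subject BOLD data stacked along a subject axis form a
3-way tensor ``X`` of shape ``(V, T, S)``.  Brain networks are modeled as a
rank-R canonical polyadic (CP) expansion

    X ~= sum_r  lambda_r  a_r o b_r o c_r

where ``a_r`` (length V) is the network's spatial map, ``b_r`` (length T) its
temporal dynamics, ``c_r`` (length S) the per-subject participation level and
``lambda_r`` its magnitude.  The solver follows the NASCAR strategy: solve the
rank-1 problem first, then repeatedly add one component (warm-starting all
previous components from the lower-rank solution) and jointly re-optimize all
factor entries with full-gradient Nadam (Nesterov-accelerated adaptive moment
estimation) updates.  The warm start makes the solution robust to
initialization and the per-rank relative error non-increasing.

Determinism and vertex-order invariance
---------------------------------------
Two properties the solver guarantees by construction:

* identical outputs for identical seed and inputs (full-gradient updates, one
  seeded RNG);
* *exact* invariance to permutations of the space axis: the solver internally
  sorts voxels into a canonical (lexicographic) order before optimizing and
  restores the caller's order on output, so floating-point accumulation order
  never depends on how the voxels were presented.  New-component spatial
  factors are initialized from the data (residual contraction against random
  time/subject vectors), never from index-coupled random draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import GrayordinateDataset

__all__ = [
    "DataTensor",
    "NascarOptions",
    "NetworkComponent",
    "Decomposition",
    "ComponentMatching",
    "build_tensor",
    "nascar_decompose",
    "match_components",
    "explained_variance",
]


class NascarDivergenceError(RuntimeError):
    """The optimizer's reconstruction error increased persistently."""


@dataclass
class DataTensor:
    """3-way array (space V, time T, subject S) plus axis metadata."""

    values: np.ndarray
    cortical_index: np.ndarray | None = None
    subcortical_index: np.ndarray | None = None
    subject_ids: list[str] | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def build_tensor(dataset: GrayordinateDataset, synced: bool) -> DataTensor:
    """Stack all subjects along a third (subject) axis.

    ``synced`` must be ``True``: the low-rank model assumes a shared temporal
    frame and does not hold for asynchronous resting-state data, so building
    the tensor from unsynchronized subjects is rejected outright.
    """
    if not synced:
        raise ValueError(
            "refusing to build the tensor from unsynchronized data: the "
            "low-rank CP model assumes temporally synchronized subjects "
            "(spontaneous BOLD activity is asynchronous across subjects; run "
            "group_brainsync first)"
        )
    return DataTensor(
        values=dataset.stacked(),
        cortical_index=dataset.cortical_index.copy(),
        subcortical_index=dataset.subcortical_index.copy(),
        subject_ids=list(dataset.subject_ids),
    )


@dataclass
class NascarOptions:
    """Optimizer settings for :func:`nascar_decompose`.

    Defaults are tuned for unit-normalized BOLD data: Nadam step size 1e-2,
    moment decays 0.9/0.999, epsilon 1e-8, at most ``max_iter`` Nadam steps
    per rank, convergence when the relative reconstruction error changes by
    less than ``tol`` between checks spaced ``check_every`` iterations apart.
    ``divergence_patience`` consecutive error increases at checks abort the
    fit with a diagnostic.

    ``max_iter`` doubles as an early-stopping regularizer: with an
    over-estimated rank, fully converging the objective lets surplus
    components absorb structured noise and bend the true networks' spatial
    maps, so the default stops each rank's joint optimization after 100
    steps (see docs/methods.md); raise it for exact-rank fits where full
    convergence is wanted.
    """

    lr: float = 1e-2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_iter: int = 100
    tol: float = 1e-6
    check_every: int = 10
    divergence_patience: int = 5


@dataclass
class NetworkComponent:
    """One rank-1 network: magnitude and unit-norm spatial/temporal/subject factors."""

    magnitude: float
    spatial: np.ndarray
    temporal: np.ndarray
    subject: np.ndarray


@dataclass
class Decomposition:
    """Ordered CP components (magnitudes descending) with fit diagnostics."""

    components: list[NetworkComponent]
    rank_requested: int
    fit_history: list[float] = field(default_factory=list)
    seed: int = 0

    @property
    def rank(self) -> int:
        return len(self.components)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([c.magnitude for c in self.components])

    def factor_matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Unit-norm factors stacked as rows: (R,V), (R,T), (R,S)."""
        return (
            np.array([c.spatial for c in self.components]),
            np.array([c.temporal for c in self.components]),
            np.array([c.subject for c in self.components]),
        )

    def reconstruct(self) -> np.ndarray:
        """Dense ``(V, T, S)`` model tensor (memory: V*T*S floats)."""
        a, b, c = self.factor_matrices()
        lam = self.magnitudes
        return np.einsum("r,rv,rt,rs->vts", lam, a, b, c)


# ----------------------------------------------------------------------
# internals

def _gradients_and_error(X1, normX2, A, B, C, T, S):
    """Full CP gradients via MTTKRPs plus the exact squared error, sharing
    one big contraction ``Z = X1.T @ A`` between the time and subject modes."""
    r = A.shape[1]
    Z = (X1.T @ A).reshape(T, S, r)
    gb_cross = np.einsum("tsr,sr->tr", Z, C)
    gc_cross = np.einsum("tsr,tr->sr", Z, B)
    kr = (B[:, None, :] * C[None, :, :]).reshape(T * S, r)
    ga_cross = X1 @ kr
    ata, btb, ctc = A.T @ A, B.T @ B, C.T @ C
    ga = A @ (btb * ctc) - ga_cross
    gb = B @ (ata * ctc) - gb_cross
    gc = C @ (ata * btb) - gc_cross
    inner = float(np.sum(ga_cross * A))
    model2 = float(np.sum(ata * btb * ctc))
    err2 = max(normX2 - 2.0 * inner + model2, 0.0)
    return (ga, gb, gc), err2


def _nadam_fit(X1, normX2, A, B, C, T, S, opts: NascarOptions):
    """Jointly optimize all factor entries; returns best factors and rel. error."""
    params = [A.copy(), B.copy(), C.copy()]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2 = opts.beta1, opts.beta2
    sqrt_norm = np.sqrt(normX2)

    best = [p.copy() for p in params]
    best_err = np.inf
    prev_check = np.inf
    n_increase = 0
    relerr = np.inf
    for it in range(1, opts.max_iter + 1):
        grads, err2 = _gradients_and_error(
            X1, normX2, params[0], params[1], params[2], T, S
        )
        relerr = np.sqrt(err2) / sqrt_norm
        if (it == 1 or it % opts.check_every == 0) and relerr < best_err:
            best_err = relerr
            best = [p.copy() for p in params]
        if it % opts.check_every == 0:
            # genuine divergence only: persistent increases well above the
            # best error seen (Nadam oscillates harmlessly near a plateau)
            if relerr > prev_check + 1e-15 and relerr > best_err * 1.02:
                n_increase += 1
                if n_increase >= opts.divergence_patience:
                    raise NascarDivergenceError(
                        f"reconstruction error increased at "
                        f"{n_increase} consecutive checks (iteration {it}, "
                        f"relative error {relerr:.3e}); try a smaller lr"
                    )
            else:
                n_increase = 0
            if abs(prev_check - relerr) < opts.tol:
                break
            prev_check = relerr
        # Nadam step (Dozat variant, bias-corrected Nesterov momentum)
        for k in range(3):
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            v[k] = b2 * v[k] + (1 - b2) * g * g
            m_hat = m[k] / (1 - b1 ** (it + 1))
            g_hat = g / (1 - b1**it)
            v_hat = v[k] / (1 - b2**it)
            params[k] -= (
                opts.lr * (b1 * m_hat + (1 - b1) * g_hat)
                / (np.sqrt(v_hat) + opts.eps)
            )

    if relerr < best_err or not np.isfinite(best_err):
        best, best_err = params, relerr
    return best[0], best[1], best[2], float(min(best_err, relerr))


def _canonical_space_order(X1: np.ndarray) -> np.ndarray:
    """Lexicographic voxel order by the first three unfolding columns."""
    ncol = X1.shape[1]
    keys = tuple(X1[:, k] for k in range(min(3, ncol) - 1, -1, -1))
    return np.lexsort(keys)


def nascar_decompose(
    tensor: DataTensor | np.ndarray,
    rank: int,
    opts: NascarOptions | None = None,
    seed: int = 0,
) -> Decomposition:
    """Rank-incremental CP decomposition with Nadam updates.

    Parameters
    ----------
    tensor
        ``DataTensor`` or raw ``(V, T, S)`` array.
    rank
        Number of components R; must satisfy ``1 <= R < min(VT, TS, VS)``.
    opts
        :class:`NascarOptions`; defaults used when ``None``.
    seed
        Seeds the random time/subject initialization of each new component
        (the only random ingredient).

    Returns
    -------
    Decomposition
        Components sorted by descending magnitude, factors unit-norm, sign
        convention: the largest-magnitude entry of every spatial factor (and
        of every subject factor) is positive.
    """
    if opts is None:
        opts = NascarOptions()
    values = tensor.values if isinstance(tensor, DataTensor) else np.asarray(tensor)
    if values.ndim != 3:
        raise ValueError("expected a 3-way tensor (V, T, S)")
    if np.isnan(values).any():
        raise ValueError("tensor contains NaN")
    vdim, tdim, sdim = values.shape
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank >= min(vdim * tdim, tdim * sdim, vdim * sdim):
        raise ValueError("rank too large for tensor dimensions")

    # canonical voxel order: makes results exactly invariant to input
    # permutations of the space axis (see module docstring)
    X1_raw = np.ascontiguousarray(values.reshape(vdim, tdim * sdim))
    order = _canonical_space_order(X1_raw)
    inverse = np.empty_like(order)
    inverse[order] = np.arange(vdim)
    X1 = np.ascontiguousarray(X1_raw[order])
    normX2 = float(np.sum(X1 * X1))

    rng = np.random.default_rng(seed)
    A = np.zeros((vdim, 0))
    B = np.zeros((tdim, 0))
    C = np.zeros((sdim, 0))
    fit_history: list[float] = []
    for _ in range(1, rank + 1):
        b_new = rng.standard_normal(tdim)
        b_new /= np.linalg.norm(b_new)
        c_new = rng.standard_normal(sdim)
        c_new /= np.linalg.norm(c_new)
        # pull the random (b, c) pair toward the dominant rank-1 direction of
        # the residual (alternating power iterations); the spatial factor is
        # always the least-squares optimum for the current (b, c), so the
        # initialization is data-driven and nearly seed-independent
        a_new = np.zeros(vdim)
        for _power in range(8):
            a_new = X1 @ (b_new[:, None] * c_new[None, :]).ravel()
            if A.shape[1]:
                a_new = a_new - A @ ((B.T @ b_new) * (C.T @ c_new))
            a_norm = np.linalg.norm(a_new)
            if a_norm < 1e-300:
                break
            za = (X1.T @ (a_new / a_norm)).reshape(tdim, sdim)
            corr = None
            if A.shape[1]:
                corr = (A.T @ (a_new / a_norm))
            b_next = za @ c_new
            if corr is not None:
                b_next = b_next - B @ (corr * (C.T @ c_new))
            b_next /= max(np.linalg.norm(b_next), 1e-300)
            c_next = za.T @ b_next
            if corr is not None:
                c_next = c_next - C @ (corr * (B.T @ b_next))
            c_next /= max(np.linalg.norm(c_next), 1e-300)
            b_new, c_new = b_next, c_next
            a_new = X1 @ (b_new[:, None] * c_new[None, :]).ravel()
            if A.shape[1]:
                a_new = a_new - A @ ((B.T @ b_new) * (C.T @ c_new))
        A = np.column_stack([A, a_new])
        B = np.column_stack([B, b_new])
        C = np.column_stack([C, c_new])
        if normX2 == 0.0:
            fit_history.append(0.0)
            continue
        A, B, C, relerr = _nadam_fit(X1, normX2, A, B, C, tdim, sdim, opts)
        fit_history.append(relerr)

    # fold scale into lambda, fix signs, sort; all reductions happen in the
    # canonical (sorted) voxel order so outputs are permutation-exact, and
    # the caller's order is restored only at the very end
    components: list[NetworkComponent] = []
    for j in range(rank):
        a, b, c = A[:, j], B[:, j], C[:, j]
        na, nb, nc = np.linalg.norm(a), np.linalg.norm(b), np.linalg.norm(c)
        lam = float(na * nb * nc)
        if lam < 1e-250:
            a = np.zeros(vdim); a[0] = 1.0
            b = np.zeros(tdim); b[0] = 1.0
            c = np.zeros(sdim); c[0] = 1.0
            lam = 0.0
        else:
            a, b, c = a / na, b / nb, c / nc
            if c[np.argmax(np.abs(c))] < 0:
                c, b = -c, -b
            if a[np.argmax(np.abs(a))] < 0:
                a, b = -a, -b
        components.append(
            NetworkComponent(magnitude=lam, spatial=a[inverse], temporal=b, subject=c)
        )
    components.sort(key=lambda comp: -comp.magnitude)
    return Decomposition(
        components=components,
        rank_requested=rank,
        fit_history=fit_history,
        seed=seed,
    )


# ----------------------------------------------------------------------

@dataclass
class ComponentMatching:
    """Greedy one-to-one matching of estimated to reference components.

    ``assignment[k]`` is the estimated-component index matched to reference
    component ``k``; ``congruence[k]`` holds the absolute cosine similarity in
    the (spatial, temporal, subject) modes; ``spatial_sign[k]`` is the sign to
    apply to the estimated spatial (and jointly temporal) factor so the
    matched spatial cosine is non-negative.
    """

    assignment: np.ndarray
    congruence: np.ndarray
    spatial_sign: np.ndarray

    @property
    def scores(self) -> np.ndarray:
        return self.congruence.prod(axis=1)


def _reference_factors(truth):
    if isinstance(truth, Decomposition):
        return truth.factor_matrices()
    # SyntheticGroundTruth-like: row-stacked factor arrays
    return (
        np.asarray(truth.spatial_maps),
        np.asarray(truth.temporal_courses),
        np.asarray(truth.subject_loadings),
    )


def match_components(
    estimated: Decomposition,
    truth,
    modes: tuple[str, ...] = ("spatial", "temporal", "subject"),
) -> ComponentMatching:
    """Match estimated components to reference networks.

    Greedy assignment maximizing, at each step, the product of absolute
    cosine similarities across the requested ``modes``; reference components
    are matched one-to-one (``estimated.rank`` must be >= the reference
    count).  Sign indeterminacy of CP (joint sign flips of two modes) is
    resolved by reporting absolute congruences and the spatial sign flip.
    ``congruence`` always reports all three modes, but only the requested
    ones enter the assignment score — after group synchronization the
    temporal frame is only identified up to a common rotation, so matching
    against pre-synchronization ground truth should use
    ``modes=("spatial", "subject")``.
    """
    ta, tb, tc = _reference_factors(truth)
    n_true = ta.shape[0]
    if estimated.rank < n_true:
        raise ValueError("estimated rank smaller than number of reference networks")
    ea, eb, ec = estimated.factor_matrices()

    def _cos(e, t):
        e = e / np.maximum(np.linalg.norm(e, axis=1, keepdims=True), 1e-300)
        t = t / np.maximum(np.linalg.norm(t, axis=1, keepdims=True), 1e-300)
        return e @ t.T

    cos_a, cos_b, cos_c = _cos(ea, ta), _cos(eb, tb), _cos(ec, tc)
    by_name = {"spatial": cos_a, "temporal": cos_b, "subject": cos_c}
    unknown = set(modes) - set(by_name)
    if unknown or not modes:
        raise ValueError(f"invalid modes {modes!r}")
    score = np.ones_like(cos_a)
    for name in modes:
        score = score * np.abs(by_name[name])

    assignment = np.full(n_true, -1)
    congruence = np.zeros((n_true, 3))
    spatial_sign = np.ones(n_true)
    work = score.copy()
    for _ in range(n_true):
        i, k = np.unravel_index(np.argmax(work), work.shape)
        assignment[k] = i
        congruence[k] = (abs(cos_a[i, k]), abs(cos_b[i, k]), abs(cos_c[i, k]))
        spatial_sign[k] = 1.0 if cos_a[i, k] >= 0 else -1.0
        work[i, :] = -np.inf
        work[:, k] = -np.inf
    return ComponentMatching(
        assignment=assignment, congruence=congruence, spatial_sign=spatial_sign
    )


def explained_variance(
    decomposition: Decomposition, tensor: DataTensor | np.ndarray
) -> float:
    """Fraction of tensor variance captured: ``1 - ||X - Xhat||^2 / ||X||^2``.

    Computed from inner products without materializing the model tensor.
    """
    values = tensor.values if isinstance(tensor, DataTensor) else np.asarray(tensor)
    vdim, tdim, sdim = values.shape
    normX2 = float(np.sum(values**2))
    if normX2 == 0.0:
        raise ValueError("zero tensor has no variance to explain")
    if not decomposition.components:
        return 0.0
    a, b, c = decomposition.factor_matrices()
    lam = decomposition.magnitudes
    X1 = values.reshape(vdim, tdim * sdim)
    kr = (b.T[:, None, :] * c.T[None, :, :]).reshape(tdim * sdim, -1)
    cross = float(np.sum((X1 @ kr) * (a.T * lam)))
    gram = (a @ a.T) * (b @ b.T) * (c @ c.T)
    model2 = float(lam @ gram @ lam)
    resid2 = max(normX2 - 2.0 * cross + model2, 0.0)
    return 1.0 - resid2 / normX2
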