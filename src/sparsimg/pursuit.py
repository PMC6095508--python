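"""Orthogonal Matching Pursuit for 2D blocks with separable dictionaries.

Given a block ``I`` of shape ``(Nx, Ny)`` and 1D dictionaries ``Dx``
(length ``Nx``) and ``Dy`` (length ``Ny``), the pursuit greedily builds

    I^k = sum_n c(n) * dx_{lx(n)} @ dy_{ly(n)}.T

At each iteration the atom pair maximising ``|dx.T @ R @ dy|`` over the
current residual ``R`` is selected; the coefficients are kept optimal in
the least-squares sense through a recursively maintained biorthogonal set
``B_n`` (so that ``c(n) = <B_n, I>_F``) together with a Gram-Schmidt
orthogonalised set ``W_n`` spanning the selected atoms.  One
re-orthogonalisation pass over each new ``W`` keeps the orthogonal set
accurate; the residual is then downdated by projection onto the newest
orthogonal direction.

The pursuit stops when the squared Frobenius norm of the residual drops
below the budget ``rho``, when ``max_atoms`` have been selected, when the
best selection score is numerically zero, or when a newly selected atom is
numerically dependent on the current span (skip-and-stop, reported in the
result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dictionaries import Dictionary1D

#: a freshly orthogonalised direction with Frobenius norm below this is
#: treated as numerically dependent on the selected span
DEPENDENCE_TOL = 1e-12

#: relative threshold under which the best selection score counts as zero
SCORE_TOL = 1e-12


@dataclass
class StoppingRule:
    """Residual budget and atom cap for one pursuit.

    ``rho`` is the squared-Frobenius residual budget (the pursuit stops as
    soon as ``||R||_F^2 < rho``); ``max_atoms`` caps the number of selected
    atoms (None means the block pixel count, the spanning limit).
    """

    rho: float = 0.0
    max_atoms: int | None = None

    def __post_init__(self):
        if self.rho < 0:
            raise ValueError("rho must be nonnegative")
        if self.max_atoms is not None and self.max_atoms < 1:
            raise ValueError("max_atoms must be a positive integer")


@dataclass
class BlockDecomposition:
    """Ordered atomic decomposition of one block.

    ``pairs`` holds 1-based ``(lx, ly)`` dictionary indices in selection
    order, ``coefficients`` the matching least-squares coefficients, and
    ``residual_sq`` the final squared Frobenius residual norm.
    ``stop_reason`` is one of ``"rho"``, ``"max_atoms"``, ``"zero_score"``,
    ``"dependent_atom"``.
    """

    pairs: list = field(default_factory=list)
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros(0))
    residual_sq: float = 0.0
    stop_reason: str = "rho"

    @property
    def k(self) -> int:
        return len(self.pairs)


def select_atom(residual: np.ndarray, Dx: Dictionary1D, Dy: Dictionary1D):
    """Best separable atom pair for the residual.

    Returns the 1-based indices ``(lx, ly)`` maximising
    ``|dx_lx.T @ residual @ dy_ly|`` and the maximum absolute value itself.
    Ties break to the smallest linearised index (lx first, then ly).
    """
    residual = np.asarray(residual, dtype=float)
    if residual.shape != (Dx.length, Dy.length):
        raise ValueError(
            f"residual shape {residual.shape} does not match dictionary "
            f"lengths ({Dx.length}, {Dy.length})"
        )
    corr = Dx.atoms.T @ residual @ Dy.atoms
    flat = int(np.argmax(np.abs(corr)))
    lx, ly = np.unravel_index(flat, corr.shape)
    return int(lx) + 1, int(ly) + 1, float(abs(corr[lx, ly]))


def omp2d_approximate(
    block: np.ndarray,
    Dx: Dictionary1D,
    Dy: Dictionary1D,
    stop: StoppingRule,
    n_reorth: int = 1,
) -> BlockDecomposition:
    """Greedy separable-dictionary approximation of one 2D block."""
    block = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains non-finite values")
    if block.shape != (Dx.length, Dy.length):
        raise ValueError("block shape does not match dictionary lengths")
    nx, ny = block.shape
    npix = nx * ny
    max_atoms = stop.max_atoms if stop.max_atoms is not None else npix

    target = block.ravel()
    resid = target.copy()
    scale = max(1.0, float(np.linalg.norm(target)))

    # columns of W: orthogonalised selected atoms; columns of B: their
    # biorthogonal duals; A holds the raw atom vectors for reconstruction
    W = np.empty((npix, 0))
    wnorm2 = np.empty(0)
    B = np.empty((npix, 0))
    pairs: list[tuple[int, int]] = []
    stop_reason = "rho"

    rsq = float(resid @ resid)
    if rsq < stop.rho:
        return BlockDecomposition([], np.zeros(0), rsq, "rho")

    while True:
        lx, ly, score = select_atom(resid.reshape(nx, ny), Dx, Dy)
        if score <= SCORE_TOL * scale:
            stop_reason = "zero_score"
            break

        a = np.outer(Dx.atoms[:, lx - 1], Dy.atoms[:, ly - 1]).ravel()
        w = a - W @ ((W.T @ a) / wnorm2) if W.shape[1] else a.copy()
        for _ in range(n_reorth):
            if W.shape[1]:
                w = w - W @ ((W.T @ w) / wnorm2)
        wn2 = float(w @ w)
        if np.sqrt(wn2) < DEPENDENCE_TOL:
            stop_reason = "dependent_atom"
            break

        b_new = w / wn2
        if B.shape[1]:
            B = B - np.outer(b_new, a @ B)
        B = np.column_stack([B, b_new])
        W = np.column_stack([W, w])
        wnorm2 = np.append(wnorm2, wn2)
        pairs.append((lx, ly))

        resid = resid - w * (float(w @ resid) / wn2)
        rsq = float(resid @ resid)
        if rsq < stop.rho:
            stop_reason = "rho"
            break
        if len(pairs) >= max_atoms:
            stop_reason = "max_atoms"
            break

    coeffs = B.T @ target if pairs else np.zeros(0)
    return BlockDecomposition(pairs, coeffs, rsq, stop_reason)


def reconstruct_block(
    dec: BlockDecomposition, Dx: Dictionary1D, Dy: Dictionary1D
) -> np.ndarray:
    """Linear combination of the selected separable atoms."""
    out_shape = (Dx.length, Dy.length)
    if dec.k == 0:
        return np.zeros(out_shape)
    ix = np.array([p[0] for p in dec.pairs], dtype=int)
    iy = np.array([p[1] for p in dec.pairs], dtype=int)
    if ix.min() < 1 or ix.max() > Dx.size or iy.min() < 1 or iy.max() > Dy.size:
        raise ValueError("atom index out of dictionary range")
    c = np.asarray(dec.coefficients, dtype=float)
    return (Dx.atoms[:, ix - 1] * c) @ Dy.atoms[:, iy - 1].T
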