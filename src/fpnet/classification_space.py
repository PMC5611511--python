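"""Construction of classification state spaces: ETR, OETR, ICA, SVD bases.

Exclusive threshold reduction (ETR) turns the non-orthogonal library matrix
L into an orthogonal basis O by keeping, in every node's row, only the
maximal entry (when it exceeds a threshold tau) and zeroing the rest.  Each
node is thereby assigned to exactly one stimulus, with the kept library
value as its association weight; columns of O have disjoint supports and
are exactly orthogonal.

Optimal ETR (OETR) then rescales the nodes with a diagonal weight matrix
D^w chosen to make the projected fixed points orthonormal, by solving

    min_w  || L^T D^w O - I ||_Fr

Every entry of L^T D^w O is linear in w and, because the columns of O have
disjoint node supports, the problem decouples into one independent linear
least-squares block per stimulus cluster; the solver below computes that
exact minimizer.  Nodes left unassigned by thresholding receive weight 0
(they do not enter the objective).

An Infomax ICA basis over L^T is provided as a comparison method, and the
raw library (SVDSep) or the leading concatenated-SVD patterns (SVDCon) can
also serve directly as (non-orthogonal) bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import ResponseCollection, ResponseMatrix
from .decomposition import LibraryMatrix, library_from_collection, svdcon

__all__ = [
    "ExclusiveBasis",
    "WeightVector",
    "ClassificationSpace",
    "etr",
    "oetr",
    "fixed_points",
    "project",
    "ica_basis",
    "build_space",
]

UNASSIGNED = -1


@dataclass
class ExclusiveBasis:
    """ETR output: at most one nonzero per row of the library matrix.

    ``assignment[n]`` is the stimulus index node ``n`` was associated with,
    or -1 when its maximal library entry did not exceed the threshold.
    """

    O: np.ndarray
    tau: float
    assignment: np.ndarray

    def __post_init__(self) -> None:
        if (np.count_nonzero(self.O, axis=1) > 1).any():
            raise ValueError("each row of O may have at most one nonzero")

    @property
    def n_nodes(self) -> int:
        return self.O.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.O.shape[1]


@dataclass
class WeightVector:
    """Diagonal of the OETR node re-weighting matrix D^w."""

    w: np.ndarray
    objective: float = float("nan")

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")

    def as_diagonal(self) -> np.ndarray:
        return np.diag(self.w)


@dataclass
class ClassificationSpace:
    """A low-dimensional projection space for network responses.

    ``basis`` is the N x m matrix B whose columns span the space (B = O for
    ETR, B = D^w O for OETR, an unmixing basis for ICA, L for SVDSep,
    leading concatenated-SVD patterns for SVDCon); ``fixed_points`` holds
    the m x m coordinates L^T B, one row per stimulus.
    """

    basis: np.ndarray
    fixed_points: np.ndarray
    method: str
    stimulus_order: list[str]
    objective: float | None = None
    converged: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def n_dim(self) -> int:
        return self.basis.shape[1]


def etr(L: LibraryMatrix | np.ndarray, tau: float = 0.0) -> ExclusiveBasis:
    """Exclusive threshold reduction of a library matrix.

    Row rule: keep the row's maximal element if it exceeds ``tau``
    (strictly), zero everything else in the row; ties go to the lowest
    stimulus index.  With ``tau = 0`` every row with a positive maximum is
    assigned.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    A = L.L if isinstance(L, LibraryMatrix) else np.asarray(L, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("library matrix must be finite")
    O = np.zeros_like(A)
    best = np.argmax(A, axis=1)  # lowest index wins ties
    rows = np.arange(A.shape[0])
    keep = A[rows, best] > tau
    O[rows[keep], best[keep]] = A[rows[keep], best[keep]]
    assignment = np.where(keep, best, UNASSIGNED)
    return ExclusiveBasis(O=O, tau=float(tau), assignment=assignment)


def oetr(L: LibraryMatrix | np.ndarray, basis: ExclusiveBasis) -> WeightVector:
    """Optimal node re-weighting: minimize ||L^T D^w O - I||_Fr over diag(D^w).

    The objective decouples over ETR clusters (columns of O have disjoint
    supports), so each cluster's weights solve an independent m x |cluster|
    least-squares problem; rank-deficient clusters get the minimum-norm
    solution.  Unassigned nodes receive weight 0 by convention.

    A stimulus with no assigned node leaves the corresponding identity
    column unreachable; a diagnostic warning is emitted and the minimizer
    over the remaining entries is still returned.
    """
    A = L.L if isinstance(L, LibraryMatrix) else np.asarray(L, dtype=float)
    O = basis.O
    n, m = A.shape
    if O.shape != (n, m):
        raise ValueError("library and exclusive basis shapes disagree")
    w = np.zeros(n)
    sq_residual = 0.0
    eye = np.eye(m)
    for j in range(m):
        members = np.flatnonzero(basis.assignment == j)
        if members.size == 0:
            warnings.warn(
                f"stimulus index {j} has no assigned node; identity column "
                "unreachable on that axis",
                stacklevel=2,
            )
            sq_residual += 1.0  # the untouched e_j column contributes ||e_j||^2
            continue
        # entry (i, j) of L^T D^w O restricted to this cluster:
        #   sum_{k in cluster} L[k, i] * O[k, j] * w_k
        M = A[members, :].T * O[members, j][None, :]  # m x |cluster|
        sol, *_ = np.linalg.lstsq(M, eye[:, j], rcond=None)
        w[members] = sol
        sq_residual += float(np.sum((M @ sol - eye[:, j]) ** 2))
    return WeightVector(w=w, objective=float(np.sqrt(sq_residual)))


def fixed_points(L: LibraryMatrix | np.ndarray, B: np.ndarray) -> np.ndarray:
    """Coordinates of the projected fixed points, L^T B (m x m)."""
    A = L.L if isinstance(L, LibraryMatrix) else np.asarray(L, dtype=float)
    return A.T @ B


def project(response: ResponseMatrix | np.ndarray, space: ClassificationSpace) -> np.ndarray:
    """Project a response onto the space: x(t) = B^T f(t), returned m x T."""
    F = response.rates if isinstance(response, ResponseMatrix) else np.asarray(response)
    return space.basis.T @ F


def ica_basis(
    L: LibraryMatrix,
    seed: int = 0,
    max_iter: int = 500,
) -> ClassificationSpace:
    """Infomax ICA comparison basis computed from L^T.

    The observed mixtures are the rows of L^T (one per stimulus, over
    nodes); extended-Infomax unmixing yields independent node-space
    components which, normalized, form the basis columns.  Non-convergence
    is flagged on the result rather than raised.
    """
    if L.n_stimuli < 2:
        raise ValueError("ICA needs at least 2 stimuli")
    from mne.preprocessing.infomax_ import infomax  # established Infomax impl

    X = L.L  # n_samples=nodes x n_features=stimuli view of L^T's columns
    # whiten (without centering, so the span of L is preserved); the bias
    # term of the natural-gradient update absorbs the nonzero mean
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if np.any(s < 1e-12 * s.max()):
        raise ValueError("library is rank deficient; ICA unmixing undefined")
    white = U * np.sqrt(X.shape[0])  # unit-variance decorrelated features
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        W, n_iter = infomax(
            white,
            rng=np.random.default_rng(seed),
            extended=False,
            max_iter=max_iter,
            return_n_iter=True,
            verbose="error",
        )
    if n_iter >= max_iter or any("converge" in str(c.message).lower() for c in caught):
        converged = False
    S = white @ W.T  # nodes x m independent components
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    B = S / norms
    B *= np.where(B.sum(axis=0) < 0, -1.0, 1.0)
    return ClassificationSpace(
        basis=B,
        fixed_points=fixed_points(L, B),
        method="ica",
        stimulus_order=list(L.stimulus_order),
        converged=converged,
        extras={"n_iter": int(n_iter)},
    )


def build_space(
    collection: ResponseCollection,
    method: str = "oetr",
    stimuli: Sequence[str] | None = None,
    tau: float = 0.0,
    seed: int = 0,
) -> ClassificationSpace:
    """Build a classification space from a collection with a named method.

    Methods: ``oetr`` (default), ``etr``, ``ica``, ``svdsep`` (raw library
    columns), ``svdcon`` (leading patterns of the concatenated SVD).
    """
    if stimuli is None:
        stimuli = list(collection.stimuli)
    stimuli = list(stimuli)
    if method == "svdcon":
        dec = svdcon(collection, stimuli)
        B = dec.patterns[:, : len(stimuli)]
        return ClassificationSpace(
            basis=B,
            fixed_points=np.zeros((len(stimuli), len(stimuli))),
            method="svdcon",
            stimulus_order=stimuli,
        )
    L = library_from_collection(collection, stimuli)
    if method == "svdsep":
        return ClassificationSpace(
            basis=L.L.copy(),
            fixed_points=fixed_points(L, L.L),
            method="svdsep",
            stimulus_order=stimuli,
        )
    if method == "ica":
        return ica_basis(L, seed=seed)
    basis = etr(L, tau)
    if method == "etr":
        B = basis.O
        return ClassificationSpace(
            basis=B,
            fixed_points=fixed_points(L, B),
            method="etr",
            stimulus_order=stimuli,
            extras={"tau": tau},
        )
    if method == "oetr":
        wv = oetr(L, basis)
        B = wv.as_diagonal() @ basis.O
        return ClassificationSpace(
            basis=B,
            fixed_points=fixed_points(L, B),
            method="oetr",
            stimulus_order=stimuli,
            objective=wv.objective,
            extras={"tau": tau},
        )
    raise ValueError(f"unknown method {method!r}")
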