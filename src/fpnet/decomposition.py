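"""SVD decompositions of response collections and library-matrix construction.

Two ways of decomposing a supervised collection are provided.  *SVDCon*
concatenates the per-stimulus (trial-averaged) response matrices along time
and takes a single SVD; *SVDSep* decomposes each stimulus's matrix
separately.  In both, the node-space singular vectors are the spatial
patterns g_k and the time courses a_k(t) = sigma_k * alpha_k(t) are their
coefficients, so that F = sum_k g_k a_k^T.  The relative energy of pattern k
is H_k = sigma_k^2 / sum_i sigma_i^2, which sums to one.

The *library matrix* L stacks the dominant (first) pattern of each
stimulus's separate decomposition as unit-norm columns, one column per
stimulus.  Its columns come from independent decompositions and are in
general non-orthogonal; downstream orthogonalization is the job of
:mod:`fpnet.classification_space`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import ResponseCollection

__all__ = [
    "EnergySpectrum",
    "Decomposition",
    "LibraryMatrix",
    "concat_collection",
    "svd_energy",
    "svdcon",
    "svdsep",
    "build_library",
    "library_from_collection",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised for inputs whose decomposition is undefined (e.g. all zeros)."""


@dataclass
class EnergySpectrum:
    """Singular values and their normalized energies H_k."""

    singular_values: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        h = np.asarray(self.energies, dtype=float)
        if np.any(s < 0) or np.any(np.diff(s) > 1e-12):
            raise ValueError("singular values must be nonnegative and nonincreasing")
        if abs(h.sum() - 1.0) > 1e-9:
            raise ValueError("energies must sum to 1")
        self.singular_values, self.energies = s, h


@dataclass
class Decomposition:
    """SVD of a nodes x time matrix: orthonormal node-space patterns plus
    time-dependent coefficients a_k(t) = sigma_k * alpha_k(t)."""

    patterns: np.ndarray  # N x k, columns orthonormal
    coefficients: np.ndarray  # k x T
    spectrum: EnergySpectrum

    def reconstruct(self) -> np.ndarray:
        return self.patterns @ self.coefficients


@dataclass
class LibraryMatrix:
    """Nodes x stimuli matrix of dominant per-stimulus patterns.

    Columns are unit norm and sign-oriented so that each column's entry sum
    is nonnegative (the dominant pattern of a nonnegative matrix always has
    such a representative); this makes the row-max rule of ETR meaningful.
    """

    L: np.ndarray
    stimulus_order: list[str]

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.ndim != 2:
            raise ValueError("L must be 2-D")
        if self.L.shape[1] != len(self.stimulus_order):
            raise ValueError("one column per stimulus required")

    @property
    def n_nodes(self) -> int:
        return self.L.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.L.shape[1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.L, columns=self.stimulus_order).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LibraryMatrix":
        df = pd.read_csv(path)
        return cls(L=df.to_numpy(dtype=float), stimulus_order=list(df.columns))


def concat_collection(
    collection: ResponseCollection, stimuli: Sequence[str] | None = None
) -> np.ndarray:
    """Time-wise concatenation of trial-averaged per-stimulus responses."""
    if stimuli is None:
        stimuli = collection.stimuli
    if not stimuli:
        raise ValueError("stimuli must be nonempty")
    return np.concatenate([collection.trial_average(s) for s in stimuli], axis=1)


def svd_energy(F: np.ndarray) -> EnergySpectrum:
    """Energy spectrum H_k = sigma_k^2 / sum sigma_i^2 of a matrix."""
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("matrix must be finite")
    s = np.linalg.svd(F, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DegenerateInputError("all-zero matrix has no energy spectrum")
    return EnergySpectrum(singular_values=s, energies=s**2 / total)


def _decompose(F: np.ndarray) -> Decomposition:
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("matrix must be finite")
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0:
        raise DegenerateInputError("all-zero matrix cannot be decomposed")
    spectrum = EnergySpectrum(singular_values=s, energies=s**2 / total)
    return Decomposition(patterns=U, coefficients=s[:, None] * Vt, spectrum=spectrum)


def svdcon(
    collection: ResponseCollection, stimuli: Sequence[str] | None = None
) -> Decomposition:
    """SVD of the concatenated collection matrix (single joint decomposition)."""
    return _decompose(concat_collection(collection, stimuli))


def svdsep(
    collection: ResponseCollection,
    stimuli: Sequence[str] | None = None,
    per_trial: bool = False,
) -> list[Decomposition]:
    """One SVD per stimulus matrix.

    By default each stimulus's trials are averaged before decomposition;
    with ``per_trial=True`` trials are concatenated along time instead.
    """
    if stimuli is None:
        stimuli = collection.stimuli
    if not stimuli:
        raise ValueError("stimuli must be nonempty")
    out = []
    for s in stimuli:
        if per_trial:
            F = np.concatenate(
                [rm.rates for rm in collection.trials[s]], axis=1
            )
        else:
            F = collection.trial_average(s)
        out.append(_decompose(F))
    return out


def build_library(
    decompositions: Sequence[Decomposition],
    stimulus_order: Sequence[str] | None = None,
) -> LibraryMatrix:
    """Stack the first pattern of each decomposition into a library matrix.

    Each column is the dominant node-space singular vector of one stimulus,
    sign-oriented to nonnegative entry sum.
    """
    if not decompositions:
        raise ValueError("need at least one decomposition")
    n = decompositions[0].patterns.shape[0]
    cols = []
    for d in decompositions:
        if d.patterns.shape[0] != n:
            raise ValueError("decompositions disagree on node count")
        v = d.patterns[:, 0].copy()
        if v.sum() < 0:
            v = -v
        cols.append(v)
    if stimulus_order is None:
        stimulus_order = [f"S{i + 1}" for i in range(len(cols))]
    return LibraryMatrix(L=np.column_stack(cols), stimulus_order=list(stimulus_order))


def library_from_collection(
    collection: ResponseCollection,
    stimuli: Sequence[str] | None = None,
    per_trial: bool = False,
) -> LibraryMatrix:
    """Convenience: SVDSep on a collection, then collect dominant patterns."""
    if stimuli is None:
        stimuli = collection.stimuli
    decs = svdsep(collection, stimuli, per_trial=per_trial)
    return build_library(decs, stimulus_order=stimuli)
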