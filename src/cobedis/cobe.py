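"""Common orthogonal basis extraction for one subject's multi-run data.

Each run is a regions-by-timepoints matrix treated as one block.  The block
is reduced to an orthonormal basis of its leading column space, and the
common directions are the leading eigenvectors of the sum of the block
subspace projectors: a unit vector ``a`` maximizing ``sum_n ||Q_n^T a||^2``
lies as close as possible to every block's retained subspace, and its
eigenvalue divided by the number of blocks is a fit score in [0, 1] that
equals 1 exactly when the direction is contained in every block.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "CobeError",
    "DegenerateInputError",
    "InvalidConfigError",
    "RankPolicy",
    "RunMatrix",
    "MultiRunStack",
    "CobeConfig",
    "CommonComponent",
    "RunResidual",
    "orthonormal_block_basis",
    "extract_common_components",
    "run_specific_residual",
    "deflate_stack",
]


class CobeError(ValueError):
    """Base error for the decomposition stage."""


class DegenerateInputError(CobeError):
    """Input matrix carries no signal (all zero after demeaning)."""


class InvalidConfigError(CobeError):
    """Configuration inconsistent with the data dimensions."""


@dataclasses.dataclass(frozen=True)
class RankPolicy:
    """How many leading directions to retain per block.

    ``kind`` is one of ``"energy"`` (smallest rank capturing at least
    ``value`` of the total squared singular values), ``"fixed"`` (exactly
    ``value`` directions) or ``"noise-floor"`` (singular values above
    ``value`` times the optimal median-based hard threshold for white
    noise; ``value`` = 1 is the Gavish-Donoho choice).  The noise-floor
    policy is the default: an energy fraction over-retains badly when the
    noise is spatially white, because most of the total energy then sits in
    the noise bulk.
    """

    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind == "energy":
            if not (0.0 < self.value <= 1.0):
                raise InvalidConfigError(
                    f"energy fraction must be in (0, 1], got {self.value}"
                )
        elif self.kind == "fixed":
            if int(self.value) != self.value or self.value < 1:
                raise InvalidConfigError(
                    f"fixed rank must be a positive integer, got {self.value}"
                )
        elif self.kind == "noise-floor":
            if self.value <= 0:
                raise InvalidConfigError("noise-floor multiplier must be positive")
        else:
            raise InvalidConfigError(f"unknown rank policy kind {self.kind!r}")

    @classmethod
    def energy(cls, fraction: float = 0.99) -> "RankPolicy":
        return cls("energy", float(fraction))

    @classmethod
    def fixed(cls, rank: int) -> "RankPolicy":
        return cls("fixed", int(rank))

    @classmethod
    def noise_floor(cls, multiplier: float = 1.0) -> "RankPolicy":
        return cls("noise-floor", float(multiplier))


def _median_hard_threshold(s: np.ndarray, shape: tuple[int, int]) -> float:
    """Optimal hard threshold for singular values under white noise,
    calibrated from the median singular value (Gavish & Donoho 2014)."""
    beta = min(shape) / max(shape)
    omega = 0.56 * beta**3 - 0.95 * beta**2 + 1.82 * beta + 1.43
    return omega * float(np.median(s))


def _as_matrix(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise CobeError(f"run values must be 2-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise CobeError("run values contain non-finite entries")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise CobeError(f"run matrix too small: shape {arr.shape}")
    return arr


@dataclasses.dataclass(frozen=True)
class RunMatrix:
    """One run: a P-regions x T-timepoints matrix."""

    subject_id: str
    run_index: int
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_matrix(self.values))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass(frozen=True)
class MultiRunStack:
    """All runs of one subject, sharing the region dimension."""

    subject_id: str
    runs: tuple[RunMatrix, ...]

    def __post_init__(self) -> None:
        runs = tuple(self.runs)
        object.__setattr__(self, "runs", runs)
        if len(runs) < 2:
            raise CobeError("a stack needs at least two runs")
        p = runs[0].n_regions
        if any(r.n_regions != p for r in runs):
            raise CobeError("all runs of a subject must share the region count")
        idx = [r.run_index for r in runs]
        if len(set(idx)) != len(idx):
            raise CobeError(f"duplicate run_index values: {sorted(idx)}")

    @property
    def n_regions(self) -> int:
        return self.runs[0].n_regions

    @property
    def n_runs(self) -> int:
        return len(self.runs)


_SIGN_RULES = ("max-abs-positive", "none")


@dataclasses.dataclass(frozen=True)
class CobeConfig:
    n_components: int = 1
    rank_policy: RankPolicy = RankPolicy.noise_floor()
    tol: float = 1e-10
    max_iter: int = 100
    sign_rule: str = "max-abs-positive"
    demean_rows: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise InvalidConfigError("n_components must be >= 1")
        if self.tol <= 0:
            raise InvalidConfigError("tol must be positive")
        if self.max_iter < 1:
            raise InvalidConfigError("max_iter must be >= 1")
        if self.sign_rule not in _SIGN_RULES:
            raise InvalidConfigError(
                f"sign_rule must be one of {_SIGN_RULES}, got {self.sign_rule!r}"
            )


@dataclasses.dataclass(frozen=True)
class CommonComponent:
    """Result of the extraction.

    ``weights`` is P x C with orthonormal columns; ``run_timecourses`` holds
    one T_n x C matrix per run (least-squares coefficients of the runs on the
    common basis); ``fit_scores`` is the per-component eigenvalue divided by
    the number of runs.  ``eigen_tie`` flags a numerically tied eigenvalue at
    the cut, in which case the returned columns are one valid choice among
    equally good ones.
    """

    subject_id: str
    weights: np.ndarray
    run_timecourses: tuple[np.ndarray, ...]
    fit_scores: np.ndarray
    eigen_tie: bool = False

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]


@dataclasses.dataclass(frozen=True)
class RunResidual:
    subject_id: str
    run_index: int
    values: np.ndarray


def _demean_rows(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=1, keepdims=True)


def orthonormal_block_basis(
    run: RunMatrix, rank_policy: RankPolicy, demean_rows: bool = True
) -> np.ndarray:
    """Orthonormal basis of the leading column space of one run.

    Returns a P x r matrix with orthonormal columns spanning the leading
    r-dimensional left singular subspace of the (optionally row-demeaned)
    run, with r set by ``rank_policy``.
    """
    x = _demean_rows(run.values) if demean_rows else run.values
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0.0:
        raise DegenerateInputError(
            f"run {run.run_index} of subject {run.subject_id} is all-zero"
            + (" after row demeaning" if demean_rows else "")
        )
    n_positive = int(np.sum(s > s[0] * 1e-12))
    if rank_policy.kind == "fixed":
        r = int(rank_policy.value)
        if r > min(x.shape):
            raise InvalidConfigError(
                f"fixed rank {r} exceeds min(P, T) = {min(x.shape)}"
            )
    elif rank_policy.kind == "energy":
        cum = np.cumsum(s**2) / total
        r = int(np.argmax(cum >= rank_policy.value - 1e-12)) + 1
    else:  # noise-floor
        thresh = rank_policy.value * _median_hard_threshold(s, x.shape)
        r = int(np.sum(s > thresh))
    r = max(1, min(r, n_positive))
    return u[:, :r]


def extract_common_components(
    stack: MultiRunStack, config: CobeConfig | None = None
) -> CommonComponent:
    """Extract the direction(s) best shared by all runs of one subject.

    The c-th weight column is the c-th leading eigenvector of
    ``M = sum_n Q_n Q_n^T`` where ``Q_n`` is the block basis of run n; the
    solver is a deterministic dense symmetric eigendecomposition, so results
    do not depend on any seed.
    """
    if config is None:
        config = CobeConfig()
    c = config.n_components
    p = stack.n_regions
    if c > p:
        raise InvalidConfigError(f"n_components {c} exceeds region count {p}")

    bases = [
        orthonormal_block_basis(run, config.rank_policy, config.demean_rows)
        for run in stack.runs
    ]
    m = np.zeros((p, p))
    for q in bases:
        m += q @ q.T
    evals, evecs = scipy.linalg.eigh(m)
    evals = evals[::-1]
    evecs = evecs[:, ::-1]

    rank = int(np.sum(evals > config.tol * max(evals[0], 1.0)))
    if c > rank:
        raise CobeError(
            f"requested {c} common components but the summed projector has "
            f"numerical rank {rank}; at most {rank} are achievable"
        )

    weights = np.ascontiguousarray(evecs[:, :c])
    fit_scores = np.clip(evals[:c] / stack.n_runs, 0.0, 1.0)
    eigen_tie = bool(c < p and (evals[c - 1] - evals[c]) < 1e-10)

    if config.sign_rule == "max-abs-positive":
        for j in range(c):
            k = int(np.argmax(np.abs(weights[:, j])))
            if weights[k, j] < 0:
                weights[:, j] = -weights[:, j]

    timecourses = []
    for run in stack.runs:
        x = _demean_rows(run.values) if config.demean_rows else run.values
        timecourses.append(x.T @ weights)

    return CommonComponent(
        subject_id=stack.subject_id,
        weights=weights,
        run_timecourses=tuple(timecourses),
        fit_scores=fit_scores,
        eigen_tie=eigen_tie,
    )


def run_specific_residual(
    stack: MultiRunStack, comp: CommonComponent
) -> list[RunResidual]:
    """Per-run residual after removing the common-subspace projection.

    ``residual_n = R_n - A (A^T R_n)``; adding the projection back
    reconstructs the run exactly.
    """
    if comp.weights.shape[0] != stack.n_regions:
        raise CobeError(
            f"component has {comp.weights.shape[0]} regions, "
            f"stack has {stack.n_regions}"
        )
    if comp.subject_id != stack.subject_id:
        raise CobeError("component and stack belong to different subjects")
    out = []
    a = comp.weights
    for run in stack.runs:
        proj = a @ (a.T @ run.values)
        out.append(
            RunResidual(
                subject_id=stack.subject_id,
                run_index=run.run_index,
                values=run.values - proj,
            )
        )
    return out


def deflate_stack(stack: MultiRunStack, weights: np.ndarray) -> MultiRunStack:
    """Remove the span of ``weights`` from every run (used for sequential
    single-component extraction)."""
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    if w.shape[0] != stack.n_regions:
        w = w.T
    if w.shape[0] != stack.n_regions:
        raise CobeError("deflation weights do not match the region count")
    runs = []
    for run in stack.runs:
        vals = run.values - w @ (w.T @ run.values)
        runs.append(RunMatrix(run.subject_id, run.run_index, vals))
    return MultiRunStack(stack.subject_id, tuple(runs))
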