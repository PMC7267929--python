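"""Subject-by-subject component correlation and dissimilar-subset selection.

The selection is a randomized maximal-set growth: seed with a uniformly
drawn pair whose absolute correlation is below the threshold, keep adding a
uniformly drawn subject that is below threshold against every current
member, stop when none qualifies.  Many restarts are run from one seeded
stream and the set with the smallest within-set maximum absolute
correlation wins (ties broken toward larger, then lexicographically
smaller, sets).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "SelectionError",
    "ComponentMatrix",
    "CommonCorrelationMatrix",
    "McdConfig",
    "McdResult",
    "common_correlation_matrix",
    "grow_dissimilar_set",
    "select_mcd",
    "subject_dissimilarity_score",
]


class SelectionError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ComponentMatrix:
    """First common component of every subject, one unit-norm column each.

    Columns are normalized on construction so that correlation and
    summarization downstream see a consistent scale.
    """

    subject_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.subject_ids)
        object.__setattr__(self, "subject_ids", ids)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise SelectionError("weights must be a P x S matrix")
        if w.shape[1] != len(ids):
            raise SelectionError(
                f"{w.shape[1]} weight columns for {len(ids)} subject ids"
            )
        if len(set(ids)) != len(ids):
            raise SelectionError("subject ids must be unique")
        if len(ids) < 2:
            raise SelectionError("need at least two subjects")
        norms = np.linalg.norm(w, axis=0)
        if np.any(norms == 0):
            bad = [ids[i] for i in np.flatnonzero(norms == 0)]
            raise SelectionError(f"all-zero weight column(s) for {bad}")
        object.__setattr__(self, "weights", w / norms)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[1]


@dataclasses.dataclass(frozen=True)
class CommonCorrelationMatrix:
    subject_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.subject_ids)
        object.__setattr__(self, "subject_ids", ids)
        r = np.asarray(self.r, dtype=float)
        s = len(ids)
        if r.shape != (s, s):
            raise SelectionError(f"matrix shape {r.shape} for {s} subjects")
        if not np.allclose(r, r.T, atol=1e-12):
            raise SelectionError("correlation matrix is not symmetric")
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise SelectionError("correlation entries outside [-1, 1]")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise SelectionError("correlation diagonal is not one")
        object.__setattr__(self, "r", r)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def index_of(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise SelectionError(f"unknown subject id {subject_id!r}") from None


def common_correlation_matrix(components: ComponentMatrix) -> CommonCorrelationMatrix:
    """Pearson correlation of the weight maps between every pair of subjects."""
    w = components.weights
    if w.shape[0] < 3:
        raise SelectionError("need at least 3 regions for Pearson correlation")
    stds = w.std(axis=0)
    if np.any(stds == 0):
        bad = [components.subject_ids[i] for i in np.flatnonzero(stds == 0)]
        raise SelectionError(f"constant weight column(s) for subject(s) {bad}")
    r = np.corrcoef(w, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CommonCorrelationMatrix(components.subject_ids, r)


@dataclasses.dataclass(frozen=True)
class McdConfig:
    threshold: float = 0.75
    n_restarts: int = 1000
    seed: int = 0
    tie_break: str = "maxcorr-size-lex"

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise SelectionError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.n_restarts < 1:
            raise SelectionError("n_restarts must be >= 1")
        if self.tie_break != "maxcorr-size-lex":
            raise SelectionError(f"unknown tie_break {self.tie_break!r}")


@dataclasses.dataclass(frozen=True)
class McdResult:
    mcd_ids: tuple[str, ...]
    cs_ids: tuple[str, ...]
    max_abs_corr_within: float
    restart_log: tuple[tuple[int, float], ...]
    config: McdConfig

    @property
    def mcd_size(self) -> int:
        return len(self.mcd_ids)


def _grow_indices(
    adj: np.ndarray, rng: np.random.Generator
) -> list[int]:
    """Grow one maximal set on the qualification graph ``adj``."""
    pairs = np.argwhere(np.triu(adj, k=1))
    if len(pairs) == 0:
        return []
    i, j = pairs[rng.integers(len(pairs))]
    members = [int(i), int(j)]
    candidates = adj[i] & adj[j]
    candidates[i] = candidates[j] = False
    while candidates.any():
        options = np.flatnonzero(candidates)
        k = int(options[rng.integers(len(options))])
        members.append(k)
        candidates &= adj[k]
        candidates[k] = False
    return members


def grow_dissimilar_set(
    corr: CommonCorrelationMatrix,
    threshold: float,
    rng: np.random.Generator,
) -> frozenset[str]:
    """One randomized maximal dissimilar set; empty if no pair qualifies."""
    adj = np.abs(corr.r) < threshold
    np.fill_diagonal(adj, False)
    members = _grow_indices(adj, rng)
    return frozenset(corr.subject_ids[i] for i in members)


def _within_max_abs(r: np.ndarray, members: Sequence[int]) -> float:
    sub = np.abs(r[np.ix_(members, members)])
    return float(np.max(sub[np.triu_indices(len(members), k=1)]))


def select_mcd(
    corr: CommonCorrelationMatrix, config: McdConfig | None = None
) -> McdResult:
    """Best-of-restarts dissimilar set and its complement.

    Deterministic for a fixed config: all restarts consume one RNG stream
    seeded from ``config.seed``, and candidate sets are ranked by
    (within-set max |r|, -size, sorted id list).
    """
    if config is None:
        config = McdConfig()
    adj = np.abs(corr.r) < config.threshold
    np.fill_diagonal(adj, False)
    rng = np.random.default_rng(config.seed)

    best_key = None
    best_members: list[int] | None = None
    best_max = np.nan
    log = []
    for _ in range(config.n_restarts):
        members = _grow_indices(adj, rng)
        if not members:
            log.append((0, float("nan")))
            continue
        mx = _within_max_abs(corr.r, members)
        log.append((len(members), mx))
        key = (mx, -len(members), tuple(sorted(members)))
        if best_key is None or key < best_key:
            best_key = key
            best_members = members
            best_max = mx
    if best_members is None:
        raise SelectionError(
            f"no subject pair with |r| < {config.threshold}; cannot form a set"
        )
    chosen = set(best_members)
    mcd = tuple(s for i, s in enumerate(corr.subject_ids) if i in chosen)
    cs = tuple(s for i, s in enumerate(corr.subject_ids) if i not in chosen)
    return McdResult(
        mcd_ids=mcd,
        cs_ids=cs,
        max_abs_corr_within=best_max,
        restart_log=tuple(log),
        config=config,
    )


def subject_dissimilarity_score(
    corr: CommonCorrelationMatrix, subject_id: str
) -> float:
    """Mean |r| between one subject and all others (lower = more dissimilar)."""
    if corr.n_subjects < 2:
        raise SelectionError("need at least two subjects")
    i = corr.index_of(subject_id)
    row = np.abs(np.delete(corr.r[i], i))
    return float(row.mean())
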