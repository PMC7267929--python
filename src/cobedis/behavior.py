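"""Behavioral battery comparisons between subject groups.

All measures are compared with a two-sided Welch test by default (the
batteries mix counts, percentages and questionnaire scores with unequal
group sizes); the familywise threshold is alpha divided by the number of
measures actually tested.  A sex-matched random subset of the comparison
group (RSSM) supports re-testing group effects under matched sex
composition.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .networks import NetworkWeightTable, compare_network_weights
from .stats import sem, two_sample_test

__all__ = [
    "BehaviorError",
    "BehaviorTable",
    "SexCompositionResult",
    "compare_behaviors",
    "sex_composition_test",
    "draw_rssm",
    "compare_mcd_vs_rssm",
    "correlate_dissimilarity_with_behaviors",
]

SEX_LEVELS = ("male", "female")


class BehaviorError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class BehaviorTable:
    """Subject x measure values plus sex, with measure -> category tags.

    Complete-case contract: missing values in any measure column are
    rejected at construction.
    """

    frame: pd.DataFrame  # index subject_id; columns: sex + measures
    categories: Mapping[str, str]

    def __post_init__(self) -> None:
        if "sex" not in self.frame.columns:
            raise BehaviorError("behavior table needs a 'sex' column")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()].tolist()
            raise BehaviorError(f"duplicate subject ids: {dup[:5]}")
        bad_sex = set(self.frame["sex"]) - set(SEX_LEVELS)
        if bad_sex:
            raise BehaviorError(f"unknown sex values: {sorted(bad_sex)}")
        measures = [c for c in self.frame.columns if c != "sex"]
        if not measures:
            raise BehaviorError("no measure columns")
        block = self.frame[measures]
        if block.isna().any().any():
            bad = block.columns[block.isna().any()].tolist()
            raise BehaviorError(f"missing values in measure(s): {bad}")
        cats = dict(self.categories)
        untagged = [m for m in measures if m not in cats]
        if untagged:
            raise BehaviorError(f"measures without a category: {untagged}")
        object.__setattr__(self, "categories", cats)
        frame = self.frame.copy()
        frame.index = frame.index.astype(str)
        frame.index.name = "subject_id"
        object.__setattr__(self, "frame", frame)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(c for c in self.frame.columns if c != "sex")

    @property
    def sex(self) -> pd.Series:
        return self.frame["sex"]


def compare_behaviors(
    behaviors: BehaviorTable,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
    measures: Sequence[str] | None = None,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-measure two-sided group comparison with Bonferroni flags."""
    a_ids = [str(s) for s in group_a_ids]
    b_ids = [str(s) for s in group_b_ids]
    if not a_ids or not b_ids:
        raise BehaviorError("both groups must be non-empty")
    if set(a_ids) & set(b_ids):
        raise BehaviorError("groups overlap")
    tested = tuple(measures) if measures is not None else behaviors.measures
    if not tested:
        raise BehaviorError("empty measure list")
    unknown = [m for m in tested if m not in behaviors.measures]
    if unknown:
        raise BehaviorError(f"unknown measure(s): {unknown}")
    fa = behaviors.frame.loc[a_ids]
    fb = behaviors.frame.loc[b_ids]
    m = len(tested)
    rows = []
    for meas in tested:
        a = fa[meas].to_numpy(dtype=float)
        b = fb[meas].to_numpy(dtype=float)
        stat, p, degenerate = two_sample_test(a, b, method=method)
        rows.append(
            {
                "measure": meas,
                "category": behaviors.categories[meas],
                "mean_mcd": float(a.mean()),
                "sem_mcd": sem(a),
                "mean_cs": float(b.mean()),
                "sem_cs": sem(b),
                "statistic": stat,
                "p_raw": p,
                "significant": bool(p < alpha / m),
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["family_size"] = m
    out.attrs["alpha"] = alpha
    return out


@dataclasses.dataclass(frozen=True)
class SexCompositionResult:
    counts: np.ndarray  # 2 x 2, rows = groups, cols = (male, female)
    statistic: float
    df: int
    p: float


def sex_composition_test(
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    sex: Mapping[str, str] | pd.Series,
) -> SexCompositionResult:
    """Pearson chi-square (no continuity correction) on the 2x2 group-by-sex
    table."""
    sex_map = dict(sex)
    counts = np.zeros((2, 2), dtype=int)
    for row, ids in enumerate((group_a_ids, group_b_ids)):
        for s in ids:
            label = sex_map[str(s)]
            counts[row, SEX_LEVELS.index(label)] += 1
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise BehaviorError(f"contingency table has an all-zero margin:\n{counts}")
    stat, p, df, _ = scipy.stats.chi2_contingency(counts, correction=False)
    return SexCompositionResult(counts=counts, statistic=float(stat), df=int(df), p=float(p))


def draw_rssm(
    cs_ids: Sequence[str],
    sex: Mapping[str, str] | pd.Series,
    target_counts: Mapping[str, int],
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Uniform draw without replacement of a sex-matched subset of CS."""
    sex_map = dict(sex)
    chosen: list[str] = []
    for level in SEX_LEVELS:
        want = int(target_counts.get(level, 0))
        pool = sorted(s for s in map(str, cs_ids) if sex_map[s] == level)
        if want > len(pool):
            raise BehaviorError(
                f"need {want} {level} subjects but CS has only {len(pool)} "
                f"(shortfall {want - len(pool)})"
            )
        if want:
            chosen.extend(rng.choice(pool, size=want, replace=False))
    return tuple(sorted(chosen))


def compare_mcd_vs_rssm(
    behaviors: BehaviorTable,
    network_table: NetworkWeightTable,
    mcd_ids: Sequence[str],
    rssm_ids: Sequence[str],
    alpha: float = 0.05,
    measure_subset: Sequence[str] | None = None,
    network_label: str = "DMN-A",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the behavior battery and the focal network contrast against a
    sex-matched CS subset.

    ``measure_subset`` defaults to the measures flagged in the full
    comparison and must be non-empty.
    """
    if set(map(str, mcd_ids)) & set(map(str, rssm_ids)):
        raise BehaviorError("MCD and RSSM sets overlap")
    if measure_subset is None:
        full = compare_behaviors(behaviors, mcd_ids, rssm_ids, alpha=alpha)
        measure_subset = full.loc[full["significant"], "measure"].tolist()
    if not list(measure_subset):
        raise BehaviorError("empty measure subset")
    behav = compare_behaviors(
        behaviors, mcd_ids, rssm_ids, alpha=alpha, measures=measure_subset
    )
    focal = NetworkWeightTable(network_table.frame[[network_label]])
    net = compare_network_weights(focal, mcd_ids, rssm_ids, alpha=alpha)
    return behav, net


def correlate_dissimilarity_with_behaviors(
    scores: Mapping[str, float] | pd.Series,
    behaviors: BehaviorTable,
    measure_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson r (with two-sided p) between a per-subject dissimilarity
    score and each measure, over the subjects present in ``scores``."""
    scores = pd.Series(dict(scores), dtype=float)
    scores.index = scores.index.astype(str)
    if len(scores) < 3:
        raise BehaviorError("need at least 3 subjects")
    if scores.std() == 0:
        raise BehaviorError("dissimilarity scores are constant")
    tested = tuple(measure_subset) if measure_subset is not None else behaviors.measures
    frame = behaviors.frame.loc[scores.index]
    rows = []
    for meas in tested:
        vals = frame[meas].to_numpy(dtype=float)
        if np.std(vals) == 0:
            r, p = float("nan"), float("nan")
        else:
            r, p = scipy.stats.pearsonr(scores.to_numpy(), vals)
        rows.append({"measure": meas, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
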