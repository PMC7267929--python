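"""Network-level summaries of component weights and group contrasts."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import ParcellationError, ParcellationLookup
from .selection import ComponentMatrix
from .stats import sem, two_sample_test

__all__ = [
    "NetworkWeightTable",
    "summarize_weights_by_network",
    "compare_network_weights",
]


@dataclasses.dataclass(frozen=True)
class NetworkWeightTable:
    """Subjects x labels matrix of mean component weights."""

    frame: pd.DataFrame  # index: subject_id, columns: labels

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)


def summarize_weights_by_network(
    components: ComponentMatrix, lookup: ParcellationLookup
) -> NetworkWeightTable:
    """Mean weight per network label for every subject.

    Hemispheres sharing a label are merged by construction (the mean runs
    over all regions carrying the label).
    """
    if lookup.n_regions != components.n_regions:
        missing = sorted(
            set(range(1, components.n_regions + 1))
            - set(lookup.frame["region_index"])
        )
        raise ParcellationError(
            f"lookup covers {lookup.n_regions} regions but components have "
            f"{components.n_regions}; unmapped region indices: {missing}"
        )
    labels = lookup.labels
    w = components.weights  # P x S
    data = {}
    for lab in labels:
        rows = lookup.regions_with_label(lab)
        data[lab] = w[rows].mean(axis=0)
    frame = pd.DataFrame(data, index=list(components.subject_ids))
    frame.index.name = "subject_id"
    return NetworkWeightTable(frame)


def compare_network_weights(
    table: NetworkWeightTable,
    group_a_ids: Sequence[str],
    group_b_ids: Sequence[str],
    alpha: float = 0.05,
    method: str = "welch",
) -> pd.DataFrame:
    """Per-label two-sided group comparison with Bonferroni flags.

    Returns one row per label with group means, standard errors, the test
    statistic, the raw p value and a ``significant`` flag set when
    ``p_raw < alpha / n_labels``.
    """
    a_ids = [str(s) for s in group_a_ids]
    b_ids = [str(s) for s in group_b_ids]
    if not a_ids or not b_ids:
        raise ValueError("both groups must be non-empty")
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    fa = table.frame.loc[a_ids]
    fb = table.frame.loc[b_ids]
    if len(fa) < 2 or len(fb) < 2:
        raise ValueError("each group needs at least two subjects per label")
    m = len(table.labels)
    rows = []
    for lab in table.labels:
        a = fa[lab].to_numpy()
        b = fb[lab].to_numpy()
        stat, p, degenerate = two_sample_test(a, b, method=method)
        rows.append(
            {
                "label": lab,
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
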