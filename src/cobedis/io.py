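"""Plain-text readers and writers for every pipeline artifact.

All formats are delimited text: run matrices are headerless TSV (P rows x T
columns), referenced from a manifest CSV; components, correlation matrices,
lookups and result tables are TSV/CSV with headers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorTable
from .cobe import CobeError, MultiRunStack, RunMatrix
from .selection import CommonCorrelationMatrix, ComponentMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "load_stacks",
    "write_components",
    "read_components",
    "write_correlation",
    "read_correlation",
    "write_groups",
    "read_groups",
    "read_behavior_table",
]


def read_matrix(path: str | Path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return arr


def write_matrix(path: str | Path, values: np.ndarray) -> None:
    np.savetxt(path, values, fmt="%.10g", delimiter="\t")


def read_manifest(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject_id", "run_index", "path"}
    missing = required - set(frame.columns)
    if missing:
        raise CobeError(f"manifest missing columns {sorted(missing)}")
    return frame


def load_stacks(
    manifest: pd.DataFrame, base_dir: str | Path
) -> dict[str, MultiRunStack]:
    """Load every subject's runs listed in the manifest.

    Raises on inconsistent region counts, naming the offending file.
    """
    base = Path(base_dir)
    stacks: dict[str, MultiRunStack] = {}
    for sid, grp in manifest.groupby("subject_id", sort=False):
        runs = []
        p_expected: int | None = None
        for _, row in grp.sort_values("run_index").iterrows():
            fpath = base / row["path"]
            values = read_matrix(fpath)
            if p_expected is None:
                p_expected = values.shape[0]
            elif values.shape[0] != p_expected:
                raise CobeError(
                    f"{fpath} has {values.shape[0]} rows, expected {p_expected} "
                    f"for subject {sid}"
                )
            runs.append(RunMatrix(str(sid), int(row["run_index"]), values))
        stacks[str(sid)] = MultiRunStack(str(sid), tuple(runs))
    return stacks


def write_components(path: str | Path, components: ComponentMatrix) -> None:
    """TSV: region_index then one column per subject (first component)."""
    frame = pd.DataFrame(
        components.weights,
        columns=[f"{sid}:1" for sid in components.subject_ids],
    )
    frame.insert(0, "region_index", np.arange(1, components.n_regions + 1))
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_components(path: str | Path) -> ComponentMatrix:
    frame = pd.read_csv(path, sep="\t")
    cols = [c for c in frame.columns if c != "region_index"]
    ids = [c.rsplit(":", 1)[0] for c in cols]
    return ComponentMatrix(tuple(ids), frame[cols].to_numpy(dtype=float))


def write_correlation(path: str | Path, corr: CommonCorrelationMatrix) -> None:
    frame = pd.DataFrame(
        corr.r, index=list(corr.subject_ids), columns=list(corr.subject_ids)
    )
    frame.index.name = "subject_id"
    frame.to_csv(path, sep="\t", float_format="%.12g")


def read_correlation(path: str | Path) -> CommonCorrelationMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    r = frame.to_numpy(dtype=float)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CommonCorrelationMatrix(tuple(str(c) for c in frame.columns), r)


def write_groups(
    path: str | Path, mcd_ids: Sequence[str], cs_ids: Sequence[str]
) -> None:
    rows = [{"subject_id": s, "group": "MCD"} for s in mcd_ids]
    rows += [{"subject_id": s, "group": "CS"} for s in cs_ids]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_groups(path: str | Path) -> tuple[tuple[str, ...], tuple[str, ...]]:
    frame = pd.read_csv(path, dtype=str)
    mcd = tuple(frame.loc[frame["group"] == "MCD", "subject_id"])
    cs = tuple(frame.loc[frame["group"] == "CS", "subject_id"])
    return mcd, cs


def read_behavior_table(
    behaviors_path: str | Path, categories_path: str | Path
) -> BehaviorTable:
    frame = pd.read_csv(behaviors_path, index_col="subject_id")
    frame.index = frame.index.astype(str)
    cats = pd.read_csv(categories_path, sep="\t")
    categories: Mapping[str, str] = dict(zip(cats["measure"], cats["category"]))
    return BehaviorTable(frame, categories)
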