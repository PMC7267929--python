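"""Synthetic multi-run datasets with planted structure.

Every subject gets a spatial map shared by all of their runs.  Majority
subjects perturb a common template (elevated weights on the DMN-A-analog
label) with small jitter, so their maps correlate strongly; subgroup
subjects get the template with the DMN-A-analog weights reduced and a large
idiosyncratic perturbation, so their maps are mutually dissimilar and the
dissimilarity-selection stage can recover them.  Runs are the planted map
times an AR(1) time course, plus run-specific low-rank structure and white
noise.  Behavioral measures carry configurable group effects on five
substance-use / antisocial-like measures and null effects elsewhere; sex is
drawn with group imbalance.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorTable
from .cobe import MultiRunStack, RunMatrix
from .parcellation import ParcellationLookup, make_lookup, write_lookup

__all__ = [
    "MeasureSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "default_battery",
    "build_template",
    "generate_subject_map",
    "generate_runs",
    "generate_behaviors",
    "generate_dataset",
]

MAJORITY = "majority"
SUBGROUP = "subgroup"


@dataclasses.dataclass(frozen=True)
class MeasureSpec:
    """One behavioral measure: group means, spread, optional male shift.

    ``clip_zero`` truncates negative draws at zero (count-like measures);
    ``sex_shift`` is added to male subjects regardless of group, which lets
    tests plant sex-confounded effects.
    """

    name: str
    category: str
    mean_majority: float
    mean_subgroup: float
    sd: float
    clip_zero: bool = False
    sex_shift: float = 0.0


# Group means of the planted substance-use measures follow the reported
# cohort contrasts; spreads are chosen so a ~16 vs ~104 split has high power
# at the Bonferroni threshold.
_PLANTED = (
    MeasureSpec("Total_Drinks_7_Days", "substance use", 4.84, 10.11, 3.0, True),
    MeasureSpec("Total_Any_Tobacco_7_Days", "substance use", 5.97, 18.05, 6.0, True),
    MeasureSpec("SSAGA_Mj_Times_Used", "substance use", 1.35, 4.59, 1.5, True),
    MeasureSpec("SSAGA_Times_Used_Illicits", "substance use", 0.53, 2.19, 0.8, True),
    MeasureSpec("DSM_Antis_Pct", "psychiatric & life function", 52.0, 58.0, 3.0, True),
)

_NULL_CATEGORIES = (
    ("alertness", 5),
    ("cognition", 12),
    ("emotion", 9),
    ("personality", 5),
    ("sensory", 6),
    ("health/family history", 8),
    ("psychiatric & life function", 8),
    ("substance use", 4),
    ("physiological", 7),
)


def default_battery() -> tuple[MeasureSpec, ...]:
    """69 measures: 5 with planted group effects, 64 nulls."""
    specs = list(_PLANTED)
    for category, count in _NULL_CATEGORIES:
        tag = "".join(w[:4].capitalize() for w in category.replace("/", " ").split())
        for i in range(1, count + 1):
            specs.append(MeasureSpec(f"{tag}_{i:02d}", category, 50.0, 50.0, 10.0))
    return tuple(specs)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    n_regions: int = 100
    n_subjects: int = 120
    subgroup_size: int = 16
    n_runs: int = 4
    n_timepoints: int = 300
    k_individual: int = 5
    noise_sd: float = 0.5
    map_jitter: float = 0.1
    dmn_reduction: float = 0.15
    subgroup_scatter: float = 0.5
    ar_coefficient: float = 0.9
    template_boost: float = 1.25
    dmn_label: str = "DMN-A"
    p_male_subgroup: float = 74 / 107
    p_male_majority: float = 323 / 681
    battery: tuple[MeasureSpec, ...] = dataclasses.field(default_factory=default_battery)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.subgroup_size < self.n_subjects):
            raise ValueError("subgroup_size must be in [0, n_subjects)")
        if self.dmn_reduction < 0 or self.noise_sd < 0:
            raise ValueError("dmn_reduction and noise_sd must be >= 0")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("ar_coefficient must be in [0, 1)")
        for p in (self.p_male_subgroup, self.p_male_majority):
            if not (0.0 <= p <= 1.0):
                raise ValueError("sex probabilities must be in [0, 1]")
        if self.map_jitter < 0 or self.subgroup_scatter < 0:
            raise ValueError("map_jitter and subgroup_scatter must be >= 0")
        if self.k_individual < 0:
            raise ValueError("k_individual must be >= 0")


def build_template(lookup: ParcellationLookup, config: SimulationConfig) -> np.ndarray:
    """Unnormalized base map: zero everywhere except the DMN-A-analog boost.

    Keeping the other label means at zero means the subgroup's idiosyncratic
    scatter (which rescales the whole map through unit-normalization) moves
    only the boosted label's mean; group contrasts outside it stay null.
    """
    t = np.zeros(lookup.n_regions)
    t[lookup.regions_with_label(config.dmn_label)] = config.template_boost
    return t


def generate_subject_map(
    config: SimulationConfig,
    lookup: ParcellationLookup,
    group_label: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """One subject's planted unit-norm spatial map."""
    t = build_template(lookup, config)
    if group_label == SUBGROUP:
        t[lookup.regions_with_label(config.dmn_label)] -= config.dmn_reduction
        noise_scale = config.subgroup_scatter
    elif group_label == MAJORITY:
        noise_scale = config.map_jitter
    else:
        raise ValueError(f"unknown group label {group_label!r}")
    v = t + noise_scale * rng.standard_normal(len(t))
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("degenerate zero map; check template_boost")
    return v / norm


def _ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean AR(1) series with unit innovation variance."""
    x = np.empty(n)
    scale = 1.0 / np.sqrt(1.0 - phi**2) if phi else 1.0
    x[0] = scale * rng.standard_normal()
    eps = rng.standard_normal(n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x - x.mean()


def generate_runs(
    true_map: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str = "sub",
) -> MultiRunStack:
    """Runs sharing ``true_map`` plus run-specific components and noise."""
    a = np.asarray(true_map, dtype=float)
    p, t_len = len(a), config.n_timepoints
    runs = []
    for n in range(1, config.n_runs + 1):
        y = _ar1(t_len, config.ar_coefficient, rng)
        r = np.outer(a, y)
        for _ in range(config.k_individual):
            b = rng.standard_normal(p)
            b -= a * (a @ b)  # run-specific maps orthogonal to the shared map
            b /= np.linalg.norm(b)
            u = _ar1(t_len, config.ar_coefficient, rng)
            r += np.outer(b, u)
        if config.noise_sd:
            r += config.noise_sd * rng.standard_normal((p, t_len))
        runs.append(RunMatrix(subject_id, n, r))
    return MultiRunStack(subject_id, tuple(runs))


def generate_behaviors(
    subject_ids: Sequence[str],
    true_labels: Sequence[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> BehaviorTable:
    """Behavior table with planted group effects and imbalanced sex."""
    ids = [str(s) for s in subject_ids]
    labels = list(true_labels)
    if len(ids) != len(labels):
        raise ValueError("subject_ids and true_labels lengths differ")
    sex = []
    for lab in labels:
        p_male = config.p_male_subgroup if lab == SUBGROUP else config.p_male_majority
        sex.append("male" if rng.random() < p_male else "female")
    data: dict[str, list] = {"sex": sex}
    for spec in config.battery:
        means = np.array(
            [
                spec.mean_subgroup if lab == SUBGROUP else spec.mean_majority
                for lab in labels
            ]
        )
        vals = means + spec.sd * rng.standard_normal(len(ids))
        if spec.sex_shift:
            vals = vals + spec.sex_shift * (np.array(sex) == "male")
        if spec.clip_zero:
            vals = np.maximum(vals, 0.0)
        data[spec.name] = vals
    frame = pd.DataFrame(data, index=ids)
    categories = {spec.name: spec.category for spec in config.battery}
    return BehaviorTable(frame, categories)


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    config: SimulationConfig
    lookup: ParcellationLookup
    subject_ids: tuple[str, ...]
    true_labels: tuple[str, ...]
    true_maps: np.ndarray  # P x S
    stacks: tuple[MultiRunStack, ...]
    behaviors: BehaviorTable

    @property
    def subgroup_ids(self) -> tuple[str, ...]:
        return tuple(
            s for s, lab in zip(self.subject_ids, self.true_labels) if lab == SUBGROUP
        )

    def write(self, out_dir: str | os.PathLike) -> Path:
        """Write the exact plain-text inputs consumed by the pipeline."""
        out = Path(out_dir)
        (out / "runs").mkdir(parents=True, exist_ok=True)
        write_lookup(self.lookup, out / "lookup.tsv")
        behav = self.behaviors.frame.reset_index()
        behav.to_csv(out / "behaviors.csv", index=False)
        cats = pd.DataFrame(
            sorted(self.behaviors.categories.items()),
            columns=["measure", "category"],
        )
        cats.to_csv(out / "categories.tsv", sep="\t", index=False)
        manifest_rows = []
        for stack in self.stacks:
            for run in stack.runs:
                rel = f"runs/{stack.subject_id}_run-{run.run_index}.tsv"
                np.savetxt(out / rel, run.values, fmt="%.10g", delimiter="\t")
                manifest_rows.append(
                    {
                        "subject_id": stack.subject_id,
                        "run_index": run.run_index,
                        "path": rel,
                    }
                )
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
        np.savetxt(out / "true_maps.tsv", self.true_maps, fmt="%.10g", delimiter="\t")
        pd.DataFrame(
            {"subject_id": self.subject_ids, "true_label": self.true_labels}
        ).to_csv(out / "true_labels.csv", index=False)
        meta = dataclasses.asdict(self.config)
        meta["battery"] = [dataclasses.asdict(m) for m in self.config.battery]
        (out / "metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
        return out


def generate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Compose maps, runs and behaviors into one reproducible dataset.

    Each ingredient consumes its own child stream of the config seed, so the
    parts are individually reproducible.
    """
    if config is None:
        config = SimulationConfig()
    lookup = make_lookup(config.n_regions)
    root = np.random.SeedSequence(config.seed)
    rng_labels, rng_maps, rng_runs, rng_behav = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    s = config.n_subjects
    ids = tuple(f"sub-{i:04d}" for i in range(1, s + 1))
    labels = np.array([MAJORITY] * s, dtype=object)
    if config.subgroup_size:
        chosen = rng_labels.choice(s, size=config.subgroup_size, replace=False)
        labels[chosen] = SUBGROUP
    labels = tuple(labels)

    maps = np.column_stack(
        [generate_subject_map(config, lookup, lab, rng_maps) for lab in labels]
    )
    stacks = tuple(
        generate_runs(maps[:, i], config, rng_runs, subject_id=ids[i])
        for i in range(s)
    )
    behaviors = generate_behaviors(ids, labels, config, rng_behav)
    return SyntheticDataset(
        config=config,
        lookup=lookup,
        subject_ids=ids,
        true_labels=labels,
        true_maps=maps,
        stacks=stacks,
        behaviors=behaviors,
    )
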