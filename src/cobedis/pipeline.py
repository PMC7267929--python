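"""Stage orchestration: simulate -> decompose -> correlate -> select ->
summarize -> compare -> rssm, with plain-file artifacts between stages.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run independently; a stage whose
prerequisite artifact is missing fails with an actionable message.  A run
report records per-stage status, timings and sha256 digests of every
written artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .behavior import (
    BehaviorError,
    BehaviorTable,
    compare_behaviors,
    compare_mcd_vs_rssm,
    draw_rssm,
    sex_composition_test,
)
from .cobe import CobeConfig, CobeError, extract_common_components
from .networks import compare_network_weights, summarize_weights_by_network
from .parcellation import ParcellationLookup, read_lookup
from .selection import (
    CommonCorrelationMatrix,
    ComponentMatrix,
    McdConfig,
    SelectionError,
    common_correlation_matrix,
    select_mcd,
)
from .simulate import SimulationConfig, generate_dataset

__all__ = [
    "PipelineError",
    "PipelineConfig",
    "RunReport",
    "load_dataset",
    "run_pipeline",
    "sweep_threshold",
    "load_pipeline_config",
]

STAGES = ("decompose", "correlate", "select", "summarize", "compare", "rssm")


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    out_dir: str
    manifest: str
    lookup: str
    behaviors: str
    categories: str
    cobe: CobeConfig = CobeConfig()
    mcd: McdConfig = McdConfig()
    alpha: float = 0.05
    network_label: str = "DMN-A"
    rssm_seed: int = 0
    rssm_n_draws: int = 1
    stages: tuple[str, ...] = STAGES
    strict: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")


def load_dataset(
    manifest_path: str | Path,
    lookup_path: str | Path,
    behaviors_path: str | Path,
    categories_path: str | Path,
    strict: bool = False,
) -> tuple[dict, ParcellationLookup, BehaviorTable, list[str]]:
    """Load and cross-validate the three input sources.

    Subjects present in the manifest but missing from the behavior table are
    excluded (complete-case restriction) and reported; in strict mode they
    are an error instead.
    """
    manifest = cio.read_manifest(manifest_path)
    base = Path(manifest_path).parent
    stacks = cio.load_stacks(manifest, base)
    lookup = read_lookup(lookup_path)
    behaviors = cio.read_behavior_table(behaviors_path, categories_path)

    for sid, stack in stacks.items():
        if stack.n_regions != lookup.n_regions:
            raise PipelineError(
                f"subject {sid}: runs have {stack.n_regions} regions but the "
                f"lookup at {lookup_path} covers {lookup.n_regions}"
            )
    behav_ids = set(behaviors.subject_ids)
    excluded = sorted(set(stacks) - behav_ids)
    if excluded and strict:
        raise PipelineError(f"subjects missing behavior rows: {excluded}")
    kept = {sid: st for sid, st in stacks.items() if sid in behav_ids}
    if len(kept) < 2:
        raise PipelineError("fewer than two subjects with complete data")
    return kept, lookup, behaviors, excluded


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunReport:
    stages: list[dict]
    config_echo: dict
    version: str

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path.name}; run the '{producer}' stage first"
        )
    return path


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order; see module docstring."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(stages=[], config_echo=_config_echo(config), version=__version__)

    stacks, lookup, behaviors, excluded = load_dataset(
        config.manifest, config.lookup, config.behaviors, config.categories,
        strict=config.strict,
    )
    if excluded:
        report.stages.append(
            {"name": "load", "status": "ok", "excluded_subjects": excluded}
        )

    def run_stage(name: str, fn) -> None:
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        entry: dict = {"name": name}
        try:
            outputs = fn()
        except Exception as exc:
            entry.update(status="failed", error=str(exc))
            report.stages.append(entry)
            report.write(out / "report.json")
            raise
        entry.update(
            status="ok",
            seconds=round(time.perf_counter() - t0, 3),
            outputs={str(p.name): _sha256(p) for p in outputs},
        )
        report.stages.append(entry)

    def decompose() -> list[Path]:
        ids = sorted(stacks)
        cols = [
            extract_common_components(stacks[sid], config.cobe).weights[:, 0]
            for sid in ids
        ]
        comps = ComponentMatrix(tuple(ids), np.column_stack(cols))
        path = out / "components.tsv"
        cio.write_components(path, comps)
        return [path]

    def correlate() -> list[Path]:
        comps = cio.read_components(_require(out / "components.tsv", "decompose"))
        corr = common_correlation_matrix(comps)
        path = out / "correlation.tsv"
        cio.write_correlation(path, corr)
        return [path]

    def select() -> list[Path]:
        corr = cio.read_correlation(_require(out / "correlation.tsv", "correlate"))
        result = select_mcd(corr, config.mcd)
        gpath = out / "groups.csv"
        cio.write_groups(gpath, result.mcd_ids, result.cs_ids)
        sizes = [s for s, _ in result.restart_log if s > 0]
        spath = out / "selection.json"
        spath.write_text(
            json.dumps(
                {
                    "seed": config.mcd.seed,
                    "threshold": config.mcd.threshold,
                    "n_restarts": config.mcd.n_restarts,
                    "mcd_size": result.mcd_size,
                    "cs_size": len(result.cs_ids),
                    "max_abs_corr_within": result.max_abs_corr_within,
                    "restart_sizes": {
                        "min": min(sizes) if sizes else 0,
                        "max": max(sizes) if sizes else 0,
                        "mean": float(np.mean(sizes)) if sizes else 0.0,
                    },
                },
                indent=2,
            )
            + "\n"
        )
        return [gpath, spath]

    def summarize() -> list[Path]:
        comps = cio.read_components(_require(out / "components.tsv", "decompose"))
        mcd, cs = cio.read_groups(_require(out / "groups.csv", "select"))
        table = summarize_weights_by_network(comps, lookup)
        tpath = out / "network_weights.csv"
        table.frame.to_csv(tpath, float_format="%.12g")
        cmp_ = compare_network_weights(table, mcd, cs, alpha=config.alpha)
        cpath = out / "network_comparison.csv"
        cmp_.to_csv(cpath, index=False, float_format="%.12g")
        return [tpath, cpath]

    def compare() -> list[Path]:
        mcd, cs = cio.read_groups(_require(out / "groups.csv", "select"))
        cmp_ = compare_behaviors(behaviors, mcd, cs, alpha=config.alpha)
        bpath = out / "behavior_comparison.csv"
        cmp_.to_csv(bpath, index=False, float_format="%.12g")
        sex = sex_composition_test(mcd, cs, behaviors.sex)
        xpath = out / "sex_test.json"
        xpath.write_text(
            json.dumps(
                {
                    "counts": sex.counts.tolist(),
                    "statistic": sex.statistic,
                    "df": sex.df,
                    "p": sex.p,
                },
                indent=2,
            )
            + "\n"
        )
        return [bpath, xpath]

    def rssm() -> list[Path]:
        mcd, cs = cio.read_groups(_require(out / "groups.csv", "select"))
        comps = cio.read_components(_require(out / "components.tsv", "decompose"))
        full = pd.read_csv(_require(out / "behavior_comparison.csv", "compare"))
        flagged = full.loc[full["significant"], "measure"].tolist()
        table = summarize_weights_by_network(comps, lookup)
        rng = np.random.default_rng(config.rssm_seed)
        targets = {
            "male": sum(behaviors.sex[s] == "male" for s in mcd),
            "female": sum(behaviors.sex[s] == "female" for s in mcd),
        }
        outputs = []
        behav_frames = []
        net_frames = []
        for draw in range(config.rssm_n_draws):
            try:
                rssm_ids = draw_rssm(cs, behaviors.sex, targets, rng)
            except BehaviorError as exc:
                # sex matching infeasible at this scale: record and move on
                spath = out / "rssm_skipped.json"
                spath.write_text(
                    json.dumps({"skipped": True, "reason": str(exc)}, indent=2)
                    + "\n"
                )
                return [spath]
            if not flagged:
                continue
            behav_cmp, net_cmp = compare_mcd_vs_rssm(
                behaviors,
                table,
                mcd,
                rssm_ids,
                alpha=config.alpha,
                measure_subset=flagged,
                network_label=config.network_label,
            )
            behav_cmp.insert(0, "draw", draw)
            net_cmp.insert(0, "draw", draw)
            behav_frames.append(behav_cmp)
            net_frames.append(net_cmp)
        if behav_frames:
            bpath = out / "rssm_behavior.csv"
            pd.concat(behav_frames).to_csv(bpath, index=False, float_format="%.12g")
            npath = out / "rssm_network.csv"
            pd.concat(net_frames).to_csv(npath, index=False, float_format="%.12g")
            outputs += [bpath, npath]
        return outputs

    for name, fn in (
        ("decompose", decompose),
        ("correlate", correlate),
        ("select", select),
        ("summarize", summarize),
        ("compare", compare),
        ("rssm", rssm),
    ):
        run_stage(name, fn)

    report.write(out / "report.json")
    return report


def sweep_threshold(
    corr: CommonCorrelationMatrix,
    thresholds: Sequence[float],
    base_config: McdConfig | None = None,
) -> pd.DataFrame:
    """MCD size and within-set max |r| per threshold, shared base seed."""
    if not list(thresholds):
        raise PipelineError("empty threshold list")
    if base_config is None:
        base_config = McdConfig()
    rows = []
    for tau in thresholds:
        cfg = dataclasses.replace(base_config, threshold=float(tau))
        try:
            result = select_mcd(corr, cfg)
            rows.append(
                {
                    "threshold": float(tau),
                    "mcd_size": result.mcd_size,
                    "max_abs_corr_within": result.max_abs_corr_within,
                }
            )
        except SelectionError:
            rows.append(
                {
                    "threshold": float(tau),
                    "mcd_size": 0,
                    "max_abs_corr_within": float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    return echo


def load_pipeline_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides.

    Recognized sections: ``paths`` (manifest, lookup, behaviors, categories,
    out_dir), ``cobe``, ``selection``, ``comparison``, ``rssm``, plus
    top-level ``stages``, ``seed`` and ``strict``.
    """
    import yaml

    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}

    paths = dict(raw.get("paths", {}))
    cobe_raw = dict(raw.get("cobe", {}))
    sel_raw = dict(raw.get("selection", {}))
    cmp_raw = dict(raw.get("comparison", {}))
    rssm_raw = dict(raw.get("rssm", {}))

    from .cobe import RankPolicy

    policy = CobeConfig().rank_policy
    if "rank_fixed" in cobe_raw:
        policy = RankPolicy.fixed(int(cobe_raw.pop("rank_fixed")))
    elif "rank_energy" in cobe_raw:
        policy = RankPolicy.energy(float(cobe_raw.pop("rank_energy")))
    elif "rank_noise_floor" in cobe_raw:
        policy = RankPolicy.noise_floor(float(cobe_raw.pop("rank_noise_floor")))
    cobe = CobeConfig(rank_policy=policy, **cobe_raw)

    seed = int(overrides.pop("seed", raw.get("seed", 0)))
    sel_raw.setdefault("seed", seed)
    mcd = McdConfig(**sel_raw)

    kwargs = {
        "out_dir": paths.get("out_dir", "cobedis_out"),
        "manifest": paths.get("manifest", "manifest.csv"),
        "lookup": paths.get("lookup", "lookup.tsv"),
        "behaviors": paths.get("behaviors", "behaviors.csv"),
        "categories": paths.get("categories", "categories.tsv"),
        "cobe": cobe,
        "mcd": mcd,
        "alpha": float(cmp_raw.get("alpha", 0.05)),
        "network_label": cmp_raw.get("network_label", "DMN-A"),
        "rssm_seed": int(rssm_raw.get("seed", seed + 1)),
        "rssm_n_draws": int(rssm_raw.get("n_draws", 1)),
        "stages": tuple(raw.get("stages", STAGES)),
        "strict": bool(raw.get("strict", False)),
    }
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)
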