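"""Region-to-network lookup tables.

Two deterministic templates are provided: a fast 100-region one for tests
and a 419-region one matching the dimensionality of a Schaefer-400 cortical
parcellation plus 19 subcortical regions.  Cortical regions are split into
left/right hemispheres within each of 17 network labels; hemispheres share
the network label so summaries merge them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "ParcellationError",
    "ParcellationLookup",
    "CORTICAL_NETWORKS",
    "SUBCORTICAL_ROIS",
    "make_lookup",
    "read_lookup",
    "write_lookup",
]


class ParcellationError(ValueError):
    pass


CORTICAL_NETWORKS = (
    "DMN-A",
    "DMN-B",
    "DMN-C",
    "VisCent",
    "VisPeri",
    "SomMotA",
    "SomMotB",
    "DorsAttnA",
    "DorsAttnB",
    "SalVentAttnA",
    "SalVentAttnB",
    "LimbicA",
    "LimbicB",
    "ContA",
    "ContB",
    "ContC",
    "TempPar",
)

SUBCORTICAL_ROIS = (
    "Accumbens_L",
    "Accumbens_R",
    "Amygdala_L",
    "Amygdala_R",
    "Caudate_L",
    "Caudate_R",
    "Cerebellum_L",
    "Cerebellum_R",
    "Diencephalon_L",
    "Diencephalon_R",
    "Hippocampus_L",
    "Hippocampus_R",
    "Pallidum_L",
    "Pallidum_R",
    "Putamen_L",
    "Putamen_R",
    "Thalamus_L",
    "Thalamus_R",
    "Brainstem",
)


@dataclasses.dataclass(frozen=True)
class ParcellationLookup:
    """Mapping region_index (1..P) -> (region_name, label, hemisphere)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"region_index", "region_name", "label", "hemisphere"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParcellationError(f"lookup missing columns {sorted(missing)}")
        idx = self.frame["region_index"].to_numpy()
        p = len(idx)
        if sorted(idx) != list(range(1, p + 1)):
            raise ParcellationError(
                "region_index values must cover 1..P exactly once"
            )
        if self.frame["label"].isna().any() or (self.frame["label"] == "").any():
            bad = self.frame.loc[
                self.frame["label"].isna() | (self.frame["label"] == ""),
                "region_index",
            ].tolist()
            raise ParcellationError(f"regions without a label: {bad}")
        frame = self.frame.sort_values("region_index").reset_index(drop=True)
        object.__setattr__(self, "frame", frame)

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.frame["label"]:
            seen.setdefault(lab, None)
        return tuple(seen)

    def regions_with_label(self, label: str) -> np.ndarray:
        """0-based row positions of the regions carrying ``label``."""
        mask = (self.frame["label"] == label).to_numpy()
        if not mask.any():
            raise ParcellationError(f"no regions with label {label!r}")
        return np.flatnonzero(mask)


def make_lookup(n_regions: int = 100) -> ParcellationLookup:
    """Deterministic template lookup with 17 cortical networks + 19 ROIs."""
    n_sub = len(SUBCORTICAL_ROIS)
    n_cort = n_regions - n_sub
    if n_cort < len(CORTICAL_NETWORKS):
        raise ParcellationError(
            f"n_regions={n_regions} leaves fewer cortical regions than networks"
        )
    base, extra = divmod(n_cort, len(CORTICAL_NETWORKS))
    rows = []
    region = 1
    for i, net in enumerate(CORTICAL_NETWORKS):
        count = base + (1 if i < extra else 0)
        for j in range(count):
            hemi = "left" if j < (count + 1) // 2 else "right"
            rows.append(
                {
                    "region_index": region,
                    "region_name": f"{net}_{hemi[0].upper()}H_{j + 1}",
                    "label": net,
                    "hemisphere": hemi,
                }
            )
            region += 1
    for roi in SUBCORTICAL_ROIS:
        hemi = (
            "left" if roi.endswith("_L") else "right" if roi.endswith("_R") else "none"
        )
        rows.append(
            {
                "region_index": region,
                "region_name": roi,
                "label": roi,
                "hemisphere": hemi,
            }
        )
        region += 1
    return ParcellationLookup(pd.DataFrame(rows))


def write_lookup(lookup: ParcellationLookup, path) -> None:
    lookup.frame.to_csv(path, sep="\t", index=False)


def read_lookup(path) -> ParcellationLookup:
    return ParcellationLookup(pd.read_csv(path, sep="\t"))
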