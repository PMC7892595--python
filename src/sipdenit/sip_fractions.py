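"""Buoyant-density bookkeeping for rRNA-SIP gradient fractions.

After isopycnic centrifugation each gradient is collected into 10 fractions
whose buoyant density (BD, g ml⁻¹) is measured on a blank gradient. ¹³C
labeled rRNA bands heavy; fractions are classified against literature
windows (heavy 1.818–1.824, light 1.770–1.784 g ml⁻¹, bounds inclusive) and
densities between the windows stay "unassigned" rather than being forced
into a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GradientWindows",
    "FractionedCounts",
    "classify_fraction",
    "pool_pairs",
    "bd_from_blank",
    "read_counts",
    "read_sample_meta",
]

META_COLUMNS = ("treatment", "replicate", "fraction_index", "buoyant_density")


@dataclass(frozen=True)
class GradientWindows:
    """Inclusive heavy/light buoyant-density windows (g ml⁻¹)."""

    heavy_lo: float = 1.818
    heavy_hi: float = 1.824
    light_lo: float = 1.770
    light_hi: float = 1.784

    def __post_init__(self) -> None:
        if not (self.light_lo <= self.light_hi < self.heavy_lo <= self.heavy_hi):
            raise ValueError("light window must lie entirely below heavy window")


def classify_fraction(bd: float, windows: GradientWindows | None = None) -> str:
    """Classify a buoyant density as ``heavy``/``light``/``unassigned``."""
    windows = windows or GradientWindows()
    if not np.isfinite(bd) or bd <= 0:
        raise ValueError("buoyant density must be positive and finite")
    if windows.heavy_lo <= bd <= windows.heavy_hi:
        return "heavy"
    if windows.light_lo <= bd <= windows.light_hi:
        return "light"
    return "unassigned"


@dataclass
class FractionedCounts:
    """OTU count table with per-sample gradient metadata.

    ``counts`` is OTUs × samples (non-negative integers); ``sample_meta`` is
    indexed by sample id with columns treatment, replicate, fraction_index,
    buoyant_density and (after construction) label. ``taxonomy`` optionally
    maps OTU id to a lineage string.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series | None = None
    windows: GradientWindows = field(default_factory=GradientWindows)

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(c.to_numpy(), np.round(c.to_numpy())):
            raise ValueError("counts must be integers")
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")
        dup = self.sample_meta.duplicated(
            subset=["treatment", "replicate", "fraction_index"]
        )
        if dup.any():
            raise ValueError(
                "fraction_index must be unique within (treatment, replicate)"
            )
        self.sample_meta = self.sample_meta.copy()
        self.sample_meta["label"] = [
            classify_fraction(bd, self.windows)
            for bd in self.sample_meta["buoyant_density"]
        ]

    def samples_with_label(self, treatment: str, label: str) -> list[str]:
        """Sample ids of a treatment whose fraction falls in ``label``."""
        m = self.sample_meta
        sel = m.index[(m["treatment"] == treatment) & (m["label"] == label)]
        return [s for s in sel if s in self.counts.columns]

    def subset(self, sample_ids: list[str]) -> pd.DataFrame:
        return self.counts[sample_ids]


def pool_pairs(fc: FractionedCounts) -> FractionedCounts:
    """Pairwise-pool the 10 fractions of each gradient into 5 pools.

    Fractions (1,2), (3,4), ... (9,10) are summed element-wise; the pooled
    buoyant density is the mean of the pair and the heavy/light label is
    recomputed from it.
    """
    meta = fc.sample_meta.loc[list(fc.counts.columns)]
    pooled_cols: dict[str, np.ndarray] = {}
    rows = []
    for (treatment, replicate), grp in meta.groupby(
        ["treatment", "replicate"], sort=True
    ):
        grp = grp.sort_values("fraction_index")
        idx = grp["fraction_index"].to_numpy()
        if len(idx) != 10 or not np.array_equal(idx, np.arange(1, 11)):
            raise ValueError(
                f"({treatment}, {replicate}) must have exactly fractions 1..10, "
                f"found {idx.tolist()}"
            )
        for p in range(5):
            pair = grp.index[2 * p : 2 * p + 2]
            sid = f"{treatment}_{replicate}_pool{p + 1}"
            pooled_cols[sid] = fc.counts[pair].sum(axis=1).to_numpy()
            rows.append(
                {
                    "sample_id": sid,
                    "treatment": treatment,
                    "replicate": replicate,
                    "fraction_index": p + 1,
                    "buoyant_density": float(
                        grp.loc[pair, "buoyant_density"].mean()
                    ),
                }
            )
    pooled = pd.DataFrame(pooled_cols, index=fc.counts.index)
    pooled_meta = pd.DataFrame(rows).set_index("sample_id")
    return FractionedCounts(
        counts=pooled,
        sample_meta=pooled_meta,
        taxonomy=fc.taxonomy,
        windows=fc.windows,
    )


def bd_from_blank(
    weights_g: np.ndarray | list[float], volume_ml: float = 0.1
) -> np.ndarray:
    """Buoyant densities (g ml⁻¹) from blank-gradient fraction weights."""
    w = np.asarray(weights_g, dtype=float)
    if volume_ml <= 0 or np.any(w <= 0):
        raise ValueError("weights and volume must be positive")
    return w / volume_ml


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read an OTU × sample count table (TSV, OTU ids in first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV: sample_id, treatment, replicate,
    fraction_index, buoyant_density."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("sample metadata must have a sample_id column")
    df = df.set_index("sample_id")
    df["replicate"] = df["replicate"].astype(str)
    return df
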