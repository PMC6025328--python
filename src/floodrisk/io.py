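"""Survey tables: reading, below-detection-limit handling, summaries.

Concentrations are stored in μg/kg dry soil throughout. Values reported by
the laboratory as below the detection limit (DL) are flagged and, before
any summation or statistical analysis, replaced by DL/2 — the conventional
substitution for left-censored environmental data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "CompoundDescriptor",
    "SampleTable",
    "SummaryStats",
    "load_registry",
    "load_samples",
    "substitute_half_dl",
    "summarize_compound",
    "summarize_table",
]

BDL_SENTINEL = "<DL"
_FLAG_SUFFIX = "_below_dl"


class Group(str, enum.Enum):
    """Broad compound class used for registry bookkeeping."""

    PAH = "PAH"
    PCB = "PCB"
    OCP = "OCP"


@dataclass(frozen=True)
class CompoundDescriptor:
    """Registry entry for one analyte."""

    id: str
    name: str
    group: Group
    detection_limit: float | None
    carcinogen_flag: bool = False

    def __post_init__(self):
        if self.detection_limit is not None and self.detection_limit <= 0:
            raise ValueError(f"{self.id}: detection limit must be positive")


@dataclass(frozen=True)
class SummaryStats:
    """Robust per-compound summary: MIN/MED/MAX, MAD and censoring rate."""

    min: float
    median: float
    max: float
    mad: float
    pct_below_dl: float


@dataclass(frozen=True)
class SampleTable:
    """Site x compound concentration matrix (μg/kg) with censoring flags."""

    site_ids: tuple[str, ...]
    compounds: tuple[CompoundDescriptor, ...]
    concentrations: np.ndarray
    below_dl: np.ndarray

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        flags = np.asarray(self.below_dl, dtype=bool)
        n, d = len(self.site_ids), len(self.compounds)
        if conc.shape != (n, d) or flags.shape != (n, d):
            raise ValueError("matrix dimensions inconsistent with ids")
        if np.any(conc < 0) or not np.all(np.isfinite(conc)):
            raise ValueError("concentrations must be finite and non-negative")
        ids = [c.id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound ids")
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "compounds", tuple(self.compounds))
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "below_dl", flags)

    @property
    def compound_ids(self) -> list[str]:
        return [c.id for c in self.compounds]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.concentrations, index=list(self.site_ids), columns=self.compound_ids
        ).rename_axis("site_id")

    def to_csv(self, path) -> None:
        """Write the value + flag dialect (one _below_dl column per compound)."""
        frame = self.to_frame()
        for j, cid in enumerate(self.compound_ids):
            frame[cid + _FLAG_SUFFIX] = self.below_dl[:, j]
        frame.to_csv(path)


def load_registry(path) -> list[CompoundDescriptor]:
    """Read a compound registry CSV: id,name,group,detection_limit,carcinogen_flag."""
    frame = pd.read_csv(path, dtype={"id": str, "name": str, "group": str})
    required = {"id", "name", "group", "detection_limit", "carcinogen_flag"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"registry missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        dl = None if pd.isna(row.detection_limit) else float(row.detection_limit)
        out.append(
            CompoundDescriptor(
                id=row.id,
                name=row.name,
                group=Group(row.group),
                detection_limit=dl,
                carcinogen_flag=bool(row.carcinogen_flag),
            )
        )
    ids = [c.id for c in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids in registry")
    return out


def write_registry(compounds, path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in compounds],
            "name": [c.name for c in compounds],
            "group": [c.group.value for c in compounds],
            "detection_limit": [c.detection_limit for c in compounds],
            "carcinogen_flag": [c.carcinogen_flag for c in compounds],
        }
    ).to_csv(path, index=False)


def load_samples(path, registry) -> SampleTable:
    """Read a site x compound CSV against a compound registry.

    Two dialects are accepted: cells holding the literal token ``<DL``
    (sentinel dialect), or an extra boolean ``<id>_below_dl`` column per
    compound (value + flag dialect). Sentinel cells are stored as DL/2
    with the flag set; explicit flags keep the stored value.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty samples file") from exc
    if "site_id" not in frame.columns:
        raise ValueError(f"{path}: missing 'site_id' column")
    registry = list(registry)
    by_id = {c.id: c for c in registry}
    missing = [c.id for c in registry if c.id not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing compound columns: {missing}")

    site_ids = frame["site_id"].astype(str).tolist()
    n, d = len(site_ids), len(registry)
    conc = np.empty((n, d))
    flags = np.zeros((n, d), dtype=bool)
    for j, comp in enumerate(registry):
        raw = frame[comp.id].astype(str).str.strip()
        sentinel = raw == BDL_SENTINEL
        values = pd.to_numeric(raw.mask(sentinel), errors="raise").to_numpy(float)
        if sentinel.any():
            if comp.detection_limit is None:
                raise ValueError(f"{comp.id}: below-DL cells but no detection limit")
            values[sentinel.to_numpy()] = comp.detection_limit / 2.0
        flag_col = comp.id + _FLAG_SUFFIX
        if flag_col in frame.columns:
            explicit = (
                frame[flag_col].astype(str).str.strip().str.lower().isin(["true", "1"])
            )
            flags[:, j] = sentinel.to_numpy() | explicit.to_numpy()
        else:
            flags[:, j] = sentinel.to_numpy()
        if np.any(values < 0):
            raise ValueError(f"{comp.id}: negative concentration")
        conc[:, j] = values
    return SampleTable(tuple(site_ids), tuple(registry), conc, flags)


def substitute_half_dl(table: SampleTable) -> SampleTable:
    """Replace flagged cells by DL/2; idempotent, other cells untouched."""
    conc = table.concentrations.copy()
    for j, comp in enumerate(table.compounds):
        mask = table.below_dl[:, j]
        if not mask.any():
            continue
        if comp.detection_limit is None:
            raise ValueError(
                f"{comp.id}: below-DL entries but no registered detection limit"
            )
        conc[mask, j] = comp.detection_limit / 2.0
    if np.any(conc <= 0):
        raise ValueError("non-positive concentration after substitution")
    return replace(table, concentrations=conc)


def summarize_compound(values, below_dl=None) -> SummaryStats:
    """MIN/MED/MAX, unscaled MAD and percent-censored for one compound.

    The MAD is the raw median absolute deviation (no 1.4826 consistency
    factor), so a column dominated by one substituted DL/2 value has
    MAD = 0.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty value vector")
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    if below_dl is None:
        pct = 0.0
    else:
        flags = np.asarray(below_dl, dtype=bool)
        if flags.shape != vals.shape:
            raise ValueError("flag vector length mismatch")
        pct = 100.0 * float(flags.mean())
    return SummaryStats(float(vals.min()), med, float(vals.max()), mad, pct)


def summarize_table(table: SampleTable) -> pd.DataFrame:
    """Per-compound survey summary (columns ordered MIN/MED/MAX/MAD/%<DL)."""
    rows = {}
    for j, comp in enumerate(table.compounds):
        s = summarize_compound(table.concentrations[:, j], table.below_dl[:, j])
        rows[comp.id] = [s.min, s.median, s.max, s.mad, s.pct_below_dl]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["min", "median", "max", "mad", "pct_below_dl"]
    ).rename_axis("compound")
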