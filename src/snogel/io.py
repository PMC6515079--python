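"""Tidy TSV interchange and run configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .design import ExperimentDesign
from .tables import MEASURED_CHANNELS, SpotVolumeTable, TableError

__all__ = [
    "read_spot_tables",
    "write_spot_tables",
    "RunConfig",
    "ConfigError",
]

TIDY_COLUMNS = ["gel_id", "channel", "spot_id", "volume"]


class ConfigError(ValueError):
    pass


def read_spot_tables(
    path: str | Path, design: ExperimentDesign | None = None
) -> dict[str, SpotVolumeTable]:
    """Read raw spot-volume tables from one tidy TSV.

    The file must have columns ``gel_id, channel, spot_id, volume``.
    Malformed rows are reported with their line number (header = line 1).
    If a design is given, the BODIPY channels are checked against its gel
    inventory and all channels must share one spot set.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"gel_id": str, "spot_id": str})
    missing = [c for c in TIDY_COLUMNS if c not in frame.columns]
    if missing:
        raise TableError(f"{path}: missing columns {missing}")

    volumes = pd.to_numeric(frame["volume"], errors="coerce")
    bad = frame.index[volumes.isna() | (volumes < 0)]
    if len(bad):
        line = int(bad[0]) + 2  # header + 1-based
        raise TableError(f"{path}: invalid or negative volume at line {line}")
    frame["volume"] = volumes

    dup = frame.duplicated(subset=["gel_id", "channel", "spot_id"])
    if dup.any():
        line = int(frame.index[dup][0]) + 2
        raise TableError(f"{path}: duplicate (gel, spot) entry at line {line}")

    tables = {
        channel: SpotVolumeTable.from_tidy(sub)
        for channel, sub in frame.groupby("channel", sort=False)
    }

    spot_sets = {ch: tuple(t.spot_ids) for ch, t in tables.items()}
    if len(set(spot_sets.values())) > 1:
        raise TableError(f"{path}: spot sets differ between channels")

    if design is not None:
        from .design import Aliquot

        expected = {
            "BD_ASC_PLUS": {g.gel_id for g in design.gels_for(Aliquot.ASC_PLUS)},
            "BD_ASC_MINUS": {g.gel_id for g in design.gels_for(Aliquot.ASC_MINUS)},
        }
        for ch, want in expected.items():
            if ch in tables:
                got = set(tables[ch].gel_ids)
                if got != want:
                    raise TableError(
                        f"{path}: {ch} gels do not match the design "
                        f"(missing {sorted(want - got)}, extra {sorted(got - want)})"
                    )
    return tables


def write_spot_tables(
    tables: Mapping[str, SpotVolumeTable], path: str | Path
) -> None:
    """Write channel tables to one tidy TSV, sorted for reproducibility."""
    frames = [tables[ch].to_tidy() for ch in sorted(tables)]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


_GATES = ("q", "p")
_BH_FAMILIES = ("per_measure_comparison", "global")
_SUMMARIES = ("mean", "median")
_NORMALIZATIONS = ("cognate", "own_total")
_PQD_SETS = ("ASC_PLUS", "ASC_MINUS")


@dataclass
class RunConfig:
    """Everything a pipeline run needs: inputs, thresholds and conventions."""

    # inputs: either a tidy TSV of measured tables, or simulation parameters
    tables_path: str | None = None
    design_path: str | None = None
    simulate: dict | None = None  # {n_spots, frac_differential, effect_range, ...}
    noise: dict = field(default_factory=dict)

    # thresholds
    fc_threshold: float = 1.5
    alpha: float = 0.05
    floor: float = 1.0

    # conventions
    gate: str = "q"                         # gate on B-H q or raw p
    bh_family: str = "per_measure_comparison"
    summary: str = "mean"
    normalization: str = "cognate"          # or each gel's own total
    pqd_gel_set: str = "ASC_PLUS"
    sno_pca_channel: str = "ratio"          # "ratio" or "asc_minus"

    seed: int = 0
    out_dir: str = "snogel_out"

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.alpha <= 0 or self.floor <= 0:
            raise ConfigError("thresholds must be positive")
        for name, value, allowed in [
            ("gate", self.gate, _GATES),
            ("bh_family", self.bh_family, _BH_FAMILIES),
            ("summary", self.summary, _SUMMARIES),
            ("normalization", self.normalization, _NORMALIZATIONS),
            ("pqd_gel_set", self.pqd_gel_set, _PQD_SETS),
            ("sno_pca_channel", self.sno_pca_channel, ("ratio", "asc_minus")),
        ]:
            if value not in allowed:
                raise ConfigError(f"unknown {name} {value!r}; expected one of {allowed}")
        if self.tables_path is None and self.simulate is None:
            raise ConfigError("either tables_path or simulate must be given")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)
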