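"""Ground-truthed simulation of multiplexed ascorbate-switch 2DE experiments.

The generator is the inverse of the quantification pipeline: it plants known
per-group abundance multipliers, S-nitrosylation (SNO) fractions and
phosphorylation levels, then emits per-gel spot-volume tables for the four
measured channels.  The observation model is

* per-sample lognormal loading factor ``L_s`` (median 1, log-sd ``loading_sd``)
  shared by both aliquot gels of a sample — loading is a property of the
  biological sample, which is what makes cognate normalisation exact;
* optional per-gel lognormal jitter ``J`` (log-sd ``gel_loading_jitter_sd``)
  to let tests quantify the bias when that assumption fails;
* per-observation multiplicative lognormal noise with mean 1 and coefficient
  of variation ``cv``;
* BODIPY signal on the ascorbate-minus aliquot suppressed by the factor
  ``1 - sno_fraction`` (SNO blocks maleimide labelling of cysteines);
* a pre-stain spillover scan recording ``spillover_coefficient`` times the
  gel's realised BODIPY signal in the Pro-Q Diamond window, and a post-stain
  PQD scan equal to the loading-scaled phospho level plus that same spillover
  component (the spillover fluorophores are physically present in both scans).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Aliquot, ExperimentDesign
from .tables import (
    BD_ASC_MINUS,
    BD_ASC_PLUS,
    PQD_POST,
    SPILL_SCAN,
    SpotVolumeTable,
)

__all__ = [
    "NoiseModel",
    "SpotTruth",
    "GroundTruth",
    "generate_ground_truth",
    "simulate_experiment",
    "ParameterError",
]

MEASURES = ("abundance", "sno", "phospho")


class ParameterError(ValueError):
    """Raised on invalid simulation parameters."""


@dataclass(frozen=True)
class NoiseModel:
    """Dispersion and nuisance parameters of the measurement process.

    cv : coefficient of variation of the per-observation lognormal noise.
    loading_sd : log-sd of the per-sample loading factor.
    gel_loading_jitter_sd : extra per-gel log-sd (0 = loading is purely a
        sample property, the regime cognate normalisation assumes).
    spillover_coefficient : fraction of BODIPY signal read in the PQD window.
    detection_floor : minimum volume treated as reliably detected downstream.
    """

    cv: float = 0.10
    loading_sd: float = 0.10
    gel_loading_jitter_sd: float = 0.0
    spillover_coefficient: float = 0.13
    detection_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.loading_sd < 0 or self.gel_loading_jitter_sd < 0:
            raise ParameterError("dispersions must be >= 0")
        if not 0 <= self.spillover_coefficient < 1:
            raise ParameterError("spillover_coefficient must be in [0, 1)")
        if self.detection_floor <= 0:
            raise ParameterError("detection_floor must be > 0")

    def to_dict(self) -> dict:
        return {
            "cv": self.cv,
            "loading_sd": self.loading_sd,
            "gel_loading_jitter_sd": self.gel_loading_jitter_sd,
            "spillover_coefficient": self.spillover_coefficient,
            "detection_floor": self.detection_floor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NoiseModel":
        return cls(**dict(d))


@dataclass(frozen=True)
class SpotTruth:
    """True, unobserved state of one protein spot.

    ``abundance_multiplier`` is multiplicative per group (control = 1),
    ``sno_fraction`` is the fraction of the spot's cysteines that are
    S-nitrosylated (in [0, 0.95]), and ``phospho_level`` is the true Pro-Q
    Diamond volume in fluorescence units.
    """

    spot_id: str
    pi: float
    mw_kda: float
    base_abundance: float
    abundance_multiplier: dict[str, float]
    sno_fraction: dict[str, float]
    phospho_level: dict[str, float]


@dataclass(frozen=True)
class GroundTruth:
    """Per-spot, per-group true abundance, SNO fraction and phospho level."""

    group_labels: tuple[str, ...]
    spots: tuple[SpotTruth, ...]

    def __post_init__(self) -> None:
        ids = [s.spot_id for s in self.spots]
        if len(set(ids)) != len(ids):
            raise ParameterError("spot_ids must be unique")
        ctl = self.group_labels[0]
        for s in self.spots:
            if s.abundance_multiplier[ctl] != 1.0:
                raise ParameterError(
                    f"{s.spot_id}: control abundance multiplier must be 1"
                )
            for g, f in s.sno_fraction.items():
                if not 0.0 <= f <= 0.95:
                    raise ParameterError(
                        f"{s.spot_id}: sno_fraction[{g}] outside [0, 0.95]"
                    )

    @property
    def spot_ids(self) -> list[str]:
        return [s.spot_id for s in self.spots]

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def multiplier(self, group: str) -> np.ndarray:
        return np.array([s.abundance_multiplier[group] for s in self.spots])

    def sno(self, group: str) -> np.ndarray:
        return np.array([s.sno_fraction[group] for s in self.spots])

    def phospho(self, group: str) -> np.ndarray:
        return np.array([s.phospho_level[group] for s in self.spots])

    def base(self) -> np.ndarray:
        return np.array([s.base_abundance for s in self.spots])

    def coords(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pI": [s.pi for s in self.spots], "mw_kda": [s.mw_kda for s in self.spots]},
            index=self.spot_ids,
        )

    def differential_spot_ids(self) -> list[str]:
        """Spots that are non-null in any measure in any non-control group."""
        ctl = self.group_labels[0]
        out = []
        for s in self.spots:
            hit = any(
                s.abundance_multiplier[g] != 1.0
                or s.sno_fraction[g] != s.sno_fraction[ctl]
                or s.phospho_level[g] != s.phospho_level[ctl]
                for g in self.group_labels[1:]
            )
            if hit:
                out.append(s.spot_id)
        return out

    # -- serialisation --------------------------------------------------- #
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "group_labels": list(self.group_labels),
            "spots": [
                {
                    "spot_id": s.spot_id,
                    "pi": s.pi,
                    "mw_kda": s.mw_kda,
                    "base_abundance": s.base_abundance,
                    "abundance_multiplier": s.abundance_multiplier,
                    "sno_fraction": s.sno_fraction,
                    "phospho_level": s.phospho_level,
                }
                for s in self.spots
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        doc = json.loads(text)
        spots = tuple(
            SpotTruth(
                spot_id=s["spot_id"],
                pi=s["pi"],
                mw_kda=s["mw_kda"],
                base_abundance=s["base_abundance"],
                abundance_multiplier=dict(s["abundance_multiplier"]),
                sno_fraction=dict(s["sno_fraction"]),
                phospho_level=dict(s["phospho_level"]),
            )
            for s in doc["spots"]
        )
        return cls(group_labels=tuple(doc["group_labels"]), spots=spots)


def generate_ground_truth(
    design: ExperimentDesign,
    n_spots: int,
    frac_differential: float,
    effect_range: tuple[float, float] = (1.5, 4.0),
    sno_range: tuple[float, float] = (0.10, 0.40),
    seed: int = 0,
    *,
    measures: Sequence[str] = MEASURES,
    sno_baseline_range: tuple[float, float] = (0.05, 0.30),
) -> GroundTruth:
    """Draw a ground truth with a fixed number of truly differential spots.

    Exactly ``round(frac_differential * n_spots)`` spots are perturbed, each
    in every measure listed in ``measures``, in one randomly chosen treatment
    group per measure; the effect direction is random and its magnitude
    uniform in ``effect_range`` (fold, for abundance and phospho) or
    ``sno_range`` (additive on the SNO fraction).  All remaining spots are
    null in all three measures.  Deterministic for a fixed seed.
    """
    if n_spots < 1:
        raise ParameterError("n_spots must be >= 1")
    if not 0.0 <= frac_differential <= 1.0:
        raise ParameterError("frac_differential must be in [0, 1]")
    if effect_range[0] < 1 or effect_range[1] < effect_range[0]:
        raise ParameterError("effect_range bounds must satisfy 1 <= lo <= hi")
    if not 0 <= sno_range[0] <= sno_range[1] <= 0.95:
        raise ParameterError("sno_range must lie within [0, 0.95]")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise ParameterError(f"unknown measures: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    groups = design.group_labels
    treatments = design.treatment_groups

    width = len(str(n_spots))
    spot_ids = [f"spot_{i + 1:0{width}d}" for i in range(n_spots)]
    pis = rng.uniform(3.5, 10.8, n_spots)
    mws = 10.0 ** rng.uniform(1.0, 2.2, n_spots)  # 10-158 kDa
    base = rng.lognormal(np.log(2.0e4), 1.0, n_spots)
    sno_base = rng.uniform(*sno_baseline_range, n_spots)
    phospho_base = rng.lognormal(np.log(5.0e3), 0.8, n_spots)

    n_diff = round(frac_differential * n_spots)
    diff_idx = set(rng.choice(n_spots, size=n_diff, replace=False).tolist())

    spots = []
    for i, sid in enumerate(spot_ids):
        mult = {g: 1.0 for g in groups}
        sno = {g: float(sno_base[i]) for g in groups}
        phos = {g: float(phospho_base[i]) for g in groups}
        if i in diff_idx and treatments:
            if "abundance" in measures:
                trt = treatments[rng.integers(len(treatments))]
                f = rng.uniform(*effect_range)
                mult[trt] = float(f if rng.random() < 0.5 else 1.0 / f)
            if "sno" in measures:
                trt = treatments[rng.integers(len(treatments))]
                d = rng.uniform(*sno_range)
                s = sno[trt] + (d if rng.random() < 0.5 else -d)
                if not 0.0 <= s <= 0.95:  # flip toward the feasible side
                    s = sno[trt] - (s - sno[trt])
                sno[trt] = float(np.clip(s, 0.0, 0.95))
            if "phospho" in measures:
                trt = treatments[rng.integers(len(treatments))]
                f = rng.uniform(*effect_range)
                phos[trt] = float(
                    phos[trt] * f if rng.random() < 0.5 else phos[trt] / f
                )
        spots.append(
            SpotTruth(
                spot_id=sid,
                pi=float(pis[i]),
                mw_kda=float(mws[i]),
                base_abundance=float(base[i]),
                abundance_multiplier=mult,
                sno_fraction=sno,
                phospho_level=phos,
            )
        )
    return GroundTruth(group_labels=tuple(groups), spots=tuple(spots))


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, shape))


def simulate_experiment(
    truth: GroundTruth,
    design: ExperimentDesign,
    noise: NoiseModel,
    *,
    pqd_aliquot: Aliquot = Aliquot.ASC_PLUS,
) -> dict[str, SpotVolumeTable]:
    """Simulate raw spot-volume tables for all four measured channels.

    Returns BODIPY tables for the ASC_PLUS and ASC_MINUS gel sets plus the
    spillover pre-stain scan and the Pro-Q Diamond post-stain scan of the
    ``pqd_aliquot`` gel set (default: the ascorbate-treated gels).
    """
    if set(design.group_labels) - set(truth.group_labels):
        raise ParameterError("design groups missing from ground truth")

    rng = np.random.default_rng(noise.seed)
    S = truth.n_spots
    base = truth.base()

    samples = design.samples()
    loading = {
        s: float(np.exp(rng.normal(0.0, noise.loading_sd))) if noise.loading_sd else 1.0
        for s in samples
    }
    jitter = {
        g.gel_id: float(np.exp(rng.normal(0.0, noise.gel_loading_jitter_sd)))
        if noise.gel_loading_jitter_sd
        else 1.0
        for g in design.gels
    }

    def bd_rows(aliquot: Aliquot) -> pd.DataFrame:
        rows, index = [], []
        for g in design.gels_for(aliquot):
            scale = loading[g.sample_id] * jitter[g.gel_id]
            signal = base * truth.multiplier(g.group)
            if aliquot is Aliquot.ASC_MINUS:
                signal = signal * (1.0 - truth.sno(g.group))
            eta = _lognormal_noise(rng, noise.cv, S)
            rows.append(scale * signal * eta)
            index.append(g.gel_id)
        return pd.DataFrame(rows, index=index, columns=truth.spot_ids)

    bd_plus = bd_rows(Aliquot.ASC_PLUS)
    bd_minus = bd_rows(Aliquot.ASC_MINUS)

    bd_lookup = {BD_ASC_PLUS: bd_plus, BD_ASC_MINUS: bd_minus}[
        BD_ASC_PLUS if pqd_aliquot is Aliquot.ASC_PLUS else BD_ASC_MINUS
    ]
    spill_rows, pqd_rows, index = [], [], []
    for g in design.gels_for(pqd_aliquot):
        bd_here = bd_lookup.loc[g.gel_id].to_numpy()
        spill = noise.spillover_coefficient * bd_here * _lognormal_noise(
            rng, noise.cv, S
        )
        scale = loading[g.sample_id] * jitter[g.gel_id]
        phospho = scale * truth.phospho(g.group) * _lognormal_noise(rng, noise.cv, S)
        # the spillover fluorophores are present in the post-stain scan too
        spill_rows.append(spill)
        pqd_rows.append(phospho + spill)
        index.append(g.gel_id)

    return {
        BD_ASC_PLUS: SpotVolumeTable(BD_ASC_PLUS, bd_plus),
        BD_ASC_MINUS: SpotVolumeTable(BD_ASC_MINUS, bd_minus),
        SPILL_SCAN: SpotVolumeTable(
            SPILL_SCAN, pd.DataFrame(spill_rows, index=index, columns=truth.spot_ids)
        ),
        PQD_POST: SpotVolumeTable(
            PQD_POST, pd.DataFrame(pqd_rows, index=index, columns=truth.spot_ids)
        ),
    }
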