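"""Normalisation and ratiometric quantification.

The normalisation model: spot volumes on every gel are multiplied by a bias
factor ``b = T_ref / T_gel`` computed from total spot volume, where ``T_ref``
is the total of a designated reference gel (an ascorbate-treated control
gel).  Because loading is a property of the biological sample, the factors of
the ascorbate-minus, spillover and Pro-Q Diamond scans are those of the
sample's cognate ascorbate-plus BODIPY gel, not of their own totals.

The observables are signed fold changes:

* ``delta_abundance`` — ratio of group-mean normalised ASC_PLUS volumes,
* ``delta_sno``       — same ratio on the ASC_MINUS channel,
* ``ror``             — ratio of ratios ``delta_sno / delta_abundance``;
  because S-nitrosylation blocks BODIPY labelling, a *negative* signed RoR
  means SNO increased in the experimental group,
* ``delta_phospho``   — ratio on the spillover-corrected PQD channel.

Ratios are expressed with the signed-reciprocal convention (r if r >= 1,
else -1/r) and capped at +/-100 when one group's summary falls below the
detection floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import Aliquot, ExperimentDesign
from .tables import (
    BD_ASC_MINUS,
    BD_ASC_PLUS,
    PQD_CORRECTED,
    PQD_POST,
    SPILL_SCAN,
    SpotVolumeTable,
    TableError,
    check_same_grid,
)

__all__ = [
    "NormalizationFactors",
    "FoldChange",
    "SpilloverCorrection",
    "SpilloverEstimate",
    "compute_bias_factors",
    "normalize",
    "correct_spillover",
    "estimate_spillover_coefficient",
    "signed_fold",
    "fold_from_summaries",
    "compute_ratios",
    "QuantificationError",
]

CAP = 100.0
MEASURE_ABUNDANCE = "abundance"
MEASURE_SNO = "sno_ror"
MEASURE_PHOSPHO = "phospho"
MEASURES = (MEASURE_ABUNDANCE, MEASURE_SNO, MEASURE_PHOSPHO)


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-gel bias factors and the cognate gel each was derived from."""

    factors: dict[str, float]
    reference_gel_id: str
    source: dict[str, str]  # gel -> ASC_PLUS gel whose factor was applied

    def __post_init__(self) -> None:
        if not math.isclose(self.factors[self.reference_gel_id], 1.0, rel_tol=0, abs_tol=0):
            raise QuantificationError("reference gel factor must be exactly 1")
        for gel, b in self.factors.items():
            if not (math.isfinite(b) and b > 0):
                raise QuantificationError(f"non-positive factor for gel {gel!r}")


def compute_bias_factors(
    asc_plus_bd: SpotVolumeTable, design: ExperimentDesign
) -> NormalizationFactors:
    """Bias factors from raw ASC_PLUS BODIPY totals, propagated to cognates.

    ``b_gel = T_ref / T_gel`` for each ascorbate-plus gel; every other gel of
    the same sample (ascorbate-minus, spillover and PQD scans) inherits the
    factor of its cognate ascorbate-plus gel.
    """
    if asc_plus_bd.normalized:
        raise QuantificationError("bias factors must be computed on raw volumes")
    totals = asc_plus_bd.totals()
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise QuantificationError(f"gel {bad!r} has non-positive total volume")
    if design.reference_gel_id not in totals.index:
        raise QuantificationError("reference gel missing from ASC_PLUS table")
    t_ref = float(totals[design.reference_gel_id])
    plus_factors = {gid: t_ref / float(t) for gid, t in totals.items()}
    # exact unity for the reference regardless of rounding
    plus_factors[design.reference_gel_id] = 1.0

    factors, source = {}, {}
    for g in design.gels:
        cognate = design.cognate_asc_plus(g.gel_id)
        if cognate.gel_id not in plus_factors:
            raise QuantificationError(
                f"no ASC_PLUS total for cognate gel {cognate.gel_id!r}"
            )
        factors[g.gel_id] = plus_factors[cognate.gel_id]
        source[g.gel_id] = cognate.gel_id
    return NormalizationFactors(
        factors=factors, reference_gel_id=design.reference_gel_id, source=source
    )


def own_total_factors(
    table: SpotVolumeTable, reference_total: float
) -> NormalizationFactors:
    """Sensitivity-analysis alternative: each gel normalised by its own total."""
    totals = table.totals()
    if (totals <= 0).any():
        raise QuantificationError("gel with non-positive total volume")
    factors = {gid: reference_total / float(t) for gid, t in totals.items()}
    ref = totals.index[0]
    factors_ref = factors[ref]
    # NormalizationFactors requires an exactly-unit reference; rescale so the
    # first gel plays that role while preserving all relative factors.
    factors = {g: b / factors_ref for g, b in factors.items()}
    return NormalizationFactors(
        factors=factors, reference_gel_id=ref, source={g: g for g in factors}
    )


def normalize(
    table: SpotVolumeTable, factors: NormalizationFactors
) -> SpotVolumeTable:
    """Multiply every gel's volumes by its (cognate-derived) bias factor."""
    if table.normalized:
        raise QuantificationError(f"{table.channel}: table already normalized")
    missing = [g for g in table.gel_ids if g not in factors.factors]
    if missing:
        raise QuantificationError(f"no bias factor for gels {missing}")
    scale = pd.Series({g: factors.factors[g] for g in table.gel_ids})
    values = table.values.mul(scale, axis=0)
    return table.with_values(values, normalized=True)


@dataclass
class SpilloverCorrection:
    """Spillover-corrected PQD table plus the clamp bookkeeping."""

    table: SpotVolumeTable
    clamped: pd.DataFrame  # boolean mask of values clamped to zero

    @property
    def n_clamped(self) -> int:
        return int(self.clamped.to_numpy().sum())


def correct_spillover(
    pqd_post: SpotVolumeTable, spill_scan: SpotVolumeTable
) -> SpilloverCorrection:
    """Subtract the measured per-spot BODIPY spillover from the PQD scan.

    Both tables must be raw scans of the same physical gels.  Differences
    that would be negative are clamped to zero and flagged; normalisation
    happens downstream with the same cognate bias factors.
    """
    if pqd_post.normalized or spill_scan.normalized:
        raise QuantificationError("spillover correction operates on raw scans")
    check_same_grid(pqd_post, spill_scan)
    diff = pqd_post.values - spill_scan.values
    clamped = diff < 0
    corrected = diff.where(~clamped, 0.0)
    return SpilloverCorrection(
        table=SpotVolumeTable(PQD_CORRECTED, corrected), clamped=clamped
    )


@dataclass(frozen=True)
class SpilloverEstimate:
    """Per-gel and pooled spillover coefficients (diagnostic only)."""

    per_gel: pd.DataFrame  # columns: slope, r2, weight
    pooled: float
    pooled_r2: float


def estimate_spillover_coefficient(
    spill_scan: SpotVolumeTable, bd_same_gels: SpotVolumeTable
) -> SpilloverEstimate:
    """Least-squares slope through the origin of spillover vs BODIPY signal.

    The pooled estimate is the volume-weighted mean of per-gel slopes.  This
    is a QC diagnostic — the correction itself subtracts the measured scan.
    """
    check_same_grid(spill_scan, bd_same_gels)
    rows = []
    for gid in spill_scan.gel_ids:
        s = spill_scan.values.loc[gid].to_numpy()
        b = bd_same_gels.values.loc[gid].to_numpy()
        denom = float(b @ b)
        if denom == 0:
            raise QuantificationError(f"gel {gid!r}: all-zero BODIPY signal")
        slope = float(s @ b) / denom
        ss_res = float(np.sum((s - slope * b) ** 2))
        ss_tot = float(s @ s)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        rows.append((gid, slope, r2, float(b.sum())))
    per_gel = pd.DataFrame(
        rows, columns=["gel_id", "slope", "r2", "weight"]
    ).set_index("gel_id")
    w = per_gel["weight"].to_numpy()
    pooled = float(np.average(per_gel["slope"], weights=w))
    pooled_r2 = float(np.average(per_gel["r2"], weights=w))
    return SpilloverEstimate(per_gel=per_gel, pooled=pooled, pooled_r2=pooled_r2)


@dataclass(frozen=True)
class FoldChange:
    """A positive group-mean ratio and its signed-reciprocal representation."""

    ratio: float
    signed: float
    capped: bool = False
    both_low: bool = False


def signed_fold(ratio: float) -> FoldChange:
    """Signed-reciprocal convention: r if r >= 1, else -1/r."""
    if not (ratio > 0 and math.isfinite(ratio)):
        raise QuantificationError(f"ratio must be positive and finite, got {ratio}")
    signed = ratio if ratio >= 1.0 else -1.0 / ratio
    return FoldChange(ratio=ratio, signed=signed)


def fold_from_summaries(numerator: float, denominator: float, eps: float) -> FoldChange:
    """Fold change of two group summaries with detection-floor capping.

    A denominator below the floor with a detected numerator caps at +100, the
    symmetric case at -100, and two undetected summaries report +1 with the
    ``both_low`` flag set.
    """
    num_low, den_low = numerator < eps, denominator < eps
    if num_low and den_low:
        return FoldChange(ratio=1.0, signed=1.0, both_low=True)
    if den_low:
        return FoldChange(ratio=float("inf"), signed=CAP, capped=True)
    if num_low:
        return FoldChange(ratio=0.0, signed=-CAP, capped=True)
    return signed_fold(numerator / denominator)


def _ror_fold(sno: FoldChange, abundance: FoldChange) -> FoldChange:
    """Ratio of ratios with cap propagation from its two components."""
    if sno.both_low or abundance.both_low:
        return FoldChange(ratio=1.0, signed=1.0, both_low=True)
    if sno.capped and abundance.capped:
        return FoldChange(ratio=1.0, signed=1.0, both_low=True)
    if sno.capped:
        return FoldChange(ratio=sno.ratio, signed=sno.signed, capped=True)
    if abundance.capped:
        signed = -CAP if abundance.signed > 0 else CAP
        return FoldChange(
            ratio=0.0 if signed < 0 else float("inf"), signed=signed, capped=True
        )
    return signed_fold(sno.ratio / abundance.ratio)


def group_summaries(
    table: SpotVolumeTable,
    design: ExperimentDesign,
    *,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-group summary (mean or median) of normalised replicate volumes."""
    if not table.normalized:
        raise QuantificationError(f"{table.channel}: summaries need normalized volumes")
    if summary not in ("mean", "median"):
        raise QuantificationError(f"unknown summary {summary!r}")
    groups = pd.Series(
        {gid: design.gel(gid).group for gid in table.gel_ids}, name="group"
    )
    counts = groups.value_counts()
    if (counts < 2).any():
        raise QuantificationError("each group needs at least 2 replicates")
    grouped = table.values.groupby(groups)
    return grouped.mean() if summary == "mean" else grouped.median()


def compute_ratios(
    tables: Mapping[str, SpotVolumeTable],
    design: ExperimentDesign,
    *,
    eps: float = 1.0,
    summary: str = "mean",
) -> pd.DataFrame:
    """Signed fold changes for every spot, comparison and measure.

    ``tables`` must hold normalised ``BD_ASC_PLUS``, ``BD_ASC_MINUS`` and
    ``PQD_CORRECTED`` tables.  Returns a tidy frame with one row per
    (comparison, measure, spot): columns ``comparison``, ``exp_group``,
    ``ctl_group``, ``measure``, ``spot_id``, ``ratio``, ``signed_fc``,
    ``capped``, ``both_low``.
    """
    for key in (BD_ASC_PLUS, BD_ASC_MINUS, PQD_CORRECTED):
        if key not in tables:
            raise QuantificationError(f"missing {key} table")
        if not tables[key].normalized:
            raise QuantificationError(f"{key}: ratios require normalized volumes")

    plus = group_summaries(tables[BD_ASC_PLUS], design, summary=summary)
    minus = group_summaries(tables[BD_ASC_MINUS], design, summary=summary)
    pqd = group_summaries(tables[PQD_CORRECTED], design, summary=summary)
    spot_ids = tables[BD_ASC_PLUS].spot_ids

    records = []
    for exp, ctl in design.comparisons():
        label = f"{exp}_vs_{ctl}"
        for sid in spot_ids:
            fc_ab = fold_from_summaries(plus.at[exp, sid], plus.at[ctl, sid], eps)
            fc_sno = fold_from_summaries(minus.at[exp, sid], minus.at[ctl, sid], eps)
            fc_ror = _ror_fold(fc_sno, fc_ab)
            fc_ph = fold_from_summaries(pqd.at[exp, sid], pqd.at[ctl, sid], eps)
            for measure, fc in (
                (MEASURE_ABUNDANCE, fc_ab),
                (MEASURE_SNO, fc_ror),
                (MEASURE_PHOSPHO, fc_ph),
            ):
                records.append(
                    (label, exp, ctl, measure, sid, fc.ratio, fc.signed, fc.capped, fc.both_low)
                )
    return pd.DataFrame(
        records,
        columns=[
            "comparison",
            "exp_group",
            "ctl_group",
            "measure",
            "spot_id",
            "ratio",
            "signed_fc",
            "capped",
            "both_low",
        ],
    )
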