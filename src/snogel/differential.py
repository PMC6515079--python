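"""Welch t-tests, Benjamini-Hochberg FDR and the selection rule.

Replicate-level quantities per measure:

* abundance — the normalised ascorbate-plus BODIPY volume of each sample;
* sno       — the per-sample ratio of normalised ascorbate-minus volume to
  the cognate ascorbate-plus volume (the replicate-level analogue of the
  ratio of ratios);
* phospho   — the normalised, spillover-corrected Pro-Q Diamond volume.

Tests are run on log2-transformed values (after flooring at the detection
floor) because all three quantities are multiplicative.  A spot counts as
significant when |signed fold change| >= 1.5 and the B-H adjusted p-value is
<= 0.05 (the raw p-value can be gated instead via ``gate="p"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import Aliquot, ExperimentDesign
from .quantification import (
    MEASURE_ABUNDANCE,
    MEASURE_PHOSPHO,
    MEASURE_SNO,
    QuantificationError,
    compute_ratios,
)
from .tables import BD_ASC_MINUS, BD_ASC_PLUS, PQD_CORRECTED, SpotVolumeTable

__all__ = [
    "WelchResult",
    "welch_t",
    "benjamini_hochberg",
    "replicate_values",
    "differential_analysis",
    "select_differential",
    "summarize",
    "StatsError",
]

# p-value sentinel for a zero-variance, unequal-means degenerate comparison
P_SENTINEL = 5e-324


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class WelchResult:
    """Welch's unequal-variance t-test statistic, df and two-sided p."""

    t: np.ndarray | float
    df: np.ndarray | float
    p: np.ndarray | float
    degenerate: np.ndarray | bool  # zero variance in both samples


def welch_t(a, b) -> WelchResult:
    """Two-sided Welch t-test of two independent samples.

    ``a`` and ``b`` are 1-D samples, or 2-D arrays of shape
    (n_observations, n_variables) tested column-wise.  Degenerate inputs
    follow the conventions: zero variance in both samples with equal means
    gives p = 1; with unequal means, p is a denormal sentinel and the
    ``degenerate`` flag is set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    scalar = a.ndim == 1
    if scalar:
        a, b = a[:, None], b[:, None]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise StatsError("welch_t requires at least 2 observations per sample")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatsError("welch_t requires finite values")

    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)

    zero_var = se2 == 0
    equal_means = ma == mb
    degenerate = zero_var & ~equal_means
    t = np.where(zero_var & equal_means, 0.0, t)
    p = np.where(zero_var & equal_means, 1.0, p)
    t = np.where(degenerate, np.copysign(np.inf, ma - mb), t)
    p = np.where(degenerate, P_SENTINEL, p)
    df = np.where(zero_var, na + nb - 2.0, df)

    if scalar:
        return WelchResult(float(t[0]), float(df[0]), float(p[0]), bool(degenerate[0]))
    return WelchResult(t, df, p, degenerate)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Sorted ascending, ``q_(i) = min_{j>=i} p_(j) * m / j`` clamped at 1,
    returned in the original order.  NaNs are excluded from the family size
    and propagated with a warning.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    nan = np.isnan(p)
    if nan.any():
        warnings.warn("NaN p-values propagated through B-H", RuntimeWarning)
    valid = ~nan
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adjusted, 1.0)
        q[valid] = out
    return q


def replicate_values(
    tables: Mapping[str, SpotVolumeTable], design: ExperimentDesign
) -> dict[str, pd.DataFrame]:
    """Per-sample replicate values for each measure.

    Returns a frame per measure indexed by sample id with one column per
    spot: the normalised ASC_PLUS volume (abundance), the per-sample
    ASC_MINUS / cognate-ASC_PLUS ratio (sno), and the normalised corrected
    PQD volume (phospho).  Values are raw ratios/volumes; log transforms
    happen at test time.
    """
    for key in (BD_ASC_PLUS, BD_ASC_MINUS, PQD_CORRECTED):
        if key not in tables:
            raise QuantificationError(f"missing {key} table")
        if not tables[key].normalized:
            raise QuantificationError(f"{key}: replicate values need normalized volumes")

    plus, minus, pqd = (
        tables[BD_ASC_PLUS],
        tables[BD_ASC_MINUS],
        tables[PQD_CORRECTED],
    )
    samples = design.samples()

    def by_sample(table: SpotVolumeTable, aliquot: Aliquot) -> pd.DataFrame:
        rows = []
        for sid in samples:
            gel = design.gel_for(sid, aliquot).gel_id
            if gel not in table.values.index:
                # PQD scans may live on either aliquot's gel set
                other = design.gel_for(
                    sid,
                    Aliquot.ASC_MINUS if aliquot is Aliquot.ASC_PLUS else Aliquot.ASC_PLUS,
                ).gel_id
                if other not in table.values.index:
                    raise StatsError(f"no {table.channel} gel for sample {sid!r}")
                gel = other
            rows.append(table.values.loc[gel])
        return pd.DataFrame(np.vstack(rows), index=samples, columns=table.spot_ids)

    abundance = by_sample(plus, Aliquot.ASC_PLUS)
    minus_by_sample = by_sample(minus, Aliquot.ASC_MINUS)
    with np.errstate(divide="ignore", invalid="ignore"):
        sno = minus_by_sample / abundance
    sno = sno.replace([np.inf, -np.inf], np.nan).fillna(0.0)
    phospho = by_sample(pqd, Aliquot.ASC_PLUS)
    return {
        MEASURE_ABUNDANCE: abundance,
        MEASURE_SNO: sno,
        MEASURE_PHOSPHO: phospho,
    }


def differential_analysis(
    tables: Mapping[str, SpotVolumeTable],
    design: ExperimentDesign,
    *,
    eps: float = 1.0,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    gate: str = "q",
    bh_family: str = "per_measure_comparison",
    summary: str = "mean",
) -> pd.DataFrame:
    """Full differential table: fold changes, Welch p, B-H q and flags.

    One row per (comparison, measure, spot).  ``bh_family`` controls the B-H
    family: ``"per_measure_comparison"`` (default) adjusts each measure and
    comparison separately; ``"global"`` adjusts all rows as one family.
    """
    if gate not in ("q", "p"):
        raise StatsError(f"unknown gate {gate!r}")
    if bh_family not in ("per_measure_comparison", "global"):
        raise StatsError(f"unknown bh_family {bh_family!r}")

    records = compute_ratios(tables, design, eps=eps, summary=summary)
    reps = replicate_values(tables, design)
    sample_groups = {s: design.sample_group(s) for s in design.samples()}

    p_cols = []
    for (exp, ctl), measure in [
        (c, m) for c in design.comparisons() for m in reps
    ]:
        frame = reps[measure]
        rows_exp = [s for s in frame.index if sample_groups[s] == exp]
        rows_ctl = [s for s in frame.index if sample_groups[s] == ctl]
        # sno replicate values are ratios near 1; volumes get the floor
        floor = np.finfo(float).tiny if measure == MEASURE_SNO else eps
        a = np.log2(np.maximum(frame.loc[rows_exp].to_numpy(), floor))
        b = np.log2(np.maximum(frame.loc[rows_ctl].to_numpy(), floor))
        res = welch_t(a, b)
        p_cols.append(
            pd.DataFrame(
                {
                    "comparison": f"{exp}_vs_{ctl}",
                    "measure": measure,
                    "spot_id": frame.columns,
                    "t": np.atleast_1d(res.t),
                    "df": np.atleast_1d(res.df),
                    "p_raw": np.atleast_1d(res.p),
                    "degenerate": np.atleast_1d(res.degenerate),
                }
            )
        )
    pvals = pd.concat(p_cols, ignore_index=True)
    records = records.merge(pvals, on=["comparison", "measure", "spot_id"], how="left")

    if bh_family == "global":
        records["q_bh"] = benjamini_hochberg(records["p_raw"].to_numpy())
    else:
        records["q_bh"] = np.nan
        for _, idx in records.groupby(["comparison", "measure"]).groups.items():
            records.loc[idx, "q_bh"] = benjamini_hochberg(
                records.loc[idx, "p_raw"].to_numpy()
            )
    return select_differential(
        records, fc_threshold=fc_threshold, alpha=alpha, gate=gate
    )


def select_differential(
    records: pd.DataFrame,
    *,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    gate: str = "q",
) -> pd.DataFrame:
    """Apply the |FC| >= threshold and p/q <= alpha selection rule.

    Adds ``significant`` (per row), ``direction`` (+1 increased, -1
    decreased, 0 not significant) and ``significant_any`` (spot significant
    in at least one comparison and measure).
    """
    records = records.copy()
    pcol = "q_bh" if gate == "q" else "p_raw"
    sig = (records["signed_fc"].abs() >= fc_threshold) & (records[pcol] <= alpha)
    sig &= ~records["both_low"].fillna(False)
    records["significant"] = sig
    records["direction"] = np.where(
        sig, np.sign(records["signed_fc"]).astype(int), 0
    )
    any_sig = records.groupby("spot_id")["significant"].transform("any")
    records["significant_any"] = any_sig
    return records


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Tally significant spots by direction per comparison and measure.

    For the ``sno_ror`` measure the directions follow the sign semantics of
    the ratio of ratios: *increased SNO* means a negative signed RoR.  Max
    and min signed fold changes are taken over the significant spots only
    (NaN when none).
    """
    rows = []
    for (comparison, measure), grp in records.groupby(
        ["comparison", "measure"], sort=False
    ):
        sig = grp[grp["significant"]]
        up = sig[sig["signed_fc"] > 0]
        down = sig[sig["signed_fc"] < 0]
        if measure == MEASURE_SNO:
            n_increased, n_decreased = len(down), len(up)  # -ve RoR = SNO up
        else:
            n_increased, n_decreased = len(up), len(down)
        rows.append(
            {
                "comparison": comparison,
                "measure": measure,
                "n_significant": len(sig),
                "n_increased": n_increased,
                "n_decreased": n_decreased,
                "max_signed_fc": sig["signed_fc"].max() if len(sig) else np.nan,
                "min_signed_fc": sig["signed_fc"].min() if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)
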