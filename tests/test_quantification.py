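import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snogel as sg
from snogel.quantification import (
    QuantificationError,
    fold_from_summaries,
    group_summaries,
)
from snogel.tables import TableError

from conftest import make_truth


def table_from_totals(design, totals):
    """Two-spot ASC_PLUS table whose per-gel totals are as given."""
    rows = {gid: [t * 0.25, t * 0.75] for gid, t in totals.items()}
    values = pd.DataFrame.from_dict(rows, orient="index", columns=["s1", "s2"])
    return sg.SpotVolumeTable(sg.BD_ASC_PLUS, values)


# ---------------------------------------------------------------- factors --
def test_bias_factor_arithmetic(design):
    totals = {g.gel_id: 200.0 for g in design.gels_for(sg.Aliquot.ASC_PLUS)}
    totals[design.reference_gel_id] = 100.0
    factors = sg.compute_bias_factors(table_from_totals(design, totals), design)
    assert factors.factors[design.reference_gel_id] == 1.0
    other = next(g for g in totals if g != design.reference_gel_id)
    assert factors.factors[other] == pytest.approx(0.5)


def test_identical_gels_give_unit_factors(design):
    totals = {g.gel_id: 321.0 for g in design.gels_for(sg.Aliquot.ASC_PLUS)}
    factors = sg.compute_bias_factors(table_from_totals(design, totals), design)
    assert all(b == pytest.approx(1.0) for b in factors.factors.values())


def test_minus_gel_inherits_cognate_plus_factor(design):
    totals = {
        g.gel_id: 100.0 * (i + 1)
        for i, g in enumerate(design.gels_for(sg.Aliquot.ASC_PLUS))
    }
    factors = sg.compute_bias_factors(table_from_totals(design, totals), design)
    for minus in design.gels_for(sg.Aliquot.ASC_MINUS):
        cognate = design.cognate_asc_plus(minus.gel_id)
        assert factors.factors[minus.gel_id] == factors.factors[cognate.gel_id]
        assert factors.source[minus.gel_id] == cognate.gel_id


def test_degenerate_gel_total_rejected(design):
    totals = {g.gel_id: 100.0 for g in design.gels_for(sg.Aliquot.ASC_PLUS)}
    totals[list(totals)[3]] = 0.0
    with pytest.raises(QuantificationError):
        sg.compute_bias_factors(table_from_totals(design, totals), design)


# -------------------------------------------------------------- normalize --
def test_normalize_scales_and_conserves_totals(design):
    rng = np.random.default_rng(1)
    totals = {
        g.gel_id: float(rng.uniform(50, 500))
        for g in design.gels_for(sg.Aliquot.ASC_PLUS)
    }
    table = table_from_totals(design, totals)
    factors = sg.compute_bias_factors(table, design)
    normalized = sg.normalize(table, factors)
    assert normalized.normalized
    t_ref = totals[design.reference_gel_id]
    np.testing.assert_allclose(normalized.totals().to_numpy(), t_ref, rtol=1e-9)
    # reference gel unchanged
    pd.testing.assert_series_equal(
        normalized.values.loc[design.reference_gel_id],
        table.values.loc[design.reference_gel_id],
    )


def test_double_normalization_guard(design):
    totals = {g.gel_id: 100.0 for g in design.gels_for(sg.Aliquot.ASC_PLUS)}
    table = table_from_totals(design, totals)
    factors = sg.compute_bias_factors(table, design)
    normalized = sg.normalize(table, factors)
    with pytest.raises(QuantificationError):
        sg.normalize(normalized, factors)


def test_missing_factor_coverage_error(design):
    totals = {g.gel_id: 100.0 for g in design.gels_for(sg.Aliquot.ASC_PLUS)}
    table = table_from_totals(design, totals)
    factors = sg.compute_bias_factors(table, design)
    stray = sg.SpotVolumeTable(
        sg.BD_ASC_PLUS, pd.DataFrame([[1.0, 2.0]], index=["nope"], columns=["s1", "s2"])
    )
    with pytest.raises(QuantificationError):
        sg.normalize(stray, factors)


# -------------------------------------------------------------- spillover --
def test_spillover_subtraction_and_clamp():
    pqd = sg.SpotVolumeTable(
        sg.PQD_POST, pd.DataFrame([[1000.0, 50.0]], index=["g"], columns=["a", "b"])
    )
    spill = sg.SpotVolumeTable(
        sg.SPILL_SCAN, pd.DataFrame([[130.0, 80.0]], index=["g"], columns=["a", "b"])
    )
    corr = sg.correct_spillover(pqd, spill)
    assert corr.table.values.at["g", "a"] == 870.0
    assert corr.table.values.at["g", "b"] == 0.0
    assert corr.n_clamped == 1 and bool(corr.clamped.at["g", "b"])


def test_zero_spillover_is_identity():
    pqd = sg.SpotVolumeTable(
        sg.PQD_POST, pd.DataFrame([[10.0, 20.0]], index=["g"], columns=["a", "b"])
    )
    spill = sg.SpotVolumeTable(
        sg.SPILL_SCAN, pd.DataFrame([[0.0, 0.0]], index=["g"], columns=["a", "b"])
    )
    corr = sg.correct_spillover(pqd, spill)
    pd.testing.assert_frame_equal(corr.table.values, pqd.values)
    assert corr.n_clamped == 0


def test_spillover_grid_mismatch_rejected():
    pqd = sg.SpotVolumeTable(
        sg.PQD_POST, pd.DataFrame([[10.0]], index=["g1"], columns=["a"])
    )
    spill = sg.SpotVolumeTable(
        sg.SPILL_SCAN, pd.DataFrame([[1.0]], index=["g2"], columns=["a"])
    )
    with pytest.raises(TableError):
        sg.correct_spillover(pqd, spill)


def test_spillover_estimator_exact_on_proportional_data():
    rng = np.random.default_rng(2)
    bd = pd.DataFrame(rng.uniform(100, 1000, (3, 50)), index=list("xyz"))
    bd.columns = [f"s{i}" for i in range(50)]
    est = sg.estimate_spillover_coefficient(
        sg.SpotVolumeTable(sg.SPILL_SCAN, 0.13 * bd),
        sg.SpotVolumeTable(sg.BD_ASC_PLUS, bd),
    )
    assert est.pooled == pytest.approx(0.13, abs=1e-12)
    assert est.pooled_r2 == pytest.approx(1.0, abs=1e-12)
    est0 = sg.estimate_spillover_coefficient(
        sg.SpotVolumeTable(sg.SPILL_SCAN, 0.0 * bd),
        sg.SpotVolumeTable(sg.BD_ASC_PLUS, bd),
    )
    assert est0.pooled == 0.0


def test_spillover_estimator_monte_carlo(design):
    truth = sg.generate_ground_truth(design, 500, 0.2, seed=6)
    tables = sg.simulate_experiment(
        truth,
        design,
        sg.NoiseModel(cv=0.05, loading_sd=0.1, spillover_coefficient=0.13, seed=6),
    )
    est = sg.estimate_spillover_coefficient(
        tables[sg.SPILL_SCAN], tables[sg.BD_ASC_PLUS]
    )
    assert est.pooled == pytest.approx(0.13, abs=0.01)


def test_all_zero_bd_gel_rejected():
    bd = pd.DataFrame([[0.0, 0.0]], index=["g"], columns=["a", "b"])
    spill = pd.DataFrame([[1.0, 1.0]], index=["g"], columns=["a", "b"])
    with pytest.raises(QuantificationError):
        sg.estimate_spillover_coefficient(
            sg.SpotVolumeTable(sg.SPILL_SCAN, spill),
            sg.SpotVolumeTable(sg.BD_ASC_PLUS, bd),
        )


# ------------------------------------------------------------ fold change --
@pytest.mark.parametrize(
    "ratio,signed", [(1.0, 1.0), (0.25, -4.0), (2.5, 2.5), (1 / 1.5, -1.5)]
)
def test_signed_fold_convention(ratio, signed):
    fc = sg.signed_fold(ratio)
    assert fc.signed == pytest.approx(signed)
    assert not fc.capped


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-6, max_value=1e6).filter(lambda r: abs(r - 1) > 1e-9))
def test_signed_fold_antisymmetry(r):
    assert sg.signed_fold(r).signed == pytest.approx(-sg.signed_fold(1 / r).signed)


def test_signed_fold_never_in_open_unit_interval():
    for r in np.geomspace(0.01, 100, 201):
        s = sg.signed_fold(float(r)).signed
        assert abs(s) >= 1.0


def test_capping_rules():
    up = fold_from_summaries(50.0, 0.5, eps=1.0)
    assert up.signed == 100.0 and up.capped
    down = fold_from_summaries(0.5, 50.0, eps=1.0)
    assert down.signed == -100.0 and down.capped
    low = fold_from_summaries(0.5, 0.2, eps=1.0)
    assert low.signed == 1.0 and low.both_low and not low.capped


# ----------------------------------------------------------------- ratios --
def test_noiseless_identifiability(design, normalized_noiseless):
    truth, normalized = normalized_noiseless
    records = sg.compute_ratios(normalized, design, eps=1.0)
    m1 = records[records.comparison == "M1_vs_M0"].set_index(["measure", "spot_id"])
    for s in truth.spots:
        assert m1.at[("abundance", s.spot_id), "ratio"] == pytest.approx(
            s.abundance_multiplier["M1"], abs=1e-9
        )
        assert m1.at[("sno_ror", s.spot_id), "ratio"] == pytest.approx(
            (1 - 0.5) / (1 - 0.2), abs=1e-9
        )
        assert m1.at[("phospho", s.spot_id), "ratio"] == pytest.approx(0.5, abs=1e-9)
        # phospho halves -> signed -2 under the reciprocal convention
        assert m1.at[("phospho", s.spot_id), "signed_fc"] == pytest.approx(-2.0, abs=1e-9)


def test_treatment_equal_control_gives_unit_folds(design):
    truth = make_truth()
    tables = sg.simulate_experiment(
        truth, design, sg.NoiseModel(cv=0, loading_sd=0, seed=0)
    )
    factors = sg.compute_bias_factors(tables[sg.BD_ASC_PLUS], design)
    corr = sg.correct_spillover(tables[sg.PQD_POST], tables[sg.SPILL_SCAN])
    normalized = {
        sg.BD_ASC_PLUS: sg.normalize(tables[sg.BD_ASC_PLUS], factors),
        sg.BD_ASC_MINUS: sg.normalize(tables[sg.BD_ASC_MINUS], factors),
        sg.PQD_CORRECTED: sg.normalize(corr.table, factors),
    }
    records = sg.compute_ratios(normalized, design)
    np.testing.assert_allclose(records["signed_fc"].to_numpy(), 1.0, atol=1e-9)


def test_sno_sign_semantics_negative_ror_means_more_sno(design):
    """Raising the treatment SNO fraction strictly lowers the RoR ratio and
    flips the signed value negative once it crosses the control level."""
    prev = np.inf
    for s_trt, expect_negative in [(0.05, False), (0.2, False), (0.4, True), (0.7, True)]:
        truth = make_truth(sno={i: {"M1": s_trt} for i in range(40)})
        tables = sg.simulate_experiment(
            truth, design, sg.NoiseModel(cv=0, loading_sd=0, seed=0)
        )
        factors = sg.compute_bias_factors(tables[sg.BD_ASC_PLUS], design)
        corr = sg.correct_spillover(tables[sg.PQD_POST], tables[sg.SPILL_SCAN])
        normalized = {
            sg.BD_ASC_PLUS: sg.normalize(tables[sg.BD_ASC_PLUS], factors),
            sg.BD_ASC_MINUS: sg.normalize(tables[sg.BD_ASC_MINUS], factors),
            sg.PQD_CORRECTED: sg.normalize(corr.table, factors),
        }
        rec = sg.compute_ratios(normalized, design)
        row = rec[(rec.comparison == "M1_vs_M0") & (rec.measure == "sno_ror")].iloc[0]
        assert row.ratio < prev
        prev = row.ratio
        assert (row.signed_fc < 0) == expect_negative


def test_scale_invariance_of_ratios(design, noiseless_tables):
    """Multiplying one sample's volumes in every channel by c>0 (a pure
    loading change) leaves all downstream ratios unchanged."""
    truth, tables = noiseless_tables

    def run(tables):
        factors = sg.compute_bias_factors(tables[sg.BD_ASC_PLUS], design)
        corr = sg.correct_spillover(tables[sg.PQD_POST], tables[sg.SPILL_SCAN])
        normalized = {
            sg.BD_ASC_PLUS: sg.normalize(tables[sg.BD_ASC_PLUS], factors),
            sg.BD_ASC_MINUS: sg.normalize(tables[sg.BD_ASC_MINUS], factors),
            sg.PQD_CORRECTED: sg.normalize(corr.table, factors),
        }
        return sg.compute_ratios(normalized, design)

    base = run(tables)
    c = 3.7
    sample = design.samples("M1")[0]
    scaled = {}
    for ch, t in tables.items():
        values = t.values.copy()
        for aliquot in sg.Aliquot:
            gid = design.gel_for(sample, aliquot).gel_id
            if gid in values.index:
                values.loc[gid] *= c
        scaled[ch] = sg.SpotVolumeTable(ch, values)
    np.testing.assert_allclose(
        run(scaled)["ratio"].to_numpy(), base["ratio"].to_numpy(), rtol=1e-9
    )


def test_ratios_require_normalized_inputs(design, noiseless_tables):
    _, tables = noiseless_tables
    corr = sg.correct_spillover(tables[sg.PQD_POST], tables[sg.SPILL_SCAN])
    raw = {
        sg.BD_ASC_PLUS: tables[sg.BD_ASC_PLUS],
        sg.BD_ASC_MINUS: tables[sg.BD_ASC_MINUS],
        sg.PQD_CORRECTED: corr.table,
    }
    with pytest.raises(QuantificationError):
        sg.compute_ratios(raw, design)


def test_insufficient_replication_rejected():
    design = sg.ExperimentDesign.balanced(n_replicates=1)
    values = pd.DataFrame(
        np.ones((6, 3)),
        index=[g.gel_id for g in design.gels_for(sg.Aliquot.ASC_PLUS)]
        + [g.gel_id for g in design.gels_for(sg.Aliquot.ASC_MINUS)],
        columns=["a", "b", "c"],
    )
    plus = sg.SpotVolumeTable(
        sg.BD_ASC_PLUS, values.iloc[:3], normalized=True
    )
    with pytest.raises(QuantificationError):
        group_summaries(plus, design)
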