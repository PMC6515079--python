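import numpy as np
import pytest

import snogel as sg


@pytest.fixture(scope="session")
def design():
    """The default 3-group x 4-replicate x 2-aliquot (24 gel) layout."""
    return sg.ExperimentDesign.balanced()


def make_truth(
    groups=("M0", "M1", "M2"),
    n_spots=40,
    base=1000.0,
    multipliers=None,
    sno=None,
    phospho=None,
):
    """Hand-built ground truth; per-group dicts default to null everywhere.

    ``multipliers``/``sno``/``phospho`` map spot index -> {group: value};
    unspecified groups fall back to the null value.
    """
    multipliers = multipliers or {}
    sno = sno or {}
    phospho = phospho or {}
    spots = []
    for i in range(n_spots):
        m = {g: 1.0 for g in groups}
        m.update(multipliers.get(i, {}))
        s = {g: 0.2 for g in groups}
        s.update(sno.get(i, {}))
        p = {g: 500.0 for g in groups}
        p.update(phospho.get(i, {}))
        spots.append(
            sg.SpotTruth(
                spot_id=f"s{i:03d}",
                pi=4.0 + 6.0 * (i % 10) / 10,
                mw_kda=20.0 + 5.0 * (i // 10),
                base_abundance=base,
                abundance_multiplier=m,
                sno_fraction=s,
                phospho_level=p,
            )
        )
    return sg.GroundTruth(group_labels=tuple(groups), spots=tuple(spots))


def balanced_truth(n_pairs=20, groups=("M0", "M1", "M2"), sno_trt=0.5, sno_ctl=0.2):
    """Abundance-balanced differential truth: multiplier pairs (m, 2-m) on
    equal base abundance keep every group's total volume equal, which makes
    total-volume normalisation exact."""
    spots = []
    for i in range(n_pairs):
        m = 1.2 + 0.6 * i / max(n_pairs - 1, 1)
        for tag, mult in (("u", m), ("d", 2.0 - m)):
            spots.append(
                sg.SpotTruth(
                    spot_id=f"s{i:03d}{tag}",
                    pi=4.0 + 6.0 * i / n_pairs,
                    mw_kda=30.0 + (0 if tag == "u" else 40.0),
                    base_abundance=1000.0,
                    abundance_multiplier={"M0": 1.0, "M1": mult, "M2": 1.0},
                    sno_fraction={"M0": sno_ctl, "M1": sno_trt, "M2": sno_ctl},
                    phospho_level={"M0": 800.0, "M1": 400.0, "M2": 800.0},
                )
            )
    return sg.GroundTruth(group_labels=tuple(groups), spots=tuple(spots))


@pytest.fixture()
def noiseless_tables(design):
    truth = balanced_truth()
    tables = sg.simulate_experiment(
        truth,
        design,
        sg.NoiseModel(cv=0.0, loading_sd=0.2, gel_loading_jitter_sd=0.0, seed=7),
    )
    return truth, tables


@pytest.fixture()
def normalized_noiseless(design, noiseless_tables):
    truth, tables = noiseless_tables
    factors = sg.compute_bias_factors(tables[sg.BD_ASC_PLUS], design)
    corrected = sg.correct_spillover(tables[sg.PQD_POST], tables[sg.SPILL_SCAN])
    normalized = {
        sg.BD_ASC_PLUS: sg.normalize(tables[sg.BD_ASC_PLUS], factors),
        sg.BD_ASC_MINUS: sg.normalize(tables[sg.BD_ASC_MINUS], factors),
        sg.PQD_CORRECTED: sg.normalize(corrected.table, factors),
    }
    return truth, normalized
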