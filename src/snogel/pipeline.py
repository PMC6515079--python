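"""End-to-end pipeline: simulate/load -> normalize -> correct -> ratios ->
differential statistics -> PCA -> report files."""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import Aliquot, ExperimentDesign
from .differential import differential_analysis, summarize
from .io import RunConfig, read_spot_tables, write_spot_tables
from .pca import grouping_diagnostic, run_pca, sno_ratio_table
from .quantification import (
    compute_bias_factors,
    correct_spillover,
    estimate_spillover_coefficient,
    normalize,
    own_total_factors,
)
from .synthetic import NoiseModel, generate_ground_truth, simulate_experiment
from .tables import (
    BD_ASC_MINUS,
    BD_ASC_PLUS,
    PQD_CORRECTED,
    PQD_POST,
    SNO_RATIO,
    SPILL_SCAN,
    SpotVolumeTable,
)

__all__ = ["PipelineResult", "run_pipeline", "analyze_tables"]


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    design: ExperimentDesign
    records: pd.DataFrame
    summary: pd.DataFrame
    spillover: object
    pca: dict
    normalized: dict[str, SpotVolumeTable]
    n_clamped_pqd: int
    n_capped: int
    out_dir: Path | None = None


def analyze_tables(
    tables: dict[str, SpotVolumeTable],
    design: ExperimentDesign,
    *,
    eps: float = 1.0,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    gate: str = "q",
    bh_family: str = "per_measure_comparison",
    summary: str = "mean",
    normalization: str = "cognate",
    sno_pca_channel: str = "ratio",
) -> PipelineResult:
    """Run the analysis stages on raw measured tables."""
    if normalization == "cognate":
        factors = compute_bias_factors(tables[BD_ASC_PLUS], design)
        factor_for = {ch: factors for ch in (BD_ASC_PLUS, BD_ASC_MINUS, SPILL_SCAN, PQD_POST)}
    else:  # own_total sensitivity alternative
        ref_total = float(
            tables[BD_ASC_PLUS].totals()[design.reference_gel_id]
        )
        factor_for = {
            ch: own_total_factors(tables[ch], ref_total)
            for ch in (BD_ASC_PLUS, BD_ASC_MINUS, SPILL_SCAN, PQD_POST)
        }

    correction = correct_spillover(tables[PQD_POST], tables[SPILL_SCAN])
    spill_est = estimate_spillover_coefficient(
        tables[SPILL_SCAN],
        tables[BD_ASC_PLUS]
        if set(tables[SPILL_SCAN].gel_ids) <= set(tables[BD_ASC_PLUS].gel_ids)
        else tables[BD_ASC_MINUS],
    )

    normalized = {
        BD_ASC_PLUS: normalize(tables[BD_ASC_PLUS], factor_for[BD_ASC_PLUS]),
        BD_ASC_MINUS: normalize(tables[BD_ASC_MINUS], factor_for[BD_ASC_MINUS]),
        PQD_CORRECTED: normalize(correction.table, factor_for[PQD_POST]),
    }

    records = differential_analysis(
        normalized,
        design,
        eps=eps,
        fc_threshold=fc_threshold,
        alpha=alpha,
        gate=gate,
        bh_family=bh_family,
        summary=summary,
    )
    counts = summarize(records)

    pca = {}
    for name, table in (
        ("abundance", normalized[BD_ASC_PLUS]),
        (
            "sno",
            sno_ratio_table(normalized[BD_ASC_MINUS], normalized[BD_ASC_PLUS], design)
            if sno_pca_channel == "ratio"
            else normalized[BD_ASC_MINUS],
        ),
        ("phospho", normalized[PQD_CORRECTED]),
    ):
        try:
            result = run_pca(table, n_components=2, eps=eps)
            _, frac = grouping_diagnostic(result, design)
            pca[name] = {"result": result, "nn_same_group_fraction": frac}
        except Exception as exc:  # degenerate channels stay reportable
            pca[name] = {"error": str(exc)}

    return PipelineResult(
        design=design,
        records=records,
        summary=counts,
        spillover=spill_est,
        pca=pca,
        normalized=normalized,
        n_clamped_pqd=correction.n_clamped,
        n_capped=int(records["capped"].sum()),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured pipeline and write the report bundle."""
    if config.design_path:
        design = ExperimentDesign.load(config.design_path)
    else:
        design = ExperimentDesign.balanced()

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim = dict(config.simulate)
        noise = NoiseModel(**{**config.noise, "seed": config.seed})
        truth = generate_ground_truth(
            design,
            n_spots=int(sim.get("n_spots", 995)),
            frac_differential=float(sim.get("frac_differential", 0.23)),
            effect_range=tuple(sim.get("effect_range", (1.5, 4.0))),
            sno_range=tuple(sim.get("sno_range", (0.10, 0.40))),
            seed=config.seed,
        )
        tables = simulate_experiment(
            truth, design, noise, pqd_aliquot=Aliquot(config.pqd_gel_set)
        )
        truth.to_json(out / "ground_truth.json")
        write_spot_tables(tables, out / "spot_volumes.tsv")
    else:
        tables = read_spot_tables(config.tables_path, design)

    result = analyze_tables(
        tables,
        design,
        eps=config.floor,
        fc_threshold=config.fc_threshold,
        alpha=config.alpha,
        gate=config.gate,
        bh_family=config.bh_family,
        summary=config.summary,
        normalization=config.normalization,
        sno_pca_channel=config.sno_pca_channel,
    )
    result.out_dir = out

    for comparison, grp in result.records.groupby("comparison", sort=False):
        grp.drop(columns=["exp_group", "ctl_group"]).to_csv(
            out / f"differential_{comparison}.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    result.summary.to_csv(
        out / "summary_counts.tsv", sep="\t", index=False, float_format="%.10g"
    )

    for name, entry in result.pca.items():
        if "result" not in entry:
            continue
        res = entry["result"]
        res.scores.to_csv(out / f"pca_{name}_scores.tsv", sep="\t")
        pd.Series(
            res.variance_explained,
            index=[f"PC{i + 1}" for i in range(len(res.variance_explained))],
            name="percent_variance",
        ).to_csv(out / f"pca_{name}_variance.tsv", sep="\t")
        _plot_scores(res, design, out / f"pca_{name}.png")

    _write_run_log(config, design, result, out / "run_log.txt")
    return result


def _plot_scores(res, design: ExperimentDesign, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = {}
    for obs in res.ids:
        gel = design.gel(obs)
        groups.setdefault(gel.group if gel else design.sample_group(obs), []).append(obs)
    for group, ids in groups.items():
        sub = res.scores.loc[ids]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1] if sub.shape[1] > 1 else 0, label=group)
    ax.set_xlabel(f"PC1 ({res.variance_explained[0]:.1f}%)")
    if len(res.variance_explained) > 1:
        ax.set_ylabel(f"PC2 ({res.variance_explained[1]:.1f}%)")
    ax.legend()
    ax.set_title(res.channel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_run_log(
    config: RunConfig, design: ExperimentDesign, result: PipelineResult, path: Path
) -> None:
    lines = [
        f"snogel {__version__} (python {sys.version.split()[0]}, "
        f"numpy {np.__version__}, pandas {pd.__version__})",
        f"seed: {config.seed}",
        f"groups: {', '.join(design.group_labels)} "
        f"(n={design.n_replicates_per_group} per group, {len(design.gels)} gels)",
        f"reference gel: {design.reference_gel_id}",
        "conventions:",
        f"  fc_threshold: {config.fc_threshold}",
        f"  alpha: {config.alpha} (gate on {config.gate})",
        f"  detection floor: {config.floor}",
        f"  bh_family: {config.bh_family}",
        f"  group summary: {config.summary}",
        f"  normalization: {config.normalization}",
        f"  pqd_gel_set: {config.pqd_gel_set}",
        f"spillover pooled estimate: {result.spillover.pooled:.4f} "
        f"(R2 {result.spillover.pooled_r2:.4f})",
        f"capped fold changes: {result.n_capped}",
        f"clamped PQD values: {result.n_clamped_pqd}",
        f"spots significant in any comparison/measure: "
        f"{int(result.records.groupby('spot_id')['significant'].any().sum())}",
    ]
    path.write_text("\n".join(lines) + "\n")
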