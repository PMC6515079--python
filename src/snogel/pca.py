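"""Gel-level principal component analysis of normalised spot volumes.

Observations are gels (or samples, for the per-sample SNO ratio channel),
variables are spots.  Volumes are log2-transformed after flooring at the
detection floor and mean-centred; components come from the singular value
decomposition of the centred matrix (covariance PCA — spots are not scaled
to unit variance, matching how normalised-volume gel analyses are usually
run; correlation PCA is available via ``scale=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .design import ExperimentDesign
from .tables import SNO_RATIO, SpotVolumeTable

__all__ = ["PCAResult", "run_pca", "grouping_diagnostic", "sno_ratio_table", "PCAError"]


class PCAError(ValueError):
    pass


@dataclass(frozen=True)
class PCAResult:
    """Scores, loadings and percent variance explained for one channel."""

    scores: pd.DataFrame            # observations x components
    variance_explained: np.ndarray  # percent, non-increasing
    loadings: pd.DataFrame          # spots x components
    channel: str

    @property
    def ids(self) -> list[str]:
        return list(self.scores.index)


def run_pca(
    table: SpotVolumeTable,
    n_components: int | None = None,
    *,
    eps: float = 1.0,
    log2: bool = True,
    scale: bool = False,
) -> PCAResult:
    """PCA of one normalised spot-volume table (observations = gels)."""
    if not table.normalized:
        raise PCAError(f"{table.channel}: PCA expects normalized volumes")
    n_obs, n_spots = table.values.shape
    if n_obs < 3:
        raise PCAError("PCA needs at least 3 gels")
    max_comp = min(n_obs - 1, n_spots)
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise PCAError(f"n_components must be in [1, {max_comp}]")

    x = table.values.to_numpy(dtype=float)
    if log2:
        # ratio channels sit near 1 and need no detection floor
        floor = np.finfo(float).tiny if table.channel == SNO_RATIO else eps
        x = np.log2(np.maximum(x, floor))
    if np.allclose(x, x[0]):
        raise PCAError("degenerate input: all gels identical")
    if scale:
        sd = x.std(axis=0, ddof=0)
        x = x / np.where(sd > 0, sd, 1.0)

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.values.index, columns=comp_names),
        variance_explained=model.explained_variance_ratio_ * 100.0,
        loadings=pd.DataFrame(
            model.components_.T, index=table.values.columns, columns=comp_names
        ),
        channel=table.channel,
    )


def grouping_diagnostic(
    result: PCAResult, design: ExperimentDesign
) -> tuple[pd.Series, float]:
    """Nearest-neighbour-same-group indicator in PC1-PC2 score space.

    Returns a per-observation boolean series and the fraction of
    observations whose nearest neighbour belongs to the same group — a
    quantitative surrogate for "samples of a group cluster together".  With
    a single group the fraction is trivially 1 and uninformative.
    """
    def group_of(obs_id: str) -> str:
        gel = design.gel(obs_id)
        if gel is not None:
            return gel.group
        return design.sample_group(obs_id)

    labels = pd.Series({i: group_of(i) for i in result.ids})
    counts = labels.value_counts()
    if len(counts) >= 2 and (counts < 2).any():
        raise PCAError("each group needs at least 2 observations")

    coords = result.scores.iloc[:, : min(2, result.scores.shape[1])].to_numpy()
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nearest = d2.argmin(axis=1)
    same = pd.Series(
        labels.to_numpy() == labels.to_numpy()[nearest], index=result.ids
    )
    return same, float(same.mean())


def sno_ratio_table(
    minus: SpotVolumeTable,
    plus: SpotVolumeTable,
    design: ExperimentDesign,
) -> SpotVolumeTable:
    """Per-sample ASC_MINUS / cognate ASC_PLUS ratio table (for SNO PCA)."""
    from .design import Aliquot

    if not (minus.normalized and plus.normalized):
        raise PCAError("sno ratio table needs normalized inputs")
    rows, index = [], []
    for sid in design.samples():
        m = minus.values.loc[design.gel_for(sid, Aliquot.ASC_MINUS).gel_id]
        p = plus.values.loc[design.gel_for(sid, Aliquot.ASC_PLUS).gel_id]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (m / p).replace([np.inf, -np.inf], np.nan).fillna(0.0)
        rows.append(r.to_numpy())
        index.append(sid)
    return SpotVolumeTable(
        SNO_RATIO,
        pd.DataFrame(rows, index=index, columns=minus.spot_ids),
        normalized=True,
    )
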