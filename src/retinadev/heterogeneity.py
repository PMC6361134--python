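"""Expression-heterogeneity (kurtosis) trajectories over development.

Early developmental samples show heavy-tailed expression distributions --
a minority of genes at extreme levels -- which smooth out as the tissue
matures. This module quantifies that with the Pearson (non-excess)
kurtosis m4/m2^2 of each sample's expression distribution and correlates
log2(kurtosis) with developmental stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PreconditionError
from .preprocess import ADULT_PCW_OFFSET, ExpressionMatrix, SampleMeta

__all__ = ["kurtosis", "kurtosis_trajectory", "KurtosisTrajectory"]


def kurtosis(values) -> float:
    """Pearson kurtosis m4/m2^2 with population moments (denominator n).

    Equals 3 for a normal distribution and is bounded below by 1 for any
    non-degenerate sample. Invariant to affine transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise PreconditionError("kurtosis: need a 1-d vector with >=4 values")
    x = x - x.mean()
    m2 = np.mean(x**2)
    if m2 == 0:
        raise PreconditionError("kurtosis: zero variance, kurtosis undefined")
    m4 = np.mean(x**4)
    return float(m4 / m2**2)


@dataclass
class KurtosisTrajectory:
    """Per-sample kurtosis and its correlation with developmental stage."""

    table: pd.DataFrame  # sample, stage, kurtosis, log2_kurtosis
    r: float
    p_value: float
    method: str = "pearson"

    def summary(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "method": self.method}


def kurtosis_trajectory(
    m: ExpressionMatrix,
    meta: SampleMeta,
    layer: str = "log_cpm",
    genes=None,
    adult_offset: float = ADULT_PCW_OFFSET,
    method: str = "pearson",
) -> KurtosisTrajectory:
    """Per-sample kurtosis of the expression distribution vs stage.

    Parameters
    ----------
    layer
        Expression layer supplying the per-sample distribution.
    genes
        Optional gene subset (e.g. protein-coding only); default all genes.
    adult_offset
        Adult samples sit at max(PCW) + offset on the stage axis.
    method
        'pearson' (default) on the numeric stage axis, or 'spearman' for a
        rank correlation invariant to monotone stage relabelling.
    """
    data = m.get_layer(layer)
    if genes is not None:
        data = data.loc[data.index.intersection(pd.Index(genes))]
    stage = meta.stage_values(adult_offset).reindex(m.samples)
    if meta.table["stage_index"].nunique() < 3:
        raise PreconditionError("kurtosis_trajectory: need >=3 distinct stages")

    rows = []
    for s in m.samples:
        try:
            k = kurtosis(data[s].to_numpy())
        except PreconditionError:
            warnings.warn(f"kurtosis_trajectory: degenerate sample {s!r} excluded")
            continue
        rows.append((s, stage[s], k, np.log2(k)))
    table = pd.DataFrame(rows, columns=["sample", "stage", "kurtosis", "log2_kurtosis"])
    if len(table) < 3:
        raise PreconditionError("kurtosis_trajectory: <3 usable samples")

    if method == "spearman":
        r, p = stats.spearmanr(table["log2_kurtosis"], table["stage"])
    elif method == "pearson":
        r, p = stats.pearsonr(table["log2_kurtosis"], table["stage"])
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return KurtosisTrajectory(table=table, r=float(r), p_value=float(p), method=method)
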