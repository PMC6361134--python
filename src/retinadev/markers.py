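"""Marker-panel onset and peak detection, and rank-based DE.

A marker panel is a small set of genes diagnostic of one retinal cell
type (RGC, cone, rod, bipolar, ...). Panel expression per sample is the
mean of a log layer over the panel genes. The onset of a panel is the
earliest developmental stage with a significant (one-sided Wilcoxon
rank-sum, default pooled stages-before vs stages-from comparison) and
sustained increase -- every stage from the onset on has a median above
the pooled pre-onset median. Peak detection finds the window with the
maximal median panel expression and tests it against each other window.

``rank_de`` is a deliberately simple rank-based two-group differential
expression routine (per-gene two-sided rank-sum on log-CPM with
Benjamini-Hochberg adjustment) used as pipeline plumbing between
adjacent windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PreconditionError, ValidationError
from .preprocess import ExpressionMatrix, SampleMeta

__all__ = [
    "MarkerPanel",
    "OnsetResult",
    "PeakResult",
    "wilcoxon_rank_sum",
    "panel_expression",
    "onset_detection",
    "peak_detection",
    "rank_de",
]


@dataclass
class MarkerPanel:
    """Named gene set for one cell type."""

    name: str
    genes: list

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"MarkerPanel {self.name!r}: empty gene list")

    def present_genes(self, m: ExpressionMatrix) -> list:
        present = [g for g in self.genes if g in m.genes]
        missing = sorted(set(self.genes) - set(present))
        if missing:
            warnings.warn(f"panel {self.name!r}: dropping missing genes {missing}")
        if not present:
            raise ValidationError(f"panel {self.name!r}: no genes present in matrix")
        return present


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided"):
    """Wilcoxon rank-sum (Mann-Whitney) test of two samples.

    ``alternative``: 'increase' tests whether y is shifted above x,
    'decrease' the reverse, 'two-sided' either. Exact enumeration is used
    when the pooled size is <= 12 and no value is shared between the two
    samples (within-sample ties never enter a cross-pair comparison),
    otherwise the normal approximation with tie correction. Returns
    (U statistic of x, p-value); for identical tied samples
    U = |x||y|/2 under midranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise PreconditionError("wilcoxon_rank_sum: empty sample")
    alt_map = {"increase": "less", "decrease": "greater", "two-sided": "two-sided"}
    if alternative not in alt_map:
        raise ValidationError(f"wilcoxon_rank_sum: unknown alternative {alternative!r}")
    no_cross_ties = not np.intersect1d(x, y).size
    method = "exact" if (x.size + y.size <= 12 and no_cross_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt_map[alternative], method=method)
    return float(res.statistic), float(res.pvalue)


def panel_expression(
    m: ExpressionMatrix, panel: MarkerPanel, layer: str = "log_cpm"
) -> pd.Series:
    """Per-sample panel score: mean of the log layer over panel genes."""
    genes = panel.present_genes(m)
    return m.get_layer(layer).loc[genes].mean(axis=0)


@dataclass
class OnsetResult:
    panel: str
    onset: object  # stage label, or None
    p_value: float | None
    stage_medians: pd.Series = field(repr=False)
    sustained: bool = False


def _stage_groups(meta: SampleMeta):
    """Stage labels in stage_index order with their sample lists."""
    t = meta.table.sort_values("stage_index")
    order = list(dict.fromkeys(t["stage_label"]))
    groups = {s: t.loc[t["stage_label"] == s, "sample"].tolist() for s in order}
    return order, groups


def onset_detection(
    m: ExpressionMatrix,
    meta: SampleMeta,
    panel: MarkerPanel,
    alpha: float = 0.05,
    layer: str = "log_cpm",
    comparison: str = "pooled",
    min_increase: float = 1.0,
) -> OnsetResult:
    """Earliest stage with a significant and sustained panel increase.

    For each candidate stage s (stage 2 onward), a one-sided rank-sum
    test asks whether expression from s on is increased over the pooled
    earlier stages (``comparison='pooled'`` pools all stages >= s;
    ``comparison='stage'`` uses the values at stage s alone). The onset
    is the earliest s with p < alpha whose increase is sustained: the
    median of every stage >= s exceeds the pooled median of stages < s
    by at least ``min_increase`` (log2 units; default 1, i.e. 2-fold).
    The margin keeps chance orderings of noise-level stage medians from
    registering as an onset; ``min_increase=0`` gives the pure ordering
    rule.
    """
    if comparison not in ("pooled", "stage"):
        raise ValidationError(f"onset_detection: unknown comparison {comparison!r}")
    expr = panel_expression(m, panel, layer=layer)
    order, groups = _stage_groups(meta)
    if len(order) < 2:
        raise PreconditionError("onset_detection: need >=2 stages")
    stage_vals = {s: expr[groups[s]].to_numpy() for s in order}
    medians = pd.Series({s: float(np.median(stage_vals[s])) for s in order})

    for i in range(1, len(order)):
        before = np.concatenate([stage_vals[s] for s in order[:i]])
        if comparison == "pooled":
            after = np.concatenate([stage_vals[s] for s in order[i:]])
        else:
            after = stage_vals[order[i]]
        _stat, p = wilcoxon_rank_sum(before, after, alternative="increase")
        if p >= alpha:
            continue
        pre_median = float(np.median(before))
        sustained = all(medians[s] > pre_median + min_increase for s in order[i:])
        if sustained:
            return OnsetResult(
                panel=panel.name,
                onset=order[i],
                p_value=p,
                stage_medians=medians,
                sustained=True,
            )
    return OnsetResult(
        panel=panel.name, onset=None, p_value=None, stage_medians=medians
    )


@dataclass
class PeakResult:
    panel: str
    peak: object  # window label
    p_values: pd.Series = field(repr=False)  # vs every other window
    tie: bool = False


def peak_detection(
    m: ExpressionMatrix,
    meta: SampleMeta,
    panel: MarkerPanel,
    alpha: float = 0.05,
    layer: str = "log_cpm",
) -> PeakResult:
    """Window with maximal median panel expression, tested vs each other window.

    A tie in medians reports the earliest window (stage order) with the
    tie flag set. Comparisons against windows with <2 samples are skipped
    with a warning.
    """
    expr = panel_expression(m, panel, layer=layer)
    windows = meta.windows().reindex(expr.index)
    order = meta.window_order()
    if len(order) < 2:
        raise PreconditionError("peak_detection: need >=2 windows")
    vals = {w: expr[windows == w].to_numpy() for w in order}
    medians = pd.Series({w: float(np.median(vals[w])) for w in order})
    best = medians.max()
    peak_candidates = [w for w in order if medians[w] == best]
    peak = peak_candidates[0]
    tie = len(peak_candidates) > 1

    pvals = {}
    for w in order:
        if w == peak:
            continue
        if len(vals[w]) < 2 or len(vals[peak]) < 2:
            warnings.warn(f"peak_detection: window {w!r} vs {peak!r} has <2 samples, skipped")
            continue
        _stat, p = wilcoxon_rank_sum(vals[w], vals[peak], alternative="increase")
        pvals[w] = p
    return PeakResult(panel=panel.name, peak=peak, p_values=pd.Series(pvals), tie=tie)


def rank_de(
    m: ExpressionMatrix,
    meta: SampleMeta,
    window_a,
    window_b,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
    layer: str = "log_cpm",
) -> pd.DataFrame:
    """Rank-based two-group DE between two windows.

    Per gene: two-sided rank-sum on the log layer, log2 fold change of
    means (b minus a), Benjamini-Hochberg q across genes; significant
    iff q < alpha and \\|log2FC\\| >= lfc_min.
    """
    windows = meta.windows()
    sa = windows.index[windows == window_a]
    sb = windows.index[windows == window_b]
    if len(sa) == 0 or len(sb) == 0:
        raise PreconditionError(f"rank_de: empty window ({window_a!r} or {window_b!r})")
    if len(sa) < 2 or len(sb) < 2:
        raise PreconditionError("rank_de: both windows need >=2 samples")
    data = m.get_layer(layer)
    a = data[sa].to_numpy()
    b = data[sb].to_numpy()
    # exact null distribution at small group sizes: the normal approximation
    # cannot reach the BH threshold when min attainable p matters
    method = "exact" if max(len(sa), len(sb)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    _rej, qvals, _a1, _a2 = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "log2FC": lfc,
            "p": pvals,
            "q": qvals,
            "significant": (qvals < alpha) & (np.abs(lfc) >= lfc_min),
        },
        index=m.genes,
    )
    return out.sort_values("p")
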