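"""circRNA developmental-dynamics statistics.

Circular RNAs are detected through backsplice junctions (a downstream
splice donor joined to an upstream acceptor). Starting from a table of
backsplice and canonical junction read counts, this module computes:

* per-sample circ:canonical ratios (global circRNA abundance) and their
  ordered-trend test across developmental windows;
* circRNA genomic span (acceptor - donor, a circle-size proxy) and its
  trend across windows;
* the Jonckheere-Terpstra test for an ordered increase across >= 2
  groups, built from pairwise Mann-Whitney counts;
* dual-controlled circRNA differential expression between adjacent
  windows -- backsplice abundance adjusted both for the sample-level
  global circ:canonical ratio and for locus-level total gene
  expression, so neither a global circRNA shift nor a linear-expression
  change of the host gene registers as circRNA regulation;
* circ-linear correlation across differentially expressed genes, with
  the <1 backsplice read per million filter;
* locus circular fraction (reads on junctions inside the circle
  interval over all junction reads of the gene);
* conservation overlap classification between two junction sets.

Coordinates are 0-based, half-open [donor, acceptor) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PreconditionError, ValidationError
from .preprocess import ExpressionMatrix, SampleMeta

__all__ = [
    "JunctionTable",
    "TrendTestResult",
    "circ_canonical_ratio",
    "biotype_proportions",
    "circ_span",
    "jonckheere_terpstra",
    "circ_trend_tests",
    "circ_de",
    "circ_linear_correlation",
    "locus_circ_fraction",
    "junction_conservation",
]

COORD_COLS = ["chrom", "donor", "acceptor", "strand", "gene", "type"]


@dataclass
class JunctionTable:
    """Backsplice and canonical junction records with per-sample counts.

    ``table`` columns: chrom, donor, acceptor, strand, gene, type
    ('backsplice' or 'canonical'), then one integer count column per
    sample. Coordinates are 0-based half-open with donor < acceptor.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COORD_COLS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"junctions: missing columns {sorted(missing)}")
        t = self.table
        if not (t["donor"] < t["acceptor"]).all():
            raise ValidationError("junctions: donor must be < acceptor")
        if not t["type"].isin(["backsplice", "canonical"]).all():
            raise ValidationError("junctions: type must be backsplice or canonical")
        key = t[["chrom", "donor", "acceptor", "strand", "type"]]
        if key.duplicated().any():
            raise ValidationError("junctions: duplicate (chrom,donor,acceptor,strand,type)")
        counts = t[self.samples]
        if (counts.to_numpy() < 0).any():
            raise ValidationError("junctions: negative counts")

    @property
    def samples(self) -> list:
        return [c for c in self.table.columns if c not in COORD_COLS]

    def counts(self, kind: str | None = None) -> pd.DataFrame:
        t = self.table if kind is None else self.table[self.table["type"] == kind]
        return t[self.samples]

    def backsplice(self) -> pd.DataFrame:
        return self.table[self.table["type"] == "backsplice"]

    def canonical(self) -> pd.DataFrame:
        return self.table[self.table["type"] == "canonical"]

    def to_bed6(self) -> pd.DataFrame:
        """BED6 export of backsplice (circRNA) intervals, 0-based half-open."""
        bs = self.backsplice()
        total = bs[self.samples].sum(axis=1)
        return pd.DataFrame(
            {
                "chrom": bs["chrom"],
                "chromStart": bs["donor"],
                "chromEnd": bs["acceptor"],
                "name": bs["gene"],
                "score": total,
                "strand": bs["strand"],
            }
        )


def circ_canonical_ratio(j: JunctionTable, sample: str) -> float:
    """Total backsplice reads / total canonical junction reads in a sample."""
    if sample not in j.samples:
        raise ValidationError(f"circ_canonical_ratio: unknown sample {sample!r}")
    bs = float(j.counts("backsplice")[sample].sum())
    can = float(j.counts("canonical")[sample].sum())
    if can == 0:
        raise PreconditionError(f"circ_canonical_ratio: zero canonical total in {sample!r}")
    return bs / can


def biotype_proportions(
    j: JunctionTable, biotype_counts: pd.Series, sample: str
) -> pd.Series:
    """Read proportions over backsplice, canonical and each other biotype."""
    if (np.asarray(biotype_counts, dtype=float) < 0).any():
        raise ValidationError("biotype_proportions: negative biotype counts")
    parts = pd.Series(
        {
            "backsplice": float(j.counts("backsplice")[sample].sum()),
            "canonical": float(j.counts("canonical")[sample].sum()),
        }
    )
    parts = pd.concat([parts, biotype_counts.astype(float)])
    total = parts.sum()
    if total <= 0:
        raise PreconditionError("biotype_proportions: zero total reads")
    return parts / total


def circ_span(record) -> int:
    """Genomic span acceptor - donor of one junction record."""
    donor, acceptor = int(record["donor"]), int(record["acceptor"])
    if donor >= acceptor:
        raise ValidationError(f"circ_span: donor {donor} not < acceptor {acceptor}")
    return acceptor - donor


@dataclass
class TrendTestResult:
    """Jonckheere-Terpstra result for the ordered-increase alternative."""

    statistic: float  # J
    null_mean: float
    null_var: float
    z: float
    p_value: float
    group_sizes: list
    alternative: str = "increase"
    p_permutation: float | None = None


def jonckheere_terpstra(
    groups, rng=None, n_permutations: int = 0
) -> TrendTestResult:
    """Jonckheere-Terpstra test for an ordered increase across groups.

    J sums, over ordered group pairs i < j, the Mann-Whitney counts
    #{x in g_i, y in g_j : x < y} + 0.5 * #{x = y}. Under the null the
    mean is (N^2 - sum n_i^2)/4 and the tie-free variance
    [N^2(2N+3) - sum n_i^2(2n_i+3)] / 72; the one-sided p comes from the
    normal approximation, optionally supplemented by a permutation p
    (``n_permutations`` label shuffles, which also accounts for ties).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise PreconditionError("jonckheere_terpstra: need >=2 ordered groups")
    if any(g.size == 0 for g in groups):
        raise PreconditionError("jonckheere_terpstra: empty group")
    sizes = [g.size for g in groups]
    n_total = sum(sizes)

    def j_stat(gs) -> float:
        j = 0.0
        for i in range(len(gs)):
            for k in range(i + 1, len(gs)):
                x = gs[i][:, None]
                y = gs[k][None, :]
                j += np.sum(x < y) + 0.5 * np.sum(x == y)
        return float(j)

    j = j_stat(groups)
    mean = (n_total**2 - sum(s**2 for s in sizes)) / 4.0
    var = (
        n_total**2 * (2 * n_total + 3) - sum(s**2 * (2 * s + 3) for s in sizes)
    ) / 72.0
    z = (j - mean) / np.sqrt(var)
    p = float(stats.norm.sf(z))

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(rng)
        pooled = np.concatenate(groups)
        bounds = np.cumsum(sizes)[:-1]
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            hits += j_stat(np.split(perm, bounds)) >= j
        p_perm = (hits + 1) / (n_permutations + 1)
    return TrendTestResult(
        statistic=j,
        null_mean=mean,
        null_var=var,
        z=float(z),
        p_value=p,
        group_sizes=sizes,
        p_permutation=p_perm,
    )


def _window_samples(j: JunctionTable, meta: SampleMeta):
    order = meta.window_order()
    windows = meta.windows()
    groups = {w: [s for s in j.samples if windows.get(s) == w] for w in order}
    return order, groups


def circ_trend_tests(
    j: JunctionTable, meta: SampleMeta, span_mode: str = "presence"
) -> tuple[TrendTestResult, TrendTestResult]:
    """Ordered-trend tests of circRNA abundance and size across windows.

    The ratio test runs Jonckheere-Terpstra on per-sample circ:canonical
    ratios grouped by window order. The span test runs it on per-window
    circRNA span lists: with ``span_mode='presence'`` each circRNA
    detected in a window (>= 1 backsplice read in any of its samples)
    contributes its span once; ``span_mode='reads'`` weights spans by
    total backsplice reads in the window.
    """
    order, groups = _window_samples(j, meta)
    if len(order) < 2:
        raise PreconditionError("circ_trend_tests: need >=2 windows")
    ratio_groups = []
    for w in order:
        vals = [circ_canonical_ratio(j, s) for s in groups[w]]
        ratio_groups.append(np.array(vals))
    ratio_res = jonckheere_terpstra(ratio_groups)

    bs = j.backsplice()
    spans = (bs["acceptor"] - bs["donor"]).to_numpy()
    span_groups = []
    for w in order:
        counts = bs[groups[w]].to_numpy().sum(axis=1)
        if span_mode == "presence":
            span_groups.append(spans[counts >= 1])
        elif span_mode == "reads":
            span_groups.append(np.repeat(spans, counts))
        else:
            raise ValidationError(f"circ_trend_tests: unknown span_mode {span_mode!r}")
    if any(g.size == 0 for g in span_groups):
        raise PreconditionError("circ_trend_tests: window without detected circRNAs")
    span_res = jonckheere_terpstra(span_groups)
    return ratio_res, span_res


def _circ_ids(bs: pd.DataFrame) -> pd.Index:
    return pd.Index(
        bs["chrom"].astype(str)
        + ":"
        + bs["donor"].astype(str)
        + "-"
        + bs["acceptor"].astype(str)
        + ":"
        + bs["strand"].astype(str)
    )


def circ_de(
    j: JunctionTable,
    m: ExpressionMatrix,
    meta: SampleMeta,
    window_a,
    window_b,
    alpha: float = 0.05,
    ratio_estimator: str = "median",
) -> pd.DataFrame:
    """Dual-controlled circRNA DE between two (adjacent) windows.

    Per circRNA and sample, the adjusted abundance is
    (backsplice / libsize) / (sample-level circRNA factor)
    / (locus expression / libsize); a two-sided rank-sum compares the
    adjusted abundances between the windows, with BH adjustment across
    circRNAs. The two denominators make the measure invariant to
    per-sample library scaling and to global circRNA-rate shifts.

    The sample-level factor is, by default, the median over detected
    circRNAs of the per-locus backsplice:canonical fraction
    (``ratio_estimator='median'``), which stays honest when a notable
    share of circles is itself regulated; ``ratio_estimator='total'``
    uses the plain total backsplice / total canonical ratio, which the
    median matches in genome-scale junction sets where regulated circles
    are a vanishing fraction.
    """
    windows = meta.windows()
    sa = [s for s in j.samples if windows.get(s) == window_a]
    sb = [s for s in j.samples if windows.get(s) == window_b]
    if len(sa) < 2 or len(sb) < 2:
        raise PreconditionError("circ_de: both windows need >=2 samples")
    use = sa + sb
    bs = j.backsplice().reset_index(drop=True)
    if bs.empty:
        raise PreconditionError("circ_de: no backsplice junctions")
    lib = m.library_sizes()
    if ratio_estimator == "total":
        global_ratio = pd.Series({s: circ_canonical_ratio(j, s) for s in use})
    elif ratio_estimator == "median":
        canon_by_gene = j.canonical().groupby("gene")[use].sum()
        locus_canon = canon_by_gene.reindex(bs["gene"]).to_numpy(dtype=float)
        bs_counts = bs[use].to_numpy(dtype=float)
        # factor estimated on circles detected in both windows, so circles
        # arising only in the later window do not flood the median with 0s
        detected = (bs[sa].sum(axis=1) > 0).to_numpy() & (
            bs[sb].sum(axis=1) > 0
        ).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = bs_counts / locus_canon
        frac = frac[detected]
        if frac.size == 0 or np.isnan(frac).all():
            raise PreconditionError("circ_de: no detected circRNA for the sample factor")
        global_ratio = pd.Series(np.nanmedian(frac, axis=0), index=use)
        if (global_ratio <= 0).any():
            raise PreconditionError(
                "circ_de: zero median circ fraction in a sample; too few detected circRNAs"
            )
    else:
        raise ValidationError(f"circ_de: unknown ratio_estimator {ratio_estimator!r}")
    locus = m.counts.reindex(bs["gene"]).astype(float)

    keep = (locus[use].to_numpy() > 0).any(axis=1)
    if not keep.all():
        dropped = bs.loc[~keep, "gene"].unique().tolist()
        warnings.warn(f"circ_de: loci with zero expression excluded: {dropped}")
        bs = bs.loc[keep].reset_index(drop=True)
        if bs.empty:
            raise PreconditionError("circ_de: no circRNA locus with nonzero expression")
        locus = m.counts.reindex(bs["gene"]).astype(float)

    adj = np.empty((len(bs), len(use)))
    for col, s in enumerate(use):
        locus_rel = locus[s].to_numpy() / lib[s]
        with np.errstate(divide="ignore", invalid="ignore"):
            adj[:, col] = (
                bs[s].to_numpy() / lib[s] / global_ratio[s] / locus_rel
            )
    adj = np.nan_to_num(adj, nan=0.0, posinf=0.0)
    a = adj[:, : len(sa)]
    b = adj[:, len(sa):]
    method = "exact" if max(len(sa), len(sb)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, axis=1)
    pvals = np.asarray(res.pvalue, dtype=float)
    eff = np.log2(b.mean(axis=1) + 1e-9) - np.log2(a.mean(axis=1) + 1e-9)
    _rej, qvals, _a1, _a2 = multipletests(pvals, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": bs["gene"].to_numpy(),
            "effect_log2": eff,
            "p": pvals,
            "q": qvals,
            "direction": np.where(eff > 0, "up", "down"),
            "significant": qvals < alpha,
        },
        index=_circ_ids(bs),
    )
    return out.sort_values("p")


def circ_linear_correlation(
    j: JunctionTable,
    m: ExpressionMatrix,
    de_genes,
    meta: SampleMeta,
    window_a,
    window_b,
    min_cpm: float = 1.0,
    pseudocount: float = 0.5,
):
    """Pearson correlation of circRNA vs host-gene expression changes.

    For each differentially expressed gene: delta_linear = log2 change of
    mean total gene expression (CPM) between the windows, delta_circ =
    log2 change of mean backsplice CPM; genes whose backsplice CPM stays
    below ``min_cpm`` in every sample of both windows are excluded.
    Returns (r, n_genes, excluded gene list).
    """
    de_genes = list(de_genes)
    if not de_genes:
        raise PreconditionError("circ_linear_correlation: empty DE gene list")
    windows = meta.windows()
    sa = [s for s in j.samples if windows.get(s) == window_a]
    sb = [s for s in j.samples if windows.get(s) == window_b]
    lib = m.library_sizes()
    bs = j.backsplice()
    bs_gene = bs.groupby("gene")[j.samples].sum()

    deltas = []
    excluded = []
    for g in de_genes:
        if g not in bs_gene.index or g not in m.genes:
            excluded.append(g)
            continue
        circ_cpm = bs_gene.loc[g, sa + sb] / lib[sa + sb] * 1e6
        if (circ_cpm[sa] < min_cpm).all() and (circ_cpm[sb] < min_cpm).all():
            excluded.append(g)
            continue
        gene_cpm = m.counts.loc[g, sa + sb] / lib[sa + sb] * 1e6
        d_lin = np.log2(gene_cpm[sb].mean() + pseudocount) - np.log2(
            gene_cpm[sa].mean() + pseudocount
        )
        d_circ = np.log2(circ_cpm[sb].mean() + pseudocount) - np.log2(
            circ_cpm[sa].mean() + pseudocount
        )
        deltas.append((d_lin, d_circ))
    if len(deltas) < 3:
        raise PreconditionError(
            f"circ_linear_correlation: only {len(deltas)} genes after filtering"
        )
    arr = np.array(deltas)
    r, _p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), len(deltas), excluded


def locus_circ_fraction(
    j: JunctionTable, gene, sample_set=None, interval=None
) -> float:
    """Fraction of a gene's junction reads inside its circRNA interval.

    Junctions whose both splice sites fall within [donor, acceptor) of
    the circle (the backsplice itself included) count as inside. By
    default the gene's most abundant backsplice defines the circle;
    pass ``interval=(donor, acceptor)`` to override.
    """
    t = j.table[j.table["gene"] == gene]
    if t.empty:
        raise ValidationError(f"locus_circ_fraction: gene {gene!r} absent")
    samples = list(sample_set) if sample_set is not None else j.samples
    if interval is None:
        bs = t[t["type"] == "backsplice"]
        if bs.empty:
            raise ValidationError(f"locus_circ_fraction: no backsplice for {gene!r}")
        top = bs.loc[bs[samples].sum(axis=1).idxmax()]
        interval = (int(top["donor"]), int(top["acceptor"]))
    lo, hi = interval
    total = float(t[samples].sum(axis=1).sum())
    if total == 0:
        raise PreconditionError(f"locus_circ_fraction: no junction reads for {gene!r}")
    inside = (t["donor"] >= lo) & (t["acceptor"] <= hi)
    return float(t.loc[inside, samples].sum(axis=1).sum()) / total


def junction_conservation(
    set_a: JunctionTable, set_b: JunctionTable
) -> tuple[int, int]:
    """Classify set_a backsplice junctions against set_b.

    Returns (n_overlapping, n_precise): precise means identical (chrom,
    donor, acceptor, strand); overlapping means the intervals intersect
    on the same chrom and strand without matching precisely. Each set_a
    record is counted at most once, precise taking priority.
    """
    a = set_a.backsplice()
    b = set_b.backsplice()
    precise_keys = set(map(tuple, b[["chrom", "donor", "acceptor", "strand"]].to_numpy()))
    n_precise = 0
    n_overlap = 0
    for _, rec in a.iterrows():
        key = (rec["chrom"], rec["donor"], rec["acceptor"], rec["strand"])
        if key in precise_keys:
            n_precise += 1
            continue
        same = b[(b["chrom"] == rec["chrom"]) & (b["strand"] == rec["strand"])]
        if ((same["donor"] < rec["acceptor"]) & (same["acceptor"] > rec["donor"])).any():
            n_overlap += 1
    return n_overlap, n_precise
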