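"""Count-matrix containers, validation and normalisation.

The pipeline operates on a genes x samples matrix of non-negative integer
read counts plus per-sample metadata giving each sample's developmental
stage in post-conception weeks (PCW), with adult samples ordered last.
Normalisation layers provided here:

* ``cpm`` / ``log_cpm`` -- counts per million with a pseudocount,
  ``log2((count + c) / (libsize + 2c) * 1e6)``;
* ``qnorm_log`` -- quantile-normalised log-CPM, the layer used for
  sample clustering;
* median-of-ratios size factors (the DESeq-style library normalisation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PreconditionError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SampleMeta",
    "size_factors",
    "log_cpm",
    "quantile_normalize",
    "read_counts",
    "read_meta",
]

#: stage value assigned to adult samples on the numeric PCW axis; adult
#: retina is plotted apart from the fetal series, so it is coded strictly
#: above the largest fetal PCW.
ADULT_PCW_OFFSET = 20.0


@dataclass
class ExpressionMatrix:
    """Genes x samples count matrix with optional derived layers.

    ``counts`` holds non-negative integers; every layer shares its index
    (gene ids) and columns (sample ids) exactly.
    """

    counts: pd.DataFrame
    layers: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("counts: duplicate gene ids")
        if c.columns.has_duplicates:
            raise ValidationError("counts: duplicate sample ids")
        if (c.to_numpy() < 0).any():
            raise ValidationError("counts: negative values present")
        for name, layer in self.layers.items():
            self._check_layer(name, layer)

    def _check_layer(self, name: str, layer: pd.DataFrame) -> None:
        if not layer.index.equals(self.counts.index) or not layer.columns.equals(
            self.counts.columns
        ):
            raise ValidationError(f"layer {name!r}: axis labels differ from counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def add_layer(self, name: str, layer: pd.DataFrame) -> None:
        self._check_layer(name, layer)
        self.layers[name] = layer

    def get_layer(self, name: str) -> pd.DataFrame:
        if name == "counts":
            return self.counts
        if name not in self.layers:
            raise ValidationError(
                f"layer {name!r} not present; available: {sorted(self.layers)}"
            )
        return self.layers[name]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class SampleMeta:
    """Per-sample developmental stage table.

    ``table`` columns: ``sample``, ``stage_label``, ``pcw`` (NaN for
    adult), ``stage_index`` (total order, adult last) and optionally
    ``window``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "stage_label", "pcw", "stage_index"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"meta: missing columns {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            raise ValidationError("meta: duplicate sample ids")
        t = self.table
        # stage_index must order consistently with pcw, adults strictly last
        fetal = t[t["pcw"].notna()]
        if len(fetal) > 1:
            by_idx = fetal.sort_values("stage_index")["pcw"].to_numpy()
            if not np.all(np.diff(by_idx) >= 0):
                raise ValidationError("meta: stage_index inconsistent with pcw order")
        adult = t[t["pcw"].isna()]
        if len(adult) and len(fetal):
            if adult["stage_index"].min() <= fetal["stage_index"].max():
                raise ValidationError("meta: adult samples must have the largest stage_index")

    @property
    def samples(self) -> pd.Index:
        return pd.Index(self.table["sample"])

    @property
    def stage_index(self) -> pd.Series:
        return self.table.set_index("sample")["stage_index"]

    @property
    def stage_labels(self) -> pd.Series:
        return self.table.set_index("sample")["stage_label"]

    def is_adult(self) -> pd.Series:
        return self.table.set_index("sample")["pcw"].isna()

    def stage_values(self, adult_offset: float = ADULT_PCW_OFFSET) -> pd.Series:
        """Numeric stage axis: PCW for fetal samples, max(PCW)+offset for adult."""
        pcw = self.table.set_index("sample")["pcw"].astype(float)
        if pcw.isna().all():
            raise ValidationError("meta: no fetal samples, stage axis undefined")
        return pcw.fillna(pcw.max() + adult_offset)

    def windows(self) -> pd.Series:
        if "window" not in self.table.columns:
            raise ValidationError("meta: no window labels assigned")
        return self.table.set_index("sample")["window"]

    def with_windows(self, labels: pd.Series) -> "SampleMeta":
        t = self.table.copy()
        t["window"] = labels.reindex(t["sample"]).to_numpy()
        return SampleMeta(t)

    def window_order(self) -> list:
        """Window labels ordered by mean stage_index of their samples."""
        w = self.windows()
        idx = self.stage_index
        means = idx.groupby(w).mean().sort_values()
        return list(means.index)


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library size factors.

    For genes with nonzero counts in every sample, factor_j is the median
    over those genes of count_gj / geometric-mean_g(count). Factors are
    returned as computed, with no rescaling.
    """
    if m.n_samples < 2:
        raise PreconditionError("size_factors: need >=2 samples")
    counts = m.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise PreconditionError(
            "size_factors: no gene has nonzero counts in every sample; "
            "use CPM normalisation instead"
        )
    sub = counts[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.samples, name="size_factor")


def log_cpm(m: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2 counts-per-million layer.

    log2((count + c) / (library_size + 2c) * 1e6) with pseudocount c > 0;
    strictly increasing in counts for fixed library size.
    """
    if pseudocount <= 0:
        raise ValidationError("log_cpm: pseudocount must be > 0")
    lib = m.library_sizes().to_numpy(dtype=float)
    if (lib == 0).any():
        bad = m.samples[lib == 0].tolist()
        raise ValidationError(f"log_cpm: zero library size for samples {bad}")
    counts = m.counts.to_numpy(dtype=float)
    vals = np.log2((counts + pseudocount) / (lib + 2.0 * pseudocount) * 1e6)
    return pd.DataFrame(vals, index=m.genes, columns=m.samples)


def quantile_normalize(layer: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns to the cross-column rank-mean distribution.

    After normalisation every column's sorted values equal the means of the
    column-wise order statistics; tied values within a column receive the
    mean of the rank-mean values their ranks span.
    """
    x = layer.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValidationError("quantile_normalize: missing values present")
    n, k = x.shape
    if k == 1:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return layer.copy()
    rank_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(k):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = rank_means
        # ties: average the rank-mean values across each tied run
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        tied_vals = assigned[order]
        for s, e in zip(starts, ends):
            if e - s > 1:
                tied_vals[s:e] = tied_vals[s:e].mean()
        assigned[order] = tied_vals
        out[:, j] = assigned
    return pd.DataFrame(out, index=layer.index, columns=layer.columns)


def read_counts(path) -> ExpressionMatrix:
    """Read a counts TSV (gene id in the first column, one column per sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty counts table")
    return ExpressionMatrix(df)


def read_meta(path) -> SampleMeta:
    """Read a sample metadata TSV (sample, stage_label, pcw, stage_index[, window])."""
    df = pd.read_csv(path, sep="\t")
    if "pcw" in df.columns:
        df["pcw"] = pd.to_numeric(df["pcw"], errors="coerce")
    return SampleMeta(df)
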