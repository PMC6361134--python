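"""Synthetic developmental time-course generator.

Emulates a bulk RNA-seq series over four developmental windows
(4.6-7.2 PCW, 7.7-10 PCW, 12-18 PCW, adult) with the statistical
structure the downstream analyses assume, plus a truth record for
parameter-recovery tests:

* negative-binomial counts with log-normal gene-level means and shared
  dispersion; log-normal library-size variation so normalisation is
  non-trivially exercised;
* window-signature genes upregulated in exactly one window, so
  clustering plus Moran-eigenvector staging can recover the windows;
* marker panels that jump by a configured fold at their onset stage and
  stay elevated (sustained increase);
* a nested pool of extreme-high "spike" genes whose per-stage fraction
  decays linearly to zero, driving the decreasing per-sample kurtosis
  (heavy early tails thin out as development proceeds); the nesting
  means later stages silence a subset of the earlier spike set, as a
  progenitor programme being shut down would;
* circRNA junction tables: canonical junction counts proportional to
  each gene's linear expression, backsplice counts Poisson with rate =
  canonical output x per-window global rate x locus multiplier; circle
  genomic spans log-normal per home window, and circles only active
  from their home window onward, which plants the increase in circle
  size over development.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SimConfig.seed``; identical configs give byte-identical TSV output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circrna import JunctionTable
from .errors import ValidationError
from .markers import MarkerPanel
from .preprocess import ExpressionMatrix, SampleMeta

__all__ = ["SimConfig", "TruthRecord", "gen_timecourse", "gen_junctions", "write_outputs"]

#: default stage grid: three fetal stages per window plus adult
DEFAULT_STAGES = [
    ("4.6", 4.6), ("5.7", 5.7), ("7.2", 7.2),
    ("7.7", 7.7), ("9.0", 9.0), ("10.0", 10.0),
    ("12.0", 12.0), ("15.0", 15.0), ("18.0", 18.0),
    ("adult", None),
]
DEFAULT_STAGE_WINDOWS = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3]

DEFAULT_PANELS = {
    "RGC": 2,
    "horizontal": 3,
    "cone": 4,
    "amacrine": 5,
    "rod": 6,
    "bipolar": 7,
    "muller": 8,
}


def _default_marker_panels() -> dict:
    # 5 genes per panel, 8-fold sustained jump at the panel's onset stage
    return {
        name: ([f"MK_{name}_{i + 1}" for i in range(5)], onset, 8.0)
        for name, onset in DEFAULT_PANELS.items()
    }


@dataclass
class SimConfig:
    """Generator parameters; defaults define the study conditions."""

    n_genes: int = 2000
    stages: list = field(default_factory=lambda: list(DEFAULT_STAGES))
    stage_windows: list = field(default_factory=lambda: list(DEFAULT_STAGE_WINDOWS))
    samples_per_stage: int = 2
    #: panel name -> (gene ids, onset stage index, fold change)
    marker_panels: dict = field(default_factory=_default_marker_panels)
    #: (starting spike-gene fraction, spike fold); fraction decays linearly
    #: to 0. A small pool of strongly dominant transcripts (~2% of genes at
    #: 32x, a quarter of the early library, several SDs into the log-CPM
    #: tail) models the heavy-tailed expression of early progenitor tissue.
    heterogeneity_decay: tuple = (0.02, 64.0)
    #: per-window signature genes and their fold; windows are separated by
    #: many moderately changed transcripts, as adjacent-window DE is in
    #: real developmental series
    window_signature: tuple = (300, 4.0)
    #: global backsplice:canonical rate per window
    circ_rate_per_window: list = field(default_factory=lambda: [0.005, 0.01, 0.02, 0.04])
    #: per-window log-normal (mu, sigma) of circle genomic span
    circ_size_params: list = field(
        default_factory=lambda: [
            (math.log(500.0), 0.6),
            (math.log(700.0), 0.6),
            (math.log(1000.0), 0.6),
            (math.log(1400.0), 0.6),
        ]
    )
    n_circ_loci: int = 150
    #: home window per circle locus; None -> round-robin over windows
    circ_home_windows: list | None = None
    #: circRNA gene id -> per-window rate multipliers (planted circ DE)
    de_circ_set: dict = field(default_factory=dict)
    #: panel name -> (gene ids, peak window index, fold): transiently
    #: elevated panels for peak-detection tests (default none)
    peak_panels: dict = field(default_factory=dict)
    nb_dispersion: float = 0.1
    canonical_fraction: float = 0.3
    library_size_cv: float = 0.2
    mean_log_mu: float = math.log(150.0)
    mean_log_sigma: float = 0.8
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("SimConfig.n_genes must be positive")
        pcw = [p for _label, p in self.stages if p is not None]
        if any(b <= a for a, b in zip(pcw, pcw[1:])):
            raise ValidationError("SimConfig.stages: PCW values must be strictly increasing")
        adult_pos = [i for i, (_l, p) in enumerate(self.stages) if p is None]
        if adult_pos and adult_pos[0] < len(self.stages) - len(adult_pos):
            raise ValidationError("SimConfig.stages: adult stages must come last")
        if len(self.stage_windows) != len(self.stages):
            raise ValidationError("SimConfig.stage_windows: one window index per stage")
        if self.samples_per_stage <= 0:
            raise ValidationError("SimConfig.samples_per_stage must be positive")
        n_stages = len(self.stages)
        for name, (_genes, onset, _fold) in self.marker_panels.items():
            if not 1 <= onset < n_stages:
                raise ValidationError(
                    f"SimConfig.marker_panels[{name!r}]: onset index {onset} "
                    f"outside [1, {n_stages - 1}]"
                )
        for name, (_genes, win, _fold) in self.peak_panels.items():
            if not 0 <= win < self.n_windows:
                raise ValidationError(
                    f"SimConfig.peak_panels[{name!r}]: window index {win} out of range"
                )
        if self.nb_dispersion <= 0:
            raise ValidationError("SimConfig.nb_dispersion must be positive")
        n_windows = self.n_windows
        if len(self.circ_rate_per_window) != n_windows:
            raise ValidationError("SimConfig.circ_rate_per_window: one rate per window")
        if any(r <= 0 for r in self.circ_rate_per_window):
            raise ValidationError("SimConfig.circ_rate_per_window: rates must be positive")
        if len(self.circ_size_params) != n_windows:
            raise ValidationError("SimConfig.circ_size_params: one (mu, sigma) per window")
        if self.circ_home_windows is not None:
            if len(self.circ_home_windows) != self.n_circ_loci:
                raise ValidationError("SimConfig.circ_home_windows: one window per locus")
            if any(not 0 <= h < n_windows for h in self.circ_home_windows):
                raise ValidationError("SimConfig.circ_home_windows: window index out of range")

    @property
    def n_windows(self) -> int:
        return max(self.stage_windows) + 1

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @classmethod
    def null(cls, seed: int = 0) -> "SimConfig":
        """Null conditions: no onsets, no spikes, no signatures, flat circ rates."""
        panels = {
            name: (genes, onset, 1.0)
            for name, (genes, onset, _f) in _default_marker_panels().items()
        }
        return cls(
            marker_panels=panels,
            heterogeneity_decay=(0.0, 1.0),
            window_signature=(0, 1.0),
            circ_rate_per_window=[0.02, 0.02, 0.02, 0.02],
            circ_size_params=[(math.log(800.0), 0.6)] * 4,
            circ_home_windows=[0] * 150,
            seed=seed,
        )

    def panels(self) -> list:
        return [MarkerPanel(name, genes) for name, (genes, _o, _f) in self.marker_panels.items()]


@dataclass
class TruthRecord:
    """Planted parameters for recovery tests."""

    seed: int
    marker_onsets: dict = field(default_factory=dict)  # panel -> stage label or None
    windows: dict = field(default_factory=dict)  # sample -> window label
    circ_trend_effect: float | None = None  # log2(last rate / first rate)
    de_circ_ids: list = field(default_factory=list)
    spike_fractions: dict = field(default_factory=dict)  # stage label -> fraction

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "marker_onsets": self.marker_onsets,
                "windows": self.windows,
                "circ_trend_effect": self.circ_trend_effect,
                "de_circ_ids": self.de_circ_ids,
                "spike_fractions": self.spike_fractions,
            },
            indent=2,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# gene id layout
# ---------------------------------------------------------------------------

def _gene_ids(config: SimConfig) -> dict:
    """Partition gene ids into marker / signature / spike / circ / background."""
    marker = [g for genes, _o, _f in config.marker_panels.values() for g in genes]
    marker += [g for genes, _w, _f in config.peak_panels.values() for g in genes]
    n_sig, _fold = config.window_signature
    signature = {
        w: [f"WS{w + 1}_{i + 1}" for i in range(n_sig)] for w in range(config.n_windows)
    }
    f0, _spike_fold = config.heterogeneity_decay
    n_spike = int(round(f0 * config.n_genes))
    spikes = [f"SPK_{i + 1:03d}" for i in range(n_spike)]
    circ = [f"CIRC_{i + 1:03d}" for i in range(config.n_circ_loci)]
    n_special = len(marker) + n_sig * config.n_windows + n_spike + len(circ)
    n_bg = config.n_genes - n_special
    if n_bg < 0:
        raise ValidationError(
            f"SimConfig.n_genes={config.n_genes} too small for {n_special} structured genes"
        )
    background = [f"G{i + 1:05d}" for i in range(n_bg)]
    all_ids = (
        marker
        + [g for w in range(config.n_windows) for g in signature[w]]
        + spikes
        + circ
        + background
    )
    return {
        "all": all_ids,
        "marker": marker,
        "signature": signature,
        "spikes": spikes,
        "circ": circ,
    }


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

def gen_timecourse(config: SimConfig):
    """Generate (ExpressionMatrix, SampleMeta, TruthRecord)."""
    config.validate()
    rng = np.random.default_rng([config.seed % (2**31), 0])
    ids = _gene_ids(config)
    genes = ids["all"]
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    # samples and metadata
    rows = []
    for idx, (label, pcw) in enumerate(config.stages):
        for rep in range(config.samples_per_stage):
            rows.append((f"S{idx:02d}r{rep + 1}", label, pcw, idx))
    meta_df = pd.DataFrame(rows, columns=["sample", "stage_label", "pcw", "stage_index"])
    samples = meta_df["sample"].tolist()
    stage_of_sample = meta_df["stage_index"].to_numpy()
    window_of_sample = np.array([config.stage_windows[i] for i in stage_of_sample])

    # gene-level base means; circle loci drawn hot: detected circRNA
    # universes are conditioned on junction coverage, so host genes sit
    # well above the median expression
    base = rng.lognormal(config.mean_log_mu, config.mean_log_sigma, size=n_genes)
    for g in ids["circ"]:
        base[gene_pos[g]] *= 20.0

    mean = np.tile(base[:, None], (1, len(samples))).astype(float)

    # window signatures
    _n_sig, sig_fold = config.window_signature
    for w, sig_genes in ids["signature"].items():
        cols = window_of_sample == w
        for g in sig_genes:
            mean[gene_pos[g], cols] *= sig_fold

    # marker onsets (sustained elevation from the onset stage on)
    truth_onsets = {}
    for name, (panel_genes, onset, fold) in config.marker_panels.items():
        if fold == 1.0:
            truth_onsets[name] = None
            continue
        truth_onsets[name] = config.stages[onset][0]
        cols = stage_of_sample >= onset
        for g in panel_genes:
            mean[gene_pos[g], cols] *= fold

    # transient peak panels (elevated in one window only)
    for name, (panel_genes, win, fold) in config.peak_panels.items():
        cols = window_of_sample == win
        for g in panel_genes:
            mean[gene_pos[g], cols] *= fold

    # nested spike pool drives decaying kurtosis
    f0, spike_fold = config.heterogeneity_decay
    n_stages = config.n_stages
    spike_fractions = {}
    if f0 > 0 and ids["spikes"]:
        pool = np.array([gene_pos[g] for g in ids["spikes"]])
        for idx, (label, _pcw) in enumerate(config.stages):
            frac = f0 * (1.0 - idx / (n_stages - 1))
            spike_fractions[label] = frac
            k = int(round(frac * config.n_genes))
            if k == 0:
                continue
            cols = stage_of_sample == idx
            mean[pool[:k][:, None], np.flatnonzero(cols)[None, :]] *= spike_fold
    else:
        spike_fractions = {label: 0.0 for label, _p in config.stages}

    # library-size variation
    cv = config.library_size_cv
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        lib_factor = rng.lognormal(-0.5 * sigma**2, sigma, size=len(samples))
    else:
        lib_factor = np.ones(len(samples))
    mean *= lib_factor[None, :]

    # negative-binomial sampling via gamma-Poisson mixture
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    counts = rng.poisson(lam)

    m = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    meta = SampleMeta(meta_df)
    truth = TruthRecord(
        seed=config.seed,
        marker_onsets=truth_onsets,
        windows={s: f"W{w + 1}" for s, w in zip(samples, window_of_sample)},
        spike_fractions=spike_fractions,
    )
    return m, meta, truth


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------

def gen_junctions(config: SimConfig, meta: SampleMeta, m: ExpressionMatrix | None = None):
    """Generate (JunctionTable, TruthRecord) for the circRNA analyses.

    Canonical junction counts are Poisson around each gene's linear
    output (``canonical_fraction`` of its read count split over its
    junctions); backsplice counts are Poisson with rate = canonical
    output x per-window rate x locus multiplier, zero before the
    circle's home window. If ``m`` is omitted the time course is
    regenerated from the config.
    """
    config.validate()
    if m is None:
        m, meta_check, _t = gen_timecourse(config)
        if not meta.table["sample"].tolist() == meta_check.table["sample"].tolist():
            raise ValidationError("gen_junctions: meta does not match config")
    missing = [s for s in meta.samples if s not in m.samples]
    if missing:
        raise ValidationError(f"gen_junctions: meta samples absent from matrix: {missing}")
    rng = np.random.default_rng([config.seed % (2**31), 1])
    samples = list(meta.samples)
    stage_of_sample = meta.table.set_index("sample")["stage_index"]
    window_of_sample = np.array(
        [config.stage_windows[stage_of_sample[s]] for s in samples]
    )
    rate_w = np.array([config.circ_rate_per_window[w] for w in window_of_sample])

    ids = _gene_ids(config)
    circ_genes = ids["circ"]
    n_windows = config.n_windows
    homes = (
        list(config.circ_home_windows)
        if config.circ_home_windows is not None
        else [i % n_windows for i in range(len(circ_genes))]
    )

    # locus-level baseline multipliers (biological variability of circ output)
    locus_mult = rng.lognormal(0.0, 0.5, size=len(circ_genes))

    gene_counts = m.counts
    records = []
    counts_rows = []

    def add(chrom, donor, acceptor, strand, gene, kind, mean_counts):
        records.append((chrom, int(donor), int(acceptor), strand, gene, kind))
        counts_rows.append(rng.poisson(np.maximum(mean_counts, 0.0)))

    de_ids = []
    for i, g in enumerate(circ_genes):
        locus_start = 1000 + i * 100_000
        span = max(
            20,
            int(round(rng.lognormal(*config.circ_size_params[homes[i]]))),
        )
        donor = locus_start + 1000
        acceptor = donor + span
        linear = gene_counts.loc[g, samples].to_numpy(dtype=float)
        canon_total = linear * config.canonical_fraction

        # canonical junctions: two inside the circle, one outside (upstream)
        third = max(span // 3, 1)
        inside = [(donor + 5, donor + 5 + third), (donor + third, acceptor - 5)]
        outside = (locus_start, locus_start + 500)
        for d, a in inside:
            add("chrS", d, min(a, acceptor), "+", g, "canonical", canon_total / 3.0)
        add("chrS", outside[0], outside[1], "+", g, "canonical", canon_total / 3.0)

        mult = np.full(len(samples), locus_mult[i])
        mult[window_of_sample < homes[i]] = 0.0
        if g in config.de_circ_set:
            per_window = np.asarray(config.de_circ_set[g], dtype=float)
            if per_window.size != n_windows:
                raise ValidationError(
                    f"SimConfig.de_circ_set[{g!r}]: need one multiplier per window"
                )
            mult = mult * per_window[window_of_sample]
            if np.unique(per_window).size > 1:
                de_ids.append(g)
        add("chrS", donor, acceptor, "+", g, "backsplice", canon_total * rate_w * mult)

    # one canonical junction for every non-circ gene
    offset = len(circ_genes) * 100_000 + 10_000
    other = [g for g in ids["all"] if g not in set(circ_genes)]
    linear = gene_counts.loc[other, samples].to_numpy(dtype=float)
    canon = linear * config.canonical_fraction
    canon_counts = rng.poisson(canon)
    for k, g in enumerate(other):
        start = offset + k * 10_000
        records.append(("chrS", start, start + 800, "+", g, "canonical"))
    rec_df = pd.DataFrame(records, columns=["chrom", "donor", "acceptor", "strand", "gene", "type"])
    count_df = pd.DataFrame(
        np.vstack([np.array(counts_rows), canon_counts]) if counts_rows else canon_counts,
        columns=samples,
    )
    table = pd.concat([rec_df, count_df], axis=1)
    rates = config.circ_rate_per_window
    truth = TruthRecord(
        seed=config.seed,
        circ_trend_effect=float(np.log2(rates[-1] / rates[0])),
        de_circ_ids=sorted(de_ids),
    )
    return JunctionTable(table), truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_outputs(outdir, config: SimConfig):
    """Run the generator and write counts/meta/junctions/truth to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m, meta, truth = gen_timecourse(config)
    junctions, jtruth = gen_junctions(config, meta, m)
    truth.circ_trend_effect = jtruth.circ_trend_effect
    truth.de_circ_ids = jtruth.de_circ_ids

    counts = m.counts.copy()
    counts.index.name = "gene"
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    meta.table.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    junctions.table.to_csv(outdir / "junctions.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    return m, meta, junctions, truth
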