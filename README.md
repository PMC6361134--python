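# retinadev

Developmental staging and circRNA dynamics for bulk RNA-seq time
courses of the developing human retina.

Developmental transcriptome series pose a recurring set of questions:
how heterogeneous is gene expression at each stage, how do the samples
group into developmental windows, when does each cell-type marker
switch on, and how does the circular RNA (circRNA) population change as
the tissue matures? `retinadev` implements an integrated, tested
pipeline for these analyses, aimed at computational biologists working
with staged bulk RNA-seq (and the matching splice-junction counts) from
fetal retina or comparable developmental series.

## What it computes

**Expression heterogeneity.** For each sample the Pearson kurtosis
m₄/m₂² of the expression distribution (log₂ CPM over genes), and the
Pearson correlation of log₂(kurtosis) with developmental stage in
post-conception weeks (PCW; adult samples are coded above the fetal
range). Early progenitor tissue shows heavy-tailed expression that
smooths out with maturation, so the trajectory is expected to fall.

**Moran-eigenvector staging.** Samples are clustered hierarchically
(median agglomeration via the Lance–Williams update
d(k, i∪j) = ½d(k,i) + ½d(k,j) − ¼d(i,j) on Euclidean distances over the
quantile-normalised log layer). The ultrametric tree becomes a
proximity matrix a_ij = 1/d_ij (reciprocal patristic distance), which
is double-centred and eigen-decomposed into Moran eigenvectors (MEs):
score columns with mean 0, variance 1 and zero mutual correlation.
Sign rules on the leading MEs ("ME1 low", "ME2 high", …) partition the
samples into developmental windows; `derive_window_rules` constructs
such rules automatically from the tree.

**Marker onset and peak.** Panel expression (mean log₂ CPM over the
panel's genes) is tested per candidate stage with a one-sided Wilcoxon
rank-sum (exact at small n): the onset is the earliest stage with a
significant increase over the pooled earlier stages that is sustained —
every later stage median above the pre-onset pooled median by at least
a 2-fold margin. Peak detection reports the window with maximal median
panel expression, tested against each other window.

**circRNA dynamics.** From backsplice/canonical junction counts:
per-sample circ:canonical read ratios and circRNA genomic spans
(acceptor − donor), each tested for an ordered increase across windows
with the Jonckheere–Terpstra statistic
J = Σ_{i<j} #{x∈gᵢ, y∈gⱼ : x < y} (ties ½); dual-controlled circRNA
differential expression (backsplice abundance adjusted for the
sample-level circRNA factor and for locus-level total expression, so
neither a global circRNA shift nor host-gene regulation masquerades as
circRNA regulation); circ–linear correlation over DE genes with the
<1 backsplice read per million filter; per-locus circular fraction;
and conservation classification of junction sets (precise vs
overlapping coordinates).

**Synthetic data.** A negative-binomial generator plants all of the
above — four developmental windows, marker onsets, decaying spike-gene
heterogeneity, rising circRNA rates and sizes — and emits a truth
record, so every analysis is validated by parameter recovery.

## Worked example

```sh
retinadev simulate --outdir sim --seed 7
retinadev report --indir sim --outdir out
```

`out/report.json` (seed 7) contains:

```json
{
 "kurtosis": {"r": -0.714, "p_value": 0.00041, "method": "pearson"},
 "n_me_components": 19,
 "marker_onsets": {"RGC": "7.2", "horizontal": "7.7", "cone": "9.0",
                   "amacrine": "10.0", "rod": "12.0", "bipolar": "15.0",
                   "muller": "18.0"},
 "circ_ratio_trend_p": 4.8e-07,
 "circ_span_trend_p": 2.8e-05,
 "circ_de_significant": {"W1_vs_W2": 34, "W2_vs_W3": 35, "W3_vs_W4": 0}
}
```

Reading: per-sample kurtosis falls with stage (r = −0.71, p = 4×10⁻⁴),
the 20 samples yield 19 ME components and the sign rules recover the
four planted windows exactly (`windows` in the report); each marker
panel's detected onset matches its planted stage; both circRNA trends
(abundance and size) are significant increases; and circRNA DE between
adjacent windows finds the circles that arise at each window boundary,
with none between W3 and adult where nothing was planted. The same
steps run on user data with the identical TSV schemas (`counts.tsv`,
`meta.tsv`, `junctions.tsv`).

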