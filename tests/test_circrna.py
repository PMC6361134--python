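import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retinadev as rd
from retinadev.errors import PreconditionError, ValidationError


def jt_table(rows, samples):
    cols = ["chrom", "donor", "acceptor", "strand", "gene", "type"] + samples
    return rd.JunctionTable(pd.DataFrame(rows, columns=cols))


def brute_force_j(groups):
    """Exhaustive pair counting oracle for the JT statistic."""
    j = 0.0
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[k]:
                    j += (x < y) + 0.5 * (x == y)
    return j


class TestJunctionTable:
    def test_coordinate_and_type_validation(self):
        with pytest.raises(ValidationError, match="donor"):
            jt_table([("chr1", 500, 100, "+", "g", "backsplice", 1)], ["s1"])
        with pytest.raises(ValidationError, match="type"):
            jt_table([("chr1", 100, 500, "+", "g", "weird", 1)], ["s1"])
        with pytest.raises(ValidationError, match="duplicate"):
            jt_table(
                [
                    ("chr1", 100, 500, "+", "g", "canonical", 1),
                    ("chr1", 100, 500, "+", "g", "canonical", 2),
                ],
                ["s1"],
            )

    def test_bed6_export_uses_half_open_coordinates(self):
        t = jt_table(
            [
                ("chr1", 100, 500, "+", "g", "backsplice", 7),
                ("chr1", 10, 90, "+", "g", "canonical", 3),
            ],
            ["s1"],
        )
        bed = t.to_bed6()
        assert bed.iloc[0].tolist() == ["chr1", 100, 500, "g", 7, "+"]


class TestRatiosAndSpans:
    def test_ratio_arithmetic(self):
        t = jt_table(
            [
                ("chr1", 100, 500, "+", "g", "backsplice", 10),
                ("chr1", 10, 90, "+", "g", "canonical", 1000),
            ],
            ["s1"],
        )
        assert rd.circ_canonical_ratio(t, "s1") == pytest.approx(0.01)

    def test_ratio_scale_invariance(self):
        rows = [
            ("chr1", 100, 500, "+", "g", "backsplice", 10, 20),
            ("chr1", 10, 90, "+", "g", "canonical", 1000, 2000),
        ]
        t = jt_table(rows, ["s1", "s2"])
        assert rd.circ_canonical_ratio(t, "s1") == pytest.approx(
            rd.circ_canonical_ratio(t, "s2")
        )

    def test_zero_canonical_rejected(self):
        t = jt_table([("chr1", 100, 500, "+", "g", "backsplice", 10)], ["s1"])
        with pytest.raises(PreconditionError, match="canonical"):
            rd.circ_canonical_ratio(t, "s1")

    def test_window_means_match_direct_recomputation(self, staged_sim):
        _cfg, _m, meta, junctions, _t, _tree, _basis = staged_sim
        windows = meta.windows()
        bs = junctions.counts("backsplice").sum(axis=0)
        can = junctions.counts("canonical").sum(axis=0)
        for w in meta.window_order():
            samples = [s for s in junctions.samples if windows[s] == w]
            expected = np.mean([bs[s] / can[s] for s in samples])
            got = np.mean([rd.circ_canonical_ratio(junctions, s) for s in samples])
            assert got == pytest.approx(expected)

    def test_span_examples(self):
        assert rd.circ_span({"donor": 100, "acceptor": 600}) == 500
        assert rd.circ_span({"donor": 100, "acceptor": 101}) == 1
        with pytest.raises(ValidationError):
            rd.circ_span({"donor": 100, "acceptor": 100})

    def test_biotype_proportions(self):
        t = jt_table(
            [
                ("chr1", 100, 500, "+", "g", "backsplice", 5),
                ("chr1", 10, 90, "+", "g", "canonical", 95),
            ],
            ["s1"],
        )
        props = rd.biotype_proportions(t, pd.Series(dtype=float), "s1")
        assert props["backsplice"] == pytest.approx(0.05)
        assert props["canonical"] == pytest.approx(0.95)
        with_bio = rd.biotype_proportions(t, pd.Series({"rRNA": 100, "lncRNA": 100}), "s1")
        assert with_bio.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValidationError):
            rd.biotype_proportions(t, pd.Series({"rRNA": -1}), "s1")


class TestJonckheereTerpstra:
    def test_two_group_example_closed_form(self):
        res = rd.jonckheere_terpstra([[1, 2], [3, 4]])
        assert res.statistic == 4.0
        assert res.null_mean == 2.0
        assert res.null_var == pytest.approx(5 / 3)

    def test_reversed_groups_give_zero(self):
        assert rd.jonckheere_terpstra([[3, 4], [1, 2]]).statistic == 0.0

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 6, size=rng.integers(2, 6)).tolist() for _ in range(k)]
            res = rd.jonckheere_terpstra(groups)
            assert res.statistic == brute_force_j(groups)
            assert 0 <= res.statistic <= res.null_mean * 2 + 1e-9

    def test_normal_p_close_to_permutation_p(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(loc=i * 0.5, size=6) for i in range(4)]
        res = rd.jonckheere_terpstra(groups, rng=99, n_permutations=4000)
        se = np.sqrt(res.p_permutation * (1 - res.p_permutation) / 4000)
        assert abs(res.p_value - res.p_permutation) <= 3 * se + 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(PreconditionError):
            rd.jonckheere_terpstra([[1.0], []])


class TestCircTrendTests:
    def test_null_p_values_uniform(self):
        """Constant planted rate: trend p over seeds is uniform."""
        ps = []
        for seed in range(200):
            cfg = rd.SimConfig.null(seed=seed)
            m, meta, truth = rd.gen_timecourse(cfg)
            j, _jt = rd.gen_junctions(cfg, meta, m)
            meta = meta.with_windows(pd.Series(truth.windows))
            ratio_res, _span = rd.circ_trend_tests(j, meta)
            ps.append(ratio_res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_reversing_window_order_flips_significance(self, staged_sim):
        _cfg, _m, meta, junctions, _t, _tree, _basis = staged_sim
        ratio_res, _ = rd.circ_trend_tests(junctions, meta)
        flipped = meta.table.copy()
        flipped["stage_index"] = -flipped["stage_index"]
        flipped["pcw"] = 50 - flipped["pcw"].fillna(30)
        flipped = flipped.sort_values("stage_index").reset_index(drop=True)
        rev_meta = rd.SampleMeta(flipped)
        rev_res, _ = rd.circ_trend_tests(junctions, rev_meta)
        assert ratio_res.p_value < 0.05
        assert rev_res.p_value > 0.95

    def test_span_medians_increase_with_window(self, staged_sim):
        _cfg, _m, meta, junctions, _t, _tree, _basis = staged_sim
        windows = meta.windows()
        bs = junctions.backsplice()
        spans = (bs["acceptor"] - bs["donor"]).to_numpy()
        meds = []
        for w in meta.window_order():
            samples = [s for s in junctions.samples if windows[s] == w]
            present = bs[samples].sum(axis=1).to_numpy() >= 1
            meds.append(np.median(spans[present]))
        assert all(b >= a for a, b in zip(meds, meds[1:]))

    def test_truth_effect_zero_iff_constant_rate(self):
        cfg = rd.SimConfig.null(seed=0)
        m, meta, _t = rd.gen_timecourse(cfg)
        _j, jt = rd.gen_junctions(cfg, meta, m)
        assert jt.circ_trend_effect == 0.0
        assert jt.de_circ_ids == []
        cfg2 = rd.SimConfig(seed=0)
        m2, meta2, _ = rd.gen_timecourse(cfg2)
        _j2, jt2 = rd.gen_junctions(cfg2, meta2, m2)
        assert jt2.circ_trend_effect == pytest.approx(3.0)


class TestCircDe:
    def test_library_scaling_invariance(self, staged_sim):
        _cfg, m, meta, junctions, _t, _tree, _basis = staged_sim
        order = meta.window_order()
        de1 = rd.circ_de(junctions, m, meta, order[1], order[2])
        # double every count of one sample: counts, canonical and backsplice
        s = junctions.samples[0]
        j2 = rd.JunctionTable(junctions.table.assign(**{s: junctions.table[s] * 2}))
        c2 = m.counts.copy()
        c2[s] = c2[s] * 2
        m2 = rd.ExpressionMatrix(c2)
        de2 = rd.circ_de(j2, m2, meta, order[1], order[2])
        np.testing.assert_allclose(
            de1["p"].to_numpy(), de2.reindex(de1.index)["p"].to_numpy(), rtol=1e-9
        )

    def test_global_rate_shift_yields_no_discoveries(self):
        fp_rates = []
        for seed in range(10):
            cfg = rd.SimConfig(seed=seed, circ_home_windows=[0] * 150)
            m, meta, truth = rd.gen_timecourse(cfg)
            j, _jt = rd.gen_junctions(cfg, meta, m)
            meta = meta.with_windows(pd.Series(truth.windows))
            de = rd.circ_de(j, m, meta, "W2", "W3")
            fp_rates.append(de["significant"].mean())
        assert np.mean(fp_rates) <= 0.05

    def test_too_small_windows_rejected(self, staged_sim):
        _cfg, m, meta, junctions, _t, _tree, _basis = staged_sim
        with pytest.raises(PreconditionError):
            rd.circ_de(junctions, m, meta, "W1", "absent")


class TestCircLinearCorrelation:
    def test_low_circ_genes_excluded(self):
        samples = ["a1", "a2", "b1", "b2"]
        lib = 1_000_000
        rows = []
        counts = {}
        for i, g in enumerate(["g0", "g1", "g2", "low"]):
            # 'low' stays below 1 backsplice read per million in every sample
            fold = i + 1
            circ = [1000, 1000, 1000 * fold, 1000 * fold] if g != "low" else [0, 0, 0, 0]
            rows.append(
                ("chr1", 100 + i * 10_000, 600 + i * 10_000, "+", g, "backsplice")
                + tuple(circ)
            )
            counts[g] = [lib // 4] * 4
        t = rd.JunctionTable(
            pd.DataFrame(
                rows,
                columns=["chrom", "donor", "acceptor", "strand", "gene", "type"] + samples,
            )
        )
        m = rd.ExpressionMatrix(pd.DataFrame(counts, index=samples).T)
        meta = rd.SampleMeta(
            pd.DataFrame(
                {
                    "sample": samples,
                    "stage_label": ["A", "A", "B", "B"],
                    "pcw": [1.0, 1.0, 2.0, 2.0],
                    "stage_index": [0, 0, 1, 1],
                    "window": ["A", "A", "B", "B"],
                }
            )
        )
        _r, n, excluded = rd.circ_linear_correlation(
            t, m, ["g0", "g1", "g2", "low"], meta, "A", "B", min_cpm=1.0
        )
        assert excluded == ["low"]
        assert n == 3

    def test_perfectly_proportional_changes_give_r_one(self):
        samples = ["a1", "a2", "b1", "b2"]
        rows = []
        counts = {}
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(6)]
        lib = 1_000_000
        for i, g in enumerate(genes):
            base = 1000 * (i + 1)
            fold = 2 ** (i % 3)
            gene_counts = [base, base, base * fold, base * fold]
            circ_counts = [c // 10 for c in gene_counts]
            rows.append(
                ("chr1", 100 + i * 10_000, 600 + i * 10_000, "+", g, "backsplice")
                + tuple(circ_counts)
            )
            counts[g] = gene_counts
        t = rd.JunctionTable(
            pd.DataFrame(
                rows,
                columns=["chrom", "donor", "acceptor", "strand", "gene", "type"] + samples,
            )
        )
        filler = {g: [lib // 10] * 4 for g in ["x1", "x2"]}
        cm = pd.DataFrame({**counts, **filler}).T
        cm.columns = samples
        m = rd.ExpressionMatrix(cm)
        meta = rd.SampleMeta(
            pd.DataFrame(
                {
                    "sample": samples,
                    "stage_label": ["A", "A", "B", "B"],
                    "pcw": [1.0, 1.0, 2.0, 2.0],
                    "stage_index": [0, 0, 1, 1],
                    "window": ["A", "A", "B", "B"],
                }
            )
        )
        r, n, excluded = rd.circ_linear_correlation(
            t, m, genes, meta, "A", "B", pseudocount=1e-6
        )
        assert n == 6
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_planted_shared_rate_gives_high_r(self):
        rs = []
        for seed in range(10):
            cfg = rd.SimConfig(seed=seed, circ_home_windows=[0] * 150)
            m, meta, truth = rd.gen_timecourse(cfg)
            j, _jt = rd.gen_junctions(cfg, meta, m)
            meta = meta.with_windows(pd.Series(truth.windows))
            genes = list(j.backsplice()["gene"].unique())
            r, _n, _ex = rd.circ_linear_correlation(j, m, genes, meta, "W2", "W3")
            rs.append(r)
        assert np.mean(rs) >= 0.6

    def test_too_few_genes_rejected(self, staged_sim):
        _cfg, m, meta, junctions, _t, _tree, _basis = staged_sim
        order = meta.window_order()
        with pytest.raises(PreconditionError):
            rd.circ_linear_correlation(
                junctions, m, ["CIRC_001"], meta, order[0], order[1]
            )


class TestLocusCircFraction:
    def test_arithmetic_example(self):
        t = jt_table(
            [
                ("chr1", 1000, 2000, "+", "g", "backsplice", 60),
                ("chr1", 1100, 1500, "+", "g", "canonical", 35),
                ("chr1", 100, 900, "+", "g", "canonical", 5),
            ],
            ["s1"],
        )
        assert rd.locus_circ_fraction(t, "g") == pytest.approx(0.95)

    def test_no_outside_junctions_gives_one(self):
        t = jt_table(
            [
                ("chr1", 1000, 2000, "+", "g", "backsplice", 10),
                ("chr1", 1100, 1500, "+", "g", "canonical", 90),
            ],
            ["s1"],
        )
        assert rd.locus_circ_fraction(t, "g") == 1.0

    def test_mixed_locus_matches_hand_classification(self):
        # junctions straddling the circle boundary count as outside
        t = jt_table(
            [
                ("chr1", 1000, 2000, "+", "g", "backsplice", 40),
                ("chr1", 1200, 1800, "+", "g", "canonical", 30),
                ("chr1", 900, 1500, "+", "g", "canonical", 20),  # straddles donor
                ("chr1", 100, 800, "+", "g", "canonical", 10),
            ],
            ["s1"],
        )
        assert rd.locus_circ_fraction(t, "g") == pytest.approx(70 / 100)

    def test_absent_gene_rejected(self):
        t = jt_table([("chr1", 100, 500, "+", "g", "backsplice", 1)], ["s1"])
        with pytest.raises(ValidationError):
            rd.locus_circ_fraction(t, "other")


class TestJunctionConservation:
    def _set(self, coords):
        rows = [
            (c, d, a, s, f"g{i}", "backsplice", 1) for i, (c, d, a, s) in enumerate(coords)
        ]
        return jt_table(rows, ["s1"])

    def test_precise_match(self):
        a = self._set([("chr1", 100, 500, "+")])
        b = self._set([("chr1", 100, 500, "+")])
        assert rd.junction_conservation(a, b) == (0, 1)

    def test_overlap_without_precise_match(self):
        a = self._set([("chr1", 100, 500, "+")])
        b = self._set([("chr1", 100, 480, "+")])
        assert rd.junction_conservation(a, b) == (1, 0)

    def test_disjoint_and_strand_mismatch(self):
        a = self._set([("chr1", 100, 500, "+")])
        assert rd.junction_conservation(a, self._set([("chr1", 600, 900, "+")])) == (0, 0)
        assert rd.junction_conservation(a, self._set([("chr1", 100, 500, "-")])) == (0, 0)
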