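"""TME scoring: ssGSEA vs a brute-force oracle, purity, CYT, z-scores,
subtype labeling and the four-score inclusion criteria."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmetyper import tme_scoring as tme
from tmetyper.preprocess import NormalizedMatrix
from tmetyper.subtype_clustering import SubtypeDecision


def brute_force_ssgsea(expression: pd.Series, set_genes, alpha: float) -> float:
    """Independent running-sum enumeration, one position at a time."""
    items = sorted(
        expression.items(), key=lambda kv: (-kv[1], kv[0])
    )  # decreasing expression, gene id tie-break
    ranks = stats.rankdata([v for _, v in expression.items()])
    rank_of = dict(zip(expression.index, ranks))
    in_set = set(set_genes)
    total_in_weight = sum(
        abs(rank_of[g]) ** alpha for g in expression.index if g in in_set
    )
    n_out = sum(1 for g in expression.index if g not in in_set)
    score = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for gene, _value in items:
        if gene in in_set:
            cum_in += abs(rank_of[gene]) ** alpha
        else:
            cum_out += 1.0
        score += cum_in / total_in_weight - cum_out / n_out
    return score


def expr_series(values, genes=None):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.Series(values, index=genes, dtype=float)


def gene_set(genes, name="set", category="immune_signature"):
    return tme.GeneSet(name=name, category=category, gene_ids=tuple(genes))


class TestSsgsea:
    def test_top_gene_alpha_zero_oracle_value(self):
        # 4 genes, set = the top-ranked gene, alpha = 0:
        # P_in jumps to 1 at position 1; P_out climbs 0, 1/3, 2/3, 1
        # -> score = 1 + 2/3 + 1/3 + 0 = 2
        expr = expr_series([4.0, 3.0, 2.0, 1.0])
        gs = gene_set(["g0"])
        oracle = brute_force_ssgsea(expr, gs.gene_ids, 0.0)
        assert oracle == pytest.approx(2.0)
        assert tme.ssgsea_score(expr, gs, alpha=0.0) == pytest.approx(oracle)

    def test_bottom_set_scores_below_top_set(self):
        expr = expr_series([10.0, 8.0, 6.0, 4.0, 2.0, 1.0])
        top = tme.ssgsea_score(expr, gene_set(["g0", "g1"]))
        bottom = tme.ssgsea_score(expr, gene_set(["g4", "g5"]))
        assert bottom < top

    def test_rank_only_dependence_at_alpha_zero(self):
        expr = expr_series([5.0, 4.0, 2.0, 1.0, 0.5])
        gs = gene_set(["g1", "g3"])
        monotone = np.exp(expr)  # strictly monotone transform
        assert tme.ssgsea_score(expr, gs, alpha=0.0) == pytest.approx(
            tme.ssgsea_score(monotone, gs, alpha=0.0)
        )

    def test_agrees_with_oracle_on_random_instances(self):
        """Vectorized scorer equals the brute-force running sum to 1e-9."""
        rng = np.random.default_rng(42)
        for i in range(100):
            n = int(rng.integers(5, 51))
            values = np.round(rng.exponential(50.0, n), 1)  # ties likely
            genes = [f"g{j:02d}" for j in range(n)]
            expr = pd.Series(values, index=genes)
            k = int(rng.integers(1, n))
            set_genes = list(rng.choice(genes, size=k, replace=False))
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            got = tme.ssgsea_score(expr, gene_set(set_genes), alpha=alpha)
            want = brute_force_ssgsea(expr, set_genes, alpha)
            assert got == pytest.approx(want, abs=1e-9), f"instance {i}"

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            tme.ssgsea_score(expr_series([1.0, 2.0]), gene_set(["nope"]))

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError, match="every expressed gene"):
            tme.ssgsea_score(expr_series([1.0, 2.0]), gene_set(["g0", "g1"]))


class TestEstimateScores:
    def test_additivity_and_extreme_sample(self, small_cohort):
        from tmetyper import preprocess as pp

        tpm = pp.fpkm_to_tpm(pp.compute_fpkm(small_cohort))
        scores = tme.estimate_scores(
            tpm, small_cohort.immune_set, small_cohort.stromal_set
        )
        np.testing.assert_allclose(
            scores["estimate_score"],
            scores["immune_score"] + scores["stromal_score"],
        )
        # subtype-B (high infiltration) mean immune score exceeds subtype A
        truth = small_cohort.true_subtype
        mean_b = scores.loc[truth == "B", "immune_score"].mean()
        mean_a = scores.loc[truth == "A", "immune_score"].mean()
        assert mean_b > mean_a


class TestPurity:
    def test_zero_score_value(self):
        assert tme.estimate_purity(0.0) == pytest.approx(
            math.cos(0.6049872018)
        )
        assert tme.estimate_purity(0.0) == pytest.approx(0.82251, abs=5e-5)

    def test_monotone_non_increasing_on_valid_range(self):
        grid = np.linspace(-4000.0, 17000.0, 500)
        purity = tme.estimate_purity(grid)
        assert not np.isnan(purity).any()
        assert (np.diff(purity) <= 1e-12).all()

    def test_clamped_to_zero_with_flag(self):
        # argument in (pi/2, pi]: cosine negative -> clamp to 0
        val, flag = tme.estimate_purity(12000.0, return_flags=True)
        assert val == 0.0
        assert flag == "clamped"

    def test_undefined_outside_zero_pi(self):
        val, flag = tme.estimate_purity(30000.0, return_flags=True)
        assert np.isnan(val)
        assert flag == "undefined"


class TestCyt:
    def test_equal_inputs(self):
        assert tme.cyt_score(3.0, 3.0, offset=0.5) == pytest.approx(3.5)

    def test_geometric_mean(self):
        assert tme.cyt_score(4.0, 9.0, offset=0.0) == pytest.approx(6.0)

    def test_symmetry(self):
        assert tme.cyt_score(2.0, 7.0) == pytest.approx(tme.cyt_score(7.0, 2.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tme.cyt_score(-1.0, 2.0)


class TestSignatureZScores:
    def _fpkm(self):
        # 3 genes x (2 tumors + 3 controls); controls have mean 10, SD 1
        data = {
            "t1": [10.0, 11.0, 12.0],
            "t2": [10.0, 10.0, 10.0],
            "c1": [9.0, 9.0, 9.0],
            "c2": [10.0, 10.0, 10.0],
            "c3": [11.0, 11.0, 11.0],
        }
        return NormalizedMatrix(
            pd.DataFrame(data, index=["m1", "m2", "m3"]), "fpkm"
        )

    def test_tumor_at_control_mean_is_zero(self):
        res = tme.signature_zscores(
            self._fpkm(), ["c1", "c2", "c3"], gene_set(["m1", "m2", "m3"], "sig")
        )
        assert res.per_sample["t2"] == pytest.approx(0.0)

    def test_one_sd_above_is_one(self):
        # t1 is exactly +1 control SD at m2 only; use a single-gene set
        res = tme.signature_zscores(
            self._fpkm(), ["c1", "c2", "c3"], gene_set(["m2"], "sig")
        )
        assert res.per_sample["t1"] == pytest.approx(1.0)

    def test_control_self_reference_mean_zero(self):
        # Scoring the controls against themselves: per-gene z has mean 0
        # by construction, so the signature mean over controls is 0.
        m = self._fpkm()
        controls = ["c1", "c2", "c3"]
        sub = NormalizedMatrix(m.values[controls], "fpkm")
        with pytest.warns(UserWarning, match="control"):
            res = tme.signature_zscores(sub, [], gene_set(["m1", "m2"], "sig"))
        assert res.reference == "cancer_samples"
        assert res.per_sample.mean() == pytest.approx(0.0, abs=1e-12)

    def test_single_control_fallback_warns(self):
        m = self._fpkm()
        with pytest.warns(UserWarning, match="control"):
            res = tme.signature_zscores(m, ["c1"], gene_set(["m1"], "sig"))
        assert res.reference == "cancer_samples"

    def test_zero_sd_genes_dropped(self):
        data = {
            "t1": [5.0, 20.0],
            "c1": [1.0, 10.0],
            "c2": [3.0, 10.0],  # gene m2 constant across controls
        }
        m = NormalizedMatrix(pd.DataFrame(data, index=["m1", "m2"]), "fpkm")
        with pytest.warns(UserWarning, match="zero reference SD"):
            res = tme.signature_zscores(m, ["c1", "c2"], gene_set(["m1", "m2"], "s"))
        assert res.n_genes_used == 1
        assert res.n_genes_dropped == 1

    def test_subtype_b_elevated_on_synthetic_markers(self, small_cohort):
        from tmetyper import preprocess as pp

        fpkm = pp.compute_fpkm(small_cohort)
        res = tme.signature_zscores(
            fpkm,
            list(small_cohort.control_ids),
            small_cohort.immune_set,
            groups=small_cohort.true_subtype.loc[small_cohort.tumor_ids],
        )
        assert res.group_means["B"] > res.group_means["A"]


def make_decision(labels, cancer_clusters=(0, 1), status="included", k=2):
    return SubtypeDecision(
        cancer_type="X",
        chosen_k=k if status == "included" else None,
        cluster_labels=labels,
        status=status,
        cancer_cluster_ids=cancer_clusters,
    )


class TestAssignSubtypes:
    def _scores(self, immune, stromal, index):
        return pd.DataFrame(
            {
                "immune_score": immune,
                "stromal_score": stromal,
                "estimate_score": np.asarray(immune) + np.asarray(stromal),
            },
            index=index,
        )

    def test_lower_mean_cluster_is_a(self):
        idx = [f"s{i}" for i in range(6)]
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=idx)
        scores = self._scores(
            [-500.0, -480, -520, 800, 790, 810],
            [-500.0, -480, -520, 800, 790, 810],
            idx,
        )
        out = tme.assign_subtypes(
            make_decision(labels), scores, [False] * 6
        )
        assert (out.loc[labels == 0, "subtype"] == "A").all()
        assert (out.loc[labels == 1, "subtype"] == "B").all()

    def test_label_invariance_under_cluster_id_swap(self):
        idx = [f"s{i}" for i in range(6)]
        scores = self._scores(
            [1.0, 2, 3, 100, 101, 102], [1.0, 2, 3, 100, 101, 102], idx
        )
        labels = pd.Series([0, 0, 0, 1, 1, 1], index=idx)
        swapped = labels.map({0: 1, 1: 0})
        out1 = tme.assign_subtypes(make_decision(labels), scores, [False] * 6)
        out2 = tme.assign_subtypes(make_decision(swapped), scores, [False] * 6)
        pd.testing.assert_series_equal(out1["subtype"], out2["subtype"])

    def test_controls_labeled_control(self):
        idx = [f"s{i}" for i in range(6)]
        labels = pd.Series([0, 0, 1, 1, 1, 1], index=idx)
        scores = self._scores([0.0, 1, 50, 51, 52, 53], [0.0] * 6, idx)
        out = tme.assign_subtypes(
            make_decision(labels), scores, [False, False, False, False, True, True]
        )
        assert (out.loc[out.index[-2:], "subtype"] == "control").all()

    def test_tie_resolves_to_lower_cluster_id(self):
        idx = [f"s{i}" for i in range(4)]
        labels = pd.Series([0, 0, 1, 1], index=idx)
        scores = self._scores([5.0, 5, 5, 5], [5.0, 5, 5, 5], idx)
        with pytest.warns(UserWarning, match="tied"):
            out = tme.assign_subtypes(make_decision(labels), scores, [False] * 4)
        assert (out.loc[labels == 0, "subtype"] == "A").all()

    def test_excluded_decision_rejected(self):
        idx = ["s0", "s1"]
        labels = pd.Series([0, 1], index=idx)
        dec = make_decision(labels, status="excluded_controls_split")
        with pytest.raises(ValueError, match="status"):
            tme.assign_subtypes(dec, self._scores([1.0, 2], [1.0, 2], idx), [False] * 2)


def criteria_scores(n=30, immune_shift=5.0, stromal_shift=5.0, cyt_shift=5.0,
                    purity_shift=-0.2, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(2 * n)]
    sub = ["A"] * n + ["B"] * n
    shift = np.array([0.0] * n + [1.0] * n)
    return pd.DataFrame(
        {
            "immune_score": rng.normal(0, 1, 2 * n) + shift * immune_shift,
            "stromal_score": rng.normal(0, 1, 2 * n) + shift * stromal_shift,
            "cyt": rng.normal(10, 1, 2 * n) + shift * cyt_shift,
            "purity": rng.normal(0.8, 0.02, 2 * n) + shift * purity_shift,
            "subtype": sub,
        },
        index=idx,
    )


class TestTmeCriteria:
    def test_all_four_significant_included(self):
        res = tme.tme_criteria_check(criteria_scores())
        assert res.status == "included"
        assert res.n_directional_significant == 4

    def test_no_difference_excluded(self):
        res = tme.tme_criteria_check(
            criteria_scores(immune_shift=0, stromal_shift=0, cyt_shift=0,
                            purity_shift=0)
        )
        assert res.status == "excluded_tme_criteria"

    def test_three_of_four_included(self):
        # purity discordant (higher in B): still retained on 3/4
        res = tme.tme_criteria_check(criteria_scores(purity_shift=+0.2))
        assert res.status == "included"
        assert res.n_directional_significant == 3

    def test_wrong_direction_not_counted(self):
        # strong but inverted differences never count as significant
        res = tme.tme_criteria_check(
            criteria_scores(immune_shift=-5, stromal_shift=-5, cyt_shift=-5,
                            purity_shift=+0.2)
        )
        assert res.status == "excluded_tme_criteria"
        assert res.n_directional_significant == 0

    def test_degenerate_variance_counts_nonsignificant(self):
        scores = criteria_scores()
        scores["cyt"] = 1.0  # constant in both arms
        res = tme.tme_criteria_check(scores)
        assert not res.details.loc["cyt", "significant"]
        assert res.status == "included"  # the other three still pass


class TestOverlapEnrichment:
    def test_tail_by_enumeration(self):
        # universe 20, query 5, set 5, overlap 3: sum the hypergeometric
        # tail C(5,k) C(15,5-k) / C(20,5) for k = 3, 4, 5
        tail = sum(
            math.comb(5, k) * math.comb(15, 5 - k) for k in (3, 4, 5)
        ) / math.comb(20, 5)
        # an instance with overlap exactly 3
        query = ["a", "b", "c", "d", "e"]
        gs = gene_set(["a", "b", "c", "x", "y"], name="ov")
        p = tme.geneset_overlap_enrichment(query, gs, universe_size=20)
        assert p == pytest.approx(tail)
        assert tail == pytest.approx(1126 / 15504)

    def test_complete_overlap_is_minimum(self):
        gs = gene_set(["a", "b", "c"])
        p_full = tme.geneset_overlap_enrichment(["a", "b", "c"], gs, 30)
        p_partial = tme.geneset_overlap_enrichment(["a", "b", "z"], gs, 30)
        assert p_full < p_partial
        assert p_full == pytest.approx(
            stats.hypergeom.pmf(3, 30, 3, 3) + stats.hypergeom.sf(3, 30, 3, 3)
        )

    def test_zero_overlap_near_one(self):
        gs = gene_set([f"s{i}" for i in range(10)])
        p = tme.geneset_overlap_enrichment([f"q{i}" for i in range(10)], gs, 25)
        assert p > 0.99

    def test_universe_too_small_rejected(self):
        gs = gene_set(["a", "b", "c"])
        with pytest.raises(ValueError):
            tme.geneset_overlap_enrichment(["a", "b"], gs, universe_size=2)


def test_gmt_roundtrip(tmp_path):
    sets = [
        tme.GeneSet("imm", "immune_signature", ("GZMA", "PRF1", "CD8A")),
        tme.GeneSet("str", "stromal_signature", ("COL1A1", "FAP")),
    ]
    path = tmp_path / "sets.gmt"
    tme.write_gmt(sets, path)
    back = tme.read_gmt(path, category="marker")
    assert [s.name for s in back] == ["imm", "str"]
    assert back[0].gene_ids == ("GZMA", "PRF1", "CD8A")


def test_gene_set_validation():
    with pytest.raises(ValueError, match="empty"):
        tme.GeneSet("x", "marker", ())
    with pytest.raises(ValueError, match="duplicate"):
        tme.GeneSet("x", "marker", ("a", "a"))
    with pytest.raises(ValueError, match="category"):
        tme.GeneSet("x", "bogus", ("a",))


def test_tme_criteria_null_inclusion_rate():
    """With no TME structure at all (constant latent infiltration and no
    hazard difference), forcing a two-way split and running the
    four-score check retains at most 5% of cohorts over 200 seeds."""
    import tmetyper.preprocess as pp
    import tmetyper.subtype_clustering as sc
    from tmetyper import SimulationConfig, generate_cohort

    n_included = 0
    n_run = 0
    for seed in range(200):
        cfg = SimulationConfig(
            n_genes=200, n_tumor_per_subtype=(15, 15), n_controls=6,
            infiltration_means=(0.3, 0.3), infiltration_sd=0.0,
            hazard_ratio=1.0, seed=seed,
        )
        ds = generate_cohort(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vst = pp.variance_stabilize(ds)
            top = pp.select_top_variable_genes(vst, 100)
            l2 = sc.cut_tree(sc.hierarchical_cluster(vst, top), 2)
            cancer2 = l2[~ds.is_control.to_numpy()]
            if cancer2.nunique() < 2 or (cancer2.value_counts() < 2).any():
                continue
            dec = sc.SubtypeDecision(
                "NULL", 2, l2, "included", tuple(int(c) for c in sorted(l2.unique()))
            )
            tpm = pp.fpkm_to_tpm(pp.compute_fpkm(ds))
            scores = tme.estimate_scores(tpm, ds.immune_set, ds.stromal_set)
            scores["purity"] = tme.estimate_purity(scores["estimate_score"])
            scores["cyt"] = tme.cyt_score(
                tpm.values.loc["GZMA"], tpm.values.loc["PRF1"]
            )
            scores = tme.assign_subtypes(dec, scores, ds.is_control)
            n_included += tme.tme_criteria_check(scores).status == "included"
        n_run += 1
    assert n_run >= 150
    assert n_included / n_run <= 0.05
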