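import numpy as np
import pandas as pd
import pytest

from exomir import io, synth
from exomir.containers import ValidationError
from exomir.stability import (
    bestkeeper,
    delta_ct_method,
    exclude_by_ct,
    genorm,
    normfinder,
    pick_references,
    reffinder_aggregate,
    stability_report,
)

from conftest import make_ct

SQRT_5_3 = np.sqrt(5.0 / 3.0)  # sample SD of {0,1,2,3}


class TestGenorm:
    def test_parallel_pair_has_zero_pairwise_variation(self, genorm_toy):
        res = genorm(genorm_toy)
        # G1 and G2 are perfectly parallel: their final-pair M is V12 = 0
        assert res.m_values["G1"] == pytest.approx(0.0, abs=1e-12)
        assert res.m_values["G2"] == pytest.approx(0.0, abs=1e-12)

    def test_toy_round_one_m_values_and_elimination(self, genorm_toy):
        res = genorm(genorm_toy)
        round1 = res.trace[0]["m"]
        assert round1["G1"] == pytest.approx(SQRT_5_3 / 2, rel=1e-9)   # 0.6455
        assert round1["G2"] == pytest.approx(SQRT_5_3 / 2, rel=1e-9)
        assert round1["G3"] == pytest.approx(SQRT_5_3, rel=1e-9)       # 1.2910
        assert res.m_values["G3"] == pytest.approx(SQRT_5_3, rel=1e-9)
        assert res.ranking[-1] == "G3"  # eliminated first = least stable

    def test_pairwise_v_equals_sd_of_ct_differences(self, random_ct_panel):
        # with E=2, log2 ratios of relative quantities reduce to Ct
        # differences, so V_jk is the sample SD of (Ct_k - Ct_j); the
        # final-pair M is exactly that pairwise SD
        ct = random_ct_panel(seed=5)
        last = genorm(ct).trace[-1]
        pair = last["genes"]
        assert len(pair) == 2
        d = (ct.values.loc[pair[0]] - ct.values.loc[pair[1]]).std(ddof=1)
        assert last["m"][pair[0]] == pytest.approx(d, abs=1e-12)
        assert last["m"][pair[1]] == pytest.approx(d, abs=1e-12)

    def test_requires_three_genes_and_complete_data(self):
        with pytest.raises(ValidationError):
            genorm(make_ct([[20, 21], [22, 23]], ["case", "control"]))
        with pytest.raises(ValidationError, match="missing"):
            genorm(
                make_ct(
                    [[20, np.nan, 21], [22, 23, 24], [25, 26, 27]],
                    ["case", "case", "control"],
                )
            )

    def test_pergene_shift_invariance(self, random_ct_panel):
        ct = random_ct_panel(seed=7)
        shifted = make_ct(
            ct.values.to_numpy() + np.arange(len(ct.values))[:, None] * 1.7,
            list(ct.groups), assays=list(ct.assays), samples=list(ct.samples),
        )
        a, b = genorm(ct), genorm(shifted)
        pd.testing.assert_series_equal(a.m_values, b.m_values, atol=1e-9)


class TestDeltaCtMethod:
    def test_toy_average_stdev(self, genorm_toy):
        avg = delta_ct_method(genorm_toy)
        assert avg["G1"] == pytest.approx(SQRT_5_3 / 2, rel=1e-9)  # mean(0, 1.2910)
        assert avg["G3"] == pytest.approx(SQRT_5_3, rel=1e-9)

    def test_identity_with_genorm_pairwise_v(self, random_ct_panel):
        # cross-method oracle: delta-Ct pairwise SD equals geNorm V at E=2,
        # so the full-panel M equals the per-gene average of pairwise SDs
        ct = random_ct_panel(seed=11, n_assays=6)
        avg = delta_ct_method(ct)
        m_round1 = pd.Series(genorm(ct).trace[0]["m"])
        pd.testing.assert_series_equal(
            avg, m_round1.loc[avg.index], atol=1e-9, check_names=False
        )

    def test_pairwise_complete_minimum(self):
        vals = [[20.0, np.nan, 21.0], [np.nan, 23.0, 24.0], [25.0, 26.0, 27.0]]
        with pytest.raises(ValidationError, match="fewer than"):
            delta_ct_method(make_ct(vals, ["case", "case", "control"]))


class TestBestKeeper:
    def test_constant_assay(self):
        bk = bestkeeper(make_ct([[20, 20, 20], [19, 20, 21]], ["case", "case", "control"]))
        assert bk.loc["a0", "sd"] == 0.0
        assert bk.loc["a0", "cv_pct"] == 0.0

    def test_mad_hand_arithmetic(self):
        bk = bestkeeper(make_ct([[19, 20, 21], [25, 25, 25], [30, 31, 32]], ["case", "case", "control"]))
        assert bk.loc["a0", "sd"] == pytest.approx(2 / 3, rel=1e-9)
        assert bk.loc["a0", "cv_pct"] == pytest.approx(100 * (2 / 3) / 20, rel=1e-9)

    def test_sample_sd_option(self):
        bk = bestkeeper(
            make_ct([[19, 20, 21], [25, 25, 25], [30, 31, 32]], ["case", "case", "control"]),
            use_sample_sd=True,
        )
        assert bk.loc["a0", "sd"] == pytest.approx(1.0, rel=1e-9)

    def test_printed_sd_cv_pair_implies_plausible_mean_ct(self):
        # internal consistency of the published panel: SD/(CV/100) returns the
        # mean Ct, e.g. U6 0.46/0.0174 ~ 26.4 cycles
        t3 = io.load_fixture("table3")
        bk = t3[t3["method"] == "bestkeeper"].set_index("gene")
        u6 = bk.loc["U6"]
        mean_ct = u6["statistic"] / (u6["extra"] / 100)
        assert mean_ct == pytest.approx(26.4, abs=0.1)
        all_means = bk["statistic"] / (bk["extra"] / 100)
        assert all_means.between(15, 40).all()


class TestNormFinder:
    def test_quiet_gene_dominates(self):
        rng = np.random.default_rng(3)
        vals = 25 + rng.normal(0, 1.0, size=(5, 12))
        vals[0] = 25.0  # zero variance, zero contrast
        ct = make_ct(vals, ["case"] * 6 + ["control"] * 6)
        nf = normfinder(ct)
        assert nf.stability.idxmin() == "a0"

    def test_group_swap_invariance(self, random_ct_panel):
        ct = random_ct_panel(seed=13, n_assays=5, n_samples=12)
        swapped = make_ct(
            ct.values.to_numpy(),
            ["control" if g == "case" else "case" for g in ct.groups],
            assays=list(ct.assays), samples=list(ct.samples),
        )
        pd.testing.assert_series_equal(
            normfinder(ct).stability, normfinder(swapped).stability, atol=1e-12
        )

    def test_global_shift_invariance(self, random_ct_panel):
        ct = random_ct_panel(seed=17)
        shifted = make_ct(
            ct.values.to_numpy() + 3.0, list(ct.groups),
            assays=list(ct.assays), samples=list(ct.samples),
        )
        pd.testing.assert_series_equal(
            normfinder(ct).stability, normfinder(shifted).stability, atol=1e-9
        )

    def test_single_group_falls_back_flagged(self):
        rng = np.random.default_rng(5)
        ct = make_ct(25 + rng.normal(0, 0.5, (4, 6)), ["case"] * 6)
        nf = normfinder(ct)
        assert nf.variant == "intragroup-only"
        assert (nf.stability >= 0).all()

    def test_planted_shifted_gene_ranked_least_stable(self):
        # one group-shifted assay among stable assays must come out least
        # stable in >= 95% of seeded replicates
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            cfg = synth.CtSimConfig(
                n_case=7, n_control=7,
                reference_assays=[(f"r{i}", 24.0 + i, 0.4) for i in range(5)],
                marker_assays=[("shifted", 26.0, -1.0, 0.4)],
                detection_limit=40.0, seed=seed,
            )
            ct = synth.simulate_ct(cfg).ct
            nf = normfinder(ct)
            wins += nf.stability.idxmax() == "shifted"
        assert wins / n_rep >= 0.95


class TestConsensus:
    def test_unanimous_ranks(self):
        stats_df = pd.DataFrame(
            {"m1": [0.1, 0.2, 0.3], "m2": [1.0, 2.0, 3.0]},
            index=["a", "b", "c"],
        )
        out = reffinder_aggregate(stats_df)
        np.testing.assert_allclose(out["consensus"], [1.0, 2.0, 3.0])

    def test_table3_u6_and_mir30a(self):
        out = reffinder_aggregate(io.table3_statistics())
        assert out.loc["U6", "consensus"] == pytest.approx(48 ** 0.25, rel=1e-9)
        assert round(out.loc["U6", "consensus"], 2) == 2.63
        assert out.loc["miR-30a-5p", "consensus"] == pytest.approx(8 ** 0.25, rel=1e-9)
        assert round(out.loc["miR-30a-5p", "consensus"], 2) == 1.68

    def test_table3_full_regression_printed_consensus(self):
        # ranking the nine candidates by each printed statistic reproduces the
        # printed consensus for 8 of 9 genes; miR-532-5p is not recomputable
        # from rounded inputs (BestKeeper SD ties at 0.6)
        out = reffinder_aggregate(io.table3_statistics())
        printed = (
            io.load_fixture("table3")
            .query("method == 'reffinder'")
            .set_index("gene")["statistic"]
        )
        for gene in printed.index:
            if gene == "miR-532-5p":
                continue
            assert round(out.loc[gene, "consensus"], 2) == pytest.approx(
                printed[gene], abs=5e-3
            ), gene

    def test_consensus_bounded_by_rank_extremes(self, random_ct_panel):
        ct = random_ct_panel(seed=19, n_assays=7)
        rep = stability_report(ct)
        rank_cols = [c for c in rep.columns if c.startswith("rank_")]
        ranks = rep[rank_cols]
        assert (rep["consensus"] >= ranks.min(axis=1) - 1e-12).all()
        assert (rep["consensus"] <= ranks.max(axis=1) + 1e-12).all()

    def test_inconsistent_gene_sets_rejected(self):
        stats_df = pd.DataFrame({"m1": [0.1, 0.2], "m2": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="m2"):
            reffinder_aggregate(stats_df)


class TestExcludeByCt:
    def test_mean_above_threshold_excluded(self):
        ct = make_ct([[34.0, 34.0], [25.0, 25.0]], ["case", "control"])
        kept, log = exclude_by_ct(ct)
        assert list(kept.assays) == ["a1"]
        assert bool(log.loc["a0", "excluded"])

    def test_boundary_exactly_33_retained(self):
        ct = make_ct([[33.0, 33.0], [25.0, 25.0]], ["case", "control"])
        kept, log = exclude_by_ct(ct)
        assert "a0" in list(kept.assays)

    def test_no_exclusions_empty_log(self):
        ct = make_ct([[30.0, 30.0], [25.0, 25.0]], ["case", "control"])
        _, log = exclude_by_ct(ct)
        assert not log["excluded"].any()

    def test_all_excluded_errors(self):
        ct = make_ct([[34.0, 34.0]], ["case", "control"])
        with pytest.raises(ValidationError):
            exclude_by_ct(ct)


def _report_for(genes, consensus):
    df = pd.DataFrame({"consensus": consensus}, index=genes)
    return df.sort_values("consensus")


class TestPickReferences:
    def test_highest_ct_member_dropped(self):
        report = _report_for(["g1", "g2", "g3", "g4"], [1.0, 1.5, 2.0, 2.5])
        ct = make_ct(
            [[26.0] * 2, [23.0] * 2, [31.0] * 2, [25.0] * 2],
            ["case", "control"],
            assays=["g1", "g2", "g3", "g4"],
        )
        picked = pick_references(report, ct, n_final=3, consensus_top=4)
        assert "g3" not in picked.references
        assert len(picked.references) == 3
        assert picked.trail[0]["dropped"] == "g3"

    def test_no_drop_when_top_equals_final(self):
        report = _report_for(["g1", "g2", "g3"], [1.0, 2.0, 3.0])
        ct = make_ct([[26.0] * 2] * 3, ["case", "control"], assays=["g1", "g2", "g3"])
        picked = pick_references(report, ct, n_final=3, consensus_top=3)
        assert picked.references == ["g1", "g2", "g3"]
        assert picked.trail == []

    def test_ct_tie_drops_worse_consensus(self):
        report = _report_for(["g1", "g2", "g3", "g4"], [1.0, 1.5, 2.0, 2.5])
        ct = make_ct(
            [[26.0] * 2, [30.0] * 2, [30.0] * 2, [25.0] * 2],
            ["case", "control"],
            assays=["g1", "g2", "g3", "g4"],
        )
        picked = pick_references(report, ct, n_final=3, consensus_top=4)
        assert picked.trail[0]["dropped"] == "g3"  # tied Ct 30, worse consensus

    def test_too_few_candidates(self):
        report = _report_for(["g1", "g2"], [1.0, 2.0])
        ct = make_ct([[26.0] * 2] * 2, ["case", "control"], assays=["g1", "g2"])
        with pytest.raises(ValidationError):
            pick_references(report, ct, n_final=3, consensus_top=4)


class TestStabilityReport:
    def test_global_shift_invariance_of_all_statistics(self, random_ct_panel):
        ct = random_ct_panel(seed=23, n_assays=6)
        shifted = make_ct(
            ct.values.to_numpy() + 2.5, list(ct.groups),
            assays=list(ct.assays), samples=list(ct.samples),
        )
        a = stability_report(ct)
        b = stability_report(shifted).loc[a.index]
        for col in ("normfinder_stability", "genorm_m", "delta_ct_avg_stdev", "consensus"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-9)
        # BestKeeper SD is shift-invariant too (its CV is not: mean changes)
        np.testing.assert_allclose(a["bestkeeper_sd"], b["bestkeeper_sd"], atol=1e-9)

    def test_planted_stable_assays_win_consensus(self):
        wins = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = synth.CtSimConfig(n_case=7, n_control=7, seed=seed)
            ct = synth.simulate_ct(cfg).ct
            rep = stability_report(ct)
            wins += rep.index[0].startswith("ref-")
        assert wins / n_rep >= 0.95
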