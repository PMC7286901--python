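"""DMS scoring: normalization, enrichment, z-classes, cross-strain flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bufferscan import (
    DataError,
    DegenerateDataError,
    MutantCountTable,
    compare_strains,
    enrichment_scores,
    normalize_counts,
    replicate_mean,
    score_table,
    zscore_classify,
)
from bufferscan.synthetic import GeneratorConfig, gen_count_table


def toy_table(counts=(10, 20, 30), coverage=1000, sample="s1"):
    n = len(counts)
    return MutantCountTable(
        counts=pd.DataFrame({
            "mutant_id": [f"m{i}" for i in range(n)],
            "position": list(range(1, n + 1)),
            "sample": sample,
            "count": list(counts),
        }),
        coverage=pd.DataFrame({
            "sample": sample, "position": list(range(1, n + 1)),
            "coverage": coverage,
        }),
        samples=pd.DataFrame({
            "sample": [sample], "strain": ["A"],
            "condition": ["selected"], "replicate": [1],
        }),
    )


class TestNormalizeCounts:
    def test_hand_computed_frequencies(self):
        out = normalize_counts(toy_table((10, 20, 30)), pseudocount=0.0)
        assert out["normalized"].tolist() == [0.01, 0.02, 0.03]

    def test_pseudocount_on_zero_count(self):
        out = normalize_counts(toy_table((0,)), pseudocount=0.5)
        assert out["normalized"].tolist() == [0.0005]

    @given(factor=st.integers(min_value=1, max_value=50))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_depth_invariance(self, factor):
        base = toy_table((5, 17, 400))
        scaled = MutantCountTable(
            counts=base.counts.assign(count=base.counts["count"] * factor),
            coverage=base.coverage.assign(
                coverage=base.coverage["coverage"] * factor),
            samples=base.samples,
        )
        a = normalize_counts(base, pseudocount=0.0)["normalized"]
        b = normalize_counts(scaled, pseudocount=0.0)["normalized"]
        assert np.allclose(a, b, rtol=1e-12)

    def test_missing_coverage_names_the_hole(self):
        table = toy_table((1, 2))
        with pytest.raises(DataError, match="position 2"):
            MutantCountTable(
                counts=table.counts,
                coverage=table.coverage.iloc[:1],
                samples=table.samples,
            )

    def test_count_above_coverage_rejected(self):
        with pytest.raises(DataError, match="exceeds coverage"):
            toy_table((1500,), coverage=1000)


class TestReplicateMean:
    def _two_reps(self, values_r1, values_r2, drop_from_r2=()):
        rows = []
        for rep, values in ((1, values_r1), (2, values_r2)):
            for i, v in enumerate(values):
                m = f"m{i}"
                if rep == 2 and m in drop_from_r2:
                    continue
                rows.append({"mutant_id": m, "position": i + 1,
                             "sample": f"s{rep}", "normalized": v})
        samples = pd.DataFrame({
            "sample": ["s1", "s2"], "strain": "A",
            "condition": "selected", "replicate": [1, 2],
        })
        return pd.DataFrame(rows), samples

    def test_arithmetic_mean_of_replicates(self):
        norm, samples = self._two_reps([0.01], [0.03])
        out = replicate_mean(norm, samples)
        assert out["mean_normalized"].tolist() == [0.02]
        assert not out["partial"].any()

    def test_partial_mutant_flagged_not_dropped(self):
        norm, samples = self._two_reps([0.01, 0.02], [0.01, 0.02],
                                       drop_from_r2=("m1",))
        out = replicate_mean(norm, samples).set_index("mutant_id")
        assert out.loc["m1", "mean_normalized"] == 0.02
        assert bool(out.loc["m1", "partial"]) is True
        assert bool(out.loc["m0", "partial"]) is False

    def test_single_replicate_flagged(self):
        norm, samples = self._two_reps([0.01], [0.03])
        out = replicate_mean(norm, samples.iloc[:1])
        assert out["single_replicate"].all()

    def test_empty_sample_sheet_rejected(self):
        norm, samples = self._two_reps([0.01], [0.03])
        with pytest.raises(ValueError, match="empty"):
            replicate_mean(norm, samples.iloc[:0])


class TestEnrichment:
    def test_identity_and_definition(self):
        idx = ["a", "b"]
        same = pd.Series([0.01, 0.02], index=idx)
        assert enrichment_scores(same, same).tolist() == [1.0, 1.0]
        E = enrichment_scores(pd.Series([0.02], index=["a"]),
                              pd.Series([0.01], index=["a"]))
        assert E.tolist() == [2.0]

    def test_key_mismatch_lists_offenders(self):
        with pytest.raises(DataError, match="b"):
            enrichment_scores(pd.Series({"a": 0.1, "b": 0.1}),
                              pd.Series({"a": 0.1}))

    def test_zero_unselected_guard(self):
        with pytest.raises(DataError, match="pseudocount"):
            enrichment_scores(pd.Series({"a": 0.1}), pd.Series({"a": 0.0}))


class TestZscoreClassify:
    def test_symmetric_panel(self):
        out = zscore_classify(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))
        assert out["z"].tolist() == [-1.0, 0.0, 1.0]

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        E = pd.Series(np.exp(rng.normal(0, 1, 200)))
        out = zscore_classify(E)
        assert abs(out["z"].mean()) < 1e-9
        assert abs(out["z"].std(ddof=1) - 1) < 1e-9

    def test_activity_labels_at_default_cuts(self):
        # panel engineered so its z-scores contain exactly 1.4 (more active
        # than average), -1.6 (less active) and -0.4 (near average): the
        # filler values keep the sample mean at 0 and sample sd at 1
        c = np.sqrt(0.66)
        z_target = np.array([1.4, -1.6, -0.4, 0.6, c, c, c, -c, -c, -c])
        assert abs(z_target.mean()) < 1e-12
        assert abs(z_target.std(ddof=1) - 1) < 1e-12
        E = pd.Series(10.0 + z_target * 2.0, index=list("abcdefghij"))
        out = zscore_classify(E)
        got = dict(zip(out.index, out["label"]))
        zs = dict(zip(out.index, out["z"].round(6)))
        assert zs["a"] == pytest.approx(1.4, abs=1e-6)
        assert got["a"] == "more_active"
        assert zs["b"] == pytest.approx(-1.6, abs=1e-6)
        assert got["b"] == "less_active"
        assert zs["c"] == pytest.approx(-0.4, abs=1e-6)
        assert got["c"] == "near_average"

    def test_degenerate_and_small_panels_rejected(self):
        with pytest.raises(DegenerateDataError):
            zscore_classify(pd.Series({"a": 1.0, "b": 1.0, "c": 1.0}))
        with pytest.raises(ValueError, match="at least 3"):
            zscore_classify(pd.Series({"a": 1.0, "b": 2.0}))


class TestSpreadsheetOracle:
    """5-mutant toy panel checked against plain-Python hand arithmetic."""

    def test_e_and_z_match_hand_calculation(self):
        counts_sel = [40, 10, 25, 5, 80]
        counts_uns = [20, 20, 20, 20, 20]
        cov_sel = [2000, 2000, 1000, 1000, 4000]
        cov_uns = [1000, 1000, 1000, 1000, 1000]
        pseudo = 0.5
        # independent spreadsheet-style computation with scalars
        norm_sel = [(c + pseudo) / v for c, v in zip(counts_sel, cov_sel)]
        norm_uns = [(c + pseudo) / v for c, v in zip(counts_uns, cov_uns)]
        e_hand = [s / u for s, u in zip(norm_sel, norm_uns)]
        mean_e = sum(e_hand) / 5
        sd_e = (sum((e - mean_e) ** 2 for e in e_hand) / 4) ** 0.5
        z_hand = [(e - mean_e) / sd_e for e in e_hand]

        sel = pd.Series(norm_sel, index=[f"m{i}" for i in range(5)])
        uns = pd.Series(norm_uns, index=[f"m{i}" for i in range(5)])
        out = zscore_classify(enrichment_scores(sel, uns))
        assert np.allclose(out["E"], e_hand, rtol=0, atol=0)
        assert np.allclose(out["z"], z_hand, rtol=1e-12)


class TestCompareStrains:
    def test_identical_strains_all_concordant(self):
        rng = np.random.default_rng(1)
        a = pd.Series(np.exp(rng.normal(-5, 1, 50)),
                      index=[f"m{i}" for i in range(50)])
        comp = compare_strains(a, a * 1.0)
        assert (comp.flags == "concordant").all()
        assert comp.slope == pytest.approx(1.0)

    def test_planted_tenfold_reduction_is_the_unique_flag(self):
        rng = np.random.default_rng(7)
        idx = [f"m{i}" for i in range(101)]
        a = pd.Series(np.exp(rng.normal(-5, 0.8, 101)), index=idx)
        b = a * np.exp(rng.normal(0, 0.05, 101))
        b["m50"] = a["m50"] / 10.0
        comp = compare_strains(a, b, ci_level=0.99)
        assert list(comp.flags.index[comp.flags == "reduced"]) == ["m50"]
        assert (comp.flags.drop("m50") == "concordant").all()

    def test_band_kinds_nest(self):
        rng = np.random.default_rng(2)
        idx = [f"m{i}" for i in range(40)]
        a = pd.Series(np.exp(rng.normal(-5, 1, 40)), index=idx)
        b = a * np.exp(rng.normal(0, 0.1, 40))
        pred = compare_strains(a, b, band="prediction")
        conf = compare_strains(a, b, band="confidence")
        # the prediction band for a new observation contains the mean band
        assert (pred.table["lower"] <= conf.table["lower"] + 1e-12).all()
        assert (pred.table["upper"] >= conf.table["upper"] - 1e-12).all()

    def test_too_few_mutants_rejected(self):
        a = pd.Series({"x": 0.1, "y": 0.2})
        with pytest.raises(ValueError, match="3 shared"):
            compare_strains(a, a)

    def test_zero_variance_rejected(self):
        a = pd.Series({"x": 0.1, "y": 0.1, "z": 0.1})
        b = pd.Series({"x": 0.1, "y": 0.2, "z": 0.3})
        with pytest.raises(DegenerateDataError):
            compare_strains(a, b)


class TestPipelineRecovery:
    def test_enrichment_tracks_true_fitness(self):
        cfg = GeneratorConfig(seed=11, n_mutants=100, depth=1_000_000)
        data = gen_count_table(cfg)
        result = score_table(data.table)
        from scipy.stats import spearmanr

        fitness = pd.Series(data.truth["fitness"])
        for strain in cfg.strains:
            sub = result["scores"]
            sub = sub[sub["strain"] == strain].set_index("mutant_id")
            rho = spearmanr(sub["E"], fitness.loc[sub.index]).statistic
            assert rho >= 0.9

    def test_full_pipeline_depth_invariance(self):
        cfg = GeneratorConfig(seed=3, n_mutants=30, depth=50_000)
        table = gen_count_table(cfg).table
        scaled = MutantCountTable(
            counts=table.counts.assign(count=table.counts["count"] * 7),
            coverage=table.coverage.assign(
                coverage=table.coverage["coverage"] * 7),
            samples=table.samples,
        )
        # pseudocount breaks exact invariance by design; compare at 0
        a = score_table(table, pseudocount=0.0)["scores"]
        b = score_table(scaled, pseudocount=0.0)["scores"]
        assert np.allclose(a["E"], b["E"], rtol=1e-12)
        assert np.allclose(a["z"], b["z"], rtol=1e-9)
        assert (a["label"] == b["label"]).all()
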