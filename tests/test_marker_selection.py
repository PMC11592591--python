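import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bcfdna import synthetic_data as sd
from bcfdna.marker_selection import (
    SelectionConfig,
    availability_filter,
    chromatin_disjoint_filter,
    count_flanking_cpgs,
    cpg_density_filter,
    dnase_filter,
    moderated_dm_test,
    rank_and_trim,
    select_markers,
)


class TestChromatinDisjoint:
    def _groups(self, n_brain, n_other):
        eps = [f"B{i}" for i in range(n_brain)] + [f"N{i}" for i in range(n_other)]
        return pd.Series(
            ["brain"] * n_brain + ["non-brain"] * n_other, index=eps
        ), eps

    def test_disjoint_probe_retained_shared_probe_dropped(self):
        groups, eps = self._groups(1, 2)
        states = pd.DataFrame(
            [["1_TssA", "15_Quies", "13_ReprPC"], ["1_TssA", "7_Enh", "1_TssA"]],
            index=["keep", "drop"],
            columns=eps,
        )
        assert chromatin_disjoint_filter(states, groups) == ["keep"]

    def test_toy_table_matches_hand_enumeration(self):
        groups, eps = self._groups(2, 2)
        rng = np.random.default_rng(4)
        brain_states = ["10_TssBiv", "11_BivFlnk"]
        other_states = ["15_Quies", "9_Het"]
        rows, expected = [], []
        for i in range(10):
            if i in (2, 5, 9):  # planted disjoint
                rows.append([rng.choice(brain_states)] * 2 + [rng.choice(other_states)] * 2)
                expected.append(f"p{i}")
            else:
                s = rng.choice(brain_states)
                rows.append([s, s, s, rng.choice(other_states)])
        states = pd.DataFrame(rows, index=[f"p{i}" for i in range(10)], columns=eps)
        assert chromatin_disjoint_filter(states, groups) == expected

    def test_missing_state_excludes_probe(self):
        groups, eps = self._groups(1, 1)
        states = pd.DataFrame(
            [["1_TssA", None], ["1_TssA", "15_Quies"]], index=["miss", "ok"], columns=eps
        )
        assert chromatin_disjoint_filter(states, groups) == ["ok"]

    def test_requires_both_groups(self):
        groups = pd.Series(["brain"], index=["B0"])
        states = pd.DataFrame([["1_TssA"]], index=["p"], columns=["B0"])
        with pytest.raises(ValueError):
            chromatin_disjoint_filter(states, groups)


class TestAvailability:
    def test_strict_threshold_on_sample_units(self):
        n = 100
        beta = pd.DataFrame(np.full((3, n), np.nan), index=["p5", "p11", "p10"],
                            columns=[f"s{i}" for i in range(n)])
        beta.iloc[0, :5] = 0.5   # 5% -> dropped
        beta.iloc[1, :11] = 0.5  # 11% -> retained
        beta.iloc[2, :10] = 0.5  # exactly 10% -> dropped (strict)
        kept = availability_filter(beta)
        assert kept == ["p11"]

    def test_matches_brute_force_count_with_dataset_units(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(30)]
        datasets = pd.Series([f"d{i // 3}" for i in range(30)], index=samples)
        beta = pd.DataFrame(
            np.where(rng.random((40, 30)) < 0.8, np.nan, 0.5),
            index=[f"p{i}" for i in range(40)], columns=samples,
        )
        kept = availability_filter(beta, dataset_ids=datasets)
        for p in beta.index:
            n_avail = sum(
                beta.loc[p, datasets.index[datasets == d]].notna().any()
                for d in datasets.unique()
            )
            assert (p in kept) == (n_avail / 10 > 0.10)


class TestModeratedT:
    def _toy_beta(self, seed=0, n_probes=40, n1=6, n2=8):
        rng = np.random.default_rng(seed)
        beta = pd.DataFrame(
            rng.uniform(0.1, 0.9, (n_probes, n1 + n2)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=[f"s{i}" for i in range(n1 + n2)],
        )
        is_brain = pd.Series([True] * n1 + [False] * n2, index=beta.columns)
        return beta, is_brain

    def test_identical_group_means_not_significant(self):
        beta = pd.DataFrame(
            [[0.4, 0.4, 0.4, 0.4, 0.4, 0.4]], index=["p0"],
            columns=[f"s{i}" for i in range(6)],
        )
        noise = pd.DataFrame(
            np.random.default_rng(0).normal(0, 0.01, (5, 6)),
            index=[f"n{i}" for i in range(5)], columns=beta.columns,
        ) + 0.5
        beta = pd.concat([beta, noise])
        is_brain = pd.Series([True, True, True, False, False, False], index=beta.columns)
        dm = moderated_dm_test(beta, is_brain)
        assert dm.loc["p0", "delta"] == 0
        assert dm.loc["p0", "p_value"] > 0.99

    def test_zero_prior_weight_equals_classical_pooled_t(self):
        beta, is_brain = self._toy_beta(3)
        dm = moderated_dm_test(beta, is_brain, prior_df_override=0)
        for p in beta.index[:10]:
            a = beta.loc[p, is_brain]
            b = beta.loc[p, ~is_brain]
            t, pv = stats.ttest_ind(a, b, equal_var=True)
            assert dm.loc[p, "t"] == pytest.approx(t, rel=1e-6)
            assert dm.loc[p, "p_value"] == pytest.approx(pv, rel=1e-6)

    def test_bh_adjustment_matches_direct_formula(self):
        beta, is_brain = self._toy_beta(5, n_probes=18)
        dm = moderated_dm_test(beta, is_brain)
        p = dm["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            adj[idx] = running
        np.testing.assert_allclose(dm["adj_p"].to_numpy(), adj, rtol=1e-12)
        # adjusted p non-decreasing in raw-p rank
        assert np.all(np.diff(dm["adj_p"].to_numpy()[order]) >= -1e-15)

    def test_probe_with_sparse_group_marked_untested(self):
        beta, is_brain = self._toy_beta(7, n_probes=5)
        beta.iloc[0, np.flatnonzero(is_brain)[1:]] = np.nan  # 1 brain obs only
        dm = moderated_dm_test(beta, is_brain)
        assert not dm.iloc[0]["tested"]
        assert np.isnan(dm.iloc[0]["adj_p"])
        assert dm.iloc[1:]["tested"].all()

    def test_agrees_with_limma_reference(self, tmp_path):
        """Cross-check moderated statistics against the limma eBayes pipeline."""
        beta, is_brain = self._toy_beta(11, n_probes=30, n1=5, n2=7)
        beta_path = tmp_path / "beta.tsv"
        beta.to_csv(beta_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{beta_path}", row.names = 1))
            design <- cbind(Intercept = 1, Brain = c(rep(1, 5), rep(0, 7)))
            fit <- eBayes(lmFit(x, design))
            tab <- topTable(fit, coef = "Brain", number = Inf, sort.by = "none")
            write.table(data.frame(probe = rownames(tab), t = tab$t, p = tab$P.Value),
                        "{out_path}", sep = "\\t", row.names = FALSE, quote = FALSE)
            """
        )
        r = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out_path, sep="\t").set_index("probe")
        dm = moderated_dm_test(beta, is_brain)
        np.testing.assert_allclose(dm["t"].to_numpy(), ref["t"].to_numpy(), rtol=1e-4)
        np.testing.assert_allclose(
            dm["p_value"].to_numpy(), ref["p"].to_numpy(), rtol=1e-4
        )


class TestRankAndTrim:
    def _dm(self, rows):
        df = pd.DataFrame(
            rows, columns=["probe_id", "delta", "adj_p"]
        ).set_index("probe_id")
        df["tested"] = True
        df["direction"] = np.where(df["delta"] > 0, "hyper", "hypo")
        return df

    def test_fewer_than_top_k_returns_all(self):
        dm = self._dm([("a", 0.6, 1e-5), ("b", 0.5, 1e-5), ("c", 0.4, 1e-5)])
        out = rank_and_trim(dm, SelectionConfig(top_k=20))
        assert list(out.index) == ["a", "b", "c"]

    def test_order_follows_absolute_delta(self):
        dm = self._dm(
            [("a", 0.4, 1e-5), ("b", -0.6, 1e-5), ("c", 0.5, 1e-5), ("d", 0.9, 0.5)]
        )
        out = rank_and_trim(dm)
        assert list(out.index) == ["b", "c", "a"]  # d fails adj_p

    def test_delta_tie_breaks_by_adjusted_p_then_id(self):
        dm = self._dm([("b", 0.5, 1e-3), ("a", 0.5, 1e-5), ("c", 0.5, 1e-3)])
        out = rank_and_trim(dm)
        assert list(out.index) == ["a", "b", "c"]

    def test_top_k_limits_each_direction(self):
        rows = [(f"h{i}", 0.9 - i * 0.01, 1e-6) for i in range(25)]
        rows += [(f"l{i}", -0.9 + i * 0.01, 1e-6) for i in range(25)]
        out = rank_and_trim(self._dm(rows), SelectionConfig(top_k=20))
        assert (out["direction"] == "hyper").sum() == 20
        assert (out["direction"] == "hypo").sum() == 20


class TestCpgDensity:
    def test_counts_match_hand_enumeration_on_constructed_sequence(self):
        # probe C at position 200 of a 400 bp sequence; flanking CpGs at
        # hand-picked offsets, some inside and some outside the 140 bp windows
        seq = list("A" * 400)
        for pos in (40, 90, 150, 198, 202, 250, 330, 345):
            seq[pos], seq[pos + 1] = "C", "G"
        seq[200], seq[201] = "C", "G"
        s = "".join(seq)
        up, down = count_flanking_cpgs(s, 200, 140)
        # upstream within [60, 199]: 90, 150, 198 -> 3 (40 is outside)
        # downstream within [202, 341]: 202, 250, 330 -> 3 (345 is outside)
        assert (up, down) == (3, 3)

    def test_zero_flanking_cpgs_dropped_and_2_2_retained(self):
        ann = pd.DataFrame(
            {
                "probe_id": ["bare", "dense"],
                "n_cpg_upstream_140": [0, 2],
                "n_cpg_downstream_140": [0, 2],
            }
        )
        assert cpg_density_filter(["bare", "dense"], ann) == ["dense"]

    def test_sequence_annotation_path(self):
        # CGs at 20, 23, 30, 37 and 41; probe C at 30 has two on each side
        ann = pd.DataFrame(
            {
                "probe_id": ["p"],
                "sequence": ["A" * 20 + "CGACG" + "A" * 5 + "CG" + "A" * 5 + "CGTTCG" + "A" * 10],
                "probe_offset": [30],
            }
        )
        s = ann.loc[0, "sequence"]
        assert s[30:32] == "CG"
        assert count_flanking_cpgs(s, 30, 140) == (2, 2)
        assert cpg_density_filter(["p"], ann) == ["p"]

    def test_missing_annotation_drops_probe(self):
        ann = pd.DataFrame(
            {"probe_id": ["x"], "n_cpg_upstream_140": [3], "n_cpg_downstream_140": [3]}
        )
        assert cpg_density_filter(["x", "ghost"], ann) == ["x"]


class TestDnase:
    def _table(self):
        return pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(10)],
                "dnase_brain": [0.0, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5],
            }
        )

    def test_zero_signal_retained_high_signal_dropped(self):
        kept, thr = dnase_filter(["p0", "p9"], self._table(), SelectionConfig(dnase_brain_max=1.0))
        assert kept == ["p0"] and thr == 1.0

    def test_default_threshold_is_percentile_of_probe_universe(self):
        kept, thr = dnase_filter(["p0", "p5"], self._table())
        assert thr == pytest.approx(np.percentile(self._table()["dnase_brain"], 33))
        assert kept == ["p0"]

    def test_missing_value_retained_with_warning(self, caplog):
        kept, _ = dnase_filter(["p0", "ghost"], self._table())
        assert kept == ["p0", "ghost"]


class TestFullCascade:
    def test_planted_markers_recovered_exactly(self):
        atlas = sd.simulate_atlas(sd.AtlasSimSpec(seed=123))
        meta = atlas.sample_meta.set_index("sample_id")
        res = select_markers(
            beta=atlas.beta,
            is_brain=meta["is_brain"],
            chromatin=atlas.chromatin,
            epigenome_groups=atlas.epigenome_groups,
            dnase=atlas.dnase,
            annotation=atlas.annotation,
            dataset_ids=meta["dataset_id"],
        )
        assert set(res.markers.index) == set(atlas.planted["probe_id"])
        directions = atlas.planted.set_index("probe_id")["direction"]
        for p in res.markers.index:
            assert res.markers.loc[p, "direction"] == directions[p]

    def test_cascade_is_monotone(self):
        atlas = sd.simulate_atlas(sd.AtlasSimSpec(seed=9, n_probes=150))
        meta = atlas.sample_meta.set_index("sample_id")
        stage1 = chromatin_disjoint_filter(atlas.chromatin, atlas.epigenome_groups)
        stage2 = availability_filter(
            atlas.beta.loc[stage1], dataset_ids=meta["dataset_id"]
        )
        dm = moderated_dm_test(atlas.beta.loc[stage2], meta["is_brain"])
        ranked = rank_and_trim(dm)
        stage5 = cpg_density_filter(ranked, atlas.annotation)
        stage6, _ = dnase_filter(stage5, atlas.dnase)
        assert set(stage2) <= set(stage1)
        assert set(ranked.index) <= set(stage2)
        assert set(stage5) <= set(ranked.index)
        assert set(stage6) <= set(stage5)
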