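import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pdxcna.genes import (
    GeneAnalysisError,
    bin_prevalence,
    hallmark_enrichment,
    project_to_genes,
    recurrent_cancer_genes,
    select_discordant_genes,
)
from pdxcna.threshold import BinStatus, PairDiscordance


def make_pair(grid, disc_idx=(), not_eval_idx=(), name="p"):
    status = np.zeros(grid.n_bins, dtype=np.int8)
    status[list(disc_idx)] = BinStatus.A_GREATER
    status[list(not_eval_idx)] = BinStatus.NOT_EVALUABLE
    n_eval = int((status != BinStatus.NOT_EVALUABLE).sum())
    n_disc = len(set(disc_idx) - set(not_eval_idx))
    return PairDiscordance(
        sample_a=f"{name}_a", sample_b=f"{name}_b", comparison_type="PT_PDX",
        bin_status=status, fraction_discordant=n_disc / max(n_eval, 1),
        n_evaluable_bins=n_eval,
    )


class TestBinPrevalence:
    def test_proportion_counts_discordant_over_evaluable(self, toy_grid):
        pairs = [make_pair(toy_grid, disc_idx=(0,), name=f"p{i}") for i in range(4)]
        pairs += [make_pair(toy_grid, name=f"q{i}") for i in range(6)]
        prev = bin_prevalence(pairs, toy_grid)
        assert prev.loc[0, "proportion"] == pytest.approx(0.4)
        assert prev.loc[0, "n_pairs_evaluable"] == 10

    def test_never_evaluable_bin_is_masked(self, toy_grid):
        pairs = [make_pair(toy_grid, not_eval_idx=(3,), name=f"p{i}") for i in range(2)]
        prev = bin_prevalence(pairs, toy_grid)
        assert np.isnan(prev.loc[3, "proportion"])
        assert prev.loc[3, "n_pairs_evaluable"] == 0

    def test_empty_pair_list_rejected(self, toy_grid):
        with pytest.raises(GeneAnalysisError):
            bin_prevalence([], toy_grid)


class TestProjectToGenes:
    def prevalence_frame(self, grid, proportions):
        prev = grid.to_frame()
        prev["proportion"] = proportions
        prev["n_pairs_evaluable"] = [0 if np.isnan(p) else 1 for p in proportions]
        return prev

    def test_single_bin_gene_takes_bin_value(self, toy_grid):
        props = [0.3] + [0.0] * (toy_grid.n_bins - 1)
        genes = pd.DataFrame([
            {"chromosome": "1", "start": 100_000, "end": 900_000, "gene_id": "g1"}
        ])
        out = project_to_genes(self.prevalence_frame(toy_grid, props), genes, toy_grid)
        assert out["g1"] == pytest.approx(0.3)

    def test_multi_bin_gene_takes_unweighted_mean(self, toy_grid):
        props = [0.2, 0.4] + [0.0] * (toy_grid.n_bins - 2)
        genes = pd.DataFrame([
            {"chromosome": "1", "start": 900_000, "end": 1_100_000, "gene_id": "g1"}
        ])
        out = project_to_genes(self.prevalence_frame(toy_grid, props), genes, toy_grid)
        assert out["g1"] == pytest.approx(0.3)

    def test_masked_bins_ignored_in_mean(self, toy_grid):
        props = [np.nan, 0.5] + [0.0] * (toy_grid.n_bins - 2)
        genes = pd.DataFrame([
            {"chromosome": "1", "start": 500_000, "end": 1_500_000, "gene_id": "g1"}
        ])
        out = project_to_genes(self.prevalence_frame(toy_grid, props), genes, toy_grid)
        assert out["g1"] == pytest.approx(0.5)

    def test_gene_on_fully_masked_bins_dropped(self, toy_grid):
        props = [np.nan] * toy_grid.n_bins
        genes = pd.DataFrame([
            {"chromosome": "1", "start": 0, "end": 500_000, "gene_id": "g1"}
        ])
        out = project_to_genes(self.prevalence_frame(toy_grid, props), genes, toy_grid)
        assert "g1" not in out.index


class TestGeneSelection:
    def test_intersection_of_top_quantile_and_proportion_floor(self):
        vals = pd.Series(
            {f"g{i}": p for i, p in enumerate([0.9, 0.8, 0.7] + [0.2] * 97)}
        )
        selected = select_discordant_genes(vals, top_quantile=0.025)
        # top 2.5% of 100 distinct-topped genes, all clearing the 0.25 floor
        assert set(selected) == {"g0", "g1", "g2"}
        # the floor bites even inside the top quantile
        low = pd.Series({f"g{i}": p for i, p in enumerate([0.9, 0.2] + [0.01] * 98)})
        assert select_discordant_genes(low, top_quantile=0.025) == ["g0"]

    def test_no_gene_above_floor_excludes_cohort(self):
        vals = pd.Series({f"g{i}": 0.1 for i in range(40)})
        assert select_discordant_genes(vals) == []

    def test_all_tied_at_cut_all_selected(self):
        vals = pd.Series({f"g{i}": 0.5 for i in range(40)})
        assert len(select_discordant_genes(vals)) == 40


class TestEnrichment:
    def test_es_zero_when_proportions_match(self):
        sets = {"S": {f"g{i}" for i in range(5)},
                "T": {f"g{i}" for i in range(5, 10)}}
        # universe 10, selection of 4 with 2 in S: x/N = 2/4 = g/G = 5/10
        selected = ["g0", "g1", "g5", "g6"]
        out = hallmark_enrichment(selected, sets).set_index("gene_set")
        assert out.loc["S", "es"] == pytest.approx(0.0)

    def test_es_natural_log_worked_example(self):
        # x=10, N=100, g=50, G=5000 -> ES = ln(10)
        genes = [f"g{i}" for i in range(5000)]
        # a 50-gene set inside a 5000-gene universe (catch-all second set)
        sets = {"S": set(genes[:50]), "REST": set(genes)}
        selected = genes[40:50] + genes[5000 - 90:]
        out = hallmark_enrichment(selected, sets).set_index("gene_set")
        assert out.loc["S", "x"] == 10
        assert out.loc["S", "universe_size"] == 5000
        assert out.loc["S", "es"] == pytest.approx(math.log(10))

    def test_hypergeometric_matches_exhaustive_enumeration(self):
        # population of 12 genes, set of 5, selection of 4: enumerate all draws
        genes = [f"g{i}" for i in range(12)]
        sets = {"S": set(genes[:5]), "REST": set(genes)}
        selected = ["g0", "g1", "g5", "g6"]
        out = hallmark_enrichment(selected, sets).set_index("gene_set")
        x_obs = 2
        n_sel = 4
        hits = 0
        total = 0
        for draw in itertools.combinations(range(12), n_sel):
            total += 1
            if sum(1 for g in draw if g < 5) >= x_obs:
                hits += 1
        assert out.loc["S", "p_value"] == pytest.approx(hits / total)

    def test_empty_intersection_sentinel(self):
        sets = {"S": {"a", "b"}, "T": {"c", "d"}}
        out = hallmark_enrichment(["c"], sets).set_index("gene_set")
        assert out.loc["S", "es"] == -np.inf
        assert out.loc["S", "p_value"] == 1.0

    def test_bh_qvalues_monotone_in_pvalue_order(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        sets = {f"S{k}": set(rng.choice(genes, 30, replace=False)) for k in range(12)}
        selected = list(rng.choice(genes, 20, replace=False))
        out = hallmark_enrichment(selected, sets).sort_values("p_value")
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()
        # BH q is monotone after the running-minimum step
        assert (np.diff(out["q_value"].to_numpy()) >= -1e-12).all()

    def test_empty_selection_rejected(self):
        with pytest.raises(GeneAnalysisError):
            hallmark_enrichment([], {"S": {"a"}})


class TestRecurrentGenes:
    def prevalence(self):
        cohorts = [f"c{i}" for i in range(8)]
        data = {c: pd.Series(dtype=float) for c in cohorts}
        df = pd.DataFrame(0.0, index=["braf", "tp53", "quiet"], columns=cohorts)
        df.loc["braf", cohorts[:5]] = 0.4   # flagged in 5 cohorts
        df.loc["tp53", cohorts[:4]] = 0.4   # only 4
        return df

    def test_min_cohort_criterion(self):
        out = recurrent_cancer_genes(self.prevalence(), min_cohorts=5)
        assert out["gene_id"].tolist() == ["braf"]
        assert out.loc[0, "n_cohorts"] == 5

    def test_cancer_gene_restriction(self):
        out = recurrent_cancer_genes(
            self.prevalence(), cancer_genes=["tp53"], min_cohorts=4
        )
        assert out["gene_id"].tolist() == ["tp53"]

    def test_all_zero_prevalence_empty(self):
        df = pd.DataFrame(0.0, index=["a"], columns=["c1", "c2", "c3", "c4", "c5"])
        assert len(recurrent_cancer_genes(df)) == 0
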