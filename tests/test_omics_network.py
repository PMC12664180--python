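"""Correlation networks, tripartite merging and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famscan.omics_network import (
    NetworkEdge,
    build_tripartite_network,
    coexpression_screen,
    hypergeometric_enrichment,
    metabolite_association,
    pearson_with_p,
)

SAMPLES = [f"{g}_{r}" for g in ("CK", "C12", "C24") for r in (1, 2, 3)]


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_with_p([1, 2, 3, 4], [3, 5, 7, 9])
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_hand_formula_example(self):
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        t = 0.8 * math.sqrt(2) / math.sqrt(1 - 0.64)
        assert p == pytest.approx(2 * stats.t.sf(t, 2))

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x, y = rng.normal(size=n), rng.normal(size=n)
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 1, 1], [1, 2, 3])

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(size=9)
        perm = rng.permutation(9)
        r1, _ = pearson_with_p(x, y)
        r2, _ = pearson_with_p(x[perm], y[perm])
        assert r1 == pytest.approx(r2)


def _frame(rows):
    return pd.DataFrame(rows, index=SAMPLES).T


class TestCoexpression:
    def test_identical_profile_r_one(self):
        profile = np.arange(1.0, 10.0)
        seeds = _frame({"s": profile})
        cands = _frame({"c": profile})
        res = coexpression_screen(seeds, cands, {"c": "MYB"})
        assert len(res.edges) == 1 and res.edges[0].r == pytest.approx(1.0)
        assert res.n_tfs == 1 and res.n_families == 1

    def test_empty_candidates(self):
        seeds = _frame({"s": np.arange(1.0, 10.0)})
        cands = pd.DataFrame(columns=SAMPLES)
        res = coexpression_screen(seeds, cands, {})
        assert res.edges == [] and res.n_tfs == 0

    def test_raising_r_min_never_adds_edges(self, bundle, sim_config):
        from famscan.synthetic_data import generate_expression

        fpkm, _ = generate_expression(bundle.manifest, sim_config, 2)
        module = bundle.manifest.expression["module"]
        seeds = fpkm.loc[module["seeds"]]
        cands = fpkm.loc[list(module["members"]) + list(module["decoys"])]
        fams = {**module["members"], **module["decoys"]}
        loose = coexpression_screen(seeds, cands, fams, r_min=0.8)
        tight = coexpression_screen(seeds, cands, fams, r_min=0.95)
        loose_pairs = {(e.source, e.target) for e in loose.edges}
        tight_pairs = {(e.source, e.target) for e in tight.edges}
        assert tight_pairs <= loose_pairs

    def test_planted_module_recovery(self, bundle, sim_config):
        from famscan.synthetic_data import generate_expression

        fpkm, _ = generate_expression(bundle.manifest, sim_config, 1)
        module = bundle.manifest.expression["module"]
        seeds = fpkm.loc[module["seeds"]]
        cands = fpkm.loc[list(module["members"]) + list(module["decoys"])]
        res = coexpression_screen(seeds, cands, {**module["members"], **module["decoys"]})
        recovered = {e.target for e in res.edges}
        assert set(module["members"]) <= recovered
        assert len(recovered - set(module["members"])) <= 2


class TestMetabolites:
    @staticmethod
    def _assoc(bundle, sim_config, seed):
        from famscan.expression_stats import call_degs, degs_to_frame
        from famscan.synthetic_data import generate_expression, generate_metabolome

        fpkm, groups = generate_expression(bundle.manifest, sim_config, seed)
        met, met_meta = generate_metabolome(bundle.manifest, sim_config, seed)
        deg = degs_to_frame(call_degs(met, groups, "CK", "Cold24h"))
        meta = met_meta.join(deg[["log2fc", "p_value", "fdr_q"]])
        seeds = bundle.manifest.expression["module"]["seeds"]
        return metabolite_association(fpkm.loc[seeds], met, meta), met_meta

    def test_planted_couplings_recovered(self, bundle, sim_config):
        res, _ = self._assoc(bundle, sim_config, 1)
        coupled = set(bundle.manifest.metabolome["coupled"])
        recovered = {e.target for e in res.edges}
        assert len(recovered & coupled) >= len(coupled) - 1
        assert len(recovered - coupled) <= 1

    def test_class_breakdown_counts(self, bundle, sim_config):
        res, met_meta = self._assoc(bundle, sim_config, 1)
        linked = {e.target for e in res.edges}
        row = res.class_breakdown.set_index("class")
        assert int(row.loc["flavonoid", "n_linked"]) == len(
            {m for m in linked if met_meta.loc[m, "class"] == "flavonoid"}
        )

    def test_constant_gene_profile_yields_no_edges(self):
        genes = _frame({"flat": np.full(9, 3.0)})
        mets = _frame({"m": np.arange(9.0)})
        meta = pd.DataFrame(
            {"class": ["flavonoid"], "log2fc": [3.0], "p_value": [0.001],
             "fdr_q": [0.001]}, index=["m"],
        )
        res = metabolite_association(genes, mets, meta)
        assert res.edges == []


class TestTripartite:
    def test_disjoint_edge_lists_merge(self):
        e1 = [NetworkEdge("w1", "t1", "tf_coexpr", 0.95, 1e-4)]
        e2 = [NetworkEdge("f1", "m1", "gene_metabolite", 0.9, 1e-3)]
        roles = {"w1": "wrky", "t1": "tf", "f1": "functional_gene", "m1": "metabolite"}
        g = build_tripartite_network([e1, e2], roles)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 2

    def test_duplicate_edge_keeps_max_abs_r(self):
        e1 = [NetworkEdge("a", "b", "tf_coexpr", 0.85, 0.01)]
        e2 = [NetworkEdge("a", "b", "tf_coexpr", 0.95, 0.001)]
        g = build_tripartite_network([e1, e2], {"a": "wrky", "b": "tf"})
        assert g.edges["a", "b"]["r"] == 0.95

    def test_conflicting_roles_rejected(self):
        e = [NetworkEdge("a", "b", "tf_coexpr", 0.9, 0.01)]
        with pytest.raises(ValueError, match="conflicting"):
            build_tripartite_network(
                [e, e], [{"a": "wrky", "b": "tf"}, {"a": "wrky", "b": "metabolite"}]
            )

    def test_export_files(self, tmp_path):
        from famscan.omics_network import export_network

        e = [NetworkEdge("a", "b", "tf_coexpr", 0.9, 0.01)]
        g = build_tripartite_network([e], {"a": "wrky", "b": "tf"})
        paths = export_network(g, tmp_path)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        sif = paths["sif"].read_text().strip().split("\t")
        assert sif == ["a", "tf_coexpr", "b"]


class TestEnrichment:
    def test_query_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        ann = {g: ["T1"] for g in universe}
        frame = hypergeometric_enrichment(universe, ann, universe)
        assert frame["p"].iloc[0] == pytest.approx(1.0)

    def test_combinatorial_value(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        ann = {f"g{i}": ["T"] for i in range(5)}
        frame = hypergeometric_enrichment(query, ann, universe)
        assert frame["p"].iloc[0] == pytest.approx(1 / 15504)

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(7)
        universe = [f"g{i}" for i in range(12)]
        members = set(rng.choice(universe, 5, replace=False))
        ann = {g: ["T"] for g in members}
        query = set(rng.choice(universe, 6, replace=False))
        k = len(query & members)
        total = hits = 0
        for draw in combinations(universe, len(query)):
            total += 1
            if len(set(draw) & members) >= k:
                hits += 1
        frame = hypergeometric_enrichment(query, ann, set(universe))
        assert frame["p"].iloc[0] == pytest.approx(hits / total)

    def test_bh_q_at_least_p(self):
        universe = {f"g{i}" for i in range(30)}
        rng = np.random.default_rng(1)
        ann = {g: [f"T{rng.integers(0, 5)}"] for g in universe}
        query = set(list(universe)[:8])
        frame = hypergeometric_enrichment(query, ann, universe)
        assert (frame["q"] >= frame["p"] - 1e-12).all()

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(set(), {}, {"g"})
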