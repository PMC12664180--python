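"""Alignment, neighbor joining, bootstrap and subgroup assignment."""

import numpy as np
import pytest

from famscan.phylogeny import (
    DistanceMatrix,
    align_domains,
    assign_subgroups,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
)


def _random_topology(rng, n):
    """Random binary tree as (children dict, root, taxa)."""
    children = {}
    active = [f"T{i}" for i in range(n)]
    counter = 0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        node = f"N{counter}"
        counter += 1
        children[node] = [(a, float(rng.uniform(0.1, 1.0))),
                         (b, float(rng.uniform(0.1, 1.0)))]
        active = [x for x in active if x not in (a, b)] + [node]
    return children, active[0], [f"T{i}" for i in range(n)]


def _path_lengths(children, root, taxa):
    anc = {}

    def walk(node, acc):
        if node not in children:
            anc[node] = dict(acc + [(node, 0.0)])
            return
        for child, bl in children[node]:
            walk(child, [(k, d + bl) for k, d in acc] + [(node, bl)])

    walk(root, [])
    out = {}
    for a in taxa:
        for b in taxa:
            if a != b:
                common = set(anc[a]) & set(anc[b])
                out[(a, b)] = min(anc[a][c] + anc[b][c] for c in common)
    return out


def _random_additive(rng, n=6):
    """Random binary tree with U(0.1, 1) branch lengths -> (dm, bipartitions)."""
    children = {}
    active = [f"T{i}" for i in range(n)]
    counter = 0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[j], active[i]
        node = f"N{counter}"
        counter += 1
        children[node] = [(a, float(rng.uniform(0.1, 1.0))),
                         (b, float(rng.uniform(0.1, 1.0)))]
        active = [x for x in active if x not in (a, b)] + [node]
    root = active[0]
    anc = {}

    def walk(node, acc):
        if node not in children:
            anc[node] = dict(acc + [(node, 0.0)])
            return
        for child, bl in children[node]:
            walk(child, [(k, d + bl) for k, d in acc] + [(node, bl)])

    walk(root, [])
    taxa = [f"T{i}" for i in range(n)]
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            common = set(anc[taxa[x]]) & set(anc[taxa[y]])
            d[x, y] = d[y, x] = min(anc[taxa[x]][c] + anc[taxa[y]][c] for c in common)

    def leafset(node):
        if node not in children:
            return frozenset([node])
        out = frozenset()
        for child, _ in children[node]:
            out |= leafset(child)
        return out

    allset = frozenset(taxa)
    bps = set()
    for node in children:
        side = leafset(node)
        canon = allset - side if taxa[0] in side else side
        if 1 < len(canon) < n - 1:
            bps.add(canon)
    return DistanceMatrix(taxa, d), bps


class TestAlign:
    def test_identical_sequences_no_gaps(self):
        aln = align_domains({"a": "WRKYGQKAAA", "b": "WRKYGQKAAA"})
        assert aln == {"a": "WRKYGQKAAA", "b": "WRKYGQKAAA"}

    def test_shorter_row_gapped_at_end(self):
        aln = align_domains({"a": "WRKYGQKA", "b": "WRKYGQK"})
        assert aln == {"a": "WRKYGQKA", "b": "WRKYGQK-"}

    def test_anchor_columns_aligned_and_ungap_roundtrip(self):
        seqs = {"a": "MMWRKYGQKCCC", "b": "WRKYGQKDD", "c": "MWRKYGQKE"}
        aln = align_domains(seqs)
        assert len({len(r) for r in aln.values()}) == 1
        starts = {row.find("WRKYGQK") for row in aln.values()}
        assert len(starts) == 1
        for name, row in aln.items():
            assert row.replace("-", "") == seqs[name]

    def test_missing_anchor_excluded(self):
        aln = align_domains({"a": "WRKYGQKAA", "b": "WRKYGQKCC", "x": "MMMMMMMM"})
        assert "x" not in aln

    def test_tree_distance_correlation_on_synthetic_domains(self):
        """p-distances track the generating tree's path lengths.

        Sequences evolve down a random tree: each branch applies a
        substitution count proportional to its length.
        """
        from scipy.stats import spearmanr

        rng = np.random.default_rng(8)
        n = 10
        children, root, taxa = _random_topology(rng, n)
        base = "WRKYGQK" + "".join(rng.choice(list("ADEFGIKLMNPQRSTVY"), 200))
        seqs = {}

        def evolve(seq, bl):
            # low rate keeps p-distances far from saturation
            chars = list(seq)
            n_sub = max(1, int(round(5 * bl)))
            for i in rng.choice(np.arange(7, len(chars)), n_sub, replace=False):
                chars[i] = rng.choice(list("ADEFGIKLMNPQRSTVY"))
            return "".join(chars)

        def walk(node, seq):
            if node not in children:
                seqs[node] = seq
                return
            for child, bl in children[node]:
                walk(child, evolve(seq, bl))

        walk(root, base)
        path = _path_lengths(children, root, taxa)
        aln = align_domains(seqs)
        pdm = p_distance_matrix(aln)
        order = [pdm.taxa.index(t) for t in taxa]
        observed = pdm.d[np.ix_(order, order)]
        iu = np.triu_indices(n, 1)
        true_d = np.array([[path[(a, b)] if a != b else 0.0 for b in taxa] for a in taxa])
        rho = spearmanr(true_d[iu], observed[iu]).statistic
        assert rho > 0.8


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        pl = tree.path_length_matrix()
        assert np.allclose(pl.d, dm.d)
        # branch lengths a=0.5, b=1.5, c=2.5 readable from the newick
        assert "A:0.5" in tree.newick() and "B:1.5" in tree.newick()

    def test_additive_matrices_recovered_exactly(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            dm, bps = _random_additive(rng, n=6)
            tree = nj_tree(dm)
            assert np.allclose(tree.path_length_matrix().d, dm.d, atol=1e-9)
            assert tree.internal_bipartitions() == bps

    def test_identical_rows_become_zero_length_siblings(self):
        d = np.array([[0, 0, 5, 5], [0, 0, 5, 5], [5, 5, 0, 8], [5, 5, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], d))
        assert frozenset({"a", "b"}) in {
            node.leaf_names() for node in tree.root.walk() if not node.is_leaf
        }
        assert tree.path_length_matrix().get("a", "b") == 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(29)
        dm, _ = _random_additive(rng, n=7)
        perm = rng.permutation(len(dm.taxa))
        dm2 = DistanceMatrix([dm.taxa[i] for i in perm], dm.d[np.ix_(perm, perm)])
        t1, t2 = nj_tree(dm), nj_tree(dm2)
        assert t1.internal_bipartitions() == t2.internal_bipartitions()

    def test_cross_check_against_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(31)
        for _ in range(5):
            dm, _ = _random_additive(rng, n=6)
            ours = nj_tree(dm).internal_bipartitions()
            sk_tree = skbio_nj(SkbioDM(dm.d, ids=dm.taxa))
            allset = frozenset(dm.taxa)
            theirs = set()
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                canon = allset - side if dm.taxa[0] in side else side
                if 1 < len(canon) < len(dm.taxa) - 1:
                    theirs.add(canon)
            assert ours == theirs


class TestBootstrap:
    @staticmethod
    def _strong_alignment():
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACDEFGHIK"), 60))
        other = "".join(rng.choice(list("LMNPQRSTV"), 30)) + base[30:]
        mid = base[:15] + other[15:45] + base[45:]
        return {"A1": base, "A2": base, "B1": other, "B2": other, "C": mid}

    def test_strong_clade_high_support(self):
        tree = bootstrap_support(self._strong_alignment(), n_reps=200, seed=0)
        supports = {node.leaf_names(): node.support
                    for node in tree.root.walk()
                    if not node.is_leaf and node.support is not None}
        clade = [s for side, s in supports.items() if side in
                 (frozenset({"B1", "B2"}), frozenset({"A1", "A2", "C"}))]
        assert clade and max(clade) >= 95

    def test_zero_reps_leaves_support_missing(self):
        tree = bootstrap_support(self._strong_alignment(), n_reps=0)
        assert all(node.support is None for node in tree.root.walk())

    def test_fixed_seed_reproducible(self):
        aln = self._strong_alignment()
        t1 = bootstrap_support(aln, n_reps=50, seed=7)
        t2 = bootstrap_support(aln, n_reps=50, seed=7)
        assert t1.newick() == t2.newick()

    def test_supports_within_bounds(self):
        tree = bootstrap_support(self._strong_alignment(), n_reps=50, seed=1)
        for node in tree.root.walk():
            if node.support is not None:
                assert 0 <= node.support <= 100


class TestSubgroups:
    def test_sister_reference_assignment(self):
        dm = DistanceMatrix(
            ["g1", "refII", "refI"],
            np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]], float),
        )
        tree = nj_tree(dm)
        out = assign_subgroups(tree, {"refII": "II", "refI": "I"})
        assert out["g1"] == "II"

    def test_synthetic_group_recovery(self, bundle, gene_models):
        """Domain-template clades recover the manifest groups exactly."""
        from famscan.family_scan import build_candidates, collapse_redundancy

        cands = collapse_redundancy(
            [c for c in build_candidates(gene_models) if c.status == "accepted"]
        )
        survivors = {c.gene_id: c for c in cands if c.status == "accepted"}
        truth = {g["id"]: g["group"] for g in bundle.manifest.genes
                 if g["kind"] == "family" and not g["isoform_of"]}
        domains = {}
        for gid, cand in survivors.items():
            h = cand.hits[-1]
            domains[gid] = cand.protein[h.dom_start:h.dom_end]
        # one reference per group: the first member of each group
        refs = {}
        for gid, grp in sorted(truth.items()):
            refs.setdefault(grp, gid)
        ref_labels = {gid: grp for grp, gid in refs.items()}
        aln = align_domains(domains)
        tree = nj_tree(p_distance_matrix(aln))
        assigned = assign_subgroups(tree, ref_labels)
        wrong = [g for g, grp in assigned.items()
                 if grp != truth[g] and g not in ref_labels]
        assert not wrong

    def test_domain_architecture_fallback(self):
        dm = DistanceMatrix(
            ["gA", "gB", "ref"],
            np.array([[0, 0.2, 0.9], [0.2, 0, 0.9], [0.9, 0.9, 0]], float),
        )
        tree = nj_tree(dm)
        out = assign_subgroups(
            tree, {"ref": "II"},
            domain_info={"gA": (2, "C2H2"), "gB": (1, "C2HC")},
        )
        # both genes nest in a reference clade here, so clade rule wins
        assert set(out) == {"gA", "gB"}
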