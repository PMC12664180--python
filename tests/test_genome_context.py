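"""Chromosome maps, anchors, collinearity, duplication classes, Ka/Ks."""

import itertools

import numpy as np
import pytest

from famscan.genome_context import (
    _CODON_AA,
    AnchorPair,
    build_chromosome_map,
    classify_duplications,
    codon_align,
    compute_ka_ks,
    detect_collinear_blocks,
    find_anchor_pairs,
    jukes_cantor,
)
from famscan.genome_io import extract_cds


class TestChromosomeMap:
    def test_terminal_window_count(self):
        genes = [("g1", "c", 50_000), ("g2", "c", 150_000), ("g3", "c", 199_000)]
        cmap = build_chromosome_map(genes, {"c": 200_000}, terminal_window_bp=60_000)
        assert cmap.terminal_count == 3

    def test_empty_family(self):
        cmap = build_chromosome_map([], {"c": 200_000})
        assert cmap.counts() == {"c": 0}
        assert sum(cmap.density["c"]) == 0

    def test_bins_sum_to_gene_count(self, bundle, primary_models):
        fam = bundle.manifest.family_gene_ids()
        genes = [(g, primary_models[g].chromosome, primary_models[g].start) for g in fam]
        cmap = build_chromosome_map(genes, bundle.manifest.chrom_lengths)
        for chrom, counts in cmap.density.items():
            assert sum(counts) == len(cmap.per_chromosome[chrom])
        assert sum(cmap.counts().values()) == len(fam)

    def test_gene_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="gX"):
            build_chromosome_map([("gX", "c", 300_000)], {"c": 200_000})


class TestAnchors:
    def test_identical_pair(self):
        pairs = find_anchor_pairs({"a": "MKLV" * 30, "b": "MKLV" * 30})
        assert len(pairs) == 1 and pairs[0].similarity == 1.0

    def test_unrelated_random_sequences_no_pair(self):
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(5):
            prots = {"a": "".join(rng.choice(aa, 300)), "b": "".join(rng.choice(aa, 300))}
            assert find_anchor_pairs(prots, prescreen=False) == []

    def test_planted_duplicates_recovered(self, bundle, primary_models):
        prots = {g: m.protein_seq for g, m in primary_models.items()}
        pairs = {frozenset((p.gene_a, p.gene_b)) for p in find_anchor_pairs(prots)}
        for dup in bundle.manifest.duplicate_pairs:
            assert frozenset((dup["a"], dup["b"])) in pairs
        for a, b in bundle.manifest.block_anchor_pairs:
            assert frozenset((a, b)) in pairs


def _brute_force_chains(items, orient, max_gap):
    """Exhaustive longest-chain oracle for small anchor sets."""
    best = []
    n = len(items)
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            ra = [items[i][0] for i in combo]
            rb = [items[i][1] for i in combo]
            if any(ra[k + 1] <= ra[k] or ra[k + 1] - ra[k] > max_gap
                   for k in range(r - 1)):
                continue
            if orient == +1:
                ok = all(0 < rb[k + 1] - rb[k] <= max_gap for k in range(r - 1))
            else:
                ok = all(0 < rb[k] - rb[k + 1] <= max_gap for k in range(r - 1))
            if ok:
                return list(combo)
    return best


class TestBlocks:
    def _index(self, ranks_a, ranks_b):
        idx = {}
        anchors = []
        for k, (ra, rb) in enumerate(zip(ranks_a, ranks_b)):
            ga, gb = f"a{k}", f"b{k}"
            idx[ga] = ("cA", ra)
            idx[gb] = ("cB", rb)
            anchors.append(AnchorPair(ga, gb, 0.9))
        return anchors, idx

    def test_perfectly_collinear(self):
        anchors, idx = self._index(range(1, 7), range(11, 17))
        blocks = detect_collinear_blocks(anchors, idx)
        assert len(blocks) == 1 and blocks[0].n_anchors == 6

    def test_shuffled_anchor_drops_to_five(self):
        anchors, idx = self._index([1, 2, 3, 4, 5, 6], [11, 12, 13, 80, 14, 15])
        blocks = detect_collinear_blocks(anchors, idx)
        assert len(blocks) == 1 and blocks[0].n_anchors == 5

    def test_matches_exhaustive_oracle_on_small_sets(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            ranks_a = sorted(rng.choice(60, n, replace=False))
            ranks_b = list(rng.choice(60, n, replace=False))
            anchors, idx = self._index(ranks_a, ranks_b)
            blocks = detect_collinear_blocks(anchors, idx, min_anchors=2, max_rank_gap=25)
            best_len = max(
                (len(_brute_force_chains(list(zip(ranks_a, ranks_b)), o, 25))
                 for o in (+1, -1)),
            )
            got = max((b.n_anchors for b in blocks), default=0)
            # chains below min_anchors are not reported
            assert got == (best_len if best_len >= 2 else 0)

    def test_order_invariance(self):
        anchors, idx = self._index([1, 2, 3, 4, 5, 6], [11, 12, 13, 80, 14, 15])
        fwd = detect_collinear_blocks(anchors, idx)
        rev = detect_collinear_blocks(anchors[::-1], idx)
        assert [b.pair_set() for b in fwd] == [b.pair_set() for b in rev]

    def test_planted_block_recovered_exactly(self, bundle, primary_models):
        prots = {g: m.protein_seq for g, m in primary_models.items()}
        anchors = find_anchor_pairs(prots)
        idx = _order_index(primary_models)
        blocks = detect_collinear_blocks(anchors, idx)
        assert len(blocks) == 1
        truth = {frozenset(p) for p in bundle.manifest.block_anchor_pairs}
        assert blocks[0].pair_set() == truth


def _order_index(primary_models):
    idx = {}
    by_chrom = {}
    for m in primary_models.values():
        by_chrom.setdefault(m.chromosome, []).append(m)
    for chrom, ms in by_chrom.items():
        for rank, m in enumerate(sorted(ms, key=lambda g: g.start)):
            idx[m.gene_id] = (chrom, rank)
    return idx


class TestClassification:
    def test_adjacent_paralogs_are_tandem(self):
        pairs = [AnchorPair("a", "b", 0.9)]
        positions = {"a": ("c", 1000, 2000), "b": ("c", 10_000, 11_000)}
        idx = {"a": ("c", 0), "b": ("c", 1)}
        out = classify_duplications(pairs, [], positions, idx)
        assert out[0].dup_class == "tandem"

    def test_partition_property(self, bundle, primary_models):
        prots = {g: m.protein_seq for g, m in primary_models.items()}
        anchors = find_anchor_pairs(prots)
        idx = _order_index(primary_models)
        blocks = detect_collinear_blocks(anchors, idx)
        fam = set(bundle.manifest.family_gene_ids())
        fam_pairs = [a for a in anchors if a.gene_a in fam and a.gene_b in fam]
        positions = {g: (m.chromosome, m.start, m.end) for g, m in primary_models.items()}
        dups = classify_duplications(fam_pairs, blocks, positions, idx)
        assert len(dups) == len(fam_pairs)
        by_class = {d.dup_class: frozenset((d.gene_a, d.gene_b)) for d in dups}
        truth = {d["dup_class"]: frozenset((d["a"], d["b"]))
                 for d in bundle.manifest.duplicate_pairs}
        assert by_class == truth


def _ng86_oracle(cds_a, cds_b):
    """Independent NG86: explicit pathway enumeration, <= 3 codons."""
    assert len(cds_a) == len(cds_b) <= 9

    def syn_sites(codon):
        aa = _CODON_AA[codon]
        s = 0.0
        for pos in range(3):
            for b in "TCAG":
                if b != codon[pos]:
                    alt = codon[:pos] + b + codon[pos + 1:]
                    if _CODON_AA[alt] == aa:
                        s += 1 / 3
        return s

    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        S += (syn_sites(ca) + syn_sites(cb)) / 2
        N += 3 - (syn_sites(ca) + syn_sites(cb)) / 2
        diff = [k for k in range(3) if ca[k] != cb[k]]
        if not diff:
            continue
        paths = []
        for perm in itertools.permutations(diff):
            cur, s, n, blocked = ca, 0, 0, False
            for pos in perm:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if _CODON_AA[nxt] == "*" and nxt != cb:
                    blocked = True
                if _CODON_AA[nxt] == _CODON_AA[cur]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n, blocked))
        usable = [(s, n) for s, n, b in paths if not b] or [(s, n) for s, n, _ in paths]
        Sd += sum(s for s, _ in usable) / len(usable)
        Nd += sum(n for _, n in usable) / len(usable)
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


class TestKaKs:
    def test_identical_cds(self):
        ka, ks, ratio = compute_ka_ks("ATGGCT", "ATGGCT")
        assert ka == 0 and ks == 0 and ratio is None

    def test_synonymous_only_difference(self):
        # Leu CTT -> CTC: fourfold-degenerate third position
        ka, ks, ratio = compute_ka_ks("CTTGCT", "CTCGCT")
        assert ka == 0 and ks > 0 and ratio == 0

    def test_matches_pathway_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        codons = [c for c, aa in _CODON_AA.items() if aa != "*"]
        checked = 0
        while checked < 60:
            n = int(rng.integers(1, 4))
            a = "".join(rng.choice(codons, n))
            b = "".join(rng.choice(codons, n))
            ka, ks, _ = compute_ka_ks(a, b)
            oka, oks = _ng86_oracle(a, b)
            if ka is None or oka is None:
                assert (ka is None) == (oka is None)
            else:
                assert ka == pytest.approx(oka, abs=1e-12)
            if ks is None or oks is None:
                assert (ks is None) == (oks is None)
            else:
                assert ks == pytest.approx(oks, abs=1e-12)
            checked += 1

    def test_symmetry(self):
        rng = np.random.default_rng(23)
        codons = [c for c, aa in _CODON_AA.items() if aa != "*"]
        for _ in range(20):
            a = "".join(rng.choice(codons, 10))
            b = "".join(rng.choice(codons, 10))
            assert compute_ka_ks(a, b) == compute_ka_ks(b, a)

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            compute_ka_ks("ATG", "ATGGCT")

    def test_planted_duplicates_under_purifying_selection(self, bundle, primary_models):
        """omega = 0.2 divergence shows Ka/Ks well below 1."""
        genome = bundle.genome
        for dup in bundle.manifest.duplicate_pairs:
            a = extract_cds(primary_models[dup["a"]], genome)
            b = extract_cds(primary_models[dup["b"]], genome)
            ka, ks, ratio = compute_ka_ks(*codon_align(a, b))
            assert ks == pytest.approx(dup["target_ks"], abs=0.15)
            assert ratio is not None and ratio < 1
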