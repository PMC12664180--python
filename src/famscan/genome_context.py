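"""Chromosomal distribution, duplication discovery/classification, Ka/Ks.

Duplication classes follow the usual census conventions: *tandem* pairs
sit on one chromosome with at most a handful of intervening genes and a
bounded separation; *segmental* pairs fall inside collinear (syntenic)
blocks found by rank-space chaining of homologous anchor pairs (a
reduced MCScanX-style procedure); everything else is *dispersed*.

Selection pressure on duplicate pairs is quantified by the Nei-Gojobori
(1986) method with Jukes-Cantor correction: per-codon synonymous and
nonsynonymous site counts are averaged over both sequences, observed
differences are averaged over all mutational pathways of each codon
pair, and the proportions p are corrected by d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Data.CodonTable import standard_dna_table

from ._align import global_identity, kmer_share

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# chromosome map

@dataclass
class ChromosomeMap:
    bin_bp: int
    per_chromosome: dict[str, list[tuple[str, int]]]  # chrom -> [(gene_id, start)]
    density: dict[str, list[int]]  # chrom -> counts per bin
    densest_bin: dict[str, int]  # chrom -> bin index of max count
    terminal_count: int  # family genes within terminal_window of either end

    def counts(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.per_chromosome.items()}


def build_chromosome_map(
    genes: Iterable[tuple[str, str, int]],
    chrom_lengths: Mapping[str, int],
    bin_bp: int = 100_000,
    terminal_window_bp: int | None = None,
) -> ChromosomeMap:
    """Bin family genes into density windows and count terminal enrichment.

    ``genes`` is an iterable of (gene_id, chromosome, start).  The
    terminal count is the number of genes lying within
    ``terminal_window_bp`` of either chromosome end (window truncated to
    half the chromosome length when larger, with a log record).
    """
    per_chrom: dict[str, list[tuple[str, int]]] = {c: [] for c in chrom_lengths}
    for gene_id, chrom, start in genes:
        if chrom not in chrom_lengths:
            raise ValueError(f"gene {gene_id}: unknown chromosome {chrom}")
        if start >= chrom_lengths[chrom]:
            raise ValueError(
                f"gene {gene_id}: start {start} beyond {chrom} length {chrom_lengths[chrom]}"
            )
        per_chrom[chrom].append((gene_id, start))
    density: dict[str, list[int]] = {}
    densest: dict[str, int] = {}
    terminal = 0
    for chrom, length in chrom_lengths.items():
        n_bins = max(1, -(-length // bin_bp))
        counts = [0] * n_bins
        for _, start in per_chrom[chrom]:
            counts[start // bin_bp] += 1
        density[chrom] = counts
        densest[chrom] = max(range(n_bins), key=lambda i: counts[i])
        if terminal_window_bp is not None:
            window = terminal_window_bp
            if window > length // 2:
                logger.info(
                    "terminal window %d truncated to %d on %s", window, length // 2, chrom
                )
                window = length // 2
            for _, start in per_chrom[chrom]:
                if start < window or start >= length - window:
                    terminal += 1
    return ChromosomeMap(
        bin_bp=bin_bp,
        per_chromosome=per_chrom,
        density=density,
        densest_bin=densest,
        terminal_count=terminal,
    )


# ---------------------------------------------------------------------------
# anchors and collinear blocks

@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    similarity: float


def find_anchor_pairs(
    proteins: Mapping[str, str],
    min_identity: float = 0.5,
    prescreen: bool = True,
) -> list[AnchorPair]:
    """All unordered protein pairs with global-alignment identity >= min_identity.

    A shared-6-mer prescreen skips the exact alignment for pairs that
    cannot plausibly reach ~50% identity; set ``prescreen=False`` to
    force the full quadratic alignment sweep.
    """
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("need at least two proteins")
    pairs = []
    for a, b in itertools.combinations(ids, 2):
        sa, sb = proteins[a], proteins[b]
        if not sa or not sb:
            continue
        if prescreen and kmer_share(sa, sb) < 0.05:
            continue
        ident = global_identity(sa, sb)
        if ident >= min_identity:
            pairs.append(AnchorPair(a, b, ident))
    return pairs


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[AnchorPair]
    orientation: int  # +1 same direction, -1 reversed

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def pair_set(self) -> set[frozenset]:
        return {frozenset((a.gene_a, a.gene_b)) for a in self.anchors}


def detect_collinear_blocks(
    anchors: Sequence[AnchorPair],
    gene_order_index: Mapping[str, tuple[str, int]],
    min_anchors: int = 5,
    max_rank_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks by rank-space dynamic programming.

    ``gene_order_index`` maps gene id -> (chromosome, rank), rank being
    the gene's position index along its chromosome.  For every
    chromosome pair the longest chain with strictly monotone ranks on
    both sides (each orientation tried separately) and consecutive rank
    gaps <= ``max_rank_gap`` is reported, repeatedly, until no chain of
    length >= ``min_anchors`` remains.  Output is deterministic and
    independent of anchor input order.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for anc in anchors:
        if anc.gene_a not in gene_order_index or anc.gene_b not in gene_order_index:
            continue
        ca, ra = gene_order_index[anc.gene_a]
        cb, rb = gene_order_index[anc.gene_b]
        if (ca, ra) > (cb, rb):
            ca, ra, cb, rb = cb, rb, ca, ra
            anc = AnchorPair(anc.gene_b, anc.gene_a, anc.similarity)
        by_pair.setdefault((ca, cb), []).append((ra, rb, anc))

    blocks: list[CollinearBlock] = []
    for (ca, cb), items in sorted(by_pair.items()):
        remaining = sorted(items, key=lambda t: (t[0], t[1]))
        while True:
            best_chain: list[int] | None = None
            best_orient = 0
            for orient in (+1, -1):
                chain = _longest_chain(remaining, orient, max_rank_gap)
                if best_chain is None or len(chain) > len(best_chain):
                    best_chain, best_orient = chain, orient
            if best_chain is None or len(best_chain) < min_anchors:
                break
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    anchors=[remaining[i][2] for i in best_chain],
                    orientation=best_orient,
                )
            )
            used = set(best_chain)
            remaining = [t for i, t in enumerate(remaining) if i not in used]
    return blocks


def _longest_chain(
    items: Sequence[tuple[int, int, AnchorPair]], orient: int, max_rank_gap: int
) -> list[int]:
    """Longest strictly-monotone chain (indices into items) via O(n^2) DP."""
    n = len(items)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for j in range(n):
        ra_j, rb_j, _ = items[j]
        for i in range(j):
            ra_i, rb_i, _ = items[i]
            if ra_i >= ra_j or 0 < ra_j - ra_i > max_rank_gap:
                continue
            if orient == +1:
                ok = rb_i < rb_j and rb_j - rb_i <= max_rank_gap
            else:
                ok = rb_i > rb_j and rb_i - rb_j <= max_rank_gap
            if ok and best_len[i] + 1 > best_len[j]:
                best_len[j] = best_len[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best_len[j], -j))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


# ---------------------------------------------------------------------------
# duplication classification

@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    dup_class: str  # tandem | segmental | dispersed
    ka: float | None = None
    ks: float | None = None

    @property
    def ratio(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks


def classify_duplications(
    family_pairs: Sequence[AnchorPair],
    blocks: Sequence[CollinearBlock],
    gene_positions: Mapping[str, tuple[str, int, int]],
    gene_order_index: Mapping[str, tuple[str, int]],
    tandem_max_intervening: int = 5,
    tandem_max_bp: int = 100_000,
) -> list[DuplicationPair]:
    """Partition family anchor pairs into tandem / segmental / dispersed.

    ``gene_positions`` maps gene id -> (chromosome, start, end) for all
    annotated genes; intervening-gene counts come from
    ``gene_order_index`` ranks.  Tandem takes precedence when a pair
    satisfies both tandem and segmental conditions.
    """
    in_block = set()
    for block in blocks:
        in_block |= block.pair_set()
    out = []
    for pair in family_pairs:
        ca, sa, ea = gene_positions[pair.gene_a]
        cb, sb, eb = gene_positions[pair.gene_b]
        dup_class = "dispersed"
        if ca == cb:
            ra = gene_order_index[pair.gene_a][1]
            rb = gene_order_index[pair.gene_b][1]
            intervening = abs(ra - rb) - 1
            distance = max(sa, sb) - min(ea, eb)
            if intervening <= tandem_max_intervening and distance <= tandem_max_bp:
                dup_class = "tandem"
        if dup_class != "tandem" and frozenset((pair.gene_a, pair.gene_b)) in in_block:
            dup_class = "segmental"
        out.append(DuplicationPair(pair.gene_a, pair.gene_b, dup_class))
    return out


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks

_CODON_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_AA[_stop] = "*"
_BASES = "TCAG"


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (fractions per position)."""
    aa = _CODON_AA[codon]
    if aa == "*":
        return 0.0
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Observed (syn, nonsyn) differences averaged over mutational pathways.

    Pathways passing through a stop codon at an intermediate step are
    excluded; if every pathway is blocked, all are used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            steps.append((current, nxt))
            if _CODON_AA[nxt] == "*" and nxt != codon_b:
                blocked = True
            current = nxt
        pathways.append((steps, blocked))
    usable = [p for p, blocked in pathways if not blocked]
    if not usable:
        usable = [p for p, _ in pathways]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            if _CODON_AA[before] == _CODON_AA[after]:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); undefined for p >= 3/4."""
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def compute_ka_ks(cds_a: str, cds_b: str) -> tuple[float | None, float | None, float | None]:
    """NG86 (ka, ks, ka/ks) for two aligned, equal-length coding sequences.

    Codon columns containing a gap or an in-frame stop in either
    sequence are skipped.  Returns (ka, ks, ratio); the ratio is None
    when ks is 0 or either correction is undefined (p >= 3/4).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("aligned CDS must have equal lengths")
    if len(cds_a) % 3 != 0:
        raise ValueError("aligned CDS length must be divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3].upper(), cds_b[i : i + 3].upper()
        if "-" in ca or "-" in cb:
            continue
        if _CODON_AA.get(ca, "*") == "*" or _CODON_AA.get(cb, "*") == "*":
            continue
        s_a, s_b = _syn_sites(ca), _syn_sites(cb)
        S += (s_a + s_b) / 2.0
        N += 3.0 - (s_a + s_b) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    if S == 0 and N == 0:
        raise ValueError("no comparable codons")
    # zero available sites with zero observed differences is a clean 0
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks, ka = jukes_cantor(ps), jukes_cantor(pn)
    if ks is None or ka is None:
        logger.warning("substitution proportion >= 3/4; Jukes-Cantor correction undefined")
        return ka, ks, None
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio


def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment of two coding sequences.

    Proteins are globally aligned and the alignment is back-threaded to
    nucleotides, giving a gapped codon alignment suitable for NG86.
    Terminal stop codons are removed first.
    """
    from Bio import Align

    from .genome_io import translate_cds

    def strip_stop(cds: str) -> str:
        if len(cds) % 3 == 0 and _CODON_AA.get(cds[-3:].upper()) == "*":
            return cds[:-3]
        return cds

    cds_a, cds_b = strip_stop(cds_a), strip_stop(cds_b)
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    alignment = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(alignment[0]), str(alignment[1])
    out_a, out_b = [], []
    ia = ib = 0
    for aa, bb in zip(row_a, row_b):
        if aa == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if bb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)
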