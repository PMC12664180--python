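"""Pairwise alignment helpers shared across modules.

The identity convention used throughout the package is
``matches / alignment_length`` from a global alignment with unit match
score, zero mismatch score and linear gap penalty -1 (end gaps penalized).
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = make_aligner()


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the best global alignment.

    Returns matches / alignment length; 1.0 for two identical sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    if seq_a == seq_b:
        return 1.0
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


@lru_cache(maxsize=4096)
def _kmer_set(seq: str, k: int) -> frozenset:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_share(seq_a: str, seq_b: str, k: int = 6) -> float:
    """Fraction of the smaller sequence's k-mers shared with the other.

    Cheap prescreen: two proteins above ~50% global identity share many
    exact 6-mers, while unrelated random sequences share essentially none.
    """
    ka, kb = _kmer_set(seq_a, k), _kmer_set(seq_b, k)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))
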