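"""WRKY family membership: domain detection, redundancy collapse, naming.

A WRKY transcription factor is recognized by its ~60-aa DNA-binding
domain: the heptapeptide anchor (canonically ``WRKYGQK``) followed by a
zinc finger of either the C2H2 type (C-x(4,5)-C-x(22,23)-H-x-H) or the
C2HC type (C-x(7)-C-x(23)-H-x-C).  Candidates lacking an intact zinc
finger downstream of the heptapeptide are rejected as incomplete.

Redundant records (splice isoforms / near-identical paralogs) are
collapsed when their domain substrings are identical AND full-length
global-alignment identity exceeds 0.95; the longest protein survives.
Survivors are named ``<prefix>1..N`` by chromosomal order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._align import global_identity
from .genome_io import GeneModel

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

HEPTAPEPTIDE = "WRKYGQK"
#: tolerated single-position deviations from the canonical heptapeptide,
#: always flagged in the hit record, never silently accepted as canonical
VARIANT_PATTERN = re.compile(r"W[RK]KYG[QKEM]K")

_C2H2 = re.compile(r"C.{4,5}C.{22,23}H.H")
_C2HC = re.compile(r"C.{7}C.{23}H.C")
#: zinc finger must lie within this many residues of the heptapeptide start
ZF_WINDOW = 90
#: nominal domain span used when no zinc finger is found
_NOMINAL_SPAN = 60


@dataclass
class WrkyDomainHit:
    """One detected WRKY domain (0-based half-open protein coordinates)."""

    protein_id: str
    dom_start: int
    dom_end: int
    heptapeptide: str
    zinc_finger: str  # 'C2H2', 'C2HC' or 'none'


@dataclass
class FamilyCandidate:
    gene: GeneModel
    hits: list[WrkyDomainHit] = field(default_factory=list)
    status: str = "accepted"  # accepted | redundant | rejected_incomplete

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id

    @property
    def protein(self) -> str:
        return self.gene.protein_seq

    def domain_key(self) -> tuple[str, ...]:
        """The literal domain substrings, the unit of the 100%-identity rule."""
        return tuple(self.protein[h.dom_start : h.dom_end] for h in self.hits)


def _validate_protein(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise ValueError(f"invalid amino-acid character {ch!r} at position {i}")


def _classify_zinc_finger(seq: str, hept_start: int) -> tuple[str, int]:
    """Return (zinc finger type, domain end) for a heptapeptide at hept_start.

    Both zinc-finger patterns are searched downstream of the heptapeptide
    within ZF_WINDOW residues of its start; the earliest-starting match
    wins (C2H2 preferred on a tie).
    """
    lo = hept_start + len(HEPTAPEPTIDE)
    window = seq[lo : hept_start + ZF_WINDOW]
    best: tuple[int, int, str] | None = None
    for zf_type, pattern in (("C2H2", _C2H2), ("C2HC", _C2HC)):
        m = pattern.search(window)
        if m is not None:
            cand = (m.start(), lo + m.end(), zf_type)
            if best is None or cand[0] < best[0]:
                best = cand
    if best is None:
        return "none", min(len(seq), hept_start + _NOMINAL_SPAN)
    return best[2], best[1]


def detect_wrky_domains(
    protein_seq: str,
    allow_variants: bool = False,
    protein_id: str = "",
) -> list[WrkyDomainHit]:
    """Detect WRKY domains in one protein.

    One hit is produced per heptapeptide occurrence (strict ``WRKYGQK``,
    or single-position variants when ``allow_variants``); each hit is
    extended downstream and classified by zinc-finger pattern.
    """
    if not protein_seq:
        return []
    _validate_protein(protein_seq)
    if len(protein_seq) < len(HEPTAPEPTIDE):
        return []
    starts: list[int] = []
    if allow_variants:
        pos = 0
        while True:
            m = VARIANT_PATTERN.search(protein_seq, pos)
            if m is None:
                break
            starts.append(m.start())
            pos = m.start() + 1
    else:
        pos = protein_seq.find(HEPTAPEPTIDE)
        while pos != -1:
            starts.append(pos)
            pos = protein_seq.find(HEPTAPEPTIDE, pos + 1)
    hits = []
    for s in starts:
        hept = protein_seq[s : s + len(HEPTAPEPTIDE)]
        if hept != HEPTAPEPTIDE:
            logger.warning(
                "%s: variant heptapeptide %s at %d (flagged, not canonical)",
                protein_id or "<protein>", hept, s,
            )
        zf, end = _classify_zinc_finger(protein_seq, s)
        hits.append(
            WrkyDomainHit(
                protein_id=protein_id,
                dom_start=s,
                dom_end=end,
                heptapeptide=hept,
                zinc_finger=zf,
            )
        )
    return hits


def build_candidates(
    genes: Iterable[GeneModel], allow_variants: bool = False
) -> list[FamilyCandidate]:
    """Run domain detection over gene models; keep those with an intact domain."""
    out = []
    for gene in genes:
        if not gene.protein_seq:
            continue
        hits = detect_wrky_domains(
            gene.protein_seq, allow_variants=allow_variants, protein_id=gene.gene_id
        )
        if not hits:
            continue
        status = (
            "accepted" if any(h.zinc_finger != "none" for h in hits) else "rejected_incomplete"
        )
        out.append(FamilyCandidate(gene=gene, hits=hits, status=status))
    return out


def collapse_redundancy(
    candidates: Sequence[FamilyCandidate],
    identity_min: float = 0.95,
) -> list[FamilyCandidate]:
    """Collapse isoform/paralog redundancy; returns all candidates with status set.

    A pair qualifies as redundant when the literal domain substrings are
    identical and full-length global identity exceeds ``identity_min``.
    Redundancy groups are single-linkage closures over qualifying pairs;
    the longest protein survives (ties broken by lexicographic gene id).
    """
    cands = list(candidates)
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # domain substrings must match exactly, so group by domain key first
    by_domain: dict[tuple[str, ...], list[int]] = {}
    for i, c in enumerate(cands):
        by_domain.setdefault(c.domain_key(), []).append(i)
    for indices in by_domain.values():
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                i, j = indices[a], indices[b]
                if global_identity(cands[i].protein, cands[j].protein) > identity_min:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    for members in groups.values():
        survivor = min(members, key=lambda i: (-len(cands[i].protein), cands[i].gene_id))
        for i in members:
            if i == survivor:
                cands[i].status = "accepted"
            else:
                cands[i].status = "redundant"
                logger.info(
                    "%s collapsed into %s", cands[i].gene_id, cands[survivor].gene_id
                )
    return cands


_NATURAL = re.compile(r"(\d+)")


def _natural_key(text: str) -> tuple:
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NATURAL.split(text))


def assign_names(
    survivors: Sequence[FamilyCandidate], prefix: str = "WRKY"
) -> dict[str, str]:
    """Name survivors prefix+1..N by (natural chromosome order, start).

    Two survivors at an identical (chromosome, start) are tie-broken by
    lexicographic gene id, with a log record.
    """
    ordered = sorted(
        survivors,
        key=lambda c: (_natural_key(c.gene.chromosome), c.gene.start, c.gene_id),
    )
    seen: dict[tuple[str, int], str] = {}
    names: dict[str, str] = {}
    for idx, cand in enumerate(ordered, start=1):
        loc = (cand.gene.chromosome, cand.gene.start)
        if loc in seen:
            logger.warning(
                "identical locus %s for %s and %s; tie broken by gene id",
                loc, seen[loc], cand.gene_id,
            )
        seen[loc] = cand.gene_id
        names[cand.gene_id] = f"{prefix}{idx}"
    return names


def scan_family(
    genes: Iterable[GeneModel],
    prefix: str = "WRKY",
    allow_variants: bool = False,
) -> tuple[list[FamilyCandidate], dict[str, str]]:
    """Detection -> redundancy collapse -> naming, end to end."""
    candidates = build_candidates(genes, allow_variants=allow_variants)
    accepted = [c for c in candidates if c.status == "accepted"]
    collapse_redundancy(accepted)
    survivors = [c for c in accepted if c.status == "accepted"]
    names = assign_names(survivors, prefix=prefix)
    return candidates, names
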