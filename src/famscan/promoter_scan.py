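"""Promoter extraction and cis-acting element counting.

Promoters are the 2000 bp immediately upstream of the annotated gene
start (strand-aware, clipped at chromosome boundaries).  Elements are
counted by IUPAC consensus matching against a curated, user-overridable
catalog; every overlapping occurrence on either strand is counted.  The
default catalog covers the elements conventionally reported for
stress-responsive promoters (TATA-box, CAAT-box, G-Box, Box 4, LTR,
ARE, MBS, MRE, ABRE, CGTCA/TGACG, GARE, W-box); it uses published
consensus strings, not any web service's internal matrices, so counts
are reproducible but not bit-compatible with such services.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .genome_io import GeneModel, revcomp

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def iupac_to_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC consensus into a lookahead regex (overlaps counted).

    N positions never match the ambiguous base N in the subject; the
    subject alphabet is ACGTN and N in the promoter matches nothing.
    """
    try:
        body = "".join(IUPAC[ch] for ch in pattern.upper())
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in pattern {pattern!r}") from exc
    return re.compile(f"(?={body})")


@dataclass
class CisElement:
    name: str
    patterns: list[str]
    category: str


class CisElementCatalog:
    """Named IUPAC consensus patterns with functional categories."""

    def __init__(self, elements: Iterable[CisElement]):
        self.elements = list(elements)
        if not self.elements:
            raise ValueError("catalog must not be empty")
        self._compiled = {
            el.name: [iupac_to_regex(p) for p in el.patterns] for el in self.elements
        }

    def names(self) -> list[str]:
        return [el.name for el in self.elements]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CisElementCatalog":
        elements = []
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if header[:3] != ["element", "patterns", "category"]:
                raise ValueError("catalog TSV must have columns element/patterns/category")
            for line in handle:
                if not line.strip():
                    continue
                name, patterns, category = line.rstrip("\n").split("\t")[:3]
                elements.append(
                    CisElement(name=name, patterns=patterns.split(","), category=category)
                )
        return cls(elements)

    @classmethod
    def default(cls) -> "CisElementCatalog":
        with resources.as_file(
            resources.files("famscan.data").joinpath("cis_elements.tsv")
        ) as path:
            return cls.from_tsv(path)


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    upstream_bp: int = 2000,
) -> dict[str, str]:
    """Strand-aware upstream promoter sequences, clipped at chromosome ends.

    For a + strand gene the promoter is the ``upstream_bp`` bases ending
    at the base before the gene start; for a - strand gene it is the
    reverse complement of the region starting just after the gene end.
    """
    out: dict[str, str] = {}
    for gene in genes:
        chrom = genome.get(gene.chromosome)
        if chrom is None:
            raise ValueError(f"gene {gene.gene_id}: chromosome {gene.chromosome} not in genome")
        if gene.strand == "+":
            lo = max(0, gene.start - upstream_bp)
            seq = chrom[lo : gene.start]
            if len(seq) < upstream_bp:
                logger.warning(
                    "%s: promoter clipped to %d bp at chromosome start", gene.gene_id, len(seq)
                )
        else:
            hi = min(len(chrom), gene.end + upstream_bp)
            seq = revcomp(chrom[gene.end : hi])
            if len(seq) < upstream_bp:
                logger.warning(
                    "%s: promoter clipped to %d bp at chromosome end", gene.gene_id, len(seq)
                )
        out[gene.gene_id] = seq
    return out


def scan_cis_elements(
    promoter: str,
    catalog: CisElementCatalog | None = None,
    both_strands: bool = True,
) -> dict[str, int]:
    """Count occurrences of every catalog element in one promoter.

    The count is the number of match positions on the forward strand
    plus, when ``both_strands``, positions on the reverse strand
    (overlaps all counted; N never matches).  Reverse-complementing the
    promoter leaves both-strand counts unchanged.
    """
    if catalog is None:
        catalog = CisElementCatalog.default()
    promoter = promoter.upper()
    if not set(promoter) <= set("ACGTN"):
        raise ValueError("promoter must be over the ACGTN alphabet")
    rc = revcomp(promoter) if both_strands else ""
    counts: dict[str, int] = {}
    for el in catalog.elements:
        n = 0
        for regex in catalog._compiled[el.name]:
            n += len(regex.findall(promoter))
            if both_strands:
                n += len(regex.findall(rc))
        counts[el.name] = n
    return counts


def scan_promoter_set(
    promoters: Mapping[str, str],
    catalog: CisElementCatalog | None = None,
    both_strands: bool = True,
) -> dict[str, dict[str, int]]:
    """gene -> element -> count, zeros included for every catalog element."""
    if catalog is None:
        catalog = CisElementCatalog.default()
    return {
        gene: scan_cis_elements(seq, catalog=catalog, both_strands=both_strands)
        for gene, seq in promoters.items()
    }
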