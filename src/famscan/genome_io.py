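"""Reading genome FASTA + GFF3 annotation into gene models.

GFF3 coordinates are 1-based inclusive per the standard; everything
internal to the package is 0-based half-open, converted here at the
boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A located gene: one transcript's coordinates, CDS and protein."""

    gene_id: str
    chromosome: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an id -> sequence dict."""
    with _open_maybe_gzip(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def load_gene_models(
    gff_path: str | Path,
    proteins: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Parse a GFF3 file into one GeneModel per mRNA (transcript).

    Transcripts inherit their parent gene's locus coordinates; the
    protein sequence is looked up in ``proteins`` by transcript id and
    falls back to the gene id.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]
        for mrna in mrnas:
            cds = sorted(
                ((c.start - 1, c.end) for c in db.children(mrna, featuretype="CDS")),
                key=lambda seg: seg[0],
            )
            tid = mrna.id
            prot = ""
            if proteins is not None:
                prot = proteins.get(tid, proteins.get(gene.id, ""))
            models.append(
                GeneModel(
                    gene_id=tid,
                    chromosome=gene.seqid,
                    start=gene.start - 1,
                    end=gene.end,
                    strand=gene.strand,
                    cds_segments=cds,
                    protein_seq=prot,
                )
            )
    return models


def extract_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Splice the CDS out of the genome, reverse-complemented on '-'."""
    chrom = genome[gene.chromosome]
    parts = [chrom[s:e] for s, e in gene.cds_segments]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = revcomp(seq)
    return seq


def translate_cds(cds: str) -> str:
    """Translate a CDS, dropping a terminal stop codon if present."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot
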