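"""Synthetic genomes, expression, metabolome and Ct tables with known truth.

The generator emulates the study design every stage of the pipeline is
aimed at: a small plant genome with a planted WRKY family (group-typed
domain architectures, isoform redundancy sets, a tandem pair and a
segmental collinear block of duplicate anchors), promoters carrying
exact cis-element copies in a match-free background, a 3-group x
3-replicate FPKM matrix (CK / Cold12h / Cold24h) with planted
fold-changes and a latent-factor co-expression module, a metabolite
table coupled to that factor, and a qPCR Ct table derived by inverting
2^-ddCt from the planted fold-changes.

Everything is driven by one master seed and recorded in a
``TruthManifest`` sufficient to recompute every expected recovery
result without touching generator internals.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .family_scan import HEPTAPEPTIDE, VARIANT_PATTERN, detect_wrky_domains
from .genome_context import _CODON_AA, compute_ka_ks
from .genome_io import revcomp, write_fasta
from .promoter_scan import CisElementCatalog

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: spacer alphabet excludes C, H and W so planted zinc fingers and
#: heptapeptides stay the earliest (and only) pattern matches
SPACER_AA = "ADEFGIKLMNPQRSTVY"

_AA_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_AA.items():
    if aa != "*":
        _AA_CODONS.setdefault(aa, []).append(codon)
for _v in _AA_CODONS.values():
    _v.sort()


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic data generator.

    Defaults mirror the emulated design: 8 chromosomes, 60 planted
    family genes (3 of them with two redundant isoforms each), 200
    decoy genes, one tandem pair 8 kb apart, one 8-anchor segmental
    block, duplicate divergence at omega = 0.2 to Ks 0.3, 2000-bp
    promoters, CK/Cold12h/Cold24h x 3 replicates, 8-fold planted
    expression effects at 10% replicate cv, a 12-member co-expression
    module targeting pairwise r ~ 0.95, and a 47/15/11
    lipid/sugar/flavonoid metabolome with 9 flavonoids coupled to the
    module factor at target |r| ~ 0.9.
    """

    n_chromosomes: int = 8
    # scattered (non-tandem, non-block) family genes per chromosome
    family_per_chromosome: tuple = (14, 8, 8, 6, 6, 5, 2, 7)
    decoys_per_chromosome: tuple = (30, 25, 25, 22, 22, 20, 14, 30)
    n_redundant_triplets: int = 3
    tandem_gap_bp: int = 8000
    block_anchors: int = 8
    tandem_chromosome: int = 2  # 0-based index: Chr3
    block_chromosomes: tuple = (1, 4)  # Chr2 x Chr5
    group_counts: Mapping[str, int] = field(
        default_factory=lambda: {"I": 16, "II": 12, "III": 10, "IV": 10, "V": 4, "VI": 8}
    )
    omega: float = 0.2
    target_ks: float = 0.3
    promoter_len: int = 2000
    max_planted_per_element: int = 4
    groups: tuple = ("CK", "Cold12h", "Cold24h")
    n_replicates: int = 3
    n_expressed_family: int = 40
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    replicate_cv: float = 0.10
    deg_fold: float = 8.0
    n_module_tfs: int = 10
    n_decoy_tfs: int = 80
    deg_base_log2_mean: float = 5.0
    deg_base_log2_sd: float = 1.0
    module_target_r: float = 0.95
    factor_tau: float = 0.15
    metabolite_classes: Mapping[str, int] = field(
        default_factory=lambda: {"lipid": 47, "sugar": 15, "flavonoid": 11}
    )
    n_coupled_flavonoids: int = 9
    coupling_target_r: float = 0.97
    ct_sd: float = 0.2
    ct_ref: float = 20.0
    ct_dct_control: float = 5.0

    @property
    def n_family_genes(self) -> int:
        return sum(self.family_per_chromosome) + 2 + 2  # + tandem pair + block pair

    @property
    def n_decoy_genes(self) -> int:
        return sum(self.decoys_per_chromosome) + 2 * (self.block_anchors - 1)

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.n_replicates)]

    def sample_groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_counts"] = dict(self.group_counts)
        d["metabolite_classes"] = dict(self.metabolite_classes)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        for key in ("family_per_chromosome", "decoys_per_chromosome", "groups",
                    "block_chromosomes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# manifest

@dataclass
class TruthManifest:
    """Complete record of planted entities; drives every recovery test."""

    seed: int
    config: dict
    chrom_lengths: dict
    genes: list  # dicts: id, kind, chrom, start, end, strand, group, domains, ...
    redundancy_sets: list
    duplicate_pairs: list  # dicts: a, b, dup_class, omega, target_ks, family
    block_anchor_pairs: list
    expected_names: dict  # gene id -> family name in chromosomal order
    promoter_counts: dict  # gene -> element -> expected both-strand count
    expression: dict
    metabolome: dict
    qpcr: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))

    def family_gene_ids(self) -> list[str]:
        return [g["id"] for g in self.genes if g["kind"] == "family" and not g.get("isoform_of")]


@dataclass
class SyntheticBundle:
    genome: dict  # chrom -> sequence
    gff_text: str
    proteins: dict  # record id -> protein (family + isoforms + decoys)
    cds: dict  # gene id -> CDS (with stop codon)
    promoters: dict  # gene id -> planted promoter string
    manifest: TruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff": outdir / "annotation.gff3",
            "proteins": outdir / "proteins.faa",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(sorted(self.genome.items()), paths["genome"])
        paths["gff"].write_text(self.gff_text)
        write_fasta(sorted(self.proteins.items()), paths["proteins"])
        self.manifest.to_json(paths["manifest"])
        return paths


# ---------------------------------------------------------------------------
# sequence helpers

def _rand_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _rand_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein screened free of canonical and variant heptapeptides."""
    while True:
        seq = "M" + _rand_seq(rng, AA20, length - 1)
        if HEPTAPEPTIDE not in seq and VARIANT_PATTERN.search(seq) is None:
            return seq


def _make_domain(rng: np.random.Generator, zf_type: str) -> str:
    """One WRKY domain string: heptapeptide + spacer + zinc finger."""
    spacer = _rand_seq(rng, SPACER_AA, 8)
    if zf_type == "C2H2":
        zf = ("C" + _rand_seq(rng, SPACER_AA, 4) + "C" + _rand_seq(rng, SPACER_AA, 22)
              + "H" + _rand_seq(rng, SPACER_AA, 1) + "H")
    elif zf_type == "C2HC":
        zf = ("C" + _rand_seq(rng, SPACER_AA, 7) + "C" + _rand_seq(rng, SPACER_AA, 23)
              + "H" + _rand_seq(rng, SPACER_AA, 1) + "C")
    else:
        raise ValueError(zf_type)
    return HEPTAPEPTIDE + spacer + zf


def _mutate_domain(rng: np.random.Generator, domain: str, n_sub: int) -> str:
    """Substitute spacer positions only, keeping anchor and zinc finger."""
    chars = list(domain)
    free = [i for i, ch in enumerate(chars) if i >= len(HEPTAPEPTIDE) and ch not in "CH"]
    for i in rng.choice(free, size=min(n_sub, len(free)), replace=False):
        chars[i] = rng.choice(list(SPACER_AA.replace(chars[i], "")))
    return "".join(chars)


GROUP_ARCH = {
    "I": ("C2H2", 2), "II": ("C2H2", 1), "III": ("C2HC", 1),
    "IV": ("C2H2", 1), "V": ("C2H2", 1), "VI": ("C2H2", 1),
}


def _family_protein(
    rng: np.random.Generator, group: str, group_domain: str
) -> tuple[str, list[tuple[int, str]]]:
    """Assemble a family protein; returns (sequence, [(domain offset, zf type)])."""
    zf_type, n_domains = GROUP_ARCH[group]
    for _ in range(60):
        parts = ["M" + _rand_seq(rng, AA20, int(rng.integers(30, 90)))]
        offsets = []
        for k in range(n_domains):
            dom = _mutate_domain(rng, group_domain, int(rng.integers(2, 6)))
            offsets.append((sum(len(p) for p in parts), zf_type))
            parts.append(dom)
            if k < n_domains - 1:
                parts.append(_rand_seq(rng, AA20, int(rng.integers(40, 80))))
        parts.append(_rand_seq(rng, AA20, int(rng.integers(25, 70))))
        seq = "".join(parts)
        hits = detect_wrky_domains(seq)
        if (
            len(hits) == n_domains
            and all(h.dom_start == off for h, (off, _) in zip(hits, offsets))
            and all(h.zinc_finger == zf_type for h in hits)
        ):
            return seq, offsets
    raise RuntimeError("failed to assemble a clean family protein")


def back_translate(rng: np.random.Generator, protein: str, stop: str = "TAA") -> str:
    codons = [rng.choice(_AA_CODONS[aa]) for aa in protein]
    return "".join(codons) + stop


def evolve_duplicate(
    rng: np.random.Generator,
    cds: str,
    omega: float,
    target_ks: float,
    masked_codons: set[int] | None = None,
    max_steps: int = 200_000,
) -> str:
    """Diverge a CDS copy by single-nucleotide proposals until Ks >= target.

    Nonsynonymous proposals are accepted with probability ``omega``;
    proposals creating stops or touching masked codons are rejected.
    Divergence is measured by the NG86 Ks against the original.
    """
    masked = masked_codons or set()
    seq = list(cds[:-3])  # keep the stop codon fixed
    original = cds
    n_codons = len(seq) // 3
    accepted = 0
    for _ in range(max_steps):
        codon_idx = int(rng.integers(0, n_codons))
        if codon_idx in masked:
            continue
        pos = 3 * codon_idx + int(rng.integers(0, 3))
        old = seq[pos]
        new = rng.choice([b for b in "ACGT" if b != old])
        codon_before = "".join(seq[3 * codon_idx : 3 * codon_idx + 3])
        seq[pos] = new
        codon_after = "".join(seq[3 * codon_idx : 3 * codon_idx + 3])
        if _CODON_AA[codon_after] == "*":
            seq[pos] = old
            continue
        if _CODON_AA[codon_after] != _CODON_AA[codon_before] and rng.random() >= omega:
            seq[pos] = old
            continue
        accepted += 1
        if accepted % 10 == 0:
            _, ks, _ = compute_ka_ks(original[:-3], "".join(seq))
            if ks is not None and ks >= target_ks:
                break
    return "".join(seq) + cds[-3:]


# ---------------------------------------------------------------------------
# promoter construction

def _background(rng: np.random.Generator, length: int) -> str:
    # C/T-only background: every catalog pattern contains A or G on each
    # strand, so no element can arise from background alone
    return _rand_seq(rng, "CT", length)


def _count_overlapping(pattern: str, text: str) -> int:
    return len(re.findall(f"(?={pattern})", text))


def _scan_counts(text: str, catalog: CisElementCatalog) -> dict[str, int]:
    """Both-strand overlapping pattern counts by direct string matching."""
    rc = revcomp(text)
    counts = {}
    for el in catalog.elements:
        counts[el.name] = sum(
            _count_overlapping(pat, text) + _count_overlapping(pat, rc)
            for pat in el.patterns
        )
    return counts


def _expected_counts(instances: list[str], catalog: CisElementCatalog) -> dict[str, int]:
    counts = {el.name: 0 for el in catalog.elements}
    for inst in instances:
        for name, n in _scan_counts(inst, catalog).items():
            counts[name] += n
    return counts


def build_promoter(
    rng: np.random.Generator,
    planted: Mapping[str, int],
    catalog: CisElementCatalog,
    length: int = 2000,
    max_tries: int = 10,
) -> tuple[str, dict[str, int]]:
    """Assemble a promoter with exactly the planted element copies.

    Elements (first catalog pattern of each; the default catalog is
    IUPAC-unambiguous) are placed in shuffled order separated by >= 4 bp
    of C/T background.  Background alone can never form a catalog match
    (every pattern needs an A or G on each strand), and gaps >= 4 bp are
    too wide for any pattern to bridge two elements, so the only risk is
    a junction match involving one element plus adjacent background;
    each junction is screened locally and resampled on violation.
    Expected counts are derived constructively from the planted strings
    (cross-pattern and palindromic both-strand matches included) and the
    final promoter is verified against them with the scanner.
    """
    from .promoter_scan import scan_cis_elements

    by_name = {el.name: el for el in catalog.elements}
    instances = []
    for name, n in planted.items():
        if name not in by_name:
            raise ValueError(f"unknown element {name}")
        instances.extend([by_name[name].patterns[0]] * n)
    total_elem = sum(len(s) for s in instances)
    n_gaps = len(instances) + 1
    if total_elem + 4 * n_gaps > length:
        raise ValueError("planted elements exceed the promoter length budget")
    expected = _expected_counts(instances, catalog)
    window = 10  # longest pattern is 7; 10 covers any junction match

    for _ in range(max_tries):
        order = list(rng.permutation(len(instances)))
        slack = length - total_elem - 4 * n_gaps
        cuts = (
            np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
            if n_gaps > 1
            else np.array([], dtype=int)
        )
        gap_lens = 4 + np.diff(np.concatenate(([0], cuts, [slack])))
        ok = True
        cur = _background(rng, int(gap_lens[0]))
        for k, idx in enumerate(order):
            inst = instances[idx]
            inst_counts = _scan_counts(inst, catalog)
            placed = False
            for _attempt in range(60):
                tail = cur[-window:]
                merged = _scan_counts(tail + inst, catalog)
                base = _scan_counts(tail, catalog)
                if all(
                    merged[n] == base[n] + inst_counts[n] for n in merged
                ):
                    placed = True
                    break
                cur = cur[: -min(3, len(cur))] + _background(rng, min(3, len(cur)))
            if not placed:
                ok = False
                break
            cur += inst
            gap_ok = False
            for _attempt in range(60):
                gap = _background(rng, int(gap_lens[k + 1]))
                tail = cur[-window:]
                if _scan_counts(tail + gap, catalog) == _scan_counts(tail, catalog):
                    gap_ok = True
                    break
            if not gap_ok:
                ok = False
                break
            cur += gap
        if not ok or len(cur) != length:
            continue
        if scan_cis_elements(cur, catalog=catalog) == expected:
            return cur, expected
    raise RuntimeError("could not assemble a match-exact promoter")


# ---------------------------------------------------------------------------
# genome + annotation

def generate_genome_annotation(config: SimConfig, seed: int) -> SyntheticBundle:
    """Generate genome FASTA, GFF3, protein FASTA and the truth manifest."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    catalog = CisElementCatalog.default()
    chroms = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]

    # group templates and scattered family genes
    group_domains = {g: _make_domain(rng, GROUP_ARCH[g][0]) for g in config.group_counts}
    group_pool = [g for g, n in config.group_counts.items() for _ in range(n)]
    if len(group_pool) != config.n_family_genes:
        raise ValueError("group counts must sum to the family size")
    rng.shuffle(group_pool)

    fam_ids = [f"FAM{i + 1:03d}" for i in range(config.n_family_genes)]
    n_scattered = sum(config.family_per_chromosome)
    scattered_fam = fam_ids[:n_scattered]
    tandem_fam = fam_ids[n_scattered : n_scattered + 2]
    block_fam = fam_ids[n_scattered + 2 :]

    proteins: dict[str, str] = {}
    domains_by_gene: dict[str, list[tuple[int, str]]] = {}
    groups_by_gene: dict[str, str] = {}
    for gid, grp in zip(fam_ids, group_pool):
        groups_by_gene[gid] = grp
    # tandem/block partners must share a group (they are duplicates)
    groups_by_gene[tandem_fam[1]] = groups_by_gene[tandem_fam[0]]
    groups_by_gene[block_fam[1]] = groups_by_gene[block_fam[0]]

    for gid in scattered_fam + [tandem_fam[0], block_fam[0]]:
        grp = groups_by_gene[gid]
        seq, offsets = _family_protein(rng, grp, group_domains[grp])
        proteins[gid] = seq
        domains_by_gene[gid] = offsets

    cds: dict[str, str] = {gid: back_translate(rng, proteins[gid]) for gid in proteins}

    # duplicate partners: evolve the CDS with domain codons masked
    duplicate_pairs = []
    for src, dst, dup_class in (
        (tandem_fam[0], tandem_fam[1], "tandem"),
        (block_fam[0], block_fam[1], "segmental"),
    ):
        masked = set()
        seq = proteins[src]
        for off, zf in domains_by_gene[src]:
            dom_len = 46 if zf == "C2H2" else 50
            masked |= set(range(off, off + dom_len))
        evolved = evolve_duplicate(rng, cds[src], config.omega, config.target_ks, masked)
        prot = _translate(evolved)
        assert HEPTAPEPTIDE in prot
        proteins[dst] = prot
        cds[dst] = evolved
        domains_by_gene[dst] = list(domains_by_gene[src])
        duplicate_pairs.append(
            {"a": src, "b": dst, "dup_class": dup_class, "omega": config.omega,
             "target_ks": config.target_ks, "family": True}
        )

    # decoys, including the block's decoy anchor pairs
    n_block_decoy_pairs = config.block_anchors - 1
    dec_ids = [f"DEC{i + 1:03d}" for i in range(config.n_decoy_genes)]
    n_scattered_dec = sum(config.decoys_per_chromosome)
    scattered_dec = dec_ids[:n_scattered_dec]
    block_dec_a = dec_ids[n_scattered_dec : n_scattered_dec + n_block_decoy_pairs]
    block_dec_b = dec_ids[n_scattered_dec + n_block_decoy_pairs :]
    for gid in scattered_dec + block_dec_a:
        proteins[gid] = _rand_protein(rng, int(rng.integers(150, 400)))
        cds[gid] = back_translate(rng, proteins[gid])
    block_anchor_pairs = []
    for src, dst in zip(block_dec_a, block_dec_b):
        evolved = evolve_duplicate(rng, cds[src], config.omega, config.target_ks)
        prot = _translate(evolved)
        assert HEPTAPEPTIDE not in prot and VARIANT_PATTERN.search(prot) is None
        proteins[dst] = prot
        cds[dst] = evolved
        block_anchor_pairs.append([src, dst])
    block_anchor_pairs.insert(config.block_anchors // 2, [block_fam[0], block_fam[1]])

    # redundant isoform sets: truncate the C-terminal tail only
    redundancy_sets = []
    iso_candidates = [
        g for g in scattered_fam
        if len(proteins[g]) - (domains_by_gene[g][-1][0] + 50) > 20
    ]
    triplet_parents = [iso_candidates[i] for i in
                       np.linspace(0, len(iso_candidates) - 1, config.n_redundant_triplets).astype(int)]
    isoforms: dict[str, str] = {}
    for parent in triplet_parents:
        L = len(proteins[parent])
        cut1, cut2 = max(3, int(0.02 * L)), max(6, int(0.035 * L))
        isoforms[f"{parent}.2"] = proteins[parent][: L - cut1]
        isoforms[f"{parent}.3"] = proteins[parent][: L - cut2]
        redundancy_sets.append([parent, f"{parent}.2", f"{parent}.3"])

    # promoters for family loci
    promoter_counts: dict[str, dict[str, int]] = {}
    promoters: dict[str, str] = {}
    element_names = catalog.names()
    family_loci = scattered_fam + tandem_fam + block_fam
    for gid in family_loci:
        planted = {
            name: int(rng.integers(0, config.max_planted_per_element + 1))
            for name in element_names
        }
        promoter, expected = build_promoter(rng, planted, catalog, config.promoter_len)
        promoters[gid] = promoter
        promoter_counts[gid] = expected

    # chromosome layout
    layout: dict[str, list[str]] = {c: [] for c in chroms}
    fam_iter = iter(scattered_fam)
    dec_iter = iter(scattered_dec)
    for ci, chrom in enumerate(chroms):
        mixed = [next(fam_iter) for _ in range(config.family_per_chromosome[ci])]
        mixed += [next(dec_iter) for _ in range(config.decoys_per_chromosome[ci])]
        rng.shuffle(mixed)
        layout[chrom] = mixed
    # tandem run and block runs inserted as consecutive slices
    t_chrom = chroms[config.tandem_chromosome]
    t_pos = int(rng.integers(0, len(layout[t_chrom]) + 1))
    layout[t_chrom][t_pos:t_pos] = list(tandem_fam)
    ba_chrom, bb_chrom = (chroms[i] for i in config.block_chromosomes)
    run_a = [p[0] for p in block_anchor_pairs]
    run_b = [p[1] for p in block_anchor_pairs]
    pos_a = int(rng.integers(0, len(layout[ba_chrom]) + 1))
    layout[ba_chrom][pos_a:pos_a] = run_a
    pos_b = int(rng.integers(0, len(layout[bb_chrom]) + 1))
    layout[bb_chrom][pos_b:pos_b] = run_b

    # assemble sequences
    genome: dict[str, str] = {}
    gene_records: list[dict] = []
    gff_lines = ["##gff-version 3"]
    chrom_lengths: dict[str, int] = {}
    for chrom in chroms:
        parts: list[str] = []
        pos = 0
        prev_id = None
        for gid in layout[chrom]:
            if prev_id is not None and {prev_id, gid} == set(tandem_fam):
                gap = config.tandem_gap_bp - config.promoter_len
            else:
                gap = int(rng.integers(1500, 4000))
            strand = "+" if rng.random() < 0.5 else "-"
            if {prev_id, gid} == set(tandem_fam):
                strand = "+"  # keep the planted tandem geometry simple
            promoter = promoters.get(gid)
            if promoter is None:
                promoter = _background(rng, config.promoter_len)
            body = cds[gid]
            filler = _rand_seq(rng, "ACGT", gap)
            parts.append(filler)
            pos += gap
            if strand == "+":
                parts.append(promoter)
                pos += len(promoter)
                start = pos
                parts.append(body)
                pos += len(body)
                end = pos
            else:
                start = pos
                parts.append(revcomp(body))
                pos += len(body)
                end = pos
                parts.append(revcomp(promoter))
                pos += len(promoter)
            kind = "family" if gid in family_loci else "decoy"
            gene_records.append(
                {"id": gid, "kind": kind, "chrom": chrom, "start": start, "end": end,
                 "strand": strand, "group": groups_by_gene.get(gid),
                 "domains": [
                     {"offset": off, "zf": zf} for off, zf in domains_by_gene.get(gid, [])
                 ],
                 "protein_len": len(proteins[gid]), "isoform_of": None}
            )
            prev_id = gid
        tail = _rand_seq(rng, "ACGT", int(rng.integers(5000, 20000)))
        parts.append(tail)
        genome[chrom] = "".join(parts)
        chrom_lengths[chrom] = len(genome[chrom])

    # GFF3 (1-based inclusive), isoforms as extra mRNAs of their parent
    iso_by_parent: dict[str, list[str]] = {}
    for iso_id in isoforms:
        iso_by_parent.setdefault(iso_id.rsplit(".", 1)[0], []).append(iso_id)
    for rec in gene_records:
        gid, chrom = rec["id"], rec["chrom"]
        s1, e1 = rec["start"] + 1, rec["end"]
        strand = rec["strand"]
        gff_lines.append(
            f"{chrom}\tfamscan_sim\tgene\t{s1}\t{e1}\t.\t{strand}\t.\tID=gene-{gid}"
        )
        for tid, prot in [(gid, proteins[gid])] + [
            (i, isoforms[i]) for i in iso_by_parent.get(gid, [])
        ]:
            gff_lines.append(
                f"{chrom}\tfamscan_sim\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\t"
                f"ID={tid};Parent=gene-{gid}"
            )
            if tid == gid:
                cs, ce = s1, e1
            else:
                span = 3 * len(prot)  # truncated isoform: protein prefix, no stop
                cs, ce = (s1, s1 + span - 1) if strand == "+" else (e1 - span + 1, e1)
            gff_lines.append(
                f"{chrom}\tfamscan_sim\tCDS\t{cs}\t{ce}\t.\t{strand}\t0\t"
                f"ID=cds-{tid};Parent={tid}"
            )
    iso_records = []
    rec_by_id = {r["id"]: r for r in gene_records}
    for parent, iso_ids in iso_by_parent.items():
        for iso_id in iso_ids:
            base = rec_by_id[parent]
            iso_records.append(
                {**base, "id": iso_id, "isoform_of": parent,
                 "protein_len": len(isoforms[iso_id])}
            )
    gene_records.extend(iso_records)

    all_proteins = {**proteins, **isoforms}

    # expected family names by (natural chromosome order, start)
    def natural_key(text: str):
        return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", text))

    survivors = sorted(
        (r for r in gene_records if r["kind"] == "family" and not r["isoform_of"]),
        key=lambda r: (natural_key(r["chrom"]), r["start"], r["id"]),
    )
    expected_names = {r["id"]: f"WRKY{i + 1}" for i, r in enumerate(survivors)}

    expression_plan = _plan_expression(rng, config, [r["id"] for r in survivors])
    metabolome_plan = _plan_metabolome(rng, config)
    qpcr_plan = {
        "genes": {g: dict(effects) for g, effects in
                  expression_plan["deg_effects"].items()},
        "ct_sd": config.ct_sd,
    }

    manifest = TruthManifest(
        seed=seed,
        config=config.to_dict(),
        chrom_lengths=chrom_lengths,
        genes=gene_records,
        redundancy_sets=redundancy_sets,
        duplicate_pairs=duplicate_pairs,
        block_anchor_pairs=block_anchor_pairs,
        expected_names=expected_names,
        promoter_counts=promoter_counts,
        expression=expression_plan,
        metabolome=metabolome_plan,
        qpcr=qpcr_plan,
    )
    return SyntheticBundle(
        genome=genome,
        gff_text="\n".join(gff_lines) + "\n",
        proteins=all_proteins,
        cds=cds,
        promoters=promoters,
        manifest=manifest,
    )


def _translate(cds: str) -> str:
    prot = "".join(_CODON_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# expression / metabolome / qPCR plans and realizations

def _plan_expression(
    rng: np.random.Generator, config: SimConfig, family_ids: list[str]
) -> dict:
    delta = float(np.log2(config.deg_fold))
    expressed = sorted(
        rng.choice(family_ids, size=config.n_expressed_family, replace=False)
    )
    silent = sorted(set(family_ids) - set(expressed))
    chosen = list(rng.permutation(expressed))
    seeds = chosen[:2]  # sustained up, module seeds
    late_up = chosen[2:4]  # up at Cold24h only
    down = chosen[4:7]
    deg_effects: dict[str, dict[str, float]] = {}
    for g in seeds:
        deg_effects[g] = {"Cold12h": config.deg_fold, "Cold24h": config.deg_fold}
    for g in late_up:
        deg_effects[g] = {"Cold24h": config.deg_fold}
    for g in down:
        deg_effects[g] = {"Cold12h": 1.0 / config.deg_fold,
                          "Cold24h": 1.0 / config.deg_fold}
    tf_families = ["AP2/ERF-ERF", "MYB", "MYB-related", "NAC", "bHLH"]
    module_tfs = {
        f"TF{i + 1:03d}": tf_families[i % len(tf_families)]
        for i in range(config.n_module_tfs)
    }
    decoy_tfs = {
        f"TFD{i + 1:03d}": tf_families[int(rng.integers(0, len(tf_families)))]
        for i in range(config.n_decoy_tfs)
    }
    functional = {"FUNC_CHS": "chalcone synthase", "FUNC_FLS": "flavonol synthase"}
    sigma_member = _calibrate_pair_noise(
        config, target_r=config.module_target_r, one_sided=False
    )
    return {
        "expressed": list(map(str, expressed)),
        "silent": list(map(str, silent)),
        "deg_effects": deg_effects,
        "module": {
            "seeds": list(map(str, seeds)),
            "members": module_tfs,
            "decoys": decoy_tfs,
            "factor_log2_by_group": {"CK": 0.0, "Cold12h": delta, "Cold24h": delta},
            "tau": config.factor_tau,
            "sigma_member": sigma_member,
        },
        "functional_genes": functional,
    }


def _plan_metabolome(rng: np.random.Generator, config: SimConfig) -> dict:
    classes: dict[str, str] = {}
    for cls, n in config.metabolite_classes.items():
        for i in range(n):
            classes[f"met_{cls}_{i + 1:02d}"] = cls
    flavonoids = [m for m, c in classes.items() if c == "flavonoid"]
    coupled = flavonoids[: config.n_coupled_flavonoids]
    sigma_coupled = _calibrate_pair_noise(
        config, target_r=config.coupling_target_r, one_sided=True
    )
    return {
        "classes": classes,
        "coupled": coupled,
        "driver": "module_factor",
        "sigma_coupled": sigma_coupled,
    }


def _replicate_log2_sd(cv: float) -> float:
    # multiplicative lognormal noise with the given cv, expressed in log2
    return float(np.sqrt(np.log1p(cv * cv)) / np.log(2.0))


def _factor_values(
    rng: np.random.Generator, config: SimConfig, factor_log2: Mapping[str, float], tau: float
) -> np.ndarray:
    g = np.array([factor_log2[s.rsplit("_", 1)[0]] for s in config.samples])
    return g + rng.normal(0.0, tau, size=len(g))


def _calibrate_pair_noise(
    config: SimConfig, target_r: float, one_sided: bool, n_sims: int = 400
) -> float:
    """Pick the entity noise sd (log2) hitting a target raw-scale Pearson r.

    Simulates pairs sharing the module latent factor (group effect +
    shared jitter) under candidate noise levels and bisects on the mean
    empirical correlation of the 2**x values.  ``one_sided`` puts the
    candidate noise on one partner only (the other uses replicate
    noise), matching the gene-metabolite coupling geometry.
    """
    cal_rng = np.random.default_rng(20240101)
    delta = float(np.log2(config.deg_fold))
    g = np.array(
        [lv for lv in (0.0, delta, delta) for _ in range(config.n_replicates)]
    )
    rep_sd = _replicate_log2_sd(config.replicate_cv)

    def mean_r(sigma: float) -> float:
        rs = []
        for _ in range(n_sims):
            f = g + cal_rng.normal(0.0, config.factor_tau, size=g.size)
            sd_x = rep_sd if one_sided else sigma
            x = 2.0 ** (f + cal_rng.normal(0.0, sd_x, size=g.size))
            y = 2.0 ** (f + cal_rng.normal(0.0, sigma, size=g.size))
            rs.append(np.corrcoef(x, y)[0, 1])
        return float(np.mean(rs))

    lo, hi = 0.01, 3.0
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if mean_r(mid) > target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_expression(
    manifest: TruthManifest, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Realize the FPKM matrix (family genes + TFs + functional genes).

    Returns (matrix, sample->group map).  Planted DEGs multiply their
    group means by the configured fold-changes; module members share the
    latent factor; replicate noise is multiplicative lognormal.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    plan = manifest.expression
    samples = config.samples
    rep_sd = _replicate_log2_sd(config.replicate_cv)
    module = plan["module"]
    factor = _factor_values(rng, config, module["factor_log2_by_group"], module["tau"])
    group_of = [s.rsplit("_", 1)[0] for s in samples]

    rows: dict[str, np.ndarray] = {}
    for gid in plan["expressed"]:
        effects = plan["deg_effects"].get(gid, {})
        if gid in plan["deg_effects"]:
            # planted DEGs are moderately-to-highly expressed, like the
            # qPCR-validated responders they emulate
            base = rng.normal(config.deg_base_log2_mean, config.deg_base_log2_sd)
        else:
            base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd)
        if gid in module["seeds"]:
            # seeds ride the latent factor (their planted fold IS the
            # factor's group effect) plus replicate noise
            log2v = base + factor + rng.normal(0.0, rep_sd, len(samples))
        else:
            shift = np.array([np.log2(effects.get(g, 1.0)) for g in group_of])
            log2v = base + shift + rng.normal(0.0, rep_sd, len(samples))
        rows[gid] = 2.0 ** log2v
    for gid in plan["silent"]:
        rows[gid] = rng.uniform(0.0, 0.4, size=len(samples))
    sigma_m = module["sigma_member"]
    for tf in module["members"]:
        base = rng.normal(config.baseline_log2_mean, 0.8)
        rows[tf] = 2.0 ** (base + factor + rng.normal(0.0, sigma_m, len(samples)))
    for tf in module["decoys"]:
        base = rng.normal(config.baseline_log2_mean, 0.8)
        rows[tf] = 2.0 ** (base + rng.normal(0.0, 4 * rep_sd, len(samples)))
    for fg in plan["functional_genes"]:
        base = rng.normal(config.baseline_log2_mean, 0.8)
        rows[fg] = 2.0 ** (base + factor + rng.normal(0.0, sigma_m, len(samples)))
    matrix = pd.DataFrame(rows, index=samples).T
    matrix.index.name = "gene"
    return matrix, config.sample_groups()


def generate_metabolome(
    manifest: TruthManifest, config: SimConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize the metabolite abundance table and its class annotation.

    Coupled metabolites ride the module latent factor (hence inherit its
    planted fold-change); uncoupled metabolites are independent noise
    around their baselines.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    plan = manifest.metabolome
    module = manifest.expression["module"]
    samples = config.samples
    rep_sd = _replicate_log2_sd(config.replicate_cv)
    factor = _factor_values(rng, config, module["factor_log2_by_group"], module["tau"])
    sigma_c = plan["sigma_coupled"]
    coupled = set(plan["coupled"])
    rows = {}
    for met, cls in plan["classes"].items():
        base = rng.normal(10.0, 1.0)
        if met in coupled:
            rows[met] = 2.0 ** (base + factor + rng.normal(0.0, sigma_c, len(samples)))
        else:
            rows[met] = 2.0 ** (base + rng.normal(0.0, 3 * rep_sd, len(samples)))
    table = pd.DataFrame(rows, index=samples).T
    table.index.name = "metabolite"
    meta = pd.DataFrame(
        {"class": [plan["classes"][m] for m in table.index]}, index=table.index
    )
    return table, meta


def generate_ct_table(
    manifest: TruthManifest, config: SimConfig, seed: int
) -> pd.DataFrame:
    """Ct table derived by inverting 2^-ddCt from planted fold-changes.

    The reference gene is held constant across groups; target Ct gets
    Gaussian noise with the configured sd (0 gives exact inversion).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    rows = []
    for gene, effects in manifest.qpcr["genes"].items():
        for sample in config.samples:
            group = sample.rsplit("_", 1)[0]
            fold = effects.get(group, 1.0)
            dct = config.ct_dct_control - np.log2(fold)
            noise = rng.normal(0.0, config.ct_sd) if config.ct_sd else 0.0
            rows.append(
                {"gene": gene, "sample": sample, "group": group,
                 "ct_target": config.ct_ref + dct + noise, "ct_ref": config.ct_ref}
            )
    return pd.DataFrame(rows)
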