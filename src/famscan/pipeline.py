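"""End-to-end orchestration of all analysis stages from one config.

Stages run in dependency order (scan -> props -> context -> phylogeny ->
promoters -> expression -> networks); any stage can be skipped by flag.
The run report is a JSON-serializable record of per-stage record counts,
the effective parameters used, output file paths and elapsed time.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .expression_stats import (
    call_degs,
    degs_to_frame,
    expressed_filter,
    relative_expression,
    row_scale,
)
from .family_scan import scan_family
from .genome_context import (
    build_chromosome_map,
    classify_duplications,
    codon_align,
    compute_ka_ks,
    detect_collinear_blocks,
    find_anchor_pairs,
)
from .genome_io import extract_cds, load_gene_models, read_fasta, write_fasta
from .omics_network import (
    build_tripartite_network,
    coexpression_screen,
    export_network,
    metabolite_association,
)
from .phylogeny import align_domains, bootstrap_support
from .promoter_scan import CisElementCatalog, extract_promoters, scan_promoter_set
from .protein_props import compute_protparam

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "scan": {"prefix": "WRKY", "allow_variants": False},
    "context": {"bin_bp": 100_000, "terminal_window_bp": None, "min_identity": 0.5,
                "min_anchors": 5, "max_rank_gap": 25,
                "tandem_max_intervening": 5, "tandem_max_bp": 100_000},
    "tree": {"n_reps": 100, "seed": 0},
    "promoters": {"upstream_bp": 2000, "catalog": None},
    "deg": {"min_fpkm": 0.5, "fc_min": 1.5, "q_max": 0.05, "pseudocount": 1.0,
            "control_group": "CK"},
    "network": {"r_min": 0.9, "min_fpkm": 0.5, "r_abs_min": 0.8, "p_max": 0.05,
                "met_fc_min": 1.5, "met_sig": "fdr"},
}


@dataclass
class RunConfig:
    inputs: dict[str, str]
    output_dir: str
    seed: int = 0
    skip: list[str] = field(default_factory=list)
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            inputs=data.get("inputs", {}),
            output_dir=data["output_dir"],
            seed=int(data.get("seed", 0)),
            skip=list(data.get("skip", [])),
            params=data.get("params", {}),
        )

    def effective(self, stage: str) -> dict[str, Any]:
        merged = dict(DEFAULT_PARAMS.get(stage, {}))
        merged.update(self.params.get(stage, {}))
        return merged


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report dict."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **info) -> None:
        report["stages"][stage] = {"params": config.effective(stage), **info}

    try:
        genome = read_fasta(config.inputs["genome"]) if "genome" in config.inputs else None
        proteins = read_fasta(config.inputs["proteins"]) if "proteins" in config.inputs else None
        models = (
            load_gene_models(config.inputs["gff"], proteins)
            if "gff" in config.inputs
            else None
        )

        survivors = []
        names: dict[str, str] = {}
        if "scan" not in config.skip and models is not None:
            p = config.effective("scan")
            candidates, names = scan_family(
                models, prefix=p["prefix"], allow_variants=p["allow_variants"]
            )
            survivors = [c for c in candidates if c.status == "accepted"]
            table = pd.DataFrame(
                {
                    "gene_id": [c.gene_id for c in candidates],
                    "name": [names.get(c.gene_id, "") for c in candidates],
                    "n_domains": [len(c.hits) for c in candidates],
                    "zinc_fingers": [
                        ",".join(h.zinc_finger for h in c.hits) for c in candidates
                    ],
                    "status": [c.status for c in candidates],
                }
            )
            path = outdir / "family_candidates.tsv"
            table.to_csv(path, sep="\t", index=False)
            write_fasta(
                [(names[c.gene_id], c.protein) for c in survivors],
                outdir / "family_proteins.faa",
            )
            report["outputs"]["scan"] = str(path)
            record("scan", n_candidates=len(candidates), n_accepted=len(survivors))

        if "props" not in config.skip and survivors:
            rows = []
            for c in survivors:
                pr = compute_protparam(c.protein)
                rows.append(
                    {"name": names[c.gene_id], "gene_id": c.gene_id, "AA": pr.length,
                     "MW": pr.mw, "pI": pr.pi, "II": pr.instability, "AI": pr.aliphatic,
                     "GRAVY": pr.gravy, "class": pr.charge_class}
                )
            path = outdir / "protein_properties.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            report["outputs"]["props"] = str(path)
            record("props", n_proteins=len(rows))

        if "context" not in config.skip and survivors and genome is not None:
            p = config.effective("context")
            chrom_lengths = {c: len(s) for c, s in genome.items()}
            cmap = build_chromosome_map(
                [(c.gene_id, c.gene.chromosome, c.gene.start) for c in survivors],
                chrom_lengths,
                bin_bp=p["bin_bp"],
                terminal_window_bp=p["terminal_window_bp"],
            )
            pd.DataFrame(
                [
                    {"chromosome": chrom, "bin": i, "count": n}
                    for chrom, counts in cmap.density.items()
                    for i, n in enumerate(counts)
                ]
            ).to_csv(outdir / "gene_density.tsv", sep="\t", index=False)
            all_prots = {m.gene_id: m.protein_seq for m in models if m.protein_seq}
            anchors = find_anchor_pairs(all_prots, min_identity=p["min_identity"])
            order_index = {}
            by_chrom: dict[str, list] = {}
            for m in models:
                by_chrom.setdefault(m.chromosome, []).append(m)
            for chrom, ms in by_chrom.items():
                for rank, m in enumerate(sorted(ms, key=lambda g: g.start)):
                    order_index[m.gene_id] = (chrom, rank)
            blocks = detect_collinear_blocks(
                anchors, order_index, min_anchors=p["min_anchors"],
                max_rank_gap=p["max_rank_gap"],
            )
            fam_ids = {c.gene_id for c in survivors}
            fam_pairs = [a for a in anchors if a.gene_a in fam_ids and a.gene_b in fam_ids]
            positions = {m.gene_id: (m.chromosome, m.start, m.end) for m in models}
            dups = classify_duplications(
                fam_pairs, blocks, positions, order_index,
                tandem_max_intervening=p["tandem_max_intervening"],
                tandem_max_bp=p["tandem_max_bp"],
            )
            model_by_id = {m.gene_id: m for m in models}
            rows = []
            for d in dups:
                cds_a = extract_cds(model_by_id[d.gene_a], genome)
                cds_b = extract_cds(model_by_id[d.gene_b], genome)
                ka, ks, ratio = compute_ka_ks(*codon_align(cds_a, cds_b))
                rows.append(
                    {"gene_a": d.gene_a, "gene_b": d.gene_b, "class": d.dup_class,
                     "Ka": ka, "Ks": ks, "Ka/Ks": ratio}
                )
            path = outdir / "duplication_pairs.tsv"
            pd.DataFrame(
                rows, columns=["gene_a", "gene_b", "class", "Ka", "Ks", "Ka/Ks"]
            ).to_csv(path, sep="\t", index=False)
            pd.DataFrame(
                [
                    {"chrom_a": b.chrom_a, "chrom_b": b.chrom_b,
                     "n_anchors": b.n_anchors, "orientation": b.orientation}
                    for b in blocks
                ]
            ).to_csv(outdir / "collinear_blocks.tsv", sep="\t", index=False)
            report["outputs"]["context"] = str(path)
            record(
                "context", n_anchors=len(anchors), n_blocks=len(blocks),
                n_family_pairs=len(dups),
                class_counts={
                    cls: sum(1 for d in dups if d.dup_class == cls)
                    for cls in ("tandem", "segmental", "dispersed")
                },
                terminal_count=cmap.terminal_count,
            )

        if "tree" not in config.skip and survivors:
            p = config.effective("tree")
            domains = {}
            for c in survivors:
                h = c.hits[-1]  # C-terminal domain carries the group signal
                domains[names[c.gene_id]] = c.protein[h.dom_start : h.dom_end]
            if len(domains) >= 4:
                alignment = align_domains(domains)
                tree = bootstrap_support(
                    alignment, n_reps=p["n_reps"], seed=p["seed"] or config.seed
                )
                path = outdir / "family_tree.nwk"
                path.write_text(tree.newick() + "\n")
                write_fasta(sorted(alignment.items()), outdir / "domain_alignment.fasta")
                report["outputs"]["tree"] = str(path)
                record("tree", n_taxa=len(domains))

        if "promoters" not in config.skip and survivors and genome is not None:
            p = config.effective("promoters")
            catalog = (
                CisElementCatalog.from_tsv(p["catalog"])
                if p["catalog"]
                else CisElementCatalog.default()
            )
            fam_models = [c.gene for c in survivors]
            promoters = extract_promoters(genome, fam_models, upstream_bp=p["upstream_bp"])
            counts = scan_promoter_set(promoters, catalog=catalog)
            matrix = pd.DataFrame(counts).T
            matrix.index.name = "gene"
            path = outdir / "cis_element_counts.tsv"
            matrix.to_csv(path, sep="\t")
            long = matrix.reset_index().melt(
                id_vars="gene", var_name="element", value_name="count"
            )
            long.to_csv(outdir / "cis_element_counts_long.tsv", sep="\t", index=False)
            report["outputs"]["promoters"] = str(path)
            record("promoters", n_promoters=len(promoters))

        fpkm = groups = None
        if "fpkm" in config.inputs:
            fpkm = pd.read_csv(config.inputs["fpkm"], sep="\t", index_col=0)
            gmap = pd.read_csv(config.inputs["groups"], sep="\t")
            groups = dict(zip(gmap["sample"], gmap["group"]))
        if "deg" not in config.skip and fpkm is not None:
            p = config.effective("deg")
            expressed = expressed_filter(fpkm, min_fpkm=p["min_fpkm"])
            scaled = row_scale(fpkm.loc[expressed])
            scaled.to_csv(outdir / "fpkm_rowscaled.tsv", sep="\t")
            group_names = sorted(set(groups.values()))
            control = p["control_group"]
            deg_counts = {}
            for other in group_names:
                if other == control:
                    continue
                records = call_degs(
                    fpkm, groups, control, other, fc_min=p["fc_min"],
                    q_max=p["q_max"], pseudocount=p["pseudocount"],
                )
                frame = degs_to_frame(records)
                frame.to_csv(outdir / f"deg_{other}_vs_{control}.tsv", sep="\t")
                deg_counts[other] = {
                    "up": int((frame["status"] == "up").sum()),
                    "down": int((frame["status"] == "down").sum()),
                }
            record("deg", n_expressed=len(expressed), deg_counts=deg_counts)
            report["outputs"]["deg"] = str(outdir / "fpkm_rowscaled.tsv")
            if "ct" in config.inputs:
                ct = pd.read_csv(config.inputs["ct"], sep="\t")
                per_sample, summary = relative_expression(ct, control_group=control)
                per_sample.to_csv(outdir / "qpcr_relative_expression.tsv", sep="\t",
                                  index=False)
                summary.to_csv(outdir / "qpcr_summary.tsv", sep="\t", index=False)

        if "network" not in config.skip and fpkm is not None and "tf_fpkm" in config.inputs:
            p = config.effective("network")
            tf_fpkm = pd.read_csv(config.inputs["tf_fpkm"], sep="\t", index_col=0)
            tf_meta = pd.read_csv(config.inputs["tf_families"], sep="\t", index_col=0)
            tf_families = dict(tf_meta.iloc[:, 0])
            coexpr = coexpression_screen(
                fpkm, tf_fpkm, tf_families, r_min=p["r_min"], min_fpkm=p["min_fpkm"]
            )
            edge_lists = [coexpr.edges]
            roles = {g: "wrky" for g in fpkm.index}
            roles.update({t: "tf" for t in tf_fpkm.index})
            if "metabolites" in config.inputs:
                met = pd.read_csv(config.inputs["metabolites"], sep="\t", index_col=0)
                met_meta = pd.read_csv(config.inputs["met_meta"], sep="\t", index_col=0)
                assoc = metabolite_association(
                    fpkm, met, met_meta, r_abs_min=p["r_abs_min"], p_max=p["p_max"],
                    met_fc_min=p["met_fc_min"], met_sig=p["met_sig"],
                )
                edge_lists.append(assoc.edges)
                roles.update({m: "metabolite" for m in met.index})
            graph = build_tripartite_network(edge_lists, roles)
            paths = export_network(graph, outdir, basename="network")
            report["outputs"]["network"] = str(paths["edges"])
            record(
                "network", n_nodes=graph.number_of_nodes(),
                n_edges=graph.number_of_edges(), n_tfs=coexpr.n_tfs,
                n_families=coexpr.n_families,
            )
    except Exception as exc:  # partial outputs are kept on disk
        report["error"] = f"{type(exc).__name__}: {exc}"
        report["elapsed_s"] = round(time.time() - t0, 3)
        (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
        raise

    report["elapsed_s"] = round(time.time() - t0, 3)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
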