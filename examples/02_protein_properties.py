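"""Physicochemical panel (AA, MW, pI, II, AI, GRAVY) for family proteins.

The same panel a family census reports: length, molecular weight,
isoelectric point, Guruprasad instability index (II > 40 = predicted
unstable in vitro), Ikai aliphatic index and Kyte-Doolittle GRAVY.
"""

from famscan.protein_props import compute_protparam, summarize_family
from famscan.synthetic_data import SimConfig, generate_genome_annotation

bundle = generate_genome_annotation(SimConfig(), seed=1)
family = bundle.manifest.family_gene_ids()
props = [compute_protparam(bundle.proteins[g]) for g in family]

p = props[0]
print(f"{family[0]}: {p.length} aa, MW {p.mw / 1000:.2f} kDa, pI {p.pi:.2f}, "
      f"II {p.instability:.2f}, AI {p.aliphatic:.2f}, GRAVY {p.gravy:.3f} "
      f"({p.charge_class})")

summary = summarize_family(props)
print(f"family of {summary.n}: length {summary.minima['length']:.0f}-"
      f"{summary.maxima['length']:.0f} aa, "
      f"mean GRAVY {summary.means['gravy']:.3f}, "
      f"II>40 in {summary.n_unstable}/{summary.n}, "
      f"acidic/basic {summary.charge_counts['acidic']}/"
      f"{summary.charge_counts['basic']}")
# Negative mean GRAVY marks the family as hydrophilic; the II>40 count
# is the usual 'predicted unstable' headline number.
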