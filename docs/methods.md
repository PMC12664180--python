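# Methods

This note documents the models and procedures famscan implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Family identification

Domain detection is pattern-based rather than profile-HMM-based: the
acceptance rule for family membership is the presence of the complete
heptapeptide plus an intact zinc finger, and that rule is what the code
implements directly. A hit is one heptapeptide occurrence (`WRKYGQK`;
with `allow_variants`, single-position variants matching
`W[RK]KYG[QKEM]K` are detected and flagged in the hit record — they are
never silently reported as canonical). The zinc finger is searched
downstream within 90 residues: C2H2 = `C-x(4,5)-C-x(22,23)-H-x-H`,
C2HC = `C-x(7)-C-x(23)-H-x-C`; when both patterns match, the
earliest-starting match wins (C2H2 on a tie), which makes
classification robust to chance cysteine/histidine runs in linker
sequence downstream of a true finger. A candidate lacking any zinc
finger is `rejected_incomplete`.

Redundancy (splice variants, near-identical paralogs) is collapsed when
two records have **identical domain substrings** (string equality from
heptapeptide start to zinc-finger end) **and** >95% full-length
identity. Identity is matches / alignment length under a global
alignment with unit match, zero mismatch, linear gap −1 and penalized
end gaps — a deliberately simple, fully documented scheme; no aligner
parameterization is inherited from any external tool. Groups are
single-linkage closures over qualifying pairs so transitive isoform
chains collapse to one survivor: the longest protein, ties broken by
lexicographically smallest gene id. Survivors are named
`<prefix>1..N` ordered by natural-sorted chromosome name then start
coordinate; identical loci tie-break deterministically by gene id and
are logged.

## Protein panel

- **MW**: sum of average (not monoisotopic) residue masses plus one
  water; the mass table is committed in
  `src/famscan/data/protparam_tables.json`.
- **pI**: unique root of the Henderson–Hasselbalch net-charge function
  under a committed Bjellqvist-style pKa set (D 4.05, E 4.45, C 9.0,
  Y 10.0, H 5.98, K 10.0, R 12.0, N-term 7.5, C-term 3.55), found by
  bisection on (0, 14) to |charge| < 1e−4. The charge function is
  strictly decreasing in pH, so bisection always converges. A fixed
  N-terminal pKa is used (no residue-specific N-term table); the tests
  therefore check against a grid-search oracle over the same charge
  model rather than promising bit-compatibility with any GUI tool
  (agreement with Biopython's Bjellqvist implementation is ~0.02 pH).
- **II** (Guruprasad): (10/L)·Σ DIWV over adjacent dipeptides, weights
  from `Bio.SeqUtils.ProtParamData.DIWV`; undefined (None) for
  length-1 sequences.
- **AI** (Ikai) and **GRAVY** (Kyte–Doolittle) as standard; `X`
  residues contribute zero hydropathy and zero DIWV weight and carry a
  nominal 110 Da mass.
- The family summary reports order statistics, means, the II > 40
  count and acidic/basic class counts; GRAVY dispersion is reported as
  mean ± sd (no significance test is attached to it).

## Genome context

Gene density uses 100-kb bins; the terminal-enrichment window is a
required parameter with **no default** — the figure usually quoted for
telomeric clustering depends on a window choice that cannot be
recovered unambiguously, so the package refuses to guess one.

Homolog anchors are all protein pairs at ≥50% global identity. A
shared-6-mer prescreen (threshold 0.05 of the smaller k-mer set) skips
alignments that cannot plausibly reach that level; it is exact in
practice for the ~90%-identity duplicates of interest and can be
disabled. Collinear blocks are maximal chains of anchors with strictly
monotone ranks on both chromosomes (each orientation tried),
consecutive rank gaps ≤25, length ≥5, found by longest-chain dynamic
programming per chromosome pair — a reduced MCScanX-style procedure
with no E-value scoring, sufficient for block membership questions.
Classification: tandem = same chromosome, ≤5 intervening annotated
genes and ≤100 kb separation; segmental = pair inside a collinear
block; else dispersed; tandem wins when both hold.

Ka/Ks is Nei–Gojobori (1986): per-codon synonymous site counts
averaged over both sequences; observed differences averaged over all
mutational pathways of each codon pair, pathways through premature
stop codons excluded (all pathways used if every one is blocked);
Jukes–Cantor correction, undefined for p ≥ 3/4 (reported missing with
a warning). Zero available sites with zero observed differences count
as a clean 0 so identical sequences give ka = ks = 0, ratio missing.
Input pairs are codon-aligned by back-threading a protein-level global
alignment onto the nucleotide sequences.

## Phylogeny

Domain sequences are aligned by anchoring on the heptapeptide:
upstream segments right-justified, downstream segments left-justified
with gaps. For the generator's indel-free domains this is exact; it
was chosen over progressive alignment because it is deterministic,
preserves the anchor columns by construction, and round-trips every
input row. Distances are p-distances with pairwise gap deletion
(Poisson correction optional). Neighbor joining follows Saitou–Nei
with the standard Q criterion; ties join the lowest-index pair, and
negative branch lengths are clamped to zero (logged). On additive
matrices the tree's path-length matrix reproduces the input to 1e−9,
which the tests verify over random 6-leaf trees; scikit-bio's `nj`
serves as an independent topology cross-check. Bootstrap support
resamples alignment columns with replacement; support is the
percentage of replicate trees containing each internal bipartition,
canonicalized rooting-independently. Subgroup assignment takes, for
each gene, the smallest **unrooted** clade (either side of any edge)
containing the gene and ≥1 reference taxon and uses the majority
reference group (alphabetical tie-break); a domain-architecture
fallback (two domains → group I analog; single C2HC domain → group III
analog) covers genes outside every reference clade.

## Promoters

Promoters are the 2000 bp upstream of the gene start, strand-aware,
clipped at chromosome ends with a warning. The element catalog is a
committed, user-overridable TSV of IUPAC consensus strings (TATA-box
`TATA`; CAAT-box `CCAAT`,`CAAT`; G-Box `CACGTG`; Box 4 `ATTAAT`; LTR
`CCGAAA`; ARE `AAACCA`; MBS `CAACTG`; MRE `AACCTAA`; ABRE `ACGTG`;
CGTCA/TGACG motifs; GARE `TCTGTTG`; W-box `TGACCA|TGACCT`). Published
consensus strings are the documented convention here; counts are
reproducible against this catalog but intentionally not claimed
bit-compatible with any web service's internal matrices. Counting:
every overlapping occurrence on both strands (a palindrome like the
G-Box counts once per strand); `N` never matches. Both-strand counts
are invariant under reverse complementation, which is tested.

## Expression and qPCR

The census-style thresholds are the contract: expressed = max FPKM
> 0.5; DEG = |log₂FC| ≥ 1.5 and BH-FDR < 0.05. The test statistic
behind the FDR is this package's declared choice — Welch's t on
log₂(FPKM + 1), pseudocount configurable — a parameter-free,
defensible reconstruction for a 3 × 3 design; no claim is made that it
reproduces any specific count-based tool. log₂FC uses raw group means
with the pseudocount. Degenerate zero-variance genes get p = 1 when
means are equal. Row scaling z-scores each gene with sample sd
(ddof = 1); constant rows map to zeros. qPCR: ΔCt = Ct_target −
Ct_ref, ΔΔCt vs the control-group mean ΔCt, output 2^−ΔΔCt (control
geometric mean 1 by construction), group summaries with Welch t vs
control.

## Networks

Pearson r carries a two-sided p from t = r·√(n−2)/√(1−r²). The
co-expression screen is positive-only (r > 0.9) by default, matching
the screening convention for co-activated regulators; `signed=False`
switches to |r|. Correlations run across all 9 samples (3 groups × 3
replicates) by default; using group means instead (n = 3) is possible
by passing an aggregated matrix, but the default is documented because
p-values depend strongly on n. Metabolite prefiltering defaults to
FDR-based significance with a flag for raw p — the two conventions
coexist in practice and the discrepancy is surfaced rather than
hidden. The tripartite merge keeps the max-|r| edge on duplicates and
refuses conflicting node roles. Enrichment is an upper-tail
hypergeometric test over a user-supplied annotation map (no ontology
retrieval) with BH correction.

## Synthetic data: what it emulates, and what it does not

The generator builds an 8-chromosome genome (~0.1–0.25 Mb each; a
desk-scale stand-in, not a full-size genome) carrying 60 family genes
among 200 decoys, with a 3-group × 3-replicate cold-stress design
(CK / Cold12h / Cold24h). Planted structure:

- **Domains**: group-typed architectures (group I analogs two C2H2
  domains, group III analogs one C2HC, others one C2H2) derived from
  per-group template domains with spacer-only substitutions; decoys
  are rejection-sampled free of canonical *and* variant heptapeptides,
  so detection sensitivity/specificity against the manifest is exactly
  1.
- **Redundancy**: three isoform triplets made by C-terminal
  truncations of 2–3.5%, satisfying the collapse criteria exactly.
- **Duplicates**: one tandem pair (8 kb apart) and one 8-anchor
  segmental block (6 decoy anchor pairs + 1 family pair). Divergence
  is simulated by single-nucleotide proposals accepted with
  probability ω = 0.2 when nonsynonymous, until the NG86-measured Ks
  reaches 0.3; domain-encoding codons are masked so the planted
  domains stay intact. This yields ~85–90% protein identity — below
  the 0.95 redundancy bar, above the 0.5 anchor bar.
- **Promoters**: C/T-only background (no catalog pattern can occur on
  either strand without an A or G), elements planted with ≥4-bp
  buffers and junction-screened locally, so scanned counts equal the
  constructive expectation exactly (including palindromic double
  counts and ABRE-inside-G-Box cross matches).
- **Expression**: log-normal baselines (log₂ mean 4, sd 1.5; planted
  DEGs at log₂ mean 5 so the pseudocount cannot erode an 8-fold
  effect below threshold), 10% replicate cv, 40 of 60 family genes
  expressed. Planted DEGs: two sustained 8-fold up (the module seeds),
  two up at 24 h only, three 8-fold down — mirroring a
  time-dependent cold response. A latent cold factor (group effects
  0/+3/+3 in log₂, within-sample jitter τ = 0.15) drives the seeds,
  10 module TFs, 2 flavonoid-pathway functional genes and 9 of 11
  flavonoids; 80 decoy TFs and all other metabolites are independent.
- **Calibration**: member noise is set by a seeded internal
  Monte-Carlo bisection so the empirical mean raw-scale pairwise
  module correlation hits the 0.95 target (measured 0.95 ± 0.01);
  metabolite coupling targets r ≈ 0.97, chosen so coupled metabolites
  — direct pathway products of the driver — are themselves
  significantly upregulated and pass the |log₂FC| ≥ 1.5, FDR < 0.05
  prefilter in a 3 v 3 design.
- **qPCR**: Ct tables invert 2^−ΔΔCt from the planted fold-changes;
  the reference gene is constant across groups and target Ct carries
  Gaussian noise (sd 0.2 by default; 0 gives exact inversion).

Everything is deterministic per (config, seed): same seed, byte-identical
artifacts.

**What passing these tests does not show about real data**: the
generator has single-exon genes, no alternative heptapeptides in
decoys, no sequencing noise model (FPKM values are drawn, not
quantified from reads), no batch effects, indel-free domains, and
idealized promoters whose background cannot contain chance elements.
Recovery being exact here validates the algorithms and their
bookkeeping, not the field performance of the thresholds on noisy
genomes.

## Problem sizes

The test suite and the acceptance script run the full family-recovery
pipeline on one 268-record genome; numeric oracles on 30 random
proteins; NJ recovery on 30–50 random 6-leaf additive trees; ω = 0.2
divergence on 60–100 simulated 150-codon duplicates; DEG power on
60–200 seeded 3 v 3 runs; network recovery on 50–100 seeded
realizations; qPCR error on 60–100 seeded Ct tables. These sizes give
binomial standard errors well inside the asserted margins while
keeping a full run in tens of seconds.

## Known limitations

- The pattern-based detector cannot score borderline divergent domains
  the way a profile HMM would; variant heptapeptides are only found
  when explicitly enabled.
- Collinearity chaining has no statistical block significance; block
  membership, not block scoring, is the supported claim.
- The DEG test is a reconstruction; on real count data a dedicated
  count-model tool is preferable and the thresholds are the only part
  carried over.
- Subgroup assignment is only as good as the supplied reference set;
  with no references in a gene's neighborhood the architecture
  fallback distinguishes just the two-domain and C2HC classes.
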