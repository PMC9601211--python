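# Methods

## The screening procedure

`opxscreen` implements a comparative-genomics screen for short periplasmic
OPX (outer-membrane polysaccharide export, Wza-like) proteins that are
genetically coupled to outer-membrane (OM) β-barrel translocons. In
canonical Wzx/Wzy- and ABC-transporter-dependent pathways, a full-length OPX
protein spans the OM itself via a C-terminal α-helical barrel (as in
*E. coli* Wza). The screen targets the alternative arrangement: a short OPX
protein that lacks the OM-spanning helix and instead pairs with a dedicated
β-barrel protein encoded nearby.

The pipeline takes per-genome gene tables, protein records, domain-hit
tables, 3-state secondary-structure (SS) strings, and β-barrel topology
annotations, and proceeds in fixed stage order:

1. **Detection.** Any protein with at least one threshold-passing hit of the
   polysaccharide export sequence domain (Pfam Poly_export, PF02563) is an
   OPX candidate. The hit table is trusted; hit thresholds (e.g. the Pfam
   gathering threshold) are applied upstream, so `meets_threshold` defaults
   to true.
2. **Context filter.** The candidate's gene neighborhood — the genes within
   `window_genes` (default 5) ranks up- and downstream on the same contig —
   is searched for seven polysaccharide-synthesis domains: ABC2_membrane
   (PF01061), ABC_tran (PF00005), Polysacc_synt (PF01943), Polysacc_synt3
   (PF13440), Wzt_C (PF14524), Wzy_C (PF04932), Wzz (PF02706). Candidates
   with no such neighbor are excluded from all further stages.
3. **Pathway assignment.** The context gene at minimal |rank offset|
   assigns the pathway. Wzy_C votes Wzx/Wzy; ABC_tran, ABC2_membrane and
   Wzt_C vote ABC; Polysacc_synt and Polysacc_synt3 — flippase-family
   domains found in Wzx/Wzy clusters — vote Wzx/Wzy. A closest gene carrying
   only Wzz (a polysaccharide copolymerase, PCP) leaves the pathway
   unassigned, because the copolymerase itself occurs in more than one
   pathway type. A Wzz-bearing neighbor that also carries a BY
   (tyrosine) kinase domain marks PCP-2 context.
4. **Redundancy removal.** Candidate sequences are collapsed by greedy
   incremental clustering at 90% identity; downstream counts run over the
   cluster representatives.
5. **Helix scan.** Each candidate's SS string is scanned for a C-terminal
   α-helix (rule below).
6. **Barrel coupling.** Neighbors hit by either of two β-barrel family
   profiles (an EpsX/ExoB-family profile and a VpsM-orthology profile;
   pseudo-accessions `EPSX_FAM`, `VPSM_FAM` in hit tables, overridable) are
   barrel candidates. A candidate is *verified* iff its predicted strand
   count is ≥ `min_strands` (default 16) **and** its localization is OM;
   predictions with fewer strands are classified false positive. An OPX gene
   is *coupled* iff at least one verified barrel lies in its window.
7. **Classification.** Every candidate falls in exactly one category from
   the (short, coupled, helix) triple, where short means length ≤
   `short_cutoff_aa` (280 aa, inclusive). Long proteins collapse helix
   status into `long_coupled` / `long_uncoupled`: the dichotomy of interest
   — coupled-without-helix versus uncoupled-with-helix — concerns the short
   class only. Helix status for long proteins is retained in the record.
8. **Summary.** Counts per category and pathway, the fraction of verified
   barrels whose closest in-window OPX is short, a 20-aa-bin length
   histogram, per-taxon category counts, and tree-ring annotation tables
   for external tree viewers.

## The C-terminal helix rule

Within the final `helix_window_aa` (20) residues of the SS string, a
qualifying helix is a contiguous segment of 'H' runs interrupted by at most
`helix_max_gaps` (1) non-helical gaps, each of length ≤ `helix_max_gap_len`
(2), whose helical residues number ≥ `helix_min_residues` (10, i.e. "more
than nine"). The call is positive iff any such segment exists; segments must
lie wholly inside the window (helices beginning upstream contribute only
their in-window residues), and 'E' and 'C' are equally non-helical.

Two interpretive choices are deliberate:

- "More than nine residues" counts **helical residues**, not the segment
  span including gaps. Counting H residues is the stricter and more
  reproducible reading of how far a helix extends; the span reading is
  available via `mode="span"`.
- "At most one gap of two residues" is read as at most one gap of length
  *at most* two — a rule admitting 2-residue gaps but rejecting 1-residue
  gaps would be incoherent.

The scanner is validated against an exhaustive segment-enumeration oracle on
all 2^14 H/C windows of length 14 and on 100,000 random H/E/C strings.

## Identity and clustering conventions

Pairwise identity is the number of identical aligned positions in a global
alignment divided by the **shorter** sequence length (the CD-HIT
convention). The alignment maximizes identities directly (match +1,
mismatch 0, gaps free), which makes the count equal to the longest-common-
subsequence length; no substitution matrix is involved because the quantity
of interest is an identity fraction, not a similarity score. Clustering is
greedy and incremental: sequences sorted by descending length (ties by id),
each joining the first cluster whose representative it matches at ≥ the
threshold. No short-word prefilter is used — at the scale this package
targets, exact all-vs-representative comparison is affordable and simpler
to verify. One consequence of the shorter-length denominator: an exact
subsequence of a longer sequence reaches identity 1.0, so "threshold 1.0
groups exact duplicates" holds in the equal-length sense.

## Tie and boundary rules (all logged where they fire)

- Pathway tie at equal |offset|: union the definitive votes of all context
  genes at the minimal distance; one distinct vote wins, conflicting votes
  yield pathway `none` with an `ambiguous_pathway` flag (explicit flagging
  beats silent misassignment), no definitive vote with Wzz present yields
  `pcp_unassigned`.
- Coupling partner tie at equal |offset|: the downstream gene is primary;
  all barrel records are emitted regardless.
- The 280-aa cutoff is inclusive; 281 aa is long.
- Strand count 16 verifies (the floor is "fewer than 16 is false positive").
- Missing topology for a barrel hit → unverified, localization `unknown`.
- Proteins without sequences pass through clustering as singletons.
- SS strings shorter than the window are scanned whole.
- Neighbor distance is measured in gene ranks, never base pairs; strand is
  recorded but carries no condition. Contigs are linear unless flagged
  circular (then ranks wrap, still without duplicating neighbors).

## Enrichment module

The pulldown decision rule operates on long-format replicate tables:
proteins are removed if their peptide count falls below
`enrich_min_peptides` (3) in *any* replicate of either arm (a bait-only
switch exists); the enrichment call requires log2 fold-change of mean bait
over mean control intensities ≥ `enrich_min_log2fc` (3.0) **and** a Welch
unequal-variance t-test p ≤ `enrich_max_p` (0.001). Welch's test is used as
the significance method directly; a moderated-variance statistic is a
possible config extension, not the default. Missing intensities are not
imputed; affected proteins are dropped and logged. If both arms have zero
variance, p is 1 when the means agree and 0 otherwise, by convention.

## The synthetic-data generator

The generator emulates the statistical structure of a large multi-genome
screen at desk scale: single-contig genomes of ranked genes, protein
lengths from a two-mode mixture (short mode ≈ N(200, 30) clipped to
138–279 aa; long mode ≈ N(575, 150) clipped to 300–1,728 aa) chosen to
straddle the 280-aa cutoff and span the realistic OPX length range, and
background domain noise (irrelevant accessions from a reserved pool) on 10%
of genes so that filters are exercised on accession identity rather than
hit presence. Six plant archetypes cover the observed classes and the
decision boundaries: `composite` (short OPX + context + verified barrel),
`wza_like` (helix, context, no barrel), `decoy_opx_no_context`,
`decoy_barrel_alone`, `decoy_barrel_few_strands` (strand count 14, directly
below the verification floor), and `pcp_only_context` (Wzz-only context,
optionally with BY-kinase for PCP-2). Plants occupy focal slots ≥ 2·window+1
genes apart, so no plant's partner or context gene can contaminate another
plant's neighborhood; SS strings are constructed and then verified against
the scanner before being emitted.

What the generator does **not** emulate: nucleotide sequences, operon
structure, phylogenetic correlation between genomes, homology between OPX
families (planted OPX sequences are random, so each survivor is its own
cluster representative), partial or erroneous annotations, and domain-hit
score distributions. Passing the recovery tests therefore demonstrates that
every filtering, assignment and classification rule behaves exactly as
specified on clean annotations — not that the screen is robust to predictor
error on real genomes.

## Problem sizes and determinism

The validation runs use 50 genomes × 60 genes with one composite and one
wza_like plant per genome and the remaining archetypes cycling across
genomes; clustering checks use families of 25 members at 5% substitution;
the enrichment null uses 10,000 proteins at 4+4 replicates. All randomness
flows from a single integer seed through one `numpy.random.Generator`, and
reruns are byte-identical. At 5% substitution a family member occasionally
drifts below 90% identity to its parent (a ~3-SD binomial event), founding
an extra singleton cluster; clusters never mix families, which is the
invariant the redundancy stage must preserve.

## Known limitations

- The exact CD-HIT parameters behind the original 90% clustering are not
  reproducible here; borderline pairs may cluster differently.
- The BY-kinase accession used for PCP-2 context is a configurable
  placeholder (default PF13614): the canonical analysis names the concept
  but not an accession.
- The coupling fraction is reported with two denominators (all verified
  barrels, and barrels near representatives only) because the choice is a
  genuine ambiguity; both are in every summary.
- The screen consumes predictions (domain hits, SS, topology, localization)
  as ground truth; upstream predictor error propagates unexamined.
- Phylogenetic tree building is out of scope by design: the package emits
  representative sequences and ring-annotation tables for external
  alignment/tree tools, not trees.
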