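"""OPX candidate detection, gene neighborhoods, context filter, pathway assignment.

OPX proteins are periplasmic outer-membrane polysaccharide export (Wza-like)
proteins detected by the polysaccharide export sequence domain Poly_export
(PF02563). To corroborate that a candidate sits in a polysaccharide
biosynthesis gene cluster, its five-gene neighborhood is searched for a
fixed set of polysaccharide-synthesis Pfam domains; candidates without such
context are excluded. The closest context gene then assigns a pathway:
Wzx/Wzy-dependent, ABC-transporter-dependent, or unassigned when the
closest context gene encodes a polysaccharide copolymerase (Wzz family).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from opxscreen.genome_io import DomainHit, GeneRecord, GeneTable, ProteinRecord

logger = logging.getLogger(__name__)

#: polysaccharide-synthesis context domains searched in OPX neighborhoods
CONTEXT_ACCS = frozenset(
    {
        "PF01061",  # ABC2_membrane
        "PF00005",  # ABC_tran
        "PF01943",  # Polysacc_synt
        "PF13440",  # Polysacc_synt3
        "PF14524",  # Wzt_C
        "PF04932",  # Wzy_C
        "PF02706",  # Wzz
    }
)

WZX_WZY_ACCS = frozenset({"PF04932", "PF01943", "PF13440"})
ABC_ACCS = frozenset({"PF00005", "PF01061", "PF14524"})
WZZ_ACC = "PF02706"


@dataclass(frozen=True)
class DomainConfig:
    """Accessions the screen keys on; all overridable.

    ``barrel_accs`` name the two custom β-barrel search profiles (one built
    from EpsX/ExoB-family homologs, one from the VpsM orthology group); any
    reported hit counts. ``tyrosine_kinase_acc`` marks BY-kinase context used
    to call PCP-2 copolymerases (placeholder accession; configurable).
    """

    opx_acc: str = "PF02563"
    context_accs: frozenset[str] = CONTEXT_ACCS
    barrel_accs: frozenset[str] = frozenset({"EPSX_FAM", "VPSM_FAM"})
    tyrosine_kinase_acc: str = "PF13614"


class HitIndex:
    """Domain hits indexed by protein; only threshold-passing hits count."""

    def __init__(self, hits: list[DomainHit]):
        self._accs: dict[str, set[str]] = {}
        for h in hits:
            if h.meets_threshold:
                self._accs.setdefault(h.protein_id, set()).add(h.domain_acc)

    def accs(self, protein_id: Optional[str]) -> frozenset[str]:
        if protein_id is None:
            return frozenset()
        return frozenset(self._accs.get(protein_id, ()))

    def has_any(self, protein_id: Optional[str], accs: frozenset[str]) -> bool:
        return bool(self.accs(protein_id) & accs)


@dataclass
class Neighborhood:
    """A focal gene and its neighbors at signed rank offsets in [-k, +k] \\ {0}."""

    focal: GeneRecord
    neighbors: list[tuple[GeneRecord, int]] = field(default_factory=list)


@dataclass
class OpxRecord:
    """One OPX candidate with its accumulated screen annotations."""

    protein_id: str
    gene_id: str
    genome_id: str
    length: int
    context_ok: bool = False
    pathway: str = "none"  # wzx_wzy | abc | pcp_unassigned | none
    pcp2_context: bool = False
    ambiguous_pathway: bool = False
    short: bool = False
    cterm_helix: Optional[bool] = None
    coupled: Optional[bool] = None
    partner_id: Optional[str] = None
    category: Optional[str] = None
    cluster_rep: Optional[str] = None
    is_representative: bool = False


def find_opx_candidates(
    hits: list[DomainHit],
    genes: GeneTable,
    proteins: dict[str, ProteinRecord],
    opx_acc: str = "PF02563",
) -> list[tuple[GeneRecord, ProteinRecord]]:
    """Proteins with >= 1 threshold-passing hit of the OPX detection domain.

    Deduplicated per protein; hits naming unknown proteins are skipped with a
    logged count. Output is ordered by (genome, contig, rank) for determinism.
    """
    seen: set[str] = set()
    unknown = 0
    out: list[tuple[GeneRecord, ProteinRecord]] = []
    for h in hits:
        if h.domain_acc != opx_acc or not h.meets_threshold:
            continue
        if h.protein_id in seen:
            continue
        seen.add(h.protein_id)
        gene = genes.gene_for_protein(h.protein_id)
        prot = proteins.get(h.protein_id)
        if gene is None or prot is None:
            unknown += 1
            continue
        out.append((gene, prot))
    if unknown:
        logger.warning("find_opx_candidates: skipped %d hits on unknown proteins", unknown)
    out.sort(key=lambda gp: (gp[0].genome_id, gp[0].contig_id, gp[0].rank))
    return out


def extract_neighborhood(focal: GeneRecord, genes: GeneTable, k: int = 5) -> Neighborhood:
    """Genes within k ranks up/downstream of the focal gene on its contig.

    Truncated at contig ends unless the contig is flagged circular, in which
    case ranks wrap (offsets stay unique and never reach the focal itself).
    """
    contig = genes.contig_genes(focal.genome_id, focal.contig_id)
    n = len(contig)
    circular = (focal.genome_id, focal.contig_id) in genes.circular
    neighbors: list[tuple[GeneRecord, int]] = []
    seen_ranks = {focal.rank}
    for off in range(-k, k + 1):
        if off == 0:
            continue
        r = focal.rank + off
        if circular:
            r %= n
            if r in seen_ranks:
                continue
            seen_ranks.add(r)
        elif not 0 <= r < n:
            continue
        neighbors.append((contig[r], off))
    neighbors.sort(key=lambda t: t[1])
    return Neighborhood(focal=focal, neighbors=neighbors)


def context_filter(
    nb: Neighborhood, hits: HitIndex, context_accs: frozenset[str] = CONTEXT_ACCS
) -> bool:
    """True iff any neighbor's protein carries a polysaccharide-context domain."""
    if not context_accs:
        raise ValueError("context_accs must be nonempty")
    return any(hits.has_any(g.protein_id, context_accs) for g, _ in nb.neighbors)


def _gene_votes(accs: frozenset[str]) -> tuple[set[str], bool]:
    """Definitive pathway votes and Wzz presence for one neighbor's domains."""
    votes = set()
    if accs & WZX_WZY_ACCS:
        votes.add("wzx_wzy")
    if accs & ABC_ACCS:
        votes.add("abc")
    return votes, WZZ_ACC in accs


def assign_pathway(
    nb: Neighborhood, hits: HitIndex, config: DomainConfig = DomainConfig()
) -> tuple[str, bool, bool]:
    """Assign a pathway from the closest context-domain-bearing neighbor.

    Returns (pathway, pcp2_context, ambiguous). Domain-to-pathway mapping:
    Wzy_C, Polysacc_synt and Polysacc_synt3 vote Wzx/Wzy (the latter two are
    flippase-family domains of Wzx/Wzy pathways); ABC_tran, ABC2_membrane
    and Wzt_C vote ABC; a closest gene carrying only Wzz leaves the pathway
    unassigned (the copolymerase itself does not discriminate).

    Tie rule at equal |offset| (documented, logged): take the union of
    definitive votes from all context genes at the minimal distance; a single
    distinct vote wins, conflicting votes yield pathway "none" with the
    ambiguous flag set, and no definitive vote with Wzz present yields
    "pcp_unassigned".

    ``pcp2_context`` is true iff any Wzz-bearing neighbor in the window also
    carries the configured tyrosine-kinase accession (PCP-2 call).
    """
    context = []
    pcp2 = False
    for gene, off in nb.neighbors:
        accs = hits.accs(gene.protein_id)
        ctx = accs & config.context_accs
        if not ctx:
            continue
        context.append((abs(off), off, ctx))
        if WZZ_ACC in ctx and config.tyrosine_kinase_acc in accs:
            pcp2 = True
    if not context:
        return "none", False, False
    min_dist = min(d for d, _, _ in context)
    votes: set[str] = set()
    any_wzz = False
    for d, _off, ctx in context:
        if d != min_dist:
            continue
        v, wzz = _gene_votes(ctx)
        votes |= v
        any_wzz = any_wzz or wzz
    if len(votes) == 1:
        return votes.pop(), pcp2, False
    if len(votes) > 1:
        logger.info(
            "assign_pathway: conflicting definitive context at distance %d from %s; "
            "flagged ambiguous", min_dist, nb.focal.gene_id,
        )
        return "none", pcp2, True
    if any_wzz:
        return "pcp_unassigned", pcp2, False
    return "none", pcp2, False  # unreachable: context genes always vote or carry Wzz
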