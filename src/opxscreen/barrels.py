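"""β-barrel partner discovery, verification, coupling, and dichotomy classification.

Candidate partner genes are neighbors hit by either of the two β-barrel
family profiles (or explicitly annotated as barrels). A candidate is
*verified* iff its predicted β-strand count is at least ``min_strands``
(default 16; fewer-stranded predictions are classified false positive) and
its predicted localization is the outer membrane. An OPX gene is *coupled*
iff a verified barrel lies within its neighborhood; the closest verified
barrel (tie broken downstream) is recorded as the primary partner.

Classification places every OPX into one of six exhaustive categories from
the (short, coupled, helix) triple; long proteins (> 280 aa) collapse helix
status into long_coupled / long_uncoupled since the dichotomy of interest
concerns the short class only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from opxscreen.detect import DomainConfig, HitIndex, Neighborhood, OpxRecord
from opxscreen.genome_io import Thresholds, TopologyAnnotation
from opxscreen.helix import HelixCall

logger = logging.getLogger(__name__)

CATEGORIES = (
    "short_coupled_nohelix",
    "short_uncoupled_helix",
    "short_coupled_helix",
    "short_uncoupled_nohelix",
    "long_coupled",
    "long_uncoupled",
)


@dataclass(frozen=True)
class BarrelRecord:
    protein_id: str
    gene_id: str
    hit_source: str  # epsx_family_hmm | vpsm_family_hmm | annotation
    strand_count: int
    localization: str
    verified: bool
    offset: int  # signed rank offset from the focal OPX gene
    focal_opx_gene: str


_SOURCE_BY_ACC = {"EPSX_FAM": "epsx_family_hmm", "VPSM_FAM": "vpsm_family_hmm"}


def find_barrel_candidates(
    nb: Neighborhood,
    barrel_hits: HitIndex,
    topo: dict[str, TopologyAnnotation],
    t: Thresholds = Thresholds(),
    config: DomainConfig = DomainConfig(),
    annotated_barrels: frozenset[str] = frozenset(),
) -> list[BarrelRecord]:
    """Barrel candidates among the neighbors of one OPX gene, verification applied.

    Neighbors hit by either barrel-family accession (any reported hit counts)
    or pre-annotated as barrels become records. Missing topology for a hit
    protein yields verified=False with localization unknown (logged).
    """
    out: list[BarrelRecord] = []
    for gene, off in nb.neighbors:
        pid = gene.protein_id
        if pid is None:
            continue
        hit_accs = barrel_hits.accs(pid) & config.barrel_accs
        if not hit_accs and pid not in annotated_barrels:
            continue
        if hit_accs:
            source = _SOURCE_BY_ACC.get(sorted(hit_accs)[0], "annotation")
        else:
            source = "annotation"
        ann = topo.get(pid)
        if ann is None:
            logger.info("no topology for barrel candidate %s; verified=False", pid)
            strand_count, localization = 0, "unknown"
        else:
            strand_count, localization = ann.strand_count, ann.localization
        verified = strand_count >= t.min_strands and localization == "OM"
        out.append(
            BarrelRecord(
                protein_id=pid,
                gene_id=gene.gene_id,
                hit_source=source,
                strand_count=strand_count,
                localization=localization,
                verified=verified,
                offset=off,
                focal_opx_gene=nb.focal.gene_id,
            )
        )
    return out


def couple(opx: OpxRecord, barrels: list[BarrelRecord]) -> OpxRecord:
    """Set the coupling flag: coupled iff >= 1 verified barrel in the neighborhood.

    The recorded partner is the verified barrel closest by |offset|; at equal
    distance the downstream (positive-offset) one is primary.
    """
    verified = [b for b in barrels if b.verified]
    opx.coupled = bool(verified)
    if verified:
        # prefer small |offset|; tie -> downstream (negative offsets sort after)
        best = min(verified, key=lambda b: (abs(b.offset), b.offset < 0))
        opx.partner_id = best.protein_id
    else:
        opx.partner_id = None
    return opx


def classify(opx: OpxRecord, helix: Optional[HelixCall], t: Thresholds = Thresholds()) -> str:
    """Assign the dichotomy category from the (short, coupled, helix) triple.

    short iff length <= short_cutoff_aa (inclusive). Raises if coupling or
    helix status is undetermined (stage-ordering violation).
    """
    if opx.coupled is None:
        raise ValueError(f"{opx.protein_id}: coupling undetermined before classify")
    opx.short = opx.length <= t.short_cutoff_aa
    if helix is not None:
        opx.cterm_helix = helix.has_cterm_helix
    if opx.short:
        if opx.cterm_helix is None:
            raise ValueError(f"{opx.protein_id}: helix status undetermined before classify")
        coupled_part = "coupled" if opx.coupled else "uncoupled"
        helix_part = "helix" if opx.cterm_helix else "nohelix"
        opx.category = f"short_{coupled_part}_{helix_part}"
    else:
        opx.category = "long_coupled" if opx.coupled else "long_uncoupled"
    return opx.category
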