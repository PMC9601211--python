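"""Redundancy removal: greedy incremental clustering at an identity threshold.

The procedure mirrors the CD-HIT style of clustering at desk scale, without
the short-word prefilter: sequences are sorted by descending length (ties by
id), and each sequence joins the first existing cluster whose representative
it matches at or above the identity threshold, else founds a new cluster.

Identity between two sequences is the number of identical aligned positions
in a global alignment divided by the length of the shorter sequence (the
CD-HIT convention). The alignment maximizes identities directly: match +1,
mismatch 0, linear gap 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from opxscreen.genome_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    representative: str
    members: list[str]
    threshold: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence length.

    Symmetric, in [0, 1]; 1.0 iff the shorter is a subsequence of the longer.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    matches = _ALIGNER.score(a, b)
    return matches / min(len(a), len(b))


def greedy_cluster(proteins: list[ProteinRecord], threshold: float = 0.90) -> list[Cluster]:
    """Cluster proteins greedily at ``threshold`` identity.

    Proteins are processed by descending length (ties by ascending id); each
    joins the first cluster whose representative it matches at >= threshold,
    else founds a new cluster with itself as representative. Representatives
    are therefore always a longest member of their cluster, and the clusters
    partition the input. Proteins without a sequence pass through as their
    own singleton clusters (logged).
    """
    ordered = sorted(proteins, key=lambda p: (-p.length, p.protein_id))
    clusters: list[Cluster] = []
    reps: list[ProteinRecord] = []
    n_missing = 0
    for prot in ordered:
        if prot.sequence is None:
            clusters.append(Cluster(prot.protein_id, [prot.protein_id], threshold))
            reps.append(prot)
            n_missing += 1
            continue
        for cluster, rep in zip(clusters, reps):
            if rep.sequence is None:
                continue
            if pairwise_identity(prot.sequence, rep.sequence) >= threshold:
                cluster.members.append(prot.protein_id)
                break
        else:
            clusters.append(Cluster(prot.protein_id, [prot.protein_id], threshold))
            reps.append(prot)
    if n_missing:
        logger.info("greedy_cluster: %d proteins without sequence kept as singletons", n_missing)
    return clusters
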