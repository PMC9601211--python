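"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives the expected answer by direct enumeration or plain
dynamic programming, sharing no code with the module it checks.
"""

from __future__ import annotations

import re


def helix_oracle(
    ss: str,
    window_aa: int = 20,
    min_residues: int = 10,
    max_gaps: int = 1,
    max_gap_len: int = 2,
    mode: str = "h_count",
) -> bool:
    """Enumerate every sub-segment of the C-terminal window and test the rule.

    Only segments starting and ending in 'H' can qualify (trimming non-H
    ends never hurts), so enumeration runs over pairs of H positions; each
    candidate segment is checked directly against the gap and size
    conditions.
    """
    window = ss[-window_aa:]
    hpos = [i for i, c in enumerate(window) if c == "H"]
    for ai in range(len(hpos)):
        for bi in range(ai, len(hpos)):
            seg = window[hpos[ai]:hpos[bi] + 1]
            gaps = [len(g) for g in re.findall(r"[^H]+", seg)]
            if len(gaps) > max_gaps or any(g > max_gap_len for g in gaps):
                continue
            size = seg.count("H") if mode == "h_count" else len(seg)
            if size >= min_residues:
                return True
    return False


def lcs_identity(a: str, b: str) -> float:
    """Identity via plain LCS dynamic programming over the shorter length.

    A global alignment scored match +1 / mismatch 0 / gap 0 maximizes the
    number of identical aligned positions, which equals the length of the
    longest common subsequence.
    """
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ai = a[i - 1]
        for j in range(1, n + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[n] / min(m, n)


def greedy_cluster_oracle(proteins, threshold: float):
    """Re-implementation of greedy clustering on the same sorted order,
    using the DP identity; returns {representative: sorted members}."""
    ordered = sorted(proteins, key=lambda p: (-p.length, p.protein_id))
    clusters: list[tuple] = []  # (rep_record, [member ids])
    for prot in ordered:
        if prot.sequence is None:
            clusters.append((prot, [prot.protein_id]))
            continue
        for rep, members in clusters:
            if rep.sequence is None:
                continue
            if lcs_identity(prot.sequence, rep.sequence) >= threshold:
                members.append(prot.protein_id)
                break
        else:
            clusters.append((prot, [prot.protein_id]))
    return {rep.protein_id: sorted(members) for rep, members in clusters}


WZX = {"PF04932", "PF01943", "PF13440"}
ABC = {"PF00005", "PF01061", "PF14524"}
WZZ = "PF02706"
CONTEXT = WZX | ABC | {WZZ}


def pathway_oracle(
    neighbors: list[tuple[int, set[str]]],
    kinase_acc: str = "PF13614",
) -> tuple[str, bool, bool]:
    """Closest-context pathway assignment by explicit enumeration.

    ``neighbors`` is a list of (signed offset, accession set). Returns
    (pathway, pcp2_context, ambiguous) under the documented closest-gene and
    tie rules.
    """
    pcp2 = any(
        WZZ in accs and kinase_acc in accs for _off, accs in neighbors
    )
    ctx = [(off, accs & CONTEXT) for off, accs in neighbors if accs & CONTEXT]
    if not ctx:
        return "none", False, False
    dmin = min(abs(off) for off, _ in ctx)
    votes: set[str] = set()
    wzz_at_min = False
    for off, accs in ctx:
        if abs(off) != dmin:
            continue
        if accs & WZX:
            votes.add("wzx_wzy")
        if accs & ABC:
            votes.add("abc")
        if WZZ in accs:
            wzz_at_min = True
    if len(votes) == 1:
        return votes.pop(), pcp2, False
    if len(votes) > 1:
        return "none", pcp2, True
    if wzz_at_min:
        return "pcp_unassigned", pcp2, False
    return "none", pcp2, False
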