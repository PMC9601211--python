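"""C-terminal α-helix detection on 3-state secondary-structure strings.

The rule: restrict to the last ``helix_window_aa`` (default 20) residues of
the protein. A qualifying helix is a contiguous segment inside that window
made of runs of 'H' interrupted by at most ``helix_max_gaps`` (default 1)
non-helical gaps, each of length at most ``helix_max_gap_len`` (default 2),
whose helical residues number at least ``helix_min_residues`` (default 10,
"more than nine"). The call is positive iff any such segment exists.

Two readings of "extended over more than nine residues" exist: counting
helical residues only (default, the stricter reading) or the segment span
including gaps. Both are exposed via ``mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from opxscreen.genome_io import SecondaryStructure, Thresholds

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HelixCall:
    protein_id: str
    has_cterm_helix: bool
    helical_residues_in_window: int
    gaps_used: int


def _h_runs(window: str) -> list[tuple[int, int]]:
    """Maximal runs of 'H' as (start, end) half-open intervals."""
    runs = []
    i = 0
    n = len(window)
    while i < n:
        if window[i] == "H":
            j = i
            while j < n and window[j] == "H":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def scan_cterm_helix(
    ss: SecondaryStructure, t: Thresholds = Thresholds(), mode: str = "h_count"
) -> HelixCall:
    """Decide whether a protein carries a C-terminal α-helix.

    Parameters
    ----------
    ss
        3-state secondary structure over {H, E, C}. Strings shorter than the
        window are evaluated whole (logged).
    t
        Thresholds; the helix_* fields apply.
    mode
        "h_count" counts helical residues toward the size requirement
        (default); "span" counts the whole segment length including gaps.
    """
    if mode not in ("h_count", "span"):
        raise ValueError(f"unknown helix mode {mode!r}")
    if len(ss.ss) < t.helix_window_aa:
        logger.info(
            "protein %s shorter than helix window (%d < %d); scanning whole string",
            ss.protein_id, len(ss.ss), t.helix_window_aa,
        )
    window = ss.ss[-t.helix_window_aa:]
    runs = _h_runs(window)
    total_h = sum(e - s for s, e in runs)

    best = 0
    best_gaps = 0
    # segments are consecutive run blocks i..j joined by gaps between them
    for i in range(len(runs)):
        h = 0
        for j in range(i, len(runs)):
            n_gaps = j - i
            if n_gaps > t.helix_max_gaps:
                break
            if j > i:
                gap_len = runs[j][0] - runs[j - 1][1]
                if gap_len > t.helix_max_gap_len:
                    break
            h += runs[j][1] - runs[j][0]
            measure = h if mode == "h_count" else runs[j][1] - runs[i][0]
            if measure > best or (measure == best and n_gaps < best_gaps):
                best = measure
                best_gaps = n_gaps

    positive = best >= t.helix_min_residues
    return HelixCall(
        protein_id=ss.protein_id,
        has_cterm_helix=positive,
        helical_residues_in_window=total_h,
        gaps_used=best_gaps if positive else 0,
    )
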