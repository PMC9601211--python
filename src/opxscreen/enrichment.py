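"""Pulldown enrichment decision rule on replicate intensity tables.

Input is a long-format table with columns protein, arm ("bait" or
"control"), replicate, peptide_count, log2_intensity. Proteins are first
filtered on peptide counts (count >= 3 in every replicate), then called
enriched when the log2 fold-change of mean bait over mean control intensity
is >= 3 and a Welch (unequal-variance) two-sample t-test on the log2
intensities gives p <= 0.001.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from opxscreen.genome_io import Thresholds

logger = logging.getLogger(__name__)

COLUMNS = ["protein", "arm", "replicate", "peptide_count", "log2_intensity"]


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pulldown table missing columns {missing}")
    bad = set(table["arm"]) - {"bait", "control"}
    if bad:
        raise ValueError(f"unknown arms {sorted(bad)}")


def peptide_filter(
    table: pd.DataFrame, t: Thresholds = Thresholds(), arms: str = "both"
) -> pd.DataFrame:
    """Retain proteins whose peptide count meets the floor in every replicate.

    ``arms`` selects which replicates the rule applies to: "both" (default)
    or "bait" only. Idempotent; the result is a row-subset of the input.
    """
    _validate(table)
    if arms not in ("both", "bait"):
        raise ValueError(f"arms must be 'both' or 'bait', got {arms!r}")
    sub = table if arms == "both" else table[table["arm"] == "bait"]
    ok = sub.groupby("protein")["peptide_count"].min() >= t.enrich_min_peptides
    keep = set(ok[ok].index)
    return table[table["protein"].isin(keep)].reset_index(drop=True)


def _welch_p(bait: np.ndarray, control: np.ndarray) -> float:
    if np.var(bait) == 0 and np.var(control) == 0:
        # degenerate: no within-arm variance; p by convention
        return 1.0 if np.mean(bait) == np.mean(control) else 0.0
    return float(stats.ttest_ind(bait, control, equal_var=False).pvalue)


def call_enriched(table: pd.DataFrame, t: Thresholds = Thresholds()) -> pd.DataFrame:
    """Per-protein log2 fold-change, Welch p-value, and the enriched call.

    log2fc = mean(bait log2 intensity) - mean(control log2 intensity);
    enriched iff log2fc >= enrich_min_log2fc and p <= enrich_max_p. Proteins
    with missing intensities in any replicate are dropped (logged).
    """
    _validate(table)
    rows = []
    n_dropped = 0
    for protein, grp in table.groupby("protein", sort=True):
        bait = grp.loc[grp["arm"] == "bait", "log2_intensity"].to_numpy(dtype=float)
        control = grp.loc[grp["arm"] == "control", "log2_intensity"].to_numpy(dtype=float)
        if len(bait) < 2 or len(control) < 2:
            raise ValueError(f"protein {protein}: need >= 2 replicates per arm")
        if np.isnan(bait).any() or np.isnan(control).any():
            n_dropped += 1
            continue
        log2fc = float(np.mean(bait) - np.mean(control))
        p = _welch_p(bait, control)
        rows.append(
            {
                "protein": protein,
                "log2fc": log2fc,
                "p": p,
                "enriched": log2fc >= t.enrich_min_log2fc and p <= t.enrich_max_p,
            }
        )
    if n_dropped:
        logger.info("call_enriched: dropped %d proteins with missing intensities", n_dropped)
    return pd.DataFrame(rows, columns=["protein", "log2fc", "p", "enriched"])
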