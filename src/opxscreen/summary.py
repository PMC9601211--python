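"""Aggregation of classified records into summary statistics; pipeline orchestration.

``run_screen`` executes the full screen on an in-memory :class:`Dataset`;
``run_pipeline`` wraps it with directory I/O, persisting every intermediate
table plus a JSON run summary. ``summarize`` condenses classified records and
barrel records into the headline numbers: candidate and representative
counts, the dichotomy category breakdown, pathway counts, the fraction of
verified barrels coupled to a short OPX protein (computed with both
plausible denominators), a length histogram, and per-taxon category counts.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from opxscreen import genome_io
from opxscreen.barrels import (
    CATEGORIES,
    BarrelRecord,
    classify,
    couple,
    find_barrel_candidates,
)
from opxscreen.cluster import Cluster, greedy_cluster
from opxscreen.dataset import Dataset, read_dataset
from opxscreen.detect import (
    DomainConfig,
    HitIndex,
    OpxRecord,
    assign_pathway,
    context_filter,
    extract_neighborhood,
    find_opx_candidates,
)
from opxscreen.genome_io import Thresholds
from opxscreen.helix import scan_cterm_helix

logger = logging.getLogger(__name__)

PATHWAYS = ("wzx_wzy", "abc", "pcp_unassigned", "none")


@dataclass
class SummaryReport:
    n_opx_total: int
    n_representatives: int
    n_short: int
    n_barrels_verified: int
    category_counts: dict[str, int]
    pathway_counts: dict[str, int]
    pathway_counts_short_coupled_nohelix: dict[str, int]
    fraction_barrels_coupled_to_short: Optional[float]
    fraction_barrels_coupled_to_short_repr: Optional[float]
    length_hist_edges: list[int]
    length_hist_counts: list[int]
    per_taxon_category_counts: dict[str, dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "n_opx_total": self.n_opx_total,
            "n_representatives": self.n_representatives,
            "n_short": self.n_short,
            "n_barrels_verified": self.n_barrels_verified,
            "category_counts": dict(self.category_counts),
            "pathway_counts": dict(self.pathway_counts),
            "pathway_counts_short_coupled_nohelix": dict(
                self.pathway_counts_short_coupled_nohelix
            ),
            "fraction_barrels_coupled_to_short": self.fraction_barrels_coupled_to_short,
            "fraction_barrels_coupled_to_short_repr": (
                self.fraction_barrels_coupled_to_short_repr
            ),
            "length_hist_edges": list(self.length_hist_edges),
            "length_hist_counts": list(self.length_hist_counts),
            "per_taxon_category_counts": {
                k: dict(v) for k, v in sorted(self.per_taxon_category_counts.items())
            },
        }


def _closest_short_fraction(
    barrels: list[BarrelRecord],
    rec_by_gene: dict[str, OpxRecord],
    t: Thresholds,
    representatives_only: bool,
) -> Optional[float]:
    """Of verified barrels, the fraction whose closest in-window OPX is short."""
    by_barrel: dict[str, list[BarrelRecord]] = {}
    for b in barrels:
        if not b.verified:
            continue
        rec = rec_by_gene.get(b.focal_opx_gene)
        if rec is None or (representatives_only and not rec.is_representative):
            continue
        by_barrel.setdefault(b.protein_id, []).append(b)
    if not by_barrel:
        return None
    n_short = 0
    for pid, recs in by_barrel.items():
        best = min(recs, key=lambda b: (abs(b.offset), b.offset < 0))
        focal = rec_by_gene[best.focal_opx_gene]
        if focal.length <= t.short_cutoff_aa:
            n_short += 1
    return n_short / len(by_barrel)


def summarize(
    records: list[OpxRecord],
    barrels: list[BarrelRecord],
    t: Thresholds = Thresholds(),
    taxa: Optional[dict[str, str]] = None,
    hist_bin_aa: int = 20,
) -> SummaryReport:
    """Condense classified records into the headline summary statistics.

    Category and pathway counts run over cluster representatives. The
    barrel-coupling fraction is reported with two denominators: all verified
    barrels found in any candidate's neighborhood, and only those found near
    a representative.
    """
    reps = [r for r in records if r.is_representative]
    rec_by_gene = {r.gene_id: r for r in records}
    cat = Counter(r.category for r in reps)
    pathway = Counter(r.pathway for r in reps)
    pathway_scn = Counter(
        r.pathway for r in reps if r.category == "short_coupled_nohelix"
    )
    verified_ids = {b.protein_id for b in barrels if b.verified}
    lengths = [r.length for r in reps]
    if lengths:
        top = (max(lengths) // hist_bin_aa + 1) * hist_bin_aa
        edges = np.arange(0, top + hist_bin_aa, hist_bin_aa)
        counts, _ = np.histogram(lengths, bins=edges)
    else:
        edges, counts = np.array([0]), np.array([], dtype=int)
    per_taxon: dict[str, dict[str, int]] = {}
    if taxa:
        for r in reps:
            taxon = taxa.get(r.genome_id, "unknown")
            per_taxon.setdefault(taxon, {c: 0 for c in CATEGORIES})
            per_taxon[taxon][r.category] += 1
    return SummaryReport(
        n_opx_total=len(records),
        n_representatives=len(reps),
        n_short=sum(r.short for r in reps),
        n_barrels_verified=len(verified_ids),
        category_counts={c: cat.get(c, 0) for c in CATEGORIES},
        pathway_counts={p: pathway.get(p, 0) for p in PATHWAYS},
        pathway_counts_short_coupled_nohelix={
            p: pathway_scn.get(p, 0) for p in PATHWAYS
        },
        fraction_barrels_coupled_to_short=_closest_short_fraction(
            barrels, rec_by_gene, t, representatives_only=False
        ),
        fraction_barrels_coupled_to_short_repr=_closest_short_fraction(
            barrels, rec_by_gene, t, representatives_only=True
        ),
        length_hist_edges=[int(e) for e in edges],
        length_hist_counts=[int(c) for c in counts],
        per_taxon_category_counts=per_taxon,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    records: list[OpxRecord]            # context survivors, fully classified
    excluded: list[OpxRecord]           # candidates failing the context filter
    barrels: list[BarrelRecord]         # all barrel candidates, verification applied
    clusters: list[Cluster]
    report: SummaryReport
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_screen(
    ds: Dataset,
    t: Thresholds = Thresholds(),
    config: DomainConfig = DomainConfig(),
    apply_context_filter: bool = True,
    helix_mode: str = "h_count",
) -> ScreenResult:
    """Execute the full screen: detect, context-filter, assign, couple,
    scan, cluster, classify, summarize.

    Coupling and helix status are evaluated per OPX gene before clustering;
    each cluster representative reports its own gene's annotations.
    """
    hit_index = HitIndex(ds.hits)
    candidates = find_opx_candidates(ds.hits, ds.genes, ds.proteins, config.opx_acc)
    survivors: list[OpxRecord] = []
    excluded: list[OpxRecord] = []
    all_barrels: list[BarrelRecord] = []
    for gene, prot in candidates:
        nb = extract_neighborhood(gene, ds.genes, t.window_genes)
        ctx_ok = context_filter(nb, hit_index, config.context_accs)
        rec = OpxRecord(
            protein_id=prot.protein_id,
            gene_id=gene.gene_id,
            genome_id=gene.genome_id,
            length=prot.length,
            context_ok=ctx_ok,
        )
        if apply_context_filter and not ctx_ok:
            excluded.append(rec)
            continue
        rec.pathway, rec.pcp2_context, rec.ambiguous_pathway = assign_pathway(
            nb, hit_index, config
        )
        barrels = find_barrel_candidates(nb, hit_index, ds.topology, t, config)
        all_barrels.extend(barrels)
        couple(rec, barrels)
        ss = ds.ss.get(prot.protein_id)
        if ss is None:
            raise KeyError(
                f"no secondary structure for OPX candidate {prot.protein_id}"
            )
        helix_call = scan_cterm_helix(ss, t, mode=helix_mode)
        classify(rec, helix_call, t)
        survivors.append(rec)

    clusters = greedy_cluster(
        [ds.proteins[r.protein_id] for r in survivors], t.cluster_identity
    )
    rep_of = {m: c.representative for c in clusters for m in c.members}
    for rec in survivors:
        rec.cluster_rep = rep_of[rec.protein_id]
        rec.is_representative = rec.cluster_rep == rec.protein_id

    report = summarize(survivors, all_barrels, t, taxa=ds.taxa or None)
    stage_counts = {
        "candidates": len(candidates),
        "excluded_no_context": len(excluded),
        "context_survivors": len(survivors),
        "clusters": len(clusters),
        "barrel_candidates": len(all_barrels),
        "barrels_verified_unique": report.n_barrels_verified,
    }
    return ScreenResult(survivors, excluded, all_barrels, clusters, report, stage_counts)


def ring_annotations(records: list[OpxRecord], path: str | Path) -> pd.DataFrame:
    """Per-representative annotation rows for external tree viewers.

    One row per representative with the pathway, coupling, size-class and
    helix columns of the classification rings; labels are never blank
    (pathway "none" is written literally).
    """
    rows = [
        {
            "protein_id": r.protein_id,
            "pathway": r.pathway,
            "coupled": str(bool(r.coupled)).lower(),
            "short": str(r.short).lower(),
            "cterm_helix": str(bool(r.cterm_helix)).lower(),
            "category": r.category,
        }
        for r in records
        if r.is_representative
    ]
    df = pd.DataFrame(
        rows, columns=["protein_id", "pathway", "coupled", "short", "cterm_helix", "category"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def _write_barrels(barrels: list[BarrelRecord], path: Path) -> None:
    rows = [
        {
            "protein_id": b.protein_id,
            "gene_id": b.gene_id,
            "focal_opx_gene": b.focal_opx_gene,
            "offset": b.offset,
            "hit_source": b.hit_source,
            "strand_count": b.strand_count,
            "localization": b.localization,
            "verified": str(b.verified).lower(),
        }
        for b in barrels
    ]
    pd.DataFrame(
        rows,
        columns=[
            "protein_id", "gene_id", "focal_opx_gene", "offset",
            "hit_source", "strand_count", "localization", "verified",
        ],
    ).to_csv(path, sep="\t", index=False)


def _write_clusters(clusters: list[Cluster], path: Path) -> None:
    rows = [
        {"cluster_id": i, "representative": c.representative, "member": m}
        for i, c in enumerate(clusters)
        for m in c.members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "representative", "member"]).to_csv(
        path, sep="\t", index=False
    )


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    t: Thresholds = Thresholds(),
    config: DomainConfig = DomainConfig(),
    apply_context_filter: bool = True,
    helix_mode: str = "h_count",
    seed: Optional[int] = None,
) -> ScreenResult:
    """File-based pipeline: read a dataset directory, screen, persist everything.

    Writes opx_records.tsv (survivors + excluded candidates), clusters.tsv,
    barrels.tsv, rings.tsv, representatives.fasta, summary.json and a
    run_summary.json echoing thresholds and per-stage record counts. Runs
    are byte-identical for identical inputs and configuration.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    ds = read_dataset(in_dir)
    result = run_screen(ds, t, config, apply_context_filter, helix_mode)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_io.write_classification(result.records + result.excluded, out_dir / "opx_records.tsv")
    _write_clusters(result.clusters, out_dir / "clusters.tsv")
    _write_barrels(result.barrels, out_dir / "barrels.tsv")
    ring_annotations(result.records, out_dir / "rings.tsv")
    with open(out_dir / "representatives.fasta", "w") as fh:
        for rec in result.records:
            if rec.is_representative:
                seq = ds.proteins[rec.protein_id].sequence
                if seq:
                    fh.write(f">{rec.protein_id}\n{seq}\n")
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(result.report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    run_summary = {
        "seed": seed,
        "thresholds": {k: getattr(t, k) for k in (
            "window_genes", "short_cutoff_aa", "helix_window_aa", "helix_min_residues",
            "helix_max_gaps", "helix_max_gap_len", "min_strands", "cluster_identity",
            "enrich_min_peptides", "enrich_min_log2fc", "enrich_max_p",
        )},
        "helix_mode": helix_mode,
        "context_filter": apply_context_filter,
        "stage_counts": result.stage_counts,
    }
    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
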