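"""Domain record types and readers/writers for all pipeline tables.

Coordinates are 1-based inclusive at I/O (GFF3 convention). Neighbor
distances are measured in gene *ranks* (0-based position in the gene order of
a contig), never in base pairs. Strand is stored but plays no role in
neighborhood math.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

SS_ALPHABET = frozenset("HEC")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene placed on a contig, with the rank used for neighbor distances."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank: int
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    length: int
    sequence: Optional[str] = None
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id}: length {self.length} < 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"protein {self.protein_id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class DomainHit:
    """A (protein, domain accession) link; drives all detection and typing."""

    protein_id: str
    domain_acc: str
    score: Optional[float] = None
    meets_threshold: bool = True

    def __post_init__(self) -> None:
        if not self.domain_acc:
            raise ValueError(f"empty domain accession for protein {self.protein_id}")


@dataclass(frozen=True)
class SecondaryStructure:
    """3-state secondary-structure string over {H, E, C}."""

    protein_id: str
    ss: str

    def __post_init__(self) -> None:
        bad = set(self.ss) - SS_ALPHABET
        if bad:
            raise ValueError(
                f"secondary structure for {self.protein_id} contains "
                f"characters outside H/E/C: {sorted(bad)}"
            )


@dataclass(frozen=True)
class TopologyAnnotation:
    """β-barrel topology: predicted strand count and subcellular localization."""

    protein_id: str
    strand_count: int
    localization: str  # OM | other | unknown

    def __post_init__(self) -> None:
        if self.strand_count < 0:
            raise ValueError(f"{self.protein_id}: negative strand count")
        if self.localization not in ("OM", "other", "unknown"):
            raise ValueError(f"{self.protein_id}: bad localization {self.localization!r}")


@dataclass(frozen=True)
class Thresholds:
    """All numeric screening thresholds, with field defaults as used throughout.

    window_genes
        Neighborhood half-width: context and partner genes are sought within
        this many genes up- and downstream of an OPX gene.
    short_cutoff_aa
        Inclusive upper length bound for the "short OPX" class.
    helix_window_aa / helix_min_residues / helix_max_gaps / helix_max_gap_len
        Parameters of the C-terminal helix rule: within the last
        ``helix_window_aa`` residues, a qualifying helix has at least
        ``helix_min_residues`` helical residues ("more than nine") and at most
        ``helix_max_gaps`` non-helical gaps, each of length at most
        ``helix_max_gap_len``.
    min_strands
        β-barrels predicted with fewer strands are classified false positive.
    cluster_identity
        Greedy clustering identity threshold for redundancy removal.
    enrich_min_peptides / enrich_min_log2fc / enrich_max_p
        Pulldown enrichment rule: peptide count in every replicate, log2
        fold-change floor, and Welch-test p-value ceiling.
    """

    window_genes: int = 5
    short_cutoff_aa: int = 280
    helix_window_aa: int = 20
    helix_min_residues: int = 10
    helix_max_gaps: int = 1
    helix_max_gap_len: int = 2
    min_strands: int = 16
    cluster_identity: float = 0.90
    enrich_min_peptides: int = 3
    enrich_min_log2fc: float = 3.0
    enrich_max_p: float = 0.001

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be positive")
        if not 0 < self.cluster_identity <= 1:
            raise ValueError("cluster_identity must be in (0, 1]")


# ---------------------------------------------------------------------------
# gene table container
# ---------------------------------------------------------------------------

@dataclass
class GeneTable:
    """Genes indexed by (genome, contig) in rank order and by protein id.

    ``circular`` flags contigs whose gene order wraps around (rank distances
    then wrap too); contigs are linear by default.
    """

    records: list[GeneRecord] = field(default_factory=list)
    circular: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
        self._by_protein: dict[str, GeneRecord] = {}
        self._by_gene: dict[str, GeneRecord] = {}
        for rec in self.records:
            self._by_contig.setdefault((rec.genome_id, rec.contig_id), []).append(rec)
            if rec.protein_id is not None:
                self._by_protein[rec.protein_id] = rec
            if rec.gene_id in self._by_gene:
                raise ValueError(f"duplicate gene_id {rec.gene_id}")
            self._by_gene[rec.gene_id] = rec
        for key, recs in self._by_contig.items():
            recs.sort(key=lambda r: r.rank)
            if [r.rank for r in recs] != list(range(len(recs))):
                raise ValueError(f"ranks on contig {key} are not contiguous 0..n-1")

    def contig_genes(self, genome_id: str, contig_id: str) -> list[GeneRecord]:
        return self._by_contig.get((genome_id, contig_id), [])

    def gene_for_protein(self, protein_id: str) -> Optional[GeneRecord]:
        return self._by_protein.get(protein_id)

    def gene(self, gene_id: str) -> GeneRecord:
        return self._by_gene[gene_id]

    def contigs(self) -> list[tuple[str, str]]:
        return sorted(self._by_contig)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GENE_COLUMNS = ["genome_id", "contig_id", "gene_id", "start", "end", "strand", "protein_id"]


def _rank_and_build(raw: list[dict]) -> GeneTable:
    """Assign 0-based ranks by ascending start within each contig."""
    seen: set[str] = set()
    for row in raw:
        if row["gene_id"] in seen:
            raise ValueError(f"duplicate gene_id {row['gene_id']}")
        seen.add(row["gene_id"])
    by_contig: dict[tuple[str, str], list[dict]] = {}
    for row in raw:
        by_contig.setdefault((row["genome_id"], row["contig_id"]), []).append(row)
    records: list[GeneRecord] = []
    for key in sorted(by_contig):
        rows = by_contig[key]
        starts = [r["start"] for r in rows]
        if starts != sorted(starts):
            logger.info("gene table: contig %s/%s not sorted by start; sorting", *key)
        rows.sort(key=lambda r: (r["start"], r["end"], r["gene_id"]))
        for rank, row in enumerate(rows):
            records.append(
                GeneRecord(
                    gene_id=row["gene_id"],
                    genome_id=row["genome_id"],
                    contig_id=row["contig_id"],
                    start=row["start"],
                    end=row["end"],
                    strand=row["strand"],
                    rank=rank,
                    protein_id=row["protein_id"] or None,
                )
            )
    return GeneTable(records)


def read_gene_table(path: str | Path, dialect: str = "tsv") -> GeneTable:
    """Read a gene table (TSV or GFF3-like CDS features) and assign ranks.

    Ranks are (re)assigned by ascending start within each contig; unsorted
    input is sorted with a logged notice. Duplicate gene ids are a hard error.
    """
    path = Path(path)
    raw: list[dict] = []
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in _GENE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for row in df.itertuples(index=False):
            raw.append(
                {
                    "genome_id": row.genome_id,
                    "contig_id": row.contig_id,
                    "gene_id": row.gene_id,
                    "start": int(row.start),
                    "end": int(row.end),
                    "strand": row.strand,
                    "protein_id": row.protein_id or None,
                }
            )
    elif dialect in ("gff3", "gff3-like"):
        genome_id = path.stem
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise ValueError(f"{path}: malformed GFF3 line: {line[:80]}")
                seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != "CDS":
                    continue
                attr = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                gene_id = attr.get("ID") or attr.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}: CDS without ID attribute: {line[:80]}")
                raw.append(
                    {
                        "genome_id": attr.get("genome_id", genome_id),
                        "contig_id": seqid,
                        "gene_id": gene_id,
                        "start": int(start),
                        "end": int(end),
                        "strand": strand,
                        "protein_id": attr.get("protein_id") or None,
                    }
                )
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")
    return _rank_and_build(raw)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    rows = [
        {
            "genome_id": r.genome_id,
            "contig_id": r.contig_id,
            "gene_id": r.gene_id,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "protein_id": r.protein_id or "",
        }
        for key in sorted({(g.genome_id, g.contig_id) for g in table.records})
        for r in table.contig_genes(*key)
    ]
    pd.DataFrame(rows, columns=_GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read domain hits from plain TSV or HMMER ``--tblout`` per-target output.

    TSV needs columns protein_id, domain_acc and optionally score and
    meets_threshold; absent meets_threshold defaults to true (hit tables are
    usually pre-thresholded upstream, e.g. at the Pfam gathering threshold).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    body = [ln.rstrip("\n") for ln in lines if ln.strip() and not ln.startswith("#")]
    if not body:
        return []
    header = body[0].split("\t")
    hits: list[DomainHit] = []
    if "protein_id" in header and "domain_acc" in header:
        idx = {c: i for i, c in enumerate(header)}
        for ln in body[1:]:
            parts = ln.split("\t")
            acc = parts[idx["domain_acc"]]
            if not acc:
                raise ValueError(f"{path}: row with empty accession: {ln!r}")
            score = None
            if "score" in idx and parts[idx["score"]] not in ("", "NA"):
                score = float(parts[idx["score"]])
            meets = True
            if "meets_threshold" in idx and parts[idx["meets_threshold"]] != "":
                meets = parts[idx["meets_threshold"]].lower() in ("true", "1", "yes")
            hits.append(DomainHit(parts[idx["protein_id"]], acc, score, meets))
        return hits
    # HMMER --tblout: whitespace-separated, >= 18 fields; target name in
    # column 0, query accession in column 3 (fall back to query name), full
    # sequence score in column 5.
    for ln in body:
        parts = ln.split()
        if len(parts) < 18:
            raise ValueError(f"{path}: unrecognized hit-table line: {ln!r}")
        acc = parts[3] if parts[3] != "-" else parts[2]
        if not acc or acc == "-":
            raise ValueError(f"{path}: row with empty accession: {ln!r}")
        acc = acc.split(".")[0]  # strip Pfam accession version
        hits.append(DomainHit(parts[0], acc, float(parts[5]), True))
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "domain_acc": h.domain_acc,
            "score": "" if h.score is None else repr(h.score),
            "meets_threshold": str(h.meets_threshold).lower(),
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_acc", "score", "meets_threshold"]).to_csv(
        path, sep="\t", index=False
    )


def read_proteins(path: str | Path, fmt: str = "auto") -> dict[str, ProteinRecord]:
    """Read proteins from FASTA (id = protein_id) or TSV (protein_id, length[, taxon])."""
    path = Path(path)
    if fmt == "auto":
        fmt = "fasta" if path.suffix in (".fa", ".faa", ".fasta") else "tsv"
    proteins: dict[str, ProteinRecord] = {}
    if fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq)
            proteins[rec.id] = ProteinRecord(rec.id, len(seq), sequence=seq)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            proteins[row.protein_id] = ProteinRecord(
                row.protein_id,
                int(row.length),
                sequence=getattr(row, "sequence", "") or None,
                taxon=getattr(row, "taxon", "") or None,
            )
    return proteins


def write_proteins(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": p.protein_id,
            "length": p.length,
            "sequence": p.sequence or "",
            "taxon": p.taxon or "",
        }
        for p in proteins
    ]
    pd.DataFrame(rows, columns=["protein_id", "length", "sequence", "taxon"]).to_csv(
        path, sep="\t", index=False
    )


def read_ss(path: str | Path) -> dict[str, SecondaryStructure]:
    """Read FASTA-like 3-state secondary-structure strings."""
    out: dict[str, SecondaryStructure] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = SecondaryStructure(rec.id, str(rec.seq))
    return out


def write_ss(ss: Iterable[SecondaryStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ss:
            fh.write(f">{rec.protein_id}\n{rec.ss}\n")


def read_topology(path: str | Path) -> dict[str, TopologyAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {
        row.protein_id: TopologyAnnotation(row.protein_id, int(row.strand_count), row.localization)
        for row in df.itertuples(index=False)
    }


def write_topology(topo: Iterable[TopologyAnnotation], path: str | Path) -> None:
    rows = [
        {"protein_id": t.protein_id, "strand_count": t.strand_count, "localization": t.localization}
        for t in topo
    ]
    pd.DataFrame(rows, columns=["protein_id", "strand_count", "localization"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# classification table round-trip (OpxRecord lives in opxscreen.detect)
# ---------------------------------------------------------------------------

_CLS_COLUMNS = [
    "protein_id",
    "gene_id",
    "genome_id",
    "length",
    "context_ok",
    "pathway",
    "pcp2_context",
    "ambiguous_pathway",
    "short",
    "cterm_helix",
    "coupled",
    "partner_id",
    "category",
    "cluster_rep",
    "is_representative",
]


def _fmt_opt_bool(v: Optional[bool]) -> str:
    return "NA" if v is None else str(v).lower()


def _parse_opt_bool(s: str) -> Optional[bool]:
    return None if s == "NA" else s == "true"


def write_classification(records: Iterable, path: str | Path) -> None:
    """Write classified OPX records as TSV; lossless through read_classification."""
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "gene_id": r.gene_id,
                "genome_id": r.genome_id,
                "length": r.length,
                "context_ok": str(r.context_ok).lower(),
                "pathway": r.pathway,
                "pcp2_context": str(r.pcp2_context).lower(),
                "ambiguous_pathway": str(r.ambiguous_pathway).lower(),
                "short": str(r.short).lower(),
                "cterm_helix": _fmt_opt_bool(r.cterm_helix),
                "coupled": _fmt_opt_bool(r.coupled),
                "partner_id": r.partner_id if r.partner_id is not None else "NA",
                "category": r.category if r.category is not None else "NA",
                "cluster_rep": r.cluster_rep if r.cluster_rep is not None else "NA",
                "is_representative": str(r.is_representative).lower(),
            }
        )
    pd.DataFrame(rows, columns=_CLS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_classification(path: str | Path) -> list:
    from opxscreen.detect import OpxRecord

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            OpxRecord(
                protein_id=row.protein_id,
                gene_id=row.gene_id,
                genome_id=row.genome_id,
                length=int(row.length),
                context_ok=row.context_ok == "true",
                pathway=row.pathway,
                pcp2_context=row.pcp2_context == "true",
                ambiguous_pathway=row.ambiguous_pathway == "true",
                short=row.short == "true",
                cterm_helix=_parse_opt_bool(row.cterm_helix),
                coupled=_parse_opt_bool(row.coupled),
                partner_id=None if row.partner_id == "NA" else row.partner_id,
                category=None if row.category == "NA" else row.category,
                cluster_rep=None if row.cluster_rep == "NA" else row.cluster_rep,
                is_representative=row.is_representative == "true",
            )
        )
    return records
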