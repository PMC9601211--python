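"""Bundle of all per-screen input tables, with directory round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from opxscreen import genome_io
from opxscreen.genome_io import (
    DomainHit,
    GeneTable,
    ProteinRecord,
    SecondaryStructure,
    TopologyAnnotation,
)


@dataclass
class Dataset:
    genes: GeneTable
    proteins: dict[str, ProteinRecord]
    hits: list[DomainHit]
    ss: dict[str, SecondaryStructure] = field(default_factory=dict)
    topology: dict[str, TopologyAnnotation] = field(default_factory=dict)
    taxa: dict[str, str] = field(default_factory=dict)  # genome_id -> taxon


def write_dataset(ds: Dataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome_io.write_gene_table(ds.genes, out / "genes.tsv")
    genome_io.write_proteins(
        sorted(ds.proteins.values(), key=lambda p: p.protein_id), out / "proteins.tsv"
    )
    genome_io.write_domain_hits(ds.hits, out / "hits.tsv")
    genome_io.write_ss(
        sorted(ds.ss.values(), key=lambda s: s.protein_id), out / "ss.fasta"
    )
    genome_io.write_topology(
        sorted(ds.topology.values(), key=lambda t: t.protein_id), out / "topology.tsv"
    )
    pd.DataFrame(
        sorted(ds.taxa.items()), columns=["genome_id", "taxon"]
    ).to_csv(out / "taxa.tsv", sep="\t", index=False)


def read_dataset(in_dir: str | Path) -> Dataset:
    d = Path(in_dir)
    taxa = {}
    if (d / "taxa.tsv").exists():
        df = pd.read_csv(d / "taxa.tsv", sep="\t", dtype=str, keep_default_na=False)
        taxa = dict(zip(df["genome_id"], df["taxon"]))
    ss = genome_io.read_ss(d / "ss.fasta") if (d / "ss.fasta").exists() else {}
    topo = genome_io.read_topology(d / "topology.tsv") if (d / "topology.tsv").exists() else {}
    return Dataset(
        genes=genome_io.read_gene_table(d / "genes.tsv"),
        proteins=genome_io.read_proteins(d / "proteins.tsv", fmt="tsv"),
        hits=genome_io.read_domain_hits(d / "hits.tsv"),
        ss=ss,
        topology=topo,
        taxa=taxa,
    )
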