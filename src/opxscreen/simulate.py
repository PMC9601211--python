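"""Seeded generator of synthetic genomes with planted export systems.

The generator emulates, at toy scale, the statistical structure of a large
prokaryotic genome screen: contigs of ranked genes, a two-mode protein length
distribution straddling the 280-aa short-OPX cutoff, background domain noise
on a fraction of genes, and planted systems of six archetypes with ground
truth:

composite
    short OPX gene (Poly_export hit, no C-terminal helix) + polysaccharide
    context gene + verified OM β-barrel partner, all within the window.
wza_like
    OPX gene with a C-terminal helix and context, but no barrel partner.
decoy_opx_no_context
    OPX hit with no polysaccharide context in the window; must be excluded
    by the context filter.
decoy_barrel_alone
    a verified-quality barrel gene with no OPX anywhere near it.
decoy_barrel_few_strands
    OPX + context + a barrel partner predicted with only 14 strands —
    just below the 16-strand verification floor; must never yield coupling.
pcp_only_context
    OPX whose only context gene carries the Wzz copolymerase domain, so the
    pathway stays unassigned; carries a C-terminal helix.

Everything is driven by a single integer seed through one numpy Generator;
outputs are byte-identical across runs with the same arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from opxscreen.dataset import Dataset
from opxscreen.detect import ABC_ACCS, WZX_WZY_ACCS, WZZ_ACC, DomainConfig
from opxscreen.genome_io import (
    DomainHit,
    GeneRecord,
    GeneTable,
    ProteinRecord,
    SecondaryStructure,
    Thresholds,
    TopologyAnnotation,
)
from opxscreen.helix import scan_cterm_helix

AA = "ACDEFGHIKLMNPQRSTVWY"

ARCHETYPES = (
    "composite",
    "wza_like",
    "decoy_opx_no_context",
    "decoy_barrel_alone",
    "decoy_barrel_few_strands",
    "pcp_only_context",
)

#: irrelevant accessions used as background noise; disjoint from all screened accs
NOISE_ACCS = tuple(f"PF9{i:04d}" for i in range(1, 21))

#: context accessions that map to a definitive pathway
_DEFINITIVE_CONTEXT = tuple(sorted(WZX_WZY_ACCS | ABC_ACCS))

_TAXA = (
    "Proteobacteria", "Bacteroidetes", "Firmicutes", "Actinobacteria",
    "Cyanobacteria", "Planctomycetes", "Verrucomicrobia",
)


@dataclass(frozen=True)
class PlantSpec:
    archetype: str
    count: int = 1
    offsets: Optional[tuple[int, ...]] = None  # allowed partner/context offsets

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth labels for one planted system."""

    gene_id: str
    genome_id: str
    protein_id: str
    archetype: str
    partner_gene_id: Optional[str]
    pathway: str
    helix: bool
    length_class: str  # short | long
    pcp2: bool
    category: Optional[str]  # expected dichotomy category; None if filtered out
    survives_context: bool


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": tr.gene_id,
            "genome_id": tr.genome_id,
            "protein_id": tr.protein_id,
            "archetype": tr.archetype,
            "partner_gene_id": tr.partner_gene_id or "NA",
            "pathway": tr.pathway,
            "helix": str(tr.helix).lower(),
            "length_class": tr.length_class,
            "pcp2": str(tr.pcp2).lower(),
            "category": tr.category or "NA",
            "survives_context": str(tr.survives_context).lower(),
        }
        for tr in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# secondary-structure construction
# ---------------------------------------------------------------------------

def generate_ss(
    length: int,
    with_cterm_helix: bool,
    seed: int | np.random.Generator,
    thresholds: Thresholds = Thresholds(),
) -> SecondaryStructure:
    """A random SS string that passes the C-terminal helix rule iff requested.

    The returned string is verified against the scanner before being
    returned; construction and verification cannot drift apart.
    """
    t = thresholds
    if length < t.helix_window_aa:
        raise ValueError(f"length {length} < helix window {t.helix_window_aa}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = t.helix_window_aa
    window = _make_window(rng, w, with_cterm_helix, t)
    # the prefix is unconstrained: the rule sees only the final window
    prefix = "".join(rng.choice(list("HEC"), size=length - w))
    ss = SecondaryStructure("synthetic", prefix + window)
    call = scan_cterm_helix(ss, t)
    assert call.has_cterm_helix == with_cterm_helix, "SS construction violated the helix rule"
    return ss


def _make_window(rng: np.random.Generator, w: int, helix: bool, t: Thresholds) -> str:
    nonh = lambda n: "".join(rng.choice(["C", "E"], size=n))
    if helix:
        h_total = int(rng.integers(t.helix_min_residues, min(w, t.helix_min_residues + 7)))
        if rng.random() < 0.5 and h_total + t.helix_max_gap_len <= w and h_total >= 2:
            gap = int(rng.integers(1, t.helix_max_gap_len + 1))
            h1 = int(rng.integers(1, h_total))
            seg = "H" * h1 + nonh(gap) + "H" * (h_total - h1)
        else:
            seg = "H" * h_total
        pad = w - len(seg)
        left = int(rng.integers(0, pad + 1))
        return nonh(left) + seg + nonh(pad - left)
    # failing window: H runs of <= 3 separated by non-H gaps of >= 3, so no
    # segment can join runs (gaps exceed helix_max_gap_len) or reach 10 H
    out: list[str] = []
    while len(out) < w:
        out.extend(nonh(int(rng.integers(3, 7))))
        out.extend("H" * int(rng.integers(0, 4)))
    return "".join(out[:w])


# ---------------------------------------------------------------------------
# sequence families for clustering tests
# ---------------------------------------------------------------------------

def generate_family(
    parent_length: int,
    n_members: int,
    substitution_rate: float,
    seed: int | np.random.Generator,
    prefix: str = "fam",
) -> list[ProteinRecord]:
    """I.i.d. point-mutated copies of a random parent sequence.

    The first record is the unmutated parent; each further member substitutes
    every position independently with probability ``substitution_rate`` (to a
    different residue), so expected identity to the parent is 1 - rate.
    """
    if not 0 <= substitution_rate < 1:
        raise ValueError("substitution_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = np.array(list(AA))
    parent = rng.choice(aa, size=parent_length)
    records = [ProteinRecord(f"{prefix}_m000", parent_length, sequence="".join(parent))]
    for i in range(1, n_members):
        seq = parent.copy()
        mut = rng.random(parent_length) < substitution_rate
        for pos in np.nonzero(mut)[0]:
            choices = [c for c in AA if c != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        records.append(ProteinRecord(f"{prefix}_m{i:03d}", parent_length, sequence="".join(seq)))
    return records


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AA))[rng.integers(0, len(AA), size=n)])


@dataclass
class _GenomeBuilder:
    genome_id: str
    contig_id: str
    rng: np.random.Generator
    thresholds: Thresholds
    config: DomainConfig
    n_genes: int
    noise_fraction: float
    genes: list[GeneRecord] = field(default_factory=list)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    hits: list[DomainHit] = field(default_factory=list)
    ss: dict[str, SecondaryStructure] = field(default_factory=dict)
    topology: dict[str, TopologyAnnotation] = field(default_factory=dict)
    taxon: str = ""

    def build_background(self) -> None:
        """Lay down all genes with background lengths and noise domains."""
        pos = 1
        for i in range(self.n_genes):
            gid = f"{self.genome_id}_g{i:03d}"
            pid = f"{self.genome_id}_p{i:03d}"
            if self.rng.random() < 0.5:
                length = int(np.clip(self.rng.normal(200, 30), 138, 279))
            else:
                length = int(np.clip(self.rng.normal(575, 150), 300, 1728))
            start = pos + int(self.rng.integers(20, 200))
            end = start + 3 * length + 2
            pos = end
            strand = "+" if self.rng.random() < 0.5 else "-"
            self.genes.append(
                GeneRecord(gid, self.genome_id, self.contig_id, start, end, strand, i, pid)
            )
            self.proteins[pid] = ProteinRecord(pid, length, taxon=self.taxon)
            if self.rng.random() < self.noise_fraction:
                acc = NOISE_ACCS[int(self.rng.integers(len(NOISE_ACCS)))]
                self.hits.append(DomainHit(pid, acc, float(self.rng.uniform(10, 40)), True))

    # -- helpers that overwrite a background gene's protein ----------------

    def _set_protein(self, idx: int, length: int, with_seq: bool = False) -> str:
        pid = self.genes[idx].protein_id
        assert pid is not None
        seq = _random_seq(self.rng, length) if with_seq else None
        self.proteins[pid] = ProteinRecord(pid, length, sequence=seq, taxon=self.taxon)
        return pid

    def _add_opx(self, idx: int, helix: bool) -> str:
        t = self.thresholds
        length = int(self.rng.integers(150, min(271, t.short_cutoff_aa - 9)))
        pid = self._set_protein(idx, length, with_seq=True)
        self.hits.append(
            DomainHit(pid, self.config.opx_acc, float(self.rng.uniform(30, 80)), True)
        )
        self.ss[pid] = SecondaryStructure(
            pid, generate_ss(length, helix, self.rng, t).ss
        )
        return pid

    def _add_context(self, idx: int, acc: str, pcp2: bool = False) -> str:
        pid = self.genes[idx].protein_id
        assert pid is not None
        self.hits.append(DomainHit(pid, acc, float(self.rng.uniform(25, 70)), True))
        if pcp2:
            self.hits.append(
                DomainHit(pid, self.config.tyrosine_kinase_acc,
                          float(self.rng.uniform(25, 70)), True)
            )
        return pid

    def _add_barrel(self, idx: int, strand_count: int, localization: str = "OM") -> str:
        pid = self.genes[idx].protein_id
        assert pid is not None
        acc = sorted(self.config.barrel_accs)[int(self.rng.integers(len(self.config.barrel_accs)))]
        self.hits.append(DomainHit(pid, acc, float(self.rng.uniform(25, 70)), True))
        self.topology[pid] = TopologyAnnotation(pid, strand_count, localization)
        return pid

    def _pick_offsets(self, spec: PlantSpec, n: int) -> list[int]:
        w = self.thresholds.window_genes
        pool = spec.offsets or tuple(o for o in range(-w, w + 1) if o != 0)
        picked = self.rng.choice(len(pool), size=n, replace=False)
        return [pool[int(i)] for i in picked]

    def plant(self, spec: PlantSpec, focal: int) -> TruthRecord:
        gid = self.genes[focal].gene_id
        arch = spec.archetype
        if arch == "composite":
            o_ctx, o_bar = self._pick_offsets(spec, 2)
            pid = self._add_opx(focal, helix=False)
            acc = _DEFINITIVE_CONTEXT[int(self.rng.integers(len(_DEFINITIVE_CONTEXT)))]
            self._add_context(focal + o_ctx, acc)
            partner_gene = self.genes[focal + o_bar].gene_id
            strands = int(self.rng.choice([16, 18, 20, 22]))
            self._add_barrel(focal + o_bar, strands)
            pathway = "wzx_wzy" if acc in WZX_WZY_ACCS else "abc"
            return TruthRecord(gid, self.genome_id, pid, arch, partner_gene, pathway,
                               False, "short", False, "short_coupled_nohelix", True)
        if arch == "wza_like":
            (o_ctx,) = self._pick_offsets(spec, 1)
            pid = self._add_opx(focal, helix=True)
            acc = _DEFINITIVE_CONTEXT[int(self.rng.integers(len(_DEFINITIVE_CONTEXT)))]
            self._add_context(focal + o_ctx, acc)
            pathway = "wzx_wzy" if acc in WZX_WZY_ACCS else "abc"
            return TruthRecord(gid, self.genome_id, pid, arch, None, pathway,
                               True, "short", False, "short_uncoupled_helix", True)
        if arch == "decoy_opx_no_context":
            pid = self._add_opx(focal, helix=False)
            return TruthRecord(gid, self.genome_id, pid, arch, None, "none",
                               False, "short", False, None, False)
        if arch == "decoy_barrel_alone":
            self._add_barrel(focal, int(self.rng.choice([16, 18, 20])))
            pid = self.genes[focal].protein_id
            assert pid is not None
            return TruthRecord(gid, self.genome_id, pid, arch, None, "none",
                               False, "short", False, None, False)
        if arch == "decoy_barrel_few_strands":
            o_ctx, o_bar = self._pick_offsets(spec, 2)
            pid = self._add_opx(focal, helix=False)
            acc = _DEFINITIVE_CONTEXT[int(self.rng.integers(len(_DEFINITIVE_CONTEXT)))]
            self._add_context(focal + o_ctx, acc)
            self._add_barrel(focal + o_bar, 14)  # just below the 16-strand floor
            pathway = "wzx_wzy" if acc in WZX_WZY_ACCS else "abc"
            return TruthRecord(gid, self.genome_id, pid, arch, None, pathway,
                               False, "short", False, "short_uncoupled_nohelix", True)
        if arch == "pcp_only_context":
            (o_ctx,) = self._pick_offsets(spec, 1)
            pid = self._add_opx(focal, helix=True)
            pcp2 = bool(self.rng.random() < 0.5)
            self._add_context(focal + o_ctx, WZZ_ACC, pcp2=pcp2)
            return TruthRecord(gid, self.genome_id, pid, arch, None, "pcp_unassigned",
                               True, "short", pcp2, "short_uncoupled_helix", True)
        raise ValueError(f"unknown archetype {arch!r}")


def generate(
    n_genomes: int,
    genes_per_contig: int,
    plant_specs: "list[PlantSpec] | Callable[[int], list[PlantSpec]]",
    seed: int,
    thresholds: Thresholds = Thresholds(),
    config: DomainConfig = DomainConfig(),
    noise_fraction: float = 0.10,
) -> tuple[Dataset, list[TruthRecord]]:
    """Generate ``n_genomes`` single-contig genomes with the requested plants.

    ``plant_specs`` is either one list applied to every genome or a callable
    mapping the genome index to a list (e.g. to cycle decoy types across
    genomes). Plants occupy focal positions spaced at least 2*window+1 genes
    apart, so no plant's partner or context gene can fall into another
    plant's neighborhood; requesting more plants than a contig holds is an
    error. Deterministic given the seed.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    rng = np.random.default_rng(seed)
    w = thresholds.window_genes
    stride = 2 * w + 1
    slots = list(range(w, genes_per_contig - w, stride))
    specs_for = plant_specs if callable(plant_specs) else (lambda g: plant_specs)

    all_genes: list[GeneRecord] = []
    proteins: dict[str, ProteinRecord] = {}
    hits: list[DomainHit] = []
    ss: dict[str, SecondaryStructure] = {}
    topology: dict[str, TopologyAnnotation] = {}
    taxa: dict[str, str] = {}
    truth: list[TruthRecord] = []

    for g in range(n_genomes):
        genome_id = f"G{g:04d}"
        taxon = _TAXA[g % len(_TAXA)]
        b = _GenomeBuilder(
            genome_id=genome_id,
            contig_id=f"{genome_id}_c1",
            rng=rng,
            thresholds=thresholds,
            config=config,
            n_genes=genes_per_contig,
            noise_fraction=noise_fraction,
            taxon=taxon,
        )
        b.build_background()
        specs = specs_for(g)
        n_plants = sum(s.count for s in specs)
        if n_plants > len(slots):
            raise ValueError(
                f"{n_plants} plants exceed contig capacity of {len(slots)} "
                f"non-overlapping slots ({genes_per_contig} genes, window {w})"
            )
        order = rng.permutation(len(slots))
        slot_iter = iter(order)
        for spec in specs:
            for _ in range(spec.count):
                focal = slots[int(next(slot_iter))]
                truth.append(b.plant(spec, focal))
        all_genes.extend(b.genes)
        proteins.update(b.proteins)
        hits.extend(b.hits)
        ss.update(b.ss)
        topology.update(b.topology)
        taxa[genome_id] = taxon

    ds = Dataset(
        genes=GeneTable(all_genes),
        proteins=proteins,
        hits=hits,
        ss=ss,
        topology=topology,
        taxa=taxa,
    )
    return ds, truth


def validation_plant_specs(genome_index: int) -> list[PlantSpec]:
    """The standard validation mix for one genome.

    Every genome gets one composite and one wza_like plant; the remaining
    archetypes (three decoy types and the PCP-only context case) cycle
    across genomes so each is exercised many times over a multi-genome run
    without exceeding per-contig slot capacity.
    """
    extras = (
        "decoy_opx_no_context",
        "decoy_barrel_alone",
        "decoy_barrel_few_strands",
        "pcp_only_context",
    )
    return [
        PlantSpec("composite", 1),
        PlantSpec("wza_like", 1),
        PlantSpec(extras[genome_index % len(extras)], 1),
    ]
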