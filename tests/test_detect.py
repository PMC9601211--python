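"""OPX candidate detection, neighborhoods, context filter, pathway assignment."""

import numpy as np
import pytest

from opxscreen.detect import (
    CONTEXT_ACCS,
    DomainConfig,
    HitIndex,
    Neighborhood,
    assign_pathway,
    context_filter,
    extract_neighborhood,
    find_opx_candidates,
)
from opxscreen.genome_io import DomainHit, GeneTable, ProteinRecord

from conftest import make_contig
from oracles import pathway_oracle

CONFIG = DomainConfig()


class TestFindCandidates:
    def _proteins(self, table):
        return {
            g.protein_id: ProteinRecord(g.protein_id, 200)
            for g in table.records
        }

    def test_basic_detection_threshold_and_dedup(self, contig12):
        prots = self._proteins(contig12)
        hits = [
            DomainHit("P1", "PF02563", 50.0, True),
            DomainHit("P2", "PF02563", 50.0, False),   # below threshold: excluded
            DomainHit("P3", "PF02563", 50.0, True),
            DomainHit("P3", "PF02563", 60.0, True),    # second hit: still one candidate
            DomainHit("P4", "PF00005", 50.0, True),    # wrong domain
        ]
        cands = find_opx_candidates(hits, contig12, prots)
        assert [g.protein_id for g, _ in cands] == ["P1", "P3"]

    def test_unknown_protein_skipped(self, contig12):
        prots = self._proteins(contig12)
        hits = [DomainHit("ghost", "PF02563", 50.0, True)]
        assert find_opx_candidates(hits, contig12, prots) == []


class TestNeighborhood:
    def test_single_gene_contig_empty(self):
        table = make_contig(1)
        nb = extract_neighborhood(table.contig_genes("G0", "c1")[0], table, 5)
        assert nb.neighbors == []

    def test_rank0_truncated_upstream(self, contig12):
        nb = extract_neighborhood(contig12.contig_genes("G0", "c1")[0], contig12, 5)
        assert [off for _, off in nb.neighbors] == [1, 2, 3, 4, 5]

    def test_rank7_of_10(self):
        table = make_contig(10)
        nb = extract_neighborhood(table.contig_genes("G0", "c1")[7], table, 5)
        assert [off for _, off in nb.neighbors] == [-5, -4, -3, -2, -1, 1, 2]

    def test_focal_excluded_and_size_bound(self, contig12):
        for gene in contig12.records:
            nb = extract_neighborhood(gene, contig12, 5)
            assert len(nb.neighbors) <= 10
            assert gene.gene_id not in {g.gene_id for g, _ in nb.neighbors}

    def test_circular_contig_wraps(self):
        table = make_contig(8)
        table.circular.add(("G0", "c1"))
        nb = extract_neighborhood(table.contig_genes("G0", "c1")[0], table, 2)
        got = {off: g.rank for g, off in nb.neighbors}
        assert got == {-2: 6, -1: 7, 1: 1, 2: 2}

    def test_circular_small_contig_never_duplicates(self):
        table = make_contig(4)
        table.circular.add(("G0", "c1"))
        nb = extract_neighborhood(table.contig_genes("G0", "c1")[0], table, 5)
        ranks = [g.rank for g, _ in nb.neighbors]
        assert sorted(ranks) == [1, 2, 3]  # every other gene exactly once


def nb_from(offset_accs, k=5):
    """Build a Neighborhood + HitIndex from {offset: accession set}."""
    table = make_contig(2 * k + 1)
    focal = table.contig_genes("G0", "c1")[k]
    nb = extract_neighborhood(focal, table, k)
    hits = [
        DomainHit(f"P{k + off}", acc, 10.0, True)
        for off, accs in offset_accs.items()
        for acc in accs
    ]
    return nb, HitIndex(hits)


class TestContextFilter:
    def test_neighbor_with_wzy_c(self):
        nb, idx = nb_from({3: {"PF04932"}})
        assert context_filter(nb, idx) is True

    def test_only_irrelevant_accessions(self):
        nb, idx = nb_from({1: {"PF99999"}, -2: {"PF12345"}})
        assert context_filter(nb, idx) is False

    def test_empty_neighborhood(self):
        table = make_contig(1)
        nb = extract_neighborhood(table.contig_genes("G0", "c1")[0], table, 5)
        assert context_filter(nb, HitIndex([])) is False

    def test_focal_domains_do_not_count(self):
        table = make_contig(11)
        focal = table.contig_genes("G0", "c1")[5]
        nb = extract_neighborhood(focal, table, 5)
        idx = HitIndex([DomainHit("P5", "PF04932", 10.0, True)])
        assert context_filter(nb, idx) is False

    def test_enlarging_k_is_monotone(self):
        table = make_contig(21)
        focal = table.contig_genes("G0", "c1")[10]
        idx = HitIndex([DomainHit("P14", "PF02706", 10.0, True)])
        results = [
            context_filter(extract_neighborhood(focal, table, k), idx)
            for k in range(1, 11)
        ]
        assert results == sorted(results)  # once true, stays true


class TestAssignPathway:
    @pytest.mark.parametrize(
        "offset_accs,expected",
        [
            ({-1: {"PF02706"}, 3: {"PF04932"}}, ("pcp_unassigned", False, False)),
            ({2: {"PF00005"}}, ("abc", False, False)),
            ({1: {"PF04932"}}, ("wzx_wzy", False, False)),
            ({2: {"PF01943"}}, ("wzx_wzy", False, False)),   # flippase family
            ({-3: {"PF02706", "PF13614"}}, ("pcp_unassigned", True, False)),  # PCP-2
            # tie at |offset| 2: one definitive side wins over a Wzz side
            ({-2: {"PF02706"}, 2: {"PF00005"}}, ("abc", False, False)),
            # tie with conflicting definitive domains: ambiguous
            ({-2: {"PF04932"}, 2: {"PF00005"}}, ("none", False, True)),
            ({}, ("none", False, False)),
        ],
    )
    def test_examples(self, offset_accs, expected):
        nb, idx = nb_from(offset_accs)
        assert assign_pathway(nb, idx, CONFIG) == expected

    def test_one_gene_with_conflicting_domains_is_ambiguous(self):
        nb, idx = nb_from({1: {"PF04932", "PF00005"}})
        assert assign_pathway(nb, idx, CONFIG) == ("none", False, True)

    def test_kinase_without_wzz_is_not_pcp2(self):
        nb, idx = nb_from({1: {"PF04932"}, 2: {"PF13614"}})
        assert assign_pathway(nb, idx, CONFIG) == ("wzx_wzy", False, False)

    def test_fuzzed_neighborhoods_match_brute_force(self):
        """Random accession layouts agree with the enumeration oracle."""
        rng = np.random.default_rng(42)
        pool = sorted(CONTEXT_ACCS) + ["PF13614", "PF99999", "PF88888"]
        for _ in range(2000):
            offsets = rng.choice(
                [o for o in range(-5, 6) if o != 0],
                size=rng.integers(0, 8), replace=False,
            )
            layout = {
                int(off): {pool[i] for i in rng.integers(0, len(pool), rng.integers(1, 4))}
                for off in offsets
            }
            nb, idx = nb_from(layout)
            expected = pathway_oracle(
                [(off, accs) for off, accs in layout.items()]
            )
            assert assign_pathway(nb, idx, CONFIG) == expected, layout
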