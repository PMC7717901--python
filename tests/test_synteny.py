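import pandas as pd
import pytest

from myelotrace import synteny
from myelotrace.synteny import (Anchor, SyntenyBlock, SyntenyError,
                                compare_locus, comparisons_to_frame,
                                extract_block, read_gene_orders_tsv,
                                render_synteny_map, select_anchors)
from myelotrace.synthetic import default_reference_order, order_to_frame


class TestExtractBlock:
    def test_paper_layout_flank_three(self, human_orders):
        block = extract_block(human_orders, "CSF1R", 3)
        by_side = {(a.side, a.gene) for a in block.candidates}
        assert ("upstream", "HMGBX3") in by_side
        assert ("downstream", "PDGFRB") in by_side
        assert ("downstream", "CDX1") in by_side

    def test_chromosome_end_gives_one_sided_block(self):
        order = {"c1": [("F", "+"), ("A", "+"), ("B", "+")]}
        block = extract_block(order, "F", 5)
        assert all(a.side == "downstream" for a in block.candidates)
        assert [a.gene for a in block.candidates] == ["A", "B"]

    def test_zero_flank_rejected(self, human_orders):
        with pytest.raises(SyntenyError, match="flank"):
            extract_block(human_orders, "CSF1R", 0)

    def test_absent_or_duplicated_focal_rejected(self, human_orders):
        with pytest.raises(SyntenyError, match="absent"):
            extract_block(human_orders, "NOPE", 3)
        dup = {"c1": [("X", "+"), ("X", "+")]}
        with pytest.raises(SyntenyError, match="duplicated"):
            extract_block(dup, "X", 1)


class TestSelectAnchors:
    REF = {"c1": [(g, "+") for g in "ABCFDEG"]}  # F focal

    def queries(self, *gene_lists):
        return {f"sp{i}": {"c1": [(g, "+") for g in genes]}
                for i, genes in enumerate(gene_lists)}

    def test_nearest_candidates_chosen_with_tie_break(self):
        block = extract_block(self.REF, "F", 3)
        queries = self.queries("ABCFDEG", "ABCFDEG")
        chosen = select_anchors(block, queries, k=3)
        # distance 1: D (downstream) before C (upstream), then distance 2: E
        assert [a.gene for a in chosen.anchors] == ["D", "C", "E"]
        assert not chosen.relaxed

    def test_candidate_missing_in_one_species_excluded(self):
        block = extract_block(self.REF, "F", 3)
        queries = self.queries("ABCFDEG", "ABCFEG")  # D missing in sp1
        chosen = select_anchors(block, queries, k=3)
        assert "D" not in [a.gene for a in chosen.anchors]
        assert [a.gene for a in chosen.anchors] == ["C", "E", "B"]

    def test_relaxation_excludes_gene_below_fraction(self):
        block = extract_block(self.REF, "F", 3)
        # D absent in 3 of 10 species (70% presence < default 80%);
        # C, E and G drop below universality but stay above the cutoff
        gene_sets = ["ABFE", "ABCFG", "ABFEG"] + ["ABCFDEG"] * 7
        chosen = select_anchors(block, self.queries(*gene_sets), k=4)
        assert chosen.relaxed
        names = [a.gene for a in chosen.anchors]
        assert "D" not in names
        assert names == ["C", "E", "B", "G"]

    def test_no_candidate_anywhere_rejected(self):
        block = extract_block(self.REF, "F", 3)
        queries = self.queries("XYZ", "XYZ")
        with pytest.raises(SyntenyError, match="no candidate"):
            select_anchors(block, queries, k=3)

    def test_anchor_count_bounds(self):
        block = extract_block(self.REF, "F", 3)
        with pytest.raises(SyntenyError, match="between 3 and 5"):
            select_anchors(block, self.queries("ABCFDEG"), k=2)


class TestCompareLocus:
    def test_identity_query_fully_retained(self, human_orders, csf1r_block):
        comp = compare_locus(csf1r_block, human_orders, "human")
        assert comp.focal_status == "retained_in_block"
        assert set(comp.anchor_status.values()) == {"retained_in_block"}
        assert comp.orientation == "same"

    def test_focal_lost_while_anchors_survive(self, human_orders,
                                              csf1r_block):
        query = {"c1": [("HMGBX3", "+"), ("PDGFRB", "+"), ("CDX1", "+")]}
        comp = compare_locus(csf1r_block, query)
        assert comp.focal_status == "lost"

    def test_translocated_to_anchor_free_chromosome(self, csf1r_block):
        query = {"c1": [("HMGBX3", "+"), ("PDGFRB", "+"), ("CDX1", "+")],
                 "c2": [("X1", "+"), ("CSF1R", "+")]}
        comp = compare_locus(csf1r_block, query)
        assert comp.focal_status == "translocated_other_chromosome"

    def test_relocated_beyond_window_on_same_chromosome(self, csf1r_block):
        filler = [(f"Z{i}", "+") for i in range(15)]
        query = {"c1": [("HMGBX3", "+"), ("PDGFRB", "+"), ("CDX1", "+")]
                 + filler + [("CSF1R", "+")]}
        comp = compare_locus(csf1r_block, query, window=10)
        assert comp.focal_status == "relocated_same_chromosome"

    def test_duplicated_query_symbols_rejected(self, csf1r_block):
        query = {"c1": [("CSF1R", "+"), ("CSF1R", "+")]}
        with pytest.raises(SyntenyError, match="duplicated"):
            compare_locus(csf1r_block, query)

    def test_invariant_under_chromosome_renaming(self, human_orders,
                                                 csf1r_block):
        renamed = {f"contig_{i}": genes
                   for i, (_, genes) in enumerate(human_orders.items())}
        a = compare_locus(csf1r_block, human_orders)
        b = compare_locus(csf1r_block, renamed)
        assert (a.focal_status, a.anchor_status, a.orientation) == \
            (b.focal_status, b.anchor_status, b.orientation)

    def test_block_lost_is_monotone_in_gene_content(self, csf1r_block):
        bare = {"c1": [("X1", "+"), ("X2", "+")]}
        assert compare_locus(csf1r_block, bare).focal_status == "block_lost"
        # adding genes can remove block_lost but never create it
        richer = {"c1": bare["c1"] + [("PDGFRB", "+")]}
        assert compare_locus(csf1r_block, richer).focal_status != "block_lost"
        not_lost = {"c1": [("CSF1R", "+")]}
        grown = {"c1": not_lost["c1"] + [("X9", "+")]}
        assert compare_locus(csf1r_block, grown).focal_status != "block_lost"


class TestNarratedJawedFishCases:
    """The four narrated jawed-fish loci classified from fixture orders."""

    def test_coelacanth_csf1r_retained(self, fig2b_orders, csf1r_block):
        comp = compare_locus(csf1r_block, fig2b_orders["coelacanth"],
                             "coelacanth")
        assert comp.focal_status == "retained_in_block"
        assert comp.orientation == "same"

    def test_whale_shark_csf1r_block_lost(self, fig2b_orders, csf1r_block):
        comp = compare_locus(csf1r_block, fig2b_orders["whale_shark"],
                             "whale_shark")
        assert comp.focal_status == "block_lost"

    def test_coelacanth_il34_anchors_relocated(self, fig2b_orders,
                                               il34_block):
        comp = compare_locus(il34_block, fig2b_orders["coelacanth"],
                             "coelacanth")
        assert comp.focal_status == "retained_in_block"
        assert comp.anchor_status["MTSS1L"] == "relocated_same_chromosome"
        assert comp.anchor_status["VAC14"] == "relocated_same_chromosome"
        assert comp.anchor_status["COG4"] == "retained_in_block"

    def test_ghost_shark_inverted_orientation(self, fig2b_orders,
                                              csf1r_block):
        comp = compare_locus(csf1r_block, fig2b_orders["ghost_shark"],
                             "ghost_shark")
        assert comp.orientation == "inverted"
        assert comp.focal_status == "lost"
        assert comp.anchor_status["HMGBX3"] == "lost"


def test_round_trip_through_gene_order_tsv(tmp_path, csf1r_block):
    ref = default_reference_order()
    frame = pd.concat([order_to_frame(ref, "human"),
                       order_to_frame(ref, "twin")], ignore_index=True)
    path = tmp_path / "orders.tsv"
    frame.to_csv(path, sep="\t", index=False)
    orders = read_gene_orders_tsv(path)
    assert orders["human"] == ref and orders["twin"] == ref
    comp = compare_locus(csf1r_block, orders["twin"], "twin")
    assert comp.focal_status == "retained_in_block"


def test_map_rendering(tmp_path, fig2b_orders, csf1r_block):
    comps = [compare_locus(csf1r_block, order, sp)
             for sp, order in fig2b_orders.items()]
    frame = comparisons_to_frame(comps)
    assert set(frame["role"]) == {"focal", "anchor"}
    out = tmp_path / "map.svg"
    render_synteny_map(comps, out)
    assert out.stat().st_size > 0
    with pytest.raises(SyntenyError):
        render_synteny_map([], tmp_path / "empty.svg")


def test_gff3_gene_order(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=HMGBX3\n"
        "c1\tsrc\tgene\t300\t400\t.\t+\t.\tID=g2;Name=CSF1R\n"
        "c1\tsrc\tgene\t500\t600\t.\t-\t.\tID=g3;Name=PDGFRB\n")
    order = synteny.read_gff3_gene_order(gff)
    assert order == {"c1": [("HMGBX3", "+"), ("CSF1R", "+"),
                            ("PDGFRB", "-")]}
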