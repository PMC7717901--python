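from __future__ import annotations

import pytest
from hypothesis import settings

from myelotrace.synteny import Anchor, SyntenyBlock

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def human_orders():
    """Minimal human reference laid out like the CSF gene neighbourhoods."""
    return {
        "chr5": [("HMGBX3", "+"), ("CSF1R", "+"), ("PDGFRB", "+"),
                 ("CDX1", "+")],
        "chr16": [("FUK", "+"), ("COG4", "+"), ("SF3B3", "+"), ("IL34", "+"),
                  ("MTSS1L", "+"), ("VAC14", "+")],
    }


@pytest.fixture
def csf1r_block():
    """CSF1R with its three narrated flanking anchors."""
    return SyntenyBlock("human", "CSF1R", 3,
                        [Anchor("PDGFRB", "downstream", 1),
                         Anchor("CDX1", "downstream", 2),
                         Anchor("HMGBX3", "upstream", 1)])


@pytest.fixture
def il34_block():
    """IL34 with its five narrated flanking anchors."""
    return SyntenyBlock("human", "IL34", 3,
                        [Anchor("SF3B3", "upstream", 1),
                         Anchor("MTSS1L", "downstream", 1),
                         Anchor("COG4", "upstream", 2),
                         Anchor("VAC14", "downstream", 2),
                         Anchor("FUK", "upstream", 3)])


def _filler(prefix: str, n: int, start: int = 1):
    return [(f"{prefix}{i:02d}", "+") for i in range(start, start + n)]


@pytest.fixture
def fig2b_orders():
    """Query gene orders transcribed from the narrated jawed-fish loci.

    Synthetic stand-ins for the real assemblies: each species' order
    realises the narrated arrangement (retention, whole-block loss,
    anchors relocated on-chromosome, inverted orientation) with filler
    genes providing chromosomal context.
    """
    return {
        # CSF1R adjacent to HMGBX3, PDGFRB, CDX1, as in the human block;
        # IL34 directly downstream of COG4 and SF3B3 while MTSS1L and
        # VAC14 sit far away on the same chromosome.
        "coelacanth": {
            "scaf1": _filler("CA", 3) + [("HMGBX3", "+"), ("CSF1R", "+"),
                                         ("PDGFRB", "+"), ("CDX1", "+")]
            + _filler("CB", 3),
            "scaf2": [("FUK", "+"), ("COG4", "+"), ("SF3B3", "+"),
                      ("IL34", "+")] + _filler("CC", 14)
            + [("MTSS1L", "+"), ("VAC14", "+")],
        },
        # CSF1R and every flanking gene absent: the section is lost.
        "whale_shark": {
            "scaf1": _filler("WA", 6),
            "scaf2": [("FUK", "+"), ("COG4", "+"), ("IL34", "+"),
                      ("MTSS1L", "+")] + _filler("WB", 3),
        },
        # PDGFRB and CDX1 co-localise in reversed order (inverted
        # orientation); HMGBX3 and CSF1R are lost.
        "ghost_shark": {
            "scaf1": [("CDX1", "-"), ("PDGFRB", "-")] + _filler("GA", 5),
            "scaf2": [("FUK", "+"), ("COG4", "+"), ("SF3B3", "+"),
                      ("MTSS1L", "+"), ("VAC14", "+")] + _filler("GB", 3),
        },
    }
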