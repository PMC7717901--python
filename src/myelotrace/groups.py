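"""Chordate lineage groups, emergence times, and shared vocabularies.

The ten lineage groups span the phylum Chordata from the jawed/jawless
fishes to placental mammals.  Each group carries the emergence time of its
earliest known ancestor in million years ago (MYA); these constants anchor
every timescale reconstruction and order the rows of presence/absence
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True, order=True)
class LineageGroup:
    """A named chordate group with the emergence time of its earliest ancestor.

    Parameters
    ----------
    name
        Group identifier, one of :data:`GROUP_NAMES`.
    emergence_mya
        Emergence time in million years ago; must be positive.
    """

    name: str
    emergence_mya: float

    def __post_init__(self) -> None:
        if self.emergence_mya <= 0:
            raise ValueError(f"emergence_mya must be > 0, got {self.emergence_mya}")


#: Emergence time (MYA) of the earliest known ancestor of each group.
EMERGENCE_MYA: dict[str, float] = {
    "jawed_fish": 410.0,
    "jawless_fish": 360.0,
    "amphibia": 350.0,
    "squamata": 330.0,
    "crocodilia": 240.0,
    "testudines": 210.0,
    "monotremata": 110.0,
    "aves": 70.0,
    "marsupialia": 65.0,
    "placentalia": 62.5,
}

GROUP_NAMES: tuple[str, ...] = tuple(EMERGENCE_MYA)

#: Default group objects, oldest first.
DEFAULT_GROUPS: tuple[LineageGroup, ...] = tuple(
    LineageGroup(name, mya)
    for name, mya in sorted(EMERGENCE_MYA.items(), key=lambda kv: -kv[1])
)

#: Myeloid cell types scored in the blood-count meta-analysis.  Azurophils
#: (a reptile granulocyte with neutrophil and monocyte features) are treated
#: as a distinct cell type.
MYELOID_CELL_TYPES: tuple[str, ...] = (
    "neutrophil",
    "heterophil",
    "azurophil",
    "eosinophil",
    "basophil",
    "monocyte",
)

#: Full closed vocabulary for blood-count records; lymphoid counts are
#: carried through parsing but excluded by the meta-analysis filter.
CELL_TYPES: tuple[str, ...] = MYELOID_CELL_TYPES + ("lymphoid_other",)

#: Gene panel for the presence/absence matrix: the CSF receptor/ligand
#: families plus the granulopoiesis C/EBP transcription factors.
GENE_PANEL: tuple[str, ...] = (
    "CSF1R",
    "IL34",
    "CSF1",
    "CSF3R",
    "CSF3",
    "CEBPA",
    "CEBPB",
    "CEBPE",
)

#: Protein families scored for shared sequence similarity.
PROTEIN_FAMILIES: tuple[str, ...] = ("CSF1R", "IL34", "CSF1", "CSF3R", "CSF3")


def assign_emergence(name: str, table: dict[str, float] | None = None) -> float:
    """Return the emergence time (MYA) for a lineage group.

    Parameters
    ----------
    name
        Lineage group name.
    table
        Optional override mapping; defaults to the built-in constants.

    Raises
    ------
    KeyError
        If ``name`` is not a known group.
    """
    table = EMERGENCE_MYA if table is None else table
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown lineage group {name!r}; known groups: {sorted(table)}"
        ) from None
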