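"""Anchor-gene synteny comparison.

Turns the manual syntenic-map procedure into an algorithm: extract the
block of genes flanking a focal gene in a reference genome, select anchor
genes (flanking genes kept as positional reference points, chosen for
proximity and for presence across the species examined — several are used
to buffer against random gene loss), then classify the fate of the focal
locus in each query genome:

``retained_in_block``
    focal gene within ``window`` gene positions of at least one anchor on
    the same chromosome;
``relocated_same_chromosome``
    focal on a chromosome carrying anchors, but outside the window;
``translocated_other_chromosome``
    focal present only on chromosomes carrying no anchor;
``lost``
    focal absent while at least one anchor survives;
``block_lost``
    focal and every anchor absent — the whole section is gone.

Orientation (same / inverted / mixed) comes from the sign of the Spearman
rank correlation between reference and query positions of the co-located
block genes.  All positions are gene-order indices (0-based); physical
coordinates are carried but not used for classification, so calls are
invariant under coordinate shifts and chromosome renaming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
from scipy import stats

from .synthetic import GeneOrder, frame_to_order

logger = logging.getLogger(__name__)

FOCAL_STATUSES = ("retained_in_block", "relocated_same_chromosome",
                  "translocated_other_chromosome", "lost", "block_lost")


class SyntenyError(ValueError):
    pass


@dataclass(frozen=True)
class Anchor:
    """A flanking gene kept as a positional reference point."""
    gene: str
    side: str                # upstream | downstream
    distance: int            # gene positions from the focal gene, >= 1


@dataclass
class CandidateBlock:
    """All genes captured around the focal gene in the reference."""
    reference_species: str
    focal_gene: str
    chromosome: str
    focal_index: int
    flank_size: int
    candidates: list[Anchor]


@dataclass
class SyntenyBlock:
    """A focal gene plus its selected anchor genes."""
    reference_species: str
    focal_gene: str
    flank_size: int
    anchors: list[Anchor]
    relaxed: bool = False    # presence constraint relaxed below all-species

    def __post_init__(self) -> None:
        if not 3 <= len(self.anchors) <= 5:
            raise SyntenyError(
                f"a block needs 3-5 anchors, got {len(self.anchors)}")
        if any(a.gene == self.focal_gene for a in self.anchors):
            raise SyntenyError("anchors must exclude the focal gene")
        if any(a.distance < 1 for a in self.anchors):
            raise SyntenyError("anchor distances must be >= 1")


@dataclass
class LocusComparison:
    """Fate of a focal locus in one query genome."""
    query_species: str
    focal_gene: str
    focal_status: str
    anchor_status: dict[str, str]
    orientation: str | None          # same | inverted | mixed | None
    evidence: dict[str, tuple[str, int, str]] = field(default_factory=dict)


def _index_order(order: GeneOrder | pd.DataFrame
                 ) -> dict[str, tuple[str, int, str]]:
    """gene -> (chromosome, order index, strand); errors on duplicates."""
    if isinstance(order, pd.DataFrame):
        order = frame_to_order(order)
    index: dict[str, tuple[str, int, str]] = {}
    for chrom, genes in order.items():
        for idx, (gene, strand) in enumerate(genes):
            if gene in index:
                raise SyntenyError(f"duplicated gene symbol {gene!r}")
            index[gene] = (chrom, idx, strand)
    return index


def apply_synonyms(order: GeneOrder, synonyms: dict[str, str]) -> GeneOrder:
    """Rename genes via a synonym table (query symbol -> canonical symbol)."""
    return {chrom: [(synonyms.get(g, g), s) for g, s in genes]
            for chrom, genes in order.items()}


def extract_block(reference_order: GeneOrder | pd.DataFrame, focal_gene: str,
                  flank_size: int, reference_species: str = "reference"
                  ) -> CandidateBlock:
    """Capture up to ``flank_size`` genes per side of the focal gene.

    The focal gene must occur exactly once in the reference; a focal gene
    at a chromosome end yields a one-sided block.  ``flank_size`` must be
    at least 1 (no anchors are derivable otherwise).
    """
    if flank_size < 1:
        raise SyntenyError("flank_size must be >= 1 (no anchors derivable)")
    if isinstance(reference_order, pd.DataFrame):
        reference_order = frame_to_order(reference_order)
    hits = [(chrom, idx) for chrom, genes in reference_order.items()
            for idx, (g, _) in enumerate(genes) if g == focal_gene]
    if not hits:
        raise SyntenyError(f"focal gene {focal_gene!r} absent from reference")
    if len(hits) > 1:
        raise SyntenyError(f"focal gene {focal_gene!r} duplicated: {hits}")
    chrom, idx = hits[0]
    genes = reference_order[chrom]
    candidates = []
    for j in range(max(0, idx - flank_size), idx):
        candidates.append(Anchor(genes[j][0], "upstream", idx - j))
    for j in range(idx + 1, min(len(genes), idx + flank_size + 1)):
        candidates.append(Anchor(genes[j][0], "downstream", j - idx))
    return CandidateBlock(reference_species, focal_gene, chrom, idx,
                          flank_size, candidates)


def select_anchors(candidate: CandidateBlock,
                   species_orders: dict[str, GeneOrder | pd.DataFrame],
                   k: int = 4, presence_fraction: float = 0.8
                   ) -> SyntenyBlock:
    """Choose the k anchors nearest the focal gene that satisfy presence.

    Candidates present in every query genome are preferred; if fewer than
    three qualify, the requirement is relaxed to presence in at least
    ``presence_fraction`` of the species (logged).  Ranking is by distance
    to the focal gene, ties broken downstream before upstream, then
    alphabetically.
    """
    if not 3 <= k <= 5:
        raise SyntenyError("anchor count k must be between 3 and 5")
    indexes = {sp: _index_order(o) for sp, o in species_orders.items()}
    n_species = len(indexes)

    def presence(gene: str) -> int:
        return sum(gene in ix for ix in indexes.values())

    ranked = sorted(candidate.candidates,
                    key=lambda a: (a.distance, a.side != "downstream", a.gene))
    universal = [a for a in ranked if presence(a.gene) == n_species]
    relaxed = False
    chosen = universal
    if len(universal) < 3:
        cutoff = presence_fraction * n_species
        chosen = [a for a in ranked if presence(a.gene) >= cutoff]
        relaxed = True
        logger.warning(
            "select_anchors(%s): only %d universal candidates; relaxed to "
            "presence >= %.0f%% (%d qualify)", candidate.focal_gene,
            len(universal), 100 * presence_fraction, len(chosen))
    if not any(presence(a.gene) > 0 for a in ranked):
        raise SyntenyError(
            f"no candidate anchor for {candidate.focal_gene!r} is present in "
            "any query species")
    if len(chosen) < 3:
        raise SyntenyError(
            f"fewer than 3 anchors available for {candidate.focal_gene!r} "
            f"even after relaxation (got {len(chosen)})")
    return SyntenyBlock(candidate.reference_species, candidate.focal_gene,
                        candidate.flank_size, chosen[:k], relaxed=relaxed)


def _orientation(ref_positions: dict[str, int],
                 query_positions: dict[str, int]) -> str | None:
    shared = sorted(set(ref_positions) & set(query_positions))
    if len(shared) < 2:
        return None
    rho = stats.spearmanr([ref_positions[g] for g in shared],
                          [query_positions[g] for g in shared]).statistic
    if pd.isna(rho) or rho == 0:
        return "mixed"
    return "same" if rho > 0 else "inverted"


def compare_locus(block: SyntenyBlock,
                  query_order: GeneOrder | pd.DataFrame,
                  query_species: str = "query",
                  reference_order: GeneOrder | pd.DataFrame | None = None,
                  window: int = 10) -> LocusComparison:
    """Locate the block genes in a query genome and classify the focal fate.

    ``window`` is the gene-order distance within which a gene counts as
    in-block ("immediately adjacent" in the qualitative reading).  Anchor
    genes are classified relative to the focal gene when it is present,
    otherwise relative to the chromosome carrying most surviving anchors.
    ``reference_order`` is only needed to orient the comparison when the
    block's own anchor ordering is insufficient (it defaults to distances
    recorded in the block).
    """
    qindex = _index_order(query_order)
    evidence = {g: qindex[g] for g in
                [block.focal_gene, *(a.gene for a in block.anchors)]
                if g in qindex}

    anchor_pos = {a.gene: qindex[a.gene] for a in block.anchors
                  if a.gene in qindex}
    focal_present = block.focal_gene in qindex

    # focal status
    if not focal_present:
        focal_status = "block_lost" if not anchor_pos else "lost"
    else:
        fchrom, fidx, _ = qindex[block.focal_gene]
        same = [idx for chrom, idx, _ in anchor_pos.values() if chrom == fchrom]
        if same and any(abs(fidx - idx) <= window for idx in same):
            focal_status = "retained_in_block"
        elif same:
            focal_status = "relocated_same_chromosome"
        else:
            focal_status = "translocated_other_chromosome"

    # reference point for anchor classification
    if focal_present:
        ref_chrom, ref_idx, _ = qindex[block.focal_gene]
    elif anchor_pos:
        chrom_counts = pd.Series([c for c, _, _ in anchor_pos.values()])
        ref_chrom = chrom_counts.mode().iloc[0]
        cluster = [i for c, i, _ in anchor_pos.values() if c == ref_chrom]
        ref_idx = int(pd.Series(cluster).median())
    else:
        ref_chrom, ref_idx = None, None

    anchor_status: dict[str, str] = {}
    for a in block.anchors:
        if a.gene not in qindex:
            anchor_status[a.gene] = "lost"
            continue
        chrom, idx, _ = qindex[a.gene]
        if ref_chrom is None:
            anchor_status[a.gene] = "retained_in_block"
        elif chrom != ref_chrom:
            anchor_status[a.gene] = "translocated_other_chromosome"
        elif abs(idx - ref_idx) <= window:
            anchor_status[a.gene] = "retained_in_block"
        else:
            anchor_status[a.gene] = "relocated_same_chromosome"

    # orientation from co-located block genes on the reference chromosome
    ref_positions = {block.focal_gene: 0}
    for a in block.anchors:
        ref_positions[a.gene] = (a.distance if a.side == "downstream"
                                 else -a.distance)
    query_positions = {g: idx for g, (chrom, idx, _) in evidence.items()
                       if ref_chrom is not None and chrom == ref_chrom
                       and abs(idx - ref_idx) <= max(window, 2 * len(ref_positions))}
    orientation = _orientation(ref_positions, query_positions)

    return LocusComparison(query_species, block.focal_gene, focal_status,
                           anchor_status, orientation, evidence)


def comparisons_to_frame(comparisons: list[LocusComparison]) -> pd.DataFrame:
    """Tabulate comparisons, one row per (species, gene) with its status."""
    rows: list[dict[str, Any]] = []
    for c in comparisons:
        rows.append({"query_species": c.query_species, "gene": c.focal_gene,
                     "role": "focal", "status": c.focal_status,
                     "orientation": c.orientation or "undefined"})
        for gene, status in c.anchor_status.items():
            rows.append({"query_species": c.query_species, "gene": gene,
                         "role": "anchor", "status": status,
                         "orientation": c.orientation or "undefined"})
    return pd.DataFrame(rows)


_STATUS_COLOURS = {
    "retained_in_block": "#2171b5",
    "relocated_same_chromosome": "#fd8d3c",
    "translocated_other_chromosome": "#9e9ac8",
    "lost": "#d9d9d9",
    "block_lost": "#969696",
}


def render_synteny_map(comparisons: list[LocusComparison], path) -> None:
    """Per-species tracks of block genes coloured by status.

    The focal gene is outlined; an inverted block flips the orientation
    glyph.  Layout is deterministic given input order.
    """
    if not comparisons:
        raise SyntenyError("nothing to render")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    fig, ax = plt.subplots(
        figsize=(1.8 + 1.1 * (1 + max(len(c.anchor_status)
                                      for c in comparisons)),
                 0.8 + 0.6 * len(comparisons)))
    for y, c in enumerate(comparisons):
        genes = [(c.focal_gene, c.focal_status, True)] + [
            (g, s, False) for g, s in sorted(c.anchor_status.items())]
        # draw in query gene order where located, absents at the end
        genes.sort(key=lambda t: (c.evidence.get(t[0], ("~", 10**9, ""))[:2]))
        for x, (gene, status, is_focal) in enumerate(genes):
            ax.barh(y, 0.9, left=x, height=0.6,
                    color=_STATUS_COLOURS[status],
                    edgecolor="black" if is_focal else "none",
                    linewidth=1.5 if is_focal else 0)
            ax.text(x + 0.45, y, gene, ha="center", va="center", fontsize=6,
                    rotation=0)
        glyph = {"same": "→", "inverted": "←"}.get(
            c.orientation or "", "·")
        ax.text(-0.4, y, glyph, ha="center", va="center", fontsize=10)
    ax.set_yticks(range(len(comparisons)),
                  [c.query_species for c in comparisons], fontsize=7)
    ax.set_xticks([])
    ax.invert_yaxis()
    ax.legend(handles=[Patch(color=col, label=s)
                       for s, col in _STATUS_COLOURS.items()],
              loc="upper left", bbox_to_anchor=(1.01, 1), fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# file input


def read_gene_orders_tsv(path) -> dict[str, GeneOrder]:
    """Read the tabular gene-order format (multi-species TSV)."""
    frame = pd.read_csv(path, sep="\t")
    return {sp: frame_to_order(sub)
            for sp, sub in frame.groupby("species", sort=True)}


def read_gff3_gene_order(path, species: str | None = None) -> GeneOrder:
    """Build a gene order from the gene features of a GFF3 file.

    Genes are ordered by start coordinate within each sequence region; the
    symbol is taken from the Name attribute (falling back to ID).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        name = (feat.attributes.get("Name") or feat.attributes.get("ID")
                or [feat.id])[0]
        rows.append((feat.seqid, feat.start, name, feat.strand or "+"))
    order: GeneOrder = {}
    for seqid, _, name, strand in sorted(rows):
        order.setdefault(seqid, []).append((name, strand))
    return order
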