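"""Synthetic data generation with known ground truth.

Every downstream stage of the pipeline (blood-count meta-analysis, gene
presence/absence, synteny classification, homology scoring, timescales) can
be exercised on data produced here, with a truth log recording each
simulated event so recovery can be checked exactly.

The generator emulates the study conditions end to end:

* a species set partitioned into chordate lineage groups, arranged in a
  star-like species tree whose leaf depths equal the group emergence times
  (million years, MY);
* protein families evolved along that tree under a Jukes-Cantor-style
  amino-acid model (uniform exchange among the 19 alternatives), with
  single-residue indels and optional whole-gene loss;
* per-species gene orders derived from a reference genome by sampled gene
  loss, segmental inversion, and translocation events;
* complete blood counts drawn per species from per-group Gamma profiles
  (counts are non-negative and right-skewed).

Randomness: one independent stream per stage, seeded by the pair
``(global seed, crc32(stage name))``, so stages are individually
reproducible and bit-identical across runs.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from typing import Any, Iterable

import dendropy
import numpy as np
import pandas as pd

from .groups import DEFAULT_GROUPS, MYELOID_CELL_TYPES, LineageGroup

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default per-group blood-count profiles, mean count in 1e9 cells/L per
#: myeloid cell type.  Values follow the published absolute counts for the
#: dominant granulocyte of each group, with the remaining cell types scaled
#: from the groups' myeloid composition percentages (see docs/methods.md).
DEFAULT_CBC_MEANS: dict[str, dict[str, float]] = {
    "jawed_fish": {"heterophil": 2.0, "neutrophil": 0.045, "eosinophil": 0.8,
                   "basophil": 0.5, "monocyte": 0.7},
    "jawless_fish": {"neutrophil": 1.5, "eosinophil": 0.3, "basophil": 0.1,
                     "monocyte": 0.4},
    "amphibia": {"heterophil": 2.9, "eosinophil": 2.27, "basophil": 3.08,
                 "monocyte": 1.52},
    "squamata": {"heterophil": 6.9, "monocyte": 5.06, "eosinophil": 1.26,
                 "basophil": 1.21, "azurophil": 0.3},
    "crocodilia": {"heterophil": 3.2, "azurophil": 1.5, "eosinophil": 1.01,
                   "basophil": 1.99, "monocyte": 0.35},
    "testudines": {"heterophil": 2.1, "monocyte": 1.2, "eosinophil": 1.88,
                   "basophil": 0.03},
    "aves": {"heterophil": 12.7, "monocyte": 0.73, "eosinophil": 0.9,
             "basophil": 0.6},
    "monotremata": {"neutrophil": 6.0, "monocyte": 0.63, "eosinophil": 0.48,
                    "basophil": 0.05},
    "marsupialia": {"neutrophil": 5.3, "monocyte": 0.55, "eosinophil": 0.53,
                    "basophil": 0.04},
    "placentalia": {"neutrophil": 5.2, "monocyte": 0.44, "eosinophil": 0.64,
                    "basophil": 0.11},
}

#: Default dispersion (coefficient of variation) of cross-species counts.
DEFAULT_CBC_DISPERSION = 0.5


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def default_cbc_profiles(dispersion: float = DEFAULT_CBC_DISPERSION
                         ) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-group ``{cell_type: (mean, dispersion)}`` profiles, 1e9 cells/L."""
    return {
        group: {ct: (mean, dispersion) for ct, mean in means.items()}
        for group, means in DEFAULT_CBC_MEANS.items()
    }


@dataclass
class SimulationConfig:
    """Parameters of a synthetic study.

    Rates are per site (or per gene) per million years except
    ``gene_loss_rate``, which is the probability of whole-gene loss per
    tree branch (protein families) or per gene per species (genome orders).
    """

    seed: int = 0
    groups: tuple[LineageGroup, ...] = DEFAULT_GROUPS
    species_per_group: int = 3
    substitution_rate: float = 0.002
    indel_rate: float = 0.0001
    gene_loss_rate: float = 0.03
    inversion_rate: float = 0.02
    translocation_rate: float = 0.02
    cbc_group_profiles: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_cbc_profiles)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one lineage group is required")
        if self.species_per_group < 1:
            raise ConfigurationError("species_per_group must be >= 1")
        for name in ("substitution_rate", "indel_rate", "gene_loss_rate",
                     "inversion_rate", "translocation_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for group, profile in self.cbc_group_profiles.items():
            for ct, (mean, disp) in profile.items():
                if mean < 0:
                    raise ConfigurationError(
                        f"negative profile mean for {group}/{ct}: {mean}")
                if disp < 0:
                    raise ConfigurationError(
                        f"negative dispersion for {group}/{ct}: {disp}")

    def species_names(self) -> list[str]:
        return [f"{g.name}_sp{i:02d}"
                for g in self.groups
                for i in range(1, self.species_per_group + 1)]


@dataclass
class SimulationTruth:
    """Ground-truth record of a simulation stage.

    Attributes
    ----------
    events
        Ordered event log; replaying it deterministically reproduces the
        simulated outputs.
    divergence
        Realized substitutions per site from the root, per species.
    lost
        Species in which the simulated gene was lost entirely.
    cbc_means
        True per-group mean count per cell type (1e9/L).
    """

    events: list[dict[str, Any]] = field(default_factory=list)
    divergence: dict[str, float] = field(default_factory=dict)
    lost: set[str] = field(default_factory=set)
    cbc_means: dict[str, dict[str, float]] = field(default_factory=dict)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for one simulation stage."""
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


def random_protein(length: int, rng: np.random.Generator) -> str:
    """Uniform random amino-acid sequence of the given length."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# species tree


def simulate_species_set(config: SimulationConfig
                         ) -> tuple[pd.DataFrame, str]:
    """Generate the species table and its Newick tree.

    Each group forms a clade hanging off the root; every leaf sits at a
    depth equal to its group's emergence time in MY (half on the stem, half
    on the terminal branch), so divergence from the root is proportional to
    emergence time by construction.

    Returns
    -------
    (species, newick)
        ``species`` has columns species, group, emergence_mya;
        ``newick`` is the tree string (internal nodes labelled by group).
    """
    rows = []
    clades = []
    for g in config.groups:
        half = g.emergence_mya / 2.0
        leaves = []
        for i in range(1, config.species_per_group + 1):
            name = f"{g.name}_sp{i:02d}"
            rows.append({"species": name, "group": g.name,
                         "emergence_mya": g.emergence_mya})
            leaves.append(f"{name}:{half:g}")
        clades.append(f"({','.join(leaves)}){g.name}:{half:g}")
    newick = f"({','.join(clades)})root;"
    return pd.DataFrame(rows), newick


def _as_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick",
                             suppress_internal_node_taxa=False)


# ---------------------------------------------------------------------------
# protein family evolution


def _evolve_branch(seq: list[str], blen: float, config: SimulationConfig,
                   rng: np.random.Generator) -> tuple[list[str], int]:
    """Apply substitutions and single-residue indels along one branch."""
    n_sub = rng.poisson(config.substitution_rate * blen * len(seq))
    for _ in range(n_sub):
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        alternatives = [a for a in AMINO_ACIDS if a != old]
        seq[pos] = alternatives[int(rng.integers(19))]
    n_indel = rng.poisson(config.indel_rate * blen * len(seq))
    for _ in range(n_indel):
        if rng.random() < 0.5 or len(seq) <= 1:
            pos = int(rng.integers(len(seq) + 1))
            seq.insert(pos, AMINO_ACIDS[int(rng.integers(20))])
        else:
            del seq[int(rng.integers(len(seq)))]
    return seq, int(n_sub)


def evolve_protein_family(root_sequence: str, tree: str | dendropy.Tree,
                          config: SimulationConfig, stage: str = "protein"
                          ) -> tuple[dict[str, str | None], SimulationTruth]:
    """Evolve a protein family from the root down a species tree.

    Per branch, the substitution count is Poisson with expectation
    ``substitution_rate * branch_length * length``, each substitution
    replacing one residue by a uniform choice among the other 19; indels
    are single-residue insertions/deletions at ``indel_rate``; whole-gene
    loss occurs with probability ``gene_loss_rate`` per branch and is
    inherited by the subtree.

    Returns
    -------
    (sequences, truth)
        ``sequences`` maps species name to its sequence, or ``None`` where
        the gene was lost.  ``truth.divergence`` holds realized
        substitutions per root-sequence site for each surviving species.
    """
    if not root_sequence:
        raise ValueError("root sequence must be non-empty")
    bad = set(root_sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"root sequence contains non-standard residues: {bad}")

    t = _as_tree(tree)
    rng = stage_rng(config.seed, stage)
    truth = SimulationTruth()
    root_len = len(root_sequence)

    # state carried down the tree: (sequence chars, cumulative subs, lost?)
    state: dict[int, tuple[list[str], int, bool]] = {
        id(t.seed_node): (list(root_sequence), 0, False)}
    sequences: dict[str, str | None] = {}

    for node in t.preorder_node_iter():
        if node is t.seed_node:
            seq, subs, lost = state[id(node)]
        else:
            pseq, psubs, plost = state[id(node.parent_node)]
            blen = node.edge.length or 0.0
            label = (node.taxon.label if node.taxon is not None
                     else (node.label or "internal"))
            if plost:
                seq, subs, lost = pseq, psubs, True
            elif config.gene_loss_rate > 0 and rng.random() < min(
                    config.gene_loss_rate, 1.0):
                truth.events.append({"type": "gene_loss", "node": label})
                seq, subs, lost = pseq, psubs, True
            else:
                seq, n_sub = _evolve_branch(list(pseq), blen, config, rng)
                subs, lost = psubs + n_sub, False
            state[id(node)] = (seq, subs, lost)
        if node.is_leaf():
            name = node.taxon.label.replace(" ", "_")
            if lost:
                sequences[name] = None
                truth.lost.add(name)
            else:
                sequences[name] = "".join(seq)
                truth.divergence[name] = subs / root_len
    return sequences, truth


# ---------------------------------------------------------------------------
# genome orders

GeneOrder = dict[str, list[tuple[str, str]]]  # chromosome -> [(gene, strand)]


def order_to_frame(order: GeneOrder, species: str) -> pd.DataFrame:
    """Serialize a gene order to the tabular layout (0-based, half-open)."""
    rows = []
    for chrom in sorted(order):
        for idx, (gene, strand) in enumerate(order[chrom]):
            rows.append({"species": species, "chromosome": chrom, "index": idx,
                         "gene": gene, "start": idx * 1000,
                         "end": idx * 1000 + 500, "strand": strand})
    return pd.DataFrame(
        rows, columns=["species", "chromosome", "index", "gene", "start",
                       "end", "strand"])


def frame_to_order(frame: pd.DataFrame) -> GeneOrder:
    """Inverse of :func:`order_to_frame` (uses the index column for order)."""
    order: GeneOrder = {}
    for chrom, sub in frame.groupby("chromosome", sort=True):
        sub = sub.sort_values("index")
        order[chrom] = list(zip(sub["gene"], sub["strand"]))
    return order


def _apply_event(order: GeneOrder, event: dict[str, Any]) -> None:
    """Apply one rearrangement event in place."""
    kind = event["type"]
    if kind == "loss":
        for genes in order.values():
            for i, (g, _) in enumerate(genes):
                if g == event["gene"]:
                    del genes[i]
                    return
    elif kind == "inversion":
        genes = order[event["chromosome"]]
        i, k = event["start"], event["length"]
        segment = genes[i:i + k]
        genes[i:i + k] = [(g, "-" if s == "+" else "+")
                          for g, s in reversed(segment)]
    elif kind == "translocation":
        found = None
        for chrom, genes in order.items():
            for i, (g, s) in enumerate(genes):
                if g == event["gene"]:
                    found = (chrom, i, s)
                    break
            if found:
                break
        if found is None:
            return
        chrom, i, strand = found
        del order[chrom][i]
        dest = order[event["to_chromosome"]]
        dest.insert(min(event["to_index"], len(dest)), (event["gene"], strand))
    else:  # pragma: no cover - defensive
        raise ValueError(f"unknown event type {kind!r}")


def replay_events(reference: GeneOrder,
                  events: Iterable[dict[str, Any]]) -> GeneOrder:
    """Replay an event log against a reference order (pure; returns a copy)."""
    order = copy.deepcopy(reference)
    for event in events:
        _apply_event(order, event)
    return order


def simulate_genome_orders(reference_order: GeneOrder | pd.DataFrame,
                           config: SimulationConfig,
                           species: list[str] | None = None,
                           stage: str = "genome"
                           ) -> tuple[dict[str, GeneOrder], SimulationTruth]:
    """Derive per-species gene orders from a reference by sampled events.

    Per species: each gene is lost independently with probability
    ``gene_loss_rate``; the number of inversions (random 2-6 gene windows,
    reversed with strands flipped) is Poisson with mean
    ``inversion_rate * n_genes``; translocations (one gene moved to a
    random position on a random chromosome) likewise at
    ``translocation_rate``.  Every event is logged with the positional
    detail needed to replay it; outputs are produced *by* replaying, so the
    log explains the outputs exactly.
    """
    if isinstance(reference_order, pd.DataFrame):
        reference_order = frame_to_order(reference_order)
    if not reference_order or not any(reference_order.values()):
        raise ValueError("reference order must be non-empty")
    all_genes = [g for genes in reference_order.values() for g, _ in genes]
    if len(all_genes) != len(set(all_genes)):
        dupes = sorted({g for g in all_genes if all_genes.count(g) > 1})
        raise ValueError(f"duplicate gene symbols in reference: {dupes}")

    rng = stage_rng(config.seed, stage)
    if species is None:
        species = config.species_names()
    chroms = sorted(reference_order)
    n_genes = len(all_genes)
    truth = SimulationTruth()
    orders: dict[str, GeneOrder] = {}

    for sp in species:
        order = copy.deepcopy(reference_order)
        log: list[dict[str, Any]] = []

        def emit(event: dict[str, Any]) -> None:
            event["species"] = sp
            log.append(event)
            _apply_event(order, event)

        if config.gene_loss_rate > 0:
            lost_mask = rng.random(n_genes) < min(config.gene_loss_rate, 1.0)
            for gene, is_lost in zip(all_genes, lost_mask):
                if is_lost:
                    emit({"type": "loss", "gene": gene})
        for _ in range(rng.poisson(config.inversion_rate * n_genes)):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = len(order[chrom])
            if size < 2:
                continue
            length = int(rng.integers(2, min(6, size) + 1))
            start = int(rng.integers(0, size - length + 1))
            emit({"type": "inversion", "chromosome": chrom,
                  "start": start, "length": length})
        for _ in range(rng.poisson(config.translocation_rate * n_genes)):
            present = [g for genes in order.values() for g, _ in genes]
            if not present:
                continue
            gene = present[int(rng.integers(len(present)))]
            to_chrom = chroms[int(rng.integers(len(chroms)))]
            to_index = int(rng.integers(0, len(order[to_chrom]) + 1))
            emit({"type": "translocation", "gene": gene,
                  "to_chromosome": to_chrom, "to_index": to_index})

        truth.events.extend(log)
        orders[sp] = order
    return orders, truth


def true_focal_status(events: list[dict[str, Any]], focal: str,
                      anchors: list[str], final_order: GeneOrder,
                      window: int = 10) -> str:
    """Ground-truth fate of a focal gene from the event log.

    Uses information the classifier never sees: which events actually hit
    the focal gene.  A focal gene lost by a loss event is ``lost``
    (``block_lost`` if every anchor was also lost); one moved by a
    translocation is classified from where it landed relative to the
    surviving anchors; a gene never hit directly is ``retained_in_block``.
    """
    lost_genes = {e["gene"] for e in events if e["type"] == "loss"}
    if focal in lost_genes:
        return "block_lost" if all(a in lost_genes for a in anchors) else "lost"

    positions: dict[str, tuple[str, int]] = {}
    for chrom, genes in final_order.items():
        for idx, (g, _) in enumerate(genes):
            positions[g] = (chrom, idx)
    moved = any(e["type"] == "translocation" and e["gene"] == focal
                for e in events)
    if not moved:
        return "retained_in_block"
    if focal not in positions:  # moved then lost is excluded above
        return "lost"
    fchrom, fidx = positions[focal]
    anchor_pos = [positions[a] for a in anchors if a in positions]
    if not anchor_pos:
        return "translocated_other_chromosome"
    same = [idx for chrom, idx in anchor_pos if chrom == fchrom]
    if not same:
        return "translocated_other_chromosome"
    if any(abs(fidx - idx) <= window for idx in same):
        return "retained_in_block"
    return "relocated_same_chromosome"


# ---------------------------------------------------------------------------
# blood counts


def simulate_cbc(config: SimulationConfig, stage: str = "cbc") -> pd.DataFrame:
    """Draw per-species complete blood counts from the group profiles.

    Counts are Gamma-distributed with the profile mean and dispersion
    (coefficient of variation): shape ``1/d**2``, scale ``mean * d**2``.
    Dispersion 0 degenerates to the exact mean.  Units 1e9 cells/L.
    """
    profiles = config.cbc_group_profiles
    for g in config.groups:
        if g.name not in profiles:
            raise ConfigurationError(f"no CBC profile for group {g.name!r}")
    rng = stage_rng(config.seed, stage)
    rows = []
    for g in config.groups:
        for i in range(1, config.species_per_group + 1):
            sp = f"{g.name}_sp{i:02d}"
            for ct in MYELOID_CELL_TYPES:
                if ct not in profiles[g.name]:
                    continue
                mean, disp = profiles[g.name][ct]
                if mean == 0 or disp == 0:
                    count = float(mean)
                else:
                    shape = 1.0 / disp ** 2
                    count = float(rng.gamma(shape, mean * disp ** 2))
                rows.append({"species": sp, "group": g.name,
                             "sex": "unspecified", "life_stage": "adult",
                             "cell_type": ct, "count": count})
    return pd.DataFrame(rows)


def true_cbc_means(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """True per-group mean count per cell type implied by the profiles."""
    return {g.name: {ct: mv[0] for ct, mv in
                     config.cbc_group_profiles[g.name].items()}
            for g in config.groups}


# ---------------------------------------------------------------------------
# reference genome for demos and fixtures


def default_reference_order(filler_per_flank: int = 12) -> GeneOrder:
    """A human-like reference gene order for the CSF gene neighbourhoods.

    Chromosome q5 carries HMGBX3 - CSF1R - PDGFRB - CDX1; q16 carries
    FUK - COG4 - SF3B3 - IL34 - MTSS1L - VAC14; q1 carries
    AMPD2 - EPS8L3 - CSF1 - AHCYL1 - STRIP1 and, in a separate region,
    CSF3R; q17 carries CSF3.  Filler genes pad each flank so that flank
    extraction and rearrangement simulation have room to act.
    """
    neighbourhoods = {
        "q5": ["HMGBX3", "CSF1R", "PDGFRB", "CDX1"],
        "q16": ["FUK", "COG4", "SF3B3", "IL34", "MTSS1L", "VAC14"],
        "q1": ["AMPD2", "EPS8L3", "CSF1", "AHCYL1", "STRIP1"],
        "q17": ["CSF3"],
    }
    order: GeneOrder = {}
    counter = 0
    for chrom, core in neighbourhoods.items():
        genes: list[tuple[str, str]] = []
        for _ in range(filler_per_flank):
            counter += 1
            genes.append((f"GENE{counter:03d}", "+"))
        genes.extend((g, "+") for g in core)
        if chrom == "q1":
            # CSF3R sits in a distinct region of the same chromosome
            for _ in range(filler_per_flank):
                counter += 1
                genes.append((f"GENE{counter:03d}", "+"))
            genes.append(("CSF3R", "+"))
        for _ in range(filler_per_flank):
            counter += 1
            genes.append((f"GENE{counter:03d}", "+"))
        order[chrom] = genes
    return order
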