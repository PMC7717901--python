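"""Pairwise protein homology scoring against a reference orthologue.

Each species' protein is aligned to the human (reference) query with a
self-contained Smith-Waterman local aligner using affine gap costs
(Gotoh's algorithm) and an integer substitution matrix (BLOSUM62 by
default, via Biopython's matrix tables).  Alignment significance follows
Karlin-Altschul statistics,

    E = K * m * n * exp(-lambda * S),

the expected number of chance local alignments scoring at least S between
a length-m query and length-n subject.  A hit is accepted as homologous
when the query coverage is at least 40% and E is at most 1e-20; accepted
percent similarities are then averaged per lineage group.

A gap of length g costs ``gap_open + g * gap_extend`` (the convention of
the standard protein search tools).  Lambda and K default to the gapped
constants commonly quoted for BLOSUM62 with an 11/1 gap scheme; they are
plain fields and can be overridden for other schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable
import logging

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"  # X: ambiguity, scores 0 vs everything
_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


def _blosum62_table() -> np.ndarray:
    table = np.zeros((21, 21), dtype=np.int64)
    blosum = substitution_matrices.load("BLOSUM62")
    for a in _ALPHABET[:20]:
        for b in _ALPHABET[:20]:
            table[_INDEX[a], _INDEX[b]] = int(blosum[a, b])
    return table


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and E-value constants."""

    matrix: np.ndarray = field(default_factory=_blosum62_table)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    kappa: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be positive")


@dataclass
class HomologyCriteria:
    """The acceptance rule for a hit: coverage >= 40% and E <= 1e-20."""

    min_query_coverage: float = 0.40
    max_evalue: float = 1e-20

    def __post_init__(self) -> None:
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


@dataclass
class AlignmentResult:
    """An optimal local alignment and its summary statistics.

    Spans are half-open residue intervals on the original sequences.
    ``aligned_pairs`` counts residue-residue columns; ``alignment_length``
    additionally counts gap columns (the denominator of the standard
    percent-identity readout).
    """

    score: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    alignment_length: int
    aligned_pairs: int
    identities: int
    positives: int
    query_length: int
    subject_length: int
    evalue: float

    @property
    def query_coverage(self) -> float:
        return (self.query_span[1] - self.query_span[0]) / self.query_length

    @property
    def percent_identity(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.identities / self.alignment_length

    @property
    def percent_positives(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.positives / self.alignment_length

    def percent_similarity(self, mode: str = "identity") -> float:
        if mode == "identity":
            return self.percent_identity
        if mode == "positives":
            return self.percent_positives
        raise ValueError(f"unknown similarity mode {mode!r}")


@dataclass(frozen=True)
class HomologyCall:
    is_homolog: bool
    reason: str  # ok | low_coverage | high_evalue | both


def _encode(seq: str, which: str) -> np.ndarray:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    try:
        return np.array([_INDEX[aa] for aa in seq], dtype=np.int64)
    except KeyError:
        for pos, aa in enumerate(seq):
            if aa not in _INDEX:
                raise ValueError(
                    f"invalid residue {aa!r} at position {pos} of {which}"
                ) from None
        raise  # pragma: no cover


def evalue(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return scheme.kappa * m * n * math.exp(-scheme.lam * score)


def local_align(query: str, subject: str,
                scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps.

    One optimal traceback is reported, ties broken diagonal > up (gap in
    subject) > left (gap in query), starting from the first maximal cell in
    row-major order.  The E-value of the reported score is filled in from
    the scheme's Karlin-Altschul constants.
    """
    scheme = scheme or ScoringScheme()
    q = _encode(query, "query")
    s = _encode(subject, "subject")
    m, n = len(q), len(s)
    sub = scheme.matrix
    first = scheme.gap_open + scheme.gap_extend  # cost of a length-1 gap
    ext = scheme.gap_extend

    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (left)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in subject (up)

    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        row_scores = sub[q[i - 1]]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - first, Ei[j - 1] - ext)
            f = max(Hp[j] - first, Fp[j] - ext)
            h = max(0, Hp[j - 1] + row_scores[s[j - 1]], e, f)
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best, bi, bj = int(h), i, j

    if best == 0:
        return AlignmentResult(0, (0, 0), (0, 0), 0, 0, 0, 0, m, n,
                               evalue(0, m, n, scheme))

    # traceback (recomputed from the three matrices; diagonal > up > left)
    i, j = bi, bj
    state = "H"
    length = pairs = ident = pos = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + sub[q[i - 1], s[j - 1]]
            if H[i][j] == diag:
                length += 1
                pairs += 1
                if q[i - 1] == s[j - 1]:
                    ident += 1
                if sub[q[i - 1], s[j - 1]] > 0:
                    pos += 1
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in subject: consume query residue
            length += 1
            opened = H[i - 1][j] - first
            extended = F[i - 1][j] - ext
            i -= 1
            state = "H" if opened >= extended else "F"
        else:  # gap in query: consume subject residue
            length += 1
            opened = H[i][j - 1] - first
            extended = E[i][j - 1] - ext
            j -= 1
            state = "H" if opened >= extended else "E"

    return AlignmentResult(
        score=best, query_span=(i, bi), subject_span=(j, bj),
        alignment_length=length, aligned_pairs=pairs, identities=ident,
        positives=pos, query_length=m, subject_length=n,
        evalue=evalue(best, m, n, scheme))


def call_homology(result: AlignmentResult,
                  criteria: HomologyCriteria | None = None) -> HomologyCall:
    """Apply the acceptance rule; boundary values are accepted."""
    criteria = criteria or HomologyCriteria()
    low_cov = result.query_coverage < criteria.min_query_coverage
    high_e = result.evalue > criteria.max_evalue
    if low_cov and high_e:
        return HomologyCall(False, "both")
    if low_cov:
        return HomologyCall(False, "low_coverage")
    if high_e:
        return HomologyCall(False, "high_evalue")
    return HomologyCall(True, "ok")


def score_species_panel(human_query: str,
                        species_sequences: dict[str, str | None],
                        scheme: ScoringScheme | None = None,
                        criteria: HomologyCriteria | None = None,
                        protein: str = "protein") -> pd.DataFrame:
    """Score every species' sequence against the reference query.

    ``species_sequences`` maps species to its (longest-isoform) sequence,
    or ``None`` where the gene is absent; absent and rule-failing species
    are kept in the table, flagged ``missing`` / non-homologous.
    """
    if not species_sequences:
        raise ValueError("empty species panel")
    scheme = scheme or ScoringScheme()
    criteria = criteria or HomologyCriteria()
    rows = []
    for species, seq in species_sequences.items():
        if not seq:
            rows.append({"species": species, "protein": protein,
                         "missing": True, "score": np.nan,
                         "percent_identity": np.nan,
                         "percent_positives": np.nan, "coverage": np.nan,
                         "evalue": np.nan, "homolog": False,
                         "reason": "missing"})
            continue
        result = local_align(human_query, seq, scheme)
        call = call_homology(result, criteria)
        rows.append({"species": species, "protein": protein, "missing": False,
                     "score": result.score,
                     "percent_identity": result.percent_identity,
                     "percent_positives": result.percent_positives,
                     "coverage": result.query_coverage,
                     "evalue": result.evalue, "homolog": call.is_homolog,
                     "reason": call.reason})
    return pd.DataFrame(rows)


def aggregate_by_group(table: pd.DataFrame, grouping: dict[str, str],
                       value: str = "percent_identity") -> pd.DataFrame:
    """Average accepted percent similarities per lineage group.

    Species that are missing or fail the homology rule are excluded from
    ``n_species``; a group left with no scored species is omitted with a
    warning.  Returns (group, protein, n_species, mean_pct, min_pct,
    max_pct, sd_pct); sd is 0 for singletons.
    """
    scored = table[table["homolog"]].copy()
    scored["group"] = scored["species"].map(grouping)
    unmapped = scored["group"].isna()
    if unmapped.any():
        raise ValueError(
            f"species without a group: {sorted(scored.loc[unmapped, 'species'])}")
    out = (scored.groupby(["group", "protein"], sort=True)[value]
           .agg(n_species="size", mean_pct="mean", min_pct="min",
                max_pct="max", sd_pct="std")
           .reset_index())
    out["sd_pct"] = out["sd_pct"].fillna(0.0)
    missing_groups = set(grouping.values()) - set(out["group"])
    if missing_groups:
        logger.warning("aggregate_by_group: no scored species in %s",
                       sorted(missing_groups))
    return out


# ---------------------------------------------------------------------------
# FASTA panel I/O (headers: species|group|protein)


def write_panel_fasta(path, sequences: dict[str, str | None],
                      grouping: dict[str, str], protein: str) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=f"{sp}|{grouping[sp]}|{protein}",
                         description="")
               for sp, seq in sequences.items() if seq]
    seqio_write(records, str(path), "fasta")


def read_panel_fasta(path) -> tuple[dict[str, str], dict[str, str], str]:
    """Read a panel FASTA; returns (sequences, species->group, protein)."""
    from Bio import SeqIO

    sequences: dict[str, str] = {}
    grouping: dict[str, str] = {}
    proteins = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"panel FASTA headers must be species|group|protein, got {rec.id!r}")
        sp, group, protein = parts
        sequences[sp] = str(rec.seq)
        grouping[sp] = group
        proteins.add(protein)
    if len(proteins) != 1:
        raise ValueError(f"panel mixes proteins: {sorted(proteins)}")
    return sequences, grouping, proteins.pop()
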