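"""Independent oracles used by the test suite.

The local-alignment oracle scores every possible local alignment by
exhaustive enumeration of aligned residue-pair subsets, with gaps between
consecutive pairs charged at affine cost.  It shares no code with the
dynamic-programming aligner: the substitution scores are read directly
from Biopython's BLOSUM62 table.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_local_score(query: str, subject: str, gap_open: int = 11,
                            gap_extend: int = 1) -> int:
    """Optimal local alignment score by exhaustive enumeration.

    Any local alignment is a non-empty increasing set of aligned residue
    pairs; unaligned stretches between consecutive pairs form (at most)
    one gap per sequence, each costing ``gap_open + len * gap_extend``.
    Alignments that interleave gaps without an intervening aligned pair
    cost strictly more under affine scoring, so this enumeration covers
    an optimum.  Feasible only for sequences of length <= ~8.
    """
    best = 0
    m, n = len(query), len(subject)
    for k in range(1, min(m, n) + 1):
        for qi in combinations(range(m), k):
            for sj in combinations(range(n), k):
                score = 0.0
                for t in range(k):
                    score += _BLOSUM62[query[qi[t]], subject[sj[t]]]
                    if t:
                        a = qi[t] - qi[t - 1] - 1
                        b = sj[t] - sj[t - 1] - 1
                        if a:
                            score -= gap_open + gap_extend * a
                        if b:
                            score -= gap_open + gap_extend * b
                if score > best:
                    best = int(score)
    return best
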