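"""Amino-acid sequence identity/similarity utility.

Convention (documented so results are reproducible): global
Needleman-Wunsch alignment with BLOSUM62, gap open 10, gap extension 0.5.
Identity is the fraction of alignment columns with identical residues;
similarity the fraction of columns whose substitution score is positive
(gap columns count in the denominator of both). Percentages are rounded
to integers.
"""

from __future__ import annotations

from Bio import Align
from Bio.Align import substitution_matrices

from .core import PocketdynError

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _validate(seq: str, which: str) -> str:
    seq = seq.strip().upper()
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise PocketdynError(
            f"sequence {which} contains non-amino-acid characters: {bad}")
    if not seq:
        raise PocketdynError(f"sequence {which} is empty")
    return seq


def sequence_identity_similarity(seq_a: str, seq_b: str,
                                 mode: str = "global_alignment",
                                 ) -> tuple[int, int]:
    """Percent identity and similarity between two protein sequences.

    mode="global_alignment": Needleman-Wunsch (BLOSUM62, open 10,
    extend 0.5), percentages over all alignment columns.
    mode="ungapped": position-wise comparison of equal-length inputs.
    """
    a = _validate(seq_a, "A")
    b = _validate(seq_b, "B")
    if mode == "ungapped":
        if len(a) != len(b):
            raise PocketdynError(
                f"ungapped mode needs equal lengths, got {len(a)} and {len(b)}")
        cols = list(zip(a, b))
    elif mode == "global_alignment":
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _BLOSUM62
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aln = aligner.align(a, b)[0]
        cols = list(zip(aln[0], aln[1]))
    else:
        raise PocketdynError(f"unknown mode {mode!r}")
    n_cols = len(cols)
    ident = sum(1 for x, y in cols if x == y and x != "-")
    similar = 0
    for x, y in cols:
        if x == "-" or y == "-":
            continue
        if _BLOSUM62[x, y] > 0:
            similar += 1
    identity = round(100.0 * ident / n_cols)
    similarity = round(100.0 * similar / n_cols)
    return int(identity), int(similarity)
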