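"""Pairwise local alignment with affine gap penalties.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(both negative). Percent identity is matches / aligned columns, counting
internal gap columns. Co-optimal alignments are broken deterministically:
prefer the smallest start on the first sequence, then on the second.

The dynamic program runs on Biopython's C aligner; this module owns the
scoring convention, tie-breaking and identity bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import islice

from Bio import Align

_VALID = set("ACGTN")

#: default scoring, tuned to BLAT-like stringency
DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -2

# cap on co-optimal alignments enumerated for tie-breaking; the choice among
# them is deterministic regardless of how many exist
_MAX_TIES = 64


@dataclass
class AlignmentResult:
    score: float
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    identity: float          # percent, 0-100
    aligned_a: str = ""
    aligned_b: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")

    @property
    def is_empty(self) -> bool:
        return self.end_a == self.start_a

    def rescore(self, match: float, mismatch: float, gap_open: float,
                gap_extend: float) -> float:
        """Recompute the score from the gapped strings (consistency check)."""
        score = 0.0
        in_gap = False
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" or y == "-":
                if not in_gap:
                    score += gap_open
                    in_gap = True
                score += gap_extend
            else:
                in_gap = False
                score += match if x == y else mismatch
        return score


def _check(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label} must be non-empty")
    s = seq.upper()
    if set(s) - _VALID:
        raise ValueError(f"{label} contains characters outside ACGTN")
    return s


def local_align(seq_a: str, seq_b: str, match: float = DEFAULT_MATCH,
                mismatch: float = DEFAULT_MISMATCH,
                gap_open: float = DEFAULT_GAP_OPEN,
                gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Optimal local alignment of two nucleotide sequences.

    Returns an empty alignment with score 0 when no positive-scoring local
    alignment exists.
    """
    a = _check(seq_a, "seq_a")
    b = _check(seq_b, "seq_b")
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        # Biopython charges open on the first gap position; our convention
        # charges open + extend for a length-1 gap
        open_gap_score=gap_open + gap_extend,
        extend_gap_score=gap_extend,
    )
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult(0.0, 0, 0, 0, 0, 0.0)
    alignments = aligner.align(a, b)
    best = min(
        islice(alignments, _MAX_TIES),
        key=lambda al: (int(al.aligned[0][0][0]), int(al.aligned[1][0][0])),
    )
    ga, gb = str(best[0]), str(best[1])
    columns = len(ga)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    (a_blocks, b_blocks) = best.aligned
    return AlignmentResult(
        score=float(score),
        start_a=int(a_blocks[0][0]), end_a=int(a_blocks[-1][1]),
        start_b=int(b_blocks[0][0]), end_b=int(b_blocks[-1][1]),
        identity=identity,
        aligned_a=ga, aligned_b=gb,
    )


def align_score(seq_a: str, seq_b: str, **params) -> float:
    """Score-only fast path (skips traceback)."""
    a = _check(seq_a, "seq_a")
    b = _check(seq_b, "seq_b")
    match = params.get("match", DEFAULT_MATCH)
    mismatch = params.get("mismatch", DEFAULT_MISMATCH)
    gap_open = params.get("gap_open", DEFAULT_GAP_OPEN)
    gap_extend = params.get("gap_extend", DEFAULT_GAP_EXTEND)
    aligner = Align.PairwiseAligner(
        mode="local", match_score=match, mismatch_score=mismatch,
        open_gap_score=gap_open + gap_extend, extend_gap_score=gap_extend,
    )
    return max(float(aligner.score(a, b)), 0.0)
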