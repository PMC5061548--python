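"""Identification and characterization of gene-family members.

Covers reciprocal-best-hit orthology between two gene sets, coding-potential
and ORF-size assessment, repertoire summaries, detection of diagnostic
deletions shared by all retrogenes in a multiple sequence alignment,
paralog-specific amplicon prediction, and classification of the duplication
mechanism (segmental duplication vs independent retrotransposition) from
flanking-sequence identity and shared TE fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .align import local_align

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneRecord:
    """One gene-family member: identity, locus, coding potential, ORF size."""

    gene_id: str
    contig: Optional[str] = None
    start: Optional[int] = None       # 0-based half-open
    end: Optional[int] = None
    strand: str = "+"
    is_retrogene: bool = True
    coding_potential: bool = False
    orf_length_aa: Optional[int] = None

    def __post_init__(self) -> None:
        if self.coding_potential and self.orf_length_aa is None:
            raise ValueError(f"{self.gene_id}: coding gene must carry an ORF length")
        if not self.coding_potential and self.orf_length_aa is not None:
            raise ValueError(f"{self.gene_id}: non-coding gene cannot carry an ORF length")
        if (self.start is None) != (self.end is None):
            raise ValueError(f"{self.gene_id}: span must give both start and end")
        if self.start is not None and not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid span")


@dataclass
class DiagnosticIndel:
    start_col: int                # alignment-column interval, 0-based half-open
    end_col: int
    length: int
    ingroup_fraction: float
    outgroup_clean: bool

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("indel length must be >= 1")
        if not 0 < self.ingroup_fraction <= 1:
            raise ValueError("ingroup coverage fraction must lie in (0, 1]")


@dataclass
class PrimerPair:
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or set(seq.upper()) - set("ACGT"):
                raise ValueError(f"{name} primer must be non-empty over ACGT")
        self.forward = self.forward.upper()
        self.reverse = self.reverse.upper()


@dataclass
class AmpliconPrediction:
    lengths: tuple[int, ...]
    ambiguous: bool

    @property
    def length(self) -> Optional[int]:
        """The unique product length, or None when absent/ambiguous."""
        return self.lengths[0] if len(self.lengths) == 1 else None


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

def reciprocal_best_hit(genes_a: dict[str, str], genes_b: dict[str, str],
                        **aligner_params) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Reciprocal-best-hit ortholog pairs between two gene sets.

    A pair (a, b) is reported iff b is a's best-scoring hit and a is b's.
    Ties break by percent identity, then lexical gene id. Returns
    (pairs, unpaired_a, unpaired_b).
    """
    if not genes_a or not genes_b:
        raise ValueError("both gene sets must be non-empty")
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for ida, sa in genes_a.items():
        for idb, sb in genes_b.items():
            res = local_align(sa, sb, **aligner_params)
            scores[(ida, idb)] = (res.score, res.identity)

    def best_of(candidates: Iterable[tuple[str, tuple[float, float]]]) -> str:
        # highest score, then highest identity, then lexically smallest id
        return min(candidates, key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0]

    best_a = {ida: best_of((idb, scores[(ida, idb)]) for idb in genes_b)
              for ida in genes_a}
    best_b = {idb: best_of((ida, scores[(ida, idb)]) for ida in genes_a)
              for idb in genes_b}
    pairs = sorted((ida, idb) for ida, idb in best_a.items() if best_b[idb] == ida)
    paired_a = {a for a, _ in pairs}
    paired_b = {b for _, b in pairs}
    return (pairs,
            sorted(set(genes_a) - paired_a),
            sorted(set(genes_b) - paired_b))


# ---------------------------------------------------------------------------
# coding potential
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _longest_orf(seq: str) -> tuple[Optional[int], int]:
    """(start, length in aa) of the longest ATG-initiated ORF over the three
    forward frames; aa length excludes the stop codon. ORFs reaching the end
    of the sequence without a stop are counted to the last full codon."""
    s = seq.upper()
    best: tuple[Optional[int], int] = (None, 0)
    for frame in range(3):
        open_start: Optional[int] = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i:i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in _STOPS:
                aa = (i - open_start) // 3
                if aa > best[1]:
                    best = (open_start, aa)
                open_start = None
        if open_start is not None:  # runs off the end without a stop
            aa = (len(s) - open_start) // 3
            if aa > best[1]:
                best = (open_start, aa)
    return best


def assess_coding_potential(sequence: str, min_orf_aa: int = 25) -> tuple[bool, Optional[int]]:
    """Coding-potential call: the longest forward-frame, ATG-initiated ORF.

    Returns ``(coding, orf_length_aa)``; ``coding`` is False (and the length
    None) when no ORF of at least ``min_orf_aa`` amino acids exists. The
    length excludes the stop codon; genes are supplied stranded, so only the
    given orientation is scanned.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    _, aa = _longest_orf(sequence)
    if aa >= min_orf_aa:
        return True, aa
    return False, None


def summarize_repertoire(records: Sequence[GeneRecord]) -> dict[str, int]:
    """Counts of {total, retrogenes, coding_retrogenes} over a record set."""
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in repertoire")
    return {
        "total": len(records),
        "retrogenes": sum(r.is_retrogene for r in records),
        "coding_retrogenes": sum(r.is_retrogene and r.coding_potential for r in records),
    }


# ---------------------------------------------------------------------------
# diagnostic indels
# ---------------------------------------------------------------------------

def find_diagnostic_indels(msa: dict[str, str], ingroup_ids: Sequence[str],
                           outgroup_ids: Sequence[str], min_len: int = 15,
                           max_len: int = 30,
                           min_ingroup_frac: float = 1.0) -> list[DiagnosticIndel]:
    """Maximal gap blocks shared by the ingroup and absent from the outgroup.

    A column qualifies when at least ``min_ingroup_frac`` of ingroup rows are
    gapped and every outgroup row is ungapped there; maximal runs of
    qualifying columns with length in [min_len, max_len] are reported.
    """
    ingroup = list(ingroup_ids)
    outgroup = list(outgroup_ids)
    if set(ingroup) & set(outgroup):
        raise ValueError("ingroup and outgroup overlap")
    for gid in ingroup + outgroup:
        if gid not in msa:
            raise KeyError(f"{gid} missing from MSA")
    lengths = {len(msa[g]) for g in ingroup + outgroup}
    if len(lengths) != 1:
        raise ValueError("ragged MSA: rows differ in length")
    ncol = lengths.pop()
    rows_in = np.array([[c == "-" for c in msa[g]] for g in ingroup])
    rows_out = np.array([[c == "-" for c in msa[g]] for g in outgroup]) \
        if outgroup else np.zeros((0, ncol), dtype=bool)
    frac_in = rows_in.mean(axis=0)
    qual = (frac_in >= min_ingroup_frac) & ~rows_out.any(axis=0)

    out: list[DiagnosticIndel] = []
    i = 0
    while i < ncol:
        if qual[i]:
            j = i
            while j < ncol and qual[j]:
                j += 1
            if min_len <= j - i <= max_len:
                out.append(DiagnosticIndel(i, j, j - i,
                                           float(frac_in[i:j].min()), True))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# amplicon prediction
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _find_sites(template: str, probe: str, max_mismatch: int) -> list[int]:
    hits = []
    n, m = len(template), len(probe)
    for i in range(n - m + 1):
        mm = sum(1 for x, y in zip(template[i:i + m], probe) if x != y)
        if mm <= max_mismatch:
            hits.append(i)
    return hits


def predict_amplicon(template: str, primers: PrimerPair,
                     max_mismatch: int = 0) -> AmpliconPrediction:
    """Predicted PCR product length(s) for a primer pair on a template.

    The forward primer must match the template and the reverse primer's
    reverse complement must match downstream of it; the product runs from the
    forward site start to the reverse site end. Multiple site combinations
    are all reported with the ambiguity flag set.
    """
    t = template.upper()
    fwd_sites = _find_sites(t, primers.forward, max_mismatch)
    rev_sites = _find_sites(t, _revcomp(primers.reverse), max_mismatch)
    lengths = sorted({
        (r + len(primers.reverse)) - f
        for f in fwd_sites
        for r in rev_sites
        if r >= f + len(primers.forward)
    })
    return AmpliconPrediction(tuple(lengths), ambiguous=len(lengths) > 1)


# ---------------------------------------------------------------------------
# duplication-mechanism classification
# ---------------------------------------------------------------------------

def _flank_identity(a: str, b: str) -> float:
    """Percent identity between two flanks: per-site for equal lengths,
    edit-distance based otherwise."""
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * matches / len(a) if a else 0.0
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(a), len(b)))


def classify_expansion_mechanism(loci, identity_threshold: float = 80.0) -> dict[str, str]:
    """Call each duplicate segmental or independently retrotransposed.

    A duplicate is ``segmental_duplication`` when its flank identity to the
    parent locus is at least ``identity_threshold`` percent AND its TE
    fingerprint labels match the parent's; otherwise
    ``independent_retrotransposition``. Loci without a parent (family
    founder, source gene) are not classified; loci missing flank sequence
    are skipped with a warning.
    """
    by_id = {l.gene_id: l for l in loci}
    calls: dict[str, str] = {}
    for locus in loci:
        if locus.parent_gene is None or getattr(locus, "mechanism", "") == "parent":
            continue
        parent = by_id.get(locus.parent_gene)
        if parent is None:
            warnings.warn(f"{locus.gene_id}: parent locus {locus.parent_gene} absent; skipped")
            continue
        if not (locus.flank_left and locus.flank_right
                and parent.flank_left and parent.flank_right):
            warnings.warn(f"{locus.gene_id}: missing flank sequence; skipped")
            continue
        ident = (_flank_identity(locus.flank_left, parent.flank_left)
                 + _flank_identity(locus.flank_right, parent.flank_right)) / 2
        same_prints = tuple(locus.fingerprints) == tuple(parent.fingerprints)
        calls[locus.gene_id] = (
            "segmental_duplication"
            if ident >= identity_threshold and same_prints
            else "independent_retrotransposition"
        )
    return calls
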