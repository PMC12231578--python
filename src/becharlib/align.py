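"""Pairwise alignment and per-allele edit calling.

Global (Needleman-Wunsch) alignment of each read against its target-site
reference yields the substitution and indel calls that define an allele;
local (Smith-Waterman) scoring assigns reads to references.  Scoring follows
amplicon-quantification convention: substitutions are cheap relative to gaps,
so a point edit is never explained away as an insertion/deletion pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align

from .seqs import is_dna

# global (allele-calling) scoring
MATCH = 5
MISMATCH = -4
GAP_OPEN = -8
GAP_EXTEND = -2

# local (read-assignment) scoring
LOCAL_MATCH = 2
LOCAL_MISMATCH = -3
LOCAL_GAP_OPEN = -5
LOCAL_GAP_EXTEND = -1


@dataclass(frozen=True)
class AlignedPair:
    """A gapped alignment: two equal-length rows with '-' for gaps."""

    ref_row: str
    query_row: str
    score: float

    def edit_ops(self) -> list[tuple[int, str, str, str]]:
        """Per-event edit calls as (ref_pos, kind, ref, alt).

        ``ref_pos`` is the 0-based reference coordinate of a substitution or
        deletion, or of the reference base immediately right of an insertion.
        Runs of gaps are reported as single multi-base events.
        """
        ops: list[tuple[int, str, str, str]] = []
        ref_pos = 0
        i = 0
        n = len(self.ref_row)
        while i < n:
            r, q = self.ref_row[i], self.query_row[i]
            if r != "-" and q != "-":
                if r != q:
                    ops.append((ref_pos, "sub", r, q))
                ref_pos += 1
                i += 1
            elif q == "-":  # deletion from the reference
                j = i
                while j < n and self.query_row[j] == "-":
                    j += 1
                deleted = self.ref_row[i:j]
                ops.append((ref_pos, "del", deleted, ""))
                ref_pos += len(deleted)
                i = j
            else:  # insertion relative to the reference
                j = i
                while j < n and self.ref_row[j] == "-":
                    j += 1
                inserted = self.query_row[i:j]
                ops.append((ref_pos, "ins", "", inserted))
                i = j
        return ops


@lru_cache(maxsize=1)
def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@lru_cache(maxsize=1)
def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = LOCAL_MATCH
    aligner.mismatch_score = LOCAL_MISMATCH
    aligner.open_gap_score = LOCAL_GAP_OPEN
    aligner.extend_gap_score = LOCAL_GAP_EXTEND
    return aligner


def global_align(query: str, reference: str) -> AlignedPair:
    """Optimal global alignment of ``query`` against ``reference``.

    Ties between co-optimal alignments are broken deterministically (first
    traceback); under the adopted scoring a substitution always outscores a
    gap pair, so ties only concern gap placement.
    """
    if not query or not reference:
        raise ValueError("sequences must be nonempty")
    if not (is_dna(query) and is_dna(reference)):
        raise ValueError("sequences must be A/C/G/T only")
    alignment = next(iter(_global_aligner().align(reference, query)))
    return AlignedPair(ref_row=str(alignment[0]), query_row=str(alignment[1]),
                       score=float(alignment.score))


def local_score(read: str, reference: str) -> float:
    """Best local-alignment score of ``read`` against ``reference``
    (score only, no traceback)."""
    return float(_local_aligner().score(reference, read))
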