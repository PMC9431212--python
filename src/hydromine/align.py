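"""Local-alignment engine shared by the search and threshold stages.

Smith-Waterman with BLOSUM62, gap open 11 / extend 1 — the scoring that
protein-vs-protein BLAST uses by default — so that identities computed
internally are commensurate with ingested BLAST tabular output.
E-values follow the Karlin-Altschul formula E = K * m * n * exp(-lambda*S)
with the standard gapped constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
LAMBDA = 0.267
K = 0.041

LN2 = math.log(2.0)


@lru_cache(maxsize=1)
def get_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """Summary of the optimal local alignment of two sequences."""

    score: float
    identities: int
    mismatches: int
    gaps: int

    @property
    def length(self) -> int:
        """Alignment length including gap columns."""
        return self.identities + self.mismatches + self.gaps

    @property
    def percent_identity(self) -> float:
        if self.length == 0:
            return 0.0
        return 100.0 * self.identities / self.length


def align_local(a: str, b: str) -> LocalAlignment | None:
    """Optimal local alignment of two sequences, or None if no positive score."""
    aligner = get_aligner()
    score = aligner.score(a, b)
    if score <= 0:
        return None
    best = aligner.align(a, b)[0]
    counts = best.counts()
    return LocalAlignment(
        score=score,
        identities=counts.identities,
        mismatches=counts.mismatches,
        gaps=counts.internal_gaps,
    )


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the optimal local alignment, in [0, 100].

    Identity = 100 * identical columns / alignment length (gap columns
    included).  Returns 0.0 when no positive-scoring local alignment
    exists.  The pair is ordered canonically before alignment so the
    function is exactly symmetric even when traceback ties exist.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if b < a:
        a, b = b, a
    aln = align_local(a, b)
    return aln.percent_identity if aln is not None else 0.0


def evalue(score: float, query_len: int, search_space_len: int) -> float:
    """Karlin-Altschul expect value for a raw Smith-Waterman score."""
    return K * query_len * search_space_len * math.exp(-LAMBDA * score)


def bitscore(score: float) -> float:
    """Normalized (bit) score for a raw Smith-Waterman score."""
    return (LAMBDA * score - math.log(K)) / LN2
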