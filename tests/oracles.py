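"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the motif oracle
enumerates every start position and every gap width recursively; the
vote oracle recounts labels naively; the alignment oracle is a separate
affine-gap local-alignment dynamic program that additionally tracks the
set of (identities, length) pairs achievable by co-optimal alignments.
"""

from __future__ import annotations

from collections import defaultdict

from hydromine.motifs import MotifPattern, region_slice


# ---------------------------------------------------------------- motifs

def brute_force_scan(sequence: str, pattern: MotifPattern) -> set[tuple[int, int]]:
    """All (start, end) matches (1-based inclusive) by exhaustive enumeration."""
    offset, sub = region_slice(
        sequence, pattern.region, pattern.effective_window(len(sequence))
    )
    tokens = list(pattern.tokens)
    found: set[tuple[int, int]] = set()

    def extend(pos: int, remaining) -> None:
        if not remaining:
            found.add((start + 1 + offset, pos + offset))
            return
        tok = remaining[0]
        for width in range(tok.min_repeat, tok.max_repeat + 1):
            segment = sub[pos : pos + width]
            if len(segment) == width and all(c in tok.residues for c in segment):
                extend(pos + width, remaining[1:])

    for start in range(len(sub)):
        extend(start, tokens)
    return found


# ---------------------------------------------------------------- voting

def brute_force_vote(labels: list[str]) -> tuple[str, bool]:
    """(winner, tie_broken) for an ordered list of top-hit class labels."""
    counts = {lab: labels.count(lab) for lab in set(labels)}
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    if len(winners) == 1:
        return winners[0], False
    return labels[0], True


# ---------------------------------------------------------------- alignment

def local_alignment_oracle(
    a: str,
    b: str,
    matrix,
    open_score: float = -11.0,
    extend_score: float = -1.0,
) -> tuple[float, set[tuple[int, int]]]:
    """Affine-gap Smith-Waterman oracle for short sequences.

    ``open_score`` is the score of the first gap column and
    ``extend_score`` of each further column.  Returns (best score, set of
    (identities, alignment_length) pairs over all co-optimal local
    alignments); the score is 0 with an empty set when no positive-scoring
    alignment exists.  States H (last column aligned), E/F (last column a
    gap) each map score -> set of (identities, length) partial outcomes.
    """
    m, n = len(a), len(b)
    H = [[defaultdict(set) for _ in range(n + 1)] for _ in range(m + 1)]
    E = [[defaultdict(set) for _ in range(n + 1)] for _ in range(m + 1)]
    F = [[defaultdict(set) for _ in range(n + 1)] for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = matrix[a[i - 1], b[j - 1]]
            ident = 1 if a[i - 1] == b[j - 1] else 0
            cell = H[i][j]
            # start a fresh alignment with this aligned pair
            if s > 0:
                cell[s].add((ident, 1))
            for prev in (H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]):
                for sc, outcomes in prev.items():
                    nsc = sc + s
                    if nsc > 0:
                        for idn, ln in outcomes:
                            cell[nsc].add((idn + ident, ln + 1))
            for src, gap in ((H[i][j - 1], open_score), (E[i][j - 1], extend_score)):
                for sc, outcomes in src.items():
                    nsc = sc + gap
                    for idn, ln in outcomes:
                        E[i][j][nsc].add((idn, ln + 1))
            for src, gap in ((H[i - 1][j], open_score), (F[i - 1][j], extend_score)):
                for sc, outcomes in src.items():
                    nsc = sc + gap
                    for idn, ln in outcomes:
                        F[i][j][nsc].add((idn, ln + 1))
            if cell:
                best = max(best, max(cell))
    if best <= 0:
        return 0.0, set()
    outcomes: set[tuple[int, int]] = set()
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if best in H[i][j]:
                outcomes |= H[i][j][best]
    return best, outcomes
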