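"""Class assignment by majority vote over the top retained hits.

The vote is taken over the top four retained hits (fewer when the
thresholding leaves fewer).  "Majority" is read as strict plurality: a
label wins outright only when its count strictly exceeds every other
label's; any tie (2-2, or all distinct) falls back to the class of the
top hit.  Voting granularity follows the hits: subgroup labels are used
when every voted hit carries one, otherwise the vote is taken at group
level.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .core import HydClass
from .homology import AlignmentHit

DEFAULT_TOP_K = 4


@dataclass
class ClassAssignment:
    query_id: str
    predicted_class: HydClass
    vote_detail: list[tuple[str, HydClass]] = field(default_factory=list)
    tie_broken: bool = False
    n_hits_used: int = 0
    mixed_metal_types: bool = False


def assign_class(
    retained_sorted_hits: Sequence[AlignmentHit],
    k: int = DEFAULT_TOP_K,
) -> ClassAssignment | None:
    """Vote a class from the top ``min(k, n)`` retained hits; None if no hits."""
    if not retained_sorted_hits:
        return None
    top = list(retained_sorted_hits[:k])
    # Vote at subgroup granularity only if every voted hit resolves to one.
    use_subgroup = all(h.subject_class.subgroup is not None for h in top)
    def vote_class(h: AlignmentHit) -> HydClass:
        return h.subject_class if use_subgroup else h.subject_class.at_group_level()

    counts = Counter(vote_class(h).label for h in top)
    ordered = counts.most_common()
    if len(ordered) == 1 or ordered[0][1] > ordered[1][1]:
        winner_label = ordered[0][0]
        tie_broken = False
    else:
        winner_label = vote_class(top[0]).label
        tie_broken = True
    winner = next(vote_class(h) for h in top if vote_class(h).label == winner_label)
    metals = {h.subject_class.metal_type for h in top}
    return ClassAssignment(
        query_id=top[0].query_id,
        predicted_class=winner,
        vote_detail=[(h.subject_id, h.subject_class) for h in top],
        tie_broken=tie_broken,
        n_hits_used=len(top),
        mixed_metal_types=len(metals) > 1,
    )
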