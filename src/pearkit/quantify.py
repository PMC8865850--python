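"""Per-sample editing, indel and specificity summaries.

Editing% is the fraction of reads carrying the intended modification (for
substitution edits, additionally free of indels); indel% is the fraction of
reads carrying a byproduct indel within the nick-site window; specificity is
editing% / indel% with the denominator floored at 0.05% — the conventional
resolution limit of amplicon sequencing — to avoid spuriously high ratios.
By default the denominator of both percentages is the total read count,
including filtered reads; ``denominator="passing"`` restricts it to reads
that survived the anchor filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .align import ReadClass

__all__ = ["QuantResult", "quantify_sample", "specificity", "INDEL_FLOOR_PCT"]

#: Default floor (in percent) applied to indel% in the specificity ratio.
INDEL_FLOOR_PCT = 0.05


def specificity(
    editing_pct: float, indel_pct: float, floor: float = INDEL_FLOOR_PCT
) -> float:
    """editing% / max(indel%, floor); 0.0 when editing% is 0."""
    if editing_pct < 0 or indel_pct < 0:
        raise ValueError("percentages must be >= 0")
    return editing_pct / max(indel_pct, floor)


@dataclass(frozen=True)
class QuantResult:
    """Aggregate classification counts and derived rates for one sample."""

    n_total: int
    n_intended: int
    n_indel: int
    n_unedited: int
    n_filtered: int
    editing_pct: float
    indel_pct: float
    specificity: float
    all_filtered: bool = False

    def __post_init__(self) -> None:
        if self.n_total != (
            self.n_intended + self.n_indel + self.n_unedited + self.n_filtered
        ):
            raise ValueError("label counts do not sum to n_total")


def quantify_sample(
    classes: Sequence[ReadClass],
    indel_floor: float = INDEL_FLOOR_PCT,
    denominator: str = "total",
) -> QuantResult:
    """Aggregate per-read classifications into the sample summary."""
    if not classes:
        raise ValueError("no reads")
    if denominator not in ("total", "passing"):
        raise ValueError(f"unknown denominator {denominator!r}")
    n_total = len(classes)
    n_intended = sum(c.label == "intended" for c in classes)
    n_indel = sum(c.label == "indel_byproduct" for c in classes)
    n_unedited = sum(c.label == "unedited" for c in classes)
    n_filtered = sum(c.label == "filtered" for c in classes)

    denom = n_total if denominator == "total" else n_total - n_filtered
    all_filtered = n_filtered == n_total
    if all_filtered:
        warnings.warn("all reads filtered", stacklevel=2)
    if denom == 0:
        editing_pct = indel_pct = 0.0
    else:
        editing_pct = 100.0 * n_intended / denom
        indel_pct = 100.0 * n_indel / denom
    return QuantResult(
        n_total=n_total,
        n_intended=n_intended,
        n_indel=n_indel,
        n_unedited=n_unedited,
        n_filtered=n_filtered,
        editing_pct=editing_pct,
        indel_pct=indel_pct,
        specificity=specificity(editing_pct, indel_pct, floor=indel_floor),
        all_filtered=all_filtered,
    )
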