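"""dsODN tag counting and off-target site filtering (GUIDE-seq style).

GUIDE-seq marks double-strand break sites by capture of a blunt 34-nt dsODN;
its presence in amplicon reads reports cleavage.  Tag integration is counted
by exact occurrence of the full dsODN, and of its 15-nt centre fragment, in
either orientation.  Candidate off-target sites are retained when they carry
at most seven mismatches against the target spacer (PAM excluded) and are
absent from background controls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .amplicon import reverse_complement

__all__ = [
    "DSODN_SEQUENCE",
    "DSODN_CENTER",
    "MAX_OFFTARGET_MISMATCHES",
    "OffTargetCandidate",
    "TagCount",
    "count_tags",
    "filter_offtargets",
]

#: The standard 34-nt GUIDE-seq dsODN.
DSODN_SEQUENCE = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"
#: Its 15-nt centre fragment (reverse complement: TTAACATATGACAAC).
DSODN_CENTER = "GTTGTCATATGTTAA"

MAX_OFFTARGET_MISMATCHES = 7


@dataclass(frozen=True)
class TagCount:
    """dsODN tag occurrence counts over a read set."""

    n_reads: int
    n_full_tag: int
    n_center_tag: int
    tag_pct_of_modified: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_full_tag <= self.n_center_tag <= self.n_reads):
            raise ValueError(
                "require 0 <= n_full_tag <= n_center_tag <= n_reads"
            )


@dataclass(frozen=True)
class OffTargetCandidate:
    """A candidate cleavage site: 20-nt protospacer (optionally +PAM),
    background status and read support."""

    site_seq: str
    in_background: bool = False
    read_count: int = 0
    locus: str = ""
    mismatches: Optional[int] = None
    retained: Optional[bool] = None


def count_tags(
    reads: Iterable[str],
    dsodn: str = DSODN_SEQUENCE,
    center: str = DSODN_CENTER,
    n_modified: Optional[int] = None,
) -> TagCount:
    """Count reads containing the full dsODN and/or its centre fragment.

    A read counts once per category if it contains the exact fragment in
    either orientation.  ``n_modified`` (reads classified as modified: indel
    or tag) sets the denominator of ``tag_pct_of_modified``; when omitted the
    percentage is left unset.
    """
    dsodn = dsodn.upper()
    center = center.upper()
    if center not in dsodn and center not in reverse_complement(dsodn):
        raise ValueError("inconsistent tag definition")
    dsodn_rc = reverse_complement(dsodn)
    center_rc = reverse_complement(center)
    n_reads = n_full = n_center = 0
    for read in reads:
        read = read.upper()
        n_reads += 1
        if center in read or center_rc in read:
            n_center += 1
        if dsodn in read or dsodn_rc in read:
            n_full += 1
    pct = None
    if n_modified is not None:
        pct = 100.0 * n_center / n_modified if n_modified else 0.0
    return TagCount(
        n_reads=n_reads, n_full_tag=n_full, n_center_tag=n_center,
        tag_pct_of_modified=pct,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def filter_offtargets(
    candidates: Sequence[OffTargetCandidate],
    target_spacer: str,
    max_mismatches: int = MAX_OFFTARGET_MISMATCHES,
) -> list[OffTargetCandidate]:
    """Retain candidates with <= ``max_mismatches`` against the spacer and
    absent from background, sorted by mismatch count then read support.

    The protospacer portion of each ``site_seq`` (its first ``len(spacer)``
    bases; a trailing 3-nt PAM is ignored) is compared position-wise.
    """
    spacer = target_spacer.upper()
    results = []
    for cand in candidates:
        site = cand.site_seq.upper()
        if len(site) not in (len(spacer), len(spacer) + 3):
            raise ValueError("site/spacer length mismatch")
        mm = _hamming(site[: len(spacer)], spacer)
        retained = mm <= max_mismatches and not cand.in_background
        results.append(replace(cand, mismatches=mm, retained=retained))
    retained_sites = [c for c in results if c.retained]
    retained_sites.sort(key=lambda c: (c.mismatches, -c.read_count))
    return retained_sites
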