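"""Splice-donor reporter logic and pegRNA construction.

The fluorescent reporter couples prime-editing activity to splicing: a split
fluorescent protein is interrupted by an intron whose 5' splice-donor site is
disabled; a prime edit that restores a functional donor context restores
splicing and hence fluorescence.  Donor activity is modelled as a lookup
against a registry of active 7-nt contexts (last exonic base + first six
intronic bases); the canonical donor is 5'-G-GT-AAGT-3' with the GT
dinucleotide obligatory.  Additional empirically active variants can be
registered (they are data, not code).

pegRNA geometry: the 3' extension is the reverse-transcriptase template (RT)
followed by the primer-binding site (PBS), read 5'->3'.  The PBS is the
reverse complement (as RNA) of the bases immediately 5' of the nick on the
protospacer strand; the RT template is the reverse complement (as RNA) of the
first ``rt_len`` bases of the *edited* sequence 3' of the nick on the
protospacer strand, and must span the intended edit.

Secondary ("complementary-strand") nicks are reported as signed offsets from
the primary nick measured along the targeted strand (the strand the spacer
anneals to): positive values are 3', negative 5', on that strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .amplicon import (
    SPACER_LEN,
    AmpliconSpec,
    ProtospacerMatch,
    cut_site,
    reverse_complement,
)

__all__ = [
    "CANONICAL_DONOR",
    "NickSpec",
    "PegRNA",
    "SpliceSite",
    "SpliceSiteRegistry",
    "design_pegrna",
    "enumerate_nicks",
    "splice_state",
]

#: Canonical 5' splice-donor context: last exonic base, obligatory GT
#: dinucleotide opening the intron, and the next four intronic bases.
CANONICAL_DONOR = "GGTAAGT"

_DNA = frozenset("ACGT")


def _to_rna(dna: str) -> str:
    return dna.replace("T", "U")


class SpliceSiteRegistry:
    """Registry of 7-nt donor contexts considered splicing-active.

    Seeded with the canonical donor; empirically validated variants are added
    with :meth:`register`.
    """

    def __init__(self, active: Optional[Iterable[str]] = None) -> None:
        self._active: set[str] = {CANONICAL_DONOR}
        for ctx in active or ():
            self.register(ctx)

    def register(self, context: str) -> None:
        self._active.add(_validate_context(context))

    def __contains__(self, context: str) -> bool:
        return context in self._active

    @property
    def active_contexts(self) -> frozenset[str]:
        return frozenset(self._active)


_DEFAULT_REGISTRY = SpliceSiteRegistry()


def _validate_context(context: str) -> str:
    if len(context) != 7 or set(context) - _DNA:
        raise ValueError("invalid donor context")
    return context


def splice_state(
    context: str, registry: Optional[SpliceSiteRegistry] = None
) -> str:
    """``"active"`` iff ``context`` is in the registered active set."""
    _validate_context(context)
    registry = registry if registry is not None else _DEFAULT_REGISTRY
    return "active" if context in registry else "inactive"


@dataclass(frozen=True)
class SpliceSite:
    """A donor context and its activity state."""

    context: str
    state: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", splice_state(self.context))


@dataclass(frozen=True)
class PegRNA:
    """A designed prime-editing guide: spacer + 3' extension (RT then PBS)."""

    spacer: str  # RNA, 20 nt
    pbs: str  # RNA
    rt_template: str  # RNA

    @property
    def extension(self) -> str:
        """The 3' extension read 5'->3': RT template then PBS."""
        return self.rt_template + self.pbs


@dataclass(frozen=True)
class NickSpec:
    """A candidate secondary nick on the complementary strand.

    ``offset`` is the signed nick-to-nick distance measured along the targeted
    strand (positive = 3' direction on the targeted DNA).
    """

    offset: int
    spacer: str  # protospacer-strand sequence of the secondary site (DNA)
    strand: str  # forward-strand orientation of the secondary protospacer
    protospacer_start: int
    cut_site: int  # forward-strand inter-base position


def design_pegrna(spec: AmpliconSpec, pbs_len: int, rt_len: int) -> PegRNA:
    """Construct the pegRNA (spacer, PBS, RT template) for ``spec``.

    Raises ``ValueError`` if the RT template does not span the intended edit
    ("RT too short to encode edit") or either segment runs off the amplicon
    ("amplicon too short").
    """
    if pbs_len < 1 or rt_len < 1:
        raise ValueError("pbs_len and rt_len must be >= 1")
    ps_ref = spec.protospacer_strand_ref
    ps_edited = spec.protospacer_strand_edited
    nick = spec.nick_on_protospacer_strand
    if nick - pbs_len < 0 or nick + rt_len > len(ps_edited):
        raise ValueError("amplicon too short")

    # the edit must lie strictly 3' of the nick on the protospacer strand and
    # be fully covered by the RT span: outside it, edited == reference
    delta = spec.edit.length_change
    if ps_edited[:nick] != ps_ref[:nick]:
        raise ValueError("edit lies 5' of the nick; prime editing writes 3'")
    if ps_edited[nick + rt_len :] != ps_ref[nick + rt_len - delta :]:
        raise ValueError("RT too short to encode edit")

    pbs_dna = ps_ref[nick - pbs_len : nick]
    rt_dna = ps_edited[nick : nick + rt_len]
    return PegRNA(
        spacer=_to_rna(spec.spacer),
        pbs=_to_rna(reverse_complement(pbs_dna)),
        rt_template=_to_rna(reverse_complement(rt_dna)),
    )


def enumerate_nicks(spec: AmpliconSpec, search_range: int) -> list[NickSpec]:
    """All complementary-strand protospacers (NGG PAM) whose nick falls within
    ``search_range`` nt of the primary nick, with signed offsets.

    Offsets follow the targeted-strand convention: the targeted strand is the
    strand the pegRNA spacer anneals to (the complement of the protospacer
    strand); positive offsets are displacements in its 3' direction.
    """
    if search_range <= 0:
        raise ValueError("search_range must be > 0")
    ref = spec.ref_seq
    n = len(ref)
    other = "-" if spec.strand == "+" else "+"
    # 3' direction of the targeted strand, in forward coordinates
    direction = -1 if spec.strand == "+" else +1

    hits: list[NickSpec] = []
    if other == "+":
        candidates = (
            (i, ref[i : i + SPACER_LEN])
            for i in range(0, n - SPACER_LEN - 2)
            if ref[i + SPACER_LEN + 1 : i + SPACER_LEN + 3] == "GG"
        )
    else:
        rc = reverse_complement(ref)
        candidates = (
            (n - (j + SPACER_LEN), rc[j : j + SPACER_LEN])
            for j in range(0, n - SPACER_LEN - 2)
            if rc[j + SPACER_LEN + 1 : j + SPACER_LEN + 3] == "GG"
        )
    for start, spacer in candidates:
        cut = cut_site(ProtospacerMatch(strand=other, start=start))
        offset = direction * (cut - spec.cut_site)
        if abs(offset) <= search_range:
            hits.append(
                NickSpec(
                    offset=offset, spacer=spacer, strand=other,
                    protospacer_start=start, cut_site=cut,
                )
            )
    hits.sort(key=lambda h: (abs(h.offset), h.offset))
    return hits
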