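"""Target geometry for amplicon-based prime-editing analysis.

An :class:`AmpliconSpec` ties together a reference amplicon, the SpCas9
protospacer addressed by a pegRNA, the nick ("cut") site implied by that
protospacer, and the intended edit.  All downstream read classification,
quantification and pegRNA design work in the coordinate frame defined here:
0-based, half-open intervals on the forward strand of the reference amplicon,
with nick sites represented as inter-base integers (the index of the first
base 3' of the nick on the forward strand).

The nick is placed between protospacer positions 17 and 18 (1-based on the
protospacer strand), i.e. 3 nt 5' of the NGG PAM — the standard SpCas9
(H840A nickase) geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AmbiguousTargetError",
    "AmpliconSpec",
    "EditSpec",
    "ProtospacerMatch",
    "TargetNotFoundError",
    "apply_edit",
    "cut_site",
    "find_protospacer",
    "invert_edit",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA = frozenset("ACGT")

SPACER_LEN = 20
#: 0-based protospacer index of the first base 3' of the nick (blunt SpCas9 nick
#: between protospacer positions 17/18, counting the protospacer 1..20).
NICK_INDEX = 17


class TargetNotFoundError(ValueError):
    """The spacer (followed by an NGG PAM) does not occur in the reference."""


class AmbiguousTargetError(ValueError):
    """The spacer+PAM occurs more than once; the target is ambiguous."""


def _check_dna(seq: str, what: str = "sequence") -> str:
    if not seq or set(seq) - _DNA:
        raise ValueError(
            f"invalid {what}: must be non-empty uppercase A/C/G/T, got {seq!r}"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class EditSpec:
    """An intended edit in forward-strand amplicon coordinates.

    ``position`` is the 0-based forward-strand offset of the first reference
    base affected (for insertions, the base before which ``alt_allele`` is
    inserted).  ``ref_allele`` is empty for insertions; ``alt_allele`` is empty
    for deletions; substitutions replace ``ref_allele`` with an equal-length
    ``alt_allele``.
    """

    kind: str
    position: int
    ref_allele: str = ""
    alt_allele: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.position < 0:
            raise ValueError("edit position must be >= 0")
        for allele, name in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if allele and set(allele) - _DNA:
                raise ValueError(f"{name}_allele must be uppercase A/C/G/T")
        if self.kind == "substitution":
            if not (len(self.ref_allele) == len(self.alt_allele) >= 1):
                raise ValueError(
                    "substitution requires equal-length non-empty alleles"
                )
        elif self.kind == "insertion":
            if self.ref_allele or not self.alt_allele:
                raise ValueError(
                    "insertion requires empty ref_allele and non-empty alt_allele"
                )
        else:  # deletion
            if self.alt_allele or not self.ref_allele:
                raise ValueError(
                    "deletion requires non-empty ref_allele and empty alt_allele"
                )

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


def apply_edit(seq: str, edit: EditSpec) -> str:
    """Apply ``edit`` to ``seq``; the result length changes by len(alt)-len(ref)."""
    _check_dna(seq)
    end = edit.position + len(edit.ref_allele)
    if end > len(seq):
        raise ValueError("edit inconsistent with reference: runs past sequence end")
    if seq[edit.position : end] != edit.ref_allele:
        raise ValueError(
            "edit inconsistent with reference: expected "
            f"{edit.ref_allele!r} at position {edit.position}, "
            f"found {seq[edit.position:end]!r}"
        )
    return seq[: edit.position] + edit.alt_allele + seq[end:]


def invert_edit(edit: EditSpec) -> EditSpec:
    """The edit that undoes ``edit`` on the edited sequence."""
    kind = {
        "substitution": "substitution",
        "insertion": "deletion",
        "deletion": "insertion",
    }[edit.kind]
    return EditSpec(
        kind=kind,
        position=edit.position,
        ref_allele=edit.alt_allele,
        alt_allele=edit.ref_allele,
    )


@dataclass(frozen=True)
class ProtospacerMatch:
    """A protospacer occurrence in forward-strand coordinates.

    ``start`` is the forward-strand offset of the leftmost base of the 20-nt
    protospacer interval ``[start, start+20)`` regardless of strand.
    """

    strand: str
    start: int
    pam_ok: bool = True

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + SPACER_LEN)


def find_protospacer(ref_seq: str, spacer: str) -> ProtospacerMatch:
    """Locate the unique occurrence of ``spacer`` followed by NGG, either strand.

    Raises :class:`TargetNotFoundError` if no NGG-adjacent occurrence exists
    and :class:`AmbiguousTargetError` if more than one does.
    """
    _check_dna(ref_seq, "reference")
    _check_dna(spacer, "spacer")
    if len(spacer) != SPACER_LEN:
        raise ValueError(f"spacer length must be {SPACER_LEN}, got {len(spacer)}")
    if len(ref_seq) < SPACER_LEN + 3:
        raise ValueError("reference too short to contain a protospacer and PAM")

    matches: list[ProtospacerMatch] = []
    # forward strand: spacer at i, PAM = ref[i+20:i+23] matching NGG
    i = ref_seq.find(spacer)
    while i != -1:
        pam = ref_seq[i + SPACER_LEN : i + SPACER_LEN + 3]
        if len(pam) == 3 and pam[1:] == "GG":
            matches.append(ProtospacerMatch(strand="+", start=i))
        i = ref_seq.find(spacer, i + 1)
    # reverse strand: search the reverse complement, map back
    rc = reverse_complement(ref_seq)
    n = len(ref_seq)
    j = rc.find(spacer)
    while j != -1:
        pam = rc[j + SPACER_LEN : j + SPACER_LEN + 3]
        if len(pam) == 3 and pam[1:] == "GG":
            matches.append(
                ProtospacerMatch(strand="-", start=n - (j + SPACER_LEN))
            )
        j = rc.find(spacer, j + 1)

    if not matches:
        raise TargetNotFoundError("target not found")
    if len(matches) > 1:
        raise AmbiguousTargetError("ambiguous target")
    return matches[0]


def cut_site(match: ProtospacerMatch) -> int:
    """Inter-base nick position on the forward strand for ``match``.

    Returned as the forward-strand index of the first base 3' of the nick
    (so the nick lies between indices ``cut-1`` and ``cut``).
    """
    if match.strand == "+":
        return match.start + NICK_INDEX
    if match.strand == "-":
        return match.start + (SPACER_LEN - NICK_INDEX)
    raise ValueError(f"invalid strand {match.strand!r}")


@dataclass(frozen=True)
class AmpliconSpec:
    """A reference amplicon plus its protospacer, nick site and intended edit."""

    name: str
    ref_seq: str
    spacer: str
    protospacer_start: int
    strand: str
    cut_site: int
    edit: EditSpec
    edited_seq: str = field(default="")

    def __post_init__(self) -> None:
        _check_dna(self.ref_seq, "reference")
        _check_dna(self.spacer, "spacer")
        if len(self.spacer) != SPACER_LEN:
            raise ValueError("spacer length must be 20")
        match = ProtospacerMatch(strand=self.strand, start=self.protospacer_start)
        # protospacer and PAM must sit where claimed
        s, e = match.interval
        if self.strand == "+":
            found = self.ref_seq[s:e]
            pam = self.ref_seq[e : e + 3]
        else:
            found = reverse_complement(self.ref_seq[s:e])
            pam = reverse_complement(self.ref_seq[s - 3 : s])
        if found != self.spacer:
            raise ValueError("protospacer_start inconsistent with spacer sequence")
        if len(pam) != 3 or pam[1:] != "GG":
            raise ValueError("no NGG PAM 3' of the protospacer")
        if self.cut_site != cut_site(match):
            raise ValueError("cut_site inconsistent with SpCas9 nick geometry")
        if not 0 < self.cut_site < len(self.ref_seq):
            raise ValueError("cut site must lie strictly inside the amplicon")
        expected = apply_edit(self.ref_seq, self.edit)
        if not self.edited_seq:
            object.__setattr__(self, "edited_seq", expected)
        elif self.edited_seq != expected:
            raise ValueError("edited_seq does not equal apply_edit(ref_seq, edit)")

    @classmethod
    def from_sequences(
        cls, name: str, ref_seq: str, spacer: str, edit: EditSpec
    ) -> "AmpliconSpec":
        """Build a spec by locating the protospacer and deriving nick and edit."""
        match = find_protospacer(ref_seq, spacer)
        return cls(
            name=name,
            ref_seq=ref_seq,
            spacer=spacer,
            protospacer_start=match.start,
            strand=match.strand,
            cut_site=cut_site(match),
            edit=edit,
        )

    @property
    def protospacer_strand_ref(self) -> str:
        """Reference sequence read 5'->3' on the protospacer strand."""
        return self.ref_seq if self.strand == "+" else reverse_complement(self.ref_seq)

    @property
    def protospacer_strand_edited(self) -> str:
        """Edited sequence read 5'->3' on the protospacer strand."""
        return (
            self.edited_seq
            if self.strand == "+"
            else reverse_complement(self.edited_seq)
        )

    @property
    def nick_on_protospacer_strand(self) -> int:
        """Inter-base nick position in protospacer-strand coordinates."""
        if self.strand == "+":
            return self.cut_site
        return len(self.ref_seq) - self.cut_site
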