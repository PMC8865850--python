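"""Semi-global read alignment and per-read classification.

Reads are aligned globally in the read with free end gaps in the reference
(the read must be fully explained; unaligned reference flanks are free), under
affine gap scores: match +1, mismatch -1, gap open -4 (covering the first
gapped base), gap extend -1.  Classification then follows the amplicon
deep-sequencing rules used for prime-editing quantification:

* reads must match at least 75% of the first 20 bp of the reference amplicon
  (the "anchor"), otherwise they are filtered;
* byproduct indels are searched within +/-2 bp of the nick site, any length;
* for substitution edits a read is "intended" only if it carries the
  alternate allele and contains no indel anywhere; for insertion/deletion
  edits a read is "intended" if the alignment contains an indel exactly
  matching the programmed edit (after left-normalisation).

The aligner engine is Bio.Align.PairwiseAligner configured for these
semantics; a provably score-optimal gapless fast path covers the common case
of reads that differ from the reference prefix by at most two substitutions
(any alignment containing an interior gap scores at least 4 below the gapless
match count, so a gapless alignment with <=2 mismatches can only be tied, and
ties are resolved in favour of mismatches over gaps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .amplicon import AmpliconSpec, reverse_complement

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    from Bio import Align as _BioAlign

__all__ = [
    "AlnOp",
    "Alignment",
    "IndelCall",
    "ReadClass",
    "align_semi_global",
    "anchor_identity",
    "classify_read",
    "classify_reads",
    "detect_cutsite_indel",
]

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -4  # cost of the first gapped base
GAP_EXTEND = -1

ANCHOR_LEN = 20
ANCHOR_MIN_IDENTITY = 0.75
CUTSITE_WINDOW = 2


@dataclass(frozen=True)
class AlnOp:
    """One alignment operation.

    ``ref_pos``/``read_pos`` are the 0-based starting offsets of the operation
    in reference and read.  Insertions ("ins") consume read only; deletions
    ("del") consume reference only.
    """

    op: str  # match | mismatch | ins | del
    length: int
    ref_pos: int
    read_pos: int


@dataclass(frozen=True)
class Alignment:
    """A semi-global alignment of a read against a reference amplicon."""

    read: str
    ref: str
    ops: tuple[AlnOp, ...]
    score: float
    ref_start: int  # first reference position covered by the read
    ref_end: int  # one past the last covered reference position

    def ref_to_read(self) -> dict[int, Optional[int]]:
        """Map each covered reference position to the read position aligned to
        it (None under a deletion)."""
        mapping: dict[int, Optional[int]] = {}
        for op in self.ops:
            if op.op in ("match", "mismatch"):
                for k in range(op.length):
                    mapping[op.ref_pos + k] = op.read_pos + k
            elif op.op == "del":
                for k in range(op.length):
                    mapping[op.ref_pos + k] = None
        return mapping

    def indels(self) -> list["IndelCall"]:
        """All indel operations, left-normalised, without cut-site filtering."""
        calls = []
        for op in self.ops:
            if op.op == "ins":
                seq = self.read[op.read_pos : op.read_pos + op.length]
                pos, seq = _left_align_insertion(self.ref, op.ref_pos, seq)
                calls.append(
                    IndelCall(kind="ins", length=op.length, ref_position=pos,
                              inserted=seq)
                )
            elif op.op == "del":
                start, end = _left_align_deletion(
                    self.ref, op.ref_pos, op.ref_pos + op.length
                )
                calls.append(
                    IndelCall(kind="del", length=op.length,
                              ref_position=(start, end))
                )
        return calls


@dataclass(frozen=True)
class IndelCall:
    """A called indel relative to the reference.

    For insertions ``ref_position`` is the inter-base insertion point; for
    deletions it is the half-open deleted interval ``(start, end)``.
    ``distance_to_cut`` is filled by :func:`detect_cutsite_indel`.
    """

    kind: str
    length: int
    ref_position: object
    inserted: str = ""
    distance_to_cut: Optional[int] = None


@dataclass(frozen=True)
class ReadClass:
    """Classification of one read: filtered, intended, indel_byproduct or
    unedited, with the supporting indel call if any."""

    label: str
    indel: Optional[IndelCall] = None
    anchor_identity: float = float("nan")
    filter_reason: Optional[str] = None  # "anchor" | "short"


def _left_align_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    # shift the insertion left while the preceding reference base equals the
    # last inserted base (VCF-style normalisation)
    while pos > 0 and seq and ref[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    return pos, seq


def _left_align_deletion(ref: str, start: int, end: int) -> tuple[int, int]:
    while start > 0 and ref[start - 1] == ref[end - 1]:
        start -= 1
        end -= 1
    return start, end


def _make_aligner() -> "_BioAlign.PairwiseAligner":
    a = _BioAlign.PairwiseAligner()
    a.mode = "global"
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_internal_insertion_score = GAP_OPEN
    a.extend_internal_insertion_score = GAP_EXTEND
    a.open_internal_deletion_score = GAP_OPEN
    a.extend_internal_deletion_score = GAP_EXTEND
    # free unaligned reference flanks (target = reference)
    a.open_left_deletion_score = 0
    a.extend_left_deletion_score = 0
    a.open_right_deletion_score = 0
    a.extend_right_deletion_score = 0
    # the read must be fully aligned: overhangs beyond the reference ends are
    # scored as ordinary insertions
    a.open_left_insertion_score = GAP_OPEN
    a.extend_left_insertion_score = GAP_EXTEND
    a.open_right_insertion_score = GAP_OPEN
    a.extend_right_insertion_score = GAP_EXTEND
    return a


_ALIGNER = _make_aligner()


def _match_mismatch_runs(
    read: str, ref: str, ref_pos: int, read_pos: int, length: int
) -> list[AlnOp]:
    ops: list[AlnOp] = []
    run_start = 0
    run_kind = None
    for k in range(length):
        kind = "match" if ref[ref_pos + k] == read[read_pos + k] else "mismatch"
        if kind != run_kind:
            if run_kind is not None:
                ops.append(
                    AlnOp(run_kind, k - run_start, ref_pos + run_start,
                          read_pos + run_start)
                )
            run_kind = kind
            run_start = k
    if run_kind is not None:
        ops.append(
            AlnOp(run_kind, length - run_start, ref_pos + run_start,
                  read_pos + run_start)
        )
    return ops


def _gapless_alignment(read: str, ref: str) -> Optional[Alignment]:
    """Best gapless placement of the read, if provably optimal overall."""
    L, N = len(read), len(ref)
    if L > N:
        return None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    f = np.frombuffer(ref.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(f, L)
    mismatches = (win != r).sum(axis=1)
    offset = int(mismatches.argmin())  # leftmost best placement
    m = int(mismatches[offset])
    # any alignment with an interior gap scores <= L - 4 - (1 if read base
    # gapped); a gapless alignment with m mismatches scores L - 2m, so m <= 2
    # guarantees (tie-broken) optimality
    if m > 2:
        return None
    ops = _match_mismatch_runs(read, ref, offset, 0, L)
    return Alignment(
        read=read, ref=ref, ops=tuple(ops), score=float(L - 2 * m),
        ref_start=offset, ref_end=offset + L,
    )


def _ops_from_biopython(read: str, ref: str, coords: np.ndarray) -> tuple[
    list[AlnOp], int, int
]:
    ops: list[AlnOp] = []
    ncol = coords.shape[1]
    ref_start = None
    ref_end = None
    for c in range(ncol - 1):
        r0, r1 = int(coords[0, c]), int(coords[0, c + 1])
        q0, q1 = int(coords[1, c]), int(coords[1, c + 1])
        if r1 > r0 and q1 > q0:  # diagonal block
            if ref_start is None:
                ref_start = r0
            ref_end = r1
            ops.extend(_match_mismatch_runs(read, ref, r0, q0, r1 - r0))
        elif r1 > r0:  # reference consumed only
            if q0 == 0 or q0 == len(read):
                continue  # free end gap: unaligned reference flank
            ops.append(AlnOp("del", r1 - r0, r0, q0))
            if ref_start is None:
                ref_start = r0
            ref_end = r1
        elif q1 > q0:  # read consumed only: insertion
            ops.append(AlnOp("ins", q1 - q0, r0, q0))
    if ref_start is None:
        ref_start = int(coords[0, 0])
        ref_end = ref_start
    return ops, ref_start, ref_end


def align_semi_global(read: str, ref: str) -> Alignment:
    """Optimal global-in-read, free-end-gaps-in-reference alignment."""
    if not read or not ref:
        raise ValueError("empty sequence")
    fast = _gapless_alignment(read, ref)
    if fast is not None:
        return fast
    result = _ALIGNER.align(ref, read)
    aln = result[0]
    ops, ref_start, ref_end = _ops_from_biopython(read, ref, aln.coordinates)
    return Alignment(
        read=read, ref=ref, ops=tuple(ops), score=float(result.score),
        ref_start=ref_start, ref_end=ref_end,
    )


def anchor_identity(aln: Alignment, anchor_len: int = ANCHOR_LEN) -> float:
    """Fraction of the first ``anchor_len`` reference bases aligned to an
    identical read base (gaps and uncovered positions count as non-matches)."""
    matched = 0
    for op in aln.ops:
        if op.op != "match":
            continue
        lo = max(op.ref_pos, 0)
        hi = min(op.ref_pos + op.length, anchor_len)
        if hi > lo:
            matched += hi - lo
    return matched / anchor_len


def detect_cutsite_indel(
    aln: Alignment,
    cut: int,
    window: int = CUTSITE_WINDOW,
    mode: str = "nearest",
) -> Optional[IndelCall]:
    """Return the indel anchored within ``window`` nt of the nick, if any.

    ``mode="nearest"`` keys on the insertion point / nearest deletion boundary;
    ``mode="overlap"`` accepts any deletion whose interval comes within
    ``window`` of the nick.  Any indel length is accepted.  When several
    indels qualify the one closest to the nick is returned.
    """
    if mode not in ("nearest", "overlap"):
        raise ValueError(f"unknown window mode {mode!r}")
    best: Optional[IndelCall] = None
    for call in aln.indels():
        if call.kind == "ins":
            dist = call.ref_position - cut
            hit = abs(dist) <= window
        else:
            start, end = call.ref_position
            if start <= cut <= end:
                dist = 0
            else:
                dist = min(start - cut, end - cut, key=abs)
            if mode == "nearest":
                hit = abs(dist) <= window
            else:  # overlap: deleted interval comes within `window` of the nick
                hit = (start - window) <= cut <= (end + window)
        if hit:
            call = IndelCall(
                kind=call.kind, length=call.length,
                ref_position=call.ref_position, inserted=call.inserted,
                distance_to_cut=dist,
            )
            if best is None or abs(dist) < abs(best.distance_to_cut):
                best = call
    return best


def _normalised_intended_indel(spec: AmpliconSpec) -> Optional[IndelCall]:
    e = spec.edit
    if e.kind == "insertion":
        pos, seq = _left_align_insertion(spec.ref_seq, e.position, e.alt_allele)
        return IndelCall(kind="ins", length=len(seq), ref_position=pos,
                         inserted=seq)
    if e.kind == "deletion":
        start, end = _left_align_deletion(
            spec.ref_seq, e.position, e.position + len(e.ref_allele)
        )
        return IndelCall(kind="del", length=end - start, ref_position=(start, end))
    return None


def _matches_intended(call: IndelCall, intended: IndelCall) -> bool:
    if call.kind != intended.kind or call.length != intended.length:
        return False
    if call.ref_position != intended.ref_position:
        return False
    if call.kind == "ins" and call.inserted != intended.inserted:
        return False
    return True


def classify_read(
    read: str,
    spec: AmpliconSpec,
    window: int = CUTSITE_WINDOW,
    window_mode: str = "nearest",
    anchor_min_identity: float = ANCHOR_MIN_IDENTITY,
    both_strands: bool = False,
) -> ReadClass:
    """Classify one read as filtered / intended / indel_byproduct / unedited.

    With ``both_strands=True`` the reverse complement is also tried and the
    orientation with the better anchor identity is used.
    """
    if not read:
        raise ValueError("empty sequence")
    aln = align_semi_global(read, spec.ref_seq)
    ident = anchor_identity(aln)
    if both_strands:
        aln_rc = align_semi_global(reverse_complement(read), spec.ref_seq)
        ident_rc = anchor_identity(aln_rc)
        if ident_rc > ident:
            aln, ident = aln_rc, ident_rc

    # fewer than 20 aligned reference bases: filtered, counted separately
    if aln.ref_end - aln.ref_start < ANCHOR_LEN:
        return ReadClass(label="filtered", anchor_identity=ident,
                         filter_reason="short")
    if ident < anchor_min_identity:
        return ReadClass(label="filtered", anchor_identity=ident,
                         filter_reason="anchor")

    indel_ops = [op for op in aln.ops if op.op in ("ins", "del")]
    edit = spec.edit

    if edit.kind == "substitution":
        # intended: alternate allele present AND no indel anywhere in the read
        mapping = aln.ref_to_read()
        has_alt = True
        for k, alt_base in enumerate(edit.alt_allele):
            rp = mapping.get(edit.position + k)
            if rp is None or aln.read[rp] != alt_base:
                has_alt = False
                break
        if has_alt and not indel_ops:
            return ReadClass(label="intended", anchor_identity=ident)
        intended_indel = None
    else:
        intended_indel = _normalised_intended_indel(spec)
        for call in aln.indels():
            if _matches_intended(call, intended_indel):
                return ReadClass(label="intended", indel=call,
                                 anchor_identity=ident)

    call = detect_cutsite_indel(aln, spec.cut_site, window=window,
                                mode=window_mode)
    if call is not None and (
        intended_indel is None or not _matches_intended(call, intended_indel)
    ):
        return ReadClass(label="indel_byproduct", indel=call,
                         anchor_identity=ident)
    return ReadClass(label="unedited", anchor_identity=ident)


def classify_reads(
    reads: Sequence[str], spec: AmpliconSpec, **kwargs
) -> list[ReadClass]:
    """Classify every read in ``reads`` against ``spec``."""
    return [classify_read(r, spec, **kwargs) for r in reads]
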