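"""Synthetic amplicon reads and cell populations with known ground truth.

Two generators exercise the whole pipeline without external data:

* :func:`simulate_reads` draws single-end reads from a mixture of templates —
  the intended edited sequence, byproduct-indel sequences, and the unedited
  reference — truncated to the read length from the amplicon 5' end, with
  i.i.d. substitution errors (an optional indel-error rate is available for
  stress tests).  Quality strings are constant high quality; the downstream
  rules apply no quality filtering.

* :func:`simulate_population` draws cells through a Bernoulli hierarchy:
  transfection -> plasmid (reporter) editing -> genomic editing, with the
  genomic-editing probability conditional on reporter-editing status.  The
  premise that reporter-edited cells are genomically edited more often than
  merely transfected cells is what the enrichment gates exploit.  Observed
  fluorescence flags (BFP = transfection marker, GFP = reporter signal) are
  the latent states perturbed by false-positive/false-negative rates.

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, EditSpec, apply_edit

__all__ = [
    "PopulationParams",
    "ReadSimParams",
    "make_demo_amplicon",
    "simulate_population",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSimParams:
    """Mixture and error model for simulated amplicon reads.

    ``byproduct_indels`` is a list of ``(EditSpec, proportion)`` pairs; the
    proportion of unedited reads is the remainder after the intended fraction
    and all byproducts.
    """

    amplicon: AmpliconSpec
    n_reads: int
    frac_intended: float
    byproduct_indels: Sequence[tuple[EditSpec, float]] = ()
    per_base_error: float = 0.0
    indel_error_rate: float = 0.0
    read_len: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        fracs = [self.frac_intended] + [p for _, p in self.byproduct_indels]
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-12:
            raise ValueError("mixture proportions must lie in [0,1] and sum <= 1")
        if not 0 <= self.per_base_error <= 1:
            raise ValueError("per_base_error must lie in [0,1]")
        if self.read_len is None:
            object.__setattr__(self, "read_len", len(self.amplicon.ref_seq))
        if self.read_len > len(self.amplicon.ref_seq):
            raise ValueError("read_len exceeds amplicon length")
        edit = self.amplicon.edit
        edit_end = edit.position + max(len(edit.ref_allele), len(edit.alt_allele))
        if self.read_len < max(20, edit_end):
            raise ValueError("read too short for classification")


def _mutate(
    seq: np.ndarray, rng: np.random.Generator, per_base_error: float
) -> np.ndarray:
    if per_base_error <= 0:
        return seq
    hits = np.nonzero(rng.random(seq.size) < per_base_error)[0]
    if hits.size == 0:
        return seq
    seq = seq.copy()
    # replace with one of the three other bases, uniformly
    cur = np.searchsorted(_BASES, seq[hits])
    shift = rng.integers(1, 4, size=hits.size)
    seq[hits] = _BASES[(cur + shift) % 4]
    return seq


def _indel_errors(
    seq: np.ndarray, rng: np.random.Generator, rate: float
) -> np.ndarray:
    if rate <= 0 or rng.random() >= rate * seq.size:
        return seq
    pos = int(rng.integers(0, seq.size))
    if rng.random() < 0.5 and seq.size > 1:
        return np.delete(seq, pos)
    base = _BASES[rng.integers(0, 4)]
    return np.insert(seq, pos, base)


def simulate_reads(
    params: ReadSimParams,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate reads; returns (records, truth).

    ``records`` is a list of ``(read_id, sequence, quality)`` tuples ready for
    FASTQ serialisation; ``truth`` is a DataFrame with one row per read
    (read_id, category, template) where category is ``intended``,
    ``byproduct_<i>`` or ``unedited``.
    """
    amp = params.amplicon
    rng = np.random.default_rng(params.seed)

    templates = [("intended", amp.edited_seq)]
    for i, (indel, _) in enumerate(params.byproduct_indels):
        templates.append((f"byproduct_{i}", apply_edit(amp.ref_seq, indel)))
    templates.append(("unedited", amp.ref_seq))
    rest = 1.0 - params.frac_intended - sum(p for _, p in params.byproduct_indels)
    probs = np.array(
        [params.frac_intended]
        + [p for _, p in params.byproduct_indels]
        + [max(rest, 0.0)]
    )
    probs = probs / probs.sum()
    tmpl_arrays = [
        np.frombuffer(seq.encode(), dtype=np.uint8) for _, seq in templates
    ]

    choices = rng.choice(len(templates), size=params.n_reads, p=probs)
    records = []
    truth_rows = []
    for i, c in enumerate(choices):
        category, _ = templates[c]
        seq = tmpl_arrays[c][: params.read_len]
        seq = _mutate(seq, rng, params.per_base_error)
        if params.indel_error_rate > 0:
            seq = _indel_errors(seq, rng, params.indel_error_rate)
        read_id = f"read_{i:06d}"
        records.append(
            (read_id, seq.tobytes().decode(), "I" * seq.size)
        )
        truth_rows.append((read_id, category, templates[c][0]))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "category", "template"]
    )
    return records, truth


@dataclass(frozen=True)
class PopulationParams:
    """Hierarchical Bernoulli model of a transfected cell population."""

    n_cells: int
    p_transfect: float
    p_plasmid_edit_given_transfect: float
    p_genomic_given_plasmid_edit: float
    p_genomic_given_transfect_only: float
    p_genomic_given_untransfect: float = 0.0
    fp_rate: float = 0.0
    fn_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.p_transfect,
            self.p_plasmid_edit_given_transfect,
            self.p_genomic_given_plasmid_edit,
            self.p_genomic_given_transfect_only,
            self.p_genomic_given_untransfect,
            self.fp_rate,
            self.fn_rate,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if (
            self.p_genomic_given_plasmid_edit
            < self.p_genomic_given_transfect_only
        ):
            raise ValueError(
                "p_genomic_given_plasmid_edit must be >= "
                "p_genomic_given_transfect_only (the enrichment premise)"
            )

    @property
    def expected_genomic_rate(self) -> float:
        """Overall genomic-editing probability, by total probability."""
        pt = self.p_transfect
        pe = self.p_plasmid_edit_given_transfect
        return (
            pt * (pe * self.p_genomic_given_plasmid_edit
                  + (1 - pe) * self.p_genomic_given_transfect_only)
            + (1 - pt) * self.p_genomic_given_untransfect
        )


def _observe(
    latent: np.ndarray, rng: np.random.Generator, fp: float, fn: float
) -> np.ndarray:
    flip = np.where(latent, rng.random(latent.size) < fn,
                    rng.random(latent.size) < fp)
    return latent ^ flip


def simulate_population(params: PopulationParams) -> pd.DataFrame:
    """Simulate cells; one row per cell.

    Columns: latent booleans ``transfected``, ``plasmid_edited``,
    ``genomic_edited`` and observed booleans ``bfp`` (transfection marker),
    ``gfp`` (reporter), ``reporter_signal`` (alias of ``gfp``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    transfected = rng.random(n) < params.p_transfect
    plasmid_edited = transfected & (
        rng.random(n) < params.p_plasmid_edit_given_transfect
    )
    p_genomic = np.where(
        plasmid_edited,
        params.p_genomic_given_plasmid_edit,
        np.where(
            transfected,
            params.p_genomic_given_transfect_only,
            params.p_genomic_given_untransfect,
        ),
    )
    genomic_edited = rng.random(n) < p_genomic
    bfp = _observe(transfected, rng, params.fp_rate, params.fn_rate)
    gfp = _observe(plasmid_edited, rng, params.fp_rate, params.fn_rate)
    return pd.DataFrame(
        {
            "transfected": transfected,
            "plasmid_edited": plasmid_edited,
            "genomic_edited": genomic_edited,
            "bfp": bfp,
            "gfp": gfp,
            "reporter_signal": gfp,
        }
    )


def make_demo_amplicon(
    seed: int = 0,
    length: int = 240,
    edit_kind: str = "substitution",
    protospacer_start: int = 60,
) -> AmpliconSpec:
    """A random but valid amplicon spec with a protospacer, NGG PAM and an
    intended edit a few bases 3' of the nick.

    For ``edit_kind="substitution"`` the edit recreates the splice-donor fix
    (an inactive G-AC-AAGT context corrected to the canonical G-GT-AAGT);
    insertion/deletion kinds place a 2-nt edit at the same position.
    """
    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = rng.choice(list("ACGT"), size=length)
        s = protospacer_start
        cut = s + 17
        # the edit sits 3' of the PAM (which spans [cut+3, cut+6))
        edit_pos = cut + 7
        if edit_kind == "substitution":
            # inactive donor context G-AC-AAGT spanning [cut+6, cut+13)
            seq[cut + 6 : cut + 13] = list("GACAAGT")
            edit = EditSpec("substitution", edit_pos, "AC", "GT")
        elif edit_kind == "insertion":
            edit = EditSpec("insertion", edit_pos, "", "GT")
        elif edit_kind == "deletion":
            ref_allele = "".join(seq[edit_pos : edit_pos + 2])
            edit = EditSpec("deletion", edit_pos, ref_allele, "")
        else:
            raise ValueError(f"unknown edit kind {edit_kind!r}")
        # NGG PAM immediately 3' of the protospacer (written after the donor
        # context so nothing clobbers it)
        seq[s + 21] = "G"
        seq[s + 22] = "G"
        ref_seq = "".join(seq)
        spacer = ref_seq[s : s + 20]
        try:
            return AmpliconSpec.from_sequences(
                name=f"demo_{edit_kind}", ref_seq=ref_seq, spacer=spacer,
                edit=edit,
            )
        except ValueError:
            continue  # rare: spacer occurs twice; redraw
    raise RuntimeError("failed to construct a demo amplicon")
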