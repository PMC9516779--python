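"""Amplicon editing-outcome profiling.

Each merged amplicon read is globally aligned to the reference with
affine gap costs (Biopython's PairwiseAligner), so a long deletion stays
one contiguous event instead of fragmenting into a shorter gap plus
mismatches; the edit script is left-realigned for deterministic gap
placement, and the read is classified by the indels overlapping a
window around the Cas9 cut: 1-bp insertions (+1 bp), deletions binned by
total deleted length (1-5, 6-10, > 10 bp), or unmodified (substitutions
alone do not count as editing). Reads sharing an indel signature form an
allele; alleles below a read-share threshold (2% by default) are excluded
from the mutation-profile composition but still count toward the overall
indel frequency.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import Align

MUTATION_CLASSES = ("+1bp", "del_1_5", "del_6_10", "del_gt10")

_VALID_READ = re.compile(r"^[ACGTN]*$")

# affine scoring: a contiguous k-bp gap must beat a shorter gap plus
# mismatches, so gap-open is large relative to the mismatch penalty
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -4
_ALIGNER.open_gap_score = -10
_ALIGNER.extend_gap_score = -1


@dataclass(frozen=True)
class EditOp:
    """One indel relative to the reference (0-based reference position).

    For insertions, ``position`` is the reference index before which the
    bases are inserted and ``bases`` holds the inserted sequence; for
    deletions the deleted interval is [position, position + length).
    """

    op: str  # "ins" | "del"
    position: int
    length: int
    bases: str = ""

    def __str__(self) -> str:
        if self.op == "ins":
            return f"ins:{self.position}:{self.length}:{self.bases}"
        return f"del:{self.position}:{self.length}"


@dataclass
class AmpliconSpec:
    """Reference amplicon with the protospacer location and cut index."""

    site_id: str
    reference: str
    protospacer_start: int
    strand: str = "+"

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        if self.protospacer_start < 0 or self.protospacer_start + 23 > len(self.reference):
            raise ValueError(f"{self.site_id}: protospacer interval outside the amplicon")

    @property
    def cut_index(self) -> int:
        """Index of the first base 3' of the cut (between protospacer 17 and 18)."""
        if self.strand == "+":
            return self.protospacer_start + 17
        return self.protospacer_start + 6  # 23-mer on minus strand: cut 3 bp from PAM


@dataclass
class MutationProfile:
    site_id: str
    total_reads: int
    discarded_reads: int
    edited_reads: int
    indel_frequency: float  # % of classified reads
    class_distribution: Dict[str, float]  # % of retained mutant reads
    insertion_rate: float  # == class_distribution["+1bp"]
    normalized_frequency: Optional[float] = None
    alleles: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "total_reads": self.total_reads,
            "discarded_reads": self.discarded_reads,
            "edited_reads": self.edited_reads,
            "indel_frequency": self.indel_frequency,
            "class_distribution": self.class_distribution,
            "insertion_rate": self.insertion_rate,
            "normalized_frequency": self.normalized_frequency,
        }


def align_read(read: str, spec: AmpliconSpec) -> Optional[List[EditOp]]:
    """Globally align ``read`` to the reference and return its indel script.

    Returns None for unalignable reads: length outside [0.5x, 1.5x] of the
    reference, or containing characters other than A/C/G/T/N. The optimal
    affine-gap alignment is computed with Biopython's PairwiseAligner;
    equivalent gap placements are normalized to the leftmost position so
    edit scripts are deterministic.
    """
    read = read.upper()
    ref = spec.reference
    if not _VALID_READ.match(read):
        return None
    if not 0.5 * len(ref) <= len(read) <= 1.5 * len(ref):
        return None
    aln = _ALIGNER.align(ref, read)[0]
    ref_blocks, read_blocks = aln.aligned
    ops: List[EditOp] = []
    prev_ref = prev_read = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        if r0 > prev_ref:
            ops.append(EditOp("del", prev_ref, r0 - prev_ref))
        if q0 > prev_read:
            ops.append(EditOp("ins", r0, q0 - prev_read, read[prev_read:q0]))
        prev_ref, prev_read = r1, q1
    if prev_ref < len(ref):
        ops.append(EditOp("del", prev_ref, len(ref) - prev_ref))
    if prev_read < len(read):
        ops.append(EditOp("ins", len(ref), len(read) - prev_read, read[prev_read:]))
    return [_left_align(op, ref) for op in ops]


def _left_align(op: EditOp, ref: str) -> EditOp:
    """Shift an indel to its leftmost equivalent placement."""
    p = op.position
    if op.op == "del":
        while p > 0 and ref[p - 1] == ref[p + op.length - 1]:
            p -= 1
        return EditOp("del", p, op.length)
    bases = op.bases
    while p > 0 and bases and bases[-1] == ref[p - 1]:
        bases = ref[p - 1] + bases[:-1]
        p -= 1
    return EditOp("ins", p, op.length, bases)


def classify_allele(ops: Sequence[EditOp], spec: AmpliconSpec, window: int = 10) -> str:
    """Mutation class of one edit script.

    A read is edited iff some indel overlaps [cut - window, cut + window].
    Edited reads are "+1bp" for a lone 1-bp insertion with no deletion,
    otherwise binned by total deleted length; pure multi-base insertions
    fall into the "other_insertion" overflow class so they cannot inflate
    the +1 bp bin.
    """
    cut = spec.cut_index
    lo, hi = cut - window, cut + window
    ins_len = del_len = n_ins = 0
    for op in ops:
        if op.op == "ins":
            if lo <= op.position <= hi:
                ins_len += op.length
                n_ins += 1
        else:
            if op.position < hi and op.position + op.length > lo:
                del_len += op.length
    if ins_len == 0 and del_len == 0:
        return "unmodified"
    if del_len == 0:
        return "+1bp" if (n_ins == 1 and ins_len == 1) else "other_insertion"
    if del_len <= 5:
        return "del_1_5"
    if del_len <= 10:
        return "del_6_10"
    return "del_gt10"


def profile_amplicon(
    reads: Iterable[Tuple[str, str]],
    spec: AmpliconSpec,
    threshold: float = 0.02,
    window: int = 10,
    threshold_basis: str = "mutant",
) -> MutationProfile:
    """Call a mutation profile from a read set.

    The overall indel frequency is edited / classified reads (no allele
    threshold); the class distribution and insertion rate are computed
    over mutant reads after dropping alleles whose read share is below
    ``threshold``. The share is relative to mutant reads by default
    (``threshold_basis="mutant"``): sites editing at a fraction of a
    percent still report a defined outcome composition, which a
    total-read basis would zero out. Pass ``threshold_basis="total"``
    to measure shares against all classified reads instead.
    """
    if threshold_basis not in ("mutant", "total"):
        raise ValueError("threshold_basis must be 'mutant' or 'total'")
    # identical read sequences share one alignment
    seq_counts: Dict[str, int] = {}
    for _, seq in reads:
        seq = seq.upper()
        seq_counts[seq] = seq_counts.get(seq, 0) + 1
    allele_counts: Dict[Tuple[EditOp, ...], int] = {}
    discarded = 0
    for seq, count in seq_counts.items():
        ops = align_read(seq, spec)
        if ops is None:
            discarded += count
            continue
        key = tuple(ops)
        allele_counts[key] = allele_counts.get(key, 0) + count
    total = sum(allele_counts.values())
    if total == 0:
        raise ValueError(f"{spec.site_id}: no alignable reads")

    rows = []
    for ops, count in allele_counts.items():
        label = classify_allele(ops, spec, window)
        rows.append(
            {
                "ops": ";".join(str(o) for o in ops) or ".",
                "class": label,
                "count": count,
                "frequency": count / total,
            }
        )
    alleles = pd.DataFrame(rows).sort_values(
        ["count", "ops"], ascending=[False, True], ignore_index=True
    )

    edited_mask = alleles["class"] != "unmodified"
    edited_reads = int(alleles.loc[edited_mask, "count"].sum())
    indel_frequency = 100.0 * edited_reads / total

    basis = edited_reads if (threshold_basis == "mutant" and edited_reads > 0) else total
    retained = alleles[edited_mask & (alleles["count"] / basis >= threshold)]
    in_classes = retained[retained["class"].isin(MUTATION_CLASSES)]
    class_total = int(in_classes["count"].sum())
    distribution = {c: 0.0 for c in MUTATION_CLASSES}
    if class_total > 0:
        for c in MUTATION_CLASSES:
            distribution[c] = (
                100.0 * int(in_classes.loc[in_classes["class"] == c, "count"].sum()) / class_total
            )
    return MutationProfile(
        site_id=spec.site_id,
        total_reads=total,
        discarded_reads=discarded,
        edited_reads=edited_reads,
        indel_frequency=indel_frequency,
        class_distribution=distribution,
        insertion_rate=distribution["+1bp"],
        alleles=alleles,
    )


def normalize_frequency(site_frequency: float, control_frequency: float) -> float:
    """Site indel frequency as a percentage of the control site's.

    The control is a single-copy euchromatic target sequenced in the same
    replicate; values above 100% are legitimate. A replicate whose control
    frequency is zero carries no usable signal and is rejected.
    """
    if control_frequency <= 0:
        raise ValueError("control indel frequency is zero; replicate must be excluded")
    return 100.0 * site_frequency / control_frequency


def fold_change(high: float, low: float) -> float:
    """Ratio of two (normalized) frequencies, reported to 2 decimals."""
    if low <= 0:
        raise ValueError("fold change undefined for a non-positive denominator")
    return round(high / low, 2)
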