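"""Edited amplicon read simulation.

Reads are pre-merged single amplicon sequences. Each read is drawn from the
planned class mixture: unmodified; a 1-bp insertion at the Cas9 cut (either
a templated duplicate of the base 5' of the cut or a fixed base); or a
deletion overlapping the cut with its size drawn from the planned bin
(1-5, 6-10, or 11-20 bp for the >10 class). Substitution sequencing errors
are applied after editing. A truth table records every read's class and
edit operation.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd

from mcsite.synthetic.plans import ALLELE_CLASSES, EditingPlan

_BASES = "ACGT"
_DEL_SIZES = {"del_1_5": (1, 5), "del_6_10": (6, 10), "del_gt10": (11, 20)}

TRUTH_COLUMNS = ["read_id", "true_class", "op"]


def simulate_amplicon_reads(
    reference: str, cut_index: int, plan: EditingPlan
) -> Tuple[List[Tuple[str, str]], pd.DataFrame]:
    """Draw reads per ``plan`` against ``reference`` cut at ``cut_index``.

    ``cut_index`` is the 0-based index of the first base 3' of the cut
    (Cas9 cleaves between ``cut_index - 1`` and ``cut_index``). Returns
    (reads, truth) where reads are (name, sequence) pairs and truth has one
    row per read with columns read_id, true_class, op.
    """
    reference = reference.upper()
    n = len(reference)
    if n < 50:
        raise ValueError(f"amplicon of {n} bp is too short to profile (minimum 50)")
    if cut_index < 17 or n - cut_index < 17:
        raise ValueError("cut index must be at least 17 bases from either amplicon end")

    rng = np.random.default_rng(plan.seed)
    classes = [c for c in ALLELE_CLASSES if plan.proportions.get(c, 0.0) > 0]
    probs = np.array([plan.proportions[c] for c in classes])
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=plan.total_reads, p=probs)

    reads, truth = [], []
    for i, k in enumerate(draws):
        label = classes[k]
        if label == "unmodified":
            seq, op = reference, "none"
        elif label == "+1bp":
            base = reference[cut_index - 1] if plan.insertion_rule == "templated" else plan.insertion_rule
            seq = reference[:cut_index] + base + reference[cut_index:]
            op = f"ins:{cut_index}:1:{base}"
        else:
            lo, hi = _DEL_SIZES[label]
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(cut_index - size, cut_index))
            start = max(1, min(start, n - size - 1))
            seq = reference[:start] + reference[start + size :]
            op = f"del:{start}:{size}"
        if plan.substitution_error > 0:
            seq = _add_substitutions(seq, plan.substitution_error, rng)
        name = f"read_{i}"
        reads.append((name, seq))
        truth.append((name, label, op))
    return reads, pd.DataFrame(truth, columns=TRUTH_COLUMNS)


def _add_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    arr = list(seq)
    for pos in hits:
        choices = [b for b in _BASES if b != arr[pos]]
        arr[pos] = choices[int(rng.integers(3))]
    return "".join(arr)
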