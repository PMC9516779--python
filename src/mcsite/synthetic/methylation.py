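"""Per-cytosine methylation call simulation.

Contexts follow the plant convention: reading 5'->3' on the strand
carrying the cytosine, C followed by G is CG; C, one base, then G is CHG;
anything else is CHH (H = A, C or T). Calls are emitted for both strands;
methylated counts are binomial draws at the planned window level.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from mcsite.fileio import CALL_COLUMNS
from mcsite.synthetic.plans import ChromatinPlan


def cytosine_contexts(seq: str, start: int = 0, end: int | None = None) -> List[Tuple[int, str, str]]:
    """List (position, strand, context) for every cytosine in seq[start:end].

    Context is determined from the full sequence, so cytosines near the
    slice boundary still see their downstream bases. A cytosine at the very
    chromosome end with no downstream base is reported as CHH.
    """
    if end is None:
        end = len(seq)
    out = []
    n = len(seq)
    for i in range(start, end):
        base = seq[i]
        if base == "C":
            if i + 1 < n and seq[i + 1] == "G":
                ctx = "CG"
            elif i + 2 < n and seq[i + 2] == "G":
                ctx = "CHG"
            else:
                ctx = "CHH"
            out.append((i, "+", ctx))
        elif base == "G":  # cytosine on the minus strand
            if i - 1 >= 0 and seq[i - 1] == "C":
                ctx = "CG"
            elif i - 2 >= 0 and seq[i - 2] == "C":
                ctx = "CHG"
            else:
                ctx = "CHH"
            out.append((i, "-", ctx))
    return out


def simulate_methylation(genome: Dict[str, str], plan: ChromatinPlan) -> pd.DataFrame:
    """Emit a per-cytosine call table realizing the planned window levels."""
    rng = np.random.default_rng(plan.seed)
    rows = []
    for spec in plan.windows:
        if spec.chrom not in genome:
            raise ValueError(f"window on unknown chromosome {spec.chrom}")
        seq = genome[spec.chrom]
        if spec.end > len(seq):
            raise ValueError(
                f"window {spec.chrom}:{spec.start}-{spec.end} exceeds chromosome length {len(seq)}"
            )
        cytosines = cytosine_contexts(seq, spec.start, spec.end)
        if not cytosines:
            warnings.warn(
                f"window {spec.chrom}:{spec.start}-{spec.end} has no cytosines; skipped",
                stacklevel=2,
            )
            continue
        level = {"CG": spec.mcg, "CHG": spec.mchg, "CHH": spec.mchh}
        for pos, strand, ctx in cytosines:
            mc = int(rng.binomial(plan.depth, level[ctx]))
            rows.append((spec.chrom, pos, strand, ctx, mc, plan.depth))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
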