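"""Genome construction with planted multicopy target families.

Background sequence is i.i.d. with a configurable GC fraction; after the
23-mers are planted, any chance background copy of a planted 23-mer (on
either strand) is rejection-sampled away, so every family's genome-wide
occurrence count is exactly its planned copy number.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from mcsite.sequtil import gc_fraction, max_homopolymer_run, revcomp
from mcsite.synthetic.plans import GenomePlan

_BASES = np.array(list("ACGT"))

REGISTRY_COLUMNS = ["family", "sequence", "chrom", "start", "end", "strand"]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return rng.choice(_BASES, size=n, p=[at, gc / 2.0, gc / 2.0, at])


def _find_exact(haystack: str, needle: str) -> List[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def build_genome(plan: GenomePlan) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Emit a genome realizing ``plan`` plus a site registry.

    Returns the genome as {chromosome: sequence} and a registry frame with
    0-based half-open coordinates (family, sequence, chrom, start, end,
    strand). The emitted sequences contain each planted 23-mer exactly at
    its registered loci and nowhere else.
    """
    rng = np.random.default_rng(plan.seed)
    chroms = {name: _random_bases(rng, length, plan.gc) for name, length in plan.chrom_lengths.items()}

    planted: Dict[str, List[Tuple[int, int]]] = {name: [] for name in plan.chrom_lengths}
    rows = []
    for fam in plan.families:
        for chrom, start, strand in fam.loci:
            embedded = fam.sequence if strand == "+" else revcomp(fam.sequence)
            chroms[chrom][start : start + 23] = list(embedded)
            planted[chrom].append((start, start + 23))
            rows.append(
                {
                    "family": fam.name,
                    "sequence": fam.sequence,
                    "chrom": chrom,
                    "start": start,
                    "end": start + 23,
                    "strand": strand,
                }
            )

    genome = {name: "".join(arr) for name, arr in chroms.items()}
    genome = _reject_collisions(genome, plan, planted, rng)
    registry = pd.DataFrame(rows, columns=REGISTRY_COLUMNS)
    return genome, registry


def _reject_collisions(
    genome: Dict[str, str],
    plan: GenomePlan,
    planted: Dict[str, List[Tuple[int, int]]],
    rng: np.random.Generator,
    max_rounds: int = 100,
) -> Dict[str, str]:
    """Re-randomize background windows that spuriously copy a planted 23-mer."""
    targets = {fam.sequence for fam in plan.families}
    targets |= {revcomp(seq) for seq in targets}
    for _ in range(max_rounds):
        dirty = False
        for chrom, seq in genome.items():
            arr = None
            for target in targets:
                for hit in _find_exact(seq, target):
                    if (hit, hit + 23) in planted[chrom]:
                        continue
                    # resample only positions outside planted intervals
                    if arr is None:
                        arr = list(seq)
                    for pos in range(hit, hit + 23):
                        if any(s <= pos < e for s, e in planted[chrom]):
                            continue
                        arr[pos] = str(_random_bases(rng, 1, plan.gc)[0])
                    dirty = True
            if arr is not None:
                genome[chrom] = "".join(arr)
        if not dirty:
            return genome
    raise RuntimeError("could not purge spurious copies of planted targets")


def random_target_sequence(
    rng: np.random.Generator,
    gc_range: Tuple[float, float] = (0.40, 0.60),
    max_run: int = 4,
) -> str:
    """Draw a 23-mer target (20-nt protospacer + NGG) passing the candidate filters."""
    while True:
        proto = "".join(rng.choice(_BASES, size=20))
        if not gc_range[0] <= gc_fraction(proto) <= gc_range[1]:
            continue
        if max_homopolymer_run(proto) > max_run:
            continue
        pam = str(rng.choice(_BASES)) + "GG"
        seq = proto + pam
        if max_homopolymer_run(seq) > max_run:
            continue
        return seq
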