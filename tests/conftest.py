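"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from mcsite.sequtil import revcomp
from mcsite.synthetic import GenomePlan, PlantedFamily, build_genome


def naive_scan(genome: Dict[str, str]) -> Dict[str, List[Tuple[str, int, str]]]:
    """Character-by-character both-strand scan for 20-mer+NGG windows.

    Independent of the regex scanner: slices every 23-base window on the
    forward sequence and on the reverse complement and applies the PAM
    test positionally.
    """
    found: Dict[str, List[Tuple[str, int, str]]] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for i in range(n - 22):
            window = seq[i : i + 23]
            if window[21] == "G" and window[22] == "G" and set(window) <= set("ACGT"):
                found.setdefault(window, []).append((chrom, i, "+"))
        rc = revcomp(seq)
        for i in range(n - 22):
            window = rc[i : i + 23]
            if window[21] == "G" and window[22] == "G" and set(window) <= set("ACGT"):
                found.setdefault(window, []).append((chrom, n - i - 23, "-"))
    return found


def naive_gc(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq)


def naive_has_run(seq: str, k: int = 5) -> bool:
    return any(seq[i : i + k] == seq[i] * k for i in range(len(seq) - k + 1))


def naive_iupac_hits(context: str, motif: str) -> List[Tuple[int, int]]:
    """All motif occurrences (either strand) by explicit IUPAC expansion."""
    from mcsite.sequtil import IUPAC
    from mcsite.discovery import revcomp_iupac

    hits = []
    for m in (motif, revcomp_iupac(motif)):
        k = len(m)
        for i in range(len(context) - k + 1):
            if all(context[i + j] in IUPAC[m[j]] for j in range(k)):
                hits.append((i, i + k))
    return sorted(set(hits))


@pytest.fixture(scope="session")
def planted_genome():
    """A 10-kb single-chromosome genome with one family planted 7 times."""
    family = PlantedFamily(
        "fam1",
        "ACGTACGTACGTACGTACGTAGG",
        [("chr1", start, "+") for start in (500, 1500, 3000, 4500, 6000, 7500, 9000)],
    )
    plan = GenomePlan(chrom_lengths={"chr1": 10_000}, families=[family], seed=42)
    genome, registry = build_genome(plan)
    return plan, genome, registry


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
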