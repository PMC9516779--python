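"""Plan objects describing what the generators should plant.

Plans are plain dataclasses that validate their own invariants on
construction and round-trip through JSON (``to_dict`` / ``from_dict``)
so a whole simulated study can be driven from one config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

ALLELE_CLASSES = ("unmodified", "+1bp", "del_1_5", "del_6_10", "del_gt10")


@dataclass
class PlantedFamily:
    """One multicopy target: a 23-mer (20-nt protospacer + NGG) and its loci.

    ``loci`` are (chromosome, start, strand) with 0-based starts of the
    23-mer interval on the forward strand; on strand "-" the reverse
    complement of ``sequence`` is written into the forward strand.
    """

    name: str
    sequence: str
    loci: List[Tuple[str, int, str]]

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != 23:
            raise ValueError(f"family {self.name}: sequence must be 23 nt, got {len(seq)}")
        if not seq.endswith("GG"):
            raise ValueError(f"family {self.name}: 23-mer must end in GG (NGG PAM)")
        if set(seq) - set("ACGT"):
            raise ValueError(f"family {self.name}: sequence contains non-ACGT characters")
        for chrom, start, strand in self.loci:
            if strand not in "+-":
                raise ValueError(f"family {self.name}: bad strand {strand!r} at {chrom}:{start}")
            if start < 0:
                raise ValueError(f"family {self.name}: negative locus start {chrom}:{start}")
        self.sequence = seq

    @property
    def copy_number(self) -> int:
        return len(self.loci)


@dataclass
class GenomePlan:
    chrom_lengths: Dict[str, int]
    families: List[PlantedFamily] = field(default_factory=list)
    organellar: List[str] = field(default_factory=list)
    gc: float = 0.36
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("GC background fraction must be in (0, 1)")
        unknown = set(self.organellar) - set(self.chrom_lengths)
        if unknown:
            raise ValueError(f"organellar names not in chrom_lengths: {sorted(unknown)}")
        # loci must fit and must not collide with each other
        occupied: Dict[str, List[Tuple[int, int, str]]] = {}
        for fam in self.families:
            for chrom, start, strand in fam.loci:
                if chrom not in self.chrom_lengths:
                    raise ValueError(f"family {fam.name}: unknown chromosome {chrom}")
                if start + 23 > self.chrom_lengths[chrom]:
                    raise ValueError(
                        f"family {fam.name}: locus {chrom}:{start} overflows "
                        f"chromosome of length {self.chrom_lengths[chrom]}"
                    )
                for other_start, other_end, other_fam in occupied.get(chrom, []):
                    if start < other_end and other_start < start + 23:
                        raise ValueError(
                            f"family {fam.name}: locus {chrom}:{start} collides with "
                            f"a locus of family {other_fam} at {chrom}:{other_start}"
                        )
                occupied.setdefault(chrom, []).append((start, start + 23, fam.name))

    @property
    def nuclear(self) -> List[str]:
        return [c for c in self.chrom_lengths if c not in self.organellar]


@dataclass
class MethylationWindowSpec:
    chrom: str
    start: int
    end: int
    mcg: float
    mchg: float
    mchh: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"window {self.chrom}:{self.start}-{self.end} has start >= end")
        for name, level in (("mCG", self.mcg), ("mCHG", self.mchg), ("mCHH", self.mchh)):
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"{name} level {level} outside [0, 1]")


@dataclass
class FeatureRegion:
    chrom: str
    start: int
    end: int
    mean: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end} has start >= end")
        if self.mean < 0:
            raise ValueError(f"planned feature signal must be non-negative, got {self.mean}")


@dataclass
class ChromatinPlan:
    windows: List[MethylationWindowSpec] = field(default_factory=list)
    depth: int = 50
    peaks: List[Tuple[str, int, int]] = field(default_factory=list)
    features: Dict[str, List[FeatureRegion]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("read depth must be >= 1")
        for chrom, start, end in self.peaks:
            if start >= end:
                raise ValueError(f"peak {chrom}:{start}-{end} has start >= end")


@dataclass
class EditingPlan:
    """Mixture of editing outcomes for one amplicon read set.

    ``proportions`` maps class labels (see ``ALLELE_CLASSES``) to
    fractions summing to 1. ``insertion_rule`` is "templated" (duplicate
    the base 5' of the cut) or a single fixed base.
    """

    total_reads: int
    proportions: Dict[str, float]
    insertion_rule: str = "templated"
    substitution_error: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(ALLELE_CLASSES)
        if unknown:
            raise ValueError(f"unknown allele classes: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if not 0.0 <= self.substitution_error <= 0.05:
            raise ValueError("substitution error rate must be in [0, 0.05]")
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if self.insertion_rule != "templated" and self.insertion_rule not in "ACGT":
            raise ValueError("insertion_rule must be 'templated' or a single base")


def plan_to_dict(plan) -> dict:
    return asdict(plan)
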