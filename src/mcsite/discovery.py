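"""Genome-wide discovery and filtering of multicopy CRISPR-Cas9 targets.

A target is a 20-nt protospacer immediately followed by an NGG PAM
(23 bases total). The scanner records every occurrence on both strands of
the nuclear chromosomes; distinctness is by literal 23-mer, so a sequence
and its reverse complement are separate catalog entries (Cas9 targeting is
strand-specific). Candidate targets then pass a filter cascade: copy-number
band (7-25 occurrences by default), no homopolymer run of 5+ bases in the
protospacer, GC fraction within 40-60% inclusive, no match in organellar
sequences, and at least one restriction-enzyme motif covering protospacer
positions 17-18 so that a cut-site indel destroys the recognition site
(in-silico CAPS screening).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from mcsite.sequtil import gc_fraction, iupac_regex, max_homopolymer_run, revcomp

_TARGET_RE = re.compile(r"(?=([ACGT]{21}GG))")

# Cas9 cleaves between protospacer positions 17 and 18 (1-based); a motif
# covering either base is destroyed by a cut-site indel.
CUT_PROXIMAL_BASES = (16, 17)  # 0-based within the 23-mer


@dataclass(frozen=True)
class TargetOccurrence:
    """One genomic occurrence of a 23-mer target, forward-strand coordinates."""

    chrom: str
    start: int  # 0-based start of the 23-mer interval on the forward strand
    strand: str

    @property
    def end(self) -> int:
        return self.start + 23

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.start}:{self.strand}"


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    motif: str  # IUPAC recognition sequence

    def __post_init__(self) -> None:
        iupac_regex(self.motif)  # raises on malformed motifs


#: Recognition motifs of commonly used commercial (NEB-style) enzymes.
DEFAULT_ENZYMES: Tuple[RestrictionEnzyme, ...] = tuple(
    RestrictionEnzyme(name, motif)
    for name, motif in [
        ("AluI", "AGCT"), ("DrdI", "GACNNNNNNGTC"), ("BsmAI", "GTCTC"),
        ("EcoRI", "GAATTC"), ("HindIII", "AAGCTT"), ("BamHI", "GGATCC"),
        ("HinfI", "GANTC"), ("DdeI", "CTNAG"), ("MseI", "TTAA"),
        ("TaqI", "TCGA"), ("HaeIII", "GGCC"), ("RsaI", "GTAC"),
        ("HpaII", "CCGG"), ("Sau3AI", "GATC"), ("NlaIII", "CATG"),
        ("BfaI", "CTAG"), ("HhaI", "GCGC"), ("AseI", "ATTAAT"),
        ("NdeI", "CATATG"), ("ScrFI", "CCNGG"), ("Fnu4HI", "GCNGC"),
        ("Tsp509I", "AATT"), ("ApoI", "RAATTY"), ("AvaII", "GGWCC"),
        ("BstNI", "CCWGG"), ("Hpy188I", "TCNGA"),
    ]
)


class TargetCatalog:
    """Mapping from distinct 23-mer target sequence to its occurrences."""

    def __init__(self, occurrences: Mapping[str, Sequence[TargetOccurrence]] | None = None):
        self._map: Dict[str, List[TargetOccurrence]] = {
            seq: list(occs) for seq, occs in (occurrences or {}).items()
        }

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, seq: str) -> bool:
        return seq in self._map

    def __iter__(self):
        return iter(self._map)

    def occurrences(self, seq: str) -> List[TargetOccurrence]:
        return self._map[seq]

    def copy_number(self, seq: str) -> int:
        return len(self._map[seq])

    def items(self):
        return self._map.items()

    def subset(self, keys: Iterable[str]) -> "TargetCatalog":
        return TargetCatalog({k: self._map[k] for k in keys})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sequence": seq, "chrom": occ.chrom, "start": occ.start,
             "end": occ.end, "strand": occ.strand}
            for seq, occs in self._map.items()
            for occ in occs
        ]
        return pd.DataFrame(rows, columns=["sequence", "chrom", "start", "end", "strand"])


def scan_pam_sites(genome: Mapping[str, str], nuclear: Iterable[str] | None = None) -> TargetCatalog:
    """Scan both strands for every 20-mer followed by NGG.

    ``nuclear`` restricts scanning (and hence copy counting) to the named
    chromosomes; organellar sequences are handled separately by
    :func:`filter_organellar`. Windows containing N are skipped. An empty
    genome yields an empty catalog.
    """
    names = list(nuclear) if nuclear is not None else list(genome)
    found: Dict[str, List[TargetOccurrence]] = {}
    for chrom in names:
        seq = genome[chrom].upper()
        length = len(seq)
        for m in _TARGET_RE.finditer(seq):
            found.setdefault(m.group(1), []).append(TargetOccurrence(chrom, m.start(), "+"))
        rc = revcomp(seq)
        for m in _TARGET_RE.finditer(rc):
            start = length - m.start() - 23
            found.setdefault(m.group(1), []).append(TargetOccurrence(chrom, start, "-"))
    return TargetCatalog(found)


def filter_copy_range(catalog: TargetCatalog, lo: int = 7, hi: int = 25) -> TargetCatalog:
    """Keep sequences whose genome-wide occurrence count is in [lo, hi]."""
    if lo > hi:
        raise ValueError(f"copy-range bounds inverted: lo={lo} > hi={hi}")
    return catalog.subset(seq for seq in catalog if lo <= catalog.copy_number(seq) <= hi)


def passes_simple_motif(protospacer: str, max_run: int = 4) -> bool:
    """Fail protospacers containing a homopolymer of 5+ identical bases."""
    return max_homopolymer_run(protospacer) <= max_run


def passes_gc(protospacer: str, lo: float = 0.40, hi: float = 0.60) -> bool:
    """GC fraction within [lo, hi], bounds inclusive (8-12 G/C on 20 nt)."""
    return lo <= gc_fraction(protospacer) <= hi


def passes_organellar(sequence: str, organellar: Mapping[str, str]) -> bool:
    """Fail iff the 23-mer matches anywhere in an organellar sequence, either strand."""
    rc = revcomp(sequence)
    for contig in organellar.values():
        contig = contig.upper()
        if sequence in contig or rc in contig:
            return False
    return True


def annotate_restriction_overlap(
    sequence: str,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    flank5: str = "",
    flank3: str = "",
) -> List[str]:
    """Enzymes whose motif occurrence covers protospacer base 17 or 18.

    Motifs are IUPAC-expanded and searched on both strands of the 23-mer
    (optionally extended with genomic flanks). Returns the names of
    matching enzymes; candidates with an empty list are dropped from the
    cascade because their mutations could not be screened by restriction
    digestion (CAPS).
    """
    context = (flank5 + sequence + flank3).upper()
    offset = len(flank5)
    cut_bases = {offset + b for b in CUT_PROXIMAL_BASES}
    hits = []
    for enzyme in enzymes:
        if _motif_covers(context, enzyme.motif, cut_bases):
            hits.append(enzyme.name)
    return hits


def _motif_covers(context: str, motif: str, cut_bases: set) -> bool:
    k = len(motif)
    n = len(context)
    for pattern in (iupac_regex(motif), iupac_regex(revcomp_iupac(motif))):
        rx = re.compile(f"(?=({pattern}))")
        for m in rx.finditer(context):
            if any(m.start() <= b < m.start() + k for b in cut_bases):
                return True
    return False


_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp_iupac(motif: str) -> str:
    return motif.upper().translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass
class FilterReport:
    """Survivor counts along the cascade plus each sequence's first failure."""

    stage_counts: Dict[str, int] = field(default_factory=dict)
    first_failure: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"stage_counts": self.stage_counts, "first_failure": self.first_failure}


CASCADE_STAGES = ["distinct", "copy_range", "simple_motif", "gc", "organellar", "restriction"]


def apply_filter_cascade(
    catalog: TargetCatalog,
    organellar: Mapping[str, str] | None = None,
    enzymes: Sequence[RestrictionEnzyme] = DEFAULT_ENZYMES,
    lo: int = 7,
    hi: int = 25,
    gc_lo: float = 0.40,
    gc_hi: float = 0.60,
    max_run: int = 4,
) -> Tuple[TargetCatalog, FilterReport]:
    """Run the full candidate cascade and report survivors per stage.

    Each dropped sequence is recorded with the first filter it failed;
    the filters are independent predicates, so the survivor set does not
    depend on their order.
    """
    if lo > hi:
        raise ValueError(f"copy-range bounds inverted: lo={lo} > hi={hi}")
    organellar = organellar or {}
    report = FilterReport()
    report.stage_counts["distinct"] = len(catalog)

    survivors = []
    for seq in catalog:
        proto = seq[:20]
        if not lo <= catalog.copy_number(seq) <= hi:
            report.first_failure[seq] = "copy_range"
        elif not passes_simple_motif(proto, max_run):
            report.first_failure[seq] = "simple_motif"
        elif not passes_gc(proto, gc_lo, gc_hi):
            report.first_failure[seq] = "gc"
        elif not passes_organellar(seq, organellar):
            report.first_failure[seq] = "organellar"
        elif not annotate_restriction_overlap(seq, enzymes):
            report.first_failure[seq] = "restriction"
        else:
            survivors.append(seq)

    # cumulative survivor counts in cascade order
    failed = report.first_failure
    remaining = set(catalog)
    for stage in CASCADE_STAGES[1:]:
        remaining = {s for s in remaining if failed.get(s) != stage}
        report.stage_counts[stage] = len(remaining)
    return catalog.subset(survivors), report


def select_mcsite_families(
    catalog: TargetCatalog, annotations: pd.DataFrame
) -> List[str]:
    """Families whose member sites span diverse chromatin contexts.

    ``annotations`` is indexed by site id ("chrom:start:strand") with
    columns ``accessibility`` (open/closed), ``domain`` and ``state``. A
    family is selected iff its members include at least one open and one
    closed site, at least three distinct methylation-domain labels, and at
    least two distinct chromatin states.
    """
    selected = []
    for seq, occs in catalog.items():
        rows = []
        for occ in occs:
            if occ.site_id not in annotations.index:
                raise ValueError(f"site {occ.site_id} has no chromatin annotation")
            rows.append(annotations.loc[occ.site_id])
        acc = {r["accessibility"] for r in rows}
        # windows lacking coverage in a context carry no domain information
        domains = {r["domain"] for r in rows} - {"no data"}
        states = {r["state"] for r in rows}
        if {"open", "closed"} <= acc and len(domains) >= 3 and len(states) >= 2:
            selected.append(seq)
    return selected
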