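#!/usr/bin/env python
"""Optional integration run against a real Arabidopsis (TAIR10) genome.

Not part of the default analysis: it needs a locally provided genome
FASTA (nuclear chromosomes Chr1-Chr5 plus ChrC/ChrM organelles), which is
not bundled. Given one, it reports the distinct-target count, the 7-25
copy band, and the survivor count of the full cascade.

Usage: python analysis/06_tair10_integration.py /path/to/TAIR10.fa
"""

import sys
from pathlib import Path

from mcsite import fileio
from mcsite.discovery import apply_filter_cascade, scan_pam_sites


def main() -> None:
    if len(sys.argv) != 2 or not Path(sys.argv[1]).exists():
        print("usage: 06_tair10_integration.py <genome.fa>  (genome not bundled; skipping)")
        return
    genome = fileio.read_fasta(sys.argv[1])
    organellar_names = [c for c in genome if c.upper() in ("CHRC", "CHRM", "MT", "PT")]
    nuclear = [c for c in genome if c not in organellar_names]
    print(f"nuclear: {nuclear}; organellar: {organellar_names}")

    catalog = scan_pam_sites(genome, nuclear=nuclear)
    print(f"distinct 20-nt+NGG targets: {len(catalog):,}")
    survivors, report = apply_filter_cascade(
        catalog, organellar={c: genome[c] for c in organellar_names}
    )
    for stage, count in report.stage_counts.items():
        print(f"  {stage}: {count:,}")


if __name__ == "__main__":
    main()
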