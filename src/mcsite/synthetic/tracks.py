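"""Accessibility peaks and chromatin-feature signal tracks."""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from mcsite.fileio import BED_COLUMNS, BEDGRAPH_COLUMNS
from mcsite.synthetic.plans import ChromatinPlan


def simulate_tracks(
    genome: Dict[str, str], plan: ChromatinPlan, bin_size: int = 50
) -> Tuple[pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Emit an accessibility peak BED frame and one bedGraph frame per feature.

    Each planned feature region is tiled with ``bin_size`` intervals whose
    value is the planned mean plus seeded Gaussian noise (sd =
    ``plan.noise_sd``); with zero noise a window average over the region
    recovers the planned mean exactly.
    """
    rng = np.random.default_rng(plan.seed + 1)
    peak_rows = []
    for chrom, start, end in plan.peaks:
        if chrom not in genome:
            raise ValueError(f"peak on unknown chromosome {chrom}")
        peak_rows.append({"chrom": chrom, "start": start, "end": end,
                          "name": "peak", "score": ".", "strand": "."})
    peaks = pd.DataFrame(peak_rows, columns=BED_COLUMNS)

    tracks: Dict[str, pd.DataFrame] = {}
    for feature, regions in plan.features.items():
        rows = []
        for region in regions:
            if region.chrom not in genome:
                raise ValueError(f"feature {feature}: unknown chromosome {region.chrom}")
            pos = region.start
            while pos < region.end:
                stop = min(pos + bin_size, region.end)
                value = region.mean + (plan.noise_sd * rng.standard_normal() if plan.noise_sd else 0.0)
                rows.append((region.chrom, pos, stop, float(value)))
                pos = stop
        tracks[feature] = pd.DataFrame(rows, columns=BEDGRAPH_COLUMNS)
    return peaks, tracks
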