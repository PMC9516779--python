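#!/usr/bin/env python
"""Associate editing with chromatin context: H/M/L grouping per family
(ANOVA + Tukey homogeneous subsets), Spearman correlations of efficiency
and +1 bp insertion rate with each normalized feature, hierarchical
clustering of features, and Kruskal-Wallis across sites per family.

Reads results/run/profiles.tsv and site_annotations.tsv; writes
groups.tsv, correlations.tsv, clusters.json.
"""

import json
from pathlib import Path

import pandas as pd

from mcsite.pipeline import stage_associate, validate_config

RUN = Path("results/run")
SIM = RUN / "simulated"


def main() -> None:
    cfg = validate_config(json.loads((SIM / "config.json").read_text()))
    profiles = pd.read_csv(RUN / "profiles.tsv", sep="\t")
    annotations = pd.read_csv(RUN / "site_annotations.tsv", sep="\t", index_col="site_id")
    contexts = pd.DataFrame(json.loads((SIM / "contexts.json").read_text()))
    families = contexts.groupby("family")["site_id"].apply(list).to_dict()

    assoc = stage_associate(profiles, annotations, families, cfg)
    assoc["groups"].to_csv(RUN / "groups.tsv", sep="\t", index=False)
    assoc["correlations"].to_csv(RUN / "correlations.tsv", sep="\t", index=False)
    (RUN / "clusters.json").write_text(
        json.dumps({k: v.to_dict() for k, v in assoc["clusters"].items()}, indent=1)
    )

    groups = assoc["groups"]
    print("H/M/L group sizes per family:")
    print(groups.groupby(["family", "group"]).size().to_string())
    corr = assoc["correlations"]
    eff = corr[corr["response"] == "efficiency"].nlargest(3, "R")
    ins = corr[corr["response"] == "insertion_rate"].nsmallest(3, "R")
    print("\nstrongest positive efficiency correlations:")
    print(eff[["feature", "R", "P"]].round(4).to_string(index=False))
    print("\nstrongest negative insertion-rate correlations:")
    print(ins[["feature", "R", "P"]].round(4).to_string(index=False))
    print("\nKruskal-Wallis (insertion rate across sites, per family):")
    for fam, res in assoc["kruskal_wallis"].items():
        print(f"  {fam}: H={res['H']:.2f}, P={res['P']:.4g}")


if __name__ == "__main__":
    main()
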