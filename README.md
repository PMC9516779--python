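# mcsite

Chromatin context changes how well CRISPR–Cas9 cuts — and what the repair
machinery leaves behind. One clean way to measure this is to find a *single*
guide sequence that happens to occur at many places in a genome (a multicopy
CRISPR site, "MCsite"), so that sequence is held fixed while DNA
methylation, accessibility and histone features vary across the copies.
`mcsite` implements that whole analysis as a tested Python pipeline:

1. **site_discovery** — scan a genome for every 20-nt protospacer followed
   by an NGG PAM, count genome-wide occurrences per distinct 23-mer, and
   apply the candidate cascade: 7–25 copies, no homopolymer run of ≥5 in
   the protospacer, GC within 40–60 % (inclusive), no match in organellar
   sequences, and a restriction-enzyme motif covering protospacer positions
   17–18 (so a cut-site indel destroys the site — in-silico CAPS).
2. **chromatin_annotation** — weighted methylation
   (Σ mC reads / Σ total reads) per context over a 100-bp tiling;
   methylation domains (unmethylated → RdDM → heterochromatin → CG-only →
   intermediate, by precedence over the mCG/mCHG/mCHH thresholds
   10 % / 40 % / 15 %); open/closed by ATAC-peak overlap; 1-kb mean feature
   signal per site, min–max normalized to [0, 1].
3. **indel_profiling** — global affine alignment of merged amplicon reads,
   indels called in a ±10 bp window around the cut (between protospacer
   positions 17 and 18), classes +1 bp / Δ1–5 / Δ6–10 / Δ>10, indel
   frequency, control-normalized frequency, and the +1 bp insertion rate.
4. **association_stats** — H/M/L grouping per family (one-way ANOVA +
   Tukey HSD homogeneous subsets), Spearman correlations of efficiency and
   insertion rate with each chromatin feature, average-linkage hierarchical
   clustering, Mann–Whitney condition comparisons, Kruskal–Wallis.
5. **synthetic** — generators for genomes with planted target families,
   per-cytosine methylation calls, peaks and feature tracks, and edited
   amplicon read sets, all with explicit ground truth, so every stage is
   testable without any downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each writes under `results/run/`):

```bash
python analysis/01_simulate.py      # genome + tracks + reads, planted truth
python analysis/02_discover.py      # scan + filter cascade
python analysis/03_annotate.py      # domains, accessibility, features
python analysis/04_profile.py       # per-replicate mutation profiles
python analysis/05_associate.py     # groups, correlations, clustering
```

`02_discover.py` prints, for the default seed:

```
distinct targets scanned: 5846
in 7-25 copy band: 2
after motif/GC/organelle/restriction cascade: 2
```

— the two planted 8-copy families survive the cascade and nothing else
does. `05_associate.py` then reports

```
H/M/L group sizes per family:
family  group
famA    H        1
        L        5
        M        2
```

which is exactly the planted structure for family A (one high-efficiency
copy in open unmethylated chromatin, two moderate, five low copies in
heterochromatic/RdDM context), and

```
strongest negative insertion-rate correlations:
     feature       R      P
H3K4me1_norm -0.9971 0.0
```

recovering the planted anti-monotone relationship between the H3-variant
features and the +1 bp insertion rate. Family A's recovered
normalized-frequency extremes sit ~230–250-fold apart, matching the
planted 249.64-fold contrast.

The same pipeline is exposed as a CLI (`mcsite simulate|discover|annotate|
profile|associate|demo`); `mcsite demo --seed 1 --out results/demo` runs
everything in one command. `analysis/06_tair10_integration.py` can run the
scanner against a locally provided Arabidopsis genome; no genome is
bundled.

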