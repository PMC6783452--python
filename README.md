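# mprasplice

Tools for designing, simulating and quantifying **massively parallel
splicing reporter assays** (MPRAs). The package targets experiments in
which tens of thousands of rationally designed 210-nt oligonucleotides —
each carrying a barcoded alternative-splicing context (retained intron,
cassette exon, or tandem 5′/3′ splice sites) with systematic sequence
manipulations — are integrated into cells and read out twice:

* **RNA**: targeted sequencing of the reporter transcript yields per-variant
  isoform counts, summarized as the *splicing ratio*
  `log2(N_iso1 / N_iso2)` (spliced/unspliced, included/skipped, or
  2nd/1st site).
* **Protein**: cells are FACS-sorted into 16 bins by `log2(GFP/mCherry)` and
  each bin is sequenced; a variant's read distribution across bins yields
  the *splicing value* (read-weighted mean of per-bin median
  `log2(GFP/mCherry)`), its variance, and the *noise strength*
  (variance/mean), a per-variant measure of cell-to-cell variability.

It is aimed at groups building or reanalyzing flow-seq style splicing
screens who need the full measurement model — library layout rules, read
filters, bin-profile QC, noise statistics and a sequence-based predictive
model — as tested, reusable code. A seeded synthetic-data generator stands
in for sequencing data, so every stage can be validated end to end against
planted ground truth.

## What is implemented

| module        | contents |
|---------------|----------|
| `libdesign`   | 210-nt oligo assembly (18-nt primers, 12-nt barcode, 162/147-nt variable region, SpeI/AatII cassette), barcode codes with pairwise Hamming ≥ 3, splice-site replacement recipes (consensus `CAGGTAAGT`, nonspliceable, GC/U12 variants, branch point), RBP/regulatory motif insertion, hairpin insertion, synonymous GC-extreme recoding, CG/GC dinucleotide injection, component swaps and tandem splice-site duplication |
| `simgen`      | planted sequence→splicing effects, isoform read counts, RNA/DNA expression reads, 16-bin sorted-cell profiles with planted cell-to-cell SD |
| `rnaquant`    | barcode demultiplexing, ≥100-read filter, pseudo-count rule, log2 splicing ratios, wild-type normalization, bootstrap CIs |
| `flowquant`   | four-step bin-profile filter cascade, Savitzky–Golay smoothing, delta-rule peak QC, weighted moments, noise strength |
| `noisemod`    | GAM noise residuals, identical-sequence randomization test against splicing-value-matched random sets, RNA-vs-protein and differential hexamer correlations |
| `seqfeatures` | regional hexamer counts, ATtRACT-style PWM log-odds scores, splice-site strength, GC features, secondary-structure features (ViennaRNA, with a base-pair-maximization fallback) |
| `splicemodel` | dedup → 90/10 holdout → 10-fold CV tuning → importance-based feature selection → gradient-boosted regression → variant-effect deltas |

## Worked example

```python
import pandas as pd
from mprasplice import simgen, rnaquant, flowquant
import numpy as np, scipy.stats as st

rng = np.random.default_rng(0)
feats = pd.DataFrame({"f1": rng.normal(size=500)}, index=[f"v{i}" for i in range(500)])
manifest = pd.DataFrame({"variant_id": feats.index,
                         "variable_region": [f"S{i}" for i in range(500)]})
cfg = simgen.SimConfig(n_variants=500, cells_per_variant=2000,
                       effect_sizes={"f1": 1.0}, seed=0)
truth, iso, profiles, medians, _ = simgen.simulate_assay(manifest, feats, cfg)

rna = rnaquant.quantify(iso)                         # log2 splicing ratios
prot = flowquant.quantify_profiles(profiles, medians["median_log2_ratio"].to_numpy())

ok = prot["splicing_value"].notna()
print(round(st.pearsonr(rna["splicing_ratio"], truth["true_rna_logratio"])[0], 3))
print(round(np.median(np.abs(prot["splicing_value"][ok]
                             - truth["true_protein_value"][ok])), 3))
```

prints

```
1.0
0.014
```

— the RNA quantification recovers the planted log2 ratios almost perfectly
at a depth of 10,000 reads/variant, and the flow-seq splicing value sits
within ~0.015 log2 units of the planted protein value for a typical variant.

A full synthetic pipeline (design → simulate → quantify → noise model) runs
from the shell:

```bash
mprasplice run-all --n-contexts 20 --seed 3 --out runs/demo
```

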