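# qmpdecomp

Quantitative microbiome profiling (QMP) of carcass decomposition: a tested
pipeline for spike-in calibrated absolute abundance, QMP-vs-RMP succession
comparison, co-occurrence networks, microbiota–metabolite integration, and
random-forest postmortem-interval (PMI) prediction — exercised end to end
on a synthetic cohort with known ground truth.

## The problem

Amplicon sequencing yields proportions, so when total microbial load
changes by orders of magnitude — the defining feature of a decomposing
carcass — relative microbiome profiling (RMP) can show a taxon "declining"
whose absolute population is flat or growing. QMP fixes the scale with
synthetic internal standards: spike-ins of known copy number `C_s` are
added to each quantified DNA extract, and each sample gets a standard
curve over its spike read counts `R_s`,

```
log10(R_s) = a · log10(C_s) + b
```

fitted by ordinary least squares. Inverting the curve converts any taxon's
read count to absolute copies, and dividing by the documented extract mass
gives **copies per gram** — the currency of every downstream analysis
here. The package implements both arms (QMP and rarefaction-based RMP) and
the analyses that expose where they disagree: early-vs-late trend
discordance on the top 100 genera (Wilcoxon + Benjamini–Hochberg),
time-decay succession rates, Spearman co-occurrence networks (|r| > 0.6,
P < 0.001) with greedy-modularity modules and module eigengenes, PCA /
PLS-DA / VIP metabolomics with PMI-correlated metabolite clusters,
Procrustes / Mantel / partial-Mantel / RDA integration, and optimized
random-forest PMI regression (IncMSE feature ranking, 10-fold CV biomarker
selection, repeated evaluation). Audience: microbial-ecology and forensic
researchers who want these methods reproducible and testable without the
original sequencing data.

Because no reads are downloaded, a first-class synthetic cohort module
generates the study design (132 samples: 48 regular soil, 42 grave soil,
42 tissue over days 0–35; bacteria and fungi profiled separately; tissue
metabolome) with known trajectories, planted decomposers, spike-ins, and
scenario presets — including the compositional trap (constant taxon over a
100×-growing load) that RMP must get wrong and QMP must get right.

## Worked example

Run the numbered drivers (each a thin wrapper over one pipeline stage;
stages share a run directory), or equivalently the `qmpdecomp` CLI
(`qmpdecomp simulate|calibrate|...|all --outdir ... --seed ...`):

```
cd analysis
python 01_simulate_cohort.py --outdir run --seed 5
python 02_calibrate_qmp.py   --outdir run --seed 5
python 06_integrate.py       --outdir run --seed 5
```

which prints (abridged):

```
simulated 132 samples: regular_soil=48, grave_soil=42, tissue=42
bacteria: 132/132 samples calibrated; slope 1.003 +/- 0.025, median R^2 0.9999
  rarefied depth: 35289 reads/sample
bacteria: Procrustes r=0.864 (M2=0.253, P=0.001), Mantel r=0.835 (P=0.001), partial Mantel r=0.144 (P=0.006)
fungi:    Procrustes r=0.859 (M2=0.261, P=0.001), Mantel r=0.840 (P=0.001), partial Mantel r=0.224 (P=0.001)
RDA: constrained fraction 0.700; top variable Pseudomonadota
```

Reading this: every sample's spike curve recovered the true unit capture
slope (a ≈ 1.00), so copies per gram track the simulated ground truth;
microbial ordinations superimpose tightly onto the metabolite PCA
(Procrustes r ≈ 0.86, permutation P = 0.001); and redundancy analysis
attributes most metabolite variance to the microbial summaries, led by
*Pseudomonadota*. The QMP-vs-RMP driver (`04_qmp_vs_rmp.py`) reports, per
sample type and domain, how many of the top 100 genera are classified
`contrasting` — RMP asserting a trend the absolute data do not support —
versus `qmp_only` (RMP blindness) and `concordant`; `07_predict_pmi.py`
prints test MAE ± SD per feature set against the null predictor
(~10.7 days on this design).

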