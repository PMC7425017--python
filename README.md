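# sifcall

Restriction-fragment-level calling of significant chromatin interactions
from Hi-C paired-end ligation data.

Hi-C libraries are dominated by uninformative ligations: un-cut or
re-circularized fragments, re-joined neighbors, and random collisions whose
frequency decays with genomic distance roughly as a power law. `sifcall`
separates genuine proximity ligations from this background at the
resolution of individual restriction fragments — no fixed binning — and
reports Significant Interacting Fragments (SIFs) with a per-anchor
resolution, plus downstream promoter–distal loop annotation and loop-set
evaluation (aggregate peak analysis, ROC/AUC).

## Model

Each observed fragment pair *l* carries a USF count *D<sub>l</sub>* (the
number of deduplicated valid read pairs mapping to it). Counts are modeled
as a two-component Poisson mixture,

&nbsp;&nbsp;&nbsp;&nbsp;*D<sub>l</sub>* ~ ω₁ Pois(λ₁) + ω₂ Pois(λ₂),&nbsp;&nbsp;ω₁ + ω₂ = 1,&nbsp;&nbsp;λ₁ ≤ λ₂,

with component 1 the random-ligation background and component 2 the
proximate (true-contact) signal. Parameters are estimated by EM and
robustified by bootstrap resampling with inner-fence outlier trimming.
Ligations caused purely by linear closeness are removed by a background
likelihood combining the power-law distance decay *p(d) ∝ d^α* with a
digestion-efficiency term (1 − E)^|k−j| over a window of neighboring
fragments. Significance is assigned per integer score *d* by a local false
discovery rate with an empirical null,

&nbsp;&nbsp;&nbsp;&nbsp;FDR<sub>d</sub> = FP<sub>d</sub> / (FP<sub>d</sub> + TP<sub>d</sub>),

where TP<sub>d</sub> is the Poisson density of the proximate component and
FP<sub>d</sub> is the density of scores resampled from the observed
multiset. A record is called when its score exceeds the fragment threshold
rate (FTR) and FDR<sub>score</sub> is below the chosen cutoff; adjacent
equal-score calls are merged, and the merged anchor length is the call's
per-side resolution.

## Worked example

The library ships a fully synthetic world with known ground truth:

```python
from sifcall import default_scenario, run_pipeline, RunConfig

fmap, pairs, truth = default_scenario(seed=1)
sifs, report = run_pipeline(pairs, fmap, RunConfig(seed=1))
print(len(pairs), report["stages"]["qc"]["valid"],
      round(report["stages"]["fit"]["lambda2"], 2), len(sifs))
```

prints

```
4000 3407 8.18 41
```

— 4000 simulated read pairs, of which 3407 survive deduplication and
ligation QC; the bootstrap EM fit places the proximate Poisson mean at
8.18 (the generator planted 50 loops with mean 8 on a background of mean
1); and at the default operating point (FTR = 1, FDR < 0.1) the caller
reports 41 SIFs, recovering 82% of the planted loops in this realization.

The same pipeline is available from the shell:

```
sifcall simulate --seed 1 -o sim/
sifcall run --config run.yaml --pairs sim/contacts.pairs \
        --frags sim/fragments.bed -o sifs.bedpe --report report.json
```

with subcommands `digest`, `qc`, `fit`, `background`, `call`, `annotate`,
`compare`, `apa`, `roc` for the individual stages.

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic world from the
given seed, runs the complete pipeline (QC → mixture fit → background
filter → FTR/FDR calling → merging), prints a short run summary, and
writes the result file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
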