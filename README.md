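# icmod

Integrative analysis of circadian multi-omics time series: transcript,
protein and phosphosite abundances measured around the clock (e.g. fly heads
sampled at CT0–21 in 3-h steps over 2 days of constant darkness, for a
wild-type and a clock-null condition).

The scientific problem: a phosphosite's intensity can oscillate simply
because its parent protein oscillates. To find rhythms that are genuinely
driven by phosphorylation/dephosphorylation, the phospho signal must be
normalized to protein abundance before rhythm detection. `icmod` implements
that pipeline end to end, for computational biologists working with
TMT-style proteomics plus RNA-seq time courses:

1. **Expression-informed reference** — only proteins whose mRNA reaches
   FPKM ≥ 1 in at least one sample are searched; reversed decoys (`REV_`)
   accompany every target; phosphosites are validated against the retained
   sequences and features not quantified in every sample are dropped.
2. **Normalization** — a bridge sample measured in two TMT batches yields a
   per-feature correction ratio for batch drift; per-sample global centering
   sets each sample's mean intensity to 1; and the **occupancy ratio**
   `phospho(site, t) / protein(parent, t)` defines the series in which
   rhythms are attributable to phosphorylation. Sites whose ratio cycles are
   *normalized circadian phosphosites* (NCPs).
3. **Rhythm detection** — harmonic regression with a jointly fitted linear
   trend: for each candidate period τ on a 0.1-h grid in [20, 28] h,

       y(t) = m + c·(t − t̄) + a·cos(2πt/τ) + b·sin(2πt/τ)

   The best τ minimizes the residual sum of squares; significance is the
   F-test against the trend-only null with the scanned period charged as an
   estimated parameter (3 vs n−5 df). Amplitude = √(a²+b²), phase = clock
   time of the fitted peak (mod 24), fold change = (m+A)/(m−A). A feature
   cycles when p < 0.01 (strict, uncorrected; BH q-values are reported).
4. **Kinase–substrate prediction** — group-based scoring: a 15-mer site
   flank is scored as its mean positional BLOSUM62 similarity (negative
   entries floored at 0) to a kinase's known substrate peptides, with the
   per-kinase threshold calibrated on reference-proteome background flanks
   to a fixed false-positive rate (10% for S/T kinases, 15% for Y kinases).
5. **Circadian-kinase enrichment** — for each kinase with n predicted
   substrates among N quantified sites, M of which are NCPs and m of its
   substrates NCPs:

       E-ratio = (m/M)/(n/N)
       p = Σ_{m'=m}^{n} C(M,m')·C(N−M,n−m')/C(N,n)   if E-ratio ≥ 1
       p = Σ_{m'=0}^{m} C(M,m')·C(N−M,n−m')/C(N,n)   otherwise

   Kinases with p < 0.05 and E-ratio > 1 are candidate circadian kinases.
6. **Signal web** — a typed graph of the circadian kinases, their NCP
   substrates, cyclic proteins attached by a single pass over a
   protein–protein interaction list, and transcription factors that both
   target a cyclic mRNA and carry a predicted site from the kinase set.
   Hubs are ranked by degree.
7. **Locomotor rhythmicity** — Sokolove–Bushell chi-squared periodogram for
   binned activity counts; a record is rhythmic when the statistic exceeds
   the (1−α) chi-squared significance line by ≥ 10.

A bundled synthetic-data generator (`icmod.synth`) produces complete studies
with planted cosine rhythms, kinase consensus motifs, batch effects and
ground truth, so every stage is testable without any download.

## Worked example

```
$ icmod synth --seed 42 --out bundle
wrote 12 files to bundle
$ icmod run --config config.yaml        # config pointing at bundle/, seed 42
{
 "n_sites": 573,
 "n_ncp": 162,
 "ncp_pct": 28.27,
 "residue_shares_pct": {"S": 80.1, "T": 14.83, "Y": 5.06},
 "n_circadian_kinases": 3
}
```

573 phosphosites survive reference mapping and completeness filtering; 162
(28.27%) have a cycling phospho/protein ratio at p < 0.01; the enrichment
test recovers exactly the three kinases whose substrate motifs were planted
preferentially on rhythmic-ratio sites (no false positives). The same flow
is available in Python:

```python
from icmod.synth import generate_multiomics, SynthConfig, pipeline_config
from icmod.pipeline import run_pipeline

bundle = generate_multiomics(SynthConfig(seed=42))
paths = bundle.write("bundle/")
report = run_pipeline(pipeline_config(paths, "results/", seed=42))
```

Subcommands `filter`, `normalize`, `rhythm`, `predict-kinases`, `enrich`,
`web` and `report` expose the individual stages; see `icmod <cmd> --help`.

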