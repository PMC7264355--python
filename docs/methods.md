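# Methods

## The occupancy-normalization model

Phosphosite intensity measured by LC-MS/MS confounds two signals: how much
of the parent protein is present, and what fraction of it is phosphorylated
(occupancy). For a site s on protein P at time t,

    phospho(s, t) = protein(P, t) · occupancy(s, t) · ε

so dividing the raw phospho series by the raw protein series, sample by
sample, leaves the occupancy series (up to noise). A protein that cycles in
abundance with constant stoichiometry yields a flat ratio; only
occupancy-driven rhythms survive. Sites whose ratio cycles are called NCPs
(normalized circadian phosphosites). The ratio uses *raw* (bridge-corrected,
uncentered) intensities: any per-sample scale factor common to protein and
phospho cancels, which also makes the ratio immune to a multiplicative batch
effect.

Operation order: bridge batch correction on raw intensities → occupancy
ratio on the corrected values → global centering of the protein matrix for
protein-level rhythm analysis only. Batch correction first, because a
per-batch intensity shift on a 2-day design aliases directly into 24-h
structure at the protein and mRNA levels.

### Bridge batch correction

One sample measured in both a reference batch and a drifted batch gives,
per feature f, the ratio r_f = bridge_ref(f)/bridge_tgt(f); every sample of
the drifted batch is multiplied by r_f. Features with a missing or zero
bridge value in either measurement have no defined ratio and are dropped,
not imputed — the downstream completeness filter discards incompletely
quantified features anyway.

## Rhythm detection

Each feature's 16-point series (CT0–21, 3-h steps, two days concatenated to
t = 0, 3, …, 45 h) is fit by least squares, for each period τ on a 0.1-h
grid over 20–28 h:

    y(t) = m + c·(t − t̄) + a·cos(2πt/τ) + b·sin(2πt/τ)

The linear term is fit *jointly* with the harmonic rather than removed
beforehand: a sequential detrend projects out part of a cosine observed
over a non-integer number of cycles (45 h ≈ 1.9 periods) and biases the
recovered period and amplitude, while the joint fit recovers a noiseless
cosine exactly. The null model is intercept + trend.

The p-value is the F-test of the harmonic model against the null with
**3 numerator degrees of freedom** (a, b, and the scanned τ) and n−5
denominator df. Treating the best-RSS period as free is what keeps the test
calibrated: with the textbook 2-df test, selecting the minimum RSS over the
period grid inflates the type-I rate roughly 2.5-fold (measured ~2.7% at
nominal 1% on iid normal series); with 3 df the measured rate is 0.7–1.2%
across seeds. An optional Yule–Walker/AIC period preselection was considered
and rejected: the dense grid is deterministic, oracle-checkable, and fast at
this problem size.

Reported statistics: amplitude √(a²+b²) (input units), mesor m, phase =
clock time of the fitted maximum mod 24 (so peaks bin onto a 24-h clock even
when τ ≠ 24), fold change (m+A)/(m−A) flagged undefined when the fitted
trough is ≤ 0, raw p, BH q. The cycling call is raw p < α (default 0.01,
strict) with no multiple-testing correction — the decision rule reported
alongside q-values for transparency. Degenerate (constant) series get
amplitude 0 and p = 1.

### Chi-squared periodogram (locomotor activity)

For binned counts x and a candidate period of K bins, using r complete
cycles: Qp = r·Σ_h (M_h − M̄)² / σ̂², where M_h are the K folded column
means, M̄ the grand mean and σ̂² the total variance of the used points;
under arrhythmicity Qp ~ χ²(K−1). The significance line is the (1−α)
quantile (α = 0.05); "power" is Qp minus the line at the best period and
power ≥ 10 declares rhythmicity (the field's convention for activity
monitors). All-zero records are reported with power 0.

## Kinase–substrate prediction

Group-based scoring: score(flank) = mean over the kinase's training
peptides of the positional similarity Σ_i max(BLOSUM62(a_i, b_i), 0), with
'*' terminus padding scoring 0. Training peptides are de-duplicated before
averaging so repeated entries cannot bias the mean. S/T-centered flanks are
scored by S/T kinases only, Y-centered by Y kinases only.

Thresholds are not fixed score cutoffs but false-positive-rate calibrations:
the threshold is the smallest observed background score s such that the
fraction of background flanks scoring ≥ s is ≤ FPR (conservative
tie-break), with background flanks sampled uniformly without replacement
from the filtered reference proteome (default n = 10,000, seed recorded).
Defaults: FPR 10% (S/T kinases), 15% (Y kinases). This scheme follows the
published group-based predictor family as an approximation; it does not
claim bit-exactness with any particular release, and group/family labels
are metadata supplied with the model files, not inferred.

## Circadian-kinase enrichment

With N quantified sites, n predicted for kinase k, M NCPs and m NCPs
predicted for k: E-ratio = (m/M)/(n/N); the p-value is the hypergeometric
tail in the direction of the effect — upper tail Σ_{m'=m}^{n} when
E-ratio ≥ 1 (ties to the upper tail), lower tail Σ_{m'=0}^{m} otherwise.
This direction-switched pair of one-tailed sums is what "two-sided" means
here; it is not a symmetric two-tailed mass test, and the observed term is
included in both directions. Binomial coefficients use exact integer
arithmetic for N ≤ 1000 and log-gamma otherwise. Classification is p < 0.05
AND E-ratio > 1, both strict, uncorrected across the kinase family (BH q
reported alongside). The same machinery serves flat gene-set enrichment
(annotations are used as flat sets, no ontology-graph propagation).

## Signal web

Three passes, deterministic and order-independent. (1) Core: predicted
kinase→site edges from the classified kinase set to NCP sites, with parent
proteins as substrate nodes. (2) PPI expansion: a cyclic protein with at
least one interaction partner in the core membership snapshot is attached —
single pass, no transitive chaining, never removing existing content.
(3) TF layer: a transcription factor qualifies only if it targets a cyclic
mRNA *and* carries a predicted site from the kinase set. Hubs are ranked by
total degree with lexicographic tie-break. Coverage is reported as three
separate fractions (direct: cyclic protein contains a covered NCP;
indirect: covered only via a PPI edge to a covering protein; union) because
the published summary statistics do not state whether the indirect
denominator excludes the direct class.

## Synthetic-data generator

The generator emulates the study design, not the instrument: 16 samples per
genotype (CT0–21 × 2 days), planted cosines
y(t) = mesor·(1 + A·cos(2π(t−φ)/24)), multiplicative log-normal noise, a
clock-null condition in which a configurable fraction (default 0.9) of
planted rhythms is flattened, a 0.5× batch effect on a 6-sample batch with
a bridge sample duplicated across batches, kinase consensus motifs written
into the protein FASTA at the planted site flanks, and a PPI/TF-target
layer. Defaults and why:

- `amplitude_rel = 0.3`, `noise_cv = 0.1` — low-amplitude oscillations
  under ~10% multiplicative noise, the regime TMT time courses occupy; an
  optional amplitude-shrink factor emulates TMT ratio compression (off by
  default).
- `noise_share = 0.5` — fraction of log-variance shared between a protein's
  measurement and its phosphopeptides' measurements in the same sample.
  The two are quantified from one physical sample, so loading and
  biological variation are common to both and cancel in the ratio; the 0.5
  default makes the occupancy-ratio series carry the nominal `noise_cv`
  rather than the √2-compounded value of fully independent noises.
- Six kinase models with generic consensus classes (basophilic R at −3,
  proline-directed P at +1, acidophilic D/E at +1..+3, and three more),
  three designated circadian; 50 training peptides each. These are motif
  archetypes, not claims about specific kinases.
- `p_ncp_circadian = 0.45`, `p_ncp_other = 0.04` — rhythmic-ratio sites are
  planted preferentially on substrates of the circadian kinases. The rates
  give ~24% NCP prevalence, above the ~17% seen in real head data, because
  the bundle is a scaled-down study (600 sites vs thousands): at desk scale
  the enrichment signal must be per-kinase detectable with ~100 substrates
  per kinase.
- The bridge sample is the same measurement re-scaled by the batch factor
  (no fresh noise), so ratio correction is exactly invertible and the
  correction can be verified to machine precision.
- Phases are uniform by default; a night-bias option concentrates NCP peaks
  in CT12–24.

What the generator does **not** model — and hence what passing tests do not
show about real data: peptide-to-protein summarization, missing-not-at-
random dropout, isobaric interference/ratio compression beyond a scalar
shrink, multiply-phosphorylated peptides (one intensity series per site is
assumed, as in the input contract), phase-dependent waveform asymmetry, and
inter-animal variability.

## Numerical choices and degenerate inputs

- Missing is NaN and is never conflated with 0; a quantified zero passes
  the completeness filter, an empty/NA cell does not.
- Period grid 20–28 h, step 0.1 h; p-values floored at 1e-300; constant
  series detected by a scale-relative variance test (≤ 1e-24 of the total
  sum of squares).
- Threshold calibration requires ≥ 100 compatible background flanks.
- Percentages in reports are rounded half-up to 2 decimals (`report.pct`),
  matching how printed tables round 0.5955% to 0.60%.
- Hub ranking and all web serializations sort nodes/edges so outputs are
  byte-stable across runs.

## Known limitations

- The rhythm detector is a single-harmonic cosinor; asymmetric waveforms
  lose power relative to multi-harmonic fits.
- The 3-df F correction calibrates the period scan well at this design
  (16 points, 20–28 h band) but is not a general selective-inference
  guarantee for other designs.
- Kinase scoring reconstructs the group-based scheme generically; per-kinase
  predictor hierarchies (group/family/subfamily fan-out) are not modeled —
  each model file is an independent predictor.
- The enrichment test's "never called" guarantee for constant-stoichiometry
  sites is statistical: each null site still carries the detector's ~1%
  type-I risk.
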