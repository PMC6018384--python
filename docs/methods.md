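# Methods

This note records the model behind `maldiderep`, the parameter choices
and their rationale, the numerical conventions, and what the synthetic
data do and do not establish about real measurements.

## The dereplication model

A whole-cell MALDI-TOF profile in linear positive mode (2–20 kDa,
masses in Da under the +1-ion convention) is dominated by ribosomal
proteins and is stable enough within a species that spectral similarity
can stand in for 16S rRNA gene similarity. The package treats each
spectrum, after preprocessing and peak alignment, as a non-negative
intensity vector; cosine similarity between vectors measures relatedness
and 1 − CS serves as the clustering distance (it is not claimed to be a
metric). UPGMA trees cut at 1 − T꜀ₛ define the dereplication bins. The
threshold T꜀ₛ is not universal: it is calibrated so that the spectral
partition mimics a chosen 16S species proxy, either closest-type-strain
phylotypes or the 98.65 % pairwise-identity rule.

## Preprocessing chain

Order is fixed (sqrt → trim → smooth → baseline → TIC → detect) and the
composition of the six steps is exactly what the pipeline computes; this
order makes the whole chain invariant to rescaling raw intensities by
any positive constant, so detector gain cancels out.

| parameter | default | meaning |
|---|---|---|
| `mass_low`, `mass_high` | 4000, 10000 Da | analysis window; 2000–20000 for full-range diagnostics |
| `sg_half_window` | 20 points | Savitzky–Golay window (2·20+1 points) |
| `sg_order` | 3 | polynomial order; unstated in common protocols, 3 is the usual default |
| `snip_iterations` | 50 | SNIP clipping sweeps |
| `snr` | 3.0 | peak signal-to-noise cutoff |
| `peak_half_window` | 20 points | strict-local-maximum window |

Numerical conventions worth knowing:

- **Half-windows are in data points**, not Da; the SG filter runs on the
  index domain, so strongly non-uniform mass axes are a documented
  limitation (linear-TOF exports are near-uniform).
- **SNIP** uses the decreasing-window sweep
  (`y[i] ← min(y[i], (y[i−k]+y[i+k])/2)`, k from 50 down to 1). Every
  step only lowers the trace, which guarantees baseline ≤ raw and a
  non-negative corrected spectrum. Linear baselines are reproduced
  exactly and removed completely.
- **Noise for peak detection** is the supersmoother fit of the processed
  intensity trace itself, floored at machine epsilon; SNR is the ratio
  of the (baseline-corrected, TIC-normalised) intensity to this level.
  Peak detection therefore runs after baseline removal and
  normalisation, consistent with the chain order. The supersmoother is
  the classic variable-span construction: three running-line smoothers
  (spans 5 %, 20 %, 50 %), per-point span selection by smoothed
  leave-one-out absolute residuals, and a final tweeter-span pass; bass
  enhancement is omitted as the noise-floor use is insensitive to it.
- **Boundary points are never peaks** (the full window must fit), which
  avoids edge artifacts at the trim boundaries.

## Peak binning and the feature matrix

Pooled peaks are split divisively at the largest internal mass gap until
every member lies within a relative tolerance (default 0.002) of the
group mean and no spectrum contributes two peaks to one bin. The
tolerance is relative because an absolute 0.002 Da would be far below
linear-TOF resolution. Splitting at the largest gap is deterministic and
order-independent, and every peak lands in exactly one bin. If two peaks
of the same spectrum are inseparable (identical masses), the more
intense one represents the spectrum in the matrix cell.

Absent peaks are back-filled by linear interpolation of the spectrum's
preprocessed trace at the bin mass — the trace is dense (1 Da grid in
the synthetic data), so higher-order interpolation would add nothing
testable. The matrix therefore has no missing values, a requirement of
both the cosine computation and the discriminant analysis.

Technical-outlier QC computes each spectrum's ACS to the other technical
replicates of its (culture, biological replicate) group and removes
outliers **iteratively**: the worst spectrum below the 0.9 cutoff is
dropped and the remaining ACS recomputed. A one-pass rule would let a
single aberrant replicate drag its well-behaved partners below the
cutoff; the iterative form removes only the aberrant one. QC runs on the
configured analysis window. Singleton groups are kept and flagged.

## Sequence identity

Global (Needleman–Wunsch) alignment with match +5, mismatch −4, affine
gaps −10/−0.5, end gaps penalised. The scoring is a standard
EDNAFULL-style scheme; for near-full-length rRNA genes above ~97 %
identity the resulting percent identities are insensitive to it.
Identity = 100·matches/(matches+mismatches): every gap-containing column
is excluded from the denominator. Sequences are assumed pre-trimmed to a
common region, so terminal-gap columns are negligible; whether terminal
gaps should be treated differently from internal ones is left as this
single documented convention rather than a configuration guess.

## Clustering and partition comparison

UPGMA heights are average inter-cluster distances (merge heights are
non-decreasing, so cuts at growing heights yield nested partitions). A
cut applies exactly the merges with height **strictly below** the
cutoff: cutting at a merge height separates that merge.

"Redundant" spectral clusters — extra clusters created by biological
variability — are defined operationally: each culture's *primary*
cluster is the cluster holding the plurality of its spectra (ties to the
lower label); a cluster that is primary for no culture is redundant.
Perfect one-cluster-per-culture partitions have zero redundancy. For the
culture-agreement counts, each culture's companions under the spectral
partition (cultures sharing its primary cluster) and under the reference
are compared: if the companion sets split into equally many groups the
culture is "separated the same way"; otherwise whichever method splits
further is credited. These two definitions are this package's
operational conventions; the summary statistics they feed (cluster
counts, dereplication rate = 100·clusters/samples) are standard.

## Threshold optimisation

The unit of the 2-fold split is the **pair**, matching the construction
of the pair dataset; note pair-level splits share individual samples
across folds, so the held-out precision/recall are not fully independent
of training — a sample-level split would be stricter but would change
the estimand. Ties among equal-F₁ grid points resolve to the mean of the
tied thresholds (symmetric and deterministic); with widely separated
similarity modes this places T꜀ₛ mid-gap. Reported test precision and
recall are means over the two held-out halves; `CS ≥ t` counts as
positive (inclusive). The seed is a required, logged parameter.

## Discriminant analysis

CAT scores follow the correlation-adjusted t-score construction:
per-class t-type contrasts (class centroid vs pooled centroid, scaled by
`sqrt(1/n_g − 1/n)` times the shrunken pooled standard deviation),
decorrelated by the inverse square root of the shrunken feature
correlation matrix (computed by eigendecomposition) and aggregated
across classes by sum of squares. Variances shrink toward their median
and correlations toward the identity with analytically estimated
intensities. Forcing the correlation shrinkage to 1 reduces CAT scores
to ordinary shrinkage t-scores exactly (tested closed-form). Numerical
parity with any particular released implementation is not claimed;
behaviour is validated by simulation (planted signals recovered, null
ranks uniform, scale invariance).

The local false discovery rate is estimated on the magnitude scale
s = √(aggregated score): Gaussian empirical null centred at the median
with MAD-based scale, kernel-density marginal, null proportion matched
at the null centre, and an antitonic-regression pass enforcing that lfdr
is non-increasing in s. Bins with lfdr < 0.2 are selected. **Limitation:**
central matching assumes most features are null; when the majority of
bins genuinely discriminate (as in dense synthetic fingerprints) the
null absorbs part of the signal and selection becomes conservative. The
cross-validated classifier therefore falls back to all bins when fewer
than two are selected.

Accuracy uses repeated stratified k-fold cross-validation (default
10×10): per training split the ranking is refit, bins selected, and a
diagonal discriminant classifier (class means, shrunken pooled
variances, empirical priors) predicts the held-out fold. Classes smaller
than the fold count reduce the fold count to the smallest class size,
with a warning.

## Synthetic data: what it emulates and what it does not

The generator mirrors the hierarchical design of a recurrent-isolate
survey: per culture a fingerprint of Gaussian peaks (default 30) with
lognormal base intensities, drawn with ≥5σ spacing inside 4–10 kDa;
biological replicates (default 4) perturb the fingerprint itself (5 %
peak dropout, 25 % lognormal intensity CV); technical replicates
(default 3) add only measurement noise (200 ppm Gaussian mass jitter,
5 % intensity CV). Traces are rendered on a 1 Da grid over 2–20 kDa with
an exponentially decaying baseline and additive Gaussian noise clipped
at zero. These defaults were chosen once to reproduce the qualitative
regime of real surveys — technical ACS above 0.99, biological ACS
clearly lower (~0.93) — and are the conditions under which all
end-to-end tests run.

Phylotype structure is planted by letting cultures of one phylotype
share a fraction (default 0.7) of their peaks. Sequence sets are built
on a two-level star (root → group ancestor → sequence) with disjoint
substitution blocks and deterministic alternative bases, so planted
pairwise identities are **exact** by construction; target combinations
that no additive configuration can realise within 0.3 identity points
are rejected rather than approximated.

Not modelled: linear-TOF peak asymmetry and mass-dependent resolution,
detector saturation, isotope structure, chemical-noise correlation,
run-to-run calibration drift, and the heavy-tailed biological
variability of real cultures. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under the stated
generative model — not that any particular threshold value (e.g. the
mid-gap T꜀ₛ of low-noise simulations) transfers to measured spectra.
Real collections have overlapping intra/inter similarity modes, and
their calibrated thresholds are dominated by biological reproducibility.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen as
the smallest sizes at which every qualitative behaviour is expressed:
collections of 5–20 cultures (60–240 spectra on 18 001-point grids),
sequence sets of ≤20 × 1 392 bp, pair tables of a few hundred to ~29 000
pairs, and discriminant matrices of ~40 × 300. The acceptance script's
simulated survey uses 20 cultures in 16 phylotypes, 4 × 3 replicates.
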