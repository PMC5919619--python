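# Methods

This note documents the models, conventions, and parameter choices behind
`lipidmrm`, and states what the synthetic-data generator does and does not
emulate.

## Mass model

All arithmetic is monoisotopic (C 12.000000, H 1.0078250, N 14.0030740,
O 15.9949146, P 30.9737615; proton 1.0072765). Species masses are built by
condensation: a ceramide is sphingoid base + fatty acid − H₂O; SM adds a
phosphocholine head (−H₂O); acylcarnitines are carnitine + fatty acid −
H₂O; cholesterol esters are cholesterol + fatty acid − H₂O.
Glycerophospholipids are represented at sum-composition level (total acyl
carbons : double bonds) because precursor/neutral-loss scans cannot resolve
sn-positions; the ether ("e-") and plasmalogen ("p-") PC variants modify
the diacyl formula by −O+H₂ and −O respectively, which makes ePC(n:d+1)
exactly isobaric with pPC(n:d) — such pairs are reported together as
co-candidates.

Adducts: [M+H]⁺, [M−H]⁻ (FFA only), and the in-source dehydrated
[M+H−H₂O]⁺ for sphingolipids. Dehydration matters: trihydroxy
(phytosphingosine, t18:0) ceramides lose water so readily in the source
that their observed precursor is the dehydrated ion — the printed
set-points of every phytoceramide (and one sphinganine ceramide) in the
reference panel are ~18 Da below the protonated species and match only
this way. Candidate ranking therefore prefers the dehydrated adduct for
t-bases and the protonated adduct for d-bases. A useful consequence of the
mass algebra: a dehydrated CerA_(x:0)2OH ion is exactly isobaric with the
protonated CerN_(x:1); when both fall in the window the result is flagged
ambiguous and the Q3 fragment plus the base-specific adduct preference
decide the top call.

## Matching tolerance and set-point quantization

Instrument set-point tables for unit-resolution QqQ methods are written to
one decimal and are routinely a few tenths of a Da below the exact
monoisotopic m/z of heavy lipids (mass defect). Matching uses a ±0.5 Da
window applied to the mass error rounded to 0.1 Da — the print precision of
set-points — so a candidate 0.52 Da from a one-decimal set-point is not
rejected by less than the quantization of the table itself. Tightening the
tolerance never adds candidates and loosening never removes them; this
monotonicity is property-tested.

## Candidate grids

Chain enumeration is bounded and config-exposed (`ChainGrid`): carbons
2–36, double bonds 0–6, at most one hydroxyl. Three chemically motivated
restrictions, each needed to keep isobaric nonsense out of the top ranks:

* **Even carbon counts** for single-chain classes (fatty-acid biosynthesis
  proceeds in C2 units; odd chains are rare in mammalian tissue). Without
  this, the unattributable FFA SIM at 487.5 would match an odd-chain 33:3.
* **Ceramide N-acyls are saturated or monounsaturated** (true of tissue
  ceramides); otherwise e.g. an absurd 18:6 N-acyl outranks the real
  α-hydroxy 16:0 at 554.2.
* **Hydroxy acyls carry ≤ 1 double bond** (skin α-/ω-hydroxy fatty acids
  are saturated or monounsaturated).

PC-family searches run over all integer sum-compositions for diacyl PC and
SM (odd totals arise from d16/d17 bases and odd N-acyls and appear in the
reference panel), but even totals only for the ether/plasmalogen variants.
They also enumerate +1-isotopologue interferences (+1.00335 Da), reported
only ever as co-candidates — mirroring "possible isotope" annotations —
never as the top call. Transitions from the oleate/arachidonate
acyl-residue scans (NL 299/321, Prec 303.1) name a chemical motif, not an
enumerable species class, and always return `not_attributed`.

Two families of rows in the packaged reference table contradict their own
printed m/z and are resolved in favor of the mass: the acylcarnitine rows
are labelled exactly 4 CH₂ below the chain matching their parent m/z (the
engine reports the mass-consistent chain), and one phytoceramide row
(650.3→282.1) is printed 6.3 Da away from its named species and resolves
to the isobaric-consistent CerNP(t18:0/24:0). Both are asserted as such in
the acceptance tests.

## Ingestion and normalization

Per-transition intensity is the trapezoidal integral of the chronogram
over the whole acquisition window — flow injection yields one burst per
transition, and the integral is robust to peak shape (whether the original
in-house processing summed or averaged points is not modeled; the integral
is this package's documented choice). File transitions map to method
transitions by nearest match within ±0.5 m/z on both quadrupoles.
TIC normalization divides by the method-wise sum per sample; it is
idempotent, scale-invariant, and rejects all-zero samples. Positive and
negative methods are normalized separately.

mzML support covers the SRM-chromatogram dialect: chromatogram elements
with 64-bit-float time/intensity arrays (optionally zlib-compressed) and
precursor/product isolation windows, written and read by this package and
round-trip-tested to within numerical precision.

## Synthetic cohort generator

The generator emulates the study design: 8 WT + 7 cpdm testing mice,
11 WT + 10 cpdm validation mice (36 total); per-transition true cpdm/WT
fold changes defaulting to the packaged discriminative panel; log-normal
within-group noise with unit mean and CV 0.2; per-sample total-intensity
factors log-normal with log-scale SD 0.3. The variance parameters are
documented knobs, not estimates — no variance components were reported for
the original data.

Fold changes are defined on the *normalized* scale. A composition cannot
change some parts and leave the rest fixed: if effect transitions were
simply multiplied, TIC normalization would shrink every stated fold change
by the closure factor (~0.75 at the defaults). The generator therefore
gives both group mean profiles total mass 1 by applying the stated fold
changes to effect transitions and spreading the compensation pro rata over
the unmodeled ones (which consequently share a small common fold change of
(1−Σ_eff b·FC)/(1−Σ_eff b) rather than exactly 1). Stated fold changes are
then recoverable by construction; the TIC factor cancels exactly.

What the generator does **not** emulate: chemical noise and isobaric
interference, detector saturation, carryover between injections,
chromatographic effects, correlated lipid co-regulation, or batch
structure. Passing tests on synthetic data therefore demonstrate that the
pipeline's estimators and classifiers recover known truth under the stated
noise model — not that real epidermis data would separate as cleanly.
Accordingly, real-data quantities such as PCA explained-variance
percentages or the FFA panel's exact misclassification counts are out of
scope; only their directions (group separation, sphingosine-ceramide share
up, ≥C26 FFA share down, Fasn fold change < 1) are asserted, on synthetic
cohorts.

A note on recovery rates: with CV 0.2 and 7/8 samples per group, the
cpdm/WT ratio of group means has a sampling CV of
√(0.2²/7 + 0.2²/8) ≈ 0.103, so a single replicate lands within 15 % of
truth only ~86 % of the time — the measured per-seed rate in the test
suite (86–89 % over 200 seeds) matches this closed form. Averaging over
200 replicates, as the acceptance script does, estimates the strongest
fold changes to well under 1 %.

## Statistics

* **t-tests**: two-sided, unpaired, equal-variance by default (Welch
  behind a flag); features with zero variance in both groups are flagged
  untested rather than given a fabricated p-value.
* **Holm–Šidák**: step-down, α = 0.05; the implementation (statsmodels) is
  property-tested against the literal definition
  p₍ⱼ₎ ≤ 1 − (1−α)^{1/(m−j+1)} on random p-vectors.
* **Volcano selection** uses the raw p-value (≤ 0.05) with a two-fold-change
  cut in either direction; the adjusted significance flag is reported
  alongside. Whether the published per-feature p-values were raw or
  adjusted is not stated anywhere authoritative; raw is this package's
  documented reading.
* **Autoscaling**: per-feature mean-centering and unit variance (ddof = 1).
  Constant features are dropped with a warning before PCA. PCA signs
  follow a fixed convention (largest-magnitude loading positive).
* **Clustering**: Ward linkage on Euclidean distances of autoscaled data —
  a documented choice; no linkage was specified for the original heat maps.
* **Fold change** is the ratio of arithmetic group means of normalized
  intensities (matching fold-change entries below 1 read as cpdm/WT).

## ROC panels

Univariate AUC comes from the Mann–Whitney U (ties counted half), oriented
so AUC ≥ 0.5, with the Youden-optimal threshold placed at the midpoint
between adjacent observed values; rank AUC equals the trapezoidal ROC
integral exactly and is cross-checked against an independent
implementation in the tests. Panels use PLS-DA — PLS regression on a 0/1
class code with two latent components (the smallest panel has three
features; component count is config-exposed) on standardized features,
class probability = ŷ clipped to [0, 1], hard calls at 0.5. Cross-validation
is repeated stratified Monte-Carlo subsampling (2/3 train, 100 repeats,
seeded) — a documented stand-in for the unreported internals of the web
tool originally used; the headline quantity, blind accuracy on the held-out
validation split, does not depend on the CV scheme. A 500-tree random
forest is available as the alternative algorithm. Training uses only
testing-split samples, and prediction refuses samples seen in training.

## Quantification and qPCR

Internal-standard quantification: concentration = (analyte area / IS area)
× IS nmol / dry weight, with 0.5 nmol IS and weights in mg (homogeneous of
degree +1 in analyte area and −1 in IS area and weight). Calibration
linearity is OLS over the spiked series (default five levels, 1–10⁴ ppm,
three replicates each); the verdict is linear at R² ≥ 0.99 — a documented
numerical cut-off for a qualitatively reported property. qPCR fold changes
use the comparative-Ct form 2^(−ΔΔCt) with per-sample ΔCt against Actb and
group-mean ΔΔCt, plus an unpaired t-test on ΔCt.

## Screening methods shipped with the package

The original supplementary transition lists are not redistributed. The
packaged methods are a synthetic reconstruction built from the
discovery-scan design over realistic chain grids, sized to the published
counts (217 positive, 83 negative transitions) and guaranteed to include
every transition of the packaged discriminative panel. They make the
pipeline runnable end to end and exercise the assembly invariants
(deduplication at 0.1 Da, polarity purity, collision-energy fill-in:
ceramides/PE/acyl-residue 22 V, PC/SM 20 V, PS/PI 16 V, CE 17 V,
acylcarnitines 30 V, negative mode 2 V, fragmentor 100 V); they are not
the instrument's actual method files, and any user-supplied TSV method is
accepted in their place.

## Problem sizes and determinism

Test-suite simulations use the study's own design (36 samples × 217/83
transitions) and 200-replicate seed banks for recovery rates; the
acceptance script runs one 36-sample cohort for the panel and 200
replicate 15-sample cohorts for fold-change estimation. Every random stage
takes an explicit seed (the pipeline derives logged per-stage sub-seeds
from the master seed), and equal seeds byte-reproduce all numeric outputs.
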