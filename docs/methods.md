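# Methods

## Analysis model

The pipeline treats each subject's brain as a 90-node network (the AAL
cortical/subcortical regions, cerebellum excluded; 45 per hemisphere)
partitioned into 8 resting-state networks: visual (VSN), somatomotor (SMN),
dorsal attention (DAN), ventral attention (VAN), limbic (LBN),
frontoparietal (FPN), default mode (DMN) and a deep gray matter network
(DGN) consisting of the bilateral caudate, putamen, pallidum and thalamus.
The per-region network assignment is not uniquely fixed by the Yeo-style
clustering convention it follows; the packaged table
(`src/rsfcnet/data/aal90_networks.tsv`) is an explicit, editable
reconstruction and should be treated as configuration. Individual
assignments (e.g. Rolandic operculum → SMN, mid-cingulate → VAN) are
defensible but not canonical; users with a preferred mapping can supply
their own TSV. The network label order VSN, SMN, DAN, VAN, LBN, FPN, DMN,
DGN is fixed and determines feature indexing everywhere.

Subject-level connectivity is the Pearson correlation matrix r of the
cleaned ROI time series. Two transforms feed the three analysis levels:

* Fisher z = atanh(r) (variance-stabilising; |r| clipped at 0.999999 so the
  transform stays finite) for the network and edge levels;
* an exponential conversion c(r) = exp(r − 1) for the integrity level,
  whose off-diagonal row means give the nodal degree
  η_i = mean_{j≠i} c(r_ij). The conversion the integrity level should use
  is cited in the literature without a printed formula; exp(r − 1) is this
  package's documented default — strictly increasing, positive, bounded
  ((e^−2, 1]), equal to 1 at r = 1 — and is pluggable
  (`rsfcnet.connectivity.CONVERSIONS`). η is a mean rather than a sum so
  its scale is independent of the node count; group contrasts are invariant
  to this affine choice.

Negative correlations enter all averages as-is (no thresholding). Whether
network-level averaging should use raw r or Fisher z is ambiguous in the
source conventions; z is the default here and r remains available by
transforming upstream.

## Temporal preprocessing

Spatial preprocessing (slice timing, realignment, normalisation, smoothing)
is out of scope and assumed done upstream. The temporal chain is applied in
the fixed order **trim → detrend → nuisance regression → band-pass**, each
step at most once (enforced at run time):

* trim: drop the first k = 10 volumes (equilibration/adaptation), e.g.
  383 → 373 time points at TR = 0.8 s;
* linear detrend: per-column OLS line removal;
* nuisance regression: OLS residual against intercept + confounds (motion,
  CSF, white matter; global signal optional). Rank-deficient confound
  designs raise an error rather than falling back to a pseudo-inverse;
* band-pass: the stated 0.01–0.08 Hz band is implemented as a zero-phase
  Butterworth band-pass, order 2, applied forward–backward — the two-sided
  cut-offs define a band even where the step is described as low-pass
  filtering. Order and family are config keys, since only the band is
  conventionally fixed. Whether filtering should precede or follow
  nuisance regression is not standardised; the order here follows the
  conventional listing, and a joint treatment is deliberately not
  attempted.

Zero-variance ROI columns are flagged, not zeroed: downstream features that
depend on a flagged node become missing values with a logged report, so
undefined correlations can never leak into the statistics silently.

## Group statistics

Every feature is tested with the same GLM,
`feature ~ intercept + group + age + sex + education`; the reported t is
the group-coefficient t, computed by Frisch–Waugh partialling so that the
4005-edge family and the permutation loop stay fully vectorised (the
equivalence with an ordinary per-feature OLS fit is asserted against
statsmodels in the tests). With no covariates this reduces exactly to the
pooled two-sample t, which unifies the "independent-samples t-test" and
"GLM controlling for covariates" descriptions into one code path.

Permutation inference uses the Freedman–Lane scheme: nuisance covariates
are regressed out of the outcomes once; the residual rows are permuted B
times (B = 5000 by default, minimum 100, seed mandatory); each permuted
outcome is refit under the full model (the permuted residuals are
re-orthogonalised against the nuisance design before the group fit);
p_perm = (1 + #{|t_b| ≥ |t_obs|}) / (B + 1). Per-feature permutation p
values are passed through Benjamini–Hochberg step-up (the `significant`
flag, q = 0.05 by default), and a max-T family-wise p is reported as a
stricter companion. Parametric p and its BH q are emitted alongside, since
which of the two enters the FDR step at the edge level is a genuine
ambiguity in common practice. Raw-label permutation is available via
`scheme="labels"` for balanced designs.

A granularity constraint follows from the discreteness of permutation p:
the smallest attainable value is 1/(B+1), and BH across m features can only
ever reject if 1/(B+1) ≤ q/m. With the 36 network features at q = 0.05
this requires B ≥ 720; with 4005 edges a *single* significant edge would
require B ≥ 80 100, although BH's step-up threshold k·q/m relaxes quickly
when many edges carry signal. Callers testing small effects at the edge
level should either raise B or rely on the parametric-p FDR column.

Clinical regressions (`scale ~ feature + age + sex + education`, patients
only, features restricted to those flagged in the group contrast) are
exploratory: no multiplicity correction is applied and the output metadata
records this. Pairs with fewer than 10 complete cases are flagged `low_n`.

Cohort description tables use Welch's t from summary statistics (it
reproduces the reference age and education comparisons better than the
pooled form); sex is compared by chi-square on counts. A known
irreproducibility is asserted in the tests rather than patched: the
emulated cohort's printed MMSE p (0.0481) is not obtainable from its
printed means/SDs/ns under either Welch or pooled t (both ≈ 0.07), and the
printed education mean (9.82) disagrees with the accompanying text (9.83);
the text value reproduces the printed p = 0.109.

## Synthetic cohorts

`rsfcnet.synthetic` generates seeded cohorts with the structure the
analysis assumes, at the emulated study's scale by default: 47 patients and
50 controls, T = 373 time points at TR = 0.8 s. Each subject's series is
stationary correlated Gaussian noise, X = G L' with G iid standard normal
and L an eigenvalue square root of the group's target correlation matrix.
Targets are block-constant: rho_within = 0.4 inside each network,
rho_between = 0.1 elsewhere — mid-range values for band-limited BOLD ROI
correlations — and the patient target subtracts `deltas` from named blocks
(defaults concentrate reductions in SMN, LBN, DGN and VSN plus three
inter-network pairs, 0.06–0.15 in size, matching the expected
disease pattern in location and the "moderate reduction" range in size).
Deltas can break positive semidefiniteness; targets are repaired by
eigenvalue clipping with diagonal renormalisation, the repair distance is
logged, and a repair that moves any entry by more than 0.05 is an error.

Demographics are drawn per group from the emulated cohort's summary rows
(age 62.34 ± 11.41 vs 61.32 ± 5.60; education 9.83 ± 3.44 vs 10.92 ± 3.18;
male proportions 18/47 vs 19/50; patient-only disease duration and H-Y
stage). Clinical scales are linear in the subject's *realized*
network-FC features, `score = intercept + Σ w_k (z_k − center_k) + noise`,
centred on the group target's expected Fisher z so intercepts equal group
means; the default weights plant positive MoCA↔DGN (and VAN–DGN) links and
negative HAMA/HAMD links to SMN/LBN/VAN/DGN. Weights (±60–150 per unit z)
were chosen once so that planted links are detectable but not trivial at
n = 47 given the ≈ 0.01–0.03 between-subject SD of a network-mean z at
T = 373; scores are left unbounded rather than truncated to scale ranges so
linear-recovery tests stay exact.

Generated series are emitted at stage `cleaned`: the generator models
*post-preprocessed* BOLD, so the pipeline's temporal chain applies only to
NIfTI/ROI-table inputs. What the generator does **not** emulate: hemodynamic
autocorrelation (an optional AR(1) knob exists, off by default — white
noise is the cleanest setting for calibration checks since autocorrelation
inflates correlation variance), motion and scanner artifacts, heavy-tailed
noise, site effects, and between-subject heterogeneity of the target
matrices (all subjects in a group share one target). Passing tests
therefore demonstrate correctness and calibration of the *analysis* under
its own assumptions, not robustness to real-data violations of them.

## Determinism and outputs

All randomness flows through a single integer seed (cohort generation and
permutation inference). Result TSVs are written with a fixed float format
(`%.10g`); rerunning a config with the same seed reproduces them byte for
byte. Per-stage wall times go to `timings.json`, kept separate from
`manifest.json` (config hash, seed, subject/feature/significant counts,
library versions) precisely so the manifest is also reproducible.

## Problem sizes used in the checks

Structural and oracle checks run on toy instances (≤ 10 nodes, brute-force
double-loop oracles, 100 random instances). Calibration checks use
40 + 40-subject cohorts at T = 373 with the 36 network features and
B = 1000 permutations: 200 no-effect replicates for false-discovery and
uniformity calibration, and 100 replicates with a 0.2 intra-DGN reduction
for detection power; these sizes give Monte-Carlo standard errors small
enough for the stated bounds while keeping a full run in the low minutes on
one CPU. The acceptance script uses 100 and 50 replicates for the same two
quantities plus one full-scale (47 + 50, T = 373) demonstration run.

## Known limitations

* The AAL→network table is a reconstruction; region-level conclusions
  depend on it.
* The integrity-level conversion exp(r − 1) is a documented stand-in for an
  unpublished formula; only monotone-transform-invariant conclusions (test
  decisions, directions) are insensitive to the exact choice.
* Permutation-p granularity bounds attainable FDR rejections (see above).
* NIfTI inputs must be voxel-aligned with the label volume; no resampling
  is performed.
* The synthetic generator's Gaussianity and shared-target assumptions make
  its power estimates optimistic relative to real cohorts.
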