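# Methods

## Model and procedure

The pipeline treats a developmental qPCR-array study as four chained
estimation problems.

**Relative quantification.** Abundance of microRNA *m* in sample *s* is
summarized as RQ = 2^−ΔCt with ΔCt = Ct(m, s) − Ct(control, s). The model
assumes ideal amplification efficiency (a factor of exactly 2 per cycle)
and a control small RNA (RNU48 by default) expressed uniformly across
samples; no efficiency correction or standard curve is applied. Because
ΔCt subtracts the control within each sample, any per-sample additive shift
of all Ct values (e.g. input-amount differences) cancels exactly — this
scale consistency is asserted as a property test. Wells at or above the
undetermined threshold (default 35 cycles, compared with ≥) and literal
`Undetermined` tokens are missing data, and missingness propagates through
every later stage; statistics are computed over the observed values only,
which the detection quorum guarantees number at least two per period.

**Detection quorum.** A microRNA is "positively expressed" only if it
amplified in at least (2 of 3, 4 of 5, 2 of 2) samples of the three
periods, all periods at once. The quorum is monotone: relaxing any
period's requirement can only grow the retained set.

**Trend classification.** Between each ordered pair of periods a
two-tailed t test compares the per-sample RQs. The pooled-variance
(classic Student) form is the default because that is the named test; a
Welch option exists (`equal_var=False`) as does a log2-RQ option (off by
default — the tests run on raw RQs). Degenerate inputs follow two
conventions chosen for the noise-free limit: both samples constant and
equal → t = 0, p = 1 (no evidence of change); both constant but different
→ p = 0 (change with zero within-group noise). Significance is strict
p < α (α = 0.05), per transition, with no multiple-testing correction at
this stage; correction belongs to the downstream screen, where the family
is explicit. A microRNA with significant transitions in both directions
does not fit a three-group scheme and is labelled AMBIGUOUS rather than
silently assigned.

**Anti-correlation screen.** Candidate (microRNA, gene) pairs come only
from the prediction databases — the screen never reports an unpredicted
pair. Profiles are the three period means (microRNA: mean RQ; gene: mean
hybridization intensity after probe averaging), with the two period
schemes paired positionally; mismatched wga windows (13–15 vs 15) are
logged, not corrected. For each pair, Pearson r; p for H₀: r = 0 from the
t transform on n − 2 degrees of freedom (|r| = 1 → p = 0 by the limit
convention); BH step-up adjustment over all candidate pairs of the scope.
The kept set satisfies r < 0 and R² ≥ 0.8, and — when the adjusted-p
toggle is on (the default) — p_adj < 0.05. Zero-variance profiles make r
undefined; such pairs are skipped and logged rather than scored 0, which
would dilute the FDR family.

With three-point profiles the p value has one degree of freedom, so
p_raw < 0.05 requires |r| ≳ 0.997: the adjusted-p cut then admits almost
nothing beyond near-perfect correlations. The R² ≥ 0.8 criterion is
therefore implemented as the primary, always-on filter and the adjusted-p
cut as a documented toggle; screens on per-sample rather than per-period
profiles (more degrees of freedom) are possible by passing sample-level
matrices as "profiles", since the screen only requires equal column
counts.

**BH families and the shared-count bound.** Each scope (miRBase alone,
TargetScan alone, intersection) is screened as an independent run with its
own BH family. A consequence worth knowing: the intersection family is
smaller, adjusts less, and can therefore pass a pair that a single-database
family rejects — so the tabulated bound
`count_shared ≤ min(count_targetscan, count_mirbase)`, which is a theorem
under the pure strength filters (the intersection's candidates are a
subset and the per-pair statistics are identical), can fail when the
adjusted-p toggle is on. The count builder checks the bound and warns by
default (raises on request); the reporting tests assert it on the packaged
published counts and on runs with the toggle off.

**Reporting conventions.** The count table's per-group `Total` row sums
the per-microRNA distinct-gene counts (the published-table convention,
which counts microRNA–gene matches); the distinct-gene census across
records — a different number whenever genes are shared between microRNAs —
is available separately (`distinct_gene_counts`). The heat-map helper
orders rows by average-linkage clustering on correlation distance; it
reproduces the *kind* of display used for such data, not any particular
legacy software's exact output, and is excluded from the acceptance
surface.

## Synthetic-study generator

The generator emulates the study design so every stage has ground truth:

* 212 microRNAs across 10 samples in periods of 3/5/2 (card scale ~350
  assays, reduced to the retained-signature scale so a full run takes
  about a second); group fractions (0.02, 0.17, 0.81) echo the observed
  4/35/173 census.
* Group I microRNAs lose `effect_size_log2` cycles per period step
  (abundance rises 2^effect-fold per step), Group II gain them, Group III
  stay at a per-microRNA baseline drawn from 23–29 cycles (control at 20).
  Gaussian noise (s.d. `ct_noise_sd`, default 0.3 cycles) is added per
  well on the Ct (log2-RQ) scale — chosen for analytic transparency; wells
  that land at/above 35 cycles become undetermined organically, and an
  explicit `dropout_rate` can force more.
* 500 genes × 2 probes over a 3/1/2-sample mRNA scheme. Genes of the 40
  planted suppression pairs get period means that are a decreasing affine
  function of their microRNA's noise-free RQ shape, so the per-period
  Pearson r → −1 as noise → 0 exactly. Unlinked genes carry no
  developmental trend: their period means follow a multiplicative random
  walk whose step size defaults to the intensity noise level
  (`background_walk_sd` decouples it), so background genes go flat — and
  their pairs are skipped as zero-variance — in the noise-free limit.
  Probe-level values add multiplicative Gaussian noise (fractional s.d.
  0.05 by default, a typical array CV).
* Both prediction files carry every planted pair (the intersection scope
  can recover all of them); 60 decoy pairs split round-robin among
  miRBase-only, TargetScan-only and both-files, written in the two
  historical dialects with per-pair site/transcript multiplicity, mixed
  symbol case, and a few non-human rows for the species filter.

What the generator does **not** emulate: batch and plate effects,
amplification-efficiency drift, probe cross-hybridization, correlated
noise between microRNAs, realistic 3'UTR sequence structure, and the fact
that the real microRNA and mRNA data come from different tissue sets and
platforms. Passing recovery tests therefore demonstrate that the chain is
implemented correctly and is sensitive at the stated noise levels — not
that the screen's biological discovery rate on real tissue matches.

All stage seeds derive deterministically from one study seed; identical
parameters give byte-identical output files (tested).

## Numerical choices

* RQ uses exact base-2 exponentiation; the control row's self-RQ is
  asserted to be exactly 1 before it is dropped.
* Ct table round trips are bit-exact: floats are written with `repr`.
* Pearson r is computed from centered dot products and clipped into
  [−1, 1] against round-off; p values use `scipy.stats.t.sf`; BH goes
  through `statsmodels.multipletests(method="fdr_bh")`. Each of these is
  verified in the tests against an independently coded oracle
  (50-digit covariance formula, incomplete-beta tail form, literal
  step-up loops) to 1e-10 relative tolerance on 1000 random instances.
* BH ties: the step-up monotonicity pass gives equal p values equal
  adjusted values regardless of sort order.
* Replicate control rows in a Ct file are averaged per sample (logged).
* Input orientation (microRNAs as rows vs columns) is detected from the
  index-header keyword, falling back to where the control id sits;
  ambiguous files are rejected, never guessed.

## Open design points, as resolved here

* **Interface.** The package is a library: the importable API plus the
  `examples/` scripts are the intended entry points, and `run_study`
  chains the stages for scripted runs. No shell CLI is shipped — every
  anticipated use is from Python.
* **miRBase transcript→symbol mapping.** Joining a 2010-era transcript
  dump to array gene symbols is annotation-era dependent; parsers accept a
  pluggable `symbol_map` (identity by default) and a `column_map` for
  dialect drift, keeping the core testable on synthetic data while
  making the real-data gap explicit.
* **Arm-naming drift** (miR-17-5p vs miR-17 across database eras) is not
  papered over: matching is exact after normalization. An arm-insensitive
  fallback was considered and rejected as a default because it silently
  merges distinct mature strands.
* **Table counting convention.** Per-microRNA counts are distinct genes;
  the totals row sums them (see Reporting conventions above).

## Limitations

* Three-point profiles give the correlation test one degree of freedom;
  the adjusted-p filter is near-vacuous there by construction, and all
  calibration claims rest on the R² criterion.
* The t tests run on raw RQs, whose noise is multiplicative; the log2
  option exists but is off by default to match the stated procedure.
* Probe averaging assumes an unambiguous probe→gene map; probes mapping
  to two genes are an error, not resolved.
* The quorum is applied to the parsed table as-is; no plate-level QC
  precedes it.
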