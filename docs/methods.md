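# Methods

## Normalization chain

Counts from the 72-gene panel are taken as given (no read mapping). A sample
is analyzed when fewer than 30 % of panel genes have a zero count and the
total read count is strictly greater than 10,000; both thresholds are applied
as strict inequalities exactly as phrased and are parameters of
`qc_filter_samples`. "Missing gene" is read as "zero count": targeted panels
report zeros, not NAs. Retained counts are converted to counts per million
within the panel (so per-sample CPM sums to 10⁶ exactly), transformed as
log2(CPM + 1) — the +1 pseudocount avoids −∞ at zero and is the only
departure from a bare log2 — then gene-median centered and per-gene
standardized (SD 1, ddof = 1). Genes with zero variance are flagged and left
unstandardized instead of dividing by zero. An optional transcript-length
correction (counts / kb before CPM) is available but off by default, since no
length table ships with the panel.

## Intrinsic subtyping and ROR-P

No published centroid values ship with the package; `train_centroids` fits
per-subtype centroids as gene-wise means of the centered, standardized
expression of labeled samples (≥ 2 per represented subtype). A sample is
assigned to the subtype whose centroid it correlates with most strongly.
Spearman correlation is the default — it is invariant under the monotone
distortions of panel sequencing, and a property test asserts that invariance —
with Pearson available. Ties break in the fixed order LumA > LumB > HER2E >
Basal and are flagged.

ROR-P is `Σₖ wₖ ρₖ + w_P · P` with weights (−0.34, 0.23, 0.12, 0.05) for
(LumA, LumB, HER2E, Basal) and w_P = 0.32, where P is the mean centered
expression of an 11-gene proliferation subset. The raw score is mapped to
0–100 by the affine convention `50 + 55·raw` with clipping, and classed at
29/53 (the node-negative boundaries of the published correlation-weighted ROR
family). The weights and boundaries follow that published family; the 0–100
rescaling is this package's own convention for its correlation scale, and all
constants are overridable YAML config. A self-trained mode
(`fit_ror_coefficients`) refits the weights by Cox regression of survival on
the four correlations plus P, with a small ridge penalty because the four
correlations are strongly mutually collinear; the fitted coefficients are
usable as `ror_coefficients` but are not individually identifiable.

## 21-gene recurrence score

Expression enters on a housekeeping-referenced scale: log2 value minus the
mean of the five housekeeping genes, plus an offset of 10 so that the
published group floors and affine map operate in their intended range. Group
scores are weighted means — HER2 (0.9·GRB7 + 0.1·ERBB2, floored at 8), ER
((0.8·ESR1 + 1.2·PGR + BCL2 + SCUBE2)/4), proliferation (mean of AURKA,
BIRC5, CCNB1, MKI67, MYBL2, floored at 6.5), invasion (mean of CTSV, MMP11) —
plus CD68, GSTM1 and BAG1 singletons. The unscaled score is the published
linear combination (coefficients 0.47, −0.34, 1.04, 0.10, 0.05, −0.08,
−0.07); the reported RS is `clip(20·(RSu − 6.7), 0, 100)`, classed at 18/31.
This is a faithful implementation of the published group structure on an
RNA-seq scale, not a vendor-exact replication of the commercial assay.

## Immune score and cutoffs

The immune score is the mean housekeeping-referenced log2 expression of the
17 immune genes, min–max rescaled to 0–100 across the cohort (hence
cohort-relative; a degenerate cohort is an error). "istrong" is score ≥
cutoff — the boundary is inclusive by specification. The default cutoff is
the 45.5 preset; `youden_cutpoint` can re-derive a cohort-specific cutoff as
the midpoint threshold maximizing sensitivity + specificity − 1 against a
survival-event indicator. Which endpoint feeds the ROC is not fixed by the
source analyses; the package defaults to the distant-metastasis event and
both endpoints are supported. Whether the published immune score is a
rescaled mean or a weighted signature is likewise unstated; the min–max
scaled mean is a declared convention and every test is agnostic to the gene
list. TILs dichotomize at 13.5 % with a strict boundary (13.5 % exactly is
"low"): unlike the immune cutoff, no inclusive reading is documented for
TILs, and no integer TILs reading can sit on the half-percent boundary.

## IHC surrogate rules

Positivity for ER/PR and basal markers is strictly > 1 % stained cells. The
St. Gallen split assigns LumB iff PR < 20 % or Ki-67 > 30 % (Ki-67 = 30 is
"low"), else LumA, and applies only to ER-positive records. The modified
surrogate tests the basal rule first — any of CK5/6, EGFR, CK14 positive AND
Ki-67 ≥ 40 % AND ER ≤ 10 % (both boundaries inclusive) — and falls through to
the St. Gallen split otherwise; basal precedence is required for the rule to
recover every molecularly basal case on the packaged reference cases. Records
with PR in (1, 20) % are LumB: the explicit PR < 20 % branch is the operative
boundary, not the bare positivity rule. No IHC rule assigns HER2-enriched;
that subtype is reachable only through expression-based classification. An
ER ≤ 1 % record can still fire the basal rule (which itself demands ER ≤
10 %); its St. Gallen field is empty because the luminal split is undefined
there.

### The packaged reference cases

The 12 basal-marker-positive cases ship as package data with per-marker
CK5/6 / EGFR / CK14 flags, Ki-67/PR/ER, grade, P53, immune group, TILs level,
ROR class and recurrence status. Three rows (cases 4, 8, 9) had run-together
digit fields in the source table; the adopted parses — Ki-67/PR/ER/grade =
(60, 5, 0, 2), (6, 60, 80, 2), (10, 0, 95, 1) — are fixed by the column order
and flagged via `ambiguous_digits`; every alternative parse leaves all
downstream counts unchanged. One printed label is internally inconsistent
with the rule set: case 7 (PR 90, Ki-67 30) is printed as IHC luminal B but
the quoted St. Gallen thresholds give luminal A at Ki-67 = 30. The fixture
preserves the printed label in `ihc_subtype`; the rule implementation follows
the thresholds.

## Synthetic cohort generator

The generator's defaults emulate the 87-patient reference cohort: subtype
proportions 0.71/0.20/0.02/0.07 (LumA/LumB/HER2E/Basal), endocrine therapy
for all, chemo/radiotherapy ~30 %, ages ~N(48.5, 10) within 30–78, sizes
mostly 0.5–2 cm. Per-gene baseline log2 means are drawn once per cohort
(U(3, 9); housekeeping 9–10.5 and tight); subtype identity adds block shifts
of ±(0.3–1.5)×`expression_separation` (default 2 log2 units) on luminal,
proliferation, HER2 and basal signature blocks. Counts are negative binomial
(overdispersion 0.15) around the exponentiated means scaled to a uniform
library size in [5×10⁴, 5×10⁵].

IHC channels are noisy logistic transforms of the corresponding latent gene
means (ER ← ESR1, PR ← PGR, Ki-67 ← MKI67), so IHC and molecular calls are
correlated but imperfect; basal latents are additionally pinned to the tail
behavior the rule set assumes (ER ≤ 10, Ki-67 ≥ 40, at least one basal marker
positive), since the surrogate concordance analysis is meaningless if basal
tumors never satisfy their own rule. A latent immune level is shared between
the 17 immune-gene means (amplitude 1.5 log2 units) and the TILs percentage
at a configurable coupling (default 0.9), giving mostly-low TILs as in the
reference cohort.

Survival is exponential proportional hazards: baseline monthly rates 0.0059
(DFS) and 0.0031 (DMFS) chosen to give roughly 30 % relapse / 17 % metastasis
at five years in an all-baseline cohort, multiplied by exp of a linear
predictor over subtype indicators, the immune latent and size > 1 cm (default
log-HRs: log 3 basal, log 1.5 LumB, log 2 HER2E, 0.3 per immune SD, log 1.5
size). DFS and DMFS are drawn independently given the covariates. Censoring
is independent uniform on (0, u), with u solved so the expected censored
fraction at the baseline hazard equals `censoring_rate` (exact under null
hazards); `censoring_rate = 0` means no censoring, which keeps the
closed-form exponential comparison in the tests exact.

What the generator does **not** emulate: real panel noise structure (GC /
length biases, batch effects), correlated DFS/DMFS event processes,
non-proportional hazards, missing data, and inter-observer IHC variability.
Passing tests therefore demonstrate that the estimators recover the
structure they assume, not that the assay generalizes to real cohorts.

## Panel composition

The 50-gene tumor list is 45 canonical intrinsic-subtype predictor genes plus
the five additional genes the 21-gene score requires (AURKA, CTSV, GSTM1,
CD68, SCUBE2), replacing ACTR3B, BLVRA, CXXC5, GPR160 and TMEM45B, so both
scores are computable from one 72-gene panel; since centroids are always
trained rather than shipped, subtype assignment adapts to whatever tumor list
is configured. The 17 immune genes are a conventional
T-cell/cytotoxicity/checkpoint panel standing in for an assay-specific list;
all scoring machinery and tests are independent of the identities. The five
housekeeping genes are the standard reference set (ACTB, GAPDH, GUSB, RPLP0,
TFRC).

## Statistics conventions

Cohen's κ is unweighted (weighted κ for the ordered risk classes is a
reasonable alternative but is not the default). The log-rank test uses the
standard aggregated-risk-set variance with ties pooled. Cox fits use the
partial likelihood via lifelines; degenerate strata (zero events on one arm —
monotone likelihood) are reported per factor with a note rather than raised,
and a joint model with more covariates than events is flagged unstable. FDR
is Benjamini–Hochberg within each declared family. The declarative factor
menu (`FACTOR_MENU`) encodes the standard clinicopathological factors —
age > 50, size > 1 cm, grade III, Ki-67 > 30 %, basal marker, surrogate and
molecular subtype (reference: basal-like), ROR and RS class (reference:
high), immune group, TILs level, P53, chemo- and radiotherapy — with
explicit reference levels.

## Problem sizes used in tests and the acceptance script

Parameter-recovery experiments run on one shared 600-sample cohort (400
train / 200 held out); convergence of subtype frequencies is checked at
n = 10,000; Cox CI coverage uses 100 seeds × 200 patients and log-HR bias 20
replicates × 2,000 patients; the log-rank null uniformity check uses 500
direct exponential simulations of 60 subjects. These sizes give the
assertions comfortable statistical margins (e.g. 3 SE bands, ±0.05 on a mean
log-HR whose replicate SE is ≈ 0.01) while keeping the default run fast.

## Known limitations

- Scores are cohort-relative where the source conventions are (immune
  min–max, trained centroids, gene-median centering): single-sample scoring
  requires a frozen reference cohort/model.
- ROR-P/RS constants are published-family conventions on this package's
  expression scale, not vendor calibrations; absolute score values should not
  be compared against commercial reports.
- The reference-cohort statistics that depend on unreleased per-patient
  expression (the published κ and concordance values, the Cox tables) are
  reproduced structurally — same estimators, factor menu and table layouts —
  not numerically.
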