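# Methods

`astromap` re-implements, as one tested pipeline package, three
quantification procedures used to characterize astrocyte heterogeneity
in adult mouse cortex (CX) and hippocampus (HP): single-cell RNA-seq
clustering with explicit thresholds, rule-based subtype mapping from
multiplexed ISH puncta counts, and Ca²⁺ transient detection and
clustering. Because the original raw sequencing data cannot be
reproduced at desk scale, every procedure is exercised on a synthetic
generator that plants the known structure; the tests and the acceptance
script score round-trip recovery of that structure.

## Single-cell pipeline (`astromap.sc`)

**QC.** Libraries with total transcript count below 54 are discarded
(the floor keeps cells with total ≥ 54). **Normalization.** Expression
is ln-normalized: `value = ln(1 + s · count / total)` with scale factor
`s = 10⁴`. The transform is zero-preserving, monotone in the count at
fixed total, and invariant to scaling a cell's library by any positive
constant.

**HVG selection.** Per gene, the ln-mean and the dispersion
(variance/mean of the ln values) are computed; a gene is selected when
both strictly exceed their thresholds. Two passes are used: (0.3, 0.1)
on all cells for higher-order typing, and (0.5, 0.5) on astrocytes for
subtype discovery. Exactly-constant genes have dispersion forced to 0.

**Clustering.** The HVG submatrix is z-scaled per gene, reduced to 20
principal components, and clustered by Euclidean Ward agglomeration;
the cluster count k is the argmax of the mean silhouette width over
k ∈ [2, 10], ties toward smaller k. Early-era single-cell toolkits
left the clustering algorithm to version-specific defaults that are
not reconstructible today; the z-scale → PCA → Ward → silhouette
pipeline was chosen instead for determinism and consistency with the
physiology clustering, and correctness is defined as recovery of
planted structure, not as matching a legacy implementation. When even the best silhouette is below 0.15 the result
is flagged "no substructure" (the floor is arbitrary but configurable).

**Higher-order typing.** Each cluster is assigned the cell type whose
marker panel (astrocyte: Slc1a3/Aqp4/Apoe; neuron, oligodendrocyte,
microglia, endothelial, OPC panels analogous) has the highest mean
ln-expression over the cluster's cells; ties go to the
lexicographically smallest type with a warning. Astrocyte-typed
clusters are extracted and re-clustered.

**Marker genes.** For a cluster versus all other cells, each gene gets
a two-sided rank-sum test (normal approximation with average-rank tie
correction; an exact small-sample path exists for validation), a fold
change defined as the linear ratio of de-logged (expm1) means with
ε = 10⁻⁹ regularization, and the fraction of cluster cells with a
nonzero count. A marker passes when p < 0.01, fold ≥ 1.28 and
fraction > 0.25. The 1.28-fold criterion is applied on the linear
scale (equivalently an ln-mean difference ≥ ln 1.28 ≈ 0.247).

## ISH quantification (`astromap.ish`)

Cells are modelled as disks centred on DAPI nuclei with area 1.3× the
nuclear area (radius `√(1.3·A/π)`); the original cell outlines are
polygons of unspecified shape with that average relative size, so the
disk is the minimal faithful model. Puncta with intensity above the
background threshold (default 100 a.u.) are counted per channel inside
the disk; a punctum covered by several overlapping disks goes to the
nearest centroid, exact ties to the lowest cell index. Counts become
per-gene calls — "+" at ≥ 5 puncta, "−" at ≤ 2, indeterminate between —
and the ordered rule table assigns subtypes:

| order | subtype | rule |
|---|---|---|
| 1 | AST4 | Frzb⁺ ∧ Ascl1⁺ ∧ Slc1a3⁺ |
| 2 | AST5 | Ogt⁻ ∧ Fam107a⁺ ∧ Slc1a3⁺ |
| 3 | AST1 | Gfap⁺ ∧ Agt⁺ ∧ Slc1a3⁺ |
| 4 | AST2 | Agt⁻ ∧ Unc13c⁺ ∧ Slc1a3⁺ |
| 5 | AST3 | Agt⁺ ∧ Slc1a3⁺ ∧ (Gfap⁻ in panel A ∨ Unc13c⁻ in panel B) |

Specific progenitor rules precede the broad mature rules; the first
satisfied rule wins; astrocytes (Slc1a3⁺) matching no rule stay
unclassified. The numeric +/− cutoffs (5/2) are a design choice — the
original calls were qualitative — and the threshold sweep quantifies
how sensitive the mapping is to exactly this kind of choice. AST3 uses
a split-panel clause because only three fluorescence channels were
available per staining (panel A: Gfap/Agt/Slc1a3; panel B:
Unc13c/Agt/Slc1a3); a requirement on a gene absent from the panel
fails its rule, except inside the split clause where unmeasured
alternatives are skipped.

Regional distributions report, per region × subtype, the mean count per
section, the SEM across sections (0 and flagged with one section), and
the fraction normalized to all Slc1a3⁺ cells of the region; cells
outside every region polygon are excluded. Coordinates are µm, origin
top-left, y down; region polygons are simple, mutually non-overlapping,
CCW-closed.

## Ca²⁺ transient analysis (`astromap.calcium`)

For each 300-s recording (BASE → TTX → PHE at 2 Hz by default; any
positive rate accepted), F₀ is the mean fluorescence of the first
100 s and the trace becomes dF/F₀. Peaks are detected with four
thresholds: dF/F₀ > 1.15 at the maximum, prominence ≥ 0.1 (standard
topographic definition), width ≥ 2 s measured at half prominence with
linear interpolation, and ≥ 1 s separation, resolved greedily in favor
of the taller peak. The width floor is enforced on the
width-at-half-prominence because that is the width the analysis
reports; boundary samples are excluded (prominence undefined there).

Per cell × condition: mean amplitude, prominence, width and peak time
over the detected peaks, frequency = peaks/duration, and AUC = the
trapezoidal integral of raw dF/F₀ over the whole condition window,
negative excursions included. Cells without a PHE transient are
dropped entirely; within BASE/TTX analyses only cells active in that
condition contribute, and the fraction of PHE-responders active in
BASE/TTX is reported. Physiology clustering z-scales the six PHE
parameters (mean peak time is kept as a feature by default, with an
exclusion flag) and runs Ward + silhouette with k ∈ [2, 8]. Group
comparisons use raw, unscaled parameters: Shapiro–Wilk per group is
recorded but never branched on (the analysis always proceeds
nonparametrically), then Kruskal–Wallis with tie correction and Dunn's
two-sided post hoc with Benjamini–Hochberg adjustment across the
pairwise family of each parameter.

## Shared statistics (`astromap.stats`)

Average-rank ties everywhere. Kruskal–Wallis and Shapiro–Wilk wrap
scipy; BH wraps statsmodels; Ward and silhouette wrap scikit-learn.
Dunn's test is implemented directly (pooled-rank mean z with the
`Σ(t³−t)/(12(N−1))` tie term) since no post-hoc package is available.
The vectorized rank-sum used for marker calling is implemented directly
and validated in the tests against scipy's exact Mann–Whitney null and
a brute-force permutation enumeration.

## Synthetic generator (`astromap.simulate`)

The generator defines the study conditions; its defaults are fixed, not
fitting knobs.

**Expression.** Counts are negative-binomial per gene with the mean set
by the cell type's fingerprint state: "high" (mean 40, shape 8), "low"
(mean 0.05), or "housekeeping" (mean 10, shape 10, all cell types).
Five subtypes at frequencies 0.365 / 0.25 / 0.30 / 0.071 / 0.014
(AST1…AST5; the AST1 and AST5 extremes are the reported values, the
middle three are placeholder fill pending the supplementary table).
The default astrocyte run has 1811 cells; the mixture run has 2031
libraries = 1811 astrocytes + 204 contaminants (neuron 80,
oligodendrocyte 50, microglia 34, endothelial 25, OPC 15, planted as
exact counts) + 16 planted low-quality libraries whose per-gene means
are scaled by 10⁻³ (total ≈ 25 ≪ 54, so the QC floor removes exactly
those 16 with overwhelming probability at any seed). Subtype labels
are multinomial draws; higher-order composition is exact.

The planted-HVG guarantee is by construction: a known set of exactly
886 genes is "high" in a subtype subset whose frequency mass lies in
[0.22, 0.78], which places both the ln-mean and the dispersion above
the (0.5, 0.5) thresholds with ≥ 20% margin (a bimodal gene with high
fraction f has ln-mean ≈ f·m and dispersion ≈ m·(1−f) for plateau
value m ≈ 2.9 at the default depth); housekeeping and pan-astrocyte
genes are high everywhere (dispersion ≈ 0.08), low genes sit far below
the mean threshold, so no other gene can cross both thresholds.
Marker genes whose fingerprint pattern falls inside the band (Gfap,
Agt, Unc13c by default) count toward the 886. Frzb/Ascl1 (mass 0.071)
and Ogt/Fam107a (0.986/0.014) legitimately fail the screen while still
carrying clean classification signal — mirroring the fact that a
highly specific marker need not be a selected HVG.

**ISH sections.** Three sections; stacked cortical layers (L1–L6) above
hippocampal strata (SO/SP/SR/SLM/SG/DG) as rectangles, nuclei at
300/mm² with truncated-normal areas (35 ± 6 µm²), per-region subtype
profiles (e.g. AST4 concentrated in SG, AST1 in L1/SLM, AST3 dominant
in L6) plus 20% Slc1a3-negative nuclei. "+" channels draw
Poisson(15) puncta and "−" channels Poisson(0.3), scattered inside
0.9× the cell disk radius; background puncta are uniform at
5·10⁻⁵/µm². Signal intensities (200 ± 25 a.u.) and background
intensities (60 ± 15 a.u.) are separated so a default threshold of 100
sits in the gap and the robustness sweep is meaningful.

**Traces.** 614 cells over L1 / L3–5 / CA1, 300 s per condition at
2 Hz, F₀ = 100 a.u., relative noise SD 0.02. Events have an
instantaneous rise snapped to the sample grid (so the planted amplitude
is the sampled maximum) and single-exponential decay. Event onsets are
confined to (105 s, 275 s) — the 100-s baseline stays event-free — and
are modelled as an onset latency (≈N(10 s, 5 s)) followed by a train
spaced ≥ 3τ apart: a shared agonist-response latency is the
physiological expectation for a bath-applied α1-agonist, and it keeps
the mean-peak-time feature's variance comparable across regimes (with
uniformly scattered events, sparse cells acquire a huge peak-time
variance that fractures planted regimes under Ward clustering). Three
PHE regimes are planted — amplitude 1.5/3.0/5.0 dF/F₀, decay τ
4/6/9 s, 2/4/6 events — mixed over regions so that cortex is dominated
by the mid regime and CA1 by the low regime. A non-responder fraction
of 0.2 receives zero PHE events; responders receive at least one.
BASE/TTX events are plain Poisson (means 1.2 / 0.7), so a realistic
fraction of cells is silent in those conditions.

**What the generator does not emulate:** sequencing depth gradients,
batch effects, ambient RNA and doublets; irregular cell shapes,
atlas-registered region geometry, optical crowding of puncta; Ca²⁺
event kinetics beyond single-exponential decay, bleaching, movement
artifacts. Passing tests therefore demonstrate that the quantification
rules are implemented correctly and recover planted structure under the
stated noise model — not that the pipelines are robust to every
artifact of real data.

## Numerical choices and degenerate inputs

Determinism throughout: generators spawn child RNG streams from a
single seed and are bit-reproducible; clustering has no stochastic
step beyond a fixed-state PCA solver. Silhouette ties break toward
smaller k; infeasible k (n ≤ k) are skipped. Zero-total cells make
normalization fail with an instruction to run QC first. Constant
vectors: Shapiro–Wilk reports W = NaN, p = 0 with a warning; constant
parameter columns are dropped before physiology clustering with a
warning. Degenerate identical groups give H = 0, p = 1. Empty peak
lists mark a cell inactive with frequency 0 and undefined means.

## Problem sizes

The default runs — 2031 × 2026 count matrix, three ISH sections with
~1250 nuclei and ~52k puncta, 614 × 3 recordings of 600 samples — were
chosen as the package's desk-scale standard: large enough that binomial
bounds and clustering recovery are meaningful, small enough that the
full test suite runs in well under a minute of compute per module.

## Known limitations

The legacy clustering defaults, the differential-expression test
variant, the exact +/− puncta cutoffs and the fluorescence background
threshold used in the original workflow are version- or
operator-specific and not reconstructible; each replacement is
documented above and the acceptance layer is defined on synthetic
recovery. The middle subtype frequencies are placeholders. Dunn's
z-based p-values use the normal approximation and, like the rank-sum
marker test, are approximate at very small group sizes.
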