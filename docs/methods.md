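# Methods

This note documents the models, parameter choices and known limitations
behind `dualsip`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Isotope arithmetic

Deltas are defined as δ = (R_sample/R_standard − 1)·1000 ‰ against VPDB for
carbon and VSMOW for hydrogen. Internally all mixing and rate computations
use atom fractions F = R/(1+R), because F is linear under elemental mass
balance while δ is only approximately so; deltas exist at the I/O boundary
only.

Reference constants (overridable on `IsotopeConstants`): R_VPDB = 0.0111802,
R_VSMOW = 1.5576·10⁻⁴; exact masses ¹²C = 12 (exact), ¹³C = 13.00335484,
¹H = 1.00782503, ²H = 2.01410178 Da (IUPAC/CIAAW). The derived substitution
mass shifts are 1.0033548 Da (¹²C→¹³C) and 1.0062768 Da (¹H→²H); displays
commonly round these to 1.0034 and 1.0063. Isotopologue matching uses the
full-precision values, since sub-ppm windows cannot be evaluated against
4-decimal constants.

**Methylation correction.** PLFAs are measured as methyl esters (FAMEs); the
derivatization adds one carbon and three hydrogens from the methanol used.
The correction is the exact mass balance
δ_FA = [(n+a)·δ_FAME − a·δ_agent]/n with a = 1 for C and a = 3 for H. The
derivatizing agent's delta is a required input with no default. All lipid
hydrogen is treated as non-exchangeable; no correction for exchangeable H is
attempted.

## DNA-SIP

Fraction read counts are pooled per gradient side (heavy/light) before
forming the 2×2 table — counts, not per-fraction ratios, respect sequencing
depth. The heavy/light cut is configurable: `density_threshold(t)` (default
t = 1.715 g/mL) or `top_k(k)`; the rule used is recorded in every output
header, because no universal cut exists and results are sensitive to it.

Zero cells receive the Haldane–Anscombe pseudocount of 0.5 added to all four
cells, applied **only** when some cell is zero, so complete tables keep exact
arithmetic. The ≥ 5-read filter is applied in its strictest form: the taxon
needs at least five reads in the heavy and the light pool of both the
labeled and the control bottle. Consensus requires a call in both duplicates
(single-label designs) or two of three replicates (dual-label designs).

**False-positive behaviour.** The RoOR > 1 rule carries no effect-size
margin: for an unlabeled taxon that is abundant enough to pass the read
filter and whose DNA bands near the density cut, each replicate has ~50%
probability of RoOR > 1 by sampling noise, and duplicate consensus is
falsely reached in roughly 30% of such cases. The read filter — which
removes rare taxa and taxa banding far from the cut — is the only
false-positive control. Community-wide false-positive rates therefore depend
on community evenness: under the package's canonical null community (below)
the rate is ≤ 5%, but for small, even communities it can be several-fold
higher. Interpret single-taxon calls near RoOR ≈ 1 with caution.

## Synthetic gradients

Buoyant density of unlabeled DNA follows ρ = 1.66 + 0.098·GC g/mL; full ¹³C
labeling shifts a genome by 0.036 g/mL, scaled linearly by the labeled atom
fraction. Bands spread as Gaussians with σ_ρ = 0.006 g/mL over a default
grid of 12 fractions spanning 1.685–1.755 g/mL. Reads are multinomial at the
configured depth (no overdispersion option is implemented).

A labeled taxon's DNA is modeled as a **two-component mixture**: a fraction
`turnover` (default 0.5) of its DNA pool was newly synthesized during the
incubation and bands at the shifted density, the remainder at the unshifted
density. This reflects that density labeling requires replication; a
single fully-shifted band would leave a labeled taxon with no light-side
reads at all, which real gradients do not show and which would make the
four-pool read filter unsatisfiable. `turnover = 1` recovers the single-band
model. Deuterated substrates are not given a separate density effect: DNA
density shifts from ¹³C and D are not distinguishable in this assay, so the
generator exposes a single composite `label_atom_fraction` per taxon.

The canonical null community (`null_community_spec`) has 100 genera with
symmetric-Dirichlet(0.15) relative abundances and GC ~ Normal(0.50, 0.06)
clipped to [0.30, 0.70] — the strongly uneven, mid-GC structure typical of
groundwater genus-level amplicon tables. `spiked_community_spec` adds one
labeled taxon (default 5% abundance, GC 0.50, full labeling) on top.

## PLFA rates and Ra/Rt

Nomenclature: `[pos]Me | cy | i | a` prefixes, `chain:double-bonds`, optional
`w`/`ω` position, optional cis/trans letter. The carbon count used for
pmol-lipid → pmol-C conversion includes branch methyls (`10Me16:0` has 17 C;
the name encodes chain length, not formula). Hydrogen inventories follow
CₙH₂ₙ₋₂ᵤO₂ with one degree of unsaturation per double bond or cyclopropane
ring.

The incorporation rate is ΔF · C_produced / t with
C_produced = (conc_Tend − conc_T0) · n_C. Two ambiguities are parameterized
rather than resolved silently:

* **D atom inventory** — the published rate form multiplies ΔF by carbon
  produced for both isotopes. Default mode is that literal form
  (`d_inventory="carbon"`); `"hydrogen"` scales by the lipid's hydrogen
  inventory instead. The mode is echoed in output provenance.
* **Source-pool normalization** — Ra (¹³C) and Rt (D) rates are divided by
  the excess label atom fraction of their source pools before the ratio, so
  unequal label strengths do not bias Ra/Rt. Defaults: f¹³C(DIC) = 0.9
  (concentrated labeled bicarbonate diluted by ambient DIC),
  fD(substrate) = 0.6 (six of veratric acid's ten hydrogens sit in the two
  CD₃ methoxy groups). Pass 1.0 for both to reproduce unnormalized ratios.

Thresholds: heterotrophic at Ra/Rt ≤ 0.3 (published bound); autotrophic at
≥ 0.8 (chosen as "approximately 1" minus a noise margin); mixed in between.
Negative rates (lipid loss or apparent label loss) are clamped to 0 with an
explicit flag by default; raw mode preserves the sign. With clamping, a pure
heterotroph's ¹³C rate is frequently exactly 0 under measurement noise, so
its median Ra/Rt is 0.

The acetogen expectation 1 − fraction_C1 comes from the two-carbon
acetyl-CoA model: one acetyl carbon from the (heterotrophic) methyl branch,
one from CO₂; balanced Wood–Ljungdahl operation with methyl transfer gives
Ra/Rt = 0.5.

**Synthetic PLFA model.** Producers are configured with a lipid profile, a
growth rate (pmol C/L/day) and a `dic_fraction` (share of new carbon fixed
from DIC). New lipid carbon carries `dic_fraction · f¹³C(DIC)` excess ¹³C;
new lipid hydrogen carries the full substrate-pool excess D regardless of
trophic mode — the model's expression of "D enrichment tracks total lipid
production". End-point deltas follow exact old/new pool mass balance, so the
rate formula applied to noise-free tables recovers the truth-record rates to
machine precision, and Ra/Rt after pool normalization equals `dic_fraction`
exactly. Real incubations dilute substrate hydrogen with water-derived
hydrogen during lipid synthesis, which would lower absolute δD and rescale
Rt; the generator omits this (no water-H mixing model), so its δD values are
higher than field data while leaving the Ra/Rt logic unchanged. Measurement
noise is Gaussian on deltas (default 2 ‰ where noise is requested).

## Isotopologue matching

Candidate isotopologues form the grid base + k¹³C·1.0033548 + kD·1.0062768 Da
with 1 ≤ k¹³C + kD ≤ max_k (default 12: the 9-carbon substrate plus CD₃
transfers in multiples of three comfortably fit). A peak within the ppm
tolerance (default 2 ppm) of exactly one grid point is assigned; within
tolerance of two or more, it is flagged ambiguous and excluded from label
counts — this prevents resolution-limited false CD₃ calls. Competing peaks
for one grid point resolve to the lower ppm error, ties to the lower m/z,
making matching deterministic and permutation-invariant. Separating the two
single-substitution shifts requires resolving power m/0.0029220 (≈ 62,300 at
m/z 182).

Label flags require a matched member at ≥ 1% of the base-peak intensity
(default; unstated upstream, recorded in provenance). The CD₃ call fires when
the maximum deuterium count is a positive multiple of three. Feature
finding, adduct handling and formula annotation are upstream concerns; the
module consumes centroided per-feature peak lists (CSV).

## Pipeline sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded per run;
generators are pure functions of (spec, seed) and reruns are byte-identical.
Benchmark problem sizes — 100-seed PLFA ensembles, 50-seed spiked-gradient
ensembles, 200-run null false-positive ensembles, 1000-table odds-ratio
cross-checks — were chosen to put Monte-Carlo error well below the decision
margins involved while keeping any single check in the seconds range.

## Known limitations

* No qSIP-style quantitative atom-fraction estimation from density shifts;
  labeling calls are binary per taxon.
* Multinomial read sampling only; no overdispersion, chimeras, or
  compositional artifacts of amplicon sequencing.
* The scenario presets' communities and producer profiles are invented
  fixtures (taxon names chosen for familiarity); they demonstrate the
  pipeline, not any field result.
* No water-hydrogen exchange model for lipid D (see above), and no
  instrument drift or calibration modeling anywhere.
* The metabolite stage tracks substrate consumption only through
  user-supplied peak areas for the two configured acids.
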