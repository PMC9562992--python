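# Methods

## The measurement model

Each variant construct's activity is the 4MU release rate (nM/hour/mg
protein) of transfected HEK293 lysate, normalized to the wild-type construct
assayed in the same run.  `percent_of_wildtype` subtracts the
mock-transfection background from both numerator and denominator and clips
sub-background signal to zero — the source protocol names the mock negative
control without stating whether it is subtracted, and subtraction with
clipping is standard enzymology practice that reduces to the plain ratio
when the mock reads zero.  Inputs supplied directly as percent of wild type
bypass this step, so both conventions are supported.

Replicates (two independent plates in the source assay; any n ≥ 1 is
accepted) are combined by arithmetic mean.  Two values exist for every
measurement: the unrounded mean, used for **every** threshold comparison,
and a one-decimal display value rounded half away from zero.  Rounding
operates on the shortest round-tripping decimal (`repr`) rather than the
binary float, so a mean whose decimal form ends in 5 (e.g. 17.45, 11.65)
rounds up the way a bench scientist reports it.  Keeping comparison and
display separate guarantees a formatting convention can never change a
classification.

"Not detectable" is a flag, not a number: the measurement compares as 0%
(hence always pathogenic-range under any calibration with a positive
boundary) and prints without inventing a value.

## Calibration

`calibrate` takes a control panel and returns the two zone boundaries:

- `pathogenic_max` = max activity over pathogenic / likely-pathogenic
  controls (below-detection → 0);
- `benign_min` = min activity over benign / likely-benign controls.

The pathogenic zone is **strictly below** `pathogenic_max`: the boundary
control itself does not classify as pathogenic-range, which is the semantics
the packaged panel implies (a 10.7% variant receives PS3, an 11.7% one does
not, while the 11% control defined the bound).  The benign zone is
`benign_min` and above, inclusive, so every benign control self-classifies.
A benign control at or below a pathogenic one means the assay does not
separate the classes; calibration raises rather than emit boundaries.

Pseudodeficiency controls — alleles with low in vitro activity and no
disease — never move a boundary.  Each must fall strictly inside the
indeterminate gap; one outside it attaches a validation warning to the
result (not an error: the boundaries remain well-defined, but the panel
deserves review).

`determine_strength` sets the strength at which PS3/BS3 may be applied.
Policy `svi` operationalizes the ClinGen SVI count rule as "total ≥ 11 with
both classes represented → moderate, else supporting"; the SVI's "balanced
mix" is not quantitative, so stricter ratios are deliberately not imposed.
The default policy is `conservative` — always supporting — because a wide
indeterminate gap with no pathogenic control inside it (11%–54% here) argues
against claiming moderate strength even at 11 controls; this mirrors the
judgment exercised in the source study.

## Evidence assignment

All threshold comparisons are strict as printed in the VCEP specification:
PM2 below 0.001 (quantified over *all* reported populations; an empty
frequency map means "absent from gnomAD" and qualifies), BS1 above 0.005 in
*any* population, PP3 above 0.7, BP4 below 0.5.  A REVEL score exactly at a
threshold, or between the two, yields no code; so does a frequency between
the PM2 and BS1 thresholds.  PM5 validates that the cited same-codon variant
is itself missense when its protein name is supplied (a nonsense or
frameshift change at the codon can never support PM5).  PP4 is decomposed
into two auditable booleans — phenotype consistency and pseudodeficiency
exclusion — because the criterion couples enzyme deficiency in blood with
the exclusion of pseudodeficiency alleles that depress measured activity
without causing disease; the pipeline does not adjudicate clinical records
itself.  PM3 is fixed at moderate; points-based PM3 scaling across multiple
probands is out of scope.

The western-blot band pattern (precursor 110 kDa / mature 76 kDa) is carried
as an annotation for the curator and never consulted by any assigner; a test
toggles it exhaustively to prove it.

## Evidence combination

The 2015 ACMG/AMP combining table is frozen as an explicit rule list over
counts by category and applied strength, so VCEP strength modifications take
effect naturally: PS3 applied at supporting increments the supporting count,
PP4 at moderate the moderate count.  Any code may carry any applied
strength, anticipating future VCEP revisions.  Two strengths have no slot in
the 2015 table and are folded to the nearest defined one: a pathogenic
stand-alone counts as very strong, and a benign moderate counts as a benign
supporting item (conservative in both directions this pipeline can reach;
neither arises from the default configuration).

Conflict semantics: when at least one pathogenic-category and one
benign-category item are present and either side alone satisfies a non-VUS
rule, the result is VUS with rationale `evidence_in_conflict`; if neither
side satisfies any rule the rationale is `insufficient_evidence`.  This is
the algorithmic reading of "expert judgment resolves conflicts to VUS".  One
consequence is documented rather than special-cased: a profile with only
pathogenic items that fails every rule (e.g. an indeterminate assay plus a
mid-range REVEL score) is labelled insufficient-evidence even where a
curator might narratively call the situation conflicting; the report
attaches an indeterminate-zone note to such rows.

The engine is verified against an independently written brute-force
transcription of the rule list over all 5^7 strength-count vectors with each
count ≤ 4.  A known quirk of the 2015 table is pinned by a test rather than
patched: two very-strong items with one moderate match no rule (the table
predates the SVI's ≥ 2 VS clarification), so tier monotonicity under added
pathogenic evidence holds — and is fuzz-tested — only over the strengths the
assigners can actually emit (at most one very-strong item).

## Synthetic data

The generator emulates the structure the calibration assumes, not the
biochemistry: true pathogenic activities uniform on [0, pathogenic_max],
benign on [benign_min, 100], the pseudodeficiency sentinel uniform strictly
inside the gap, and additive zero-mean Gaussian replicate noise clipped at
zero.  Defaults mirror the real panel: 7 + 4 + 1 controls, boundaries
11%/54%, two replicates, noise scale 1.0% (the real assay's replicate pairs
differ by ≤ 1.7 percentage points, so 1% matches that spread's order of
magnitude).  Uniform zone distributions are a choice of convenience — no
distribution is stated for real panels — and are configuration-exposed.

What passing synthetic tests does *not* show: transfection-efficiency or
batch effects between runs, correlated (non-Gaussian) replicate error,
heteroscedasticity between high- and low-activity constructs, or any
relationship between activity and the other evidence axes (frequency, REVEL,
phase), which the observation generator draws independently.  Results on
real panels therefore still require the calibration sanity checks (class
separation, sentinel placement) that the library enforces.

Monte-Carlo check (run by `analysis/04_synthetic_validation.py` and the test
suite): over 200 seeded panels with replicate noise σ = 2%, the calibrated
boundaries stay within 3σ of the true boundaries in ≥ 95% of trials.  The
problem sizes (200 panels, 200 fuzzed observations, count vectors ≤ 4) keep
the whole suite in seconds while exercising every stratum.

## Numerical and degenerate-input choices

- Boundary ties: pathogenic zone strict (`< pathogenic_max`), benign zone
  inclusive (`>= benign_min`); see Calibration.
- Ties in rounding: half away from zero on the printed decimal.
- Replicate count n = 1 is accepted (the mean is the value); an empty
  replicate list is an error, not a silent zero.
- An empty variants table produces a valid, zero-row report.
- Table parsing reports file, line and column on the first bad cell;
  calibration failure aborts the pipeline before any variant is classified.
- Floats are serialized with `repr`, so TSV round-trips are bit-identical
  and fixture generation is byte-stable.

## Known limitations

- The activity thresholds are properties of the packaged control panel, not
  of the gene: a different panel yields different boundaries, and the
  conservative-policy default reflects the sparse sampling of the
  indeterminate range by current controls.
- Codes outside the set used here (PVS1, PS1/2/4, PM1/4/6, PP1/2/5, BS2–4,
  BP1–3/5–7) are accepted by the engine as pass-through profile entries but
  have no assigners.
- The frozen combining table inherits the 2015 gaps noted above; revising
  the rule list (e.g. to the SVI ≥ 2 VS clarification or a points-based
  system) is a deliberate, test-visible change.
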