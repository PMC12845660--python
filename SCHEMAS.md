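# File schemas

All tables are UTF-8 comma-separated CSV with a mandatory header row and
"." decimals. Units: m/z and masses in Da, retention time in minutes,
concentrations in ng/L (the PFOS MAC-EQS of 36 µg/L is stored as
36000 ng/L). MS2 spectra travel as MGF.

## Feature table (`features/<sample>.csv`, `blanks/<blank>.csv`)

| column | type | meaning |
|---|---|---|
| feature_id | str, unique | detected-signal identifier |
| sample_id | str | owning sample |
| mz | float > 0 | measured [M−H]⁻ m/z |
| rt | float ≥ 0 | retention time, min |
| area | float > 0 | integrated peak area |
| snr | float ≥ 0 | chromatographic signal-to-noise |
| ms2_ref | str, optional | spectrum id in the MGF file |

## Suspect list (`suspects.csv`)

`name, formula, neutral_mass, suspect_id, class, expected_rt, in_library`.
`neutral_mass` must agree with the monoisotopic mass of `formula` within
0.001 Da. `expected_rt` is present only for compounds with an authentic
standard; `in_library` marks compounds with curated MS2 library entries.

## MS2 spectra (`spectra.mgf`)

Standard MGF; `TITLE` is the spectrum id referenced by `ms2_ref`,
`PEPMASS` the precursor m/z.

## MS1 isotope envelopes (`envelopes.csv`)

`feature_id, mz, rel_intensity` — observed isotopologue peaks per feature,
intensities relative to the base peak.

## Diagnostic fragments / neutral losses (`fragments.csv`, `losses.csv`)

`name, mz` (fragment anion m/z, electron mass included) and `name, mass`
(neutral loss mass).

## Calibration (`calibration.csv`)

`native_id, labeled_id, conc_native, conc_labeled, area_native,
area_labeled` — one row per level, grouped by native/labeled pair.

## Sample metadata (`meta.csv`)

`sample_id, site_number, settlement, water_body, position, is_blank`.
Odd site numbers are upstream, even are downstream; blanks set
`is_blank=True` and ignore the parity rule.

## RPF table (`rpf.csv`)

`compound_id, rpf` — relative potency factor versus PFOA (PFOA = 1).
The shipped defaults are the published relative-potency placeholder set
and are user-editable.

## Hazard table (`hazard.csv`)

`compound_id` plus the 18 attribute columns, grouped 3/2/3/10:
persistence `biowin1, biowin3, biowin5` (biodegradation probabilities;
lower = more persistent), bioaccumulation `log_bcf, log_kow`,
ecotoxicity `fish_lc50_96h_neglog, daphnia_lc50_48h_neglog,
algae_ec50_96h_neglog` (−log10 mg/L), and ten human-health endpoints
`carcinogenicity, developmental_toxicity, mutagenicity,
endocrine_disruption, hepatotoxicity, skin_irritation, eye_irritation,
sensitization, repeated_dose_toxicity, oral_rat_ld50_neglog`.

## Concentrations (`concentrations.csv`)

`sample_id, compound_id, conc, mql, status, qc_flags, snr` with
`status ∈ {quantified, semi_quantified, below_mql, not_detected}` and
`qc_flags` a `|`-joined subset of `{low_snr, ion_ratio, rt_drift}`.

## Stage outputs

- `annotations.csv`: group_id, suspect_id/name, ppm_error, isotope_score,
  the five evidence flags, confidence level, consensus m/z and RT, member
  feature ids.
- `series.csv`: series_id, base_unit, kmd_centroid, `|`-joined members.
- `eqs.csv`: per-sample ΣPFAS, ΣPFOAeq and the three exceedance flags.
- `river_summary.csv`: per water body and quantity — n, mean, sd, min, max.
- `risk.csv`: ToxPi, DF, max concentration, magnitude, exposure,
  normalized exposure, RI and category per compound.
- `tests.csv`: per-compound Wilcoxon W, raw and FDR-adjusted p,
  Shapiro–Wilk W and p.
- `ground_truth.json` (synthetic runs): planted concentrations, true and
  realized detection frequencies, per-feature labels
  (pfas/decoy/background), CF2 series membership, true RRFs, hazard ranks.
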