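# fluorscreen

Suspect screening, semi-quantification, compliance screening and risk
prioritization of per- and polyfluoroalkyl substances (PFAS) in surface
waters, built for LC–HRMS feature tables.

Routine PFAS monitoring quantifies a few dozen compounds with authentic
standards, while thousands of PFAS are in commerce. `fluorscreen`
implements the full screening-to-prioritization chain a water-quality
laboratory needs around a targeted method:

1. **Mass-defect analytics** (`fluorscreen.chem`) — monoisotopic masses,
   standard and Kendrick mass defects with CF₂/CH₂ bases, carbon-normalized
   "PFAS plot" coordinates, homologous-series detection, and constrained
   molecular-formula enumeration. A CF₂ homologous series shares a single
   Kendrick mass defect, KMD = round(KM) − KM with KM = m · 50 / m(CF₂).
2. **Suspect screening** (`fluorscreen.screen`) — cross-sample feature
   grouping (0.2 min / 5 ppm), blank subtraction (sample/blank ratio ≤ 5 is
   background), suspect matching at ±5 ppm on the [M−H]⁻ ion, isotope-pattern
   scoring (threshold 80, ±30 % intensity tolerance), diagnostic-fragment and
   neutral-loss matching, and identification-confidence levels L1–L5 with
   L1–L3 retained.
3. **Quantification** (`fluorscreen.quantify`) — isotope-dilution relative
   response factors (RRF = slope of area ratio vs concentration ratio through
   the origin), surrogate-RRF semi-quantification for compounds without
   standards (nearest retention time, then subclass, then mass), QC gates
   (S/N > 3, ion-ratio uncertainty < 30 %, |ΔRT| ≤ 0.1 min for targets), an
   MQL anchored at S/N = 10, and blank correction.
4. **EQS compliance** (`fluorscreen.eqs`) — lower-bound ΣPFAS per sample,
   relative-potency-factor PFOA equivalents
   (ΣPFOAeq = Σᵢ cᵢ·RPFᵢ) against the proposed 4.4 ng/L group standard and
   the PFOS standards (AA 0.65 ng/L, MAC 36 µg/L), and per-river summaries.
5. **Risk prioritization** (`fluorscreen.risk`) — 18 PBT attributes
   normalized and weighted (1/9 persistence, 1/6 bioaccumulation, 1/18
   ecotoxicity, 1/60 human health; weights sum to exactly 1) into a ToxPi
   score; exposure = DF × normalized concentration magnitude; risk index
   RI = ToxPi × normalized exposure, binned high / medium / low / negligible
   at 0.1 / 0.01 / 0.001.
6. **Paired statistics** (`fluorscreen.stats`) — upstream/downstream
   differences per settlement, exact Wilcoxon signed-rank (full sign
   enumeration for n ≤ 25, midrank ties), Shapiro–Wilk normality, and
   Benjamini–Hochberg FDR across compounds.
7. **Synthetic study** (`fluorscreen.simulate`) — a fully ground-truthed
   24-sample survey generator (12 settlements × upstream/downstream over 5
   water bodies, 10 targets + 10 suspect-screening compounds, a dominant
   ultra-short-chain acid, planted CF₂ series, decoys, blank-borne
   background) used throughout the test suite for recovery checks.

## Worked example

Run the whole pipeline on the synthetic study:

```sh
fluorscreen run --seed 1 --out run1
```

`run1/report.md` then contains, among other tables (numbers for seed 1):

```
- Level 1: 10 annotations      # targets confirmed by standard RT + MS2
- Level 2: 5 annotations       # curated-library MS2 matches
- Level 3: 5 annotations       # formula + diagnostic-fragment evidence

- Group EQS (> 4.4 ng/L as PFOA-eq): 22/24 samples exceed
- PFOS AA-EQS (> 0.65 ng/L): 24/24 samples exceed
- PFOS MAC-EQS (> 36000.0 ng/L): 0/24 samples exceed
```

and a risk ranking whose head is

```
compound_id    toxpi       df       ri  category
TFA         0.077214 1.000000 0.077214  medium
ADONA       0.513100 0.791667 0.007984  low
PFPrA       0.184933 1.000000 0.006493  low
```

The top line is the methodologically interesting one: TFA has one of the
*lowest* hazard (ToxPi) scores, yet its occurrence two orders of magnitude
above every other PFAS, at 100 % detection frequency, drives the largest
risk index — concentration and detection frequency, not intrinsic
toxicity, set the priority. High-ToxPi legacy compounds (PFOS, PFOA, PFNA)
rank low because their concentrations are small.

Individual stages are exposed as subcommands (`simulate`, `kmd`, `screen`,
`quantify`, `eqs`, `risk`, `stats`), all thin wrappers over the library;
`fluorscreen run --from-stage eqs --out run1` resumes from on-disk
intermediates.

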