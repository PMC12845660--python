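"""Synthetic-study generator with machine-readable ground truth.

Emulates a 24-sample river survey: 12 settlements, each sampled upstream
and downstream, spread over 5 water bodies, with ~10 target PFAS
(quantified against authentic standards) and ~10 suspect-screening
compounds, one of which (a TFA analogue) dominates the concentration
profile by 1-2 orders of magnitude. Generators cover the concentration
study, per-sample HRMS feature tables with planted CF2 homologous series,
non-fluorinated decoys and blank-borne background signals, MS2 spectra,
MS1 isotope envelopes, internal calibration series, and an 18-attribute
PBT hazard table. Everything planted is recorded in the ground truth.

All generators are deterministic given (design, seed). Concentration
noise is lognormal (positive, right-skewed) with configurable CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem, databases
from .chem import PROTON_MASS, monoisotopic_mass
from .msio import Feature, FragmentSpectrum, SampleMeta, SuspectEntry
from .quantify import CalibrationCurve, CalibrationLevel
from .risk import ATTRIBUTE_SCHEMA


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class CompoundSpec:
    name: str
    formula: str
    subclass: str  # PFCA | PFSA | FTS | ether | H-PFCA | pesticide
    true_rt: float  # minutes
    mean_conc: float  # ng/L
    detect_prob: float
    rpf: float | None = None
    is_target: bool = False
    in_library: bool = False
    dominant: bool = False
    rrf_true: float | None = None  # None for SSA compounds -> surrogate's RRF
    is_conc: float = 2.0  # internal-standard spike, ng/L

    def __post_init__(self):
        if self.mean_conc < 0:
            raise ValueError(f"{self.name}: mean_conc must be >= 0")
        if not 0 <= self.detect_prob <= 1:
            raise ValueError(f"{self.name}: detect_prob must be in [0, 1]")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def ion_mz(self) -> float:
        return self.neutral_mass - PROTON_MASS


AREA_IS = 1e5  # labeled internal-standard peak area (arbitrary units)

DEFAULT_SETTLEMENTS: list[tuple[str, str]] = [
    ("Backo Novo Selo", "Danube"), ("Backa Palanka", "Danube"),
    ("Novi Sad", "Danube"), ("Zemun", "Danube"), ("Belgrade", "Danube"),
    ("Smederevo", "Danube"),
    ("Kula", "Great Backa Canal"), ("Vrbas", "Great Backa Canal"),
    ("Srbobran", "Great Backa Canal"),
    ("Becej", "Tisa"), ("Pancevo", "Tamis"), ("Novi Beograd", "Sava"),
]


def default_compounds() -> list[CompoundSpec]:
    """The default roster: 10 targets + 10 suspect-screening compounds.

    Mean concentrations and detection frequencies follow typical
    urban-impacted river profiles dominated by short-chain PFCAs with a
    TFA analogue 2 orders of magnitude above the rest; RPFs are the
    published relative-potency placeholder set (PFOA = 1).
    """
    T, S = True, False
    rows = [
        # name, formula, subclass, rt, mean, df, rpf, target, library,
        # dominant, rrf_true
        ("PFBA", "C4HF7O2", "PFCA", 1.0, 1.8, 1.0, 0.05, T, S, S, 0.80),
        ("PFPeA", "C5HF9O2", "PFCA", 1.6, 1.5, 0.958, 0.03, T, S, S, 1.10),
        ("PFHxA", "C6HF11O2", "PFCA", 2.2, 0.25, 0.333, 0.01, T, S, S, 0.90),
        ("PFHpA", "C7HF13O2", "PFCA", 2.8, 0.15, 0.167, 0.505, T, S, S, 1.20),
        ("PFOA", "C8HF15O2", "PFCA", 3.4, 1.0, 1.0, 1.0, T, S, S, 1.00),
        ("PFNA", "C9HF17O2", "PFCA", 4.0, 0.3, 0.9, 10.0, T, S, S, 0.95),
        ("PFBS", "C4HF9O3S", "PFSA", 1.8, 0.5, 1.0, 0.001, T, S, S, 1.05),
        ("PFHxS", "C6HF13O3S", "PFSA", 2.9, 0.5, 1.0, 0.6, T, S, S, 0.85),
        ("PFOS", "C8HF17O3S", "PFSA", 4.2, 1.2, 1.0, 2.0, T, S, S, 1.15),
        ("6:2 FTS", "C8H5F13O3S", "FTS", 3.1, 1.5, 1.0, 0.02, T, S, S, 0.90),
        ("TFA", "C2HF3O2", "PFCA", 0.6, 513.0, 1.0, 0.002, S, S, T, None),
        ("PFPrA", "C3HF5O2", "PFCA", 0.8, 17.9, 1.0, 0.03, S, S, S, None),
        ("TFMS", "CHF3O3S", "PFSA", 0.7, 3.83, 0.875, 0.001, S, S, S, None),
        ("ADONA", "C7H2F12O4", "ether", 3.0, 11.2, 0.75, 0.03, S, T, S, None),
        ("9H-PFNA", "C9H2F16O2", "H-PFCA", 3.8, 1.11, 0.333, 0.1, S, S, S, None),
        ("7H-PFHpA", "C7H2F12O2", "H-PFCA", 2.6, 0.63, 1.0, 0.1, S, S, S, None),
        ("Flupropanate", "C3H2F4O2", "pesticide", 0.9, 5.95, 0.8, None, S, T, S, None),
        ("Fluxapyroxad", "C18H12F5N3O", "pesticide", 4.5, 0.5, 0.5, None, S, T, S, None),
        ("Isoxaflutole", "C15H12F3NO4S", "pesticide", 4.4, 0.4, 0.4, None, S, T, S, None),
        ("Fluometuron", "C10H11F3N2O", "pesticide", 3.9, 0.3, 0.3, None, S, T, S, None),
    ]
    return resolve_rrf_true([CompoundSpec(*r) for r in rows])


def resolve_rrf_true(compounds: list[CompoundSpec]) -> list[CompoundSpec]:
    """Fill SSA compounds' generating RRF with their surrogate target's.

    The surrogate is the nearest-RT target (ties: same subclass, then
    nearest neutral mass) -- the same rule the quantification stage uses,
    so a correctly assigned surrogate is unbiased by construction.
    """
    from .quantify import assign_surrogate

    @dataclass
    class _T:
        name: str
        rt: float
        subclass: str
        neutral_mass: float

    targets = [c for c in compounds if c.is_target and c.rrf_true is not None]
    if not targets:
        return compounds
    proxies = [_T(t.name, t.true_rt, t.subclass, t.neutral_mass)
               for t in targets]
    rrf_of = {t.name: t.rrf_true for t in targets}
    out = []
    for c in compounds:
        if c.rrf_true is None:
            surr = assign_surrogate(c.true_rt, c.subclass, c.neutral_mass,
                                    proxies)
            c = replace(c, rrf_true=rrf_of[surr])
        out.append(c)
    return out


@dataclass
class StudyDesign:
    settlements: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_SETTLEMENTS))
    compounds: list[CompoundSpec] = field(default_factory=default_compounds)
    seed: int = 0
    conc_cv: float = 0.30          # lognormal site-level CV
    sigma_ppm: float = 1.0         # m/z relative error SD
    rt_jitter: float = 0.02        # min
    downstream_effect: float = 1.0  # multiplier on downstream means (1 = null)
    n_decoys: int = 50
    n_background: int = 5
    n_blanks: int = 2
    area_noise: float = 0.0        # multiplicative area noise SD
    snr_per_ng: float = 50.0       # S/N units per ng/L (MQL anchor 0.2 ng/L)

    def __post_init__(self):
        if not self.compounds:
            raise ValueError("design needs at least one compound")
        if len({wb for _, wb in self.settlements}) < 2:
            raise ValueError("need water bodies from a set of >= 2 names")

    @property
    def n_samples(self) -> int:
        return 2 * len(self.settlements)


def make_meta(design: StudyDesign) -> list[SampleMeta]:
    """Sample metadata: odd site numbers upstream, even downstream."""
    meta = []
    site = 1
    for settlement, body in design.settlements:
        for position in ("upstream", "downstream"):
            meta.append(SampleMeta(sample_id=f"S{site:02d}", site_number=site,
                                   settlement=settlement, water_body=body,
                                   position=position))
            site += 1
    for b in range(design.n_blanks):
        meta.append(SampleMeta(sample_id=f"BLK{b + 1}", site_number=0,
                               settlement="blank", water_body="blank",
                               position="blank", is_blank=True))
    return meta


def make_suspect_list(compounds) -> list[SuspectEntry]:
    return [SuspectEntry(name=c.name, formula=c.formula,
                         neutral_mass=c.neutral_mass,
                         suspect_id=f"SUS{i + 1:04d}",
                         compound_class=c.subclass,
                         expected_rt=c.true_rt if c.is_target else None,
                         in_library=c.in_library)
            for i, c in enumerate(compounds)]


# ---------------------------------------------------------------------------
# concentration study
# ---------------------------------------------------------------------------

def gen_study(design: StudyDesign):
    """Concentration matrix (samples x compounds, ng/L) plus ground truth.

    Per-sample concentrations are lognormal around each compound's mean
    (CV = ``design.conc_cv``), zeroed where an independent
    Bernoulli(detect_prob) draw fails. ``downstream_effect`` multiplies
    downstream means (1.0 = no settlement effect, the study's null).
    """
    rng = np.random.default_rng(design.seed)
    meta = [m for m in make_meta(design) if not m.is_blank]
    cv = design.conc_cv
    sigma = np.sqrt(np.log(1 + cv ** 2))
    mu_shift = -sigma ** 2 / 2  # unit-mean lognormal multiplier
    data = {}
    truth_detect: dict[str, float] = {}
    for comp in design.compounds:
        col = []
        detected = 0
        for m in meta:
            hit = rng.random() < comp.detect_prob
            mean = comp.mean_conc
            if m.position == "downstream":
                mean *= design.downstream_effect
            conc = mean * np.exp(rng.normal(mu_shift, sigma)) if hit else 0.0
            detected += hit
            col.append(conc)
        data[comp.name] = col
        truth_detect[comp.name] = detected / len(meta)
    matrix = pd.DataFrame(data, index=[m.sample_id for m in meta])
    ground_truth = {
        "concentrations": matrix.to_dict(orient="index"),
        "realized_detection_frequency": truth_detect,
        "true_detection_prob": {c.name: c.detect_prob for c in design.compounds},
        "dominant": [c.name for c in design.compounds if c.dominant],
        "mean_conc": {c.name: c.mean_conc for c in design.compounds},
    }
    return matrix, ground_truth


# ---------------------------------------------------------------------------
# feature tables, MS2 and envelopes
# ---------------------------------------------------------------------------

def _ms2_peaks(comp: CompoundSpec) -> list[tuple[float, float]]:
    """Class-typical diagnostic MS2 peaks for a planted compound."""
    ion = comp.ion_mz
    co2 = monoisotopic_mass("CO2")
    peaks: list[tuple[float, float]] = []
    if comp.subclass in ("PFCA", "ether", "H-PFCA"):
        peaks.append((ion - co2, 100.0))  # decarboxylation
        peaks.append((databases.DIAGNOSTIC_FRAGMENTS["CF3-"], 35.0))
        if chem.parse_formula(comp.formula).get("C", 0) >= 4:
            peaks.append((databases.DIAGNOSTIC_FRAGMENTS["C2F5-"], 20.0))
    elif comp.subclass in ("PFSA", "FTS"):
        peaks.append((databases.DIAGNOSTIC_FRAGMENTS["SO3-"], 100.0))
        peaks.append((databases.DIAGNOSTIC_FRAGMENTS["FSO3-"], 60.0))
    else:  # pesticides: aromatic fragments outside the PFAS fragment DB
        peaks.append((ion - 26.0030, 100.0))  # HCN-like loss product
        peaks.append((77.0391, 40.0))         # phenyl cation analogue
    return sorted(peaks)


def gen_feature_table(design: StudyDesign):
    """Per-sample features, blank features, MS2 spectra, MS1 envelopes
    and ground truth.

    Planted per detected compound per sample: one [M-H]- feature with
    relative m/z error ~ N(0, sigma_ppm), RT jitter, area proportional to
    the planted concentration and S/N proportional to concentration.
    Additionally planted: non-fluorinated decoy features (random masses
    with hydrocarbon-like positive mass defects, kept away from suspect
    masses and CF2-series Kendrick bands) and background features present
    in blanks at >= 1/5 of the sample intensity. Ground truth labels every
    feature (pfas / decoy / background), records the CF2 homologous series
    implied by the compound roster, and the planted concentrations.
    """
    rng = np.random.default_rng(design.seed + 1)
    matrix, study_truth = gen_study(design)
    meta = make_meta(design)
    samples = [m for m in meta if not m.is_blank]
    blanks = [m for m in meta if m.is_blank]

    sample_features: list[Feature] = []
    blank_features: list[Feature] = []
    spectra: list[FragmentSpectrum] = []
    envelope_rows: list[dict] = []
    truth_features: dict[str, dict] = {}
    fid = 0

    def new_id():
        nonlocal fid
        fid += 1
        return f"F{fid:05d}"

    # --- planted PFAS features -------------------------------------------
    comp_by_name = {c.name: c for c in design.compounds}
    series_members: dict[str, list[str]] = {}
    for sm in samples:
        for name, conc in matrix.loc[sm.sample_id].items():
            if conc <= 0:
                continue
            comp = comp_by_name[name]
            f_id = new_id()
            mz = comp.ion_mz * (1 + rng.normal(0, design.sigma_ppm) * 1e-6)
            rt = max(0.0, comp.true_rt + rng.normal(0, design.rt_jitter))
            spec_id = f"MS2_{f_id}"
            # area follows the isotope-dilution response model so that the
            # quantification stage can invert it with the fitted RRF
            noise = (1 + rng.normal(0, design.area_noise)
                     if design.area_noise > 0 else 1.0)
            area = (comp.rrf_true or 1.0) * (conc / comp.is_conc) * AREA_IS \
                * max(noise, 1e-6)
            sample_features.append(Feature(
                feature_id=f_id, sample_id=sm.sample_id, mz=mz, rt=rt,
                area=area, snr=conc * design.snr_per_ng, ms2_ref=spec_id))
            spectra.append(FragmentSpectrum(spec_id, comp.ion_mz,
                                            _ms2_peaks(comp)))
            for off, rel in _envelope_cache(comp.formula):
                envelope_rows.append({"feature_id": f_id, "mz": mz + off,
                                      "rel_intensity": rel})
            truth_features[f_id] = {"kind": "pfas", "compound": name,
                                    "sample_id": sm.sample_id, "conc": conc}

    # --- CF2 homologous series implied by the roster ----------------------
    # truth tolerances carry a noise allowance: with many sample copies per
    # compound, a pair whose theoretical spacing/KMD discrepancy lies within
    # tolerance + ~3 SD of the cross-feature noise will almost surely link
    # at least once, and the transitive closure then merges the compounds
    truth_ppm = 5.0 + 3.0 * np.sqrt(2) * design.sigma_ppm
    truth_kmd = 0.002 + 3.0 * np.sqrt(2) * design.sigma_ppm * 1e-6 * 500.0
    for key, members in _cf2_series(design.compounds, kmd_tol=truth_kmd,
                                    unit_tol_ppm=truth_ppm).items():
        ids = [f for f, t in truth_features.items()
               if t["compound"] in members]
        if ids:
            series_members[key] = sorted(ids)

    # --- background features (also in blanks, ratio <= 5) -----------------
    # background and decoy masses stay out of every planted compound's CF2
    # Kendrick band and out of each other's, so no accidental series form
    background_ids = []
    bg_specs = []
    used_kmds: list[float] = []
    for b in range(design.n_background):
        mz = float(rng.uniform(120, 550))
        mz = _avoid_collisions(mz, design.compounds, rng,
                               extra_kmds=used_kmds)
        used_kmds.append(chem.kendrick(mz, "CF2").kmd)
        bg_specs.append((mz, float(rng.uniform(0.5, 11.5)),
                         float(rng.uniform(2.0, 4.5))))  # sample/blank ratio < 5
    for i, (mz, rt, ratio) in enumerate(bg_specs):
        base_area = float(rng.uniform(5e4, 5e5))
        for sm in samples:
            f_id = new_id()
            sample_features.append(Feature(
                feature_id=f_id, sample_id=sm.sample_id,
                mz=mz * (1 + rng.normal(0, design.sigma_ppm) * 1e-6),
                rt=rt, area=base_area, snr=50.0))
            truth_features[f_id] = {"kind": "background",
                                    "sample_id": sm.sample_id,
                                    "background_id": i,
                                    "sample_blank_ratio": ratio}
            background_ids.append(f_id)
        for bm in blanks:
            f_id = new_id()
            blank_features.append(Feature(
                feature_id=f_id, sample_id=bm.sample_id,
                mz=mz * (1 + rng.normal(0, design.sigma_ppm) * 1e-6),
                rt=rt, area=base_area / ratio, snr=20.0))
            truth_features[f_id] = {"kind": "background_blank",
                                    "sample_id": bm.sample_id,
                                    "background_id": i}

    # --- non-fluorinated decoys -------------------------------------------
    decoy_ids = []
    for _ in range(design.n_decoys):
        mz = float(rng.uniform(100, 600))
        # hydrocarbon-like positive mass defect; decoys also keep out of
        # each other's CF2 Kendrick band so no accidental series arise
        mz = float(np.floor(mz) + rng.uniform(0.05, 0.45))
        mz = _avoid_collisions(mz, design.compounds, rng,
                               extra_kmds=used_kmds)
        used_kmds.append(chem.kendrick(mz, "CF2").kmd)
        rt = float(rng.uniform(0.5, 11.5))
        sm = samples[int(rng.integers(len(samples)))]
        f_id = new_id()
        sample_features.append(Feature(
            feature_id=f_id, sample_id=sm.sample_id, mz=mz, rt=rt,
            area=float(rng.uniform(1e4, 1e6)), snr=float(rng.uniform(5, 100))))
        truth_features[f_id] = {"kind": "decoy", "sample_id": sm.sample_id}
        decoy_ids.append(f_id)

    ground_truth = {
        **study_truth,
        "features": truth_features,
        "series": series_members,
        "background_feature_ids": background_ids,
        "decoy_feature_ids": decoy_ids,
    }
    envelopes = pd.DataFrame(envelope_rows,
                             columns=["feature_id", "mz", "rel_intensity"])
    return sample_features, blank_features, spectra, envelopes, ground_truth


_ENV_CACHE: dict[str, list[tuple[float, float]]] = {}


def _envelope_cache(formula: str):
    if formula not in _ENV_CACHE:
        from .screen import theoretical_envelope
        _ENV_CACHE[formula] = theoretical_envelope(formula)
    return _ENV_CACHE[formula]


def _cf2_series(compounds, kmd_tol: float = 0.002,
                unit_tol_ppm: float = 5.0) -> dict[str, list[str]]:
    """Ground-truth CF2 series among the planted compounds.

    Series are what is mathematically present in the noise-free planted
    ion masses at the screening tolerances: compounds whose theoretical
    [M-H]- masses share a CF2 Kendrick band and are spaced by integer CF2
    multiples. This includes true formula homologs (e.g. the PFCA chain)
    and any near-isobaric spacing coincidences among the planted masses.
    """
    class _C:
        def __init__(self, c):
            self.feature_id = c.name
            self.mz = c.ion_mz
    found = chem.find_homologous_series([_C(c) for c in compounds], "CF2",
                                        kmd_tol, unit_tol_ppm)
    return {f"CF2_series_{i}": sorted(s.member_feature_ids)
            for i, s in enumerate(found)}


def _avoid_collisions(mz: float, compounds, rng, min_ppm: float = 50.0,
                      kmd_guard: float = 0.005, extra_guard: float = 0.0025,
                      extra_kmds=()) -> float:
    """Resample mz until it is far from suspect ions and CF2-KMD bands.

    ``extra_kmds`` (previously placed decoys) get a narrower guard, just
    above the series-detection KMD tolerance, so decoys never share a
    Kendrick band with each other or with any planted compound.
    """
    from .chem import kendrick
    planted = [kendrick(c.ion_mz, "CF2").kmd for c in compounds]
    for _ in range(5000):
        kmd = kendrick(mz, "CF2").kmd
        ok = (not any(abs(mz - c.ion_mz) <= min_ppm * 1e-6 * c.ion_mz
                      for c in compounds)
              and not any(abs(kmd - k) <= kmd_guard for k in planted)
              and not any(abs(kmd - k) <= extra_guard for k in extra_kmds))
        if ok:
            return mz
        mz = float(np.floor(rng.uniform(100, 600)) + rng.uniform(0.05, 0.45))
    raise RuntimeError("could not place a collision-free decoy mass")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def gen_calibration(compounds, levels: int = 7, seed: int = 0,
                    sigma: float = 0.05, conc_lo: float = 0.5,
                    conc_hi: float = 50.0):
    """Internal calibration series per target compound.

    Native areas follow area = RRF_true * (C/C_IS) * area_IS * (1 + eps),
    eps ~ N(0, sigma). Returns (curves, ground_truth) where ground truth
    records each compound's RRF_true.
    """
    if levels < 3:
        raise ValueError("need >= 3 calibration levels")
    if conc_hi / conc_lo < 10:
        raise ValueError("levels must span >= 1 order of magnitude")
    rng = np.random.default_rng(seed)
    concs = np.geomspace(conc_lo, conc_hi, levels)
    area_is = AREA_IS
    curves = []
    rrf_true = {}
    targets = [c for c in compounds if c.is_target]
    for comp in targets:
        rrf = comp.rrf_true if comp.rrf_true is not None \
            else float(rng.uniform(0.5, 1.5))
        rrf_true[comp.name] = rrf
        lvls = []
        for c in concs:
            eps = rng.normal(0, sigma) if sigma > 0 else 0.0
            area = rrf * (c / comp.is_conc) * area_is * (1 + eps)
            lvls.append(CalibrationLevel(conc_native=float(c),
                                         conc_labeled=comp.is_conc,
                                         area_native=float(area),
                                         area_labeled=area_is))
        curves.append(CalibrationCurve(native_id=comp.name,
                                       labeled_id=f"M-{comp.name}",
                                       levels=lvls))
    return curves, {"rrf_true": rrf_true}


# ---------------------------------------------------------------------------
# hazard table
# ---------------------------------------------------------------------------

def gen_hazard_table(compounds, seed: int = 0):
    """18-attribute PBT hazard matrix on plausible scales, plus ground truth.

    Hazard increases with perfluorinated chain length: biodegradation
    probabilities (Biowin) fall, log BCF / log Kow and toxicity potencies
    (-log10 mg/L) rise, human-endpoint scores rise, all with seeded noise.
    Ground truth retains the generating hazard ranks.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    propensity = {}
    for comp in compounds:
        nc = chem.parse_formula(comp.formula).get("C", 1)
        nf = chem.parse_formula(comp.formula).get("F", 0)
        drive = 0.6 * nc + 0.2 * nf  # generating hazard propensity
        propensity[comp.name] = drive
        r = {}
        for a in ATTRIBUTE_SCHEMA["persistence"]:
            r[a] = float(np.clip(0.95 - 0.05 * drive + rng.normal(0, 0.03),
                                 0.01, 0.99))
        r["log_bcf"] = float(0.25 * drive + rng.normal(0, 0.15))
        r["log_kow"] = float(0.35 * drive - 1.0 + rng.normal(0, 0.2))
        for a in ATTRIBUTE_SCHEMA["ecotoxicity"]:
            r[a] = float(0.2 * drive - 1.5 + rng.normal(0, 0.25))
        for a in ATTRIBUTE_SCHEMA["human"]:
            if a == "oral_rat_ld50_neglog":
                r[a] = float(0.1 * drive - 2.0 + rng.normal(0, 0.2))
            else:
                r[a] = float(np.clip(0.05 * drive + rng.normal(0, 0.08),
                                     0.0, 1.0))
        rows[comp.name] = r
    hazard = pd.DataFrame.from_dict(rows, orient="index")
    hazard.index.name = "compound_id"
    order = sorted(propensity, key=propensity.get, reverse=True)
    truth = {"generating_propensity": propensity,
             "generating_rank": {name: i + 1 for i, name in enumerate(order)}}
    return hazard, truth


def default_rpf_table(compounds) -> dict[str, float]:
    return {c.name: c.rpf for c in compounds if c.rpf is not None}
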