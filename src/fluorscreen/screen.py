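"""Suspect-screening core.

Cross-sample feature grouping, blank subtraction, suspect matching,
isotope-pattern scoring, diagnostic-fragment / neutral-loss matching and
identification-confidence assignment (levels 1-5, with levels 1-3 retained
for interpretation).

The confidence levels follow the community identification framework for
HRMS annotation: level 1 is confirmed with an authentic standard (accurate
mass + retention time + MS2), level 2 a curated-library MS2 match, level 3
a tentative structure supported by fragment evidence, level 4 an
unequivocal molecular formula, level 5 an accurate mass only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .chem import PROTON_MASS
from .msio import Feature


# ---------------------------------------------------------------------------
# cross-sample grouping
# ---------------------------------------------------------------------------

@dataclass
class FeatureGroup:
    """Features from different samples judged to be the same compound signal."""
    group_id: int
    features: list[Feature]

    @property
    def consensus_mz(self) -> float:
        w = np.array([f.area for f in self.features])
        m = np.array([f.mz for f in self.features])
        return float((w * m).sum() / w.sum())

    @property
    def consensus_rt(self) -> float:
        return float(np.mean([f.rt for f in self.features]))

    @property
    def max_area(self) -> float:
        return max(f.area for f in self.features)

    @property
    def max_snr(self) -> float:
        return max(f.snr for f in self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def ms2_refs(self) -> list[str]:
        return [f.ms2_ref for f in self.features if f.ms2_ref]


def _within(f1: Feature, f2: Feature, rt_tol: float, mz_tol_ppm: float) -> bool:
    if abs(f1.rt - f2.rt) > rt_tol:
        return False
    return abs(f1.mz - f2.mz) <= mz_tol_ppm * 1e-6 * max(f1.mz, f2.mz)


def group_across_samples(features, rt_tol: float = 0.2,
                         mz_tol_ppm: float = 5.0) -> list[FeatureGroup]:
    """Transitive-closure grouping on |dRT| <= rt_tol and |dm/z| <= ppm tol.

    Each feature lands in exactly one group; the group consensus m/z is the
    intensity-weighted mean. Deterministic: features are pre-sorted by m/z.
    """
    feats = sorted(features, key=lambda f: (f.mz, f.rt, f.feature_id))
    n = len(feats)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        # features sorted by mz: stop scanning once mz difference exceeds tol
        for j in range(i + 1, n):
            if feats[j].mz - feats[i].mz > mz_tol_ppm * 1e-6 * feats[j].mz:
                break
            if _within(feats[i], feats[j], rt_tol, mz_tol_ppm):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for gid, idxs in enumerate(sorted(comps.values(), key=lambda c: feats[c[0]].mz)):
        groups.append(FeatureGroup(gid, [feats[i] for i in idxs]))
    return groups


def blank_subtract(groups, blank_groups, max_ratio: float = 5.0,
                   rt_tol: float = 0.2, mz_tol_ppm: float = 5.0):
    """Split groups into (retained, background) using the sample/blank ratio.

    A group whose maximum sample area is at most ``max_ratio`` times the
    maximum area of a matching blank group (same m/z within ppm tolerance,
    same RT within tolerance) is background and removed; groups with no
    matching blank signal are retained. The boundary ratio counts as
    background.
    """
    retained, background = [], []
    for g in groups:
        blank_area = 0.0
        for b in blank_groups:
            if (abs(g.consensus_rt - b.consensus_rt) <= rt_tol
                    and abs(g.consensus_mz - b.consensus_mz)
                    <= mz_tol_ppm * 1e-6 * max(g.consensus_mz, b.consensus_mz)):
                blank_area = max(blank_area, b.max_area)
        if blank_area > 0 and g.max_area / blank_area <= max_ratio:
            background.append(g)
        else:
            retained.append(g)
    return retained, background


# ---------------------------------------------------------------------------
# suspect matching
# ---------------------------------------------------------------------------

@dataclass
class EvidenceFlags:
    mass_match: bool = False
    formula_assigned: bool = False
    ms2_library_match: bool = False
    ms2_insilico_fragment_match: bool = False
    rt_standard_match: bool = False

    def any(self) -> bool:
        return (self.mass_match or self.formula_assigned
                or self.ms2_library_match or self.ms2_insilico_fragment_match
                or self.rt_standard_match)


@dataclass
class Annotation:
    feature_id: str  # group identifier in cross-sample screening
    suspect_id: str
    ppm_error: float
    isotope_score: float | None
    evidence: EvidenceFlags
    confidence: int


def match_suspects(groups, suspects, tol_ppm: float = 5.0):
    """Candidate (group, suspect) pairs within the precursor ppm tolerance.

    The theoretical ion is the deprotonated suspect, neutral mass minus the
    proton mass; ppm error is signed, (measured - theoretical)/theoretical.
    """
    out = []
    for g in groups:
        mz = g.consensus_mz
        for s in suspects:
            theo = s.neutral_mass - PROTON_MASS
            ppm = (mz - theo) / theo * 1e6
            if abs(ppm) <= tol_ppm:
                out.append((g, s, ppm))
    return out


# ---------------------------------------------------------------------------
# isotope pattern scoring
# ---------------------------------------------------------------------------

def _isotope_table(el: str):
    """[(nominal shift, mass delta, abundance)] for one element."""
    from pyteomics.mass import nist_mass
    mono_mass, _ = nist_mass[el][0]
    mono_nominal = round(mono_mass)
    out = []
    for iso, (m, ab) in nist_mass[el].items():
        if iso == 0 or ab <= 0:
            continue
        out.append((iso - mono_nominal, m - mono_mass, ab))
    out.sort()
    return out


def theoretical_envelope(formula: str | dict, max_shift: int = 4,
                         prune: float = 1e-10):
    """Aggregated isotopologue envelope of a neutral formula.

    Returns a list of ``(mass_offset, relative_intensity)`` per nominal
    shift 0..max_shift, intensities relative to the most abundant peak,
    mass offsets abundance-averaged within each nominal bin.
    """
    counts = chem.parse_formula(formula) if isinstance(formula, str) else formula
    # dist: shift -> (probability, probability-weighted mass offset)
    dist = {0: (1.0, 0.0)}
    for el, n in counts.items():
        table = _isotope_table(el)
        single = {s: (p, p * dm) for s, dm, p in table}
        for _ in range(n):
            new: dict[int, list[float]] = {}
            for s1, (p1, pm1) in dist.items():
                for s2, (p2, pm2) in single.items():
                    s = s1 + s2
                    if s > max_shift:
                        continue
                    p = p1 * p2
                    if p < prune:
                        continue
                    acc = new.setdefault(s, [0.0, 0.0])
                    acc[0] += p
                    acc[1] += p1 * pm2 + p2 * pm1
            dist = {s: (v[0], v[1]) for s, v in new.items()}
    base = max(p for p, _ in dist.values())
    env = []
    for s in sorted(dist):
        p, pm = dist[s]
        env.append((pm / p + 0.0, p / base, s))
    # (mean mass offset within bin, relative intensity, nominal shift)
    return [(off, rel) for off, rel, _ in env]


def score_isotope_pattern(observed_peaks, formula, intensity_tol: float = 0.30,
                          match_tol_ppm: float = 10.0,
                          min_rel: float = 0.05) -> float:
    """Similarity (0-100) of an observed isotope envelope to a formula.

    Surrogate scoring function: the theoretical envelope is computed from
    the formula; observed and theoretical peaks are matched within
    ``match_tol_ppm``; for each theoretical isotopologue above ``min_rel``
    relative abundance the relative intensity deviation is computed,
    deviations within ``intensity_tol`` count as zero, larger deviations
    are capped at 1, and a missing expected peak scores a full deviation.
    Score = 100 * (1 - mean deviation).

    ``observed_peaks``: list of (mz, intensity); the first/most intense
    peak anchors the envelope.
    """
    if not observed_peaks:
        raise ValueError("empty isotope envelope")
    obs = sorted(observed_peaks)
    obs_base_int = max(i for _, i in obs)
    obs_rel = [(mz, i / obs_base_int) for mz, i in obs]
    mono = chem.monoisotopic_mass(formula)
    theo = theoretical_envelope(formula)
    # anchor: observed base peak mz corresponds to the most intense theoretical
    t_base_off = max(theo, key=lambda t: t[1])[0]
    o_base_mz = max(obs, key=lambda p: p[1])[0]
    devs = []
    for off, rel in theo:
        if rel < min_rel:
            continue
        want = o_base_mz + (off - t_base_off)
        tol = match_tol_ppm * 1e-6 * want
        matched = [r for mz, r in obs_rel if abs(mz - want) <= tol]
        if not matched:
            devs.append(1.0)
            continue
        r = max(matched)
        d = abs(r - rel) / rel
        devs.append(0.0 if d <= intensity_tol else min(d, 1.0))
    if not devs:
        return 0.0
    return 100.0 * (1.0 - float(np.mean(devs)))


# ---------------------------------------------------------------------------
# MS2 fragment / neutral-loss matching
# ---------------------------------------------------------------------------

@dataclass
class FragmentMatches:
    fragment_hits: list[str] = field(default_factory=list)
    neutral_loss_hits: list[str] = field(default_factory=list)

    def any(self) -> bool:
        return bool(self.fragment_hits or self.neutral_loss_hits)


def match_fragments(spectrum, fragment_db: dict[str, float],
                    neutral_loss_db: dict[str, float],
                    tol_ppm: float = 10.0) -> FragmentMatches:
    """Match MS2 peaks against diagnostic fragments and neutral losses.

    A fragment hit is a peak within ``tol_ppm`` of a database m/z; a
    neutral-loss hit is a (precursor - peak) difference matching a database
    loss within ``tol_ppm`` on the precursor scale.
    """
    if not fragment_db or not neutral_loss_db:
        raise ValueError("fragment and neutral-loss databases must be nonempty")
    out = FragmentMatches()
    peaks = [mz for mz, _ in spectrum.peaks]
    for name, ref in fragment_db.items():
        tol = tol_ppm * 1e-6 * ref
        if any(abs(p - ref) <= tol for p in peaks):
            out.fragment_hits.append(name)
    prec = spectrum.precursor_mz
    for name, loss in neutral_loss_db.items():
        tol = tol_ppm * 1e-6 * prec
        if any(abs((prec - p) - loss) <= tol for p in peaks):
            out.neutral_loss_hits.append(name)
    return out


# ---------------------------------------------------------------------------
# confidence assignment
# ---------------------------------------------------------------------------

def assign_confidence(evidence: EvidenceFlags) -> int:
    """Best (lowest) applicable identification confidence level.

    Decision table:
      L1: authentic-standard RT match + accurate mass + MS2 evidence
      L2: accurate mass + curated-library MS2 match
      L3: formula assigned + in-silico/diagnostic fragment evidence
      L4: formula assigned
      L5: accurate mass only
    """
    e = evidence
    if not e.any():
        raise ValueError("no evidence set; feature is unannotatable")
    if e.rt_standard_match and not e.mass_match:
        raise ValueError("inconsistent flags: rt_standard_match requires mass_match")
    ms2_any = e.ms2_library_match or e.ms2_insilico_fragment_match
    if e.rt_standard_match and e.mass_match and ms2_any:
        return 1
    if e.mass_match and e.ms2_library_match:
        return 2
    if e.formula_assigned and e.ms2_insilico_fragment_match:
        return 3
    if e.formula_assigned:
        return 4
    if e.mass_match:
        return 5
    raise ValueError("no applicable level: evidence lacks both an accurate "
                     "mass and a formula assignment")


def retain_confident(annotations, max_level: int = 3):
    """Keep annotations at or below ``max_level``; report per-level counts."""
    counts = {lvl: 0 for lvl in range(1, 6)}
    for a in annotations:
        counts[a.confidence] += 1
    kept = [a for a in annotations if a.confidence <= max_level]
    return kept, counts
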