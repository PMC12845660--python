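"""Exact-mass arithmetic, Kendrick analytics and formula enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fluorscreen import chem
from fluorscreen.chem import (CF2_EXACT, KENDRICK_BASES, enumerate_formulas,
                              find_homologous_series, kendrick, mass_defect,
                              monoisotopic_mass, parse_formula,
                              pfas_plot_coords)


class _F:
    def __init__(self, fid, mz):
        self.feature_id = fid
        self.mz = mz


# expected values computed by summing IUPAC/NIST most-abundant-isotope
# atomic masses (C 12, H 1.0078250, F 18.9984032, O 15.9949146)
@pytest.mark.parametrize("formula, expected", [
    ("C2HF3O2", 113.99286),   # trifluoroacetic acid
    ("CF2", 49.9968066),
    ("C8HF15O2", 413.97370),  # PFOA
])
def test_monoisotopic_mass_reference_values(formula, expected):
    assert monoisotopic_mass(formula) == pytest.approx(expected, abs=1e-5)


def test_monoisotopic_mass_rejects_empty_and_unknown():
    with pytest.raises(chem.FormulaError):
        monoisotopic_mass("")
    with pytest.raises(chem.FormulaError):
        monoisotopic_mass("C2Xe3")


def test_parse_formula_counts_and_hill_rendering():
    counts = parse_formula("C8H5F13O3S")
    assert counts == {"C": 8, "H": 5, "F": 13, "O": 3, "S": 1}
    assert chem.format_formula(counts) == "C8H5F13O3S"


@pytest.mark.parametrize("m, expected", [
    (49.9968066, -0.0031934),
    (100.0, 0.0),
    (413.9735, -0.0265),
])
def test_mass_defect(m, expected):
    assert mass_defect(m) == pytest.approx(expected, abs=1e-7)


def test_mass_defect_requires_positive_mass():
    with pytest.raises(ValueError):
        mass_defect(-1.0)


def test_kendrick_base_unit_maps_to_nominal():
    k = kendrick(CF2_EXACT, "CF2")
    assert k.kendrick_mass == pytest.approx(50.0, abs=1e-9)
    assert k.kmd == pytest.approx(0.0, abs=1e-9)


def test_cf2_homologs_share_kmd():
    pfba = monoisotopic_mass("C4HF7O2")
    pfpea = monoisotopic_mass("C5HF9O2")
    assert pfpea - pfba == pytest.approx(CF2_EXACT, abs=1e-9)
    assert kendrick(pfba, "CF2").kmd == pytest.approx(
        kendrick(pfpea, "CF2").kmd, abs=1e-6)


def test_kmd_not_linear_in_mass():
    # doubling the mass wraps the Kendrick fractional part past the
    # rounding boundary, so the KMD is not simply doubled
    m = 100.3
    assert kendrick(2 * m, "CF2").kmd != pytest.approx(
        2 * kendrick(m, "CF2").kmd, abs=1e-3)


@given(st.integers(min_value=1, max_value=8),
       st.integers(min_value=1, max_value=6))
def test_kmd_invariant_under_cf2_insertion(n_start, k):
    """kmd(f) == kmd(f + k*CF2) for any formula and k >= 1."""
    base = {"C": n_start, "H": 1, "F": 2 * n_start - 1, "O": 2}
    m0 = monoisotopic_mass(base)
    m1 = m0 + k * CF2_EXACT
    assert kendrick(m0, "CF2").kmd == pytest.approx(
        kendrick(m1, "CF2").kmd, abs=1e-6)


def test_kendrick_roundtrip_consistency():
    for m in (113.99286, 413.97358, 250.1):
        k = kendrick(m, "CH2")
        assert k.kmd == pytest.approx(round(k.kendrick_mass) - k.kendrick_mass,
                                      abs=1e-9)
        assert k.nominal_km == round(k.kendrick_mass)


def test_pfas_plot_coords():
    assert pfas_plot_coords(100.0, 2) == chem.PfasPlotCoords(0.0, 50.0)
    tfa = monoisotopic_mass("C2HF3O2")
    c = pfas_plot_coords(tfa, 2)
    assert c.md_per_c == pytest.approx(-0.00357, abs=1e-5)
    assert c.mz_per_c == pytest.approx(56.99643, abs=1e-5)
    with pytest.raises(ValueError):
        pfas_plot_coords(100.0, 0)


# ---------------------------------------------------------------------------
# homologous series
# ---------------------------------------------------------------------------

def _pfca_ions(n_lo=4, n_hi=9):
    return [chem.monoisotopic_mass({"C": n, "H": 1, "F": 2 * n - 1, "O": 2})
            - chem.PROTON_MASS for n in range(n_lo, n_hi + 1)]


def test_planted_pfca_series_recovered():
    feats = [_F(f"p{i}", mz) for i, mz in enumerate(_pfca_ions())]
    series = find_homologous_series(feats, "CF2")
    assert len(series) == 1
    assert sorted(series[0].member_feature_ids) == sorted(f.feature_id
                                                          for f in feats)


def test_no_series_without_cf2_spacing():
    feats = [_F("a", 100.000), _F("b", 163.000)]
    assert find_homologous_series(feats, "CF2") == []


def _series_oracle(feats, base, kmd_tol, unit_tol_ppm, max_units=10):
    """O(n^3) boolean-matrix closure oracle for series detection."""
    n = len(feats)
    feats = sorted(feats, key=lambda f: f.mz)
    kmds = [kendrick(f.mz, base).kmd for f in feats]
    exact = KENDRICK_BASES[base][0]
    prox = [[abs(kmds[i] - kmds[j]) <= kmd_tol for j in range(n)]
            for i in range(n)]
    for k in range(n):  # transitive closure of kmd proximity
        for i in range(n):
            for j in range(n):
                prox[i][j] = prox[i][j] or (prox[i][k] and prox[k][j])
    out = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        cluster = [j for j in range(n) if prox[i][j]]
        seen.update(cluster)
        link = {(a, b): False for a in cluster for b in cluster}
        for a, b in itertools.permutations(cluster, 2):
            dm = abs(feats[a].mz - feats[b].mz)
            tol = unit_tol_ppm * 1e-6 * max(feats[a].mz, feats[b].mz)
            link[(a, b)] = any(abs(dm - k * exact) <= tol
                               for k in range(1, max_units + 1))
        for a in cluster:
            link[(a, a)] = True
        for k in cluster:
            for a in cluster:
                for b in cluster:
                    link[(a, b)] = link[(a, b)] or (link[(a, k)]
                                                    and link[(k, b)])
        comp_seen = set()
        for a in cluster:
            if a in comp_seen:
                continue
            comp = sorted(b for b in cluster if link[(a, b)])
            comp_seen.update(comp)
            if len(comp) >= 2:
                out.append(frozenset(feats[b].feature_id for b in comp))
    return set(out)


def test_series_matches_bruteforce_oracle_on_random_features():
    rng = np.random.default_rng(5)
    for trial in range(10):
        mzs = list(rng.uniform(100, 500, size=12))
        # plant a 3-member CF2 chain to make nonempty cases common
        m0 = float(rng.uniform(150, 250))
        mzs += [m0, m0 + CF2_EXACT, m0 + 2 * CF2_EXACT]
        feats = [_F(f"f{i}", m) for i, m in enumerate(mzs)]
        got = {frozenset(s.member_feature_ids)
               for s in find_homologous_series(feats, "CF2")}
        want = _series_oracle(feats, "CF2", 0.002, 5.0)
        assert got == want


def test_series_with_decoys_recovers_only_planted(default_design):
    """On the full synthetic study, every detected series is a planted
    compound family and every planted family is detected; no decoy or
    background feature ever joins a series."""
    from fluorscreen.simulate import gen_feature_table
    feats, _, _, _, truth = gen_feature_table(default_design)
    series = find_homologous_series(feats, "CF2")
    tf = truth["features"]
    got = {frozenset(tf[i]["compound"] for i in s.member_feature_ids
                     if tf[i]["kind"] == "pfas")
           for s in series}
    for s in series:  # no decoy/background contamination
        assert all(tf[i]["kind"] == "pfas" for i in s.member_feature_ids)
    want = {frozenset(tf[i]["compound"] for i in ids)
            for ids in truth["series"].values()}
    assert got == want


# ---------------------------------------------------------------------------
# formula enumeration
# ---------------------------------------------------------------------------

def _enum_oracle(mz, tol_ppm, elements, max_counts):
    """Unfiltered brute force over the full count grid."""
    neutral = mz + chem.PROTON_MASS
    tol = tol_ppm * 1e-6 * neutral
    hits = []
    ranges = [range(max_counts.get(el, 0) + 1) for el in elements]
    for combo in itertools.product(*ranges):
        counts = {el: c for el, c in zip(elements, combo) if c > 0}
        if not counts:
            continue
        if abs(monoisotopic_mass(counts) - neutral) <= tol:
            hits.append(counts)
    return hits


def test_enumerate_contains_tfa():
    mz = monoisotopic_mass("C2HF3O2") - chem.PROTON_MASS
    res = enumerate_formulas(mz, elements=("C", "H", "F", "O"),
                             max_counts={"C": 20, "H": 20, "F": 20, "O": 20})
    assert {"C": 2, "H": 1, "F": 3, "O": 2} in [f for f, _ in res]


def test_enumerate_exact_tolerance_returns_generator():
    mz = monoisotopic_mass("C2HF3O2") - chem.PROTON_MASS
    res = enumerate_formulas(mz, tol_ppm=1e-6,
                             elements=("C", "H", "F", "O"),
                             max_counts={"C": 6, "H": 6, "F": 6, "O": 6})
    assert [f for f, _ in res] == [{"C": 2, "H": 1, "F": 3, "O": 2}]


def test_enumerate_zero_bounds_empty():
    res = enumerate_formulas(200.0, elements=("C", "H", "F", "O"),
                             max_counts={"C": 0, "H": 0, "F": 0, "O": 0})
    assert res == []


def test_enumerate_empty_element_set_errors():
    with pytest.raises(ValueError):
        enumerate_formulas(200.0, elements=())


@pytest.mark.parametrize("target", ["C2HF3O2", "C4HF7O2", "C3H6O3"])
def test_enumerate_equals_bruteforce_small_window(target):
    elements = ("C", "H", "F", "O")
    bounds = {"C": 10, "H": 12, "F": 10, "O": 6}
    mz = monoisotopic_mass(target) - chem.PROTON_MASS
    got = enumerate_formulas(mz, tol_ppm=20, elements=elements,
                             max_counts=bounds, heuristic_filter=None)
    want = _enum_oracle(mz, 20, elements, bounds)
    assert sorted(map(chem.format_formula, (f for f, _ in got))) \
        == sorted(map(chem.format_formula, want))
    # sorted by |ppm error|
    errs = [abs(e) for _, e in got]
    assert errs == sorted(errs)
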