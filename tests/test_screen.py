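"""Grouping, blank subtraction, suspect matching, isotope scoring,
fragment matching and confidence assignment."""

import itertools

import numpy as np
import pytest

from fluorscreen import chem, databases, screen
from fluorscreen.msio import Feature, FragmentSpectrum, SuspectEntry
from fluorscreen.screen import (Annotation, EvidenceFlags, assign_confidence,
                                blank_subtract, group_across_samples,
                                match_fragments, match_suspects,
                                retain_confident, score_isotope_pattern)


def _f(fid, sample, mz, rt, area=1000.0, snr=10.0):
    return Feature(fid, sample, mz, rt, area, snr)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_two_features_within_tolerance_group_together():
    feats = [_f("a", "S1", 400.0000, 2.00), _f("b", "S2", 400.0008, 2.10)]
    groups = group_across_samples(feats)
    assert len(groups) == 1


def test_rt_separation_splits_groups():
    feats = [_f("a", "S1", 400.0, 2.0), _f("b", "S2", 400.0, 2.5)]
    assert len(group_across_samples(feats)) == 2


def _grouping_oracle(feats, rt_tol, ppm):
    n = len(feats)
    adj = [[False] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        if (abs(feats[i].rt - feats[j].rt) <= rt_tol
                and abs(feats[i].mz - feats[j].mz)
                <= ppm * 1e-6 * max(feats[i].mz, feats[j].mz)):
            adj[i][j] = adj[j][i] = True
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(j for j in range(n) if adj[k][j] and j not in comp)
        seen |= comp
        comps.append(frozenset(feats[k].feature_id for k in comp))
    return set(comps)


def test_grouping_equals_bruteforce_closure():
    rng = np.random.default_rng(17)
    for _ in range(10):
        feats = [_f(f"f{i}", f"S{i % 4}",
                    float(rng.choice([200, 200.0005, 200.001, 300, 300.0009])),
                    float(rng.choice([1.0, 1.1, 1.25, 2.0])))
                 for i in range(30)]
        got = {frozenset(g.feature_ids)
               for g in group_across_samples(feats)}
        assert got == _grouping_oracle(feats, 0.2, 5.0)


def test_consensus_mz_is_intensity_weighted():
    feats = [_f("a", "S1", 400.0000, 2.0, area=100.0),
             _f("b", "S2", 400.0010, 2.0, area=300.0)]
    g = group_across_samples(feats)[0]
    assert g.consensus_mz == pytest.approx((100 * 400.0 + 300 * 400.001) / 400)


# ---------------------------------------------------------------------------
# blank subtraction
# ---------------------------------------------------------------------------

def _group(gid, mz, rt, area):
    return screen.FeatureGroup(gid, [_f(f"g{gid}", "S1", mz, rt, area=area)])


@pytest.mark.parametrize("sample_area, blank_area, is_background", [
    (1000.0, 250.0, True),   # ratio 4 <= 5 -> background
    (1000.0, 100.0, False),  # ratio 10 -> retained
    (1000.0, 200.0, True),   # ratio exactly 5 -> background (boundary)
])
def test_blank_subtract_ratio_rule(sample_area, blank_area, is_background):
    g = _group(0, 300.0, 2.0, sample_area)
    b = _group(1, 300.0, 2.0, blank_area)
    retained, background = blank_subtract([g], [b])
    assert (g in background) is is_background
    assert (g in retained) is not is_background


def test_blank_subtract_no_blank_match_retains():
    g = _group(0, 300.0, 2.0, 1000.0)
    b = _group(1, 400.0, 2.0, 1e6)
    retained, background = blank_subtract([g], [b])
    assert retained == [g] and background == []


# ---------------------------------------------------------------------------
# suspect matching
# ---------------------------------------------------------------------------

def _suspect(name, formula, rt=None, lib=False):
    return SuspectEntry(name, formula, chem.monoisotopic_mass(formula),
                        f"ID_{name}", "PFCA", rt, lib)


def test_match_suspects_ppm_window():
    theo = 412.96640
    neutral = theo + chem.PROTON_MASS
    sus = SuspectEntry("X", "C8HF15O2", chem.monoisotopic_mass("C8HF15O2"),
                       "S1", "PFCA")
    # use a synthetic suspect at exactly the stated theoretical ion mass
    sus.neutral_mass = neutral
    g_hit = _group(0, 412.96800, 2.0, 1.0)
    g_miss = _group(1, 412.97100, 2.0, 1.0)
    hits = match_suspects([g_hit, g_miss], [sus], tol_ppm=5.0)
    assert len(hits) == 1
    _, _, ppm = hits[0]
    assert ppm == pytest.approx(3.87, abs=0.05)


def test_match_suspects_zero_tolerance_exact():
    sus = _suspect("TFA", "C2HF3O2")
    g = _group(0, sus.neutral_mass - chem.PROTON_MASS, 0.6, 1.0)
    hits = match_suspects([g], [sus], tol_ppm=0.0)
    assert len(hits) == 1 and hits[0][2] == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# isotope pattern scoring
# ---------------------------------------------------------------------------

def test_isotope_self_match_scores_100():
    env = screen.theoretical_envelope("C8HF17O3S")
    mono = chem.monoisotopic_mass("C8HF17O3S")
    obs = [(mono + off, rel) for off, rel in env]
    assert score_isotope_pattern(obs, "C8HF17O3S") == pytest.approx(100.0)


def test_chlorine_pattern_discriminates():
    """A C-only observed envelope against a one-Cl formula misses the
    ~32% M+2 isotopologue and falls below the 80% threshold."""
    obs_formula = "C6H12O6"
    env = screen.theoretical_envelope(obs_formula)
    mono = chem.monoisotopic_mass(obs_formula)
    obs = [(mono + off, rel) for off, rel in env]
    assert score_isotope_pattern(obs, "C6H11ClO5") < 80.0


def test_uniform_30pct_perturbation_stays_above_threshold():
    env = screen.theoretical_envelope("C8HF17O3S")
    mono = chem.monoisotopic_mass("C8HF17O3S")
    scale = max(rel * 1.3 for _, rel in env)
    obs = [(mono + off, rel * 1.3 / scale) for off, rel in env]
    assert score_isotope_pattern(obs, "C8HF17O3S") >= 80.0


def test_isotope_score_rejects_empty():
    with pytest.raises(ValueError):
        score_isotope_pattern([], "C2HF3O2")


# ---------------------------------------------------------------------------
# fragment matching
# ---------------------------------------------------------------------------

def test_cf3_fragment_hit():
    spec = FragmentSpectrum("s", 412.9664, [(68.9952, 100.0)])
    m = match_fragments(spec, databases.DIAGNOSTIC_FRAGMENTS,
                        databases.NEUTRAL_LOSSES)
    assert "CF3-" in m.fragment_hits


def test_no_hits_when_nothing_matches():
    spec = FragmentSpectrum("s", 500.0, [(123.4567, 10.0)])
    m = match_fragments(spec, databases.DIAGNOSTIC_FRAGMENTS,
                        databases.NEUTRAL_LOSSES)
    assert not m.any()


def test_co2_neutral_loss_hit():
    prec = 412.9664
    co2 = chem.monoisotopic_mass("CO2")  # 43.98983
    spec = FragmentSpectrum("s", prec, [(prec - co2, 100.0)])
    m = match_fragments(spec, databases.DIAGNOSTIC_FRAGMENTS,
                        databases.NEUTRAL_LOSSES)
    assert "CO2" in m.neutral_loss_hits


# ---------------------------------------------------------------------------
# confidence
# ---------------------------------------------------------------------------

def _confidence_oracle(mass, formula, lib, insilico, rt):
    """Independent rule-table coding of the identification levels."""
    ms2 = lib or insilico
    table = [
        (rt and mass and ms2, 1),
        (mass and lib, 2),
        (formula and insilico, 3),
        (formula, 4),
        (mass, 5),
    ]
    for cond, lvl in table:
        if cond:
            return lvl
    return None


def test_confidence_matches_truth_table_all_32():
    for flags in itertools.product([False, True], repeat=5):
        mass, formula, lib, insilico, rt = flags
        ev = EvidenceFlags(mass, formula, lib, insilico, rt)
        want = _confidence_oracle(*flags)
        if (rt and not mass) or want is None:
            # inconsistent flags, or evidence with no applicable level
            with pytest.raises(ValueError):
                assign_confidence(ev)
        else:
            assert assign_confidence(ev) == want


def test_confidence_monotone_in_evidence():
    """Setting any additional flag never worsens (increases) the level."""
    names = ["mass_match", "formula_assigned", "ms2_library_match",
             "ms2_insilico_fragment_match", "rt_standard_match"]
    for flags in itertools.product([False, True], repeat=5):
        ev = EvidenceFlags(**dict(zip(names, flags)))
        if not ev.any() or (ev.rt_standard_match and not ev.mass_match):
            continue
        try:
            base = assign_confidence(ev)
        except ValueError:  # unannotatable evidence combination
            continue
        for k, name in enumerate(names):
            if flags[k]:
                continue
            more = list(flags)
            more[k] = True
            ev2 = EvidenceFlags(**dict(zip(names, more)))
            if ev2.rt_standard_match and not ev2.mass_match:
                continue
            assert assign_confidence(ev2) <= base


def test_retain_confident():
    anns = [Annotation("g", "s", 0.0, None, EvidenceFlags(mass_match=True),
                       lvl) for lvl in (1, 2, 3, 4, 5)]
    kept, counts = retain_confident(anns)
    assert sorted(a.confidence for a in kept) == [1, 2, 3]
    assert counts == {1: 1, 2: 1, 3: 1, 4: 1, 5: 1}
    kept5, _ = retain_confident(anns, max_level=5)
    assert len(kept5) == 5
    all5 = [Annotation("g", "s", 0.0, None, EvidenceFlags(mass_match=True), 5)]
    assert retain_confident(all5)[0] == []
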