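"""Exact-mass arithmetic for PFAS screening.

Monoisotopic masses, standard and Kendrick mass defects (CF2 / CH2 bases),
carbon-normalized "PFAS plot" coordinates, homologous-series detection and
constrained molecular-formula enumeration.

Conventions
-----------
* All masses in Da; all ions singly charged [M-H]- (negative electrospray).
* Kendrick mass defect is ``round(KM) - KM`` so that members of a CF2
  homologous series share an identical KMD.
* Nominal repeat-unit masses are 50 (CF2) and 14 (CH2).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

#: Elements admitted in formulas (negative-mode PFAS screening scope).
SCHEMA_ELEMENTS = ("C", "H", "F", "O", "S", "P", "N", "Cl", "Br")

#: Monoisotopic (most abundant isotope) atomic masses, Da.
MONO_MASS = {el: _pmass.nist_mass[el][0][0] for el in SCHEMA_ELEMENTS}

PROTON_MASS = 1.007276  # Da, charge carrier for [M-H]-
ELECTRON_MASS = 0.000548579909  # Da

CF2_EXACT = MONO_MASS["C"] + 2 * MONO_MASS["F"]
CH2_EXACT = MONO_MASS["C"] + 2 * MONO_MASS["H"]

#: base unit -> (exact mass, nominal mass)
KENDRICK_BASES = {"CF2": (CF2_EXACT, 50), "CH2": (CH2_EXACT, 14)}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or out-of-schema elemental formulas."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string (e.g. ``C2HF3O2``) into counts.

    Only elements in :data:`SCHEMA_ELEMENTS` are accepted; counts must be
    positive integers.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in SCHEMA_ELEMENTS:
            raise FormulaError(f"element {el!r} outside schema {SCHEMA_ELEMENTS}")
        if n <= 0:
            raise FormulaError(f"non-positive count for {el} in {text!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(text.strip()):
        raise FormulaError(f"trailing garbage in formula {text!r}")
    if not counts:
        raise FormulaError(f"no elements in formula {text!r}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render counts in Hill order (C, H, then alphabetical)."""
    order = ["C", "H"] + sorted(el for el in counts if el not in ("C", "H"))
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) of an elemental formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if not counts:
        raise FormulaError("empty formula")
    try:
        return sum(MONO_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r}") from exc


def ion_mz(formula: str | dict[str, int], charge: int = -1) -> float:
    """m/z of the deprotonated ion [M-H]- (the only species considered)."""
    if charge != -1:
        raise ValueError("only singly charged [M-H]- ions are supported")
    return monoisotopic_mass(formula) - PROTON_MASS


def mass_defect(m: float) -> float:
    """Standard mass defect: m - round(m), in [-0.5, 0.5)."""
    if m <= 0:
        raise ValueError("mass must be positive")
    return m - round(m)


@dataclass(frozen=True)
class KendrickCoords:
    base: str
    kendrick_mass: float
    kmd: float
    nominal_km: int


def kendrick(m: float, base: str = "CF2") -> KendrickCoords:
    """Kendrick mass and mass defect for the CF2 or CH2 repeat-unit base.

    ``KM = m * nominal / exact``; ``KMD = round(KM) - KM``. Homologs
    differing by whole repeat units share the same KMD.
    """
    if m <= 0:
        raise ValueError("mass must be positive")
    try:
        exact, nominal = KENDRICK_BASES[base]
    except KeyError:
        raise ValueError(f"unknown Kendrick base {base!r}; use CF2 or CH2")
    km = m * nominal / exact
    return KendrickCoords(base=base, kendrick_mass=km, kmd=round(km) - km,
                          nominal_km=round(km))


@dataclass(frozen=True)
class PfasPlotCoords:
    """Carbon-normalized coordinates used to separate PFAS from CH-rich organics."""
    md_per_c: float
    mz_per_c: float


def pfas_plot_coords(m: float, n_carbon: int) -> PfasPlotCoords:
    """Mass defect and mass divided by carbon count ('PFAS plot' axes)."""
    if n_carbon < 1:
        raise ValueError("carbon count must be >= 1")
    return PfasPlotCoords(md_per_c=mass_defect(m) / n_carbon, mz_per_c=m / n_carbon)


@dataclass
class HomologSeries:
    series_id: int
    base_unit: str
    member_feature_ids: list = field(default_factory=list)
    kmd_centroid: float = 0.0


def find_homologous_series(features, base: str = "CF2", kmd_tol: float = 0.002,
                           unit_tol_ppm: float = 5.0, max_units: int = 10):
    """Detect homologous series among features by shared Kendrick mass defect.

    Features are sorted by m/z; KMD agreement within ``kmd_tol`` defines
    candidate clusters (transitive closure), within which members are linked
    when their mass difference is an integer multiple (1..``max_units``) of
    the repeat-unit exact mass within ``unit_tol_ppm`` of the larger mass.
    Connected components with >= 2 members become series.

    ``features`` may be any objects with ``feature_id`` and ``mz`` attributes.
    """
    feats = sorted(features, key=lambda f: f.mz)
    n = len(feats)
    if n < 2:
        return []
    exact, _ = KENDRICK_BASES[base]
    kmds = [kendrick(f.mz, base).kmd for f in feats]

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # KMD clusters by transitive closure
    for i in range(n):
        for j in range(i + 1, n):
            if abs(kmds[i] - kmds[j]) <= kmd_tol:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    series_out = []
    sid = 0
    for members in clusters.values():
        if len(members) < 2:
            continue
        # link by repeat-unit spacing within the cluster
        sub_parent = {i: i for i in members}

        def sfind(i):
            while sub_parent[i] != i:
                sub_parent[i] = sub_parent[sub_parent[i]]
                i = sub_parent[i]
            return i

        for a, b in itertools.combinations(members, 2):
            dm = abs(feats[a].mz - feats[b].mz)
            tol = unit_tol_ppm * 1e-6 * max(feats[a].mz, feats[b].mz)
            for k in range(1, max_units + 1):
                if abs(dm - k * exact) <= tol:
                    ra, rb = sfind(a), sfind(b)
                    if ra != rb:
                        sub_parent[rb] = ra
                    break
        comps: dict[int, list[int]] = {}
        for i in members:
            comps.setdefault(sfind(i), []).append(i)
        for comp in comps.values():
            if len(comp) < 2:
                continue
            comp.sort(key=lambda i: feats[i].mz)
            series_out.append(HomologSeries(
                series_id=sid, base_unit=base,
                member_feature_ids=[feats[i].feature_id for i in comp],
                kmd_centroid=sum(kmds[i] for i in comp) / len(comp)))
            sid += 1
    return series_out


def rdbe(counts: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents (halogens count as hydrogen)."""
    c = counts.get("C", 0)
    h = (counts.get("H", 0) + counts.get("F", 0) + counts.get("Cl", 0)
         + counts.get("Br", 0))
    n = counts.get("N", 0) + counts.get("P", 0)
    return c + 1 + n / 2 - h / 2


def _default_filters(counts: dict[str, int]) -> bool:
    """Heuristic plausibility filters biased toward PFAS-like compositions.

    Approximations chosen for this package, not a reconstruction of any
    vendor rule set: RDBE >= 0; F <= 2C+1; for acyclic C/H/F/O species
    H+F <= 2C+2.
    """
    c = counts.get("C", 0)
    if c == 0:
        return False
    if rdbe(counts) < 0:
        return False
    if counts.get("F", 0) > 2 * c + 1:
        return False
    if set(counts) <= {"C", "H", "F", "O"}:
        if counts.get("H", 0) + counts.get("F", 0) > 2 * c + 2:
            return False
    return True


def enumerate_formulas(mz: float, charge: int = -1, tol_ppm: float = 5.0,
                       elements=("C", "H", "F", "O", "S"),
                       max_counts: dict[str, int] | None = None,
                       heuristic_filter=_default_filters):
    """Enumerate elemental formulas matching an [M-H]- m/z within a ppm window.

    Exhaustive bounded depth-first search over element counts with mass
    pruning; candidates pass ``heuristic_filter`` (set to ``None`` to
    disable) and are returned sorted by absolute ppm error.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if not elements:
        raise ValueError("empty element set")
    for el in elements:
        if el not in SCHEMA_ELEMENTS:
            raise FormulaError(f"element {el!r} outside schema")
    if charge != -1:
        raise ValueError("only charge -1 supported")
    neutral = mz + PROTON_MASS
    tol = tol_ppm * 1e-6 * neutral
    if max_counts is None:
        max_counts = {el: int((neutral + tol) // MONO_MASS[el]) for el in elements}
    order = sorted(elements, key=lambda e: -MONO_MASS[e])
    results: list[tuple[float, dict[str, int]]] = []

    def emit(counts: dict[str, int], remaining: float):
        cand = {el: n for el, n in counts.items() if n > 0}
        if not cand:
            return
        if heuristic_filter is None or heuristic_filter(cand):
            err = remaining / neutral * 1e6  # measured - theoretical, ppm
            results.append((err, cand))

    def recurse(idx: int, counts: dict[str, int], remaining: float):
        el = order[idx]
        m_el = MONO_MASS[el]
        nmax = min(max_counts.get(el, 0), int((remaining + tol) // m_el))
        if idx == len(order) - 1:
            # lightest element: solve for the count directly
            lo = max(0, int((remaining - tol) // m_el))
            for cnt in range(lo, nmax + 1):
                rem = remaining - cnt * m_el
                if abs(rem) <= tol:
                    counts[el] = cnt
                    emit(counts, rem)
            counts.pop(el, None)
            return
        for cnt in range(nmax + 1):
            rem = remaining - cnt * m_el
            if rem < -tol:
                break
            counts[el] = cnt
            recurse(idx + 1, counts, rem)
        counts.pop(el, None)

    recurse(0, {}, neutral)
    results.sort(key=lambda t: abs(t[0]))
    return [(cand, err) for err, cand in results]
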