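"""Isotope-dilution quantification and surrogate-RRF semi-quantification.

Targets with authentic native + isotopically labeled standards are
quantified through relative response factors (RRFs) fitted from internal
calibration; compounds found only by suspect screening are semi-quantified
with the RRF of the most similar target (retention time, then subclass,
then neutral mass). QC gates follow the acquisition rules: S/N > 3,
qualifier/quantifier ion-ratio uncertainty < 30 %, and RT deviation within
+/-0.1 min for standard-confirmed targets. The method quantification limit
(MQL) is anchored at the concentration producing S/N = 10, assuming S/N
proportional to concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibrationLevel:
    conc_native: float
    conc_labeled: float
    area_native: float
    area_labeled: float


@dataclass
class CalibrationCurve:
    native_id: str
    labeled_id: str
    levels: list[CalibrationLevel]


@dataclass
class RRFRecord:
    native_id: str
    labeled_id: str
    rrf: float
    fit_r2: float


@dataclass
class ConcentrationRecord:
    sample_id: str
    compound_id: str
    conc: float  # ng/L
    mql: float | None = None
    status: str = "quantified"  # quantified|semi_quantified|below_mql|not_detected
    qc_flags: set = field(default_factory=set)
    snr: float = 0.0


def fit_rrf(curve: CalibrationCurve) -> RRFRecord:
    """Least-squares slope through the origin of area ratio vs conc ratio.

    RRF = slope of (A_native/A_labeled) against (C_native/C_labeled).
    """
    if len(curve.levels) < 3:
        raise ValueError(f"{curve.native_id}: need >= 3 calibration levels")
    x = np.array([lv.conc_native / lv.conc_labeled for lv in curve.levels])
    y = np.array([lv.area_native / lv.area_labeled for lv in curve.levels])
    sxx = float(x @ x)
    if sxx == 0 or not np.any(y != 0):
        raise ValueError(f"{curve.native_id}: degenerate calibration")
    slope = float(x @ y) / sxx
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RRFRecord(curve.native_id, curve.labeled_id, slope, r2)


def quantify_target(area: float, is_area: float, is_conc: float,
                    rrf: float) -> float:
    """Concentration (ng/L) by isotope dilution: (A/A_IS) * C_IS / RRF."""
    if is_area <= 0:
        raise ValueError("internal-standard area must be > 0")
    if rrf <= 0:
        raise ValueError("rrf must be > 0")
    return (area / is_area) * is_conc / rrf


def assign_surrogate(ssa_rt: float, ssa_subclass: str, ssa_mass: float,
                     targets) -> str:
    """Pick the surrogate target for an SSA compound.

    ``targets`` is an iterable of objects with ``name``/``compound_id``,
    ``rt``, ``subclass`` and ``neutral_mass`` attributes. Choice minimizes
    |dRT|; ties prefer the same subclass, then the smallest |d neutral mass|.
    """
    cands = list(targets)
    if not cands:
        raise ValueError("no targets with an RRF available")

    def ident(t):
        return getattr(t, "compound_id", None) or t.name

    def key(t):
        return (round(abs(t.rt - ssa_rt), 9),
                0 if t.subclass == ssa_subclass else 1,
                abs(t.neutral_mass - ssa_mass),
                ident(t))

    return ident(min(cands, key=key))


def qc_gate(snr: float, ion_ratio_uncertainty: float, rt_dev: float,
            is_target: bool):
    """Apply the quantification QC rules; returns (passed, flags).

    Fails when S/N <= 3, ion-ratio uncertainty >= 0.30, or, for
    standard-confirmed targets only, |RT deviation| > 0.1 min. Boundary
    readings are literal: S/N exactly 3 fails, ratio exactly 30 % fails,
    RT deviation exactly 0.1 min passes.
    """
    for v in (snr, ion_ratio_uncertainty, rt_dev):
        if not math.isfinite(v):
            raise ValueError("QC inputs must be finite")
    flags = set()
    if not snr > 3:
        flags.add("low_snr")
    if not ion_ratio_uncertainty < 0.30:
        flags.add("ion_ratio")
    if is_target and abs(rt_dev) > 0.1:
        flags.add("rt_drift")
    return (not flags, flags)


def estimate_mql(records) -> float:
    """MQL (ng/L) from accepted records: min over conc * (10 / S/N).

    Assumes S/N scales linearly with concentration, anchoring the MQL at
    the concentration that would produce S/N = 10.
    """
    usable = [r for r in records if r.snr > 0 and r.conc > 0]
    if not usable:
        raise ValueError("no records with positive S/N to anchor the MQL")
    return min(r.conc * 10.0 / r.snr for r in usable)


def blank_correct(conc: float, blank_conc: float) -> float:
    """Subtract the procedural-blank concentration, floored at zero."""
    if conc < 0 or blank_conc < 0:
        raise ValueError("concentrations must be >= 0")
    return max(conc - blank_conc, 0.0)
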