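"""PFOA-equivalent environmental-quality-standard (EQS) compliance screening.

Concentrations are aggregated per sample under a lower-bound convention
(non-detects contribute zero), converted to PFOA equivalents with
compound-specific relative potency factors (RPFs), and compared against
the proposed EU group EQS of 4.4 ng/L for the sum of PFOA equivalents and
the PFOS standards for inland surface waters (annual average 0.65 ng/L,
maximum allowable concentration 36 ug/L = 36000 ng/L). A value exactly at
a standard does not exceed it (strict comparison).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_EQS_NG_L = 4.4
PFOS_AA_EQS_NG_L = 0.65
PFOS_MAC_EQS_NG_L = 36000.0

_ZERO_STATUSES = {"not_detected", "below_mql"}


@dataclass
class EqsResult:
    sample_id: str
    sum_pfas_quant: float
    sum_pfoa_eq: float
    exceeds_group_eqs: bool
    pfos_conc: float
    exceeds_pfos_aa: bool
    exceeds_pfos_mac: bool
    pfoa_eq_contributions: dict[str, float] = field(default_factory=dict)


def _effective_conc(record) -> float:
    if record.status in _ZERO_STATUSES:
        return 0.0
    return record.conc


def sum_pfas(records) -> float:
    """Lower-bound sum of concentrations for one sample (ng/L)."""
    return float(sum(_effective_conc(r) for r in records))


def pfoa_equivalents(records, rpf_table: dict[str, float]):
    """Per-compound and summed PFOA equivalents for one sample.

    PFOAeq_i = conc_i * rpf_i. Compounds without an RPF are excluded with
    a warning. Returns (per_compound dict, total, fractional contributions).
    """
    per = {}
    for r in records:
        c = _effective_conc(r)
        if r.compound_id not in rpf_table:
            if c > 0:
                warnings.warn(f"no RPF for {r.compound_id}; excluded from "
                              "PFOA-equivalent sum", stacklevel=2)
            continue
        per[r.compound_id] = per.get(r.compound_id, 0.0) + c * rpf_table[r.compound_id]
    total = float(sum(per.values()))
    contrib = ({k: v / total for k, v in per.items()} if total > 0
               else {k: 0.0 for k in per})
    return per, total, contrib


def check_eqs(sample_id: str, records, rpf_table: dict[str, float],
              pfos_id: str = "PFOS") -> EqsResult:
    """Full per-sample compliance outcome against group and PFOS standards."""
    total_pfas = sum_pfas(records)
    _, total_eq, contrib = pfoa_equivalents(records, rpf_table)
    pfos = float(sum(_effective_conc(r) for r in records
                     if r.compound_id == pfos_id))
    return EqsResult(
        sample_id=sample_id,
        sum_pfas_quant=total_pfas,
        sum_pfoa_eq=total_eq,
        exceeds_group_eqs=total_eq > GROUP_EQS_NG_L,
        pfos_conc=pfos,
        exceeds_pfos_aa=pfos > PFOS_AA_EQS_NG_L,
        exceeds_pfos_mac=pfos > PFOS_MAC_EQS_NG_L,
        pfoa_eq_contributions=contrib,
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def river_summary(eqs_results, meta) -> pd.DataFrame:
    """Per-water-body mean/sd/min/max of sum-PFAS and sum-PFOAeq.

    Means are over samples (not settlements); sd is the sample standard
    deviation (ddof=1), reported as 0 with ``single_sample=True`` for
    water bodies with one sample. Values are full precision; round at the
    presentation layer with :func:`round_sig`.
    """
    body_of = {m.sample_id: m.water_body for m in meta if not m.is_blank}
    rows = []
    by_body: dict[str, list] = {}
    for r in eqs_results:
        if r.sample_id not in body_of:
            raise KeyError(f"sample {r.sample_id} missing from metadata")
        by_body.setdefault(body_of[r.sample_id], []).append(r)
    for body in sorted(by_body):
        rs = by_body[body]
        for col, vals in (("sum_pfas", [x.sum_pfas_quant for x in rs]),
                          ("sum_pfoa_eq", [x.sum_pfoa_eq for x in rs])):
            v = np.asarray(vals, dtype=float)
            single = len(v) == 1
            rows.append({
                "water_body": body, "quantity": col, "n_samples": len(v),
                "mean": float(v.mean()),
                "sd": 0.0 if single else float(v.std(ddof=1)),
                "min": float(v.min()), "max": float(v.max()),
                "single_sample": single,
            })
    return pd.DataFrame(rows)
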