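"""Three-step risk prioritization: ToxPi hazard, exposure, risk index.

Step 1 normalizes 18 persistence/bioaccumulation/toxicity (PBT) attributes
per compound to 0-1 (min-max across compounds, after aligning direction so
higher always means more hazardous) and aggregates them into a
Toxicological Priority Index (ToxPi) with group weights 1/9 per
persistence attribute (3), 1/6 per bioaccumulation attribute (2), 1/18 per
ecotoxicity attribute (3) and 1/60 per human-health attribute (10); the
weights sum to exactly 1, so ToxPi lies in [0, 1].

Step 2 computes exposure as detection frequency times normalized maximum
concentration magnitude, itself min-max normalized across compounds.

Step 3 multiplies ToxPi by normalized exposure into a risk index (RI)
classified as high (RI > 0.1), medium (0.01 < RI <= 0.1), low
(0.001 < RI <= 0.01) or negligible (RI <= 0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

#: attribute schema: group -> ordered attribute names (3/2/3/10)
ATTRIBUTE_SCHEMA: dict[str, list[str]] = {
    "persistence": ["biowin1", "biowin3", "biowin5"],
    "bioaccumulation": ["log_bcf", "log_kow"],
    "ecotoxicity": ["fish_lc50_96h_neglog", "daphnia_lc50_48h_neglog",
                    "algae_ec50_96h_neglog"],
    "human": ["carcinogenicity", "developmental_toxicity", "mutagenicity",
              "endocrine_disruption", "hepatotoxicity", "skin_irritation",
              "eye_irritation", "sensitization", "repeated_dose_toxicity",
              "oral_rat_ld50_neglog"],
}

ALL_ATTRIBUTES = [a for grp in ATTRIBUTE_SCHEMA.values() for a in grp]

#: group weight per attribute, exact rationals
GROUP_WEIGHTS: dict[str, Fraction] = {
    "persistence": Fraction(1, 9),
    "bioaccumulation": Fraction(1, 6),
    "ecotoxicity": Fraction(1, 18),
    "human": Fraction(1, 60),
}

#: attributes where a LOWER raw value means MORE hazardous (reflected
#: before min-max): Biowin biodegradation probabilities.
DEFAULT_REFLECTED = {"biowin1", "biowin3", "biowin5"}

RI_THRESHOLDS = (0.1, 0.01, 0.001)  # high > 0.1 >= medium > 0.01 >= low > 0.001


def attribute_weights() -> dict[str, Fraction]:
    return {a: GROUP_WEIGHTS[grp] for grp, attrs in ATTRIBUTE_SCHEMA.items()
            for a in attrs}


def normalize_attributes(hazard: pd.DataFrame,
                         reflected: set[str] | None = None) -> pd.DataFrame:
    """Min-max normalize each attribute across compounds after direction
    alignment. Constant attributes normalize to all zeros."""
    if len(hazard) < 2:
        raise ValueError("normalization needs >= 2 compounds")
    missing = [a for a in ALL_ATTRIBUTES if a not in hazard.columns]
    if missing:
        raise ValueError(f"hazard table missing attributes {missing}")
    reflected = DEFAULT_REFLECTED if reflected is None else reflected
    out = pd.DataFrame(index=hazard.index)
    for a in ALL_ATTRIBUTES:
        v = hazard[a].astype(float)
        if a in reflected:
            v = -v
        rng = v.max() - v.min()
        out[a] = 0.0 if rng == 0 else (v - v.min()) / rng
    return out


def toxpi_score(normalized: pd.DataFrame,
                weights: dict | None = None) -> pd.Series:
    """Weighted sum of normalized attributes per compound (ToxPi, 0-1)."""
    w = attribute_weights() if weights is None else weights
    if set(w) != set(ALL_ATTRIBUTES):
        raise ValueError("weight vector does not match the 3/2/3/10 schema")
    total = sum(Fraction(x) for x in w.values())
    if total != 1:
        raise ValueError(f"weights sum to {total}, not 1")
    score = sum(float(w[a]) * normalized[a] for a in ALL_ATTRIBUTES)
    return pd.Series(score, index=normalized.index, name="toxpi")


def magnitude(c_i: float, c_min: float, c_max: float) -> float:
    """Normalized concentration magnitude (c_i - c_min)/(c_max - c_min).

    c_i is the maximum observed concentration of the compound; c_min/c_max
    are the min/max of those maxima across compounds.
    """
    if c_max < c_min:
        raise ValueError("c_max must be >= c_min")
    if c_max == c_min:
        warnings.warn("degenerate magnitude range; returning 0", stacklevel=2)
        return 0.0
    return (c_i - c_min) / (c_max - c_min)


def exposure(df: float, mag: float) -> float:
    """Exposure = detection frequency (fraction) x magnitude."""
    if not 0 <= df <= 1:
        raise ValueError("detection frequency must be in [0, 1]")
    return df * mag


def normalize_exposure(values) -> np.ndarray:
    """Min-max normalize exposures across compounds to 0-1."""
    v = np.asarray(list(values), dtype=float)
    rng = v.max() - v.min()
    if rng == 0:
        warnings.warn("degenerate exposure range; returning zeros", stacklevel=2)
        return np.zeros_like(v)
    return (v - v.min()) / rng


def risk_index(toxpi: float, exposure_norm: float) -> float:
    if not (0 <= toxpi <= 1 and 0 <= exposure_norm <= 1):
        raise ValueError("toxpi and exposure_norm must be in [0, 1]")
    return toxpi * exposure_norm


def classify(ri: float) -> str:
    """RI category; boundary values belong to the lower category."""
    hi, med, low = RI_THRESHOLDS
    if ri > hi:
        return "high"
    if ri > med:
        return "medium"
    if ri > low:
        return "low"
    return "negligible"


@dataclass
class RiskRecord:
    compound_id: str
    toxpi: float
    df: float
    c_i: float
    magnitude: float
    exposure: float
    exposure_norm: float
    ri: float
    category: str


def prioritize(hazard: pd.DataFrame, conc_max: dict[str, float],
               detection_freq: dict[str, float],
               reflected: set[str] | None = None) -> pd.DataFrame:
    """Full three-step prioritization.

    ``conc_max``: compound -> maximum observed concentration (ng/L);
    ``detection_freq``: compound -> detection frequency as a fraction.
    Only compounds present in all three inputs are ranked.
    """
    compounds = [c for c in hazard.index if c in conc_max and c in detection_freq]
    if len(compounds) < 2:
        raise ValueError("need >= 2 compounds with hazard, conc and DF")
    hz = hazard.loc[compounds]
    # clip float summation drift; both quantities are mathematically in [0,1]
    toxpi = toxpi_score(normalize_attributes(hz, reflected)).clip(0.0, 1.0)
    cmaxes = np.array([conc_max[c] for c in compounds], dtype=float)
    c_min, c_max = float(cmaxes.min()), float(cmaxes.max())
    mags = np.array([magnitude(c, c_min, c_max) for c in cmaxes])
    dfs = np.array([detection_freq[c] for c in compounds], dtype=float)
    expo = dfs * mags
    expo_n = np.clip(normalize_exposure(expo), 0.0, 1.0)
    rows = []
    for i, c in enumerate(compounds):
        ri = risk_index(float(toxpi[c]), float(expo_n[i]))
        rows.append({"compound_id": c, "toxpi": float(toxpi[c]),
                     "df": float(dfs[i]), "c_i": float(cmaxes[i]),
                     "magnitude": float(mags[i]), "exposure": float(expo[i]),
                     "exposure_norm": float(expo_n[i]), "ri": ri,
                     "category": classify(ri)})
    out = pd.DataFrame(rows).set_index("compound_id")
    return out.sort_values("ri", ascending=False)


def toxpi_group_breakdown(hazard: pd.DataFrame,
                          reflected: set[str] | None = None) -> pd.DataFrame:
    """Per-group weighted contribution to each compound's ToxPi (for plots)."""
    normed = normalize_attributes(hazard, reflected)
    out = pd.DataFrame(index=normed.index)
    for grp, attrs in ATTRIBUTE_SCHEMA.items():
        w = float(GROUP_WEIGHTS[grp])
        out[grp] = sum(w * normed[a] for a in attrs)
    out["toxpi"] = out.sum(axis=1)
    return out
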