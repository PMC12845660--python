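"""Readers and writers for the tables and spectra the pipeline touches.

All tabular formats are UTF-8 comma-separated CSV with a mandatory header
row and "." decimals; MS2 spectra travel as MGF. Column schemas are
documented in SCHEMAS.md at the repository root.

Units: retention time in minutes, concentration in ng/L, masses in Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from . import chem


class SchemaError(ValueError):
    """A table failed validation; the message names file, row and field."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One detected HRMS signal in one sample (singly charged, negative)."""
    feature_id: str
    sample_id: str
    mz: float
    rt: float
    area: float
    snr: float
    ms2_ref: str | None = None

    def __post_init__(self):
        if self.mz <= 0:
            raise SchemaError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise SchemaError(f"feature {self.feature_id}: rt must be >= 0")
        if self.area <= 0:
            raise SchemaError(f"feature {self.feature_id}: area must be > 0")
        if self.snr < 0:
            raise SchemaError(f"feature {self.feature_id}: snr must be >= 0")


@dataclass
class FragmentSpectrum:
    spectrum_id: str
    precursor_mz: float
    peaks: list[tuple[float, float]]

    def __post_init__(self):
        if not self.peaks:
            raise SchemaError(f"spectrum {self.spectrum_id}: no peaks")
        self.peaks = sorted(self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise SchemaError(f"spectrum {self.spectrum_id}: negative intensity")


@dataclass
class SuspectEntry:
    """A suspect-list compound; neutral mass must agree with its formula."""
    name: str
    formula: str
    neutral_mass: float
    suspect_id: str
    compound_class: str
    expected_rt: float | None = None
    in_library: bool = False

    def __post_init__(self):
        calc = chem.monoisotopic_mass(self.formula)
        if abs(calc - self.neutral_mass) > 0.001:
            raise SchemaError(
                f"suspect {self.suspect_id} ({self.name}): neutral_mass "
                f"{self.neutral_mass} deviates from formula mass {calc:.5f} "
                f"by more than 0.001 Da")


@dataclass
class SampleMeta:
    sample_id: str
    site_number: int
    settlement: str
    water_body: str
    position: str  # upstream | downstream
    is_blank: bool = False

    def __post_init__(self):
        if self.is_blank:
            return
        if self.position not in ("upstream", "downstream"):
            raise SchemaError(f"sample {self.sample_id}: bad position "
                              f"{self.position!r}")
        want = "downstream" if self.site_number % 2 == 0 else "upstream"
        if self.position != want:
            raise SchemaError(
                f"sample {self.sample_id}: site {self.site_number} must be "
                f"{want} (even sites downstream, odd upstream)")


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            raise SchemaError(f"{path}: non-numeric value in column {c!r}, "
                              f"row {int(bad[0]) + 2} (1-based incl. header)")
        df[c] = converted
    return df


FEATURE_COLUMNS = ["feature_id", "sample_id", "mz", "rt", "area", "snr", "ms2_ref"]


def read_feature_table(path) -> list[Feature]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"feature_id": str, "sample_id": str,
                                  "ms2_ref": str},
                     float_precision="round_trip")
    _require_columns(df, ["feature_id", "sample_id", "mz", "rt", "area", "snr"], path)
    _numeric(df, ["mz", "rt", "area", "snr"], path)
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate feature_id {dup!r}")
    out = []
    for idx, row in df.iterrows():
        ms2 = row.get("ms2_ref")
        if ms2 is not None and (pd.isna(ms2) or ms2 == ""):
            ms2 = None
        try:
            out.append(Feature(row["feature_id"], row["sample_id"],
                               float(row["mz"]), float(row["rt"]),
                               float(row["area"]), float(row["snr"]), ms2))
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_feature_table(features, path) -> None:
    rows = [{"feature_id": f.feature_id, "sample_id": f.sample_id, "mz": f.mz,
             "rt": f.rt, "area": f.area, "snr": f.snr,
             "ms2_ref": f.ms2_ref or ""} for f in features]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_suspect_list(path) -> list[SuspectEntry]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"suspect_id": str},
                     float_precision="round_trip")
    _require_columns(df, ["name", "formula", "neutral_mass", "suspect_id",
                          "class"], path)
    _numeric(df, ["neutral_mass"], path)
    out = []
    for idx, row in df.iterrows():
        rt = row.get("expected_rt")
        rt = None if rt is None or pd.isna(rt) else float(rt)
        lib = row.get("in_library", False)
        lib = bool(lib) and not pd.isna(lib)
        try:
            out.append(SuspectEntry(row["name"], row["formula"],
                                    float(row["neutral_mass"]),
                                    str(row["suspect_id"]), row["class"],
                                    rt, lib))
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_suspect_list(suspects, path) -> None:
    pd.DataFrame([{"name": s.name, "formula": s.formula,
                   "neutral_mass": s.neutral_mass, "suspect_id": s.suspect_id,
                   "class": s.compound_class,
                   "expected_rt": "" if s.expected_rt is None else s.expected_rt,
                   "in_library": s.in_library} for s in suspects]).to_csv(
        path, index=False)


def read_mgf(path) -> list[FragmentSpectrum]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec.get("params", {})
            sid = str(params.get("title", f"spectrum_{i}"))
            pep = params.get("pepmass", (None,))
            prec = float(pep[0]) if pep and pep[0] is not None else 0.0
            peaks = list(zip((float(x) for x in spec["m/z array"]),
                             (float(y) for y in spec["intensity array"])))
            out.append(FragmentSpectrum(sid, prec, peaks))
    return out


def write_mgf(spectra, path) -> None:
    entries = []
    for s in spectra:
        mzs, ints = zip(*s.peaks)
        entries.append({"m/z array": np.asarray(mzs),
                        "intensity array": np.asarray(ints),
                        "params": {"title": s.spectrum_id,
                                   "pepmass": s.precursor_mz,
                                   "charge": "1-"}})
    _mgf.write(entries, str(path), file_mode="w")


def read_rpf(path) -> dict[str, float]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["compound_id", "rpf"], path)
    _numeric(df, ["rpf"], path)
    if (df["rpf"] < 0).any():
        bad = df.index[df["rpf"] < 0][0]
        raise SchemaError(f"{path}: negative rpf at row {int(bad) + 2}")
    return dict(zip(df["compound_id"], df["rpf"]))


def write_rpf(rpf: dict[str, float], path) -> None:
    pd.DataFrame({"compound_id": list(rpf), "rpf": list(rpf.values())}
                 ).to_csv(path, index=False)


def read_hazard(path) -> pd.DataFrame:
    """Read a compound x attribute hazard table (index = compound_id)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["compound_id"], path)
    df = df.set_index("compound_id")
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="raise")
    return df


def write_hazard(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="compound_id")


def read_meta(path) -> list[SampleMeta]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str},
                     float_precision="round_trip")
    _require_columns(df, ["sample_id", "site_number", "settlement",
                          "water_body", "position"], path)
    out = []
    for idx, row in df.iterrows():
        blank = bool(row.get("is_blank", False))
        try:
            out.append(SampleMeta(row["sample_id"], int(row["site_number"]),
                                  row["settlement"], row["water_body"],
                                  row["position"], blank))
        except SchemaError as exc:
            raise SchemaError(f"{path}: row {idx + 2}: {exc}") from exc
    return out


def write_meta(meta, path) -> None:
    pd.DataFrame([{"sample_id": m.sample_id, "site_number": m.site_number,
                   "settlement": m.settlement, "water_body": m.water_body,
                   "position": m.position, "is_blank": m.is_blank}
                  for m in meta]).to_csv(path, index=False)


def read_fragment_db(path) -> dict[str, float]:
    """Diagnostic fragment name -> fragment ion m/z."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _require_columns(df, ["name", "mz"], path)
    _numeric(df, ["mz"], path)
    return dict(zip(df["name"], df["mz"]))


def read_neutral_loss_db(path) -> dict[str, float]:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    _require_columns(df, ["name", "mass"], path)
    _numeric(df, ["mass"], path)
    return dict(zip(df["name"], df["mass"]))


def write_simple_db(db: dict[str, float], path, value_col: str) -> None:
    pd.DataFrame({"name": list(db), value_col: list(db.values())}
                 ).to_csv(path, index=False)


def read_calibration(path):
    """Calibration CSV -> list of CalibrationCurve (grouped by native_id)."""
    from .quantify import CalibrationCurve, CalibrationLevel
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["native_id", "labeled_id", "conc_native",
                          "conc_labeled", "area_native", "area_labeled"], path)
    _numeric(df, ["conc_native", "conc_labeled", "area_native",
                  "area_labeled"], path)
    curves = []
    for (nid, lid), grp in df.groupby(["native_id", "labeled_id"], sort=True):
        levels = [CalibrationLevel(r.conc_native, r.conc_labeled,
                                   r.area_native, r.area_labeled)
                  for r in grp.itertuples()]
        curves.append(CalibrationCurve(str(nid), str(lid), levels))
    return curves


def write_calibration(curves, path) -> None:
    rows = []
    for c in curves:
        for lv in c.levels:
            rows.append({"native_id": c.native_id, "labeled_id": c.labeled_id,
                         "conc_native": lv.conc_native,
                         "conc_labeled": lv.conc_labeled,
                         "area_native": lv.area_native,
                         "area_labeled": lv.area_labeled})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


_STATUSES = {"quantified", "semi_quantified", "below_mql", "not_detected"}


def read_concentrations(path):
    """Concentration CSV -> list of ConcentrationRecord."""
    from .quantify import ConcentrationRecord
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "compound_id": str},
                     float_precision="round_trip")
    _require_columns(df, ["sample_id", "compound_id", "conc", "status"], path)
    _numeric(df, ["conc"], path)
    out = []
    for idx, r in df.iterrows():
        if r["status"] not in _STATUSES:
            raise SchemaError(f"{path}: row {idx + 2}: bad status "
                              f"{r['status']!r}")
        mql = r.get("mql")
        mql = None if mql is None or pd.isna(mql) else float(mql)
        flags = r.get("qc_flags", "")
        flags = set() if pd.isna(flags) or not flags else set(str(flags).split("|"))
        snr = r.get("snr", 0.0)
        snr = 0.0 if pd.isna(snr) else float(snr)
        out.append(ConcentrationRecord(r["sample_id"], r["compound_id"],
                                       float(r["conc"]), mql, r["status"],
                                       flags, snr))
    return out


def write_concentrations(records, path) -> None:
    pd.DataFrame([{"sample_id": r.sample_id, "compound_id": r.compound_id,
                   "conc": r.conc, "mql": "" if r.mql is None else r.mql,
                   "status": r.status,
                   "qc_flags": "|".join(sorted(r.qc_flags)),
                   "snr": r.snr} for r in records]).to_csv(
        path, index=False, float_format="%.17g")
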