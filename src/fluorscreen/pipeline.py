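"""End-to-end pipeline: simulate -> screen -> quantify -> eqs -> risk -> stats.

Each stage reads its inputs from, and writes its outputs to, a working
directory, so a run can resume from any stage (``from_stage``). All stage
parameters live in :class:`PipelineConfig`, loadable from TOML; defaults
are the workflow's standard operating values (5 ppm precursor tolerance,
0.2 min grouping, blank ratio 5, isotope threshold 80, group EQS
4.4 ng/L, PFOS AA/MAC EQS 0.65 / 36000 ng/L, risk thresholds
0.1/0.01/0.001).
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, databases, eqs as eqs_mod, msio, quantify as quant_mod, risk as risk_mod, screen as screen_mod, simulate, stats as stats_mod
from .simulate import AREA_IS, StudyDesign

log = logging.getLogger("fluorscreen")

STAGES = ["simulate", "screen", "quantify", "eqs", "risk", "stats", "report"]


@dataclass
class ToleranceConfig:
    ppm: float = 5.0
    rt_tol: float = 0.2
    kmd_tol: float = 0.002
    blank_ratio: float = 5.0
    isotope_threshold: float = 80.0
    ms2_tol_ppm: float = 10.0
    rt_standard_tol: float = 0.1


@dataclass
class EqsConfig:
    group: float = 4.4
    pfos_aa: float = 0.65
    pfos_mac: float = 36000.0
    include_ssa: bool = False


@dataclass
class RiskConfig:
    thresholds: tuple = (0.1, 0.01, 0.001)


@dataclass
class PipelineConfig:
    out_dir: str = "fluorscreen_run"
    seed: int = 0
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    eqs: EqsConfig = field(default_factory=EqsConfig)
    risk: RiskConfig = field(default_factory=RiskConfig)
    is_conc: float = 2.0  # internal-standard spike, ng/L

    def validate(self) -> None:
        t = self.tolerances
        for name in ("ppm", "rt_tol", "kmd_tol", "blank_ratio",
                     "isotope_threshold", "ms2_tol_ppm"):
            if getattr(t, name) <= 0:
                raise ValueError(f"tolerance {name} must be > 0")
        th = tuple(self.risk.thresholds)
        if not (th[0] > th[1] > th[2] > 0):
            raise ValueError(f"risk thresholds must be descending, got {th}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(
            out_dir=raw.get("out_dir", "fluorscreen_run"),
            seed=int(raw.get("seed", 0)),
            tolerances=ToleranceConfig(**raw.get("tolerances", {})),
            eqs=EqsConfig(**raw.get("eqs", {})),
            risk=RiskConfig(**{k: tuple(v) if k == "thresholds" else v
                               for k, v in raw.get("risk", {}).items()}),
            is_conc=float(raw.get("is_conc", 2.0)),
        )
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, design: StudyDesign | None = None):
    out = Path(cfg.out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "blanks").mkdir(parents=True, exist_ok=True)
    design = design or StudyDesign(seed=cfg.seed)
    log.info("simulate: %d samples, %d compounds, seed %d",
             design.n_samples, len(design.compounds), design.seed)
    meta = simulate.make_meta(design)
    feats, blank_feats, spectra, envelopes, truth = \
        simulate.gen_feature_table(design)
    for sid in sorted({f.sample_id for f in feats}):
        msio.write_feature_table([f for f in feats if f.sample_id == sid],
                                 out / "features" / f"{sid}.csv")
    for sid in sorted({f.sample_id for f in blank_feats}):
        msio.write_feature_table([f for f in blank_feats if f.sample_id == sid],
                                 out / "blanks" / f"{sid}.csv")
    msio.write_mgf(spectra, out / "spectra.mgf")
    envelopes.to_csv(out / "envelopes.csv", index=False)
    msio.write_meta(meta, out / "meta.csv")
    msio.write_suspect_list(simulate.make_suspect_list(design.compounds),
                            out / "suspects.csv")
    msio.write_rpf(simulate.default_rpf_table(design.compounds),
                   out / "rpf.csv")
    curves, cal_truth = simulate.gen_calibration(design.compounds,
                                                 seed=design.seed + 2)
    msio.write_calibration(curves, out / "calibration.csv")
    hazard, hz_truth = simulate.gen_hazard_table(design.compounds,
                                                 seed=design.seed + 3)
    msio.write_hazard(hazard, out / "hazard.csv")
    msio.write_simple_db(databases.DIAGNOSTIC_FRAGMENTS,
                         out / "fragments.csv", "mz")
    msio.write_simple_db(databases.NEUTRAL_LOSSES, out / "losses.csv", "mass")
    truth = {**truth, **cal_truth, "hazard": hz_truth,
             "targets": [c.name for c in design.compounds if c.is_target]}
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return truth


def _read_dir_features(d: Path):
    feats = []
    for p in sorted(d.glob("*.csv")):
        feats.extend(msio.read_feature_table(p))
    return feats


def stage_screen(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    t = cfg.tolerances
    log.info("screen: ppm=%.3g rt_tol=%.3g blank_ratio=%.3g isotope>=%.3g",
             t.ppm, t.rt_tol, t.blank_ratio, t.isotope_threshold)
    feats = _read_dir_features(out / "features")
    blank_feats = _read_dir_features(out / "blanks")
    suspects = msio.read_suspect_list(out / "suspects.csv")
    spectra = {s.spectrum_id: s for s in msio.read_mgf(out / "spectra.mgf")}
    frag_db = msio.read_fragment_db(out / "fragments.csv")
    loss_db = msio.read_neutral_loss_db(out / "losses.csv")
    env_df = pd.read_csv(out / "envelopes.csv")
    env_by_feature = {fid: list(zip(g["mz"], g["rel_intensity"]))
                      for fid, g in env_df.groupby("feature_id")}

    groups = screen_mod.group_across_samples(feats, t.rt_tol, t.ppm)
    blank_groups = screen_mod.group_across_samples(blank_feats, t.rt_tol, t.ppm)
    retained, background = screen_mod.blank_subtract(
        groups, blank_groups, t.blank_ratio, t.rt_tol, t.ppm)
    candidates = screen_mod.match_suspects(retained, suspects, t.ppm)

    rows = []
    for g, s, ppm_err in candidates:
        has_ms2 = bool(g.ms2_refs())
        insilico = False
        for ref in g.ms2_refs():
            sp = spectra.get(ref)
            if sp and screen_mod.match_fragments(sp, frag_db, loss_db,
                                                 t.ms2_tol_ppm).any():
                insilico = True
                break
        iso_score = None
        for f in g.features:
            if f.feature_id in env_by_feature:
                iso_score = screen_mod.score_isotope_pattern(
                    env_by_feature[f.feature_id], s.formula)
                break
        formula_ok = iso_score is None or iso_score >= t.isotope_threshold
        ev = screen_mod.EvidenceFlags(
            mass_match=True,
            formula_assigned=formula_ok,
            ms2_library_match=s.in_library and has_ms2,
            ms2_insilico_fragment_match=insilico,
            rt_standard_match=(s.expected_rt is not None
                               and abs(g.consensus_rt - s.expected_rt)
                               <= t.rt_standard_tol),
        )
        level = screen_mod.assign_confidence(ev)
        rows.append({
            "group_id": g.group_id, "suspect_id": s.suspect_id,
            "suspect_name": s.name, "ppm_error": ppm_err,
            "isotope_score": "" if iso_score is None else iso_score,
            "confidence": level, "mass_match": ev.mass_match,
            "formula_assigned": ev.formula_assigned,
            "ms2_library_match": ev.ms2_library_match,
            "ms2_insilico_fragment_match": ev.ms2_insilico_fragment_match,
            "rt_standard_match": ev.rt_standard_match,
            "consensus_mz": g.consensus_mz, "consensus_rt": g.consensus_rt,
            "feature_ids": "|".join(g.feature_ids),
            "abs_ppm": abs(ppm_err),
        })
    ann = pd.DataFrame(rows)
    if len(ann):
        ann = ann.sort_values(["group_id", "abs_ppm"]).drop(columns=["abs_ppm"])
    ann.to_csv(out / "annotations.csv", index=False)

    # homologous series over retained group consensus masses
    class _G:  # minimal feature-like view of a group
        def __init__(self, g):
            self.feature_id = f"G{g.group_id}"
            self.mz = g.consensus_mz
    series = []
    if len(retained) >= 2:
        series = chem.find_homologous_series([_G(g) for g in retained], "CF2",
                                             t.kmd_tol, t.ppm)
    pd.DataFrame([{"series_id": s.series_id, "base_unit": s.base_unit,
                   "kmd_centroid": s.kmd_centroid,
                   "members": "|".join(s.member_feature_ids)}
                  for s in series]).to_csv(out / "series.csv", index=False)
    pd.DataFrame([{"group_id": g.group_id,
                   "feature_ids": "|".join(g.feature_ids)}
                  for g in background]).to_csv(out / "background_groups.csv",
                                               index=False)
    return ann


def stage_quantify(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    ann = pd.read_csv(out / "annotations.csv")
    suspects = {s.suspect_id: s for s in
                msio.read_suspect_list(out / "suspects.csv")}
    curves = msio.read_calibration(out / "calibration.csv")
    rrfs = {c.native_id: quant_mod.fit_rrf(c) for c in curves}
    feats = {f.feature_id: f for f in _read_dir_features(out / "features")}
    meta = [m for m in msio.read_meta(out / "meta.csv") if not m.is_blank]
    sample_ids = [m.sample_id for m in meta]
    log.info("quantify: %d fitted RRFs, %d annotation rows", len(rrfs), len(ann))

    # retain levels 1-3, best candidate per group (smallest |ppm|, then
    # highest isotope score)
    ann = ann[ann["confidence"] <= 3].copy()
    if len(ann):
        ann["abs_ppm"] = ann["ppm_error"].abs()
        iso = pd.to_numeric(ann["isotope_score"], errors="coerce").fillna(-1)
        ann["iso_rank"] = -iso
        ann = (ann.sort_values(["group_id", "abs_ppm", "iso_rank"])
               .groupby("group_id", as_index=False).first())

    targets = [s for s in suspects.values() if s.expected_rt is not None]

    class _T:
        def __init__(self, s):
            self.name = s.name
            self.compound_id = s.name
            self.rt = s.expected_rt
            self.subclass = s.compound_class
            self.neutral_mass = s.neutral_mass

    proxies = [_T(s) for s in targets if s.name in rrfs]

    records = []
    for _, row in ann.iterrows():
        s = suspects[str(row["suspect_id"])]
        is_target = s.expected_rt is not None
        if is_target and s.name in rrfs:
            rrf = rrfs[s.name].rrf
            surrogate = s.name
        else:
            surrogate = quant_mod.assign_surrogate(
                float(row["consensus_rt"]), s.compound_class,
                s.neutral_mass, proxies)
            rrf = rrfs[surrogate].rrf
        per_sample = {}
        for fid in str(row["feature_ids"]).split("|"):
            f = feats.get(fid)
            if f is None:
                continue
            conc = quant_mod.quantify_target(f.area, AREA_IS, cfg.is_conc, rrf)
            rt_dev = (f.rt - s.expected_rt) if is_target else 0.0
            ok, flags = quant_mod.qc_gate(f.snr, 0.0, rt_dev, is_target)
            per_sample[f.sample_id] = (conc if ok else 0.0, flags, f.snr, ok)
        accepted = [quant_mod.ConcentrationRecord(sid, s.name, c, None,
                                                  "quantified", fl, snr)
                    for sid, (c, fl, snr, ok) in per_sample.items() if ok]
        try:
            mql = quant_mod.estimate_mql(accepted)
        except ValueError:
            mql = None
        for sid in sample_ids:
            if sid in per_sample:
                conc, flags, snr, ok = per_sample[sid]
                if not ok:
                    status, conc = "not_detected", 0.0
                elif mql is not None and conc < mql:
                    status = "below_mql"
                else:
                    status = "quantified" if is_target else "semi_quantified"
                records.append(quant_mod.ConcentrationRecord(
                    sid, s.name, conc, mql, status, flags, snr))
            else:
                records.append(quant_mod.ConcentrationRecord(
                    sid, s.name, 0.0, mql, "not_detected", set(), 0.0))
    msio.write_concentrations(records, out / "concentrations.csv")
    pd.DataFrame([{"native_id": r.native_id, "labeled_id": r.labeled_id,
                   "rrf": r.rrf, "fit_r2": r.fit_r2}
                  for r in rrfs.values()]).to_csv(out / "rrfs.csv", index=False)
    return records


def stage_eqs(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    records = msio.read_concentrations(out / "concentrations.csv")
    rpf = msio.read_rpf(out / "rpf.csv")
    meta = msio.read_meta(out / "meta.csv")
    suspects = msio.read_suspect_list(out / "suspects.csv")
    target_names = {s.name for s in suspects if s.expected_rt is not None}
    by_sample: dict[str, list] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)
    results = []
    for sid in sorted(by_sample):
        rs = by_sample[sid]
        scope = rs if cfg.eqs.include_ssa else \
            [r for r in rs if r.compound_id in target_names]
        res = eqs_mod.check_eqs(sid, scope, rpf)
        results.append(res)
    pd.DataFrame([{
        "sample_id": r.sample_id, "sum_pfas_quant": r.sum_pfas_quant,
        "sum_pfoa_eq": r.sum_pfoa_eq,
        "exceeds_group_eqs": r.exceeds_group_eqs, "pfos_conc": r.pfos_conc,
        "exceeds_pfos_aa": r.exceeds_pfos_aa,
        "exceeds_pfos_mac": r.exceeds_pfos_mac,
    } for r in results]).to_csv(out / "eqs.csv", index=False)
    summary = eqs_mod.river_summary(results, meta)
    summary.to_csv(out / "river_summary.csv", index=False)
    log.info("eqs: %d/%d samples exceed the %.2g ng/L group EQS",
             sum(r.exceeds_group_eqs for r in results), len(results),
             eqs_mod.GROUP_EQS_NG_L)
    return results, summary


def stage_risk(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    records = msio.read_concentrations(out / "concentrations.csv")
    hazard = msio.read_hazard(out / "hazard.csv")
    detected: dict[str, list] = {}
    n_samples = len({r.sample_id for r in records})
    conc_max, df_frac = {}, {}
    for r in records:
        detected.setdefault(r.compound_id, []).append(r)
    for comp, rs in detected.items():
        hits = [r for r in rs if r.status in ("quantified", "semi_quantified")]
        if not hits:
            continue
        conc_max[comp] = max(r.conc for r in hits)
        df_frac[comp] = len(hits) / n_samples
    table = risk_mod.prioritize(hazard, conc_max, df_frac)
    table.to_csv(out / "risk.csv")
    risk_mod.toxpi_group_breakdown(
        hazard.loc[table.index]).to_csv(out / "toxpi_breakdown.csv")
    log.info("risk: top compound %s (RI=%.3g, %s)", table.index[0],
             table["ri"].iloc[0], table["category"].iloc[0])
    return table


def stage_stats(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    records = msio.read_concentrations(out / "concentrations.csv")
    meta = msio.read_meta(out / "meta.csv")
    results = stats_mod.test_all_compounds(records, meta)
    pd.DataFrame([{
        "compound_id": r.compound_id, "n_pairs": r.n_pairs,
        "n_nonzero_pairs": r.n_nonzero_pairs,
        "w_statistic": "" if r.w_statistic is None else r.w_statistic,
        "p_value": "" if r.p_value is None else r.p_value,
        "p_adjusted": "" if r.p_adjusted is None else r.p_adjusted,
        "shapiro_w": "" if r.shapiro_w is None else r.shapiro_w,
        "shapiro_p": "" if r.shapiro_p is None else r.shapiro_p,
    } for r in results]).to_csv(out / "tests.csv", index=False)
    return results


def stage_report(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    ann = pd.read_csv(out / "annotations.csv")
    eqs_df = pd.read_csv(out / "eqs.csv")
    summary = pd.read_csv(out / "river_summary.csv")
    risk_df = pd.read_csv(out / "risk.csv")
    tests = pd.read_csv(out / "tests.csv")
    lines = ["# fluorscreen run report", ""]
    lines += ["## Confidence-level tally", ""]
    tally = ann.groupby("confidence").size() if len(ann) else pd.Series(dtype=int)
    for lvl in range(1, 6):
        lines.append(f"- Level {lvl}: {int(tally.get(lvl, 0))} annotations")
    lines += ["", "## Per-river summary (ng/L)", "",
              summary.to_markdown(index=False), ""]
    n = len(eqs_df)
    lines += ["## EQS compliance", "",
              f"- Group EQS (> {cfg.eqs.group} ng/L as PFOA-eq): "
              f"{int(eqs_df['exceeds_group_eqs'].sum())}/{n} samples exceed",
              f"- PFOS AA-EQS (> {cfg.eqs.pfos_aa} ng/L): "
              f"{int(eqs_df['exceeds_pfos_aa'].sum())}/{n} samples exceed",
              f"- PFOS MAC-EQS (> {cfg.eqs.pfos_mac} ng/L): "
              f"{int(eqs_df['exceeds_pfos_mac'].sum())}/{n} samples exceed", ""]
    lines += ["## Risk ranking", "", risk_df.to_markdown(index=False), ""]
    sig = tests[pd.to_numeric(tests["p_adjusted"], errors="coerce") < 0.05]
    lines += ["## Upstream/downstream testing", "",
              f"- {len(sig)} of {len(tests)} compounds significant after "
              "FDR correction", ""]
    (out / "report.md").write_text("\n".join(lines))
    import platform
    manifest = {
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "python": platform.python_version(),
        "numpy": np.__version__, "pandas": pd.__version__,
        "stages": STAGES,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def run_pipeline(cfg: PipelineConfig, from_stage: str = "simulate",
                 design: StudyDesign | None = None):
    """Run all stages from ``from_stage`` onward; earlier stage outputs
    must already exist in ``cfg.out_dir``."""
    cfg.validate()
    if from_stage not in STAGES:
        raise ValueError(f"unknown stage {from_stage!r}; choose from {STAGES}")
    start = STAGES.index(from_stage)
    funcs = {"simulate": lambda: stage_simulate(cfg, design),
             "screen": lambda: stage_screen(cfg),
             "quantify": lambda: stage_quantify(cfg),
             "eqs": lambda: stage_eqs(cfg),
             "risk": lambda: stage_risk(cfg),
             "stats": lambda: stage_stats(cfg),
             "report": lambda: stage_report(cfg)}
    outputs = {}
    for name in STAGES[start:]:
        log.info("=== stage %s ===", name)
        try:
            outputs[name] = funcs[name]()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return outputs
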