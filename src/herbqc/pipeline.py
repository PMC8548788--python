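"""End-to-end orchestration: generate -> process -> quantify -> fingerprint
-> chemometrics -> doe, with config handling and report emission.

Every stage draws its randomness from a named substream of one root seed,
so a run is reproducible end to end; ``run_pipeline`` writes the report
tables (similarity, RCF, contents/agreement, variance/loadings, range
analysis) as delimited text plus a machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics, doe, fingerprint, quantify
from .calibration import rcf_robustness
from .chromatogram import (
    PeakTable,
    baseline_correct,
    build_peak_table,
    detect_peaks,
    match_peaks,
)
from .fixtures import load_fixture
from .synthetic_data import (
    MIXED_STANDARD_MG_ML,
    StudyDesign,
    default_design,
    sample_contents,
    simulate_study,
    standard_areas,
)

log = logging.getLogger(__name__)

#: Instrument-condition grid for RCF robustness (flow ml/min, column temp C).
RCF_CONDITIONS = tuple((f, t) for f in (0.6, 0.8, 1.0) for t in (30, 35, 40))


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    seed: int = 0
    n_batches: int = 15
    detector_cv: float = 0.02
    baseline_drift_mau: float = 1.0
    proportional_response: bool = False
    match_tolerance_min: float = 0.2
    similarity_method: str = "cosine"
    similarity_threshold: float = 0.82
    reference_batch: str = "S15"
    retain_threshold: float = 0.8
    hca_mode: str = "squared-euclidean"
    min_peak_height_mau: float = 0.5
    output_dir: str = "herbqc_output"

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("n_batches must be >= 2")
        if not 0 <= self.detector_cv <= 0.1:
            raise ValueError("detector_cv must be in [0, 0.1]")
        if self.similarity_method not in ("cosine", "pearson"):
            raise ValueError("similarity_method must be 'cosine' or 'pearson'")
        if not 0 < self.similarity_threshold <= 1:
            raise ValueError("similarity_threshold must be in (0, 1]")
        if self.match_tolerance_min <= 0:
            raise ValueError("match_tolerance_min must be positive")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(mapping)


def _substream(seed: int, stage: int) -> int:
    """Named child seed for a pipeline stage, kept below 2**31."""
    child = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return int(child.generate_state(1)[0] % (2**31))


def measure_rcf_table(design: StudyDesign, seed: int) -> pd.DataFrame:
    """RCFs of every analyte vs the marker over the condition grid.

    The detector response is condition-independent in this model, so the
    spread across conditions comes only from injection noise — mirroring
    the small RSDs expected of a robust RCF.
    """
    rows = []
    marker = design.marker.name
    for i, (flow, temp) in enumerate(RCF_CONDITIONS):
        areas = standard_areas(design, MIXED_STANDARD_MG_ML, seed=seed + i)
        f = areas / pd.Series(MIXED_STANDARD_MG_ML)
        row = {"flow_rate_ml_min": flow, "column_temp_c": temp}
        for name in design.compound_names:
            if name == marker:
                continue
            row[name] = f[marker] / f[name]
        rows.append(row)
    return pd.DataFrame(rows)


def process_study(design: StudyDesign, chromatograms, config: RunConfig | None = None):
    """Baseline-correct, detect and integrate peaks, build the peak table.

    Returns (corrected traces, per-sample (trace, peaks) pairs, common-peak
    table). The common-peak table keeps only peaks present in every sample;
    quantification uses :func:`compound_area_matrix` on the pairs instead.
    """
    cfg = config or RunConfig()
    corrected = [baseline_correct(c) for c in chromatograms]
    samples = [
        (c, detect_peaks(c, min_height=cfg.min_peak_height_mau, min_prominence=cfg.min_peak_height_mau / 2))
        for c in corrected
    ]
    table = build_peak_table(
        samples,
        reference_rts=design.all_retention_times(),
        compound_names=design.peak_labels(),
        tolerance=cfg.match_tolerance_min,
    )
    return corrected, samples, table


def compound_area_matrix(design: StudyDesign, samples, tolerance: float = 0.2) -> pd.DataFrame:
    """Per-sample areas of the quantified compounds, NaN where a compound's
    peak was not found (e.g. clipped below the detection floor).

    Unlike the strict common-peak table used for fingerprints, this matrix
    keeps every sample: quantification can flag an absent peak per cell.
    """
    rts = [c.retention_time for c in design.compounds]
    rows = {}
    for chrom, peaks in samples:
        assign = match_peaks(peaks, rts, tolerance=tolerance)
        rows[chrom.sample_id] = [
            assign.matched[i].area if i in assign.matched else np.nan
            for i in range(len(rts))
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=design.compound_names)


def quantify_study(
    design: StudyDesign, areas: pd.DataFrame, f_si: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """ESM and QAMS contents (mg/g) from a sample x compound area matrix.

    Returns (esm, qams, flags): ``esm`` covers every quantified compound,
    ``qams`` the non-marker analytes derived from the marker peak with the
    relative correction factors ``f_si``. A NaN area (peak not found) gives
    content 0 with flag ``peak_missing``; a missing marker peak aborts.
    """
    marker = design.marker.name
    by_name = {c.name: c for c in design.compounds}
    if areas[marker].isna().any():
        bad = list(areas.index[areas[marker].isna()])
        raise ValueError(f"marker peak missing in samples {bad}")

    esm = {}
    qams = {}
    flags = {}
    for name, spec in by_name.items():
        vals, fl = [], []
        for a in areas[name]:
            if np.isnan(a):
                vals.append(0.0)
                fl.append("peak_missing")
                continue
            cv = quantify.esm_content(float(a), spec.calibration, design.dilution)
            vals.append(cv.value)
            fl.append(cv.flag)
        esm[name] = pd.Series(vals, index=areas.index)
        flags[name] = pd.Series(fl, index=areas.index, dtype=object)

    a_s = areas[marker]
    c_s = esm[marker] * design.dilution.mass_g / design.dilution.volume_ml  # mg/ml in extract
    for name in by_name:
        if name == marker:
            continue
        qams[name] = pd.Series(
            [
                0.0
                if np.isnan(ai)
                else quantify.qams_content(float(ai), float(as_), float(cs), float(f_si[name]), design.dilution)
                for ai, as_, cs in zip(areas[name], a_s, c_s)
            ],
            index=areas.index,
        )
    return pd.DataFrame(esm), pd.DataFrame(qams), pd.DataFrame(flags)


@dataclass
class QAMSComparison:
    """Products of a simulated ESM-vs-QAMS study."""

    design: StudyDesign
    contents: pd.DataFrame  # true contents
    peak_table: PeakTable
    esm: pd.DataFrame
    qams: pd.DataFrame
    flags: pd.DataFrame
    rcf_table: pd.DataFrame
    f_si: pd.Series
    agreement: pd.DataFrame
    chromatograms: list = field(default_factory=list)


def run_qams_comparison(
    design: StudyDesign,
    seed: int,
    contents: pd.DataFrame | None = None,
    config: RunConfig | None = None,
) -> QAMSComparison:
    """Simulate a study and compare ESM with QAMS quantification.

    The relative correction factors are measured from the mixed-standard
    injections over the instrument-condition grid and averaged, as a
    robustness-backed f_si per analyte.
    """
    cfg = config or RunConfig()
    if contents is None:
        contents = sample_contents(design, cfg.n_batches, _substream(seed, 0))
    chroms = simulate_study(design, contents, _substream(seed, 1))
    corrected, samples, table = process_study(design, chroms, cfg)
    areas = compound_area_matrix(design, samples, tolerance=cfg.match_tolerance_min)
    rcf_table = measure_rcf_table(design, _substream(seed, 2))
    f_si = rcf_robustness(rcf_table, condition_cols=("flow_rate_ml_min", "column_temp_c")).loc["mean"]
    esm, qams, flags = quantify_study(design, areas, f_si)
    analytes = [n for n in design.compound_names if n != design.marker.name]
    agreement = quantify.agreement_table(esm[analytes], qams[analytes])
    return QAMSComparison(
        design=design,
        contents=contents.loc[esm.index],
        peak_table=table,
        esm=esm,
        qams=qams,
        flags=flags,
        rcf_table=rcf_table,
        f_si=f_si,
        agreement=agreement,
        chromatograms=corrected,
    )


def _content_report(cmp: QAMSComparison) -> pd.DataFrame:
    """Per-batch content table shaped like the published comparison table."""
    marker = cmp.design.marker.name
    out = pd.DataFrame({f"{marker}_esm": cmp.esm[marker].round(3)})
    for name in cmp.qams.columns:
        e, q = cmp.esm[name], cmp.qams[name]
        out[f"{name}_esm"] = e.round(3)
        out[f"{name}_qams"] = q.round(3)
        out[f"{name}_re"] = [
            round(100 * (b - a) / a, 2) if a > 0 else np.nan for a, b in zip(e, q)
        ]
        out[f"{name}_rsd"] = [
            round(quantify.pair_rsd(a, b), 2) if a + b > 0 else np.nan for a, b in zip(e, q)
        ]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the machine-readable summary that is also written as
    ``summary.json``. Idempotent for a fixed seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_design(config.seed).with_noise(
        detector_cv=config.detector_cv, baseline_drift_mau=config.baseline_drift_mau
    )
    if config.proportional_response:
        design = design.proportional_response()
    log.info(
        "run: seed=%d tolerance=%.2f similarity=%s linkage=%s",
        config.seed, config.match_tolerance_min, config.similarity_method, config.hca_mode,
    )

    cmp = run_qams_comparison(design, config.seed, config=config)

    sim = fingerprint.similarity_report(
        cmp.chromatograms,
        reference_id=config.reference_batch if config.reference_batch in cmp.esm.index else None,
        method=config.similarity_method,
        threshold=config.similarity_threshold,
    )

    rcf_summary = rcf_robustness(cmp.rcf_table, condition_cols=("flow_rate_ml_min", "column_temp_c"))
    fm = chemometrics.factor_analysis(cmp.esm, retain_threshold=config.retain_threshold)
    tree = chemometrics.hca(cmp.esm, mode=config.hca_mode)

    table2 = load_fixture("table2_orthogonal")
    ra = doe.range_analysis(doe.from_frame(table2))

    reports = {
        "similarity.csv": sim.round(4),
        "rcf.csv": pd.concat([cmp.rcf_table.round(4), rcf_summary.round(4)]),
        "contents.csv": _content_report(cmp),
        "variance.csv": fm.variance_table.round(3),
        "loadings.csv": pd.concat(
            {"rotated": fm.rotated_loadings.round(3), "coefficients": fm.score_coefficients.round(3)},
            axis=1,
        ),
        "ranking.csv": pd.DataFrame(
            {"score": fm.composite.round(3), "ranking": fm.ranking, "similarity": sim["similarity"].round(3)}
        ),
        "range_analysis.csv": pd.concat([ra.k.round(3), ra.r.rename("R").to_frame().T, ra.r_rounded.rename("R_rounded").to_frame().T]),
        "hca_merges.csv": pd.DataFrame(tree.merges, columns=["left", "right", "distance", "size"]).round(6),
    }
    for fname, frame in reports.items():
        frame.to_csv(out / fname)

    flagged = sim.index[sim["below_threshold"]].tolist()
    summary = {
        "seed": config.seed,
        "n_batches": int(len(cmp.esm)),
        "n_common_peaks": int(cmp.peak_table.areas.shape[1]),
        "similarity_min": round(float(sim["similarity"].min()), 4),
        "batches_below_threshold": flagged,
        "f_si": {k: round(float(v), 4) for k, v in cmp.f_si.items()},
        "rcf_rsd_percent": {k: round(float(v), 2) for k, v in rcf_summary.loc["rsd_percent"].items()},
        "max_abs_re_percent": round(float(cmp.agreement["max_abs_re"].max()), 3),
        "min_pearson_r": round(float(cmp.agreement["pearson_r"].min()), 4),
        "retained_factors": int(fm.rotated_loadings.shape[1]),
        "cumulative_variance_percent": round(float(fm.variance_table["cum_pct"].iloc[fm.rotated_loadings.shape[1] - 1]), 3),
        "best_batch": str(fm.ranking.idxmin()),
        "doe_factor_order": doe.rank_factors(ra),
        "parameters": {
            "match_tolerance_min": config.match_tolerance_min,
            "similarity_method": config.similarity_method,
            "similarity_threshold": config.similarity_threshold,
            "hca_mode": config.hca_mode,
            "retain_threshold": config.retain_threshold,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
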