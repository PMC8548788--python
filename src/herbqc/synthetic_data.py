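"""Synthetic HPLC study generator.

Emulates the data-generating process the analysis assumes: 15 batches of an
herbal material, each yielding a 0-27 min chromatogram with 10 common peaks
(6 quantified phenolics plus 4 unidentified peaks), Gaussian peak shapes, a
linear detector response per compound, a 1 g / 30 ml extraction dilution,
and the replicate/spike designs used for method validation (precision,
stability, repeatability, recovery).

Everything is a pure function of (design, seed): the same inputs always
produce the same traces.

Units: contents mg per g dry material; solution concentrations ug/ml
(1 mg/ml = 1000 ug/ml); areas mAU*min; times minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .chromatogram import Chromatogram

TIME_MAX = 27.0  # gradient span, minutes
GRID_STEP = 0.004  # sampling interval, minutes
PEAK_SD = 0.08  # Gaussian peak sd, minutes (typical isocratic HPLC width)

#: Mixed-standard working concentrations, mg/ml (apigenin stock is weaker).
MIXED_STANDARD_MG_ML = {
    "chlorogenic_acid": 0.167,
    "caffeic_acid": 0.167,
    "p_coumaric_acid": 0.167,
    "cichoric_acid": 0.167,
    "luteolin": 0.167,
    "apigenin": 0.083,
}


@dataclass(frozen=True)
class Dilution:
    """Extraction dilution: mass_g of powder into volume_ml of solvent."""

    mass_g: float = 1.0
    volume_ml: float = 30.0

    def __post_init__(self) -> None:
        if self.mass_g <= 0 or self.volume_ml <= 0:
            raise ValueError("dilution mass and volume must be positive")

    def content_to_conc(self, content_mg_g: float) -> float:
        """mg/g dry material -> injection concentration in ug/ml."""
        return content_mg_g * self.mass_g / self.volume_ml * 1000.0

    def conc_to_content(self, conc_ug_ml: float) -> float:
        """ug/ml in the extract -> mg/g dry material."""
        return conc_ug_ml * self.volume_ml / (1000.0 * self.mass_g)


@dataclass(frozen=True)
class NoiseModel:
    baseline_drift_mau: float = 1.0  # amplitude of low-order polynomial drift
    detector_cv: float = 0.02  # multiplicative per-peak area noise


@dataclass(frozen=True)
class CompoundSpec:
    name: str
    retention_time: float
    calibration: CalibrationCurve
    content_range: tuple[float, float]  # mg/g sampling range
    is_marker: bool = False


@dataclass(frozen=True)
class UnidentifiedPeak:
    """A common peak with no standard: fixed response, nominal concentration."""

    retention_time: float
    response_factor: float  # area per ug/ml
    nominal_conc_ug_ml: float
    batch_variation: float = 0.3  # +- fractional spread across batches


@dataclass(frozen=True)
class StudyDesign:
    batch_ids: tuple[str, ...]
    compounds: tuple[CompoundSpec, ...]
    unidentified_peaks: tuple[UnidentifiedPeak, ...]
    dilution: Dilution = field(default_factory=Dilution)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        markers = [c for c in self.compounds if c.is_marker]
        if len(markers) != 1:
            raise ValueError(f"exactly one marker compound required, got {len(markers)}")
        rt_list = self.all_retention_times()
        if any(b <= a for a, b in zip(rt_list, rt_list[1:])):
            raise ValueError("retention times must be strictly increasing")
        if rt_list[0] < 0 or rt_list[-1] > TIME_MAX:
            raise ValueError(f"retention times must lie within [0, {TIME_MAX}] min")

    @property
    def marker(self) -> CompoundSpec:
        return next(c for c in self.compounds if c.is_marker)

    @property
    def compound_names(self) -> list[str]:
        return [c.name for c in self.compounds]

    def all_retention_times(self) -> list[float]:
        """Retention times of all common peaks, in elution order."""
        rts = [(c.retention_time, c.name) for c in self.compounds]
        rts += [(u.retention_time, "") for u in self.unidentified_peaks]
        return [t for t, _ in sorted(rts)]

    def peak_labels(self) -> list[str]:
        """Compound name per common peak in elution order ("" if unidentified)."""
        rts = [(c.retention_time, c.name) for c in self.compounds]
        rts += [(u.retention_time, "") for u in self.unidentified_peaks]
        return [name for _, name in sorted(rts)]

    def with_noise(self, detector_cv: float | None = None, baseline_drift_mau: float | None = None) -> "StudyDesign":
        noise = NoiseModel(
            baseline_drift_mau=self.noise.baseline_drift_mau if baseline_drift_mau is None else baseline_drift_mau,
            detector_cv=self.noise.detector_cv if detector_cv is None else detector_cv,
        )
        return replace(self, noise=noise)

    def noiseless(self) -> "StudyDesign":
        return self.with_noise(detector_cv=0.0, baseline_drift_mau=0.0)

    def proportional_response(self) -> "StudyDesign":
        """Zero all calibration intercepts, keeping slopes.

        This is the regime in which the single-marker working equation
        C_i = f_si * C_s * A_i / A_s is exact; see the methods note.
        """
        comps = tuple(
            replace(c, calibration=replace(c.calibration, intercept=0.0))
            for c in self.compounds
        )
        return replace(self, compounds=comps)


# Retention times are a generator choice (2-25 min, >= 0.8 min apart); the
# elution order of the named compounds follows their common-peak numbering
# (2, 4, 7, 8, 9, 10) with the four unidentified peaks at 1, 3, 5, 6.
_RETENTION_MIN = {
    "chlorogenic_acid": 6.1,
    "caffeic_acid": 9.4,
    "p_coumaric_acid": 15.1,
    "cichoric_acid": 17.8,
    "luteolin": 20.6,
    "apigenin": 23.4,
}
_UNIDENTIFIED = (
    UnidentifiedPeak(retention_time=3.2, response_factor=15.0, nominal_conc_ug_ml=40.0),
    UnidentifiedPeak(retention_time=8.0, response_factor=25.0, nominal_conc_ug_ml=25.0),
    UnidentifiedPeak(retention_time=11.2, response_factor=12.0, nominal_conc_ug_ml=60.0),
    UnidentifiedPeak(retention_time=13.0, response_factor=18.0, nominal_conc_ug_ml=35.0),
)


def default_design(seed: int = 0) -> StudyDesign:
    """The default 15-batch, 10-common-peak study design.

    Calibration curves and linear ranges come from the reference calibration
    table; per-compound content sampling ranges span the observed min/max
    contents of the reference content table; the marker is cichoric acid and
    the dilution is 1 g into 30 ml.
    """
    from .fixtures import load_fixture

    cal = load_fixture("table3_calibration").set_index("compound")
    contents = load_fixture("table6_contents").set_index("batch")
    compounds = []
    for name in MIXED_STANDARD_MG_ML:
        row = cal.loc[name]
        curve = CalibrationCurve(
            compound=name,
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r_squared=float(row["r_squared"]),
            linear_range=(float(row["range_low_ug_ml"]), float(row["range_high_ug_ml"])),
        )
        esm_col = contents[f"{name}_esm"]
        compounds.append(
            CompoundSpec(
                name=name,
                retention_time=_RETENTION_MIN[name],
                calibration=curve,
                content_range=(float(esm_col.min()), float(esm_col.max())),
                is_marker=name == "cichoric_acid",
            )
        )
    return StudyDesign(
        batch_ids=tuple(f"S{i}" for i in range(1, 16)),
        compounds=tuple(compounds),
        unidentified_peaks=_UNIDENTIFIED,
        seed=int(seed),
    )


def sample_contents(
    design: StudyDesign, n_batches: int, seed: int, groups: int | None = None
) -> pd.DataFrame:
    """Draw true contents (mg/g) for ``n_batches`` batches.

    By default each content is uniform within the compound's design range.
    With ``groups=k``, batches are assigned round-robin to k planted content
    profiles (group centres spread across each compound's range, with a
    small jitter), giving the study a known cluster structure for testing
    the chemometric stages; the assignment is stored in ``.attrs["groups"]``.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches")
    rng = np.random.default_rng(seed)
    names = design.compound_names
    ids = [design.batch_ids[i] if i < len(design.batch_ids) else f"S{i + 1}" for i in range(n_batches)]
    lo = np.array([c.content_range[0] for c in design.compounds])
    hi = np.array([c.content_range[1] for c in design.compounds])
    if groups is None:
        values = rng.uniform(lo, hi, size=(n_batches, len(names)))
        frame = pd.DataFrame(values, index=ids, columns=names)
    else:
        if groups < 2:
            raise ValueError("groups must be >= 2")
        labels = np.arange(n_batches) % groups
        # Each group gets a distinct random profile location per compound,
        # held well inside the range so the jitter cannot escape it.
        centres = lo + (rng.permuted(np.arange(groups))[:, None] + 0.5) / groups * (hi - lo)
        jitter = rng.uniform(-0.05, 0.05, size=(n_batches, len(names))) * (hi - lo)
        values = np.clip(centres[labels] + jitter, lo, hi)
        frame = pd.DataFrame(values, index=ids, columns=names)
        frame.attrs["groups"] = labels.tolist()
    if (frame[design.marker.name] <= 0).any():
        raise RuntimeError("marker contents must be positive")  # ranges guarantee this
    return frame


def _peak_area(design: StudyDesign, spec: CompoundSpec, content_mg_g: float) -> tuple[float, str | None]:
    """True (noise-free) peak area for a content, with extrapolation flags."""
    if content_mg_g < 0:
        raise ValueError(f"{spec.name}: negative content {content_mg_g}")
    if content_mg_g == 0:
        return 0.0, "absent"
    conc = design.dilution.content_to_conc(content_mg_g)
    area = spec.calibration.predict(conc)
    flag = None
    if not spec.calibration.in_range(conc):
        flag = "below_range" if conc < spec.calibration.linear_range[0] else "above_range"
    if area < 0:
        return 0.0, "clipped"
    return area, flag


def _add_gaussian(time: np.ndarray, signal: np.ndarray, center: float, area: float) -> None:
    if area <= 0:
        return
    h = area / (PEAK_SD * np.sqrt(2 * np.pi))
    lo = np.searchsorted(time, center - 6 * PEAK_SD)
    hi = np.searchsorted(time, center + 6 * PEAK_SD)
    t = time[lo:hi]
    signal[lo:hi] += h * np.exp(-0.5 * ((t - center) / PEAK_SD) ** 2)


def simulate_chromatogram(
    design: StudyDesign, contents_row, seed: int, sample_id: str = ""
) -> Chromatogram:
    """Simulate one batch chromatogram from its true contents.

    Each quantified compound contributes a Gaussian at its retention time
    whose integrated area equals the calibration prediction at the injected
    concentration (content * mass / volume, in ug/ml), multiplied by
    (1 + detector noise). Unidentified common peaks get their nominal
    concentration scaled by a per-batch factor. A polynomial baseline drift
    of the configured amplitude is added last.

    Negative predicted areas (possible below the linear range when the
    calibration intercept is negative) are clipped to 0 and flagged in
    ``metadata["flags"]``.
    """
    rng = np.random.default_rng(seed)
    contents = pd.Series(contents_row, dtype=float)
    missing = set(design.compound_names) - set(contents.index)
    if missing:
        raise ValueError(f"contents_row missing compounds: {sorted(missing)}")
    if (contents < 0).any():
        raise ValueError("contents must be non-negative")

    time = np.arange(0.0, TIME_MAX + GRID_STEP / 2, GRID_STEP)
    signal = np.zeros_like(time)
    flags: dict[str, str] = {}
    true_areas: dict[str, float] = {}

    cv = design.noise.detector_cv
    for spec in design.compounds:
        area, flag = _peak_area(design, spec, float(contents[spec.name]))
        if flag:
            flags[spec.name] = flag
        if cv > 0 and area > 0:
            area = max(area * (1.0 + cv * rng.standard_normal()), 0.0)
        elif cv > 0:
            rng.standard_normal()  # keep the stream aligned across designs
        true_areas[spec.name] = area
        _add_gaussian(time, signal, spec.retention_time, area)

    for i, u in enumerate(design.unidentified_peaks):
        conc = u.nominal_conc_ug_ml * (1.0 + u.batch_variation * rng.uniform(-1, 1))
        area = u.response_factor * conc
        if cv > 0:
            area = max(area * (1.0 + cv * rng.standard_normal()), 0.0)
        true_areas[f"U{i + 1}"] = area
        _add_gaussian(time, signal, u.retention_time, area)

    drift = design.noise.baseline_drift_mau
    if drift > 0:
        u01 = time / TIME_MAX
        coef = rng.uniform(0.2, 1.0, size=3)
        poly = coef[0] + coef[1] * u01 + coef[2] * u01**2
        signal += drift * poly / poly.max()

    return Chromatogram(
        time=time,
        intensity=signal,
        sample_id=sample_id,
        metadata={"flags": flags, "true_areas": true_areas, "seed": int(seed)},
    )


def standard_areas(design: StudyDesign, conc_mg_ml: dict, seed: int | None = None) -> pd.Series:
    """Peak areas of a standard solution injected directly (no dilution).

    ``conc_mg_ml`` maps compound name to its concentration in the standard
    (mg/ml). Detector noise is applied when the design carries any and a
    seed is given.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    out = {}
    for spec in design.compounds:
        if spec.name not in conc_mg_ml:
            continue
        conc_ug = conc_mg_ml[spec.name] * 1000.0
        area = max(spec.calibration.predict(conc_ug), 0.0)
        if rng is not None and design.noise.detector_cv > 0:
            area = max(area * (1.0 + design.noise.detector_cv * rng.standard_normal()), 0.0)
        out[spec.name] = area
    return pd.Series(out)


@dataclass
class ValidationSets:
    """Replicate and spike designs for method validation.

    ``precision``: 6 injections of the same mixed standard solution;
    ``stability``: the same sample solution at 6 time points over 24 h;
    ``repeatability``: 6 independent preparations of one batch; all three
    are injection x compound area tables. ``recovery`` holds spiked-sample
    records on the content scale (base, added, found in mg/g).
    """

    precision: pd.DataFrame
    stability: pd.DataFrame
    repeatability: pd.DataFrame
    recovery: pd.DataFrame


def simulate_validation_sets(design: StudyDesign, cv: float, seed: int) -> ValidationSets:
    """Generate the four validation data sets at a given detector cv.

    Replicate areas are the true area times (1 + cv * N(0,1)); recovered
    spike contents likewise. With cv=0 all replicates are identical and all
    recoveries are exactly 100%.
    """
    if not 0.0 <= cv <= 0.1:
        raise ValueError(f"cv must be in [0, 0.1], got {cv}")
    rng = np.random.default_rng(seed)
    names = design.compound_names

    base_area = standard_areas(design, MIXED_STANDARD_MG_ML).reindex(names)

    def replicate_table(n: int, index) -> pd.DataFrame:
        noise = 1.0 + cv * rng.standard_normal(size=(n, len(names)))
        return pd.DataFrame(np.maximum(base_area.to_numpy() * noise, 0.0), index=index, columns=names)

    precision = replicate_table(6, [f"inj{i + 1}" for i in range(6)])
    stability = replicate_table(6, pd.Index([0, 2, 6, 8, 16, 24], name="hours"))

    # Repeatability: six preparations of one batch at its reference contents.
    ref_content = pd.Series({c.name: 0.5 * sum(c.content_range) for c in design.compounds})
    prep_area = pd.Series(
        {c.name: _peak_area(design, c, float(ref_content[c.name]))[0] for c in design.compounds}
    ).reindex(names)
    noise = 1.0 + cv * rng.standard_normal(size=(6, len(names)))
    repeatability = pd.DataFrame(
        np.maximum(prep_area.to_numpy() * noise, 0.0),
        index=[f"prep{i + 1}" for i in range(6)],
        columns=names,
    )

    # Recovery: spike the same batch at ~50/100/150% of its base content.
    records = []
    for spec in design.compounds:
        base = float(ref_content[spec.name])
        for level, frac in (("low", 0.5), ("medium", 1.0), ("high", 1.5)):
            added = frac * base
            for rep in range(3):
                found = (base + added) * (1.0 + cv * rng.standard_normal())
                records.append(
                    {
                        "compound": spec.name,
                        "level": level,
                        "replicate": rep + 1,
                        "base_mg_g": base,
                        "added_mg_g": added,
                        "found_mg_g": max(found, 0.0),
                    }
                )
    return ValidationSets(
        precision=precision,
        stability=stability,
        repeatability=repeatability,
        recovery=pd.DataFrame(records),
    )


def simulate_study(
    design: StudyDesign, contents: pd.DataFrame, seed: int
) -> list[Chromatogram]:
    """Simulate one chromatogram per batch, with per-batch seed substreams."""
    seeds = np.random.SeedSequence(seed).spawn(len(contents))
    return [
        simulate_chromatogram(design, contents.iloc[i], seeds[i].generate_state(1)[0] % (2**31), sample_id=str(contents.index[i]))
        for i in range(len(contents))
    ]
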