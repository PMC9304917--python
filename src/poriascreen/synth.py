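"""Synthetic FT-NIR spectra, HPLC common-peak tables, and calibration series.

The reference design these emulate: 200 sclerotium samples (2 parts x 10 growing
regions, 3 replicate scans each) on a 10,000-4,000 cm^-1 grid at 4 cm^-1
resolution, with between-part spectral differences larger than between-region
differences; an HPLC table of 9 common peaks of which 6 discriminate the
parts; and 5-analyte triterpenoid calibration series.

Spectra are sums of Gaussian overtone/combination bands at the conventional
FT-NIR assignments for fungal polysaccharide/triterpenoid material (C-H
overtones near 8,300 and 6,850 cm^-1, O-H/C-H combination bands near 5,600,
5,200, 4,400 and 4,100 cm^-1) over a low-order polynomial baseline. The part
effect scales the bands inside the two discriminating windows
(7,200-5,350 and 5,200-4,000 cm^-1); the region effect is a smaller per-region
band rescaling. Scatter follows the standard multiplicative + additive model
that MSC and SNV are designed to remove, drawn per record so replicate scans
of a sample differ by realistic re-presentation effects — that replicate
variation is what the 2D correlation maps read out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from poriascreen._seeds import stream
from poriascreen.spectra import PORIA, PORIAE_CUTIS, SpectraSet

_DEFAULT_BANDS = (8300.0, 6850.0, 5600.0, 5200.0, 4400.0, 4100.0)
# amplitude (absorbance units) and half-width (cm^-1) per default band
_DEFAULT_AMPLITUDES = (0.45, 0.30, 0.50, 0.60, 0.40, 0.35)
_DEFAULT_WIDTHS = (260.0, 220.0, 230.0, 180.0, 130.0, 110.0)
# wavenumber windows carrying the part difference
PART_WINDOWS = ((5350.0, 7200.0), (4000.0, 5200.0))
# replicate-level fraction of the sample-level scatter / drift scales:
# back-to-back scans share packing and instrument state almost entirely
_REPLICATE_JITTER = 0.2


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass
class SynthConfig:
    """Knobs of the spectral generator.

    part_effect is the fractional band-intensity difference between the two
    parts inside the discriminating windows; region_effect the (smaller)
    fractional per-region rescaling. noise_sd is additive white noise in
    absorbance units; baseline_drift_sd the scale of per-record offset/tilt;
    scatter_sd the sd of the per-record multiplicative scatter factor.
    """

    n_per_part: int = 100
    n_regions: int = 10
    n_replicates: int = 3
    grid_start: float = 10_000.0
    grid_end: float = 4_000.0
    grid_step: float = 4.0
    band_centers: tuple[float, ...] = _DEFAULT_BANDS
    part_effect: float = 0.12
    region_effect: float = 0.03
    noise_sd: float = 0.002
    baseline_drift_sd: float = 0.01
    scatter_sd: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.grid_step <= 0:
            raise ConfigError("grid_step must be > 0")
        if self.grid_start <= self.grid_end:
            raise ConfigError("grid_start must exceed grid_end")
        n_grid = int(round((self.grid_start - self.grid_end) / self.grid_step)) + 1
        if n_grid < 8:
            raise ConfigError(f"grid of length {n_grid} < 8")
        if self.region_effect < 0:
            raise ConfigError("region_effect must be >= 0")
        if self.part_effect < self.region_effect or (
            self.part_effect == self.region_effect and self.part_effect > 0
        ):
            raise ConfigError("part_effect must exceed region_effect")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2 (2DCOS needs >= 2 traces)")
        if self.n_per_part < 1 or self.n_regions < 1:
            raise ConfigError("n_per_part and n_regions must be >= 1")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_start - self.grid_end) / self.grid_step)) + 1
        return self.grid_start - self.grid_step * np.arange(n)


def _band_params(centers: tuple[float, ...]) -> tuple[np.ndarray, np.ndarray]:
    if tuple(centers) == _DEFAULT_BANDS:
        return np.array(_DEFAULT_AMPLITUDES), np.array(_DEFAULT_WIDTHS)
    c = np.asarray(centers, dtype=float)
    return np.full(c.size, 0.4), np.full(c.size, 150.0)


def generate_spectra(config: SynthConfig) -> SpectraSet:
    """Simulate the replicated two-part, multi-region FT-NIR dataset.

    Returns ``2 * n_per_part * n_replicates`` records. Identical seeds give
    bitwise-identical output.
    """
    config.validate()
    wn = config.grid()
    centers = np.asarray(config.band_centers, dtype=float)
    amps, widths = _band_params(config.band_centers)
    in_window = np.zeros(centers.size, dtype=bool)
    for lo, hi in PART_WINDOWS:
        in_window |= (centers >= lo) & (centers <= hi)

    # fixed per-region band rescaling, shared by both parts
    rng_region = stream(config.seed, "synth-regions")
    region_u = rng_region.uniform(-0.5, 0.5, size=(config.n_regions, centers.size))

    # smooth concave baseline common to all records
    x01 = (config.grid_start - wn) / (config.grid_start - config.grid_end)
    baseline = 0.10 + 0.05 * x01 + 0.03 * x01**2

    profiles = amps[None, :] * np.exp(
        -0.5 * ((wn[:, None] - centers[None, :]) / widths[None, :]) ** 2
    )  # (p, n_bands)

    rng_rec = stream(config.seed, "synth-records")
    rows, parts, regions, sids, reps = [], [], [], [], []
    for part, sign in ((PORIA, +0.5), (PORIAE_CUTIS, -0.5)):
        for i in range(config.n_per_part):
            region = i % config.n_regions + 1
            sid = f"{part}-R{region:02d}-S{i:03d}"
            gains = np.ones(centers.size)
            gains[in_window] *= 1.0 + sign * config.part_effect
            gains *= 1.0 + config.region_effect * region_u[region - 1]
            clean = baseline + (profiles * gains[None, :]).sum(axis=1)
            # Scatter and baseline drift are two-level: the large components
            # are per sample (packing of this portion of powder, slow
            # instrument drift between samples), while replicate scans taken
            # back-to-back differ by a small jitter plus a monotone scan-order
            # scatter component (the powder compacts a little with each
            # re-scan). The ordered component is what makes the replicate
            # series a usable 2DCOS perturbation: a perturbation series must
            # vary systematically along its ordering variable, not only by
            # iid noise.
            scatter_s = rng_rec.standard_normal()
            offset_s = config.baseline_drift_sd * rng_rec.standard_normal()
            tilt_s = config.baseline_drift_sd * rng_rec.standard_normal()
            for rep in range(1, config.n_replicates + 1):
                order = rep - (config.n_replicates + 1) / 2.0
                scatter = 1.0 + config.scatter_sd * (
                    scatter_s + order + _REPLICATE_JITTER * rng_rec.standard_normal()
                )
                offset = offset_s + _REPLICATE_JITTER * (
                    config.baseline_drift_sd * rng_rec.standard_normal()
                )
                tilt = tilt_s + _REPLICATE_JITTER * (
                    config.baseline_drift_sd * rng_rec.standard_normal()
                )
                noise = config.noise_sd * rng_rec.standard_normal(wn.size)
                rows.append(scatter * clean + offset + tilt * x01 + noise)
                parts.append(part)
                regions.append(region)
                sids.append(sid)
                reps.append(rep)

    return SpectraSet(
        wavenumbers=wn,
        absorbance=np.array(rows),
        part_label=np.array(parts, dtype=object),
        region_label=np.array(regions),
        sample_id=np.array(sids, dtype=object),
        replicate_id=np.array(reps),
        meta={"generator": "synth.generate_spectra", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# HPLC common-peak tables
# ---------------------------------------------------------------------------

_DEFAULT_PEAK_LABELS = (2, 4, 5, 6, 8, 13, 14, 15, 16)
_DEFAULT_DISCRIMINANT = frozenset({4, 6, 13, 14, 15, 16})
# base (pre-normalization) mean areas; the three non-discriminant common
# peaks carry most of the mass so sum-normalization closure stays mild
_DEFAULT_BASE_AREAS = {
    2: 0.30, 4: 0.05, 5: 0.28, 6: 0.05, 8: 0.17, 13: 0.03, 14: 0.04,
    15: 0.05, 16: 0.03,
}


@dataclass
class PeakTableConfig:
    """Configuration of the common-peak area generator.

    Columns are labeled with chromatogram peak numbers (the 9 common peaks of
    a longer elution profile), so discriminant peaks are given as labels.
    ``effect_sizes`` maps peak label -> multiplicative shift applied in the
    *Poria* class; peaks not listed default to ``default_effect`` when
    discriminant, 1.0 otherwise.
    """

    n_peaks: int = 9
    peak_labels: tuple[int, ...] = _DEFAULT_PEAK_LABELS
    discriminant_peaks: frozenset[int] = _DEFAULT_DISCRIMINANT
    effect_sizes: dict[int, float] = field(default_factory=dict)
    default_effect: float = 1.8
    area_cv: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if len(self.peak_labels) != self.n_peaks:
            raise ConfigError("peak_labels length must equal n_peaks")
        if not set(self.discriminant_peaks) <= set(self.peak_labels):
            raise ConfigError("discriminant_peaks must be a subset of peak_labels")
        if self.default_effect <= 0 or any(
            e <= 0 for e in self.effect_sizes.values()
        ):
            raise ConfigError("effect sizes must be > 0")
        if self.area_cv < 0:
            raise ConfigError("area_cv must be >= 0")

    def effect_for(self, label: int) -> float:
        if label in self.effect_sizes:
            return self.effect_sizes[label]
        return self.default_effect if label in self.discriminant_peaks else 1.0


@dataclass
class PeakTable:
    """Samples x common-peak relative areas, rows summing to 1."""

    peak_labels: tuple[int, ...]
    areas: np.ndarray  # (n, n_peaks)
    part_label: np.ndarray
    sample_id: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.areas, columns=[f"peak_{l}" for l in self.peak_labels]
        )
        df.insert(0, "sample_id", self.sample_id)
        df.insert(1, "part", self.part_label)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PeakTable":
        df = pd.read_csv(path)
        peak_cols = [c for c in df.columns if c.startswith("peak_")]
        return cls(
            peak_labels=tuple(int(c.split("_")[1]) for c in peak_cols),
            areas=df[peak_cols].to_numpy(),
            part_label=df["part"].to_numpy(dtype=object),
            sample_id=df["sample_id"].to_numpy(dtype=object),
        )

    def y01(self, positive: str = PORIA) -> np.ndarray:
        return (self.part_label.astype(str) == positive).astype(float)


def generate_peak_table(config: PeakTableConfig, n_per_part: int) -> PeakTable:
    """Two-class relative-area table with planted discriminant peaks.

    Discriminant peaks are multiplicatively shifted in the *Poria* class;
    per-sample lognormal noise with coefficient of variation ``area_cv`` is
    applied before sum-normalizing each row to relative areas.
    """
    config.validate()
    if n_per_part < 1:
        raise ConfigError("n_per_part must be >= 1")
    labels = tuple(config.peak_labels)
    base = np.array([_DEFAULT_BASE_AREAS.get(l, 0.1) for l in labels])
    effects = np.array([config.effect_for(l) for l in labels])
    sigma = np.sqrt(np.log1p(config.area_cv**2))

    rng = stream(config.seed, "synth-peaks")
    rows, parts, sids = [], [], []
    for part, boost in ((PORIA, effects), (PORIAE_CUTIS, np.ones_like(effects))):
        mean = base * boost
        z = rng.standard_normal((n_per_part, len(labels)))
        raw = mean[None, :] * np.exp(sigma * z - 0.5 * sigma**2)
        for i in range(n_per_part):
            rows.append(raw[i] / raw[i].sum())
            parts.append(part)
            sids.append(f"{part}-H{i:03d}")
    return PeakTable(
        peak_labels=labels,
        areas=np.array(rows),
        part_label=np.array(parts, dtype=object),
        sample_id=np.array(sids, dtype=object),
    )


# ---------------------------------------------------------------------------
# Calibration standards
# ---------------------------------------------------------------------------

# (name, (low, high) ug/ml, true slope, true intercept); slopes/intercepts in
# peak-area units per (ug/ml) as printed by typical DAD integrators
_DEFAULT_ANALYTES = (
    ("dehydrotumulosic acid", (5.00, 999.0), 1.52e7, 8.1e4),
    ("poricoic acid A", (0.22, 6730.0), 1.9016e7, 1.5074e6),
    ("dehydropachymic acid", (2.4, 480.0), 1.21e7, 5.6e4),
    ("pachymic acid", (10.3, 1240.0), 7.9057e6, 4.2996e4),
    ("dehydrotrametenolic acid", (0.49, 2450.0), 2.1538e7, 1.0719e5),
)


@dataclass
class CalibrationConfig:
    """Standard-series generator: per-analyte range, true line, and noise.

    ``noise_sd`` is relative — the additive area noise has standard deviation
    ``noise_sd * (slope * high + intercept)`` so analytes whose slopes span
    orders of magnitude are comparably noisy.
    """

    analytes: tuple = _DEFAULT_ANALYTES
    n_levels: int = 6
    noise_sd: float = 0.002
    spacing: str = "geometric"  # or "linear"
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 3:
            raise ConfigError("n_levels must be >= 3 to fit and assess linearity")
        if self.spacing not in ("geometric", "linear"):
            raise ConfigError("spacing must be 'geometric' or 'linear'")
        for name, (lo, hi), slope, intercept in self.analytes:
            if not (0 < lo < hi):
                raise ConfigError(f"range for {name} must be positive, increasing")


@dataclass
class CalibrationData:
    """Per-analyte (concentration, area) standard series."""

    analytes: list[dict]  # name, concentration, area, true_slope, true_intercept

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for a in self.analytes:
            for c, y in zip(a["concentration"], a["area"]):
                recs.append(
                    {"analyte": a["name"], "concentration_ug_ml": c, "area": y}
                )
        return pd.DataFrame(recs)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def analyte(self, name: str) -> dict:
        for a in self.analytes:
            if a["name"] == name:
                return a
        raise KeyError(name)


def generate_calibration_set(config: CalibrationConfig) -> CalibrationData:
    """Serial-dilution standard curves with additive area noise.

    Levels are geometrically spaced over each analyte's range, the usual
    layout of a dilution series spanning decades.
    """
    config.validate()
    rng = stream(config.seed, "synth-calibration")
    out = []
    for name, (lo, hi), slope, intercept in config.analytes:
        if config.spacing == "geometric":
            conc = np.geomspace(lo, hi, config.n_levels)
        else:
            conc = np.linspace(lo, hi, config.n_levels)
        sd = config.noise_sd * (slope * hi + intercept)
        area = slope * conc + intercept + sd * rng.standard_normal(config.n_levels)
        out.append(
            {
                "name": name,
                "concentration": conc,
                "area": area,
                "true_slope": slope,
                "true_intercept": intercept,
            }
        )
    return CalibrationData(analytes=out)
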