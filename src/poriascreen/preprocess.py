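"""Spectral pretreatment: replicate averaging, SG second derivative, SNV, MSC.

Second derivative (SD) removes wavelength-linear baseline drift and sharpens
overlapped absorption bands; standard normal variate (SNV) and multiplicative
scatter correction (MSC) remove the per-record multiplicative/additive scatter
of diffuse-reflectance measurements. All math is orientation-agnostic: the
grid may run 10,000 -> 4,000 cm^-1 (the plotting convention) or ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from poriascreen.spectra import SpectraSet


@dataclass
class PreprocessSpec:
    """Pretreatment choice and Savitzky-Golay parameters.

    The window/order defaults (17 points, cubic) are common FT-NIR practice;
    the derivative is scaled by the true grid spacing so output units are
    absorbance / (cm^-1)^2.
    """

    method: str = "none"  # none | SD | SNV | MSC
    sg_window: int = 17
    sg_polyorder: int = 3
    msc_reference: str | np.ndarray = "mean"

    def validate(self) -> None:
        if self.method not in ("none", "SD", "SNV", "MSC"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "SD":
            if self.sg_polyorder < 2:
                raise ValueError("sg_polyorder must be >= 2 for a 2nd derivative")
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
                raise ValueError("sg_window must be odd and > sg_polyorder")


def average_replicates(s: SpectraSet) -> SpectraSet:
    """One record per sample: the arithmetic mean over its replicate scans."""
    sids = s.unique_samples()
    counts = s.replicate_counts()
    expected = counts[sids[0]]
    for sid, c in counts.items():
        if c != expected:
            raise ValueError(f"sample {sid!r} has {c} replicates, expected {expected}")
    str_ids = s.sample_id.astype(str)
    rows, parts, regions, reps = [], [], [], []
    for sid in sids:
        mask = str_ids == sid
        rows.append(s.absorbance[mask].mean(axis=0))
        parts.append(s.part_label[mask][0])
        regions.append(s.region_label[mask][0])
        reps.append(1)
    return SpectraSet(
        wavenumbers=s.wavenumbers.copy(),
        absorbance=np.array(rows),
        part_label=np.array(parts, dtype=object),
        region_label=np.array(regions),
        sample_id=np.array(sids, dtype=object),
        replicate_id=np.array(reps),
        meta={**s.meta, "averaged": True},
    )


def second_derivative(s: SpectraSet, spec: PreprocessSpec | None = None) -> SpectraSet:
    """Savitzky-Golay second derivative per record.

    Edge points where the window does not fit are filled by evaluating the
    boundary polynomial fit (scipy's ``mode="interp"``), so the output grid
    equals the input grid with no NaNs; the edge rule is flagged in metadata.
    """
    spec = spec or PreprocessSpec(method="SD")
    if spec.sg_polyorder < 2 or spec.sg_window % 2 == 0 or (
        spec.sg_window <= spec.sg_polyorder
    ):
        raise ValueError("need odd sg_window > sg_polyorder >= 2")
    steps = np.diff(s.wavenumbers)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-8):
        raise ValueError("second derivative requires a uniform grid")
    if spec.sg_window >= s.n_points:
        raise ValueError("sg_window must be smaller than the grid length")
    delta = abs(steps[0]) if steps.size else 1.0
    out = savgol_filter(
        s.absorbance,
        window_length=spec.sg_window,
        polyorder=spec.sg_polyorder,
        deriv=2,
        delta=delta,
        axis=1,
        mode="interp",
    )
    # a descending grid flips the sign of odd derivatives only; the 2nd
    # derivative is orientation-invariant, so no sign fix is needed
    return s.with_absorbance(
        out, preprocess="SD", sg_window=spec.sg_window,
        sg_polyorder=spec.sg_polyorder, edge_rule="boundary-polynomial",
    )


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: each record centered and scaled to unit sd."""
    mean = s.absorbance.mean(axis=1, keepdims=True)
    sd = s.absorbance.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(
            f"constant record(s) cannot be SNV-scaled: {[s.sample_id[i] for i in flat]}"
        )
    return s.with_absorbance((s.absorbance - mean) / sd, preprocess="SNV")


def msc(s: SpectraSet, spec: PreprocessSpec | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each record x is regressed on the reference r (x ~= a*r + b by least
    squares) and replaced by (x - b) / a. Reference defaults to the set mean.
    """
    spec = spec or PreprocessSpec(method="MSC")
    if isinstance(spec.msc_reference, str):
        if spec.msc_reference != "mean":
            raise ValueError("msc_reference must be 'mean' or an explicit spectrum")
        ref = s.absorbance.mean(axis=0)
    else:
        ref = np.asarray(spec.msc_reference, dtype=float)
        if ref.shape != (s.n_points,):
            raise ValueError("explicit MSC reference length must match the grid")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference is constant")
    X = s.absorbance
    a = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(a == 0):
        raise ValueError("record orthogonal to MSC reference (slope 0)")
    b = X.mean(axis=1) - a * ref.mean()
    out = (X - b[:, None]) / a[:, None]
    return s.with_absorbance(out, preprocess="MSC")


def mean_spectrum(s: SpectraSet) -> np.ndarray:
    """Grand mean spectrum of the set (used for plots and MSC reference)."""
    return s.absorbance.mean(axis=0)


def apply(s: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Dispatch on ``spec.method``; ``none`` returns the input unchanged."""
    spec.validate()
    if spec.method == "none":
        return s
    if spec.method == "SD":
        return second_derivative(s, spec)
    if spec.method == "SNV":
        return snv(s)
    return msc(s, spec)
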