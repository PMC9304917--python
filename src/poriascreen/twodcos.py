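"""Generalized two-dimensional correlation spectroscopy (2DCOS).

A perturbation-ordered series of m spectra is spread into a synchronous map
Phi(v1, v2) = W(v1)^T W(v2) / (m - 1) (in-phase intensity co-variation), an
asynchronous map Psi(v1, v2) = W(v1)^T N W(v2) / (m - 1) built with the
antisymmetric Hilbert-Noda transform N_jk = 1 / (pi (k - j)) (out-of-phase
variation), and their element-wise product, the integrated map (i2DCOS).
W holds the dynamic spectra: the series minus a reference (conventionally the
series mean). Diagonal features of Phi are auto-peaks (always >= 0);
off-diagonal features are cross-peaks.

Here the perturbation series of a sample is its replicate scans, so each
sample yields one (synchronous, asynchronous, integrated) map triple.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from poriascreen.spectra import SpectraSet


@dataclass
class DynamicSpectra:
    """Mean- (or reference-) subtracted perturbation series, m traces x p points."""

    W: np.ndarray
    reference: np.ndarray
    perturbation_interval: float = 1.0

    @property
    def m(self) -> int:
        return self.W.shape[0]


@dataclass
class CorrelationMaps:
    sync: np.ndarray
    async_: np.ndarray
    integrated: np.ndarray
    wavenumbers: np.ndarray
    sample_id: str = ""


def dynamic_spectra(
    traces: np.ndarray, reference: str | np.ndarray = "mean"
) -> DynamicSpectra:
    """Subtract the reference spectrum from each trace of the series."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 perturbation-ordered traces")
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError("reference must be 'mean' or an explicit spectrum")
        ref = traces.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (traces.shape[1],):
            raise ValueError("reference length must match the trace grid")
    return DynamicSpectra(W=traces - ref, reference=ref)


def synchronous(d: DynamicSpectra) -> np.ndarray:
    """Phi = W^T W / (m - 1): symmetric, PSD, non-negative auto-peak diagonal."""
    return d.W.T @ d.W / (d.m - 1)


def hilbert_noda(m: int) -> np.ndarray:
    """The m x m Hilbert-Noda matrix: 0 on the diagonal, 1/(pi (k - j)) off it."""
    if m < 1:
        raise ValueError("m must be >= 1")
    j = np.arange(m)
    diff = j[None, :] - j[:, None]
    with np.errstate(divide="ignore"):
        N = np.where(diff == 0, 0.0, 1.0 / (np.pi * np.where(diff == 0, 1, diff)))
    return N


def asynchronous(d: DynamicSpectra) -> np.ndarray:
    """Psi = W^T N W / (m - 1): antisymmetric with zero diagonal.

    For m = 2 mean-centered dynamics the two traces are opposite, so Psi
    vanishes identically; at least 3 traces are needed for a nonzero map.
    """
    N = hilbert_noda(d.m)
    return d.W.T @ N @ d.W / (d.m - 1)


def integrated(sync: np.ndarray, async_: np.ndarray) -> np.ndarray:
    """Element-wise product Phi * Psi (antisymmetric, like Psi)."""
    sync = np.asarray(sync, dtype=float)
    async_ = np.asarray(async_, dtype=float)
    if sync.shape != async_.shape:
        raise ValueError(f"shape mismatch {sync.shape} vs {async_.shape}")
    return sync * async_


@dataclass
class MapImage:
    """Fixed-size rendering of a correlation map.

    ``pixels`` is (height, width, channels) in [0, 1]; a zero map renders as
    flat mid-scale (0.5) since the symmetric diverging scale centers at 0.
    """

    pixels: np.ndarray
    sample_id: str
    kind: str  # sync | async | integrated


def _resample(map_: np.ndarray, size: int) -> np.ndarray:
    """Deterministic bilinear resampling to size x size."""
    p = map_.shape[0]
    if p == size:
        return map_.astype(float)
    src = np.linspace(0, p - 1, size)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, p - 1)
    f = src - i0
    rows = map_[i0] * (1 - f)[:, None] + map_[i1] * f[:, None]
    cols = rows[:, i0] * (1 - f)[None, :] + rows[:, i1] * f[None, :]
    return cols


def render_map(
    map_: np.ndarray,
    size: int = 64,
    color_scale: float | None = None,
    sample_id: str = "",
    kind: str = "",
) -> MapImage:
    """Render a correlation map on a symmetric diverging scale centered at 0.

    ``color_scale`` fixes the saturation amplitude (shared scales make two
    maps comparable); by default the map's own max |value| is used. Values
    map linearly to [0, 1] with 0 -> 0.5 and saturation beyond +-color_scale.
    """
    map_ = np.asarray(map_, dtype=float)
    if not np.all(np.isfinite(map_)):
        raise ValueError("map contains non-finite values")
    amp = float(np.abs(map_).max()) if color_scale is None else float(color_scale)
    small = _resample(map_, size)
    if amp == 0:
        px = np.full((size, size), 0.5)
    else:
        px = np.clip(small / (2 * amp) + 0.5, 0.0, 1.0)
    return MapImage(pixels=px[:, :, None], sample_id=sample_id, kind=kind)


def save_map_png(img: MapImage, path: str | Path, cmap: str = "RdBu_r") -> None:
    """Write a MapImage to PNG through a matplotlib diverging colormap."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colored = plt.get_cmap(cmap)(img.pixels[:, :, 0])
    plt.imsave(str(path), colored)


def downsample_grid(s: SpectraSet, n_points: int) -> SpectraSet:
    """Reduce the wavenumber grid by averaging contiguous blocks.

    Bounds the p x p correlation maps; block averaging keeps band shapes while
    suppressing white noise.
    """
    p = s.n_points
    if n_points >= p:
        return s
    edges = np.linspace(0, p, n_points + 1).astype(int)
    wn = np.array([s.wavenumbers[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    ab = np.stack(
        [s.absorbance[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])],
        axis=1,
    )
    return SpectraSet(
        wavenumbers=wn,
        absorbance=ab,
        part_label=s.part_label,
        region_label=s.region_label,
        sample_id=s.sample_id,
        replicate_id=s.replicate_id,
        meta={**s.meta, "downsampled_to": n_points},
    )


def per_sample_maps(
    s: SpectraSet, max_grid: int = 64, reference: str | np.ndarray = "mean"
) -> list[CorrelationMaps]:
    """One (sync, async, integrated) triple per sample.

    Each sample's replicate scans form its perturbation series; 200 samples
    with 3 replicates therefore yield 200 triples = 600 maps. The grid is
    block-averaged down to ``max_grid`` points first.
    """
    small = downsample_grid(s, max_grid)
    for sid, count in small.replicate_counts().items():
        if count < 2:
            raise ValueError(f"sample {sid!r} has {count} replicate(s); need >= 2")
    out = []
    for sid in small.unique_samples():
        traces = small.sample_traces(sid)
        d = dynamic_spectra(traces, reference)
        phi = synchronous(d)
        psi = asynchronous(d)
        out.append(
            CorrelationMaps(
                sync=phi,
                async_=psi,
                integrated=integrated(phi, psi),
                wavenumbers=small.wavenumbers,
                sample_id=str(sid),
            )
        )
    return out


# -- brute-force oracles (reference implementations for verification) -------


def synchronous_bruteforce(d: DynamicSpectra) -> np.ndarray:
    """Double-loop evaluation of Phi; oracle for the matrix form."""
    m, p = d.W.shape
    out = np.zeros((p, p))
    for v1 in range(p):
        for v2 in range(p):
            acc = 0.0
            for i in range(m):
                acc += d.W[i, v1] * d.W[i, v2]
            out[v1, v2] = acc / (m - 1)
    return out


def asynchronous_bruteforce(d: DynamicSpectra) -> np.ndarray:
    """Triple-loop evaluation of Psi; oracle for the matrix form."""
    m, p = d.W.shape
    N = hilbert_noda(m)
    out = np.zeros((p, p))
    for v1 in range(p):
        for v2 in range(p):
            acc = 0.0
            for i in range(m):
                for j in range(m):
                    acc += d.W[i, v1] * N[i, j] * d.W[j, v2]
            out[v1, v2] = acc / (m - 1)
    return out
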