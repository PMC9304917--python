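"""In-memory container for replicated FT-NIR spectra with part/region labels."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

PORIA = "Poria"
PORIAE_CUTIS = "PoriaeCutis"


@dataclass
class SpectraSet:
    """A stack of absorbance records on a shared wavenumber grid.

    Attributes
    ----------
    wavenumbers : (p,) float array, strictly monotone (conventionally
        descending, 10,000 -> 4,000 cm^-1).
    absorbance : (n, p) float array, one row per scanned record.
    part_label : (n,) str array, each ``"Poria"`` or ``"PoriaeCutis"``.
    region_label : (n,) int array, growing-region index (1-based).
    sample_id : (n,) str array; replicate scans of one physical sample share
        the id.
    replicate_id : (n,) int array, 1-based scan order within a sample. This
        scan order is the perturbation order used by the 2D correlation maps.
    meta : free-form provenance dict (preprocessing flags etc.).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    part_label: np.ndarray
    region_label: np.ndarray
    sample_id: np.ndarray
    replicate_id: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.part_label = np.asarray(self.part_label, dtype=object)
        self.region_label = np.asarray(self.region_label, dtype=int)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.replicate_id = np.asarray(self.replicate_id, dtype=int)
        self.validate()

    # -- contracts ---------------------------------------------------------

    def validate(self) -> None:
        n, p = self.absorbance.shape
        if self.wavenumbers.shape != (p,):
            raise ValueError(
                f"grid length {self.wavenumbers.size} != spectrum length {p}"
            )
        d = np.diff(self.wavenumbers)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumber grid must be strictly monotone")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        for name in ("part_label", "region_label", "sample_id", "replicate_id"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} length != number of records ({n})")
        counts = self.replicate_counts()
        if counts and len(set(counts.values())) > 1:
            raise ValueError(f"unequal replicate counts per sample: {counts}")

    # -- views -------------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def replicate_counts(self) -> dict:
        ids, counts = np.unique(self.sample_id.astype(str), return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def unique_samples(self) -> list[str]:
        """Sample ids in first-appearance order."""
        seen: dict[str, None] = {}
        for sid in self.sample_id:
            seen.setdefault(str(sid), None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[mask],
            part_label=self.part_label[mask],
            region_label=self.region_label[mask],
            sample_id=self.sample_id[mask],
            replicate_id=self.replicate_id[mask],
            meta=dict(self.meta),
        )

    def sample_traces(self, sid: str) -> np.ndarray:
        """Replicate traces of one sample, ordered by replicate_id (m x p)."""
        mask = self.sample_id.astype(str) == str(sid)
        if not mask.any():
            raise KeyError(f"unknown sample_id {sid!r}")
        order = np.argsort(self.replicate_id[mask], kind="stable")
        return self.absorbance[mask][order]

    def with_absorbance(self, absorbance: np.ndarray, **meta) -> "SpectraSet":
        out = replace(self, absorbance=np.asarray(absorbance, dtype=float))
        out.meta = {**self.meta, **meta}
        return out

    def y01(self, positive: str = PORIA) -> np.ndarray:
        """0/1 class coding: 1 for the discriminating class, 0 for the rest."""
        return (self.part_label.astype(str) == positive).astype(float)

    # -- serialization -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the grid as rows with a JSON label sidecar.

        Header ``wavenumber_cm-1, <sample_id>_<replicate>, ...``; one row per
        grid point; floats with 10 significant digits. The sidecar
        ``<path>.labels.json`` holds part/region labels and meta.
        """
        path = Path(path)
        cols = [
            f"{sid}_{rep}" for sid, rep in zip(self.sample_id, self.replicate_id)
        ]
        df = pd.DataFrame(self.absorbance.T, columns=cols)
        df.insert(0, "wavenumber_cm-1", self.wavenumbers)
        df.to_csv(path, index=False, float_format="%.10g")
        sidecar = {
            "part_label": self.part_label.astype(str).tolist(),
            "region_label": self.region_label.tolist(),
            "sample_id": self.sample_id.astype(str).tolist(),
            "replicate_id": self.replicate_id.tolist(),
            "meta": self.meta,
        }
        Path(str(path) + ".labels.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectraSet":
        path = Path(path)
        df = pd.read_csv(path)
        side = json.loads(Path(str(path) + ".labels.json").read_text())
        return cls(
            wavenumbers=df["wavenumber_cm-1"].to_numpy(),
            absorbance=df.drop(columns="wavenumber_cm-1").to_numpy().T,
            part_label=np.array(side["part_label"], dtype=object),
            region_label=np.array(side["region_label"]),
            sample_id=np.array(side["sample_id"], dtype=object),
            replicate_id=np.array(side["replicate_id"]),
            meta=side.get("meta", {}),
        )
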