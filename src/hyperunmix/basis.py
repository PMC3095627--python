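"""Tissue basis spectra: extraction from ROIs, normalization, aggregation.

A basis spectrum is the mean excitation-emission signature of one tissue type
(epithelium, lamina propria, collagen, lymphatic tissue), extracted by
averaging pixels of an expert-chosen ROI at every excitation wavelength in
every emission band.  Because absolute amplitude varies with imaging depth
while spectral shape is stable, each per-site spectrum is normalized to the
maximum of its blue-band excitation spectrum *before* averaging across sites
and animals; the normalization preserves the relative amplitudes of the bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .hyperstack import (
    EmissionBands,
    ExcitationAxis,
    HyperStack,
    ROIMask,
    ValidationError,
)

#: Canonical tissue component names, in conventional display order.
CANONICAL_LABELS = ("epithelium", "lamina_propria", "collagen", "lymphatic")

NORMALIZATION_BAND = "blue"


@dataclass
class BasisSpectrum:
    """Excitation-emission signature of one tissue type.

    ``values[i, b]`` is the mean intensity at excitation index ``i`` in band
    ``b``; ``std`` (same shape, optional) is the sample standard deviation.
    ``normalized`` means the blue-band excitation spectrum has maximum 1.
    """

    label: str
    values: np.ndarray
    wavelengths_nm: np.ndarray
    band_names: tuple
    std: np.ndarray | None = None
    n_sites: int = 1
    n_animals: int = 1
    normalized: bool = False
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.band_names = tuple(self.band_names)
        if self.std is not None:
            self.std = np.asarray(self.std, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("basis values must be [n_ex, n_bands]")
        if self.values.shape != (len(self.wavelengths_nm), len(self.band_names)):
            raise ValidationError(
                f"basis shape {self.values.shape} inconsistent with axis "
                f"({len(self.wavelengths_nm)} wavelengths, {len(self.band_names)} bands)"
            )
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValidationError("basis values must be finite and non-negative")
        if self.std is not None and self.std.shape != self.values.shape:
            raise ValidationError("std must match the shape of values")
        if self.normalized:
            b = self.band_names.index(NORMALIZATION_BAND)
            if not np.isclose(self.values[:, b].max(), 1.0):
                raise ValidationError(
                    "normalized flag set but blue-band excitation maximum is not 1"
                )

    def band_column(self, name: str) -> np.ndarray:
        return self.values[:, self.band_names.index(name)]


@dataclass
class BasisSet:
    """Ordered collection of basis spectra on one shared axis."""

    spectra: list

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("a basis set needs at least one spectrum")
        first = self.spectra[0]
        labels = [s.label for s in self.spectra]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate basis labels: {labels}")
        for s in self.spectra[1:]:
            if not np.array_equal(s.wavelengths_nm, first.wavelengths_nm):
                raise ValidationError("basis spectra on different excitation axes")
            if s.band_names != first.band_names:
                raise ValidationError("basis spectra with different emission bands")
            if s.normalized != first.normalized:
                raise ValidationError("mixed normalization states in basis set")
            if s.calibrated != first.calibrated:
                raise ValidationError("mixed calibration states in basis set")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, label: str) -> BasisSpectrum:
        for s in self.spectra:
            if s.label == label:
                return s
        raise KeyError(f"no basis spectrum labelled {label!r}")

    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.spectra)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    @property
    def band_names(self) -> tuple:
        return self.spectra[0].band_names

    @property
    def normalized(self) -> bool:
        return self.spectra[0].normalized

    @property
    def calibrated(self) -> bool:
        return self.spectra[0].calibrated

    def matrix(self) -> np.ndarray:
        """Stack all signatures into a ``[k, n_ex, n_bands]`` array."""
        return np.stack([s.values for s in self.spectra], axis=0)

    def map(self, fn) -> "BasisSet":
        return BasisSet([fn(s) for s in self.spectra])


# ---------------------------------------------------------------------------
# operations


def extract_roi_spectrum(stack: HyperStack, roi: ROIMask, label: str) -> BasisSpectrum:
    """Average a stack over an ROI into a raw (unnormalized) basis spectrum.

    ``values[i, b]`` is the ROI mean at wavelength ``i`` in band ``b``;
    ``std`` is the sample (n-1) standard deviation across ROI pixels, zero for
    a single-pixel ROI.
    """
    roi.require_nonempty()
    if roi.mask.shape != stack.data.shape[:2]:
        raise ValidationError("ROI shape does not match stack frame")
    pixels = stack.data[roi.mask].astype(float)  # [n_roi, n_ex, n_bands]
    values = pixels.mean(axis=0)
    if pixels.shape[0] > 1:
        std = pixels.std(axis=0, ddof=1)
        std[std <= 1e-12 * np.abs(values)] = 0.0  # identical pixels: exact 0
    else:
        std = np.zeros_like(values)
    return BasisSpectrum(
        label=label,
        values=values,
        std=std,
        wavelengths_nm=stack.excitation.wavelengths_nm.copy(),
        band_names=stack.emission.names,
        normalized=False,
        calibrated=bool(stack.meta.get("calibrated", False)),
    )


def normalize_basis(spec: BasisSpectrum) -> BasisSpectrum:
    """Normalize so the blue-band excitation spectrum has maximum 1.

    Every entry (and std) is divided by the same scalar, preserving relative
    band amplitudes; the operation is idempotent and scale-invariant.
    """
    b = spec.band_names.index(NORMALIZATION_BAND)
    peak = float(spec.values[:, b].max())
    if peak <= 0:
        raise ValidationError(
            f"cannot normalize {spec.label!r}: blue-band column is all zero"
        )
    return replace(
        spec,
        values=spec.values / peak,
        std=None if spec.std is None else spec.std / peak,
        normalized=True,
    )


def aggregate_bases(specs) -> BasisSpectrum:
    """Average normalized per-site spectra of one tissue into the mean basis.

    All inputs must be normalized (per-site normalization happens before
    averaging), share label and shape.  ``std`` is the elementwise sample
    standard deviation across sites; provenance counts are summed, pooling
    all sites equally.
    """
    specs = list(specs)
    if not specs:
        raise ValidationError("aggregate_bases needs at least one spectrum")
    first = specs[0]
    for s in specs:
        if s.label != first.label:
            raise ValidationError(
                f"mixed labels in aggregation: {first.label!r} vs {s.label!r}"
            )
        if s.values.shape != first.values.shape:
            raise ValidationError("mixed shapes in aggregation")
        if not s.normalized:
            raise ValidationError(
                f"spectrum for {s.label!r} is not normalized; normalize each site "
                "before aggregating"
            )
    stackv = np.stack([s.values for s in specs], axis=0)
    values = stackv.mean(axis=0)
    std = stackv.std(axis=0, ddof=1) if len(specs) > 1 else np.zeros_like(values)
    std[std <= 1e-12 * np.abs(values)] = 0.0  # identical sites: exact 0
    # the mean of per-site normalized spectra need not have blue max exactly 1
    blue = first.band_names.index(NORMALIZATION_BAND)
    still_normalized = bool(np.isclose(values[:, blue].max(), 1.0))
    return replace(
        first,
        values=values,
        std=std,
        n_sites=sum(s.n_sites for s in specs),
        n_animals=sum(s.n_animals for s in specs),
        normalized=still_normalized,
    )


# ---------------------------------------------------------------------------
# packaged synthetic basis set


def _gauss(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _sigmoid(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - center) / width))


def canonical_basis(
    axis: ExcitationAxis | None = None, bands: EmissionBands | None = None
) -> BasisSet:
    """Synthetic four-tissue basis set for tests, demos and simulation.

    These are smooth analytic stand-ins, generated from closed-form curves,
    not measurements: epithelium is blue-dominant at short excitation (NADH)
    with a flat green contribution (FAD); lamina propria adds a short-
    wavelength red peak (blood porphyrins); collagen is blue-only and rises
    with excitation wavelength (SHG transmits poorly below ~780 nm); lymphatic
    tissue is broad and similar across all three bands (phospholipid-like).
    """
    axis = axis or ExcitationAxis.default()
    bands = bands or EmissionBands.default()
    x = axis.wavelengths_nm
    curves = {
        "epithelium": {
            "blue": 1.00 * _gauss(x, 730.0, 45.0),
            "green": 0.35 * (0.8 + 0.2 * _gauss(x, 800.0, 120.0)),
            "red": 0.05 * _gauss(x, 760.0, 60.0),
        },
        "lamina_propria": {
            "blue": 0.60 * _gauss(x, 745.0, 50.0),
            "green": 0.45 * _gauss(x, 765.0, 60.0),
            "red": 0.50 * _gauss(x, 725.0, 30.0),
        },
        "collagen": {
            "blue": 1.00 * _sigmoid(x, 800.0, 25.0),
            "green": 0.02 * np.ones_like(x),
            "red": 0.01 * np.ones_like(x),
        },
        "lymphatic": {
            "blue": 0.50 * _gauss(x, 790.0, 80.0),
            "green": 0.45 * _gauss(x, 800.0, 85.0),
            "red": 0.40 * _gauss(x, 810.0, 90.0),
        },
    }
    spectra = []
    for label in CANONICAL_LABELS:
        values = np.zeros((len(axis), len(bands)))
        for b, name in enumerate(bands.names):
            values[:, b] = curves[label].get(name, 0.001 * np.ones_like(x))
        spectra.append(
            BasisSpectrum(
                label=label,
                values=values,
                wavelengths_nm=x.copy(),
                band_names=bands.names,
            )
        )
    return BasisSet(spectra)


# ---------------------------------------------------------------------------
# disk format: one TSV + JSON header per spectrum, directory per set


def save_basis_spectrum(spec: BasisSpectrum, path) -> Path:
    """Write one basis spectrum as TSV plus a ``<path>.json`` header."""
    path = Path(path)
    cols = {"wavelength_nm": spec.wavelengths_nm}
    for b, name in enumerate(spec.band_names):
        cols[name] = spec.values[:, b]
    if spec.std is not None:
        for b, name in enumerate(spec.band_names):
            cols[f"std_{name}"] = spec.std[:, b]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
    header = {
        "label": spec.label,
        "band_names": list(spec.band_names),
        "n_sites": spec.n_sites,
        "n_animals": spec.n_animals,
        "normalized": spec.normalized,
        "calibrated": spec.calibrated,
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))
    return path


def load_basis_spectrum(path) -> BasisSpectrum:
    path = Path(path)
    header = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t")
    band_names = tuple(header["band_names"])
    values = df[list(band_names)].to_numpy(dtype=float)
    std_cols = [f"std_{b}" for b in band_names]
    std = df[std_cols].to_numpy(dtype=float) if all(c in df for c in std_cols) else None
    return BasisSpectrum(
        label=header["label"],
        values=values,
        std=std,
        wavelengths_nm=df["wavelength_nm"].to_numpy(dtype=float),
        band_names=band_names,
        n_sites=int(header.get("n_sites", 1)),
        n_animals=int(header.get("n_animals", 1)),
        normalized=bool(header.get("normalized", False)),
        calibrated=bool(header.get("calibrated", False)),
    )


def save_basis_set(basis: BasisSet, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for spec in basis:
        save_basis_spectrum(spec, directory / f"{spec.label}.tsv")
    (directory / "basis_set.json").write_text(
        json.dumps({"labels": list(basis.labels)}, indent=1)
    )
    return directory


def load_basis_set(directory) -> BasisSet:
    directory = Path(directory)
    index = directory / "basis_set.json"
    if not index.exists():
        raise FileNotFoundError(f"missing basis set index {index}")
    labels = json.loads(index.read_text())["labels"]
    return BasisSet([load_basis_spectrum(directory / f"{label}.tsv") for label in labels])
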