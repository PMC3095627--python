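"""Hyperspectral stack data model and lossless TIFF + JSON-sidecar I/O.

An excitation-scanning two-photon acquisition produces, for every pixel, an
excitation spectrum in each of a small number of fixed emission bands.  The
central container here is :class:`HyperStack`: a 4-D array of detector counts
indexed ``[row, col, excitation_index, band_index]`` together with its
excitation axis (nm) and emission-band definitions.

On disk a stack is a plain multi-page grayscale TIFF whose page order is
excitation-major then band (``page = ex_index * n_bands + band_index``), plus
a JSON sidecar ``<path>.json`` carrying the axes and free-form metadata.
Round-tripping is bit-exact for integer data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Default excitation grid: 710..920 nm inclusive in 5 nm steps (43 values).
DEFAULT_WAVELENGTHS_NM = tuple(range(710, 921, 5))

#: Default simultaneous emission bands (name, low nm, high nm).
DEFAULT_BANDS = (("blue", 350.0, 505.0), ("green", 505.0, 560.0), ("red", 560.0, 650.0))

EXCITATION_RANGE_NM = (650.0, 1100.0)


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class DialectError(ValueError):
    """On-disk files disagree with each other (e.g. page count vs sidecar)."""


@dataclass(frozen=True)
class ExcitationAxis:
    """Strictly increasing excitation wavelengths in nm, within 650-1100 nm."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", w)
        if w.ndim != 1 or w.size == 0:
            raise ValidationError("excitation axis must be a non-empty 1-D sequence")
        if not np.all(np.diff(w) > 0):
            raise ValidationError("excitation wavelengths must be strictly increasing")
        lo, hi = EXCITATION_RANGE_NM
        if w[0] < lo or w[-1] > hi:
            raise ValidationError(
                f"excitation wavelengths must lie within [{lo:g}, {hi:g}] nm, "
                f"got [{w[0]:g}, {w[-1]:g}]"
            )

    @classmethod
    def default(cls) -> "ExcitationAxis":
        return cls(np.asarray(DEFAULT_WAVELENGTHS_NM, dtype=float))

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of an exact wavelength on the axis."""
        idx = np.nonzero(np.isclose(self.wavelengths_nm, wavelength_nm))[0]
        if idx.size == 0:
            raise KeyError(f"{wavelength_nm} nm is not on the excitation axis")
        return int(idx[0])

    def select_range(self, low_nm: float, high_nm: float) -> np.ndarray:
        """Indices of wavelengths within ``[low_nm, high_nm]`` inclusive."""
        return np.nonzero(
            (self.wavelengths_nm >= low_nm) & (self.wavelengths_nm <= high_nm)
        )[0]


@dataclass(frozen=True)
class EmissionBands:
    """Ordered, non-overlapping emission windows (name, low nm, high nm)."""

    bands: tuple

    def __post_init__(self) -> None:
        bands = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ValidationError("at least one emission band is required")
        names = [b[0] for b in bands]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate band names: {names}")
        for name, lo, hi in bands:
            if not lo < hi:
                raise ValidationError(f"band {name!r}: low {lo:g} must be < high {hi:g}")
        # pairwise: order is free (it fixes the page layout), overlap is not
        for i, (n1, lo1, hi1) in enumerate(bands):
            for n2, lo2, hi2 in bands[i + 1 :]:
                if max(lo1, lo2) < min(hi1, hi2):
                    raise ValidationError(f"bands {n1!r} and {n2!r} overlap")

    @classmethod
    def default(cls) -> "EmissionBands":
        return cls(DEFAULT_BANDS)

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def names(self) -> tuple:
        return tuple(b[0] for b in self.bands)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no emission band named {name!r}; have {self.names}") from None


@dataclass
class HyperStack:
    """4-D stack of detector counts ``[row, col, ex_index, band_index]``.

    Intensities are finite and non-negative; the trailing two axes agree with
    ``excitation`` and ``emission``.
    """

    data: np.ndarray
    excitation: ExcitationAxis
    emission: EmissionBands
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.validate()

    def validate(self) -> None:
        d = self.data
        if d.ndim != 4:
            raise ValidationError(f"stack data must be 4-D, got {d.ndim}-D")
        if d.shape[2] != len(self.excitation):
            raise ValidationError(
                f"axis 2 ({d.shape[2]}) != number of excitation wavelengths "
                f"({len(self.excitation)})"
            )
        if d.shape[3] != len(self.emission):
            raise ValidationError(
                f"axis 3 ({d.shape[3]}) != number of emission bands ({len(self.emission)})"
            )
        if np.issubdtype(d.dtype, np.floating) and not np.isfinite(d).all():
            raise ValidationError("stack contains non-finite intensities")
        if d.size and d.min() < 0:
            raise ValidationError("stack contains negative intensities")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_ex(self) -> int:
        return self.data.shape[2]

    @property
    def n_bands(self) -> int:
        return self.data.shape[3]

    def pixel_spectrum(self, row: int, col: int) -> np.ndarray:
        """Return a *copy* of the ``[n_ex, n_bands]`` spectrum at one pixel.

        A copy is returned so that mutating the result can never corrupt the
        stack.  Negative indices are rejected: wraparound indexing silently
        hides off-by-one errors in ROI bookkeeping.
        """
        nrow, ncol = self.data.shape[:2]
        if not (0 <= row < nrow and 0 <= col < ncol):
            raise IndexError(
                f"pixel ({row}, {col}) out of bounds for {nrow}x{ncol} frame"
            )
        return self.data[row, col].copy()


@dataclass(frozen=True)
class ROIMask:
    """Boolean region-of-interest mask over a stack's spatial frame."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValidationError("ROI mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def require_nonempty(self) -> None:
        if self.n_pixels == 0:
            raise ValidationError("ROI mask selects no pixels")

    @classmethod
    def full(cls, shape: tuple) -> "ROIMask":
        return cls(np.ones(shape, dtype=bool))

    @classmethod
    def from_png(cls, path) -> "ROIMask":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr > 0)

    def to_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.mask * np.uint8(255))).save(path)


# ---------------------------------------------------------------------------
# disk format


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def save_hyperstack(stack: HyperStack, path) -> Path:
    """Write a stack as a multi-page TIFF plus a ``<path>.json`` sidecar.

    Page order is excitation-major then band; integer data round-trips
    bit-exactly through :func:`load_hyperstack`.
    """
    stack.validate()
    path = Path(path)
    d = stack.data
    nrow, ncol, n_ex, n_b = d.shape
    pages = np.ascontiguousarray(
        np.moveaxis(d, (2, 3), (0, 1)).reshape(n_ex * n_b, nrow, ncol)
    )
    if np.issubdtype(d.dtype, np.floating):
        pages = pages.astype(np.float32)
    # minisblack: one grayscale page per (excitation, band) plane; otherwise
    # small frames get mis-guessed as RGB(A) samples
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar = {
        "wavelengths_nm": [float(w) for w in stack.excitation.wavelengths_nm],
        "bands": [list(b) for b in stack.emission.bands],
        "shape": [int(nrow), int(ncol), int(n_ex), int(n_b)],
        "dtype": str(pages.dtype),
        "meta": stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_hyperstack(path) -> HyperStack:
    """Read a stack written by :func:`save_hyperstack`.

    Negative raw values (amplifier offsets) are clipped to zero with a logged
    count; the forward model is non-negative and the acquisition convention
    for offsets is instrument-specific.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path} for stack {path}"
        )
    sidecar = json.loads(sidecar_path.read_text())
    axis = ExcitationAxis(np.asarray(sidecar["wavelengths_nm"], dtype=float))
    bands = EmissionBands(tuple(tuple(b) for b in sidecar["bands"]))
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_ex, n_b = len(axis), len(bands)
    if pages.shape[0] != n_ex * n_b:
        raise DialectError(
            f"{path}: TIFF holds {pages.shape[0]} pages but sidecar declares "
            f"{n_ex} wavelengths x {n_b} bands = {n_ex * n_b}"
        )
    nrow, ncol = pages.shape[1:]
    data = np.moveaxis(pages.reshape(n_ex, n_b, nrow, ncol), (0, 1), (2, 3))
    n_neg = int((data < 0).sum())
    if n_neg:
        logger.warning("%s: clipped %d negative raw values to 0", path, n_neg)
        data = np.clip(data, 0, None)
    return HyperStack(
        data=np.ascontiguousarray(data),
        excitation=axis,
        emission=bands,
        meta=dict(sidecar.get("meta", {})),
    )
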