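"""Pixel-by-pixel non-negative least-squares unmixing of hyperspectral stacks.

The detected signal at each pixel is modelled as a non-negative linear
combination of tissue basis spectra (linear mixing of the fluorescence and
SHG of its constituents).  The design matrix concatenates, per component, the
excitation spectra of the bands in use — blue and green by default; the red
band is excluded by default because its relative amplitude varies strongly
with depth (hemoglobin attenuation differs most in the red emission window)
and tends to spoil fits.  Each pixel is solved independently with NNLS; the
squared Euclidean norm of the residual over all wavelengths and used bands is
mapped alongside the coefficients as a goodness-of-fit surface.

Unmixing deliberately consumes *uncalibrated* spectra: the instrument
envelope K multiplies basis and data identically, so it cancels from the fit
(up to per-component positive scalars), and skipping the division avoids
injecting its noise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.optimize import nnls as _scipy_nnls

from .basis import BasisSet
from .hyperstack import HyperStack, ValidationError

logger = logging.getLogger(__name__)

#: Default emission bands entering the fit (red excluded).
DEFAULT_BANDS_USED = ("blue", "green")

#: Condition number above which NNLS solution non-uniqueness is logged.
CONDITION_WARN = 1e8

#: Convergence threshold / iteration cap for the free-band-amplitude scheme.
FREE_BAND_TOL = 1e-8
FREE_BAND_MAX_ITER = 50


@dataclass(frozen=True)
class UnmixConfig:
    """Configuration of one unmixing run.

    bands_used: emission bands concatenated into the fit (default blue+green).
    components: basis labels in fit order; None means all, in set order.
    display_reference: component whose map is scaled to max 1 for display.
    free_band_amplitude: fit one extra positive multiplier per non-blue band
        per pixel (alternating NNLS), to absorb depth-dependent band
        attenuation.
    """

    bands_used: tuple = DEFAULT_BANDS_USED
    components: tuple | None = None
    display_reference: str = "epithelium"
    free_band_amplitude: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands_used", tuple(self.bands_used))
        if not self.bands_used:
            raise ValidationError("bands_used must not be empty")
        if self.components is not None:
            object.__setattr__(self, "components", tuple(self.components))


@dataclass
class CoefficientMaps:
    """Per-pixel component abundances, ``coeffs[row, col, component]``.

    Units are arbitrary (relative abundance); after display scaling the
    reference component's maximum is 1 and ``max_values`` records each
    component's maximum on that scale (the per-panel "m.v." annotation).
    """

    coeffs: np.ndarray
    labels: tuple
    scaled: bool = False
    max_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.labels = tuple(self.labels)
        if self.coeffs.ndim != 3 or self.coeffs.shape[2] != len(self.labels):
            raise ValidationError("coeffs must be [rows, cols, n_components]")
        if (self.coeffs < 0).any():
            raise ValidationError("coefficients must be non-negative")

    def component(self, label: str) -> np.ndarray:
        return self.coeffs[:, :, self.labels.index(label)]


@dataclass
class ResidualMap:
    """Squared Euclidean norm of the per-pixel fit residual (counts^2)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("residual map must be 2-D")
        if (self.values < 0).any():
            raise ValidationError("residuals are squared norms and cannot be negative")


# ---------------------------------------------------------------------------
# solver


def nnls_solve(A: np.ndarray, b: np.ndarray) -> tuple:
    """Solve ``min ||Ax - b||^2  s.t.  x >= 0``; return ``(x, rnorm2)``.

    ``rnorm2`` is the squared residual norm at the solution — the per-pixel
    goodness-of-fit statistic.  Uses the Lawson-Hanson active-set algorithm,
    with a fast path when the unconstrained least-squares solution is already
    feasible (then it is the NNLS solution).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if A.ndim != 2 or b.ndim != 1 or A.shape[0] != b.shape[0]:
        raise ValidationError(f"incompatible shapes A{A.shape}, b{b.shape}")
    if not (np.isfinite(A).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite values in NNLS inputs")
    x, _ = _scipy_nnls(A, b)
    r = b - A @ x
    return x, float(r @ r)


def build_design_matrix(basis: BasisSet, cfg: UnmixConfig) -> np.ndarray:
    """Concatenate basis excitation spectra over the bands in use.

    Column j is component j's excitation spectra for ``cfg.bands_used``
    concatenated in band order; shape is ``[n_ex * n_bands_used, k]``.  The
    basis must be normalized (blue-band maximum 1 per component) first.
    """
    if not basis.normalized:
        raise ValidationError(
            "basis set is not normalized; apply normalize_basis to each spectrum "
            "before building the design matrix"
        )
    labels = cfg.components if cfg.components is not None else basis.labels
    for name in cfg.bands_used:
        if name not in basis.band_names:
            raise ValidationError(f"band {name!r} not present in basis set")
    columns = []
    for label in labels:
        spec = basis[label]
        columns.append(np.concatenate([spec.band_column(bn) for bn in cfg.bands_used]))
    A = np.stack(columns, axis=1)
    cond = np.linalg.cond(A)
    if cond > CONDITION_WARN:
        logger.warning(
            "design matrix condition number %.3g > %.1g: NNLS solution may be "
            "non-unique; the active-set solution is returned deterministically",
            cond,
            CONDITION_WARN,
        )
    return A


def _concat_pixels(stack: HyperStack, bands_used) -> np.ndarray:
    """Flatten a stack into ``[n_pixels, n_ex * n_bands_used]`` observations."""
    idx = [stack.emission.index(bn) for bn in bands_used]
    nrow, ncol = stack.data.shape[:2]
    # [row, col, band_used, ex] -> concat ex-major per band
    sel = stack.data[:, :, :, idx].astype(float)  # [r, c, ex, bu]
    sel = np.moveaxis(sel, 3, 2)  # [r, c, bu, ex]
    return sel.reshape(nrow * ncol, len(idx) * stack.n_ex)


def _fit_pixels(A: np.ndarray, B: np.ndarray) -> tuple:
    """NNLS for every row of B against the shared design matrix A.

    Fast path: pixels whose unconstrained solution ``A^+ b`` is feasible are
    solved in one batched least-squares; the rest fall back to the active-set
    solver.  Both routes minimize the same objective, so results are
    independent of which path a pixel takes and of pixel order.
    """
    n_pix = B.shape[0]
    k = A.shape[1]
    pinv = np.linalg.pinv(A)
    X = B @ pinv.T  # unconstrained solutions
    R = B - X @ A.T
    rnorm2 = np.einsum("ij,ij->i", R, R)
    feasible = (X >= -1e-12).all(axis=1)
    X = np.where(X < 0, 0.0, X)
    for i in np.nonzero(~feasible)[0]:
        X[i], rnorm2[i] = nnls_solve(A, B[i])
    # exact zeros for identically-zero pixels
    zero = ~B.any(axis=1)
    X[zero] = 0.0
    rnorm2[zero] = 0.0
    # an exact in-model fit leaves only rounding dust (~(eps*||b||)^2); report 0
    bnorm2 = np.einsum("ij,ij->i", B, B)
    snap = (1e3 * np.finfo(float).eps) ** 2 * bnorm2
    rnorm2[rnorm2 <= snap] = 0.0
    np.clip(rnorm2, 0.0, None, out=rnorm2)
    return X.reshape(n_pix, k), rnorm2


def _fit_pixel_free_bands(A_bands: list, obs_bands: list) -> tuple:
    """Alternating NNLS over coefficients and per-band multipliers.

    ``A_bands[b]`` / ``obs_bands[b]`` are the per-band design blocks and
    observations; band 0 (blue) has its multiplier pinned at 1.  Multipliers
    start at 1 and alternate with the coefficient NNLS until the squared
    residual decreases by less than FREE_BAND_TOL or FREE_BAND_MAX_ITER.
    """
    n_bands = len(A_bands)
    g = np.ones(n_bands)
    prev = np.inf
    x = np.zeros(A_bands[0].shape[1])
    rnorm2 = prev
    for _ in range(FREE_BAND_MAX_ITER):
        A = np.concatenate([g[b] * A_bands[b] for b in range(n_bands)], axis=0)
        b_vec = np.concatenate(obs_bands)
        x, rnorm2 = nnls_solve(A, b_vec)
        for b in range(1, n_bands):
            pred = A_bands[b] @ x
            denom = float(pred @ pred)
            g[b] = max(float(pred @ obs_bands[b]) / denom, 0.0) if denom > 0 else 1.0
        rnorm2 = sum(
            float(np.sum((g[b] * (A_bands[b] @ x) - obs_bands[b]) ** 2))
            for b in range(n_bands)
        )
        if prev - rnorm2 < FREE_BAND_TOL:
            break
        prev = rnorm2
    return x, rnorm2


def unmix_stack(
    stack: HyperStack, basis: BasisSet, cfg: UnmixConfig | None = None
) -> tuple:
    """Unmix every pixel; return ``(CoefficientMaps, ResidualMap)``.

    Per-pixel fits are independent and results are order-independent.  The
    stack and basis must agree on the excitation axis and on calibration
    state (mixing a calibrated basis with an uncalibrated stack, or vice
    versa, silently biases coefficients and is refused).
    """
    cfg = cfg or UnmixConfig()
    if not np.array_equal(stack.excitation.wavelengths_nm, basis.wavelengths_nm):
        raise ValidationError("stack and basis set use different excitation axes")
    stack_calibrated = bool(stack.meta.get("calibrated", False))
    if stack_calibrated != basis.calibrated:
        raise ValidationError(
            f"calibration mismatch: stack calibrated={stack_calibrated}, "
            f"basis calibrated={basis.calibrated}"
        )
    for bn in cfg.bands_used:
        stack.emission.index(bn)  # raises KeyError if missing
    labels = cfg.components if cfg.components is not None else basis.labels
    A = build_design_matrix(basis, cfg)
    nrow, ncol = stack.data.shape[:2]
    B = _concat_pixels(stack, cfg.bands_used)

    if cfg.free_band_amplitude:
        band_idx = [stack.emission.index(bn) for bn in cfg.bands_used]
        n_ex = stack.n_ex
        A_bands = [A[i * n_ex : (i + 1) * n_ex] for i in range(len(band_idx))]
        X = np.zeros((B.shape[0], A.shape[1]))
        rnorm2 = np.zeros(B.shape[0])
        for p in range(B.shape[0]):
            obs_bands = [B[p, i * n_ex : (i + 1) * n_ex] for i in range(len(band_idx))]
            if not any(ob.any() for ob in obs_bands):
                continue
            X[p], rnorm2[p] = _fit_pixel_free_bands(A_bands, obs_bands)
    else:
        X, rnorm2 = _fit_pixels(A, B)

    maps = CoefficientMaps(coeffs=X.reshape(nrow, ncol, len(labels)), labels=labels)
    residual = ResidualMap(values=rnorm2.reshape(nrow, ncol))
    return maps, residual


def scale_coefficient_maps(
    maps: CoefficientMaps, cfg: UnmixConfig | None = None
) -> CoefficientMaps:
    """Scale all maps so the display-reference component's maximum is 1.

    Every component map is divided by the same scalar, preserving pixelwise
    ratios between components; each component's resulting maximum is recorded
    in ``max_values`` for panel annotation.  Idempotent.
    """
    cfg = cfg or UnmixConfig()
    ref = cfg.display_reference
    if ref not in maps.labels:
        raise ValidationError(
            f"display reference {ref!r} not among components {maps.labels}"
        )
    peak = float(maps.component(ref).max())
    if peak <= 0:
        raise ValidationError(
            f"reference component {ref!r} map is all zero; choose a different "
            "display_reference"
        )
    coeffs = maps.coeffs / peak
    max_values = {
        label: float(coeffs[:, :, j].max()) for j, label in enumerate(maps.labels)
    }
    return CoefficientMaps(
        coeffs=coeffs, labels=maps.labels, scaled=True, max_values=max_values
    )


# ---------------------------------------------------------------------------
# disk format


def save_coefficient_maps(
    maps: CoefficientMaps, residual: ResidualMap | None, path
) -> Path:
    """Write maps (and optionally the residual) as float32 TIFF + JSON."""
    path = Path(path)
    pages = [maps.coeffs[:, :, j].astype(np.float32) for j in range(len(maps.labels))]
    if residual is not None:
        pages.append(residual.values.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages, axis=0))
    meta = {
        "labels": list(maps.labels),
        "scaled": maps.scaled,
        "max_values": maps.max_values,
        "has_residual": residual is not None,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_coefficient_maps(path) -> tuple:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    labels = tuple(meta["labels"])
    coeffs = np.moveaxis(pages[: len(labels)], 0, 2).astype(float)
    maps = CoefficientMaps(
        coeffs=coeffs,
        labels=labels,
        scaled=bool(meta["scaled"]),
        max_values=dict(meta.get("max_values", {})),
    )
    residual = (
        ResidualMap(values=pages[len(labels)].astype(float))
        if meta.get("has_residual")
        else None
    )
    return maps, residual
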