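"""Spectral calibration against a reference fluorophore.

Detected two-photon fluorescence carries a wavelength-dependent instrument
envelope K(lambda_ex) — laser power, pulse width, repetition rate, dispersion
and NA all vary with the tuned wavelength.  Rather than evaluating K from
instrument constants, it is measured operationally: scan a homogeneous well of
FAD (whose two-photon excitation spectrum is approximately flat over
710-900 nm) and take the green-band mean spectrum as K up to a scalar.
Dividing any measured spectrum by this envelope removes K from every emission
band; per-band scale factors (from equal-power LED back-illumination) correct
detector/filter response differences, with blue as the unit reference.

Calibrated spectra are for interpretation and plotting; unmixing consumes
uncalibrated spectra, since K multiplies basis and data identically and
cancels in the fit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hyperstack import HyperStack, ROIMask, ValidationError

logger = logging.getLogger(__name__)

# Physical constants used only by the simulator's parametric envelope option.
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s

#: floor = FLOOR_FRACTION * max(envelope) guards the division at range edges.
FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class InstrumentParams:
    """Laser/objective parameters entering the parametric envelope.

    P may be scalar (flat power) or per-wavelength (mW); tau_p is the pulse
    width (s), f_p the repetition rate (Hz), NA the numerical aperture.
    """

    P: np.ndarray
    tau_p: float
    f_p: float
    NA: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "P", np.atleast_1d(np.asarray(self.P, dtype=float)))
        if (self.P <= 0).any() or self.tau_p <= 0 or self.f_p <= 0 or self.NA <= 0:
            raise ValidationError("all instrument parameters must be positive")


@dataclass
class CalibrationProfile:
    """Measured instrument envelope plus per-band scale factors.

    ``envelope[i]`` is proportional to K at wavelength ``wavelengths_nm[i]``
    (arbitrary units); ``channel_scale[b]`` multiplies band ``band_names[b]``
    after the envelope division, with blue fixed at 1.
    """

    wavelengths_nm: np.ndarray
    envelope: np.ndarray
    band_names: tuple
    channel_scale: np.ndarray
    floor: float

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.channel_scale = np.asarray(self.channel_scale, dtype=float)
        self.band_names = tuple(self.band_names)
        if self.envelope.shape != self.wavelengths_nm.shape:
            raise ValidationError("envelope and wavelength axis differ in length")
        if (self.envelope <= 0).any():
            raise ValidationError("envelope must be strictly positive after flooring")
        if len(self.channel_scale) != len(self.band_names):
            raise ValidationError("one channel scale per band is required")
        if (self.channel_scale <= 0).any():
            raise ValidationError("channel scales must be positive")
        if "blue" in self.band_names:
            b = self.band_names.index("blue")
            if not np.isclose(self.channel_scale[b], 1.0):
                raise ValidationError("blue channel scale must be exactly 1")

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "wavelengths_nm": self.wavelengths_nm.tolist(),
                    "envelope": self.envelope.tolist(),
                    "band_names": list(self.band_names),
                    "channel_scale": self.channel_scale.tolist(),
                    "floor": self.floor,
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        d = json.loads(Path(path).read_text())
        return cls(
            wavelengths_nm=np.asarray(d["wavelengths_nm"], dtype=float),
            envelope=np.asarray(d["envelope"], dtype=float),
            band_names=tuple(d["band_names"]),
            channel_scale=np.asarray(d["channel_scale"], dtype=float),
            floor=float(d["floor"]),
        )


def measure_reference_envelope(
    fad_stack: HyperStack, roi: ROIMask, band: str = "green"
) -> CalibrationProfile:
    """Estimate the envelope from a homogeneous reference-fluorophore scan.

    For a fluorophore whose quantum efficiency, collection efficiency and
    two-photon cross-section are wavelength-invariant over the scan (FAD),
    the ROI-mean spectrum in one band equals K times a scalar.  Values at or
    below the floor (1e-6 of the envelope max) are replaced by the floor with
    a warning so downstream division stays finite.
    """
    roi.require_nonempty()
    if roi.mask.shape != fad_stack.data.shape[:2]:
        raise ValidationError("ROI shape does not match stack frame")
    b = fad_stack.emission.index(band)
    envelope = fad_stack.data[roi.mask, :, b].mean(axis=0).astype(float)
    floor = FLOOR_FRACTION * float(envelope.max())
    if floor <= 0:
        raise ValidationError("reference scan is identically zero in this band")
    n_low = int((envelope <= floor).sum())
    if n_low:
        logger.warning(
            "reference envelope: %d wavelength(s) at or below floor %.3g; floored",
            n_low,
            floor,
        )
        envelope = np.maximum(envelope, floor)
    return CalibrationProfile(
        wavelengths_nm=fad_stack.excitation.wavelengths_nm.copy(),
        envelope=envelope,
        band_names=fad_stack.emission.names,
        channel_scale=np.ones(len(fad_stack.emission)),
        floor=floor,
    )


def compute_channel_scale_factors(led_readings, reference: str = "blue") -> dict:
    """Per-band scale factors from equal-power LED readings.

    ``scale[b] = reading[reference] / reading[b]`` so the reference band maps
    to exactly 1.  Readings are mean detected intensities under narrow-band
    LEDs adjusted to identical optical power in each band.
    """
    readings = dict(led_readings)
    if reference not in readings:
        raise ValidationError(f"no reading for reference band {reference!r}")
    for name, value in readings.items():
        if not np.isfinite(value) or value <= 0:
            raise ValidationError(f"LED reading for {name!r} must be positive, got {value}")
    ref = float(readings[reference])
    return {name: ref / float(value) for name, value in readings.items()}


def apply_spectral_calibration(
    spectrum: np.ndarray, cal: CalibrationProfile
) -> np.ndarray:
    """Divide an ``[n_ex, n_bands]`` spectrum by the envelope and scale bands.

    ``out[i, b] = spectrum[i, b] / envelope[i] * channel_scale[b]``.  The
    operation is scale-equivariant, so relative spectral shapes survive.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 2:
        raise ValidationError("spectrum must be a 2-D [n_ex, n_bands] matrix")
    if spectrum.shape[0] != len(cal.envelope):
        raise ValidationError(
            f"spectrum has {spectrum.shape[0]} wavelengths but the profile has "
            f"{len(cal.envelope)}"
        )
    if spectrum.shape[1] != len(cal.channel_scale):
        raise ValidationError(
            f"spectrum has {spectrum.shape[1]} bands but the profile has "
            f"{len(cal.channel_scale)}"
        )
    out = spectrum / cal.envelope[:, None] * cal.channel_scale[None, :]
    if not np.isfinite(out).all():
        raise ValidationError("calibration produced non-finite values")
    return out


def calibrate_stack(stack: HyperStack, cal: CalibrationProfile) -> HyperStack:
    """Apply the spectral calibration to every pixel of a stack.

    The result is marked ``meta['calibrated'] = True`` so the unmixing stage
    can refuse to mix calibrated and uncalibrated inputs.
    """
    if stack.n_ex != len(cal.envelope):
        raise ValidationError("stack and calibration profile axes differ in length")
    if stack.n_bands != len(cal.channel_scale):
        raise ValidationError("stack and calibration profile band counts differ")
    data = (
        stack.data.astype(float)
        / cal.envelope[None, None, :, None]
        * cal.channel_scale[None, None, None, :]
    )
    meta = dict(stack.meta)
    meta["calibrated"] = True
    return HyperStack(data=data, excitation=stack.excitation, emission=stack.emission, meta=meta)
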