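"""Quantitative backscattered electron imaging (qBEI) calibration.

qBEI encodes the local mean atomic number of a polished bone surface in an
8-bit gray level.  Calibration against two reference materials — pure carbon
(Z = 6) and pure aluminum (Z = 13) — fixes a linear map from gray level to
backscatter coefficient η, and a second affine map through two configured
(gray-equivalent, wt% Ca) anchor points converts η to calcium content.

The backscatter coefficient of an element is evaluated with Reuter's
polynomial η(Z) = -0.0254 + 0.016 Z - 1.86·10⁻⁴ Z² + 8.3·10⁻⁷ Z³.  The
default anchors map the carbon reference to 0 wt% Ca and the aluminum
reference to 39.86 wt% Ca (the calcium mass fraction of pure
hydroxyapatite); both the references' gray positions and the anchors are
conventions of this package and fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "CaMap",
    "backscatter_coefficient",
    "build_calibration",
    "default_calibration",
    "apply_calibration",
    "Z_CARBON",
    "Z_ALUMINUM",
]

Z_CARBON = 6
Z_ALUMINUM = 13

#: wt% Ca of stoichiometric hydroxyapatite, the default high anchor.
CA_HYDROXYAPATITE_WT = 39.86


def backscatter_coefficient(z: float) -> float:
    """Reuter's polynomial for the electron backscatter coefficient η(Z)."""
    return -0.0254 + 0.016 * z - 1.86e-4 * z**2 + 8.3e-7 * z**3


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine gray-level → wt% Ca map, wt%Ca = c0 + c1·GL.

    Also records the reference construction: gray positions of the carbon
    and aluminum standards and their backscatter coefficients.
    """

    c0: float
    c1: float
    gl_carbon: float
    gl_aluminum: float
    eta_carbon: float
    eta_aluminum: float

    def __post_init__(self) -> None:
        if not self.gl_aluminum > self.gl_carbon:
            raise ValueError("gl_aluminum must exceed gl_carbon")
        if not self.c1 > 0:
            raise ValueError("calibration slope must be positive")

    def eta_from_gray(self, gl):
        """Linear gray → η map fixed by the two reference materials."""
        slope = (self.eta_aluminum - self.eta_carbon) / (
            self.gl_aluminum - self.gl_carbon
        )
        return self.eta_carbon + (np.asarray(gl, float) - self.gl_carbon) * slope

    def ca_from_gray(self, gl):
        return self.c0 + self.c1 * np.asarray(gl, float)

    def gray_from_ca(self, ca):
        return (np.asarray(ca, float) - self.c0) / self.c1


def build_calibration(
    gl_carbon: float = 25.0,
    gl_aluminum: float = 225.0,
    anchors: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> CalibrationCurve:
    """Construct the two-reference calibration curve.

    Parameters
    ----------
    gl_carbon, gl_aluminum : float
        Gray levels measured on the carbon and aluminum reference samples
        (0 <= gl_carbon < gl_aluminum <= 255).
    anchors : pair of (gray_equivalent, wt% Ca), optional
        Two points tying the gray/η scale to calcium content.  Default:
        ``(gl_carbon, 0.0)`` and ``(gl_aluminum, 39.86)``.
    """
    if not (0 <= gl_carbon < gl_aluminum <= 255):
        raise ValueError("need 0 <= gl_carbon < gl_aluminum <= 255")
    if anchors is None:
        anchors = ((gl_carbon, 0.0), (gl_aluminum, CA_HYDROXYAPATITE_WT))
    (g0, w0), (g1, w1) = anchors
    if abs(g1 - g0) < 1e-12:
        raise ValueError("degenerate anchors: gray-equivalents coincide")
    eta_c = backscatter_coefficient(Z_CARBON)
    eta_al = backscatter_coefficient(Z_ALUMINUM)
    eta_slope = (eta_al - eta_c) / (gl_aluminum - gl_carbon)
    eta0 = eta_c + (g0 - gl_carbon) * eta_slope
    eta1 = eta_c + (g1 - gl_carbon) * eta_slope
    # η → wt% Ca affine through the two anchors, composed back onto GL
    wt_per_eta = (w1 - w0) / (eta1 - eta0)
    c1 = wt_per_eta * eta_slope
    c0 = w0 + (eta_c - eta0) * wt_per_eta - c1 * gl_carbon
    return CalibrationCurve(
        c0=float(c0),
        c1=float(c1),
        gl_carbon=float(gl_carbon),
        gl_aluminum=float(gl_aluminum),
        eta_carbon=float(eta_c),
        eta_aluminum=float(eta_al),
    )


def default_calibration() -> CalibrationCurve:
    return build_calibration()


@dataclass
class CaMap:
    """Gray-level image with its calibration and derived calcium map."""

    gray: np.ndarray
    curve: CalibrationCurve
    ca_wt: np.ndarray
    mean_ca_wt: float
    sd_ca_wt: float
    histogram_counts: np.ndarray  # counts per gray level 0..255


def apply_calibration(image: np.ndarray, curve: CalibrationCurve) -> CaMap:
    """Convert an 8-bit gray-level image to a calcium-content map."""
    gray = np.asarray(image)
    if not np.issubdtype(gray.dtype, np.integer):
        raise ValueError("qBEI input must be an integer gray-level image")
    if gray.min() < 0 or gray.max() > 255:
        raise ValueError("gray levels must lie in 0..255")
    ca = curve.ca_from_gray(gray)
    counts = np.bincount(gray.ravel().astype(np.int64), minlength=256)
    return CaMap(
        gray=gray,
        curve=curve,
        ca_wt=ca,
        mean_ca_wt=float(ca.mean()),
        sd_ca_wt=float(ca.std(ddof=1)) if ca.size > 1 else 0.0,
        histogram_counts=counts,
    )
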