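"""Colour-math core: sRGB linearization, RGB→XYZ→xy/L*a*b*, and ΔC / ΔE*ab.

All conversions operate in double precision on scalars or numpy arrays whose
last axis holds the three channels.  The RGB→XYZ transform is the standard
D65 linear-sRGB matrix

    | X |   | 0.4124  0.3576  0.1805 | | R |
    | Y | = | 0.2126  0.7152  0.0722 | | G |
    | Z |   | 0.0193  0.1192  0.9505 | | B |

whose row sums (0.9505, 1.0000, 1.0890) are the tristimulus values of the
D65 white; any gray input (r = g = b) therefore lands on the chromaticity
(0.31273, 0.32902).  Chromaticity is the intensity-normalized projection

    x = X / (X + Y + Z),   y = Y / (X + Y + Z)

and the colour-difference statistic between two chromaticity points is the
plain Euclidean distance

    ΔC = sqrt((x1 − x2)² + (y1 − y2)²).

Consumer cameras store gamma-encoded values; the matrix above is defined on
linear light, so by default encoded channels are passed through the piecewise
sRGB electro-optical transfer function before the matrix.  Because source
imagery is not always known to be gamma-encoded, linearization can be turned
off per run via :class:`ConversionOptions`; the choice is recorded in all
downstream outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "D65_WHITE_XYZ",
    "D65_WHITE_XY",
    "ConversionOptions",
    "decode_channel",
    "encode_channel",
    "rgb_to_xyz",
    "xyz_to_xy",
    "xyz_to_lab",
    "delta_c",
    "delta_e_ab",
]

#: Linear-sRGB → CIE 1931 XYZ matrix (D65 illuminant, 2° observer).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: Tristimulus values of the white implied by the matrix (its row sums).
D65_WHITE_XYZ = tuple(RGB_TO_XYZ_MATRIX.sum(axis=1))

#: Chromaticity of that white point, (x, y) ≈ (0.31273, 0.32902).
D65_WHITE_XY = (
    D65_WHITE_XYZ[0] / sum(D65_WHITE_XYZ),
    D65_WHITE_XYZ[1] / sum(D65_WHITE_XYZ),
)

# sRGB transfer-function constants
_SRGB_DECODE_THRESHOLD = 0.04045
_SRGB_ENCODE_THRESHOLD = 0.0031308
_SRGB_LINEAR_SLOPE = 12.92
_SRGB_OFFSET = 0.055
_SRGB_GAMMA = 2.4

# CIELAB companding constants (6/29 threshold)
_LAB_DELTA = 6.0 / 29.0
_LAB_DELTA3 = _LAB_DELTA**3
_LAB_SLOPE = 1.0 / (3.0 * _LAB_DELTA**2)
_LAB_INTERCEPT = 4.0 / 29.0


@dataclass(frozen=True)
class ConversionOptions:
    """Knobs of the RGB→XYZ→(xy, L*a*b*) pipeline.

    Parameters
    ----------
    linearize
        Apply the piecewise sRGB gamma decoding before the matrix (default).
        Turn off to treat stored channel values as linear light, emulating a
        workflow that feeds raw 8-bit histogram means straight into the
        matrix.
    reference_white
        XYZ of the white used by the L*a*b* conversion.  Defaults to the
        matrix row sums so every conversion in the package is internally
        consistent with the same matrix.
    """

    linearize: bool = True
    reference_white: tuple[float, float, float] = field(default=D65_WHITE_XYZ)

    def __post_init__(self) -> None:
        if len(self.reference_white) != 3 or any(
            not np.isfinite(w) or w <= 0 for w in self.reference_white
        ):
            raise ValueError(
                f"reference_white components must be finite and > 0, "
                f"got {self.reference_white!r}"
            )

    def summary(self) -> dict:
        """JSON-serializable echo for output metadata."""
        return {
            "linearize": self.linearize,
            "reference_white": [float(w) for w in self.reference_white],
        }


def _check_unit_range(c: np.ndarray, name: str) -> None:
    bad = ~((c >= 0.0) & (c <= 1.0))
    if np.any(bad):
        offending = np.asarray(c)[bad].ravel()[0]
        raise ValueError(f"{name} must lie in [0, 1]; got {offending!r}")


def decode_channel(c, options: ConversionOptions = ConversionOptions()):
    """Gamma-decode an encoded channel intensity to linear light.

    Applies the piecewise sRGB EOTF: values below 0.04045 are divided by
    12.92, the rest follow ((c + 0.055) / 1.055) ** 2.4.  When
    ``options.linearize`` is off the input is returned unchanged.  Accepts
    scalars or arrays; monotone non-decreasing; fixes 0 and 1.
    """
    c = np.asarray(c, dtype=float)
    _check_unit_range(c, "encoded channel intensity")
    if not options.linearize:
        return c if c.ndim else float(c)
    lo = c <= _SRGB_DECODE_THRESHOLD
    out = np.where(
        lo,
        c / _SRGB_LINEAR_SLOPE,
        ((c + _SRGB_OFFSET) / (1.0 + _SRGB_OFFSET)) ** _SRGB_GAMMA,
    )
    return out if out.ndim else float(out)


def encode_channel(c, options: ConversionOptions = ConversionOptions()):
    """Inverse of :func:`decode_channel` (the sRGB OETF)."""
    c = np.asarray(c, dtype=float)
    _check_unit_range(c, "linear channel intensity")
    if not options.linearize:
        return c if c.ndim else float(c)
    lo = c <= _SRGB_ENCODE_THRESHOLD
    out = np.where(
        lo,
        c * _SRGB_LINEAR_SLOPE,
        (1.0 + _SRGB_OFFSET) * c ** (1.0 / _SRGB_GAMMA) - _SRGB_OFFSET,
    )
    return out if out.ndim else float(out)


def rgb_to_xyz(rgb):
    """Map linear RGB (last axis = channels, each in [0, 1]) to XYZ.

    Pure matrix product with :data:`RGB_TO_XYZ_MATRIX`; linear in the input.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected 3 channels on the last axis, got shape {rgb.shape}")
    _check_unit_range(rgb, "linear RGB channel")
    out = rgb @ RGB_TO_XYZ_MATRIX.T
    return out


def xyz_to_xy(xyz):
    """Project XYZ onto the CIE 1931 chromaticity plane.

    Scale-invariant: any positive multiple of the input gives the same (x, y).

    Raises
    ------
    ValueError
        If any input has X + Y + Z = 0 (pure black) — chromaticity is
        undefined there and callers must decide their own exclusion policy.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"expected 3 components on the last axis, got shape {xyz.shape}")
    if np.any(xyz < 0):
        raise ValueError("tristimulus values must be non-negative")
    s = xyz.sum(axis=-1)
    if np.any(s == 0):
        raise ValueError(
            "undefined chromaticity: X + Y + Z = 0 (pure black); "
            "exclude black pixels before projecting"
        )
    out = xyz[..., :2] / s[..., np.newaxis]
    return out


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _LAB_DELTA3, np.cbrt(t), _LAB_SLOPE * t + _LAB_INTERCEPT)


def xyz_to_lab(xyz, options: ConversionOptions = ConversionOptions()):
    """Convert XYZ to CIELAB (CIE 1976 L*a*b*).

    Standard cube-root companding with the 6/29 linear segment.  The
    reference white (``options.reference_white``) maps to (100, 0, 0) and
    black to (0, 0, 0); L* depends only on Y/Yn.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError(f"expected 3 components on the last axis, got shape {xyz.shape}")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("non-finite tristimulus input")
    white = np.asarray(options.reference_white, dtype=float)
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def delta_c(p1, p2) -> float:
    """ΔC: Euclidean distance between two xy chromaticity points.

    Symmetric, non-negative, zero iff the points coincide; this is the
    colour-shift statistic used to quantify biofilm staining between a
    reference group and an immersed group.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape[-1] != 2 or p2.shape[-1] != 2:
        raise ValueError("chromaticity points must have two components (x, y)")
    return float(np.hypot(p1[..., 0] - p2[..., 0], p1[..., 1] - p2[..., 1]))


def delta_e_ab(l1, l2) -> float:
    """ΔE*ab (CIE76): Euclidean distance between two L*a*b* triples."""
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape[-1] != 3 or l2.shape[-1] != 3:
        raise ValueError("Lab triples must have three components (L, a, b)")
    return float(np.sqrt(np.sum((l1 - l2) ** 2, axis=-1)))
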