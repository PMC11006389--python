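"""Oxygen-hemoglobin dissociation curve (Hill model) and blood O2 content.

The conversion between blood oxygen partial pressure (P_O2, mmHg) and
hemoglobin saturation (S, percent) uses the Hill equation

    S = 100 * P^n / (P50^n + P^n)

where ``P50`` is the half-saturation pressure and ``n`` the cooperativity
exponent.  Saturation is carried in **percent** (0-100) everywhere in this
package.  Hb-bound O2 content is

    C = (S / 100) * [Hb] * capacity          (ml O2 per dl blood)

with hemoglobin concentration ``[Hb]`` in g/dl and a binding capacity in
ml O2 per g Hb at full saturation.  Dissolved O2 is deliberately excluded:
all content figures are Hb-bound only.

The default curve parameters (P50 = 36 mmHg, n = 2.9 at reference pH 7.5)
are placeholder values for the emperor-penguin curve at resting pH and
should be recalibrated against a measured curve before use on real
recordings.  None of the packaged analyses depend on the defaults: synthetic
data are produced through the exact inverse of the same curve, so the
forward and inverse transforms cancel, and the content arithmetic involves
saturations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputDomainError

__all__ = [
    "ODCParams",
    "BloodParams",
    "DEFAULT_ODC",
    "DEFAULT_BLOOD",
    "saturation_from_po2",
    "po2_from_saturation",
    "o2_content",
    "saturation_from_content",
    "av_o2_difference",
]


@dataclass(frozen=True)
class ODCParams:
    """Hill-curve parameters.

    Parameters
    ----------
    p50_mmHg
        P_O2 at 50% saturation, mmHg.  Must be positive.
    hill_n
        Hill cooperativity exponent.  Must be positive; ``hill_n = 1``
        reduces the curve to the rectangular hyperbola ``P / (P50 + P)``.
    ph_ref
        Reference pH of the curve.  Informational only: the package applies
        no Bohr or temperature correction, and never alters this value.
    """

    p50_mmHg: float = 36.0
    hill_n: float = 2.9
    ph_ref: float = 7.5

    def __post_init__(self) -> None:
        if not (self.p50_mmHg > 0):
            raise InputDomainError(f"p50_mmHg must be positive, got {self.p50_mmHg}")
        if not (self.hill_n > 0):
            raise InputDomainError(f"hill_n must be positive, got {self.hill_n}")


@dataclass(frozen=True)
class BloodParams:
    """Hemoglobin concentration and O2 binding capacity.

    Defaults are 18 g Hb per dl blood and 1.34 ml O2 per g Hb at full
    saturation, i.e. a full-capacity Hb-bound content of 24.12 ml O2/dl.
    """

    hb_g_dl: float = 18.0
    o2_capacity_ml_g: float = 1.34

    def __post_init__(self) -> None:
        if self.hb_g_dl < 0:
            raise InputDomainError(f"hb_g_dl must be non-negative, got {self.hb_g_dl}")
        if not (self.o2_capacity_ml_g > 0):
            raise InputDomainError(
                f"o2_capacity_ml_g must be positive, got {self.o2_capacity_ml_g}"
            )

    @property
    def capacity_ml_dl(self) -> float:
        """Hb-bound O2 content at 100% saturation (ml O2/dl)."""
        return self.hb_g_dl * self.o2_capacity_ml_g


DEFAULT_ODC = ODCParams()
DEFAULT_BLOOD = BloodParams()


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, np.isscalar(x) or arr.ndim == 0


def _maybe_scalar(arr: np.ndarray, scalar: bool):
    return float(arr) if scalar else arr


def saturation_from_po2(po2_mmHg, odc: ODCParams = DEFAULT_ODC):
    """Convert P_O2 (mmHg) to Hb saturation (percent) via the Hill curve.

    Accepts scalars or arrays.  Strictly increasing in P_O2, with
    ``S(0) = 0`` and ``S -> 100`` as ``P -> inf``.
    """
    p, scalar = _as_array(po2_mmHg)
    if np.any(~np.isfinite(p)):
        raise InputDomainError("non-finite P_O2 sample encountered")
    if np.any(p < 0):
        bad = p[p < 0].flat[0]
        raise InputDomainError(f"negative P_O2 sample: {bad!r} mmHg")
    # (P/P50)^n form avoids overflow for large P at large n
    ratio = np.power(p / odc.p50_mmHg, odc.hill_n)
    sat = 100.0 * ratio / (1.0 + ratio)
    return _maybe_scalar(sat, scalar)


def po2_from_saturation(sat_percent, odc: ODCParams = DEFAULT_ODC):
    """Exact analytic inverse of :func:`saturation_from_po2`.

    Defined for saturations in ``[0, 100)``; 100% has no finite inverse.
    """
    s, scalar = _as_array(sat_percent)
    if np.any(~np.isfinite(s)):
        raise InputDomainError("non-finite saturation sample encountered")
    if np.any((s < 0) | (s >= 100)):
        bad = s[(s < 0) | (s >= 100)].flat[0]
        raise InputDomainError(
            f"saturation {bad!r}% outside [0, 100): inverse is unbounded at 100%"
        )
    frac = s / 100.0
    po2 = odc.p50_mmHg * np.power(frac / (1.0 - frac), 1.0 / odc.hill_n)
    return _maybe_scalar(po2, scalar)


def _check_sat(sat):
    s, scalar = _as_array(sat)
    if np.any(~np.isfinite(s)) or np.any((s < 0) | (s > 100)):
        raise InputDomainError(f"saturation outside [0, 100]: {sat!r}")
    return s, scalar


def o2_content(sat_percent, blood: BloodParams = DEFAULT_BLOOD):
    """Hb-bound O2 content (ml O2/dl) at a given saturation (percent)."""
    s, scalar = _check_sat(sat_percent)
    return _maybe_scalar(s / 100.0 * blood.capacity_ml_dl, scalar)


def saturation_from_content(content_ml_dl, blood: BloodParams = DEFAULT_BLOOD):
    """Saturation (percent) implied by an Hb-bound O2 content (ml O2/dl).

    Inverse of :func:`o2_content`; content must lie in ``[0, capacity]``.
    """
    c, scalar = _as_array(content_ml_dl)
    cap = blood.capacity_ml_dl
    if cap <= 0:
        raise InputDomainError("blood has zero O2 capacity; saturation undefined")
    if np.any(~np.isfinite(c)) or np.any((c < -1e-12) | (c > cap + 1e-12)):
        raise InputDomainError(
            f"content {content_ml_dl!r} ml/dl outside [0, {cap}] for this blood"
        )
    sat = np.clip(100.0 * c / cap, 0.0, 100.0)
    return _maybe_scalar(sat, scalar)


def av_o2_difference(art_sat_percent, ven_sat_percent, blood: BloodParams = DEFAULT_BLOOD):
    """Arterio-venous difference in Hb-bound O2 content (ml O2/dl).

    ``o2_content(arterial) - o2_content(venous)``; negative values indicate
    arterialized venous blood (venous saturation above arterial) and are
    reported as such, never clipped.
    """
    return o2_content(art_sat_percent, blood) - o2_content(ven_sat_percent, blood)
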