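"""Closed-form models of electron backscatter from internal lead shielding.

When a lead slab is placed at depth inside tissue during electron-beam
radiotherapy, electrons undergo multiple elastic Coulomb scattering in the
high-Z material and a fraction track back toward the source.  The resulting
upstream dose enhancement is quantified by the electron backscatter factor
(EBF): the ratio of dose at a point at, or upstream of, the Pb interface to
the dose at the same point without the Pb present.

This module evaluates:

* the legacy single-exponential interface model ``EBF = 1 + 0.735 exp(-0.052 Em)``
  (valid 3--35 MeV), :func:`ebf_klevenhagen`;
* the legacy upstream intensity model ``EBI(t) = A exp(-k t)`` with
  user-supplied constants, :func:`ebi_legacy`;
* the double-exponential interface model
  ``EBF(Em) = 1 + C1 exp(-C2 Em) - C3 exp(-C4 Em)`` (valid 0.2--14 MeV),
  :func:`ebf_at_interface`;
* its upstream extension ``EBF(Em, t) = 1 + (EBF(Em) - 1) exp(-k(Em) t)``
  with the energy-dependent decay coefficient ``k(Em) = -C5 ln(Em) + C6``,
  :func:`ebf_upstream` and :func:`decay_coefficient`;
* the depth-to-energy map ``Em = E0 (1 - z/Rp)`` and the beam-quality
  relation ``E0 = 2.33 R50[cm]``.

Units are mm for depths/distances and MeV for energies throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EBFCoefficients",
    "BeamParameters",
    "BackscatterObservation",
    "LegacyDecayModel",
    "EnergyRangeWarning",
    "KLEVENHAGEN_VALID_MEV",
    "MODEL_VALID_MEV",
    "R50_TO_E0_PER_CM",
    "mean_energy_at_depth",
    "e0_from_r50",
    "ebf_klevenhagen",
    "ebi_legacy",
    "ebf_at_interface",
    "decay_coefficient",
    "ebf_upstream",
    "normalized_ebi",
    "peak_enhancement_energy",
    "enhancement_range",
]

#: validity range of the legacy single-exponential interface model, MeV
KLEVENHAGEN_VALID_MEV = (3.0, 35.0)
#: validity range of the double-exponential model, MeV
MODEL_VALID_MEV = (0.2, 14.0)
#: mean surface energy per unit half-value depth, MeV/cm
R50_TO_E0_PER_CM = 2.33

_COEFF_KEYS = ("c1", "c2", "c3", "c4", "c5", "c6")


class EnergyRangeWarning(UserWarning):
    """A model was evaluated outside the energy range it was fitted over."""


def _validity(em, valid: tuple[float, float], what: str, strict: bool) -> None:
    em = np.asarray(em, dtype=float)
    if np.any(em < valid[0]) or np.any(em > valid[1]):
        msg = (
            f"{what} evaluated outside its validated range "
            f"{valid[0]}-{valid[1]} MeV"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, EnergyRangeWarning, stacklevel=3)


def _as_float_or_array(x, out):
    """Return a scalar float when the input was scalar, else the array."""
    if np.ndim(x) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class EBFCoefficients:
    """Coefficients of the composed backscatter model.

    ``c1``/``c3`` are dimensionless amplitudes and ``c2``/``c4`` rates in
    1/MeV of the double-exponential interface model; ``c5`` (slope on
    ln(Em)) and ``c6`` (intercept) parameterise the upstream decay
    coefficient, both in 1/mm.  ``ci_halfwidths`` optionally carries 95%
    confidence half-widths in the same order and units.
    """

    c1: float
    c2: float
    c3: float
    c4: float
    c5: float
    c6: float
    ci_halfwidths: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError(f"all six coefficients must be strictly positive, got {vals}")
        if self.ci_halfwidths is not None:
            ci = tuple(float(v) for v in self.ci_halfwidths)
            if len(ci) != 6 or any(v < 0 for v in ci):
                raise ValueError("ci_halfwidths must be six nonnegative values")
            object.__setattr__(self, "ci_halfwidths", ci)
        if not (self.c1 > self.c3 and self.c2 < self.c4):
            # Nonnegative enhancement for all Em > 0 is only guaranteed when
            # the positive term dominates; flag rather than refuse.
            warnings.warn(
                "coefficient set violates c1 > c3 and c2 < c4; the interface "
                "enhancement may go negative at some energies",
                UserWarning,
                stacklevel=2,
            )

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.c1, self.c2, self.c3, self.c4, self.c5, self.c6)

    def as_dict(self) -> dict[str, float]:
        d = dict(zip(_COEFF_KEYS, self.as_tuple()))
        if self.ci_halfwidths is not None:
            d.update({f"ci_{k}": v for k, v in zip(_COEFF_KEYS, self.ci_halfwidths)})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EBFCoefficients":
        missing = [k for k in _COEFF_KEYS if k not in d]
        if missing:
            raise ValueError(f"coefficient set missing keys: {missing}")
        ci = None
        if all(f"ci_{k}" in d for k in _COEFF_KEYS):
            ci = tuple(float(d[f"ci_{k}"]) for k in _COEFF_KEYS)
        return cls(*(float(d[k]) for k in _COEFF_KEYS), ci_halfwidths=ci)

    @classmethod
    def from_file(cls, path) -> "EBFCoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def default(cls) -> "EBFCoefficients":
        """The published Siemens Artiste coefficient set with 95% CIs."""
        with resources.files("ebfkit.data").joinpath("default_coefficients.json").open() as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class BeamParameters:
    """Beam-quality parameters of a clinical electron beam.

    ``e0_mev`` is the mean energy at the phantom surface, ``rp_mm`` the
    practical range and ``r50_mm`` the depth of the distal 50% dose level,
    all on the central axis.  ``nominal_mev`` is the accelerator's labelled
    energy and is informational only.
    """

    e0_mev: float
    rp_mm: float
    r50_mm: float
    nominal_mev: float | None = None

    def __post_init__(self) -> None:
        if not (self.e0_mev > 0):
            raise ValueError("e0_mev must be positive")
        if not (0 < self.r50_mm < self.rp_mm):
            raise ValueError("require 0 < r50_mm < rp_mm")


@dataclass(frozen=True)
class BackscatterObservation:
    """One extracted backscatter value.

    ``em_mev`` is the mean electron energy at the Pb interface, ``t_mm`` the
    upstream distance from the interface at which the dose ratio ``ebf`` was
    scored, and ``is_interface`` marks the first upstream voxel, whose value
    is attributed to the interface itself (t = 0 in the model).
    """

    em_mev: float
    t_mm: float
    ebf: float
    is_interface: bool = False

    def __post_init__(self) -> None:
        if self.em_mev < 0:
            raise ValueError("em_mev must be nonnegative")
        if self.t_mm < 0:
            raise ValueError("t_mm must be nonnegative")
        if not (self.ebf > 0):
            raise ValueError("ebf must be positive")


@dataclass(frozen=True)
class LegacyDecayModel:
    """Constants of the legacy upstream intensity model EBI(t) = A exp(-k t).

    A and k depend on the primary beam energy and are user-supplied; the
    original tabulation is not packaged here.
    """

    amplitude_a: float
    decay_k: float

    def __post_init__(self) -> None:
        if not (self.amplitude_a > 0 and self.decay_k > 0):
            raise ValueError("amplitude_a and decay_k must be positive")


# ---------------------------------------------------------------------------
# beam quality / depth-energy mapping


def mean_energy_at_depth(beam: BeamParameters, z) -> float | np.ndarray:
    """Mean electron energy at depth ``z`` mm: Em = E0 (1 - z/Rp).

    Clamped at 0 for z >= Rp (no primary electrons beyond the practical
    range).  ``z`` may be a scalar or array; negative depths are rejected.
    """
    z_arr = np.asarray(z, dtype=float)
    if np.any(z_arr < 0):
        raise ValueError("depth z must be nonnegative")
    em = np.maximum(0.0, beam.e0_mev * (1.0 - z_arr / beam.rp_mm))
    return _as_float_or_array(z, em)


def e0_from_r50(r50_mm: float) -> float:
    """Mean surface energy from the half-value depth: E0 = 2.33 R50[cm]."""
    if not (r50_mm > 0):
        raise ValueError("r50_mm must be positive")
    return R50_TO_E0_PER_CM * (r50_mm / 10.0)


# ---------------------------------------------------------------------------
# legacy models


def ebf_klevenhagen(em, *, strict: bool = False) -> float | np.ndarray:
    """Legacy interface backscatter factor: 1 + 0.735 exp(-0.052 Em).

    Warns (or raises, in strict mode) outside the 3--35 MeV range the model
    was measured over.
    """
    em_arr = np.asarray(em, dtype=float)
    if np.any(em_arr < 0):
        raise ValueError("em must be nonnegative")
    _validity(em_arr, KLEVENHAGEN_VALID_MEV, "legacy interface model", strict)
    out = 1.0 + 0.735 * np.exp(-0.052 * em_arr)
    return _as_float_or_array(em, out)


def ebi_legacy(t, model: LegacyDecayModel) -> float | np.ndarray:
    """Legacy upstream intensity EBI(t) = A exp(-k t), t in mm."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    out = model.amplitude_a * np.exp(-model.decay_k * t_arr)
    return _as_float_or_array(t, out)


# ---------------------------------------------------------------------------
# double-exponential model


def ebf_at_interface(em, coeffs: EBFCoefficients | None = None, *, strict: bool = False):
    """Interface backscatter factor EBF(Em) = 1 + C1 exp(-C2 Em) - C3 exp(-C4 Em).

    Warns (or raises, in strict mode) outside the fitted 0.2--14 MeV range.
    """
    coeffs = coeffs or EBFCoefficients.default()
    em_arr = np.asarray(em, dtype=float)
    if np.any(em_arr < 0):
        raise ValueError("em must be nonnegative")
    _validity(em_arr, MODEL_VALID_MEV, "interface backscatter model", strict)
    out = 1.0 + coeffs.c1 * np.exp(-coeffs.c2 * em_arr) - coeffs.c3 * np.exp(-coeffs.c4 * em_arr)
    return _as_float_or_array(em, out)


def decay_coefficient(em, coeffs: EBFCoefficients | None = None, *, strict: bool = False):
    """Upstream decay coefficient k(Em) = max(0, -C5 ln(Em) + C6), in 1/mm.

    Monotone non-increasing in Em.  The raw expression turns negative above
    Em = exp(C6/C5) (about 24 MeV for the default set, outside the validated
    range); it is clamped to 0 there with a warning.
    """
    coeffs = coeffs or EBFCoefficients.default()
    em_arr = np.asarray(em, dtype=float)
    if np.any(em_arr <= 0):
        raise ValueError("em must be strictly positive")
    _validity(em_arr, MODEL_VALID_MEV, "decay-coefficient model", strict)
    raw = -coeffs.c5 * np.log(em_arr) + coeffs.c6
    if np.any(raw < 0):
        warnings.warn(
            "decay coefficient clamped to 0 (Em above exp(C6/C5))",
            UserWarning,
            stacklevel=2,
        )
    out = np.maximum(0.0, raw)
    return _as_float_or_array(em, out)


def ebf_upstream(em, t, coeffs: EBFCoefficients | None = None, *, strict: bool = False):
    """Backscatter factor at upstream distance ``t`` mm from the interface.

    EBF(Em, t) = 1 + (EBF(Em) - 1) exp(-k(Em) t).  The decay acts on the
    enhancement EBF - 1, so the value never drops below 1 and tends to 1 as
    t grows.  At t = 0 it reduces exactly to :func:`ebf_at_interface`.  For
    Em = 0 (interface at or beyond the practical range) there are no primary
    electrons to backscatter and the value is 1 for any t > 0.
    """
    coeffs = coeffs or EBFCoefficients.default()
    scalar = np.ndim(em) == 0 and np.ndim(t) == 0
    em_arr, t_arr = np.broadcast_arrays(
        np.asarray(em, dtype=float), np.asarray(t, dtype=float)
    )
    if np.any(em_arr < 0):
        raise ValueError("em must be nonnegative")
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    _validity(em_arr, MODEL_VALID_MEV, "upstream backscatter model", strict)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EnergyRangeWarning)
        enh = np.asarray(ebf_at_interface(em_arr, coeffs)) - 1.0
    pos = em_arr > 0
    k = np.maximum(0.0, -coeffs.c5 * np.log(np.where(pos, em_arr, 1.0)) + coeffs.c6)
    # Em = 0 with t > 0: k -> +inf in the limit, enhancement extinguished.
    factor = np.where(pos, np.exp(-k * t_arr), np.where(t_arr > 0, 0.0, 1.0))
    out = 1.0 + enh * factor
    return float(out) if scalar else out


def normalized_ebi(em, t, coeffs: EBFCoefficients | None = None, *, strict: bool = False):
    """Upstream enhancement relative to the interface: exp(-k(Em) t) in (0, 1].

    Defined as (EBF(Em, t) - 1) / (EBF(Em) - 1); undefined when the
    interface enhancement is zero.
    """
    coeffs = coeffs or EBFCoefficients.default()
    scalar = np.ndim(em) == 0 and np.ndim(t) == 0
    em_arr, t_arr = np.broadcast_arrays(
        np.asarray(em, dtype=float), np.asarray(t, dtype=float)
    )
    if np.any(em_arr <= 0):
        raise ValueError("em must be strictly positive")
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    _validity(em_arr, MODEL_VALID_MEV, "relative intensity model", strict)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EnergyRangeWarning)
        enh = np.asarray(ebf_at_interface(em_arr, coeffs)) - 1.0
        k = np.asarray(decay_coefficient(em_arr, coeffs))
    if np.any(enh <= 0):
        raise ValueError("interface enhancement is zero; relative intensity undefined")
    out = np.exp(-k * t_arr)
    return float(out) if scalar else out


def peak_enhancement_energy(coeffs: EBFCoefficients | None = None) -> float:
    """Energy at which the interface enhancement peaks, in MeV.

    Closed-form argmax of the double-exponential model:
    Em* = ln(C3 C4 / (C1 C2)) / (C4 - C2), valid when the log argument is
    positive and C2 != C4.  With the default coefficients the peak sits near
    3.5 MeV, consistent with the backscatter factor first rising with energy
    and then falling off.
    """
    coeffs = coeffs or EBFCoefficients.default()
    if math.isclose(coeffs.c2, coeffs.c4, rel_tol=0.0, abs_tol=1e-12):
        raise ValueError("degenerate model: c2 == c4 has no interior peak")
    arg = (coeffs.c3 * coeffs.c4) / (coeffs.c1 * coeffs.c2)
    if arg <= 0 or (math.log(arg) / (coeffs.c4 - coeffs.c2)) <= 0:
        raise ValueError("model has no interior enhancement peak for Em > 0")
    return math.log(arg) / (coeffs.c4 - coeffs.c2)


def enhancement_range(
    em: float, epsilon: float, coeffs: EBFCoefficients | None = None
) -> float:
    """Upstream distance at which the enhancement falls to ``epsilon``.

    Solves EBF(Em, t) = 1 + epsilon for t:
    t = ln((EBF(Em) - 1) / epsilon) / k(Em), in mm.  Requires
    0 < epsilon < EBF(Em) - 1 and a positive decay coefficient.
    """
    coeffs = coeffs or EBFCoefficients.default()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EnergyRangeWarning)
        enh = ebf_at_interface(em, coeffs) - 1.0
        k = decay_coefficient(em, coeffs)
    if not (0 < epsilon < enh):
        raise ValueError(
            f"epsilon must lie in (0, interface enhancement {enh:.4g}), got {epsilon}"
        )
    if k <= 0:
        raise ValueError("decay coefficient is zero; enhancement range is infinite")
    return math.log(enh / epsilon) / k
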