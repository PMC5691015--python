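"""Comparisons of the fitted backscatter model against legacy equations and
against measurement-style observation sets.

``deviation_stats`` mirrors a film-style validation: per-observation ratios
of observed to modelled backscatter, summarised as mean, 1-sigma standard
deviation, and maximum absolute percent deviation.  ``exclude_series``
implements a generic filter for dropping a suspect measurement series
(e.g. one acquired without saturation-thickness Pb) before computing the
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import (
    BackscatterObservation,
    EBFCoefficients,
    EnergyRangeWarning,
    decay_coefficient,
    ebf_at_interface,
    ebf_klevenhagen,
    ebf_upstream,
)

__all__ = [
    "DeviationStats",
    "LegacyKModel",
    "deviation_stats",
    "exclude_series",
    "mean_abs_percent_difference",
    "compare_interface_models",
    "compare_decay_coefficients",
]


@dataclass(frozen=True)
class DeviationStats:
    """Summary of observed/modelled backscatter ratios."""

    mean_ratio: float
    sd_ratio: float
    max_abs_percent_dev: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_ratio < 0:
            raise ValueError("sd_ratio must be nonnegative")


@dataclass(frozen=True)
class LegacyKModel:
    """A user-supplied legacy decay-coefficient curve with validity range."""

    label: str
    k_of_em: Callable[[float], float]
    valid_mev: tuple[float, float] | None = None


def _model_values(observations, coeffs, interface_at_t0):
    em = np.array([o.em_mev for o in observations])
    t = np.array(
        [0.0 if (o.is_interface and interface_at_t0) else o.t_mm for o in observations]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ebf_upstream(em, t, coeffs)


def deviation_stats(
    observations: Sequence[BackscatterObservation],
    coeffs: EBFCoefficients | None = None,
    *,
    interface_at_t0: bool = True,
) -> DeviationStats:
    """Observed/predicted ratio statistics over an observation set."""
    if not observations:
        raise ValueError("empty observation set")
    coeffs = coeffs or EBFCoefficients.default()
    model = np.atleast_1d(_model_values(observations, coeffs, interface_at_t0))
    if np.any(model <= 0):
        raise ValueError("model produced nonpositive backscatter values")
    observed = np.array([o.ebf for o in observations])
    ratios = observed / model
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return DeviationStats(
        mean_ratio=float(np.mean(ratios)),
        sd_ratio=sd,
        max_abs_percent_dev=float(np.max(np.abs(ratios - 1.0)) * 100.0),
        n=len(ratios),
    )


def exclude_series(
    observations: Sequence[BackscatterObservation],
    predicate: Callable[[BackscatterObservation], bool],
) -> list[BackscatterObservation]:
    """Drop every observation matching ``predicate`` (a suspect series)."""
    return [o for o in observations if not predicate(o)]


def mean_abs_percent_difference(
    observations: Sequence[BackscatterObservation],
    coeffs: EBFCoefficients,
    *,
    threshold: float = 1.05,
    interface_at_t0: bool = True,
) -> tuple[float, int]:
    """Mean |observed - model| / model in percent, over observations whose
    observed backscatter exceeds ``threshold``.

    Returns (mean absolute percent difference, number of observations used).
    """
    obs = [o for o in observations if o.ebf > threshold]
    if not obs:
        raise ValueError(f"no observations with backscatter above {threshold}")
    model = np.atleast_1d(_model_values(obs, coeffs, interface_at_t0))
    observed = np.array([o.ebf for o in obs])
    diffs = np.abs(observed - model) / model * 100.0
    return float(np.mean(diffs)), len(obs)


def compare_interface_models(
    coeffs: EBFCoefficients | None = None,
    em_grid=None,
) -> pd.DataFrame:
    """Tabulate the double-exponential and legacy interface models.

    Percent difference follows the convention 100 (legacy - new) / new, so
    a legacy overestimate reads as positive.
    """
    coeffs = coeffs or EBFCoefficients.default()
    em = np.atleast_1d(np.asarray(em_grid if em_grid is not None else np.arange(0.2, 14.01, 0.2)))
    if np.any(em <= 0):
        raise ValueError("energy grid must be strictly positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EnergyRangeWarning)
        new = np.atleast_1d(ebf_at_interface(em, coeffs))
        legacy = np.atleast_1d(ebf_klevenhagen(em))
    return pd.DataFrame(
        {
            "em_mev": em,
            "ebf_double_exp": new,
            "ebf_legacy": legacy,
            "percent_diff": 100.0 * (legacy - new) / new,
        }
    )


def compare_decay_coefficients(
    coeffs: EBFCoefficients | None = None,
    legacy_models: Sequence[LegacyKModel] = (),
    em_grid=None,
) -> pd.DataFrame:
    """Tabulate the decay coefficient k(Em) beside legacy curves.

    Each legacy model is evaluated only inside its declared validity range;
    cells outside it are NaN.  With no legacy models the table carries the
    fitted-model column alone.
    """
    coeffs = coeffs or EBFCoefficients.default()
    em = np.atleast_1d(np.asarray(em_grid if em_grid is not None else np.arange(0.5, 14.01, 0.5)))
    if np.any(em <= 0):
        raise ValueError("energy grid must be strictly positive")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        table = {"em_mev": em, "k_model": np.atleast_1d(decay_coefficient(em, coeffs))}
    for m in legacy_models:
        col = np.full(em.shape, np.nan)
        for i, e in enumerate(em):
            if m.valid_mev is None or (m.valid_mev[0] <= e <= m.valid_mev[1]):
                col[i] = m.k_of_em(float(e))
        table[f"k_{m.label}"] = col
    return pd.DataFrame(table)
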