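"""Melting-temperature extraction from nanoDSF-style melt curves and the
downstream ΔTm bookkeeping: stabilizing classification, selection for
combination, and additivity analysis of multi-point variants.

The canonical readout is the 350/330 nm fluorescence ratio; Tm is the
midpoint of a two-state logistic fit with linear pre- and post-transition
baselines, with a smoothed first-derivative maximum as fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .selection import MutationSpec

STABILIZING_DELTA_TM = 1.0  # °C, strict
SELECTION_DELTA_TM = 2.0    # °C, inclusive


class NoTransitionError(ValueError):
    """The melt curve shows no detectable unfolding transition."""


@dataclass
class MeltCurve:
    """Fluorescence melt curve recorded at 330 and 350 nm."""

    temperatures: np.ndarray
    f330: np.ndarray
    f350: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f330 = np.asarray(self.f330, dtype=float)
        self.f350 = np.asarray(self.f350, dtype=float)
        if not (len(self.temperatures) == len(self.f330) == len(self.f350)):
            raise ValueError("series lengths differ")
        if len(self.temperatures) < 10:
            raise ValueError("need at least 10 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def ratio(self) -> np.ndarray:
        return self.f350 / self.f330

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature": self.temperatures, "f330": self.f330, "f350": self.f350}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeltCurve":
        df = pd.read_csv(path)
        return cls(
            temperatures=df["temperature"].to_numpy(),
            f330=df["f330"].to_numpy(),
            f350=df["f350"].to_numpy(),
        )


@dataclass
class VariantTm:
    """A named variant with its melting temperature (°C)."""

    name: str
    mutations: frozenset[MutationSpec]
    tm: float
    tm_err: float = 0.0
    delta_tm: float | None = None

    def with_reference(self, reference_tm: float) -> "VariantTm":
        return VariantTm(
            name=self.name, mutations=self.mutations, tm=self.tm,
            tm_err=self.tm_err, delta_tm=delta_tm(self.tm, reference_tm),
        )


@dataclass(frozen=True)
class AdditivityReport:
    """Observed multi-point ΔTm versus the sum of single-mutant ΔTm values."""

    singles: tuple[tuple[str, float], ...]
    expected_sum: float
    observed: float
    deviation: float  # expected - observed; positive = sub-additive


def two_state_ratio(
    T: np.ndarray,
    bf: float, df: float, bu: float, du: float, tm: float, slope: float,
) -> np.ndarray:
    """Two-state logistic with linear folded/unfolded baselines."""
    base_f = bf + df * T
    base_u = bu + du * T
    return base_f + (base_u - base_f) / (1.0 + np.exp((tm - T) / slope))


def _smoothed_derivative(curve: MeltCurve) -> tuple[np.ndarray, np.ndarray]:
    r = curve.ratio
    window = min(5, len(r) - (1 - len(r) % 2))  # odd, <= series length
    smooth = savgol_filter(r, window_length=max(window, 3), polyorder=2)
    dr = np.gradient(smooth, curve.temperatures)
    return smooth, dr


def _derivative_tm(curve: MeltCurve) -> float:
    """Temperature of the smoothed first-derivative maximum, refined by a
    parabola through the peak and its neighbours."""
    T = curve.temperatures
    _, dr = _smoothed_derivative(curve)
    i = int(np.argmax(dr))
    if i == 0 or i == len(T) - 1:
        return float(T[i])
    x = T[i - 1: i + 2]
    y = dr[i - 1: i + 2]
    coef = np.polyfit(x, y, 2)
    if coef[0] >= 0:
        return float(T[i])
    return float(-coef[1] / (2 * coef[0]))


def extract_tm(
    curve: MeltCurve, method: str = "two_state_fit"
) -> tuple[float, dict]:
    """Melting temperature from the 350/330 ratio curve.

    ``two_state_fit`` (default) fits the logistic two-state model with
    linear baselines and returns the fitted midpoint; ``derivative``
    returns the temperature of the smoothed first-derivative maximum.
    A flat ratio raises NoTransitionError; a non-converging fit falls back
    to the derivative method with a warning.
    """
    T = curve.temperatures
    r = curve.ratio
    smooth, dr = _smoothed_derivative(curve)
    amplitude = float(smooth.max() - smooth.min())
    noise = float(np.std(r - smooth))
    if amplitude < 1e-12 or amplitude < 4.0 * noise:
        raise NoTransitionError(
            f"no detectable transition (amplitude {amplitude:.3g}, "
            f"noise {noise:.3g})"
        )
    tm0 = _derivative_tm(curve)
    if method == "derivative":
        return tm0, {"method": "derivative", "amplitude": amplitude}
    if method != "two_state_fit":
        raise ValueError(f"unknown method {method!r}")
    # initial baselines from the curve ends
    k = max(3, len(T) // 10)
    bf0 = float(np.mean(r[:k]))
    bu0 = float(np.mean(r[-k:]))
    p0 = [bf0, 0.0, bu0, 0.0, tm0, 1.0]
    lo = [-np.inf, -np.inf, -np.inf, -np.inf, T[0], 1e-3]
    hi = [np.inf, np.inf, np.inf, np.inf, T[-1], (T[-1] - T[0])]
    try:
        popt, _ = curve_fit(
            two_state_ratio, T, r, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        warnings.warn(f"two-state fit did not converge ({exc}); "
                      "falling back to derivative method")
        return tm0, {"method": "derivative_fallback", "amplitude": amplitude}
    fitted = two_state_ratio(T, *popt)
    rmse = float(np.sqrt(np.mean((fitted - r) ** 2)))
    tm = float(popt[4])
    diagnostics = {
        "method": "two_state_fit",
        "params": {
            "bf": popt[0], "df": popt[1], "bu": popt[2], "du": popt[3],
            "tm": tm, "slope": popt[5],
        },
        "rmse": rmse,
        "amplitude": amplitude,
    }
    return tm, diagnostics


def delta_tm(variant_tm: float, reference_tm: float) -> float:
    """ΔTm = variant - reference, reported to 0.1 °C."""
    return round(variant_tm - reference_tm, 1)


def additivity_report(
    singles: Sequence[tuple[str, float]], observed_delta: float
) -> AdditivityReport:
    """Compare an observed multi-point ΔTm with the sum of single ΔTm values."""
    expected = round(sum(d for _, d in singles), 1)
    return AdditivityReport(
        singles=tuple(singles),
        expected_sum=expected,
        observed=round(observed_delta, 1),
        deviation=round(expected - observed_delta, 1),
    )


def classify_variants(
    variants: Sequence[VariantTm],
    stabilizing_threshold: float = STABILIZING_DELTA_TM,
    selection_threshold: float = SELECTION_DELTA_TM,
) -> tuple[list[VariantTm], list[VariantTm]]:
    """Stabilizing (ΔTm > threshold, strict) and selected-for-combination
    (ΔTm >= threshold, inclusive) variants, each sorted by ΔTm descending.

    Variants without a ΔTm (the reference itself) are ignored.
    """
    with_delta = [v for v in variants if v.delta_tm is not None]
    stabilizing = sorted(
        (v for v in with_delta if v.delta_tm > stabilizing_threshold),
        key=lambda v: -v.delta_tm,
    )
    selected = sorted(
        (v for v in with_delta if v.delta_tm >= selection_threshold),
        key=lambda v: -v.delta_tm,
    )
    return stabilizing, selected


def load_variant_table(path: str | Path, reference: str = "FGF21-WT") -> list[VariantTm]:
    """Read a variant Tm CSV (variant, mutations, tm, tm_err) and attach ΔTm
    relative to the named reference row."""
    df = pd.read_csv(path)
    if reference not in set(df["variant"]):
        raise ValueError(f"reference {reference!r} not in table")
    ref_tm = float(df.loc[df["variant"] == reference, "tm"].iloc[0])
    out = []
    for _, row in df.iterrows():
        muts = frozenset(
            MutationSpec.parse(m)
            for m in str(row.get("mutations") or "").split("+")
            if m and m != "nan"
        )
        v = VariantTm(
            name=str(row["variant"]), mutations=muts,
            tm=float(row["tm"]), tm_err=float(row.get("tm_err", 0.0)),
        )
        if v.name != reference:
            v = v.with_reference(ref_tm)
        out.append(v)
    return out
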