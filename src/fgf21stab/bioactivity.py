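"""Cell-assay quantification: four-parameter-logistic (4PL) ED50 fitting of
proliferation dose-response data, pERK/ERK densitometry normalization, and
residual-activity profiling after thermal preincubation.

The 4PL model is  f(x) = bottom + (top - bottom) / (1 + (ed50/x)^hill),
so hill > 0 gives an increasing response and f(ed50) is the midpoint —
the median effective dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DoseResponse:
    """Dose series (ng/ml) with replicate responses (fluorescence units)."""

    doses: np.ndarray
    responses: np.ndarray  # shape (n_doses, n_replicates)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if np.any(self.doses <= 0):
            raise ValueError("doses must be positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be sorted ascending")
        if self.responses.shape[0] != len(self.doses):
            raise ValueError("responses must have one row per dose")

    @property
    def mean_response(self) -> np.ndarray:
        return self.responses.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.responses,
            columns=[f"rep{i+1}" for i in range(self.responses.shape[1])],
        )
        df.insert(0, "dose", self.doses)
        return df

    @classmethod
    def from_csv(cls, path: str | Path, **metadata) -> "DoseResponse":
        df = pd.read_csv(path)
        reps = [c for c in df.columns if c.startswith("rep")]
        return cls(
            doses=df["dose"].to_numpy(),
            responses=df[reps].to_numpy(),
            metadata=metadata,
        )


@dataclass(frozen=True)
class Ed50Fit:
    ed50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    reason: str = ""


@dataclass(frozen=True)
class DensitometryRecord:
    """Band densities (mean grey values) of one lane/condition."""

    perk: float
    erk: float
    loading: float
    condition: str = ""

    def __post_init__(self) -> None:
        if min(self.perk, self.erk, self.loading) <= 0:
            raise ValueError("band densities must be positive")


def four_pl(x: np.ndarray, bottom: float, top: float, ed50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (ed50 / x) ** hill)


def fit_dose_response(data: DoseResponse) -> Ed50Fit:
    """Unweighted least-squares 4PL fit with multi-start initialization.

    Starts from hill in {0.5, 1, 2} with ed50 at the geometric mean of the
    doses; ed50 is bounded to [min dose / 10, max dose * 10].  The converged
    flag is honest: a flat response (fitted amplitude indistinguishable from
    residual noise) reports converged = False with a reason.
    """
    x = np.repeat(data.doses, data.responses.shape[1])
    y = data.responses.ravel()
    if len(np.unique(data.doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    ymin, ymax = float(y.min()), float(y.max())
    yrange = ymax - ymin
    if yrange <= 0:
        return Ed50Fit(
            ed50=np.nan, hill=np.nan, top=ymax, bottom=ymin, rss=0.0,
            converged=False, reason="flat response (zero dynamic range)",
        )
    ed50_0 = float(np.exp(np.mean(np.log(data.doses))))
    lo = [ymin - yrange, ymin - yrange, data.doses.min() / 10.0, 0.05]
    hi = [ymax + yrange, ymax + yrange, data.doses.max() * 10.0, 20.0]
    best = None
    for hill0 in (0.5, 1.0, 2.0):
        p0 = [ymin, ymax, ed50_0, hill0]
        try:
            popt, _ = curve_fit(
                four_pl, x, y, p0=p0, bounds=(lo, hi), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((four_pl(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return Ed50Fit(
            ed50=np.nan, hill=np.nan, top=ymax, bottom=ymin, rss=np.inf,
            converged=False, reason="fit did not converge",
        )
    popt, rss = best
    bottom, top, ed50, hill = (float(v) for v in popt)
    if top < bottom:  # canonicalize: top is the high asymptote
        bottom, top, hill = top, bottom, -hill
    n = len(y)
    rmse = np.sqrt(rss / n)
    amplitude = top - bottom
    if amplitude < 2.0 * rmse or amplitude < 1e-9 * max(abs(top), 1.0):
        return Ed50Fit(
            ed50=ed50, hill=hill, top=top, bottom=bottom, rss=rss,
            converged=False, reason="flat response (amplitude within noise)",
        )
    return Ed50Fit(
        ed50=ed50, hill=hill, top=top, bottom=bottom, rss=rss, converged=True
    )


def normalize_densitometry(
    sample: DensitometryRecord, negative_control: DensitometryRecord
) -> float:
    """pERK/ERK ratio (each band first divided by its loading control)
    relative to the negative control."""
    def ratio(rec: DensitometryRecord) -> float:
        return (rec.perk / rec.loading) / (rec.erk / rec.loading)

    return ratio(sample) / ratio(negative_control)


def residual_activity_profile(
    conditions: Mapping[str, DoseResponse],
    reference: str,
    active_fraction: float = 0.2,
) -> pd.DataFrame:
    """Fit every preincubation condition and flag residual activity.

    ``active`` requires a converged fit whose dynamic range (top - bottom)
    is at least ``active_fraction`` of the reference condition's dynamic
    range.  Returns a table of (condition, ed50, max_response, dynamic
    range, active, reason).
    """
    if reference not in conditions:
        raise ValueError(f"missing reference condition {reference!r}")
    fits = {name: fit_dose_response(dr) for name, dr in conditions.items()}
    ref = fits[reference]
    if not ref.converged:
        raise ValueError("reference condition fit did not converge")
    ref_range = ref.top - ref.bottom
    rows = []
    for name, fit in fits.items():
        if not fit.converged:
            active, reason = False, fit.reason or "fit did not converge"
            dyn = 0.0
        else:
            dyn = fit.top - fit.bottom
            active = dyn >= active_fraction * ref_range
            reason = "" if active else (
                f"dynamic range {dyn:.3g} below {active_fraction:.0%} of reference"
            )
        rows.append(
            {
                "condition": name,
                "ed50": fit.ed50 if fit.converged else np.nan,
                "max_response": fit.top if fit.converged else np.nan,
                "dynamic_range": dyn,
                "active": active,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
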