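"""Probit LD50 estimation from dose-group mortality (Miller-Tainter style).

Percent mortality per treated dose is corrected for background (control)
lethality with Abbott's formula, endpoint-corrected so 0% and 100% stay
finite, transformed to probits (5 + inverse standard normal), and regressed
against log10 dose by unweighted least squares. The LD50 is the dose where
the fitted probit line crosses 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

MORTALITY_COLUMNS = ["dose_ug", "dose_mg_per_kg", "n", "deaths"]


class DegenerateControlError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class LD50Estimate:
    ld50: float                       # mg/kg
    slope: float                      # probit units per log10 dose
    intercept: float
    r_squared: float
    table: pd.DataFrame               # per-dose: dose, corrected %, probit
    ci_low: float | None = None
    ci_high: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ld50_mg_per_kg": self.ld50,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "flags": self.flags,
            "per_dose": self.table.to_dict(orient="records"),
        }


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MORTALITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"mortality table missing columns: {missing}")
    if (table["deaths"] > table["n"]).any() or (table["deaths"] < 0).any():
        raise ValueError("deaths must satisfy 0 <= deaths <= n")
    if (table["dose_mg_per_kg"] < 0).any():
        raise ValueError("doses must be non-negative")
    if table["dose_mg_per_kg"].duplicated().any():
        raise ValueError("doses must be unique")
    return table


def control_correct(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Abbott correction of treated-group mortality for control lethality.

    Returns the treated rows with a ``corrected_pct`` column (clipped to
    [0, 100]) and any clipping flags; the zero-dose row is removed from the
    fit set.
    """
    table = _validate(table)
    control = table[table["dose_mg_per_kg"] == 0]
    if control.empty:
        raise ValueError("mortality table must contain a zero-dose control row")
    p0 = float(control["deaths"].sum() / control["n"].sum())
    if p0 >= 1.0:
        raise DegenerateControlError("100% control mortality: correction undefined")
    treated = table[table["dose_mg_per_kg"] > 0].copy()
    flags: list[str] = []
    p = treated["deaths"] / treated["n"]
    corrected = (p - p0) / (1.0 - p0)
    for dose, val in zip(treated["dose_mg_per_kg"], corrected):
        if val < 0:
            flags.append(f"dose {dose}: treated mortality below control, clipped to 0%")
    treated["corrected_pct"] = 100.0 * corrected.clip(0.0, 1.0)
    return treated, flags


def probit_transform(percent: float, n: int) -> float:
    """Probit (5 + inverse-normal) with 0/100% endpoint corrections.

    0% is replaced by ``100 * 0.25/n`` and 100% by ``100 * (n - 0.25)/n`` so
    the transform stays finite for any group size.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must be in [0, 100]")
    if percent == 0.0:
        percent = 100.0 * (0.25 / n)
    elif percent == 100.0:
        percent = 100.0 * ((n - 0.25) / n)
    return 5.0 + float(norm.ppf(percent / 100.0))


def fit_ld50(
    table: pd.DataFrame,
    n_boot: int = 0,
    ci_level: float = 0.95,
    seed: int = 0,
) -> LD50Estimate:
    """Unweighted probit-vs-log10(dose) regression; LD50 where probit = 5.

    ``n_boot > 0`` adds a nonparametric bootstrap CI: deaths are resampled
    binomially per dose from the observed fractions and the fit repeated.
    """
    treated, flags = control_correct(table)
    if len(treated) < 2:
        raise InsufficientDataError("need at least 2 treated doses")
    logd = np.log10(treated["dose_mg_per_kg"].to_numpy(dtype=float))
    probits = np.array(
        [probit_transform(p, int(n)) for p, n in zip(treated["corrected_pct"], treated["n"])]
    )
    slope, intercept = np.polyfit(logd, probits, 1)
    if slope == 0:
        raise InsufficientDataError("zero slope: LD50 not identifiable")
    fitted = slope * logd + intercept
    ss_res = float(((probits - fitted) ** 2).sum())
    ss_tot = float(((probits - probits.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    ld50 = 10.0 ** ((5.0 - intercept) / slope)

    per_dose = treated[["dose_mg_per_kg", "n", "deaths", "corrected_pct"]].copy()
    per_dose["probit"] = probits

    est = LD50Estimate(
        ld50=float(ld50), slope=float(slope), intercept=float(intercept),
        r_squared=r2, table=per_dose, flags=flags,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        base = table.copy()
        p_hat = base["deaths"] / base["n"]
        for _ in range(n_boot):
            b = base.copy()
            b["deaths"] = rng.binomial(base["n"].to_numpy(), p_hat.to_numpy())
            try:
                boots.append(fit_ld50(b).ld50)
            except (InsufficientDataError, DegenerateControlError):
                continue
        if boots:
            lo = (1.0 - ci_level) / 2.0
            est.ci_low = float(np.quantile(boots, lo))
            est.ci_high = float(np.quantile(boots, 1.0 - lo))
    return est
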