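"""Body-temperature prediction models for an emersed intertidal mussel.

Four approaches of increasing complexity:

1. ``predict_air_proxy`` — air temperature used directly as body temperature.
2. ``predict_elvin_gonor`` — a fixed empirical regression on air temperature
   and solar irradiance, T_mussel = T_air + 5.03 L (L in Langleys/min) or,
   in SI units, T_mussel = T_air + 7.21e-3 S (S in W/m^2).
3. ``fit_site_regression`` / ``predict_site_regression`` — the same functional
   form refit per site against logger temperatures over emersed hours.
4. ``steady_state_temperature`` — a simplified steady-state heat budget
   balancing absorbed shortwave, longwave exchange with sky and ground,
   convection and ground conduction, solved for the equilibrium body
   temperature each hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .series import BodyTemperatureSeries

#: Stefan-Boltzmann constant, W m^-2 K^-4.
SIGMA_SB = 5.670374419e-8

#: Langleys per minute in one W/m^2, derived from 1 Langley = 1 cal/cm^2
#: and 1 cal = 4.184 J: (60 s/min) / (4.184 J/cal * 1e4 cm^2/m^2).
LANGLEYS_MIN_PER_WM2 = 60.0 / (4.184 * 1.0e4)

#: Empirical solar coefficients of the fixed mussel-temperature regression.
EG_SOLAR_COEFF_LANGLEY = 5.03  # deg C per (Langley/min)
EG_SOLAR_COEFF_SI = 7.21e-3  # deg C per (W/m^2), as conventionally printed


@dataclass(frozen=True)
class RegressionCoefficients:
    """Fitted coefficients of T_body ~ intercept + air_coeff*T_air + solar_coeff*S."""

    intercept: float
    air_coeff: float
    solar_coeff: float
    n: int
    intercept_se: float = float("nan")
    air_se: float = float("nan")
    solar_se: float = float("nan")

    def __post_init__(self):
        for v in (self.intercept, self.air_coeff, self.solar_coeff):
            if not np.isfinite(v):
                raise ValueError("regression coefficients must be finite")
        if self.n < 3:
            raise ValueError("regression must be fitted on at least 3 records")


@dataclass(frozen=True)
class HeatBudgetParams:
    """Parameters of the steady-state heat budget.

    The convective coefficient follows a forced-convection scaling
    ``h = convective_coeff_scale * (wind / characteristic_length) ** convective_exponent``
    with the wind speed floored at 0.1 m/s (free-convection floor). The sky
    is treated as a grey body ``sky_temp_depression`` kelvin below air
    temperature (constant-cloud assumption) and the ground is assumed to be
    at air temperature.
    """

    shortwave_absorptivity: float = 0.75  # dimensionless, [0, 1]
    emissivity: float = 0.96  # dimensionless, [0, 1]
    characteristic_length: float = 0.075  # m, mid-size mussel shell length
    convective_coeff_scale: float = 4.0  # W m^-2 K^-1 per (m/s / m)^exponent
    convective_exponent: float = 0.5  # dimensionless
    sky_temp_depression: float = 15.0  # K below air temperature
    ground_contact_conductance: float = 10.0  # W m^-2 K^-1
    solar_projection: float = 0.5  # projected/total area ratio

    def __post_init__(self):
        for name in (
            "shortwave_absorptivity",
            "emissivity",
            "characteristic_length",
            "convective_coeff_scale",
            "convective_exponent",
            "ground_contact_conductance",
            "solar_projection",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sky_temp_depression < 0:
            raise ValueError("sky_temp_depression must be >= 0")
        if self.shortwave_absorptivity > 1 or self.emissivity > 1:
            raise ValueError("absorptivity and emissivity must be <= 1")


# ---------------------------------------------------------------------------
# 1. Air-temperature proxy.

def predict_air_proxy(air_temp: pd.Series, site_id: str = "", microsite_id: str = "") -> BodyTemperatureSeries:
    """Body temperature = air temperature (identity copy, source ``air_proxy``)."""
    return BodyTemperatureSeries(
        temps=air_temp.astype(float).rename("body_temp"),
        site_id=site_id,
        microsite_id=microsite_id,
        source="air_proxy",
    )


# ---------------------------------------------------------------------------
# 2. Fixed empirical regression.

def predict_elvin_gonor(air_temp, solar, units: str = "si"):
    """Fixed-regression body temperature from air temperature and solar.

    ``units="si"`` expects solar in W/m^2 and uses the printed SI
    coefficient 7.21e-3; ``units="langley"`` expects Langleys/min and uses
    5.03. Negative solar is rejected.
    """
    solar_arr = np.asarray(solar, dtype=float)
    if np.any(solar_arr < 0):
        raise ValueError("solar irradiance must be non-negative")
    if units == "si":
        coeff = EG_SOLAR_COEFF_SI
    elif units == "langley":
        coeff = EG_SOLAR_COEFF_LANGLEY
    else:
        raise ValueError("units must be 'si' or 'langley'")
    return air_temp + coeff * solar


# ---------------------------------------------------------------------------
# 3. Site-fitted regression.

def fit_site_regression(
    air_temp: pd.Series,
    solar: pd.Series,
    observed: pd.Series,
    mask: pd.Series,
    include_intercept: bool = True,
) -> RegressionCoefficients:
    """OLS fit of observed body temperature on (1, T_air, S) over emersed hours.

    All inputs must share an index; rows that are submerged or incomplete
    are dropped. Raises on rank deficiency, naming the collinear column.
    """
    df = pd.DataFrame(
        {"air_temp": air_temp, "solar": solar, "observed": observed, "emersed": mask}
    )
    df = df[df["emersed"].fillna(False).astype(bool)].drop(columns="emersed").dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 emersed, fully observed records, got {len(df)}")
    for col in ("air_temp", "solar"):
        if np.ptp(df[col].to_numpy()) == 0.0:
            raise ValueError(f"design is rank-deficient: column '{col}' is constant")
    x = df[["air_temp", "solar"]]
    if include_intercept:
        x = sm.add_constant(x)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise ValueError("design is rank-deficient: 'air_temp' and 'solar' are collinear")
    fit = sm.OLS(df["observed"], x).fit()
    params = fit.params
    bse = fit.bse
    if include_intercept:
        icpt, icpt_se = float(params["const"]), float(bse["const"])
    else:
        icpt, icpt_se = 0.0, 0.0
    return RegressionCoefficients(
        intercept=icpt,
        air_coeff=float(params["air_temp"]),
        solar_coeff=float(params["solar"]),
        n=int(fit.nobs),
        intercept_se=icpt_se,
        air_se=float(bse["air_temp"]),
        solar_se=float(bse["solar"]),
    )


def predict_site_regression(coeffs: RegressionCoefficients, air_temp, solar):
    """Evaluate the fitted affine model."""
    return coeffs.intercept + coeffs.air_coeff * air_temp + coeffs.solar_coeff * solar


# ---------------------------------------------------------------------------
# 4. Steady-state heat budget.

def heat_budget_residual(body_temp_c, air_temp_c, solar, wind, params: HeatBudgetParams):
    """Net heat flux (W/m^2) into the body at a trial body temperature.

    Positive residual means the body would warm; the equilibrium temperature
    is the root. The residual is strictly decreasing in body temperature, so
    the root is unique.
    """
    p = params
    tb = np.asarray(body_temp_c, dtype=float) + 273.15
    ta = np.asarray(air_temp_c, dtype=float) + 273.15
    tsky = ta - p.sky_temp_depression
    tground = ta  # stated model assumption
    h = convective_coefficient(wind, p)
    return (
        p.shortwave_absorptivity * p.solar_projection * np.asarray(solar, dtype=float)
        + p.emissivity * SIGMA_SB * (tsky**4 - tb**4)
        + p.emissivity * SIGMA_SB * (tground**4 - tb**4)
        + h * (ta - tb)
        + p.ground_contact_conductance * (tground - tb)
    )


def convective_coefficient(wind, params: HeatBudgetParams):
    """Convective exchange coefficient h(wind), W m^-2 K^-1; wind floored at 0.1 m/s."""
    w = np.maximum(np.asarray(wind, dtype=float), 0.1)
    return params.convective_coeff_scale * (w / params.characteristic_length) ** params.convective_exponent


def steady_state_temperature(
    air_temp,
    solar,
    wind,
    params: HeatBudgetParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
):
    """Equilibrium body temperature (deg C) from the steady energy balance.

    Solved by safeguarded Newton iteration (bisection fallback) to
    ``|residual| < tol`` W/m^2 inside the guaranteed bracket
    [T_air - 40, T_air + 60] deg C. Vectorised over array inputs.
    """
    p = params if params is not None else HeatBudgetParams()
    ta, s, w = np.broadcast_arrays(
        np.asarray(air_temp, dtype=float),
        np.asarray(solar, dtype=float),
        np.asarray(wind, dtype=float),
    )
    scalar = ta.ndim == 0
    ta = np.atleast_1d(ta).astype(float)
    s = np.atleast_1d(s).astype(float)
    w = np.atleast_1d(w).astype(float)
    if np.any(s < 0):
        raise ValueError("solar irradiance must be non-negative")
    if np.any(w < 0):
        raise ValueError("wind speed must be non-negative")

    h = convective_coefficient(w, p)
    lin = h + p.ground_contact_conductance
    lo = ta - 40.0
    hi = ta + 60.0
    tb = ta.copy()
    resid = heat_budget_residual(tb, ta, s, w, p)
    for _ in range(max_iter):
        if np.all(np.abs(resid) < tol):
            break
        # Maintain the bracket: residual decreases in tb, so a positive
        # residual means the root lies above the current iterate.
        lo = np.where(resid > 0, tb, lo)
        hi = np.where(resid <= 0, tb, hi)
        dresid = -(8.0 * p.emissivity * SIGMA_SB * (tb + 273.15) ** 3 + lin)
        step = resid / dresid
        cand = tb - step
        outside = (cand <= lo) | (cand >= hi)
        tb = np.where(outside, 0.5 * (lo + hi), cand)
        resid = heat_budget_residual(tb, ta, s, w, p)
    else:
        raise RuntimeError(
            f"heat budget failed to converge: max |residual| = {np.abs(resid).max():.3e} W/m^2"
        )
    return float(tb[0]) if scalar else tb


def predict_heat_budget(
    air_temp: pd.Series,
    solar: pd.Series,
    wind: pd.Series,
    params: HeatBudgetParams | None = None,
    site_id: str = "",
    microsite_id: str = "",
) -> BodyTemperatureSeries:
    """Series wrapper around :func:`steady_state_temperature`."""
    temps = pd.Series(
        steady_state_temperature(air_temp.to_numpy(), solar.to_numpy(), wind.to_numpy(), params),
        index=air_temp.index,
        name="body_temp",
    )
    return BodyTemperatureSeries(temps=temps, site_id=site_id, microsite_id=microsite_id, source="heat_budget")
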