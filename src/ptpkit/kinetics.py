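"""Enzyme kinetics and thermodynamics fits.

Models
------
* Michaelis-Menten: v = Vmax * S / (K_M + S); kcat = Vmax / [E] when the
  enzyme concentration is supplied.
* Bell-shaped pH-rate profile for catalysis controlled by two ionizations
  (one group required protonated, one deprotonated):

      kcat(pH) = kcat_lim / (1 + [H+]/K_E1 + K_E2/[H+]),  [H+] = 10^(-pH)

  maximal exactly at pH = (pK_E1 + pK_E2)/2. The fit is unweighted least
  squares on log10-transformed rates.
* Arrhenius: ln k vs 1/T linear regression; Ea = -slope * R. The R^2 of
  the line doubles as the deviation-from-Arrhenius diagnostic.
* Pseudo-first-order oxidative inactivation: k_obs per peroxide
  concentration from ln(residual activity) vs time, then the second-order
  k_inact as the slope of k_obs vs [H2O2] (free intercept reported; it
  captures spontaneous inactivation).
* Transition-state theory: dG_act = R*T*ln(k_B*T / (h*k)), transmission
  coefficient 1.
* Denaturation-enthalpy scaling: dH(T), affine in temperature and linear
  in molecular mass, from structure-energetics specific-enthalpy
  coefficients.

Physical constants are CODATA 2018. Temperatures in kelvin internally;
helpers accept Celsius where noted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import FitError, FitWarning, ParameterError

# CODATA 2018
BOLTZMANN_J_K = 1.380649e-23
PLANCK_J_S = 6.62607015e-34
GAS_CONSTANT_J = 8.31446261815324
GAS_CONSTANT_KCAL = GAS_CONSTANT_J / 4184.0  # kcal mol^-1 K^-1
CELSIUS_OFFSET = 273.15


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

@dataclass
class MMFitResult:
    vmax: float
    km: float
    vmax_se: float
    km_se: float
    kcat: float | None = None

    def predict(self, s):
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


def mm_fit(substrate, rate, enzyme_conc: float | None = None) -> MMFitResult:
    """Nonlinear least squares of v = Vmax*S/(K_M + S)."""
    s = np.asarray(substrate, dtype=float)
    v = np.asarray(rate, dtype=float)
    if np.unique(s).size < 3:
        raise ParameterError("need at least 3 distinct substrate concentrations")
    p0 = (float(v.max()) * 1.2 or 1.0, float(np.median(s)))
    try:
        popt, pcov = optimize.curve_fit(
            lambda x, vmax, km: vmax * x / (km + x), s, v, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    kcat = popt[0] / enzyme_conc if enzyme_conc else None
    return MMFitResult(popt[0], popt[1], se[0], se[1], kcat)


# ---------------------------------------------------------------------------
# bell pH-rate profile
# ---------------------------------------------------------------------------

@dataclass
class BellParameters:
    """kcat_lim (s^-1) and the two ionization constants (molar)."""

    kcat_lim: float
    k_e1: float
    k_e2: float

    def __post_init__(self):
        if min(self.kcat_lim, self.k_e1, self.k_e2) <= 0:
            raise ParameterError("bell parameters must be positive")

    @property
    def pk_e1(self) -> float:
        return float(-np.log10(self.k_e1))

    @property
    def pk_e2(self) -> float:
        return float(-np.log10(self.k_e2))

    @property
    def ph_optimum(self) -> float:
        return 0.5 * (self.pk_e1 + self.pk_e2)


@dataclass
class BellFitResult:
    params: BellParameters
    pk_se: tuple
    fallback_limb: str | None = None


def bell_model(ph, params: BellParameters):
    """kcat at given pH under the two-ionization bell equation."""
    ph = np.asarray(ph, dtype=float)
    h = 10.0 ** (-ph)
    out = params.kcat_lim / (1.0 + h / params.k_e1 + params.k_e2 / h)
    return float(out) if out.ndim == 0 else out


def _bell_log10(ph, log_kcat_lim, pk1, pk2):
    h = 10.0 ** (-np.asarray(ph, dtype=float))
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)
    return log_kcat_lim - np.log10(1.0 + h / k1 + k2 / h)


def bell_fit(ph, kcat) -> BellFitResult:
    """Fit the bell equation on log10-transformed rates.

    Monotone (no-bell) data triggers a :class:`FitWarning` and a one-limb
    fallback fit for the visible ionization; the hidden pK is then reported
    as NaN-free but flagged via ``fallback_limb``.
    """
    ph = np.asarray(ph, dtype=float)
    kcat = np.asarray(kcat, dtype=float)
    if ph.size < 5:
        raise ParameterError("bell fit needs at least 5 pH points")
    if np.any(kcat <= 0):
        raise ParameterError("rates must be positive for the log transform")
    order = np.argsort(ph)
    ph, kcat = ph[order], kcat[order]
    y = np.log10(kcat)

    imax = int(np.argmax(kcat))
    if imax in (0, ph.size - 1):
        limb = "basic" if imax == 0 else "acid"
        warnings.warn(
            f"pH-rate data is monotone (no bell); fitting the {limb} limb only",
            FitWarning,
        )
        if limb == "acid":
            fun = lambda x, lk, pk1: lk - np.log10(1.0 + 10.0 ** (-x) / 10.0 ** (-pk1))
            p0 = (y.max() + 0.1, ph[ph.size // 2])
            popt, pcov = optimize.curve_fit(fun, ph, y, p0=p0, maxfev=10000)
            params = BellParameters(10.0 ** popt[0], 10.0 ** (-popt[1]), 1e-14)
            se = np.sqrt(np.diag(pcov))
            return BellFitResult(params, (se[1], float("inf")), "acid")
        fun = lambda x, lk, pk2: lk - np.log10(1.0 + 10.0 ** (-pk2) / 10.0 ** (-x))
        p0 = (y.max() + 0.1, ph[ph.size // 2])
        popt, pcov = optimize.curve_fit(fun, ph, y, p0=p0, maxfev=10000)
        params = BellParameters(10.0 ** popt[0], 1e2, 10.0 ** (-popt[1]))
        se = np.sqrt(np.diag(pcov))
        return BellFitResult(params, (float("inf"), se[1]), "basic")

    p0 = (y[imax] + 0.3, ph[imax] - 0.7, ph[imax] + 0.7)
    try:
        popt, pcov = optimize.curve_fit(_bell_log10, ph, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"bell fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    params = BellParameters(10.0 ** popt[0], 10.0 ** (-popt[1]), 10.0 ** (-popt[2]))
    return BellFitResult(params, (se[1], se[2]))


# ---------------------------------------------------------------------------
# peroxide inactivation
# ---------------------------------------------------------------------------

@dataclass
class InactivationResult:
    """k_obs per concentration and the second-order k_inact."""

    k_obs: pd.DataFrame           # columns: concentration_M, k_obs, r_squared
    k_inact: float                # M^-1 s^-1
    intercept: float              # s^-1, spontaneous inactivation
    r_squared: float
    forced_origin: bool = False


def inactivation_fit(data: pd.DataFrame, force_origin: bool = False,
                     conc_col: str = "concentration_M", time_col: str = "time_s",
                     activity_col: str = "activity") -> InactivationResult:
    """Two-stage fit: ln(residual activity) vs time per concentration
    (negated slope = k_obs), then k_obs vs concentration (slope = k_inact)."""
    if np.any(np.asarray(data[activity_col]) <= 0):
        raise ParameterError("residual activities must be positive")
    rows = []
    for conc, group in data.groupby(conc_col):
        if len(group) < 3:
            raise ParameterError(
                f"need >= 3 time points per concentration (got {len(group)} at {conc})"
            )
        t = group[time_col].to_numpy(dtype=float)
        lna = np.log(group[activity_col].to_numpy(dtype=float))
        res = stats.linregress(t, lna)
        rows.append({
            "concentration_M": float(conc),
            "k_obs": -res.slope,
            "r_squared": res.rvalue**2,
        })
    k_obs = pd.DataFrame(rows).sort_values("concentration_M", ignore_index=True)
    if len(k_obs) < 3:
        raise ParameterError("need k_obs at >= 3 peroxide concentrations")
    c = k_obs["concentration_M"].to_numpy()
    k = k_obs["k_obs"].to_numpy()
    if force_origin:
        slope = float(np.sum(c * k) / np.sum(c * c))
        pred = slope * c
        ss_res = np.sum((k - pred) ** 2)
        ss_tot = np.sum((k - k.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return InactivationResult(k_obs, slope, 0.0, float(r2), True)
    res = stats.linregress(c, k)
    return InactivationResult(k_obs, float(res.slope), float(res.intercept),
                              float(res.rvalue**2))


# ---------------------------------------------------------------------------
# Arrhenius
# ---------------------------------------------------------------------------

@dataclass
class ArrheniusResult:
    ea_kcal: float
    ln_a: float
    r_squared: float   # deviation-from-Arrhenius diagnostic

    def predict(self, temperature_k):
        t = np.asarray(temperature_k, dtype=float)
        return np.exp(self.ln_a - self.ea_kcal / (GAS_CONSTANT_KCAL * t))


def arrhenius_fit(temperature_k, k) -> ArrheniusResult:
    """ln k vs 1/T regression; Ea in kcal/mol."""
    t = np.asarray(temperature_k, dtype=float)
    k = np.asarray(k, dtype=float)
    if t.size < 3:
        raise ParameterError("need at least 3 temperatures")
    if np.any(k <= 0) or np.any(t <= 0):
        raise ParameterError("rates and temperatures must be positive")
    res = stats.linregress(1.0 / t, np.log(k))
    return ArrheniusResult(-res.slope * GAS_CONSTANT_KCAL, float(res.intercept),
                           float(res.rvalue**2))


# ---------------------------------------------------------------------------
# transition-state theory
# ---------------------------------------------------------------------------

def tst_activation_free_energy(rate: float, temperature_k: float) -> float:
    """dG_act (kcal/mol) = R*T*ln(k_B*T/(h*k)), transmission coefficient 1."""
    if rate <= 0 or temperature_k <= 0:
        raise ParameterError("rate and temperature must be positive")
    prefactor = BOLTZMANN_J_K * temperature_k / PLANCK_J_S
    return GAS_CONSTANT_KCAL * temperature_k * float(np.log(prefactor / rate))


def rate_from_activation_free_energy(dg_kcal: float, temperature_k: float) -> float:
    """Inverse of :func:`tst_activation_free_energy`."""
    prefactor = BOLTZMANN_J_K * temperature_k / PLANCK_J_S
    return prefactor * float(np.exp(-dg_kcal / (GAS_CONSTANT_KCAL * temperature_k)))


# ---------------------------------------------------------------------------
# fold change and denaturation enthalpy
# ---------------------------------------------------------------------------

def fold_change(a: float, b: float, rounding: str = "none") -> float:
    """Ratio a/b with the stated rounding convention."""
    if b <= 0:
        raise ParameterError("denominator must be positive")
    ratio = a / b
    if rounding == "none":
        return ratio
    if rounding == "nearest_int":
        return float(round(ratio))
    if rounding == "one_decimal":
        return round(ratio, 1)
    if rounding == "one_sig_fig":
        if ratio == 0:
            return 0.0
        exp = int(np.floor(np.log10(abs(ratio))))
        return round(ratio, -exp)
    raise ParameterError(f"unknown rounding {rounding!r}")


@dataclass
class EnthalpyModel:
    """Specific denaturation enthalpy, affine in temperature.

    Coefficients are the least-squares calibration of the
    structure-energetics scaling against a 17 kDa reference protein's
    anchor values (191/215/239/262 kcal/mol at 90/100/110/120 Celsius);
    dH scales linearly with molecular mass.
    """

    specific_enthalpy_ref: float = 12.641176470588237  # cal g^-1 at T_ref
    specific_heat_cap: float = 0.13941176470588235     # cal g^-1 K^-1
    t_ref_c: float = 100.0

    def __post_init__(self):
        if self.specific_heat_cap < 0:
            raise ParameterError("specific heat capacity must be >= 0")


DEFAULT_ENTHALPY_MODEL = EnthalpyModel()


def denaturation_enthalpy(mass_kda: float, temperature_c: float,
                          model: EnthalpyModel | None = None) -> float:
    """dH_den(T) in kcal/mol for a protein of given molecular mass (kDa).

    mass_kDa * specific enthalpy (cal/g) is numerically kcal/mol because
    1 kDa = 1000 g/mol.
    """
    if mass_kda <= 0:
        raise ParameterError("mass must be positive")
    m = model or DEFAULT_ENTHALPY_MODEL
    specific = m.specific_enthalpy_ref + m.specific_heat_cap * (temperature_c - m.t_ref_c)
    return mass_kda * specific
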