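"""CD-based helix quantification.

Three complementary estimates of helical content from far-UV circular
dichroism:

* direct helicity from the mean residue ellipticity at 222 nm against the
  -39,500 deg cm^2 dmol^-1 full-helix reference;
* a two-state (disordered <-> helical) cosolvent titration in TFE, whose
  linear free-energy extrapolation to water yields the aqueous equilibrium
  constant K and hence the helical population f = K/(1+K); and
* a two-state van't Hoff thermal melt with linear folded/unfolded baselines,
  giving the denaturation midpoint Tm.

The TFE model is dG(x) = m * (midpoint - x) so that K(x) =
exp(m * (x - midpoint) / (R*T)): K = 1 at the transition midpoint and
K_water = exp(-m * midpoint / (R*T)) at 0% cosolvent. The m-value is carried
in cal mol^-1 %^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .constants import CELSIUS_OFFSET, R_CAL, T_CD_K, THETA222_FULL_HELIX
from .datatypes import FitResult, TitrationCurve
from .fitting import nls_fit

__all__ = [
    "Helicity",
    "helicity_from_theta222",
    "helix_population_from_K",
    "tfe_two_state_signal",
    "fit_tfe_titration",
    "melt_signal",
    "fit_thermal_melt",
]


@dataclass(frozen=True)
class Helicity:
    """Percent helix from [Theta]222; ``raw`` is unclamped."""

    percent: float
    raw: float


def helicity_from_theta222(theta222: float) -> Helicity:
    """Percent helix = 100 * theta222 / (-39,500), clamped to [0, 100].

    The reference is a per-residue (mean residue ellipticity) value; no
    chain-length correction is applied.
    """
    if not np.isfinite(theta222):
        raise ValueError("theta222 must be finite")
    raw = 100.0 * theta222 / THETA222_FULL_HELIX
    return Helicity(percent=float(np.clip(raw, 0.0, 100.0)), raw=float(raw))


def helix_population_from_K(k: float) -> float:
    """Fraction helix f = K/(1+K) for the disordered <-> helical equilibrium."""
    if k < 0:
        raise ValueError("equilibrium constant must be >= 0")
    return k / (1.0 + k)


def tfe_two_state_signal(
    tfe_percent,
    *,
    m_value: float,
    midpoint: float,
    theta_coil: float,
    theta_helix: float,
    temperature: float = T_CD_K,
) -> np.ndarray:
    """Mean residue ellipticity along a TFE titration under the two-state model."""
    x = np.asarray(tfe_percent, dtype=float)
    # f = K/(1+K) with K = exp(dG-derived argument); logistic form is
    # overflow-safe in the high-cooperativity limit
    f = expit(m_value * (x - midpoint) / (R_CAL * temperature))
    return theta_coil + (theta_helix - theta_coil) * f


def fit_tfe_titration(curve: TitrationCurve, temperature: float = T_CD_K) -> FitResult:
    """Fit {m_value, midpoint, theta_coil, theta_helix} to a TFE titration.

    Reports the water-extrapolated equilibrium constant ``k_water`` and
    helical fraction ``f_helix_water`` with uncertainties propagated from the
    (m, midpoint) covariance. A midpoint refined outside the data span, or a
    signal with no transition, is returned flagged non-converged rather than
    silently extrapolated.
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 titration points spanning the transition")
    x, y = curve.x, curve.y
    span = float(np.ptp(y))
    if span == 0.0 or span < 1e-9 * max(1.0, float(np.max(np.abs(y)))):
        return FitResult(
            params={"m_value": float("nan"), "midpoint": float("nan")},
            converged=False,
            model_id="tfe_two_state",
            fixed={"temperature_K": temperature},
            message="signal independent of cosolvent: model unidentifiable",
        )

    def model(p, xx):
        m, mid, tc, th = p
        return tfe_two_state_signal(
            xx, m_value=m, midpoint=mid, theta_coil=tc, theta_helix=th,
            temperature=temperature,
        )

    tc0 = float(y[np.argmin(x)])
    th0 = float(y[np.argmax(x)])
    mid0 = float(x[np.argmin(np.abs(y - 0.5 * (tc0 + th0)))])
    rt = R_CAL * temperature
    m0 = 4.0 * rt / max(np.ptp(x) / 4.0, 1e-6)  # transition width ~ quarter of span
    result, cov = nls_fit(
        model,
        x,
        y,
        [m0, mid0, tc0, th0],
        ["m_value", "midpoint", "theta_coil", "theta_helix"],
        bounds=([1e-6, -np.inf, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
        model_id="tfe_two_state",
        fixed={"temperature_K": temperature},
    )
    m, mid = result.params["m_value"], result.params["midpoint"]
    k_water = float(np.exp(-m * mid / rt))
    f_water = helix_population_from_K(k_water)
    result.params["k_water"] = k_water
    result.params["f_helix_water"] = f_water
    if cov is not None:
        # u = m*mid/RT; delta-method through K = exp(-u), f = K/(1+K)
        g = np.array([mid / rt, m / rt])
        var_u = float(g @ cov[:2, :2] @ g)
        if var_u >= 0:
            sd_u = np.sqrt(var_u)
            result.stderr["k_water"] = k_water * sd_u
            result.stderr["f_helix_water"] = k_water / (1.0 + k_water) ** 2 * sd_u
    if not (np.min(x) <= mid <= np.max(x)):
        result.converged = False
        result.message = (
            f"midpoint {mid:.3g}% outside titrated range "
            f"[{np.min(x):.3g}, {np.max(x):.3g}]%: extrapolation refused"
        )
    return result


def melt_signal(
    t_kelvin,
    *,
    tm: float,
    dh_vh_kcal: float,
    folded_intercept: float,
    folded_slope: float,
    unfolded_intercept: float,
    unfolded_slope: float,
) -> np.ndarray:
    """Two-state van't Hoff melt with linear pre-/post-transition baselines."""
    t = np.asarray(t_kelvin, dtype=float)
    dh_cal = dh_vh_kcal * 1000.0
    fu = expit((dh_cal / R_CAL) * (1.0 / tm - 1.0 / t))
    folded = folded_intercept + folded_slope * t
    unfolded = unfolded_intercept + unfolded_slope * t
    return folded * (1.0 - fu) + unfolded * fu


_MELT_PARAMS = [
    "tm",
    "dh_vh",
    "folded_intercept",
    "folded_slope",
    "unfolded_intercept",
    "unfolded_slope",
]


def fit_thermal_melt(curve: TitrationCurve) -> FitResult:
    """Fit a two-state thermal melt; temperatures in K, ``tm_C`` also reported.

    Baselines are seeded from the terminal thirds of the scan and the midpoint
    from the half-signal crossing. Flat scans (no transition) come back
    flagged non-converged.
    """
    if len(curve) < 10:
        raise ValueError("need at least 10 points across the melt")
    t, y = curve.x, curve.y
    if not (np.all(np.diff(t) > 0) or np.all(np.diff(t) < 0)):
        raise ValueError("temperature grid must be monotone")
    if np.ptp(y) == 0.0:
        return FitResult(
            params={"tm": float("nan")},
            converged=False,
            model_id="melt_two_state",
            message="no transition detected (flat signal)",
        )

    k = max(len(t) // 3, 2)
    f_int, f_slope = _line(t[:k], y[:k])
    u_int, u_slope = _line(t[-k:], y[-k:])
    mid_level = 0.5 * ((f_int + f_slope * t) + (u_int + u_slope * t))
    tm0 = float(t[np.argmin(np.abs(y - mid_level))])

    def model(p, tt):
        return melt_signal(
            tt,
            tm=p[0],
            dh_vh_kcal=p[1],
            folded_intercept=p[2],
            folded_slope=p[3],
            unfolded_intercept=p[4],
            unfolded_slope=p[5],
        )

    lo = [float(np.min(t)), 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [float(np.max(t)), 5000.0, np.inf, np.inf, np.inf, np.inf]
    result, _ = nls_fit(
        model,
        t,
        y,
        [tm0, 80.0, f_int, f_slope, u_int, u_slope],
        _MELT_PARAMS,
        bounds=(lo, hi),
        model_id="melt_two_state",
        starts=[[tm0, dh, f_int, f_slope, u_int, u_slope] for dh in (30.0, 200.0)],
    )
    result.params["tm_C"] = result.params["tm"] - CELSIUS_OFFSET
    if "tm" in result.stderr:
        result.stderr["tm_C"] = result.stderr["tm"]
    # a midpoint pinned at the scan edge means the transition was not sampled
    if not (np.min(t) + 1e-9 < result.params["tm"] < np.max(t) - 1e-9):
        result.converged = False
        result.message = "melt midpoint at the edge of the scanned range"
    return result


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)
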