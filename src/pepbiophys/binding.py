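"""1:1 binding quantification.

Two routes to the same dissociation constant:

* fluorescence titrations fitted with the exact ligand-depletion (quadratic
  mass-balance) isotherm, appropriate when the fixed receptor concentration is
  comparable to Kd so the free-ligand approximation fails; and
* isothermal titration calorimetry fitted with the single-set-of-sites model
  including the standard perfusion (displaced-volume) correction.

The receptor here is tropomyosin in protomer (single-chain) units; feeding
dimer units would halve the apparent stoichiometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FitResult, ItcIsotherm, TitrationCurve
from .fitting import nls_fit

__all__ = [
    "QuadraticBindingModel",
    "eval_quadratic_binding",
    "quadratic_binding_signal",
    "fit_fluorescence_titration",
    "itc_mass_balance",
    "itc_injection_heats",
    "fit_itc",
]

KD_BOUNDS_UM = (1e-3, 1e4)
#: receptor/Kd ratio beyond which a titration is effectively stoichiometric
#: and carries no Kd information.
TIGHT_BINDING_C = 900.0


@dataclass(frozen=True)
class QuadraticBindingModel:
    """Signal model F(L) for a 1:1 complex with ligand depletion."""

    f0: float
    dfmax: float
    kd: float  # uM
    receptor_total: float  # uM, fixed during the titration

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be positive")


def _complex_conc(receptor: np.ndarray, ligand: np.ndarray, kd: float) -> np.ndarray:
    """Equilibrium [complex] from the 1:1 quadratic mass balance (same units in/out)."""
    b = receptor + ligand + kd
    disc = b * b - 4.0 * receptor * ligand
    # disc >= (receptor - ligand)^2 + kd*(...) > 0 for valid inputs
    disc = np.maximum(disc, 0.0)
    return 0.5 * (b - np.sqrt(disc))


def quadratic_binding_signal(
    ligand_total, *, f0: float, dfmax: float, kd: float, receptor_total: float
) -> np.ndarray:
    """F = F0 + dFmax * [complex]/[receptor]_T with [complex] from the exact
    quadratic solution; saturates at F0 + dFmax."""
    ligand = np.asarray(ligand_total, dtype=float)
    if np.any(ligand < 0):
        raise ValueError("ligand_total must be >= 0")
    if kd <= 0 or receptor_total <= 0:
        raise ValueError("kd and receptor_total must be positive")
    complex_ = _complex_conc(np.full_like(ligand, receptor_total), ligand, kd)
    return f0 + dfmax * complex_ / receptor_total


def eval_quadratic_binding(model: QuadraticBindingModel, ligand_total) -> np.ndarray:
    return quadratic_binding_signal(
        ligand_total,
        f0=model.f0,
        dfmax=model.dfmax,
        kd=model.kd,
        receptor_total=model.receptor_total,
    )


def fit_fluorescence_titration(
    curve: TitrationCurve, receptor_total: float
) -> FitResult:
    """Least-squares fit of {f0, dfmax, kd} with the receptor concentration fixed.

    Multistart over log-spaced Kd values guards against the occasionally flat
    Kd likelihood of the quadratic model. Kd estimates in the tight-binding
    (stoichiometric) regime or pinned at the search bounds are flagged.
    """
    if len(curve) < 6:
        raise ValueError("need at least 6 titration points")
    if receptor_total <= 0:
        raise ValueError("receptor_total must be positive")
    x, y = curve.x, curve.y

    def model(p, lig):
        f0, dfmax, kd = p
        return quadratic_binding_signal(
            lig, f0=f0, dfmax=dfmax, kd=kd, receptor_total=receptor_total
        )

    f0_0 = float(y[np.argmin(x)])
    df_0 = float(y[np.argmax(x)] - f0_0) or 1.0
    kd_starts = np.geomspace(0.1, 1000.0, 5)
    result, _ = nls_fit(
        model,
        x,
        y,
        [f0_0, df_0, kd_starts[2]],
        ["f0", "dfmax", "kd"],
        bounds=([-np.inf, -np.inf, KD_BOUNDS_UM[0]], [np.inf, np.inf, KD_BOUNDS_UM[1]]),
        model_id="fluorescence_quadratic_1to1",
        fixed={"receptor_total_uM": receptor_total},
        starts=[[f0_0, df_0, k] for k in kd_starts],
    )
    kd_hat = result.params["kd"]
    flags = []
    if kd_hat <= KD_BOUNDS_UM[0] * 1.05 or kd_hat >= KD_BOUNDS_UM[1] * 0.95:
        flags.append("kd pinned at search bound")
    if receptor_total / kd_hat >= TIGHT_BINDING_C:
        flags.append(
            "kd unidentifiable: tight-binding (stoichiometric) regime, "
            "titration carries no Kd information"
        )
    if result.stderr.get("kd", 0.0) > abs(kd_hat):
        flags.append("kd unidentifiable: standard error exceeds estimate")
    result.message = "; ".join(flags)
    return result


# --- ITC -------------------------------------------------------------------


def itc_mass_balance(
    *,
    kd: float,
    n_sites: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
    inj_vol_ul,
    cell_vol_ml: float,
) -> dict:
    """Simulate the in-cell composition over an injection series.

    Per injection of volume v the cell contents are diluted by (1 - v/V0)
    (perfusion/displacement convention) and titrant is added at (v/V0) of the
    syringe concentration. Returns the per-injection total macromolecule,
    titrant and bound (complex) concentrations plus the complex displaced out
    of the cell, all in uM except displaced moles (nmol).
    """
    v0_ul = cell_vol_ml * 1000.0
    inj = np.asarray(inj_vol_ul, dtype=float)
    m = cell_conc_uM
    x = 0.0
    bound_prev = 0.0
    m_t, x_t, bound = [], [], []
    displaced_nmol = 0.0
    for v in inj:
        f = 1.0 - v / v0_ul
        displaced_nmol += bound_prev * v * 1e-3  # uM * ul = 1e-3 nmol
        m *= f
        x = x * f + syringe_conc_uM * (v / v0_ul)
        b = float(
            _complex_conc(
                np.array(n_sites * m), np.array(x), kd
            )
        )
        m_t.append(m)
        x_t.append(x)
        bound.append(b)
        bound_prev = b
    return {
        "macromolecule_uM": np.array(m_t),
        "titrant_uM": np.array(x_t),
        "bound_uM": np.array(bound),
        "displaced_complex_nmol": displaced_nmol,
    }


def itc_injection_heats(
    *,
    kd: float,
    dh_kcal: float,
    n_sites: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
    inj_vol_ul,
    cell_vol_ml: float,
) -> np.ndarray:
    """Per-injection heats (ucal) from the single-site model.

    q_i = V0 * dH * ([B]_i - [B]_{i-1} * (1 - v_i/V0)): the heat of complex
    newly formed in the cell, net of the complex displaced by the injection.
    """
    v0_ul = cell_vol_ml * 1000.0
    balance = itc_mass_balance(
        kd=kd,
        n_sites=n_sites,
        cell_conc_uM=cell_conc_uM,
        syringe_conc_uM=syringe_conc_uM,
        inj_vol_ul=inj_vol_ul,
        cell_vol_ml=cell_vol_ml,
    )
    bound = balance["bound_uM"]
    inj = np.asarray(inj_vol_ul, dtype=float)
    prev = np.concatenate([[0.0], bound[:-1]])
    delta_uM = bound - prev * (1.0 - inj / v0_ul)
    # uM * mL = nmol; * kcal/mol = ucal
    return delta_uM * cell_vol_ml * (dh_kcal * 1000.0) * 1e-3


def fit_itc(
    isotherm: ItcIsotherm, dilution_heats_ucal: np.ndarray | None = None
) -> FitResult:
    """Fit {kd, dh, n} to an injection-heat series.

    Dilution-control heats, when given, are subtracted point-wise before
    fitting. A flat (near-zero-enthalpy) isotherm is flagged unidentifiable
    rather than fitted; Wiseman c-values outside [1, 1000] trigger a
    low-confidence warning on Kd.
    """
    if len(isotherm) < 10:
        raise ValueError("need at least 10 injections")
    heats = isotherm.heats_ucal.copy()
    if dilution_heats_ucal is not None:
        dil = np.asarray(dilution_heats_ucal, dtype=float)
        if dil.shape != heats.shape:
            raise ValueError("dilution heats must match injection count")
        heats = heats - dil

    fixed = {
        "cell_conc_uM": isotherm.cell_conc_uM,
        "syringe_conc_uM": isotherm.syringe_conc_uM,
        "cell_volume_ml": isotherm.cell_volume_ml,
    }
    scale = float(np.max(np.abs(heats))) if heats.size else 0.0
    if scale < 1e-9:
        return FitResult(
            params={"kd": float("nan"), "dh": 0.0, "n": float("nan")},
            converged=False,
            model_id="itc_single_site",
            fixed=fixed,
            message="no measurable heat (dH ~ 0): kd unidentifiable",
        )

    inj = isotherm.injection_volumes_ul

    def model(p, _x):
        kd, dh, n = p
        return itc_injection_heats(
            kd=kd,
            dh_kcal=dh,
            n_sites=n,
            cell_conc_uM=isotherm.cell_conc_uM,
            syringe_conc_uM=isotherm.syringe_conc_uM,
            inj_vol_ul=inj,
            cell_vol_ml=isotherm.cell_volume_ml,
        )

    # crude dh start: all heat assigned to saturating the cell macromolecule
    cell_nmol = isotherm.cell_conc_uM * isotherm.cell_volume_ml
    dh0 = float(np.sum(heats) / (cell_nmol * 1000.0)) or 0.1  # kcal/mol
    kd_starts = np.geomspace(0.5, 500.0, 5)
    result, _ = nls_fit(
        model,
        np.arange(len(isotherm), dtype=float),
        heats,
        [kd_starts[2], dh0, 1.0],
        ["kd", "dh", "n"],
        bounds=([1e-4, -np.inf, 0.1], [1e6, np.inf, 10.0]),
        model_id="itc_single_site",
        fixed=fixed,
        starts=[[k, dh0, 1.0] for k in kd_starts],
    )
    c_value = result.params["n"] * isotherm.cell_conc_uM / result.params["kd"]
    if not (1.0 <= c_value <= 1000.0):
        result.message = (
            f"low confidence in kd: Wiseman c = {c_value:.3g} outside [1, 1000]"
        )
    return result
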