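"""Seeded synthetic-data generators with known ground truth.

Every measurement modality in the package has a generator here that evaluates
the corresponding closed-form model at stated true parameters and adds
seeded Gaussian noise, so each analysis stage can be tested by parameter
recovery without external data. Defaults reflect the study conditions:
20 uM peptide CD at 5 C, fluorescence titrations of 10 uM (protomer)
tropomyosin with 0-15 uM peptide, ITC with a 1.4 ml cell at 30 uM titrated
from a 609 uM syringe in 10 ul injections, bipolar-PFG decays with
delta = 2.25 ms, Delta = 200 ms, tau = 100 us over 16 linear gradient steps
spanning 2-95% of a 0.55 T/m coil, and force-pCa series at
pCa 6.5, 6.3, 6.0, 5.8, 5.5, 5.0, 4.5.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .binding import itc_injection_heats, quadratic_binding_signal
from .cd import melt_signal, tfe_two_state_signal
from .constants import DEFAULT_MAX_GRADIENT_T_PER_M, GAMMA_H, T_CD_K
from .contractility import hill_force
from .datatypes import (
    DecaySeries,
    GroundTruth,
    ItcIsotherm,
    NoiseSpec,
    TitrationCurve,
)
from .diffusion import stejskal_tanner_b

__all__ = [
    "gen_binding_titration",
    "gen_tfe_titration",
    "gen_thermal_melt",
    "gen_gradient_decay",
    "gen_relaxation_series",
    "gen_itc_isotherm",
    "gen_force_pca",
    "default_gradient_grid",
    "DEFAULT_PCA_GRID",
    "write_with_ground_truth",
]

#: pCa values at which calcium-activated force is examined.
DEFAULT_PCA_GRID = (6.5, 6.3, 6.0, 5.8, 5.5, 5.0, 4.5)


def default_gradient_grid(
    n: int = 16,
    lo_fraction: float = 0.02,
    hi_fraction: float = 0.95,
    max_gradient: float = DEFAULT_MAX_GRADIENT_T_PER_M,
) -> np.ndarray:
    """Linear gradient-strength grid (T/m): n steps between fractions of the
    maximum coil strength."""
    return np.linspace(lo_fraction, hi_fraction, n) * max_gradient


def gen_binding_titration(
    kd: float,
    f0: float,
    dfmax: float,
    receptor_total: float,
    ligand_grid,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, GroundTruth]:
    """Fluorescence titration obeying the quadratic 1:1 ligand-depletion model."""
    ligand = np.atleast_1d(np.asarray(ligand_grid, dtype=float))
    if np.any(ligand < 0):
        raise ValueError("ligand concentrations must be >= 0")
    if np.any(np.diff(ligand) <= 0):
        raise ValueError("ligand grid must be strictly increasing")
    y = quadratic_binding_signal(
        ligand, f0=f0, dfmax=dfmax, kd=kd, receptor_total=receptor_total
    )
    curve = TitrationCurve(
        ligand, noise.perturb(y), x_label="ligand_uM", y_label="signal"
    )
    gt = GroundTruth(
        "fluorescence_quadratic_1to1",
        {"kd": kd, "f0": f0, "dfmax": dfmax, "receptor_total": receptor_total},
    )
    return curve, gt


def gen_tfe_titration(
    m_value: float,
    midpoint: float,
    theta_coil: float,
    theta_helix: float,
    temperature: float = T_CD_K,
    tfe_grid=None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, GroundTruth]:
    """[Theta]222 vs %TFE sigmoid from the two-state helix-coil model."""
    if m_value <= 0:
        raise ValueError("m_value must be positive")
    x = np.linspace(0.0, 50.0, 14) if tfe_grid is None else np.asarray(tfe_grid, float)
    if np.any((x < 0) | (x > 100)):
        raise ValueError("TFE percentages must lie in [0, 100]")
    y = tfe_two_state_signal(
        x,
        m_value=m_value,
        midpoint=midpoint,
        theta_coil=theta_coil,
        theta_helix=theta_helix,
        temperature=temperature,
    )
    curve = TitrationCurve(x, noise.perturb(y), x_label="tfe_percent", y_label="theta222")
    gt = GroundTruth(
        "tfe_two_state",
        {
            "m_value": m_value,
            "midpoint": midpoint,
            "theta_coil": theta_coil,
            "theta_helix": theta_helix,
            "temperature": temperature,
        },
    )
    return curve, gt


def gen_thermal_melt(
    tm: float,
    dh_vh: float,
    baselines: tuple[float, float, float, float] = (-12000.0, 8.0, -4000.0, 3.0),
    t_grid=None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, GroundTruth]:
    """Two-state van't Hoff melt with linear baselines over 20-90 C by default.

    ``baselines`` is (folded intercept, folded slope, unfolded intercept,
    unfolded slope) against temperature in K; ``dh_vh`` in kcal/mol.
    """
    if dh_vh <= 0:
        raise ValueError("van't Hoff enthalpy must be positive")
    t = (
        np.linspace(293.15, 363.15, 71)
        if t_grid is None
        else np.asarray(t_grid, dtype=float)
    )
    if not (np.all(np.diff(t) > 0) or np.all(np.diff(t) < 0)):
        raise ValueError("temperature grid must be monotone")
    if not (np.min(t) <= tm <= np.max(t)):
        raise ValueError("tm must lie within the temperature grid span")
    fi, fs, ui, us = baselines
    y = melt_signal(
        t,
        tm=tm,
        dh_vh_kcal=dh_vh,
        folded_intercept=fi,
        folded_slope=fs,
        unfolded_intercept=ui,
        unfolded_slope=us,
    )
    curve = TitrationCurve(t, noise.perturb(y), x_label="temperature_K", y_label="theta222")
    gt = GroundTruth(
        "melt_two_state",
        {
            "tm": tm,
            "dh_vh": dh_vh,
            "folded_intercept": fi,
            "folded_slope": fs,
            "unfolded_intercept": ui,
            "unfolded_slope": us,
        },
    )
    return curve, gt


def gen_gradient_decay(
    d: float,
    delta_ms: float = 2.25,
    big_delta_ms: float = 200.0,
    tau_us: float = 100.0,
    g_grid=None,
    i0: float = 1.0,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[DecaySeries, GroundTruth]:
    """Stejskal-Tanner gradient decay for a species with D in cm^2/s.

    ``g_grid`` holds gradient strengths in T/m (default: 16 linear steps over
    2-95% of the 0.55 T/m coil maximum). ln(I/I0) is linear in G^2.
    """
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    g = default_gradient_grid() if g_grid is None else np.asarray(g_grid, dtype=float)
    if np.any(g < 0):
        raise ValueError("gradient strengths must be >= 0")
    b = stejskal_tanner_b(delta_ms, big_delta_ms, tau_us)
    y = i0 * np.exp(-d * 1e-4 * b * g**2)
    series = DecaySeries(g, noise.perturb(y), t_label="g_T_per_m")
    gt = GroundTruth(
        "stejskal_tanner",
        {
            "d": d,
            "i0": i0,
            "delta_ms": delta_ms,
            "big_delta_ms": big_delta_ms,
            "tau_us": tau_us,
            "gamma": GAMMA_H,
        },
    )
    return series, gt


def gen_relaxation_series(
    r: float,
    i0: float = 100.0,
    delays_ms=None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[DecaySeries, GroundTruth]:
    """Mono-exponential relaxation decay I(t) = I0 exp(-t R), delays in ms."""
    if r < 0:
        raise ValueError("relaxation rate must be >= 0")
    t = (
        np.array([10.0, 50.0, 100.0, 180.0, 280.0, 400.0, 550.0])
        if delays_ms is None
        else np.asarray(delays_ms, dtype=float)
    )
    if np.any(t < 0):
        raise ValueError("delays must be >= 0")
    y = i0 * np.exp(-t * 1e-3 * r)
    series = DecaySeries(t, noise.perturb(y), t_label="delay_ms")
    return series, GroundTruth("monoexp_relaxation", {"r": r, "i0": i0})


def gen_itc_isotherm(
    kd: float,
    dh: float,
    n_sites: float = 1.0,
    cell_conc: float = 30.0,
    syringe_conc: float = 609.0,
    inj_vol_ul=None,
    cell_vol_ml: float = 1.4,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[ItcIsotherm, GroundTruth]:
    """Injection-heat series from the single-site model with displaced-volume
    bookkeeping. ``dh`` in kcal/mol, heats in ucal; noise sigma in ucal."""
    inj = (
        np.full(28, 10.0) if inj_vol_ul is None else np.asarray(inj_vol_ul, dtype=float)
    )
    if inj.size > 100:
        raise ValueError("injection series longer than 100 not modeled")
    for name, v in (
        ("kd", kd),
        ("n_sites", n_sites),
        ("cell_conc", cell_conc),
        ("syringe_conc", syringe_conc),
        ("cell_vol_ml", cell_vol_ml),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    heats = itc_injection_heats(
        kd=kd,
        dh_kcal=dh,
        n_sites=n_sites,
        cell_conc_uM=cell_conc,
        syringe_conc_uM=syringe_conc,
        inj_vol_ul=inj,
        cell_vol_ml=cell_vol_ml,
    )
    isotherm = ItcIsotherm(
        injection_volumes_ul=inj,
        heats_ucal=noise.perturb(heats),
        cell_conc_uM=cell_conc,
        syringe_conc_uM=syringe_conc,
        cell_volume_ml=cell_vol_ml,
    )
    gt = GroundTruth(
        "itc_single_site",
        {
            "kd": kd,
            "dh": dh,
            "n": n_sites,
            "cell_conc_uM": cell_conc,
            "syringe_conc_uM": syringe_conc,
            "cell_volume_ml": cell_vol_ml,
        },
    )
    return isotherm, gt


def gen_force_pca(
    f_max: float = 1.0,
    pca50: float = 5.7,
    n_hill: float = 2.5,
    pca_grid=DEFAULT_PCA_GRID,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[TitrationCurve, GroundTruth]:
    """Force-pCa curve obeying the Hill equation on the [Ca] scale."""
    if n_hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    pca = np.asarray(pca_grid, dtype=float)
    if not (np.min(pca) <= pca50 <= np.max(pca)):
        raise ValueError("pca50 must lie within the pCa grid span")
    y = hill_force(pca, f_max=f_max, pca50=pca50, n_hill=n_hill)
    curve = TitrationCurve(pca, noise.perturb(y), x_label="pca", y_label="force")
    gt = GroundTruth(
        "hill_force_pca", {"f_max": f_max, "pca50": pca50, "n_hill": n_hill}
    )
    return curve, gt


def write_with_ground_truth(dataset, gt: GroundTruth, path: str | Path,
                            seed: int | None = None) -> Path:
    """Write a dataset CSV with ground-truth key=value header comments and a
    sidecar JSON (same stem, ``.truth.json``) carrying seed and model id."""
    path = Path(path)
    frame = dataset.to_frame()
    lines = [f"# model_id={gt.model_id}"]
    lines += [f"# {k}={v!r}" for k, v in sorted(gt.params.items())]
    body = frame.to_csv(index=False, float_format="%.10g")
    path.write_text("\n".join(lines) + "\n" + body)
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(
        json.dumps({"seed": seed, **gt.to_dict()}, indent=2, sort_keys=True) + "\n"
    )
    return path
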