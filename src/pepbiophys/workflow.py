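"""Run-configuration handling and end-to-end orchestration.

`run(config)` dispatches one analysis modality on CSV input and writes JSON
fit results; the ``report`` modality recomputes the package's battery of
internal consistency checks (mass accounting, helicity arithmetic, scale-law
radii, and parameter-recovery round trips at the study conditions) and
emits a pass/fail table. All randomness flows from the single configured
seed and outputs are byte-stable for a fixed config+seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import binding, cd, contractility, diffusion, nmr, synth
from .constants import DEFAULT_MAX_GRADIENT_T_PER_M, T_CD_K
from .datatypes import DecaySeries, ItcIsotherm, NoiseSpec, TitrationCurve
from .sequence import WT_C27, C27_START, PeptideSequence, apply_point_mutation, average_mass

log = logging.getLogger("pepbiophys")

__all__ = ["RunConfig", "WorkflowError", "NonConvergenceError", "run", "reproduce_report"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NONCONVERGENCE = 3

Modality = Literal[
    "cd-tfe", "melt", "dosy", "fluor", "itc", "nmr-relax", "force-pca", "synth", "report"
]


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    modality: Modality
    input: str | None = None
    constants: dict[str, float] = Field(default_factory=dict)
    seed: int = 0
    outdir: str = "."

    model_config = {"extra": "forbid"}

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except FileNotFoundError:
            raise WorkflowError(f"config file not found: {path}")
        except json.JSONDecodeError as err:
            raise WorkflowError(f"malformed config {path}: {err}")
        try:
            return cls(**payload)
        except ValidationError as err:
            raise WorkflowError(f"invalid config {path}: {err}")


class WorkflowError(RuntimeError):
    """Input/validation failure (exit code 2)."""


class NonConvergenceError(RuntimeError):
    """A mandatory fit did not converge (exit code 3)."""


def _require_input(config: RunConfig) -> Path:
    if not config.input:
        raise WorkflowError(f"modality {config.modality!r} requires an input file")
    path = Path(config.input)
    if not path.exists():
        raise WorkflowError(f"input file not found: {path}")
    return path


def _load_curve(path: Path) -> TitrationCurve:
    try:
        return TitrationCurve.from_csv(path)
    except Exception as err:
        raise WorkflowError(f"malformed CSV {path}: {err}")


def _write_json(payload: dict, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    return path


def _check_converged(result) -> None:
    if not result.converged:
        raise NonConvergenceError(
            f"fit {result.model_id} did not converge: {result.message}"
        )


def run(config: RunConfig) -> list[Path]:
    """Execute one modality; returns the list of written artifacts.

    Raises :class:`WorkflowError` on bad inputs and
    :class:`NonConvergenceError` when a mandatory fit fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    consts = config.constants
    m = config.modality

    if m == "cd-tfe":
        curve = _load_curve(_require_input(config))
        result = cd.fit_tfe_titration(curve, consts.get("temperature_K", T_CD_K))
        _check_converged(result)
        return [_write_json(result.to_dict(), outdir / "tfe_fit.json")]

    if m == "melt":
        curve = _load_curve(_require_input(config))
        result = cd.fit_thermal_melt(curve)
        _check_converged(result)
        return [_write_json(result.to_dict(), outdir / "melt_fit.json")]

    if m == "dosy":
        path = _require_input(config)
        df = pd.read_csv(path, comment="#")
        if "g_T_per_m" in df.columns:
            g = df["g_T_per_m"].to_numpy()
        elif "g_fraction" in df.columns:
            g = df["g_fraction"].to_numpy() * consts.get(
                "max_gradient_T_per_m", DEFAULT_MAX_GRADIENT_T_PER_M
            )
        else:
            raise WorkflowError(f"{path}: need a g_T_per_m or g_fraction column")
        if "intensity" not in df.columns:
            raise WorkflowError(f"{path}: need an intensity column")
        exp = diffusion.PfgExperiment(
            DecaySeries(g, df["intensity"].to_numpy(), t_label="g_T_per_m"),
            delta_ms=consts.get("delta_ms", 2.25),
            big_delta_ms=consts.get("big_delta_ms", 200.0),
            tau_us=consts.get("tau_us", 100.0),
        )
        result = diffusion.fit_diffusion(exp)
        _check_converged(result)
        payload = result.to_dict()
        if "d_reference_cm2_s" in consts:
            rh = diffusion.rh_from_reference(
                result.params["d"],
                consts["d_reference_cm2_s"],
                consts.get("rh_reference_A", 2.12),
            )
            payload["rh_measured_A"] = rh
            if "mw_da" in consts:
                pred, sd = diffusion.rh_scale_law(consts["mw_da"])
                payload["rh_scale_law_A"] = pred
                payload["rh_scale_law_sd_A"] = sd
        return [_write_json(payload, outdir / "dosy_fit.json")]

    if m == "fluor":
        curve = _load_curve(_require_input(config))
        receptor = consts.get("receptor_total_uM", 10.0)
        result = binding.fit_fluorescence_titration(curve, receptor)
        _check_converged(result)
        return [_write_json(result.to_dict(), outdir / "fluor_fit.json")]

    if m == "itc":
        path = _require_input(config)
        df = pd.read_csv(path, comment="#")
        for col in ("injection_vol_ul", "heat_ucal"):
            if col not in df.columns:
                raise WorkflowError(f"{path}: missing column {col!r}")
        isotherm = ItcIsotherm(
            injection_volumes_ul=df["injection_vol_ul"].to_numpy(),
            heats_ucal=df["heat_ucal"].to_numpy(),
            cell_conc_uM=consts.get("cell_conc_uM", 30.0),
            syringe_conc_uM=consts.get("syringe_conc_uM", 609.0),
            cell_volume_ml=consts.get("cell_volume_ml", 1.4),
        )
        result = binding.fit_itc(isotherm)
        _check_converged(result)
        return [_write_json(result.to_dict(), outdir / "itc_fit.json")]

    if m == "nmr-relax":
        path = _require_input(config)
        df = pd.read_csv(path, comment="#")
        for col in ("residue", "delay_ms", "intensity"):
            if col not in df.columns:
                raise WorkflowError(f"{path}: missing column {col!r}")
        rows = {}
        for residue, grp in df.groupby("residue"):
            series = DecaySeries(
                grp["delay_ms"].to_numpy(), grp["intensity"].to_numpy(),
                t_label="delay_ms",
            )
            result = nmr.fit_relaxation_rate(series)
            _check_converged(result)
            rows[str(int(residue))] = result.to_dict()
        return [_write_json(rows, outdir / "relaxation_fits.json")]

    if m == "force-pca":
        path = _require_input(config)
        df = pd.read_csv(path, comment="#")
        for col in ("replicate", "condition", "pca", "force"):
            if col not in df.columns:
                raise WorkflowError(f"{path}: missing column {col!r}")
        fits: dict[str, dict[str, object]] = {}
        for (rep, cond), grp in df.groupby(["replicate", "condition"]):
            curve = contractility.ForcePcaCurve(
                grp["pca"].to_numpy(), grp["force"].to_numpy(),
                condition=str(cond), replicate=str(rep),
            )
            result = contractility.fit_hill(curve)
            _check_converged(result)
            fits.setdefault(str(cond), {})[str(rep)] = result
        payload = {
            cond: {rep: r.to_dict() for rep, r in reps.items()}
            for cond, reps in fits.items()
        }
        artifacts = [_write_json(payload, outdir / "hill_fits.json")]
        if len(fits) == 2:
            (c_name, c_fits), (t_name, t_fits) = sorted(fits.items())
            comparison = contractility.compare_conditions(c_fits, t_fits)
            artifacts.append(
                _write_json(
                    {
                        "control": c_name,
                        "treated": t_name,
                        "tests": comparison.tests,
                        "pairs": comparison.table.to_dict(orient="records"),
                        "unpaired": comparison.unpaired,
                    },
                    outdir / "condition_comparison.json",
                )
            )
        return artifacts

    if m == "synth":
        return _emit_synthetic_suite(outdir, config.seed)

    if m == "report":
        return reproduce_report(outdir, config.seed)

    raise WorkflowError(f"unknown modality {m!r}")  # pragma: no cover


def _emit_synthetic_suite(outdir: Path, seed: int) -> list[Path]:
    """One seeded synthetic dataset per modality, CSV + ground-truth sidecar."""
    artifacts = []
    curve, gt = synth.gen_binding_titration(
        8.0, 0.0, 1.0, 10.0, np.linspace(0.0, 15.0, 12),
        NoiseSpec(sigma=0.02, seed=seed),
    )
    artifacts.append(synth.write_with_ground_truth(curve, gt, outdir / "fluor.csv", seed))
    curve, gt = synth.gen_tfe_titration(
        86.5, 16.0, 0.0, -39500.0, noise=NoiseSpec(sigma=300.0, seed=seed + 1)
    )
    artifacts.append(synth.write_with_ground_truth(curve, gt, outdir / "tfe.csv", seed + 1))
    curve, gt = synth.gen_thermal_melt(
        316.25, 100.0, noise=NoiseSpec(sigma=100.0, seed=seed + 2)
    )
    artifacts.append(synth.write_with_ground_truth(curve, gt, outdir / "melt.csv", seed + 2))
    series, gt = synth.gen_gradient_decay(
        9.9e-6, noise=NoiseSpec(sigma=0.005, seed=seed + 3)
    )
    artifacts.append(synth.write_with_ground_truth(series, gt, outdir / "dosy.csv", seed + 3))
    series, gt = synth.gen_relaxation_series(
        2.3, noise=NoiseSpec(sigma=0.5, seed=seed + 4)
    )
    artifacts.append(
        synth.write_with_ground_truth(series, gt, outdir / "relaxation.csv", seed + 4)
    )
    isotherm, gt = synth.gen_itc_isotherm(
        11.0, 0.35, noise=NoiseSpec(sigma=0.02, seed=seed + 5)
    )
    artifacts.append(synth.write_with_ground_truth(isotherm, gt, outdir / "itc.csv", seed + 5))
    curve, gt = synth.gen_force_pca(noise=NoiseSpec(sigma=0.01, seed=seed + 6))
    artifacts.append(
        synth.write_with_ground_truth(curve, gt, outdir / "force_pca.csv", seed + 6)
    )
    return artifacts


def reproduce_report(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Recompute the package's internal consistency battery and write a
    JSON + Markdown pass/fail table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    checks: list[dict] = []

    def check(name, value, expected, tol, unit=""):
        ok = abs(value - expected) <= tol
        checks.append(
            {
                "check": name,
                "value": float(value),
                "expected": float(expected),
                "tolerance": float(tol),
                "unit": unit,
                "status": "pass" if ok else "FAIL",
            }
        )

    wt = PeptideSequence(WT_C27, C27_START, name="HcTnI-C27")
    mut = apply_point_mutation(wt, 192, "H")
    check("average mass, wild-type 27-mer", round(average_mass(wt), 2), 3180.55, 0.005, "Da")
    check("average mass, Arg192His variant", round(average_mass(mut), 2), 3161.50, 0.005, "Da")
    check(
        "helicity from theta222 = -1829.7",
        round(cd.helicity_from_theta222(-1829.7).percent, 1),
        4.6,
        0.05,
        "%",
    )
    checks.append(
        {
            "check": "helicity from theta222 = -2669.8 (unrounded; conventionally quoted as 6.7)",
            "value": cd.helicity_from_theta222(-2669.8).raw,
            "expected": 6.7,
            "tolerance": 0.1,
            "unit": "%",
            "status": "info",
        }
    )
    check(
        "helical population from K = 0.0818",
        100.0 * cd.helix_population_from_K(0.0818),
        7.5,
        0.1,
        "%",
    )
    rh, _sd = diffusion.rh_scale_law(3180.55)
    check("scale-law Rh at 3180.55 Da", round(rh, 1), 15.2, 0.05, "A")

    # parameter-recovery round trips at the study conditions (noise-free)
    curve, _ = synth.gen_thermal_melt(316.25, 100.0)
    melt_fit = cd.fit_thermal_melt(curve)
    check("melt recovery: Tm", melt_fit.params["tm_C"], 43.1, 0.1, "C")

    series, gt = synth.gen_gradient_decay(9.9e-6)
    exp = diffusion.PfgExperiment(series)
    d_fit = diffusion.fit_diffusion(exp)
    check("diffusion recovery: D", d_fit.params["d"] * 1e6, 9.9, 0.01, "1e-6 cm2/s")

    for kd_true, label in ((8.0, "wild-type"), (15.0, "mutant")):
        fl_curve, _ = synth.gen_binding_titration(
            kd_true, 0.0, 1.0, 10.0, np.linspace(0.0, 15.0, 12)
        )
        fl_fit = binding.fit_fluorescence_titration(fl_curve, 10.0)
        check(f"fluorescence recovery: Kd ({label})", fl_fit.params["kd"], kd_true,
              0.001 * kd_true, "uM")

    isotherm, _ = synth.gen_itc_isotherm(11.0, 0.35)
    itc_fit = binding.fit_itc(isotherm)
    check("ITC recovery: Kd", itc_fit.params["kd"], 11.0, 0.11, "uM")
    check("ITC recovery: dH", itc_fit.params["dh"], 0.35, 0.0035, "kcal/mol")

    payload = {"seed": seed, "checks": checks}
    json_path = _write_json(payload, outdir / "report.json")
    lines = [
        "| check | value | expected | unit | status |",
        "|---|---|---|---|---|",
    ]
    for c in checks:
        lines.append(
            f"| {c['check']} | {c['value']:.6g} | {c['expected']:.6g} | "
            f"{c['unit']} | {c['status']} |"
        )
    md_path = outdir / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return [json_path, md_path]
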