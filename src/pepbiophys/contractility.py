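"""Hill analysis of skinned-fiber force-pCa data.

Calcium-activated force follows the Hill equation in calcium concentration,

    F = F_max * [Ca]^n / ([Ca]^n + Ca50^n),    [Ca] = 10^(-pCa),

fitted on the concentration scale with pCa50 = -log10(Ca50) derived
afterwards. A *right shift* of the force-pCa curve (lower pCa50) means
calcium desensitisation. Paired treatment/control comparisons use the paired
Student t-test on per-replicate differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import FitResult, TitrationCurve
from .fitting import nls_fit

__all__ = [
    "ForcePcaCurve",
    "hill_force",
    "fit_hill",
    "compare_conditions",
    "paired_t",
    "ConditionComparison",
]


@dataclass
class ForcePcaCurve:
    """Force measurements over a pCa series for one fiber/condition."""

    pca: np.ndarray
    force: np.ndarray
    condition: str = ""
    replicate: str = ""
    sl_um: float | None = None

    def __post_init__(self) -> None:
        self.pca = np.asarray(self.pca, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.pca.shape != self.force.shape:
            raise ValueError("pca and force must have the same length")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")
        # small negative excursions from baseline noise are tolerated
        fmax = float(np.max(self.force)) if self.force.size else 0.0
        if np.any(self.force < -0.1 * max(fmax, 0.0)) or fmax <= 0:
            raise ValueError("forces must be >= 0 up to baseline noise")

    def __len__(self) -> int:
        return self.pca.size

    def normalized(self) -> "ForcePcaCurve":
        fmax = float(np.max(self.force))
        if fmax == 0:
            raise ValueError("cannot normalise an all-zero force curve")
        return ForcePcaCurve(
            self.pca, self.force / fmax, self.condition, self.replicate, self.sl_um
        )


def hill_force(pca, *, f_max: float, pca50: float, n_hill: float) -> np.ndarray:
    """Hill equation evaluated on the pCa scale."""
    if n_hill <= 0:
        raise ValueError("Hill coefficient must be positive")
    pca = np.asarray(pca, dtype=float)
    # F/Fmax = [Ca]^n/([Ca]^n + Ca50^n) = logistic in n*(pCa50 - pCa)*ln(10)
    return f_max * expit(n_hill * (pca50 - pca) * np.log(10.0))


def fit_hill(curve: ForcePcaCurve) -> FitResult:
    """Fit {f_max, pca50, n_hill} to a force-pCa curve.

    pCa50 and n_hill are invariant to rescaling the forces; f_max scales
    linearly. Curves with no transition inside the sampled range come back
    flagged non-converged.
    """
    if len(curve) < 5:
        raise ValueError("need at least 5 force-pCa points")
    pca, force = curve.pca, curve.force
    if np.ptp(force) == 0:
        return FitResult(
            params={"pca50": float("nan")},
            converged=False,
            model_id="hill_force_pca",
            message="no force transition in the sampled pCa range",
        )

    def model(p, x):
        return hill_force(x, f_max=p[0], pca50=p[1], n_hill=p[2])

    fmax0 = float(np.max(force))
    order = np.argsort(pca)
    half = 0.5 * fmax0
    pca50_0 = float(np.interp(half, force[order][::-1], pca[order][::-1]))
    lo = [0.0, float(np.min(pca)) - 1.0, 1e-3]
    hi = [np.inf, float(np.max(pca)) + 1.0, 50.0]
    result, _ = nls_fit(
        model,
        pca,
        force,
        [fmax0, pca50_0, 2.0],
        ["f_max", "pca50", "n_hill"],
        bounds=(lo, hi),
        model_id="hill_force_pca",
        starts=[[fmax0, pca50_0, n] for n in (1.0, 4.0)],
    )
    if not (np.min(pca) <= result.params["pca50"] <= np.max(pca)):
        result.converged = False
        result.message = "fitted pCa50 outside the sampled pCa range"
    return result


def paired_t(differences) -> tuple[float, float]:
    """Paired Student t-test from its closed-form definition.

    t = mean(d) / (sd(d)/sqrt(n)) with the two-sided p from the t(n-1)
    distribution. All-zero differences give (0, 1) by convention.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return (0.0, 1.0) if np.all(d == 0) else (float("inf"), 0.0)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


@dataclass
class ConditionComparison:
    table: pd.DataFrame
    tests: dict[str, dict[str, float]]
    unpaired: list[str]


def compare_conditions(
    control: dict[str, FitResult], treated: dict[str, FitResult]
) -> ConditionComparison:
    """Per-replicate Hill-parameter differences (treated - control) with paired tests.

    Keys are replicate identifiers. A negative mean d(pCa50) is a right shift
    of the force-pCa curve, i.e. calcium desensitisation. Replicates present
    in only one condition are reported in ``unpaired`` and excluded.
    """
    common = sorted(set(control) & set(treated))
    unpaired = sorted(set(control) ^ set(treated))
    if len(common) < 2:
        raise ValueError("need at least 2 paired replicates")
    rows = []
    for rep in common:
        c, t = control[rep], treated[rep]
        rows.append(
            {
                "replicate": rep,
                "d_pca50": t.params["pca50"] - c.params["pca50"],
                "d_f_max": t.params["f_max"] - c.params["f_max"],
                "d_n_hill": t.params["n_hill"] - c.params["n_hill"],
            }
        )
    table = pd.DataFrame(rows)
    tests = {}
    for name in ("d_pca50", "d_f_max", "d_n_hill"):
        t_stat, p = paired_t(table[name].to_numpy())
        tests[name] = {
            "mean": float(table[name].mean()),
            "t": t_stat,
            "p": p,
            "n_pairs": len(common),
        }
    return ConditionComparison(table=table, tests=tests, unpaired=unpaired)
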