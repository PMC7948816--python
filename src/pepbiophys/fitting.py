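"""Shared nonlinear least-squares machinery.

A thin wrapper around :func:`scipy.optimize.least_squares` that standardises
parameter naming, standard-error extraction from the Jacobian, and the
:class:`~pepbiophys.datatypes.FitResult` contract.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datatypes import FitResult

log = logging.getLogger("pepbiophys")

__all__ = ["nls_fit"]


def _covariance(jac: np.ndarray, rss: float, n_obs: int, n_par: int) -> np.ndarray | None:
    """Covariance of the estimates from the Jacobian at the solution.

    Returns None when the problem is rank-deficient (unidentifiable directions).
    """
    dof = max(n_obs - n_par, 1)
    try:
        jtj = jac.T @ jac
        cov = np.linalg.inv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    return cov


def nls_fit(
    model: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    p0: Sequence[float],
    param_names: Sequence[str],
    *,
    bounds: tuple | None = None,
    model_id: str = "",
    fixed: dict | None = None,
    weights: np.ndarray | None = None,
    starts: Sequence[Sequence[float]] | None = None,
) -> tuple[FitResult, np.ndarray | None]:
    """Fit ``y ~ model(params, x)`` by trust-region least squares.

    ``starts`` may give additional start vectors (multistart); the best final
    residual wins. Returns the FitResult and the covariance matrix (ordered as
    ``param_names``) for downstream uncertainty propagation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bounds is None:
        bounds = (-np.inf, np.inf)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def resid(p: np.ndarray) -> np.ndarray:
        return (model(p, x) - y) * w

    best = None
    for start in [list(p0)] + [list(s) for s in (starts or [])]:
        try:
            sol = least_squares(resid, start, bounds=bounds, method="trf")
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return (
            FitResult(
                params=dict(zip(param_names, p0)),
                converged=False,
                model_id=model_id,
                fixed=dict(fixed or {}),
                message="optimisation failed to start",
            ),
            None,
        )

    rss = float(2.0 * best.cost)
    cov = _covariance(best.jac, rss, y.size, len(param_names))
    stderr: dict[str, float] = {}
    if cov is not None:
        diag = np.diag(cov)
        stderr = {
            name: float(np.sqrt(v)) for name, v in zip(param_names, diag) if v >= 0
        }
    result = FitResult(
        params={name: float(v) for name, v in zip(param_names, best.x)},
        stderr=stderr,
        rss=rss,
        converged=bool(best.success),
        model_id=model_id,
        fixed=dict(fixed or {}),
    )
    log.info("fit %s: converged=%s fixed=%s", model_id, result.converged, result.fixed)
    return result, cov
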