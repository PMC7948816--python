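"""Shared containers: titration curves, decay series, ITC isotherms, noise
specifications, ground truths and the :class:`FitResult` contract that every
fitting routine in the package returns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "TitrationCurve",
    "DecaySeries",
    "ItcIsotherm",
    "FitResult",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise with a reproducible seed.

    sigma is in the units of the signal it perturbs; ``sigma=0`` yields the
    noise-free model curve. Identical seeds give byte-identical series.
    """

    sigma: float = 0.0
    seed: int | None = None
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.kind != "gaussian":
            raise ValueError(f"unsupported noise kind: {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.sigma == 0:
            return y.copy()
        return y + self.rng().normal(0.0, self.sigma, size=y.shape)


@dataclass(frozen=True)
class GroundTruth:
    """True parameter values attached to a synthetic dataset."""

    model_id: str
    params: Mapping[str, float]

    def to_dict(self) -> dict:
        return {"model_id": self.model_id, "params": dict(self.params)}


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class TitrationCurve:
    """Ordered (x, signal) observations for TFE, thermal, ligand or pCa titrations."""

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray | None = None
    x_label: str = "x"
    y_label: str = "signal"

    def __post_init__(self) -> None:
        self.x = _as_1d(self.x, "x")
        self.y = _as_1d(self.y, "y")
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")
        if self.sigma is not None:
            self.sigma = _as_1d(self.sigma, "sigma")
            if self.sigma.shape != self.x.shape:
                raise ValueError("sigma must match x in length")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        data = {self.x_label: self.x, self.y_label: self.y}
        if self.sigma is not None:
            data["sigma"] = self.sigma
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(
        cls, path: str | Path, x_col: str | None = None, y_col: str | None = None
    ) -> "TitrationCurve":
        df = pd.read_csv(path, comment="#")
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: need at least two columns, got {cols}")
        xc = x_col or cols[0]
        yc = y_col or cols[1]
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns and yc != "sigma" else None
        return cls(df[xc].to_numpy(), df[yc].to_numpy(), sigma, x_label=xc, y_label=yc)


@dataclass
class DecaySeries:
    """(control-variable, intensity) pairs for gradient or relaxation-delay decays."""

    t: np.ndarray
    intensity: np.ndarray
    t_label: str = "t"

    def __post_init__(self) -> None:
        self.t = _as_1d(self.t, "t")
        self.intensity = _as_1d(self.intensity, "intensity")
        if self.t.shape != self.intensity.shape:
            raise ValueError("t and intensity must have the same length")

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.t_label: self.t, "intensity": self.intensity})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecaySeries":
        df = pd.read_csv(path, comment="#")
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(), t_label=cols[0])


@dataclass
class ItcIsotherm:
    """Per-injection volumes and heats with cell/syringe bookkeeping.

    Concentrations are micromolar ([cell] is the macromolecule in the cell,
    [syringe] the titrant), volumes in microlitres (injections) and millilitres
    (cell), heats in microcalories.
    """

    injection_volumes_ul: np.ndarray
    heats_ucal: np.ndarray
    cell_conc_uM: float
    syringe_conc_uM: float
    cell_volume_ml: float

    def __post_init__(self) -> None:
        self.injection_volumes_ul = _as_1d(self.injection_volumes_ul, "injection_volumes_ul")
        self.heats_ucal = _as_1d(self.heats_ucal, "heats_ucal")
        if self.injection_volumes_ul.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats must have the same length")
        if np.any(self.injection_volumes_ul <= 0):
            raise ValueError("injection volumes must be positive")
        for name in ("cell_conc_uM", "syringe_conc_uM", "cell_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def __len__(self) -> int:
        return self.injection_volumes_ul.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "injection_vol_ul": self.injection_volumes_ul,
                "heat_ucal": self.heats_ucal,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``params`` holds the estimates (including any derived quantities), ``stderr``
    the 1-sigma standard errors for the subset of parameters where they are
    defined, ``fixed`` the constants held fixed during the fit, and ``model_id``
    names the model so results are self-describing. ``message`` carries
    warnings such as identifiability flags.
    """

    params: dict[str, float]
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = 0.0
    converged: bool = True
    model_id: str = ""
    fixed: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    message: str = ""

    def __post_init__(self) -> None:
        extra = set(self.stderr) - set(self.params)
        if extra:
            raise ValueError(f"stderr for unknown parameters: {sorted(extra)}")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    def __getitem__(self, name: str) -> float:
        return self.params[name]

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "fixed": self.fixed,
            "seed": self.seed,
            "message": self.message,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
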