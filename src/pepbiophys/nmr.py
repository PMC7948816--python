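"""Residue-level NMR observables.

Covers the analyses used to place a disordered peptide on the random-coil /
nascent-helix axis and to map its binding to a large partner:

* sequence-corrected conformational shifts of H-alpha protons against
  random-coil reference values, with the |dd| <= 0.1 ppm random-coil band;
* amide chemical shift perturbation (CSP) as the Euclidean distance
  sqrt(ddH^2 + (0.14 * ddN)^2);
* mono-exponential R1/R2 relaxation fits I(t) = I0 exp(-t R);
* steady-state heteronuclear NOE ratios I_sat/I_nonsat with noise-propagated
  uncertainties; and
* NOE-contact bookkeeping: class/separation counts, nascent-helix windows
  from runs of sequential NN(i, i+1) contacts, and helix-like calls from
  medium-range (i, i+3)/(i, i+4) contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .constants import CSP_N15_SCALE, RANDOM_COIL_SHIFT_BAND_PPM
from .datatypes import DecaySeries, FitResult
from .fitting import nls_fit
from .sequence import PeptideSequence

__all__ = [
    "ResidueNmrRecord",
    "RelaxationRecord",
    "NoeContact",
    "NoeSummary",
    "random_coil_ha_reference",
    "conformational_shift",
    "secondary_shift_table",
    "csp",
    "fit_relaxation_rate",
    "het_noe",
    "compare_free_bound",
    "classify_contact_strength",
    "noe_summary",
]


@lru_cache(maxsize=1)
def _rc_table() -> dict:
    raw = resources.files("pepbiophys.data").joinpath("random_coil_ha.json").read_text()
    return json.loads(raw)


def random_coil_ha_reference(
    code: str, next_code: str | None = None, table: dict | None = None
) -> tuple[float, float]:
    """(random-coil H-alpha shift, nearest-neighbour correction) in ppm.

    The correction is an additive term depending on the identity of the
    following residue (proline and aromatic neighbours); a custom ``table``
    with the same JSON layout may be supplied.
    """
    tab = table or _rc_table()
    try:
        rc = float(tab["ha_ppm"][code])
    except KeyError:
        raise ValueError(f"no random-coil H-alpha reference for residue {code!r}")
    corr = 0.0
    if next_code is not None:
        nc = tab.get("neighbour_corrections", {})
        if next_code == "P":
            corr += float(nc.get("next_is_proline", 0.0))
        elif next_code in set(tab.get("aromatic_codes", [])):
            corr += float(nc.get("next_is_aromatic", 0.0))
    return rc, corr


@dataclass(frozen=True)
class ResidueNmrRecord:
    """Observed and reference shifts for one residue (paper numbering)."""

    residue: int
    code: str
    ha_obs_ppm: float
    ha_rc_ppm: float
    correction_ppm: float = 0.0
    hn_obs_ppm: float | None = None
    n15_obs_ppm: float | None = None

    @property
    def delta_ppm(self) -> float:
        """Conformational shift dd = observed - (random-coil + correction)."""
        return self.ha_obs_ppm - (self.ha_rc_ppm + self.correction_ppm)


def conformational_shift(
    record: ResidueNmrRecord, threshold: float = RANDOM_COIL_SHIFT_BAND_PPM
) -> tuple[str, float]:
    """Classify one residue as random-coil (|dd| <= threshold) or not."""
    delta = record.delta_ppm
    label = "random-coil" if abs(delta) <= threshold else "non-random-coil"
    return label, delta


def secondary_shift_table(
    seq: PeptideSequence,
    observed_ha_ppm: dict[int, float],
    threshold: float = RANDOM_COIL_SHIFT_BAND_PPM,
    table: dict | None = None,
) -> pd.DataFrame:
    """Per-residue conformational-shift table for the observed residues.

    Residue keys use the sequence's parent-protein numbering; missing
    reference values raise naming the residue.
    """
    rows = []
    for resnum, obs in sorted(observed_ha_ppm.items()):
        code = seq.residue_at(resnum)
        next_code = (
            seq.residue_at(resnum + 1) if resnum + 1 <= seq.end_number else None
        )
        try:
            rc, corr = random_coil_ha_reference(code, next_code, table)
        except ValueError as err:
            raise ValueError(f"residue {code}{resnum}: {err}") from err
        record = ResidueNmrRecord(resnum, code, obs, rc, corr)
        label, delta = conformational_shift(record, threshold)
        rows.append(
            {
                "residue": resnum,
                "code": code,
                "ha_obs_ppm": obs,
                "ha_rc_ppm": rc,
                "correction_ppm": corr,
                "delta_ppm": delta,
                "classification": label,
            }
        )
    return pd.DataFrame(rows)


def csp(delta_h: float, delta_n: float, n_scale: float = CSP_N15_SCALE) -> float:
    """Amide chemical shift perturbation sqrt(ddH^2 + (n_scale * ddN)^2), ppm."""
    if not (np.isfinite(delta_h) and np.isfinite(delta_n)):
        raise ValueError("shift differences must be finite")
    return float(np.hypot(delta_h, n_scale * delta_n))


def fit_relaxation_rate(series: DecaySeries) -> FitResult:
    """Two-parameter fit I(t) = I0 exp(-t R) to a relaxation-delay series.

    Delays in ms, rate reported in s^-1; standard errors come from the fit
    covariance. Series whose intensity grows with delay are flagged.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 relaxation delays")
    t_ms, intensity = series.t, series.intensity
    if np.any(intensity <= 0):
        raise ValueError("intensities must be positive")
    slope, log_i0 = np.polyfit(t_ms * 1e-3, np.log(intensity), 1)
    if slope > 0:
        return FitResult(
            params={"r": float("nan"), "i0": float(np.exp(log_i0))},
            converged=False,
            model_id="monoexp_relaxation",
            message="intensities increase with delay: not a relaxation decay",
        )

    def model(p, tt):
        i0, r = p
        return i0 * np.exp(-tt * 1e-3 * r)

    result, _ = nls_fit(
        model,
        t_ms,
        intensity,
        [float(np.exp(log_i0)), max(-slope, 0.0)],
        ["i0", "r"],
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        model_id="monoexp_relaxation",
    )
    return result


def het_noe(i_sat: float, i_nonsat: float, noise_sd: float = 0.0) -> tuple[float, float]:
    """Steady-state heteronuclear NOE = I_sat / I_nonsat with its uncertainty.

    The spectral background noise enters both intensities:
    sd = |NOE| * sqrt((noise/I_sat)^2 + (noise/I_nonsat)^2).
    Ratios outside [-1, 1.2] are physically suspect for backbone amides in
    this regime and trigger a warning.
    """
    if i_nonsat == 0:
        raise ValueError("reference (non-saturated) intensity must be non-zero")
    ratio = i_sat / i_nonsat
    sd = abs(ratio) * float(np.hypot(noise_sd / i_sat, noise_sd / i_nonsat)) if i_sat else 0.0
    if not (-1.0 <= ratio <= 1.2):
        import warnings

        warnings.warn(f"hetNOE ratio {ratio:.3g} outside the expected [-1, 1.2] band",
                      stacklevel=2)
    return float(ratio), float(sd)


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue relaxation summary (rates in s^-1)."""

    residue: int
    r1: float
    r2: float
    noe: float | None = None
    r1_err: float = 0.0
    r2_err: float = 0.0
    noe_err: float = 0.0

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("relaxation rates must be positive")


@dataclass
class FreeBoundComparison:
    table: pd.DataFrame
    unmatched_free: list[int]
    unmatched_bound: list[int]


def compare_free_bound(
    free: list[RelaxationRecord], bound: list[RelaxationRecord]
) -> FreeBoundComparison:
    """Per-residue differences (bound - free) in R1, R2 and hetNOE.

    Residues present in only one set are reported, not silently dropped; the
    table is ranked by |dR2|, the most sensitive reporter of complex
    formation for a small peptide binding a large partner.
    """
    free_map = {r.residue: r for r in free}
    bound_map = {r.residue: r for r in bound}
    common = sorted(set(free_map) & set(bound_map))
    if not common:
        raise ValueError("no residues in common between free and bound sets")
    rows = []
    for res in common:
        f, b = free_map[res], bound_map[res]
        row = {
            "residue": res,
            "d_r1": b.r1 - f.r1,
            "d_r1_sd": float(np.hypot(f.r1_err, b.r1_err)),
            "d_r2": b.r2 - f.r2,
            "d_r2_sd": float(np.hypot(f.r2_err, b.r2_err)),
        }
        if f.noe is not None and b.noe is not None:
            row["d_noe"] = b.noe - f.noe
            row["d_noe_sd"] = float(np.hypot(f.noe_err, b.noe_err))
        else:
            row["d_noe"] = np.nan
            row["d_noe_sd"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.reindex(
        table["d_r2"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
    return FreeBoundComparison(
        table=table,
        unmatched_free=sorted(set(free_map) - set(bound_map)),
        unmatched_bound=sorted(set(bound_map) - set(free_map)),
    )


# --- NOE contact bookkeeping ------------------------------------------------

CONTACT_KINDS = {"NN", "alphaN", "betaN", "gammaN", "alphabeta"}
CONTACT_CLASSES = ("strong", "medium", "weak")


@dataclass(frozen=True)
class NoeContact:
    """A proton-proton contact between residues i and j (i < j recommended)."""

    i: int
    j: int
    kind: str
    strength: str = "medium"
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if abs(self.i - self.j) < 1:
            raise ValueError("contact must link two distinct residues")
        if self.kind not in CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}; use {sorted(CONTACT_KINDS)}")
        if self.strength not in CONTACT_CLASSES:
            raise ValueError(f"strength must be one of {CONTACT_CLASSES}")

    @property
    def separation(self) -> int:
        return abs(self.j - self.i)


def classify_contact_strength(
    intensities, thresholds: tuple[float, float] | None = None
) -> list[str]:
    """Bin bar heights into weak/medium/strong.

    Default thresholds are the lower and upper tertiles of the observed
    intensity distribution; explicit (low, high) cut points may be given.
    """
    arr = np.asarray(intensities, dtype=float)
    if thresholds is None:
        low, high = np.quantile(arr, [1 / 3, 2 / 3])
    else:
        low, high = thresholds
        if low > high:
            raise ValueError("thresholds must satisfy low <= high")
    return [
        "weak" if v < low else ("strong" if v > high else "medium") for v in arr
    ]


@dataclass
class NoeSummary:
    counts_by_kind: dict[str, int]
    counts_by_separation: dict[int, int]
    counts_by_class: dict[str, int]
    nascent_helix_windows: list[tuple[int, int]] = field(default_factory=list)
    helix_like: bool = False

    @property
    def nascent_helix(self) -> bool:
        return bool(self.nascent_helix_windows)


def noe_summary(
    contacts: list[NoeContact],
    sequence: PeptideSequence | None = None,
    min_sequential_run: int = 3,
) -> NoeSummary:
    """Summarise a contact list and make secondary-structure calls.

    A *nascent helix* window is flagged where at least ``min_sequential_run``
    consecutive sequential NN(i, i+1) contacts cluster (an operational
    reading of the conventional qualitative definition); a *helix-like* call
    requires at least one medium-range (i, i+3) or (i, i+4) contact. Output
    is independent of input ordering.
    """
    if sequence is not None:
        for c in contacts:
            for res in (c.i, c.j):
                if not (sequence.start_number <= res <= sequence.end_number):
                    raise ValueError(
                        f"contact references residue {res} outside sequence "
                        f"{sequence.start_number}-{sequence.end_number}"
                    )
    counts_by_kind: dict[str, int] = {}
    counts_by_sep: dict[int, int] = {}
    counts_by_class: dict[str, int] = {}
    for c in contacts:
        counts_by_kind[c.kind] = counts_by_kind.get(c.kind, 0) + 1
        counts_by_sep[c.separation] = counts_by_sep.get(c.separation, 0) + 1
        counts_by_class[c.strength] = counts_by_class.get(c.strength, 0) + 1

    nn_starts = sorted({min(c.i, c.j) for c in contacts if c.kind == "NN" and c.separation == 1})
    windows: list[tuple[int, int]] = []
    run_start = None
    prev = None
    for i in nn_starts + [None]:
        if run_start is None:
            run_start = i
        elif i is None or i != prev + 1:
            run_len = prev - run_start + 1
            if run_len >= min_sequential_run:
                windows.append((run_start, prev + 1))  # +1: last contact spans prev..prev+1
            run_start = i
        prev = i

    helix_like = any(c.separation in (3, 4) for c in contacts)
    return NoeSummary(
        counts_by_kind=counts_by_kind,
        counts_by_separation=counts_by_sep,
        counts_by_class=counts_by_class,
        nascent_helix_windows=windows,
        helix_like=helix_like,
    )
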