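"""Melting-temperature estimation and ΔTm hit calling for thermal shift assays.

A thermal shift assay (TSA, differential scanning fluorimetry) follows a
reporter-dye fluorescence signal as a protein unfolds with temperature.  A
two-state unfolding transition with linear folded/unfolded baselines gives a
Boltzmann sigmoid

    F(T) = B_f(T) + (B_u(T) − B_f(T)) / (1 + exp((Tm − T)/w))

whose midpoint is the melting temperature Tm.  Ligand binding stabilises the
folded state and raises Tm; a ligand is called a binder ("hit") when the mean
shift ΔTm = Tm(+ligand) − Tm(reference) over replicates reaches the 2 °C
significance cutoff.  Stabilisation is required for a hit; strong negative
shifts are flagged as destabilising but never called hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import ttest_1samp, ttest_ind

__all__ = [
    "HIT_THRESHOLD_C",
    "MeltCurve",
    "TmEstimate",
    "TmMethod",
    "ShiftCall",
    "estimate_tm",
    "compute_shift",
    "call_hits",
    "analyze_plate",
    "read_curves_csv",
    "write_calls_tsv",
]

#: ΔTm significance cutoff (°C) for ligand identification.
HIT_THRESHOLD_C = 2.0

#: Minimal transition amplitude, in multiples of residual noise, for a usable fit.
MIN_AMPLITUDE_SNR = 3.0


class TmMethod(str, Enum):
    BOLTZMANN_FIT = "boltzmann_fit"
    DERIVATIVE_MAX = "derivative_max"


@dataclass
class MeltCurve:
    """One fluorescence-vs-temperature series for a single well."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    well_id: str = ""
    lbd_id: str = ""
    ligand_id: str = "reference"
    replicate: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must have equal length")
        if self.temperature.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")


@dataclass
class TmEstimate:
    tm: float
    method: TmMethod
    fit_rmse: float
    usable: bool
    amplitude: float = np.nan


@dataclass
class ShiftCall:
    """Replicate-aggregated thermal shift for one (LBD, ligand) pair."""

    lbd_id: str
    ligand_id: str
    delta_tm_mean: float
    delta_tm_sd: float
    n_replicates: int
    is_hit: bool
    destabilizing: bool
    p_value: float = np.nan


def _boltzmann(t, tm, width, f0, s0, f1, s1):
    frac = 1.0 / (1.0 + np.exp(np.clip((tm - t) / width, -500, 500)))
    return (f0 + s0 * t) + ((f1 + s1 * t) - (f0 + s0 * t)) * frac


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    window = max(int(window), 1)
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(ypad, kernel, mode="valid")


def _derivative_tm(curve: MeltCurve) -> tuple[float, float, float]:
    """Tm from the maximum of a smoothed dF/dT; returns (tm, rmse, amplitude)."""
    t, f = curve.temperature, curve.fluorescence
    step = float(np.median(np.diff(t)))
    # window = max(5 points, 1 °C) — robust on 0.5 °C-step plates
    window = max(5, int(round(1.0 / step)) | 1)
    fs = _smooth(f, window)
    dfdt = np.gradient(fs, t)
    i = int(np.argmax(dfdt))
    tm = float(t[i])
    resid = f - fs
    amplitude = float(np.max(fs) - np.min(fs))
    return tm, float(np.sqrt(np.mean(resid**2))), amplitude


def estimate_tm(curve: MeltCurve, method: TmMethod | str = TmMethod.BOLTZMANN_FIT) -> TmEstimate:
    """Estimate the melting temperature of one curve.

    ``boltzmann_fit`` fits the two-state sigmoid with linear baselines by
    nonlinear least squares (falling back to ``derivative_max`` on
    non-convergence); ``derivative_max`` takes the maximum of a smoothed
    first derivative.  Degenerate curves — flat, or with transition amplitude
    below :data:`MIN_AMPLITUDE_SNR` times the residual noise — are returned
    with ``usable=False``.
    """
    method = TmMethod(method)
    t, f = curve.temperature, curve.fluorescence
    d_tm, d_rmse, amplitude = _derivative_tm(curve)

    noise = d_rmse if d_rmse > 0 else 1e-12
    if amplitude < MIN_AMPLITUDE_SNR * noise or amplitude == 0.0:
        return TmEstimate(tm=np.nan, method=method, fit_rmse=d_rmse, usable=False,
                          amplitude=amplitude)

    if method is TmMethod.DERIVATIVE_MAX:
        usable = t[0] < d_tm < t[-1]
        return TmEstimate(tm=d_tm, method=method, fit_rmse=d_rmse, usable=usable,
                          amplitude=amplitude)

    span = t[-1] - t[0]
    p0 = [d_tm, max(span / 20.0, 0.5), float(f[0]), 0.0, float(f[-1]), 0.0]
    try:
        popt, _ = curve_fit(
            _boltzmann, t, f, p0=p0,
            bounds=([t[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
                    [t[-1], span, np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        est = estimate_tm(curve, TmMethod.DERIVATIVE_MAX)
        est.method = TmMethod.DERIVATIVE_MAX
        return est
    resid = f - _boltzmann(t, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    tm = float(popt[0])
    usable = t[0] < tm < t[-1]
    return TmEstimate(tm=tm, method=TmMethod.BOLTZMANN_FIT, fit_rmse=rmse, usable=usable,
                      amplitude=amplitude)


def compute_shift(ref: TmEstimate, with_ligand: TmEstimate) -> float:
    """Signed thermal shift ΔTm = Tm(+ligand) − Tm(reference), °C."""
    if not (ref.usable and with_ligand.usable):
        raise ValueError("cannot compute a shift from unusable Tm estimates")
    return float(with_ligand.tm - ref.tm)


def call_hits(
    shifts: Iterable[tuple[str, str, float]],
    threshold: float = HIT_THRESHOLD_C,
    p_values: dict[tuple[str, str], float] | None = None,
) -> list[ShiftCall]:
    """Aggregate per-replicate shifts and call hits at the significance cutoff.

    ``shifts`` yields ``(lbd_id, ligand_id, delta_tm)`` per replicate.  A
    group is a hit when its mean ΔTm ≥ ``threshold`` (inclusive); a mean
    shift ≤ −threshold is flagged destabilising but not a hit.  When no
    external p-values are supplied a one-sample two-tailed t-test of the
    replicate shifts against zero is reported (n ≥ 2); significance is
    reported alongside, never used for the hit decision.
    """
    rows = list(shifts)
    groups: dict[tuple[str, str], list[float]] = {}
    for lbd, ligand, dtm in rows:
        groups.setdefault((lbd, ligand), []).append(float(dtm))
    calls = []
    for (lbd, ligand), values in sorted(groups.items()):
        arr = np.asarray(values)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if p_values is not None and (lbd, ligand) in p_values:
            p = float(p_values[(lbd, ligand)])
        elif arr.size > 1 and sd > 0:
            p = float(ttest_1samp(arr, 0.0).pvalue)
        else:
            p = np.nan
        calls.append(
            ShiftCall(
                lbd_id=lbd, ligand_id=ligand,
                delta_tm_mean=mean, delta_tm_sd=sd, n_replicates=int(arr.size),
                is_hit=mean >= threshold,
                destabilizing=mean <= -threshold,
                p_value=p,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Plate pipeline and I/O
# ---------------------------------------------------------------------------

CURVE_COLUMNS = ["well", "lbd_id", "ligand_id", "replicate", "temperature_C", "fluorescence"]


def read_curves_csv(path: str | Path) -> list[MeltCurve]:
    """Read long-format melt curves (columns: well, lbd_id, ligand_id,
    replicate, temperature_C, fluorescence)."""
    df = pd.read_csv(path)
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
    curves = []
    for (well, lbd, ligand, rep), grp in df.groupby(
        ["well", "lbd_id", "ligand_id", "replicate"], sort=True
    ):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                temperature=grp["temperature_C"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                well_id=str(well), lbd_id=str(lbd), ligand_id=str(ligand),
                replicate=int(rep),
            )
        )
    return curves


def analyze_plate(
    curves: Sequence[MeltCurve],
    threshold: float = HIT_THRESHOLD_C,
    method: TmMethod | str = TmMethod.BOLTZMANN_FIT,
    reference_ligand: str = "reference",
) -> pd.DataFrame:
    """Full plate analysis: Tm per well, ΔTm per replicate, hit call per pair.

    Replicate ΔTm pairs reference and ligand wells of the same LBD by
    replicate index.  The reported p-value is a Welch two-sample t-test
    between reference and ligand Tm replicates.
    """
    tms: dict[tuple[str, str, int], TmEstimate] = {}
    for c in curves:
        tms[(c.lbd_id, c.ligand_id, c.replicate)] = estimate_tm(c, method)

    shifts: list[tuple[str, str, float]] = []
    tm_groups: dict[tuple[str, str], list[float]] = {}
    for (lbd, ligand, rep), est in tms.items():
        if est.usable:
            tm_groups.setdefault((lbd, ligand), []).append(est.tm)
        if ligand == reference_ligand:
            continue
        ref = tms.get((lbd, reference_ligand, rep))
        if ref is None or not (ref.usable and est.usable):
            continue
        shifts.append((lbd, ligand, compute_shift(ref, est)))

    p_values: dict[tuple[str, str], float] = {}
    for (lbd, ligand), tm_list in tm_groups.items():
        if ligand == reference_ligand:
            continue
        ref_list = tm_groups.get((lbd, reference_ligand), [])
        if len(tm_list) > 1 and len(ref_list) > 1:
            p_values[(lbd, ligand)] = float(
                ttest_ind(tm_list, ref_list, equal_var=False).pvalue
            )

    calls = call_hits(shifts, threshold=threshold, p_values=p_values)
    return pd.DataFrame(
        {
            "lbd_id": [c.lbd_id for c in calls],
            "ligand_id": [c.ligand_id for c in calls],
            "n": [c.n_replicates for c in calls],
            "delta_tm_mean": [c.delta_tm_mean for c in calls],
            "delta_tm_sd": [c.delta_tm_sd for c in calls],
            "is_hit": [c.is_hit for c in calls],
            "destabilizing": [c.destabilizing for c in calls],
            "p_value": [c.p_value for c in calls],
        }
    )


def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)
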