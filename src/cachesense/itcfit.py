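"""One-site ITC binding model: forward simulation, fitting, independence test.

Isothermal titration calorimetry titrates a ligand (syringe, concentration
``X_syr``) into a macromolecule solution (cell, concentration ``M0``, active
volume ``V0``) and records the heat released per injection.  Under the
standard single-set-of-sites ("one binding site") model with stoichiometry
``n``, dissociation constant ``K_D`` and molar enthalpy ``ΔH``, the bound
fraction after each injection follows from mass action, and per-injection
heats are differences of the cumulative heat with a perfusion-displacement
correction for the volume pushed out of the cell.

The module also implements the presaturation (competitive) design used to ask
whether two ligands occupy independent sites: the protein is saturated with
ligand B before titrating ligand A.  If the sites are independent the
apparent ``K_D`` of A is unchanged; if A and B share a site it is inflated by
the competition factor ``1 + [B]/K_D(B)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ITCTitration",
    "OneSiteFit",
    "IndependenceVerdict",
    "simulate_heats",
    "simulate_two_site_heats",
    "simulate_competitive_heats",
    "fit_one_site",
    "assess_independence",
    "read_titration_csv",
    "write_titration_csv",
]

#: c-value window outside which a one-site fit carries little information.
C_VALUE_RANGE = (0.1, 1000.0)


@dataclass
class ITCTitration:
    """An integrated ITC titration (heats per injection, geometry, metadata).

    Heats are integrated per-injection values in µcal, as produced by
    instrument software after baseline integration; raw power traces are out
    of scope.  ``exclude_first`` marks the customary discard of the first
    (diffusion-compromised) injection from fitting.
    """

    cell_volume_uL: float
    cell_conc_M: float
    syringe_conc_M: float
    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    presaturant: str | None = None
    presaturant_conc_M: float = 0.0
    exclude_first: bool = True
    heat_units: str = "ucal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.heat_units == "uJ":  # canonicalise to µcal (thermochemical calorie)
            self.heats_ucal = self.heats_ucal / 4.184
            self.heat_units = "ucal"
        elif self.heat_units != "ucal":
            raise ValueError(f"unknown heat units {self.heat_units!r} (ucal or uJ)")
        if self.injection_volumes_uL.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats must have equal length")
        if self.cell_volume_uL <= 0 or self.cell_conc_M <= 0 or self.syringe_conc_M <= 0:
            raise ValueError("cell volume and concentrations must be positive")
        if np.any(self.injection_volumes_uL <= 0):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes_uL.size)

    def usable_mask(self) -> np.ndarray:
        mask = np.ones(self.n_injections, dtype=bool)
        if self.exclude_first and self.n_injections > 0:
            mask[0] = False
        return mask


@dataclass
class OneSiteFit:
    """Fitted one-site parameters with 95% confidence intervals.

    ``kd_M`` is the dissociation constant in molar, ``dh_cal_per_mol`` the
    binding enthalpy, ``n`` the stoichiometry and ``q_offset_ucal`` a
    per-injection residual dilution heat absorbed by the fit.  ``converged``
    False disables downstream use; ``low_information`` flags c-values
    (``n·M0/K_D``) outside the informative window.
    """

    n: float
    kd_M: float
    dh_cal_per_mol: float
    q_offset_ucal: float
    ci95: dict[str, tuple[float, float]]
    converged: bool
    c_value: float
    low_information: bool
    rmse_ucal: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["ci95"] = {k: list(v) for k, v in self.ci95.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "OneSiteFit":
        d = json.loads(Path(path).read_text())
        d["ci95"] = {k: tuple(v) for k, v in d["ci95"].items()}
        return cls(**d)


@dataclass
class IndependenceVerdict:
    """Outcome of the presaturation comparison of two one-site fits."""

    independent: bool
    kd_ratio: float
    ci_overlap: bool


def _bound_fraction(x_t: np.ndarray, m_t: np.ndarray, n: float, kd: float) -> np.ndarray:
    """Physical root of the one-site quadratic for the fractional saturation Θ.

    Θ² − Θ·(1 + X/(nM) + Kd/(nM)) + X/(nM) = 0, taking the root in [0, 1].
    """
    xr = x_t / (n * m_t)
    kr = kd / (n * m_t)
    b = 1.0 + xr + kr
    disc = b * b - 4.0 * xr
    if np.any(disc < 0):
        raise ValueError("negative discriminant in binding polynomial: invalid geometry")
    return 0.5 * (b - np.sqrt(disc))


def _concentrations(
    cell_conc_M: float,
    syringe_conc_M: float,
    injection_volumes_uL: np.ndarray,
    cell_volume_uL: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell concentrations of macromolecule and titrant after each injection.

    Uses the standard perfusion-displacement correction for an overflow cell:
    injected volume displaces an equal volume of (averaged) cell content.
    """
    v_cum = np.cumsum(injection_volumes_uL)
    r = v_cum / cell_volume_uL
    m_t = cell_conc_M * (1.0 - r / 2.0) / (1.0 + r / 2.0)
    x_t = syringe_conc_M * r / (1.0 + r / 2.0)
    return m_t, x_t, v_cum


def simulate_heats(
    n: float,
    kd_M: float,
    dh_cal_per_mol: float,
    cell_conc_M: float,
    syringe_conc_M: float,
    injection_volumes_uL: Sequence[float],
    cell_volume_uL: float,
) -> np.ndarray:
    """Per-injection heats (µcal) for the one-site model.

    Cumulative heat after injection i is ``Q_i = n·Θ_i·[M]_i·ΔH·V0``; the
    observed per-injection heat adds back the heat carried out with the
    displaced volume: ``q_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2``.
    """
    dv = np.asarray(injection_volumes_uL, dtype=float)
    if cell_volume_uL <= 0 or np.any(dv <= 0):
        raise ValueError("volumes must be positive")
    if kd_M <= 0 or n <= 0:
        raise ValueError("n and kd must be positive")
    m_t, x_t, _ = _concentrations(cell_conc_M, syringe_conc_M, dv, cell_volume_uL)
    theta = _bound_fraction(x_t, m_t, n, kd_M)
    v0_L = cell_volume_uL * 1e-6
    q_cum = n * theta * m_t * dh_cal_per_mol * v0_L * 1e6  # µcal
    q_prev = np.concatenate([[0.0], q_cum[:-1]])
    return q_cum - q_prev + (dv / cell_volume_uL) * (q_cum + q_prev) / 2.0


def simulate_two_site_heats(
    site_a: tuple[float, float, float],
    site_b: tuple[float, float, float],
    cell_conc_M: float,
    syringe_conc_M: float,
    injection_volumes_uL: Sequence[float],
    cell_volume_uL: float,
    site_b_presaturated: bool = False,
) -> np.ndarray:
    """Heats for a protein with two *independent* sites titrated by one ligand.

    Each site is a ``(n, kd_M, dh_cal_per_mol)`` triple.  With
    ``site_b_presaturated`` the second site is already occupied by its own
    (different) ligand and contributes no heat — the experimental design used
    to test whether two pockets interact.
    """
    q = simulate_heats(*site_a, cell_conc_M, syringe_conc_M, injection_volumes_uL, cell_volume_uL)
    if not site_b_presaturated:
        q = q + simulate_heats(
            *site_b, cell_conc_M, syringe_conc_M, injection_volumes_uL, cell_volume_uL
        )
    return q


def simulate_competitive_heats(
    n: float,
    kd_M: float,
    dh_cal_per_mol: float,
    competitor_conc_M: float,
    competitor_kd_M: float,
    cell_conc_M: float,
    syringe_conc_M: float,
    injection_volumes_uL: Sequence[float],
    cell_volume_uL: float,
) -> np.ndarray:
    """Heats when the titrant competes with a prebound ligand for one shared site.

    Uses the weak-competition apparent-constant result
    ``K_D,app = K_D·(1 + [B]/K_D(B))``: a presaturating competitor at a shared
    site inflates the apparent dissociation constant, which is what the
    independence test must detect.
    """
    kd_app = kd_M * (1.0 + competitor_conc_M / competitor_kd_M)
    return simulate_heats(
        n, kd_app, dh_cal_per_mol, cell_conc_M, syringe_conc_M,
        injection_volumes_uL, cell_volume_uL,
    )


def fit_one_site(titration: ITCTitration, fix_n: float | None = None) -> OneSiteFit:
    """Weighted nonlinear least-squares fit of the one-site model.

    Fits (n, K_D, ΔH, q_offset) to the usable injections with multi-start
    initialisation over a log-spaced K_D grid; 95% intervals come from the
    Gauss–Newton approximation to the parameter covariance.  Requires at
    least 8 usable injections.

    ``fix_n`` pins the stoichiometry to a known value — standard practice
    for shallow (low c-value) titrations such as presaturation controls,
    where n and ΔH are jointly unidentifiable.
    """
    mask = titration.usable_mask()
    if int(mask.sum()) < 8:
        raise ValueError("fit requires at least 8 usable injections")
    q_obs = titration.heats_ucal[mask]
    dv = titration.injection_volumes_uL
    m0, xs, v0 = titration.cell_conc_M, titration.syringe_conc_M, titration.cell_volume_uL

    def residuals(p: np.ndarray) -> np.ndarray:
        if fix_n is None:
            n_, log_kd, dh_, off = p
        else:
            (log_kd, dh_, off), n_ = p, fix_n
        q = simulate_heats(n_, 10.0 ** log_kd, dh_, m0, xs, dv, v0)
        return q[mask] + off - q_obs

    scale = max(np.max(np.abs(q_obs)), 1e-12)
    dh_guess = np.sum(q_obs) / (m0 * v0 * 1e-6 * 1e6)  # cal/mol if saturating
    if abs(dh_guess) < 1e-9:
        dh_guess = -1000.0
    starts = []
    for log_kd0 in (-7.0, -6.0, -5.0, -4.0, -3.0):
        for n0 in ((1.0,) if fix_n is not None else (0.5, 1.0, 2.0)):
            if fix_n is None:
                starts.append([n0, log_kd0, dh_guess, 0.0])
            else:
                starts.append([log_kd0, dh_guess, 0.0])
    if fix_n is None:
        lower = [1e-3, -12.0, -1e7, -scale]
        upper = [100.0, 0.0, 1e7, scale]
        x_scale = [1.0, 1.0, max(abs(dh_guess), 1.0), max(scale, 1.0)]
    else:
        lower, upper = [-12.0, -1e7, -scale], [0.0, 1e7, scale]
        x_scale = [1.0, max(abs(dh_guess), 1.0), max(scale, 1.0)]

    best = None
    for p0 in starts:
        try:
            sol = least_squares(
                residuals, p0, bounds=(lower, upper),
                method="trf", x_scale=x_scale, max_nfev=4000,
            )
        except (ValueError, RuntimeError):
            continue
        # keep the best finite-cost solution even when the step tolerance was
        # not reached (flat n·ΔH valleys at low c-value); reliability is
        # signalled through low_information, not by discarding the fit
        if np.isfinite(sol.cost) and (best is None or sol.cost < best.cost):
            best = sol
        if best is not None and best.cost < (1e-8 * scale) ** 2 * q_obs.size:
            break  # essentially exact fit; further starts cannot improve

    n_params = 4 if fix_n is None else 3
    if best is None:
        return OneSiteFit(
            n=np.nan, kd_M=np.nan, dh_cal_per_mol=np.nan, q_offset_ucal=np.nan,
            ci95={}, converged=False, c_value=np.nan, low_information=True,
            rmse_ucal=np.nan,
        )

    if fix_n is None:
        n_, log_kd, dh_, off = best.x
    else:
        (log_kd, dh_, off), n_ = best.x, float(fix_n)
    kd = 10.0 ** log_kd
    dof = max(q_obs.size - n_params, 1)
    s2 = 2.0 * best.cost / dof
    jac = best.jac
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        sd_fit = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        sd_fit = np.full(n_params, np.inf)
    if fix_n is None:
        sd = sd_fit
    else:
        sd = np.concatenate([[0.0], sd_fit])  # n fixed: zero-width interval
    # delta-method interval for kd from the log10 parameter (exponent clipped
    # to avoid overflow when the information matrix is singular)
    kd_lo = 10.0 ** np.clip(log_kd - 1.96 * sd[1], -300, 300)
    kd_hi = 10.0 ** np.clip(log_kd + 1.96 * sd[1], -300, 300)
    ci = {
        "n": (n_ - 1.96 * sd[0], n_ + 1.96 * sd[0]),
        "kd_M": (kd_lo, kd_hi),
        "dh_cal_per_mol": (dh_ - 1.96 * sd[2], dh_ + 1.96 * sd[2]),
        "q_offset_ucal": (off - 1.96 * sd[3], off + 1.96 * sd[3]),
    }
    c_value = n_ * m0 / kd
    return OneSiteFit(
        n=float(n_), kd_M=float(kd), dh_cal_per_mol=float(dh_), q_offset_ucal=float(off),
        ci95=ci, converged=True, c_value=float(c_value),
        low_information=not (C_VALUE_RANGE[0] <= c_value <= C_VALUE_RANGE[1]),
        rmse_ucal=float(np.sqrt(np.mean(residuals(best.x) ** 2))),
    )


def assess_independence(
    fit_alone: OneSiteFit, fit_presaturated: OneSiteFit, max_fold: float = 3.0
) -> IndependenceVerdict:
    """Decide whether presaturation with a second ligand perturbed binding.

    The sites are called independent when the two K_D 95% intervals overlap
    and the point estimates agree within ``max_fold`` (default 3-fold).  Both
    fits must have converged.
    """
    if not (fit_alone.converged and fit_presaturated.converged):
        raise ValueError("independence assessment requires two converged fits")
    ratio = fit_presaturated.kd_M / fit_alone.kd_M
    lo_a, hi_a = fit_alone.ci95["kd_M"]
    lo_b, hi_b = fit_presaturated.ci95["kd_M"]
    overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
    independent = overlap and (1.0 / max_fold <= ratio <= max_fold)
    return IndependenceVerdict(independent=independent, kd_ratio=float(ratio), ci_overlap=overlap)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = (
    "cell_volume_uL", "cell_conc_M", "syringe_conc_M", "presaturant", "presaturant_conc_M",
)


def write_titration_csv(titration: ITCTitration, path: str | Path) -> None:
    """Write a titration as commented ``# key=value`` header lines + CSV rows."""
    lines = [
        f"# cell_volume_uL={titration.cell_volume_uL}",
        f"# cell_conc_M={titration.cell_conc_M}",
        f"# syringe_conc_M={titration.syringe_conc_M}",
        f"# presaturant={titration.presaturant or ''}",
        f"# presaturant_conc_M={titration.presaturant_conc_M}",
        "injection_index,volume_uL,heat_ucal",
    ]
    for i, (v, q) in enumerate(zip(titration.injection_volumes_uL, titration.heats_ucal), 1):
        lines.append(f"{i},{v:.6g},{q:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_titration_csv(path: str | Path) -> ITCTitration:
    """Read the CSV dialect written by :func:`write_titration_csv`."""
    header: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            header[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    missing = [k for k in ("cell_volume_uL", "cell_conc_M", "syringe_conc_M") if k not in header]
    if missing:
        raise ValueError(f"titration CSV missing header keys: {missing}")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(body)))
    return ITCTitration(
        cell_volume_uL=float(header["cell_volume_uL"]),
        cell_conc_M=float(header["cell_conc_M"]),
        syringe_conc_M=float(header["syringe_conc_M"]),
        injection_volumes_uL=df["volume_uL"].to_numpy(),
        heats_ucal=df["heat_ucal"].to_numpy(),
        presaturant=header.get("presaturant") or None,
        presaturant_conc_M=float(header.get("presaturant_conc_M") or 0.0),
    )
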