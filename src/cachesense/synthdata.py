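"""Seeded generators for synthetic TSA, ITC, sequence and growth inputs.

Each generator produces data with exactly the statistical structure its
matching analysis stage assumes — a two-state Boltzmann melt with linear
baselines, one-site (or two-independent-site) ITC heats under a stated
injection schedule, family scaffolds with pocket residues planted at
reference-aligned positions, and lag/logistic growth curves — plus
homoscedastic Gaussian noise.  True parameters are recorded in each output's
metadata so round-trip parameter-recovery tests need no external data.

All randomness flows from ``numpy.random.default_rng(config.seed)`` created
per call; identical configurations reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import itcfit, seqscan
from .growthkin import GrowthCurve
from .itcfit import ITCTitration
from .thermoshift import CURVE_COLUMNS, MeltCurve

__all__ = [
    "SimConfig",
    "MeltModelParams",
    "boltzmann_melt",
    "gen_melt_curve",
    "gen_shift_experiment",
    "gen_itc_titration",
    "gen_motif_sequences",
    "gen_growth_curve",
    "write_melt_csv",
    "write_growth_csv",
    "write_sequences",
]


@dataclass
class SimConfig:
    """Shared simulation knobs: seed, noise level, sampling grid, replicates."""

    seed: int = 0
    noise_sd: float = 0.0
    grid: np.ndarray | None = None
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")
        if self.grid is not None:
            self.grid = np.asarray(self.grid, dtype=float)
            if np.any(np.diff(self.grid) <= 0):
                raise ValueError("grid must be strictly increasing")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class MeltModelParams:
    """Two-state melt: Boltzmann sigmoid between linear folded/unfolded baselines."""

    tm: float
    width: float = 1.0
    f_folded_intercept: float = 0.0
    f_folded_slope: float = 0.0
    f_unfolded_intercept: float = 1.0
    f_unfolded_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("transition width must be positive")
        if self._unfolded(self.tm) <= self._folded(self.tm):
            raise ValueError("unfolded baseline must exceed folded baseline at tm "
                             "(fluorescence rises on unfolding)")

    def _folded(self, t):
        return self.f_folded_intercept + self.f_folded_slope * np.asarray(t)

    def _unfolded(self, t):
        return self.f_unfolded_intercept + self.f_unfolded_slope * np.asarray(t)


def boltzmann_melt(t: np.ndarray, params: MeltModelParams) -> np.ndarray:
    """Noiseless model fluorescence F(T)."""
    t = np.asarray(t, dtype=float)
    bf, bu = params._folded(t), params._unfolded(t)
    frac = 1.0 / (1.0 + np.exp(np.clip((params.tm - t) / params.width, -500, 500)))
    return bf + (bu - bf) * frac


def gen_melt_curve(
    params: MeltModelParams,
    config: SimConfig,
    well_id: str = "A1",
    lbd_id: str = "sim",
    ligand_id: str = "reference",
    replicate: int = 1,
) -> MeltCurve:
    """One synthetic melt curve on ``config.grid`` with Gaussian noise.

    Refuses grids that do not span the transition (tm ± 3 widths): a fit on
    such a curve would be unconstrained, not merely noisy.
    """
    if config.grid is None:
        raise ValueError("SimConfig.grid (temperatures, °C) is required")
    t = config.grid
    if t[0] > params.tm - 3 * params.width or t[-1] < params.tm + 3 * params.width:
        raise ValueError(
            f"grid [{t[0]}, {t[-1]}] °C does not cover the transition "
            f"tm={params.tm} ± 3×width={3 * params.width}"
        )
    f = boltzmann_melt(t, params) + config.rng().normal(0.0, config.noise_sd, size=t.size)
    return MeltCurve(
        temperature=t.copy(), fluorescence=f,
        well_id=well_id, lbd_id=lbd_id, ligand_id=ligand_id, replicate=replicate,
        meta={"true_tm": params.tm, "true_width": params.width},
    )


def gen_shift_experiment(
    tm_ref: float,
    shifts: dict[str, float],
    config: SimConfig,
    lbd_id: str = "sim",
    width: float = 1.0,
) -> list[MeltCurve]:
    """Reference + ligand melt curves with planted ΔTm per ligand, replicated.

    Generates ``config.replicate_count`` reference curves and, for every
    ligand in ``shifts``, replicate curves whose true Tm is
    ``tm_ref + shift``.  Seeds derive deterministically from ``config.seed``.
    """
    curves = []
    conditions = [("reference", 0.0)] + sorted(shifts.items())
    for ci, (ligand, shift) in enumerate(conditions):
        for rep in range(1, config.replicate_count + 1):
            sub = SimConfig(
                seed=(config.seed * 1009 + ci * 101 + rep) % (2**31),
                noise_sd=config.noise_sd, grid=config.grid,
            )
            params = MeltModelParams(tm=tm_ref + shift, width=width)
            curves.append(
                gen_melt_curve(params, sub, well_id=f"{ligand}-{rep}",
                               lbd_id=lbd_id, ligand_id=ligand, replicate=rep)
            )
    return curves


def gen_itc_titration(
    kd_M: float,
    dh_cal_per_mol: float,
    n: float,
    cell_conc_M: float,
    syringe_conc_M: float,
    schedule_uL: Sequence[float],
    cell_volume_uL: float,
    config: SimConfig,
) -> ITCTitration:
    """One-site synthetic titration: model heats plus Gaussian noise (µcal).

    Flags ``low_saturation_warning`` in metadata when the schedule never
    brings the molar ratio past 10% of the stoichiometric point — such a fit
    is ill-conditioned by design, not by accident.
    """
    q = itcfit.simulate_heats(
        n, kd_M, dh_cal_per_mol, cell_conc_M, syringe_conc_M, schedule_uL, cell_volume_uL
    )
    q = q + config.rng().normal(0.0, config.noise_sd, size=q.size)
    dv = np.asarray(schedule_uL, dtype=float)
    v_cum = float(np.sum(dv))
    x_over_nm = (syringe_conc_M * v_cum / cell_volume_uL) / (n * cell_conc_M)
    meta = {
        "true_kd_M": kd_M, "true_dh_cal_per_mol": dh_cal_per_mol, "true_n": n,
        "low_saturation_warning": bool(x_over_nm < 0.1),
    }
    return ITCTitration(
        cell_volume_uL=cell_volume_uL, cell_conc_M=cell_conc_M,
        syringe_conc_M=syringe_conc_M, injection_volumes_uL=dv, heats_ucal=q,
        meta=meta,
    )


def gen_motif_sequences(
    family: str,
    specificity: str,
    count: int,
    background_mut_rate: float,
    config: SimConfig,
    library: seqscan.MotifLibrary | None = None,
) -> tuple[list[seqscan.SensorDomainRecord], pd.DataFrame]:
    """Sequences with a family's pocket residues planted for one specificity.

    Starts from the packaged reference of the motif carrying the requested
    specificity (sub-specificity, determinant-rule label, or ligand class),
    plants the determinant residue when the specificity is determinant-
    resolved, and mutates every non-motif position independently at
    ``background_mut_rate``.  Truth labels are returned alongside.
    """
    library = library or seqscan.load_default_library()
    motifs = library.family_motifs(family)
    if not motifs:
        raise ValueError(f"unknown family {family!r}; known: {sorted(library.families())}")

    target = None
    determinant_plant: dict[int, str] = {}
    for m in motifs:
        if specificity in (m.sub_specificity, m.ligand_class):
            target = m
            break
        for pos, rules in m.determinant_rules.items():
            for residue, label in rules.items():
                if label == specificity:
                    target = m
                    determinant_plant[pos] = residue
        if target is not None:
            break
    if target is None:
        raise ValueError(
            f"unknown specificity {specificity!r} for family {family!r}; "
            f"valid options: {sorted(library.specificities(family))}"
        )

    base = list(library.references[target.reference_id])
    for pos, residue in determinant_plant.items():
        base[pos - 1] = residue
    protected = {
        p.pos for m in motifs if m.reference_id == target.reference_id for p in m.positions
    }
    rng = config.rng()
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    tag = specificity.replace(" ", "_").replace("-", "_")

    records, truth_rows = [], []
    for i in range(count):
        seq = base.copy()
        for j in range(len(seq)):
            if (j + 1) in protected:
                continue
            if rng.random() < background_mut_rate:
                choices = aa[aa != seq[j]]
                seq[j] = str(rng.choice(choices))
        lbd_id = f"{family}_{tag}_{i:03d}"
        records.append(seqscan.SensorDomainRecord(
            lbd_id=lbd_id, sequence="".join(seq), domain_family=family,
        ))
        truth_rows.append({
            "lbd_id": lbd_id, "family": family, "specificity": specificity,
            "ligand_class": target.ligand_class, "module": target.module,
        })
    truth = pd.DataFrame(truth_rows,
                         columns=["lbd_id", "family", "specificity", "ligand_class", "module"])
    return records, truth


def gen_growth_curve(
    lag_h: float,
    mumax_per_h: float,
    od0: float,
    capacity: float,
    config: SimConfig,
    strain: str = "sim",
    condition: str = "none",
    replicate: int = 1,
) -> GrowthCurve:
    """Three-phase growth: constant at ``od0`` until the lag ends, then
    logistic growth at per-capita rate ``mumax·(1 − OD/capacity)``.

    ``capacity=inf`` gives a pure exponential.  The per-capita rate of the
    noiseless model is maximal the instant the lag ends, so the recorded
    truth is ``t(μmax) = max(lag, grid start)``.
    """
    if not (0 < od0 < capacity):
        raise ValueError("need 0 < od0 < capacity")
    if mumax_per_h <= 0:
        raise ValueError("mumax must be positive")
    if config.grid is None:
        raise ValueError("SimConfig.grid (hours) is required")
    t = config.grid
    if t[-1] <= lag_h:
        raise ValueError(f"grid ends at {t[-1]} h, before the lag ({lag_h} h) ends")
    dt = np.clip(t - lag_h, 0.0, None)
    if np.isinf(capacity):
        od = od0 * np.exp(mumax_per_h * dt)
    else:
        a = (capacity - od0) / od0
        od = capacity / (1.0 + a * np.exp(-mumax_per_h * dt))
    od = od + config.rng().normal(0.0, config.noise_sd, size=t.size)
    true_t = float(max(lag_h, t[0]))
    return GrowthCurve(
        time_h=t.copy(), od=od, strain=strain, condition=condition, replicate=replicate,
        meta={"true_t_mumax": true_t, "true_mumax": mumax_per_h, "true_lag_h": lag_h},
    )


# ---------------------------------------------------------------------------
# Writers matching the analysis modules' input dialects
# ---------------------------------------------------------------------------

def write_melt_csv(curves: Sequence[MeltCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "well": c.well_id, "lbd_id": c.lbd_id, "ligand_id": c.ligand_id,
            "replicate": c.replicate, "temperature_C": c.temperature,
            "fluorescence": c.fluorescence,
        }))
    pd.concat(frames, ignore_index=True)[CURVE_COLUMNS].to_csv(path, index=False)


def write_growth_csv(curves: Sequence[GrowthCurve], path: str | Path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "time_h": c.time_h, "od": c.od, "strain": c.strain,
            "condition": c.condition, "replicate": c.replicate,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_sequences(
    records: Sequence[seqscan.SensorDomainRecord],
    truth: pd.DataFrame,
    fasta_path: str | Path,
    truth_path: str | Path,
) -> None:
    """FASTA plus a sidecar TSV of truth labels."""
    with open(fasta_path, "w") as fh:
        for r in records:
            fh.write(f">{r.lbd_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
    truth.to_csv(truth_path, sep="\t", index=False)
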