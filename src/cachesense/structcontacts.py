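"""Ligand-coordination geometry: hydrogen bonds, water bridges, π-stacking.

Works on experimental structure files (PDB or mmCIF) containing a protein
and small-molecule ligands (e.g. uracil, het code URA, and acetate, ACT).
Hydrogen bonds are distance-only contacts between polar heavy atoms (N, O)
within a cutoff (default 3.5 Å) — the convention used when reporting
donor–acceptor distances without modelled hydrogens.  Water-mediated links
are waters bonded to both ligand and protein under the same cutoff.
π-stacking is reported as the ring-centroid distance between the ligand ring
and aromatic side chains (F, W, Y, H) within a centroid cutoff (default
4.5 Å); for tryptophan both rings are measured and the nearer reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "StructureModel",
    "LigandSite",
    "ContactReport",
    "load_structure",
    "find_ligand_sites",
    "hydrogen_bonds",
    "pi_stacking",
    "contact_report",
    "report_to_tsv",
]

HBOND_DMAX_A = 3.5
STACK_DMAX_A = 4.5
ENVIRONMENT_RADIUS_A = 6.0
POLAR_ELEMENTS = {"N", "O"}

#: Ring-atom templates. Ligand het codes map to one ring; aromatic residues
#: map to one or (TRP) two rings.
LIGAND_RING_ATOMS: dict[str, list[str]] = {
    "URA": ["N1", "C2", "N3", "C4", "C5", "C6"],
}
RESIDUE_RING_ATOMS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
    "TRP": [["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"],
            ["CG", "CD1", "NE1", "CE2", "CD2"]],
}
WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class Atom:
    chain: str
    resnum: int
    resname: str
    name: str
    element: str
    xyz: tuple[float, float, float]
    is_hetero: bool
    occupancy: float = 1.0

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.xyz)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_NAMES

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)

    def label(self) -> str:
        return f"{self.resname}{self.resnum}.{self.name}"


@dataclass
class StructureModel:
    atoms: list[Atom]
    source: str = ""
    resolution_A: float | None = None

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key(), []).append(a)
        return out


@dataclass
class LigandSite:
    ligand_key: tuple[str, int, str]
    ligand_atoms: list[Atom]
    environment: list[Atom]
    module: str | None = None


@dataclass
class ContactReport:
    site: str
    hbonds: list[dict] = field(default_factory=list)
    waters: list[dict] = field(default_factory=list)
    stacks: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def load_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Load a PDB or mmCIF file into a flat atom list.

    Format is inferred from the extension unless given as ``"pdb"`` or
    ``"cif"``.  Keeps the first model of multi-model files, altloc '' or
    'A' only, and all waters.
    """
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"structure file missing or empty: {path}")
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "cif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise ValueError(f"unknown structure format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    return from_gemmi(st, source=str(path))


def from_gemmi(st: gemmi.Structure, source: str = "") -> StructureModel:
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                if at.altloc not in ("", "\x00", "A"):
                    continue
                atoms.append(Atom(
                    chain=chain.name, resnum=res.seqid.num, resname=res.name,
                    name=at.name, element=at.element.name.upper(),
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    is_hetero=het, occupancy=at.occ,
                ))
    if not atoms:
        raise ValueError(f"no atoms parsed from {source or 'structure'}")
    if not all(np.isfinite(a.pos).all() for a in atoms):
        raise ValueError("non-finite coordinates in structure")
    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    return StructureModel(atoms=atoms, source=source, resolution_A=resolution)


def find_ligand_sites(
    model: StructureModel,
    ligand_names: Iterable[str],
    environment_radius: float = ENVIRONMENT_RADIUS_A,
    module_bounds: Sequence[tuple[str, int, int, str]] | None = None,
) -> list[LigandSite]:
    """One site per het residue matching a 3-letter code in ``ligand_names``.

    The environment holds all protein and water atoms within
    ``environment_radius`` of any ligand atom.  When ``module_bounds``
    (chain, first, last, label) rows are supplied, each site is labelled by
    the range containing the plurality of its protein environment residues.
    """
    names = {n.upper() for n in ligand_names}
    sites = []
    residues = model.residues()
    for key, ligand_atoms in residues.items():
        if key[2].upper() not in names:
            continue
        lig_xyz = np.array([a.xyz for a in ligand_atoms])
        environment = []
        for a in model.atoms:
            if a.residue_key() == key:
                continue
            if a.resname.upper() in names and a.is_hetero and not a.is_water:
                continue  # other ligand copies are not pocket environment
            d = np.min(np.linalg.norm(lig_xyz - a.pos, axis=1))
            if d <= environment_radius:
                environment.append(a)
        module = None
        if module_bounds:
            votes: dict[str, int] = {}
            for resk in {a.residue_key() for a in environment if not a.is_water}:
                for chain, first, last, label in module_bounds:
                    if resk[0] == chain and first <= resk[1] <= last:
                        votes[label] = votes.get(label, 0) + 1
            if votes:
                module = max(votes, key=lambda k: votes[k])
        sites.append(LigandSite(ligand_key=key, ligand_atoms=ligand_atoms,
                                environment=environment, module=module))
    sites.sort(key=lambda s: s.ligand_key)
    return sites


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.pos - b.pos))


def hydrogen_bonds(site: LigandSite, dmax: float = HBOND_DMAX_A) -> tuple[list[dict], list[dict]]:
    """Direct and water-mediated hydrogen bonds at a ligand site.

    Returns ``(direct, water_mediated)``.  Direct bonds pair a ligand polar
    heavy atom with a protein polar heavy atom at ≤ ``dmax``.  A water
    mediates when its oxygen is within ``dmax`` of both a ligand polar atom
    and a protein polar atom; each such water yields one entry per partner
    link, including the water–ligand leg.
    """
    lig_polar = [a for a in site.ligand_atoms if a.element in POLAR_ELEMENTS]
    prot_polar = [a for a in site.environment
                  if a.element in POLAR_ELEMENTS and not a.is_water]
    waters = [a for a in site.environment if a.is_water and a.element == "O"]

    direct = []
    for la in lig_polar:
        for pa in prot_polar:
            d = _dist(la, pa)
            if d <= dmax:
                direct.append({
                    "partner": pa.label(), "partner_resnum": pa.resnum,
                    "partner_resname": pa.resname,
                    "ligand_atom": la.name, "distance_A": round(d, 3),
                })
    mediated = []
    for w in waters:
        lig_links = [(la, _dist(la, w)) for la in lig_polar if _dist(la, w) <= dmax]
        prot_links = [(pa, _dist(pa, w)) for pa in prot_polar if _dist(pa, w) <= dmax]
        if not lig_links or not prot_links:
            continue
        for la, d in lig_links:
            mediated.append({"water": w.label(), "partner": f"ligand.{la.name}",
                             "partner_resnum": w.resnum, "distance_A": round(d, 3)})
        for pa, d in prot_links:
            mediated.append({"water": w.label(), "partner": pa.label(),
                             "partner_resnum": pa.resnum, "distance_A": round(d, 3)})
    direct.sort(key=lambda h: (h["partner_resnum"], h["partner"], h["ligand_atom"]))
    return direct, mediated


def _ring_centroid(atoms: list[Atom], names: list[str]) -> np.ndarray | None:
    by_name = {a.name: a for a in atoms}
    if not all(n in by_name for n in names):
        return None
    return np.mean([by_name[n].pos for n in names], axis=0)


def pi_stacking(
    site: LigandSite,
    model: StructureModel,
    centroid_max: float = STACK_DMAX_A,
) -> list[dict]:
    """Aromatic residues whose ring centroid is near the ligand ring centroid.

    The ligand must have a packaged ring template (see
    :data:`LIGAND_RING_ATOMS`); ligands without one (e.g. acetate) return an
    empty list.  Residues with incomplete ring atoms are skipped.
    """
    template = LIGAND_RING_ATOMS.get(site.ligand_key[2].upper())
    if template is None:
        return []
    lig_centroid = _ring_centroid(site.ligand_atoms, template)
    if lig_centroid is None:
        return []
    residues = model.residues()
    env_res = {a.residue_key() for a in site.environment if not a.is_water}
    stacks = []
    for key in sorted(env_res):
        rings = RESIDUE_RING_ATOMS.get(key[2])
        if rings is None:
            continue
        dists = []
        for ring in rings:
            c = _ring_centroid(residues[key], ring)
            if c is not None:
                dists.append(float(np.linalg.norm(c - lig_centroid)))
        if dists and min(dists) <= centroid_max:
            stacks.append({
                "residue": f"{key[2]}{key[1]}", "resnum": key[1],
                "centroid_distance_A": round(min(dists), 3),
            })
    stacks.sort(key=lambda s: s["resnum"])
    return stacks


def contact_report(
    site: LigandSite,
    model: StructureModel,
    hbond_dmax: float = HBOND_DMAX_A,
    stack_dmax: float = STACK_DMAX_A,
) -> ContactReport:
    direct, mediated = hydrogen_bonds(site, dmax=hbond_dmax)
    stacks = pi_stacking(site, model, centroid_max=stack_dmax)
    name = f"{site.ligand_key[2]}{site.ligand_key[1]}"
    if site.module:
        name += f"({site.module})"
    return ContactReport(site=name, hbonds=direct, waters=mediated, stacks=stacks)


def report_to_tsv(reports: Sequence[ContactReport], path: str | Path) -> None:
    rows = []
    for r in reports:
        for h in r.hbonds:
            rows.append({"site": r.site, "partner": h["partner"], "type": "hbond",
                         "distance_A": h["distance_A"]})
        for w in r.waters:
            rows.append({"site": r.site, "partner": f"{w['water']}~{w['partner']}",
                         "type": "water_mediated", "distance_A": w["distance_A"]})
        for s in r.stacks:
            rows.append({"site": r.site, "partner": s["residue"], "type": "pi_stack",
                         "distance_A": s["centroid_distance_A"]})
    pd.DataFrame(rows, columns=["site", "partner", "type", "distance_A"]).to_csv(
        path, sep="\t", index=False
    )
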