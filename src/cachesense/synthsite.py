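"""Synthetic stand-in structure for the A4 sensory-domain ligand sites.

This module builds, from scratch, a minimal *synthetic* structure that
realises the published coordination geometry of the bimodular dCache
uracil/SCFA sensor: a uracil molecule hydrogen-bonded to R116/T145/N178/N180
at 2.9 Å, a water in tetrahedral coordination bridging uracil (2.8 Å) with
Y176 (3.1 Å), N178 (2.9 Å) and D205 (2.7 Å), π-stacking rings of F129 and
W160 at centroid distances 3.8 Å and 3.6 Å, and an acetate coordinated by
Y225 (2.6 Å), H238 (2.7 Å), Y273 (2.5 Å) and K280 (2.9 Å) in the proximal
module.  The header carries the deposited entry's published resolution
(1.46 Å) so resolution parsing is exercised.

It is NOT the deposited experimental structure (PDB 9HVJ): only the atoms
relevant to contact geometry are present, and their coordinates are
constructed, not measured.  It exists so the contact-geometry pipeline can
be exercised end-to-end without a structure download; point the same
functions at the real deposited file to analyse the experimental entry.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "build_synthetic_a4_site",
    "write_synthetic_a4_site",
    "A4_MODULE_BOUNDS",
]

#: (chain, first residue, last residue, label) — membrane-distal module
#: residues 57–206, membrane-proximal module residues 35–56 and 207–303.
A4_MODULE_BOUNDS = [
    ("A", 57, 206, "distal"),
    ("A", 35, 56, "proximal"),
    ("A", 207, 303, "proximal"),
]

_RING_R = 1.38  # aromatic ring radius, Å


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _hexagon(center, radius=_RING_R, z=0.0, phase_deg=0.0) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        ang = np.deg2rad(phase_deg + 60.0 * k)
        pts.append(np.asarray(center) + np.array(
            [radius * np.cos(ang), radius * np.sin(ang), z]))
    return pts


def _coordinates() -> dict:
    """All atom coordinates, keyed (resname, resnum, atom name)."""
    coords: dict[tuple[str, int, str], np.ndarray] = {}

    # --- uracil ring in the z=0 plane, centroid at the origin ---
    angles = {"N1": 90, "C2": 150, "N3": 210, "C4": 270, "C5": 330, "C6": 30}
    for name, ang in angles.items():
        a = np.deg2rad(ang)
        coords[("URA", 401, name)] = _RING_R * np.array([np.cos(a), np.sin(a), 0.0])
    # exocyclic carbonyl oxygens, radial
    for cname, oname in (("C2", "O2"), ("C4", "O4")):
        c = coords[("URA", 401, cname)]
        coords[("URA", 401, oname)] = c + 1.22 * _unit(c)

    o2 = coords[("URA", 401, "O2")]
    o4 = coords[("URA", 401, "O4")]
    n1 = coords[("URA", 401, "N1")]
    n3 = coords[("URA", 401, "N3")]

    # --- direct hydrogen-bond donors at 2.9 Å ---
    coords[("ARG", 116, "NH1")] = o2 + 2.9 * _unit(o2)
    coords[("THR", 145, "OG1")] = n3 + 2.9 * _unit(n3)
    coords[("ASN", 178, "ND2")] = o4 + 2.9 * _unit([0.0, -np.cos(np.deg2rad(40)),
                                                    -np.sin(np.deg2rad(40))])
    coords[("ASN", 180, "ND2")] = n1 + 2.9 * _unit(n1)

    # --- bridging water: tetrahedral links 2.8 (uracil O4) / 3.1 / 2.9 / 2.7 ---
    water = o4 + 2.8 * _unit([0.33, -0.18, 0.926])
    coords[("HOH", 501, "O")] = water
    coords[("TYR", 176, "OH")] = water + 3.1 * _unit([0.75, 0.10, 0.65])
    coords[("ASN", 178, "OD1")] = water + 2.9 * _unit([-0.30, -0.60, 0.74])
    coords[("ASP", 205, "OD1")] = water + 2.7 * _unit([0.20, -0.90, 0.39])

    # --- stacking rings: centroids at 3.8 Å (F129) and 3.6 Å (W160) ---
    phe_names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    for name, p in zip(phe_names, _hexagon([0, 0, 0], z=3.8, phase_deg=15)):
        coords[("PHE", 129, name)] = p
    trp6_names = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
    trp6 = _hexagon([0, 0, 0], z=-3.6, phase_deg=0)
    for name, p in zip(trp6_names, trp6):
        coords[("TRP", 160, name)] = p
    # fused five-membered ring beyond the CD2–CE2 edge, same plane
    edge_mid = (trp6[0] + trp6[1]) / 2.0
    out = _unit(edge_mid - np.array([0, 0, -3.6]))
    five_centroid = edge_mid + 1.14 * out
    perp = _unit(np.cross(out, [0, 0, 1.0]))
    coords[("TRP", 160, "CG")] = five_centroid + 1.2 * (-perp) + 0.35 * out
    coords[("TRP", 160, "CD1")] = five_centroid + 1.2 * out
    coords[("TRP", 160, "NE1")] = five_centroid + 1.2 * perp + 0.35 * out

    # --- acetate site in the proximal module, 30 Å away ---
    base = np.array([30.0, 0.0, 0.0])
    coords[("ACT", 402, "CH3")] = base + [-1.0, 0.0, 0.0]
    coords[("ACT", 402, "C")] = base + [0.5, 0.0, 0.0]
    act_o = base + [1.2, 0.75, 0.0]
    act_oxt = base + [1.2, -0.75, 0.0]
    coords[("ACT", 402, "O")] = act_o
    coords[("ACT", 402, "OXT")] = act_oxt
    coords[("TYR", 225, "OH")] = act_o + 2.6 * _unit([0.5, 0.866, 0.0])
    coords[("HIS", 238, "NE2")] = act_oxt + 2.7 * _unit([0.5, -0.866, 0.0])
    coords[("TYR", 273, "OH")] = act_o + 2.5 * _unit([0.0, 0.65, 0.76])
    coords[("LYS", 280, "NZ")] = act_oxt + 2.9 * _unit([0.0, -0.55, -0.835])
    return coords


_HET_RESNAMES = {"URA", "ACT", "HOH"}


def build_synthetic_a4_site() -> gemmi.Structure:
    """Assemble the synthetic site model as a gemmi Structure (chain A)."""
    coords = _coordinates()
    st = gemmi.Structure()
    st.name = "synthetic dCache uracil/SCFA site stand-in"
    st.resolution = 1.46
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    by_residue: dict[tuple[str, int], list[tuple[str, np.ndarray]]] = {}
    for (resname, resnum, atom), xyz in coords.items():
        by_residue.setdefault((resname, resnum), []).append((atom, xyz))
    for (resname, resnum) in sorted(by_residue, key=lambda k: (k[1], k[0])):
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resnum, " ")
        res.het_flag = "H" if resname in _HET_RESNAMES else "A"
        for atom_name, xyz in sorted(by_residue[(resname, resnum)]):
            at = gemmi.Atom()
            at.name = atom_name
            at.element = gemmi.Element(atom_name[0])
            at.pos = gemmi.Position(*xyz)
            at.occ = 1.0
            at.b_iso = 15.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_synthetic_a4_site(path: str | Path, fmt: str | None = None) -> Path:
    """Write the synthetic site to ``path`` as PDB or mmCIF (by extension)."""
    path = Path(path)
    st = build_synthetic_a4_site()
    if fmt is None:
        fmt = "cif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if fmt == "cif":
        doc = st.make_mmcif_document()
        block = doc.sole_block()
        block.set_pair("_refine.entry_id", "SYNT")
        block.set_pair("_refine.pdbx_refine_id", "'X-RAY DIFFRACTION'")
        block.set_pair("_refine.ls_d_res_high", f"{st.resolution:.2f}")
        path.write_text(doc.as_string())
    else:
        path.write_text(st.make_pdb_string())
    return path
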