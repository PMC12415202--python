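"""Alignment-based ligand-specificity classification of Cache sensory domains.

Cache-superfamily ligand-binding domains recognise their ligands through a
small set of binding-pocket residues whose identities track ligand class:
sCache_2 domains bind short-chain carboxylic acids through a conserved
aromatic box (Y101/W103/Y153/K166 in K1 numbering) with the residue at
position 114 acting as the specificity determinant (Leu → L-lactate,
His → pyruvate); dCache_1 domains carry a membrane-distal pocket whose motif
distinguishes uracil (R116/T145/N178/N180 plus the shared aromatics
F129/W160/Y176/D205, A4 numbering), amines, amino acids and purines, and a
membrane-proximal pocket (Y225/H238/Y273/K280) that binds SCFAs.

The classifier operationalises "prediction by sequence alignment" as:
align the query to packaged family references (BLOSUM62, affine gaps),
map the motif's reference-numbered pocket positions onto the query, and
call a ligand class when every required position carries an allowed residue,
with determinant rules resolving sub-specificity.  Each bimodular (dCache)
query can receive two independent calls, one per module.

The packaged references are synthetic scaffolds carrying the documented
pocket residues at the documented numbering (full-length reference sequences
are not redistributed); user-supplied references and motif libraries are
accepted everywhere a packaged one is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "GAP",
    "SensorDomainRecord",
    "MotifPosition",
    "SpecificityMotif",
    "AlignmentMap",
    "LigandPrediction",
    "MotifLibrary",
    "load_default_library",
    "align_to_references",
    "extract_pocket_residues",
    "classify_specificity",
    "classify_record",
    "scan_fasta",
]

GAP = "-"
IDENTITY_FLOOR = 0.20
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SensorDomainRecord:
    """One extracytoplasmic sensory domain."""

    lbd_id: str
    sequence: str
    organism: str = ""
    receptor_class: str = ""  # MCP | HK | DGC
    domain_family: str = ""  # dCache_1 | sCache_2 | sCache_3_3 | SMP_2 | 4HB | other

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("*", "")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.lbd_id}: non-amino-acid characters {sorted(bad)}")


@dataclass
class MotifPosition:
    pos: int  # 1-based reference residue number
    allowed: frozenset[str]
    role: str  # required | determinant | accessory


@dataclass
class SpecificityMotif:
    motif_id: str
    family: str
    reference_id: str
    module: str  # distal | proximal | mono
    ligand_class: str
    sub_specificity: str | None
    positions: list[MotifPosition]
    determinant_rules: dict[int, dict[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        nums = [p.pos for p in self.positions]
        if nums != sorted(nums) or len(set(nums)) != len(nums):
            raise ValueError(f"{self.motif_id}: positions must be strictly increasing")
        for pos in self.determinant_rules:
            if pos not in set(nums):
                raise ValueError(f"{self.motif_id}: determinant rule at non-motif position {pos}")

    @property
    def scored_positions(self) -> list[MotifPosition]:
        """Positions counted toward confidence (required + determinant)."""
        return [p for p in self.positions if p.role in ("required", "determinant")]


@dataclass
class AlignmentMap:
    """Query↔reference residue-number correspondences from one pairwise alignment."""

    family: str
    reference_id: str
    score: float
    identity: float
    pairs: dict[int, int]  # reference residue number -> query residue number (1-based)

    def query_residue(self, sequence: str, ref_pos: int) -> str:
        qpos = self.pairs.get(ref_pos)
        return sequence[qpos - 1] if qpos is not None else GAP


@dataclass
class LigandPrediction:
    lbd_id: str
    module: str
    ligand_class: str | None
    sub_specificity: str | None
    confidence: float
    motif_id: str | None
    matched_residues: dict[int, str] = field(default_factory=dict)
    no_call_reason: str | None = None


class MotifLibrary:
    """Packaged (or user-supplied) motif definitions plus reference sequences."""

    def __init__(self, motifs: list[SpecificityMotif], references: dict[str, str],
                 documented: dict[str, list[dict]] | None = None) -> None:
        self.motifs = motifs
        self.references = references
        self.documented = documented or {}
        self.ref_family = {m.reference_id: m.family for m in motifs}
        missing = {m.reference_id for m in motifs} - set(references)
        if missing:
            raise ValueError(f"motifs reference unknown sequences: {sorted(missing)}")

    @classmethod
    def from_files(cls, motifs_json: str | Path, references_fasta: str | Path) -> "MotifLibrary":
        raw = json.loads(Path(motifs_json).read_text())
        motifs = []
        for m in raw["motifs"]:
            motifs.append(
                SpecificityMotif(
                    motif_id=m["motif_id"],
                    family=m["family"],
                    reference_id=m["reference_id"],
                    module=m["module"],
                    ligand_class=m["ligand_class"],
                    sub_specificity=m.get("sub_specificity"),
                    positions=[
                        MotifPosition(p["pos"], frozenset(p["allowed"]), p["role"])
                        for p in m["positions"]
                    ],
                    determinant_rules={
                        int(k): dict(v) for k, v in m.get("determinant_rules", {}).items()
                    },
                    provenance=m.get("provenance", ""),
                )
            )
        refs = {r.id: str(r.seq) for r in SeqIO.parse(str(references_fasta), "fasta")}
        documented = {
            rid: info.get("documented_specificity", [])
            for rid, info in raw.get("references", {}).items()
        }
        return cls(motifs, refs, documented)

    def families(self) -> set[str]:
        return {m.family for m in self.motifs}

    def family_motifs(self, family: str) -> list[SpecificityMotif]:
        return [m for m in self.motifs if m.family == family]

    def specificities(self, family: str) -> set[str]:
        out = set()
        for m in self.family_motifs(family):
            if m.sub_specificity:
                out.add(m.sub_specificity)
            out.add(m.ligand_class)
            for rules in m.determinant_rules.values():
                out.update(rules.values())
        return out


def load_default_library() -> MotifLibrary:
    data = resources.files("cachesense") / "data"
    return MotifLibrary.from_files(data / "motifs.json", data / "references.fasta")


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def _align_pair(query: str, ref: str, family: str, reference_id: str) -> AlignmentMap:
    aln = _aligner().align(query.replace("X", "A"), ref)[0]
    pairs: dict[int, int] = {}
    matches = 0
    for (qs, qe), (rs, re_) in zip(*aln.aligned):
        for off in range(qe - qs):
            qp, rp = qs + off, rs + off
            pairs[rp + 1] = qp + 1
            if query[qp] == ref[rp]:
                matches += 1
    identity = matches / max(min(len(query), len(ref)), 1)
    return AlignmentMap(
        family=family, reference_id=reference_id,
        score=float(aln.score), identity=identity, pairs=pairs,
    )


def align_to_references(
    query: SensorDomainRecord,
    library: MotifLibrary,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[AlignmentMap]:
    """Align a query to every packaged reference, best first.

    Returns an empty list when the best identity (identical aligned pairs
    over the shorter sequence length) falls below ``identity_floor`` —
    the query is then considered outside all covered families.
    """
    if not library.references:
        raise ValueError("empty reference set")
    if len(query.sequence) < 60:
        raise ValueError(f"{query.lbd_id}: query shorter than 60 residues")
    maps = [
        _align_pair(query.sequence, rseq, library.ref_family.get(rid, ""), rid)
        for rid, rseq in library.references.items()
    ]
    maps.sort(key=lambda m: m.score, reverse=True)
    if maps[0].identity < identity_floor:
        return []
    return maps


def extract_pocket_residues(
    amap: AlignmentMap, motif: SpecificityMotif, query_sequence: str
) -> dict[int, str]:
    """Query residue aligned to each motif position (``GAP`` when unaligned)."""
    if motif.reference_id != amap.reference_id:
        raise ValueError(
            f"alignment is to {amap.reference_id}, motif anchored to {motif.reference_id}"
        )
    return {p.pos: amap.query_residue(query_sequence, p.pos) for p in motif.positions}


def _evaluate_motif(
    motif: SpecificityMotif, residues: dict[int, str]
) -> tuple[bool, float, str | None]:
    """(all-required-matched, confidence, resolved sub-specificity)."""
    scored = motif.scored_positions
    matched = sum(1 for p in scored if residues[p.pos] in p.allowed)
    confidence = matched / len(scored) if scored else 0.0
    required_ok = all(
        residues[p.pos] in p.allowed for p in motif.positions if p.role == "required"
    )
    sub = motif.sub_specificity
    for pos, rules in motif.determinant_rules.items():
        sub = rules.get(residues[pos], None)
    return required_ok, confidence, sub


def classify_specificity(
    query: SensorDomainRecord,
    library: MotifLibrary,
    alignments: Sequence[AlignmentMap],
) -> list[LigandPrediction]:
    """Apply every motif of the best-matching family, one call per module.

    A motif matches when all its required positions carry an allowed residue
    in the query; determinant rules then resolve sub-specificity.  Ties
    between matching motifs of the same module break by confidence, then by
    the alignment score of the motif's reference.  Modules without a match
    yield a ``no_call`` prediction naming the reason.
    """
    if not alignments:
        return [LigandPrediction(
            lbd_id=query.lbd_id, module="mono", ligand_class=None, sub_specificity=None,
            confidence=0.0, motif_id=None, no_call_reason="no_family_match",
        )]
    family = alignments[0].family
    by_ref = {a.reference_id: a for a in alignments}
    motifs = library.family_motifs(family)
    if not motifs:
        return [LigandPrediction(
            lbd_id=query.lbd_id, module="mono", ligand_class=None, sub_specificity=None,
            confidence=0.0, motif_id=None, no_call_reason="family_uncovered",
        )]

    predictions: list[LigandPrediction] = []
    for module in sorted({m.module for m in motifs}):
        candidates = []
        for motif in motifs:
            if motif.module != module:
                continue
            amap = by_ref.get(motif.reference_id)
            if amap is None:
                continue
            residues = extract_pocket_residues(amap, motif, query.sequence)
            ok, confidence, sub = _evaluate_motif(motif, residues)
            candidates.append((ok, confidence, amap.score, motif, residues, sub))
        matching = [c for c in candidates if c[0]]
        if matching:
            _, confidence, _, motif, residues, sub = max(matching, key=lambda c: (c[1], c[2]))
            predictions.append(LigandPrediction(
                lbd_id=query.lbd_id, module=module,
                ligand_class=motif.ligand_class, sub_specificity=sub,
                confidence=confidence, motif_id=motif.motif_id,
                matched_residues=residues,
            ))
        else:
            best = max(candidates, key=lambda c: c[1], default=None)
            predictions.append(LigandPrediction(
                lbd_id=query.lbd_id, module=module,
                ligand_class=None, sub_specificity=None,
                confidence=best[1] if best else 0.0,
                motif_id=best[3].motif_id if best else None,
                matched_residues=best[4] if best else {},
                no_call_reason="required_position_mismatch" if best else "no_motif_for_module",
            ))
    return predictions


def classify_record(
    query: SensorDomainRecord,
    library: MotifLibrary | None = None,
    identity_floor: float = IDENTITY_FLOOR,
) -> list[LigandPrediction]:
    """Convenience wrapper: align then classify one record."""
    library = library or load_default_library()
    alignments = align_to_references(query, library, identity_floor=identity_floor)
    return classify_specificity(query, library, alignments)


def scan_fasta(
    fasta_path: str | Path,
    metadata: pd.DataFrame | None = None,
    library: MotifLibrary | None = None,
    identity_floor: float = IDENTITY_FLOOR,
) -> pd.DataFrame:
    """Run align → extract → classify for every record of a FASTA file.

    ``metadata`` may carry lbd_id, organism, receptor_class, domain_family
    columns keyed on lbd_id.  Returns one row per (record, module) call.
    """
    library = library or load_default_library()
    meta_by_id: dict[str, dict] = {}
    if metadata is not None:
        if "lbd_id" not in metadata.columns:
            raise ValueError("metadata table requires an lbd_id column")
        meta_by_id = metadata.set_index("lbd_id").to_dict("index")

    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        try:
            record = SensorDomainRecord(lbd_id=rec.id, sequence=seq,
                                        **{k: str(v) for k, v in meta_by_id.get(rec.id, {}).items()
                                           if k in ("organism", "receptor_class", "domain_family")})
        except ValueError as exc:
            raise ValueError(f"unreadable FASTA record {rec.id!r}: {exc}") from exc
        for pred in classify_record(record, library, identity_floor=identity_floor):
            rows.append({
                "lbd_id": pred.lbd_id,
                "organism": meta_by_id.get(rec.id, {}).get("organism", ""),
                "module": pred.module,
                "ligand_class": pred.ligand_class,
                "sub_specificity": pred.sub_specificity,
                "confidence": pred.confidence,
                "motif_id": pred.motif_id,
                "no_call_reason": pred.no_call_reason,
            })
    columns = ["lbd_id", "organism", "module", "ligand_class", "sub_specificity",
               "confidence", "motif_id", "no_call_reason"]
    return pd.DataFrame(rows, columns=columns)
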