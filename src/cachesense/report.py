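"""Evidence aggregation: receptor-by-ligand specificity matrix and tallies.

Merges experimentally supported ligand assignments (thermal-shift hits,
converged ITC fits) with alignment-based predictions into one evidence
table, then summarises it as headline counts (distinct ligand-binding
domains with assigned ligands, split by receptor class and domain family),
a ligand-class composition, and an organism × ligand-class specificity
matrix in which experimental evidence dominates predicted evidence.

The ligand-class taxonomy groups L-lactate, formate and the other short-chain
fatty/carboxylic acids under "carboxylic acid".  A curated results table of
the main-text-verifiable assignments ships with the package
(``data/curated_results.tsv``); ids not named in the source text are
anonymized and unstated organism attributions are left blank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "EVIDENCE_COLUMNS",
    "LIGAND_CLASS_MAP",
    "LIGAND_CLASS_ORDER",
    "classify_ligand",
    "load_curated_fixture",
    "merge_evidence",
    "tally",
    "build_matrix",
    "SpecificityMatrix",
]

EVIDENCE_COLUMNS = [
    "lbd_id", "organism", "receptor_class", "domain_family",
    "ligand", "ligand_class", "evidence", "source",
]

#: Canonical column order for the specificity matrix.
LIGAND_CLASS_ORDER = [
    "carboxylic acid", "amino acid", "amine", "purine", "pyrimidine", "indole",
]

#: Ligand → class taxonomy (short-chain carboxylic acids are one class).
LIGAND_CLASS_MAP: dict[str, str] = {
    "l-lactate": "carboxylic acid",
    "d-lactate": "carboxylic acid",
    "pyruvate": "carboxylic acid",
    "formate": "carboxylic acid",
    "acetate": "carboxylic acid",
    "propionate": "carboxylic acid",
    "butyrate": "carboxylic acid",
    "succinate": "carboxylic acid",
    "maleate": "carboxylic acid",
    "itaconate": "carboxylic acid",
    "methylmalonate": "carboxylic acid",
    "scfa": "carboxylic acid",
    "uracil": "pyrimidine",
    "uridine": "pyrimidine",
    "5-fluorouracil": "pyrimidine",
    "ethylamine": "amine",
    "methylamine": "amine",
    "epinephrine": "amine",
    "indole": "indole",
    "l-threonine": "amino acid",
    "amino acids": "amino acid",
    "purines": "purine",
    "adenine": "purine",
}


def classify_ligand(ligand: str) -> str:
    """Map a ligand name to its chemical class (falls back to the name itself)."""
    return LIGAND_CLASS_MAP.get(ligand.strip().lower(), ligand.strip().lower())


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    for col in EVIDENCE_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"evidence table missing column {col!r}")
    bad = set(records["evidence"]) - {"experimental", "predicted"}
    if bad:
        raise ValueError(f"invalid values in column 'evidence': {sorted(bad)}")
    return records


def load_curated_fixture() -> pd.DataFrame:
    """The packaged curated assignment table (main-text-verifiable entries)."""
    path = resources.files("cachesense") / "data" / "curated_results.tsv"
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return _validate(df)


def merge_evidence(
    hits: pd.DataFrame | None,
    itc_fits: pd.DataFrame | None,
    predictions: pd.DataFrame | None,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Combine hit calls, ITC fits and scan predictions into evidence records.

    ``hits`` needs lbd_id, ligand_id, is_hit; ``itc_fits`` lbd_id, ligand_id,
    converged; ``predictions`` lbd_id plus ligand_class (and optionally
    sub_specificity); ``metadata`` maps lbd_id to organism, receptor_class
    and domain_family, and must cover every experimental lbd.  One record is
    kept per (lbd, ligand, evidence); experimental supersedes predicted for
    the same (lbd, ligand class), and contradictions are warned about.
    """
    meta = metadata.set_index("lbd_id")
    rows: list[dict] = []

    def meta_for(lbd: str, experimental: bool) -> dict:
        if lbd in meta.index:
            m = meta.loc[lbd]
            return {k: str(m.get(k, "") or "") for k in
                    ("organism", "receptor_class", "domain_family")}
        if experimental:
            raise ValueError(f"experimental lbd_id {lbd!r} absent from metadata")
        return {"organism": "", "receptor_class": "", "domain_family": ""}

    if hits is not None:
        for _, r in hits.iterrows():
            if not bool(r["is_hit"]):
                continue
            rows.append({
                "lbd_id": r["lbd_id"], **meta_for(str(r["lbd_id"]), True),
                "ligand": r["ligand_id"], "ligand_class": classify_ligand(str(r["ligand_id"])),
                "evidence": "experimental", "source": "tsa",
            })
    if itc_fits is not None:
        for _, r in itc_fits.iterrows():
            if not bool(r.get("converged", True)):
                continue
            rows.append({
                "lbd_id": r["lbd_id"], **meta_for(str(r["lbd_id"]), True),
                "ligand": r["ligand_id"], "ligand_class": classify_ligand(str(r["ligand_id"])),
                "evidence": "experimental", "source": "itc",
            })
    if predictions is not None:
        for _, r in predictions.iterrows():
            if not r.get("ligand_class"):
                continue
            ligand = r.get("sub_specificity") or r["ligand_class"]
            rows.append({
                "lbd_id": r["lbd_id"], **meta_for(str(r["lbd_id"]), False),
                "ligand": ligand, "ligand_class": str(r["ligand_class"]),
                "evidence": "predicted", "source": "scan",
            })

    df = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    if df.empty:
        return df
    df = df.drop_duplicates(subset=["lbd_id", "ligand", "evidence", "source"])
    # experimental supersedes predicted within the same (lbd, ligand class)
    exp_pairs = set(map(tuple, df[df.evidence == "experimental"][["lbd_id", "ligand_class"]].values))
    keep = df.apply(
        lambda r: r.evidence == "experimental"
        or (r.lbd_id, r.ligand_class) not in exp_pairs,
        axis=1,
    )
    # a predicted class with no experimental support for an lbd that *has*
    # experimental evidence of a different class is a logged conflict
    exp_lbds = set(df[df.evidence == "experimental"].lbd_id)
    for _, r in df[keep & (df.evidence == "predicted")].iterrows():
        if r.lbd_id in exp_lbds:
            warnings.warn(
                f"{r.lbd_id}: prediction {r.ligand_class!r} not matched by "
                "experimental evidence; keeping experimental records",
                stacklevel=2,
            )
    return df[keep].reset_index(drop=True)


def tally(records: pd.DataFrame) -> dict:
    """Headline counts over an evidence table.

    Distinct LBDs with ≥1 experimental ligand (total, by receptor class, by
    domain family) and the ligand-class composition counted as distinct
    (LBD, class) pairs — a bimodular domain binding uracil and SCFAs counts
    once in the total but in both classes of the composition.
    """
    records = _validate(records)
    exp = records[records.evidence == "experimental"]
    by_class = exp.groupby("receptor_class")["lbd_id"].nunique().to_dict()
    by_family = exp.groupby("domain_family")["lbd_id"].nunique().to_dict()
    composition = (
        exp.drop_duplicates(["lbd_id", "ligand_class"])
        .groupby("ligand_class")["lbd_id"].count().to_dict()
    )
    composition_all = (
        records.drop_duplicates(["lbd_id", "ligand_class"])
        .groupby("ligand_class")["lbd_id"].count().to_dict()
    )
    return {
        "n_lbds_with_experimental_ligand": int(exp["lbd_id"].nunique()),
        "by_receptor_class": {k: int(v) for k, v in sorted(by_class.items())},
        "by_domain_family": {k: int(v) for k, v in sorted(by_family.items())},
        "ligand_class_composition_experimental": {
            k: int(v) for k, v in sorted(composition.items())
        },
        "ligand_class_composition_all": {
            k: int(v) for k, v in sorted(composition_all.items())
        },
    }


@dataclass
class SpecificityMatrix:
    """Organism × ligand-class evidence levels with per-cell contributors."""

    values: pd.DataFrame  # cells: "experimental" | "predicted" | ""
    contributors: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


def build_matrix(records: pd.DataFrame) -> SpecificityMatrix:
    """Pivot evidence records into the specificity matrix.

    Rows are organisms (blank organisms grouped as "(unattributed)"),
    alphabetical; columns follow the canonical ligand-class order with any
    extra classes appended alphabetically.  Within a cell, experimental
    evidence dominates predicted regardless of record order.
    """
    records = _validate(records)
    if records.empty:
        return SpecificityMatrix(values=pd.DataFrame())
    rec = records.copy()
    rec["organism"] = rec["organism"].replace("", "(unattributed)").fillna("(unattributed)")
    organisms = sorted(rec["organism"].unique())
    classes = [c for c in LIGAND_CLASS_ORDER if c in set(rec["ligand_class"])]
    classes += sorted(set(rec["ligand_class"]) - set(LIGAND_CLASS_ORDER))
    values = pd.DataFrame("", index=organisms, columns=classes, dtype=object)
    values.index.name = "organism"
    contributors: dict[tuple[str, str], list[str]] = {}
    for _, r in rec.iterrows():
        key = (r.organism, r.ligand_class)
        contributors.setdefault(key, [])
        if r.lbd_id not in contributors[key]:
            contributors[key].append(r.lbd_id)
        current = values.at[r.organism, r.ligand_class]
        if r.evidence == "experimental" or current == "":
            values.at[r.organism, r.ligand_class] = (
                "experimental" if "experimental" in (current, r.evidence) else r.evidence
            )
    for key in contributors:
        contributors[key].sort()
    return SpecificityMatrix(values=values, contributors=contributors)
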