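"""Motif classification: alignment mapping, determinants, pocket extraction."""

import numpy as np
import pytest

from cachesense import seqscan, synthdata
from cachesense.seqscan import SensorDomainRecord
from cachesense.synthdata import SimConfig


def _record(lbd_id, seq):
    return SensorDomainRecord(lbd_id=lbd_id, sequence=seq)


class TestAlignment:
    def test_self_alignment_identity_one(self, library):
        seq = library.references["K1_sCache_2"]
        maps = seqscan.align_to_references(_record("self", seq), library)
        best = maps[0]
        assert best.reference_id == "K1_sCache_2"
        assert best.identity == pytest.approx(1.0)
        assert all(best.pairs[i] == i for i in best.pairs)

    def test_planted_scache2_beats_dcache_references(self, library):
        records, _ = synthdata.gen_motif_sequences(
            "sCache_2", "L-lactate", 3, 0.05, SimConfig(seed=5), library)
        for rec in records:
            maps = seqscan.align_to_references(rec, library)
            assert maps[0].family == "sCache_2"

    def test_shuffled_sequences_mostly_no_call(self, library):
        rng = np.random.default_rng(17)
        base = list(library.references["A4_dCache_1UR"])
        no_call = 0
        for i in range(100):
            s = base.copy()
            rng.shuffle(s)
            if not seqscan.align_to_references(_record(f"sh{i}", "".join(s)), library):
                no_call += 1
        assert no_call >= 95

    def test_short_query_rejected(self, library):
        with pytest.raises(ValueError, match="60"):
            seqscan.align_to_references(_record("short", "ACDEFGHIKL"), library)

    def test_empty_reference_set_rejected(self, library):
        empty = seqscan.MotifLibrary(motifs=[], references={})
        with pytest.raises(ValueError, match="empty reference"):
            seqscan.align_to_references(
                _record("q", library.references["K1_sCache_2"]), empty)


class TestPocketExtraction:
    def test_scache2_reference_pocket(self, library):
        seq = library.references["K1_sCache_2"]
        amap = seqscan.align_to_references(_record("K1", seq), library)[0]
        motif = next(m for m in library.motifs if m.motif_id == "sCache_2_scca")
        residues = seqscan.extract_pocket_residues(amap, motif, seq)
        assert residues == {101: "Y", 103: "W", 114: "L", 135: "M",
                            153: "Y", 155: "F", 166: "K"}

    def test_a4_reference_distal_pocket(self, library):
        seq = library.references["A4_dCache_1UR"]
        maps = seqscan.align_to_references(_record("A4", seq), library)
        amap = next(m for m in maps if m.reference_id == "A4_dCache_1UR")
        motif = next(m for m in library.motifs if m.motif_id == "dCache_1UR_distal_uracil")
        residues = seqscan.extract_pocket_residues(amap, motif, seq)
        assert residues == {116: "R", 129: "F", 145: "T", 160: "W",
                            176: "Y", 178: "N", 180: "N", 205: "D"}

    def test_deletion_yields_gap_marker(self, library):
        seq = library.references["K1_sCache_2"]
        deleted = seq[:109] + seq[118:]  # removes residues 110-118 incl. position 114
        maps = seqscan.align_to_references(_record("del", deleted), library)
        amap = next(m for m in maps if m.reference_id == "K1_sCache_2")
        motif = next(m for m in library.motifs if m.motif_id == "sCache_2_scca")
        residues = seqscan.extract_pocket_residues(amap, motif, deleted)
        assert residues[114] == seqscan.GAP


class TestClassification:
    def test_all_references_self_classify_with_confidence_one(self, library):
        for rid, seq in library.references.items():
            preds = seqscan.classify_record(_record(rid, seq), library)
            documented = library.documented[rid]
            called = {(p.module, p.ligand_class, p.sub_specificity)
                      for p in preds if p.ligand_class}
            for spec in documented:
                assert (spec["module"], spec["ligand_class"],
                        spec["sub_specificity"]) in called
            assert all(p.confidence == pytest.approx(1.0)
                       for p in preds if p.ligand_class)

    def test_determinant_flip_changes_only_subspecificity(self, library):
        seq = library.references["K1_sCache_2"]
        mutant = seq[:113] + "H" + seq[114:]
        wt = seqscan.classify_record(_record("wt", seq), library)
        mut = seqscan.classify_record(_record("mut", mutant), library)
        assert wt[0].sub_specificity == "L-lactate"
        assert mut[0].sub_specificity == "pyruvate"
        assert wt[0].ligand_class == mut[0].ligand_class == "carboxylic acid"
        assert wt[0].motif_id == mut[0].motif_id

    def test_four_residue_swap_converts_uracil_to_amine(self, library):
        seq = list(library.references["A4_dCache_1UR"])
        for pos, res in {116: "D", 145: "A", 178: "W", 180: "Y"}.items():
            seq[pos - 1] = res
        preds = seqscan.classify_record(_record("swap", "".join(seq)), library)
        distal = next(p for p in preds if p.module == "distal")
        assert distal.ligand_class == "amine"
        assert not any(p.sub_specificity == "uracil" for p in preds)

    def test_proximal_mutations_leave_distal_call_unchanged(self, library):
        seq = list(library.references["A4_dCache_1UR"])
        for pos in (225, 238, 273, 280):
            seq[pos - 1] = "A"
        preds = seqscan.classify_record(_record("proxmut", "".join(seq)), library)
        distal = next(p for p in preds if p.module == "distal")
        proximal = next(p for p in preds if p.module == "proximal")
        assert distal.sub_specificity == "uracil" and distal.confidence == 1.0
        assert proximal.ligand_class is None

    def test_distal_mutations_leave_proximal_call_unchanged(self, library):
        seq = list(library.references["A4_dCache_1UR"])
        for pos in (116, 145, 178, 180):
            seq[pos - 1] = "A"
        preds = seqscan.classify_record(_record("distmut", "".join(seq)), library)
        proximal = next(p for p in preds if p.module == "proximal")
        assert proximal.sub_specificity == "SCFA" and proximal.confidence == 1.0

    def test_padding_invariance(self, library):
        rng = np.random.default_rng(23)
        flank = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTV"), size=30))
        seq = library.references["K1_sCache_2"]
        plain = seqscan.classify_record(_record("p", seq), library)
        padded = seqscan.classify_record(_record("pp", flank + seq + flank), library)
        assert [(p.ligand_class, p.sub_specificity) for p in plain] == \
               [(p.ligand_class, p.sub_specificity) for p in padded]


class TestScanFasta:
    def _write(self, tmp_path, records, truth):
        fasta = tmp_path / "in.faa"
        synthdata.write_sequences(records, truth, fasta, tmp_path / "truth.tsv")
        return fasta

    def test_planted_set_fully_recovered(self, library, tmp_path):
        records, truth = synthdata.gen_motif_sequences(
            "sCache_2", "L-lactate", 10, 0.0, SimConfig(seed=2), library)
        fasta = self._write(tmp_path, records, truth)
        preds = seqscan.scan_fasta(fasta, library=library)
        hits = preds[preds.sub_specificity == "L-lactate"]
        assert set(hits.lbd_id) == set(truth.lbd_id)

    def test_accuracy_non_increasing_with_mutation_rate(self, library, tmp_path):
        accuracies = []
        for rate in (0.0, 0.05, 0.1, 0.2):
            records, truth = synthdata.gen_motif_sequences(
                "dCache_1", "uracil", 25, rate, SimConfig(seed=31), library)
            fasta = self._write(tmp_path, records, truth)
            preds = seqscan.scan_fasta(fasta, library=library)
            ok = set(preds[preds.sub_specificity == "uracil"].lbd_id)
            accuracies.append(len(ok) / len(records))
        assert accuracies[0] == 1.0
        assert all(a >= b - 1e-9 for a, b in zip(accuracies, accuracies[1:]))

    def test_empty_fasta_gives_empty_table(self, library, tmp_path):
        fasta = tmp_path / "empty.faa"
        fasta.write_text("")
        preds = seqscan.scan_fasta(fasta, library=library)
        assert preds.empty
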