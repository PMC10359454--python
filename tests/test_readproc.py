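"""Hairpin reconstruction, methylation calling and context tabulation."""

import numpy as np
import pandas as pd
import pytest

from deepenz import readproc as rp
from deepenz import synthdata as sd
from deepenz._seq import revcomp


class TestReconstructHairpin:
    def test_c_free_pair_is_identity(self):
        rec = rp.reconstruct_hairpin("TGT", "ACA")
        assert rec.original == "TGT"
        assert not rec.ambiguous.any()

    def test_protected_upper_c(self):
        # lower read 5'->3' "TCG": aligned under upper "CGA" it pairs
        # C<->G (protected upper C), G<->C (protected lower C), A<->T
        rec = rp.reconstruct_hairpin("CGA", "TCG")
        assert rec.original == "CGA"
        assert rec.upper_retained[0]
        assert rec.lower_retained[1]

    def test_converted_upper_c(self):
        # upper read T with paired lower G means the original was C
        rec = rp.reconstruct_hairpin("TGA", "TCG")
        assert rec.original == "CGA"
        assert not rec.upper_retained[0]

    def test_contradiction_flags_ambiguous(self):
        rec = rp.reconstruct_hairpin("CAA", "TTA")  # C paired with A
        assert rec.ambiguous[0]
        assert rec.original[0] == "N"

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            rp.reconstruct_hairpin("ACGT", "ACG")

    def test_round_trip_recovers_simulated_molecules(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 2000, seed=1)
        model = sd.TrueRateModel.from_arrays({"HM": np.full(256, 0.7)})
        pool = sd.simulate_kinetics(pool, model, dose=1.0, seed=2)
        reads = sd.emit_reads(pool, conversion=1.0, error_rate=0.0, seed=3)
        seqs = pool.sequences()
        for i in (0, 7, 500, 1999):
            rec = rp.reconstruct_hairpin(reads.read1[i], reads.read2[i])
            assert rec.original == seqs[i]
            assert rec.upper_retained[pool.cpg_pos] == bool(pool.upper_state[i])


class TestCallSite:
    def _recon(self, read1, read2):
        return rp.reconstruct_hairpin(read1, read2)

    def test_hemimethylated_call(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 100, seed=4)
        model = sd.TrueRateModel.from_arrays({"HM": np.full(256, 1000.0)})
        pool = sd.simulate_kinetics(pool, model, dose=1.0, seed=5)
        reads = sd.emit_reads(pool, seed=6)
        rec = self._recon(reads.read1[0], reads.read2[0])
        call = rp.call_site(rec, pool.cpg_pos, flank_len=10,
                            substrate_class="HM", dose=1.0)
        assert call.call_upper == rp.CALL_METHYLATED
        assert call.call_lower == rp.CALL_METHYLATED  # lower 5mC protected
        assert call.nncgnn[2:4] == "CG"
        assert len(call.flank_context) == 22

    def test_unmethylated_both_strands(self):
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 10, seed=7)
        reads = sd.emit_reads(pool, seed=8)
        rec = self._recon(reads.read1[0], reads.read2[0])
        call = rp.call_site(rec, pool.cpg_pos)
        assert call.call_upper == rp.CALL_UNMETHYLATED
        assert call.call_lower == rp.CALL_UNMETHYLATED

    def test_ambiguous_flank_excluded(self):
        # corrupt a base inside the NNCGNN window of an otherwise clean pair
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 1, seed=9)
        reads = sd.emit_reads(pool, seed=10)
        p = pool.cpg_pos
        r1 = list(reads.read1[0])
        r1[p - 2] = {"A": "C", "C": "A", "G": "C", "T": "G"}[r1[p - 2]]
        rec = self._recon("".join(r1), reads.read2[0])
        call = rp.call_site(rec, p)
        assert call.call_upper == rp.CALL_AMBIGUOUS


class TestTabulateContexts:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["substrate_class", "dose", "window", "nncgnn",
                     "call_upper", "call_lower"],
        )

    def test_simple_counts(self):
        win = "A" * 8 + "AACGTT" + "A" * 8
        rows = [("HM", 1.0, win, "AACGTT", 1 if i < 4 else 0, 1) for i in range(10)]
        counts = rp.tabulate_contexts(self._records(rows))
        row = counts.iloc[0]
        assert (row["n_methylated"], row["n_total"]) == (4, 10)

    def test_um_lower_strand_booked_under_revcomp(self):
        win = "A" * 8 + "GACGTA" + "A" * 8
        rows = [("UM", 1.0, win, "GACGTA", 0, 1)]
        counts = rp.tabulate_contexts(self._records(rows))
        by_ctx = counts.set_index("nncgnn")
        assert revcomp("GACGTA") == "TACGTC"
        assert by_ctx.loc["TACGTC", "n_methylated"] == 1
        assert by_ctx.loc["GACGTA", "n_methylated"] == 0
        assert counts["n_total"].sum() == 2  # both strands of one molecule

    def test_totals_conserved_and_order_invariant(self):
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 3000, seed=11)
        records = sd.to_call_records(pool)
        counts = rp.tabulate_contexts(records)
        assert counts["n_total"].sum() == 2 * len(records)  # UM double strand
        shuffled = records.sample(frac=1, random_state=0).reset_index(drop=True)
        counts2 = rp.tabulate_contexts(shuffled)
        key = ["substrate_class", "dose", "nncgnn"]
        pd.testing.assert_frame_equal(
            counts.sort_values(key).reset_index(drop=True),
            counts2.sort_values(key).reset_index(drop=True),
        )

    def test_per_molecule_policy(self):
        win = "A" * 8 + "GACGTA" + "A" * 8
        rows = [("UM", 1.0, win, "GACGTA", 0, 1), ("UM", 1.0, win, "GACGTA", 0, 0)]
        counts = rp.tabulate_contexts(self._records(rows), class_rule="per-molecule")
        assert counts["n_total"].sum() == 2  # one event per molecule
        assert counts["n_methylated"].sum() == 1

    def test_hm_counts_upper_only(self):
        win = "A" * 8 + "GACGTA" + "A" * 8
        rows = [("HM", 1.0, win, "GACGTA", 0, 1)] * 5
        counts = rp.tabulate_contexts(self._records(rows))
        assert counts["n_total"].sum() == 5
        assert counts["n_methylated"].sum() == 0


class TestProcessReadPairs:
    def test_unknown_barcode_goes_to_unassigned(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 20, seed=12)
        reads = sd.emit_reads(pool, seed=13)
        barcodes = {"XX": "TTTTTT"}  # matches nothing
        records, qc = rp.process_read_pairs(
            reads.read1, reads.read2, barcodes, cpg_pos=pool.cpg_pos,
            flank_len=10, dose=1.0, expected_len=67,
        )
        assert qc.unassigned == 20
        assert qc.assigned == 0
        assert records.empty

    def test_size_filter_counts_discards(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 10, seed=14)
        reads = sd.emit_reads(pool, seed=15)
        r1 = reads.read1[:]
        r1[0] = r1[0][:30]  # truncated read
        _records, qc = rp.process_read_pairs(
            r1, reads.read2, {"HM": sd.DEFAULT_BARCODES["HM"]},
            cpg_pos=pool.cpg_pos, flank_len=10, dose=1.0, expected_len=67,
        )
        assert qc.discarded_size == 1
        assert qc.assigned == 9

    def test_one_mismatch_demultiplexing(self):
        bc = sd.DEFAULT_BARCODES["HM"]
        read = "A" + bc[1:] + "T" * 20
        exact = rp.demultiplex([read], {"HM": bc}, max_mismatch=0)
        fuzzy = rp.demultiplex([read], {"HM": bc}, max_mismatch=1)
        assert exact["unassigned"].size == 1
        assert fuzzy["HM"].size == 1

    def test_ambiguity_grows_with_error_rate(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 4000, seed=16)
        fractions = []
        for err in (0.0, 0.01, 0.05):
            reads = sd.emit_reads(pool, error_rate=err, seed=17)
            records, qc = rp.process_read_pairs(
                reads.read1, reads.read2, {"HM": sd.DEFAULT_BARCODES["HM"]},
                cpg_pos=pool.cpg_pos, flank_len=10, dose=1.0, expected_len=67,
                max_mismatch=1,
            )
            total = max(qc.assigned, 1)
            fractions.append(qc.ambiguous / total)
        assert fractions[0] == 0.0
        assert fractions[0] < fractions[1] < fractions[2]


class TestBackground:
    def test_exact_fractions(self):
        counts = pd.DataFrame(
            {
                "substrate_class": ["HM", "UM"],
                "dose": [0.0, 0.0],
                "nncgnn": ["AACGAA", "AACGAA"],
                "n_methylated": [0, 50],
                "n_total": [10_000, 10_000],
            }
        )
        bg = rp.estimate_background(counts)
        assert bg["HM"] == 0.0
        assert bg["UM"] == pytest.approx(0.005)

    def test_zero_total_reported_missing(self):
        counts = pd.DataFrame(
            {
                "substrate_class": ["HM"],
                "dose": [0.0],
                "nncgnn": ["AACGAA"],
                "n_methylated": [0],
                "n_total": [0],
            }
        )
        assert np.isnan(rp.estimate_background(counts)["HM"])

    def test_incomplete_conversion_background(self):
        # conversion 0.995 on an unenzymed control reads ~0.5% false 5mC
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 10_000, seed=18)
        reads = sd.emit_reads(pool, conversion=0.995, seed=19)
        records, _qc = rp.process_read_pairs(
            reads.read1, reads.read2, {"UM": sd.DEFAULT_BARCODES["UM"]},
            cpg_pos=pool.cpg_pos, flank_len=10, dose=0.0, expected_len=67,
        )
        counts = rp.tabulate_contexts(records)
        bg = rp.estimate_background(counts)["UM"]
        n = counts["n_total"].sum()
        assert abs(bg - 0.005) < 3 * np.sqrt(0.005 * 0.995 / n)


def test_fastq_round_trip(tmp_path):
    pool = sd.generate_pool(sd.SubstrateSpec("OH"), 100, seed=20)
    reads = sd.emit_reads(pool, seed=21)
    path = tmp_path / "r1.fastq"
    sd.write_fastq(path, reads.ids, reads.read1)
    ids, seqs = rp.read_fastq(path)
    assert ids == reads.ids
    assert seqs == reads.read1
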