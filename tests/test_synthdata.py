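"""Substrate pool, kinetics and read-emission simulators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deepenz import synthdata as sd
from deepenz._seq import ALL_NNCGNN, revcomp


class TestGeneratePool:
    def test_single_cpg_and_initial_states(self):
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 1000, seed=1)
        assert len(pool) == 1000
        p, fl = pool.cpg_pos, pool.flank_len
        for seq in pool.sequences():
            win = seq[p - fl : p + fl + 2]
            # every CpG in the randomized window lies inside the NNCGNN core
            starts = [i for i in range(len(win) - 1) if win[i : i + 2] == "CG"]
            assert all(fl - 2 <= s <= fl + 2 for s in starts)
            assert seq[p : p + 2] == "CG"
        assert (pool.lower_state == sd.MOD_C).all()
        assert (pool.upper_state == sd.MOD_C).all()

        hm = sd.generate_pool(sd.SubstrateSpec("HM"), 1, seed=2)
        seq, lower, upper, cls, dose = hm.molecules[0]
        assert (lower, upper, cls) == ("5mC", "C", "HM")

    def test_all_256_contexts_realizable(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 60000, seed=3)
        assert set(pool.contexts) == set(ALL_NNCGNN)

    def test_strict_policy_excludes_double_cpg_contexts(self):
        pool = sd.generate_pool(
            sd.SubstrateSpec("HM"), 20000, seed=3, single_cpg="strict"
        )
        assert all("CG" not in ctx.replace("CG", "xx", 1) for ctx in set(pool.contexts))

    def test_flank_base_frequencies_uniform_without_rejection(self):
        # i.i.d. uniform flanks (N-base synthesis): every base within 1%
        # of 0.25 at every flank position
        pool = sd.generate_pool(
            sd.SubstrateSpec("UM"), 100_000, seed=7, single_cpg="off"
        )
        p, fl = pool.cpg_pos, pool.flank_len
        cols = list(range(p - fl, p)) + list(range(p + 2, p + 2 + fl))
        for b in range(4):
            freqs = (pool.seqs[:, cols] == b).mean(axis=0)
            assert np.abs(freqs - 0.25).max() < 0.01

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="flank_len"):
            sd.SubstrateSpec("HM", flank_len=1)
        with pytest.raises(ValueError, match="CpG"):
            sd.SubstrateSpec("HM", barcode="ACGT")
        with pytest.raises(ValueError, match="total_len"):
            sd.SubstrateSpec("HM", total_len=20)
        with pytest.raises(ValueError):
            sd.generate_pool(sd.SubstrateSpec("HM"), 0, seed=1)


class TestSimulateKinetics:
    def test_zero_dose_methylates_nothing(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 2000, seed=1)
        model = sd.TrueRateModel.from_arrays({"HM": np.full(256, 1.0)})
        out = sd.simulate_kinetics(pool, model, dose=0.0, seed=2)
        assert out.upper_state.sum() == 0

    def test_half_life_dose_gives_half_methylation(self):
        # k*dose = ln 2 at plateau 1 -> expected fraction 0.5 within 3 SE
        n = 10_000
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), n, seed=3)
        model = sd.TrueRateModel.from_arrays({"HM": np.full(256, 0.5)})
        out = sd.simulate_kinetics(pool, model, dose=np.log(2) / 0.5, seed=4)
        frac = out.upper_state.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_zero_rate_context_never_methylated(self):
        rates = np.full(256, 2.0)
        dead = ALL_NNCGNN.index("AACGAA")
        rates[dead] = 0.0
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 30000, seed=5)
        model = sd.TrueRateModel.from_arrays({"HM": rates})
        for dose in (0.5, 10.0):
            out = sd.simulate_kinetics(pool, model, dose, seed=6)
            idx = out.context_idx == dead
            assert idx.sum() > 0
            assert out.upper_state[idx].sum() == 0

    def test_unknown_context_error_names_it(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 10, seed=1)
        model = sd.TrueRateModel({("HM", "AACGAA"): 1.0})
        with pytest.raises(KeyError, match="context [ACGT]{2}CG[ACGT]{2}"):
            sd.simulate_kinetics(pool, model, 1.0)

    def test_um_lower_strand_uses_revcomp_rate(self):
        # lower-strand target of a UM dyad follows the reverse-complement
        # context's rate: zeroing one context's revcomp kills lower events
        rates = np.full(256, 5.0)
        ctx = "GACGTA"
        rates[ALL_NNCGNN.index(revcomp(ctx))] = 0.0
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 40000, seed=8)
        model = sd.TrueRateModel.from_arrays({"UM": rates})
        out = sd.simulate_kinetics(pool, model, dose=1.0, seed=9)
        sel = np.array([c == ctx for c in out.contexts])
        assert sel.sum() > 50
        assert (out.lower_state[sel] == sd.MOD_5MC).sum() == 0
        assert out.upper_state[sel].mean() > 0.9


class TestEmitReads:
    def test_conversion_chemistry_at_cpg(self):
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 50, seed=1)
        reads = sd.emit_reads(pool, conversion=1.0, error_rate=0.0, seed=2)
        L = len(reads.read1[0])
        p = pool.cpg_pos
        for r1, r2 in zip(reads.read1, reads.read2):
            assert r1[p] == "T"  # unmethylated upper C converted
            assert r2[L - 1 - p] == "G"  # paired G untouched
            assert r2[L - 2 - p] == "T"  # unmethylated lower C converted

        hm = sd.generate_pool(sd.SubstrateSpec("HM"), 50, seed=3)
        model = sd.TrueRateModel.from_arrays({"HM": np.full(256, 100.0)})
        hm = sd.simulate_kinetics(hm, model, dose=10.0, seed=4)
        assert hm.upper_state.all()
        reads = sd.emit_reads(hm, conversion=1.0, seed=5)
        for r1, r2 in zip(reads.read1, reads.read2):
            assert r1[p] == "C"  # 5mC protected
            assert r2[L - 2 - p] == "C"  # lower-strand 5mC protected

    def test_partial_conversion_rate(self):
        # at conversion 0.99 about 1% of unmethylated Cs still read C
        pool = sd.generate_pool(sd.SubstrateSpec("UM"), 3000, seed=6)
        reads = sd.emit_reads(pool, conversion=0.99, seed=7)
        n_c = sum(r.count("C") for r in reads.read1)
        n_positions = int((pool.seqs == 1).sum())
        assert n_positions > 10_000
        frac = n_c / n_positions
        se = np.sqrt(0.01 * 0.99 / n_positions)
        assert abs(frac - 0.01) < 3 * se

    def test_determinism_and_conservation(self, tmp_path):
        pool = sd.generate_pool(sd.SubstrateSpec("OH"), 500, seed=8)
        r_a = sd.emit_reads(pool, seed=9)
        r_b = sd.emit_reads(pool, seed=9)
        assert len(r_a) == len(pool)  # one read pair per molecule
        pa, pb = tmp_path / "a.fastq", tmp_path / "b.fastq"
        sd.write_fastq(pa, r_a.ids, r_a.read1)
        sd.write_fastq(pb, r_b.ids, r_b.read1)
        assert pa.read_bytes() == pb.read_bytes()

    def test_amplicon_layout_contains_linker(self):
        pool = sd.generate_pool(sd.SubstrateSpec("HM"), 3, seed=10)
        reads = sd.emit_reads(pool, seed=11)
        amp = reads.amplicons()[0]
        assert sd.DEFAULT_LINKER in amp
        assert amp == reads.read1[0] + sd.DEFAULT_LINKER + reads.read2[0]
        assert "C" not in sd.DEFAULT_LINKER


class TestLongSubstrate:
    def test_default_patterned_substrate(self):
        spec = sd.generate_long_substrate(seed=1)
        assert len(spec.sequence) == 349
        assert len(spec.cpg_sites) == 44
        assert len(spec.hm_sites) == 18
        assert len(spec.um_sites) == 26
        for i in range(44):
            assert spec.sequence[spec.cpg_sites[i] : spec.cpg_sites[i] + 2] == "CG"
            matches = sd.default_pattern_rule(spec.fourmer(i))
            assert matches == (spec.pattern[i] == "5mC")
        # exactly 44 CpGs in total
        assert spec.sequence.count("CG") == 44

    @pytest.mark.parametrize(
        "rule,n_match,expected",
        [(lambda f: False, 0, 0), (lambda f: True, 44, 44)],
        ids=["always-false", "always-true"],
    )
    def test_degenerate_pattern_rules(self, rule, n_match, expected):
        spec = sd.generate_long_substrate(seed=2, pattern_rule=rule, n_match=n_match)
        assert sum(s == "5mC" for s in spec.pattern) == expected

    def test_site_series_simulation(self):
        spec = sd.generate_long_substrate(seed=3)
        k = np.full(44, 10.0)
        series = sd.simulate_long_site_series(spec, k, doses=[10.0], n_reads=200)
        assert (series["fraction"] > 0.99).all()
        series0 = sd.simulate_long_site_series(spec, k, doses=[0.0], n_reads=200)
        assert (series0["n_methylated"] == 0).all()


class TestGenomicTable:
    def test_constant_half_methylation(self):
        spec = sd.SyntheticGenomeSpec(
            n_chroms=1, chrom_len=20000, context_effect=0.5, coverage_mean=50
        )
        genome, cov = sd.simulate_genomic_table(spec, seed=1)
        total = (cov["count_methylated"] + cov["count_unmethylated"]).sum()
        frac = cov["count_methylated"].sum() / total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / total)

    def test_zero_effect_gives_zero_counts(self):
        spec = sd.SyntheticGenomeSpec(n_chroms=1, chrom_len=5000, context_effect=0.0)
        _genome, cov = sd.simulate_genomic_table(spec, seed=2)
        assert (cov["count_methylated"] == 0).all()

    def test_rows_are_upper_strand_cpgs(self):
        spec = sd.SyntheticGenomeSpec(n_chroms=2, chrom_len=4000)
        genome, cov = sd.simulate_genomic_table(spec, seed=3)
        for chrom, sub in cov.groupby("chrom"):
            seq = genome[chrom]
            for pos in sub["start"]:
                assert seq[pos - 1 : pos + 1] == "CG"


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pool_generation_deterministic(seed):
    a = sd.generate_pool(sd.SubstrateSpec("HM"), 50, seed=seed)
    b = sd.generate_pool(sd.SubstrateSpec("HM"), 50, seed=seed)
    assert (a.seqs == b.seqs).all()


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=60))
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq
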