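"""Simulator: reference generation, methylation draws, conversion, errors, IO."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest

import tapscall
from tapscall.sim import (
    SimConfig,
    SimTruth,
    Simulator,
    read_truth_tables,
    simulate,
    write_truth_tables,
)


def cpg_scan(seq: str) -> list[int]:
    return [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ref_length": 100},
            {"n_reads": 0},
            {"gc_fraction": 1.5},
            {"conversion_rate": -0.1},
            {"sub_rate": 2.0},
            {"cpg_enrichment": -1.0},
            {"site_levels": "gamma(1,2)"},
            {"site_levels": [0.5, 1.2]},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestReference:
    def test_deterministic_by_seed(self):
        cfg = SimConfig(ref_length=4000, seed=7)
        seq1, sites1 = Simulator(cfg).generate_reference()
        seq2, sites2 = Simulator(cfg).generate_reference()
        assert seq1 == seq2
        assert np.array_equal(sites1, sites2)

    def test_site_list_matches_sequence_scan(self):
        seq, sites = Simulator(SimConfig(seed=3)).generate_reference()
        assert sites.tolist() == cpg_scan(seq)
        assert set(seq) <= set("ACGT")

    def test_enrichment_scales_density(self):
        base = Simulator(SimConfig(cpg_enrichment=1.0, seed=9)).generate_reference()[1]
        rich = Simulator(SimConfig(cpg_enrichment=3.0, seed=9)).generate_reference()[1]
        assert rich.size > 2 * base.size

    def test_no_cpg_possible_fails(self):
        with pytest.raises(ValueError, match="no CpG"):
            Simulator(SimConfig(gc_fraction=0.0, cpg_enrichment=0.0, seed=1)).generate_reference()


class TestMethylationDraw:
    def test_extreme_levels_are_deterministic(self):
        sim = Simulator(SimConfig(site_levels=1.0, n_reads=20, seed=1))
        truth = sim.draw_methylation([10, 20, 30])
        assert truth.molecule_states.all() and truth.molecule_states_bottom.all()
        sim0 = Simulator(SimConfig(site_levels=0.0, n_reads=20, seed=1))
        truth0 = sim0.draw_methylation([10, 20, 30])
        assert not truth0.molecule_states.any()

    def test_realized_mean_is_binomial_around_level(self):
        # 10,000 molecules at level 0.5: mean within 3*sqrt(0.25/10000)
        sim = Simulator(SimConfig(site_levels=0.5, n_reads=10_000, seed=4))
        truth = sim.draw_methylation([100])
        assert abs(truth.molecule_states.mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_strand_symmetry_flag(self):
        sym = Simulator(SimConfig(site_levels=0.5, n_reads=200, seed=5))
        t = sym.draw_methylation(list(range(0, 100, 2)))
        assert np.array_equal(t.molecule_states, t.molecule_states_bottom)
        asym = Simulator(SimConfig(site_levels=0.5, n_reads=200, seed=5, strand_symmetric_methylation=False))
        ta = asym.draw_methylation(list(range(0, 100, 2)))
        assert not np.array_equal(ta.molecule_states, ta.molecule_states_bottom)

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError):
            Simulator(SimConfig(seed=1)).draw_methylation([])


def _single_site_scene(n_reads: int, seed: int, **over) -> tuple[str, SimTruth, "tapscall.sim.ReadSet"]:
    """Fully methylated single-CpG reference read by full-length reads."""
    seq = "A" * 150 + "CG" + "A" * 148
    cfg = SimConfig(
        n_reads=n_reads,
        site_levels=1.0,
        conversion_rate=1.0,
        false_conversion_rate=0.0,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        read_length_mean=10_000.0,
        read_length_sd=1.0,
        seed=seed,
        **over,
    )
    sim = Simulator(cfg)
    truth = sim.draw_methylation([150])
    reads = sim.convert_and_read("ref", seq, truth)
    return seq, truth, reads


class TestConversion:
    def test_strand_determines_tg_or_ca(self):
        # error-free full conversion: top-strand reads show TG at the site,
        # bottom-strand reads (reference-forward) show CA, never TA
        _, truth, reads = _single_site_scene(40, seed=6)
        strands = dict(zip(truth.read_provenance["read_id"], truth.read_provenance["strand"]))
        seen = set()
        for rec in reads.sam:
            dinuc = rec.query_sequence[150:152]  # 150M-aligned from 0 (full length)
            expected = "TG" if strands[rec.query_name] == "+" else "CA"
            assert dinuc == expected
            seen.add(expected)
        assert seen == {"TG", "CA"}

    def test_fastq_carries_strand_of_origin_sequence(self):
        _, truth, reads = _single_site_scene(20, seed=8)
        strands = dict(zip(truth.read_provenance["read_id"], truth.read_provenance["strand"]))
        fastq = dict(reads.fastq)
        comp = str.maketrans("ACGT", "TGCA")
        for rec in reads.sam:
            fwd = rec.query_sequence
            if strands[rec.query_name] == "+":
                assert fastq[rec.query_name] == fwd
            else:
                assert fastq[rec.query_name] == fwd.translate(comp)[::-1]

    def test_conversion_rate_binomial(self):
        # fully methylated, conversion 0.85: converted fraction within 3 sigma
        seq = ("A" * 10 + "CG" + "A" * 8) * 20  # 20 CpGs in 400 bp... length >= 200
        sites = cpg_scan(seq)
        cfg = SimConfig(
            n_reads=600, site_levels=1.0, conversion_rate=0.85, false_conversion_rate=0.0,
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            read_length_mean=10_000.0, read_length_sd=1.0, seed=12,
        )
        sim = Simulator(cfg)
        truth = sim.draw_methylation(sites)
        reads = sim.convert_and_read("ref", seq, truth)
        converted = total = 0
        strands = dict(zip(truth.read_provenance["read_id"], truth.read_provenance["strand"]))
        for rec in reads.sam:
            for p in sites:
                dinuc = rec.query_sequence[p : p + 2]
                total += 1
                converted += dinuc in ("TG", "CA")
                # a converted call always matches the read's originating strand
                if dinuc == "TG":
                    assert strands[rec.query_name] == "+"
                if dinuc == "CA":
                    assert strands[rec.query_name] == "-"
        assert total >= 10_000
        p_hat, sd = converted / total, np.sqrt(0.85 * 0.15 / total)
        assert abs(p_hat - 0.85) < 3 * sd

    def test_false_conversion_rate_binomial(self):
        seq = ("A" * 10 + "CG" + "A" * 8) * 20
        sites = cpg_scan(seq)
        cfg = SimConfig(
            n_reads=600, site_levels=0.0, conversion_rate=1.0, false_conversion_rate=0.1,
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
            read_length_mean=10_000.0, read_length_sd=1.0, seed=13,
        )
        sim = Simulator(cfg)
        truth = sim.draw_methylation(sites)
        reads = sim.convert_and_read("ref", seq, truth)
        converted = total = 0
        for rec in reads.sam:
            for p in sites:
                total += 1
                converted += rec.query_sequence[p : p + 2] in ("TG", "CA")
        p_hat, sd = converted / total, np.sqrt(0.1 * 0.9 / total)
        assert abs(p_hat - 0.1) < 3 * sd


class TestErrorModel:
    def test_realized_error_rates_match_config(self, noisy_scene):
        config, reference, truth, reads, _ = noisy_scene
        n_ref = n_del = n_ins = n_match_bases = n_sub = 0
        for rec in reads.sam:
            ref_cursor = rec.reference_start
            read_cursor = 0
            for op, length in rec.cigartuples:
                if op == 0:  # M: count substitutions against the converted base
                    for k in range(length):
                        ref_base = reference.sequence[ref_cursor + k]
                        read_base = rec.query_sequence[read_cursor + k]
                        # conversion can legitimately turn C->T / G->A; skip those
                        if not (
                            (ref_base == "C" and read_base == "T")
                            or (ref_base == "G" and read_base == "A")
                        ):
                            n_match_bases += 1
                            n_sub += read_base != ref_base
                    ref_cursor += length
                    read_cursor += length
                    n_ref += length
                elif op == 1:
                    n_ins += length
                    read_cursor += length
                elif op == 2:
                    n_del += length
                    n_ref += length
                    ref_cursor += length
        for rate, count, total in (
            (config.del_rate, n_del, n_ref),
            (config.ins_rate, n_ins, n_ref),
        ):
            sd = np.sqrt(rate * (1 - rate) / total)
            assert abs(count / total - rate) < 4 * sd
        # substitutions measured only at non-convertible bases; sub of C->T is
        # excluded above so the observed rate is slightly under sub_rate
        sub_rate_obs = n_sub / n_match_bases
        assert 0.8 * config.sub_rate < sub_rate_obs <= config.sub_rate * 1.1

    def test_cigar_span_matches_provenance(self, noisy_scene):
        _, _, truth, reads, _ = noisy_scene
        prov = truth.read_provenance.set_index("read_id")
        for rec in reads.sam:
            span = sum(length for op, length in rec.cigartuples if op in (0, 2))
            row = prov.loc[rec.query_name]
            assert rec.reference_start == row["start"]
            assert rec.reference_start + span == row["end"]


class TestOutputs:
    def test_simulate_is_byte_deterministic(self, tmp_path):
        cfg = SimConfig(n_reads=30, seed=44)
        p1 = simulate(cfg, tmp_path / "a")
        p2 = simulate(cfg, tmp_path / "b")
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_sam_is_valid_and_matches_reads(self, tmp_path):
        cfg = SimConfig(n_reads=25, seed=45)
        paths = simulate(cfg, tmp_path)
        refs = tapscall.load_reference(paths["reference"])
        segs = list(tapscall.iter_alignments(paths["sam"]))
        assert len(segs) == 25
        for seg in segs:
            assert 0 <= seg.ref_start < seg.ref_end <= len(refs[0])

    def test_truth_tables_round_trip(self, tmp_path, clean_scene):
        _, _, truth, _, _ = clean_scene
        write_truth_tables(truth, tmp_path)
        back = read_truth_tables(tmp_path)
        assert np.array_equal(back.site_positions, truth.site_positions)
        assert np.allclose(back.site_levels, truth.site_levels)
        assert np.array_equal(back.molecule_states, truth.molecule_states)
        assert np.array_equal(back.molecule_states_bottom, truth.molecule_states_bottom)
        assert back.read_provenance.equals(truth.read_provenance.reset_index(drop=True))

    def test_empty_molecule_set_gives_header_only_tables(self, tmp_path):
        sim = Simulator(SimConfig(seed=1))
        truth = sim.draw_methylation([5, 9], n_molecules=0)
        paths = write_truth_tables(truth, tmp_path)
        assert len(paths["reads"].read_text().strip().splitlines()) == 1
        assert len(paths["sites"].read_text().strip().splitlines()) == 1 + 2  # 2 sites
        back = read_truth_tables(tmp_path)
        assert back.molecule_states.shape[0] == 0
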