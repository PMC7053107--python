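"""Shared fixtures and independent oracles.

The alignment oracle here deliberately avoids the production code path:
it expands the CIGAR into explicit alignment columns (one per consumed
unit) and reads the reference->read map off the columns, so it can check
the pysam-backed CIGAR walk used by the package.
"""

from __future__ import annotations

import re

import numpy as np
import pysam
import pytest

from tapscall.alignment_io import AlignedSegment, ReferenceIndex
from tapscall.sim import SimConfig, Simulator

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def make_segment(
    pos0: int,
    cigar: str,
    seq: str,
    read_id: str = "r1",
    ref_name: str = "ref",
    ref_len: int = 100000,
    flag: int = 0,
    mapq: int = 60,
) -> AlignedSegment:
    """Build a package AlignedSegment from raw SAM fields."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    )
    rec = pysam.AlignedSegment(header)
    rec.query_name = read_id
    rec.flag = flag
    rec.reference_id = 0
    rec.reference_start = pos0
    rec.mapping_quality = mapq
    rec.cigarstring = cigar
    rec.query_sequence = seq
    return AlignedSegment.from_pysam(rec)


def naive_ref_to_read(pos0: int, cigar: str, seq: str) -> dict[int, tuple[int, str]]:
    """Alignment-matrix reconstruction of the reference->read map.

    Expands the CIGAR into one column per consumed unit: each column
    holds (reference index or None, read index or None); matched columns
    yield the mapping entries.
    """
    columns: list[tuple[int | None, int | None]] = []
    ref_i, read_i = pos0, 0
    for count, op in _CIGAR_RE.findall(cigar):
        for _ in range(int(count)):
            if op in "M=X":
                columns.append((ref_i, read_i))
                ref_i += 1
                read_i += 1
            elif op in "DN":
                columns.append((ref_i, None))
                ref_i += 1
            elif op in "IS":
                columns.append((None, read_i))
                read_i += 1
            # H and P consume nothing
    return {r: (q, seq[q]) for r, q in columns if r is not None and q is not None}


def random_cigar_and_seq(rng: np.random.Generator, max_ref_span: int = 40) -> tuple[str, str]:
    """A random valid (CIGAR, SEQ) pair starting and ending on a match."""
    ops = ["M"]
    n_ops = int(rng.integers(0, 8))
    for _ in range(n_ops):
        ops.append(rng.choice(["M", "I", "D"]))
    ops.append("M")
    parts, ref_span, read_len = [], 0, 0
    prev = None
    for op in ops:
        if op == prev:  # merge to keep the CIGAR canonical
            continue
        count = int(rng.integers(1, 6))
        parts.append(f"{count}{op}")
        if op in "MD":
            ref_span += count
        if op in "MI":
            read_len += count
        prev = op
    if rng.random() < 0.3:
        parts.insert(0, f"{int(rng.integers(1, 4))}S")
        read_len += int(parts[0][:-1])
    if rng.random() < 0.3:
        parts.append(f"{int(rng.integers(1, 4))}S")
        read_len += int(parts[-1][:-1])
    seq = "".join(rng.choice(list("ACGT"), size=read_len))
    return "".join(parts), seq


@pytest.fixture(scope="session")
def clean_scene():
    """Error-free, fully converted simulation on a 4-kb reference.

    Per-site called ratios must reproduce the realized molecule states
    exactly in this regime, so it anchors the exact-recovery tests.
    """
    config = SimConfig(
        n_reads=500,
        conversion_rate=1.0,
        false_conversion_rate=0.0,
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        seed=101,
    )
    sim = Simulator(config)
    seq, sites = sim.generate_reference()
    truth = sim.draw_methylation(sites)
    reads = sim.convert_and_read("ref", seq, truth)
    reference = ReferenceIndex.from_sequence("ref", seq)
    segments = [AlignedSegment.from_pysam(r) for r in reads.sam]
    return config, reference, truth, reads, segments


@pytest.fixture(scope="session")
def noisy_scene():
    """Same scene in the ~10% long-read error regime, deep coverage."""
    config = SimConfig(
        n_reads=200,
        conversion_rate=1.0,
        false_conversion_rate=0.0,
        sub_rate=0.05,
        ins_rate=0.03,
        del_rate=0.03,
        read_length_mean=4000.0,
        read_length_sd=500.0,
        seed=202,
    )
    sim = Simulator(config)
    seq, sites = sim.generate_reference()
    truth = sim.draw_methylation(sites)
    reads = sim.convert_and_read("ref", seq, truth)
    reference = ReferenceIndex.from_sequence("ref", seq)
    segments = [AlignedSegment.from_pysam(r) for r in reads.sam]
    return config, reference, truth, reads, segments


def realized_covering_fraction(truth, pos: int, site_index: int) -> float:
    """Truth methylation among reads whose span covers the full dinucleotide."""
    prov = truth.read_provenance
    cover = prov[(prov["start"] <= pos) & (prov["end"] >= pos + 2)]
    states = [
        truth.molecule_states[m, site_index]
        if strand == "+"
        else truth.molecule_states_bottom[m, site_index]
        for m, strand in zip(cover["molecule"], cover["strand"])
    ]
    return float(np.mean(states)) if states else float("nan")
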