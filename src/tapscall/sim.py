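"""Synthetic TAPS-converted long-read datasets.

TAPS chemistry oxidizes 5mC/5hmC to 5caC and reduces it to dihydrouracil,
which amplifies as thymine: a methylated cytosine is read as T while
unmethylated cytosines are untouched.  On the forward strand of the
reference a methylated CpG therefore appears as TG; a molecule sequenced
from the bottom strand carries the conversion on its own C, which shows up
reference-forward as CA (the reference G position reads A).  Unmethylated
CpGs stay CG.  This module generates references, per-molecule methylation
states, converted reads with a configurable substitution/indel error model,
and the matching truth alignments (SAM) and truth tables, so the caller and
the evaluation code can be exercised without any sequencing data.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SimConfig",
    "SimTruth",
    "Simulator",
    "generate_reference",
    "draw_methylation",
    "convert_and_read",
    "write_truth_tables",
    "read_truth_tables",
    "simulate",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")

_BETA_RE = re.compile(r"^\s*beta\(\s*([0-9.eE+-]+)\s*,\s*([0-9.eE+-]+)\s*\)\s*$")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated TAPS long-read experiment.

    The defaults describe a 4-kb amplicon sequenced in the high-error
    Nanopore regime (~10% total error): substitution 5%, insertion 3%,
    deletion 3%.  Conversion is near-complete (0.97 true conversion,
    0.5% false conversion on unmethylated cytosines), matching the
    near-quantitative chemistry validated by restriction digestion.

    Parameters
    ----------
    ref_length : int
        Reference length in bases (>= 200).
    gc_fraction : float
        GC content of the background sequence, in [0, 1].
    cpg_enrichment : float
        Multiplier (>= 0) on the CpG density expected from independent
        bases at ``gc_fraction``; 1.0 leaves the i.i.d. sequence as is,
        0 strips all CpGs (an error: the reference must keep >= 1 site).
    site_levels : str | Sequence[float] | float
        Per-site methylation fractions: ``"beta(a,b)"`` draws each site's
        level from a Beta distribution; a scalar applies one level to all
        sites; a sequence gives explicit per-site fractions.
    n_reads : int
        Number of reads (one amplified molecule per read).
    read_length_mean, read_length_sd : float
        Mean and SD (bases) of the log-normal read-length model,
        truncated to [100, ref_length].
    conversion_rate : float
        Probability a methylated C is read as T.
    false_conversion_rate : float
        Probability an unmethylated C (any context) is read as T.
    sub_rate, ins_rate, del_rate : float
        Per-base sequencing error rates applied after conversion.
    strand_symmetric_methylation : bool
        If True (default) both strands of a molecule share the
        methylation state at each CpG, as under maintenance methylation.
    seed : int
        Seed of the single RNG stream; identical configs give
        byte-identical outputs.
    """

    ref_length: int = 4000
    gc_fraction: float = 0.5
    cpg_enrichment: float = 1.0
    site_levels: str | float | Sequence[float] = "beta(0.5,0.5)"
    n_reads: int = 500
    read_length_mean: float = 3000.0
    read_length_sd: float = 1500.0
    conversion_rate: float = 0.97
    false_conversion_rate: float = 0.005
    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.03
    strand_symmetric_methylation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_length < 200:
            raise ValueError(f"ref_length must be >= 200, got {self.ref_length}")
        if self.n_reads < 1:
            raise ValueError(f"n_reads must be positive, got {self.n_reads}")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")
        for name in (
            "gc_fraction",
            "conversion_rate",
            "false_conversion_rate",
            "sub_rate",
            "ins_rate",
            "del_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if isinstance(self.site_levels, str):
            if _BETA_RE.match(self.site_levels) is None:
                raise ValueError(
                    f"site_levels string must look like 'beta(a,b)', got {self.site_levels!r}"
                )
        elif isinstance(self.site_levels, (int, float)):
            if not 0.0 <= float(self.site_levels) <= 1.0:
                raise ValueError("scalar site_levels must be in [0, 1]")
        else:
            lv = np.asarray(self.site_levels, dtype=float)
            if lv.size and (lv.min() < 0 or lv.max() > 1):
                raise ValueError("site_levels fractions must all be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulation.

    ``molecule_states`` holds the top-strand state (molecule x site, 0/1);
    ``molecule_states_bottom`` equals it under strand-symmetric
    methylation and is an independent draw otherwise.  ``read_provenance``
    is filled once reads have been emitted: one row per read with the
    molecule id, originating strand (+/-) and the reference interval
    [start, end) the read covers.
    """

    site_positions: np.ndarray
    site_levels: np.ndarray
    molecule_states: np.ndarray
    molecule_states_bottom: np.ndarray
    read_provenance: pd.DataFrame | None = None

    def realized_site_levels(self) -> np.ndarray:
        """Fraction of molecule strands methylated at each site (both strands pooled)."""
        both = np.concatenate([self.molecule_states, self.molecule_states_bottom])
        if both.shape[0] == 0:
            return np.full(self.site_positions.size, np.nan)
        return both.mean(axis=0)


@dataclass
class ReadSet:
    """Emitted reads plus their truth alignments, kept as plain records."""

    fastq: list[tuple[str, str]] = field(default_factory=list)  # (read_id, strand-of-origin seq)
    sam: list[pysam.AlignedSegment] = field(default_factory=list)


def _parse_site_levels(levels: str | float | Sequence[float], n_sites: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(levels, str):
        m = _BETA_RE.match(levels)
        assert m is not None  # validated in SimConfig
        a, b = float(m.group(1)), float(m.group(2))
        return rng.beta(a, b, size=n_sites)
    if isinstance(levels, (int, float)):
        return np.full(n_sites, float(levels))
    lv = np.asarray(levels, dtype=float)
    if lv.size != n_sites:
        raise ValueError(f"site_levels has {lv.size} entries for {n_sites} CpG sites")
    return lv


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class Simulator:
    """Stateful simulator: one RNG stream, draws ordered deterministically.

    The high-level :func:`simulate` drives the stages in a fixed order
    (reference -> methylation -> reads); calling the stage methods in any
    other order is allowed but changes the stream consumed by later stages.
    """

    def __init__(self, config: SimConfig) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)

    # -- reference ---------------------------------------------------------

    def generate_reference(self) -> tuple[str, np.ndarray]:
        """Random reference sequence plus its sorted CpG 'C' positions.

        Bases are drawn i.i.d. at ``gc_fraction``, then CpG dinucleotides
        are planted or stripped to bring the count to ``cpg_enrichment``
        times the i.i.d. expectation.  Fails if no CpG site can be placed.
        """
        cfg = self.config
        gc = cfg.gc_fraction
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arr = self.rng.choice(_BASES, size=cfg.ref_length, p=p)

        def cpg_positions(a: np.ndarray) -> np.ndarray:
            return np.flatnonzero((a[:-1] == _C) & (a[1:] == _G))

        expected = (cfg.ref_length - 1) * (gc / 2) ** 2
        target = int(round(cfg.cpg_enrichment * expected))
        sites = cpg_positions(arr)
        if target > sites.size:
            # plant CpGs at random even positions until the target is met
            candidates = self.rng.permutation(cfg.ref_length - 1)
            for pos in candidates:
                if sites.size >= target:
                    break
                if arr[pos] == _C and arr[pos + 1] == _G:
                    continue
                arr[pos], arr[pos + 1] = _C, _G
                sites = cpg_positions(arr)
        elif target < sites.size:
            drop = self.rng.choice(sites, size=sites.size - target, replace=False)
            arr[drop + 1] = _A  # break the dinucleotide on the G side
            sites = cpg_positions(arr)

        if sites.size == 0:
            raise ValueError(
                "reference has no CpG site (ref_length/gc_fraction/cpg_enrichment "
                "too small to place one)"
            )
        return arr.tobytes().decode("ascii"), sites

    # -- methylation -------------------------------------------------------

    def draw_methylation(self, sites: Sequence[int], n_molecules: int | None = None) -> SimTruth:
        """Draw per-site levels and per-molecule binary states.

        Each molecule's top-strand state at site ``s`` is an independent
        Bernoulli(site_levels[s]) draw; the bottom strand copies it under
        strand-symmetric methylation and is an independent draw otherwise.
        """
        sites = np.asarray(sites, dtype=np.int64)
        if sites.size == 0:
            raise ValueError("draw_methylation requires a non-empty site list")
        cfg = self.config
        if n_molecules is None:
            n_molecules = cfg.n_reads
        levels = _parse_site_levels(cfg.site_levels, sites.size, self.rng)
        top = (self.rng.random((n_molecules, sites.size)) < levels).astype(np.uint8)
        if cfg.strand_symmetric_methylation:
            bottom = top.copy()
        else:
            bottom = (self.rng.random((n_molecules, sites.size)) < levels).astype(np.uint8)
        return SimTruth(sites, levels, top, bottom)

    # -- conversion, errors, reads ----------------------------------------

    def convert_and_read(
        self,
        ref_name: str,
        ref_seq: str,
        truth: SimTruth,
        header: pysam.AlignmentHeader | None = None,
    ) -> ReadSet:
        """Emit TAPS-converted reads and their truth alignments.

        One read per molecule.  Top-strand molecules convert their
        cytosines (methylated CpG C -> T with ``conversion_rate``, any
        other C -> T with ``false_conversion_rate``); bottom-strand
        molecules convert their own cytosines, which reference-forward
        turns the G of a methylated CpG into A.  Substitution, insertion
        and deletion errors are applied after conversion and are
        reflected exactly in the CIGAR.  SAM SEQ is stored
        reference-forward (FLAG 16 marks bottom-strand origin; the
        originating strand is also in the ``ZS`` tag, the molecule id in
        ``ZM``).  The FASTQ carries the strand-of-origin sequence.
        """
        cfg = self.config
        rng = self.rng
        ref = np.frombuffer(ref_seq.encode("ascii"), dtype=np.uint8)
        L = ref.size
        sites = truth.site_positions
        n_reads = truth.molecule_states.shape[0]
        if header is None:
            header = pysam.AlignmentHeader.from_dict(
                {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": ref_name, "LN": L}]}
            )

        # log-normal read lengths truncated to [100, L]
        mean, sd = cfg.read_length_mean, cfg.read_length_sd
        sigma2 = math.log(1 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2
        lengths = np.exp(rng.normal(mu, math.sqrt(sigma2), size=n_reads))
        lengths = np.clip(np.round(lengths).astype(np.int64), 100, L)
        starts = rng.integers(0, L - lengths + 1)
        strands = rng.integers(0, 2, size=n_reads)  # 0 = top, 1 = bottom

        out = ReadSet()
        prov_rows = []
        for i in range(n_reads):
            start, span = int(starts[i]), int(lengths[i])
            end = start + span
            is_bottom = bool(strands[i])
            arr = ref[start:end].copy()

            in_span = (sites >= start) & (sites < end)
            local = sites[in_span] - start
            if is_bottom:
                # bottom-strand C's sit at reference G positions
                states = truth.molecule_states_bottom[i, in_span].astype(bool)
                g_local = local + 1
                g_local_ok = g_local < span  # CpG G may fall just past the read end
                meth = np.zeros(span, dtype=bool)
                meth[g_local[states & g_local_ok]] = True
                base_mask = arr == _G
                u = rng.random(span)
                hit = base_mask & np.where(meth, u < cfg.conversion_rate, u < cfg.false_conversion_rate)
                arr[hit] = _A
            else:
                states = truth.molecule_states[i, in_span].astype(bool)
                meth = np.zeros(span, dtype=bool)
                meth[local[states]] = True
                base_mask = arr == _C
                u = rng.random(span)
                hit = base_mask & np.where(meth, u < cfg.conversion_rate, u < cfg.false_conversion_rate)
                arr[hit] = _T

            seq_fwd, cigar = self._apply_errors(arr)
            read_id = f"read{i:05d}"
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.flag = 16 if is_bottom else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = cigar
            a.query_sequence = seq_fwd
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq_fwd))
            a.set_tag("ZS", "-" if is_bottom else "+", "A")
            a.set_tag("ZM", i, "i")
            out.sam.append(a)
            out.fastq.append((read_id, _revcomp(seq_fwd) if is_bottom else seq_fwd))
            prov_rows.append((read_id, i, "-" if is_bottom else "+", start, end))

        truth.read_provenance = pd.DataFrame(
            prov_rows, columns=["read_id", "molecule", "strand", "start", "end"]
        )
        return out

    def _apply_errors(self, arr: np.ndarray) -> tuple[str, str]:
        """Apply per-base substitution/indel errors; return (SEQ, CIGAR)."""
        cfg = self.config
        rng = self.rng
        n = arr.size
        if cfg.sub_rate == 0 and cfg.ins_rate == 0 and cfg.del_rate == 0:
            return arr.tobytes().decode("ascii"), f"{n}M"
        u = rng.random((n, 3))
        del_mask = u[:, 0] < cfg.del_rate
        sub_mask = (~del_mask) & (u[:, 1] < cfg.sub_rate)
        ins_mask = u[:, 2] < cfg.ins_rate  # insertion opens after this reference base

        emitted = arr.copy()
        n_sub = int(sub_mask.sum())
        if n_sub:
            # substitute with one of the three other bases, uniformly
            idx = (np.searchsorted(_BASES, emitted[sub_mask]) + rng.integers(1, 4, size=n_sub)) % 4
            emitted[sub_mask] = _BASES[idx]
        ins_bases = _BASES[rng.integers(0, 4, size=int(ins_mask.sum()))]

        read: list[int] = []
        ops: list[str] = []
        j = 0
        for i in range(n):
            if del_mask[i]:
                ops.append("D")
            else:
                ops.append("M")
                read.append(emitted[i])
            if ins_mask[i]:
                ops.append("I")
                read.append(ins_bases[j])
                j += 1
        # leading/trailing D is not a valid alignment: trim and adjust later?
        # Instead, force the first and last reference base to be M so the
        # alignment span matches provenance exactly.
        if ops and ops[0] == "D":
            ops[0] = "M"
            read.insert(0, emitted[0])
        if ops and ops[-1] == "D":
            ops[-1] = "M"
            read.append(emitted[-1])
        cigar_parts = []
        prev, count = ops[0], 1
        for op in ops[1:]:
            if op == prev:
                count += 1
            else:
                cigar_parts.append(f"{count}{prev}")
                prev, count = op, 1
        cigar_parts.append(f"{count}{prev}")
        return bytes(read).decode("ascii"), "".join(cigar_parts)


# -- module-level wrappers -------------------------------------------------


def generate_reference(config: SimConfig) -> tuple[str, np.ndarray]:
    return Simulator(config).generate_reference()


def draw_methylation(sites: Sequence[int], config: SimConfig, n_molecules: int | None = None) -> SimTruth:
    return Simulator(config).draw_methylation(sites, n_molecules)


def convert_and_read(ref_name: str, ref_seq: str, truth: SimTruth, config: SimConfig) -> ReadSet:
    return Simulator(config).convert_and_read(ref_name, ref_seq, truth)


# -- output ----------------------------------------------------------------


def write_truth_tables(truth: SimTruth, outdir: str | Path, prefix: str = "truth") -> dict[str, Path]:
    """Write tab-delimited truth tables; lossless round-trip via :func:`read_truth_tables`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / f"{prefix}_sites.tsv",
        "reads": outdir / f"{prefix}_reads.tsv",
        "states": outdir / f"{prefix}_states.tsv",
    }
    pd.DataFrame(
        {
            "pos": truth.site_positions,
            "level": truth.site_levels,
            "realized_level": truth.realized_site_levels(),
        }
    ).to_csv(paths["sites"], sep="\t", index=False)
    prov = truth.read_provenance
    if prov is None:
        prov = pd.DataFrame(columns=["read_id", "molecule", "strand", "start", "end"])
    prov.to_csv(paths["reads"], sep="\t", index=False)
    cols = [str(p) for p in truth.site_positions]
    top = pd.DataFrame(truth.molecule_states, columns=cols)
    bot = pd.DataFrame(truth.molecule_states_bottom, columns=cols)
    top.insert(0, "strand", "+")
    bot.insert(0, "strand", "-")
    top.insert(0, "molecule", np.arange(len(top)))
    bot.insert(0, "molecule", np.arange(len(bot)))
    pd.concat([top, bot]).to_csv(paths["states"], sep="\t", index=False)
    return paths


def read_truth_tables(outdir: str | Path, prefix: str = "truth") -> SimTruth:
    outdir = Path(outdir)
    sites = pd.read_csv(outdir / f"{prefix}_sites.tsv", sep="\t")
    prov = pd.read_csv(
        outdir / f"{prefix}_reads.tsv",
        sep="\t",
        dtype={"read_id": str, "molecule": np.int64, "strand": str, "start": np.int64, "end": np.int64},
    )
    states = pd.read_csv(outdir / f"{prefix}_states.tsv", sep="\t")
    pos_cols = [c for c in states.columns if c not in ("molecule", "strand")]
    top = states[states["strand"] == "+"].sort_values("molecule")
    bot = states[states["strand"] == "-"].sort_values("molecule")
    return SimTruth(
        site_positions=sites["pos"].to_numpy(np.int64),
        site_levels=sites["level"].to_numpy(float),
        molecule_states=top[pos_cols].to_numpy(np.uint8),
        molecule_states_bottom=bot[pos_cols].to_numpy(np.uint8),
        read_provenance=prov if len(prov) else prov,
    )


def write_fasta(name: str, seq: str, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_sam(records: list[pysam.AlignedSegment], header: pysam.AlignmentHeader, path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def simulate(config: SimConfig, outdir: str | Path, ref_name: str = "sim_ref") -> dict[str, Path]:
    """Run the full simulation and write FASTA/FASTQ/SAM/truth tables.

    Returns the paths written.  Identical configs (including seed) produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = Simulator(config)
    seq, sites = sim.generate_reference()
    truth = sim.draw_methylation(sites)
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": ref_name, "LN": len(seq)}]}
    )
    reads = sim.convert_and_read(ref_name, seq, truth, header=header)
    paths = {
        "reference": outdir / "reference.fa",
        "fastq": outdir / "reads.fastq",
        "sam": outdir / "reads.sam",
    }
    write_fasta(ref_name, seq, paths["reference"])
    write_fastq(reads.fastq, paths["fastq"])
    write_sam(reads.sam, header, paths["sam"])
    paths.update(write_truth_tables(truth, outdir))
    return paths
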