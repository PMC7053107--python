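"""References and alignments as the caller sees them.

Everything downstream works on 0-based, half-open coordinates.  A read is
exposed as an :class:`AlignedSegment` holding a partial map from reference
position to (read position, read base) built from the CIGAR; reference
positions under a deletion or outside the aligned span are simply absent,
which is what lets the caller mark a CpG observation as missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = ["ReferenceIndex", "AlignedSegment", "load_reference", "iter_alignments", "filter_by_length"]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class ReferenceIndex:
    """One reference record plus the sorted positions of its CpG sites.

    ``cpg_sites`` holds the 0-based position of the C of every CG
    dinucleotide on the forward strand; dinucleotides containing N are
    excluded (an N never equals C or G, so the scan handles this for free).
    """

    name: str
    sequence: str
    cpg_sites: np.ndarray

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "ReferenceIndex":
        seq = sequence.upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"reference {name!r} contains non-nucleotide characters: {sorted(bad)}")
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        sites = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        return cls(name=name, sequence=seq, cpg_sites=sites)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedSegment:
    """A primary alignment with its reference->read coordinate map.

    ``ref_to_read`` maps each aligned reference position to
    ``(read position, read base)``; positions consumed by a deletion, or
    clipped/outside the span, are absent.  SAM stores SEQ
    reference-forward, so the bases here compare directly against the
    reference regardless of ``is_reverse``.
    """

    read_id: str
    ref_name: str
    ref_start: int
    ref_end: int
    is_reverse: bool
    is_secondary_or_supplementary: bool
    mapq: int
    read_length: int
    ref_to_read: dict[int, tuple[int, str]]

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedSegment":
        seq = rec.query_sequence or ""
        mapping = {
            rpos: (qpos, seq[qpos])
            for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
        }
        return cls(
            read_id=rec.query_name or "",
            ref_name=rec.reference_name or "",
            ref_start=rec.reference_start,
            ref_end=rec.reference_end or rec.reference_start,
            is_reverse=rec.is_reverse,
            is_secondary_or_supplementary=rec.is_secondary or rec.is_supplementary,
            mapq=rec.mapping_quality,
            read_length=rec.query_length,
            ref_to_read=mapping,
        )


def load_reference(path: str | Path) -> list[ReferenceIndex]:
    """Load every record of a FASTA file as a :class:`ReferenceIndex`.

    Lowercase is normalized to uppercase; an empty file or a record with
    characters outside A/C/G/T/N is an error.
    """
    records = [ReferenceIndex.from_sequence(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def iter_alignments(
    path: str | Path,
    min_mapq: int = 0,
    include_secondary: bool = False,
    strict: bool = True,
) -> Iterator[AlignedSegment]:
    """Stream primary alignments from a SAM or BAM file.

    Unmapped records are skipped; secondary/supplementary records are
    skipped unless ``include_secondary``.  A malformed record raises in
    strict mode and is logged and skipped otherwise.
    """
    with pysam.AlignmentFile(str(path), require_index=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if (rec.is_secondary or rec.is_supplementary) and not include_secondary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            try:
                yield AlignedSegment.from_pysam(rec)
            except Exception as exc:  # pragma: no cover - defensive
                if strict:
                    raise ValueError(f"malformed alignment record {rec.query_name!r}: {exc}") from exc
                logger.warning("skipping malformed record %r: %s", rec.query_name, exc)


def filter_by_length(
    segments: Iterable[AlignedSegment],
    min_len: int = 0,
    max_len: float = math.inf,
) -> Iterator[AlignedSegment]:
    """Keep segments with ``min_len <= read_length <= max_len`` (inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    n_in = n_out = 0
    for seg in segments:
        n_in += 1
        if min_len <= seg.read_length <= max_len:
            n_out += 1
            yield seg
    logger.info("length filter [%s, %s]: kept %d of %d reads", min_len, max_len, n_out, n_in)
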