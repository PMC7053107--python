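"""Per-site CpG methylation calling from TAPS-converted alignments.

At each reference CpG, every read contributes one reference-forward
dinucleotide observation: TG (methylated C seen on the top strand), CA
(methylated C seen through the bottom strand), CG (unmethylated), TA
(impossible on a single converted strand, so evidence of error or
variant), or OTHER.  The per-site methylation ratio pools both strands:

    ratio = (TG + CA) / (TG + CA + CG)

A site where too many observations fall outside {TG, CA, CG} — measured
by (TG + CA + CG) / NN, with NN the count of all informative
observations — is flagged as a likely variant rather than methylation.
Apparent conversion in an unconverted (non-TAPS) control marks the same
way a homozygous C->T variant that the NN fraction alone cannot see.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignedSegment, ReferenceIndex

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCall",
    "SiteMethylationRecord",
    "classify_site",
    "call_methylation",
    "apply_control_mask",
    "write_site_table",
    "read_site_table",
    "records_to_frame",
]


class SiteCall(str, Enum):
    """Classification of one read's dinucleotide at one CpG site."""

    TG = "TG"
    CA = "CA"
    CG = "CG"
    TA = "TA"
    OTHER = "OTHER"
    MISSING = "MISSING"


_DINUC = {"TG": SiteCall.TG, "CA": SiteCall.CA, "CG": SiteCall.CG, "TA": SiteCall.TA}


@dataclass
class SiteMethylationRecord:
    """Counts and methylation ratio at one CpG site (0-based C position).

    ``nn`` counts every informative (non-missing) observation; ``ratio``
    is (TG+CA)/(TG+CA+CG), NaN when that denominator is zero.  TA is
    tallied but excluded from both numerator and denominator.
    """

    ref_name: str
    pos: int
    n_tg: int = 0
    n_ca: int = 0
    n_cg: int = 0
    n_ta: int = 0
    n_other: int = 0
    passes_nn_filter: bool = False
    control_masked: bool = False

    @property
    def nn(self) -> int:
        return self.n_tg + self.n_ca + self.n_cg + self.n_ta + self.n_other

    @property
    def ratio(self) -> float:
        denom = self.n_tg + self.n_ca + self.n_cg
        return (self.n_tg + self.n_ca) / denom if denom else math.nan


def classify_site(segment: AlignedSegment, site_pos: int) -> SiteCall:
    """Classify one read's observation at a reference CpG.

    MISSING when either dinucleotide position is unaligned (deletion,
    clip, outside the span); OTHER when an insertion opens between the
    two read positions or the bases do not form TG/CA/CG/TA.
    """
    first = segment.ref_to_read.get(site_pos)
    second = segment.ref_to_read.get(site_pos + 1)
    if first is None or second is None:
        return SiteCall.MISSING
    (q1, b1), (q2, b2) = first, second
    if q2 != q1 + 1:  # insertion opened inside the dinucleotide
        return SiteCall.OTHER
    return _DINUC.get(b1 + b2, SiteCall.OTHER)


def call_methylation(
    segments: Iterable[AlignedSegment],
    reference: ReferenceIndex,
    nn_threshold: float = 0.8,
    min_depth: int = 1,
    apply_nn_filter: bool = True,
) -> list[SiteMethylationRecord]:
    """Aggregate per-read site calls into per-site methylation records.

    Returns one record per CpG site with at least ``min_depth``
    informative observations, sorted by position.  When
    ``apply_nn_filter`` is False the filter flag is set True everywhere
    (appropriate for references where variants are not expected).
    """
    sites = reference.cpg_sites
    counts = {c: np.zeros(sites.size, dtype=np.int64) for c in (SiteCall.TG, SiteCall.CA, SiteCall.CG, SiteCall.TA, SiteCall.OTHER)}
    for seg in segments:
        if seg.ref_name != reference.name:
            continue
        lo = int(np.searchsorted(sites, seg.ref_start))
        hi = int(np.searchsorted(sites, seg.ref_end))
        for si in range(lo, hi):
            call = classify_site(seg, int(sites[si]))
            if call is not SiteCall.MISSING:
                counts[call][si] += 1

    records: list[SiteMethylationRecord] = []
    for si, pos in enumerate(sites):
        rec = SiteMethylationRecord(
            ref_name=reference.name,
            pos=int(pos),
            n_tg=int(counts[SiteCall.TG][si]),
            n_ca=int(counts[SiteCall.CA][si]),
            n_cg=int(counts[SiteCall.CG][si]),
            n_ta=int(counts[SiteCall.TA][si]),
            n_other=int(counts[SiteCall.OTHER][si]),
        )
        if rec.nn < min_depth:
            continue
        if not apply_nn_filter:
            rec.passes_nn_filter = True
        elif rec.nn > 0:
            rec.passes_nn_filter = (rec.n_tg + rec.n_ca + rec.n_cg) / rec.nn > nn_threshold
        records.append(rec)
    return records


def apply_control_mask(
    records: Sequence[SiteMethylationRecord],
    control_records: Sequence[SiteMethylationRecord],
    control_ratio_max: float = 0.05,
) -> list[SiteMethylationRecord]:
    """Mask sites that look converted in an unconverted control.

    In a non-TAPS control no CpG should read TG/CA; a control ratio above
    ``control_ratio_max``, or a control that itself fails the NN filter,
    marks the site as a genetic variant.  Sites without a control record
    are left unmasked and logged.  Modifies and returns ``records``.
    """
    rec_refs = {r.ref_name for r in records}
    ctl_refs = {r.ref_name for r in control_records}
    if records and control_records and not (rec_refs & ctl_refs):
        raise ValueError(f"control references {sorted(ctl_refs)} do not match {sorted(rec_refs)}")
    control = {(r.ref_name, r.pos): r for r in control_records}
    n_missing = 0
    for rec in records:
        ctl = control.get((rec.ref_name, rec.pos))
        if ctl is None:
            n_missing += 1
            continue
        ctl_ratio = ctl.ratio
        if not ctl.passes_nn_filter or (not math.isnan(ctl_ratio) and ctl_ratio > control_ratio_max):
            rec.control_masked = True
    if n_missing:
        logger.warning("%d sites had no control record and were left unmasked", n_missing)
    return list(records)


_COLUMNS = [
    "ref_name", "pos", "n_tg", "n_ca", "n_cg", "n_ta", "n_other",
    "nn", "ratio", "passes_nn_filter", "control_masked",
]


def records_to_frame(records: Sequence[SiteMethylationRecord]) -> pd.DataFrame:
    rows = [
        (r.ref_name, r.pos, r.n_tg, r.n_ca, r.n_cg, r.n_ta, r.n_other,
         r.nn, r.ratio, r.passes_nn_filter, r.control_masked)
        for r in records
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_site_table(
    records: Sequence[SiteMethylationRecord],
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write per-site records as TSV (round-trippable) or bedMethyl.

    The TSV header documents that ``pos`` is the 0-based position of the
    CpG C.  The bedMethyl variant emits chrom/start/end, coverage and
    percent-methylated columns (percent from the TG/CA/CG ratio).
    """
    df = records_to_frame(records)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# tapscall site table; pos is the 0-based position of the CpG 'C'\n")
            fh.write("# ratio = (n_tg + n_ca) / (n_tg + n_ca + n_cg); nn = all informative reads\n")
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")
    elif fmt == "bedmethyl":
        with open(path, "w") as fh:
            for r in records:
                pct = "NA" if math.isnan(r.ratio) else f"{r.ratio * 100:g}"
                score = min(1000, r.nn)
                fh.write(
                    f"{r.ref_name}\t{r.pos}\t{r.pos + 2}\tCpG\t{score}\t+\t"
                    f"{r.pos}\t{r.pos + 2}\t0,0,0\t{r.nn}\t{pct}\n"
                )
    else:
        raise ValueError(f"unknown site-table format {fmt!r}")


def read_site_table(path: str | Path) -> list[SiteMethylationRecord]:
    """Read back a TSV written by :func:`write_site_table`."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SiteMethylationRecord(
                ref_name=str(row.ref_name),
                pos=int(row.pos),
                n_tg=int(row.n_tg),
                n_ca=int(row.n_ca),
                n_cg=int(row.n_cg),
                n_ta=int(row.n_ta),
                n_other=int(row.n_other),
                passes_nn_filter=bool(row.passes_nn_filter),
                control_masked=bool(row.control_masked),
            )
        )
    return records
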