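"""Single-molecule methylation phasing.

Long reads observe many CpGs on the same molecule, so methylation can be
phased: the read x site matrix records each read's binary state at each
CpG (1 for TG/CA, 0 for CG, NA when uninformative).  Ranking reads by
their mean methylation over a region (typically a CpG island) separates
epiallele populations, and the pairwise inter-site correlation over reads
informative at both sites exposes which sites are co-methylated or
mutually exclusive along single molecules.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .alignment_io import AlignedSegment, ReferenceIndex
from .caller import SiteCall, classify_site

logger = logging.getLogger(__name__)

__all__ = ["build_read_matrix", "rank_reads", "site_correlation"]

_CELL = {SiteCall.TG: 1.0, SiteCall.CA: 1.0, SiteCall.CG: 0.0}


def build_read_matrix(
    segments: Iterable[AlignedSegment],
    reference: ReferenceIndex,
    region: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Read x CpG-site methylation state matrix over a reference region.

    Rows are read ids (ordered by alignment start, then read id), columns
    CpG 'C' positions within ``region`` (0-based half-open; default the
    whole reference).  Cells are 1.0 for a methylated observation
    (TG/CA), 0.0 for unmethylated (CG) and NaN otherwise.  Only reads
    whose aligned span overlaps at least one region CpG get a row.
    """
    start, end = region if region is not None else (0, len(reference))
    sites = reference.cpg_sites
    sites = sites[(sites >= start) & (sites < end)]
    if sites.size == 0:
        logger.warning("region [%d, %d) of %s contains no CpG site", start, end, reference.name)
        return pd.DataFrame(index=pd.Index([], name="read_id"))

    rows: list[tuple[int, str, np.ndarray]] = []
    for seg in segments:
        if seg.ref_name != reference.name:
            continue
        lo = int(np.searchsorted(sites, seg.ref_start))
        hi = int(np.searchsorted(sites, seg.ref_end))
        if hi <= lo:
            continue
        cells = np.full(sites.size, np.nan)
        for si in range(lo, hi):
            cells[si] = _CELL.get(classify_site(seg, int(sites[si])), np.nan)
        rows.append((seg.ref_start, seg.read_id, cells))

    rows.sort(key=lambda t: (t[0], t[1]))
    matrix = pd.DataFrame(
        [cells for _, _, cells in rows],
        index=pd.Index([rid for _, rid, _ in rows], name="read_id"),
        columns=sites,
    )
    return matrix


def rank_reads(matrix: pd.DataFrame, ranking_region: tuple[int, int] | None = None) -> pd.DataFrame:
    """Order reads by decreasing mean methylation within ``ranking_region``.

    The mean is taken over informative (non-NA) cells of the columns
    falling in the region; reads with no informative cell there go last
    in their original relative order.  Ties are broken by read id.
    Returns the reordered matrix.
    """
    if ranking_region is None:
        cols = matrix.columns
    else:
        start, end = ranking_region
        cols = [c for c in matrix.columns if start <= c < end]
    if len(cols) == 0:
        raise ValueError("ranking region contains no CpG column")
    means = matrix[cols].mean(axis=1, skipna=True)
    informative = means.notna()
    ranked = sorted(
        matrix.index[informative],
        key=lambda rid: (-means[rid], rid),
    )
    order = list(ranked) + list(matrix.index[~informative])
    return matrix.loc[order]


def site_correlation(matrix: pd.DataFrame, min_pairs: int = 10) -> pd.DataFrame:
    """Pairwise Pearson correlation between CpG sites over single reads.

    Each pair uses only reads informative at both sites; pairs with fewer
    than ``min_pairs`` complete observations, and pairs where either site
    has zero variance, are NaN.  The diagonal is 1 where the site has
    enough observations and positive variance, NaN otherwise.
    """
    if matrix.shape[1] < 2:
        raise ValueError("site correlation requires at least 2 CpG columns")
    corr = matrix.corr(method="pearson", min_periods=max(min_pairs, 2))
    n_obs = matrix.notna().sum(axis=0)
    var = matrix.var(axis=0, skipna=True)
    for c in corr.columns:
        ok = n_obs[c] >= min_pairs and var[c] > 0
        corr.loc[c, c] = 1.0 if ok else np.nan
    return corr
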