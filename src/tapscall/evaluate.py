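"""Evaluation of methylation calls against an orthogonal truth track.

Two statistics: Pearson correlation between two per-site methylation
tracks restricted to sites covered deeply in both (the standard way to
compare a long-read caller against short-read bisulfite or TAPS data),
and ROC/AUC after binarizing the truth track at a methylation-level
cutoff (default: level > 3% counts as methylated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .caller import SiteMethylationRecord, records_to_frame

__all__ = ["MethylationTrack", "ROCResult", "track_correlation", "binarize_truth", "roc_auc"]


@dataclass
class MethylationTrack:
    """Per-site methylation levels with depth: columns ref_name, pos, ratio, depth."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ref_name", "pos", "ratio", "depth"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"track is missing columns {sorted(missing)}")
        ratios = self.df["ratio"].dropna()
        if len(ratios) and (ratios.min() < 0 or ratios.max() > 1):
            raise ValueError("track ratios must be in [0, 1]")
        if self.df.duplicated(subset=["ref_name", "pos"]).any():
            raise ValueError("track has duplicate positions")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(
        cls,
        records: Sequence[SiteMethylationRecord],
        require_pass: bool = False,
        drop_masked: bool = False,
    ) -> "MethylationTrack":
        """Build a track from caller output; depth is the site's NN count.

        ``require_pass`` drops sites failing the NN (SNP) filter;
        ``drop_masked`` drops sites masked by the non-TAPS control.
        """
        df = records_to_frame(records)
        if require_pass:
            df = df[df["passes_nn_filter"]]
        if drop_masked:
            df = df[~df["control_masked"]]
        out = df[["ref_name", "pos", "ratio"]].copy()
        out["depth"] = df["nn"].to_numpy()
        return cls(out.dropna(subset=["ratio"]).reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path: str | Path, ref_name: str | None = None) -> "MethylationTrack":
        """Read a tab-delimited track: columns pos + ratio/level, optional ref_name/depth.

        Sites without a depth column are given infinite depth so that
        depth thresholds never exclude them (appropriate for simulator
        truth tables and externally aggregated tracks).
        """
        df = pd.read_csv(path, sep="\t", comment="#")
        if "ratio" not in df.columns:
            # simulator truth tables: prefer the realized per-molecule level
            # (what a perfect caller recovers) over the intended one
            for alt in ("realized_level", "level"):
                if alt in df.columns:
                    df = df.rename(columns={alt: "ratio"})
                    break
        if "ref_name" not in df.columns:
            df["ref_name"] = ref_name if ref_name is not None else "ref"
        if "depth" not in df.columns:
            df["depth"] = math.inf
        return cls(df[["ref_name", "pos", "ratio", "depth"]])


@dataclass
class ROCResult:
    """ROC curve and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _merge(a: MethylationTrack, b: MethylationTrack) -> pd.DataFrame:
    return a.df.merge(b.df, on=["ref_name", "pos"], suffixes=("_a", "_b"))


def track_correlation(
    a: MethylationTrack,
    b: MethylationTrack,
    min_depth: int = 8,
) -> tuple[float, int]:
    """Pearson r over sites with depth strictly above ``min_depth`` in both tracks.

    Returns ``(r, n_sites)``.  Fewer than 3 usable shared sites leaves
    the correlation undefined and raises ``ValueError``.
    """
    merged = _merge(a, b)
    merged = merged[(merged["depth_a"] > min_depth) & (merged["depth_b"] > min_depth)]
    merged = merged.dropna(subset=["ratio_a", "ratio_b"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} shared sites with depth > {min_depth} in both tracks; correlation undefined")
    r, _ = stats.pearsonr(merged["ratio_a"], merged["ratio_b"])
    return float(r), n


def binarize_truth(truth: MethylationTrack, cutoff: float = 0.03) -> pd.DataFrame:
    """Label each site methylated (1) iff its level is strictly above ``cutoff``."""
    out = truth.df[["ref_name", "pos"]].copy()
    out["label"] = (truth.df["ratio"] > cutoff).astype(int)
    return out


def roc_auc(pred: MethylationTrack, labels: pd.DataFrame) -> ROCResult:
    """ROC of predicted ratios against binary truth labels over shared sites.

    Thresholds sweep the distinct predicted ratios (ties grouped); AUC is
    the area under the resulting curve by the trapezoidal rule.  Requires
    at least one positive and one negative label among shared sites.
    """
    merged = pred.df.merge(labels, on=["ref_name", "pos"]).dropna(subset=["ratio"])
    y = merged["label"].to_numpy(int)
    score = merged["ratio"].to_numpy(float)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("ROC requires at least one positive and one negative label among shared sites")
    fpr, tpr, thresholds = _skm.roc_curve(y, score, drop_intermediate=False)
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_skm.auc(fpr, tpr)))
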