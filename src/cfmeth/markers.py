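"""Per-block methylation tables, sample clustering QC, and cell-type-specific
marker discovery.

Marker calling follows the atlas-based recipe: per block and sample, mean
methylation is the pooled call ratio across the block's CpGs, set to NA when
the block's mean read depth in that sample falls below a floor.  A block is a
marker for a target cell type when (i) at most 1/3 of target or background
samples are NA, (ii) |mean(target) - mean(background)| >= 0.3, and (iii) a
two-sided Welch t-test between the groups gives p <= 0.05.  Hypomethylated
markers (target below background) are ranked by the gap between the
background's 2.5th centile and the target's 75th centile, then truncated to
the requested top-k.  No multiple-testing correction is applied; the raw
p <= 0.05 rule is deliberate and matched by the ranking step that follows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io import BetaTrack, Block

__all__ = [
    "MarkerConfig",
    "block_methylation_table",
    "find_markers",
    "marker_union",
    "cluster_samples",
    "SampleClustering",
]

#: Marker-set sizes explored by the spike-in optimisation.
TOP_K_GRID: tuple[int, ...] = (25, 50, 100, 250, 300, 400, 500)


@dataclass(frozen=True)
class MarkerConfig:
    delta: float = 0.3  # minimum |mean(target) - mean(background)|
    p_max: float = 0.05  # Welch t-test threshold (raw, uncorrected)
    min_depth: float = 5.0  # mean reads per CpG below which a cell is NA
    max_na_fraction: float = 1.0 / 3.0
    q_target: float = 0.75  # centile of the target group used for ranking
    q_background: float = 0.025  # centile of the background group
    top_k: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must lie in (0, 1]")
        if not 0.0 < self.p_max < 1.0:
            raise ValueError("p_max must lie in (0, 1)")


def block_methylation_table(
    tracks: Mapping[str, BetaTrack],
    blocks: Sequence[Block],
    min_depth: float = 5.0,
    include_flagged: bool = False,
) -> pd.DataFrame:
    """Samples x blocks table of mean methylation, NA below the depth floor.

    The per-cell value is (sum of methylated calls)/(sum of total calls)
    across the block's CpGs; mean depth is total calls / number of CpGs.
    Blocks flagged undersized by segmentation are excluded by default.
    Column labels are the positional block ids into ``blocks``.
    """
    blocks = list(blocks)
    use = [j for j, b in enumerate(blocks) if include_flagged or not b.flagged]
    if not use:
        raise ValueError("no usable blocks")
    a = np.array([blocks[j].start_idx for j in use]) - 1
    b = np.array([blocks[j].end_idx for j in use])
    n_cpgs = (b - a).astype(float)

    rows = {}
    for name, track in tracks.items():
        mc = np.concatenate([[0], np.cumsum(track.meth)])
        tc = np.concatenate([[0], np.cumsum(track.total)])
        meth = mc[b] - mc[a]
        tot = tc[b] - tc[a]
        depth = tot / n_cpgs
        with np.errstate(invalid="ignore", divide="ignore"):
            val = np.where(tot > 0, meth / np.maximum(tot, 1), np.nan)
        rows[name] = np.where(depth >= min_depth, val, np.nan)
    return pd.DataFrame.from_dict(rows, orient="index", columns=use)


def find_markers(
    table: pd.DataFrame,
    sample_types: Mapping[str, str],
    target_type: str,
    blocks: Sequence[Block],
    config: MarkerConfig | None = None,
) -> pd.DataFrame:
    """Derive the ranked marker set of one cell type.

    Parameters
    ----------
    table
        Output of :func:`block_methylation_table` (samples x block ids).
    sample_types
        Sample name -> cell-type label; the background is the pool of all
        non-target samples (not the mean of type means).
    target_type
        Cell type to derive markers for.
    blocks
        The block list the table's column ids index into.

    Returns
    -------
    DataFrame with one row per marker, ordered by ranking score descending
    (ties: smaller p, then genomic order), columns
    ``block_id, chrom, start, end, start_idx, end_idx, n_cpgs, direction,
    mean_target, mean_background, delta, p, score``.
    """
    config = config or MarkerConfig()
    types = pd.Series({s: sample_types[s] for s in table.index})
    t_mask = (types == target_type).to_numpy()
    if not t_mask.any():
        raise KeyError(f"no samples of target type {target_type!r}")
    X = table.to_numpy(dtype=float)
    T, B = X[t_mask], X[~t_mask]
    if T.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 target and >= 2 background samples")

    na_t = np.isnan(T).mean(axis=0)
    na_b = np.isnan(B).mean(axis=0)
    usable = (na_t <= config.max_na_fraction) & (na_b <= config.max_na_fraction)
    # Welch needs >= 2 observed values per side
    usable &= ((~np.isnan(T)).sum(axis=0) >= 2) & ((~np.isnan(B)).sum(axis=0) >= 2)
    if not usable.any():
        return _empty_marker_frame()

    cols = np.flatnonzero(usable)
    Tm, Bm = T[:, cols], B[:, cols]
    mt = np.nanmean(Tm, axis=0)
    mb = np.nanmean(Bm, axis=0)
    delta = mt - mb
    # blocks where both groups are near-constant trip scipy's precision
    # warning; they are filtered by the delta rule anyway
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(
            Tm, Bm, axis=0, equal_var=False, nan_policy="omit"
        ).pvalue
    keep = (np.abs(delta) >= config.delta) & (p <= config.p_max) & np.isfinite(p)
    if not keep.any():
        return _empty_marker_frame()
    cols, mt, mb, delta, p = cols[keep], mt[keep], mb[keep], delta[keep], p[keep]
    Tm, Bm = Tm[:, keep], Bm[:, keep]

    hypo = delta < 0
    qt_hi = np.nanquantile(Tm, config.q_target, axis=0)
    qb_lo = np.nanquantile(Bm, config.q_background, axis=0)
    qt_lo = np.nanquantile(Tm, 1.0 - config.q_target, axis=0)
    qb_hi = np.nanquantile(Bm, 1.0 - config.q_background, axis=0)
    # hypo: background's low tail minus target's high tail; mirrored for hyper
    score = np.where(hypo, qb_lo - qt_hi, qt_lo - qb_hi)

    block_ids = np.asarray(table.columns)[cols]
    rec = pd.DataFrame(
        {
            "block_id": block_ids,
            "direction": np.where(hypo, "hypo", "hyper"),
            "mean_target": mt,
            "mean_background": mb,
            "delta": delta,
            "p": p,
            "score": score,
        }
    )
    binfo = [blocks[j] for j in block_ids]
    rec.insert(1, "chrom", [b.chrom for b in binfo])
    rec.insert(2, "start", [b.start for b in binfo])
    rec.insert(3, "end", [b.end for b in binfo])
    rec.insert(4, "start_idx", [b.start_idx for b in binfo])
    rec.insert(5, "end_idx", [b.end_idx for b in binfo])
    rec.insert(6, "n_cpgs", [b.n_cpgs for b in binfo])
    rec = rec.sort_values(
        ["score", "p", "start_idx"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return rec.head(config.top_k)


def marker_union(marker_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of per-type marker sets, deduplicated by block.

    A block claimed by several cell types (possible with lax thresholds) is
    kept once, attributed to the type where it scored highest.
    """
    frames = []
    for t, df in marker_sets.items():
        d = df.copy()
        d.insert(0, "cell_type", t)
        frames.append(d)
    allm = pd.concat(frames, ignore_index=True)
    allm = (
        allm.sort_values("score", ascending=False, kind="stable")
        .drop_duplicates("block_id")
        .sort_values("start_idx", kind="stable")
        .reset_index(drop=True)
    )
    return allm


def _empty_marker_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "block_id", "chrom", "start", "end", "start_idx", "end_idx",
            "n_cpgs", "direction", "mean_target", "mean_background",
            "delta", "p", "score",
        ]
    )


# ---------------------------------------------------------------------------
# clustering QC
# ---------------------------------------------------------------------------


@dataclass
class SampleClustering:
    """Hierarchical clustering of samples on high-variance blocks."""

    linkage: np.ndarray
    samples: list[str]
    block_ids: np.ndarray  # table columns used

    def flat_labels(self, n_clusters: int) -> pd.Series:
        lab = fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(lab, index=self.samples)


def cluster_samples(table: pd.DataFrame, top_fraction: float = 0.01) -> SampleClustering:
    """Average-linkage, L1-distance clustering on top-variance blocks.

    Blocks with any NA across samples are excluded; of the remainder the top
    ``floor(top_fraction * n_blocks)`` (at least 1) by variance are used.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 samples to cluster")
    X = table.to_numpy(dtype=float)
    complete = ~np.isnan(X).any(axis=0)
    if not complete.any():
        raise ValueError(
            "no NA-free blocks; relax the depth floor or increase coverage"
        )
    k = max(1, int(np.floor(top_fraction * table.shape[1])))
    var = X[:, complete].var(axis=0, ddof=1)
    order = np.argsort(var, kind="stable")[::-1][: min(k, var.size)]
    cols = np.flatnonzero(complete)[order]
    Z = linkage(
        pdist(X[:, cols], metric="cityblock"),
        method="average",
        optimal_ordering=True,
    )
    return SampleClustering(Z, list(table.index), np.asarray(table.columns)[cols])
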