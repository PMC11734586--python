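"""Read-level (U/X/M) classification, reference-atlas construction and
non-negative least-squares deconvolution of cfDNA mixtures.

Each sequenced molecule overlapping a marker region is classified by the
fraction of methylated CpGs it carries *inside* that region: mostly
Unmethylated (``f <= 0.25``), mostly Methylated (``f >= 0.75``) or miXed,
with molecules observing fewer than 3 CpGs in the region excluded.  The
reference atlas is the markers x cell-types matrix of U-molecule
proportions; a mixture's per-marker U proportions are then explained as a
non-negative combination of the atlas columns (NNLS), and the weights are
normalised to cell-type proportions summing to one.

The model/results split follows the statsmodels convention::

    model = UXMDeconvolution(sample_fragments, atlas)
    result = model.fit()
    print(result.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import FragmentSet

__all__ = [
    "UXMConfig",
    "classify_fragment",
    "fragment_uxm_counts",
    "ReferenceAtlas",
    "build_atlas",
    "UXMDeconvolution",
    "DeconvolutionResult",
    "deconvolve",
]

_ALPHABET = frozenset("CT.")


@dataclass(frozen=True)
class UXMConfig:
    """Thresholds of the read-level classifier."""

    min_cpgs: int = 3  # observed CpGs a molecule must show inside a region
    u_threshold: float = 0.25  # methylated fraction at or below -> U
    m_threshold: float = 0.75  # methylated fraction at or above -> M

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_threshold < self.m_threshold <= 1.0:
            raise ValueError("need 0 <= u_threshold < m_threshold <= 1")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")


def classify_fragment(pattern: str, config: UXMConfig | None = None) -> str:
    """Classify one pattern as ``"U"``, ``"X"``, ``"M"`` or ``"excluded"``.

    Only observed calls (C/T) count; with fewer than ``min_cpgs`` of them
    the molecule is excluded.
    """
    config = config or UXMConfig()
    if not set(pattern) <= _ALPHABET:
        raise ValueError(f"invalid pattern characters in {pattern!r}")
    n = len(pattern) - pattern.count(".")
    if n < config.min_cpgs:
        return "excluded"
    f = pattern.count("C") / n
    if f <= config.u_threshold:
        return "U"
    if f >= config.m_threshold:
        return "M"
    return "X"


def _marker_lookup(markers: pd.DataFrame, n_cpgs: int) -> np.ndarray:
    """CpG serial -> marker row (or -1).  Markers must not overlap."""
    lut = np.full(n_cpgs, -1, dtype=np.int64)
    for row, (a, b) in enumerate(zip(markers["start_idx"], markers["end_idx"])):
        if (lut[a - 1 : b] != -1).any():
            raise ValueError("marker regions overlap in CpG-index space")
        lut[a - 1 : b] = row
    return lut


def fragment_uxm_counts(
    fragments: FragmentSet,
    markers: pd.DataFrame,
    config: UXMConfig | None = None,
) -> pd.DataFrame:
    """Per-marker U/X/M molecule counts for one sample.

    A molecule is counted toward a marker only if it observes at least
    ``min_cpgs`` CpGs inside the marker's CpG range; classification uses
    those inside calls only, so flanking CpGs cannot dilute the region.
    Multiplicity counts weight the tallies.

    Returns a DataFrame indexed like ``markers`` with columns U, X, M.
    """
    config = config or UXMConfig()
    lut = _marker_lookup(markers, fragments.genome.n_cpgs)
    frag, cpg, is_meth, w = fragments.explode_calls()
    out = np.zeros((len(markers), 3), dtype=float)
    if frag.size:
        mid = lut[cpg - 1]
        keep = mid >= 0
        frag, mid, is_meth, w = frag[keep], mid[keep], is_meth[keep], w[keep]
    if frag.size:
        key = frag * np.int64(len(markers)) + mid
        uniq, inv = np.unique(key, return_inverse=True)
        n = np.bincount(inv)
        c = np.bincount(inv, weights=is_meth.astype(float))
        # first occurrence per group: weights are constant within a fragment
        rev = np.full(uniq.size, inv.size, dtype=np.int64)
        np.minimum.at(rev, inv, np.arange(inv.size))
        gw = w[rev]
        gm = (uniq % len(markers)).astype(np.int64)
        ok = n >= config.min_cpgs
        f = np.where(n > 0, c / np.maximum(n, 1), 0.0)
        cls = np.where(f <= config.u_threshold, 0, np.where(f >= config.m_threshold, 2, 1))
        for cl in (0, 1, 2):
            m = ok & (cls == cl)
            np.add.at(out[:, cl], gm[m], gw[m])
    return pd.DataFrame(out, index=markers.index, columns=["U", "X", "M"])


@dataclass
class ReferenceAtlas:
    """Markers x cell types matrix of U-molecule proportions.

    ``u_prop`` holds NaN where a cell type contributed no eligible molecule
    to a marker; such rows are unusable for deconvolution and are dropped by
    :class:`UXMDeconvolution` (with the count in the result's diagnostics).
    """

    markers: pd.DataFrame
    u_prop: pd.DataFrame  # markers x cell types, in [0, 1] or NaN
    depth: pd.DataFrame  # molecules backing each proportion
    config: UXMConfig = field(default_factory=UXMConfig)

    @property
    def cell_types(self) -> list[str]:
        return list(self.u_prop.columns)

    @property
    def usable(self) -> np.ndarray:
        return ~self.u_prop.isna().any(axis=1).to_numpy()

    def to_tsv(self, path) -> None:
        out = self.markers.copy()
        for t in self.cell_types:
            out[t] = self.u_prop[t].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def build_atlas(
    reference_sets: Mapping[str, Sequence[FragmentSet]],
    markers: pd.DataFrame,
    config: UXMConfig | None = None,
) -> ReferenceAtlas:
    """Build the U-proportion reference atlas from labelled samples.

    Replicate samples of a cell type are pooled before the proportion
    U/(U+X+M) is formed per marker.
    """
    config = config or UXMConfig()
    if not len(markers):
        raise ValueError("marker set is empty")
    u_prop, depth = {}, {}
    for cell_type, replicates in reference_sets.items():
        if not replicates:
            raise ValueError(f"{cell_type}: needs >= 1 reference sample")
        counts = sum(
            (fragment_uxm_counts(fs, markers, config) for fs in replicates[1:]),
            fragment_uxm_counts(replicates[0], markers, config),
        )
        tot = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u_prop[cell_type] = np.where(tot > 0, counts["U"] / tot, np.nan)
        depth[cell_type] = tot.to_numpy()
    return ReferenceAtlas(
        markers.reset_index(drop=True),
        pd.DataFrame(u_prop, index=pd.RangeIndex(len(markers))),
        pd.DataFrame(depth, index=pd.RangeIndex(len(markers))),
        config,
    )


@dataclass
class DeconvolutionResult:
    """Estimated cell-type proportions of one mixture.

    ``proportions`` are non-negative and sum to one (all-NaN if the sample
    was degenerate: no usable marker had any signal).
    """

    proportions: pd.Series
    resid_norm: float
    n_markers_used: int
    n_markers_dropped: int
    degenerate: bool = False

    @property
    def n_detected(self) -> int:
        """Cell types assigned a strictly positive proportion."""
        if self.degenerate:
            return 0
        return int((self.proportions > 0).sum())

    def summary(self) -> str:
        lines = [
            "UXM deconvolution result",
            "=" * 44,
            f"markers used / dropped : {self.n_markers_used} / {self.n_markers_dropped}",
            f"residual norm          : {self.resid_norm:.6g}",
            f"cell types detected    : {self.n_detected}",
            "-" * 44,
            f"{'cell type':<24}{'proportion':>12}",
        ]
        for t, v in self.proportions.sort_values(ascending=False).items():
            lines.append(f"{t:<24}{v:>12.4f}")
        return "\n".join(lines)


class UXMDeconvolution:
    """NNLS deconvolution model of one cfDNA sample against an atlas.

    Parameters
    ----------
    fragments
        The mixture's fragment set.
    atlas
        :class:`ReferenceAtlas` over marker regions.
    config
        Classifier thresholds; defaults to the atlas's own.
    weighted
        If True, rows are weighted by the square root of the sample's
        molecule count in the marker (heteroscedasticity weighting);
        default unweighted.
    """

    def __init__(
        self,
        fragments: FragmentSet,
        atlas: ReferenceAtlas,
        config: UXMConfig | None = None,
        weighted: bool = False,
    ):
        if len(fragments) == 0:
            raise ValueError("sample fragment set is empty")
        self.fragments = fragments
        self.atlas = atlas
        self.config = config or atlas.config
        self.weighted = weighted

    def fit(self) -> DeconvolutionResult:
        atlas = self.atlas
        counts = fragment_uxm_counts(self.fragments, atlas.markers, self.config)
        tot = counts.sum(axis=1).to_numpy()
        usable = (tot > 0) & atlas.usable
        n_drop = int((~usable).sum())
        types = atlas.cell_types
        if not usable.any():
            return self._degenerate(types, n_drop)
        with np.errstate(invalid="ignore", divide="ignore"):
            b = (counts["U"].to_numpy() / np.maximum(tot, 1))[usable]
        A = atlas.u_prop.to_numpy(dtype=float)[usable]
        if self.weighted:
            wr = np.sqrt(tot[usable])
            A = A * wr[:, None]
            b = b * wr
        w, rnorm = nnls(A, b)
        total = w.sum()
        if total <= 0:
            return self._degenerate(types, n_drop, int(usable.sum()), rnorm)
        return DeconvolutionResult(
            proportions=pd.Series(w / total, index=types),
            resid_norm=float(rnorm),
            n_markers_used=int(usable.sum()),
            n_markers_dropped=n_drop,
        )

    @staticmethod
    def _degenerate(types, n_drop, n_used=0, rnorm=float("nan")):
        return DeconvolutionResult(
            proportions=pd.Series(np.nan, index=types),
            resid_norm=float(rnorm),
            n_markers_used=n_used,
            n_markers_dropped=n_drop,
            degenerate=True,
        )


def deconvolve(
    fragments: FragmentSet,
    atlas: ReferenceAtlas,
    config: UXMConfig | None = None,
    weighted: bool = False,
) -> DeconvolutionResult:
    """Functional wrapper: ``UXMDeconvolution(...).fit()``."""
    return UXMDeconvolution(fragments, atlas, config, weighted).fit()
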