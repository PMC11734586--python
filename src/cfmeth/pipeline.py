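"""End-to-end synthetic pipeline: atlas -> markers -> UXM atlas.

Convenience layer used by the evaluation experiments, the CLI and the
acceptance workflow.  Starting from a realized :class:`SyntheticAtlas` it
simulates the reference cohort, derives per-CpG beta tracks, segments the
genome, builds the block methylation table, finds per-type markers for the
requested (top_k, min_cpg) configurations and assembles the U-proportion
reference atlases used for deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import ReferenceAtlas, UXMConfig, build_atlas
from .io import BetaTrack, Block, FragmentSet, beta_from_fragments
from .markers import MarkerConfig, block_methylation_table, find_markers, marker_union
from .segmentation import SegmentationConfig, segment
from .synthetic import SyntheticAtlas

__all__ = ["ReferencePipeline"]


@dataclass
class ReferencePipeline:
    """Reference cohort plus everything derived from it."""

    atlas: SyntheticAtlas
    samples: dict[str, FragmentSet]
    sample_types: dict[str, str]
    tracks: dict[str, BetaTrack]
    blocks_by_min_cpg: dict[int, list[Block]]
    tables_by_min_cpg: dict[int, pd.DataFrame]

    @classmethod
    def build(
        cls,
        atlas: SyntheticAtlas,
        coverage: float = 30.0,
        min_cpgs: Sequence[int] = (3,),
        seed: int = 0,
        marker_config: MarkerConfig | None = None,
        segmentation_penalty: float = 0.05,
        use_true_blocks: bool = False,
    ) -> "ReferencePipeline":
        """Simulate the reference cohort and run segmentation + tabling.

        With ``use_true_blocks`` the generator's planted block boundaries are
        used directly instead of re-deriving them by the segmentation DP
        (useful for isolating downstream stages in tests).
        """
        mc = marker_config or MarkerConfig()
        ss = np.random.SeedSequence(seed)
        samples, sample_types, tracks = {}, {}, {}
        for t in atlas.spec.cell_types:
            for r in range(atlas.spec.n_replicates):
                s = int(ss.spawn(1)[0].generate_state(1, dtype=np.uint32)[0] % (2**31))
                name = f"{t}_rep{r + 1}"
                fs = atlas.simulate_reference_sample(t, coverage, s)
                samples[name] = fs
                sample_types[name] = t
                tracks[name] = beta_from_fragments(fs)

        track_list = list(tracks.values())
        blocks_by, tables_by = {}, {}
        for m in min_cpgs:
            if use_true_blocks:
                blocks = list(atlas.blocks)
            else:
                blocks = segment(
                    track_list,
                    SegmentationConfig(min_cpg=m, penalty=segmentation_penalty),
                )
            blocks_by[m] = blocks
            tables_by[m] = block_methylation_table(
                tracks, blocks, min_depth=mc.min_depth
            )
        return cls(atlas, samples, sample_types, tracks, blocks_by, tables_by)

    # -- markers and atlases ----------------------------------------------

    def markers_for(
        self, min_cpg: int, top_k: int, config: MarkerConfig | None = None
    ) -> dict[str, pd.DataFrame]:
        """Per-cell-type hypomethylated marker sets for one configuration."""
        cfg = replace(config or MarkerConfig(), top_k=top_k)
        table = self.tables_by_min_cpg[min_cpg]
        blocks = self.blocks_by_min_cpg[min_cpg]
        out = {}
        for t in self.atlas.spec.cell_types:
            m = find_markers(table, self.sample_types, t, blocks, cfg)
            out[t] = m[m["direction"] == "hypo"].reset_index(drop=True)
        return out

    def reference_atlas(
        self,
        min_cpg: int = 3,
        top_k: int = 500,
        marker_config: MarkerConfig | None = None,
        uxm_config: UXMConfig | None = None,
    ) -> ReferenceAtlas:
        """Markers for every type + pooled replicate U proportions."""
        marker_sets = self.markers_for(min_cpg, top_k, marker_config)
        union = marker_union(marker_sets)
        by_type: dict[str, list[FragmentSet]] = {}
        for name, fs in self.samples.items():
            by_type.setdefault(self.sample_types[name], []).append(fs)
        return build_atlas(by_type, union, uxm_config)

    def atlases_for_grid(
        self,
        marker_counts: Sequence[int],
        min_cpgs: Sequence[int],
        marker_config: MarkerConfig | None = None,
        uxm_config: UXMConfig | None = None,
    ) -> dict[tuple[int, int], ReferenceAtlas]:
        return {
            (k, m): self.reference_atlas(m, k, marker_config, uxm_config)
            for k in marker_counts
            for m in min_cpgs
        }
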