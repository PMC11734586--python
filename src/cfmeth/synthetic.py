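"""Synthetic atlases, reference samples and cfDNA mixtures.

This module generates fragment-level WGBS data with the statistical
structure the downstream analysis assumes, so that segmentation, marker
discovery, atlas construction and deconvolution are all testable without any
external download:

* a multi-cell-type reference atlas in which each cell type carries a set of
  planted, private hypomethylated blocks (mean methylation ~0.10) against a
  methylated baseline (~0.85) — separations well above the 0.3 marker
  threshold by construction;
* fragment-level reads of 3-10 CpGs with bisulfite-conversion noise in both
  directions;
* plasma-like cfDNA mixtures with a blood-dominated background composition
  and a spike-in of a rare cell type at a known fraction (the 0-10% grid of
  the detection-limit experiments).

All randomness flows through explicit seeds; identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeCpGIndex
from .io import Block, FragmentSet

__all__ = [
    "AtlasSpec",
    "MixtureSpec",
    "MixtureTruth",
    "SyntheticAtlas",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_BACKGROUND",
    "make_genome",
    "simulate_reference_sample",
    "simulate_mixture",
]

#: Cell types of the desk-scale atlas.  The first four are the blood lineages
#: that dominate plasma cfDNA; the two neuronal types are absent from healthy
#: plasma and serve as spike-in targets.
DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "Granulocyte",
    "Megakaryocyte",
    "Monocyte",
    "Lymphocyte",
    "Endothelium",
    "Hepatocyte",
    "Erythroblast",
    "Adipocyte",
    "CorticalNeuron",
    "MotorNeuron",
)

#: Blood-dominated plasma background: four blood types carry 90% of cfDNA,
#: the remainder is spread over solid-tissue types; neuronal DNA is absent.
DEFAULT_BACKGROUND: dict[str, float] = {
    "Granulocyte": 0.35,
    "Megakaryocyte": 0.25,
    "Monocyte": 0.15,
    "Lymphocyte": 0.15,
    "Endothelium": 0.04,
    "Hepatocyte": 0.03,
    "Erythroblast": 0.02,
    "Adipocyte": 0.01,
    "CorticalNeuron": 0.0,
    "MotorNeuron": 0.0,
}


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters of the synthetic reference atlas.

    Defaults emulate, at desk scale, a multi-tissue methylation atlas with
    enough private hypomethylated blocks per cell type to support the
    500-marker deconvolution configuration.
    """

    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_replicates: int = 3
    n_blocks: int = 6000
    n_private_per_type: int = 500
    cpgs_per_block: tuple[int, int] = (3, 8)  # inclusive range
    intra_block_gap: tuple[int, int] = (2, 60)  # bp between CpGs in a block
    inter_block_gap: tuple[int, int] = (500, 3000)
    max_block_bp: int = 5000
    baseline_beta_mean: float = 0.85
    baseline_beta_sd: float = 0.04
    hypo_beta_mean: float = 0.10
    hypo_beta_sd: float = 0.03
    replicate_jitter_sd: float = 0.03
    conversion_error: float = 0.005  # unmethylated C read as C
    inappropriate_conversion: float = 0.005  # methylated C read as T
    fragment_cpgs: tuple[int, int] = (3, 10)
    n_chroms: int = 2
    structure_seed: int = 7  # genome + planted-block layout

    def __post_init__(self) -> None:
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("cell types must be unique")
        if self.n_private_per_type * len(self.cell_types) > self.n_blocks:
            raise ValueError("not enough blocks for disjoint private sets")
        for m in (self.baseline_beta_mean, self.hypo_beta_mean):
            if not 0.0 <= m <= 1.0:
                raise ValueError("beta means must lie in [0, 1]")
        if abs(self.baseline_beta_mean - self.hypo_beta_mean) < 0.3:
            raise ValueError(
                "planted separation below the 0.3 marker threshold"
            )
        worst = (self.cpgs_per_block[1] - 1) * self.intra_block_gap[1] + 2
        if worst > self.max_block_bp:
            raise ValueError("CpG spacing can exceed max_block_bp")


@dataclass(frozen=True)
class MixtureSpec:
    """One synthetic cfDNA mixture: background composition plus a spike."""

    spike_cell_type: str = "MotorNeuron"
    spike_fraction: float = 0.01
    coverage: float = 10.0
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND)
    )

    def __post_init__(self) -> None:
        total = float(sum(self.background.values()))
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"background fractions sum to {total}, not 1")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike fraction must lie in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    def composition(self, cell_types: Sequence[str]) -> np.ndarray:
        """Final per-type fractions with the spike substituted in."""
        if self.spike_cell_type not in cell_types:
            raise KeyError(f"unknown spike cell type {self.spike_cell_type!r}")
        w = np.array([self.background.get(t, 0.0) for t in cell_types], float)
        w *= 1.0 - self.spike_fraction
        w[list(cell_types).index(self.spike_cell_type)] += self.spike_fraction
        return w


@dataclass(frozen=True)
class MixtureTruth:
    """Exact realized composition of a simulated mixture."""

    fractions: dict[str, float]
    spike_cell_type: str
    spike_fraction_nominal: float
    spike_fraction_realized: float
    n_fragments: int


class SyntheticAtlas:
    """A realized synthetic atlas: genome, blocks, per-type beta profile.

    Built deterministically from an :class:`AtlasSpec` and a structure seed;
    all read-level simulation then flows through per-call seeds.
    """

    def __init__(self, spec: AtlasSpec, seed: int | None = None):
        self.spec = spec
        seed = spec.structure_seed if seed is None else seed
        rng = np.random.default_rng(seed)
        self.genome, self.blocks = _make_genome_and_blocks(spec, rng)
        n_types, n_blocks = len(spec.cell_types), spec.n_blocks

        # Disjoint private hypomethylated block sets, one per cell type.
        order = rng.permutation(n_blocks)
        self.private_blocks: dict[str, np.ndarray] = {}
        for i, t in enumerate(spec.cell_types):
            lo = i * spec.n_private_per_type
            self.private_blocks[t] = np.sort(
                order[lo : lo + spec.n_private_per_type]
            )

        baseline = np.clip(
            rng.normal(spec.baseline_beta_mean, spec.baseline_beta_sd, n_blocks),
            0.0,
            1.0,
        )
        self.block_beta = np.tile(baseline, (n_types, 1))
        for i, t in enumerate(spec.cell_types):
            idx = self.private_blocks[t]
            self.block_beta[i, idx] = np.clip(
                rng.normal(spec.hypo_beta_mean, spec.hypo_beta_sd, idx.size),
                0.0,
                1.0,
            )

        # per-CpG block membership (blocks tile the genome's CpGs)
        self.block_of_cpg = np.empty(self.genome.n_cpgs, dtype=np.int64)
        for j, b in enumerate(self.blocks):
            self.block_of_cpg[b.start_idx - 1 : b.end_idx] = j

    # -- beta profiles -----------------------------------------------------

    def _type_index(self, cell_type: str) -> int:
        try:
            return self.spec.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None

    def cpg_beta(self, cell_type: str, rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-CpG Bernoulli methylation probability for one sample.

        With ``rng`` given, per-block replicate jitter is drawn, emulating
        biological variation between individuals/replicates of a type.
        """
        betas = self.block_beta[self._type_index(cell_type)].copy()
        if rng is not None and self.spec.replicate_jitter_sd > 0:
            betas = np.clip(
                betas + rng.normal(0.0, self.spec.replicate_jitter_sd, betas.size),
                0.0,
                1.0,
            )
        return betas[self.block_of_cpg]

    def _observed_p(self, p: np.ndarray) -> np.ndarray:
        """True methylation probability -> observed-'C' probability."""
        s = self.spec
        return p * (1.0 - s.inappropriate_conversion) + (1.0 - p) * s.conversion_error

    # -- simulation --------------------------------------------------------

    def simulate_reference_sample(
        self, cell_type: str, coverage: float, seed: int
    ) -> FragmentSet:
        """Simulate one reference WGBS sample of a pure cell type.

        Fragments carry 3-10 CpGs; each call is Bernoulli in the block's
        (jittered) beta, then perturbed by the conversion error rates.
        Realized coverage lands within ~1% of the target.
        """
        rng = np.random.default_rng(seed)
        p = self._observed_p(self.cpg_beta(cell_type, rng))
        starts, lens = _draw_fragments(self.genome, self.spec, coverage, rng)
        return _emit_fragments(self.genome, starts, lens, p[None, :],
                               np.zeros(starts.size, dtype=np.int64), rng)

    def simulate_mixture(
        self, mix: MixtureSpec, seed: int
    ) -> tuple[FragmentSet, MixtureTruth]:
        """Simulate a cfDNA mixture; returns fragments plus the truth record.

        Each fragment's source cell type is drawn from the background
        composition with the spike fraction substituted in; one jitter
        realization per type models the unseen individual the sample comes
        from.
        """
        rng = np.random.default_rng(seed)
        types = self.spec.cell_types
        w = mix.composition(types)
        p = np.stack([self._observed_p(self.cpg_beta(t, rng)) for t in types])
        starts, lens = _draw_fragments(self.genome, self.spec, mix.coverage, rng)
        src = rng.choice(len(types), size=starts.size, p=w)
        frags = _emit_fragments(self.genome, starts, lens, p, src, rng)
        counts = np.bincount(src, minlength=len(types))
        fractions = {t: float(c) / starts.size for t, c in zip(types, counts)}
        truth = MixtureTruth(
            fractions=fractions,
            spike_cell_type=mix.spike_cell_type,
            spike_fraction_nominal=mix.spike_fraction,
            spike_fraction_realized=fractions[mix.spike_cell_type],
            n_fragments=int(starts.size),
        )
        return frags, truth


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _make_genome_and_blocks(
    spec: AtlasSpec, rng: np.random.Generator
) -> tuple[GenomeCpGIndex, list[Block]]:
    lo, hi = spec.cpgs_per_block
    sizes = rng.integers(lo, hi + 1, spec.n_blocks)
    glo, ghi = spec.intra_block_gap
    blo, bhi = spec.inter_block_gap

    per_chrom = np.array_split(np.arange(spec.n_blocks), spec.n_chroms)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    positions, block_ranges = [], []  # block_ranges: (chrom_i, first, last) serial
    serial = 1
    for ci, block_ids in enumerate(per_chrom):
        pos_list = []
        cur = int(rng.integers(1, 10_000))
        for b in block_ids:
            n = int(sizes[b])
            gaps = rng.integers(glo, ghi + 1, n - 1) if n > 1 else np.empty(0, int)
            block_pos = cur + np.concatenate([[0], np.cumsum(gaps)])
            span = int(block_pos[-1] - block_pos[0]) + 2
            if span > spec.max_block_bp:
                raise ValueError("generated block exceeds max_block_bp")
            pos_list.append(block_pos)
            block_ranges.append((ci, serial, serial + n - 1))
            serial += n
            cur = int(block_pos[-1]) + int(rng.integers(blo, bhi + 1))
        positions.append(np.concatenate(pos_list))
    genome = GenomeCpGIndex(tuple(chrom_names), tuple(positions))
    blocks = [
        Block.from_serial_range(genome, first, last)
        for _, first, last in block_ranges
    ]
    return genome, blocks


def _draw_fragments(
    genome: GenomeCpGIndex, spec: AtlasSpec, coverage: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fragment start serials and CpG lengths for a target coverage."""
    lmin, lmax = spec.fragment_cpgs
    mean_len = 0.5 * (lmin + lmax)
    n_cpg = genome.n_cpgs
    n_frags = max(1, int(round(coverage * n_cpg / mean_len)))
    lens = rng.integers(lmin, lmax + 1, n_frags)
    starts = 1 + (rng.random(n_frags) * (n_cpg - lens + 1)).astype(np.int64)
    # truncate fragments at chromosome boundaries
    ci = genome.serial_to_chrom(starts)
    chrom_last = np.array([genome.chrom_serial_range(c)[1] for c in genome.chroms])
    lens = np.minimum(lens, chrom_last[ci] - starts + 1)
    return starts, lens


def _emit_fragments(
    genome: GenomeCpGIndex,
    starts: np.ndarray,
    lens: np.ndarray,
    p_by_source: np.ndarray,  # (n_sources, n_cpgs) observed-'C' probabilities
    source: np.ndarray,  # per-fragment source row
    rng: np.random.Generator,
) -> FragmentSet:
    n = starts.size
    total = int(lens.sum())
    first = np.cumsum(lens) - lens
    within = np.arange(total) - np.repeat(first, lens)
    cpg0 = np.repeat(starts, lens) + within - 1  # 0-based CpG array index
    src = np.repeat(source, lens)
    calls = rng.random(total) < p_by_source[src, cpg0]
    chars = np.where(calls, np.uint8(ord("C")), np.uint8(ord("T")))
    s = chars.tobytes().decode("ascii")
    bounds = np.concatenate([[0], np.cumsum(lens)])
    patterns = [s[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    ci = genome.serial_to_chrom(starts)
    df = pd.DataFrame(
        {
            "chrom": [genome.chroms[i] for i in ci],
            "start": starts,
            "pattern": patterns,
            "count": np.ones(n, dtype=np.int64),
        }
    )
    df = df.sort_values(["start", "pattern"], kind="stable").reset_index(drop=True)
    return FragmentSet(df, genome, validate=False)


# ---------------------------------------------------------------------------
# module-level convenience wrappers
# ---------------------------------------------------------------------------


def make_genome(spec: AtlasSpec, seed: int) -> GenomeCpGIndex:
    """Generate the CpG index alone (blocks respect the 5000-bp span cap)."""
    rng = np.random.default_rng(seed)
    genome, _ = _make_genome_and_blocks(spec, rng)
    return genome


def simulate_reference_sample(
    atlas_spec: AtlasSpec, cell_type: str, coverage: float, seed: int
) -> FragmentSet:
    return SyntheticAtlas(atlas_spec).simulate_reference_sample(
        cell_type, coverage, seed
    )


def simulate_mixture(
    mixture_spec: MixtureSpec, atlas_spec: AtlasSpec, seed: int
) -> tuple[FragmentSet, MixtureTruth]:
    return SyntheticAtlas(atlas_spec).simulate_mixture(mixture_spec, seed)
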