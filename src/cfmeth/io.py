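"""Readers, writers and utilities for fragment-level methylation data.

The central on-disk format is the PAT dialect used by fragment-aware WGBS
pipelines: a tab-separated, CpG-index-sorted file with columns

    chrom    start_cpg_serial    pattern    count

where the pattern string encodes one sequenced molecule's CpG calls over the
alphabet ``C`` (methylated), ``T`` (unmethylated) and ``.`` (unobserved), and
``count`` is the multiplicity of identical molecules.  Per-CpG count tracks
("BETA" tracks: methylated and total read counts per CpG serial index) and
BED emission for blocks round out the I/O surface.

Coverage is defined throughout as mean observed CpG calls per CpG site:
(total C/T calls across all fragments) / (CpGs in the genome).
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeCpGIndex

__all__ = [
    "FragmentRecord",
    "FragmentSet",
    "BetaTrack",
    "Block",
    "read_pat",
    "write_pat",
    "merge_fragment_sets",
    "resample_to_coverage",
    "beta_from_fragments",
    "read_beta",
    "write_beta",
    "blocks_to_bed",
    "blocks_to_frame",
    "DEFAULT_COVERAGE_GRID",
]

#: The coverage sweep used in the spike-in detection-limit experiments.
DEFAULT_COVERAGE_GRID: tuple[float, ...] = (2.5, 5.0, 10.0, 20.0, 30.0)

_PATTERN_ALPHABET = frozenset("CT.")


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced molecule's CpG methylation pattern.

    ``start`` is the 1-based genome-wide serial index of the first CpG the
    pattern covers; ``count`` is the number of identical molecules observed.
    """

    chrom: str
    start: int
    pattern: str
    count: int = 1

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValueError("pattern must have length >= 1")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not set(self.pattern) <= _PATTERN_ALPHABET:
            bad = set(self.pattern) - _PATTERN_ALPHABET
            raise ValueError(f"invalid pattern characters: {sorted(bad)}")

    @property
    def n_observed(self) -> int:
        """Number of observed (non-'.') CpG calls."""
        return len(self.pattern) - self.pattern.count(".")


class FragmentSet:
    """A collection of fragments anchored to one :class:`GenomeCpGIndex`.

    Internally a :class:`pandas.DataFrame` with columns
    ``chrom, start, pattern, count``; rows are kept in file order (sorted by
    serial start index for anything this package writes).
    """

    COLUMNS = ("chrom", "start", "pattern", "count")

    def __init__(self, df: pd.DataFrame, genome: GenomeCpGIndex, validate: bool = True):
        df = df.reset_index(drop=True)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        self.df = df[list(self.COLUMNS)]
        self.genome = genome
        if validate and len(df):
            self._validate()

    def _validate(self) -> None:
        df = self.df
        if (df["count"] < 1).any():
            raise ValueError("fragment counts must be >= 1")
        lens = df["pattern"].str.len().to_numpy()
        if (lens < 1).any():
            raise ValueError("patterns must have length >= 1")
        bad = ~df["pattern"].map(lambda p: set(p) <= _PATTERN_ALPHABET)
        if bad.any():
            raise ValueError(f"invalid pattern at row {int(np.flatnonzero(bad)[0])}")
        for chrom, sub in df.groupby("chrom", sort=False):
            first, last = self.genome.chrom_serial_range(str(chrom))
            ends = sub["start"].to_numpy() + sub["pattern"].str.len().to_numpy() - 1
            if (sub["start"] < first).any() or (ends > last).any():
                raise ValueError(f"fragment outside CpG index on {chrom}")

    # -- container basics --------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield FragmentRecord(row.chrom, int(row.start), row.pattern, int(row.count))

    @property
    def n_fragments(self) -> int:
        """Total molecule count (multiplicities included)."""
        return int(self.df["count"].sum()) if len(self.df) else 0

    @property
    def n_calls(self) -> int:
        """Total observed CpG calls (multiplicities included)."""
        if not len(self.df):
            return 0
        obs = (
            self.df["pattern"].str.len() - self.df["pattern"].str.count(r"\.")
        ).to_numpy()
        return int((obs * self.df["count"].to_numpy()).sum())

    def coverage(self) -> float:
        """Mean observed CpG calls per CpG site of the genome."""
        return self.n_calls / self.genome.n_cpgs

    def sorted(self) -> "FragmentSet":
        df = self.df.sort_values(
            ["start", "pattern", "count"], kind="stable"
        ).reset_index(drop=True)
        return FragmentSet(df, self.genome, validate=False)

    # -- call-level view ---------------------------------------------------

    def explode_calls(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flatten to per-CpG calls.

        Returns ``(frag_row, cpg_serial, is_meth, weight)`` over observed
        (non-'.') calls only; ``weight`` is the fragment multiplicity.
        """
        df = self.df
        n = len(df)
        if n == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z, z.astype(bool), z
        pats = df["pattern"].tolist()
        lens = np.fromiter((len(p) for p in pats), dtype=np.int64, count=n)
        chars = np.frombuffer("".join(pats).encode("ascii"), dtype=np.uint8)
        frag = np.repeat(np.arange(n), lens)
        first = np.cumsum(lens) - lens
        within = np.arange(lens.sum()) - np.repeat(first, lens)
        cpg = np.repeat(df["start"].to_numpy(np.int64), lens) + within
        keep = chars != ord(".")
        is_meth = chars == ord("C")
        w = np.repeat(df["count"].to_numpy(np.int64), lens)
        return frag[keep], cpg[keep], is_meth[keep], w[keep]


@dataclass
class BetaTrack:
    """Per-CpG methylated/total read counts aligned to a genome index."""

    meth: np.ndarray
    total: np.ndarray
    genome: GenomeCpGIndex

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape or self.meth.size != self.genome.n_cpgs:
            raise ValueError("meth/total must have one entry per genome CpG")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.meth > self.total).any():
            raise ValueError("methylated count exceeds total")

    @property
    def beta(self) -> np.ndarray:
        """Methylation fraction per CpG; NaN where uncovered."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / self.total, np.nan)

    def __add__(self, other: "BetaTrack") -> "BetaTrack":
        if self.genome != other.genome:
            raise ValueError("BetaTracks use different CpG indices")
        return BetaTrack(self.meth + other.meth, self.total + other.total, self.genome)


@dataclass(frozen=True)
class Block:
    """A run of consecutive CpGs treated as one co-methylation unit.

    Serial CpG indices are 1-based inclusive; ``start``/``end`` are the
    0-based half-open genomic interval used for BED emission (the interval
    covers the C of the first CpG through the G of the last).
    """

    chrom: str
    start: int
    end: int
    start_idx: int
    end_idx: int
    flagged: bool = False  # undersized relative to the min_cpg constraint

    @property
    def n_cpgs(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def span(self) -> int:
        return self.end - self.start

    @classmethod
    def from_serial_range(
        cls, genome: GenomeCpGIndex, first: int, last: int, flagged: bool = False
    ) -> "Block":
        ci, pos = genome.serial_to_position([first, last])
        if ci[0] != ci[1]:
            raise ValueError("block crosses a chromosome boundary")
        chrom = genome.chroms[int(ci[0])]
        # BED: 0-based half-open, C of first CpG .. G of last CpG
        return cls(chrom, int(pos[0]) - 1, int(pos[1]) + 1, first, last, flagged)


# ---------------------------------------------------------------------------
# PAT I/O
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_pat(path, genome: GenomeCpGIndex) -> FragmentSet:
    """Read a PAT file (gzip-transparent) into a :class:`FragmentSet`.

    Raises
    ------
    ValueError
        On a malformed line (naming the line number) or a fragment that
        falls outside the genome's CpG index.
    """
    rows = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 tab-separated columns")
            chrom, start_s, pattern, count_s = parts
            try:
                start, count = int(start_s), int(count_s)
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer start or count") from None
            if count < 1 or len(pattern) < 1 or not set(pattern) <= _PATTERN_ALPHABET:
                raise ValueError(f"{path}:{ln}: invalid pattern or count")
            rows.append((chrom, start, pattern, count))
    df = pd.DataFrame(rows, columns=list(FragmentSet.COLUMNS))
    if not len(df):
        df = pd.DataFrame(
            {"chrom": pd.Series(dtype=str), "start": pd.Series(dtype=np.int64),
             "pattern": pd.Series(dtype=str), "count": pd.Series(dtype=np.int64)}
        )
    return FragmentSet(df, genome)


def write_pat(fragments: FragmentSet, path) -> None:
    """Write a PAT file in the set's stored row order (gzip-transparent).

    ``write_pat(read_pat(f))`` reproduces ``f`` byte-identically for sorted
    input, since row order is preserved on read.
    """
    with _open_text(path, "wt") as fh:
        for row in fragments.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.pattern}\t{row.count}\n")


# ---------------------------------------------------------------------------
# Fragment-set algebra
# ---------------------------------------------------------------------------


def merge_fragment_sets(sets: Sequence[FragmentSet]) -> FragmentSet:
    """Multiset union of fragment sets sharing one CpG index.

    Identical ``(chrom, start, pattern)`` rows have their counts summed; the
    output is re-sorted by serial start index.  Total fragment count is
    conserved.
    """
    if not sets:
        raise ValueError("need at least one fragment set")
    genome = sets[0].genome
    for s in sets[1:]:
        if s.genome != genome:
            raise ValueError("fragment sets use different CpG indices")
    df = pd.concat([s.df for s in sets], ignore_index=True)
    if len(df):
        df = (
            df.groupby(["chrom", "start", "pattern"], as_index=False, sort=False)["count"]
            .sum()
            .sort_values(["start", "pattern"], kind="stable")
            .reset_index(drop=True)
        )
    return FragmentSet(df, genome, validate=False)


def resample_to_coverage(
    fragments: FragmentSet,
    target_coverage: float,
    seed: int,
) -> FragmentSet:
    """Down-/up-sample a fragment set to a target coverage.

    Down-sampling draws molecules without replacement (a random permutation
    is consumed until the realized call total reaches the target);
    up-sampling keeps the full set and draws additional molecules with
    replacement.  Realized coverage lands within one fragment of the target.
    Deterministic given ``seed``.
    """
    if target_coverage <= 0:
        raise ValueError("target_coverage must be positive")
    if len(fragments) == 0:
        raise ValueError("cannot resample an empty fragment set")
    genome = fragments.genome
    target_calls = target_coverage * genome.n_cpgs
    df = fragments.df
    obs = (df["pattern"].str.len() - df["pattern"].str.count(r"\.")).to_numpy(np.int64)
    counts = df["count"].to_numpy(np.int64)
    current = int((obs * counts).sum())
    if abs(current - target_calls) <= obs.max():
        return FragmentSet(df.copy(), genome, validate=False)

    rng = np.random.default_rng(seed)
    copies = np.repeat(np.arange(len(df)), counts)  # one entry per molecule

    def _take(rows: np.ndarray) -> FragmentSet:
        out = df.iloc[rows].copy()
        out = (
            out.groupby(["chrom", "start", "pattern"], as_index=False, sort=False)
            .size()
            .rename(columns={"size": "count"})
            .sort_values(["start", "pattern"], kind="stable")
            .reset_index(drop=True)
        )
        return FragmentSet(out[list(FragmentSet.COLUMNS)], genome, validate=False)

    if target_calls < current:  # down-sample without replacement
        perm = rng.permutation(copies)
        cum = np.cumsum(obs[perm])
        k = int(np.searchsorted(cum, target_calls, side="left")) + 1
        return _take(perm[:k])
    # up-sample: keep everything, add draws with replacement
    extra_needed = target_calls - current
    mean_obs = obs.mean()
    draws = rng.choice(copies, size=int(np.ceil(extra_needed / mean_obs * 1.5)) + 1)
    cum = np.cumsum(obs[draws])
    k = int(np.searchsorted(cum, extra_needed, side="left")) + 1
    while k > draws.size:  # pathological: draw more
        more = rng.choice(copies, size=draws.size)
        draws = np.concatenate([draws, more])
        cum = np.cumsum(obs[draws])
        k = int(np.searchsorted(cum, extra_needed, side="left")) + 1
    return _take(np.concatenate([copies, draws[:k]]))


def beta_from_fragments(fragments: FragmentSet) -> BetaTrack:
    """Collapse fragments to a per-CpG (methylated, total) count track.

    A 'C' call contributes to both counts, a 'T' only to the total, and '.'
    to neither, each weighted by the fragment multiplicity.
    """
    genome = fragments.genome
    meth = np.zeros(genome.n_cpgs, dtype=np.int64)
    total = np.zeros(genome.n_cpgs, dtype=np.int64)
    _, cpg, is_meth, w = fragments.explode_calls()
    np.add.at(total, cpg - 1, w)
    np.add.at(meth, cpg[is_meth] - 1, w[is_meth])
    return BetaTrack(meth, total, genome)


# ---------------------------------------------------------------------------
# BETA and BED emission
# ---------------------------------------------------------------------------


def write_beta(track: BetaTrack, path) -> None:
    """Write a BETA track: one ``meth<TAB>total`` row per CpG serial index."""
    with _open_text(path, "wt") as fh:
        for m, t in zip(track.meth, track.total):
            fh.write(f"{m}\t{t}\n")


def read_beta(path, genome: GenomeCpGIndex) -> BetaTrack:
    arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if arr.shape != (genome.n_cpgs, 2):
        raise ValueError(
            f"expected {genome.n_cpgs} rows x 2 columns, got {arr.shape}"
        )
    return BetaTrack(arr[:, 0], arr[:, 1], genome)


def blocks_to_frame(blocks: Iterable[Block]) -> pd.DataFrame:
    """Tabulate blocks (BED coordinates plus CpG serial range)."""
    return pd.DataFrame(
        [
            (b.chrom, b.start, b.end, b.start_idx, b.end_idx, b.n_cpgs, b.flagged)
            for b in blocks
        ],
        columns=["chrom", "start", "end", "start_idx", "end_idx", "n_cpgs", "flagged"],
    )


def blocks_to_bed(blocks: Iterable[Block], path) -> None:
    """Emit blocks as BED (0-based half-open), name = CpG serial range."""
    with _open_text(path, "wt") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.start_idx}-{b.end_idx}\n")
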