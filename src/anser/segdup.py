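"""Segmental-duplication extraction from genome self-alignment blocks.

Alignment blocks longer than 1 kb with more than 90% identity (both
strict inequalities) are retained as candidate segmental duplications,
after discarding trivial self-hits (a block aligning an interval to
itself on the same strand).  Both copies of every surviving block are
projected onto their chromosomes and overlapping or abutting intervals
are unioned into a non-redundant interval set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger("anser")

BLOCK_COLUMNS = ["chrom_q", "start_q", "end_q", "chrom_t", "start_t", "end_t",
                 "strand", "pct_identity"]


@dataclass
class AlignmentBlock:
    """One self-alignment block, 0-based half-open on both copies."""

    chrom_q: str
    start_q: int
    end_q: int
    chrom_t: str
    start_t: int
    end_t: int
    strand: str
    pct_identity: float

    def __post_init__(self) -> None:
        if self.end_q <= self.start_q or self.end_t <= self.start_t:
            raise ValueError("block interval end must exceed start")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError("percent identity outside [0, 100]")

    @property
    def length(self) -> int:
        return self.end_q - self.start_q

    @property
    def is_self_hit(self) -> bool:
        return (self.chrom_q == self.chrom_t and self.strand == "+"
                and self.start_q == self.start_t and self.end_q == self.end_t)


@dataclass
class SDSet:
    """Non-redundant segmental-duplication intervals per chromosome."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def total_sd_bases(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def read_blocks(path: str | Path) -> list[AlignmentBlock]:
    """Read a block TSV (header per ``BLOCK_COLUMNS``), skipping bad rows."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"block table missing columns: {missing}")
    blocks = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            blocks.append(AlignmentBlock(str(row.chrom_q), int(row.start_q),
                                         int(row.end_q), str(row.chrom_t),
                                         int(row.start_t), int(row.end_t),
                                         str(row.strand), float(row.pct_identity)))
        except (ValueError, TypeError) as exc:
            logger.warning("line %d rejected: %s", lineno, exc)
    return blocks


def blocks_from_frame(df: pd.DataFrame) -> list[AlignmentBlock]:
    return [AlignmentBlock(*[row[c] for c in BLOCK_COLUMNS])
            for _, row in df.iterrows()]


def filter_blocks(blocks: list[AlignmentBlock], min_len: int = 1000,
                  min_identity: float = 90.0) -> list[AlignmentBlock]:
    """Keep blocks strictly longer than min_len with identity strictly
    above min_identity, dropping trivial self-hits."""
    return [b for b in blocks
            if b.length > min_len and b.pct_identity > min_identity
            and not b.is_self_hit]


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of possibly overlapping intervals; abutting intervals merge."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_nonredundant(blocks: list[AlignmentBlock],
                       sides: str = "both") -> SDSet:
    """Project block copies onto chromosomes and union into an SDSet.

    ``sides`` selects which copies contribute intervals: "both" (a
    duplication has two copies; the default), "query" or "target".
    """
    if sides not in {"both", "query", "target"}:
        raise ValueError("sides must be both|query|target")
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        if sides in {"both", "query"}:
            per_chrom.setdefault(b.chrom_q, []).append((b.start_q, b.end_q))
        if sides in {"both", "target"}:
            per_chrom.setdefault(b.chrom_t, []).append((b.start_t, b.end_t))
    return SDSet({c: _union(iv) for c, iv in sorted(per_chrom.items())})


def segdup_summary(blocks: list[AlignmentBlock], min_len: int = 1000,
                   min_identity: float = 90.0, sides: str = "both") -> tuple[SDSet, dict]:
    kept = filter_blocks(blocks, min_len, min_identity)
    sds = merge_nonredundant(kept, sides=sides)
    return sds, {"n_blocks_in": len(blocks), "n_kept": len(kept),
                 "total_sd_bases": sds.total_sd_bases}
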