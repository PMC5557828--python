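"""Per-fragment pooled read counts and library totals.

The fragment-ratio statistic consumes, for every fragment, the number of
reads from the female pool and from the male pool mapped to it, plus a pair
of library totals used for normalization.  Counts arrive either as a
samtools ``idxstats`` style TSV (name, length, mapped, unmapped) or are
computed directly from a coordinate-sorted BAM whose reference sequences
are the fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import pysam

from .fragments import InputFormatError, parse_fragment_name

logger = logging.getLogger(__name__)

TotalsMode = Literal["mapped_reads", "total_reads"]


@dataclass(frozen=True)
class PoolCounts:
    """Mapped-read counts for one pool, keyed by reference (fragment) name."""

    label: str
    counts: Mapping[str, int]
    lengths: Mapping[str, int]

    def total_mapped(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class CountTable:
    """Joint female/male count table with library totals.

    ``rows`` is indexed by fragment name with integer columns ``F`` (female
    pool mapped reads), ``M`` (male pool mapped reads) and ``length`` (bp).
    ``totals_mode`` records whether the totals are sums of mapped reads over
    this table or externally supplied sequenced-library sizes.
    """

    rows: pd.DataFrame
    f_total_reads: int
    m_total_reads: int
    totals_mode: TotalsMode

    def __post_init__(self) -> None:
        if self.f_total_reads <= 0:
            raise ValueError("female library total must be positive")
        if (self.rows[["F", "M"]] < 0).any().any():
            raise ValueError("negative read counts in table")
        for name, length in self.rows["length"].items():
            _, _, parsed_len = parse_fragment_name(str(name))
            if parsed_len != length:
                raise InputFormatError(
                    f"fragment {name}: stored length {length} != length "
                    f"{parsed_len} encoded in the name"
                )


def parse_idxstats(path: str | Path, pool_label: str = "") -> PoolCounts:
    """Parse a 4-column idxstats TSV into per-fragment mapped counts.

    Columns are reference name, reference length, mapped reads, unmapped
    reads; the terminal ``*`` row (unplaced reads) is skipped.
    """
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            name, length_s, mapped_s, _unmapped_s = fields
            if name == "*":
                continue
            try:
                length, mapped = int(length_s), int(mapped_s)
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: non-integer length/count fields"
                ) from None
            if mapped < 0 or length < 0:
                raise InputFormatError(f"{path}:{lineno}: negative value")
            if name in counts:
                raise InputFormatError(
                    f"{path}:{lineno}: duplicate reference name {name!r}"
                )
            counts[name] = mapped
            lengths[name] = length
    if not counts:
        logger.warning("idxstats file %s contains no reference rows", path)
    return PoolCounts(pool_label, counts, lengths)


def write_idxstats(pool: PoolCounts, path: str | Path,
                   unmapped: int = 0) -> None:
    """Write counts back in idxstats layout (with a terminal ``*`` row)."""
    with open(path, "w") as fh:
        for name, mapped in pool.counts.items():
            fh.write(f"{name}\t{pool.lengths[name]}\t{mapped}\t0\n")
        fh.write(f"*\t0\t0\t{unmapped}\n")


def count_from_bam(bam_path: str | Path, pool_label: str = "",
                   dedup: bool = True) -> PoolCounts:
    """Count primary mapped alignments per reference sequence of a BAM.

    Secondary and supplementary alignments are never counted; duplicates
    are excluded when ``dedup`` (the default, matching a Picard-marked
    input).  Equivalent to samtools idxstats when the BAM carries no
    secondary/duplicate records.
    """
    bam_path = Path(bam_path)
    if not bam_path.with_suffix(bam_path.suffix + ".bai").exists() and \
            not bam_path.with_suffix(".bai").exists():
        raise FileNotFoundError(
            f"{bam_path}: no BAM index found; run 'samtools index' first"
        )
    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for name, length in zip(bam.references, bam.lengths):
            counts[name] = 0
            lengths[name] = length
        for aln in bam.fetch():
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if dedup and aln.is_duplicate:
                continue
            counts[aln.reference_name] += 1
    return PoolCounts(pool_label, counts, lengths)


def build_count_table(
    female: PoolCounts,
    male: PoolCounts,
    totals_mode: TotalsMode = "mapped_reads",
    external_totals: tuple[int, int] | None = None,
) -> CountTable:
    """Outer-join the two pools into a CountTable and fix the totals.

    A fragment present in only one pool is zero-filled in the other
    (absence from an idxstats report means zero mapped reads).  With
    ``totals_mode="total_reads"`` the sequenced library sizes must be
    supplied as ``external_totals=(F_total, M_total)``.
    """
    names = list(dict.fromkeys([*female.counts, *male.counts]))
    only_f = [n for n in names if n not in male.counts]
    only_m = [n for n in names if n not in female.counts]
    if only_f or only_m:
        logger.warning(
            "count table outer join zero-filled %d female-only and %d "
            "male-only fragments", len(only_f), len(only_m)
        )
    lengths = {}
    for n in names:
        lf, lm = female.lengths.get(n), male.lengths.get(n)
        if lf is not None and lm is not None and lf != lm:
            raise InputFormatError(
                f"fragment {n}: length differs between pools ({lf} vs {lm})"
            )
        lengths[n] = lf if lf is not None else lm
    rows = pd.DataFrame(
        {
            "F": [female.counts.get(n, 0) for n in names],
            "M": [male.counts.get(n, 0) for n in names],
            "length": [lengths[n] for n in names],
        },
        index=pd.Index(names, name="fragment"),
    )
    if totals_mode == "total_reads":
        if external_totals is None:
            raise ValueError(
                "totals_mode='total_reads' requires external_totals="
                "(F_total_reads, M_total_reads)"
            )
        f_total, m_total = external_totals
    elif totals_mode == "mapped_reads":
        f_total = int(rows["F"].sum())
        m_total = int(rows["M"].sum())
    else:
        raise ValueError(f"unknown totals_mode {totals_mode!r}")
    return CountTable(rows, f_total, m_total, totals_mode)
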