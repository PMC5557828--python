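"""The normalized female:male fragment-ratio statistic.

For fragment *i* with female-pool count F_i and male-pool count M_i:

    R_i      = F_i / M_i
    norm     = M_total / F_total
    R_i_norm = R_i * norm

Under an XX/XY system R_i_norm concentrates near 0 for Y-linked fragments
(females carry no Y), near 1 for autosomal fragments and near 2 for X-linked
fragments (two female X copies vs one male copy).  Fragments with fewer than
``min_male_reads`` male reads are set aside as low-coverage; Y candidates
are the deep fragments with R_i_norm strictly below the threshold
(0.3 by default, 0.15 for the stringent marker pass).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .counts import CountTable

Y_MAX_DEFAULT = 0.3
STRINGENT_MAX_DEFAULT = 0.15
MIN_MALE_READS_DEFAULT = 15
X_MIN_DEFAULT = 1.5
AUTO_BAND_DEFAULT = (0.6, 1.4)

BANDS = ("Y_candidate", "autosome_like", "X_like", "low_coverage",
         "unclassified")


@dataclass(frozen=True)
class RatioRecord:
    fragment: str
    F: int
    M: int
    r: float | None          # F/M, None when M == 0
    r_norm: float | None     # (F/M) * norm, None when M == 0
    passes_depth: bool
    band: str


def compute_norm(table: CountTable) -> float:
    """Library-size normalization factor M_total / F_total."""
    return table.m_total_reads / table.f_total_reads


def classify_fragment(
    r_norm: float | None,
    m_reads: int,
    y_max: float = Y_MAX_DEFAULT,
    min_male_reads: int = MIN_MALE_READS_DEFAULT,
    x_min: float = X_MIN_DEFAULT,
    auto_band: tuple[float, float] = AUTO_BAND_DEFAULT,
) -> str:
    """Band assignment; low coverage trumps any ratio value.

    Thresholds are strict: a fragment at exactly ``y_max`` is not a Y
    candidate.  The X and autosome band edges are diagnostic only — the
    method's inference uses only the Y threshold and the depth filter.
    """
    if m_reads < min_male_reads:
        return "low_coverage"
    assert r_norm is not None  # M >= min_male_reads >= 1
    if r_norm < y_max:
        return "Y_candidate"
    if r_norm >= x_min:
        return "X_like"
    if auto_band[0] <= r_norm <= auto_band[1]:
        return "autosome_like"
    return "unclassified"


def compute_ratios(
    table: CountTable,
    norm: float | None = None,
    y_max: float = Y_MAX_DEFAULT,
    min_male_reads: int = MIN_MALE_READS_DEFAULT,
    x_min: float = X_MIN_DEFAULT,
    auto_band: tuple[float, float] = AUTO_BAND_DEFAULT,
) -> list[RatioRecord]:
    """Compute R_i, R_i_norm and a band for every fragment in the table."""
    if norm is None:
        norm = compute_norm(table)
    if not (norm > 0 and math.isfinite(norm)):
        raise ValueError(f"norm must be positive and finite, got {norm}")
    records = []
    for name, row in table.rows.iterrows():
        f, m = int(row["F"]), int(row["M"])
        if m > 0:
            r = f / m
            r_norm = r * norm
        else:
            r = r_norm = None
        band = classify_fragment(r_norm, m, y_max=y_max,
                                 min_male_reads=min_male_reads,
                                 x_min=x_min, auto_band=auto_band)
        records.append(RatioRecord(str(name), f, m, r, r_norm,
                                   passes_depth=m >= min_male_reads,
                                   band=band))
    return records


def select_candidates(
    records: Iterable[RatioRecord],
    y_max: float = Y_MAX_DEFAULT,
) -> list[RatioRecord]:
    """Deep fragments with R_i_norm strictly below ``y_max``.

    Monotone in the threshold: candidates(t1) is a subset of candidates(t2)
    whenever t1 <= t2.
    """
    return [
        r for r in records
        if r.passes_depth and r.r_norm is not None and r.r_norm < y_max
    ]


def write_ratios_tsv(records: Sequence[RatioRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tF\tM\tR\tR_norm\tpasses_depth\tband\n")
        for r in records:
            r_s = "NA" if r.r is None else repr(r.r)
            rn_s = "NA" if r.r_norm is None else repr(r.r_norm)
            fh.write(f"{r.fragment}\t{r.F}\t{r.M}\t{r_s}\t{rn_s}\t"
                     f"{int(r.passes_depth)}\t{r.band}\n")


def read_ratios_tsv(path: str | Path) -> list[RatioRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["fragment", "F"]:
            raise ValueError(f"{path}: not a ratio TSV")
        for line in fh:
            frag, f, m, r, rn, pd_, band = line.rstrip("\n").split("\t")
            records.append(RatioRecord(
                frag, int(f), int(m),
                None if r == "NA" else float(r),
                None if rn == "NA" else float(rn),
                bool(int(pd_)), band,
            ))
    return records
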