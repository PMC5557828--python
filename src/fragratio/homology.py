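"""Stringent-candidate homology filtering against a female assembly.

Fragments that look Y-linked by depth ratio but share strong homology with
the female assembly are poor marker candidates: a PCR primer pair designed
on them would amplify in both sexes.  Stringent candidates (R_i_norm <
0.15) are therefore searched against the female assembly with a nucleotide
aligner, and any fragment with a hit at e-value < 1e-5 is discarded.  This
module consumes the standard 12-column tabular alignment report (BLAST
outfmt 6), so any aligner emitting that dialect works.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .fragments import InputFormatError, parse_fragment_name
from .ratios import RatioRecord

logger = logging.getLogger(__name__)

EVALUE_MAX_DEFAULT = 1e-5


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular alignment output (1-based inclusive
    subject/query coordinates; s_start > s_end marks a minus-strand hit)."""

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float


def parse_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Parse outfmt-6 style hits, keeping file order; '#' lines skipped."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise InputFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = AlignmentHit(
                    query=fields[0], subject=fields[1],
                    pct_identity=float(fields[2]), aln_len=int(fields[3]),
                    mismatches=int(fields[4]), gap_opens=int(fields[5]),
                    q_start=int(fields[6]), q_end=int(fields[7]),
                    s_start=int(fields[8]), s_end=int(fields[9]),
                    evalue=float(fields[10]), bit_score=float(fields[11]),
                )
            except ValueError:
                raise InputFormatError(
                    f"{path}:{lineno}: malformed numeric field"
                ) from None
            if hit.evalue < 0:
                raise InputFormatError(f"{path}:{lineno}: negative e-value")
            hits.append(hit)
    return hits


def filter_by_homology(
    stringent_candidates: Iterable[RatioRecord | str],
    hits: Iterable[AlignmentHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
) -> list[str]:
    """Discard candidates with any female-assembly hit below ``evalue_max``.

    A fragment's best hit is its minimum-e-value hit, so "any hit below the
    threshold" and "best hit below the threshold" select the same set.
    The comparison is strict (<); with no hits the candidate set is
    returned unchanged.  Order of the input candidates is preserved.
    """
    names = [c.fragment if isinstance(c, RatioRecord) else c
             for c in stringent_candidates]
    known = set(names)
    flagged: set[str] = set()
    for hit in hits:
        if hit.query not in known:
            logger.warning("alignment hit for unknown fragment %r ignored",
                           hit.query)
            continue
        if hit.evalue < evalue_max:
            flagged.add(hit.query)
    return [n for n in names if n not in flagged]


def export_marker_candidates(
    retained: Sequence[str],
    fragment_fasta: str | Path,
    ratio_by_name: Mapping[str, RatioRecord],
    out_fasta: str | Path,
    out_tsv: str | Path,
) -> None:
    """Write retained marker fragments as FASTA + TSV (sorted by scaffold,
    ordinal) for downstream primer design."""
    seqs = {rec.id: rec for rec in SeqIO.parse(str(fragment_fasta), "fasta")}
    missing = [n for n in retained if n not in seqs]
    if missing:
        raise KeyError(
            f"{len(missing)} retained fragments missing from {fragment_fasta}:"
            f" e.g. {missing[:3]}"
        )
    if not retained:
        logger.warning("no marker candidates retained; writing empty outputs")
    ordered = sorted(retained, key=lambda n: (parse_fragment_name(n)[0],
                                              parse_fragment_name(n)[1]))
    SeqIO.write([seqs[n] for n in ordered], str(out_fasta), "fasta")
    with open(out_tsv, "w") as fh:
        fh.write("fragment\tscaffold\tR_norm\tF\tM\n")
        for name in ordered:
            rec = ratio_by_name[name]
            rn = "NA" if rec.r_norm is None else repr(rec.r_norm)
            fh.write(f"{name}\t{parse_fragment_name(name)[0]}\t{rn}\t"
                     f"{rec.F}\t{rec.M}\n")
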