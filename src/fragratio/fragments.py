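"""Split softmasked scaffolds into unmasked fragments.

A softmasked assembly marks repeat bases as lowercase.  The fragment-ratio
method treats every maximal run of uppercase, non-N bases as an independent
unit ("fragment") of read-depth comparison between the sexed pools.  Runs
shorter than a minimum length (default 200 bp) are discarded, and retained
fragments are named ``{scaffold}_{ordinal}_{length}`` with 1-based ordinals
assigned along the scaffold after the length filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_MIN_FRAGMENT_LEN = 200

_ALLOWED = set("ACGTNacgtn")
_FRAGMENT_RE = re.compile(r"[ACGT]+")
_FRAGMENT_RE_KEEP_N = re.compile(r"[ACGTN]+")
_NAME_RE = re.compile(r"^(?P<scaffold>.+)_(?P<ordinal>\d+)_(?P<length>\d+)$")


class InputFormatError(ValueError):
    """Raised for malformed input files (bad characters, bad columns)."""


@dataclass(frozen=True)
class MaskedScaffold:
    """A scaffold sequence where lowercase marks repeat-masked bases."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InputFormatError(f"scaffold {self.id!r}: empty sequence")
        bad = next((i for i, c in enumerate(self.seq) if c not in _ALLOWED), None)
        if bad is not None:
            raise InputFormatError(
                f"scaffold {self.id!r}: invalid character {self.seq[bad]!r} "
                f"at offset {bad}"
            )


@dataclass(frozen=True)
class Fragment:
    """An unmasked segment of a scaffold, 0-based half-open coordinates."""

    scaffold_id: str
    ordinal: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.scaffold_id}_{self.ordinal}_{self.length}"


def parse_fragment_name(name: str) -> tuple[str, int, int]:
    """Split ``Sca971_3_662`` into (scaffold_id, ordinal, length).

    The scaffold id may itself contain underscores; the last two
    underscore-separated fields are the ordinal and length.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"fragment name {name!r} does not parse as "
                         "'{scaffold}_{ordinal}_{length}'")
    return m["scaffold"], int(m["ordinal"]), int(m["length"])


def split_softmasked(
    scaffold: MaskedScaffold,
    min_len: int = DEFAULT_MIN_FRAGMENT_LEN,
    split_on_n: bool = True,
) -> list[Fragment]:
    """Decompose a scaffold into its retained unmasked fragments.

    Maximal runs of uppercase A/C/G/T (N also splits when ``split_on_n``,
    the default, since assembly gaps are not repeat-free sequence) are
    collected in scaffold order; runs shorter than ``min_len`` are dropped,
    and ordinals are assigned 1-based over the retained runs.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    pattern = _FRAGMENT_RE if split_on_n else _FRAGMENT_RE_KEEP_N
    fragments: list[Fragment] = []
    ordinal = 0
    for m in pattern.finditer(scaffold.seq):
        if m.end() - m.start() < min_len:
            continue
        ordinal += 1
        fragments.append(Fragment(scaffold.id, ordinal, m.start(), m.end()))
    return fragments


def split_assembly(
    scaffolds: Iterable[MaskedScaffold],
    min_len: int = DEFAULT_MIN_FRAGMENT_LEN,
    split_on_n: bool = True,
) -> dict[str, list[Fragment]]:
    """``split_softmasked`` over an assembly; keys are scaffold ids."""
    out: dict[str, list[Fragment]] = {}
    for sc in scaffolds:
        if sc.id in out:
            raise InputFormatError(f"duplicate scaffold id {sc.id!r}")
        out[sc.id] = split_softmasked(sc, min_len=min_len, split_on_n=split_on_n)
    return out


def masked_fraction(scaffolds: Iterable[MaskedScaffold]) -> float:
    """Fraction of repeat-masked (lowercase) bases among non-N bases.

    N/n bases are assembly gaps, not sequence, and are excluded from both
    numerator and denominator, matching the convention of reporting repeat
    content over resolved bases.
    """
    masked = total = 0
    n_scaffolds = 0
    for sc in scaffolds:
        n_scaffolds += 1
        for c in sc.seq:
            if c in "Nn":
                continue
            total += 1
            if c.islower():
                masked += 1
    if n_scaffolds == 0:
        raise ValueError("masked_fraction requires at least one scaffold")
    if total == 0:
        raise ValueError("masked_fraction: no non-N bases in input")
    return masked / total


def read_softmasked_fasta(path: str | Path) -> list[MaskedScaffold]:
    """Read a (possibly line-wrapped) softmasked FASTA, preserving case."""
    scaffolds = [
        MaskedScaffold(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for sc in scaffolds:
        if sc.id in seen:
            raise InputFormatError(f"duplicate scaffold id {sc.id!r} in {path}")
        seen.add(sc.id)
    return scaffolds


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fragments_bed(fragments: Sequence[Fragment], path: str | Path) -> None:
    """BED4: scaffold, 0-based start, half-open end, fragment name."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.scaffold_id}\t{f.start}\t{f.end}\t{f.name}\n")


def write_fragments_tsv(fragments: Sequence[Fragment], path: str | Path) -> None:
    """Manifest TSV: scaffold_id, ordinal, start, end, length, name."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tordinal\tstart\tend\tlength\tname\n")
        for f in fragments:
            fh.write(
                f"{f.scaffold_id}\t{f.ordinal}\t{f.start}\t{f.end}\t"
                f"{f.length}\t{f.name}\n"
            )


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    fragments: list[Fragment] = []
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n").split("\t")[:2] != ["scaffold_id", "ordinal"]:
            raise InputFormatError(f"{path}: not a fragment manifest TSV")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise InputFormatError(f"{path}:{lineno}: expected 6 columns")
            sc, ordinal, start, end, _length, _name = fields
            fragments.append(Fragment(sc, int(ordinal), int(start), int(end)))
    return fragments


def write_fragments_fasta(
    fragments: Sequence[Fragment],
    scaffolds: Mapping[str, MaskedScaffold],
    path: str | Path,
) -> None:
    """FASTA of fragment subsequences, uppercased, keyed by fragment name."""
    records = []
    for f in fragments:
        try:
            sc = scaffolds[f.scaffold_id]
        except KeyError:
            raise KeyError(f"fragment {f.name}: scaffold {f.scaffold_id!r} "
                           "not in assembly") from None
        subseq = sc.seq[f.start:f.end].upper()
        records.append(SeqRecord(Seq(subseq), id=f.name, description=""))
    SeqIO.write(records, str(path), "fasta")
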