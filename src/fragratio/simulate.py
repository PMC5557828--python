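"""Synthetic softmasked genomes and pooled counts with known truth.

Emulates the structure the depth-ratio method runs on: a male reference of
autosomal, X-linked and Y-linked scaffolds whose repeat-masked runs break
each scaffold into unmasked fragments, and per-fragment mapped-read counts
for a female pool and a male pool under the XX/XY copy-number model —

    copies per diploid male genome:   autosome 2, X 1, Y 1
    copies per diploid female genome: autosome 2, X 2, Y 0

so the expected count for a fragment of length L at haploid-equivalent
pool depth d is Poisson(d * copies/2 * L / read_len).  A configurable
"leakage" rate deposits extra female reads on Y fragments, emulating
residual X-Y homology that pulls the Y ratio above zero.  Y scaffolds
carry a higher repeat density by default, mirroring the repeat
accumulation seen on real Y-linked sequence.

All randomness flows through one numpy Generator seeded from the config,
so identical configs produce byte-identical genomes and counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counts import CountTable, PoolCounts, build_count_table, write_idxstats
from .enrichment import ScaffoldEnrichment, enrich_scaffolds
from .fragments import (
    DEFAULT_MIN_FRAGMENT_LEN,
    Fragment,
    MaskedScaffold,
    split_softmasked,
)
from .ratios import RatioRecord

CLASSES = ("A", "X", "Y")

_COPIES_MALE = {"A": 2, "X": 1, "Y": 1}
_COPIES_FEMALE = {"A": 2, "X": 2, "Y": 0}

# Mean unmasked-run length controlling fragment sizes (bp); chosen so that
# most runs clear the 200-bp retention filter, like the real assembly whose
# retained fragments have an N50 near 1.8 kb.
_UNMASKED_RUN_MEAN = 750


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic pool-seq experiment.

    Defaults follow the motivating study's design where stated: pooled
    depth ~25x per pool, 150-bp reads, genome-wide repeat density ~17.5%
    with ~30.7% on Y scaffolds, and a genome dominated by autosomes with
    small X and Y complements.  ``leakage`` is the fraction of female-pool
    haploid depth deposited on Y fragments through X-homologous sequence
    (0 = fully diverged Y).
    """

    seed: int = 0
    n_auto: int = 50
    n_x: int = 5
    n_y: int = 5
    scaffold_len_range: tuple[int, int] = (8_000, 16_000)
    repeat_density: float = 0.1753
    repeat_density_y: float = 0.3071
    depth_f: float = 25.0
    depth_m: float = 25.0
    leakage: float = 0.0
    read_len: int = 150
    overdispersion: float | None = None  # NB size parameter; None = Poisson

    def __post_init__(self) -> None:
        if not (0 <= self.leakage <= 1):
            raise ValueError(f"leakage must be in [0,1], got {self.leakage}")
        if min(self.n_auto, self.n_x, self.n_y) < 0:
            raise ValueError("scaffold counts must be non-negative")
        if min(self.depth_f, self.depth_m) < 0 or self.read_len < 1:
            raise ValueError("depths must be >= 0 and read_len >= 1")
        for d in (self.repeat_density, self.repeat_density_y):
            if not (0 <= d < 1):
                raise ValueError(f"repeat density must be in [0,1), got {d}")
        if self.scaffold_len_range[0] < DEFAULT_MIN_FRAGMENT_LEN:
            raise ValueError(
                "scaffold_len_range minimum below the minimum fragment "
                "length; no fragment could survive"
            )
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive when set")


@dataclass
class SimTruth:
    """Ground-truth chromosome class per scaffold and fragment."""

    scaffold_class: dict[str, str]
    fragment_class: dict[str, str] = field(default_factory=dict)
    expected_counts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def classes_of(self, names: Iterable[str]) -> list[str]:
        return [self.fragment_class[n] for n in names]


def _random_scaffold(rng: np.random.Generator, length: int,
                     density: float) -> str:
    """Interleave uppercase unmasked runs with lowercase repeat runs at the
    requested masked-base density, then trim to the target length."""
    up_mean = _UNMASKED_RUN_MEAN
    mask_mean = max(1.0, density / max(1e-9, 1 - density) * up_mean)
    parts: list[str] = []
    total = 0
    bases = np.array(list("ACGT"))
    while total < length:
        up_len = int(rng.integers(up_mean // 2, up_mean * 3 // 2 + 1))
        parts.append("".join(rng.choice(bases, size=up_len)))
        total += up_len
        if density > 0 and total < length:
            m_len = max(1, int(rng.integers(max(1, int(mask_mean // 2)),
                                            int(mask_mean * 3 // 2) + 2)))
            parts.append("".join(rng.choice(bases, size=m_len)).lower())
            total += m_len
    return "".join(parts)[:length]


def simulate_genome(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[MaskedScaffold], SimTruth]:
    """Generate softmasked scaffolds with class labels A/X/Y.

    Scaffolds are named ``Sca1..Sca{n}`` in autosome, X, Y order; Y
    scaffolds use ``repeat_density_y``.  Deterministic given the config
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.scaffold_len_range
    scaffolds: list[MaskedScaffold] = []
    truth = SimTruth(scaffold_class={})
    idx = 0
    for cls, count in (("A", config.n_auto), ("X", config.n_x),
                       ("Y", config.n_y)):
        density = config.repeat_density_y if cls == "Y" else config.repeat_density
        for _ in range(count):
            idx += 1
            sid = f"Sca{idx}"
            length = int(rng.integers(lo, hi + 1))
            scaffolds.append(MaskedScaffold(sid, _random_scaffold(rng, length,
                                                                  density)))
            truth.scaffold_class[sid] = cls
    if not scaffolds:
        raise ValueError("config generates no scaffolds")
    return scaffolds, truth


def simulate_pool_counts(
    fragments: Sequence[Fragment],
    truth: SimTruth,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PoolCounts, PoolCounts]:
    """Draw female/male per-fragment counts under the copy-number model.

    Counts are Poisson with mean depth * copies/2 * L / read_len per pool
    (gamma-mixed to negative binomial when ``overdispersion`` is set); Y
    fragments additionally receive Poisson(leakage * depth_f * L /
    read_len) female reads.  Fills ``truth.fragment_class`` and
    ``truth.expected_counts`` as a side product.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    f_counts: dict[str, int] = {}
    m_counts: dict[str, int] = {}
    lengths: dict[str, int] = {}

    def _draw(lam: float) -> int:
        if lam == 0:
            return 0
        if config.overdispersion is not None:
            lam = rng.gamma(config.overdispersion, lam / config.overdispersion)
        return int(rng.poisson(lam))

    for frag in fragments:
        cls = truth.scaffold_class[frag.scaffold_id]
        per_copy = frag.length / config.read_len / 2
        lam_m = config.depth_m * _COPIES_MALE[cls] * per_copy
        lam_f = config.depth_f * _COPIES_FEMALE[cls] * per_copy
        if cls == "Y":
            lam_f += config.leakage * config.depth_f * frag.length / config.read_len
        name = frag.name
        truth.fragment_class[name] = cls
        truth.expected_counts[name] = (lam_f, lam_m)
        f_counts[name] = _draw(lam_f)
        m_counts[name] = _draw(lam_m)
        lengths[name] = frag.length
    return (PoolCounts("female", f_counts, dict(lengths)),
            PoolCounts("male", m_counts, dict(lengths)))


def simulate_experiment(
    config: SimConfig,
    min_len: int = DEFAULT_MIN_FRAGMENT_LEN,
) -> tuple[list[MaskedScaffold], list[Fragment], SimTruth, CountTable]:
    """Genome -> fragments -> counts, end to end, one seed."""
    rng = np.random.default_rng(config.seed)
    scaffolds, truth = simulate_genome(config, rng)
    fragments = [f for sc in scaffolds
                 for f in split_softmasked(sc, min_len=min_len)]
    female, male = simulate_pool_counts(fragments, truth, config, rng)
    table = build_count_table(female, male, totals_mode="mapped_reads")
    return scaffolds, fragments, truth, table


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment\tclass\texpected_F\texpected_M\n")
        for name, cls in truth.fragment_class.items():
            ef, em = truth.expected_counts.get(name, (float("nan"),) * 2)
            fh.write(f"{name}\t{cls}\t{ef:.6g}\t{em:.6g}\n")


def write_idxstats_pair(table: CountTable, female_path: str | Path,
                        male_path: str | Path) -> None:
    """Export the two pools of a count table as idxstats-style TSVs."""
    lengths = {str(n): int(l) for n, l in table.rows["length"].items()}
    f = PoolCounts("female", {str(n): int(v)
                              for n, v in table.rows["F"].items()}, lengths)
    m = PoolCounts("male", {str(n): int(v)
                            for n, v in table.rows["M"].items()}, lengths)
    write_idxstats(f, female_path)
    write_idxstats(m, male_path)


def write_genome_fasta(scaffolds: Sequence[MaskedScaffold],
                       path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(sc.seq), id=sc.id, description="") for sc in scaffolds],
        str(path), "fasta",
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    scaffold_sensitivity: float      # true-Y scaffolds called enriched / true Y
    scaffold_fdr: float              # non-Y among enriched calls
    n_enriched: int
    n_true_y_scaffolds: int
    fragment_confusion: dict[str, dict[str, int]]  # true class -> called Y?

    def fragment_sensitivity(self) -> float:
        y = self.fragment_confusion.get("Y", {})
        called = y.get("called_y", 0)
        total = called + y.get("not_called", 0)
        return called / total if total else float("nan")


def evaluate_recovery(
    enrichments: Sequence[ScaffoldEnrichment],
    candidates: Iterable[RatioRecord | str],
    truth: SimTruth,
    alpha: float = 1e-5,
) -> RecoveryReport:
    """Score scaffold-level calls and the fragment-level threshold rule
    against the simulation truth."""
    cand_names = {c.fragment if isinstance(c, RatioRecord) else c
                  for c in candidates}
    unknown = cand_names - truth.fragment_class.keys()
    if unknown:
        raise ValueError(f"candidates not covered by truth: "
                         f"{sorted(unknown)[:3]}...")
    enriched = {e.scaffold_id for e in enrichments if e.p_value < alpha}
    unknown_sc = enriched - truth.scaffold_class.keys()
    if unknown_sc:
        raise ValueError(f"enriched scaffolds not covered by truth: "
                         f"{sorted(unknown_sc)[:3]}...")
    true_y = {s for s, c in truth.scaffold_class.items() if c == "Y"}
    tp = len(enriched & true_y)
    sensitivity = tp / len(true_y) if true_y else float("nan")
    fdr = (len(enriched) - tp) / len(enriched) if enriched else 0.0
    confusion = {cls: {"called_y": 0, "not_called": 0} for cls in CLASSES}
    for name, cls in truth.fragment_class.items():
        key = "called_y" if name in cand_names else "not_called"
        confusion[cls][key] += 1
    return RecoveryReport(sensitivity, fdr, len(enriched), len(true_y),
                          confusion)


def null_enriched_fraction(
    n_scaffolds: int,
    fragments_per_scaffold: int,
    candidate_fraction: float,
    alpha: float,
    rng: np.random.Generator,
) -> float:
    """Fraction of scaffolds called enriched when candidate status is
    assigned uniformly at random — a calibration check: for a valid test
    this stays at or below alpha up to binomial sampling error."""
    names = [f"Sca{s}_{j}_250"
             for s in range(1, n_scaffolds + 1)
             for j in range(1, fragments_per_scaffold + 1)]
    n_cand = int(round(candidate_fraction * len(names)))
    cand_idx = rng.choice(len(names), size=n_cand, replace=False)
    cand = [names[i] for i in cand_idx]
    enr = enrich_scaffolds(names, cand, alpha=alpha,
                           include_zero_candidate=True)
    return sum(e.p_value < alpha for e in enr) / n_scaffolds
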