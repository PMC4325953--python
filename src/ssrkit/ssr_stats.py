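"""Summary statistics over detected SSRs.

Densities are expressed as SSRs per megabase with Mb = 10^6 bases exactly
(so 200,744 SSRs over 1,532 Mb gives 131.03 SSRs/Mb, one SSR every 7.63 kb),
relative frequencies as percentages within a dataset, and per-period means
of complete-unit counts. Report rounding is half-up to 2 decimals; internal
values stay unrounded.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Genome
from .ssr_engine import SSRRecord

MB = 1_000_000


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up rounding for report output (banker's rounding would drift
    from conventionally printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def density_per_mb(count: int, length_bases: float) -> float:
    """SSRs per million bases."""
    if length_bases <= 0:
        raise ValueError("sequence length must be positive")
    return count / (length_bases / MB)


def relative_frequency(count: int, total: int) -> float:
    """100 * count / total, as percent (unrounded)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError("count cannot exceed total")
    return 100.0 * count / total


def fold_ratio(count_a: int, count_b: int) -> float:
    """How many times more abundant class a is than class b."""
    if count_b <= 0:
        raise ValueError("denominator count must be positive")
    return count_a / count_b


@dataclass(frozen=True)
class PeriodSummary:
    period: int
    count: int
    rel_freq_percent: float
    mean_repeat_number: float
    density: float


@dataclass(frozen=True)
class GenomeSummary:
    """Genome-wide totals by motif size class (periods 1-6)."""

    total_count: int
    total_length_mb: float
    overall_density: float
    spacing_kb: float
    per_period: tuple[PeriodSummary, ...]
    per_class_counts: Mapping[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Motif-size-class table: count, relative frequency, mean repeat
        number and density per period, plus a total row."""
        names = {
            1: "Mononucleotide",
            2: "Dinucleotide",
            3: "Trinucleotide",
            4: "Tetranucleotide",
            5: "Pentanucleotide",
            6: "Hexanucleotide",
        }
        rows = [
            {
                "SSR type": names[p.period],
                "Count": p.count,
                "Rel. freq. (%)": round_half_up(p.rel_freq_percent),
                "Mean repeat number": round_half_up(p.mean_repeat_number),
                "Density (SSR/Mb)": round_half_up(p.density),
            }
            for p in self.per_period
        ]
        rows.append(
            {
                "SSR type": "Total",
                "Count": self.total_count,
                "Rel. freq. (%)": 100.0,
                "Mean repeat number": float("nan"),
                "Density (SSR/Mb)": round_half_up(self.overall_density),
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    length: int
    count: int
    density: float
    per_class_counts: Mapping[str, int]
    per_period_counts: Mapping[int, int]


def _check_chromosomes(records: Sequence[SSRRecord], genome: Genome) -> None:
    for r in records:
        if r.chromosome not in genome:
            raise KeyError(f"record references unknown chromosome {r.chromosome!r}")


def summarize_genome(records: Sequence[SSRRecord], genome: Genome) -> GenomeSummary:
    """Genome-wide summary partitioned by motif period 1-6."""
    _check_chromosomes(records, genome)
    total = len(records)
    length_mb = genome.total_length / MB
    by_period: dict[int, list[SSRRecord]] = defaultdict(list)
    for r in records:
        by_period[r.period].append(r)
    per_period = []
    for p in range(1, 7):
        rs = by_period.get(p, [])
        per_period.append(
            PeriodSummary(
                period=p,
                count=len(rs),
                rel_freq_percent=relative_frequency(len(rs), total) if total else 0.0,
                mean_repeat_number=(
                    sum(r.unit_count for r in rs) / len(rs) if rs else 0.0
                ),
                density=density_per_mb(len(rs), genome.total_length),
            )
        )
    overall = density_per_mb(total, genome.total_length)
    return GenomeSummary(
        total_count=total,
        total_length_mb=length_mb,
        overall_density=overall,
        spacing_kb=1000.0 / overall if overall else float("inf"),
        per_period=tuple(per_period),
        per_class_counts=dict(Counter(r.canonical_motif for r in records)),
    )


def summarize_chromosomes(
    records: Sequence[SSRRecord], genome: Genome
) -> list[ChromosomeSummary]:
    """Per-chromosome counts and densities, in genome order."""
    _check_chromosomes(records, genome)
    by_chrom: dict[str, list[SSRRecord]] = defaultdict(list)
    for r in records:
        by_chrom[r.chromosome].append(r)
    out = []
    for chrom in genome:
        rs = by_chrom.get(chrom.name, [])
        out.append(
            ChromosomeSummary(
                chromosome=chrom.name,
                length=chrom.length,
                count=len(rs),
                density=density_per_mb(len(rs), chrom.length),
                per_class_counts=dict(Counter(r.canonical_motif for r in rs)),
                per_period_counts=dict(Counter(r.period for r in rs)),
            )
        )
    return out


def density_range(summaries: Iterable[ChromosomeSummary]) -> tuple[float, float, float]:
    """(min, max, max/min) of chromosome densities."""
    ds = [s.density for s in summaries]
    if not ds:
        raise ValueError("no chromosome summaries")
    lo, hi = min(ds), max(ds)
    return lo, hi, hi / lo if lo else float("inf")


def chromosome_table(summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    """Per-chromosome report mirroring the count/density column layout."""
    return pd.DataFrame(
        {
            "Chromosome": [s.chromosome for s in summaries],
            "Total SSR No.": [s.count for s in summaries],
            "Density (SSR/Mb)": [round_half_up(s.density) for s in summaries],
        }
    )


def class_spectrum(records: Sequence[SSRRecord]) -> pd.DataFrame:
    """Long-format canonical-motif spectrum (count per class per period)."""
    counts = Counter((r.period, r.canonical_motif) for r in records)
    rows = [
        {"period": p, "canonical_motif": m, "count": c}
        for (p, m), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["period", "canonical_motif", "count"])
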