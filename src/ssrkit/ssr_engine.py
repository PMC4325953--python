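"""Microsatellite detection and motif standardization.

A microsatellite (SSR) is a tandem repeat of a 1-6 bp motif; here an SSR must
have at least 3 complete units and at least 15 bp total length. Motifs are
standardized so that one canonical string represents all cyclic rotations of
a motif and of its reverse complement (AG stands for AG, GA, CT and TC): SSR
coordinates are strandless, so frequencies of a motif class must pool both
strands and every read frame. Canonical motifs are always primitive — a run
of ATAT... is an AT repeat, never an "ATAT" repeat — which is what makes the
per-period class counts (2, 4, 10, 33, 102, 350 for periods 1-6) well
defined.

Two search modes are provided. *perfect* reports maximal exact tandem runs.
*fixed_penalty* grows each run of >= 3 perfect units outward through
mismatches, scoring +1 per base that matches the periodic expectation and a
fixed penalty (default -5) per mismatch, keeping the extension while the
running score stays within 10 of its maximum, and reporting the max-score
extent when the final score reaches ``min_score``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator

from .genome_io import Chromosome

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_motif(motif: str) -> None:
    if not motif:
        raise ValueError("empty motif")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")


def primitive_root(motif: str) -> str:
    """Shortest string whose repetition gives `motif` (ATAT -> AT)."""
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    raise AssertionError("unreachable")


def is_primitive(motif: str) -> bool:
    return len(primitive_root(motif)) == len(motif)


@dataclass(frozen=True)
class MotifClass:
    """A standardized motif: one representative for a rotation/strand orbit.

    `canonical` is the lexicographically smallest member of `orbit`, the set
    of all cyclic rotations of the motif and of its reverse complement.
    Orbit size divides 2 x period (rotation orbit of a primitive motif has
    exactly `period` members; the reverse-complement copy either coincides
    with it or doubles it).
    """

    canonical: str
    orbit: frozenset[str]

    @property
    def period(self) -> int:
        return len(self.canonical)


def _orbit(motif: str) -> frozenset[str]:
    rots = {motif[i:] + motif[:i] for i in range(len(motif))}
    rc = reverse_complement(motif)
    rots |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return frozenset(rots)


@lru_cache(maxsize=None)
def canonical_motif(motif: str) -> MotifClass:
    """Standardized class of `motif`.

    The motif is first reduced to its primitive root, then the class is the
    lexicographic minimum over all rotations of the root and of its reverse
    complement. Idempotent and invariant under rotation and strand flip.
    """
    _check_motif(motif)
    root = primitive_root(motif)
    orbit = _orbit(root)
    return MotifClass(min(orbit), orbit)


@lru_cache(maxsize=None)
def enumerate_motif_classes(period: int) -> tuple[MotifClass, ...]:
    """All standardized classes of primitive motifs of exactly `period` bp.

    Classes are disjoint and their orbits cover every primitive k-mer.
    Counts for periods 1..6 are 2, 4, 10, 33, 102, 350.
    """
    if not 1 <= period <= 6:
        raise ValueError(f"period must be in 1..6, got {period}")
    classes: dict[str, MotifClass] = {}
    for tup in itertools.product("ACGT", repeat=period):
        kmer = "".join(tup)
        if not is_primitive(kmer):
            continue
        cls = canonical_motif(kmer)
        classes.setdefault(cls.canonical, cls)
    return tuple(classes[c] for c in sorted(classes))


@dataclass(frozen=True)
class SSRRecord:
    """One detected microsatellite locus (internal 0-based half-open coords).

    `unit_count` counts complete motif units (floor of length / period);
    leftover bases are `tail_bases` and remain inside `total_length`.
    """

    chromosome: str
    start: int
    end: int
    period: int
    observed_motif: str
    canonical_motif: str
    mismatches: int = 0
    score: int = 0

    @property
    def total_length(self) -> int:
        return self.end - self.start

    @property
    def unit_count(self) -> int:
        return self.total_length // self.period

    @property
    def tail_bases(self) -> int:
        return self.total_length % self.period


@dataclass(frozen=True)
class SearchParams:
    """Detection thresholds.

    min_total_length / min_units mirror the marker-development settings
    (>= 15 bp and >= 3 repeats, motifs of 1-6 bp). `mode` is "perfect" or
    "fixed_penalty"; in the latter each mismatch costs `mismatch_penalty`,
    extension stops once the running score drops `xdrop` below its maximum,
    and a record is kept when score >= min_score.
    """

    min_total_length: int = 15
    min_units: int = 3
    max_period: int = 6
    mode: str = "perfect"
    mismatch_penalty: int = 5
    min_score: int = 15
    xdrop: int = 10

    def __post_init__(self) -> None:
        if self.mode not in ("perfect", "fixed_penalty"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 1 <= self.max_period <= 6:
            raise ValueError("max_period must be in 1..6")


def _perfect_runs(seq: str, period: int) -> Iterator[tuple[int, int]]:
    """Maximal 0-based half-open regions that are exact period-p tandem runs.

    A region [a, b) satisfies seq[i] == seq[i+p] for all a <= i < b-p, with
    every base in ACGT (N breaks runs), and cannot be extended either way.
    Regions shorter than 2 full units are yielded too; callers filter.
    """
    n = len(seq)
    p = period
    i = 0
    run_start: int | None = None
    # scan i over positions where seq[i] == seq[i+p]
    while i + p < n:
        ok = seq[i] == seq[i + p] and seq[i] in "ACGT" and seq[i + p] in "ACGT"
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            yield run_start, i + p
            run_start = None
        i += 1
    if run_start is not None:
        yield run_start, i + p  # == n: the trailing run reaches the end


def _resolve_overlaps(cands: list[SSRRecord]) -> list[SSRRecord]:
    """Greedy selection: higher score first, then smaller start, shorter period."""
    chosen: list[SSRRecord] = []
    occupied: list[tuple[int, int]] = []
    for rec in sorted(cands, key=lambda r: (-r.score, r.start, r.period)):
        if any(rec.start < e and s < rec.end for s, e in occupied):
            continue
        chosen.append(rec)
        occupied.append((rec.start, rec.end))
    return sorted(chosen, key=lambda r: r.start)


def _perfect_candidates(chrom: Chromosome, params: SearchParams) -> list[SSRRecord]:
    seq = chrom.sequence
    cands = []
    for p in range(1, params.max_period + 1):
        for a, b in _perfect_runs(seq, p):
            motif = seq[a : a + p]
            if len(motif) < p or any(c not in "ACGT" for c in motif):
                continue
            if not is_primitive(motif):
                continue  # attributed to its primitive period instead
            length = b - a
            if length < params.min_total_length or length // p < params.min_units:
                continue
            cands.append(
                SSRRecord(
                    chromosome=chrom.name,
                    start=a,
                    end=b,
                    period=p,
                    observed_motif=motif,
                    canonical_motif=canonical_motif(motif).canonical,
                    mismatches=0,
                    score=length,
                )
            )
    return cands


def _extend_fixed_penalty(
    seq: str, a: int, b: int, motif: str, params: SearchParams
) -> tuple[int, int]:
    """Grow perfect seed [a, b) outward through mismatches; return best extent.

    The expected base at position j is motif[(j - a) mod p]. Each side is
    extended independently; the running score is +1 per match and
    -mismatch_penalty per mismatch, stopping at N, at the sequence end, or
    when the score falls `xdrop` below its side maximum. The returned extent
    is trimmed to the maximum-score prefix of each side.
    """
    p = len(motif)
    n = len(seq)

    best_right = b
    run = best = 0
    j = b
    while j < n and seq[j] in "ACGT":
        exp = motif[(j - a) % p]
        run += 1 if seq[j] == exp else -params.mismatch_penalty
        if run > best:
            best, best_right = run, j + 1
        if run < best - params.xdrop:
            break
        j += 1

    best_left = a
    run = best = 0
    j = a - 1
    while j >= 0 and seq[j] in "ACGT":
        exp = motif[(j - a) % p]
        run += 1 if seq[j] == exp else -params.mismatch_penalty
        if run > best:
            best, best_left = run, j
        if run < best - params.xdrop:
            break
        j -= 1
    return best_left, best_right


def _imperfect_candidates(chrom: Chromosome, params: SearchParams) -> list[SSRRecord]:
    seq = chrom.sequence
    cands: dict[tuple[int, int, int], SSRRecord] = {}
    for p in range(1, params.max_period + 1):
        for a, b in _perfect_runs(seq, p):
            if b - a < 3 * p:  # seed must be 3 perfect units
                continue
            motif = seq[a : a + p]
            if not is_primitive(motif):
                continue
            lo, hi = _extend_fixed_penalty(seq, a, b, motif, params)
            mism = sum(
                1 for j in range(lo, hi) if seq[j] != motif[(j - a) % p]
            )
            length = hi - lo
            score = (length - mism) - params.mismatch_penalty * mism
            if score < params.min_score or length // p < params.min_units:
                continue
            if length < params.min_total_length:
                continue
            key = (lo, hi, p)
            rec = SSRRecord(
                chromosome=chrom.name,
                start=lo,
                end=hi,
                period=p,
                observed_motif=motif,
                canonical_motif=canonical_motif(motif).canonical,
                mismatches=mism,
                score=score,
            )
            prev = cands.get(key)
            if prev is None or rec.score > prev.score:
                cands[key] = rec
    return list(cands.values())


def find_ssrs(
    chromosome: Chromosome, params: SearchParams | None = None
) -> list[SSRRecord]:
    """Detect SSRs on one chromosome.

    Returns non-overlapping records sorted by start. In perfect mode every
    maximal exact tandem run passing the thresholds is reported exactly once,
    attributed to its primitive period; in fixed_penalty mode runs may span
    mismatches (see module docstring). N always terminates a run.
    """
    params = params or SearchParams()
    if params.mode == "perfect":
        cands = _perfect_candidates(chromosome, params)
    else:
        cands = _imperfect_candidates(chromosome, params)
    return _resolve_overlaps(cands)


def find_ssrs_genome(genome: Iterable[Chromosome], params: SearchParams | None = None):
    """Detect SSRs over every chromosome; concatenated in genome order."""
    out: list[SSRRecord] = []
    for chrom in genome:
        out.extend(find_ssrs(chrom, params))
    return out
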