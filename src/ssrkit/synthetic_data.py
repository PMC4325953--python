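"""Synthetic genomes with planted SSRs and duplicated flank blocks.

The simulator builds FASTA-ready chromosomes from an i.i.d. background base
model at a chosen GC content, plants perfect (or deliberately mismatched)
SSR tracts at fixed positions, and optionally copies whole SSR windows —
flank + tract + flank — to other loci at a chosen percent identity, which
is what makes an SSR repetitive within its chromosome or shared across
chromosomes. A machine-readable truth table records, for every planted SSR,
the record the detector must report and the specificity label the screen
must assign, so detection and screening can be tested against exact ground
truth.

Two guarantees make the truth exact rather than probable:

* local rejection resampling — background bases inside any planted window
  (plus one flank width of margin) are redrawn until no chance SSR passing
  the detection thresholds remains there and the planted tract is detected
  at exactly its planted coordinates;
* duplicate-block mutations are confined to flank bases, never the repeat
  tract, so a copied SSR stays a perfect SSR at any identity.

Background SSRs far from any plant are allowed (real genomes have them);
they are appended to the truth table post hoc by the independent
backreference-regex scanner :func:`regex_find_ssrs`, which is also the
reference oracle for the detection engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .genome_io import Chromosome, Genome
from .ssr_engine import (
    SSRRecord,
    SearchParams,
    canonical_motif,
    is_primitive,
)
from . import specificity as _spec

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# independent regex-based SSR scanner (reference oracle)

_BACKREF = {
    p: re.compile(r"(?=(([ACGT]{%d})\2{2,}))" % p) for p in range(1, 7)
}


def regex_find_ssrs(
    chromosome: Chromosome, params: SearchParams | None = None
) -> list[SSRRecord]:
    """Perfect-mode SSR scan via backreference regex, independent of the
    period-comparison scanner in :mod:`ssrkit.ssr_engine`.

    For each period p the pattern ``(([ACGT]{p})\\2{2,})`` is applied with an
    overlapped lookahead; every match is normalized to its maximal run by
    extending both directions one base at a time (including a partial tail
    unit), non-primitive units are dropped, thresholds applied, and overlaps
    resolved by the same published rule (longer first, then smaller start,
    then shorter period).
    """
    params = params or SearchParams()
    seq = chromosome.sequence
    n = len(seq)
    seen: set[tuple[int, int, int]] = set()
    cands: list[SSRRecord] = []
    for p in range(1, params.max_period + 1):
        for m in _BACKREF[p].finditer(seq):
            a = m.start()
            b = a + len(m.group(1))
            # maximal run: grow while the periodicity continues
            while b < n and seq[b] in "ACGT" and seq[b] == seq[b - p]:
                b += 1
            while a > 0 and seq[a - 1] in "ACGT" and seq[a - 1] == seq[a - 1 + p]:
                a -= 1
            key = (a, b, p)
            if key in seen:
                continue
            seen.add(key)
            motif = seq[a : a + p]
            if not is_primitive(motif):
                continue
            length = b - a
            if length < params.min_total_length or length // p < params.min_units:
                continue
            cands.append(
                SSRRecord(
                    chromosome=chromosome.name,
                    start=a,
                    end=b,
                    period=p,
                    observed_motif=motif,
                    canonical_motif=canonical_motif(motif).canonical,
                    mismatches=0,
                    score=length,
                )
            )
    chosen: list[SSRRecord] = []
    occupied: list[tuple[int, int]] = []
    for rec in sorted(cands, key=lambda r: (-r.score, r.start, r.period)):
        if any(rec.start < e and s < rec.end for s, e in occupied):
            continue
        chosen.append(rec)
        occupied.append((rec.start, rec.end))
    return sorted(chosen, key=lambda r: r.start)


# --------------------------------------------------------------------------
# simulation spec

@dataclass(frozen=True)
class PlantedSSR:
    """A repeat tract to write into the background at a fixed locus."""

    chromosome: str
    position: int
    motif: str  # observed unit, written as-is
    unit_count: int
    mismatch_positions: tuple[int, ...] = ()  # tract-local, fixed_penalty tests

    @property
    def length(self) -> int:
        return len(self.motif) * self.unit_count


@dataclass(frozen=True)
class DuplicateBlock:
    """Copy the window of planted SSR `source_index` elsewhere.

    `identity` is the percent identity of the copy; mutations are placed in
    the flanks only. A same-chromosome destination makes the source SSR
    repetitive within its chromosome; another chromosome makes it shared
    across.
    """

    source_index: int
    dest_chromosome: str
    dest_position: int
    identity: float = 100.0


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one synthetic genome."""

    chromosome_lengths: dict[str, int]
    gc_percent: float = 35.0  # AT-rich, as in plant nuclear background
    ssrs: tuple[PlantedSSR, ...] = ()
    duplicates: tuple[DuplicateBlock, ...] = ()
    seed: int = 0
    flank_width: int = 200
    search: SearchParams = field(default_factory=SearchParams)


@dataclass(frozen=True)
class TruthRow:
    """Expected detection record and specificity label for one SSR."""

    chromosome: str
    start: int
    end: int
    canonical_motif: str
    unit_count: int
    mismatches: int
    label: Optional[str]  # None for background SSRs (label not asserted)
    planted: bool


TruthTable = list[TruthRow]


def _validate(spec: SimSpec) -> None:
    intervals: dict[str, list[tuple[int, int]]] = {}
    for s in spec.ssrs:
        if s.chromosome not in spec.chromosome_lengths:
            raise ValueError(f"unknown chromosome {s.chromosome!r}")
        if s.unit_count < 3 or not is_primitive(s.motif):
            raise ValueError(f"planted SSR must be >=3 units of a primitive motif: {s}")
        end = s.position + s.length
        if s.position < 0 or end > spec.chromosome_lengths[s.chromosome]:
            raise ValueError(f"chromosome too short for plant {s}")
        intervals.setdefault(s.chromosome, []).append((s.position, end))
    for db in spec.duplicates:
        if not 0 < db.identity <= 100:
            raise ValueError("identity must be in (0, 100]")
        src = spec.ssrs[db.source_index]
        w = spec.flank_width
        lo = max(0, src.position - w)
        hi = min(spec.chromosome_lengths[src.chromosome], src.position + src.length + w)
        dest_end = db.dest_position + (hi - lo)
        if db.dest_chromosome not in spec.chromosome_lengths:
            raise ValueError(f"unknown chromosome {db.dest_chromosome!r}")
        if db.dest_position < 0 or dest_end > spec.chromosome_lengths[db.dest_chromosome]:
            raise ValueError(f"chromosome too short for duplicate block {db}")
        intervals.setdefault(db.dest_chromosome, []).append((db.dest_position, dest_end))
    for chrom, ivs in intervals.items():
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"planted features overlap on {chrom}: [{s1},{e1}) and [{s2},{e2})"
                )


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    g = gc / 200.0
    return rng.choice(_BASES, size=n, p=[0.5 - g, g, g, 0.5 - g])


_OTHER = {"A": "C", "C": "A", "G": "T", "T": "G"}


def _build_tract(plant: PlantedSSR) -> str:
    tract = list(plant.motif * plant.unit_count)
    for pos in plant.mismatch_positions:
        tract[pos] = _OTHER[tract[pos]]
    return "".join(tract)


def simulate_genome(spec: SimSpec) -> tuple[Genome, TruthTable]:
    """Build the genome and its truth table; same seed, same bytes."""
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    arrays: dict[str, np.ndarray] = {
        name: _random_bases(rng, length, spec.gc_percent)
        for name, length in spec.chromosome_lengths.items()
    }

    protected: dict[str, list[tuple[int, int]]] = {
        name: [] for name in arrays
    }  # tract intervals that resampling must never touch
    for plant in spec.ssrs:
        tract = _build_tract(plant)
        arr = arrays[plant.chromosome]
        arr[plant.position : plant.position + len(tract)] = list(tract)
        protected[plant.chromosome].append(
            (plant.position, plant.position + len(tract))
        )

    # local rejection resampling around every planted tract
    w = spec.flank_width
    for plant in spec.ssrs:
        _scrub_region(
            arrays[plant.chromosome],
            plant.chromosome,
            max(0, plant.position - w),
            min(len(arrays[plant.chromosome]), plant.position + plant.length + w),
            protected[plant.chromosome],
            (plant.position, plant.position + plant.length),
            spec,
            rng,
            perfect_plant=not plant.mismatch_positions,
        )

    # copy duplicate blocks (after scrubbing, so copies inherit clean flanks)
    dup_truth: list[TruthRow] = []
    for db in spec.duplicates:
        src = spec.ssrs[db.source_index]
        src_arr = arrays[src.chromosome]
        lo = max(0, src.position - w)
        hi = min(len(src_arr), src.position + src.length + w)
        block = src_arr[lo:hi].copy()
        t0, t1 = src.position - lo, src.position - lo + src.length
        n_mut = round((1.0 - db.identity / 100.0) * len(block))
        flank_idx = np.concatenate([np.arange(0, t0), np.arange(t1, len(block))])
        if n_mut > len(flank_idx):
            raise ValueError(
                f"identity {db.identity} needs {n_mut} mutations but only "
                f"{len(flank_idx)} flank bases are available"
            )
        if n_mut:
            for idx in rng.choice(flank_idx, size=n_mut, replace=False):
                block[idx] = _OTHER[str(block[idx])]
        dest = arrays[db.dest_chromosome]
        dest[db.dest_position : db.dest_position + len(block)] = block
        protected[db.dest_chromosome].append(
            (db.dest_position + t0, db.dest_position + t1)
        )
        dup_truth.append(
            TruthRow(
                chromosome=db.dest_chromosome,
                start=db.dest_position + t0,
                end=db.dest_position + t1,
                canonical_motif=canonical_motif(src.motif).canonical,
                unit_count=src.unit_count,
                mismatches=len(src.mismatch_positions),
                label=_expected_label(db, src),
                planted=True,
            )
        )

    genome = Genome(
        [Chromosome(name, "".join(arrays[name])) for name in spec.chromosome_lengths]
    )

    truth: TruthTable = []
    for i, plant in enumerate(spec.ssrs):
        label = _spec.CHROMOSOME_SPECIFIC
        for db in spec.duplicates:
            if db.source_index == i:
                label = (
                    _spec.REPETITIVE_WITHIN
                    if db.dest_chromosome == plant.chromosome
                    else _spec.SHARED_ACROSS
                )
        truth.append(
            TruthRow(
                chromosome=plant.chromosome,
                start=plant.position,
                end=plant.position + plant.length,
                canonical_motif=canonical_motif(plant.motif).canonical,
                unit_count=plant.unit_count,
                mismatches=len(plant.mismatch_positions),
                label=label,
                planted=True,
            )
        )
    truth.extend(dup_truth)

    # background SSRs recorded post hoc by the independent scanner
    planted_iv = {
        (r.chromosome, r.start, r.end) for r in truth
    }
    for chrom in genome:
        for rec in regex_find_ssrs(chrom, spec.search):
            if (rec.chromosome, rec.start, rec.end) not in planted_iv:
                truth.append(
                    TruthRow(
                        chromosome=rec.chromosome,
                        start=rec.start,
                        end=rec.end,
                        canonical_motif=rec.canonical_motif,
                        unit_count=rec.unit_count,
                        mismatches=0,
                        label=None,
                        planted=False,
                    )
                )
    truth.sort(key=lambda r: (r.chromosome, r.start))
    return genome, truth


def _expected_label(db: DuplicateBlock, src: PlantedSSR) -> str:
    return (
        _spec.REPETITIVE_WITHIN
        if db.dest_chromosome == src.chromosome
        else _spec.SHARED_ACROSS
    )


def _scrub_region(
    arr: np.ndarray,
    chrom_name: str,
    lo: int,
    hi: int,
    protect: list[tuple[int, int]],
    plant_iv: tuple[int, int],
    spec: SimSpec,
    rng: np.random.Generator,
    perfect_plant: bool = True,
    max_rounds: int = 200,
) -> None:
    """Resample background bases in [lo, hi) until the only SSR the scanner
    reports there is the planted tract at exactly its planted coordinates
    (for a mismatched plant: until nothing outside the tract is reported)."""
    perfect = replace(spec.search, mode="perfect")
    p0, p1 = plant_iv
    planted_tracts = {
        (s, e)
        for plant2 in spec.ssrs
        if plant2.chromosome == chrom_name
        for s, e in [(plant2.position, plant2.position + plant2.length)]
    }
    for _ in range(max_rounds):
        text = "".join(arr[lo:hi])
        found = regex_find_ssrs(Chromosome(chrom_name, text), perfect)
        if perfect_plant:
            # another plant falling inside this window is fine; sub-runs of
            # its own tract are not (the plant must be reported exactly once)
            bad = [
                r for r in found if (lo + r.start, lo + r.end) not in planted_tracts
            ]
            ok_plant = any((lo + r.start, lo + r.end) == plant_iv for r in found)
        else:
            # sub-runs of a mismatched tract are expected; anything reaching
            # outside the tract is background to scrub (other plants exempt)
            bad = [
                r
                for r in found
                if (lo + r.start < p0 or lo + r.end > p1)
                and (lo + r.start, lo + r.end) not in planted_tracts
            ]
            ok_plant = True
        if not bad and ok_plant:
            return
        # redraw every non-protected base of the offending stretches
        regions = [(lo + r.start, lo + r.end) for r in bad] or [(lo, hi)]
        for s, e in regions:
            for j in range(s, e):
                if any(ps <= j < pe for ps, pe in protect):
                    continue
                arr[j] = _random_bases(rng, 1, spec.gc_percent)[0]
    raise RuntimeError(
        f"could not scrub background around plant {plant_iv} on {chrom_name}"
    )


def truth_to_tsv(truth: TruthTable) -> str:
    """Serialize a truth table (1-based inclusive coordinates, like every
    emitted table)."""
    lines = ["chrom\tstart\tend\tcanonical_motif\tunit_count\tmismatches\tlabel\tplanted"]
    for r in truth:
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    r.chromosome,
                    r.start + 1,
                    r.end,
                    r.canonical_motif,
                    r.unit_count,
                    r.mismatches,
                    r.label if r.label is not None else ".",
                    int(r.planted),
                )
            )
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# canned study conditions

def default_benchmark_spec(seed: int = 0) -> SimSpec:
    """The standard screening benchmark: three 12 kb chromosomes, AT-rich
    background (35% GC), a mix of chromosome-specific, within-chromosome
    repetitive and cross-chromosome shared plants at >= 95% identity."""
    plants = (
        PlantedSSR("chrA", 1_000, "AT", 9),
        PlantedSSR("chrA", 3_000, "AAT", 6),
        PlantedSSR("chrA", 5_200, "AG", 8),
        PlantedSSR("chrB", 1_500, "AAAT", 5),
        PlantedSSR("chrB", 4_000, "A", 17),
        PlantedSSR("chrC", 2_200, "ACG", 6),
    )
    dups = (
        DuplicateBlock(0, "chrB", 7_000, identity=100.0),  # shared across
        DuplicateBlock(1, "chrA", 8_000, identity=97.0),   # repetitive within
        DuplicateBlock(3, "chrC", 6_000, identity=95.0),   # shared across
    )
    return SimSpec(
        chromosome_lengths={"chrA": 12_000, "chrB": 12_000, "chrC": 12_000},
        gc_percent=35.0,
        ssrs=plants,
        duplicates=dups,
        seed=seed,
    )
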