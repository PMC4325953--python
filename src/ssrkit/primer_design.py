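"""Constraint-based PCR primer selection for SSR marker loci.

For each flank window a forward primer is taken from the 5' flank and a
reverse primer (reverse complement of the plus strand) from the 3' flank so
that the product spans the whole repeat tract. Hard constraints follow
standard SSR-marker practice: primer length 17-27 bp (optimum 20), product
size 125-250 bp, annealing temperature 60 degC (within a +-3 degC window),
GC content 20-80% (optimum 50%), and no homopolymer run of 5 or more bases
inside a primer. Among passing pairs the minimum-penalty pair is returned,

    penalty = sum over both primers of
              |len - 20| + 0.5 * |GC - 50| + 1.0 * |Tm - 60|

with ties broken by leftmost forward start, then smallest product, so that
design is deterministic. Tm is the nearest-neighbor melting temperature at
50 mM monovalent salt and 0.25 uM oligo.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .specificity import FlankWindow
from .ssr_engine import reverse_complement


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return 100.0 * sum(b in "GC" for b in seq) / len(seq)


@lru_cache(maxsize=1 << 16)
def melting_temperature(seq: str, na_mM: float = 50.0, oligo_uM: float = 0.25) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Uses the unified nearest-neighbor thermodynamic table with the salt
    correction applied to the entropy term; default conditions are 50 mM
    monovalent cation and 0.25 uM oligonucleotide.
    """
    if not 10 <= len(seq) <= 40:
        raise ValueError(f"sequence length {len(seq)} outside 10..40")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"non-ACGT character in {seq!r}")
    return float(
        _mt.Tm_NN(
            seq,
            nn_table=_mt.DNA_NN3,
            Na=na_mM,
            K=0,
            Tris=0,
            Mg=0,
            dNTPs=0,
            dnac1=oligo_uM * 1000.0,  # nM
            dnac2=0,
            selfcomp=False,
            saltcorr=5,
        )
    )


@dataclass(frozen=True)
class PrimerConstraints:
    len_min: int = 17
    len_max: int = 27
    len_opt: int = 20
    product_min: int = 125
    product_max: int = 250
    tm_target: float = 60.0
    tm_tol: float = 3.0
    gc_min: float = 20.0
    gc_max: float = 80.0
    gc_opt: float = 50.0
    max_homopolymer: int = 4  # longest allowed identical-base run

    def __post_init__(self) -> None:
        if not self.len_min <= self.len_opt <= self.len_max:
            raise ValueError("primer length bounds must satisfy min <= opt <= max")
        if self.product_min > self.product_max:
            raise ValueError("product_min must not exceed product_max")
        if not self.gc_min <= self.gc_opt <= self.gc_max:
            raise ValueError("GC bounds must satisfy min <= opt <= max")


@dataclass(frozen=True)
class PrimerPair:
    """A designed pair; positions are 0-based on the window's plus strand.

    `forward` reads the plus strand from fwd_start; `reverse` is the reverse
    complement of the plus strand ending at rev_start + len(reverse). The
    product runs from fwd_start to that point and covers the SSR tract.
    """

    forward: str
    reverse: str
    fwd_start: int
    rev_start: int
    product_size: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    penalty: float


def _has_homopolymer(seq: str, limit: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > limit:
            return True
    return False


def _candidates(flank: str, offset: int, c: PrimerConstraints):
    """(start, seq, tm, gc, penalty) for every passing primer in one flank.

    `offset` shifts flank-local starts to window coordinates. Cheap filters
    (alphabet, homopolymer, GC) run before the thermodynamic one.
    """
    out = []
    for length in range(c.len_min, c.len_max + 1):
        for i in range(0, len(flank) - length + 1):
            seq = flank[i : i + length]
            if any(b not in "ACGT" for b in seq):
                continue
            if _has_homopolymer(seq, c.max_homopolymer):
                continue
            gc = gc_content(seq)
            if not c.gc_min <= gc <= c.gc_max:
                continue
            tm = melting_temperature(seq)
            if abs(tm - c.tm_target) > c.tm_tol:
                continue
            pen = (
                abs(length - c.len_opt)
                + 0.5 * abs(gc - c.gc_opt)
                + 1.0 * abs(tm - c.tm_target)
            )
            out.append((offset + i, seq, tm, gc, pen))
    return out


def design_primers(
    window: FlankWindow, constraints: PrimerConstraints | None = None
) -> Optional[PrimerPair]:
    """Pick the minimum-penalty primer pair for one SSR window, or None.

    Enumerates every constraint-satisfying placement (forward primer in the
    5' flank, reverse in the 3' flank, product spanning the tract and inside
    the product-size bounds). Returns None when a flank is missing entirely
    or no placement passes.
    """
    c = constraints or PrimerConstraints()
    if window.flank5_len == 0 or window.flank3_len == 0:
        return None
    seq = window.sequence
    fwd_cands = _candidates(seq[: window.tract_start], 0, c)
    rev_cands = [
        # reverse primer anneals to the plus strand; rev_start is where the
        # plus-strand binding site begins
        (start, reverse_complement(s), tm, gc, pen)
        for start, s, tm, gc, pen in _candidates(
            seq[window.tract_end :], window.tract_end, c
        )
    ]
    if not fwd_cands or not rev_cands:
        return None
    best: Optional[PrimerPair] = None
    best_key: tuple[float, int, int] | None = None
    for fstart, fseq, ftm, fgc, fpen in fwd_cands:
        for rstart, rseq, rtm, rgc, rpen in rev_cands:
            product = rstart + len(rseq) - fstart
            if not c.product_min <= product <= c.product_max:
                continue
            key = (fpen + rpen, fstart, product)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    forward=fseq,
                    reverse=rseq,
                    fwd_start=fstart,
                    rev_start=rstart,
                    product_size=product,
                    fwd_tm=ftm,
                    rev_tm=rtm,
                    fwd_gc=fgc,
                    rev_gc=rgc,
                    penalty=fpen + rpen,
                )
    return best


def validate_pair(
    pair: PrimerPair, window: FlankWindow, constraints: PrimerConstraints | None = None
) -> bool:
    """Re-check a returned pair against every hard constraint."""
    c = constraints or PrimerConstraints()
    plus_site = window.sequence[pair.rev_start : pair.rev_start + len(pair.reverse)]
    return (
        c.len_min <= len(pair.forward) <= c.len_max
        and c.len_min <= len(pair.reverse) <= c.len_max
        and c.product_min <= pair.product_size <= c.product_max
        and abs(pair.fwd_tm - c.tm_target) <= c.tm_tol
        and abs(pair.rev_tm - c.tm_target) <= c.tm_tol
        and c.gc_min <= pair.fwd_gc <= c.gc_max
        and c.gc_min <= pair.rev_gc <= c.gc_max
        and pair.fwd_start + len(pair.forward) <= window.tract_start
        and pair.rev_start >= window.tract_end
        and window.sequence[pair.fwd_start : pair.fwd_start + len(pair.forward)]
        == pair.forward
        and reverse_complement(plus_site) == pair.reverse
        and not _has_homopolymer(pair.forward, c.max_homopolymer)
        and not _has_homopolymer(pair.reverse, c.max_homopolymer)
    )
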