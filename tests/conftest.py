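"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ssrkit.genome_io import Chromosome
from ssrkit.specificity import AlignParams, FlankWindow

BASES = np.array(list("ACGT"))
AT_RICH = [0.325, 0.175, 0.175, 0.325]  # 35% GC


def random_sequence(rng: np.random.Generator, n: int, p=AT_RICH) -> str:
    return "".join(rng.choice(BASES, size=n, p=p))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_chromosome(rng) -> Chromosome:
    return Chromosome("chr_t", random_sequence(rng, 5000))


def make_window(ssr_id: str, chrom: str, flank5: str, tract: str, flank3: str) -> FlankWindow:
    return FlankWindow(
        ssr_id=ssr_id,
        chromosome=chrom,
        sequence=flank5 + tract + flank3,
        flank5_len=len(flank5),
        flank3_len=len(flank3),
        truncated5=len(flank5) < 200,
        truncated3=len(flank3) < 200,
    )


# --------------------------------------------------------------------------
# exhaustive ungapped local-alignment oracle (Kadane over every diagonal)

def best_ungapped_score(q: str, t: str, match: int = 1, mismatch: int = -2) -> int:
    """Highest-scoring ungapped local alignment between two strings,
    computed exhaustively (independent of the seed-and-extend path)."""
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    m, n = len(qa), len(ta)
    best = 0
    for d in range(-(n - 1), m):
        i0, i1 = max(0, d), min(m, n + d)
        if i1 <= i0:
            continue
        x = np.where(qa[i0:i1] == ta[i0 - d : i1 - d], match, mismatch).astype(np.int64)
        cs = np.cumsum(x)
        floor = np.minimum.accumulate(np.concatenate(([0], cs[:-1])))
        best = max(best, int((cs - floor).max()))
    return best


def oracle_hit_pairs(
    windows: list[FlankWindow], params: AlignParams
) -> set[tuple[str, str]]:
    """All ordered (query, target) pairs whose exhaustive best ungapped score
    passes the E-value threshold, using the same statistics as the search."""
    pairs = set()
    log_thr = math.log10(params.e_threshold)
    for q in windows:
        n_db = sum(len(t.sequence) for t in windows if t.ssr_id != q.ssr_id)
        for t in windows:
            if t.ssr_id == q.ssr_id:
                continue
            s = best_ungapped_score(q.sequence, t.sequence, params.match, params.mismatch)
            log_e = (
                math.log10(params.k_ * len(q.sequence) * n_db)
                - params.lambda_ * s / math.log(10)
            )
            if log_e <= log_thr:
                pairs.add((q.ssr_id, t.ssr_id))
    return pairs
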