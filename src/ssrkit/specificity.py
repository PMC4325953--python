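"""Flank-uniqueness screening for chromosome-specific SSRs.

Each SSR is represented by a *flank window*: up to 200 bp of 5' context, the
repeat tract, and up to 200 bp of 3' context. Windows are compared all
against all with an ungapped seed-and-extend local search (exact 12-mer
seeds, +1 match / -2 mismatch, x-drop 20) and hits are ranked by the
Karlin-Altschul expectation E = K * m * n * exp(-lambda * S) with m the
query length and n the summed length of the current target set. An SSR is

* *repetitive_within* if its window is similar (E <= threshold) to another
  window on the same chromosome — windows are clustered single-linkage and
  any member of a cluster of size >= 2 is repetitive;
* *shared_across* if it is unique within its chromosome but similar to a
  window on another chromosome of the comparison set;
* *chromosome_specific* otherwise: unique on its own chromosome and without
  similar counterpart anywhere else at the chosen E-value threshold
  (default 1e-100 for ~400 bp of flank, the value that separates true
  cross-chromosome duplications from chance similarity; 1e-10..1e-150 is
  the documented sensitivity range).

Seeds lying entirely within the repeat tract are suppressed so that two
SSRs sharing only a motif never seed an alignment; flank context decides
similarity. Alignments may still extend through the tract.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_io import Chromosome, Genome
from .ssr_engine import SSRRecord


@dataclass(frozen=True)
class FlankWindow:
    """An SSR plus its 5'/3' context, the unit of similarity comparison.

    `tract_start`/`tract_end` locate the repeat within `sequence`
    (tract_start == flank5_len). Truncation flags mark windows whose flank
    was cut short by a chromosome end.
    """

    ssr_id: str
    chromosome: str
    sequence: str
    flank5_len: int
    flank3_len: int
    truncated5: bool
    truncated3: bool

    @property
    def tract_start(self) -> int:
        return self.flank5_len

    @property
    def tract_end(self) -> int:
        return len(self.sequence) - self.flank3_len

    def __len__(self) -> int:
        return len(self.sequence)


def extract_flanks(
    record: SSRRecord, chromosome: Chromosome, width: int = 200
) -> FlankWindow:
    """Cut the repeat tract plus up to `width` bp of context on each side."""
    if record.chromosome != chromosome.name:
        raise ValueError(
            f"record on {record.chromosome!r} does not lie on {chromosome.name!r}"
        )
    if not (0 <= record.start < record.end <= chromosome.length):
        raise ValueError(
            f"record [{record.start}, {record.end}) outside chromosome "
            f"{chromosome.name!r} of length {chromosome.length}"
        )
    lo = max(0, record.start - width)
    hi = min(chromosome.length, record.end + width)
    return FlankWindow(
        ssr_id=f"{record.chromosome}:{record.start}-{record.end}",
        chromosome=record.chromosome,
        sequence=chromosome.sequence[lo:hi],
        flank5_len=record.start - lo,
        flank3_len=hi - record.end,
        truncated5=record.start - lo < width,
        truncated3=hi - record.end < width,
    )


def extract_all_flanks(
    records: Sequence[SSRRecord], genome: Genome, width: int = 200
) -> list[FlankWindow]:
    return [extract_flanks(r, genome[r.chromosome], width) for r in records]


@dataclass(frozen=True)
class AlignParams:
    """Seed-and-extend search settings.

    lambda_/k_ are the Karlin-Altschul statistical constants for ungapped
    +1/-2 scoring (lambda = 1.28 nats per score unit, K = 0.46); they turn a
    raw score into an expectation given query length m and database length n.
    """

    seed_k: int = 12
    match: int = 1
    mismatch: int = -2
    xdrop: int = 20
    lambda_: float = 1.28
    k_: float = 0.46
    e_threshold: float = 1e-100
    mask_tract_seeds: bool = True
    include_tract: bool = True


@dataclass(frozen=True)
class AlignmentHit:
    """Best local similarity found between two windows (no self-hits)."""

    query_id: str
    target_id: str
    score: int
    align_len: int
    log10_evalue: float

    @property
    def e_value(self) -> float:
        return 10.0 ** self.log10_evalue if self.log10_evalue > -300 else 0.0


def _log10_evalue(score: int, m: int, n: int, params: AlignParams) -> float:
    # E = K m n exp(-lambda S), computed in log10 to survive huge scores
    return (
        math.log10(params.k_ * m * n) - params.lambda_ * score / math.log(10)
        if m > 0 and n > 0
        else math.inf
    )


def _window_text(w: FlankWindow, params: AlignParams) -> str:
    if params.include_tract:
        return w.sequence
    return w.sequence[: w.tract_start] + w.sequence[w.tract_end :]


def _seed_positions(text: str, w: FlankWindow, params: AlignParams):
    """Start positions of seedable k-mers (ACGT-only, optionally excluding
    k-mers fully inside the repeat tract)."""
    k = params.seed_k
    for i in range(len(text) - k + 1):
        kmer = text[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        if (
            params.mask_tract_seeds
            and params.include_tract
            and i >= w.tract_start
            and i + k <= w.tract_end
        ):
            continue
        yield i, kmer


def _extend_ungapped(
    q: str, t: str, qpos: int, tpos: int, params: AlignParams
) -> tuple[int, int, int]:
    """Extend an exact k-mer seed both ways with x-drop.

    Returns (score, left, right): the total score and how far the alignment
    reaches beyond the seed on each side (alignment length = k+left+right).
    """
    k = params.seed_k
    score = k * params.match

    best = run = 0
    i, j = qpos + k, tpos + k
    right = 0
    while i < len(q) and j < len(t):
        if q[i] == "N" or t[j] == "N":
            break
        run += params.match if q[i] == t[j] else params.mismatch
        if run > best:
            best, right = run, i - (qpos + k) + 1
        if run < best - params.xdrop:
            break
        i += 1
        j += 1
    score += best

    best = run = 0
    i, j = qpos - 1, tpos - 1
    left = 0
    while i >= 0 and j >= 0:
        if q[i] == "N" or t[j] == "N":
            break
        run += params.match if q[i] == t[j] else params.mismatch
        if run > best:
            best, left = run, qpos - i
        if run < best - params.xdrop:
            break
        i -= 1
        j -= 1
    score += best
    return score, left, right


class _WindowIndex:
    """Exact k-mer index over a fixed target window set."""

    def __init__(self, targets: Sequence[FlankWindow], params: AlignParams):
        self.params = params
        self.targets = list(targets)
        self.texts = [_window_text(t, params) for t in self.targets]
        self.total_length = sum(len(x) for x in self.texts)
        self.kmers: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ti, (t, text) in enumerate(zip(self.targets, self.texts)):
            for pos, kmer in _seed_positions(text, t, params):
                self.kmers[kmer].append((ti, pos))

    def search(self, query: FlankWindow) -> list[AlignmentHit]:
        """Best hit per target with E <= threshold, self-hits excluded."""
        params = self.params
        qtext = _window_text(query, params)
        # database length excludes the query's own window when indexed
        n = self.total_length - sum(
            len(self.texts[i])
            for i, t in enumerate(self.targets)
            if t.ssr_id == query.ssr_id
        )
        if n <= 0:
            return []
        best_per_diag: dict[tuple[int, int], tuple[int, int]] = {}
        covered_to: dict[tuple[int, int], int] = {}  # q-end reached per diagonal
        for qpos, kmer in _seed_positions(qtext, query, params):
            for ti, tpos in self.kmers.get(kmer, ()):
                if self.targets[ti].ssr_id == query.ssr_id:
                    continue
                key = (ti, qpos - tpos)
                # seeds inside a previous extension on this diagonal belong
                # to the same alignment; a seed beyond it starts a new one
                if qpos < covered_to.get(key, -1):
                    continue
                score, left, right = _extend_ungapped(
                    qtext, self.texts[ti], qpos, tpos, params
                )
                alen = params.seed_k + left + right
                covered_to[key] = qpos + params.seed_k + right
                prev = best_per_diag.get(key)
                if prev is None or score > prev[0]:
                    best_per_diag[key] = (score, alen)
        best_per_target: dict[int, tuple[int, int]] = {}
        for (ti, _), (score, alen) in best_per_diag.items():
            if ti not in best_per_target or score > best_per_target[ti][0]:
                best_per_target[ti] = (score, alen)
        hits = []
        log_thr = math.log10(params.e_threshold)
        for ti, (score, alen) in best_per_target.items():
            log_e = _log10_evalue(score, len(qtext), n, params)
            if log_e <= log_thr:
                hits.append(
                    AlignmentHit(
                        query_id=query.ssr_id,
                        target_id=self.targets[ti].ssr_id,
                        score=score,
                        align_len=alen,
                        log10_evalue=log_e,
                    )
                )
        hits.sort(key=lambda h: (h.log10_evalue, h.target_id))
        return hits


def similarity_search(
    query: FlankWindow,
    targets: Sequence[FlankWindow],
    params: AlignParams | None = None,
) -> list[AlignmentHit]:
    """Search one window against a target set; hits sorted by E-value."""
    params = params or AlignParams()
    if not targets:
        return []
    return _WindowIndex(targets, params).search(query)


def all_pairs_hits(
    windows: Sequence[FlankWindow], params: AlignParams | None = None
) -> list[AlignmentHit]:
    """All-vs-all search within one window set (each window queried against
    the others, sharing one index)."""
    params = params or AlignParams()
    index = _WindowIndex(windows, params)
    out: list[AlignmentHit] = []
    for w in windows:
        out.extend(index.search(w))
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclass(frozen=True)
class RepetitionStats:
    """Within-chromosome repetition of SSR windows (single-linkage clusters)."""

    chromosome: str
    total: int
    uni_count: int
    uni_percent: float
    mean_repetitions: float  # mean cluster size over clusters of size >= 2
    max_repetitions: int
    clusters: tuple[tuple[str, ...], ...]


def within_chromosome_repetition(
    windows: Sequence[FlankWindow], params: AlignParams | None = None
) -> RepetitionStats:
    """Cluster same-chromosome windows by similarity; singletons are uniSSRs."""
    params = params or AlignParams()
    chroms = {w.chromosome for w in windows}
    if len(chroms) > 1:
        raise ValueError(f"windows span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop() if chroms else ""
    uf = _UnionFind(len(windows))
    pos = {w.ssr_id: i for i, w in enumerate(windows)}
    for hit in all_pairs_hits(windows, params):
        uf.union(pos[hit.query_id], pos[hit.target_id])
    members: dict[int, list[str]] = defaultdict(list)
    for i, w in enumerate(windows):
        members[uf.find(i)].append(w.ssr_id)
    clusters = tuple(tuple(m) for m in members.values())
    rep_sizes = [len(c) for c in clusters if len(c) >= 2]
    uni = sum(1 for c in clusters if len(c) == 1)
    return RepetitionStats(
        chromosome=chrom,
        total=len(windows),
        uni_count=uni,
        uni_percent=100.0 * uni / len(windows) if windows else 100.0,
        mean_repetitions=sum(rep_sizes) / len(rep_sizes) if rep_sizes else 0.0,
        max_repetitions=max(rep_sizes, default=1 if windows else 0),
        clusters=clusters,
    )


CHROMOSOME_SPECIFIC = "chromosome_specific"
REPETITIVE_WITHIN = "repetitive_within"
SHARED_ACROSS = "shared_across"


@dataclass(frozen=True)
class ChromosomeSpecificity:
    chromosome: str
    total: int
    uni_count: int
    uni_percent: float
    specific_count: int
    specific_percent: float
    mean_repetitions: float
    max_repetitions: int


@dataclass
class SpecificityReport:
    """Exhaustive, mutually exclusive per-SSR labels plus per-chromosome
    tallies. Chromosome-specific SSRs are always a subset of the uniSSRs."""

    labels: dict[str, str]
    per_chromosome: list[ChromosomeSpecificity]
    hits: list[AlignmentHit] = field(default_factory=list)

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)


def cross_chromosome_screen(
    windows: Sequence[FlankWindow], params: AlignParams | None = None
) -> SpecificityReport:
    """Label every SSR window across a (possibly multi-genome) chromosome set.

    Within-chromosome repetition is assessed first; the surviving uniSSRs
    are then searched against every window on every other chromosome, and
    those without a similar counterpart are chromosome-specific.
    """
    params = params or AlignParams()
    by_chrom: dict[str, list[FlankWindow]] = defaultdict(list)
    for w in windows:
        by_chrom[w.chromosome].append(w)

    labels: dict[str, str] = {}
    all_hits: list[AlignmentHit] = []
    rep_stats: dict[str, RepetitionStats] = {}
    for chrom in sorted(by_chrom):
        stats = within_chromosome_repetition(by_chrom[chrom], params)
        rep_stats[chrom] = stats
        for cluster in stats.clusters:
            if len(cluster) >= 2:
                for sid in cluster:
                    labels[sid] = REPETITIVE_WITHIN

    for chrom in sorted(by_chrom):
        others = [w for c, ws in by_chrom.items() if c != chrom for w in ws]
        if not others:
            for w in by_chrom[chrom]:
                labels.setdefault(w.ssr_id, CHROMOSOME_SPECIFIC)
            continue
        index = _WindowIndex(others, params)
        for w in by_chrom[chrom]:
            if labels.get(w.ssr_id) == REPETITIVE_WITHIN:
                continue
            hits = index.search(w)
            all_hits.extend(hits)
            labels[w.ssr_id] = SHARED_ACROSS if hits else CHROMOSOME_SPECIFIC

    per_chrom = []
    for chrom in sorted(by_chrom):
        ws = by_chrom[chrom]
        stats = rep_stats[chrom]
        specific = sum(
            1 for w in ws if labels[w.ssr_id] == CHROMOSOME_SPECIFIC
        )
        per_chrom.append(
            ChromosomeSpecificity(
                chromosome=chrom,
                total=len(ws),
                uni_count=stats.uni_count,
                uni_percent=stats.uni_percent,
                specific_count=specific,
                specific_percent=100.0 * specific / len(ws) if ws else 0.0,
                mean_repetitions=stats.mean_repetitions,
                max_repetitions=stats.max_repetitions,
            )
        )
    return SpecificityReport(labels=labels, per_chromosome=per_chrom, hits=all_hits)


def assign_markers(
    markers: Mapping[str, str],
    genome: Genome,
    params: AlignParams | None = None,
    margin_log10: float = 10.0,
) -> dict[str, str]:
    """Assign marker sequences to chromosomes by best similarity.

    Each whole chromosome is treated as one target; a marker is assigned to
    the chromosome of its best hit only when that hit passes the E-value
    threshold and beats the runner-up chromosome by `margin_log10` orders of
    magnitude in E-value; otherwise the marker is reported ``"ambiguous"``
    (or ``"unmapped"`` when nothing passes at all). Homologous chromosome
    pairs typically yield two near-equal hits and come back ambiguous.
    """
    from dataclasses import replace as _replace

    params = params or AlignParams()
    # whole chromosomes are wrapped as flankless windows, so the whole
    # sequence counts as "tract"; seed masking must be off here
    params = _replace(params, mask_tract_seeds=False)
    targets = [
        FlankWindow(
            ssr_id=c.name,
            chromosome=c.name,
            sequence=c.sequence,
            flank5_len=0,
            flank3_len=0,
            truncated5=False,
            truncated3=False,
        )
        for c in genome
    ]
    index = _WindowIndex(targets, params)
    out: dict[str, str] = {}
    for name, seq in markers.items():
        query = FlankWindow(
            ssr_id=f"marker:{name}",
            chromosome="?",
            sequence=seq.upper(),
            flank5_len=0,
            flank3_len=0,
            truncated5=False,
            truncated3=False,
        )
        hits = index.search(query)
        if not hits:
            out[name] = "unmapped"
        elif (
            len(hits) == 1
            or hits[1].log10_evalue - hits[0].log10_evalue >= margin_log10
        ):
            out[name] = hits[0].target_id
        else:
            out[name] = "ambiguous"
    return out
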