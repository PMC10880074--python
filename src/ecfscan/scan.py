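"""Bipartite -35/-10 promoter scanning with empirical E-values.

A *placement* puts the -35 box at offset ``pos35`` of a window (given in
transcription orientation), the -10 box ``spacer`` bases further along
(spacer within the pair's 15-17 nt range), and, when the window is
anchored on a TSS, requires 3-6 bases strictly between the last base of
the -10 box and the TSS base.  The total score is the sum of the two box
log-probability scores; the best match per window is the placement with
the maximal total.

Significance is assessed empirically: the window is shuffled ``n`` times
(preserving its mononucleotide counts exactly), each shuffle is scanned in
the same mode, and the E-value is the fraction of shuffles whose best
total is at least the observed total.

Coordinates are 0-based within window sequences; genomic coordinates in
:class:`SequenceWindow` and on emitted hits are 1-based inclusive on the
forward strand.  Minus-strand windows hold the reverse complement, so box
order in ``seq`` is always -35 -> -10 -> TSS.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio.Seq import reverse_complement

from .pssm import PssmPair, encode
from .tss import TssRecord

__all__ = [
    "SequenceWindow",
    "PromoterHit",
    "Placements",
    "window_from_genome",
    "placement_scores",
    "all_hits",
    "best_hit",
    "materialize_hits",
    "evalue_from_null",
    "best_totals",
    "null_best_totals",
    "empirical_evalue",
    "tss_anchored_scan",
    "window_rng",
]

logger = logging.getLogger("ecfscan")

NEG_INF = float("-inf")
_TIE_TOL = 1e-12


@dataclass(eq=False)
class SequenceWindow:
    """A sequence region in transcription orientation.

    ``genomic_start``/``genomic_end`` are 1-based inclusive forward-strand
    coordinates; for minus-strand windows ``seq`` is the reverse complement
    of the forward-strand slice.  ``anchor_tss_offset`` is the index of the
    TSS base within ``seq`` for TSS-anchored windows (the last base for
    ``tss_upstream`` windows).
    """

    window_id: str
    source: str  # tss_upstream | feature_window | genome_tile | synthetic
    contig: str | None
    strand: str
    genomic_start: int
    genomic_end: int
    seq: str
    anchor_tss_offset: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.seq) != self.genomic_end - self.genomic_start + 1:
            raise ValueError(
                f"{self.window_id}: sequence length {len(self.seq)} does not match "
                f"coordinates [{self.genomic_start}, {self.genomic_end}]"
            )
        if self.anchor_tss_offset is not None and not (
            0 <= self.anchor_tss_offset < len(self.seq)
        ):
            raise ValueError(f"{self.window_id}: anchor offset outside sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PromoterHit:
    """One scored bipartite placement.

    ``pos35``/``pos10`` are 0-based box start offsets within the window
    sequence; ``g35_*``/``g10_*`` are 1-based inclusive forward-strand
    genomic coordinates (None for purely synthetic windows).
    ``tss_distance`` counts the bases strictly between the last base of
    the -10 box and the TSS base.
    """

    window_id: str
    pos35: int
    pos10: int
    spacer: int
    s35: float
    s10: float
    total: float
    tss_distance: int | None = None
    evalue: float | None = None
    contig: str | None = None
    strand: str | None = None
    g35_start: int | None = None
    g35_end: int | None = None
    g10_start: int | None = None
    g10_end: int | None = None
    feature_id: str | None = None

    @property
    def genomic_span(self) -> tuple[int, int] | None:
        """Forward-strand 1-based inclusive span covering both boxes."""
        if self.g35_start is None or self.g10_end is None:
            return None
        coords = (self.g35_start, self.g35_end, self.g10_start, self.g10_end)
        return (min(coords), max(coords))


class Placements(NamedTuple):
    """Vectorised placement geometry and scores for one or more sequences.

    ``p35``, ``spacer`` and ``tss_distance`` have shape (k,) and describe
    the k geometry-valid placements; ``s35``, ``s10`` have shape (R, k)
    for R sequence rows.  ``tss_distance`` is -1 for unanchored scans.
    """

    p35: np.ndarray
    spacer: np.ndarray
    tss_distance: np.ndarray
    s35: np.ndarray
    s10: np.ndarray

    @property
    def p10(self) -> np.ndarray:
        return self.p35 + self.l35 + self.spacer

    @property
    def total(self) -> np.ndarray:
        return self.s35 + self.s10

    # -35 box length, set by placement_scores (needed by the p10 property)
    l35: int = 0


def _box_position_scores(enc2d: np.ndarray, logprob: np.ndarray) -> np.ndarray:
    """Score every start offset of a box: out[r, p] = score at offset p."""
    R, N = enc2d.shape
    L = logprob.shape[1]
    P = N - L + 1
    if P <= 0:
        return np.zeros((R, 0))
    out = np.zeros((R, P))
    for j in range(L):
        out += logprob[:, j][enc2d[:, j : j + P]]
    return out


def _geometry(
    pair: PssmPair, n: int, anchor: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All geometry-valid (p35, spacer, tss_distance) triples for length n."""
    l35, l10 = pair.pssm35.length, pair.pssm10.length
    p35_parts, sp_parts, d_parts = [], [], []
    p35_max = n - l35 + 1
    p10_max = n - l10 + 1
    for sp in range(pair.spacer_min, pair.spacer_max + 1):
        off = l35 + sp
        if anchor is None:
            hi = min(p35_max, p10_max - off)
            if hi > 0:
                p35 = np.arange(hi, dtype=np.int64)
                p35_parts.append(p35)
                sp_parts.append(np.full(hi, sp, dtype=np.int64))
                d_parts.append(np.full(hi, -1, dtype=np.int64))
        else:
            for d in range(pair.tss_dist_min, pair.tss_dist_max + 1):
                p10 = anchor - l10 - d
                p35 = p10 - off
                if p35 >= 0 and 0 <= p10 < p10_max:
                    p35_parts.append(np.array([p35], dtype=np.int64))
                    sp_parts.append(np.array([sp], dtype=np.int64))
                    d_parts.append(np.array([d], dtype=np.int64))
    if not p35_parts:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy(), z.copy()
    return (
        np.concatenate(p35_parts),
        np.concatenate(sp_parts),
        np.concatenate(d_parts),
    )


def placement_scores(
    enc: np.ndarray, pair: PssmPair, anchor: int | None = None
) -> Placements:
    """Score every geometry-valid placement for one or many sequences.

    ``enc`` is an encoded sequence (1-D) or a stack of equal-length
    sequences (2-D, one row each).
    """
    enc2d = np.atleast_2d(enc)
    n = enc2d.shape[1]
    p35, sp, d = _geometry(pair, n, anchor)
    b35 = _box_position_scores(enc2d, pair.pssm35.logprob)
    b10 = _box_position_scores(enc2d, pair.pssm10.logprob)
    p10 = p35 + pair.pssm35.length + sp
    pl = Placements(p35, sp, d, b35[:, p35], b10[:, p10])
    return pl._replace(l35=pair.pssm35.length)


def best_totals(
    enc2d: np.ndarray, pair: PssmPair, anchor: int | None = None
) -> np.ndarray:
    """Best placement total per row; -inf for rows with no valid placement."""
    pl = placement_scores(enc2d, pair, anchor)
    R = np.atleast_2d(enc2d).shape[0]
    if pl.p35.size == 0:
        return np.full(R, NEG_INF)
    return pl.total.max(axis=1)


def _make_hit(
    window: SequenceWindow,
    pair: PssmPair,
    p35: int,
    sp: int,
    s35: float,
    s10: float,
    d: int,
) -> PromoterHit:
    l35, l10 = pair.pssm35.length, pair.pssm10.length
    p10 = p35 + l35 + sp
    hit = PromoterHit(
        window_id=window.window_id,
        pos35=int(p35),
        pos10=int(p10),
        spacer=int(sp),
        s35=float(s35),
        s10=float(s10),
        total=float(s35 + s10),
        tss_distance=int(d) if d >= 0 else None,
        contig=window.contig,
        strand=window.strand,
    )
    if window.contig is not None:
        if window.strand == "+":
            hit.g35_start = window.genomic_start + int(p35)
            hit.g35_end = hit.g35_start + l35 - 1
            hit.g10_start = window.genomic_start + int(p10)
            hit.g10_end = hit.g10_start + l10 - 1
        else:
            hit.g35_end = window.genomic_end - int(p35)
            hit.g35_start = hit.g35_end - l35 + 1
            hit.g10_end = window.genomic_end - int(p10)
            hit.g10_start = hit.g10_end - l10 + 1
    return hit


def all_hits(window: SequenceWindow, pair: PssmPair) -> list[PromoterHit]:
    """Every placement satisfying the geometry, fully scored.

    Deterministic order: by ``pos35``, then spacer.  A window too short
    for any placement yields an empty list.
    """
    enc = encode(window.seq)
    pl = placement_scores(enc, pair, window.anchor_tss_offset)
    if pl.p35.size == 0:
        return []
    order = np.lexsort((pl.spacer, pl.p35))
    return [
        _make_hit(window, pair, pl.p35[i], pl.spacer[i], pl.s35[0, i],
                  pl.s10[0, i], pl.tss_distance[i])
        for i in order
    ]


def _best_index(pl: Placements, l35: int) -> int:
    """Index of the maximal-total placement; ties -> smaller spacer, then
    the placement closest to the 3' end (largest -10 box offset)."""
    t = pl.total[0]
    m = t.max()
    cand = np.flatnonzero(t >= m - _TIE_TOL)
    p10 = pl.p35[cand] + l35 + pl.spacer[cand]
    return int(cand[np.lexsort((-p10, pl.spacer[cand]))[0]])


def materialize_hits(
    window: SequenceWindow,
    pair: PssmPair,
    pl: Placements,
    indices: Iterable[int] | None = None,
) -> list[PromoterHit]:
    """Build :class:`PromoterHit` objects from placement indices.

    With ``indices=None`` a one-element list holding the best placement
    (maximal total, documented tie-breaks) is returned.  This is the fast
    path for callers that keep the vectorised :class:`Placements` around.
    """
    if pl.p35.size == 0:
        return []
    if indices is None:
        indices = [_best_index(pl, pair.pssm35.length)]
    return [
        _make_hit(window, pair, pl.p35[i], pl.spacer[i], pl.s35[0, i],
                  pl.s10[0, i], pl.tss_distance[i])
        for i in indices
    ]


def best_hit(window: SequenceWindow, pair: PssmPair) -> PromoterHit | None:
    """The placement maximising the total score, or None when none fits."""
    enc = encode(window.seq)
    pl = placement_scores(enc, pair, window.anchor_tss_offset)
    if pl.p35.size == 0:
        return None
    i = _best_index(pl, pair.pssm35.length)
    return _make_hit(window, pair, pl.p35[i], pl.spacer[i], pl.s35[0, i],
                     pl.s10[0, i], pl.tss_distance[i])


def shuffled_rows(enc: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent exact shuffles (permutations) of an encoded sequence."""
    tiled = np.tile(enc, (n, 1))
    return rng.permuted(tiled, axis=1)


def null_best_totals(
    window: SequenceWindow,
    pair: PssmPair,
    n: int = 1000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Best totals of n exact shuffles of the window, scanned in the same
    (anchored or free) mode as the window itself."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    enc = encode(window.seq)
    rows = shuffled_rows(enc, n, rng)
    return best_totals(rows, pair, window.anchor_tss_offset)


def evalue_from_null(
    null: np.ndarray, total: float, estimator: str = "kn"
) -> float:
    """Fraction of null best scores at least as extreme as ``total``.

    ``"kn"`` returns k/n (0 is attainable); ``"k1n1"`` returns the
    add-one variant (k+1)/(n+1).
    """
    k = int(np.count_nonzero(null >= total - 1e-9))
    n = null.size
    if estimator == "kn":
        return k / n
    if estimator == "k1n1":
        return (k + 1) / (n + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def empirical_evalue(
    window: SequenceWindow,
    pair: PssmPair,
    observed: PromoterHit,
    n: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    estimator: str = "kn",
) -> float:
    """Empirical E-value of an observed hit against composition-matched
    shuffles of its own window (seeded and reproducible)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    null = null_best_totals(window, pair, n, rng)
    return evalue_from_null(null, observed.total, estimator)


def window_rng(seed: int, window_id: str) -> np.random.Generator:
    """Deterministic per-window RNG, independent of evaluation order."""
    return np.random.default_rng([seed, zlib.crc32(window_id.encode())])


def window_from_genome(
    genome: dict[str, str],
    contig: str,
    strand: str,
    gstart: int,
    gend: int,
    window_id: str,
    source: str,
    anchored_last_base: bool = False,
) -> SequenceWindow:
    """Extract a window in transcription orientation, clipping at edges."""
    if contig not in genome:
        raise KeyError(f"unknown contig {contig!r}")
    clen = len(genome[contig])
    clipped = gstart < 1 or gend > clen
    gs, ge = max(1, gstart), min(clen, gend)
    if gs > ge:
        raise ValueError(f"{window_id}: window [{gstart}, {gend}] outside contig")
    seq = genome[contig][gs - 1 : ge]
    if strand == "-":
        seq = reverse_complement(seq)
    anchor = len(seq) - 1 if anchored_last_base else None
    return SequenceWindow(
        window_id=window_id,
        source=source,
        contig=contig,
        strand=strand,
        genomic_start=gs,
        genomic_end=ge,
        seq=seq,
        anchor_tss_offset=anchor,
        clipped=clipped,
    )


def tss_anchored_scan(
    tss: Iterable[TssRecord],
    genome: dict[str, str],
    pair: PssmPair,
    window_len: int = 40,
    max_evalue: float = 0.05,
    n_null: int = 1000,
    seed: int = 0,
    estimator: str = "kn",
) -> list[PromoterHit]:
    """Best anchored promoter hit upstream of each TSS, E-value filtered.

    The window covers ``window_len`` bases ending at (and including) the
    TSS, in transcription orientation.  Hits with E-value > ``max_evalue``
    are removed.  Windows clipped at the contig edge are flagged; windows
    too short for any placement are logged and skipped.
    """
    hits: list[PromoterHit] = []
    for rec in tss:
        if rec.contig not in genome:
            raise ValueError(f"TSS record on unknown contig: {rec}")
        clen = len(genome[rec.contig])
        if not (1 <= rec.position <= clen):
            raise ValueError(f"TSS off contig ({rec.contig} length {clen}): {rec}")
        if rec.strand == "+":
            gstart, gend = rec.position - window_len + 1, rec.position
        else:
            gstart, gend = rec.position, rec.position + window_len - 1
        wid = f"tss:{rec.contig}:{rec.strand}:{rec.position}"
        window = window_from_genome(
            genome, rec.contig, rec.strand, gstart, gend, wid,
            source="tss_upstream", anchored_last_base=True,
        )
        hit = best_hit(window, pair)
        if hit is None:
            logger.info("window %s too short for any placement; skipped", wid)
            continue
        rng = window_rng(seed, wid)
        hit.evalue = empirical_evalue(
            window, pair, hit, n=n_null, rng=rng, estimator=estimator
        )
        if hit.evalue <= max_evalue:
            hits.append(hit)
    return hits
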