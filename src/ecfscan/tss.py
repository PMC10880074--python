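"""Transcription start site (TSS) calling from per-base 5'-end read counts.

Cappable-seq style protocols enrich primary transcript 5' ends; after
mapping, the first base of each read marks a candidate TSS and the per-base
tallies of read starts ("alignments per base", Rns) form a stranded count
track.  Every position is normalised to a relative read score

    RRS = (Rns / Rt) * 1e6,

where Rt is the sample's total number of mapped TSS reads.  Nearby
positions are merged into clusters whenever the gap between neighbouring
TSS does not exceed ``max_gap`` (default 3 nt); each cluster is represented
by its dominant (maximal-Rns) member, and dominant TSS above an RRS
threshold (1.5 / 3.0 / 7.5 in common use, 3.0 downstream) are retained.
Comparing two samples, a TSS is *strain specific* to sample A when no
retained TSS of sample B lies within ``tolerance`` nt on the same
contig/strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StartCountTrack",
    "TssRecord",
    "TssCluster",
    "compute_rrs",
    "cluster_tss",
    "select_tss",
    "call_tss",
    "strain_specific_tss",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "tss_table",
    "write_tss_tsv",
    "read_tss_tsv",
    "write_dominant_bed",
]

DEFAULT_MIN_RRS = 3.0
DEFAULT_MAX_GAP = 3


@dataclass(eq=False)
class StartCountTrack:
    """Per-base read 5'-end counts for one contig/strand of one sample.

    ``rt`` is the sample-wide total of mapped TSS reads (all contigs and
    strands), used as the RRS denominator; it must be at least this
    track's stored sum.
    """

    sample_id: str
    contig: str
    strand: str
    positions: np.ndarray  # 1-based, sorted, unique
    counts: np.ndarray  # positive integers, parallel to positions
    rt: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        pos = np.asarray(self.positions, dtype=np.int64)
        cnt = np.asarray(self.counts, dtype=np.int64)
        if pos.shape != cnt.shape:
            raise ValueError("positions and counts must be parallel arrays")
        order = np.argsort(pos, kind="stable")
        pos, cnt = pos[order], cnt[order]
        keep = cnt > 0
        pos, cnt = pos[keep], cnt[keep]
        if pos.size and (np.diff(pos) == 0).any():
            raise ValueError("duplicate positions in count track")
        if (cnt < 0).any():
            raise ValueError("negative counts")
        if pos.size and pos[0] < 1:
            raise ValueError("positions are 1-based and must be >= 1")
        if self.rt < int(cnt.sum()):
            raise ValueError(
                f"rt={self.rt} is smaller than the stored read total {int(cnt.sum())}"
            )
        self.positions, self.counts = pos, cnt

    @classmethod
    def from_dict(
        cls, sample_id: str, contig: str, strand: str, counts: dict[int, int], rt: int
    ) -> "StartCountTrack":
        pos = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
        cnt = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
        return cls(sample_id, contig, strand, pos, cnt, rt)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TssRecord:
    """One candidate TSS position with its raw count and RRS."""

    contig: str
    strand: str
    position: int
    rns: int
    rrs: float


@dataclass(eq=False)
class TssCluster:
    """A maximal run of TSS with neighbouring gaps <= max_gap.

    ``dominant`` is the member with the highest Rns; ties break to the
    most upstream member (5'-most on the strand).
    """

    members: list[TssRecord]
    dominant: TssRecord = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        strand = self.members[0].strand
        best = max(
            self.members,
            key=lambda r: (r.rns, r.position if strand == "-" else -r.position),
        )
        self.dominant = best

    @property
    def span(self) -> tuple[int, int]:
        return (self.members[0].position, self.members[-1].position)


def compute_rrs(track: StartCountTrack) -> list[TssRecord]:
    """Score every nonzero position of a track: RRS = Rns / Rt * 1e6."""
    if track.rt <= 0:
        raise ValueError(f"empty sample: {track.sample_id} has Rt = {track.rt}")
    scale = 1e6 / track.rt
    return [
        TssRecord(track.contig, track.strand, int(p), int(c), float(c) * scale)
        for p, c in zip(track.positions, track.counts)
    ]


def cluster_tss(
    records: list[TssRecord], max_gap: int = DEFAULT_MAX_GAP
) -> list[TssCluster]:
    """Merge positions into clusters where neighbouring gaps <= max_gap.

    The gap is the positional difference between neighbouring TSS, so a
    difference of ``max_gap`` still clusters while ``max_gap + 1`` splits.
    All records must come from one contig/strand.
    """
    if not records:
        return []
    keys = {(r.contig, r.strand) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple contig/strand pairs: {sorted(keys)}")
    recs = sorted(records, key=lambda r: r.position)
    pos = np.array([r.position for r in recs], dtype=np.int64)
    breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
    return [TssCluster(list(chunk)) for chunk in np.split(np.asarray(recs, dtype=object), breaks)]


def select_tss(
    clusters: list[TssCluster], min_rrs: float = DEFAULT_MIN_RRS
) -> list[TssRecord]:
    """Dominant TSS of each cluster whose RRS >= min_rrs (inclusive)."""
    return [c.dominant for c in clusters if c.dominant.rrs >= min_rrs]


def call_tss(
    tracks: list[StartCountTrack],
    min_rrs: float = DEFAULT_MIN_RRS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[TssRecord]:
    """Full per-sample calling: RRS, clustering, dominant selection.

    Accepts all tracks of one sample (any contigs/strands) and returns the
    retained dominant TSS sorted by (contig, strand, position).
    """
    out: list[TssRecord] = []
    for track in tracks:
        out.extend(select_tss(cluster_tss(compute_rrs(track), max_gap), min_rrs))
    return sorted(out, key=lambda r: (r.contig, r.strand, r.position))


def strain_specific_tss(
    a: list[TssRecord], b: list[TssRecord], tolerance: int = 3
) -> list[TssRecord]:
    """Members of ``a`` with no member of ``b`` within +-tolerance nt.

    Matching is restricted to the same contig and strand.  ``a`` and ``b``
    should both be threshold-passing dominant TSS from the same reference.
    """
    b_pos: dict[tuple[str, str], np.ndarray] = {}
    for rec in b:
        b_pos.setdefault((rec.contig, rec.strand), []).append(rec.position)  # type: ignore[union-attr]
    b_sorted = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in b_pos.items()}
    out = []
    for rec in a:
        arr = b_sorted.get((rec.contig, rec.strand))
        if arr is not None and arr.size:
            i = int(np.searchsorted(arr, rec.position))
            near = []
            if i < arr.size:
                near.append(arr[i])
            if i > 0:
                near.append(arr[i - 1])
            if any(abs(int(p) - rec.position) <= tolerance for p in near):
                continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# File formats


def read_counts_tsv(path: str | Path, sample_id: str, rt: int | None = None
                    ) -> list[StartCountTrack]:
    """Read a 4-column TSV (contig, strand, 1-based position, count).

    ``rt`` defaults to the file's stored read total (i.e. the sample is
    assumed fully contained in the file).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["contig", "strand", "position", "count"],
        dtype={"contig": str, "strand": str, "position": np.int64, "count": np.int64},
    )
    total = int(df["count"].sum())
    rt = total if rt is None else rt
    tracks = []
    for (contig, strand), grp in df.groupby(["contig", "strand"], sort=True):
        tracks.append(
            StartCountTrack(sample_id, contig, strand,
                            grp["position"].to_numpy(), grp["count"].to_numpy(), rt)
        )
    return tracks


def write_counts_tsv(tracks: list[StartCountTrack], path: str | Path) -> None:
    rows = []
    for t in sorted(tracks, key=lambda t: (t.contig, t.strand)):
        for p, c in zip(t.positions, t.counts):
            rows.append((t.contig, t.strand, int(p), int(c)))
    pd.DataFrame(rows, columns=["contig", "strand", "position", "count"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bedgraph(
    path: str | Path, strand: str, sample_id: str, rt: int | None = None
) -> list[StartCountTrack]:
    """Read one strand's bedGraph (0-based half-open) into count tracks.

    Each interval's value is taken as the per-base 5'-end count of every
    base in the interval.  ``rt`` defaults to the stored total of this
    file; pass the sample-wide total when the sample spans several files.
    """
    df = pd.read_csv(
        path, sep=r"\s+", comment="t", header=None,
        names=["contig", "start", "end", "value"],
        dtype={"contig": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    pos_by_contig: dict[str, list[np.ndarray]] = {}
    cnt_by_contig: dict[str, list[np.ndarray]] = {}
    for row in df.itertuples(index=False):
        val = int(round(row.value))
        if val == 0:
            continue
        positions = np.arange(row.start + 1, row.end + 1, dtype=np.int64)
        pos_by_contig.setdefault(row.contig, []).append(positions)
        cnt_by_contig.setdefault(row.contig, []).append(
            np.full(positions.size, val, dtype=np.int64)
        )
    stored = sum(int(np.concatenate(v).sum()) for v in cnt_by_contig.values()) or 0
    rt = stored if rt is None else rt
    tracks = []
    for contig in sorted(pos_by_contig):
        tracks.append(
            StartCountTrack(
                sample_id, contig, strand,
                np.concatenate(pos_by_contig[contig]),
                np.concatenate(cnt_by_contig[contig]), rt,
            )
        )
    return tracks


def write_bedgraph(tracks: list[StartCountTrack], path: str | Path) -> None:
    """Write tracks (one strand) as bedGraph, merging equal-count runs."""
    strands = {t.strand for t in tracks}
    if len(strands) > 1:
        raise ValueError("bedGraph files are per-strand; got mixed strands")
    lines = []
    for t in sorted(tracks, key=lambda t: t.contig):
        run_start = None
        prev_pos = prev_cnt = None
        for p, c in zip(t.positions, t.counts):
            p, c = int(p), int(c)
            if prev_pos is not None and p == prev_pos + 1 and c == prev_cnt:
                prev_pos = p
                continue
            if prev_pos is not None:
                lines.append(f"{t.contig}\t{run_start - 1}\t{prev_pos}\t{prev_cnt}")
            run_start, prev_pos, prev_cnt = p, p, c
        if prev_pos is not None:
            lines.append(f"{t.contig}\t{run_start - 1}\t{prev_pos}\t{prev_cnt}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def tss_table(clusters_by_track: dict[tuple[str, str], list[TssCluster]],
              min_rrs: float = DEFAULT_MIN_RRS) -> pd.DataFrame:
    """Flatten clusters into the standard TSS table.

    Columns: contig, strand, position, rns, rrs, cluster_id, dominant.
    """
    rows = []
    cid = 0
    for (contig, strand) in sorted(clusters_by_track):
        for cluster in clusters_by_track[(contig, strand)]:
            cid += 1
            for rec in cluster.members:
                rows.append(
                    (rec.contig, rec.strand, rec.position, rec.rns, rec.rrs,
                     cid, rec is cluster.dominant)
                )
    return pd.DataFrame(
        rows, columns=["contig", "strand", "position", "rns", "rrs",
                       "cluster_id", "dominant"],
    )


def write_tss_tsv(records: list[TssRecord], path: str | Path) -> None:
    rows = [(r.contig, r.strand, r.position, r.rns, r.rrs)
            for r in sorted(records, key=lambda r: (r.contig, r.strand, r.position))]
    pd.DataFrame(rows, columns=["contig", "strand", "position", "rns", "rrs"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_tss_tsv(path: str | Path) -> list[TssRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        TssRecord(str(r.contig), str(r.strand), int(r.position), int(r.rns),
                  float(r.rrs))
        for r in df.itertuples(index=False)
    ]


def write_dominant_bed(records: list[TssRecord], path: str | Path) -> None:
    """BED6 of dominant TSS (score column carries the RRS)."""
    lines = [
        f"{r.contig}\t{r.position - 1}\t{r.position}\ttss_{i}\t{r.rrs:.6g}\t{r.strand}"
        for i, r in enumerate(
            sorted(records, key=lambda r: (r.contig, r.strand, r.position)), 1
        )
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
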