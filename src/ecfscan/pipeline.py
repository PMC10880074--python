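"""Genome-wide off-target promoter prediction pipeline.

Orchestrates the full procedure for one ECF group: optional TSS calling
from 5'-end count tracks and strain-specific TSS extraction, TSS-anchored
promoter scanning, collection of promoter placements upstream of
DE-supported regulated units, Pareto-front cutoff calibration, scanning of
500-up/100-down windows around every annotated feature, conjunctive
filtering, an optional intersection with externally supplied low
duplex-stability intervals, and a report with a genome background score
distribution.

E-values are expensive (1,000 shuffles per window), so the genome-wide
stage computes them only where they can still matter: with calibrated
cutoffs, for placements that already pass the three score cutoffs (the
filter is a conjunction, so this is exact); without calibration, for the
best placement per window.  Each window's shuffle null is generated once
from a window-id-derived seed and cached, so calibration and filtering
see identical E-values regardless of evaluation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrate import (
    CutoffSet,
    RegulatedUnit,
    apply_cutoffs,
    calibrate_cutoffs,
    pareto_front,
    read_de_table,
)
from .pssm import PssmPair, encode, load_pssm_pair
from .scan import (
    PromoterHit,
    SequenceWindow,
    all_hits,
    best_totals,
    evalue_from_null,
    materialize_hits,
    null_best_totals,
    placement_scores,
    tss_anchored_scan,
    window_from_genome,
    window_rng,
)
from .tss import StartCountTrack, call_tss, read_bedgraph, read_counts_tsv, \
    strain_specific_tss, write_tss_tsv

__all__ = [
    "GenomeFeature",
    "BackgroundScan",
    "PredictionReport",
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "extract_feature_windows",
    "genome_background_scan",
    "run_offtarget_pipeline",
    "hits_to_frame",
    "write_hits_gff3",
]

logger = logging.getLogger("ecfscan")

_TOL = 1e-12


@dataclass(frozen=True)
class GenomeFeature:
    """One annotated feature, GFF3-style 1-based inclusive coordinates."""

    feature_id: str
    contig: str
    strand: str
    start: int
    end: int
    feature_type: str = "gene"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.feature_id}: invalid span {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.feature_id}: strand must be '+' or '-'")

    @property
    def tx_start(self) -> int:
        """Strand-aware transcriptional/translational start coordinate."""
        return self.start if self.strand == "+" else self.end


# ---------------------------------------------------------------------------
# Standard-format IO


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in
               sorted(genome.items())]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | Path, feature_types: tuple[str, ...] | None = None
              ) -> list[GenomeFeature]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for f in db.all_features():
        if feature_types and f.featuretype not in feature_types:
            continue
        out.append(
            GenomeFeature(
                feature_id=f.id, contig=f.seqid, strand=f.strand,
                start=f.start, end=f.end, feature_type=f.featuretype,
            )
        )
    return out


def write_gff3(features: list[GenomeFeature], genome: dict[str, str],
               path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for name in sorted(genome):
        lines.append(f"##sequence-region {name} 1 {len(genome[name])}")
    for f in sorted(features, key=lambda f: (f.contig, f.start)):
        lines.append(
            f"{f.contig}\tecfscan\t{f.feature_type}\t{f.start}\t{f.end}\t.\t"
            f"{f.strand}\t.\tID={f.feature_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Window extraction and background


def extract_feature_windows(
    genome: dict[str, str],
    features: list[GenomeFeature],
    up: int = 500,
    down: int = 100,
) -> list[SequenceWindow]:
    """Windows from ``up`` nt upstream to ``down`` nt downstream of each
    feature's strand-aware start, in transcription orientation.

    Windows are clipped (and flagged) at contig edges; a feature outside
    its contig is an error.
    """
    windows = []
    for f in features:
        if f.contig not in genome:
            raise ValueError(f"{f.feature_id}: unknown contig {f.contig!r}")
        clen = len(genome[f.contig])
        if f.end > clen:
            raise ValueError(f"{f.feature_id}: feature extends beyond contig ({clen})")
        if f.strand == "+":
            gstart, gend = f.start - up, f.start + down
        else:
            gstart, gend = f.end - down, f.end + up
        windows.append(
            window_from_genome(
                genome, f.contig, f.strand, gstart, gend,
                window_id=f"feat:{f.feature_id}", source="feature_window",
            )
        )
    return windows


@dataclass
class BackgroundScan:
    """Genome-wide distribution of per-tile best promoter scores."""

    scores: np.ndarray
    tile_len: int
    step: int

    def summary(self, bins: int = 30) -> dict:
        s = self.scores[np.isfinite(self.scores)]
        if s.size == 0:
            return {"n_tiles": 0}
        qs = [1, 5, 25, 50, 75, 95, 99]
        hist, edges = np.histogram(s, bins=bins)
        return {
            "n_tiles": int(s.size),
            "mean": float(s.mean()),
            "sd": float(s.std()),
            "quantiles": {str(q): float(np.percentile(s, q)) for q in qs},
            "histogram": {
                "edges": [float(e) for e in edges],
                "counts": [int(c) for c in hist],
            },
        }


def genome_background_scan(
    genome: dict[str, str],
    pair: PssmPair,
    tile_len: int = 601,
    step: int = 300,
    seed: int = 0,
) -> BackgroundScan:
    """Best unanchored placement total per tile, both strands.

    Deterministic given the genome and pair (no E-values are computed at
    this stage; ``seed`` is accepted for interface symmetry).
    """
    if tile_len < pair.min_placement_len:
        raise ValueError("tile_len shorter than the minimal placement length")
    from Bio.Seq import reverse_complement

    chunks = []
    for contig in sorted(genome):
        for strand in "+-":
            seq = genome[contig] if strand == "+" else reverse_complement(genome[contig])
            if len(seq) < tile_len:
                continue
            enc = encode(seq)
            rows = np.lib.stride_tricks.sliding_window_view(enc, tile_len)[::step]
            chunks.append(best_totals(np.ascontiguousarray(rows), pair))
    scores = np.concatenate(chunks) if chunks else np.zeros(0)
    return BackgroundScan(scores=scores, tile_len=tile_len, step=step)


# ---------------------------------------------------------------------------
# Stability-interval intersection (externally produced, e.g. PromPredict)


def read_bed_intervals(path: str | Path) -> dict[str, np.ndarray]:
    """Read BED intervals as 1-based inclusive (contig -> (n, 2) array)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["contig", "start", "end"])
    out = {}
    for contig, grp in df.groupby("contig", sort=True):
        iv = np.stack([grp["start"].to_numpy() + 1, grp["end"].to_numpy()], axis=1)
        out[str(contig)] = iv[np.argsort(iv[:, 0])]
    return out


def _span_overlaps(intervals: dict[str, np.ndarray], contig: str,
                   span: tuple[int, int]) -> bool:
    iv = intervals.get(contig)
    if iv is None or iv.size == 0:
        return False
    return bool(((iv[:, 0] <= span[1]) & (iv[:, 1] >= span[0])).any())


# ---------------------------------------------------------------------------
# Configuration and report


@dataclass
class PipelineConfig:
    """All inputs and knobs of one pipeline run.

    Sequence/table fields accept in-memory objects or file paths;
    ``pair`` must be a :class:`PssmPair` (use :meth:`from_yaml` to build
    one from matrix files).
    """

    genome: dict[str, str] | str
    features: list[GenomeFeature] | str
    pair: PssmPair
    treatment_tracks: list[StartCountTrack] | None = None
    control_tracks: list[StartCountTrack] | None = None
    de_units: list[RegulatedUnit] | str | None = None
    min_rrs: float = 3.0
    max_gap: int = 3
    specific_tolerance: int = 3
    window_len: int = 40
    upstream: int = 500
    downstream: int = 100
    evalue_max: float = 0.05
    n_null: int = 1000
    relax: float = 0.05
    fixed_max_evalue: float | None = None
    calibrate: bool = True
    background: bool = True
    tile_len: int = 601
    step: int = 300
    stability_bed: str | None = None
    estimator: str = "kn"
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        pair = load_pssm_pair(
            raw["pssm35"], raw["pssm10"], raw.get("ecf_group", "ECF"),
            pseudocount=raw.get("pseudocount", 0.01),
        )
        tracks: dict[str, list[StartCountTrack] | None] = {
            "treatment": None, "control": None,
        }
        for sample in tracks:
            spec = raw.get("counts", {}).get(sample)
            if spec is None:
                continue
            if "tsv" in spec:
                tracks[sample] = read_counts_tsv(spec["tsv"], sample,
                                                 rt=spec.get("rt"))
            else:
                fwd = read_bedgraph(spec["fwd"], "+", sample)
                rev = read_bedgraph(spec["rev"], "-", sample)
                rt = spec.get("rt") or sum(t.total for t in fwd + rev)
                for t in fwd + rev:
                    t.rt = rt
                tracks[sample] = fwd + rev
        keys = (
            "min_rrs", "max_gap", "specific_tolerance", "window_len", "upstream",
            "downstream", "evalue_max", "n_null", "relax", "fixed_max_evalue",
            "calibrate", "background", "tile_len", "step", "stability_bed",
            "estimator", "seed", "out_dir",
        )
        kwargs = {k: raw[k] for k in keys if k in raw}
        return cls(
            genome=raw["genome"],
            features=raw["annotation"],
            pair=pair,
            treatment_tracks=tracks["treatment"],
            control_tracks=tracks["control"],
            de_units=raw.get("de_table"),
            **kwargs,
        )

    def echo(self) -> dict:
        return {
            "ecf_group": self.pair.ecf_group,
            "pssm35": self.pair.pssm35.motif_id,
            "pssm10": self.pair.pssm10.motif_id,
            "spacer_range": [self.pair.spacer_min, self.pair.spacer_max],
            "tss_dist_range": [self.pair.tss_dist_min, self.pair.tss_dist_max],
            "min_rrs": self.min_rrs,
            "max_gap": self.max_gap,
            "specific_tolerance": self.specific_tolerance,
            "window_len": self.window_len,
            "upstream": self.upstream,
            "downstream": self.downstream,
            "evalue_max": self.evalue_max,
            "n_null": self.n_null,
            "relax": self.relax,
            "fixed_max_evalue": self.fixed_max_evalue,
            "calibrate": self.calibrate,
            "estimator": self.estimator,
            "seed": self.seed,
        }


@dataclass
class PredictionReport:
    """End result of a pipeline run."""

    retained: list[PromoterHit]
    anchored_hits: list[PromoterHit]
    specific_tss: list
    n_features: int
    features_with_hit: list[str]
    unique_promoters: list[dict]
    cutoffs: CutoffSet | None
    background: dict | None
    tss_stats: dict
    config_echo: dict

    @property
    def n_features_with_hit(self) -> int:
        return len(self.features_with_hit)

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_features_with_hit": self.n_features_with_hit,
            "features_with_hit": self.features_with_hit,
            "n_retained_hits": len(self.retained),
            "n_unique_promoters": len(self.unique_promoters),
            "unique_promoters": self.unique_promoters,
            "tss_stats": self.tss_stats,
            "n_anchored_hits": len(self.anchored_hits),
            "cutoffs": self.cutoffs.to_dict() if self.cutoffs else None,
            "background": self.background,
            "config": self.config_echo,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_dict(), sort_keys=True, indent=2) + "\n"
        )
        hits_to_frame(self.retained).to_csv(
            out / "retained_hits.tsv", sep="\t", index=False, float_format="%.10g"
        )
        hits_to_frame(self.anchored_hits).to_csv(
            out / "anchored_hits.tsv", sep="\t", index=False, float_format="%.10g"
        )
        write_hits_gff3(self.retained, out / "retained_hits.gff3")
        write_tss_tsv(self.specific_tss, out / "tss_specific.tsv")
        if self.cutoffs is not None:
            (out / "cutoffs.json").write_text(
                json.dumps(self.cutoffs.to_dict(), sort_keys=True, indent=2) + "\n"
            )
        if self.background is not None and "histogram" in self.background:
            h = self.background["histogram"]
            pd.DataFrame(
                {"bin_left": h["edges"][:-1], "bin_right": h["edges"][1:],
                 "count": h["counts"]}
            ).to_csv(out / "background_hist.tsv", sep="\t", index=False,
                     float_format="%.10g")


_HIT_COLUMNS = [
    "window_id", "feature_id", "contig", "strand", "g35_start", "g35_end",
    "g10_start", "g10_end", "pos35", "pos10", "spacer", "tss_distance",
    "s35", "s10", "total", "evalue",
]


def hits_to_frame(hits: list[PromoterHit]) -> pd.DataFrame:
    rows = [
        {c: getattr(h, c) for c in _HIT_COLUMNS}
        for h in hits
    ]
    df = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    return df.sort_values(
        ["contig", "strand", "g35_start", "window_id", "pos35", "spacer"],
        kind="stable",
    ).reset_index(drop=True)


def write_hits_gff3(hits: list[PromoterHit], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    df = hits_to_frame(hits)
    for i, r in enumerate(df.itertuples(index=False), 1):
        span = (min(r.g35_start, r.g10_start), max(r.g35_end, r.g10_end))
        attrs = (
            f"ID=promoter_{i};window={r.window_id};s35={r.s35:.4f};"
            f"s10={r.s10:.4f};evalue={r.evalue:.6g};spacer={r.spacer}"
        )
        if r.feature_id is not None and not pd.isna(r.feature_id):
            attrs += f";feature={r.feature_id}"
        lines.append(
            f"{r.contig}\tecfscan\tpromoter\t{span[0]}\t{span[1]}\t"
            f"{r.total:.4f}\t{r.strand}\t.\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# The pipeline


def _load(cfg: PipelineConfig):
    genome = read_fasta(cfg.genome) if isinstance(cfg.genome, (str, Path)) else cfg.genome
    features = (
        read_gff3(cfg.features) if isinstance(cfg.features, (str, Path))
        else cfg.features
    )
    de_units = (
        read_de_table(cfg.de_units) if isinstance(cfg.de_units, (str, Path))
        else cfg.de_units
    )
    return genome, features, de_units


def run_offtarget_pipeline(cfg: PipelineConfig) -> PredictionReport:
    """Execute the full off-target prediction flow; see the module docs.

    Fully deterministic for a fixed config and seed: every stochastic step
    (the shuffle nulls) draws from a per-window RNG derived from
    ``cfg.seed`` and the window id.
    """
    genome, features, de_units = _load(cfg)
    pair = cfg.pair

    # --- stage 1: TSS calling and strain-specific extraction
    specific: list = []
    tss_stats: dict = {"n_treatment": None, "n_control": None, "n_specific": None}
    def _call(tracks):
        # a sample with zero emitted reads simply has no TSS to call
        if not tracks or sum(t.total for t in tracks) == 0:
            return []
        return call_tss(tracks, cfg.min_rrs, cfg.max_gap)

    if cfg.treatment_tracks:
        treat = _call(cfg.treatment_tracks)
        ctrl = _call(cfg.control_tracks)
        specific = strain_specific_tss(treat, ctrl, cfg.specific_tolerance)
        tss_stats = {
            "n_treatment": len(treat),
            "n_control": len(ctrl),
            "n_specific": len(specific),
        }
        logger.info(
            "TSS: %d treatment, %d control, %d strain-specific",
            len(treat), len(ctrl), len(specific),
        )

    # --- stage 2: anchored scan upstream of strain-specific TSS
    anchored = (
        tss_anchored_scan(
            specific, genome, pair, cfg.window_len, cfg.evalue_max,
            cfg.n_null, cfg.seed, cfg.estimator,
        )
        if specific else []
    )

    # --- stage 3: feature windows and shared per-window nulls
    windows = extract_feature_windows(genome, features, cfg.upstream, cfg.downstream)
    null_cache: dict[str, np.ndarray] = {}

    def window_null(w: SequenceWindow) -> np.ndarray:
        if w.window_id not in null_cache:
            null_cache[w.window_id] = null_best_totals(
                w, pair, cfg.n_null, window_rng(cfg.seed, w.window_id)
            )
        return null_cache[w.window_id]

    # --- stage 4: cutoff calibration from DE-supported units
    cutoffs: CutoffSet | None = None
    if cfg.calibrate and de_units:
        feat_window = {f.feature_id: w for f, w in zip(features, windows)}
        hits_by_unit: dict[str, list[PromoterHit]] = {}
        for unit in de_units:
            if not unit.is_regulated():
                continue
            w = next(
                (feat_window[m] for m in unit.members if m in feat_window), None
            )
            if w is None:
                hits_by_unit[unit.unit_id] = []
                continue
            front = pareto_front(all_hits(w, pair))
            null = window_null(w)
            for h in front:
                h.evalue = evalue_from_null(null, h.total, cfg.estimator)
            hits_by_unit[unit.unit_id] = front
        cutoffs = calibrate_cutoffs(
            de_units, hits_by_unit, cfg.relax, cfg.fixed_max_evalue
        )
        logger.info("calibrated cutoffs: %s", cutoffs.to_dict())

    # --- stage 5: genome-wide scan and conjunctive filtering
    retained: list[PromoterHit] = []
    for f, w in zip(features, windows):
        pl = placement_scores(encode(w.seq), pair, w.anchor_tss_offset)
        if pl.p35.size == 0:
            continue
        total = pl.total[0]
        if cutoffs is not None:
            mask = (
                (pl.s35[0] >= cutoffs.min_s35 - _TOL)
                & (pl.s10[0] >= cutoffs.min_s10 - _TOL)
                & (total >= cutoffs.min_total - _TOL)
            )
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            cands = materialize_hits(w, pair, pl, idx)
            null = window_null(w)
            for h in cands:
                h.evalue = evalue_from_null(null, h.total, cfg.estimator)
                h.feature_id = f.feature_id
            kept = apply_cutoffs(cands, cutoffs)
        else:
            best = materialize_hits(w, pair, pl)[0]
            best.feature_id = f.feature_id
            best.evalue = evalue_from_null(
                window_null(w), best.total, cfg.estimator
            )
            kept = [best] if best.evalue <= cfg.evalue_max else []
        retained.extend(kept)

    # --- stage 6: optional intersection with low-stability intervals
    if cfg.stability_bed:
        intervals = read_bed_intervals(cfg.stability_bed)
        retained = [
            h for h in retained
            if _span_overlaps(intervals, h.contig, h.genomic_span)
        ]

    # --- stage 7: report
    features_with_hit = sorted({h.feature_id for h in retained})
    unique: dict[tuple, dict] = {}
    for h in retained:
        key = (h.contig, h.strand, h.g35_start, h.g10_start)
        entry = unique.setdefault(
            key,
            {"contig": h.contig, "strand": h.strand, "g35_start": h.g35_start,
             "g10_start": h.g10_start, "total": h.total, "features": []},
        )
        entry["features"].append(h.feature_id)
    unique_promoters = [
        {**v, "features": sorted(v["features"])}
        for _, v in sorted(unique.items(), key=lambda kv: kv[0])
    ]
    background = (
        genome_background_scan(genome, pair, cfg.tile_len, cfg.step,
                               cfg.seed).summary()
        if cfg.background else None
    )
    report = PredictionReport(
        retained=retained,
        anchored_hits=anchored,
        specific_tss=specific,
        n_features=len(features),
        features_with_hit=features_with_hit,
        unique_promoters=unique_promoters,
        cutoffs=cutoffs,
        background=background,
        tss_stats=tss_stats,
        config_echo=cfg.echo(),
    )
    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report
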