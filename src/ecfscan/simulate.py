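"""Synthetic genomes, count tracks and DE tables with known ground truth.

The generator emulates the study design the pipeline targets: a bacterial
genome with annotated features, a subset of "regulated" features carrying
a planted bipartite promoter (drawn from a PSSM pair at consensus or
sampled strength, spacer 15-17 nt, TSS 3-6 nt downstream of the -10 box),
5'-end read-start pileups concentrated on the planted TSS in the
*treatment* (overexpression) sample only, sparse background read starts
in both samples, and a DE table flagging exactly the planted units.

Noise model: background read starts occur independently per strand-base
with Poisson rate ``noise_rate * depth / 1e6``.  The default rate of
1e-4 per base at 10^6 reads reproduces the sparse background density seen
in real Cappable-seq control samples (on the order of one spurious TSS
per 10 kb of strand); the background is deliberately sparse — dense
per-base noise would fuse the <=3-nt-gap TSS clusters into contiguous
runs, which enriched 5'-end data do not show.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .calibrate import RegulatedUnit, write_de_table
from .pipeline import GenomeFeature, write_fasta, write_gff3
from .pssm import Pssm, PssmPair, consensus, decode, encode
from .tss import StartCountTrack, write_bedgraph

__all__ = [
    "PlantedPromoter",
    "SyntheticTruth",
    "SyntheticDataset",
    "sample_site",
    "generate_genome",
    "simulate_tss_counts",
    "simulate_de_table",
    "simulate_dataset",
    "write_dataset",
]

CONSENSUS = "consensus"
SAMPLED = "sampled"


@dataclass(frozen=True)
class PlantedPromoter:
    """Ground truth for one planted promoter site.

    Spans are 1-based inclusive forward-strand coordinates; ``site_seq``
    is the -35 + spacer + -10 sequence in transcription orientation.
    """

    contig: str
    strand: str
    tss_position: int
    spacer: int
    tss_distance: int
    m35_span: tuple[int, int]
    m10_span: tuple[int, int]
    site_seq: str
    strength: str
    feature_id: str
    unit_id: str


@dataclass
class SyntheticTruth:
    """Everything planted into a synthetic dataset."""

    planted_promoters: list[PlantedPromoter]
    planted_regulated_units: dict[str, float | None]
    planted_tss: list[tuple[str, str, int, float]]  # contig, strand, pos, mass
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted_promoters": [asdict(p) for p in self.planted_promoters],
            "planted_regulated_units": self.planted_regulated_units,
            "planted_tss": [list(t) for t in self.planted_tss],
            "seed": self.seed,
        }


class SampledSite(NamedTuple):
    seq: str  # -35 box + spacer + -10 box, transcription orientation
    spacer: int
    l35: int
    l10: int


def _sample_box(pssm: Pssm, rng: np.random.Generator) -> str:
    probs = pssm.probabilities()
    draws = [int(rng.choice(4, p=probs[:, j])) for j in range(pssm.length)]
    return decode(np.asarray(draws))


def sample_site(
    pair: PssmPair,
    strength: str = CONSENSUS,
    rng: np.random.Generator | None = None,
    gc: float = 0.5,
) -> SampledSite:
    """Draw one promoter site: -35 box + random spacer (15-17 nt) + -10 box.

    ``consensus`` strength uses the per-column maximal-probability bases
    (the maximal-scoring site); ``sampled`` draws each box column-wise
    from the PSSM probabilities.  Spacer bases are drawn i.i.d. at the
    given GC content.
    """
    rng = np.random.default_rng() if rng is None else rng
    if strength == CONSENSUS:
        b35, b10 = consensus(pair.pssm35), consensus(pair.pssm10)
    elif strength == SAMPLED:
        b35, b10 = _sample_box(pair.pssm35, rng), _sample_box(pair.pssm10, rng)
    else:
        raise ValueError(f"strength must be {CONSENSUS!r} or {SAMPLED!r}")
    sp = int(rng.integers(pair.spacer_min, pair.spacer_max + 1))
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    spacer_seq = decode(rng.choice(4, size=sp, p=base_p))
    return SampledSite(b35 + spacer_seq + b10, sp,
                       pair.pssm35.length, pair.pssm10.length)


def _revcomp_enc(enc: np.ndarray) -> np.ndarray:
    return (3 - enc)[::-1]


def generate_genome(
    pair: PssmPair,
    n_features: int = 200,
    contig_len: int = 100_000,
    gc: float = 0.6,
    n_regulated: int = 10,
    strength: str = CONSENSUS,
    seed: int = 0,
    feature_len: int = 300,
    contig: str = "chr",
) -> tuple[dict[str, str], list[GenomeFeature], SyntheticTruth]:
    """Random genome with evenly spaced features and planted promoters.

    Features alternate strands along one contig of i.i.d. sequence at the
    requested GC.  For each of ``n_regulated`` randomly chosen features a
    promoter site is planted upstream so that its TSS falls 20-60 nt
    upstream of the feature start (a typical bacterial 5' UTR) and the
    whole site lies inside the feature's 500-up/100-down window.
    """
    if n_regulated > n_features:
        raise ValueError("n_regulated cannot exceed n_features")
    rng = np.random.default_rng(seed)
    margin = 700
    if n_features > 1:
        step = (contig_len - 2 * margin - feature_len) / (n_features - 1)
    else:
        step = 0.0
    min_sep = feature_len + 150  # room for a UTR + promoter site
    if n_features > 1 and step < min_sep:
        raise ValueError(
            f"infeasible packing: {n_features} features of {feature_len} bp "
            f"need >= {min_sep} bp spacing, contig offers {step:.0f}"
        )
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    enc = rng.choice(4, size=contig_len, p=base_p).astype(np.uint8)

    features: list[GenomeFeature] = []
    for i in range(n_features):
        start = margin + int(round(i * step))
        strand = "+" if i % 2 == 0 else "-"
        features.append(
            GenomeFeature(
                feature_id=f"gene{i:04d}", contig=contig, strand=strand,
                start=start, end=start + feature_len - 1,
            )
        )

    regulated_idx = np.sort(rng.choice(n_features, size=n_regulated, replace=False))
    planted: list[PlantedPromoter] = []
    planted_spans: list[tuple[int, int]] = []
    for i in regulated_idx:
        f = features[int(i)]
        utr = int(rng.integers(20, 61))
        d = int(rng.integers(pair.tss_dist_min, pair.tss_dist_max + 1))
        site = sample_site(pair, strength, rng, gc=gc)
        site_len = len(site.seq)
        if f.strand == "+":
            tss = f.start - utr
            site_start = tss - d - site_len  # forward coord of first site base
            site_end = tss - d - 1
            m35 = (site_start, site_start + site.l35 - 1)
            m10 = (site_end - site.l10 + 1, site_end)
            enc[site_start - 1 : site_end] = encode(site.seq)
        else:
            tss = f.end + utr
            site_start = tss + d + 1
            site_end = tss + d + site_len
            m35 = (site_end - site.l35 + 1, site_end)
            m10 = (site_start, site_start + site.l10 - 1)
            enc[site_start - 1 : site_end] = _revcomp_enc(encode(site.seq))
        if not (1 <= site_start and site_end <= contig_len):
            raise ValueError("infeasible packing: planted site outside contig")
        span = (min(site_start, tss), max(site_end, tss))
        for other in planted_spans:
            if span[0] <= other[1] and other[0] <= span[1]:
                raise ValueError("infeasible packing: planted sites overlap")
        planted_spans.append(span)
        uid = f"u_{f.feature_id}"
        planted.append(
            PlantedPromoter(
                contig=contig, strand=f.strand, tss_position=tss, spacer=site.spacer,
                tss_distance=d, m35_span=m35, m10_span=m10, site_seq=site.seq,
                strength=strength, feature_id=f.feature_id, unit_id=uid,
            )
        )

    k = len(planted)
    truth = SyntheticTruth(
        planted_promoters=planted,
        planted_regulated_units={p.unit_id: None for p in planted},
        planted_tss=[
            (p.contig, p.strand, p.tss_position, 1.0 / k if k else 0.0)
            for p in planted
        ],
        seed=seed,
    )
    return {contig: decode(enc)}, features, truth


def simulate_tss_counts(
    truth: SyntheticTruth,
    genome: dict[str, str],
    depth: int = 1_000_000,
    signal_fraction: float = 0.1,
    noise_rate: float = 1e-4,
    seed: int = 0,
) -> dict[str, list[StartCountTrack]]:
    """Per-base 5'-end count tracks for a treatment and a control sample.

    Treatment: ``depth * signal_fraction`` reads multinomially assigned to
    the planted TSS (with +-1 nt jitter, 10/80/10), plus sparse Poisson
    background at rate ``noise_rate * depth / 1e6`` per strand-base.
    Control: background only.  Rt is set to each sample's emitted total.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    lam = noise_rate * depth / 1e6
    samples: dict[str, list[StartCountTrack]] = {}
    jitter_p = np.array([0.1, 0.8, 0.1])

    # signal allocation (treatment only)
    signal: dict[tuple[str, str], dict[int, int]] = {}
    k = len(truth.planted_tss)
    n_sig = int(round(depth * signal_fraction)) if k else 0
    if n_sig:
        masses = np.array([m for (_, _, _, m) in truth.planted_tss], dtype=float)
        alloc = rng.multinomial(n_sig, masses / masses.sum())
        for (contig, strand, pos, _), reads in zip(truth.planted_tss, alloc):
            jit = rng.multinomial(int(reads), jitter_p)
            d = signal.setdefault((contig, strand), {})
            for off, cnt in zip((-1, 0, 1), jit):
                if cnt:
                    d[pos + off] = d.get(pos + off, 0) + int(cnt)

    for sample in ("treatment", "control"):
        tracks = []
        for contig in sorted(genome):
            clen = len(genome[contig])
            for strand in "+-":
                counts: dict[int, int] = {}
                if lam > 0:
                    noise = rng.poisson(lam, clen)
                    for pos in np.flatnonzero(noise):
                        counts[int(pos) + 1] = int(noise[pos])
                if sample == "treatment":
                    for pos, cnt in signal.get((contig, strand), {}).items():
                        counts[pos] = counts.get(pos, 0) + cnt
                tracks.append(
                    StartCountTrack.from_dict(
                        sample, contig, strand, counts, rt=sum(counts.values())
                    )
                )
        rt = sum(t.total for t in tracks)
        for t in tracks:
            t.rt = rt
        samples[sample] = tracks
    return samples


def simulate_de_table(
    truth: SyntheticTruth,
    features: list[GenomeFeature],
    effect_log2fc: float = 4.0,
    null_padj: float = 0.2,
    seed: int = 0,
) -> list[RegulatedUnit]:
    """One monocistronic unit per feature; planted units get the effect.

    Planted units receive ``log2fc = effect_log2fc`` and ``padj = 1e-6``;
    all others receive small log2fc noise and ``padj`` drawn uniformly
    from [null_padj, 1], so the standard DE filter (log2fc > 2,
    padj < 0.05) recovers exactly the planted set whenever the effect
    exceeds 2.
    """
    rng = np.random.default_rng(seed)
    planted_units = {p.unit_id for p in truth.planted_promoters}
    units = []
    for f in features:
        uid = f"u_{f.feature_id}"
        if uid in planted_units:
            units.append(RegulatedUnit(uid, (f.feature_id,), float(effect_log2fc), 1e-6))
            truth.planted_regulated_units[uid] = float(effect_log2fc)
        else:
            units.append(
                RegulatedUnit(
                    uid, (f.feature_id,),
                    float(rng.normal(0.0, 0.3)),
                    float(rng.uniform(null_padj, 1.0)),
                )
            )
    return units


@dataclass
class SyntheticDataset:
    """A complete simulated input set for the pipeline."""

    genome: dict[str, str]
    features: list[GenomeFeature]
    truth: SyntheticTruth
    tracks: dict[str, list[StartCountTrack]]
    de_units: list[RegulatedUnit]


def simulate_dataset(
    pair: PssmPair,
    n_features: int = 200,
    contig_len: int = 100_000,
    gc: float = 0.6,
    n_regulated: int = 10,
    strength: str = CONSENSUS,
    depth: int = 1_000_000,
    signal_fraction: float = 0.1,
    noise_rate: float = 1e-4,
    effect_log2fc: float = 4.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate genome, annotation, count tracks, DE table and truth."""
    child = np.random.SeedSequence(seed).generate_state(3)
    genome, features, truth = generate_genome(
        pair, n_features, contig_len, gc, n_regulated, strength, seed=int(child[0])
    )
    truth.seed = seed
    tracks = simulate_tss_counts(
        truth, genome, depth, signal_fraction, noise_rate, seed=int(child[1])
    )
    de_units = simulate_de_table(
        truth, features, effect_log2fc, seed=int(child[2])
    )
    return SyntheticDataset(genome, features, truth, tracks, de_units)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write FASTA, GFF3, per-strand bedGraphs, DE TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.genome, out / "genome.fasta")
    write_gff3(ds.features, ds.genome, out / "features.gff3")
    for sample, tracks in ds.tracks.items():
        for strand, tag in (("+", "fwd"), ("-", "rev")):
            write_bedgraph(
                [t for t in tracks if t.strand == strand],
                out / f"{sample}.{tag}.bedgraph",
            )
        rt = sum(t.total for t in tracks)
        (out / f"{sample}.rt.txt").write_text(f"{rt}\n")
    write_de_table(ds.de_units, out / "de_table.tsv")
    (out / "truth.json").write_text(
        json.dumps(ds.truth.to_dict(), sort_keys=True, indent=2) + "\n"
    )
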