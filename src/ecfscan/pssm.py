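"""Position-specific scoring matrices for bipartite ECF promoters.

Extracytoplasmic function (ECF) sigma factors recognise promoters through
two short boxes: a -35 element bound by the sigma4 domain and a -10 element
bound by sigma2, separated by a 15-17 nt spacer, with the transcription
start site (TSS) a few bases downstream of the -10 box.  Each box is
modelled as a 4 x L matrix of base-2 log-probabilities (rows in fixed
A, C, G, T order).  A match score is the sum of the log-probabilities of
the observed bases, so scores are always <= 0 and scores closer to 0 mean
greater similarity to the motif.

Matrix files are tab-delimited, 4 rows (A, C, G, T) by L columns, with an
optional leading row label and an optional ``#type=counts|freqs|logprobs``
header; when the header is absent the value range is used to guess the
encoding.  MEME minimal format is accepted as an alternate input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ALPHABET",
    "MINUS35",
    "MINUS10",
    "Pssm",
    "PssmPair",
    "encode",
    "decode",
    "load_pssm",
    "load_pssm_pair",
    "pssm_from_frequencies",
    "read_meme",
    "bundled_pair",
    "score_subsequence",
    "consensus",
]

ALPHABET = "ACGT"
MINUS35 = "minus35"
MINUS10 = "minus10"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3).

    Ambiguity codes and any non-ACGT character raise ``ValueError``.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _ENCODE[raw]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


@dataclass(eq=False)
class Pssm:
    """One promoter box as a 4 x L base-2 log-probability matrix.

    Parameters
    ----------
    motif_id
        Free-text identifier, e.g. ``"ECF02_m35"``.
    box
        Either ``"minus35"`` or ``"minus10"``.
    logprob
        Array of shape ``(4, length)``; rows in A, C, G, T order; every
        entry is ``log2`` of a probability, so <= 0, and each column's
        probabilities sum to 1.
    pseudocount
        The pseudocount fraction that was added per base when the matrix
        was converted from counts/frequencies (0 if loaded as-is).
    """

    motif_id: str
    box: str
    logprob: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.box not in (MINUS35, MINUS10):
            raise ValueError(f"box must be {MINUS35!r} or {MINUS10!r}, got {self.box!r}")
        m = np.asarray(self.logprob, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"logprob must be 4 x L with L >= 1, got shape {m.shape}")
        if (m > 1e-12).any():
            raise ValueError("log-probabilities must be <= 0")
        colsums = np.power(2.0, m).sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"column {bad} probabilities sum to {colsums[bad]:.12f}, expected 1"
            )
        self.logprob = m

    @property
    def length(self) -> int:
        return self.logprob.shape[1]

    def score(self, seq: str | np.ndarray) -> float:
        return score_subsequence(self, seq)

    def consensus(self) -> str:
        return consensus(self)

    def probabilities(self) -> np.ndarray:
        """Column-normalised base probabilities, shape (4, L)."""
        return np.power(2.0, self.logprob)


@dataclass(eq=False)
class PssmPair:
    """A -35/-10 matrix pair plus its placement geometry.

    ``spacer_*`` bound the number of bases between the end of the -35 box
    and the start of the -10 box; ``tss_dist_*`` bound the number of bases
    strictly between the last base of the -10 box and the TSS base.
    """

    ecf_group: str
    pssm35: Pssm
    pssm10: Pssm
    spacer_min: int = 15
    spacer_max: int = 17
    tss_dist_min: int = 3
    tss_dist_max: int = 6

    def __post_init__(self) -> None:
        if self.pssm35.box != MINUS35:
            raise ValueError("pssm35 must have box='minus35'")
        if self.pssm10.box != MINUS10:
            raise ValueError("pssm10 must have box='minus10'")
        for lo, hi, name in (
            (self.spacer_min, self.spacer_max, "spacer"),
            (self.tss_dist_min, self.tss_dist_max, "tss_dist"),
        ):
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name} range [{lo}, {hi}]")

    @property
    def min_placement_len(self) -> int:
        """Shortest window that admits an (unanchored) placement."""
        return self.pssm35.length + self.spacer_min + self.pssm10.length

    def consensus_total(self) -> float:
        """The maximal attainable total score (both boxes at consensus)."""
        return self.pssm35.score(consensus(self.pssm35)) + self.pssm10.score(
            consensus(self.pssm10)
        )


def score_subsequence(pssm: Pssm, seq: str | np.ndarray) -> float:
    """Sum of per-column log-probabilities of the observed bases (bits).

    ``seq`` must have exactly ``pssm.length`` bases over {A, C, G, T}.
    """
    enc = encode(seq) if isinstance(seq, str) else np.asarray(seq)
    if enc.shape[0] != pssm.length:
        raise ValueError(
            f"sequence length {enc.shape[0]} != matrix length {pssm.length}"
        )
    return float(pssm.logprob[enc, np.arange(pssm.length)].sum())


def consensus(pssm: Pssm) -> str:
    """Per-column maximal-probability base; ties break by A < C < G < T."""
    # np.argmax returns the first maximum, which is the alphabet tie-break.
    return decode(np.argmax(pssm.logprob, axis=0))


def pssm_from_frequencies(
    motif_id: str, box: str, freqs: np.ndarray, pseudocount: float = 0.01
) -> Pssm:
    """Convert a 4 x L frequency matrix to log-probabilities.

    Each column is renormalised, then a pseudocount ``eps`` is mixed in as
    ``(f + eps) / (1 + 4 eps)``.  A zero frequency with ``eps = 0`` is a
    hard error (its log would be -inf), which forces a pseudocount for
    sparse columns.
    """
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 2 or f.shape[0] != 4:
        raise ValueError(f"frequency matrix must be 4 x L, got shape {f.shape}")
    if (f < 0).any():
        r, c = np.unravel_index(int(np.argmin(f)), f.shape)
        raise ValueError(f"negative value at row {ALPHABET[r]}, column {c}")
    colsums = f.sum(axis=0)
    if (colsums <= 0).any():
        bad = int(np.argmax(colsums <= 0))
        raise ValueError(f"column {bad} sums to zero")
    f = f / colsums
    eps = float(pseudocount)
    if eps < 0:
        raise ValueError("pseudocount must be >= 0")
    p = (f + eps) / (1.0 + 4.0 * eps)
    if (p <= 0).any():
        r, c = np.unravel_index(int(np.argmin(p)), p.shape)
        raise ValueError(
            f"zero probability for base {ALPHABET[r]} in column {c} "
            "with pseudocount 0; use a positive pseudocount"
        )
    return Pssm(motif_id=motif_id, box=box, logprob=np.log2(p), pseudocount=eps)


def _guess_kind(m: np.ndarray) -> str:
    if (m < 0).any():
        return "logprobs"
    if (m > 1.0 + 1e-9).any():
        return "counts"
    colsums = m.sum(axis=0)
    if np.allclose(colsums, 1.0, atol=0.05):
        return "freqs"
    # Small non-negative values that do not sum to ~1 per column: treat as
    # counts (e.g. a matrix of 0/1 site tallies).
    return "counts"


def load_pssm(
    path: str | Path, box: str, pseudocount: float = 0.01, motif_id: str | None = None
) -> Pssm:
    """Load a tab-delimited 4 x L matrix file as a :class:`Pssm`.

    The file may declare its encoding with a ``#type=counts|freqs|logprobs``
    header; otherwise the encoding is guessed from the value range.  Rows
    may carry a leading A/C/G/T label.  Columns are renormalised after
    pseudocount addition.
    """
    path = Path(path)
    kind = None
    rows: list[list[float]] = []
    labels: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*type\s*=\s*(counts|freqs|logprobs)", line)
            if m:
                kind = m.group(1)
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if fields and fields[0].rstrip(":").upper() in tuple(ALPHABET):
            labels.append(fields[0].rstrip(":").upper())
            fields = fields[1:]
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed matrix line {line!r}") from exc
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 rows (A, C, G, T), found {len(rows)}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: rows have unequal lengths")
    m = np.asarray(rows, dtype=float)
    if labels:
        if sorted(labels) != list(ALPHABET):
            raise ValueError(f"{path}: row labels must be A, C, G, T, got {labels}")
        order = [labels.index(b) for b in ALPHABET]
        m = m[order]
    if kind is None:
        kind = _guess_kind(m)
    if kind == "logprobs":
        if (m > 1e-12).any():
            raise ValueError(f"{path}: declared logprobs but contains positive values")
        m = np.power(2.0, m)
    elif kind == "counts" and (m < 0).any():
        r, c = np.unravel_index(int(np.argmin(m)), m.shape)
        raise ValueError(f"{path}: negative count at row {ALPHABET[r]}, column {c}")
    name = motif_id or path.stem
    return pssm_from_frequencies(name, box, m, pseudocount=pseudocount)


def load_pssm_pair(
    path35: str | Path,
    path10: str | Path,
    ecf_group: str,
    pseudocount: float = 0.01,
    **geometry: int,
) -> PssmPair:
    """Load a -35 and a -10 matrix file into a :class:`PssmPair`."""
    return PssmPair(
        ecf_group=ecf_group,
        pssm35=load_pssm(path35, MINUS35, pseudocount, motif_id=f"{ecf_group}_m35"),
        pssm10=load_pssm(path10, MINUS10, pseudocount, motif_id=f"{ecf_group}_m10"),
        **geometry,
    )


def read_meme(path: str | Path, pseudocount: float = 0.01) -> dict[str, np.ndarray]:
    """Read motifs from a MEME minimal-format file.

    Returns a mapping motif name -> 4 x L frequency matrix (rows A, C, G,
    T).  Combine with :func:`pssm_from_frequencies` to build a
    :class:`Pssm`; the caller decides which motif is which box.
    """
    text = Path(path).read_text().splitlines()
    motifs: dict[str, np.ndarray] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(text) and not text[j].strip().startswith(
                "letter-probability matrix"
            ):
                j += 1
            if j == len(text):
                raise ValueError(f"{path}: MOTIF {name} has no probability matrix")
            m = re.search(r"w=\s*(\d+)", text[j])
            if not m:
                raise ValueError(f"{path}: MOTIF {name}: missing w= in matrix header")
            w = int(m.group(1))
            block = []
            for k in range(j + 1, j + 1 + w):
                block.append([float(x) for x in text[k].split()])
            # MEME stores rows = positions, columns = A C G T.
            motifs[name] = np.asarray(block, dtype=float).T
            i = j + w
        i += 1
    return motifs


_BUNDLED = {
    "ecf02": ("synthetic_ecf02_minus35.tsv", "synthetic_ecf02_minus10.tsv"),
    "ecf11": ("synthetic_ecf11_minus35.tsv", "synthetic_ecf11_minus10.tsv"),
}


def bundled_pair(name: str = "ecf02", pseudocount: float = 0.01) -> PssmPair:
    """Load one of the bundled synthetic example matrix pairs.

    These matrices are synthetic stand-ins shaped like group-specific ECF
    promoter preferences (a strongly preferred consensus base per column
    over an uneven minor-base background); they are intended for testing
    and simulation.  Real group-specific PSSM files can be dropped in via
    :func:`load_pssm_pair`.
    """
    try:
        f35, f10 = _BUNDLED[name.lower()]
    except KeyError:
        raise KeyError(f"no bundled pair {name!r}; available: {sorted(_BUNDLED)}")
    base = resources.files("ecfscan") / "data"
    with resources.as_file(base / f35) as p35, resources.as_file(base / f10) as p10:
        return load_pssm_pair(p35, p10, ecf_group=name.upper(), pseudocount=pseudocount)
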