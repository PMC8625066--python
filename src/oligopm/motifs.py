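"""Promoter extraction and position-weight-matrix scanning.

The regulatory question: do the 500 bp regions upstream of transporter
start codons carry binding sites for nitrogen-regulation transcription
factors (e.g. the NCR activator Gln3 or the repressor Cup9)?  Windows are
scanned on both strands with additive per-position PWM scores; a window's
score is rescaled between the motif's minimum and maximum attainable
scores (min–max relative score in [0, 1]) and positions scoring strictly
above the cutoff (default 0.95) are reported as hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, ValidationError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_UPSTREAM_BP = 500
DEFAULT_CUTOFF = 0.95


@dataclass
class PWM:
    """Additive position-weight matrix over A/C/G/T.

    ``scores`` has shape (width, 4) in A C G T column order.  Matrices
    distributed as frequencies can be converted with
    :meth:`from_frequencies` (log-odds against a uniform background with a
    small pseudocount).
    """

    motif_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise ValidationError("PWM scores must have shape (width, 4)")
        if self.scores.shape[0] < 1:
            raise ValidationError("PWM width must be >= 1")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("PWM scores must be finite")

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.scores.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        # reverse positions; complementing A<->T, C<->G flips column order
        return PWM(self.motif_id, self.scores[::-1, ::-1].copy())

    @classmethod
    def from_frequencies(
        cls,
        motif_id: str,
        freqs: np.ndarray,
        pseudocount: float = 0.01,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> "PWM":
        """Convert a per-position base-frequency matrix to log2-odds scores."""
        f = np.asarray(freqs, dtype=float)
        if np.any(f < 0):
            raise ValidationError("frequencies must be non-negative")
        f = f + pseudocount
        f = f / f.sum(axis=1, keepdims=True)
        bg = np.asarray(background, dtype=float)
        return cls(motif_id, np.log2(f / bg))

    @classmethod
    def from_consensus(
        cls, motif_id: str, consensus: str, match: float = 2.0, mismatch: float = 0.0
    ) -> "PWM":
        """Degenerate PWM scoring *match* at the consensus base, else *mismatch*."""
        scores = np.full((len(consensus), 4), mismatch, dtype=float)
        for i, base in enumerate(consensus.upper()):
            if base not in _BASE_INDEX:
                raise ValidationError(f"consensus contains non-ACGT base {base!r}")
            scores[i, _BASE_INDEX[base]] = match
        return cls(motif_id, scores)


@dataclass
class PromoterWindow:
    """Up-to-500 bp of sequence immediately upstream of a start codon.

    Base 1 is the most-upstream base; the window reads toward the start
    codon on the gene's coding strand.
    """

    gene_id: str
    sequence: str
    truncated: bool = False
    strand_of_gene: str = "+"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(ALPHABET + "N")
        if bad:
            raise ValidationError(f"promoter {self.gene_id!r}: bad bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    """One above-cutoff PWM match inside a promoter window (1-based start)."""

    motif_id: str
    start: int
    strand: str
    score: float
    relative_score: float
    gene_id: str = ""


def extract_promoter(
    contigs: Mapping[str, str],
    gene_id: str,
    contig: str,
    start: int,
    end: int,
    strand: str,
    upstream_bp: int = DEFAULT_UPSTREAM_BP,
) -> PromoterWindow:
    """Cut the *upstream_bp* bases upstream of a gene's start codon.

    Coordinates are 1-based inclusive on the forward strand of *contig*.
    For a ``+`` gene the window ends immediately before *start*; for a
    ``-`` gene it is the reverse complement of the block immediately after
    *end*.  Windows are truncated (and flagged) at contig edges.
    """
    if contig not in contigs:
        raise CoordinateError(f"contig {contig!r} not in genome")
    seq = str(contigs[contig]).upper()
    n = len(seq)
    if not (1 <= start <= end <= n):
        raise CoordinateError(
            f"gene {gene_id!r}: coordinates {start}-{end} outside contig "
            f"{contig!r} (length {n})"
        )
    if strand == "+":
        lo = max(0, start - 1 - upstream_bp)
        window = seq[lo : start - 1]
        truncated = (start - 1) < upstream_bp
    elif strand == "-":
        hi = min(n, end + upstream_bp)
        window = str(Seq(seq[end:hi]).reverse_complement())
        truncated = (n - end) < upstream_bp
    else:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    return PromoterWindow(
        gene_id=gene_id, sequence=window, truncated=truncated, strand_of_gene=strand
    )


def score_window(pwm: PWM, window_seq: str) -> tuple[float, float]:
    """Additive score and min–max relative score of one width-length window."""
    s = window_seq.upper()
    if len(s) != pwm.width:
        raise ValidationError(
            f"window length {len(s)} does not match motif width {pwm.width}"
        )
    try:
        idx = [_BASE_INDEX[b] for b in s]
    except KeyError as exc:
        raise ValidationError(f"window contains non-ACGT base {exc.args[0]!r}") from exc
    score = float(pwm.scores[np.arange(pwm.width), idx].sum())
    return score, _relative(pwm, score)


def _relative(pwm: PWM, score: float | np.ndarray) -> float | np.ndarray:
    span = pwm.max_score - pwm.min_score
    if span == 0:
        # degenerate motif: every window attains the unique score
        return np.ones_like(score, dtype=float) if np.ndim(score) else 1.0
    return (score - pwm.min_score) / span


def _scan_one_strand(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Scores for every offset; NaN where the window overlaps an N."""
    w = pwm.width
    n_windows = idx.size - w + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_windows, np.nan)
    if valid.any():
        safe = np.where(windows[valid] >= 0, windows[valid], 0)
        scores[valid] = pwm.scores[np.arange(w), safe].sum(axis=1)
    return scores


def scan_promoter(
    pwm: PWM, window: PromoterWindow, cutoff: float = DEFAULT_CUTOFF
) -> list[MotifHit]:
    """All positions on both strands with relative score strictly above *cutoff*.

    Hit starts are 1-based leftmost positions within the window regardless
    of strand.  Positions overlapping an N are skipped.  A window shorter
    than the motif yields an empty list with a warning.
    """
    L = len(window)
    if L < pwm.width:
        warnings.warn(
            f"promoter {window.gene_id!r} ({L} bp) shorter than motif "
            f"{pwm.motif_id!r} ({pwm.width} bp); no scan performed",
            stacklevel=2,
        )
        return []
    idx = np.array([_BASE_INDEX.get(b, -1) for b in window.sequence], dtype=int)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _scan_one_strand(mat, idx)
        rel = _relative(pwm, scores)
        for off in np.flatnonzero(np.asarray(rel) > cutoff):
            hits.append(
                MotifHit(
                    motif_id=pwm.motif_id,
                    start=int(off) + 1,
                    strand=strand,
                    score=float(scores[off]),
                    relative_score=float(np.asarray(rel)[off]),
                    gene_id=window.gene_id,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))  # '+' sorts before '-'
    return hits


def scan_promoters(
    pwms: Iterable[PWM],
    windows: Iterable[PromoterWindow],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Scan every motif against every window; return a tidy hits table."""
    rows = []
    windows = list(windows)
    for pwm in pwms:
        for window in windows:
            for h in scan_promoter(pwm, window, cutoff=cutoff):
                rows.append(
                    {
                        "gene_id": h.gene_id,
                        "motif_id": h.motif_id,
                        "start": h.start,
                        "strand": h.strand,
                        "score": h.score,
                        "relative_score": h.relative_score,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "motif_id", "start", "strand", "score", "relative_score"]
    )


# ---------------------------------------------------------------------------
# File formats

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def read_promoter_fasta(path: str, upstream_bp: int = DEFAULT_UPSTREAM_BP) -> list[PromoterWindow]:
    """Read pre-extracted promoter windows directly from FASTA."""
    out = []
    for rec_id, seq in read_fasta(path).items():
        if len(seq) > upstream_bp:
            raise ValidationError(
                f"promoter {rec_id!r} is {len(seq)} bp, longer than the "
                f"{upstream_bp} bp window"
            )
        out.append(
            PromoterWindow(gene_id=rec_id, sequence=seq, truncated=len(seq) < upstream_bp)
        )
    return out


def read_coords(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str, "strand": str})
    required = {"gene_id", "contig", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"coordinates file {path!r} missing columns {sorted(required - set(df.columns))}"
        )
    return df


def read_pwms(path: str) -> list[PWM]:
    """Parse a simple PWM text file.

    Each motif is a ``>motif_id`` header followed by width rows of four
    whitespace-separated scores in A C G T order.
    """
    motifs: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows
        if name is not None:
            if not rows:
                raise ValidationError(f"motif {name!r} has no score rows")
            motifs.append(PWM(name, np.array(rows)))
        rows = []

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValidationError(
                        f"PWM row must have 4 columns (A C G T): {line!r}"
                    )
                rows.append(vals)
    flush()
    return motifs


def write_pwms(pwms: Iterable[PWM], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.scores:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def write_hits(hits: pd.DataFrame, path: str) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format="%.6f")
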