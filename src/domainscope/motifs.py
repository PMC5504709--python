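"""CTCF motif scanning and peak orientation annotation.

A JASPAR position-frequency matrix is converted to a log-odds position
weight matrix and slid along both strands of a DNA sequence; hits above a
relative score threshold are reported with forward-strand coordinates.
ChIP-seq peaks are then annotated by the orientation of the motifs they
contain — the divergent/convergent geometry of CTCF sites constrains which
loops cohesin can form, so orientation is the biologically meaningful label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import motifs as bio_motifs

from .core import GenomicRegion

__all__ = [
    "PFM",
    "MotifHit",
    "read_jaspar_pfm",
    "pfm_to_pwm",
    "scan_sequence",
    "annotate_peak_orientation",
]

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PFM:
    """Position-frequency matrix: 4 x L counts, rows A, C, G, T."""

    counts: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM must be 4 x L")
        if self.counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(self.counts < 0) or np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("PFM counts must be non-negative with no empty column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start on the forward strand
    strand: str    # "+" (forward) / "-" (reverse)
    score: float   # log-odds


def read_jaspar_pfm(path) -> PFM:
    """Read a JASPAR-format PFM file (first motif)."""
    with open(path) as fh:
        m = bio_motifs.read(fh, "jaspar")
    counts = np.array([m.counts[b] for b in BASES], dtype=float)
    return PFM(counts, name=m.name or m.matrix_id or "")


def pfm_to_pwm(
    pfm: PFM,
    background: np.ndarray | None = None,
    pseudocount: float = 0.8,
) -> np.ndarray:
    """Log-odds PWM: log2 of pseudocounted frequency over background.

    ``pwm[b, k] = log2(((counts[b, k] + pc * bg[b]) / (col_total_k + pc)) / bg[b])``
    with the pseudocount distributed according to the background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    if np.any(bg <= 0):
        raise ValueError("background must have no zero entry")
    col_total = pfm.counts.sum(axis=0)
    freq = (pfm.counts + pseudocount * bg[:, None]) / (col_total + pseudocount)
    return np.log2(freq / bg[:, None])


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_one_strand(seq: str, pwm: np.ndarray, min_score: float):
    """Yield (start, score) of windows scoring >= min_score; N windows skipped."""
    L = pwm.shape[1]
    code = np.full(len(seq), -1, dtype=int)
    for b, base in enumerate(BASES):
        code[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = b
    for start in range(len(seq) - L + 1):
        window = code[start : start + L]
        if np.any(window < 0):  # contains N or other ambiguity
            continue
        score = float(pwm[window, np.arange(L)].sum())
        if score >= min_score:
            yield start, score


def scan_sequence(
    seq: str, pwm: np.ndarray, threshold: float = 0.8
) -> list[MotifHit]:
    """Scan both strands for PWM hits above ``threshold * max_attainable``.

    The reverse strand is scanned as the reverse complement; hit positions
    always refer to the forward strand (0-based start of the motif span).
    Overlapping opposite-strand hits are both reported. Sequences shorter
    than the motif yield an empty list.
    """
    seq = seq.upper()
    L = pwm.shape[1]
    if len(seq) < L:
        return []
    max_score = float(pwm.max(axis=0).sum())
    min_score = threshold * max_score
    hits = [MotifHit(s, "+", sc) for s, sc in _scan_one_strand(seq, pwm, min_score)]
    rc = _reverse_complement(seq)
    hits += [
        MotifHit(len(seq) - s - L, "-", sc)
        for s, sc in _scan_one_strand(rc, pwm, min_score)
    ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


def annotate_peak_orientation(
    peaks: list[GenomicRegion], hits: list[MotifHit]
) -> list[str]:
    """Label each peak by the orientation of the motifs inside it.

    A peak with hits on one strand takes the orientation of its best hit
    ("forward"/"reverse"). With hits on both strands the relative order
    decides: a reverse motif upstream of a forward motif points the two
    motifs apart ("divergent"); the opposite order is "convergent". Peaks
    with no hit are "none". Hit positions are interpreted on the same
    coordinate system as the peaks.
    """
    pos = [h.position for h in hits]
    if pos != sorted(pos):
        raise ValueError("hits must be sorted by position")
    labels = []
    for peak in peaks:
        inside = [h for h in hits if peak.start <= h.position < peak.end]
        fwd = [h for h in inside if h.strand == "+"]
        rev = [h for h in inside if h.strand == "-"]
        if not inside:
            labels.append("none")
        elif fwd and rev:
            best_f = max(fwd, key=lambda h: h.score)
            best_r = max(rev, key=lambda h: h.score)
            labels.append("divergent" if best_r.position < best_f.position else "convergent")
        elif fwd:
            labels.append("forward")
        else:
            labels.append("reverse")
    return labels
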