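"""PWM motif scanning and cumulative-binomial enrichment.

A JASPAR-style position frequency matrix (PFM) of base counts is turned
into a log-odds position weight matrix (PWM) against a 0-order
background; sequences are scanned on both strands, with hits reported
at a relative-score threshold (score rescaled to [0, 1] between the
matrix's worst and best attainable scores).  Motif enrichment between a
target and a background sequence set is the one-sided cumulative
binomial probability of observing at least the target's per-sequence
hit rate given the background rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as sps

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

UNIFORM_BACKGROUND = np.full(4, 0.25)


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PFM:
    """Position frequency matrix: 4 x L base counts (rows A, C, G, T)."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise ValueError("motif length must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("all-zero column in PFM")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_consensus(cls, motif_id: str, consensus: str) -> "PFM":
        """Degenerate PFM putting all weight on one sequence."""
        counts = np.zeros((4, len(consensus)))
        for j, b in enumerate(consensus.upper()):
            counts[_BASE_INDEX[b], j] = 1.0
        return cls(motif_id, counts)


def read_jaspar(path) -> list[PFM]:
    """Read PFMs from a JASPAR file (bracketed or 4-line raw dialect)."""
    from Bio import motifs as bio_motifs

    out = []
    for fmt in ("jaspar", "pfm-four-columns"):
        try:
            with open(path) as fh:
                parsed = bio_motifs.parse(fh, fmt)
                for m in parsed:
                    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
                    out.append(PFM(m.matrix_id or m.name or "motif", counts))
            if out:
                return out
        except Exception:
            out = []
            continue
    # raw 4-line dialect: one row of numbers per base, A/C/G/T order
    with open(path) as fh:
        rows, motif_id = [], "motif"
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            rows.append([float(x) for x in line.replace(",", " ").split()])
    if len(rows) != 4:
        raise ValueError(f"cannot parse PFM file {path}")
    return [PFM(motif_id, np.array(rows))]


@dataclass
class PWM:
    """Log-odds scoring matrix with its attainable score range."""

    motif_id: str
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.log_odds.shape[0] != 4:
            raise ValueError("log_odds must be 4 x L")
        if np.any(self.background <= 0) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be positive and sum to 1")
        self.max_score = float(self.log_odds.max(axis=0).sum())
        self.min_score = float(self.log_odds.min(axis=0).sum())

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id + "_rc",
            self.log_odds[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )

    def relative(self, score: float) -> float:
        """Rescale a raw log-odds score to [0, 1]."""
        if self.max_score == self.min_score:
            return 1.0
        return (score - self.min_score) / (self.max_score - self.min_score)


def pfm_to_pwm(
    pfm: PFM,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Standard log2-odds PWM from a frequency matrix.

    Per column, base probability is
    ``(count + pc * bg_b) / sum_b'(count + pc * bg_b')`` and the matrix
    entry is ``log2(prob / bg_b)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    smoothed = pfm.counts + pseudocount * bg[:, None]
    probs = smoothed / smoothed.sum(axis=0, keepdims=True)
    return PWM(pfm.motif_id, np.log2(probs / bg[:, None]), bg, pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """One scoring window: forward coordinates even for - strand hits."""

    seq_id: str
    offset: int
    strand: str
    score: float
    relative_score: float


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Raw scores of every length-L window of an index-encoded sequence.

    ``idx`` holds 0-3 for ACGT and -1 for other characters; windows
    containing a -1 score NaN.
    """
    L = log_odds.shape[1]
    n_win = len(idx) - L + 1
    if n_win <= 0:
        return np.zeros(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(L):
        col_idx = idx[j : j + n_win]
        invalid = col_idx < 0
        bad |= invalid
        scores += np.where(invalid, 0.0, log_odds[np.clip(col_idx, 0, 3), j])
    scores[bad] = np.nan
    return scores


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    idx = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        idx[arr == ord(b)] = i
    return idx


def scan_sequence(
    seq: str,
    pwm: PWM,
    threshold: float = 0.8,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All windows on both strands with relative score >= threshold.

    The reverse strand is scored on the reverse complement of each
    window and reported at forward-strand coordinates.  Windows with
    non-ACGT characters are skipped; sequences shorter than the motif
    yield no hits.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    L = pwm.length
    idx = _encode(seq)
    if len(idx) < L:
        return []
    hits = []
    fwd = _window_scores(idx, pwm.log_odds)
    rev = _window_scores(idx, pwm.reverse_complement().log_odds)
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.flatnonzero(~np.isnan(scores)):
            rel = pwm.relative(float(scores[off]))
            if rel >= threshold:
                hits.append(MotifHit(seq_id, int(off), strand, float(scores[off]), rel))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def has_hit(seq: str, pwm: PWM, threshold: float) -> bool:
    """Whether a sequence contains at least one window above threshold."""
    L = pwm.length
    idx = _encode(seq)
    if len(idx) < L:
        return False
    for lo in (pwm.log_odds, pwm.reverse_complement().log_odds):
        scores = _window_scores(idx, lo)
        valid = scores[~np.isnan(scores)]
        if valid.size and pwm.relative(float(valid.max())) >= threshold:
            return True
    return False


@dataclass
class EnrichmentResult:
    """One-sided binomial motif enrichment of targets vs background."""

    motif_id: str
    n_target: int
    k_with_hit: int
    background_rate: float
    p_value: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "motif_id": self.motif_id,
            "n_target": self.n_target,
            "k_with_hit": self.k_with_hit,
            "background_rate": self.background_rate,
            "p_value": self.p_value,
            "threshold": self.threshold,
        }


def binomial_enrichment(
    targets: Sequence[str],
    background: Union[Sequence[str], float],
    pwm: PWM,
    threshold: float = 0.8,
) -> EnrichmentResult:
    """Cumulative-binomial motif enrichment.

    ``k`` of the ``n`` target sequences contain at least one hit; the
    per-sequence background rate ``q`` is estimated from the background
    set (clamped away from 0 and 1 by half a count) or given directly.
    The p-value is ``P[X >= k]`` for ``X ~ Binomial(n, q)``.
    """
    n = len(targets)
    if n < 1:
        raise ValueError("need at least one target sequence")
    k = sum(has_hit(s, pwm, threshold) for s in targets)
    if isinstance(background, (int, float)):
        q = float(background)
        if not 0.0 < q < 1.0:
            raise ValueError("background rate must lie in (0, 1)")
    else:
        n_bg = len(background)
        if n_bg == 0:
            raise ValueError("empty background sequence set")
        raw = sum(has_hit(s, pwm, threshold) for s in background) / n_bg
        q = float(np.clip(raw, 1.0 / (2 * n_bg), 1.0 - 1.0 / (2 * n_bg)))
    p = float(sps.binom.sf(k - 1, n, q))
    return EnrichmentResult(pwm.motif_id, n, k, q, min(max(p, 0.0), 1.0), threshold)


def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA (wrapped lines allowed) as an id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_peak_sequences(peaks, genome: dict[str, str]) -> list[tuple[str, str]]:
    """Peak sequences from a genome dict, BED half-open, uppercased."""
    out = []
    for i, iv in enumerate(peaks):
        if iv.chrom not in genome:
            raise KeyError(f"chromosome {iv.chrom!r} absent from genome")
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"peak {iv.name or i} [{iv.start},{iv.end}) exceeds "
                f"{iv.chrom} length {len(chrom_seq)}"
            )
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        out.append((name, chrom_seq[iv.start : iv.end].upper()))
    return out


def hits_to_bed(hits: Sequence[MotifHit], pwm: PWM, path) -> None:
    """Write hits as BED6; score column is relative score x 1000."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.offset}\t{h.offset + pwm.length}\t{pwm.motif_id}"
                f"\t{round(h.relative_score * 1000)}\t{h.strand}\n"
            )
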