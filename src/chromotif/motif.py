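"""Position-specific scoring matrices and promoter scanning.

A PSSM here is a per-position nucleotide *probability* matrix describing a
transcription factor's binding preference.  The module provides the three
quantities the rest of the package builds on:

* **information content** — relative entropy of the matrix against the
  genomic background, in bits; measures how specific a motif is.
* **similarity** — the length-averaged dot product between two matrices,
  maximised over ungapped alignments when lengths differ; lies in [0, 1].
* **log-odds scanning** — every window of a sequence (both strands) is
  scored as sum_i log2(p(i, base_i) / p_b(base_i)); windows at or above a
  threshold become :class:`MotifHit` records, and the *cumulative matching
  score* of a promoter is the sum of its hit scores.  That cumulative score
  is the motif feature fed to the target-gene classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default scan threshold, as a fraction of a PSSM's maximum achievable score
DEFAULT_SCORE_FRACTION = 0.6
#: default pseudocount added to probabilities before taking log-odds
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class Background:
    """Background nucleotide frequencies (A, C, G, T)."""

    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background must have exactly 4 frequencies")
        if np.any(f <= 0) or not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must be positive and sum to 1")
        object.__setattr__(self, "freqs", f)

    def __getitem__(self, base: str) -> float:
        return float(self.freqs[_CODE[base]])


def background_from_gc(gc: float) -> Background:
    """Background from a GC fraction: A=T=(1-gc)/2, C=G=gc/2.

    The yeast genome has GC content ~0.37, which is the default used
    throughout the package.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError(f"GC fraction must be in (0, 1), got {gc}")
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    return Background(np.array([at, cg, cg, at]))


@dataclass
class PSSM:
    """Probability matrix for one motif: shape (n, 4), rows sum to 1."""

    id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError(f"PSSM {self.id!r}: matrix must be (n>=1, 4)")
        if np.any(p < 0):
            raise ValueError(f"PSSM {self.id!r}: negative weights")
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError(f"PSSM {self.id!r}: rows must sum to 1 within 1e-9")
        self.probs = p

    @property
    def n(self) -> int:
        """Motif length."""
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.probs.argmax(axis=1))

    def log_odds(self, bg: Background, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        """(n, 4) log2-odds matrix; pseudocount is added then rows renormalized."""
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        q = self.probs + pseudocount
        q = q / q.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            return np.log2(q / bg.freqs)

    def max_score(self, bg: Background, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
        """Best achievable log-odds score (consensus at every position)."""
        return float(self.log_odds(bg, pseudocount).max(axis=1).sum())

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.id, self.probs[::-1, ::-1].copy())


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on forward coordinates of a sequence."""

    seq_id: str
    offset: int  # 0-based window start on the forward strand
    strand: str  # '+' or '-'
    score: float  # log-odds, bits


def information_content(pssm: PSSM, bg: Background, pseudocount: float = 0.0) -> float:
    """Relative entropy of a PSSM against the background, in bits.

    IC = sum_{i,j} p(i,j) * log2(p(i,j) / p_b(j)), with 0*log(0) = 0.  A
    matrix equal to the background at every position has IC 0; sharper
    matrices have larger IC.  We use the positive (KL-divergence) sign
    convention so that higher IC means a more specific motif.
    """
    q = pssm.probs
    if pseudocount > 0:
        q = q + pseudocount
        q = q / q.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log2(q / bg.freqs), 0.0)
    return float(terms.sum())


def pssm_similarity(p1: PSSM, p2: PSSM, min_overlap: int | None = None) -> float:
    """Averaged per-position dot product between two PSSMs, in [0, 1].

    Equal lengths: (1/n) sum_i sum_j p1(i,j) p2(i,j).  Unequal lengths: the
    maximum over all ungapped offsets, dividing by the overlap length, with
    overlap required to be at least min(3, shorter length).  Symmetric.
    """
    a, b = p1.probs, p2.probs
    if min_overlap is None:
        min_overlap = min(3, min(len(a), len(b)))
    if len(a) > len(b):
        a, b = b, a  # a is the shorter
    na, nb = len(a), len(b)
    best = 0.0
    # slide the short matrix across the long one, no gaps
    for shift in range(-(na - min_overlap), nb - min_overlap + 1):
        lo_a, lo_b = max(0, -shift), max(0, shift)
        ov = min(na - lo_a, nb - lo_b)
        if ov < min_overlap:
            continue
        dot = float((a[lo_a : lo_a + ov] * b[lo_b : lo_b + ov]).sum())
        best = max(best, dot / ov)
    return best


def _encode(seq: str) -> np.ndarray:
    """Map sequence to codes A=0 C=1 G=2 T=3, anything else (N) = 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def _window_scores(lod: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score of every window; NaN where the window contains a non-ACGT base."""
    n, L = lod.shape[0], len(codes)
    nw = L - n + 1
    if nw <= 0:
        return np.empty(0)
    # pad log-odds with a NaN column so code 4 (N) poisons the window score
    padded = np.hstack([lod, np.full((n, 1), np.nan)])
    scores = np.zeros(nw)
    for i in range(n):
        scores += padded[i, codes[i : i + nw]]
    return scores


def scan_sequence(
    pssm: PSSM,
    seq: str,
    bg: Background,
    score_threshold: float | None = None,
    both_strands: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seq_id: str = "",
) -> list[MotifHit]:
    """Find motif occurrences at or above a log-odds threshold.

    Every window of length n on the requested strand(s) is scored; windows
    containing N are skipped.  ``score_threshold=None`` uses the default of
    60% of the PSSM's maximum achievable score.  Hits are reported on
    forward coordinates, sorted by offset ('+' before '-' at ties).
    Sequences shorter than the motif yield an empty list.
    """
    if score_threshold is None:
        score_threshold = DEFAULT_SCORE_FRACTION * pssm.max_score(bg, pseudocount)
    if not math.isfinite(score_threshold) and score_threshold > 0:
        return []
    codes = _encode(seq)
    hits: list[MotifHit] = []
    lod = pssm.log_odds(bg, pseudocount)
    fwd = _window_scores(lod, codes)
    for off in np.flatnonzero(fwd >= score_threshold):
        hits.append(MotifHit(seq_id, int(off), "+", float(fwd[off])))
    if both_strands:
        # scoring the reverse complement of each window == scanning the
        # reverse-complemented PSSM along the forward sequence
        rev = _window_scores(lod[::-1, ::-1], codes)
        for off in np.flatnonzero(rev >= score_threshold):
            hits.append(MotifHit(seq_id, int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def cumulative_match_score(hits: list[MotifHit]) -> float:
    """Sum of hit scores for one (gene, motif) pair; 0 for no hits."""
    return float(sum(h.score for h in hits))


def sample_site(pssm: PSSM, rng: np.random.Generator) -> str:
    """Draw one site from the PSSM (per-position multinomial)."""
    idx = [rng.choice(4, p=row) for row in pssm.probs]
    return "".join(ALPHABET[j] for j in idx)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
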