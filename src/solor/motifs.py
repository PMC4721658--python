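"""Homeodomain binding-site model: PSWM construction and scanning.

Homeodomain (HD) transcription-factor binding sites recur in OR gene
promoters and in the enhancer elements (P, H) that regulate OR clusters.
The matrix here is built the way such a motif model is derived from a
handful of annotated enhancer sites: each seed site is extended to the
boundaries of the imperfect inverted repeat (hemi-palindrome) that contains
it, oriented consistently, and the extended sites are stacked into a
position-specific weight matrix (PSWM).  Promoter windows are then scanned
with log-odds scores whose p-values come from the exact score distribution
under the background model, computed by dynamic programming over
integer-discretised column scores — the same construction FIMO-style
scanners use.

Score discretisation is 1/1000 bit per unit.  Word scores used for both
scanning and p-values are sums of the discretised column scores, so the
reported p-value is exact for the reported score (discretisation perturbs
scores by < width/2000 bits, never the score/p-value correspondence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

__all__ = [
    "InvertedRepeat",
    "SeedSite",
    "PositionWeightMatrix",
    "MotifHit",
    "find_inverted_repeats",
    "extend_seed_sites",
    "build_pswm",
    "exact_pvalue",
    "scan_sequence",
    "scan_promoters",
]

_BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(_BASES)}
RESOLUTION = 1000  # discretisation: score units per bit


# ---------------------------------------------------------------------------
# Inverted repeats (hemi-palindromes)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InvertedRepeat:
    """Arms are half-open intervals on the scanned sequence; the right arm
    reverse-complements the left one within ``mismatches``."""

    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop_length: int
    mismatches: int

    @property
    def arm_length(self) -> int:
        return self.left_arm[1] - self.left_arm[0]


def find_inverted_repeats(
    seq: str, min_arm: int = 4, max_loop: int = 10, max_mismatch: int = 0
) -> list[InvertedRepeat]:
    """All maximal inverted repeats of ``seq`` under the given constraints.

    For every loop placement the arms are grown outward from the loop until
    one more base pair would exceed ``max_mismatch`` or run off the
    sequence; arms of at least ``min_arm`` are reported.  Overlapping
    repeats are all reported.
    """
    if min_arm < 3:
        raise ValueError("min_arm must be >= 3")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        return []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    seen = set()
    for loop in range(max_loop + 1):
        for a in range(n - loop + 1):  # loop occupies [a, a+loop)
            b = a + loop
            arm = 0
            mism = 0
            # grow: left arm [a-arm, a), right arm [b, b+arm)
            while a - arm - 1 >= 0 and b + arm < n:
                l = seq[a - arm - 1]
                r = seq[b + arm]
                pair_mismatch = comp.get(l) != r
                if mism + pair_mismatch > max_mismatch:
                    break
                mism += pair_mismatch
                arm += 1
            if arm >= min_arm:
                rep = InvertedRepeat((a - arm, a), (b, b + arm), loop, mism)
                key = (rep.left_arm, rep.right_arm)
                if key not in seen:
                    seen.add(key)
                    out.append(rep)
    out.sort(key=lambda r: (r.left_arm, r.right_arm))
    return out


# ---------------------------------------------------------------------------
# Seed sites and their palindrome-guided extension
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedSite:
    sequence: str
    origin: str = ""
    orientation: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence.upper()) - set(_BASES):
            raise ValueError("seed sites must be non-empty A/C/G/T strings")


def _locate(needle: str, haystack: str) -> tuple[int, str] | None:
    i = haystack.find(needle)
    if i >= 0:
        return i, "+"
    i = haystack.find(reverse_complement(needle))
    if i >= 0:
        return i, "-"
    return None


def extend_seed_sites(
    seeds: list[SeedSite],
    element_seq: str,
    min_arm: int = 4,
    max_loop: int = 10,
    max_mismatch: int = 1,
) -> list[SeedSite]:
    """Extend annotated seed binding sites to inverted-repeat boundaries.

    Each seed is located on the enhancer element (either strand); the
    inverted-repeat arm(s) overlapping the occurrence define its extended
    boundaries.  Minus-strand occurrences are reverse-complemented so that
    all outputs read in a consistent orientation, and shorter extensions are
    padded symmetrically from the element so every output has equal length.
    """
    element_seq = element_seq.upper()
    repeats = find_inverted_repeats(element_seq, min_arm, max_loop, max_mismatch)
    arms = sorted(
        {r.left_arm for r in repeats} | {r.right_arm for r in repeats}
    )

    spans: list[tuple[int, int, str]] = []
    for seed in seeds:
        loc = _locate(seed.sequence.upper(), element_seq)
        if loc is None:
            raise ValueError(f"seed {seed.sequence!r} not found on element")
        start, strand = loc
        end = start + len(seed.sequence)
        lo, hi = start, end
        for a0, a1 in arms:
            if a0 < end and start < a1:  # overlap
                lo, hi = min(lo, a0), max(hi, a1)
        spans.append((lo, hi, strand))

    width = max(hi - lo for lo, hi, _ in spans)
    out = []
    for (lo, hi, strand), seed in zip(spans, seeds):
        pad = width - (hi - lo)
        lo2 = max(0, lo - pad // 2)
        hi2 = min(len(element_seq), lo2 + width)
        lo2 = max(0, hi2 - width)
        s = element_seq[lo2:hi2]
        if strand == "-":
            s = reverse_complement(s)
        out.append(SeedSite(s, origin=seed.origin, orientation=strand))
    return out


# ---------------------------------------------------------------------------
# PSWM
# ---------------------------------------------------------------------------

@dataclass
class PositionWeightMatrix:
    """Counts, frequencies and log-odds (bits) of a nucleotide motif.

    ``frequencies[i, b] = (counts[i, b] + pseudocount * background[b]) /
    (n_sites + pseudocount)``; ``log_odds = log2(frequencies / background)``.
    """

    counts: np.ndarray  # (width, 4)
    frequencies: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    n_sites: int
    name: str = "motif"

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def information_content(self) -> float:
        """Total information content in bits (relative entropy vs background)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(
                self.frequencies > 0, self.frequencies * self.log_odds, 0.0
            )
        return float(terms.sum())

    def scaled_scores(self) -> np.ndarray:
        """Column scores discretised to integer units of 1/RESOLUTION bit.

        Zero-frequency cells (possible only at pseudocount 0) are floored at
        -32 bits so the score grid stays finite; no realistic threshold is
        affected."""
        lo = np.maximum(self.log_odds, -32.0)
        return np.round(lo * RESOLUTION).astype(np.int64)


def build_pswm(
    sites: list[SeedSite] | list[str],
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    name: str = "motif",
) -> PositionWeightMatrix:
    """Tally equal-length sites into a PSWM.

    ``pseudocount`` is distributed across bases proportionally to the
    background (default uniform), the common convention when the matrix is
    built from a handful of sites.
    """
    seqs = [s.sequence if isinstance(s, SeedSite) else s for s in sites]
    if not seqs:
        raise ValueError("at least one site required")
    seqs = [s.upper() for s in seqs]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("sites must all have equal length")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must sum to 1")
    counts = np.zeros((width, 4))
    for s in seqs:
        for i, c in enumerate(s):
            counts[i, _IDX[c]] += 1
    freqs = (counts + pseudocount * bg) / (len(seqs) + pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(freqs / bg)
    return PositionWeightMatrix(
        counts, freqs, log_odds, bg, pseudocount, len(seqs), name
    )


# ---------------------------------------------------------------------------
# Exact p-values
# ---------------------------------------------------------------------------

def score_distribution(pswm: PositionWeightMatrix) -> tuple[int, np.ndarray]:
    """Exact distribution of the discretised word score under background.

    Returns ``(offset, probs)`` where ``probs[s - offset]`` is the
    probability that a random width-w word (i.i.d. background) attains
    integer score ``s``.  Computed by per-column convolution.
    """
    scores = pswm.scaled_scores()
    bg = pswm.background
    cur = np.array([1.0])  # point mass at score 0 before any column
    cur_lo = 0
    for col in scores:
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            s = int(col[b])
            start = cur_lo + s - new_lo
            new[start : start + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    return cur_lo, cur


def survival_function(pswm: PositionWeightMatrix) -> tuple[int, np.ndarray]:
    """``(offset, sf)`` with ``sf[s - offset] = P(score >= s)``."""
    offset, probs = score_distribution(pswm)
    sf = np.cumsum(probs[::-1])[::-1]
    return offset, sf


def exact_pvalue(pswm: PositionWeightMatrix, score_bits: float) -> float:
    """P(random background word scores >= ``score_bits``).

    The score is discretised to the matrix's integer grid; p = 1 for any
    score at or below the minimum attainable.  Scores above the maximum
    attainable are clamped to the maximum (keeping p in (0, 1]).
    """
    if not np.isfinite(score_bits):
        raise ValueError("score must be finite")
    offset, sf = survival_function(pswm)
    s = int(round(score_bits * RESOLUTION))
    s = min(max(s, offset), offset + len(sf) - 1)
    return float(min(sf[s - offset], 1.0))


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based window coordinate of the hit's leftmost base
    strand: str
    score: float  # bits
    p_value: float
    matched: str


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for b, i in _IDX.items():
        code[ord(b)] = i
    return code[arr]


def _window_scores(enc: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Integer score at every start position; positions containing a non-ACGT
    base get the sentinel minimum (excluded later)."""
    w = scores.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        col = enc[i : i + n]
        ok = col >= 0
        valid &= ok
        out += np.where(ok, scores[i, np.clip(col, 0, 3)], 0)
    out[~valid] = np.iinfo(np.int64).min
    return out


def scan_sequence(
    pswm: PositionWeightMatrix,
    seq: str,
    sequence_id: str = "seq",
    p_threshold: float = 1e-4,
    _sf: tuple[int, np.ndarray] | None = None,
) -> list[MotifHit]:
    """Report every position x strand whose p-value is <= ``p_threshold``.

    Minus-strand matches are scored on the reverse complement and reported
    in window coordinates (start of the leftmost base).  When both strands
    hit the same position with equal score (palindromic match) only the
    plus strand is reported.  Positions whose word contains non-ACGT
    characters are skipped.
    """
    offset, sf = _sf if _sf is not None else survival_function(pswm)
    # smallest integer score whose p-value clears the threshold
    idx = np.searchsorted(-sf, -p_threshold, side="left")
    s_min = offset + idx
    if idx >= len(sf):
        return []
    scores = pswm.scaled_scores()
    w = pswm.width
    seq = seq.upper()
    if len(seq) < w:
        return []
    enc = _encode(seq)
    fwd = _window_scores(enc, scores)
    rc = reverse_complement(seq)
    rev = _window_scores(_encode(rc), scores)[::-1]  # rev[i]: hit starting at i on -

    hits = []
    for i in np.nonzero(fwd >= s_min)[0]:
        s = int(fwd[i])
        hits.append(
            MotifHit(sequence_id, int(i), "+", s / RESOLUTION,
                     float(sf[s - offset]), seq[i : i + w])
        )
    plus_at = {h.start: h.score for h in hits}
    for i in np.nonzero(rev >= s_min)[0]:
        s = int(rev[i])
        if plus_at.get(int(i)) == s / RESOLUTION:
            continue  # palindromic duplicate; keep the + strand report
        hits.append(
            MotifHit(sequence_id, int(i), "-", s / RESOLUTION,
                     float(sf[s - offset]),
                     reverse_complement(seq[i : i + w]))
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_promoters(
    pswm: PositionWeightMatrix,
    windows,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan a collection of promoter windows (objects with ``gene_id`` and
    ``sequence`` attributes, or (id, sequence) pairs); windows shorter than
    the matrix are skipped."""
    sf = survival_function(pswm)
    hits: list[MotifHit] = []
    for win in windows:
        if hasattr(win, "sequence"):
            name, seq = win.gene_id, win.sequence
        else:
            name, seq = win
        if len(seq) < pswm.width:
            import warnings

            warnings.warn(f"{name}: window shorter than motif width, skipped")
            continue
        hits.extend(scan_sequence(pswm, seq, name, p_threshold, _sf=sf))
    return hits
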