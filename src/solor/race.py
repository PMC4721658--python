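"""From 5' RACE clones to putative minimal promoters.

The pipeline mirrors how transcription start sites (TSSs) of OR genes are
located experimentally: Sanger-sequenced 5' RACE clones are polished from
adapter/vector backbone, spliced-aligned against a genomic reference window,
the 5'-terminal base of each aligned clone is read as a TSS, the most
upstream TSS per gene is chosen, and a putative minimal promoter is defined
as a fixed-length window (301 bp by default) centred on it.

Spliced alignment here is exact k-mer seeding + collinear chaining +
bounded extension rather than full dynamic programming: reference windows
may reach 100 kb while clones are short, and RACE clones are near-identical
to the genome, so anchors recover the exon structure directly.  Reference
gaps of at least ``min_intron`` bp (default 20, so that a documented 21-bp
OR intron remains representable) are treated as introns; shorter reference
gaps are treated as alignment deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .solitary import GenomicInterval

__all__ = [
    "RaceClone",
    "AlignmentBlock",
    "SplicedAlignment",
    "TssCall",
    "PromoterWindow",
    "CloneUnusableError",
    "UnmappedCloneError",
    "polish_clone",
    "map_clone",
    "select_tss",
    "define_promoter",
    "check_probe_specificity",
]

_DNA = set("ACGTN")


class CloneUnusableError(ValueError):
    """Polishing left fewer than the minimum usable clone length."""


class UnmappedCloneError(ValueError):
    """No collinear chain covers enough of the clone."""


@dataclass
class RaceClone:
    """One polished 5' RACE clone.

    ``source`` records the RNA preparation: WOM (whole olfactory mucosa) or
    OSN (sorted olfactory sensory neurons)."""

    clone_id: str
    sequence: str
    source: str = "WOM"
    gene_id: str = ""
    fully_sequenced_3prime: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - _DNA:
            raise ValueError(f"{self.clone_id}: non-ACGTN characters in sequence")
        if len(self.sequence) < 30:
            raise CloneUnusableError(
                f"{self.clone_id}: clone shorter than 30 bp after polishing"
            )


@dataclass(frozen=True)
class AlignmentBlock:
    """One exon block: reference interval plus the clone span it covers
    (clone coordinates refer to the mapped orientation of the clone)."""

    reference: GenomicInterval
    clone_start: int
    clone_end: int


@dataclass
class SplicedAlignment:
    clone_id: str
    blocks: list[AlignmentBlock]
    strand: str
    mismatches: int
    canonical_introns: list[bool]

    @property
    def clone_coverage(self) -> int:
        return sum(b.clone_end - b.clone_start for b in self.blocks)


@dataclass
class TssCall:
    gene_id: str
    sequence_id: str
    position: int  # 0-based reference coordinate of the 5'-terminal base
    strand: str
    support: list[str] = field(default_factory=list)
    all_ends: list[int] = field(default_factory=list)


@dataclass
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    sequence: str
    nominal_length: int = 301
    truncated: bool = False


# ---------------------------------------------------------------------------
# Polishing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def polish_clone(
    raw: str, adapters: list[str], max_mismatch: int = 2, min_length: int = 30
) -> str:
    """Strip adapter/vector backbone from the ends of a raw clone read.

    The longest prefix (and suffix) equal to an adapter — forward or
    reverse-complement, within ``max_mismatch`` substitutions — is removed;
    stripping repeats until no adapter remains, so the operation is
    idempotent.  Raises :class:`CloneUnusableError` when fewer than
    ``min_length`` bases remain.
    """
    raw = raw.upper()
    variants = sorted(
        {a.upper() for a in adapters} | {reverse_complement(a.upper()) for a in adapters},
        key=len,
        reverse=True,
    )
    if variants and len(raw) <= max(len(v) for v in variants):
        raise ValueError("raw read not longer than the longest adapter")

    seq = raw
    changed = True
    while changed:
        changed = False
        for ad in variants:
            la = len(ad)
            if len(seq) > la and _hamming(seq[:la], ad) <= max_mismatch:
                seq = seq[la:]
                changed = True
            if len(seq) > la and _hamming(seq[-la:], ad) <= max_mismatch:
                seq = seq[:-la]
                changed = True
    if len(seq) < min_length:
        raise CloneUnusableError(
            f"polished length {len(seq)} < {min_length}; clone unusable"
        )
    return seq


# ---------------------------------------------------------------------------
# Spliced mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingParams:
    k: int = 15
    min_intron: int = 20
    min_coverage: float = 0.8
    max_window: int = 100_000


def _seed_segments(clone: str, index: dict[str, list[int]], k: int):
    """Maximal runs of consecutive k-mer hits on a common diagonal.

    Returns segments as (q_start, q_end, r_start, r_end), half-open on both
    the clone and the reference.
    """
    hits: list[tuple[int, int]] = []  # (diag, q)
    for q in range(len(clone) - k + 1):
        for r in index.get(clone[q : q + k], ()):
            hits.append((r - q, q))
    hits.sort()
    segments = []
    i = 0
    while i < len(hits):
        d, q0 = hits[i]
        q1 = q0
        while i + 1 < len(hits) and hits[i + 1][0] == d and hits[i + 1][1] == q1 + 1:
            i += 1
            q1 = hits[i][1]
        segments.append((q0, q1 + k, d + q0, d + q1 + k))
        i += 1
    segments.sort()
    return segments


def _chain(segments: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Best collinear chain by covered clone bases (simple DP)."""
    n = len(segments)
    if n == 0:
        return []
    OVERLAP = 15  # chance matches can extend a seed run past a junction
    score = [s[1] - s[0] for s in segments]
    back = [-1] * n
    for j in range(n):
        qj0, qj1, rj0, rj1 = segments[j]
        for i in range(j):
            qi0, qi1, ri0, ri1 = segments[i]
            if qi1 <= qj0 + OVERLAP and ri1 <= rj0 + OVERLAP and qi1 < qj1 and ri1 < rj1:
                cand = score[i] + (qj1 - max(qj0, qi1))
                if cand > score[j]:
                    score[j] = cand
                    back[j] = i
    j = max(range(n), key=lambda t: (score[t], -segments[t][0]))
    chain = []
    while j != -1:
        chain.append(segments[j])
        j = back[j]
    return chain[::-1]


def _map_one_strand(
    clone: str, ref: str, params: MappingParams
) -> tuple[list[list[int]], int] | None:
    """Map one orientation of a clone; returns (blocks, mismatches) with
    blocks as mutable [q0, q1, r0, r1], or None when no chain is found."""
    k = params.k
    if len(clone) < k:
        return None
    index: dict[str, list[int]] = {}
    for r in range(len(ref) - k + 1):
        index.setdefault(ref[r : r + k], []).append(r)
    chain = _chain(_seed_segments(clone, index, k))
    if not chain:
        return None

    blocks: list[list[int]] = [list(chain[0])]
    mismatches = 0
    for seg in chain[1:]:
        q0, q1, r0, r1 = seg
        pq0, pq1, pr0, pr1 = blocks[-1]
        if q0 < pq1 or r0 < pr1:
            # overlapping claims on the clone/reference: release the
            # ambiguous bases from both sides and let the junction search
            # place the boundary
            o = max(pq1 - q0, pr1 - r0)
            if o >= (pq1 - pq0) or o >= (q1 - q0):
                break
            blocks[-1][1] -= o
            blocks[-1][3] -= o
            pq1 -= o
            pr1 -= o
            q0 += o
            r0 += o
        qgap = q0 - pq1
        rgap = r0 - pr1
        if rgap - qgap >= params.min_intron and qgap >= 0:
            # intron: distribute the unseeded clone bases (if any) across the
            # junction, maximising matches, preferring a canonical GT..AG
            best = None
            for s in range(qgap + 1):
                left_m = _hamming(clone[pq1 : pq1 + s], ref[pr1 : pr1 + s])
                right_m = _hamming(clone[q0 - (qgap - s) : q0], ref[r0 - (qgap - s) : r0])
                il, ir = pr1 + s, r0 - (qgap - s)
                canonical = ref[il : il + 2] == "GT" and ref[ir - 2 : ir] == "AG"
                key = (-(left_m + right_m), canonical, -s)
                if best is None or key > best[0]:
                    best = (key, s, left_m + right_m)
            _, s, mm = best
            mismatches += mm
            blocks[-1][1] = pq1 + s
            blocks[-1][3] = pr1 + s
            blocks.append([q0 - (qgap - s), q1, r0 - (qgap - s), r1])
        elif rgap == qgap and qgap >= 0:
            # same diagonal: exonic mismatch run, merge
            mismatches += _hamming(clone[pq1:q0], ref[pr1:r0])
            blocks[-1][1] = q1
            blocks[-1][3] = r1
        elif 0 <= rgap != qgap >= 0:
            # short indel inside an exon: keep as separate blocks, count the
            # unmatched bases as mismatches
            mismatches += max(qgap, rgap)
            blocks.append(list(seg))
        else:
            break  # inconsistent remainder of the chain; stop extending

    # Exact extension of the clone's unseeded ends: advance while bases
    # match and stop at the first disagreement.  A disagreement marks
    # either a sequencing error near the clone end (the residue is left
    # soft-clipped) or an unseeded tail crossing a splice junction; greedy
    # mismatch absorption would walk into introns on chance matches.
    def _extend(q: int, r: int, step: int) -> tuple[int, int]:
        while True:
            probe_q = q if step > 0 else q - 1
            probe_r = r if step > 0 else r - 1
            if not (0 <= probe_q < len(clone) and 0 <= probe_r < len(ref)):
                break
            if clone[probe_q] != ref[probe_r]:
                break
            q += step
            r += step
        return q, r

    q0, _, r0, _ = blocks[0]
    blocks[0][0], blocks[0][2] = _extend(q0, r0, -1)
    _, q1, _, r1 = blocks[-1]
    blocks[-1][1], blocks[-1][3] = _extend(q1, r1, +1)
    return blocks, mismatches


def map_clone(
    clone: RaceClone,
    reference_window: str,
    window_interval: GenomicInterval | None = None,
    params: MappingParams | None = None,
) -> SplicedAlignment:
    """Spliced-align a polished clone against a genomic reference window.

    Both orientations are attempted and the one with more matched bases is
    kept.  Raises :class:`UnmappedCloneError` when no chain covers at least
    ``params.min_coverage`` of the clone.
    """
    params = params or MappingParams()
    ref = reference_window.upper()
    if len(ref) > params.max_window:
        raise ValueError(f"reference window exceeds {params.max_window} bp")

    candidates = []
    for strand, seq in (("+", clone.sequence), ("-", reverse_complement(clone.sequence))):
        res = _map_one_strand(seq, ref, params)
        if res is not None:
            blocks, mism = res
            covered = sum(b[1] - b[0] for b in blocks)
            candidates.append((covered - mism, strand, blocks, mism))
    if not candidates:
        raise UnmappedCloneError(f"{clone.clone_id}: no seed chain found")
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, strand, blocks, mism = candidates[0]

    covered = sum(b[1] - b[0] for b in blocks)
    if covered < params.min_coverage * len(clone.sequence):
        raise UnmappedCloneError(
            f"{clone.clone_id}: best chain covers {covered}/{len(clone.sequence)} bp"
        )

    offset = window_interval.start if window_interval else 0
    seq_id = window_interval.sequence_id if window_interval else "window"
    out_blocks = [
        AlignmentBlock(
            GenomicInterval(seq_id, offset + r0, offset + r1, "+"), q0, q1
        )
        for q0, q1, r0, r1 in blocks
    ]
    canonical = []
    for left, right in zip(blocks, blocks[1:]):
        il, ir = left[3], right[2]
        canonical.append(
            ir - il >= params.min_intron
            and ref[il : il + 2] == "GT"
            and ref[ir - 2 : ir] == "AG"
        )
    return SplicedAlignment(clone.clone_id, out_blocks, strand, mism, canonical)


# ---------------------------------------------------------------------------
# TSS selection and promoter definition
# ---------------------------------------------------------------------------

def clone_five_prime_end(aln: SplicedAlignment) -> int:
    """Reference coordinate of the clone's 5'-terminal base.

    A clone mapping to the minus strand of the window reads rightward-to-
    leftward, so its 5' end is the last base of the last block.
    """
    if aln.strand == "+":
        return aln.blocks[0].reference.start
    return aln.blocks[-1].reference.end - 1


def select_tss(
    alignments: list[SplicedAlignment], strand: str, gene_id: str = ""
) -> TssCall:
    """Pick the most upstream TSS among mapped clones of one gene.

    The TSS of each clone is its 5'-terminal reference coordinate; "most
    upstream" is the minimum on the plus strand and the maximum on the
    minus strand.  All clone 5' ends are retained in ``all_ends``.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    if any(a.strand != strand for a in alignments):
        raise ValueError("alignments mix strands")
    ends = [clone_five_prime_end(a) for a in alignments]
    pos = min(ends) if strand == "+" else max(ends)
    support = [a.clone_id for a, e in zip(alignments, ends) if e == pos]
    return TssCall(
        gene_id=gene_id,
        sequence_id=alignments[0].blocks[0].reference.sequence_id,
        position=pos,
        strand=strand,
        support=sorted(support),
        all_ends=sorted(ends),
    )


def define_promoter(
    tss: TssCall,
    genome_sequence: str,
    nominal_length: int = 301,
    sequence_offset: int = 0,
) -> PromoterWindow:
    """Define the putative minimal promoter: ``nominal_length`` bp (odd,
    default 301) centred on the TSS, reported on the plus strand.

    ``genome_sequence`` is the sequence of the reference the TSS coordinate
    refers to, starting at ``sequence_offset``.  Windows are clamped at
    sequence bounds and flagged ``truncated``.
    """
    if nominal_length % 2 == 0:
        raise ValueError("nominal_length must be odd (window centred on the TSS)")
    flank = (nominal_length - 1) // 2
    lo = tss.position - flank
    hi = tss.position + flank + 1
    start = max(lo, sequence_offset)
    end = min(hi, sequence_offset + len(genome_sequence))
    if end <= start:
        raise ValueError("TSS lies outside the supplied sequence")
    seq = genome_sequence[start - sequence_offset : end - sequence_offset].upper()
    return PromoterWindow(
        gene_id=tss.gene_id,
        interval=GenomicInterval(tss.sequence_id, start, end, "+"),
        sequence=seq,
        nominal_length=nominal_length,
        truncated=(start != lo or end != hi),
    )


# ---------------------------------------------------------------------------
# Riboprobe specificity
# ---------------------------------------------------------------------------

def _identity_best_local(probe: str, target: str, aligner: PairwiseAligner) -> float:
    aln = aligner.align(probe, target)
    if len(aln) == 0 or aln.score <= 0:
        return 0.0
    counts = aln[0].counts()
    # Homology is probe-wide: matched bases over the shorter of the two
    # sequences, not over local-alignment columns — the best local alignment
    # of unrelated DNA is a short near-perfect segment whose column identity
    # says nothing about cross-hybridisation over the probe's length.
    return counts.identities / min(len(probe), len(target))


def check_probe_specificity(
    probe: str,
    off_target_cds: list[str],
    max_identity: float = 0.75,
    ids: list[str] | None = None,
) -> tuple[bool, tuple[float, str] | None]:
    """Check a riboprobe against off-target coding sequences.

    Identity is matches / alignment columns (gaps included) of the best
    local alignment, on both strands; the probe passes when the worst-case
    identity does not exceed ``max_identity`` (default 0.75, the usual cap
    on homology with non-target OR genes).  Returns ``(pass, worst)`` with
    ``worst=None`` for an empty off-target set.
    """
    probe = probe.upper()
    if len(probe) < 100:
        raise ValueError("probe shorter than 100 bp")
    if not off_target_cds:
        return True, None
    if ids is None:
        ids = [f"offtarget_{i}" for i in range(len(off_target_cds))]

    aligner = PairwiseAligner(
        mode="local",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-2.0,
        extend_gap_score=-1.0,
    )
    worst_ident, worst_id = -1.0, ""
    for name, cds in zip(ids, off_target_cds):
        cds = cds.upper()
        ident = max(
            _identity_best_local(probe, cds, aligner),
            _identity_best_local(probe, reverse_complement(cds), aligner),
        )
        if ident > worst_ident:
            worst_ident, worst_id = ident, name
    return worst_ident <= max_identity, (worst_ident, worst_id)
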