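"""Classification of odorant-receptor (OR) genes as *solitary*.

Most OR genes sit in dense genomic clusters (mean intergenic spacing around
25 kb).  A gene is called *solitary* when no other OR gene lies within more
than 1 Mb of its transcript coordinates on either side.  The key per-gene
statistic is the MDAS (maximum distance as solitary): the width, in bp, of
the OR-free interval around the transcript, i.e. the smaller of the upstream
and downstream gaps to the nearest OR neighbours.

Conventions
-----------
* Intervals are 0-based, half-open ``[start, end)``.
* The gap between two transcripts is ``start(downstream) - end(upstream)``;
  overlapping transcripts have a non-positive gap and are never isolated
  from each other.
* The isolation test is strict (``gap > threshold``).
* A gene with no OR neighbour on one side (first/last on its sequence) uses
  the single defined gap for both the test and the MDAS; a gene alone on its
  sequence is solitary with MDAS reported as "alone".
* Upstream/downstream ordering of neighbours follows the sort order
  ``(start, end, gene_id)`` so that ties (identical coordinates) are broken
  deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "GeneRecord",
    "GeneAnnotationSet",
    "SolitaryCall",
    "SolitaryConfig",
    "OrthologMap",
    "classify_solitary",
    "solitary_summary",
    "conservation_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence_id:
            raise ValueError("sequence_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneRecord:
    """One OR transcript with its intact/pseudogene status."""

    gene_id: str
    symbol: str
    interval: GenomicInterval
    intact: bool = True


@dataclass
class GeneAnnotationSet:
    """Per-species OR transcript annotation."""

    species: str
    assembly: str
    genes: list[GeneRecord]
    sequence_lengths: dict[str, int] | None = None

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if self.sequence_lengths is not None:
                L = self.sequence_lengths.get(g.interval.sequence_id)
                if L is not None and g.interval.end > L:
                    raise ValueError(
                        f"{g.gene_id}: interval end {g.interval.end} exceeds "
                        f"declared length {L} of {g.interval.sequence_id}"
                    )


@dataclass
class SolitaryConfig:
    """Parameters of the isolation scan.

    isolation_threshold_bp
        A gene is solitary when both defined flanking gaps strictly exceed
        this distance.  Default 1,000,000 bp (1 Mb).
    include_pseudogenes_as_neighbors
        Whether pseudogenes break the isolation of nearby genes.
    report_pseudogene_calls
        Whether pseudogenes themselves receive a SolitaryCall.
    """

    isolation_threshold_bp: int = 1_000_000
    include_pseudogenes_as_neighbors: bool = True
    report_pseudogene_calls: bool = True

    def __post_init__(self) -> None:
        if self.isolation_threshold_bp <= 0:
            raise ValueError("isolation_threshold_bp must be > 0")


@dataclass
class SolitaryCall:
    """Isolation verdict for one gene.

    ``mdas_bp`` is None (and ``alone`` True) when the gene is the only OR
    gene on its sequence.  A flanking gap is None when there is no OR
    neighbour on that side.
    """

    gene_id: str
    solitary: bool
    mdas_bp: int | None
    alone: bool = False
    upstream_gap_bp: int | None = None
    downstream_gap_bp: int | None = None
    nearest_solitary_partner: str | None = None
    partner_distance_bp: int | None = None

    @property
    def mdas_mb(self) -> float | None:
        """MDAS in Mb rounded to one decimal, as conventionally reported."""
        if self.mdas_bp is None:
            return None
        return round(self.mdas_bp / 1e6, 1)


@dataclass
class OrthologGroup:
    group_id: str
    members: list[tuple[str, str]]  # (species, gene_id)


@dataclass
class OrthologMap:
    groups: list[OrthologGroup]
    source: str = "OGG"

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for grp in self.groups:
            for member in grp.members:
                if member in seen:
                    raise ValueError(
                        f"{member} appears in more than one group of {self.source}"
                    )
                seen.add(member)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _sort_key(g: GeneRecord) -> tuple[int, int, str]:
    return (g.interval.start, g.interval.end, g.gene_id)


def classify_solitary(
    annotation: GeneAnnotationSet,
    config: SolitaryConfig | None = None,
) -> list[SolitaryCall]:
    """Classify every OR gene of ``annotation`` by genomic isolation.

    Returns one :class:`SolitaryCall` per gene (pseudogenes included or not
    per ``config.report_pseudogene_calls``), in the annotation's gene order.
    """
    config = config or SolitaryConfig()
    if not annotation.genes:
        raise ValueError("annotation contains no genes")
    annotation.validate()
    thr = config.isolation_threshold_bp

    by_seq: dict[str, list[GeneRecord]] = {}
    for g in annotation.genes:
        by_seq.setdefault(g.interval.sequence_id, []).append(g)

    calls: dict[str, SolitaryCall] = {}
    for seq_id, genes in by_seq.items():
        order = sorted(genes, key=_sort_key)
        neighbor_ok = [
            g.intact or config.include_pseudogenes_as_neighbors for g in order
        ]
        n = len(order)
        # prefix max of transcript ends over admissible upstream neighbours
        prev_end: list[int | None] = [None] * n
        best: int | None = None
        for i, g in enumerate(order):
            prev_end[i] = best
            if neighbor_ok[i]:
                best = g.interval.end if best is None else max(best, g.interval.end)
        next_start: list[int | None] = [None] * n
        best = None
        for i in range(n - 1, -1, -1):
            next_start[i] = best
            if neighbor_ok[i]:
                s = order[i].interval.start
                best = s if best is None else min(best, s)

        for i, g in enumerate(order):
            up = None if prev_end[i] is None else g.interval.start - prev_end[i]
            down = None if next_start[i] is None else next_start[i] - g.interval.end
            if up is None and down is None:
                call = SolitaryCall(g.gene_id, solitary=True, mdas_bp=None, alone=True)
            else:
                gaps = [x for x in (up, down) if x is not None]
                call = SolitaryCall(
                    g.gene_id,
                    solitary=all(x > thr for x in gaps),
                    mdas_bp=min(gaps),
                    upstream_gap_bp=up,
                    downstream_gap_bp=down,
                )
            calls[g.gene_id] = call

    _annotate_partners(calls, by_seq)

    intact = {g.gene_id: g.intact for g in annotation.genes}
    return [
        calls[g.gene_id]
        for g in annotation.genes
        if intact[g.gene_id] or config.report_pseudogene_calls
    ]


def _annotate_partners(
    calls: Mapping[str, SolitaryCall], by_seq: Mapping[str, list[GeneRecord]]
) -> None:
    """Attach, to each solitary gene, its nearest solitary gene on the same
    sequence (outer-gap distance), mirroring reported solitary-gene pairs."""
    for seq_id, genes in by_seq.items():
        sol = sorted(
            (g for g in genes if calls[g.gene_id].solitary), key=_sort_key
        )
        for i, g in enumerate(sol):
            best_id, best_d = None, None
            for j, h in enumerate(sol):
                if i == j:
                    continue
                d = max(
                    g.interval.start - h.interval.end,
                    h.interval.start - g.interval.end,
                )
                if best_d is None or d < best_d or (d == best_d and h.gene_id < best_id):
                    best_id, best_d = h.gene_id, d
            calls[g.gene_id].nearest_solitary_partner = best_id
            calls[g.gene_id].partner_distance_bp = best_d


# ---------------------------------------------------------------------------
# Summaries and cross-species conservation
# ---------------------------------------------------------------------------

@dataclass
class SolitarySummary:
    n_genes: int
    n_solitary: int
    n_intact_solitary: int
    n_solitary_pseudogenes: int
    per_sequence: dict[str, int]
    mdas_mb: dict[str, float | None]
    most_isolated: str | None


def solitary_summary(
    calls: Sequence[SolitaryCall], annotation: GeneAnnotationSet
) -> SolitarySummary:
    """Tabulate solitary calls: intact/pseudogene counts, per-sequence
    distribution, MDAS in Mb (1 decimal) and the most isolated gene."""
    info = {g.gene_id: g for g in annotation.genes}
    sol = [c for c in calls if c.solitary]
    per_seq: dict[str, int] = {}
    for c in sol:
        seq = info[c.gene_id].interval.sequence_id
        per_seq[seq] = per_seq.get(seq, 0) + 1
    with_mdas = [c for c in sol if c.mdas_bp is not None]
    most = max(with_mdas, key=lambda c: c.mdas_bp).gene_id if with_mdas else None
    return SolitarySummary(
        n_genes=len(calls),
        n_solitary=len(sol),
        n_intact_solitary=sum(1 for c in sol if info[c.gene_id].intact),
        n_solitary_pseudogenes=sum(1 for c in sol if not info[c.gene_id].intact),
        per_sequence=per_seq,
        mdas_mb={c.gene_id: c.mdas_mb for c in sol},
        most_isolated=most,
    )


@dataclass
class ConservationRow:
    focal_gene: str
    focal_mdas_mb: float | None
    species: str
    ortholog: str
    ortholog_mdas_mb: float | None
    ortholog_solitary: bool
    near_solitary: bool


def conservation_table(
    focal_calls: Sequence[SolitaryCall],
    other_species_calls: Mapping[str, Sequence[SolitaryCall]],
    ortholog_map: OrthologMap,
    near_solitary_floor_bp: int = 500_000,
) -> list[ConservationRow]:
    """Cross-species conservation of the solitary status.

    For each focal solitary gene, list orthologs (per ``ortholog_map``) in
    other species that are themselves solitary, with their MDAS.  Orthologs
    that miss the threshold but are still isolated beyond
    ``near_solitary_floor_bp`` are reported with ``near_solitary=True``
    (e.g. a 0.6 Mb-isolated rat ortholog of an otherwise unmatched gene).
    """
    ortholog_map.validate()
    focal = {c.gene_id: c for c in focal_calls}
    others = {sp: {c.gene_id: c for c in cs} for sp, cs in other_species_calls.items()}

    rows: list[ConservationRow] = []
    for grp in ortholog_map.groups:
        focal_members = [g for sp, g in grp.members if g in focal and focal[g].solitary]
        for fg in focal_members:
            for sp, g in grp.members:
                if g == fg or g in focal:
                    continue
                if sp not in others:
                    raise ValueError(f"no solitary calls supplied for species {sp!r}")
                call = others[sp].get(g)
                if call is None:
                    continue
                isolated_enough = call.alone or (
                    call.mdas_bp is not None and call.mdas_bp > near_solitary_floor_bp
                )
                if not isolated_enough:
                    continue
                rows.append(
                    ConservationRow(
                        focal_gene=fg,
                        focal_mdas_mb=focal[fg].mdas_mb,
                        species=sp,
                        ortholog=g,
                        ortholog_mdas_mb=call.mdas_mb,
                        ortholog_solitary=call.solitary,
                        near_solitary=not call.solitary,
                    )
                )
    rows.sort(key=lambda r: (r.focal_gene, r.species, r.ortholog))
    return rows
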