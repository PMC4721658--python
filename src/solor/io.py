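"""Readers and writers for the formats the pipeline consumes and emits.

Annotations come in as BED6 or GFF3 (converted to the internal 0-based
half-open convention on read; BED passes through), sequences as FASTA,
tables as TSV.  Motifs are written in MEME minimal format, trees as
Newick, distance matrices in square PHYLIP layout.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alleles import AllelePanel, LAB_GROUP, MultiAlignment, REFERENCE_GROUP
from .motifs import MotifHit, PositionWeightMatrix
from .phylo import DistanceMatrix
from .race import RaceClone
from .solitary import (
    ConservationRow,
    GeneAnnotationSet,
    GeneRecord,
    GenomicInterval,
    SolitaryCall,
)

__all__ = [
    "read_annotation",
    "read_chrom_sizes",
    "write_solitary_calls",
    "write_conservation_table",
    "read_fasta",
    "write_fasta",
    "read_race_clones",
    "read_allele_panel",
    "write_meme_motif",
    "read_meme_motif",
    "write_motif_hits",
    "write_phylip_matrix",
    "write_ranking",
]

_PSEUDO_RE = re.compile(r"-ps\d*$")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["seq", "length"])
    return dict(zip(df["seq"], df["length"].astype(int)))


def _read_bed(path: str | Path) -> list[GeneRecord]:
    import pyranges as pr

    df = pr.read_bed(str(path)).df
    genes = []
    for row in df.itertuples(index=False):
        name = getattr(row, "Name", None) or f"{row.Chromosome}:{row.Start}-{row.End}"
        strand = getattr(row, "Strand", "+")
        genes.append(
            GeneRecord(
                gene_id=str(name),
                symbol=str(name),
                interval=GenomicInterval(
                    str(row.Chromosome), int(row.Start), int(row.End),
                    strand if strand in "+-" else "+",
                ),
                intact=_PSEUDO_RE.search(str(name)) is None,
            )
        )
    return genes


def _read_gff3(
    path: str | Path,
    feature_types: tuple[str, ...] = ("transcript", "mRNA", "gene"),
    gene_id_attr: str = "gene_id",
    biotype_attr: str = "biotype",
) -> list[GeneRecord]:
    import pyranges as pr

    df = pr.read_gff3(str(path)).df  # pyranges converts to 0-based half-open
    df = df[df["Feature"].isin(feature_types)]
    genes = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gid = (
            getattr(row, gene_id_attr, None)
            or getattr(row, "ID", None)
            or getattr(row, "Name", None)
        )
        if gid is None or (isinstance(gid, float)) or gid in seen:
            continue
        gid = str(gid)
        seen.add(gid)
        biotype = str(getattr(row, biotype_attr, "") or "protein_coding")
        strand = getattr(row, "Strand", "+")
        genes.append(
            GeneRecord(
                gene_id=gid,
                symbol=str(getattr(row, "Name", None) or gid),
                interval=GenomicInterval(
                    str(row.Chromosome), int(row.Start), int(row.End),
                    strand if strand in "+-" else "+",
                ),
                intact="pseudogene" not in biotype,
            )
        )
    return genes


def read_annotation(
    path: str | Path,
    species: str = "unknown",
    assembly: str = "unknown",
    chrom_sizes: str | Path | None = None,
    **gff_kwargs,
) -> GeneAnnotationSet:
    """Read OR transcript annotation from BED6 or GFF3 (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        genes = _read_gff3(path, **gff_kwargs)
    else:
        genes = _read_bed(path)
    sizes = read_chrom_sizes(chrom_sizes) if chrom_sizes else None
    ann = GeneAnnotationSet(species, assembly, genes, sizes)
    ann.validate()
    return ann


def write_annotation_bed(annotation: GeneAnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            iv = g.interval
            fh.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n"
            )


def write_solitary_calls(
    calls: Iterable[SolitaryCall],
    annotation: GeneAnnotationSet,
    path: str | Path,
) -> None:
    info = {g.gene_id: g for g in annotation.genes}
    rows = []
    for c in calls:
        iv = info[c.gene_id].interval
        rows.append(
            {
                "gene_id": c.gene_id,
                "sequence_id": iv.sequence_id,
                "start": iv.start,
                "end": iv.end,
                "intact": info[c.gene_id].intact,
                "solitary": c.solitary,
                "mdas_bp": "alone" if c.alone else c.mdas_bp,
                "mdas_mb": "alone" if c.alone else f"{c.mdas_mb:.1f}",
                "upstream_gap_bp": c.upstream_gap_bp,
                "downstream_gap_bp": c.downstream_gap_bp,
                "nearest_solitary_partner": c.nearest_solitary_partner,
                "partner_distance_bp": c.partner_distance_bp,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_conservation_table(rows: Iterable[ConservationRow], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in rows]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_race_clones(path: str | Path) -> list[RaceClone]:
    """RACE clone FASTA with headers of the form ``>12 WOM Olfr266`` (clone
    number, sample kind, gene name)."""
    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        source = tokens[1] if len(tokens) > 1 else "WOM"
        gene = tokens[2] if len(tokens) > 2 else ""
        clones.append(
            RaceClone(
                clone_id=f"{gene}_{source}_{tokens[0]}" if gene else rec.id,
                sequence=str(rec.seq).upper(),
                source="OSN" if source.upper().startswith("OSN") else "WOM",
                gene_id=gene,
            )
        )
    return clones


def infer_panel_group(allele_id: str) -> str:
    """Heuristic group from an allele header token.

    C57BL-style ids map to the reference, population names to their wild
    group, anything else to a laboratory strain; an all-population
    consensus row ("Wild_consensus") is tagged separately and excluded from
    classification.
    """
    token = allele_id.lower()
    if "c57bl" in token:
        return REFERENCE_GROUP
    for pop in ("France", "Germany", "Iran"):
        if pop.lower() in token:
            return f"wild:{pop}"
    if "wild_consensus" in token or token == "w":
        return "wild_consensus"
    return LAB_GROUP


def read_allele_panel(
    path: str | Path,
    gene_id: str | None = None,
    groups_tsv: str | Path | None = None,
) -> AllelePanel:
    """Multi-FASTA allele panel; groups inferred from headers, overridable
    via a two-column TSV (allele_id, group)."""
    seqs = read_fasta(path)
    overrides: dict[str, str] = {}
    if groups_tsv:
        with open(groups_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) >= 2:
                    overrides[row[0]] = row[1]
    groups = {aid: overrides.get(aid, infer_panel_group(aid)) for aid in seqs}
    consensus_rows = [a for a, g in groups.items() if g == "wild_consensus"]
    for a in consensus_rows:
        seqs.pop(a)
        groups.pop(a)
    refs = [a for a, g in groups.items() if g == REFERENCE_GROUP]
    if len(refs) != 1:
        raise ValueError(f"panel must contain exactly one reference allele, got {refs}")
    return AllelePanel(
        gene_id=gene_id or Path(path).stem,
        reference_id=refs[0],
        sequences=seqs,
        groups=groups,
    )


def write_alignment_fasta(alignment: MultiAlignment, path: str | Path) -> None:
    write_fasta(alignment.rows, path)


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def write_meme_motif(pswm: PositionWeightMatrix, path: str | Path) -> None:
    """MEME minimal motif format."""
    bg = pswm.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        fh.write(f"MOTIF {pswm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pswm.width} "
            f"nsites= {pswm.n_sites} E= 0\n"
        )
        for row in pswm.frequencies:
            fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")


def read_meme_motif(path: str | Path) -> PositionWeightMatrix:
    """Read back a minimal MEME motif (frequencies; counts reconstructed
    from nsites)."""
    lines = Path(path).read_text().splitlines()
    bg = np.full(4, 0.25)
    name = "motif"
    nsites = 0
    freqs: list[list[float]] = []
    in_matrix = False
    for i, line in enumerate(lines):
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            bg = np.array([float(toks[j]) for j in (1, 3, 5, 7)])
        elif line.startswith("MOTIF"):
            name = line.split()[1]
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"nsites=\s*(\d+)", line)
            nsites = int(m.group(1)) if m else 1
            in_matrix = True
        elif in_matrix:
            toks = line.split()
            if len(toks) == 4:
                freqs.append([float(t) for t in toks])
            else:
                in_matrix = False
    f = np.array(freqs)
    with np.errstate(divide="ignore"):
        lo = np.log2(f / bg)
    return PositionWeightMatrix(
        counts=f * nsites,
        frequencies=f,
        log_odds=lo,
        background=bg,
        pseudocount=0.0,
        n_sites=nsites,
        name=name,
    )


def write_motif_hits(hits: Iterable[MotifHit], path: str | Path, width: int) -> None:
    """FIMO-style hit table (1-based inclusive coordinates)."""
    rows = [
        {
            "sequence_name": h.sequence_id,
            "start": h.start + 1,
            "stop": h.start + width,
            "strand": h.strand,
            "score": f"{h.score:.4f}",
            "p-value": f"{h.p_value:.3g}",
            "matched_sequence": h.matched,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sequence_name", "start", "stop", "strand", "score",
            "p-value", "matched_sequence",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distances, trees, rankings
# ---------------------------------------------------------------------------

def write_phylip_matrix(matrix: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.ids)}\n")
        for i, name in enumerate(matrix.ids):
            vals = " ".join(f"{x:.6f}" for x in matrix.values[i])
            fh.write(f"{name:<12s} {vals}\n")


def write_ranking(scores, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rank": i + 1,
                "gene_id": s.gene_id,
                "mean_pairwise_tn93": f"{s.mean_pairwise_distance:.6f}",
                "n_pairs": s.n_pairs,
            }
            for i, s in enumerate(scores)
        ]
    ).to_csv(path, sep="\t", index=False)
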