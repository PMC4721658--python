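"""Synthetic inputs with planted truth for every analysis stage.

Each generator is a pure function of its configuration (seed included) and
returns both the data and the planted ground truth, so the downstream
operation can be checked for exact recovery in the noise-free limit.

The defaults emulate the biological setting the analyses assume: an OR
repertoire of roughly 1100 genes arranged in about 50 genomic clusters with
~25 kb intergenic spacing, 8 planted intact solitary genes plus 3 solitary
pseudogenes; 301-bp promoter allele panels with a C57BL/6J reference, three
wild populations of 8 alleles each and 36 laboratory strains; RACE clones
as adapter-prefixed spliced transcript 5' fragments; over-dispersed
(negative binomial) neuron counts for 8 genes in 3 animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alleles import AllelePanel, LAB_GROUP, REFERENCE_GROUP, WILD_GROUPS
from .solitary import GeneAnnotationSet, GeneRecord, GenomicInterval

__all__ = [
    "SyntheticGenomeConfig",
    "SyntheticPanelConfig",
    "SyntheticCountConfig",
    "GeneModel",
    "generate_or_annotation",
    "generate_promoter_panel",
    "generate_gene_model",
    "generate_race_clones",
    "generate_cell_counts",
]

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


# ---------------------------------------------------------------------------
# OR annotation with planted solitary genes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenomeConfig:
    n_chromosomes: int = 19
    chromosome_length: int = 120_000_000
    n_clusters: int = 50
    cluster_size_range: tuple[int, int] = (5, 40)
    intra_cluster_gap: int = 25_000
    n_planted_solitary: int = 8
    n_planted_solitary_pseudogenes: int = 3
    planted_mdas_range: tuple[int, int] = (1_200_000, 45_000_000)
    cluster_pseudogene_fraction: float = 0.25
    n_alone_scaffolds: int = 0
    gene_length_range: tuple[int, int] = (900, 3_000)
    seed: int = 0


@dataclass
class PlantedSolitary:
    gene_id: str
    mdas_bp: int | None  # None = alone on its sequence
    alone: bool
    intact: bool


def generate_or_annotation(
    config: SyntheticGenomeConfig | None = None,
) -> tuple[GeneAnnotationSet, list[PlantedSolitary]]:
    """Synthetic OR annotation: clustered genes plus planted solitary genes.

    The planted truth records exactly which genes are solitary and their
    true MDAS, derived from the placement arithmetic (not from any
    classifier).  Raises when the requested features cannot be placed on
    the configured chromosomes.
    """
    cfg = config or SyntheticGenomeConfig()
    rng = np.random.default_rng(cfg.seed)
    threshold = 1_000_000  # planted genes are isolated beyond the 1 Mb bar

    if cfg.cluster_size_range[0] < 2:
        raise ValueError("clusters need >= 2 genes (singletons would be solitary)")

    # Build the feature list: clusters and solitary genes, then shuffle.
    features: list[dict] = []
    for c in range(cfg.n_clusters):
        size = int(rng.integers(cfg.cluster_size_range[0], cfg.cluster_size_range[1] + 1))
        features.append({"kind": "cluster", "size": size, "id": c})
    n_sol = cfg.n_planted_solitary + cfg.n_planted_solitary_pseudogenes
    for s in range(n_sol):
        mdas = int(rng.integers(*cfg.planted_mdas_range))
        features.append(
            {
                "kind": "solitary",
                "id": s,
                "mdas": mdas,
                "slack": int(rng.integers(200_000, 2_000_000)),
                "intact": s < cfg.n_planted_solitary,
            }
        )
    rng.shuffle(features)

    def glen() -> int:
        return int(rng.integers(*cfg.gene_length_range))

    inter_cluster = lambda: int(rng.integers(1_500_000, 4_000_000))

    genes: list[GeneRecord] = []
    truth: list[PlantedSolitary] = []
    seq_lengths: dict[str, int] = {
        f"chr{i + 1}": cfg.chromosome_length for i in range(cfg.n_chromosomes)
    }

    chrom = 0
    cursor = int(rng.integers(2_000_000, 4_000_000))
    prev_feature: dict | None = None
    gene_counter = 0
    placements: list[tuple[dict, list[GeneRecord], str]] = []

    def next_chromosome() -> None:
        nonlocal chrom, cursor, prev_feature
        chrom += 1
        cursor = int(rng.integers(2_000_000, 4_000_000))
        prev_feature = None

    for feat in features:
        while True:
            if chrom >= cfg.n_chromosomes:
                raise ValueError("features do not fit on the configured chromosomes")
            # required gap to the previous feature on this chromosome
            gap = 0
            if prev_feature is not None:
                gap = inter_cluster()
                if prev_feature["kind"] == "solitary":
                    gap = max(gap, prev_feature["mdas"] + prev_feature["slack"])
                if feat["kind"] == "solitary":
                    gap = max(gap, feat["mdas"]) if prev_feature[
                        "kind"
                    ] != "solitary" else max(gap, feat["mdas"])
            elif feat["kind"] == "solitary":
                # first feature: upstream side is chromosome start (no OR
                # neighbour), keep some margin
                gap = 0
            # estimated span
            if feat["kind"] == "cluster":
                span = feat["size"] * (
                    cfg.gene_length_range[1] + cfg.intra_cluster_gap
                )
            else:
                span = cfg.gene_length_range[1] + feat["mdas"] + feat["slack"]
            if cursor + gap + span + 1_000_000 > cfg.chromosome_length:
                next_chromosome()
                continue
            break

        start = cursor + gap
        seq = f"chr{chrom + 1}"
        placed: list[GeneRecord] = []
        if feat["kind"] == "cluster":
            pos = start
            for k in range(feat["size"]):
                L = glen()
                intact = bool(rng.random() >= cfg.cluster_pseudogene_fraction)
                gid = f"OrC{feat['id']:02d}g{k:02d}" + ("" if intact else "-ps1")
                placed.append(
                    GeneRecord(gid, gid, GenomicInterval(seq, pos, pos + L), intact)
                )
                pos += L + int(
                    max(5_000, rng.normal(cfg.intra_cluster_gap, 5_000))
                )
            cursor = placed[-1].interval.end
        else:
            L = glen()
            gid = ("OrSol" if feat["intact"] else "OrSol-ps") + f"{feat['id']:02d}"
            placed.append(
                GeneRecord(gid, gid, GenomicInterval(seq, start, start + L), feat["intact"])
            )
            cursor = start + L
        gene_counter += len(placed)
        placements.append((feat, placed, seq))
        prev_feature = feat | {"end": cursor}

    # derive planted truth from the placement coordinates
    by_seq: dict[str, list[GeneRecord]] = {}
    for _, placed, seq in placements:
        by_seq.setdefault(seq, []).extend(placed)
    for feat, placed, seq in placements:
        if feat["kind"] != "solitary":
            continue
        g = placed[0]
        order = sorted(by_seq[seq], key=lambda x: x.interval.start)
        i = order.index(g)
        up = g.interval.start - order[i - 1].interval.end if i > 0 else None
        down = (
            order[i + 1].interval.start - g.interval.end
            if i + 1 < len(order)
            else None
        )
        gaps = [x for x in (up, down) if x is not None]
        truth.append(
            PlantedSolitary(
                g.gene_id,
                mdas_bp=min(gaps) if gaps else None,
                alone=not gaps,
                intact=feat["intact"],
            )
        )

    # optional scaffolds carrying one OR gene each ("alone" cases)
    for s in range(cfg.n_alone_scaffolds):
        seq = f"scaffold_{s + 1}"
        seq_lengths[seq] = 9_000_000
        L = glen()
        start = int(rng.integers(1_000_000, 5_000_000))
        gid = f"OrScaf{s:02d}"
        by_seq.setdefault(seq, []).append(
            GeneRecord(gid, gid, GenomicInterval(seq, start, start + L), True)
        )
        truth.append(PlantedSolitary(gid, mdas_bp=None, alone=True, intact=True))

    genes = [g for seq in sorted(by_seq) for g in sorted(by_seq[seq], key=lambda x: x.interval.start)]
    ann = GeneAnnotationSet("synthetic", "synth1", genes, seq_lengths)
    ann.validate()
    # sanity: planted solitary genes really are beyond the threshold
    for t in truth:
        if t.mdas_bp is not None and t.mdas_bp <= threshold:
            raise AssertionError("planted solitary gene not isolated enough")
    return ann, truth


# ---------------------------------------------------------------------------
# Promoter allele panels with planted variation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPanelConfig:
    promoter_length: int = 301
    n_wild_per_population: int = 8
    n_lab_strains: int = 36
    substitution_rate: float = 0.0005  # background, per site per allele
    planted_mutant_sites: int = 0  # all wild alleles share an alt base
    planted_lab_variant_sites: int = 0  # one lab strain differs
    planted_population_mismatches: dict[str, int] = field(default_factory=dict)
    indel_rate: float = 0.0
    gene_id: str = "gene"
    seed: int = 0


@dataclass
class PlantedPanelTruth:
    mutant_positions: list[int]
    polymorphic_positions: list[int]
    per_population_mismatch: dict[str, int]


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def generate_promoter_panel(
    config: SyntheticPanelConfig | None = None,
) -> tuple[AllelePanel, PlantedPanelTruth]:
    """Allele panel with planted mutant / polymorphic / population patterns.

    * mutant sites: every wild allele carries the same alternative base
      (the reference keeps its own) — the all-wild-differ pattern;
    * lab variant sites: a single laboratory strain differs — the
      polymorphic-only pattern;
    * per-population mismatches: every allele of one population carries the
      same alternative base, so that population's consensus differs from
      the reference at exactly that many columns (mutant sites add to every
      population's total).

    The planted truth is exact when background rates are zero; background
    substitutions/indels may add further polymorphic columns.
    """
    cfg = config or SyntheticPanelConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.promoter_length
    n_planted = (
        cfg.planted_mutant_sites
        + cfg.planted_lab_variant_sites
        + sum(cfg.planted_population_mismatches.values())
    )
    if n_planted > L:
        raise ValueError("more planted sites than promoter positions")

    ref = random_dna(rng, L)
    pops = [g.split(":", 1)[1] for g in WILD_GROUPS]
    for p in cfg.planted_population_mismatches:
        if p not in pops:
            raise ValueError(f"unknown population {p!r}")

    sites = rng.choice(L, size=n_planted, replace=False)
    pos_iter = iter(int(x) for x in sites)
    mutant_pos = [next(pos_iter) for _ in range(cfg.planted_mutant_sites)]
    lab_pos = [next(pos_iter) for _ in range(cfg.planted_lab_variant_sites)]
    pop_pos = {
        p: [next(pos_iter) for _ in range(k)]
        for p, k in cfg.planted_population_mismatches.items()
    }

    sequences: dict[str, str] = {"C57BL6J": ref}
    groups: dict[str, str] = {"C57BL6J": REFERENCE_GROUP}

    mutant_alt = {i: _mutate_base(rng, ref[i]) for i in mutant_pos}
    pop_alt = {
        p: {i: _mutate_base(rng, ref[i]) for i in positions}
        for p, positions in pop_pos.items()
    }

    def background(seq: list[str]) -> list[str]:
        if cfg.substitution_rate > 0:
            hits = np.nonzero(rng.random(L) < cfg.substitution_rate)[0]
            for i in hits:
                seq[i] = _mutate_base(rng, seq[i])
        if cfg.indel_rate > 0:
            # single-base deletions only; keeps planted columns addressable
            keep = rng.random(len(seq)) >= cfg.indel_rate
            seq = [c for c, k in zip(seq, keep) if k]
        return seq

    for pop in pops:
        for w in range(cfg.n_wild_per_population):
            s = list(ref)
            for i, alt in mutant_alt.items():
                s[i] = alt
            for i, alt in pop_alt.get(pop, {}).items():
                s[i] = alt
            s = background(s)
            aid = f"{pop}_{w + 1:02d}"
            sequences[aid] = "".join(s)
            groups[aid] = f"wild:{pop}"

    variant_strain = int(rng.integers(cfg.n_lab_strains)) if cfg.n_lab_strains else 0
    for t in range(cfg.n_lab_strains):
        s = list(ref)
        if t == variant_strain:
            for i in lab_pos:
                s[i] = _mutate_base(rng, ref[i])
        s = background(s)
        aid = f"strain_{t + 1:02d}"
        sequences[aid] = "".join(s)
        groups[aid] = LAB_GROUP

    panel = AllelePanel(cfg.gene_id, "C57BL6J", sequences, groups)
    per_pop = {
        p: len(pop_pos.get(p, [])) + cfg.planted_mutant_sites for p in pops
    }
    truth = PlantedPanelTruth(
        mutant_positions=sorted(mutant_pos),
        polymorphic_positions=sorted(mutant_pos + lab_pos + [i for v in pop_pos.values() for i in v]),
        per_population_mismatch=per_pop,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# RACE clones from a known gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A reference window with exon blocks (window coordinates), a set of
    alternative TSS positions inside the first exon, and a strand."""

    window: str
    exons: list[tuple[int, int]]
    tss_positions: list[int]
    strand: str = "+"

    @property
    def most_upstream_tss(self) -> int:
        return min(self.tss_positions) if self.strand == "+" else max(self.tss_positions)


def generate_gene_model(
    rng: np.random.Generator,
    window_length: int = 6_000,
    n_exons: int | None = None,
    n_tss: int = 3,
    strand: str = "+",
    min_exon: int = 60,
) -> GeneModel:
    """Random gene model on a random window, introns flanked by GT..AG."""
    n_exons = n_exons or int(rng.integers(2, 4))
    w = list(random_dna(rng, window_length))
    margin = 400
    usable = window_length - 2 * margin
    exon_lens = rng.integers(min_exon, 300, n_exons)
    intron_lens = rng.integers(80, 400, n_exons - 1)
    need = int(exon_lens.sum() + intron_lens.sum())
    if need > usable:
        raise ValueError("window too small for the requested structure")
    start = margin + int(rng.integers(0, usable - need + 1))
    exons: list[tuple[int, int]] = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < n_exons - 1:
            il = int(intron_lens[i])
            w[pos] = "G"
            w[pos + 1] = "T"
            w[pos + il - 2] = "A"
            w[pos + il - 1] = "G"
            pos += il
    e0, e1 = exons[0]
    # alternative TSSs inside the first exon, keeping >= min_exon of exon 1
    picks = sorted(set(int(x) for x in rng.integers(e0, e1 - min_exon + 1, n_tss)))
    tss = picks if picks else [e0]
    window = "".join(w)
    if strand == "-":
        from Bio.Seq import reverse_complement

        L = window_length
        window = reverse_complement(window)
        exons = [(L - b, L - a) for a, b in reversed(exons)]
        tss = [L - 1 - t for t in tss]
    return GeneModel(window, exons, tss, strand)


def generate_race_clones(
    model: GeneModel,
    n_clones: int = 8,
    error_rate: float = 0.0,
    adapter: str = "AAGCAGTGGTATCAACGCAGAGT",
    seed: int = 0,
    min_insert: int = 80,
) -> list[tuple[str, str]]:
    """(clone_id, raw sequence) pairs: adapter + spliced 5' fragment.

    Each clone starts at a sampled TSS and extends a random distance into
    the spliced transcript; per-base substitution errors at ``error_rate``.
    Clone sequences read in mRNA sense (5'->3').
    """
    rng = np.random.default_rng(seed)
    from Bio.Seq import reverse_complement

    window = model.window
    if model.strand == "-":
        # work in transcript orientation: flip the window and coordinates
        L = len(window)
        window = reverse_complement(window)
        exons = [(L - b, L - a) for a, b in reversed(model.exons)]
        tss_positions = sorted(L - 1 - t for t in model.tss_positions)
    else:
        exons = model.exons
        tss_positions = model.tss_positions

    clones = []
    for i in range(n_clones):
        # every planted TSS is sampled at least once when n_clones allows,
        # so the most upstream TSS is always represented
        if i < len(tss_positions):
            t = int(tss_positions[i])
        else:
            t = int(rng.choice(tss_positions))
        parts = []
        for a, b in exons:
            if b <= t:
                continue
            parts.append(window[max(a, t) : b])
        transcript = "".join(parts)
        take = int(rng.integers(min_insert, len(transcript) + 1))
        insert = list(transcript[:take])
        if error_rate > 0:
            hits = np.nonzero(rng.random(len(insert)) < error_rate)[0]
            for j in hits:
                insert[j] = _mutate_base(rng, insert[j])
        clones.append((f"clone_{i + 1:02d}", adapter + "".join(insert)))
    return clones


# ---------------------------------------------------------------------------
# Cell counts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCountConfig:
    n_genes: int = 8
    n_animals: int = 3
    mean_range: tuple[float, float] = (100.0, 2_100.0)
    dispersion: float = 10.0  # negative-binomial size; larger = tighter
    per_gene_dispersion_range: tuple[float, float] | None = (2.0, 5_000.0)
    seed: int = 0


def generate_cell_counts(
    config: SyntheticCountConfig | None = None,
) -> tuple[dict[str, list[int]], dict[str, float]]:
    """Over-dispersed per-animal totals; truth = the generating means.

    Counts are negative binomial with per-gene mean drawn from
    ``mean_range`` and per-gene size parameter drawn log-uniformly from
    ``per_gene_dispersion_range`` (heterogeneous dispersion produces the
    broad CV spread seen across OR genes); a fixed ``dispersion`` is used
    when the range is None.
    """
    cfg = config or SyntheticCountConfig()
    rng = np.random.default_rng(cfg.seed)
    counts: dict[str, list[int]] = {}
    means: dict[str, float] = {}
    for g in range(cfg.n_genes):
        m = float(rng.uniform(*cfg.mean_range))
        if cfg.per_gene_dispersion_range is not None:
            lo, hi = cfg.per_gene_dispersion_range
            k = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            k = cfg.dispersion
        p = k / (k + m)
        gid = f"gene_{g + 1:02d}"
        counts[gid] = [int(x) for x in rng.negative_binomial(k, p, cfg.n_animals)]
        means[gid] = m
    return counts, means
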