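import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20160121)


def make_annotation(genes, species="test", assembly="t1", sequence_lengths=None):
    """Build a GeneAnnotationSet from (gene_id, seq, start, end[, intact])."""
    from solor.solitary import GeneAnnotationSet, GeneRecord, GenomicInterval

    records = []
    for g in genes:
        gid, seq, start, end = g[:4]
        intact = g[4] if len(g) > 4 else True
        records.append(
            GeneRecord(gid, gid, GenomicInterval(seq, start, end), intact)
        )
    return GeneAnnotationSet(species, assembly, records, sequence_lengths)


def brute_force_solitary(annotation, threshold_bp=1_000_000, include_pseudo=True):
    """Independent all-pairs isolation oracle.

    For every gene, every other admissible gene on the same sequence is
    assigned to a side by (start, end, gene_id) order and the minimal gap
    per side is taken; no sorting/prefix tricks shared with the
    implementation.
    """
    out = {}
    genes = annotation.genes
    for g in genes:
        key_g = (g.interval.start, g.interval.end, g.gene_id)
        up, down = None, None
        for h in genes:
            if h.gene_id == g.gene_id:
                continue
            if h.interval.sequence_id != g.interval.sequence_id:
                continue
            if not (h.intact or include_pseudo):
                continue
            key_h = (h.interval.start, h.interval.end, h.gene_id)
            if key_h < key_g:
                gap = g.interval.start - h.interval.end
                up = gap if up is None else min(up, gap)
            else:
                gap = h.interval.start - g.interval.end
                down = gap if down is None else min(down, gap)
        if up is None and down is None:
            out[g.gene_id] = (True, None, True)
        else:
            gaps = [x for x in (up, down) if x is not None]
            out[g.gene_id] = (all(x > threshold_bp for x in gaps), min(gaps), False)
    return out


def random_annotation(rng, max_genes=200, n_seqs=5):
    """Random gene placements, including overlapping and tied intervals."""
    n = int(rng.integers(2, max_genes + 1))
    genes = []
    for i in range(n):
        seq = f"chr{int(rng.integers(1, n_seqs + 1))}"
        start = int(rng.integers(0, 50_000_000))
        length = int(rng.integers(500, 5_000))
        intact = bool(rng.random() > 0.2)
        genes.append((f"g{i:04d}", seq, start, start + length, intact))
    return make_annotation(genes)
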