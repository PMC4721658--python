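"""Allele panels: progressive MSA, consensus calling, variation classes."""

import numpy as np
import pytest

from solor.alleles import (
    AllelePanel,
    MsaParams,
    MultiAlignment,
    classify_variation,
    count_population_mismatches,
    population_consensus,
    progressive_msa,
)
from solor.simulate import SyntheticPanelConfig, generate_promoter_panel, random_dna


def needleman_wunsch_score(a, b, match=2.0, mismatch=-1.0, gap=-5.0):
    """Linear-gap global alignment score (independent DP oracle; a gap of
    length 1 costs the same as one affine gap opening)."""
    la, lb = len(a), len(b)
    M = np.zeros((la + 1, lb + 1))
    M[:, 0] = np.arange(la + 1) * gap
    M[0, :] = np.arange(lb + 1) * gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1] + s, M[i - 1, j] + gap, M[i, j - 1] + gap)
    return M[la, lb]


def three_way_sp_score(a, b, c, match=2.0, mismatch=-1.0, gap=-5.0):
    """Exhaustive 3-sequence sum-of-pairs DP (linear gap cost)."""
    la, lb, lc = len(a), len(b), len(c)
    NEG = -1e18

    def col(x, y):
        if x is None and y is None:
            return 0.0
        if x is None or y is None:
            return gap
        return match if x == y else mismatch

    D = np.full((la + 1, lb + 1, lc + 1), NEG)
    D[0, 0, 0] = 0.0
    for i in range(la + 1):
        for j in range(lb + 1):
            for k in range(lc + 1):
                cur = D[i, j, k]
                if cur == NEG:
                    continue
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            if di == dj == dk == 0:
                                continue
                            ni, nj, nk = i + di, j + dj, k + dk
                            if ni > la or nj > lb or nk > lc:
                                continue
                            x = a[i] if di else None
                            y = b[j] if dj else None
                            z = c[k] if dk else None
                            sc = col(x, y) + col(x, z) + col(y, z)
                            if cur + sc > D[ni, nj, nk]:
                                D[ni, nj, nk] = cur + sc
    return D[la, lb, lc]


def sp_score_of_alignment(rows, match=2.0, mismatch=-1.0, gap=-5.0):
    ids = list(rows)
    total = 0.0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            for x, y in zip(rows[ids[i]], rows[ids[j]]):
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += gap
                else:
                    total += match if x == y else mismatch
    return total


class TestProgressiveMsa:
    def test_identical_sequences_align_gap_free(self, rng):
        s = random_dna(rng, 80)
        aln = progressive_msa({f"s{i}": s for i in range(5)})
        assert aln.n_columns == 80
        assert all(row == s for row in aln.rows.values())

    def test_single_deletion_gives_single_gap_column(self, rng):
        a = random_dna(rng, 70)
        b = a[:30] + a[31:]
        aln = progressive_msa({"a": a, "b": b})
        assert aln.n_columns == 70
        assert aln.rows["a"] == a
        assert aln.rows["b"].count("-") == 1

    def test_pairwise_score_attains_nw_optimum(self, rng):
        # single-base indels only, so affine and linear costs coincide
        for _ in range(5):
            a = random_dna(rng, 60)
            b = list(a)
            b[int(rng.integers(10, 50))] = "ACGT"[int(rng.integers(4))]
            del b[int(rng.integers(10, 40))]
            b = "".join(b)
            aln = progressive_msa({"a": a, "b": b})
            got = sp_score_of_alignment(aln.rows)
            assert got == pytest.approx(needleman_wunsch_score(a, b))

    def test_three_way_sum_of_pairs_optimum(self, rng):
        # compatible pairwise optima: substitutions plus one deletion
        a = random_dna(rng, 60)
        b = list(a)
        b[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[20]]
        b = "".join(b)
        c = a[:40] + a[41:]
        aln = progressive_msa({"a": a, "b": b, "c": c})
        assert sp_score_of_alignment(aln.rows) == pytest.approx(
            three_way_sp_score(a, b, c)
        )

    def test_degapping_round_trips(self, rng):
        seqs = {}
        for i in range(6):
            s = list(random_dna(rng, 90))
            for _ in range(int(rng.integers(0, 3))):
                del s[int(rng.integers(0, len(s)))]
            seqs[f"s{i}"] = "".join(s)
        aln = progressive_msa(seqs)
        for sid, s in seqs.items():
            assert aln.degapped(sid) == s

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({"a": "ACGT" * 20, "b": "ACGU" * 20})

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            progressive_msa({"a": "ACGT" * 20})


class TestConsensus:
    @staticmethod
    def _aln(cols):
        """cols: list of strings, one per row."""
        rows = {f"m{i:02d}": r for i, r in enumerate(cols)}
        return MultiAlignment(rows, len(cols[0])), list(rows)

    def test_unanimous_column(self):
        aln, ids = self._aln(["ACGT" * 15] * 7)
        assert population_consensus(aln, ids) == "ACGT" * 15

    def test_majority_above_threshold_called(self):
        aln, ids = self._aln(["A" * 60] * 13 + ["G" * 60] * 11)
        assert population_consensus(aln, ids)[0] == "A"  # 13/24 = 0.54

    def test_tie_below_threshold_is_n(self):
        aln, ids = self._aln(["A" * 60] * 12 + ["G" * 60] * 12)
        assert population_consensus(aln, ids)[0] == "N"

    def test_empty_member_set_rejected(self):
        aln, _ = self._aln(["ACGT" * 15] * 3)
        with pytest.raises(ValueError):
            population_consensus(aln, [])

    def test_gap_participates_as_symbol(self):
        aln, ids = self._aln(["A-" * 30] * 3)
        assert population_consensus(aln, ids) == "A-" * 30

    def test_raising_threshold_never_turns_n_into_base(self, rng):
        rows = [
            "".join(rng.choice(list("ACGT-"), 40)) for _ in range(9)
        ]
        aln, ids = self._aln(rows)
        prev = population_consensus(aln, ids, threshold=0.4)
        for thr in (0.51, 0.67, 0.9):
            cur = population_consensus(aln, ids, threshold=thr)
            for p, c in zip(prev, cur):
                if p == "N":
                    assert c == "N"
            prev = cur


class TestClassifyVariation:
    def test_planted_mutant_pattern(self):
        cfg = SyntheticPanelConfig(planted_mutant_sites=5, substitution_rate=0, seed=11)
        panel, truth = generate_promoter_panel(cfg)
        rep = classify_variation(progressive_msa(panel.sequences), panel)
        assert rep.mutant and rep.polymorphic
        assert rep.mutant_positions == truth.mutant_positions

    def test_single_lab_strain_variant_is_polymorphic_only(self):
        cfg = SyntheticPanelConfig(
            planted_lab_variant_sites=1, substitution_rate=0, seed=12
        )
        panel, truth = generate_promoter_panel(cfg)
        rep = classify_variation(progressive_msa(panel.sequences), panel)
        assert rep.polymorphic and not rep.mutant

    def test_identical_panel_has_no_variation(self):
        cfg = SyntheticPanelConfig(substitution_rate=0, seed=13)
        panel, _ = generate_promoter_panel(cfg)
        rep = classify_variation(progressive_msa(panel.sequences), panel)
        assert not rep.mutant and not rep.polymorphic
        assert rep.per_population_mismatch == {"France": 0, "Germany": 0, "Iran": 0}

    def test_invariant_to_row_order_and_renaming(self):
        cfg = SyntheticPanelConfig(
            planted_mutant_sites=2, planted_lab_variant_sites=1,
            substitution_rate=0, seed=14,
        )
        panel, _ = generate_promoter_panel(cfg)
        aln = progressive_msa(panel.sequences)
        rep = classify_variation(aln, panel)

        renamed = {f"z_{k}": v for k, v in reversed(list(panel.sequences.items()))}
        panel2 = AllelePanel(
            panel.gene_id,
            "z_C57BL6J",
            renamed,
            {f"z_{k}": v for k, v in panel.groups.items()},
        )
        rep2 = classify_variation(progressive_msa(renamed), panel2)
        assert (rep.mutant, rep.polymorphic) == (rep2.mutant, rep2.polymorphic)
        assert rep.mutant_positions == rep2.mutant_positions

    def test_consensus_mode_matches_on_clean_panels(self):
        cfg = SyntheticPanelConfig(planted_mutant_sites=3, substitution_rate=0, seed=15)
        panel, truth = generate_promoter_panel(cfg)
        aln = progressive_msa(panel.sequences)
        strict = classify_variation(aln, panel, mutant_against="individuals")
        cons = classify_variation(aln, panel, mutant_against="consensus")
        assert strict.mutant_positions == cons.mutant_positions == truth.mutant_positions

    def test_missing_reference_rejected(self):
        cfg = SyntheticPanelConfig(substitution_rate=0, seed=16)
        panel, _ = generate_promoter_panel(cfg)
        aln = progressive_msa(
            {k: v for k, v in panel.sequences.items() if k != panel.reference_id}
        )
        with pytest.raises(ValueError, match="reference"):
            classify_variation(aln, panel)


class TestPopulationMismatches:
    def test_identical_consensus_counts_zero(self):
        cfg = SyntheticPanelConfig(substitution_rate=0, seed=21)
        panel, _ = generate_promoter_panel(cfg)
        aln = progressive_msa(panel.sequences)
        assert count_population_mismatches(aln, panel, "Iran") == 0

    def test_planted_substitutions_counted(self):
        cfg = SyntheticPanelConfig(
            planted_population_mismatches={"Iran": 3}, substitution_rate=0, seed=22
        )
        panel, truth = generate_promoter_panel(cfg)
        aln = progressive_msa(panel.sequences)
        assert count_population_mismatches(aln, panel, "Iran") == 3
        assert count_population_mismatches(aln, panel, "Germany") == 0

    def test_unknown_population_rejected(self):
        cfg = SyntheticPanelConfig(substitution_rate=0, seed=23)
        panel, _ = generate_promoter_panel(cfg)
        aln = progressive_msa(panel.sequences)
        with pytest.raises(ValueError):
            count_population_mismatches(aln, panel, "Atlantis")

    def test_totals_additive_across_genes(self):
        totals = {"Iran": 0, "Germany": 0}
        plan = [({"Iran": 2, "Germany": 3}), ({"Iran": 1, "Germany": 4})]
        for i, planted in enumerate(plan):
            cfg = SyntheticPanelConfig(
                planted_population_mismatches=planted,
                substitution_rate=0,
                seed=30 + i,
                gene_id=f"g{i}",
            )
            panel, _ = generate_promoter_panel(cfg)
            aln = progressive_msa(panel.sequences)
            for pop in totals:
                totals[pop] += count_population_mismatches(aln, panel, pop)
        assert totals == {"Iran": 3, "Germany": 7}
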