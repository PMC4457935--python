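"""Read processing, alignment, variant calling and population tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from evoselect.amplicon_enrichment import (
    GenotypeRecord,
    ReadPair,
    Scoring,
    call_substitutions,
    enrichment_trajectories,
    join_unmerged,
    merge_read_pairs,
    quality_trim,
    revcomp,
    smith_waterman,
    tabulate_population,
    translate_genotype,
)
from evoselect.reference import substitution_for_aa_change


def _pair(fwd, rev, fq=30, rq=30, id="p"):
    return ReadPair(
        id,
        fwd,
        np.full(len(fwd), fq, dtype=int) if np.isscalar(fq) else np.asarray(fq),
        rev,
        np.full(len(rev), rq, dtype=int) if np.isscalar(rq) else np.asarray(rq),
    )


class TestMerge:
    def test_fully_overlapping_pair(self, region):
        amp = region.cds_sequence[100:200]
        pair = _pair(amp, revcomp(amp))
        merged = merge_read_pairs(pair)
        assert merged.merged and merged.sequence == amp

    def test_non_overlapping_pair_flagged(self):
        pair = _pair("A" * 40, "C" * 40)  # revcomp(C*40) = G*40, no overlap
        assert merge_read_pairs(pair) is None

    def test_partial_overlap_resolves_mismatch_by_quality(self, region):
        # 250-nt amplicon tiled by two 140-nt reads with a 30-nt overlap
        amp = region.cds_sequence[100:350]
        fwd = amp[:140]
        rev_template = list(amp[110:250])
        rev_template[20] = {"A": "C", "C": "A", "G": "T", "T": "G"}[rev_template[20]]
        rev = revcomp("".join(rev_template))
        # forward read higher quality at the disagreeing base
        rq = np.full(140, 20)
        pair = _pair(fwd, rev, fq=35, rq=rq)
        merged = merge_read_pairs(pair, min_overlap=6, max_mismatch_frac=0.08)
        assert merged.merged
        assert len(merged.sequence) == 250
        assert merged.sequence == amp  # higher-quality (correct) base won

    def test_short_overlap_below_minimum_rejected(self, region):
        amp = region.cds_sequence[100:180]
        pair = _pair(amp[:42], revcomp(amp[38:]))  # 4-nt overlap
        assert merge_read_pairs(pair, min_overlap=6) is None


class TestQualityTrim:
    def test_all_high_quality_unchanged(self):
        seq, qual = quality_trim("ACGTA", np.array([30, 30, 30, 30, 30]), 20)
        assert seq == "ACGTA" and qual.size == 5

    def test_all_low_quality_empties_read(self):
        seq, qual = quality_trim("ACGT", np.array([10, 10, 10, 10]), 20)
        assert seq == "" and qual.size == 0

    def test_trims_from_first_low_quality_base(self):
        seq, qual = quality_trim("ACGTA", np.array([40, 40, 40, 10, 40]), 20)
        assert seq == "ACG"
        np.testing.assert_array_equal(qual, [40, 40, 40])

    @given(st.lists(st.integers(2, 41), min_size=1, max_size=30))
    def test_never_lengthens_and_prefix_is_clean(self, quals):
        seq = "A" * len(quals)
        out, oq = quality_trim(seq, np.array(quals), 20)
        assert len(out) <= len(seq)
        assert (oq >= 20).all()


class TestJoin:
    def test_palindromic_reverse(self):
        merged = join_unmerged(_pair("ACGT", "ACGT"))
        assert merged.sequence == "ACGTACGT"

    def test_poly_a(self):
        assert join_unmerged(_pair("AAAA", "TTTT")).sequence == "AAAAAAAA"

    def test_contains_both_amplicon_ends(self, region):
        amp = region.cds_sequence[0:250]
        pair = _pair(amp[:100], revcomp(amp[150:]))
        merged = join_unmerged(pair)
        assert merged.sequence.startswith(amp[:100])
        assert merged.sequence.endswith(amp[150:])
        assert not merged.merged


def _naive_sw_score(q, r, sc: Scoring):
    """Plain full-matrix affine-gap local alignment score (oracle)."""
    NEG = float("-inf")
    m, n = len(q), len(r)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open, E[i][j - 1] + sc.gap_extend)
            F[i][j] = max(H[i - 1][j] + sc.gap_open, F[i - 1][j] + sc.gap_extend)
            s = sc.match if q[i - 1] == r[j - 1] else sc.mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_window_aligns_gapless(self, region):
        aln = smith_waterman(region.window_sequence, region.cds_sequence)
        assert aln.score == 2 * 177
        assert (aln.ref_start, aln.ref_end) == (235, 411)
        assert all(q is not None and r is not None for q, r in aln.aligned_pairs)
        assert aln.recompute_score(Scoring()) == aln.score

    def test_single_match_against_mismatching_reference(self):
        aln = smith_waterman("ACGT", "TTTT", Scoring(match=2, mismatch=-3))
        assert aln.score == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_gapped_alignment_score_recomputes(self, region):
        q = region.cds_sequence[50:90] + region.cds_sequence[95:140]
        aln = smith_waterman(q, region.cds_sequence)
        assert aln.recompute_score(Scoring()) == pytest.approx(aln.score)

    def test_matches_naive_oracle_on_random_instances(self, rng):
        sc = Scoring()
        for _ in range(60):
            q = "".join(rng.choice(list("ACGT"), rng.integers(5, 50)))
            r = "".join(rng.choice(list("ACGT"), rng.integers(20, 120)))
            aln = smith_waterman(q, r, sc)
            assert aln.score == pytest.approx(_naive_sw_score(q, r, sc))
            assert aln.score >= 0


class TestCallSubstitutions:
    def test_perfect_read_full_coverage(self, region):
        aln = smith_waterman(region.cds_sequence[200:440], region.cds_sequence)
        subs, mask = call_substitutions(aln, region)
        assert subs == [] and mask.all()

    def test_known_edit_called_in_cds_coordinates(self, region):
        q = list(region.cds_sequence[200:440])
        ref = q[34]  # CDS position 235, first base of codon 79
        alt = {"A": "C", "C": "A", "G": "C", "T": "G"}[ref]
        q[34] = alt
        subs, mask = call_substitutions(
            smith_waterman("".join(q), region.cds_sequence), region
        )
        assert subs == [(235, ref, alt)]
        assert mask.all()

    def test_deletion_leaves_positions_uncovered(self, region):
        q = region.cds_sequence[200:299] + region.cds_sequence[302:440]
        subs, mask = call_substitutions(
            smith_waterman(q, region.cds_sequence), region
        )
        assert subs == []
        uncovered = np.flatnonzero(~mask) + region.nt_start
        np.testing.assert_array_equal(uncovered, [300, 301, 302])

    def test_n_bases_are_uncovered_not_variant(self, region):
        q = list(region.cds_sequence[200:440])
        q[40] = "N"
        subs, mask = call_substitutions(
            smith_waterman("".join(q), region.cds_sequence), region
        )
        assert subs == []
        assert not mask[241 - region.nt_start]  # CDS 241 uncovered

    def test_per_position_count_identity(self, region, rng):
        """covered = ref count + sum of alt counts at every position."""
        from evoselect.amplicon_enrichment import analyze_read_pairs
        from evoselect.selection_sim import (
            SequencingConfig,
            population_from_fractions,
            generate_reads,
        )

        pop = population_from_fractions({"WT": 0.8, "V79L": 0.2}, 100, region)
        pairs = generate_reads(
            pop, region, SequencingConfig(n_pairs=200, error_rate=0.01), rng
        )
        result = analyze_read_pairs(pairs, region)
        pc = result.position_counts
        win = region.window_sequence
        for offset in range(0, 177, 13):
            row = pc.iloc[offset]
            assert row["covered"] == row[list("ACGT")].sum()
            assert row[win[offset]] > 0


class TestTranslateGenotype:
    def test_no_substitutions_is_wild_type(self, region):
        rec = translate_genotype([], region)
        assert rec.genotype_class == "wild_type_protein"
        assert rec.label == "WT"

    def test_double_missense_labels(self, region):
        subs = [
            substitution_for_aa_change(region, "E86G"),
            substitution_for_aa_change(region, "C90G"),
        ]
        rec = translate_genotype(subs, region)
        assert rec.aa_changes == ("E86G", "C90G")
        assert rec.genotype_class == "double"
        assert rec.label == "E86G/C90G"

    def test_silent_change_stays_wild_type_protein(self, region):
        # codon 80 TCT -> TCC, both Ser
        pos = 3 * 79 + 3  # third base of codon 80 (CDS 240)
        assert region.cds_sequence[pos - 1] == "T"
        rec = translate_genotype([(pos, "T", "C")], region)
        assert rec.genotype_class == "wild_type_protein"
        assert rec.aa_changes == ()
        assert rec.substitutions == ((pos, "T", "C"),)

    def test_substitution_outside_window_rejected(self, region):
        with pytest.raises(ValueError, match="outside window"):
            translate_genotype([(10, region.cds_sequence[9], "A")], region)

    def test_two_hits_in_one_codon_yield_one_change(self, region):
        # codon 79 GTT -> CAT (V79H) via two substitutions
        rec = translate_genotype([(235, "G", "C"), (236, "T", "A")], region)
        assert rec.aa_changes == ("V79H",)
        assert rec.genotype_class == "single"


def _records(spec):
    """Build per-read records from {label_or_None: n_reads}."""
    out = []
    for rec, n in spec:
        out.extend([rec] * n)
    return out


class TestTabulate:
    def _wt(self):
        return GenotypeRecord((), (), "wild_type_protein")

    def _single(self, label="V79L"):
        return GenotypeRecord((), (label,), "single")

    def test_all_wild_type(self):
        table = tabulate_population([self._wt()] * 100)
        assert table.class_fractions["wild_type_protein"] == 1.0
        assert table.reported_aa_changes.empty

    def test_ten_percent_variant(self):
        recs = [self._wt()] * 90 + [self._single()] * 10
        table = tabulate_population(recs, threshold=0.005)
        assert table.fraction_of("V79L") == pytest.approx(0.10)
        assert "V79L" in table.reported_aa_changes.index

    def test_rare_variant_suppressed_but_retained(self):
        recs = [self._wt()] * 999 + [self._single("H97Y")] * 1
        table = tabulate_population(recs, threshold=0.005)
        assert "H97Y" not in table.reported_aa_changes.index
        assert table.fraction_of("H97Y") == pytest.approx(0.001)

    def test_multi_mutant_attribution_with_class_split(self):
        double = GenotypeRecord((), ("E86G", "C90G"), "double")
        recs = [self._wt()] * 80 + [double] * 12 + [self._single("E86G")] * 8
        table = tabulate_population(recs)
        row = table.aa_changes.loc["E86G"]
        assert row["count"] == 20
        assert row["single"] == 8 and row["double"] == 12
        assert table.fraction_of("C90G") == pytest.approx(0.12)
        assert sum(table.class_fractions.values()) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate_population([])


class TestTrajectories:
    def _table(self, cycle, fracs, total=1000):
        recs = []
        n_var = 0
        for label, f in fracs.items():
            n = round(f * total)
            n_var += n
            recs.extend([GenotypeRecord((), (label,), "single")] * n)
        recs.extend(
            [GenotypeRecord((), (), "wild_type_protein")] * (total - n_var)
        )
        return tabulate_population(recs, cycle=cycle)

    def test_monotone_riser_and_fold(self):
        tables = [
            self._table(c, {"I102L": f})
            for c, f in [(4, 0.01), (5, 0.02), (6, 0.04)]
        ]
        (traj,) = enrichment_trajectories(tables)
        assert traj.label == "I102L"
        assert traj.monotone_increase
        assert traj.fold_change == pytest.approx(4.0)

    def test_constant_fraction_is_not_monotone(self):
        tables = [self._table(c, {"V79L": 0.02}) for c in (1, 2, 3)]
        (traj,) = enrichment_trajectories(tables)
        assert not traj.monotone_increase
        assert traj.fold_change == pytest.approx(1.0)

    def test_absent_cycle_recorded_as_zero(self):
        tables = [
            self._table(1, {}),
            self._table(2, {"H97Y": 0.03}),
        ]
        (traj,) = enrichment_trajectories(tables)
        assert traj.fractions[0] == 0.0
        assert traj.fold_change == float("inf")

    def test_unordered_cycles_rejected(self):
        tables = [self._table(2, {"V79L": 0.02}), self._table(1, {"V79L": 0.03})]
        with pytest.raises(ValueError, match="strictly increasing"):
            enrichment_trajectories(tables)

    def test_requires_two_cycles(self):
        with pytest.raises(ValueError):
            enrichment_trajectories([self._table(1, {})])
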