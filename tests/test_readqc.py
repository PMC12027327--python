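import numpy as np
import pytest

from guidearray import readqc, simreads
from guidearray.designer import ligated_unit, predicted_insert_for
from guidearray.dna import revcomp
from guidearray.readqc import (
    InsertCall,
    MutationCall,
    SegmentationError,
    abundance_matrix,
    assembly_efficiency,
    assign_grna,
    bin_unit_count,
    classify_mutations,
    consensus_insert,
    extract_insert,
    mutation_rate,
    segment_units,
    similarity,
)

FLANK_UP = "ACCGATTACCGGAATTCCGGAT"
FLANK_DOWN = "TTGGCCAATTGGCCATATCGGA"
INSERT = "ACGATCGATTAGGATCCATTGGACCATG"


def levenshtein(a: str, b: str) -> int:
    """Independent DP oracle for edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestExtractInsert:
    def test_flanked_insert_found_on_plus_strand(self):
        read = "TTTT" + FLANK_UP + INSERT + FLANK_DOWN + "GGGG"
        call = extract_insert(read, FLANK_UP, FLANK_DOWN, circular=False)
        assert call.insert == INSERT
        assert call.strand == "+"

    def test_reverse_complement_read_gives_same_insert(self):
        read = "TTTT" + FLANK_UP + INSERT + FLANK_DOWN + "GGGG"
        call = extract_insert(revcomp(read), FLANK_UP, FLANK_DOWN, circular=False)
        assert call.insert == INSERT
        assert call.strand == "-"

    def test_missing_downstream_flank_yields_no_insert(self):
        read = "TTTT" + FLANK_UP + INSERT
        call = extract_insert(read, FLANK_UP, FLANK_DOWN, circular=False)
        assert call.insert is None

    def test_origin_spanning_insert_recovered_from_doubled_read(self):
        plasmid = FLANK_UP + INSERT + FLANK_DOWN + "CATGATCCATGGTACGATCG"
        mid = len(FLANK_UP) + len(INSERT) // 2
        rotated = plasmid[mid:] + plasmid[:mid]
        call = extract_insert(rotated, FLANK_UP, FLANK_DOWN, circular=True)
        assert call.insert == INSERT

    def test_noisy_flanks_within_edit_budget(self):
        up = FLANK_UP[:10] + "A" + FLANK_UP[11:]
        read = "TT" + up + INSERT + FLANK_DOWN + "GG"
        call = extract_insert(read, FLANK_UP, FLANK_DOWN, circular=False)
        assert call.insert == INSERT

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            extract_insert("ACGT" * 20, "ACGTACGT", FLANK_DOWN)


class TestBinUnitCount:
    def test_exact_multiples_bin_exactly(self):
        for k in range(1, 11):
            assert bin_unit_count(k * 411, 411, 10) == k

    def test_zero_length_is_unbinned(self):
        assert bin_unit_count(0, 411, 10) is None

    def test_above_max_units_is_unbinned(self):
        assert bin_unit_count(11 * 411, 411, 10) is None

    def test_noisy_lengths_recover_their_bin(self):
        rng = np.random.default_rng(4)
        for k in range(1, 11):
            for _ in range(20):
                noisy = round(k * 411 + rng.uniform(-0.1, 0.1) * 411)
                assert bin_unit_count(noisy, 411, 10) == k

    def test_custom_tolerance(self):
        assert bin_unit_count(450, 411, 10, tolerance=20) is None
        assert bin_unit_count(420, 411, 10, tolerance=20) == 1


class TestAssemblyEfficiency:
    def _calls(self, counts):
        return [
            InsertCall(read_id=f"r{i}", insert="A", unit_count=c)
            for i, c in enumerate(counts)
        ]

    def test_all_full_length(self):
        df = assembly_efficiency(self._calls([10] * 8))
        assert df.fraction.tolist() == [1.0]
        assert df.unit_count.tolist() == [10]

    def test_fractions_sum_to_one_and_unbinned_reported(self):
        calls = self._calls([10, 10, 7, None, 3])
        df = assembly_efficiency(calls)
        assert df.fraction.sum() == pytest.approx(1.0)
        assert df.attrs["unbinned"] == 1

    def test_replicate_means(self):
        calls = self._calls([10, 10, 5, 10])
        df = assembly_efficiency(calls, replicates=["a", "a", "b", "b"])
        assert df.attrs["mean_fraction"][10] == pytest.approx((1.0 + 0.5) / 2)

    def test_zero_binned_reads_is_an_error(self):
        with pytest.raises(ValueError, match="binned"):
            assembly_efficiency(self._calls([None, None]))


class TestSegmentUnits:
    def test_error_free_insert_segments_exactly(self, design10):
        units = segment_units(design10.predicted_insert, design10, 10)
        for pos, unit in enumerate(units, start=1):
            assert unit == ligated_unit(pos, design10).sequence

    def test_substituted_insert_keeps_boundaries(self, design10):
        rng = np.random.default_rng(11)
        insert = list(design10.predicted_insert)
        n_subs = int(0.05 * len(insert))
        for pos in rng.choice(len(insert), size=n_subs, replace=False):
            insert[pos] = "ACGT"[(("ACGT".index(insert[pos])) + 1) % 4]
        units = segment_units("".join(insert), design10, 10)
        for pos, unit in enumerate(units, start=1):
            expected = ligated_unit(pos, design10).sequence
            # substitutions only: boundaries should not shift materially
            assert abs(len(unit) - len(expected)) <= 3

    def test_wrong_unit_count_fails(self, design10):
        with pytest.raises(SegmentationError):
            segment_units(design10.predicted_insert[: 2 * 411], design10, 10)

    def test_low_identity_flagged(self, design10):
        rng = np.random.default_rng(12)
        garbage = "".join(rng.choice(list("ACGT"), size=len(design10.predicted_insert)))
        with pytest.raises(SegmentationError, match="identity"):
            segment_units(garbage, design10, 10)


class TestAssignGrna:
    def test_exact_match_scores_100(self, design10, pool10):
        unit = ligated_unit(3, design10).sequence
        gid, score = assign_grna(unit, pool10, design10, position=3)
        assert gid == design10.names[2]
        assert score == 100.0

    def test_single_substitution_scores_95(self, design10, pool10):
        unit = ligated_unit(1, design10)
        s, _e = unit.regions["spacer"]
        seq = list(unit.sequence)
        seq[s + 5] = "ACGT"[("ACGT".index(seq[s + 5]) + 1) % 4]
        gid, score = assign_grna("".join(seq), pool10, design10, position=1)
        assert gid == design10.names[0]
        assert score == pytest.approx(95.0)

    def test_identical_pool_members_are_ambiguous(self, design10):
        pool = {"a": design10.spacers[0], "b": design10.spacers[0]}
        unit = ligated_unit(1, design10).sequence
        gid, score = assign_grna(unit, pool, design10, position=1)
        assert gid == "ambiguous"
        assert score == 100.0

    def test_unrelated_spacer_is_unassigned(self, design10):
        pool = {"x": "G" * 10 + "C" * 10}
        unit = ligated_unit(1, design10).sequence
        gid, score = assign_grna(unit, pool, design10, position=1)
        assert gid == "unassigned"
        assert score < 80

    def test_empty_pool_rejected(self, design10):
        with pytest.raises(ValueError, match="empty"):
            assign_grna("ACGT", {}, design10)

    def test_matches_exhaustive_edit_distance_oracle(self, design10):
        rng = np.random.default_rng(13)
        pool = {f"g{i}": simreads.random_spacer(rng) for i in range(20)}
        for trial in range(25):
            gid = f"g{rng.integers(20)}"
            spacer = list(pool[gid])
            for _ in range(rng.integers(0, 3)):
                spacer[rng.integers(len(spacer))] = "ACGT"[rng.integers(4)]
            spacer = "".join(spacer)
            unit = (design10.overhangs[0] + design10.refs.u6 + spacer
                    + design10.refs.scaffold)
            observed = readqc.extract_spacer(unit, design10, position=1)
            scores = {
                g: 100 * (1 - levenshtein(observed, sp)
                          / max(len(observed), len(sp)))
                for g, sp in pool.items()
            }
            best = max(scores.values())
            oracle = sorted(g for g, s in scores.items() if s == best)
            got, score = assign_grna(unit, pool, design10, position=1)
            assert score == pytest.approx(best)
            if len(oracle) == 1 and best >= 80:
                assert got == oracle[0]
            elif best >= 80:
                assert got == "ambiguous"


class TestAbundanceMatrix:
    def test_ordered_reads_fill_only_their_positions(self, design10, pool10):
        calls = [
            InsertCall(
                read_id=f"r{i}", insert="A", unit_count=10,
                assignments=[(name, 100.0) for name in design10.names],
            )
            for i in range(5)
        ]
        mat = abundance_matrix(calls, 10, pool10)
        for pos, name in enumerate(design10.names, start=1):
            assert mat.counts.loc[pos, name] == 5
        assert mat.counts.to_numpy().sum() == 50

    def test_totals_are_column_sums(self, design10, pool10):
        calls = [
            InsertCall(
                read_id="r0", insert="A", unit_count=10,
                assignments=[(design10.names[0], 100.0)] * 10,
            )
        ]
        mat = abundance_matrix(calls, 10, pool10)
        assert mat.totals[design10.names[0]] == 10
        assert (mat.totals == mat.counts.sum(axis=0)).all()


class TestClassifyMutations:
    def test_identical_sequences_have_no_calls(self, design10):
        unit = ligated_unit(2, design10)
        assert classify_mutations(unit.sequence, unit) == []

    def test_primer_region_substitution_is_inconsequential(self, design10):
        unit = ligated_unit(1, design10)
        seq = list(unit.sequence)
        seq[2] = "A" if seq[2] != "A" else "C"
        calls = classify_mutations("".join(seq), unit)
        assert len(calls) == 1
        assert calls[0].region == "fwd_primer_region"
        assert calls[0].kind == "substitution"
        assert not calls[0].consequential

    def test_spacer_deletion_is_consequential(self, design10):
        unit = ligated_unit(1, design10)
        s, _e = unit.regions["spacer"]
        seq = unit.sequence[: s + 4] + unit.sequence[s + 5:]
        calls = classify_mutations(seq, unit)
        dels = [c for c in calls if c.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].region == "spacer"
        assert dels[0].consequential

    def test_u6_insertion_is_consequential(self, design10):
        unit = ligated_unit(1, design10)
        s, e = unit.regions["u6"]
        mid = (s + e) // 2
        base = "A" if unit.sequence[mid] != "A" else "C"
        seq = unit.sequence[:mid] + base + unit.sequence[mid:]
        calls = classify_mutations(seq, unit)
        assert any(c.kind == "insertion" and c.consequential for c in calls)

    def test_length_ratio_guard(self, design10):
        unit = ligated_unit(1, design10)
        with pytest.raises(ValueError, match="length ratio"):
            classify_mutations("ACGT", unit)


class TestMutationRate:
    def test_no_mutations_gives_zero(self):
        assert mutation_rate([[], [], []]) == 0.0

    def test_21_of_280_units_gives_7_5_percent(self):
        calls = []
        for i in range(280):
            if i < 21:
                calls.append([MutationCall(1, "spacer", "substitution", 0, "A", "C")])
            else:
                calls.append([MutationCall(1, "fwd_primer_region", "substitution",
                                           0, "A", "C")])
        assert mutation_rate(calls) == pytest.approx(0.075)

    def test_zero_units_rejected(self):
        with pytest.raises(ValueError):
            mutation_rate([])


class TestConsensus:
    def test_majority_vote_restores_clone_sequence(self, design10):
        rng = np.random.default_rng(14)
        expected = predicted_insert_for(design10)
        # clone has one real deletion; each read adds random substitutions
        clone = expected[:100] + expected[101:]
        reads = []
        for _ in range(9):
            read = list(clone)
            for pos in rng.choice(len(read), size=30, replace=False):
                read[pos] = "ACGT"[rng.integers(4)]
            reads.append("".join(read))
        cons = consensus_insert(reads, expected)
        assert cons == clone

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus_insert([], "ACGT")


def test_similarity_scale():
    assert similarity("ACGT", "ACGT") == 100.0
    assert similarity("ACGT", "ACGA") == pytest.approx(75.0)
    assert similarity("", "") == 100.0


class TestEndToEnd:
    def test_error_free_pipeline_recovers_everything(self, design10, pool10):
        cfg = simreads.ReadSimConfig(
            n_reads=15, full_length_fraction=1.0,
            per_unit_consequential_rate=0.0,
            sub_rate=0, ins_rate=0, del_rate=0, seed=21,
        )
        clones = simreads.simulate_clone_population(design10, cfg, n_clones=5)
        reads, _truth = simreads.simulate_reads(clones, cfg)
        calls = readqc.analyze_reads(reads, design10, pool=pool10)
        assert all(c.unit_count == 10 for c in calls)
        for c in calls:
            assert [g for g, _ in c.assignments] == design10.names
            assert not any(m.consequential for m in c.mutations)

    def test_strand_invariance_on_simulated_reads(self, design10):
        cfg = simreads.ReadSimConfig(
            n_reads=10, full_length_fraction=1.0,
            per_unit_consequential_rate=0.0,
            sub_rate=0.02, ins_rate=0.005, del_rate=0.005, seed=22,
        )
        clones = simreads.simulate_clone_population(design10, cfg, n_clones=3)
        reads, _ = simreads.simulate_reads(clones, cfg)
        backbone = design10.refs.vector_backbone
        for read_id, seq, _q in reads:
            fwd = extract_insert(seq, backbone[-30:], backbone[:30])
            rev = extract_insert(revcomp(seq), backbone[-30:], backbone[:30])
            assert fwd.insert == rev.insert
            assert fwd.insert is not None

    def test_library_mode_abundance_is_roughly_uniform(self, design10):
        rng = np.random.default_rng(23)
        pool = {f"lib{i}": simreads.random_spacer(rng) for i in range(10)}
        cfg = simreads.ReadSimConfig(
            n_reads=120, full_length_fraction=1.0,
            per_unit_consequential_rate=0.0,
            sub_rate=0.02, ins_rate=0.005, del_rate=0.005,
            pool=pool, seed=24,
        )
        clones = simreads.simulate_clone_population(design10, cfg, n_clones=120)
        reads, truth = simreads.simulate_reads(clones, cfg, per_clone=1)
        calls = readqc.analyze_reads(reads, design10, pool=pool, classify=False)
        full = [c for c in calls if c.unit_count == 10]
        assert len(full) >= 100
        mat = abundance_matrix(full, 10, pool)
        assigned = mat.counts[sorted(pool)].to_numpy()
        # every guide appears at every position in a uniform library
        assert assigned.sum() >= 0.98 * 10 * len(full)
        tmap = {t["read_id"]: t["spacer_ids"].split(",") for t in truth}
        good = total = 0
        for c in full:
            for (gid, _s), true_id in zip(c.assignments, tmap[c.read_id]):
                good += gid == true_id
                total += 1
        assert good / total >= 0.99
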