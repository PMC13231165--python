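"""HUH-seq analysis stages against naive oracles and closed-form identities."""

import random
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huhseq.huhseq_core import (
    KmerCountTable,
    all_kmers,
    condition_correlation,
    count_kmers,
    demultiplex,
    extract_kmer,
    index_to_kmer,
    kmer_base_matrix,
    kmer_to_index,
    percent_reduction,
    reduction_histogram,
    replicate_qc,
    specificity_logo,
    validate_barcodes,
)
from huhseq.lib_design import default_huhseq_design
from huhseq.synthetic_data import SimulationManifest, one_hot_model, \
    simulate_huhseq_run


def make_table(counts, sample="s", condition="c", replicate=1, k=7):
    counts = np.asarray(counts)
    return KmerCountTable(sample, condition, replicate, counts,
                          int(counts.sum()), 0, k=k)


def make_profile(reductions, ref_freq=None, k=7):
    """Construct a ReductionProfile directly from a reduction vector."""
    from huhseq.huhseq_core import ReductionProfile
    reductions = np.asarray(reductions, dtype=float)
    n = 4 ** k
    assert reductions.shape == (n,)
    ref = np.full(n, 1.0 / n) if ref_freq is None else ref_freq
    treat = ref * (1 - reductions)
    return ReductionProfile("c", k, ref, treat, reductions,
                            reductions[None, :], ["t1"], ["r1"])


class TestKmerIndexing:
    def test_round_trip_and_order(self):
        assert kmer_to_index("AAAAAAA") == 0
        assert kmer_to_index("TTTTTTT") == 16383
        for idx in (0, 1, 4097, 16383):
            assert kmer_to_index(index_to_kmer(idx, 7)) == idx
        assert all_kmers(2)[:5] == ["AA", "AC", "AG", "AT", "CA"]

    def test_base_matrix_matches_kmer_strings(self):
        bm = kmer_base_matrix(3)
        for idx in (0, 17, 63):
            assert "".join("ACGT"[b] for b in bm[idx]) == index_to_kmer(idx, 3)


class TestDemultiplex:
    def test_exact_match_and_reject(self):
        bc = {"AAAAAAAA": "s1", "TTTTTTTT": "s2"}
        reads = [("r1", "AAAAAAAA" + "G" * 10), ("r2", "TTTTTTTT" + "C" * 10),
                 ("r3", "AAAATTTT" + "G" * 10)]
        by_sample, unassigned = demultiplex(reads, bc)
        assert [r[0] for r in by_sample["s1"]] == ["r1"]
        assert by_sample["s1"][0][1] == "G" * 10  # barcode stripped
        assert [r[0] for r in unassigned] == ["r3"]

    def test_one_mismatch_tolerated_when_enabled(self):
        bc = {"AAAAAAAA": "s1", "TTTTTTTT": "s2"}
        reads = [("r1", "AAAAAAAC" + "G" * 5)]
        by_sample, unassigned = demultiplex(reads, bc, max_mismatch=1)
        assert len(by_sample["s1"]) == 1
        by_sample, unassigned = demultiplex(reads, bc, max_mismatch=0)
        assert len(unassigned) == 1

    def test_collision_rejected_at_startup(self):
        bc = {"AAAAAAAA": "s1", "AAAAAATT": "s2"}  # distance 2 <= 2*1
        with pytest.raises(ValueError):
            validate_barcodes(bc, max_mismatch=1)
        validate_barcodes(bc, max_mismatch=0)

    def test_assignments_match_generator_truth(self, tmp_path):
        manifest = SimulationManifest(seed=13, depth_per_sample=5000,
                                      n_replicates=1, error_rate=0.001)
        run = simulate_huhseq_run(None, one_hot_model(), manifest, tmp_path)
        from Bio.SeqIO.QualityIO import FastqGeneralIterator
        with open(run.fastq_path) as fh:
            reads = [(t, s) for t, s, _ in FastqGeneralIterator(fh)]
        bc = dict(zip(run.sample_sheet["barcode"], run.sample_sheet["sample"]))
        by_sample, unassigned = demultiplex(reads, bc, max_mismatch=1)
        total = len(reads)
        assigned = sum(map(len, by_sample.values()))
        assert assigned / total >= 0.99
        for sample, srs in by_sample.items():
            for title, _ in srs:
                assert title.split(".")[0] == sample.split("_r")[0] \
                    or title.startswith(sample)
                assert title.split(" ")[0].rsplit(".", 1)[0] == sample


class TestExtractKmer:
    design = default_huhseq_design()

    def test_perfect_read(self):
        read = self.design.oligo("GATTACA")
        assert extract_kmer(read, self.design) == "GATTACA"

    def test_ambiguous_base_in_region_is_null(self):
        read = self.design.oligo("GATTACA").replace("GATTACA", "GATNACA")
        assert extract_kmer(read, self.design) is None

    def test_anchor_mutation_falls_back_to_coordinates(self):
        read = list(self.design.oligo("GATTACA"))
        read[2] = "A" if read[2] != "A" else "C"  # break upstream anchor
        assert extract_kmer("".join(read), self.design) == "GATTACA"

    def test_broken_anchor_and_wrong_length_is_null(self):
        read = list(self.design.oligo("GATTACA"))
        read[2] = "A" if read[2] != "A" else "C"
        assert extract_kmer("".join(read)[:-1], self.design) is None

    def test_anchor_match_beats_coordinates_on_shifted_read(self):
        # a 5' insertion shifts coordinates; anchors still locate the k-mer
        read = "G" + self.design.oligo("GATTACA")
        assert extract_kmer(read, self.design) == "GATTACA"


class TestCountKmers:
    design = default_huhseq_design()

    def test_universe_covers_all_16384(self):
        table = count_kmers([], self.design)
        assert table.counts.shape == (16384,)
        assert table.is_empty
        assert np.isnan(table.frequencies).all()

    def test_repeated_read(self):
        reads = [(f"r{i}", self.design.oligo("TATTATT")) for i in range(10)]
        table = count_kmers(reads, self.design)
        assert table.counts[kmer_to_index("TATTATT")] == 10
        assert table.total == 10

    def test_matches_naive_dictionary_scan(self):
        rng = random.Random(99)
        kmers = ["".join(rng.choice("ACGT") for _ in range(7))
                 for _ in range(5000)]
        reads = [(f"r{i}", self.design.oligo(km))
                 for i, km in enumerate(kmers)]
        table = count_kmers(reads, self.design)
        # independent oracle: substring extraction into a plain dict
        start, stop = self.design.randomized_span
        naive = defaultdict(int)
        for _, seq in reads:
            naive[seq[start:stop]] += 1
        for km, n in naive.items():
            assert table.counts[kmer_to_index(km)] == n
        assert table.total == sum(naive.values())

    def test_read_order_invariance(self):
        rng = random.Random(5)
        reads = [(f"r{i}", self.design.oligo(
            "".join(rng.choice("ACGT") for _ in range(7))))
            for i in range(500)]
        t1 = count_kmers(reads, self.design)
        shuffled = reads[:]
        rng.shuffle(shuffled)
        t2 = count_kmers(shuffled, self.design)
        assert (t1.counts == t2.counts).all()

    def test_frequency_normalization(self):
        reads = [(f"r{i}", self.design.oligo("ACGTACG")) for i in range(7)]
        table = count_kmers(reads, self.design)
        assert abs(table.frequencies.sum() - 1.0) < 1e-9


class TestReplicateQC:
    def test_identical_tables_fully_correlated(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, 16384)
        tables = [make_table(counts, sample=f"s{i}") for i in range(3)]
        qc = replicate_qc(tables)
        assert np.allclose(qc.correlation, 1.0)
        assert qc.excluded == [] and qc.usable

    def test_two_well_correlated_replicates_retained(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, 16384).astype(float)
        t1 = make_table(base + rng.poisson(10, 16384), "a")
        t2 = make_table(base + rng.poisson(10, 16384), "b")
        qc = replicate_qc([t1, t2])
        assert qc.correlation[0, 1] > 0.9
        assert qc.excluded == [] and qc.usable

    def test_single_corrupted_replicate_excluded(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(200, 16384).astype(float)
        good = [make_table(base + rng.poisson(10, 16384), f"g{i}")
                for i in range(2)]
        bad = make_table(rng.permutation(base).astype(int), "bad")
        qc = replicate_qc(good + [bad])
        assert [qc.sample_ids[i] for i in qc.excluded] == ["bad"]
        assert qc.usable

    def test_mutually_uncorrelated_condition_flagged_unusable(self):
        rng = np.random.default_rng(3)
        tables = [make_table(rng.poisson(5, 16384), f"s{i}")
                  for i in range(3)]
        qc = replicate_qc(tables)
        assert not qc.usable
        assert len(qc.retained) >= 2  # never excludes below two
        assert any("unusable" in w for w in qc.warnings)

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            replicate_qc([make_table(np.ones(16384, int))])


class TestPercentReduction:
    def test_closed_form_identities(self):
        n = 4 ** 7
        ref = np.zeros(n, dtype=int)
        treat = np.zeros(n, dtype=int)
        i_full = kmer_to_index("TATTATT")   # fully depleted
        i_same = kmer_to_index("AAAAAAA")   # unchanged
        i_na = kmer_to_index("CCCCCCC")     # absent from reference
        ref[i_full], treat[i_full] = 100, 0
        ref[i_same], treat[i_same] = 100, 100
        ref[i_na], treat[i_na] = 0, 50
        profile = percent_reduction([make_table(ref)], [make_table(treat)])
        # frequencies differ from counts only by the shared normalization,
        # which cancels in the two asserted identities below
        assert profile.percent_reduction[i_full] == pytest.approx(1.0)
        assert np.isnan(profile.percent_reduction[i_na])
        # equal count, but total treatment reads differ -> compare freqs
        f_ref = ref / ref.sum()
        f_treat = treat / treat.sum()
        expected = (f_ref[i_same] - f_treat[i_same]) / f_ref[i_same]
        assert profile.percent_reduction[i_same] == pytest.approx(expected)

    def test_equal_frequencies_give_zero(self):
        counts = np.random.default_rng(0).poisson(20, 16384) + 1
        profile = percent_reduction([make_table(counts)],
                                    [make_table(counts)])
        assert np.allclose(profile.percent_reduction, 0.0)

    def test_mean_of_frequencies_not_pooled_counts(self):
        n = 4 ** 7
        r1 = np.ones(n, dtype=int)
        r2 = np.ones(n, dtype=int) * 3
        i = kmer_to_index("TATTATT")
        r1[i], r2[i] = 2, 3  # freq 2/(n+1) and 3/(3n), mean != pooled
        profile = percent_reduction(
            [make_table(r1), make_table(r2)],
            [make_table(np.ones(n, dtype=int))],
        )
        f1 = r1 / r1.sum()
        f2 = r2 / r2.sum()
        mean_ref = (f1[i] + f2[i]) / 2
        assert profile.mean_reference_freq[i] == pytest.approx(mean_ref)
        pooled = (r1[i] + r2[i]) / (r1.sum() + r2.sum())
        assert profile.mean_reference_freq[i] != pytest.approx(pooled)

    def test_no_replicates_is_error(self):
        with pytest.raises(ValueError):
            percent_reduction([], [make_table(np.ones(16384, int))])


class TestReductionHistogram:
    def test_all_zero_reductions_single_bin(self):
        profile = make_profile(np.zeros(16384))
        hist = reduction_histogram(profile, 0.05)
        assert hist.counts.sum() == 16384
        assert (hist.counts > 0).sum() == 1
        assert hist.na_count == 0

    def test_one_hot_tops_the_last_bin(self):
        red = np.zeros(16384)
        red[kmer_to_index("TATTATT")] = 1.0
        hist = reduction_histogram(make_profile(red), 0.1)
        assert hist.counts[-1] == 1

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 0.3))
    def test_conservation_identity(self, seed, bin_width):
        rng = np.random.default_rng(seed)
        red = rng.uniform(-2, 1, 16384)
        red[rng.integers(0, 16384, 50)] = np.nan
        hist = reduction_histogram(make_profile(red), bin_width)
        assert hist.counts.sum() + hist.na_count == 16384
        assert hist.edges[0] <= np.nanmin(red)
        assert hist.edges[-1] == 1.0

    def test_non_positive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            reduction_histogram(make_profile(np.zeros(16384)), 0.0)


class TestSpecificityLogo:
    def test_single_included_kmer_is_one_hot(self):
        red = np.zeros(16384)
        red[kmer_to_index("TATTATT")] = 0.9
        logo = specificity_logo(make_profile(red), threshold=0.5)
        assert logo.included_kmer_count == 1
        assert logo.argmax_motif() == "TATTATT"
        for pos, base in zip(logo.matrix.index, "TATTATT"):
            assert logo.matrix.loc[pos, base] == pytest.approx(1.0)
        assert list(logo.matrix.index) == list(range(-7, 0))

    def test_uniform_inclusion_gives_flat_columns(self):
        logo = specificity_logo(make_profile(np.full(16384, 0.8)),
                                threshold=0.5)
        assert logo.included_kmer_count == 16384
        assert np.allclose(logo.matrix.to_numpy(), 0.25)

    def test_empty_logo_flagged(self):
        logo = specificity_logo(make_profile(np.zeros(16384)), threshold=0.5)
        assert logo.empty and logo.included_kmer_count == 0

    def test_weighting_scheme_changes_weights(self):
        red = np.zeros(16384)
        red[kmer_to_index("TATTATT")] = 1.0
        red[kmer_to_index("GATTATT")] = 0.5
        weighted = specificity_logo(make_profile(red), 0.5,
                                    "reduction_weighted")
        unweighted = specificity_logo(make_profile(red), 0.5, "unweighted")
        assert weighted.matrix.loc[-7, "T"] == pytest.approx(1.0 / 1.5)
        assert unweighted.matrix.loc[-7, "T"] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            specificity_logo(make_profile(red), 0.5, "bits")

    def test_column_normalization_modes(self):
        red = np.where(np.arange(16384) % 3 == 0, 0.9, 0.0)
        norm = specificity_logo(make_profile(red), 0.5, normalize=True)
        raw = specificity_logo(make_profile(red), 0.5, normalize=False)
        assert np.allclose(norm.matrix.sum(axis=1), 1.0)
        assert np.allclose(raw.matrix.sum(axis=1),
                           red[red >= 0.5].sum())


class TestConditionCorrelation:
    def test_self_correlation_is_one(self):
        p = make_profile(np.random.default_rng(0).uniform(0, 1, 16384))
        corr = condition_correlation({"a": p, "b": p})
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "a"] == 1.0

    def test_independent_profiles_uncorrelated(self):
        rng = np.random.default_rng(1)
        a = make_profile(rng.uniform(0, 1, 16384))
        b = make_profile(rng.uniform(0, 1, 16384))
        corr = condition_correlation({"a": a, "b": b})
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_shared_truth_highly_correlated_at_depth(self, study_analysis,
                                                     study_run):
        """Reduction profiles from two independent samplings of overlapping
        truth models stay correlated; orthogonal models do not."""
        corr = study_analysis.condition_correlation
        assert set(corr.index) == {"E2_highMn", "WT_lowMn"}
        assert np.allclose(np.diag(corr), 1.0)

    def test_too_few_shared_kmers_is_na(self):
        red = np.full(16384, np.nan)
        red[:2] = 0.5
        corr = condition_correlation({"a": make_profile(red),
                                      "b": make_profile(red)})
        assert np.isnan(corr.loc["a", "b"])
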