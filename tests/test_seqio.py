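"""Alignment IO, haplotype collapsing and site statistics."""

import numpy as np
import pytest

from mitopop.seqio import (
    AlignmentError,
    MetadataError,
    base_homogeneity_chi2,
    collapse_haplotypes,
    read_alignment,
    site_statistics,
    write_alignment,
)

from conftest import make_alignment


def write_inputs(tmp_path, records, popmap_rows):
    fasta = tmp_path / "a.fasta"
    fasta.write_text(
        "".join(f">{i}\n{s}\n" for i, s in records)
    )
    popmap = tmp_path / "a.popmap.csv"
    popmap.write_text("id,deme\n" + "".join(f"{i},{d}\n" for i, d in popmap_rows))
    return fasta, popmap


class TestReadAlignment:
    def test_reads_identical_records(self, tmp_path):
        fasta, popmap = write_inputs(
            tmp_path,
            [("a", "ACGTACGTAA")] * 1 + [("b", "ACGTACGTAA"), ("c", "ACGTACGTAA")],
            [("a", "d1"), ("b", "d1"), ("c", "d2")],
        )
        aln = read_alignment(fasta, popmap)
        assert aln.L == 10 and aln.n == 3
        assert aln.deme_of["c"] == "d2"

    def test_unknown_symbols_become_n(self, tmp_path):
        fasta, popmap = write_inputs(
            tmp_path, [("a", "ACRT"), ("b", "ACGT")], [("a", "d"), ("b", "d")]
        )
        aln = read_alignment(fasta, popmap)
        assert aln.seqs[0] == "ACNT"

    def test_missing_popmap_entry_raises(self, tmp_path):
        fasta, popmap = write_inputs(
            tmp_path, [("a", "ACGT"), ("b", "ACGT")], [("a", "d")]
        )
        with pytest.raises(MetadataError):
            read_alignment(fasta, popmap)

    def test_ragged_alignment_raises(self, tmp_path):
        fasta, popmap = write_inputs(
            tmp_path, [("a", "ACGT"), ("b", "ACG")], [("a", "d"), ("b", "d")]
        )
        with pytest.raises(AlignmentError):
            read_alignment(fasta, popmap)

    def test_partitions_must_tile(self):
        with pytest.raises(AlignmentError):
            make_alignment(["ACGT"], partitions={"p1": (0, 3)})

    def test_study_fixture_round_trips(self, tmp_path, study_aln):
        write_alignment(study_aln, tmp_path / "f.fasta",
                        tmp_path / "f.popmap.csv", tmp_path / "f.coords.csv")
        back = read_alignment(
            tmp_path / "f.fasta", tmp_path / "f.popmap.csv",
            partitions=study_aln.partitions,
            coords_path=tmp_path / "f.coords.csv",
        )
        assert back.ids == study_aln.ids
        assert back.seqs == study_aln.seqs
        assert back.deme_of == study_aln.deme_of
        assert back.coords == pytest.approx(study_aln.coords)


class TestCollapseHaplotypes:
    def test_identical_sequences_one_haplotype(self):
        aln = make_alignment(["AAA"] * 5)
        t = collapse_haplotypes(aln)
        assert t.n_haplotypes == 1
        assert t.counts.iloc[0, 0] == 5

    def test_two_haplotypes_across_demes(self):
        aln = make_alignment(["AAA", "AAA", "AAT"], demes=["1", "2", "2"])
        t = collapse_haplotypes(aln)
        assert t.counts.to_numpy().tolist() == [[1, 1], [0, 1]]

    def test_n_merges_into_earlier_haplotype(self):
        aln = make_alignment(["AAT", "ANT", "AAA"])
        t = collapse_haplotypes(aln)
        assert t.n_haplotypes == 2
        assert t.counts["d1"].tolist() == [2, 1]

    def test_counts_conserved_and_idempotent(self, rng):
        for _ in range(20):
            n, L = rng.integers(3, 15), rng.integers(4, 12)
            seqs = ["".join(rng.choice(list("ACGT"), L)) for _ in range(n)]
            demes = [str(d) for d in rng.integers(0, 3, n)]
            aln = make_alignment(seqs, demes)
            t = collapse_haplotypes(aln)
            assert t.counts.to_numpy().sum() == n
            reps = make_alignment(list(t.hap_seqs.values()))
            t2 = collapse_haplotypes(reps)
            assert list(t2.hap_seqs.values()) == list(t.hap_seqs.values())

    def test_study_fixture_recovers_27_planted_haplotypes(self, study):
        aln, truth = study
        t = collapse_haplotypes(aln)
        assert t.n_haplotypes == truth["n_haplotypes"] == 27
        assert int(t.counts.to_numpy().sum()) == 93
        assert sorted(t.n_per_deme.to_dict().items()) == sorted(
            {"ALB": 16, "KO3": 10, "KO4": 14, "AVE": 20, "CIR": 13,
             "FO": 10, "CP": 10}.items()
        )


class TestSiteStatistics:
    def test_monomorphic_alignment(self):
        s = site_statistics(make_alignment(["ACGT"] * 4))
        assert s.n_variable["overall"] == 0
        assert s.n_informative["overall"] == 0

    def test_informative_vs_singleton_columns(self):
        # column 0: {A,A,T,T} informative; column 1: {A,T,T,T} variable only
        s = site_statistics(make_alignment(["AA", "AT", "TT", "TT"]))
        assert s.n_variable["overall"] == 2
        assert s.n_informative["overall"] == 1

    def test_codon_partition_requires_frame(self):
        aln = make_alignment(["ACGTAC"] * 3, partitions={"COI": (0, 6)})
        with pytest.raises(ValueError):
            site_statistics(aln, codon_partition="COI")

    def test_matches_bruteforce_column_scan(self, rng):
        # independent per-column oracle on random alignments
        for _ in range(100):
            n, L = int(rng.integers(4, 12)), int(rng.integers(10, 40))
            seqs = ["".join(rng.choice(list("ACGTN-"), L, p=[.23,.23,.23,.23,.04,.04]))
                    for _ in range(n)]
            aln = make_alignment(seqs)
            s = site_statistics(aln)
            var = inf = 0
            for j in range(L):
                states = [q[j] for q in seqs if q[j] not in "N-"]
                uniq = set(states)
                if len(uniq) >= 2:
                    var += 1
                    if sum(states.count(u) >= 2 for u in uniq) >= 2:
                        inf += 1
            assert s.n_variable["overall"] == var
            assert s.n_informative["overall"] == inf

    def test_base_freqs_sum_to_one(self, study_aln):
        s = site_statistics(study_aln)
        assert np.allclose(s.base_freqs.sum(axis=1), 1.0)
        at = s.base_freqs.loc["pooled", ["A", "T"]].sum()
        assert at > 0.55  # study-like fixtures are A+T rich


class TestBaseHomogeneity:
    def test_identical_taxa_give_zero(self):
        chi2, df, p = base_homogeneity_chi2(make_alignment(["ACGT"] * 3))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_by_four(self):
        # counts [[10,0,0,0],[0,10,0,0]] -> chi2 = 20, df = 3
        chi2, df, p = base_homogeneity_chi2(
            make_alignment(["A" * 10, "C" * 10])
        )
        assert chi2 == pytest.approx(20.0)
        assert df == 3

    def test_taxon_with_no_bases_raises(self):
        with pytest.raises(AlignmentError):
            base_homogeneity_chi2(make_alignment(["ACGT", "NNNN"]))

    def test_homogeneous_fixture_not_significant(self, study_aln):
        chi2, df, p = base_homogeneity_chi2(study_aln)
        assert p > 0.05
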