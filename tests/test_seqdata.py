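"""Alignment I/O, pseudogene screening, codon frequencies, identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonsel.genetics import MISSING, STANDARD_CODE
from codonsel.seqdata import (
    AlignmentError,
    FrameError,
    estimate_frequencies,
    pairwise_identity,
    read_codon_alignment,
    screen_orfs,
    write_codon_alignment,
)

from conftest import make_alignment


def write_fasta(tmp_path, records, name="a.fasta"):
    path = tmp_path / name
    path.write_text("".join(f">{n}\n{s}\n" for n, s in records.items()))
    return path


class TestReading:
    def test_decodes_codons(self, tmp_path):
        path = write_fasta(tmp_path, {"s1": "ATGAAA", "s2": "ATGCCC"})
        aln = read_codon_alignment(path)
        assert aln.length == 2
        idx = STANDARD_CODE.index
        assert list(aln.row("s1")) == [idx["ATG"], idx["AAA"]]

    def test_frame_error_names_sequence(self, tmp_path):
        path = write_fasta(tmp_path, {"bad": "ATGAAAG"})
        with pytest.raises(FrameError, match="bad"):
            read_codon_alignment(path)

    def test_unequal_lengths_rejected(self, tmp_path):
        path = write_fasta(tmp_path, {"s1": "ATGAAA", "s2": "ATG"})
        with pytest.raises(AlignmentError):
            read_codon_alignment(path)

    def test_ambiguity_and_gaps_become_missing(self, tmp_path):
        path = write_fasta(tmp_path, {"s1": "ATGN--AAA", "s2": "ATGCCCAAA"})
        aln = read_codon_alignment(path)
        assert aln.row("s1")[1] == MISSING
        assert aln.row("s1")[0] != MISSING

    def test_phylip_relaxed_sequential(self, tmp_path):
        path = tmp_path / "a.phy"
        path.write_text(" 2 6\nlong_name_one ATGAAA\ns2 ATGCCC\n")
        aln = read_codon_alignment(path, format="phylip")
        assert aln.taxa == ["long_name_one", "s2"]
        assert aln.length == 2

    @pytest.mark.parametrize("fmt", ["fasta", "phylip"])
    def test_write_read_round_trip(self, tmp_path, fmt):
        recs = {"s1": "ATGAAACCC", "s2": "ATG---CCC", "s3": "ATGAAATTT"}
        aln = read_codon_alignment(write_fasta(tmp_path, recs))
        out = tmp_path / f"rt.{fmt}"
        write_codon_alignment(aln, out, format=fmt)
        back = read_codon_alignment(out, format=fmt)
        assert back.taxa == aln.taxa
        assert back.nuc_seqs == aln.nuc_seqs


class TestOrfScreen:
    def test_premature_stop_excluded(self):
        aln = make_alignment({"ok": "ATGAAACCC", "bad": "ATGTAACCC"})
        kept, report = screen_orfs(aln)
        assert report.status == {"ok": "kept", "bad": "premature-stop"}
        assert kept.taxa == ["ok"]

    def test_terminal_stop_is_fine(self):
        aln = make_alignment({"s1": "ATGAAATAA", "s2": "ATGAAAGGG"})
        kept, report = screen_orfs(aln)
        assert report.status["s1"] == "kept"

    def test_frameshift_gap_run_excluded(self):
        # a single-nucleotide deletion breaks the reading frame
        aln = make_alignment({"ok": "ATGAAACCC", "fs": "ATGA-ACCC"})
        _, report = screen_orfs(aln)
        assert report.status["fs"] == "frameshift"

    def test_codon_sized_gap_kept(self):
        aln = make_alignment({"s1": "ATGAAACCC", "s2": "ATG---CCC"})
        kept, _ = screen_orfs(aln)
        assert set(kept.taxa) == {"s1", "s2"}

    def test_idempotent(self):
        aln = make_alignment(
            {"ok": "ATGAAACCC", "bad": "ATGTAACCC", "fs": "ATGA-ACCC"}
        )
        kept, _ = screen_orfs(aln)
        again, rep2 = screen_orfs(kept)
        assert again.taxa == kept.taxa
        assert all(s == "kept" for s in rep2.status.values())

    def test_all_pseudogenes_is_an_error(self):
        aln = make_alignment({"bad": "ATGTAACCC"})
        with pytest.raises(AlignmentError, match="no functional"):
            screen_orfs(aln)


class TestFrequencies:
    def test_equal_is_exactly_uniform(self):
        aln = make_alignment({"s1": "ATGAAA"})
        f = estimate_frequencies(aln, "equal")
        assert np.all(f.pi == 1.0 / 61)

    def test_f61_count_dominance(self):
        aln = make_alignment({"s1": "AAAAAAAAA", "s2": "AAAAAAAAA"})
        f = estimate_frequencies(aln, "F61")
        assert np.argmax(f.pi) == STANDARD_CODE.index["AAA"]

    def test_f3x4_matches_enumeration_oracle(self):
        # oracle: count positional nucleotides (with the 0.5 pseudocount),
        # enumerate all 61 sense codons, multiply, renormalize
        recs = {"s1": "ATGAAACCC", "s2": "ATGCTTCCA"}
        aln = make_alignment(recs)
        counts = {p: {n: 0.5 for n in "TCAG"} for p in range(3)}
        for seq in recs.values():
            for i in range(0, len(seq), 3):
                for p in range(3):
                    counts[p][seq[i + p]] += 1
        freqs = {
            p: {n: c / sum(counts[p].values()) for n, c in counts[p].items()}
            for p in range(3)
        }
        expect = np.array(
            [
                freqs[0][c[0]] * freqs[1][c[1]] * freqs[2][c[2]]
                for c in STANDARD_CODE.sense_codons
            ]
        )
        expect /= expect.sum()
        got = estimate_frequencies(aln, "F3x4")
        np.testing.assert_allclose(got.pi, expect, atol=1e-12)

    @pytest.mark.parametrize("scheme", ["equal", "F1x4", "F3x4", "F61"])
    def test_all_schemes_sum_to_one_and_positive(self, scheme):
        aln = make_alignment({"s1": "ATGAAACCCGGG", "s2": "ATGAAACCAGGA"})
        f = estimate_frequencies(aln, scheme)
        assert abs(f.pi.sum() - 1.0) < 1e-12
        assert np.all(f.pi > 0)


class TestIdentity:
    def test_self_identity_is_100(self):
        aln = make_alignment({"s1": "ATGAAACCC", "s2": "ATGAAATTT"})
        assert pairwise_identity(aln, "s1", "s1") == 100

    def test_hand_computed_value(self):
        # 5 of 6 shared nucleotides identical -> 83%
        aln = make_alignment({"s1": "ATGAAA", "s2": "ATGAAC"})
        assert pairwise_identity(aln, "s1", "s2", "nucleotide") == 83
        # AAA vs AAC: K vs N -> 1 of 2 amino acids -> 50%
        assert pairwise_identity(aln, "s1", "s2", "amino-acid") == 50

    @pytest.mark.parametrize("level", ["nucleotide", "amino-acid"])
    def test_symmetric(self, level):
        aln = make_alignment({"s1": "ATGAAACCC", "s2": "ATGCAATCC"})
        assert pairwise_identity(aln, "s1", "s2", level) == pairwise_identity(
            aln, "s2", "s1", level
        )

    def test_missing_columns_excluded(self):
        aln = make_alignment({"s1": "ATG---CCC", "s2": "ATGAAACCC"})
        assert pairwise_identity(aln, "s1", "s2") == 100

    def test_no_shared_columns_is_error(self):
        aln = make_alignment({"s1": "ATG---", "s2": "---AAA"})
        with pytest.raises(AlignmentError):
            pairwise_identity(aln, "s1", "s2")


@settings(max_examples=25, deadline=None)
@given(
    st.lists(
        st.sampled_from(STANDARD_CODE.sense_codons), min_size=2, max_size=30
    ),
    st.integers(0, 2**31 - 1),
)
def test_frequency_schemes_normalize_on_random_alignments(codons, seed):
    rng = np.random.default_rng(seed)
    seqs = {}
    for i in range(3):
        picks = rng.permutation(codons)
        seqs[f"t{i}"] = "".join(picks)
    aln = make_alignment(seqs)
    for scheme in ("F1x4", "F3x4", "F61"):
        f = estimate_frequencies(aln, scheme)
        assert abs(f.pi.sum() - 1.0) < 1e-12
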