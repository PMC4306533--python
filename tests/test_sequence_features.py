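"""Family-discriminating positions, N-terminal charge, numbering maps."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capbind import synthetic_data as sd
from capbind.binding_model import ValidationError
from capbind.sequence_features import (
    AlignmentFormatError,
    LabelledAlignment,
    find_discriminating_positions,
    load_numbering_offsets,
    load_site_annotations,
    map_numbering,
    nterm_charge,
    read_alignment,
    write_alignment,
)


def brute_force_positions(aln, threshold, gap_policy="strict"):
    """Independent per-column enumeration of discriminating positions."""
    fam_a, fam_b = aln.families
    hits = []
    for col in range(aln.length):
        result = {}
        ok = True
        for fam, rows in (("a", aln.family(fam_a)), ("b", aln.family(fam_b))):
            residues = [s[col] for s in rows]
            if gap_policy == "strict" and "-" in residues:
                ok = False
                break
            residues = [r for r in residues if r != "-"]
            if not residues:
                ok = False
                break
            counts = Counter(residues)
            modal, n = counts.most_common(1)[0]
            result[fam] = (modal, n / len(residues))
        if not ok:
            continue
        (ma, ca), (mb, cb) = result["a"], result["b"]
        if ma != mb and ca >= threshold and cb >= threshold:
            hits.append(col)
    return hits


class TestReadAlignment:
    def test_fasta_fixture(self, toy_alignment_files):
        fasta, _, labels = toy_alignment_files
        aln = read_alignment(fasta, "fasta", labels)
        assert len(aln.sequences) == 4
        assert aln.length == 8
        assert aln.reference_id == "a1"

    def test_clustal_and_fasta_agree(self, toy_alignment_files):
        fasta, clustal, labels = toy_alignment_files
        a1 = read_alignment(fasta, "fasta", labels)
        a2 = read_alignment(clustal, "clustal", labels)
        assert a1.sequences == a2.sequences

    def test_round_trips_through_writer(self, toy_alignment_files, tmp_path):
        fasta, _, labels = toy_alignment_files
        aln = read_alignment(fasta, "fasta", labels)
        out = tmp_path / "rt.fasta"
        write_alignment(aln, out)
        back = read_alignment(out, "fasta", labels)
        assert back.sequences == aln.sequences

    def test_ragged_fasta_rejected(self, tmp_path):
        bad = tmp_path / "ragged.fasta"
        bad.write_text(">a\nMKWE\n>b\nMKW\n")
        with pytest.raises(AlignmentFormatError):
            read_alignment(bad, "fasta", {"a": "A", "b": "B"})

    def test_unlabeled_sequence_rejected(self, toy_alignment_files):
        fasta, _, labels = toy_alignment_files
        labels = dict(labels)
        del labels["b2"]
        with pytest.raises(ValidationError):
            read_alignment(fasta, "fasta", labels)


class TestDiscriminatingPositions:
    def _aln(self, rows):
        return LabelledAlignment(sequences=rows, reference_id=rows[0][0])

    def test_perfect_split_reported(self, toy_alignment_files):
        fasta, _, labels = toy_alignment_files
        aln = read_alignment(fasta, "fasta", labels)
        hits = find_discriminating_positions(aln, threshold=1.0)
        assert [h.column for h in hits] == [3]  # E vs S column
        assert hits[0].consensus_a == "E"
        assert hits[0].consensus_b == "S"
        assert hits[0].conservation_a == 1.0
        assert hits[0].conservation_b == 1.0
        assert hits[0].reference_position == 4

    def test_identical_column_not_reported(self):
        rows = [
            ("a1", "A", "MW"), ("a2", "A", "MW"),
            ("b1", "B", "MW"), ("b2", "B", "MW"),
        ]
        assert find_discriminating_positions(self._aln(rows)) == []

    def test_threshold_gates_imperfect_conservation(self):
        """7/8 within-family consensus passes at 0.85, fails at strict 1.0."""
        a_rows = [("a%d" % i, "A", "E") for i in range(8)]
        b_rows = [("b%d" % i, "B", "S") for i in range(7)] + [("b7", "B", "T")]
        aln = self._aln(a_rows + b_rows)
        strict = find_discriminating_positions(aln, threshold=1.0)
        loose = find_discriminating_positions(aln, threshold=0.85)
        assert strict == []
        assert [h.column for h in loose] == [0]
        assert loose == [
            h for h in loose if h.column in brute_force_positions(aln, 0.85)
        ]

    def test_gap_policies(self):
        rows = [
            ("a1", "A", "E-"), ("a2", "A", "EE"),
            ("b1", "B", "SS"), ("b2", "B", "SS"),
        ]
        aln = self._aln(rows)
        strict = find_discriminating_positions(aln, threshold=1.0, gap_policy="strict")
        ignore = find_discriminating_positions(aln, threshold=1.0, gap_policy="ignore")
        assert [h.column for h in strict] == [0]  # column 1 has a gap in family A
        assert [h.column for h in ignore] == [0, 1]

    def test_small_family_rejected(self):
        rows = [("a1", "A", "E"), ("b1", "B", "S"), ("b2", "B", "S")]
        with pytest.raises(ValidationError):
            find_discriminating_positions(self._aln(rows))

    def test_annotation_tags_nearby_sites(self, toy_alignment_files):
        fasta, _, labels = toy_alignment_files
        aln = read_alignment(fasta, "fasta", labels)
        hits = find_discriminating_positions(
            aln, annotations={5: "cap-pocket"}, near_window=2
        )
        assert hits[0].near_site == "cap-pocket"  # position 4, site 5, |d|=1

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n_disc=st.integers(0, 10),
        noise=st.floats(0.0, 0.3),
        threshold=st.sampled_from([0.75, 0.875, 1.0]),
    )
    def test_matches_brute_force_on_random_alignments(self, seed, n_disc, noise, threshold):
        seqs, _ = sd.simulate_family_alignment(
            n_per_family=8, length=40, n_discriminating=n_disc,
            within_family_noise=noise, seed=seed,
        )
        aln = LabelledAlignment(sequences=seqs, reference_id=seqs[0][0])
        got = [h.column for h in find_discriminating_positions(aln, threshold=threshold)]
        assert got == brute_force_positions(aln, threshold)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000), noise=st.floats(0.0, 0.3))
    def test_raising_threshold_never_adds_positions(self, seed, noise):
        seqs, _ = sd.simulate_family_alignment(
            n_per_family=6, length=30, n_discriminating=5,
            within_family_noise=noise, seed=seed,
        )
        aln = LabelledAlignment(sequences=seqs, reference_id=seqs[0][0])
        lo = {h.column for h in find_discriminating_positions(aln, threshold=0.75)}
        hi = {h.column for h in find_discriminating_positions(aln, threshold=1.0)}
        assert hi <= lo


class TestNtermCharge:
    @pytest.mark.parametrize(
        "seq, window, expected",
        [
            ("KKRK", 4, 4),
            ("DDEE", 4, -4),
            ("MKKRDE", 6, 1),
            ("", 0, 0),
            ("MAHH", 4, 0),
        ],
    )
    def test_examples(self, seq, window, expected):
        assert nterm_charge(seq, window) == expected

    def test_histidine_configurable(self):
        assert nterm_charge("HH", 2, his_charge=1) == 2

    def test_window_tiling_is_additive(self):
        seq = "MKKRDEWKDERK"
        total = nterm_charge(seq, 12)
        assert total == nterm_charge(seq[:6], 6) + nterm_charge(seq[6:], 6)

    def test_errors(self):
        with pytest.raises(ValidationError):
            nterm_charge("MK-X", 4)
        with pytest.raises(ValidationError):
            nterm_charge("MK", 5)


class TestNumbering:
    def test_frog_1a_to_1b_shift(self):
        # the 1a convention runs 4 residues behind: Trp98 -> Trp102
        assert map_numbering(98, 4) == 102
        assert map_numbering(206, 4) == 210
        assert map_numbering(207, 4) == 211

    def test_zero_offset_identity(self):
        assert map_numbering(55, 0) == 55

    def test_below_one_rejected(self):
        with pytest.raises(ValidationError):
            map_numbering(3, -4)

    def test_bundled_offsets_and_annotations(self):
        offsets = load_numbering_offsets()
        assert offsets["heIF4E1a"] == 0
        assert offsets["XeIF4E1b"] == 0
        assert offsets["XeIF4E1a"] == 4
        sites = load_site_annotations()
        assert "cap-pocket" in sites[102]
        assert "cap-pocket" in sites[210]
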