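"""Reference families, the built-in aligner and consensus-probe extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import (
    consensus_oracle,
    global_enumeration_score,
    maximal_runs_oracle,
)
from phenoscreen.families import (
    ConsensusProbe,
    MultipleAlignment,
    ProbeConfig,
    ReferenceFamily,
    align_family,
    call_consensus_columns,
    extract_probes,
    read_alignment,
    read_family,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _aln(rows, family_id="fam"):
    return MultipleAlignment(
        rows=tuple((f"s{i}", r) for i, r in enumerate(rows)),
        family_id=family_id,
    )


class TestReadFamily:
    def test_toy_fasta_round_trip(self, tmp_path):
        p = tmp_path / "fam.fasta"
        p.write_text(">a\nACDE\n>b\nACDF\n>c\nACDY\n")
        fam = read_family(p, "PH")
        assert [m[0] for m in fam.members] == ["a", "b", "c"]
        assert fam.members[1] == ("b", "ACDF")

    def test_duplicate_header_names_the_id(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACDE\n>a\nACDF\n")
        with pytest.raises(ValueError, match="'a'"):
            read_family(p, "PH")

    def test_forty_member_family(self, tmp_path, rng):
        # family of the size of a typical curated PH reference set
        recs = "".join(
            f">ph{i:02d}\n" + "".join(rng.choice(list(AA), 50)) + "\n"
            for i in range(40)
        )
        p = tmp_path / "ph.fasta"
        p.write_text(recs)
        assert len(read_family(p, "PH")) == 40

    @pytest.mark.parametrize("bad", [">a\nAC1E\n>b\nACDE\n", ""])
    def test_bad_input_rejected(self, tmp_path, bad):
        p = tmp_path / "bad.fasta"
        p.write_text(bad)
        with pytest.raises(ValueError):
            read_family(p, "X")

    def test_single_member_family_rejected(self):
        with pytest.raises(ValueError, match=">=2"):
            ReferenceFamily("X", (("only", "ACDE"),))


class TestAlignFamily:
    def test_identical_sequences_align_gapless(self):
        fam = ReferenceFamily("X", (("a", "MKVL" * 5), ("b", "MKVL" * 5)))
        aln = align_family(fam)
        assert aln.n_cols == 20
        assert all("-" not in s for _, s in aln.rows)

    def test_pairwise_matches_enumeration_oracle(self):
        fam = ReferenceFamily("X", (("a", "ACDE"), ("b", "ACE")))
        aln = align_family(fam)
        assert aln.n_cols == 4
        assert aln.rows[1][1].count("-") == 1
        best, (ga, gb) = global_enumeration_score("ACDE", "ACE")
        assert (aln.rows[0][1], aln.rows[1][1]) == (ga, gb)

    def test_prealigned_passes_through(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAC-DE\n>b\nACWDE\n")
        aln = read_alignment(p, "X")
        assert align_family(aln) is aln

    def test_degap_recovers_members(self, rng):
        members = tuple(
            (f"m{i}", "".join(rng.choice(list(AA), rng.integers(20, 40))))
            for i in range(5)
        )
        aln = align_family(ReferenceFamily("X", members))
        assert tuple(aln.degapped()) == members

    def test_single_member_errors(self):
        fam = ReferenceFamily.__new__(ReferenceFamily)  # bypass invariant
        object.__setattr__(fam, "family_id", "X")
        object.__setattr__(fam, "members", (("a", "ACDE"),))
        with pytest.raises(ValueError, match="pre-aligned"):
            align_family(fam)


class TestConsensus:
    @pytest.mark.parametrize(
        "column, tau, expect",
        [
            (["A", "A", "A", "G"], 0.5, (True, "A")),  # 3/4 >= 1/2
            (["W", "W"], 1.0, (True, "W")),            # unanimous
            (["A", "A", "G", "G"], 0.5, (True, "A")),  # modal tie -> alphabetical
            (["A", "G", "C", "T"], 0.5, (False, None)),
            (["A", "A", "-", "-"], 0.5, (True, "A")),  # gaps count in denominator
            (["A", "-", "-", "-"], 0.5, (False, None)),
        ],
    )
    def test_column_calls(self, column, tau, expect):
        aln = _aln(["".join(column[i]) for i in range(len(column))])
        calls = call_consensus_columns(aln, ProbeConfig(consensus_threshold=tau))
        assert calls[0] == expect

    def test_matches_oracle_on_random_alignments(self, rng):
        for _ in range(50):
            n, m = rng.integers(2, 10), rng.integers(1, 50)
            rows = [
                "".join(rng.choice(list(AA + "---"), m)) for _ in range(n)
            ]
            aln = _aln(rows)
            got = call_consensus_columns(aln, ProbeConfig())
            assert got == consensus_oracle(rows, 0.5)

    def test_raising_tau_never_adds_callable_columns(self, rng):
        rows = ["".join(rng.choice(list(AA[:4] + "-"), 40)) for _ in range(6)]
        aln = _aln(rows)
        n_callable = [
            sum(ok for ok, _ in call_consensus_columns(aln, ProbeConfig(t)))
            for t in (0.3, 0.5, 0.7, 0.9, 1.0)
        ]
        assert n_callable == sorted(n_callable, reverse=True)


class TestExtractProbes:
    def _calls(self, pattern, residue="A"):
        return [(c == "1", residue if c == "1" else None) for c in pattern]

    def test_single_run_with_span(self):
        pattern = "000" + "1" * 10 + "00"
        aln = _aln(["A" * len(pattern)] * 2)
        probes = extract_probes(aln, self._calls(pattern), ProbeConfig())
        assert len(probes) == 1
        assert probes[0].column_span == (3, 13)
        assert probes[0].sequence == "A" * 10

    def test_short_runs_dropped(self):
        pattern = "11111" + "0" + "1" * 9
        aln = _aln(["A" * len(pattern)] * 2)
        probes = extract_probes(aln, self._calls(pattern), ProbeConfig())
        assert [p.column_span for p in probes] == [(6, 15)]

    def test_fully_conserved_alignment_gives_one_probe(self):
        aln = _aln(["MKVLWAALLVTFLAGCQAKVEQAVETEPEPELRQQT" + "DEWQ"] * 3)
        calls = call_consensus_columns(aln, ProbeConfig())
        probes = extract_probes(aln, calls, ProbeConfig())
        assert len(probes) == 1
        assert probes[0].sequence == aln.rows[0][1]

    def test_no_long_run_warns_and_returns_empty(self, caplog):
        aln = _aln(["AAAA"] * 2)
        calls = self._calls("1111")
        with caplog.at_level("WARNING"):
            probes = extract_probes(aln, calls, ProbeConfig(min_region_len=8))
        assert probes == []
        assert any("conserved run" in r.message for r in caplog.records)

    def test_matches_run_oracle_and_lmin_monotone(self, rng):
        for _ in range(30):
            pattern = "".join(rng.choice(["0", "1"], 50))
            aln = _aln(["A" * 50] * 2)
            counts = []
            for lmin in (2, 4, 8):
                cfg = ProbeConfig(min_region_len=lmin)
                probes = extract_probes(aln, self._calls(pattern), cfg)
                flags = [c == "1" for c in pattern]
                assert [p.column_span for p in probes] == maximal_runs_oracle(
                    flags, lmin
                )
                counts.append(len(probes))
            assert counts == sorted(counts, reverse=True)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(
        st.text(alphabet=AA, min_size=5, max_size=30), min_size=2, max_size=6
    )
)
def test_alignment_degap_round_trip_property(seqs):
    """Degapping any alignment row reproduces the member byte-for-byte."""
    members = tuple((f"s{i}", s) for i, s in enumerate(seqs))
    aln = align_family(ReferenceFamily("X", members))
    assert tuple(aln.degapped()) == members


def test_probe_invariants_enforced():
    with pytest.raises(ValueError):
        ConsensusProbe("p", "f", "AC-DE", (0, 5))
    with pytest.raises(ValueError):
        ConsensusProbe("p", "f", "ACDE", (0, 5))
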