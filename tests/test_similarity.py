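"""Local alignment, hit qualification and BLAST tabular ingestion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panstrep import (
    BLAST12,
    BLAST14,
    OrthologueCriteria,
    SimilarityHit,
    all_vs_all,
    hit_passes,
    local_align,
    read_blast_tab,
)
from panstrep.errors import ConfigurationError, InputFormatError
from panstrep.similarity import candidate_pairs

from oracles import sw_gotoh


def make_hit(identity=85.0, qcov=0.9, scov=0.8, evalue=1e-20):
    return SimilarityHit(
        query_id="a",
        subject_id="b",
        percent_identity=identity,
        alignment_length=100,
        query_coverage=qcov,
        subject_coverage=scov,
        evalue=evalue,
        bitscore=100.0,
    )


class TestLocalAlign:
    def test_self_alignment_is_perfect(self):
        aln = local_align("PELICAN", "PELICAN")
        assert aln.percent_identity == 100.0
        assert aln.query_coverage == 1.0
        assert aln.subject_coverage == 1.0

    def test_matches_dp_oracle_on_worked_pair(self):
        aln = local_align("PELICAN", "COELACANTH")
        score, identity, qcov, scov, length = sw_gotoh("PELICAN", "COELACANTH")
        assert aln.score == score
        assert aln.percent_identity == pytest.approx(identity)
        assert aln.query_coverage == pytest.approx(qcov)
        assert aln.subject_coverage == pytest.approx(scov)
        assert aln.alignment_length == length

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            a = "".join(aa[i] for i in rng.integers(20, size=rng.integers(20, 70)))
            b = list(a)
            for pos in rng.choice(len(a), size=len(a) // 4, replace=False):
                b[pos] = aa[rng.integers(20)]
            b = "".join(b)
            oracle = sw_gotoh(a, b)
            aln = local_align(a, b)
            assert aln.score == oracle[0]
            assert aln.percent_identity == pytest.approx(oracle[1])
            assert aln.alignment_length == oracle[4]

    def test_all_mismatch_pair_yields_empty_hit(self):
        # A vs W scores negative under BLOSUM62: no positive local alignment
        assert local_align("AAAA", "WWWW") is None

    def test_invalid_residue_error_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            local_align("AC1DEF", "ACDEF")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_align("", "ACDEF")


class TestHitPasses:
    @pytest.mark.parametrize(
        "identity, qcov, scov, evalue, expected",
        [
            (85.0, 0.9, 0.8, 1e-20, True),
            # thresholds inclusive for identity/coverage, strict for E-value
            (80.0, 0.70, 0.70, 9.9e-6, True),
            (79.999, 0.70, 0.70, 1e-20, False),
            (80.0, 0.70, 0.70, 1e-5, False),  # E-value exactly at threshold
            (85.0, 0.9, 0.69, 1e-20, False),  # both sequences must be covered
            (85.0, 0.69, 0.9, 1e-20, False),
            (100.0, 1.0, 1.0, 1e-300, True),
        ],
    )
    def test_boundary_semantics(self, identity, qcov, scov, evalue, expected):
        hit = make_hit(identity, qcov, scov, evalue)
        assert hit_passes(hit, OrthologueCriteria()) is expected

    @given(
        identity=st.floats(0, 100),
        qcov=st.floats(0.01, 1.0),
        scov=st.floats(0.01, 1.0),
        evalue=st.floats(0, 1),
        d_identity=st.floats(0, 20),
        d_cov=st.floats(0, 0.3),
    )
    @settings(max_examples=200, deadline=None)
    def test_tightening_criteria_never_adds_hits(
        self, identity, qcov, scov, evalue, d_identity, d_cov
    ):
        hit = make_hit(identity, qcov, scov, evalue)
        loose = OrthologueCriteria()
        tight = OrthologueCriteria(
            min_identity=min(100.0, loose.min_identity + d_identity),
            min_coverage_both=min(1.0, loose.min_coverage_both + d_cov),
            max_evalue=loose.max_evalue / 10,
        )
        if hit_passes(hit, tight):
            assert hit_passes(hit, loose)


class TestAllVsAll:
    def test_identical_pair_gives_two_directed_hits(self):
        seq = "MKT" * 40  # length 120
        hits = all_vs_all({"g1_p": seq, "g2_p": seq})
        assert len(hits) == 2
        assert {(h.query_id, h.subject_id) for h in hits} == {
            ("g1_p", "g2_p"),
            ("g2_p", "g1_p"),
        }
        assert all(h.percent_identity == 100.0 for h in hits)

    def test_planted_identity_recovered(self):
        rng = np.random.default_rng(23)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        parent = "".join(aa[i] for i in rng.integers(20, size=200))
        child = list(parent)
        for pos in rng.choice(200, size=20, replace=False):
            child[pos] = aa[(aa.index(parent[pos]) + 1) % 20]
        hits = all_vs_all({"a": parent, "b": "".join(child)})
        assert hits[0].percent_identity == pytest.approx(90.0, abs=2.0)

    def test_prefilter_equals_exhaustive_on_qualifying_pairs(self):
        # mixed related/unrelated set; the k-mer prefilter must not
        # change the set of qualifying pairs
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        proteins = {}
        for g in range(15):  # 15 groups of 4 related sequences
            parent = "".join(aa[i] for i in rng.integers(20, size=120))
            for m in range(4):
                child = list(parent)
                for pos in rng.choice(120, size=6, replace=False):
                    child[pos] = aa[rng.integers(20)]
                proteins[f"r{g:02d}_{m}"] = "".join(child)
        for u in range(40):  # unrelated fillers
            proteins[f"u{u:02d}"] = "".join(aa[i] for i in rng.integers(20, size=120))
        criteria = OrthologueCriteria()
        fast = all_vs_all(proteins, criteria=criteria, prefilter=True)
        slow = all_vs_all(proteins, criteria=criteria, prefilter=False)
        pairs = lambda hits: {(h.query_id, h.subject_id) for h in hits}
        assert pairs(fast) == pairs(slow)

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            all_vs_all({"a": "ACDEF"})

    def test_candidate_pairs_require_shared_kmers(self):
        pairs = candidate_pairs({"a": "ACDEFGHIKL", "b": "ACDEFGHIKL", "c": "WWWWWWWWWW"})
        assert pairs == [("a", "b")]


class TestReadBlastTab:
    def _row(self, **overrides):
        base = dict(
            qseqid="p1", sseqid="p2", pident="85.0", length="70", mismatch="10",
            gapopen="0", qstart="1", qend="70", sstart="1", send="70",
            evalue="1e-20", bitscore="120", qlen="100", slen="100",
        )
        base.update(overrides)
        return "\t".join(base[c] for c in BLAST14)

    def test_coverage_from_span_and_length(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row() + "\n")
        result = read_blast_tab(path)
        (hit,) = result.hits
        assert hit.query_coverage == pytest.approx(0.70)
        assert hit.subject_coverage == pytest.approx(0.70)
        assert hit.evalue == 1e-20

    def test_self_hits_skipped_and_counted(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row(sseqid="p1") + "\n" + self._row() + "\n")
        result = read_blast_tab(path)
        assert len(result.hits) == 1
        assert result.n_self_hits_skipped == 1

    def test_twelve_column_dialect_is_configuration_error(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("irrelevant\n")
        with pytest.raises(ConfigurationError, match="qlen"):
            read_blast_tab(path, columns=BLAST12)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(self._row() + "\n" + self._row(qstart="xx") + "\n")
        with pytest.raises(InputFormatError, match="line 2"):
            read_blast_tab(path)
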