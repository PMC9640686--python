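"""Pairwise protein similarity: alignment, all-vs-all search, hit filtering.

Orthologue evidence is a directed pairwise hit that passes three
criteria at once: alignment identity >= 80%, alignment coverage >= 70%
of *both* sequences, and E-value < 1e-5.  Hits can either be computed
here (Smith-Waterman local alignment, desk-scale replacement for an
all-vs-all BLASTP) or ingested from BLAST tabular files; in the latter
case the file's E-values are authoritative.

Identity follows the BLAST ``pident`` convention: the denominator is
the full alignment length including gap columns.  Coverage is the
aligned span on each sequence divided by its full length (qcovs-like).
E-values for the built-in aligner use a Karlin-Altschul approximation
with fixed gapped BLOSUM62 parameters; at the thresholds used here the
identity and coverage criteria dominate, so the approximation serves
only as a filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, InputFormatError
from .io import ProteinRecord, iter_tsv_rows

logger = logging.getLogger(__name__)

# Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1
# (the BLAST defaults for proteins).
_KA_LAMBDA = 0.267
_KA_K = 0.041

# Residues scored directly by BLOSUM62; U/O/J are mapped to X before
# alignment, anything else is rejected.
_BLOSUM_RESIDUES = frozenset("ARNDCQEGHILKMFPSTWYVBZX")
_MAPPED_TO_X = frozenset("UOJ")


@dataclass(frozen=True)
class SimilarityHit:
    """A directed pairwise alignment result."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_coverage: float
    subject_coverage: float
    evalue: float
    bitscore: float

    def reversed(self) -> "SimilarityHit":
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            query_coverage=self.subject_coverage,
            subject_coverage=self.query_coverage,
        )


@dataclass(frozen=True)
class OrthologueCriteria:
    """Thresholds a hit must meet to count as orthologue evidence.

    Defaults: identity >= 80%, coverage >= 0.70 on both sequences
    (inclusive), E-value < 1e-5 (strict).
    """

    min_identity: float = 80.0
    min_coverage_both: float = 0.70
    max_evalue: float = 1e-5


def hit_passes(hit: SimilarityHit, criteria: OrthologueCriteria = OrthologueCriteria()) -> bool:
    """True iff the hit qualifies as orthologue evidence.

    Identity and coverage thresholds are inclusive; the E-value
    threshold is strict, matching the inequality directions of the
    clustering criteria.
    """
    return (
        hit.evalue < criteria.max_evalue
        and hit.percent_identity >= criteria.min_identity
        and min(hit.query_coverage, hit.subject_coverage) >= criteria.min_coverage_both
    )


@dataclass(frozen=True)
class LocalAlignment:
    """Summary of an optimal Smith-Waterman local alignment."""

    score: float
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    alignment_length: int
    evalue: float
    bitscore: float


def _validate_sequence(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    out = []
    for pos, ch in enumerate(seq.upper(), start=1):
        if ch in _BLOSUM_RESIDUES:
            out.append(ch)
        elif ch in _MAPPED_TO_X:
            out.append("X")
        else:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} of {which} sequence"
            )
    return "".join(out)


def _make_aligner(open_gap: float, extend_gap: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def bitscore_from_raw(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2)


def evalue_from_raw(raw_score: float, query_len: int, subject_len: int) -> float:
    return query_len * subject_len * 2.0 ** (-bitscore_from_raw(raw_score))


def local_align(
    query: str,
    subject: str,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
    matrix: str = "BLOSUM62",
) -> LocalAlignment | None:
    """Optimal local alignment of two amino-acid sequences.

    Returns ``None`` when no positive-scoring local alignment exists
    (an "empty hit", e.g. two sequences with no scoring residue pair).
    Gap scores follow the Biopython convention: ``open_gap`` is the
    score of the first gap column, ``extend_gap`` of each further one.
    """
    q = _validate_sequence(query, "query")
    s = _validate_sequence(subject, "subject")
    aligner = _make_aligner(open_gap, extend_gap, matrix)
    score = aligner.score(q, s)
    if score <= 0:
        return None
    return _alignment_stats(aligner, q, s, score)


def _alignment_stats(
    aligner: Align.PairwiseAligner, q: str, s: str, score: float
) -> LocalAlignment:
    aln = aligner.align(q, s)[0]
    counts = aln.counts()
    length = aln.length
    q_span = int(aln.coordinates[0, -1] - aln.coordinates[0, 0])
    s_span = int(aln.coordinates[1, -1] - aln.coordinates[1, 0])
    return LocalAlignment(
        score=float(score),
        percent_identity=100.0 * counts.identities / length,
        query_coverage=q_span / len(q),
        subject_coverage=s_span / len(s),
        alignment_length=int(length),
        evalue=evalue_from_raw(score, len(q), len(s)),
        bitscore=bitscore_from_raw(score),
    )


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def candidate_pairs(
    proteins: Mapping[str, str], k: int = 5, min_shared_kmers: int = 2
) -> list[tuple[str, str]]:
    """Unordered protein-id pairs sharing >= ``min_shared_kmers`` distinct k-mers.

    Inverted-index prefilter used to avoid aligning all O(n^2) pairs.
    Unrelated random sequences essentially never share two 5-mers, so
    at the 80%-identity threshold the prefilter is lossless in
    practice; an exhaustive no-prefilter mode is available for
    verification.
    """
    index: dict[str, list[str]] = {}
    for pid in sorted(proteins):
        for kmer in _kmer_set(proteins[pid], k):
            index.setdefault(kmer, []).append(pid)
    shared: dict[tuple[str, str], int] = {}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                pair = (bucket[i], bucket[j])
                shared[pair] = shared.get(pair, 0) + 1
    return sorted(p for p, n in shared.items() if n >= min_shared_kmers)


def all_vs_all(
    proteins: Iterable[ProteinRecord] | Mapping[str, str],
    criteria: OrthologueCriteria | None = None,
    prefilter: bool = True,
    k: int = 5,
    min_shared_kmers: int = 2,
) -> list[SimilarityHit]:
    """All-vs-all local alignment over a protein set.

    Every ordered pair with a positive-scoring local alignment yields a
    directed hit (two per unordered pair); self-pairs are excluded and
    the output is sorted by (query_id, subject_id).  When ``criteria``
    is given, only qualifying hits are returned.  ``prefilter=False``
    aligns every pair exhaustively.
    """
    if not isinstance(proteins, Mapping):
        proteins = {r.protein_id: r.sequence for r in proteins}
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValueError("all_vs_all requires at least 2 proteins")
    if prefilter:
        pairs = candidate_pairs(proteins, k=k, min_shared_kmers=min_shared_kmers)
    else:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]]
    aligner = _make_aligner(-11.0, -1.0, "BLOSUM62")
    validated = {pid: _validate_sequence(proteins[pid], pid) for pid in ids}
    hits: list[SimilarityHit] = []
    for a, b in pairs:
        qa, sb = validated[a], validated[b]
        score = aligner.score(qa, sb)
        if score <= 0:
            continue
        # E-value depends on the score alone and is symmetric, so a
        # failing pair can be discarded before the costly traceback.
        if criteria is not None and evalue_from_raw(score, len(qa), len(sb)) >= criteria.max_evalue:
            continue
        aln = _alignment_stats(aligner, qa, sb, score)
        fwd = SimilarityHit(
            query_id=a,
            subject_id=b,
            percent_identity=aln.percent_identity,
            alignment_length=aln.alignment_length,
            query_coverage=aln.query_coverage,
            subject_coverage=aln.subject_coverage,
            evalue=aln.evalue,
            bitscore=aln.bitscore,
        )
        for hit in (fwd, fwd.reversed()):
            if criteria is None or hit_passes(hit, criteria):
                hits.append(hit)
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


# --------------------------------------------------------------------------
# BLAST tabular ingestion
# --------------------------------------------------------------------------

#: Standard ``-outfmt 6`` column order.
BLAST12 = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

#: ``-outfmt '6 std qlen slen'``; required for the dual-coverage criterion.
BLAST14 = BLAST12 + ["qlen", "slen"]


@dataclass
class BlastTabResult:
    """Hits parsed from a BLAST tabular file plus a skip log."""

    hits: list[SimilarityHit]
    n_self_hits_skipped: int = 0

    def __iter__(self) -> Iterator[SimilarityHit]:
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def read_blast_tab(
    path: str | Path, columns: Sequence[str] = BLAST14
) -> BlastTabResult:
    """Parse a headerless BLAST tabular hit file.

    ``columns`` declares the column order.  ``qlen``/``slen`` are
    mandatory: without them per-side coverage -- which the orthologue
    criterion requires -- cannot be computed, so a 12-column dialect is
    a configuration error, not a soft fallback.  Self-hits are skipped
    and counted.
    """
    columns = list(columns)
    required = {"qseqid", "sseqid", "pident", "length", "qstart", "qend",
                "sstart", "send", "evalue", "bitscore"}
    missing = required - set(columns)
    if missing:
        raise ConfigurationError(f"dialect lacks required columns: {sorted(missing)}")
    if "qlen" not in columns or "slen" not in columns:
        raise ConfigurationError(
            "dialect lacks qlen/slen columns; per-side coverage cannot be "
            "computed (rerun BLAST with -outfmt '6 std qlen slen')"
        )
    idx = {name: i for i, name in enumerate(columns)}
    hits: list[SimilarityHit] = []
    n_self = 0
    for lineno, fields in iter_tsv_rows(path):
        if len(fields) != len(columns):
            raise InputFormatError(
                f"expected {len(columns)} columns, found {len(fields)}", line=lineno
            )
        try:
            qid = fields[idx["qseqid"]]
            sid = fields[idx["sseqid"]]
            if qid == sid:
                n_self += 1
                continue
            qstart, qend = int(fields[idx["qstart"]]), int(fields[idx["qend"]])
            sstart, send = int(fields[idx["sstart"]]), int(fields[idx["send"]])
            qlen, slen = int(fields[idx["qlen"]]), int(fields[idx["slen"]])
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=float(fields[idx["pident"]]),
                    alignment_length=int(fields[idx["length"]]),
                    query_coverage=(abs(qend - qstart) + 1) / qlen,
                    subject_coverage=(abs(send - sstart) + 1) / slen,
                    evalue=float(fields[idx["evalue"]]),
                    bitscore=float(fields[idx["bitscore"]]),
                )
            )
        except (ValueError, IndexError) as exc:
            raise InputFormatError(f"malformed row: {exc}", line=lineno) from exc
    if n_self:
        logger.info("read_blast_tab: skipped %d self-hit rows", n_self)
    return BlastTabResult(hits=hits, n_self_hits_skipped=n_self)
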