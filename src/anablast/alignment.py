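"""Low-stringency protein homology search.

The profile signal downstream is built from *weak* alignments: local
hits far below conventional significance thresholds (bit score >= ~30,
E-values allowed up to 200,000).  This module provides

* SEG low-complexity masking of queries (Wootton-Federhen two-pass),
* a Smith-Waterman affine-gap local aligner for self-contained runs
  against small clustered databases,
* Karlin-Altschul bit-score / E-value conversion,
* a parser for precomputed hits in the 12-column tabular format
  ("outfmt 6"), so genome-scale searches can be run in an external
  engine and fed back into the profiling stage.

The default scheme is BLOSUM90 with gap open 10 / extend 1 — a matrix
biased toward short, high-identity alignments, which is what ancient
coding footprints look like.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .translation import FramedTranslation

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)


def _load_ka_table() -> dict:
    with resources.files("anablast.data").joinpath("ka_params.json").open() as fh:
        return json.load(fh)


class LocalAlignment(NamedTuple):
    """One local alignment (HSP): raw score plus query/subject intervals."""

    raw_score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul stats.

    ``lam``/``k`` default to the published gapped parameters for the
    chosen matrix and gap combination (shipped in ``data/ka_params.json``);
    ``effective_search_space`` is the m*n product used for E-values and is
    normally set per query by :func:`search_hits`.
    """

    matrix_name: str = "BLOSUM90"
    gap_open: int = 10
    gap_extend: int = 1
    lam: float | None = None
    k: float | None = None
    effective_search_space: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = substitution_matrices.load(self.matrix_name)
        if self.lam is None or self.k is None:
            table = _load_ka_table()
            key = f"{self.gap_open},{self.gap_extend}"
            try:
                params = table[self.matrix_name][key]
            except KeyError:
                raise ValueError(
                    f"no Karlin-Altschul parameters known for {self.matrix_name} "
                    f"with gaps ({self.gap_open},{self.gap_extend}); pass lam/k explicitly"
                ) from None
            self.lam = self.lam if self.lam is not None else params["lambda"]
            self.k = self.k if self.k is not None else params["K"]
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")

    def aligner(self) -> PairwiseAligner:
        aligner = PairwiseAligner(mode="local")
        aligner.substitution_matrix = self.matrix
        # affine convention: first gap residue costs open+extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def raw_floor(self, bit_threshold: float) -> int:
        """Smallest integer raw score whose bit score reaches the threshold."""
        return math.ceil((bit_threshold * LN2 + math.log(self.k)) / self.lam)


@dataclass(frozen=True)
class AlignmentHit:
    """One retained local alignment of a framed query against one cluster."""

    query_id: str
    q_start: int
    q_end: int
    subject_cluster: str
    raw_score: int
    bit_score: float
    evalue: float

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start:
            raise ValueError(f"empty query interval in hit on {self.subject_cluster}")


@dataclass
class SearchConfig:
    """Low-stringency retention parameters of the search stage."""

    bit_threshold: float = 30.0
    evalue_cap: float = 200_000.0
    max_hits_per_query: int = 10_000
    seg_enabled: bool = True
    seg_window: int = 12
    seg_locut: float = 2.2
    seg_hicut: float = 2.5
    max_hsps_per_subject: int = 4

    def __post_init__(self) -> None:
        if self.max_hits_per_query <= 0:
            raise ValueError("max_hits_per_query must be positive")
        if self.evalue_cap <= 0:
            raise ValueError("evalue_cap must be positive")


# ---------------------------------------------------------------------------
# SEG low-complexity masking
# ---------------------------------------------------------------------------

def _window_entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mask_positions(protein: str, window: int, locut: float, hicut: float) -> set[int]:
    n = len(protein)
    if n == 0:
        return set()
    w = min(window, n)
    codes = np.frombuffer(protein.encode(), dtype=np.uint8)
    # trigger pass: windows with entropy <= locut
    triggered: list[tuple[int, int]] = []
    for i in range(n - w + 1):
        counts = np.bincount(codes[i : i + w], minlength=128)
        if _window_entropy(counts) <= locut:
            if triggered and i <= triggered[-1][1]:
                triggered[-1] = (triggered[-1][0], i + w)
            else:
                triggered.append((i, i + w))
    # extension pass: grow each segment while its entropy stays <= hicut
    masked: set[int] = set()
    for s, e in triggered:
        while s > 0:
            counts = np.bincount(codes[s - 1 : e], minlength=128)
            if _window_entropy(counts) <= hicut:
                s -= 1
            else:
                break
        while e < n:
            counts = np.bincount(codes[s : e + 1], minlength=128)
            if _window_entropy(counts) <= hicut:
                e += 1
            else:
                break
        masked.update(range(s, e))
    return masked


def seg_mask(
    protein: str, window: int = 12, locut: float = 2.2, hicut: float = 2.5
) -> str:
    """Mask low-complexity stretches with lowercase 'x'.

    Two-pass procedure: length-``window`` segments whose compositional
    entropy (bits) is <= ``locut`` trigger; triggered segments are extended
    to maximal surrounding stretches with entropy <= ``hicut``.  Masking is
    computed on the upper-cased sequence, so it is idempotent.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    upper = protein.upper()
    positions = _mask_positions(upper, window, locut, hicut)
    positions.update(i for i, c in enumerate(protein) if c == "x")
    return "".join(
        "x" if i in positions else c for i, c in enumerate(upper)
    )


# ---------------------------------------------------------------------------
# Local alignment and Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def to_bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalize a raw alignment score: bits = (lambda*raw - ln K)/ln 2."""
    return (scheme.lam * raw_score - math.log(scheme.k)) / LN2


def evalue(bits: float, effective_search_space: float) -> float:
    """Expected chance hits at this bit score: E = m*n * 2^(-bits)."""
    return effective_search_space * math.pow(2.0, -bits)


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    raw_floor: int = 1,
    max_hsps: int = 1,
) -> list[LocalAlignment]:
    """Smith-Waterman local alignment(s) of ``query`` against ``subject``.

    Returns the optimal local alignment and, when ``max_hsps`` > 1, further
    query-non-overlapping suboptimal alignments (found by splitting the
    query around each reported HSP), all with raw score >= ``raw_floor``.
    Lowercase 'x' masking characters score as the matrix's 'X' column.
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    aligner = scheme.aligner()
    q = query.upper().replace("*", "X")
    s = subject.upper().replace("*", "X")

    hits: list[LocalAlignment] = []
    pending: list[tuple[int, str]] = [(0, q)]
    while pending and len(hits) < max_hsps:
        q_off, q_sub = pending.pop(0)
        if not q_sub:
            continue
        score = aligner.score(q_sub, s)
        if score < raw_floor or score <= 0:
            continue
        aln = next(iter(aligner.align(q_sub, s)))
        q_blocks, s_blocks = aln.aligned
        qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
        ss, se = int(s_blocks[0][0]), int(s_blocks[-1][1])
        hits.append(LocalAlignment(int(round(score)), q_off + qs, q_off + qe, ss, se))
        # further HSPs must not overlap this one on the query
        pending.append((q_off, q_sub[:qs]))
        pending.append((q_off + qe, q_sub[qe:]))
    hits.sort(key=lambda h: (-h.raw_score, h.q_start))
    return hits


# ---------------------------------------------------------------------------
# Database search and tabular-hit parsing
# ---------------------------------------------------------------------------

def load_protein_db(db: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Load a clustered protein database (one record per cluster)."""
    if isinstance(db, Mapping):
        records = dict(db)
    else:
        records = {}
        for record in SeqIO.parse(str(db), "fasta"):
            if record.id in records:
                raise ValueError(f"duplicate cluster identifier {record.id!r}")
            records[record.id] = str(record.seq).upper()
    if not records:
        raise ValueError("protein database is empty")
    return records


def _sort_and_cap(hits: list[AlignmentHit], max_hits: int) -> list[AlignmentHit]:
    hits.sort(key=lambda h: (-h.bit_score, h.subject_cluster, h.q_start))
    return hits[:max_hits]


def search_hits(
    t: FramedTranslation,
    db: str | Path | Mapping[str, str],
    scheme: ScoringScheme,
    config: SearchConfig | None = None,
) -> list[AlignmentHit]:
    """Align one framed peptide against every cluster representative.

    The query is SEG-masked (subjects are not), all local alignments with
    bit score >= ``bit_threshold`` and E-value <= ``evalue_cap`` are kept,
    and the result is truncated to the ``max_hits_per_query`` best by bit
    score, with deterministic ordering (bit desc, subject id, q_start).
    """
    config = config or SearchConfig()
    records = load_protein_db(db)
    query = t.protein
    if config.seg_enabled and query:
        query = seg_mask(query, config.seg_window, config.seg_locut, config.seg_hicut)
    if not query or set(query) <= {"x", "X"}:
        return []
    total_residues = sum(len(s) for s in records.values())
    space = max(len(query), 1) * total_residues
    floor = scheme.raw_floor(config.bit_threshold)
    hits: list[AlignmentHit] = []
    for cluster_id, subject in records.items():
        for aln in local_align(
            query, subject, scheme, raw_floor=floor, max_hsps=config.max_hsps_per_subject
        ):
            bits = to_bit_score(aln.raw_score, scheme)
            e = evalue(bits, space)
            if bits >= config.bit_threshold and e <= config.evalue_cap:
                hits.append(
                    AlignmentHit(
                        query_id=t.query_id,
                        q_start=aln.q_start,
                        q_end=aln.q_end,
                        subject_cluster=cluster_id,
                        raw_score=aln.raw_score,
                        bit_score=bits,
                        evalue=e,
                    )
                )
    return _sort_and_cap(hits, config.max_hits_per_query)


def parse_external_hits(
    path: str | Path,
    frame_ids: Iterable[str],
    config: SearchConfig | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Parse 12-column tabular search output and filter like ``search_hits``.

    Expected columns (tab-separated): qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore, with 1-based inclusive
    query coordinates (converted here to 0-based half-open).  Lines whose
    query id is not in ``frame_ids`` are skipped with a warning.  Raw
    scores are not present in this format and are recorded as 0.
    """
    config = config or SearchConfig()
    known = set(frame_ids)
    per_query: dict[str, list[AlignmentHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"line {lineno}: expected 12 tab-separated columns")
            qseqid, sseqid = fields[0], fields[1]
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                e = float(fields[10])
                bits = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric field ({exc})") from None
            if qseqid not in known:
                logger.warning("line %d: unknown query id %r, skipped", lineno, qseqid)
                continue
            if bits < config.bit_threshold or e > config.evalue_cap:
                continue
            per_query.setdefault(qseqid, []).append(
                AlignmentHit(
                    query_id=qseqid,
                    q_start=qstart - 1,
                    q_end=qend,
                    subject_cluster=sseqid,
                    raw_score=0,
                    bit_score=bits,
                    evalue=e,
                )
            )
    return {
        qid: _sort_and_cap(hits, config.max_hits_per_query)
        for qid, hits in per_query.items()
    }


def write_hits_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (1-based inclusive coords).

    Identity/length/mismatch/gapopen and subject coordinates are not
    tracked per hit; they are emitted as the alignment length on the query
    and zeros, which keeps the column layout parseable by standard tools.
    """
    with open(path, "w") as fh:
        for h in hits:
            length = h.q_end - h.q_start
            fh.write(
                f"{h.query_id}\t{h.subject_cluster}\t0.0\t{length}\t0\t0\t"
                f"{h.q_start + 1}\t{h.q_end}\t0\t0\t{h.evalue:.2e}\t{h.bit_score:.1f}\n"
            )
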