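"""Alignment-accumulation profiles, peak calling and null calibration.

The central statistic: for each residue position of a framed peptide,
count how many *distinct* database clusters have at least one retained
alignment covering that position.  Translations of coding DNA pile up
weak alignments from homologous families and produce tall peaks; random
peptides from non-coding DNA rarely accumulate more than a handful.  A
cutoff calibrated on shuffled-sequence controls (70 accumulated
sequences at genome scale against a UniRef50-sized database) separates
the two regimes.

Peaks are maximal runs of supra-cutoff positions; their peptides can be
concatenated across frames and stop masks to reconstruct degenerate
(fossil) coding sequences that frameshifts and nonsense mutations have
fragmented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment import AlignmentHit
from .translation import FramedTranslation, protein_to_genomic

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Profile:
    """Per-position accumulation counts over one framed peptide."""

    frame_id: str
    counts: np.ndarray  # non-negative integers, one per residue

    @property
    def max_height(self) -> int:
        return int(self.counts.max()) if len(self.counts) else 0


@dataclass(frozen=True)
class Peak:
    """A maximal supra-cutoff interval of a profile."""

    frame_id: str
    frame_code: int
    p_start: int
    p_end: int
    height: int
    chrom: str
    start: int
    end: int
    strand: str
    significant: bool = True


def accumulate_profile(
    hits: Sequence[AlignmentHit],
    t: FramedTranslation,
    count_mode: str = "clusters",
) -> Profile:
    """Build the accumulation profile of one framed peptide.

    ``count_mode='clusters'`` (default): counts[p] is the number of
    distinct subject clusters with >=1 hit covering position p, so many
    HSPs from one cluster add only once.  ``count_mode='alignments'``
    counts every HSP.
    """
    if count_mode not in ("clusters", "alignments"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    n = t.length
    counts = np.zeros(n, dtype=np.int64)
    if count_mode == "clusters":
        per_cluster: dict[str, np.ndarray] = {}
        for h in hits:
            _check_hit(h, t)
            cov = per_cluster.setdefault(h.subject_cluster, np.zeros(n, dtype=bool))
            cov[h.q_start : h.q_end] = True
        for cov in per_cluster.values():
            counts += cov
    else:
        for h in hits:
            _check_hit(h, t)
            counts[h.q_start : h.q_end] += 1
    return Profile(frame_id=t.query_id, counts=counts)


def _check_hit(h: AlignmentHit, t: FramedTranslation) -> None:
    if h.query_id != t.query_id:
        raise ValueError(f"hit query {h.query_id!r} does not belong to {t.query_id!r}")
    if h.q_start < 0 or h.q_end > t.length:
        raise ValueError(
            f"hit interval [{h.q_start},{h.q_end}) outside [0,{t.length}) of {t.query_id}"
        )


def call_peaks(
    profile: Profile,
    t: FramedTranslation,
    cutoff: int = 70,
    merge_gap: int = 0,
    min_length: int = 1,
    strict: bool = False,
) -> list[Peak]:
    """Call significant peaks: maximal runs of positions with count >= cutoff.

    Runs separated by at most ``merge_gap`` sub-cutoff positions are
    merged; runs shorter than ``min_length`` residues are dropped.
    ``strict`` switches the inequality to a strict ``>``.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    counts = profile.counts
    above = counts > cutoff if strict else counts >= cutoff
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    # bridge short sub-cutoff gaps
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    peaks = []
    for s, e in merged:
        if e - s < min_length:
            continue
        chrom, g_start, g_end, strand = protein_to_genomic(t, s, e)
        peaks.append(
            Peak(
                frame_id=profile.frame_id,
                frame_code=t.frame_code,
                p_start=s,
                p_end=e,
                height=int(counts[s:e].max()),
                chrom=chrom,
                start=g_start,
                end=g_end,
                strand=strand,
                significant=True,
            )
        )
    return peaks


def calibrate_cutoff(
    control_max_heights: Sequence[int], quantile: float = 1.0
) -> int:
    """Empirical-null cutoff from per-control maximum profile heights.

    Returns the stated quantile (default: the maximum) of the control
    maxima, plus one — the smallest height never reached by that fraction
    of null sequences.
    """
    if len(control_max_heights) == 0:
        raise ValueError("need at least one control region")
    if not (0.0 <= quantile <= 1.0):
        raise ValueError("quantile must be in [0,1]")
    value = np.quantile(np.asarray(control_max_heights), quantile, method="higher")
    return int(value) + 1


def estimate_true_positive_fraction(
    n_significant_real: int, n_significant_shuffled: int
) -> float:
    """Expected fraction of real significant peaks that are true positives.

    With N significant calls on real regions and N0 on their shuffled
    (null) counterparts, about N0 of the real calls are expected by
    chance, so the true-positive fraction is 1 - N0/N.
    """
    if n_significant_real <= 0:
        raise ValueError("n_significant_real must be positive")
    if n_significant_shuffled < 0:
        raise ValueError("n_significant_shuffled must be non-negative")
    if n_significant_shuffled > n_significant_real:
        raise ValueError(
            "control peak count exceeds real peak count "
            f"({n_significant_shuffled} > {n_significant_real}): the null is "
            "noisier than the signal; inspect the search parameters"
        )
    return 1.0 - n_significant_shuffled / n_significant_real


def trim_peak_overlaps(
    peaks: Sequence[Peak],
    translations: Mapping[int, FramedTranslation],
    strand: str,
) -> list[Peak]:
    """Resolve small genomic overlaps between peaks by trimming downstream ones.

    Adjacent peaks in different frames routinely overlap by a few codons at
    a frameshift boundary, because weak alignments extend slightly past the
    shift point.  This orders the peaks 5'->3' and trims the 5' end of each
    later peak until it no longer overlaps the previous one (whole codons;
    peaks trimmed away entirely are dropped), producing input acceptable to
    :func:`concatenate_peaks`.
    """
    ordered = sorted(peaks, key=lambda p: p.start, reverse=(strand == "-"))
    out: list[Peak] = []
    for p in ordered:
        if out:
            prev = out[-1]
            overlap = (
                (prev.end - p.start) if strand == "+" else (p.end - prev.start)
            )
            if overlap > 0:
                drop = -(-overlap // 3)  # ceil in codons
                new_start = p.p_start + drop
                if new_start >= p.p_end:
                    continue
                t = translations[p.frame_code]
                chrom, g_start, g_end, _ = protein_to_genomic(t, new_start, p.p_end)
                p = Peak(
                    frame_id=p.frame_id, frame_code=p.frame_code,
                    p_start=new_start, p_end=p.p_end,
                    height=p.height,  # run maximum of the untrimmed peak
                    chrom=chrom, start=g_start, end=g_end, strand=p.strand,
                    significant=p.significant,
                )
        out.append(p)
    return out


def concatenate_peaks(
    peaks: Sequence[Peak],
    translations: Mapping[int, FramedTranslation],
    strand: str,
) -> str:
    """Frameshift- and stop-tolerant peptide reconstruction.

    Orders the peaks 5'->3' on the given strand, extracts each peak's
    peptide from its own reading frame, strips the 'X' mask characters and
    joins the pieces — the reconstruction used to interpret pseudogenes
    and other fossil coding sequences.
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    sel = [p for p in peaks]
    for p in sel:
        if p.strand != strand:
            raise ValueError(f"peak {p.frame_id}[{p.p_start},{p.p_end}) not on strand {strand}")
    sel.sort(key=lambda p: p.start, reverse=(strand == "-"))
    for a, b in zip(sel, sel[1:]):
        lo, hi = (b, a) if strand == "-" else (a, b)
        if hi.start < lo.end and lo.start < hi.end:
            raise ValueError(
                f"overlapping peaks {a.frame_id}[{a.start},{a.end}) and "
                f"{b.frame_id}[{b.start},{b.end})"
            )
    parts = []
    for p in sel:
        t = translations[p.frame_code]
        parts.append(t.protein[p.p_start : p.p_end].replace("X", ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Track exports
# ---------------------------------------------------------------------------

def write_profile_bedgraph(
    profile: Profile, t: FramedTranslation, path: str | Path
) -> None:
    """Export one frame's profile as bedGraph (0-based half-open, int scores)."""
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=anablast_frame{t.frame_code}\n")
        counts = profile.counts
        i = 0
        while i < len(counts):
            j = i
            while j < len(counts) and counts[j] == counts[i]:
                j += 1
            if counts[i] > 0:
                chrom, g_start, g_end, _ = protein_to_genomic(t, i, j)
                fh.write(f"{chrom}\t{min(g_start, g_end)}\t{max(g_start, g_end)}\t{int(counts[i])}\n")
            i = j


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, int]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), int(f[3])))
    return rows


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Peaks as BED6: name=frame id, score=height, strand."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.frame_id}\t{p.height}\t{p.strand}\n")


def write_peaks_gff3(peaks: Iterable[Peak], path: str | Path) -> None:
    """Peaks as GFF3 ``anablast_peak`` features with frame and height attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in peaks:
            attrs = f"ID=peak_{p.chrom}_{p.start}_{p.end}_f{p.frame_code};frame={p.frame_code};height={p.height}"
            fh.write(
                f"{p.chrom}\tanablast\tanablast_peak\t{p.start + 1}\t{p.end}\t"
                f"{p.height}\t{p.strand}\t.\t{attrs}\n"
            )
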