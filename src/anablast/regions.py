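"""Inter-exon region extraction and null-control sequence generation.

The scan unit of the whole pipeline is the *inter-exon region*: the DNA
between two consecutive annotated exons on a chromosome, after merging
overlapping exon intervals across all genes and strands.  Gaps that fall
inside the exon span of a single transcript are introns; everything else
is intergenic.  Null controls are built from real regions either by
uniform nucleotide shuffling or by plain 3'->5' character reversal.

All internal coordinates are 0-based half-open.  GFF3 input (1-based
inclusive) is converted on read; BED output is written natively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")

#: allowed provenance labels for a region
SOURCES = ("intergenic", "intron", "control_shuffled", "control_reversed", "user")


@dataclass(frozen=True)
class GenomeRegion:
    """A located DNA segment with provenance.

    ``start``/``end`` are genomic, 0-based half-open.  ``source`` records
    how the region was obtained; shuffled/reversed controls carry the id
    of the region they were derived from in ``origin_id``.
    """

    chrom: str
    start: int
    end: int
    sequence: str
    source: str = "user"
    origin_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span "
                f"{self.end - self.start} for {self.chrom}:{self.start}-{self.end}"
            )
        seq = self.sequence.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in region sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        if self.source not in SOURCES:
            raise ValueError(f"unknown region source {self.source!r}")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


def load_genome(genome_file: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a mapping ``{sequence id: upper-case DNA}``.

    Duplicate record identifiers are rejected.
    """
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(genome_file), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence identifier {record.id!r} in {genome_file}")
        genome[record.id] = str(record.seq).upper()
    return genome


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def extract_inter_exon_regions(
    annotation: str | Path,
    genome: Mapping[str, str],
    include_termini: bool = False,
) -> list[GenomeRegion]:
    """Extract all inter-exon regions (intergenic and intronic) of a genome.

    Exon intervals are merged across all genes and strands per chromosome;
    each gap between consecutive merged blocks becomes one region.  A gap
    lying inside the exon span of a single transcript (GFF3 ``Parent`` of
    the exon features) is labelled ``intron``, any other gap ``intergenic``.
    Chromosome termini (before the first exon, after the last) are skipped
    unless ``include_termini`` is set, in which case they are intergenic.
    """
    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    exons_by_chrom: dict[str, list[tuple[int, int]]] = {}
    parent_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_exons = 0
    for exon in db.features_of_type("exon"):
        n_exons += 1
        chrom = exon.seqid
        if chrom not in genome:
            raise ValueError(f"exon on unknown sequence {chrom!r}")
        start, end = exon.start - 1, exon.end  # GFF3 1-based inclusive -> half-open
        if start < 0 or end > len(genome[chrom]):
            raise ValueError(
                f"exon {chrom}:{exon.start}-{exon.end} outside chromosome bounds "
                f"(length {len(genome[chrom])})"
            )
        exons_by_chrom.setdefault(chrom, []).append((start, end))
        for parent in exon.attributes.get("Parent", []):
            parent_exons.setdefault((chrom, parent), []).append((start, end))
    if n_exons == 0:
        logger.warning("annotation %s contains no exon features", annotation)
        return []

    # transcript spans decide intron vs intergenic labels
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for (chrom, _parent), ivs in parent_exons.items():
        spans_by_chrom.setdefault(chrom, []).append(
            (min(s for s, _ in ivs), max(e for _, e in ivs))
        )

    regions: list[GenomeRegion] = []
    for chrom in sorted(exons_by_chrom):
        merged = _merge_intervals(exons_by_chrom[chrom])
        spans = spans_by_chrom.get(chrom, [])
        seq = genome[chrom]
        gaps: list[tuple[int, int, str]] = []
        if include_termini and merged[0][0] > 0:
            gaps.append((0, merged[0][0], "intergenic"))
        for (_, e1), (s2, _) in zip(merged, merged[1:]):
            if s2 > e1:
                inside = any(ss <= e1 and s2 <= se for ss, se in spans)
                gaps.append((e1, s2, "intron" if inside else "intergenic"))
        if include_termini and merged[-1][1] < len(seq):
            gaps.append((merged[-1][1], len(seq), "intergenic"))
        for start, end, source in gaps:
            regions.append(
                GenomeRegion(chrom, start, end, seq[start:end], source=source)
            )
    return regions


def shuffle_region(region: GenomeRegion, seed: int) -> GenomeRegion:
    """Uniformly permute a region's nucleotides (seeded; composition kept)."""
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(region.sequence.encode(), dtype="S1")
    shuffled = rng.permutation(letters).tobytes().decode()
    return replace(
        region, sequence=shuffled, source="control_shuffled", origin_id=region.region_id
    )


def reverse_region(region: GenomeRegion) -> GenomeRegion:
    """3'->5' character reversal (not reverse complement): a biologically
    meaningless sequence with identical composition and local structure."""
    return replace(
        region,
        sequence=region.sequence[::-1],
        source="control_reversed",
        origin_id=region.region_id,
    )


def write_regions_bed(regions: Iterable[GenomeRegion], path: str | Path) -> None:
    """Write regions as BED6 (name=source, score=0, strand='.')."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.source}\t0\t.\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    """Read BED6 lines back as tuples (chrom, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(float(f[4])), f[5]))
    return rows
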