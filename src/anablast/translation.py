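"""Six-frame translation with stop masking and exact coordinate mapping.

Frames are numbered 1-6: frames 1-3 read the forward strand at offsets
0/1/2, frames 4-6 read the reverse complement (5'->3') at offsets 0/1/2.
Stop codons are masked with 'X' rather than terminating the peptide, so
downstream homology accumulation is independent of ORF structure; codons
containing N also become 'X'.  Every framed peptide keeps an exact
residue<->codon mapping back to genomic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq

from .regions import GenomeRegion

logger = logging.getLogger(__name__)

FRAME_CODES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class FramedTranslation:
    """One of the six reading-frame peptides of a genome region."""

    region: GenomeRegion
    strand: str  # '+' or '-'
    frame_offset: int  # 0, 1 or 2 on the read strand
    frame_code: int  # 1-3 forward, 4-6 reverse
    protein: str

    @property
    def length(self) -> int:
        return len(self.protein)

    @property
    def query_id(self) -> str:
        return f"{self.region.region_id}|frame{self.frame_code}"


def _translate(dna: str) -> str:
    # stops are masked, not terminal; codons containing N are masked even
    # when the ambiguity would resolve (e.g. GTN), since an uncalled base
    # cannot support an alignment
    usable = len(dna) - len(dna) % 3
    dna = dna[:usable]
    protein = list(str(Seq(dna).translate()).replace("*", "X"))
    for i in range(len(protein)):
        if "N" in dna[3 * i : 3 * i + 3]:
            protein[i] = "X"
    return "".join(protein)


def six_frame_translate(region: GenomeRegion) -> list[FramedTranslation]:
    """Translate a region in all six frames, stops masked with 'X'.

    Trailing partial codons are dropped.  Regions shorter than one codon
    yield six empty translations (with a warning).
    """
    if len(region) < 3:
        logger.warning("region %s shorter than one codon", region.region_id)
    forward = region.sequence
    reverse = str(Seq(forward).reverse_complement())
    out = []
    for frame_code in FRAME_CODES:
        offset = (frame_code - 1) % 3
        strand = "+" if frame_code <= 3 else "-"
        src = forward if strand == "+" else reverse
        out.append(
            FramedTranslation(
                region=region,
                strand=strand,
                frame_offset=offset,
                frame_code=frame_code,
                protein=_translate(src[offset:]),
            )
        )
    return out


def protein_to_genomic(
    t: FramedTranslation, p_start: int, p_end: int
) -> tuple[str, int, int, str]:
    """Map a residue interval of a framed peptide to genomic coordinates.

    Returns ``(chrom, start, end, strand)`` with start/end 0-based
    half-open on the forward genomic axis regardless of strand.
    """
    if not (0 <= p_start < p_end <= t.length):
        raise ValueError(
            f"residue interval [{p_start},{p_end}) out of range for "
            f"{t.query_id} of length {t.length}"
        )
    r = t.region
    if t.strand == "+":
        start = r.start + t.frame_offset + 3 * p_start
        end = r.start + t.frame_offset + 3 * p_end
    else:
        end = r.end - t.frame_offset - 3 * p_start
        start = r.end - t.frame_offset - 3 * p_end
    return (r.chrom, start, end, t.strand)


def genomic_to_protein(t: FramedTranslation, start: int, end: int) -> tuple[int, int]:
    """Inverse of :func:`protein_to_genomic` for codon-aligned intervals."""
    r = t.region
    if t.strand == "+":
        p_start, rem1 = divmod(start - r.start - t.frame_offset, 3)
        p_end, rem2 = divmod(end - r.start - t.frame_offset, 3)
    else:
        p_start, rem1 = divmod(r.end - t.frame_offset - end, 3)
        p_end, rem2 = divmod(r.end - t.frame_offset - start, 3)
    if rem1 or rem2 or not (0 <= p_start < p_end <= t.length):
        raise ValueError(
            f"genomic interval [{start},{end}) is not codon-aligned in frame "
            f"{t.frame_code} of {t.region.region_id}"
        )
    return (p_start, p_end)


def write_translations_fasta(
    translations: Iterable[FramedTranslation], path: str | Path
) -> None:
    """Export framed peptides as FASTA, record ids ``<region_id>|frame<1-6>``."""
    with open(path, "w") as fh:
        for t in translations:
            fh.write(f">{t.query_id}\n{t.protein}\n")
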