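"""Synthetic genomes, annotations and clustered protein databases.

The detection signal the pipeline exploits is *family redundancy*: a
query derived from a real coding sequence aligns weakly to many distinct
cluster representatives descended from a common ancestor, while a random
peptide does not.  The generator therefore builds protein families as
descendants of a family ancestor (members a few percent diverged from
it, with a short invariant block so every pair shares an exact 8-mer),
then plants coding material derived from family members into an
otherwise random genome:

* ``intact_gene`` — a back-translated (possibly diverged) protein copy;
* ``pseudogene_stops`` — the same with nonsense codons injected;
* ``pseudogene_frameshift`` — the coding sequence broken by +1 nt
  insertions, shifting the reading frame mid-gene;
* ``terminal_subtraction`` — only the amino-terminal part survives;
* ``foreign_fragment`` — an internal fragment, as left by horizontal
  transfer or rearrangement.

Dummy single-exon genes flank every implant so the planted material
falls in inter-exon (intergenic) regions, and a truth table records
where everything is for detection scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .profiling import Peak

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_TABLE = unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
_STOP_CODONS = list(_TABLE.stop_codons)

IMPLANT_KINDS = (
    "intact_gene",
    "pseudogene_stops",
    "pseudogene_frameshift",
    "terminal_subtraction",
    "foreign_fragment",
)

#: residues at the start of every family ancestor that members never mutate,
#: guaranteeing a shared exact block within each family
CONSERVED_BLOCK = 12


@dataclass
class ImplantSpec:
    """One planted coding element and, after generation, where it landed."""

    kind: str
    source_protein: str
    divergence: float = 0.2
    n_stops: int = 0
    n_frameshifts: int = 0
    frame: int = 1
    truth_interval: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in IMPLANT_KINDS:
            raise ValueError(f"unknown implant kind {self.kind!r}")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")
        if self.frame not in range(1, 7):
            raise ValueError("frame must be in 1..6")

    @property
    def strand(self) -> str:
        return "+" if self.frame <= 3 else "-"


def generate_protein_db(
    n_clusters: int = 200,
    length_range: tuple[int, int] = (80, 120),
    n_families: int = 20,
    member_divergence: tuple[float, float] = (0.05, 0.15),
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate a clustered protein database with family structure.

    Families are sets of records descended from a random ancestor; each
    member mutates the ancestor at a per-family rate drawn from
    ``member_divergence``, leaving the first ``CONSERVED_BLOCK`` residues
    untouched.  Returns ``(records, family_table)`` where the table has
    columns record_id / family_id / length.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_families = min(n_families, n_clusters)
    rng = np.random.default_rng(seed)
    sizes = [n_clusters // n_families] * n_families
    for i in range(n_clusters % n_families):
        sizes[i] += 1
    records: dict[str, str] = {}
    rows = []
    for fam, size in enumerate(sizes):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=length))
        rate = float(rng.uniform(*member_divergence))
        for m in range(size):
            member = mutate_protein(ancestor, rate, rng, keep_prefix=CONSERVED_BLOCK)
            rid = f"F{fam:02d}_M{m:02d}"
            records[rid] = member
            rows.append({"record_id": rid, "family_id": f"F{fam:02d}", "length": length})
    return records, pd.DataFrame(rows)


def mutate_protein(
    protein: str, rate: float, rng: np.random.Generator, keep_prefix: int = 0
) -> str:
    """Substitute each residue with probability ``rate`` (never to itself)."""
    out = list(protein)
    for i in range(keep_prefix, len(out)):
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform random synonymous codons."""
    return "".join(_CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein)


def random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _build_insert(spec: ImplantSpec, protein: str, rng: np.random.Generator) -> str:
    """Coding DNA of one implant, read 5'->3' on the coding strand."""
    if spec.kind == "terminal_subtraction":
        protein = protein[: max(10, int(0.6 * len(protein)))]
    elif spec.kind == "foreign_fragment":
        k = max(10, int(0.4 * len(protein)))
        start = (len(protein) - k) // 2
        protein = protein[start : start + k]
    protein = mutate_protein(protein, spec.divergence, rng)
    if spec.kind == "pseudogene_frameshift":
        n_chunks = spec.n_frameshifts + 1
        bounds = np.linspace(0, len(protein), n_chunks + 1).astype(int)
        parts = []
        for i in range(n_chunks):
            parts.append(back_translate(protein[bounds[i] : bounds[i + 1]], rng))
            if i < n_chunks - 1:
                parts.append(str(rng.choice(list("ACGT"))))  # +1 frameshift
        return "".join(parts)
    dna = back_translate(protein, rng)
    if spec.kind == "pseudogene_stops" and spec.n_stops > 0:
        n_codons = len(dna) // 3
        idx = np.linspace(1, n_codons - 2, spec.n_stops).astype(int)
        dna_list = list(dna)
        for ci in idx:
            stop = _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
            dna_list[3 * ci : 3 * ci + 3] = stop
        dna = "".join(dna_list)
    return dna


def generate_genome_with_implants(
    implants: Sequence[ImplantSpec],
    db: Mapping[str, str],
    chrom: str = "chrS",
    flank: int = 30,
    exon_length: int = 60,
    gc: float = 0.36,
    seed: int = 0,
) -> tuple[dict[str, str], str, list[dict]]:
    """Build a synthetic chromosome with one implant per inter-exon region.

    Layout: ``[pad][exon] ([flank implant flank][exon])*[pad]`` — every
    implant sits between two dummy single-exon genes, so region extraction
    labels its surroundings intergenic.  Flank lengths are adjusted by up
    to 2 nt so each implant lands in its requested reading frame relative
    to the enclosing region.  Returns ``(genome, gff3_text, truth)``; each
    truth entry records chrom/start/end/strand/frame/kind/source and the
    specs' ``truth_interval`` fields are filled in place.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    pos = 0
    exons: list[tuple[int, int]] = []
    truth: list[dict] = []

    def emit(seq: str) -> None:
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    def emit_exon() -> None:
        exons.append((pos, pos + exon_length))
        emit(random_dna(exon_length, gc, rng))

    emit(random_dna(flank, gc, rng))
    emit_exon()
    for spec in implants:
        if spec.source_protein not in db:
            raise ValueError(f"source protein {spec.source_protein!r} not in database")
        insert = _build_insert(spec, db[spec.source_protein], rng)
        genomic_insert = insert if spec.strand == "+" else str(Seq(insert).reverse_complement())
        region_start = pos
        # left flank tuned so the implant starts in the requested frame
        flank_l = flank
        if spec.strand == "+":
            flank_l += ((spec.frame - 1) - flank_l) % 3
        emit(random_dna(flank_l, gc, rng))
        implant_start = pos
        emit(genomic_insert)
        implant_end = pos
        flank_r = flank
        if spec.strand == "-":
            # frame offset on the reverse strand is measured from region end
            flank_r += ((spec.frame - 4) - flank_r) % 3
        emit(random_dna(flank_r, gc, rng))
        spec.truth_interval = (chrom, implant_start, implant_end)
        truth.append(
            {
                "chrom": chrom,
                "start": implant_start,
                "end": implant_end,
                "strand": spec.strand,
                "frame": spec.frame,
                "kind": spec.kind,
                "source_protein": spec.source_protein,
                "region_start": region_start,
            }
        )
        emit_exon()
    emit(random_dna(flank, gc, rng))
    genome = {chrom: "".join(parts)}

    gff_lines = ["##gff-version 3"]
    for i, (s, e) in enumerate(exons):
        gid, tid = f"dummy{i:03d}", f"dummy{i:03d}.1"
        gff_lines.append(f"{chrom}\tsim\tgene\t{s + 1}\t{e}\t.\t+\t.\tID={gid}")
        gff_lines.append(f"{chrom}\tsim\tmRNA\t{s + 1}\t{e}\t.\t+\t.\tID={tid};Parent={gid}")
        gff_lines.append(f"{chrom}\tsim\texon\t{s + 1}\t{e}\t.\t+\t.\tID={tid}.e1;Parent={tid}")
    return genome, "\n".join(gff_lines) + "\n", truth


def write_truth_bed(truth: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            name = f"{t['kind']}|frame{t['frame']}|{t['source_protein']}"
            fh.write(f"{t['chrom']}\t{t['start']}\t{t['end']}\t{name}\t0\t{t['strand']}\n")


def write_protein_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n{seq}\n")


def evaluate_detection(
    peaks: Sequence[Peak],
    truth: Sequence[dict],
    require_frame: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Score detected implants against the truth table.

    An implant counts as detected if any significant peak overlaps its
    truth interval by >=1 bp on the correct strand (and, when
    ``require_frame`` is set, in the exact reading frame).  Returns
    ``(sensitivity, specificity, per_implant_table)`` where specificity is
    1 - false peaks / total peaks (1.0 when there are no peaks).
    """
    rows = []
    used: set[int] = set()
    for t in truth:
        matching = [
            (i, p)
            for i, p in enumerate(peaks)
            if p.significant
            and p.chrom == t["chrom"]
            and p.strand == t["strand"]
            and p.start < t["end"]
            and t["start"] < p.end
            and (not require_frame or p.frame_code == t["frame"])
        ]
        used.update(i for i, _ in matching)
        rows.append(
            {
                "kind": t["kind"],
                "frame": t["frame"],
                "strand": t["strand"],
                "start": t["start"],
                "end": t["end"],
                "detected": bool(matching),
                "n_peaks": len(matching),
                "best_height": max((p.height for _, p in matching), default=0),
            }
        )
    table = pd.DataFrame(rows)
    n_truth = len(truth)
    sensitivity = float(table["detected"].sum() / n_truth) if n_truth else 1.0
    # false peaks judged without the frame requirement: a peak overlapping a
    # real implant on the right strand is not a false call
    false_peaks = [
        p
        for i, p in enumerate(peaks)
        if p.significant
        and not any(
            p.chrom == t["chrom"]
            and p.strand == t["strand"]
            and p.start < t["end"]
            and t["start"] < p.end
            for t in truth
        )
    ]
    n_peaks = sum(1 for p in peaks if p.significant)
    specificity = 1.0 - len(false_peaks) / n_peaks if n_peaks else 1.0
    return sensitivity, specificity, table


def default_benchmark(
    seed: int = 0,
    n_clusters: int = 200,
    n_families: int = 20,
    divergence: float = 0.2,
) -> tuple[dict[str, str], pd.DataFrame, list[ImplantSpec], dict[str, str], str, list[dict]]:
    """The package's standard synthetic study: db, implants, genome, truth.

    Ten implants (two intact genes, stop- and frameshift-carrying
    pseudogenes, a terminal subtraction and a foreign fragment, spread
    over forward and reverse frames) at the stated divergence, against a
    200-cluster / 20-family database.
    """
    records, families = generate_protein_db(
        n_clusters=n_clusters, n_families=n_families, seed=seed
    )
    fam_ids = sorted(families["family_id"].unique())
    rng = np.random.default_rng(seed + 1)
    kinds = [
        ("intact_gene", {}),
        ("intact_gene", {}),
        ("pseudogene_stops", {"n_stops": 3}),
        ("pseudogene_stops", {"n_stops": 2}),
        ("pseudogene_frameshift", {"n_frameshifts": 1}),
        ("terminal_subtraction", {}),
        ("foreign_fragment", {}),
        ("intact_gene", {}),
        ("pseudogene_stops", {"n_stops": 1}),
        ("intact_gene", {}),
    ]
    frames = [1, 4, 2, 5, 1, 3, 6, 2, 4, 1]
    implants = []
    for (kind, extra), frame, fam in zip(kinds, frames, fam_ids):
        members = families.loc[families["family_id"] == fam, "record_id"].tolist()
        source = members[int(rng.integers(len(members)))]
        implants.append(
            ImplantSpec(kind=kind, source_protein=source, divergence=divergence,
                        frame=frame, **extra)
        )
    genome, gff3, truth = generate_genome_with_implants(
        implants, records, seed=seed + 2
    )
    return records, families, implants, genome, gff3, truth
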