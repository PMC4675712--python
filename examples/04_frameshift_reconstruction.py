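"""Reconstruct a frameshifted pseudogene from adjacent peaks.

A coding sequence broken by a +1 nt insertion produces two adjacent
peaks in different reading frames.  Concatenating their peptides
(ignoring the frameshift and any stop masks) reconstructs the ancestral
protein: the joined peptide aligns to the source protein with a higher
score than either part alone.
"""

import tempfile
from pathlib import Path

import anablast as ab
from anablast import pipeline

records, _, implants, genome, gff3, truth = ab.default_benchmark(seed=0)
with tempfile.TemporaryDirectory() as td:
    gff = Path(td) / "annotation.gff3"
    gff.write_text(gff3)
    regions = ab.extract_inter_exon_regions(gff, genome)

spec = next(s for s in implants if s.kind == "pseudogene_frameshift")
chrom, t_start, t_end = spec.truth_interval
region = next(r for r in regions if r.start <= t_start and t_end <= r.end)

scheme, config = ab.ScoringScheme(), ab.SearchConfig()
scan = pipeline.scan_region(region, records, scheme, config, cutoff=3)
print(f"region {region.region_id}: peaks "
      f"{[(p.frame_code, p.start, p.end) for p in scan.peaks]}")

source = records[spec.source_protein]


def raw(peptide: str) -> int:
    alns = ab.local_align(peptide, source, scheme)
    return alns[0].raw_score if alns else 0


trimmed = ab.trim_peak_overlaps(scan.peaks, scan.translations, spec.strand)
joined = ab.concatenate_peaks(trimmed, scan.translations, spec.strand)
for p in trimmed:
    part = scan.translations[p.frame_code].protein[p.p_start:p.p_end].replace("X", "")
    print(f"  frame {p.frame_code} peptide ({len(part)} aa): raw score {raw(part)}")
print(f"  concatenated peptide ({len(joined)} aa): raw score {raw(joined)}")
# the concatenated score exceeds both parts: the two peaks are fragments
# of one ancestral coding sequence split by a frameshift
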