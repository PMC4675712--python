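"""End-to-end orchestration: regions -> translation -> search -> profiles -> peaks.

This is the library face of the genome scan.  `scan_region` runs the six
frames of one region; `scan_regions` aggregates a whole region set into a
summary table; `calibrate_cutoff` runs the same machinery on shuffled
controls to pick the empirical significance cutoff; `run_control`
re-scans shuffled copies of real regions and derives the expected
true-positive fraction of the real scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import profiling
from .alignment import AlignmentHit, ScoringScheme, SearchConfig, load_protein_db, search_hits
from .profiling import Peak, Profile
from .regions import GenomeRegion, shuffle_region
from .translation import FramedTranslation, six_frame_translate

logger = logging.getLogger(__name__)


@dataclass
class RegionScan:
    """Scan result of one region: translations, profiles and peaks per frame."""

    region: GenomeRegion
    translations: dict[int, FramedTranslation]
    hits: dict[int, list[AlignmentHit]]
    profiles: dict[int, Profile]
    peaks: list[Peak]

    @property
    def max_height(self) -> int:
        return max((p.max_height for p in self.profiles.values()), default=0)

    @property
    def n_significant(self) -> int:
        return len(self.peaks)


def scan_region(
    region: GenomeRegion,
    db: Mapping[str, str],
    scheme: ScoringScheme,
    config: SearchConfig,
    cutoff: int = 70,
    merge_gap: int = 0,
    min_length: int = 1,
    count_mode: str = "clusters",
    hits_by_frame: Mapping[int, Sequence[AlignmentHit]] | None = None,
) -> RegionScan:
    """Run the full per-region pipeline.

    When ``hits_by_frame`` is given (precomputed external search output,
    keyed by frame code) the internal aligner is skipped.
    """
    translations = {t.frame_code: t for t in six_frame_translate(region)}
    hits: dict[int, list[AlignmentHit]] = {}
    profiles: dict[int, Profile] = {}
    peaks: list[Peak] = []
    for code, t in translations.items():
        if hits_by_frame is not None:
            frame_hits = list(hits_by_frame.get(code, []))
        elif t.length == 0:
            frame_hits = []
        else:
            frame_hits = search_hits(t, db, scheme, config)
        hits[code] = frame_hits
        profile = profiling.accumulate_profile(frame_hits, t, count_mode=count_mode)
        profiles[code] = profile
        peaks.extend(
            profiling.call_peaks(profile, t, cutoff=cutoff, merge_gap=merge_gap, min_length=min_length)
        )
    return RegionScan(region, translations, hits, profiles, peaks)


def scan_regions(
    regions: Sequence[GenomeRegion],
    db: Mapping[str, str] | str | Path,
    scheme: ScoringScheme | None = None,
    config: SearchConfig | None = None,
    cutoff: int = 70,
    merge_gap: int = 0,
    min_length: int = 1,
    count_mode: str = "clusters",
) -> tuple[list[RegionScan], pd.DataFrame]:
    """Scan a region set; returns per-region results and a summary table.

    The summary lists, per region, the maximum profile height of each
    frame and the number of significant peaks.
    """
    scheme = scheme or ScoringScheme()
    config = config or SearchConfig()
    records = load_protein_db(db)
    scans = []
    rows = []
    for region in regions:
        scan = scan_region(
            region, records, scheme, config, cutoff, merge_gap, min_length, count_mode
        )
        scans.append(scan)
        row: dict = {
            "region_id": region.region_id,
            "source": region.source,
            "length": len(region),
        }
        for code in range(1, 7):
            row[f"max_height_frame{code}"] = scan.profiles[code].max_height
        row["max_height"] = scan.max_height
        row["n_significant_peaks"] = scan.n_significant
        rows.append(row)
        logger.info(
            "scanned %s (%s): max height %d, %d significant peak(s)",
            region.region_id, region.source, scan.max_height, scan.n_significant,
        )
    return scans, pd.DataFrame(rows)


def calibrate_cutoff(
    control_regions: Sequence[GenomeRegion],
    db: Mapping[str, str] | str | Path,
    scheme: ScoringScheme | None = None,
    config: SearchConfig | None = None,
    quantile: float = 1.0,
    count_mode: str = "clusters",
) -> int:
    """Empirical significance cutoff from null-control regions.

    Runs the full pipeline on every control, records each control's
    maximum profile height over all six frames, and returns the requested
    quantile of those maxima (default: the overall maximum) plus one.
    """
    if len(control_regions) == 0:
        raise ValueError("need at least one control region")
    scheme = scheme or ScoringScheme()
    config = config or SearchConfig()
    records = load_protein_db(db)
    maxima = []
    for region in control_regions:
        scan = scan_region(
            region, records, scheme, config, cutoff=1, count_mode=count_mode
        )
        maxima.append(scan.max_height)
    return profiling.calibrate_cutoff(maxima, quantile=quantile)


def run_control(
    regions: Sequence[GenomeRegion],
    db: Mapping[str, str] | str | Path,
    n_significant_real: int,
    scheme: ScoringScheme | None = None,
    config: SearchConfig | None = None,
    cutoff: int = 70,
    n_shuffles: int = 1,
    seed: int = 0,
    count_mode: str = "clusters",
) -> tuple[pd.DataFrame, float | None]:
    """Shuffled-control scan and true-positive-fraction estimate.

    Each region is shuffled ``n_shuffles`` times (seeds derived from
    ``seed``) and scanned at the given cutoff.  Returns the per-control
    summary and ``1 - n_control_peaks/n_significant_real`` (None when the
    real scan had no significant peaks, in which case no estimate is
    defined).
    """
    controls = []
    for i, region in enumerate(regions):
        for j in range(n_shuffles):
            controls.append(shuffle_region(region, seed=seed + 1_000_003 * i + j))
    scans, summary = scan_regions(
        controls, db, scheme, config, cutoff=cutoff, count_mode=count_mode
    )
    n_control = int(summary["n_significant_peaks"].sum())
    if n_significant_real > 0:
        fraction = profiling.estimate_true_positive_fraction(n_significant_real, n_control)
    else:
        fraction = None
        logger.warning("real scan had no significant peaks; true-positive fraction undefined")
    return summary, fraction
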