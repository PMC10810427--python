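"""Copy-number estimation from read depth over the trimmed reference.

The estimator is a depth ratio: mean depth inside a repeat's estimation
window divided by the median depth of the whole (trimmed) mitochondrial
genome, rounded to the nearest integer.  Because the trimmed reference keeps
one copy per array, reads from all k true copies pile onto that one unit and
the ratio estimates k directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import DepthProfile, Region
from .reference_build import TrimmedReference, default_window

__all__ = [
    "CopyNumberEstimate",
    "SampleUnusableError",
    "estimate_copies",
    "detect_plateau",
    "batch_estimate",
]


class SampleUnusableError(ValueError):
    """The sample's depth profile cannot support a copy-number estimate."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Plain ``round`` rounds halves to even, which would bias ratio data at
    .5 boundaries; half-away-from-zero is symmetric for the all-positive
    ratios seen here.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    repeat_label: str
    window: Region
    mean_window_depth: float
    median_genome_depth: float
    ratio: float
    copies: int
    coding_median_depth: float


def estimate_copies(
    profile: DepthProfile,
    window: Region,
    genome_region: Region | None = None,
    coding_region: Region | None = None,
    repeat_label: str = "",
) -> CopyNumberEstimate:
    """Depth-ratio copy number for one repeat in one sample.

    ``genome_region`` defaults to the whole profile and provides the
    normalizing median; the repeat windows make up under a couple of percent
    of positions, so leaving them in does not move the median.  The coding
    median is carried as a covariate for downstream models, not used for
    normalization.
    """
    L = len(profile)
    if genome_region is None:
        genome_region = Region(profile.ref_id, 1, L)
    if coding_region is None:
        coding_region = genome_region
    med = float(np.median(profile.window_values(genome_region)))
    if med <= 0:
        raise SampleUnusableError(
            f"sample {profile.sample_id!r}: zero median depth over "
            f"{genome_region.start}..{genome_region.end}"
        )
    mean_win = float(np.mean(profile.window_values(window)))
    ratio = mean_win / med
    return CopyNumberEstimate(
        sample_id=profile.sample_id,
        repeat_label=repeat_label,
        window=window,
        mean_window_depth=mean_win,
        median_genome_depth=med,
        ratio=ratio,
        copies=round_half_away(ratio),
        coding_median_depth=float(np.median(profile.window_values(coding_region))),
    )


def detect_plateau(
    profile: DepthProfile,
    array_unit: Region,
    tolerance: float = 0.15,
    min_run: int = 10,
    fallback_margin: int = 25,
) -> Region:
    """Longest run inside the retained unit that is flat to within ``tolerance``.

    A run qualifies when every depth in it lies within ``tolerance`` of the
    run's own median, which delimits the high-depth plateau without assuming
    fixed window coordinates.  If no run of at least ``min_run`` positions
    exists the margin-based default window is returned with a warning.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    values = profile.window_values(array_unit).astype(float)
    n = len(values)
    best: tuple[int, int] | None = None
    for i in range(n):
        run = []
        for j in range(i, n):
            run.append(values[j])
            med = float(np.median(run))
            lo, hi = med * (1 - tolerance), med * (1 + tolerance)
            if min(run) < lo or max(run) > hi:
                break
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
    if best is None or best[1] - best[0] + 1 < min_run:
        warnings.warn(
            f"no flat run of >= {min_run} positions in unit "
            f"{array_unit.start}..{array_unit.end}; falling back to the default window",
            stacklevel=2,
        )
        return default_window(array_unit, fallback_margin)
    return Region(array_unit.seq_id, array_unit.start + best[0], array_unit.start + best[1])


def batch_estimate(
    profiles: list[DepthProfile],
    manifest: TrimmedReference,
    metadata: pd.DataFrame | None = None,
    *,
    auto_window: bool = False,
) -> pd.DataFrame:
    """One row per sample x repeat, joined with sample metadata.

    Samples that fail estimation are kept with an explicit ``status`` code
    instead of being dropped.  A sample-id mismatch between profiles and
    metadata is an error that lists the orphans on both sides.
    """
    L = len(manifest.sequence)
    if metadata is not None:
        prof_ids = {p.sample_id for p in profiles}
        meta_ids = set(metadata["sample_id"])
        if prof_ids != meta_ids:
            raise ValueError(
                "sample id mismatch; profiles without metadata: "
                f"{sorted(prof_ids - meta_ids)}; metadata without profiles: "
                f"{sorted(meta_ids - prof_ids)}"
            )
    rows = []
    for profile in profiles:
        for entry in manifest.repeats:
            label = entry.repeat.label
            if len(profile) != L:
                rows.append(
                    dict(sample_id=profile.sample_id, repeat_label=label, status="length_mismatch")
                )
                continue
            window = (
                detect_plateau(profile, entry.retained_unit)
                if auto_window
                else entry.estimation_window
            )
            try:
                est = estimate_copies(
                    profile, window, coding_region=manifest.coding_region, repeat_label=label
                )
            except SampleUnusableError:
                rows.append(
                    dict(sample_id=profile.sample_id, repeat_label=label, status="zero_median")
                )
                continue
            rows.append(
                dict(
                    sample_id=est.sample_id,
                    repeat_label=label,
                    mean_window_depth=est.mean_window_depth,
                    median_genome_depth=est.median_genome_depth,
                    coding_median_depth=est.coding_median_depth,
                    ratio=est.ratio,
                    copies=est.copies,
                    status="ok",
                )
            )
    table = pd.DataFrame(rows)
    if metadata is not None:
        table = table.merge(metadata, on="sample_id", how="left")
    return table
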