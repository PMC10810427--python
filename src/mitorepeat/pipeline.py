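"""End-to-end orchestration used by the CLI, the tests and the acceptance run."""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import estimate_copies
from .genome_io import CircularSequence, DepthProfile, depth_from_sam
from .reference_build import TrimmedReference, trim_reference
from .repeat_detect import find_tandem_repeats
from .simulate import (
    SimulationConfig,
    TruthRecord,
    build_genome,
    map_reads,
    simulate_depth,
    simulate_reads,
)

__all__ = ["SimulationResult", "run_simulation", "detect_and_trim"]


@dataclass
class SimulationResult:
    truth: TruthRecord
    manifest: TrimmedReference
    profile: DepthProfile
    estimates: dict[str, int]  # repeat label -> rounded copies
    ratios: dict[str, float]


def detect_and_trim(genome: CircularSequence, **detect_kwargs) -> TrimmedReference:
    repeats = find_tandem_repeats(genome, **detect_kwargs)
    return trim_reference(genome, repeats)


def run_simulation(config: SimulationConfig, path: str = "reads") -> SimulationResult:
    """Simulate one sample and estimate its repeat copy numbers.

    ``path='reads'`` exercises the mechanistic loop (reads, internal mapper,
    SAM pile-up with supplementary split segments included, exactly as a
    samtools-depth run would count them); ``path='depth'`` draws the depth
    profile directly from the idealized plateau model.
    """
    genome, truth = build_genome(config)
    manifest = detect_and_trim(genome)
    if not manifest.repeats:
        raise RuntimeError("no repeats detected in the simulated genome")
    if path == "reads":
        reads = simulate_reads(genome, config)
        sam_text = map_reads(reads, manifest)
        with tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False) as fh:
            fh.write(sam_text)
            sam_path = fh.name
        try:
            profile = depth_from_sam(
                sam_path,
                len(manifest.sequence),
                include_supplementary=True,
                sample_id=truth.sample_id,
            )
        finally:
            Path(sam_path).unlink(missing_ok=True)
    elif path == "depth":
        profile = simulate_depth(manifest, truth, config)
    else:
        raise ValueError(f"unknown path {path!r}")
    estimates, ratios = {}, {}
    for entry in manifest.repeats:
        est = estimate_copies(
            profile,
            entry.estimation_window,
            coding_region=manifest.coding_region,
            repeat_label=entry.repeat.label,
        )
        estimates[entry.repeat.label] = est.copies
        ratios[entry.repeat.label] = est.ratio
    return SimulationResult(truth, manifest, profile, estimates, ratios)
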