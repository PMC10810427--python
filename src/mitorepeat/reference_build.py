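"""Build the trimmed reference: each tandem array reduced to a single unit.

Reads from every true copy of a repeat then pile onto the one retained copy,
which is what turns per-sample read depth into a copy-number signal.  The
5'-most copy is retained so all upstream coordinates (the whole coding
region) are unchanged by trimming; a fractional tail copy stays attached so
downstream coordinates remain well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import CircularSequence, Region
from .repeat_detect import TandemRepeat

__all__ = ["TrimmedReference", "trim_reference", "default_window"]


@dataclass(frozen=True)
class RepeatManifestEntry:
    repeat: TandemRepeat
    retained_unit: Region  # trimmed coordinates, span == period
    estimation_window: Region  # trimmed coordinates, inside the retained unit


@dataclass
class TrimmedReference:
    """Trimmed sequence plus the manifest needed for copy-number estimation."""

    sequence: CircularSequence
    repeats: list[RepeatManifestEntry]
    coding_region: Region
    liftover: np.ndarray  # original 1-based -> trimmed 1-based, 0 where excised

    def to_trimmed(self, original_pos: int) -> int | None:
        v = int(self.liftover[original_pos - 1])
        return v or None

    def to_original(self, trimmed_pos: int) -> int:
        hits = np.flatnonzero(self.liftover == trimmed_pos)
        if hits.size != 1:
            raise KeyError(f"trimmed position {trimmed_pos} has no unique pre-image")
        return int(hits[0]) + 1

    def windows(self) -> dict[str, Region]:
        return {e.repeat.label: e.estimation_window for e in self.repeats}


def default_window(retained_unit: Region, margin: int = 25) -> Region:
    """Shrink a retained unit symmetrically to an interior estimation window.

    The default 25 bp margin keeps the window clear of the depth ramps that
    read mapping produces at array junctions while leaving at least 20 bp of
    window inside an 80 bp unit.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if 2 * margin >= retained_unit.span():
        raise ValueError(
            f"margin {margin} too large for unit of span {retained_unit.span()}"
        )
    return Region(
        retained_unit.seq_id, retained_unit.start + margin, retained_unit.end - margin
    )


def trim_reference(
    seq: CircularSequence,
    repeats: list[TandemRepeat],
    *,
    window_margin: int = 25,
    explicit_windows: dict[str, Region] | None = None,
    coding_region: Region | None = None,
) -> TrimmedReference:
    """Excise all whole copies but the 5'-most from each repeat array.

    Fractional tail copies are kept attached to the retained unit.  The
    liftover from original to trimmed coordinates is exact and invertible
    outside the excised segments.  ``explicit_windows`` (keyed by repeat
    label, in trimmed coordinates) overrides the margin-based default, which
    is how externally calibrated window coordinates are injected.
    """
    n = len(seq)
    for rep in repeats:
        if rep.array.wraps:
            raise ValueError(
                f"repeat {rep.label!r} wraps the origin; rotate the reference first"
            )
    ordered = sorted(repeats, key=lambda r: r.array.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.array.start <= a.array.end:
            raise ValueError(
                f"overlapping repeat arrays: {a.label!r} {a.array.start}..{a.array.end} "
                f"and {b.label!r} {b.array.start}..{b.array.end}"
            )

    keep = np.ones(n, dtype=bool)
    for rep in ordered:
        whole = int(rep.copies_in_ref)  # floor: tail copy is kept
        if whole < 1:
            raise ValueError(f"repeat {rep.label!r} has fewer than one whole copy")
        excise_start = rep.array.start + rep.period  # after the retained 5'-most unit
        excise_end = rep.array.start + rep.period * whole - 1
        if whole > 1:
            keep[excise_start - 1 : excise_end] = False

    liftover = np.zeros(n, dtype=np.int64)
    liftover[keep] = np.arange(1, int(keep.sum()) + 1)
    trimmed_seq = CircularSequence(
        seq.id,
        "".join(seq.residues[i] for i in np.flatnonzero(keep)),
        seq.circular,
    )

    entries: list[RepeatManifestEntry] = []
    for rep in ordered:
        t_start = int(liftover[rep.array.start - 1])
        unit = Region(seq.id, t_start, t_start + rep.period - 1)
        if explicit_windows and rep.label in explicit_windows:
            window = explicit_windows[rep.label]
            if not (unit.start <= window.start <= window.end <= unit.end):
                raise ValueError(
                    f"explicit window {window.start}..{window.end} outside retained "
                    f"unit {unit.start}..{unit.end} of repeat {rep.label!r}"
                )
        else:
            # degrade the margin for units too short to take it, keeping at
            # least a third of the unit (minimum 1 bp) as window
            span = unit.span()
            margin_eff = min(window_margin, max(0, (span - max(1, span // 3)) // 2))
            window = default_window(unit, margin_eff)
        entries.append(RepeatManifestEntry(rep, unit, window))

    for a, b in zip(entries, entries[1:]):
        if b.estimation_window.start <= a.estimation_window.end:
            raise ValueError("estimation windows of distinct repeats overlap")

    if coding_region is None:
        if entries:
            coding_region = Region(seq.id, 1, entries[0].retained_unit.start - 1)
        else:
            coding_region = Region(seq.id, 1, len(trimmed_seq))
    return TrimmedReference(trimmed_seq, entries, coding_region, liftover)
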