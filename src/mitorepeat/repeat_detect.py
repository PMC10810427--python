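"""Tandem-repeat detection and self-similarity dot plots.

The detector finds arrays of near-identical units (minisatellite-scale
repeats) in a possibly circular DNA sequence.  Candidate periods come from
the offsets of k-mer self-matches; array bounds are then grown unit by unit
against a running majority-rule consensus, and each call is canonicalized to
the smallest period that still explains the array.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genome_io import CircularSequence, Region

__all__ = ["TandemRepeat", "DotPlotMatch", "self_dotplot", "find_tandem_repeats"]

_CODE = {c: i for i, c in enumerate("ACGT")}


def encode(seq: str) -> np.ndarray:
    """2-bit encode A/C/G/T; other IUPAC codes map to 4 (never match anything)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.uint8)
    for c, v in _CODE.items():
        out[arr == ord(c)] = v
    return out


@dataclass(frozen=True)
class DotPlotMatch:
    """An off-diagonal gap-free self-match (a_start < b_start, 1-based)."""

    a_start: int
    b_start: int
    length: int
    identity: float


@dataclass(frozen=True)
class TandemRepeat:
    """A detected tandem array.

    ``copies_in_ref`` counts unit copies in the analysed sequence and may
    carry a fractional tail.  ``identity`` is the mean identity of the whole
    copies to the majority-rule consensus.
    """

    label: str
    period: int
    copies_in_ref: float
    array: Region
    unit_consensus: str
    identity: float


# ---------------------------------------------------------------------------
# dot plot


def _seed_diagonals(codes: np.ndarray, k: int, max_offset: int | None = None) -> set[int]:
    """Offsets d > 0 for which the sequence shares at least one exact k-mer with itself."""
    n = len(codes)
    if n < k:
        return set()
    packed = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        col = codes[j : j + n - k + 1]
        packed = packed * 5 + col
        valid &= col < 4
    buckets: dict[int, list[int]] = {}
    for i in np.flatnonzero(valid):
        buckets.setdefault(int(packed[i]), []).append(int(i))
    diags: set[int] = set()
    for positions in buckets.values():
        if len(positions) < 2:
            continue
        for a, b in itertools.combinations(positions, 2):
            d = b - a
            if max_offset is None or d <= max_offset:
                diags.add(d)
    return diags


def self_dotplot(
    seq: CircularSequence | str,
    window: int = 50,
    min_identity: float = 0.9,
    k: int = 12,
) -> list[DotPlotMatch]:
    """All maximal off-diagonal gap-free self-matches of length >= window.

    A position pair qualifies when some length-``window`` alignment at that
    diagonal reaches ``min_identity``; runs of qualifying windows on the same
    diagonal are merged into one maximal match.  Symmetric pairs are reported
    once, with a_start < b_start.

    The k-mer seed is capped so that any qualifying window is guaranteed to
    contain an exact seed (pigeonhole on its mismatch count), which makes the
    output identical to a full all-pairs scan.
    """
    s = seq.residues if isinstance(seq, CircularSequence) else seq
    n = len(s)
    if window < 4:
        raise ValueError("window must be >= 4")
    if not 0.5 <= min_identity <= 1.0:
        raise ValueError("min_identity must be in [0.5, 1]")
    if n < window + 1:
        raise ValueError(f"sequence of length {n} too short for window {window}")
    codes = encode(s)
    mism = int(np.floor(window * (1.0 - min_identity)))
    guarantee = (window - mism) // (mism + 1)
    k_eff = max(4, min(k, guarantee if guarantee >= 4 else k, window))
    need = int(np.ceil(window * min_identity))
    seq_id = seq.id if isinstance(seq, CircularSequence) else "seq"
    matches: list[DotPlotMatch] = []
    for d in sorted(_seed_diagonals(codes, k_eff)):
        m = n - d  # aligned length on this diagonal
        if m < window:
            continue
        eq = (codes[:m] == codes[d : d + m]) & (codes[:m] < 4)
        csum = np.concatenate([[0], np.cumsum(eq)])
        wins = csum[window:] - csum[:-window]  # matches in window starting at i
        ok = np.flatnonzero(wins >= need)
        if ok.size == 0:
            continue
        # merge runs of consecutive qualifying starts into maximal segments
        breaks = np.flatnonzero(np.diff(ok) > 1)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [ok.size - 1]])
        for rs, re_ in zip(run_starts, run_ends):
            i0, i1 = int(ok[rs]), int(ok[re_])
            length = i1 - i0 + window
            ident = float((csum[i0 + length] - csum[i0]) / length)
            matches.append(DotPlotMatch(i0 + 1, i0 + d + 1, length, round(ident, 6)))
    matches.sort(key=lambda m: (m.a_start, m.b_start))
    return matches


# ---------------------------------------------------------------------------
# tandem repeat finding


def _consensus(units: np.ndarray) -> np.ndarray:
    """Per-column majority over a (n_units x period) code matrix."""
    counts = np.stack([(units == c).sum(axis=0) for c in range(4)])
    return counts.argmax(axis=0).astype(np.uint8)


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0:
        return 0.0
    return float(np.mean((a == b) & (a < 4)))


def _offset_identity(codes: np.ndarray, start: int, end: int, q: int) -> float:
    """Mean identity of positions i vs i+q over [start, end) (0-based, end exclusive)."""
    hi = end - q
    if hi <= start:
        return 0.0
    a = codes[start:hi]
    b = codes[start + q : end]
    return _identity(a, b)


def _grow_array(
    codes: np.ndarray, anchor: int, period: int, min_identity: float
) -> tuple[int, int, int, np.ndarray, float]:
    """Grow whole units outward from ``anchor`` against a running consensus.

    The anchor must lie inside the array, in phase with a copy boundary.
    Growth tolerates one isolated diverged copy: if the adjacent unit fails
    the identity threshold but the unit beyond it passes, both are accepted.

    Returns (start, end, whole_left, consensus, identity) where [start, end)
    includes fractional tails and whole_left is the 0-based boundary of the
    5'-most whole unit (a valid re-anchoring point for other periods).
    """
    n = len(codes)
    p = period
    units = [codes[anchor : anchor + p]]
    left, right = anchor, anchor + p  # half-open span of whole units
    cons = units[0].copy()

    def try_side(direction: int) -> bool:
        nonlocal left, right, cons
        for step in (1, 2):  # adjacent unit, then skip-one rescue
            if direction > 0:
                lo, hi = right + (step - 1) * p, right + step * p
            else:
                hi, lo = left - (step - 1) * p, left - step * p
            if lo < 0 or hi > n:
                return False
            cand = codes[lo:hi] if direction > 0 else codes[lo:hi]
            if _identity(cand, cons) >= min_identity:
                new = [codes[right + j * p : right + (j + 1) * p] for j in range(step)] if direction > 0 else [
                    codes[left - (j + 1) * p : left - j * p] for j in range(step)
                ]
                if direction > 0:
                    units.extend(new)
                    right += step * p
                else:
                    for u in new:
                        units.insert(0, u)
                    left -= step * p
                cons = _consensus(np.stack(units))
                return True
        return False

    while True:
        grown = try_side(+1)
        grown = try_side(-1) or grown
        if not grown:
            break
    mat = np.stack(units)
    cons = _consensus(mat)
    ident = float(np.mean([(u == cons).mean() for u in mat]))
    # fractional tails: longest flanking stretch matching the consensus at the
    # threshold, trimmed back to the last matching base
    def tail(side: str) -> int:
        best = 0
        for t in range(1, p):
            if side == "right":
                if right + t > n:
                    break
                seg, ref = codes[right : right + t], cons[:t]
            else:
                if left - t < 0:
                    break
                seg, ref = codes[left - t : left], cons[p - t :]
            if _identity(seg, ref) >= min_identity and seg[-1 if side == "right" else 0] == (
                ref[-1 if side == "right" else 0]
            ):
                best = t
        return best

    tr = tail("right")
    tl = tail("left")
    return left - tl, right + tr, left, cons, ident


def find_tandem_repeats(
    seq: CircularSequence,
    min_period: int = 10,
    max_period: int = 2000,
    min_copies: float = 2.0,
    min_identity: float = 0.9,
    k: int = 12,
) -> list[TandemRepeat]:
    """Detect tandem repeat arrays; empty list when nothing qualifies.

    Candidate (period, locus) pairs come from diagonals of exact k-mer
    self-matches.  Each candidate is refined by consensus growth, reduced to
    its canonical (smallest explaining) period, and overlapping calls are
    resolved by span, then identity, then smaller period.
    """
    n = len(seq)
    max_period = min(max_period, n // 2)
    if min_period < 1 or min_period > max_period:
        return []
    circular = seq.circular
    s = seq.residues + seq.residues if circular else seq.residues
    codes = encode(s)
    m_len = len(codes)

    # seed clusters per diagonal
    k_eff = min(k, max(min_period, 4) + k)  # seeds may span unit boundaries freely
    packed_ok = m_len >= k_eff
    candidates: list[tuple[int, int, int]] = []  # (period, run_start, run_end) 0-based
    if packed_ok:
        # bucket k-mer positions
        packed = np.zeros(m_len - k_eff + 1, dtype=np.int64)
        valid = np.ones(m_len - k_eff + 1, dtype=bool)
        for j in range(k_eff):
            col = codes[j : j + m_len - k_eff + 1]
            packed = packed * 5 + col
            valid &= col < 4
        buckets: dict[int, list[int]] = {}
        for i in np.flatnonzero(valid):
            buckets.setdefault(int(packed[i]), []).append(int(i))
        seeds_by_diag: dict[int, list[int]] = {}
        for positions in buckets.values():
            if len(positions) < 2:
                continue
            for ai in range(len(positions) - 1):
                a = positions[ai]
                for bi in range(ai + 1, len(positions)):
                    d = positions[bi] - a
                    if d > max_period:
                        break
                    if d >= min_period:
                        seeds_by_diag.setdefault(d, []).append(a)
        for d, starts in seeds_by_diag.items():
            starts = sorted(set(starts))
            # cluster seeds separated by at most one unit length
            run = [starts[0]]
            clusters = []
            for x in starts[1:]:
                if x - run[-1] <= d:
                    run.append(x)
                else:
                    clusters.append(run)
                    run = [x]
            clusters.append(run)
            for cl in clusters:
                covered = cl[-1] + k_eff - cl[0]
                if covered + k_eff >= d:  # seeds span about one full unit
                    candidates.append((d, cl[0], cl[-1]))

    calls: list[TandemRepeat] = []
    seen_spans: set[tuple[int, int, int]] = set()
    for p, c0, _c1 in candidates:
        anchor = c0
        if anchor + p > m_len:
            continue
        if circular and anchor >= n:
            # duplicate of a candidate anchored in the first copy of the doubled sequence
            continue
        left, right, whole_left, cons, ident = _grow_array(codes, anchor, p, min_identity)
        span = right - left
        if circular and span > n:
            right = left + n
            span = n
        copies = span / p
        if copies < min_copies or ident < min_identity:
            continue
        # canonical period: smallest divisor of p that still explains the array
        whole_end = whole_left + int((right - whole_left) // p) * p
        best_p, best_cons = p, cons
        # A pair of copies q apart carries twice the per-copy divergence, so the
        # cheap offset filter runs at 2*min_identity - 1; the consensus re-growth
        # (copy vs majority consensus, ~ per-copy divergence) makes the decision.
        offset_floor = max(0.5, 2.0 * min_identity - 1.0)
        for q in range(min_period, p):
            if p % q:
                continue
            if _offset_identity(codes, whole_left, whole_end, q) >= offset_floor:
                l2, r2, _wl2, cons2, ident2 = _grow_array(codes, whole_left, q, min_identity)
                if (r2 - l2) >= 0.75 * span and ident2 >= min_identity:
                    best_p, best_cons = q, cons2
                    left, right = l2, r2
                    if circular and right - left > n:
                        right = left + n
                    span = right - left
                    ident = ident2
                    copies = span / q
                break
        p, cons = best_p, best_cons
        if copies < min_copies:
            continue
        key = (p, left % n if circular else left, span)
        if key in seen_spans:
            continue
        seen_spans.add(key)
        if circular:
            start1 = left % n + 1
            end0 = left + span - 1
            wraps = end0 >= n and start1 > 1
            end1 = end0 % n + 1
        else:
            if left >= n:
                continue
            start1, end1, wraps = left + 1, left + span, False
        calls.append(
            TandemRepeat(
                label="",
                period=p,
                copies_in_ref=round(copies, 4),
                array=Region(seq.id, start1, end1, wraps),
                unit_consensus="".join("ACGT"[c] for c in cons),
                identity=round(ident, 4),
            )
        )

    # resolve overlaps: longest span, then identity, then smaller period
    def covered(c: TandemRepeat) -> set[int]:
        if c.array.wraps:
            return set(range(c.array.start - 1, n)) | set(range(0, c.array.end))
        return set(range(c.array.start - 1, c.array.end))

    # rank by matched evidence (span beyond one unit), so a harmonic call with a
    # slightly longer span cannot outrank the same array at its true period
    calls.sort(key=lambda c: (-(c.array.span(n) - c.period), -c.identity, c.period, c.array.start))
    kept: list[TandemRepeat] = []
    taken: set[int] = set()
    for c in calls:
        pos = covered(c)
        if len(pos & taken) > len(pos) // 4:  # substantially overlapping an accepted call
            continue
        kept.append(c)
        taken |= pos
    kept.sort(key=lambda c: c.array.start)
    # fractional tails are heuristic; a tail that reaches into the next call
    # is trimmed back so arrays never overlap
    for i in range(len(kept) - 1):
        a, b = kept[i], kept[i + 1]
        if a.array.wraps or b.array.wraps:
            continue
        overlap = a.array.end - b.array.start + 1
        if 0 < overlap < a.period:
            new_end = b.array.start - 1
            span2 = new_end - a.array.start + 1
            kept[i] = TandemRepeat(
                a.label,
                a.period,
                round(span2 / a.period, 4),
                Region(a.array.seq_id, a.array.start, new_end),
                a.unit_consensus,
                a.identity,
            )
    kept = [c for c in kept if c.copies_in_ref >= min_copies]
    # label by period rank: longest period = "long", next = "short" when two calls
    if len(kept) == 2 and kept[0].period != kept[1].period:
        longer = max(kept, key=lambda c: c.period)
        kept = [
            TandemRepeat(
                "long" if c is longer else "short",
                c.period,
                c.copies_in_ref,
                c.array,
                c.unit_consensus,
                c.identity,
            )
            for c in kept
        ]
    else:
        kept = [
            TandemRepeat(f"tr{i + 1}", c.period, c.copies_in_ref, c.array, c.unit_consensus, c.identity)
            for i, c in enumerate(kept)
        ]
    return kept
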