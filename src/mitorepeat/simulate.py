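"""Synthetic data with known truth: genomes, reads, a naive mapper, depth.

Everything here is a pure function of (config, seed).  The generator emulates
the structure the copy-number estimator relies on: a mitochondrial-sized
circular genome whose non-coding region carries a long (256 bp) and a short
(80 bp) tandem array with configurable per-sample copy numbers, 150 bp
paired-end reads drawn uniformly from the circle, and the depth-inflation
effect whereby reads from all k true copies pile onto the single retained
copy of the trimmed reference.

The internal mapper is deliberately naive — exact k-mer seeding plus ungapped
best-segment extension, with split placement of the remainder as
supplementary records.  Split placement matters: a read crossing a copy
junction has no full-length gap-free image in the trimmed reference, and only
by mapping its pieces separately do all of its bases land on the retained
unit.  It is a test harness, not a production aligner; real use ingests
externally produced alignments or depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import CircularSequence, DepthProfile, Region
from .reference_build import TrimmedReference

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "build_genome",
    "simulate_reads",
    "write_fastq",
    "map_reads",
    "simulate_depth",
    "make_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped defaults: 15,542 bp coding region, 256/80 bp units,
    150 bp paired reads, and modal copy numbers 5 (long) and 34 (short)."""

    seed: int = 0
    coding_length: int = 15542
    long_unit_length: int = 256
    short_unit_length: int = 80
    k_long: int = 5
    k_short: int = 34
    divergence_between_copies: float = 0.01
    coverage: float = 50.0
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 50
    error_rate: float = 0.005
    noise_model: str = "poisson"  # poisson | negative_binomial
    nb_dispersion: float = 0.1
    # NCR layout: chosen so the retained long unit sits at 16725..16980 of the
    # trimmed reference, mirroring the real coordinate frame
    spacer_before: int = 1182
    spacer_between: int = 20
    spacer_after: int = 600

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_between_copies <= 0.05:
            raise ValueError("divergence_between_copies must be in [0, 0.05]")
        if not 0 <= self.error_rate <= 0.02:
            raise ValueError("error_rate must be in [0, 0.02]")
        if self.k_long < 1 or self.k_short < 1:
            raise ValueError("copy numbers must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    k_long: int
    k_short: int
    config: SimulationConfig
    long_array: Region | None = None
    short_array: Region | None = None


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, hits.size, dtype=np.uint8)) % 4
    return out


def build_genome(config: SimulationConfig) -> tuple[CircularSequence, TruthRecord]:
    """A circular genome: coding segment, spacer, long array, spacer, short
    array, spacer.  Copies are independently mutated from their unit template
    at the configured divergence."""
    rng = np.random.default_rng(config.seed)
    coding = _random_codes(rng, config.coding_length)
    sp1 = _random_codes(rng, config.spacer_before)
    sp2 = _random_codes(rng, config.spacer_between)
    sp3 = _random_codes(rng, config.spacer_after)
    long_unit = _random_codes(rng, config.long_unit_length)
    short_unit = _random_codes(rng, config.short_unit_length)
    div = config.divergence_between_copies
    long_arr = np.concatenate([_mutate(rng, long_unit, div) for _ in range(config.k_long)])
    short_arr = np.concatenate([_mutate(rng, short_unit, div) for _ in range(config.k_short)])
    parts = [coding, sp1, long_arr, sp2, short_arr, sp3]
    genome = np.concatenate(parts)
    long_start = config.coding_length + config.spacer_before + 1
    short_start = long_start + len(long_arr) + config.spacer_between
    sample_id = f"sim{config.seed}"
    seq = CircularSequence(sample_id, _codes_to_str(genome), circular=True)
    truth = TruthRecord(
        sample_id,
        config.k_long,
        config.k_short,
        config,
        long_array=Region(sample_id, long_start, long_start + len(long_arr) - 1),
        short_array=Region(sample_id, short_start, short_start + len(short_arr) - 1),
    )
    return seq, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: CircularSequence, config: SimulationConfig
) -> list[tuple[str, str, str]]:
    """Paired 150 bp reads from fragments drawn uniformly on the circle.

    The pair count is round(coverage * L / (2 * read_length)); R2 is the
    reverse complement of the fragment end.  Substitution errors only.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = len(genome)
    rl = config.read_length
    n_pairs = int(round(config.coverage * L / (2 * rl)))
    doubled = np.frombuffer(genome.residues.encode(), dtype=np.uint8)
    codes = np.zeros(len(doubled), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        codes[doubled == b] = i
    codes2 = np.concatenate([codes, codes])

    starts = rng.integers(0, L, n_pairs)
    inserts = np.clip(
        rng.normal(config.insert_mean, config.insert_sd, n_pairs).round().astype(int),
        rl,
        L,
    )
    idx = np.arange(rl)
    r1 = codes2[starts[:, None] + idx]
    ends = starts + inserts - rl
    r2_fwd = codes2[(ends % L)[:, None] + idx]
    r2 = (3 - r2_fwd)[:, ::-1]  # reverse complement
    if config.error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < config.error_rate
            mat[mask] = (mat[mask] + rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)) % 4
    return [
        (f"{genome.id}:p{i}", _codes_to_str(r1[i]), _codes_to_str(r2[i]))
        for i in range(n_pairs)
    ]


def write_fastq(reads: list[tuple[str, str, str]], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in reads:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


# ---------------------------------------------------------------------------
# naive internal mapper


def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 packed k-mers at every start of a 1-D code array (int64)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : j + n]
    return out


def _pack_kmers_2d(mat: np.ndarray, k: int) -> np.ndarray:
    n = mat.shape[1] - k + 1
    out = np.zeros((mat.shape[0], n), dtype=np.int64)
    for j in range(k):
        out = out * 4 + mat[:, j : j + n]
    return out


class _RefIndex:
    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.codes = codes
        packed = _pack_kmers(codes, k)
        order = np.argsort(packed, kind="stable")
        sorted_vals = packed[order]
        self._vals = sorted_vals
        self._pos = order

    def lookup(self, value: int, cap: int = 8) -> np.ndarray:
        lo = np.searchsorted(self._vals, value, "left")
        hi = np.searchsorted(self._vals, value, "right")
        return self._pos[lo : min(hi, lo + cap)]


def _best_segments(eq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized maximal-scoring segment (match +1, mismatch -2) per row.

    Returns (score, start, end) with end exclusive, in read coordinates.
    """
    m, n = eq.shape
    cur = np.zeros(m, dtype=np.int32)
    cur_start = np.zeros(m, dtype=np.int32)
    best = np.zeros(m, dtype=np.int32)
    best_start = np.zeros(m, dtype=np.int32)
    best_end = np.zeros(m, dtype=np.int32)
    for j in range(n):
        val = np.where(eq[:, j], 1, -2).astype(np.int32)
        reset = cur <= 0
        cur_start = np.where(reset, j, cur_start)
        cur = np.where(reset, val, cur + val)
        improved = cur > best
        best = np.where(improved, cur, best)
        best_start = np.where(improved, cur_start, best_start)
        best_end = np.where(improved, j + 1, best_end)
    return best, best_start, best_end


@dataclass
class _Placement:
    read_index: int
    mate: int  # 0 or 1
    reverse: bool
    ref_start: int  # 0-based ref position of the segment
    seg_start: int  # read coordinates (original orientation as emitted)
    seg_end: int
    supplementary: bool


def _place_batch(
    read_codes: np.ndarray,
    index: _RefIndex,
    k: int,
    min_score: int,
    seed_step: int,
    lengths: np.ndarray | None = None,
) -> list[tuple[int, int, int, int] | None]:
    """Best gap-free segment per read against the reference.

    Returns per-read (diag, seg_start, seg_end, score) or None; ``diag`` is
    the 0-based reference position aligned with read offset 0.  ``lengths``
    gives the true length of each row when rows are padded.
    """
    n_reads, rl = read_codes.shape
    ref_codes = index.codes
    ref_len = len(ref_codes)
    if rl < k:
        return [None] * n_reads
    packed = _pack_kmers_2d(read_codes, k)
    n_off = packed.shape[1]
    base_offsets = list(range(0, n_off, seed_step))
    if base_offsets[-1] != n_off - 1:
        base_offsets.append(n_off - 1)
    cand_read: list[int] = []
    cand_diag: list[int] = []
    for i in range(n_reads):
        row_max = n_off if lengths is None else max(0, int(lengths[i]) - k + 1)
        diags: set[int] = set()
        row = packed[i]
        for off in base_offsets:
            if off >= row_max:
                continue
            for pos in index.lookup(int(row[off])):
                diags.add(int(pos) - off)
        if not diags and row_max > 1:  # dense fallback for seed-poor reads
            for off in range(row_max):
                for pos in index.lookup(int(row[off])):
                    diags.add(int(pos) - off)
        for d in diags:
            cand_read.append(i)
            cand_diag.append(d)
    if not cand_read:
        return [None] * n_reads
    cand_read_a = np.asarray(cand_read)
    cand_diag_a = np.asarray(cand_diag)
    # gather ref rows; out-of-bounds positions get sentinel 4 (never match)
    ref_pad = np.full(ref_len + 2 * rl, 4, dtype=np.uint8)
    ref_pad[rl : rl + ref_len] = ref_codes
    gather = cand_diag_a[:, None] + np.arange(rl)[None, :] + rl
    np.clip(gather, 0, len(ref_pad) - 1, out=gather)
    eq = ref_pad[gather] == read_codes[cand_read_a]
    score, seg_start, seg_end = _best_segments(eq)
    best: list[tuple[int, int, int, int] | None] = [None] * n_reads
    for ci in range(len(cand_read)):
        i = cand_read_a[ci]
        s = int(score[ci])
        if s < min_score:
            continue
        entry = (int(cand_diag_a[ci]), int(seg_start[ci]), int(seg_end[ci]), s)
        prev = best[i]
        if prev is None or s > prev[3] or (s == prev[3] and entry[0] < prev[0]):
            best[i] = entry
    return best


def map_reads(
    reads: list[tuple[str, str, str]],
    ref: CircularSequence | TrimmedReference,
    k: int = 31,
    *,
    min_segment_score: int = 15,
    min_split: int = 20,
    split_seed_k: int = 13,
    mapq: int = 60,
) -> str:
    """Map paired reads to a linear view of the reference; returns SAM text.

    Placement is exact k-mer seeding followed by ungapped best-segment
    extension (match +1, mismatch -2); ties break to the leftmost reference
    position.  Read portions left unaligned by the primary segment are
    re-seeded (smaller k) and emitted as supplementary records with soft
    clips, so every sufficiently long piece of a junction-spanning read
    deposits depth where it belongs.  Unplaced reads are emitted unmapped.
    """
    if isinstance(ref, TrimmedReference):
        ref = ref.sequence
    ref_codes = np.zeros(len(ref), dtype=np.uint8)
    raw = np.frombuffer(ref.residues.encode(), dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        ref_codes[raw == b] = i
    index = _RefIndex(ref_codes, k)

    rl = len(reads[0][1]) if reads else 0
    n = len(reads)
    flat: list[str] = []
    for _, s1, s2 in reads:
        flat.append(s1)
        flat.append(s2)
    mat = np.zeros((2 * n, rl), dtype=np.uint8)
    raw = np.frombuffer("".join(flat).encode(), dtype=np.uint8).reshape(2 * n, rl)
    for i, b in enumerate(b"ACGT"):
        mat[raw == b] = i
    rc = (3 - mat)[:, ::-1]

    fwd = _place_batch(mat, index, k, min_segment_score, seed_step=10)
    rev = _place_batch(rc, index, k, min_segment_score, seed_step=10)

    # rescue pass: a read whose every k-mer straddles a mismatch (likely when
    # repeat copies diverge and the unit is short) re-seeds at the split k
    split_index = _RefIndex(ref_codes, split_seed_k)
    missing = [i for i in range(2 * n) if fwd[i] is None and rev[i] is None]
    if missing:
        f2 = _place_batch(mat[missing], split_index, split_seed_k, min_segment_score, seed_step=6)
        r2 = _place_batch(rc[missing], split_index, split_seed_k, min_segment_score, seed_step=6)
        for j, i in enumerate(missing):
            fwd[i], rev[i] = f2[j], r2[j]

    placements: list[list[_Placement]] = [[] for _ in range(2 * n)]
    leftover_codes: list[np.ndarray] = []
    leftover_meta: list[tuple[int, bool, int]] = []  # (flat index, reverse, read-coord offset)
    chosen_orientation: list[bool | None] = [None] * (2 * n)
    for i in range(2 * n):
        f, r = fwd[i], rev[i]
        pick, reverse = None, False
        if f is not None and (r is None or f[3] >= r[3]):
            pick = f
        elif r is not None:
            pick, reverse = r, True
        if pick is None:
            continue
        diag, a, b, _s = pick
        chosen_orientation[i] = reverse
        placements[i].append(
            _Placement(i // 2, i % 2, reverse, diag + a, a, b, supplementary=False)
        )
        codes_i = rc[i] if reverse else mat[i]
        for lo, hi in ((0, a), (b, rl)):
            if hi - lo >= min_split:
                leftover_codes.append(codes_i[lo:hi])
                leftover_meta.append((i, reverse, lo))

    if leftover_codes:
        width = max(len(c) for c in leftover_codes)
        sub = np.full((len(leftover_codes), width), 5, dtype=np.uint8)
        lengths = np.zeros(len(leftover_codes), dtype=int)
        for j, c in enumerate(leftover_codes):
            sub[j, : len(c)] = c
            lengths[j] = len(c)
        placed = _place_batch(sub, split_index, split_seed_k, min_segment_score, seed_step=6, lengths=lengths)
        for j, hit in enumerate(placed):
            if hit is None:
                continue
            diag, a, b, _s = hit
            if b > lengths[j]:
                b = int(lengths[j])
            if b - a < min_split // 2:
                continue
            i, reverse, off = leftover_meta[j]
            placements[i].append(
                _Placement(i // 2, i % 2, reverse, diag + a, off + a, off + b, True)
            )

    comp = str.maketrans("ACGT", "TGCA")
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{ref.id}\tLN:{len(ref)}",
        "@PG\tID:mitorepeat\tPN:mitorepeat-naive-mapper",
    ]
    for i in range(2 * n):
        name = reads[i // 2][0]
        seq_orig = reads[i // 2][1 + i % 2]
        base_flag = 0x1 | (0x40 if i % 2 == 0 else 0x80)
        if not placements[i]:
            lines.append(
                f"{name}\t{base_flag | 0x4}\t*\t0\t0\t*\t*\t0\t0\t{seq_orig}\t*"
            )
            continue
        for pl in placements[i]:
            flag = base_flag | (0x10 if pl.reverse else 0) | (0x800 if pl.supplementary else 0)
            seq = seq_orig.translate(comp)[::-1] if pl.reverse else seq_orig
            cig = []
            if pl.seg_start:
                cig.append(f"{pl.seg_start}S")
            cig.append(f"{pl.seg_end - pl.seg_start}M")
            if rl - pl.seg_end:
                cig.append(f"{rl - pl.seg_end}S")
            lines.append(
                f"{name}\t{flag}\t{ref.id}\t{pl.ref_start + 1}\t{mapq}\t{''.join(cig)}"
                f"\t*\t0\t0\t{seq}\t*"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# direct depth simulation


def simulate_depth(
    manifest: TrimmedReference,
    truth: TruthRecord,
    config: SimulationConfig | None = None,
) -> DepthProfile:
    """Idealized per-position depth over the trimmed reference.

    Expected depth is coverage everywhere and k x coverage across each
    retained unit.  The flanks stay at baseline: on the trimmed reference
    only the single 5'-most copy borders non-repeat sequence, so collapsed
    array reads cannot spill outside the unit.  What mapping does produce is
    a shoulder just inside the unit edges, where junction-crossing reads
    lose their shortest split segment; that is modelled as a linear ramp of
    ``edge_ramp`` positions rising from baseline to the plateau.
    """
    config = config or truth.config
    L = len(manifest.sequence)
    lam = config.coverage
    expected = np.full(L, float(lam))
    k_by_label = {"long": truth.k_long, "short": truth.k_short}
    for entry in manifest.repeats:
        k = k_by_label.get(entry.repeat.label)
        if k is None:
            k = 1
        unit = entry.retained_unit
        a, b = unit.slice0()
        ramp = min(24, (b - a) // 3)
        expected[a:b] = np.maximum(expected[a:b], k * lam)
        for step in range(ramp):
            val = lam + (k - 1) * lam * (step + 1) / (ramp + 1)
            expected[a + step] = min(expected[a + step], val)
            expected[b - 1 - step] = min(expected[b - 1 - step], val)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if config.noise_model == "poisson":
        depth = rng.poisson(expected)
    elif config.noise_model == "negative_binomial":
        phi = config.nb_dispersion
        lam_draw = rng.gamma(1.0 / phi, phi * expected)
        depth = rng.poisson(lam_draw)
    elif config.noise_model == "none":
        depth = np.round(expected).astype(np.int64)
    else:
        raise ValueError(f"unknown noise model {config.noise_model!r}")
    return DepthProfile(truth.sample_id, manifest.sequence.id, depth.astype(np.int64))


# ---------------------------------------------------------------------------
# cohort generator for the statistical stage

_POPULATIONS = {
    "AE": (10, True), "CH": (30, False), "CT": (10, True), "CY": (10, True),
    "DK": (10, False), "EC": (10, True), "WC": (10, True), "FR": (5, False),
    "GB": (15, True), "GR": (10, False), "IO": (5, True), "IR": (12, True),
    "IS": (10, False), "IT": (10, False), "PT": (10, False), "SB": (5, False),
}
_TISSUES = ["blood", "feather", "muscle", "internal_organ"]
_HAPLOGROUPS = ["A1", "A2", "A3", "A4", "B", "C"]


def make_cohort(
    seed: int = 0,
    n_samples: int = 172,
    *,
    base_long: float = 5.0,
    tissue_effect: dict | None = None,
    island_effect: float = 0.0,
    age_effect: float = 0.0,
    sex_effect: float = 0.0,
    noise_sd: float = 3.0,
    short_slope: float = 2.2,
    short_base: float = 34.0,
    short_noise_sd: float = 8.5,
    age_missing_rate: float = 0.5,
    confound_age_tissue: bool = False,
) -> pd.DataFrame:
    """A metadata table with generated copy numbers for the two repeats.

    Population sizes and the island flag mirror the sampled western
    palearctic populations; tissue, sex, age class and haplogroup are drawn
    per sample.  ``k_long`` is ``base_long`` plus the configured factor
    effects plus Gaussian noise; ``k_short`` follows ``k_long`` linearly with
    its own noise, which induces the long/short correlation the copy numbers
    show.  With ``confound_age_tissue`` the allocation copies the sampling
    imbalance of the real cohort: island birds are mostly adults sampled
    from muscle or internal organs, mainland birds mostly juveniles sampled
    from blood or feathers, so an age contrast in the full cohort can be an
    artifact of tissue even when the generative age effect is zero.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if tissue_effect is None:
        tissue_effect = {"blood": 0.0, "feather": 0.0, "muscle": 2.5, "internal_organ": 2.5}
    pops, islands = [], []
    for pop, (size, isl) in _POPULATIONS.items():
        pops += [pop] * size
        islands += [isl] * size
    pops, islands = pops[:n_samples], islands[:n_samples]
    while len(pops) < n_samples:
        pops.append("CH")
        islands.append(False)
    order = rng.permutation(n_samples)
    pops = [pops[i] for i in order]
    islands = [islands[i] for i in order]

    rows = []
    for i in range(n_samples):
        island = islands[i]
        if confound_age_tissue:
            if island:
                tissue = rng.choice(["muscle", "internal_organ"], p=[0.5, 0.5])
                age = rng.choice(["adult", "juvenile"], p=[0.8, 0.2])
            else:
                tissue = rng.choice(["blood", "feather"], p=[0.7, 0.3])
                age = rng.choice(["adult", "juvenile"], p=[0.1, 0.9])
        else:
            tissue = rng.choice(_TISSUES)
            age = rng.choice(["adult", "juvenile"])
        sex = rng.choice(["F", "M"])
        hap = rng.choice(_HAPLOGROUPS, p=[0.35, 0.2, 0.1, 0.1, 0.15, 0.1])
        mu = (
            base_long
            + tissue_effect.get(tissue, 0.0)
            + (island_effect if island else 0.0)
            + (age_effect if age == "adult" else 0.0)
            + (sex_effect if sex == "M" else 0.0)
        )
        k_long = max(1, round(mu + rng.normal(0, noise_sd)))
        k_short = max(
            1, round(short_base + short_slope * (k_long - base_long) + rng.normal(0, short_noise_sd))
        )
        rows.append(
            dict(
                sample_id=f"s{i:03d}",
                population=pops[i],
                island=island,
                sex=sex,
                age_class=age if rng.random() > age_missing_rate else None,
                tissue=tissue,
                haplogroup=hap,
                median_coverage=float(np.round(rng.lognormal(np.log(300), 0.5), 1)),
                long=k_long,
                short=k_short,
            )
        )
    return pd.DataFrame(rows)
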