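"""Whole-genome self-comparison for segmental duplications (SDs).

The detector follows the classic assembly-comparison recipe: annotated
repeats are excised (leaving the "unique" genome, with an exact coordinate
map back to the assembly), the condensed sequence is cut into trackable
400-kb fragments, and the fragment set is compared against itself with
exact k-mer seeding (k=16), per-diagonal two-hit chaining and gapped
realignment. Raw alignments must exceed 88% identity over more than 200 bp.
Repeats are then reinserted by lifting the alignments back to assembly
coordinates; neighbouring alignments separated only by annotated repeats
are merged; each candidate is globally realigned on the assembly sequence
and its ends are trimmed while terminal 50-bp windows fall below 85%
identity. A duplication is reported when the final alignment is longer
than 1 kb with more than 90% identity.

Identity is matches / alignment columns, with indel columns counting
against identity.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .core import Genome, GenomicInterval


@dataclass(frozen=True)
class SDParams:
    k: int = 16
    max_occurrences: int = 64  # k-mers seen more often are masked
    max_seed_gap: int = 400  # bp between consecutive seeds on one diagonal
    min_seeds: int = 2  # two-hit requirement
    min_seed_span: int = 120
    raw_min_length: int = 200
    raw_min_identity: float = 88.0
    final_min_length: int = 1000
    final_min_identity: float = 90.0
    pad: int = 400  # realignment margin around lifted candidates
    trim_window: int = 50
    trim_identity: float = 85.0
    max_join: int = 10_000  # max repeat-only gap bridged when merging
    small_join: int = 200  # abutting alignments (fragment-boundary splits)
    fragment_size: int = 400_000
    max_self_overlap: float = 0.10  # copies overlapping more are dropped
    detect_reverse: bool = True


@dataclass
class CoordinateMap:
    """Exact condensed <-> original coordinate map for one chromosome."""

    cond_starts: list[int]
    orig_starts: list[int]
    lengths: list[int]

    def to_original(self, cond_pos: int) -> int:
        i = bisect.bisect_right(self.cond_starts, cond_pos) - 1
        if i < 0 or cond_pos >= self.cond_starts[i] + self.lengths[i]:
            raise ValueError(f"condensed position {cond_pos} out of range")
        return self.orig_starts[i] + (cond_pos - self.cond_starts[i])

    def to_condensed(self, orig_pos: int) -> int:
        i = bisect.bisect_right(self.orig_starts, orig_pos) - 1
        if i < 0 or orig_pos >= self.orig_starts[i] + self.lengths[i]:
            raise ValueError(f"original position {orig_pos} inside a repeat")
        return self.cond_starts[i] + (orig_pos - self.orig_starts[i])

    def interval_to_original(self, start: int, end: int) -> tuple[int, int]:
        return self.to_original(start), self.to_original(end - 1) + 1


@dataclass(frozen=True)
class RawAlignment:
    """Alignment in repeat-removed (condensed) coordinates."""

    chrom_a: str
    a_start: int
    a_end: int
    chrom_b: str
    b_start: int
    b_end: int
    orientation: str  # forward | reverse
    identity: float
    aligned_length: int


@dataclass
class SegmentMap:
    """Piecewise-linear correspondence copy_a <-> copy_b.

    Blocks are (a_start, b_anchor, length, step): position a_start + t maps
    to b_anchor + step * t (step is -1 for reverse-orientation SDs).
    """

    blocks: list[tuple[int, int, int, int]] = field(default_factory=list)

    def project(self, pos_a: int) -> int:
        """Map a copy_a position to copy_b (nearest mapped base in gaps)."""
        if not self.blocks:
            raise ValueError("empty segment map")
        best = None
        best_dist = None
        for a0, b0, length, step in self.blocks:
            if a0 <= pos_a < a0 + length:
                return b0 + step * (pos_a - a0)
            dist = a0 - pos_a if pos_a < a0 else pos_a - (a0 + length - 1)
            if best_dist is None or dist < best_dist:
                best_dist = dist
                best = b0 + step * (0 if pos_a < a0 else length - 1)
        return best  # type: ignore[return-value]

    def project_interval(self, start: int, end: int) -> tuple[int, int]:
        p, q = self.project(start), self.project(end - 1)
        lo, hi = min(p, q), max(p, q)
        return lo, hi + 1


@dataclass
class SegmentalDuplication:
    copy_a: GenomicInterval
    copy_b: GenomicInterval
    identity: float
    aligned_length: int
    orientation: str
    segment_map: SegmentMap = field(default_factory=SegmentMap)

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation}")

    @property
    def sd_id(self) -> str:
        a, b = self.copy_a, self.copy_b
        return f"{a.chromosome}:{a.start}-{a.end}|{b.chromosome}:{b.start}-{b.end}"


# ---------------------------------------------------------------------------
# Stage 1: repeat removal
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [(s, e) for s, e in merged]
    return out


def remove_repeats(
    sequences: Mapping[str, str], repeats: Iterable[GenomicInterval]
) -> tuple[dict[str, str], dict[str, CoordinateMap]]:
    """Excise annotated repeats; return condensed sequences and maps."""
    merged = merge_intervals(repeats)
    condensed: dict[str, str] = {}
    maps: dict[str, CoordinateMap] = {}
    for chrom, seq in sequences.items():
        reps = merged.get(chrom, [])
        for s, e in reps:
            if s < 0 or e > len(seq):
                raise ValueError(f"repeat {chrom}:{s}-{e} outside chromosome")
        pieces = []
        cond_starts, orig_starts, lengths = [], [], []
        pos = 0
        cond = 0
        for s, e in reps + [(len(seq), len(seq))]:
            if s > pos:
                pieces.append(seq[pos:s])
                cond_starts.append(cond)
                orig_starts.append(pos)
                lengths.append(s - pos)
                cond += s - pos
            pos = max(pos, e)
        condensed[chrom] = "".join(pieces)
        maps[chrom] = CoordinateMap(cond_starts, orig_starts, lengths)
    return condensed, maps


# ---------------------------------------------------------------------------
# Stage 2: fragmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    chromosome: str
    offset: int  # start in condensed chromosome coordinates
    sequence: str


def fragment(
    condensed: Mapping[str, str], size: int = 400_000
) -> list[Fragment]:
    """Cut condensed sequences into trackable fragments of <= ``size`` bp."""
    out = []
    for chrom in sorted(condensed):
        seq = condensed[chrom]
        for start in range(0, len(seq), size):
            out.append(Fragment(chrom, start, seq[start : start + size]))
        if not seq:
            continue
    return out


# ---------------------------------------------------------------------------
# Stage 3: seeded pairwise alignment
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


def _encode(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _BASE_CODE[arr]
    invalid = codes < 0
    return np.where(invalid, 0, codes).astype(np.uint64), invalid


def _kmer_codes(codes: np.ndarray, invalid: np.ndarray, k: int):
    """Forward and reverse-complement k-mer codes plus a validity mask."""
    n = len(codes)
    if n < k:
        empty = np.empty(0, dtype=np.uint64)
        return empty, empty, np.empty(0, dtype=bool)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    comp = _COMP[codes.astype(np.int8)].astype(np.uint64)
    for j in range(k):
        fwd |= codes[j : m + j] << np.uint64(2 * (k - 1 - j))
        rev |= comp[j : m + j] << np.uint64(2 * j)
    bad = np.cumsum(np.concatenate(([0], invalid.astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, rev, valid


def _match_pairs(
    fwd: np.ndarray, rev: np.ndarray, valid: np.ndarray, params: SDParams
):
    """Seed hits (i, j, reverse?) with i < j, from sorted k-mer codes."""
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return np.empty((0, 2), dtype=np.int64), np.empty((0, 2), dtype=np.int64)
    f = fwd[idx]
    # mask hyper-frequent k-mers
    order = np.argsort(f, kind="stable")
    fs = f[order]
    boundaries = np.nonzero(np.concatenate(([True], fs[1:] != fs[:-1], [True])))[0]
    fwd_hits = []
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        cnt = e - s
        if cnt < 2 or cnt > params.max_occurrences:
            continue
        pos = np.sort(idx[order[s:e]])
        for x in range(len(pos)):
            for y in range(x + 1, len(pos)):
                fwd_hits.append((pos[x], pos[y]))
    rev_hits = []
    if params.detect_reverse:
        r = rev[idx]
        rorder = np.argsort(r, kind="stable")
        rs = r[rorder]
        # match forward codes against reverse-complement codes
        lo = np.searchsorted(rs, fs, side="left")
        hi = np.searchsorted(rs, fs, side="right")
        hit_rows = np.nonzero((hi > lo) & (hi - lo <= params.max_occurrences))[0]
        for t in hit_rows:
            a_i = int(idx[order[t]])
            for b_i in idx[rorder[lo[t] : hi[t]]]:
                if a_i < int(b_i):
                    rev_hits.append((a_i, int(b_i)))
    fa = np.array(fwd_hits, dtype=np.int64).reshape(-1, 2)
    ra = np.array(rev_hits, dtype=np.int64).reshape(-1, 2)
    return fa, ra


def _cluster_diagonal(
    hits: np.ndarray, key: np.ndarray, params: SDParams
) -> list[tuple[int, int, int, int, int]]:
    """Group hits by diagonal key, chain by i-gaps; return candidate boxes.

    Returns (i_min, i_max, j_min, j_max, n_seeds) per chained cluster.
    """
    boxes = []
    order = np.lexsort((hits[:, 0], key))
    hits = hits[order]
    key = key[order]
    start = 0
    for t in range(1, len(hits) + 1):
        if t == len(hits) or key[t] != key[start] or (
            hits[t, 0] - hits[t - 1, 0] > params.max_seed_gap
        ):
            group = hits[start:t]
            if len(group) >= params.min_seeds:
                i_min, i_max = int(group[0, 0]), int(group[-1, 0])
                j_min, j_max = int(group[:, 1].min()), int(group[:, 1].max())
                boxes.append((i_min, i_max, j_min, j_max, len(group)))
            start = t
    return boxes


def _revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def alignment_rows(a: str, b: str) -> tuple[str, str, str]:
    """Global (NW) alignment rows for two sequences via edlib."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["matched_aligned"], nice["target_aligned"]


def _identity_from_match_row(match_row: str) -> tuple[float, int]:
    columns = len(match_row)
    matches = match_row.count("|")
    return (100.0 * matches / columns if columns else 0.0), columns


def pairwise_align(
    fragments: Sequence[Fragment], params: SDParams = SDParams()
) -> list[RawAlignment]:
    """Self-comparison of the fragment set by k-mer seeding and chaining."""
    # concatenate fragments with invalid separators so seeds cannot bridge
    sep = "N" * params.k
    parts, offsets, frag_index = [], [], []
    pos = 0
    for f in fragments:
        parts.append(f.sequence)
        offsets.append(pos)
        frag_index.append(f)
        pos += len(f.sequence) + len(sep)
        parts.append(sep)
    concat = "".join(parts)
    codes, invalid = _encode(concat)
    fwd, rev, valid = _kmer_codes(codes, invalid, params.k)
    fwd_hits, rev_hits = _match_pairs(fwd, rev, valid, params)

    boxes: list[tuple[int, int, int, int, str]] = []
    if len(fwd_hits):
        diag = fwd_hits[:, 1] - fwd_hits[:, 0]
        for i_min, i_max, j_min, j_max, _ in _cluster_diagonal(
            fwd_hits, diag, params
        ):
            boxes.append((i_min, i_max + params.k, j_min, j_max + params.k, "forward"))
    if len(rev_hits):
        anti = rev_hits[:, 0] + rev_hits[:, 1]
        for i_min, i_max, j_min, j_max, _ in _cluster_diagonal(
            rev_hits, anti, params
        ):
            boxes.append((i_min, i_max + params.k, j_min, j_max + params.k, "reverse"))

    def locate(global_pos: int) -> tuple[int, int]:
        fi = bisect.bisect_right(offsets, global_pos) - 1
        return fi, global_pos - offsets[fi]

    out = []
    for gi0, gi1, gj0, gj1, orientation in boxes:
        if gi1 - gi0 < params.min_seed_span or gj1 - gj0 < params.min_seed_span:
            continue
        fa, a0 = locate(gi0)
        fa2, a1 = locate(gi1 - 1)
        fb, b0 = locate(gj0)
        fb2, b1 = locate(gj1 - 1)
        if fa != fa2 or fb != fb2:
            continue  # box crosses a fragment boundary (separator)
        fra, frb = frag_index[fa], frag_index[fb]
        seq_a = fra.sequence[a0 : a1 + 1]
        seq_b = frb.sequence[b0 : b1 + 1]
        if orientation == "reverse":
            seq_b = _revcomp(seq_b)
        _, match_row, _ = alignment_rows(seq_a, seq_b)
        identity, columns = _identity_from_match_row(match_row)
        if identity <= params.raw_min_identity or columns <= params.raw_min_length:
            continue
        raw = RawAlignment(
            fra.chromosome, fra.offset + a0, fra.offset + a1 + 1,
            frb.chromosome, frb.offset + b0, frb.offset + b1 + 1,
            orientation, identity, columns,
        )
        # trivial self-hit: identical coordinates
        if (
            raw.chrom_a == raw.chrom_b
            and raw.a_start == raw.b_start
            and raw.a_end == raw.b_end
        ):
            continue
        out.append(raw)
    out.sort(key=lambda r: (r.chrom_a, r.a_start, r.chrom_b, r.b_start))
    return out


# ---------------------------------------------------------------------------
# Stage 4: repeat reinsertion, merging, trimming, finalization
# ---------------------------------------------------------------------------

def _repeat_coverage(
    repeats: dict[str, list[tuple[int, int]]], chrom: str, start: int, end: int
) -> float:
    if end <= start:
        return 1.0
    cov = 0
    for s, e in repeats.get(chrom, []):
        cov += max(0, min(e, end) - max(s, start))
    return cov / (end - start)


def _lift(raw: RawAlignment, maps: Mapping[str, CoordinateMap]):
    a = maps[raw.chrom_a].interval_to_original(raw.a_start, raw.a_end)
    b = maps[raw.chrom_b].interval_to_original(raw.b_start, raw.b_end)
    return a, b


def _merge_lifted(
    lifted: list[tuple[str, int, int, str, int, int, str]],
    repeats: dict[str, list[tuple[int, int]]],
    params: SDParams,
) -> list[tuple[str, int, int, str, int, int, str]]:
    """Merge alignments separated only by repeat sequence on both copies."""
    lifted = sorted(lifted)
    merged: list[list] = []
    for rec in lifted:
        ca, a0, a1, cb, b0, b1, orient = rec
        joined = False
        for m in merged:
            if m[0] != ca or m[3] != cb or m[6] != orient or orient != "forward":
                continue
            gap_a = a0 - m[2]
            gap_b = b0 - m[5]
            abutting = (
                gap_a <= params.small_join and gap_b <= params.small_join
            )
            repeat_bridged = (
                0 <= gap_a <= params.max_join
                and 0 <= gap_b <= params.max_join
                and _repeat_coverage(repeats, ca, m[2], a0) >= 0.8
                and _repeat_coverage(repeats, cb, m[5], b0) >= 0.8
            )
            if abutting or repeat_bridged:
                m[2] = max(m[2], a1)
                m[5] = max(m[5], b1)
                joined = True
                break
        if not joined:
            merged.append(list(rec))
    return [tuple(m) for m in merged]  # type: ignore[return-value]


def _column_arrays(row_a: str, match_row: str, row_b: str):
    match = np.frombuffer(match_row.encode(), dtype=np.uint8) == ord("|")
    a_gap = np.frombuffer(row_a.encode(), dtype=np.uint8) == ord("-")
    b_gap = np.frombuffer(row_b.encode(), dtype=np.uint8) == ord("-")
    a_pos = np.cumsum(~a_gap) - 1  # index into seq_a per column (-1 before start)
    b_pos = np.cumsum(~b_gap) - 1
    return match, a_gap, b_gap, a_pos, b_pos


def _trim_bounds(match: np.ndarray, params: SDParams) -> tuple[int, int] | None:
    """Largest [left, right) window whose terminal windows pass the cutoff."""
    w = params.trim_window
    thr = params.trim_identity / 100.0
    n = len(match)
    if n < w:
        return None
    cs = np.concatenate(([0], np.cumsum(match)))
    win = (cs[w:] - cs[:-w]) / w  # win[i] = identity of columns [i, i+w)
    ok = np.nonzero(win >= thr)[0]
    if len(ok) == 0:
        return None
    left = int(ok[0])
    right = int(ok[-1]) + w
    # shave residual terminal mismatches inside the passing windows
    while left < right and not match[left]:
        left += 1
    while right > left and not match[right - 1]:
        right -= 1
    if right - left < w:
        return None
    return left, right


def _segment_map_from_columns(
    match, a_gap, b_gap, a_pos, b_pos, left, right,
    a_offset: int, b_offset: int, b_len: int, reverse: bool,
) -> SegmentMap:
    blocks = []
    run_start = None
    for col in range(left, right + 1):
        in_run = col < right and not a_gap[col] and not b_gap[col]
        if in_run and run_start is None:
            run_start = col
        elif not in_run and run_start is not None:
            a0 = a_offset + int(a_pos[run_start])
            length = int(a_pos[col - 1]) - int(a_pos[run_start]) + 1
            if reverse:
                # column's b coordinate counts along the reverse complement
                b_anchor = b_offset + (b_len - 1 - int(b_pos[run_start]))
                blocks.append((a0, b_anchor, length, -1))
            else:
                blocks.append((a0, b_offset + int(b_pos[run_start]), length, 1))
            run_start = None
    return SegmentMap(blocks)


def reinsert_and_trim(
    raw_alignments: Sequence[RawAlignment],
    maps: Mapping[str, CoordinateMap],
    sequences: Mapping[str, str],
    repeats: Iterable[GenomicInterval],
    params: SDParams = SDParams(),
) -> list[SegmentalDuplication]:
    """Lift raw alignments to assembly coordinates and finalize SD calls."""
    repeat_ivs = merge_intervals(repeats)
    lifted = []
    for raw in raw_alignments:
        (a0, a1), (b0, b1) = _lift(raw, maps)
        lifted.append((raw.chrom_a, a0, a1, raw.chrom_b, b0, b1, raw.orientation))
    merged = _merge_lifted(lifted, repeat_ivs, params)

    out: list[SegmentalDuplication] = []
    for ca, a0, a1, cb, b0, b1, orient in merged:
        pa0 = max(0, a0 - params.pad)
        pa1 = min(len(sequences[ca]), a1 + params.pad)
        pb0 = max(0, b0 - params.pad)
        pb1 = min(len(sequences[cb]), b1 + params.pad)
        seq_a = sequences[ca][pa0:pa1]
        seq_b = sequences[cb][pb0:pb1]
        reverse = orient == "reverse"
        if reverse:
            seq_b = _revcomp(seq_b)
        row_a, match_row, row_b = alignment_rows(seq_a, seq_b)
        match, a_gap, b_gap, a_pos, b_pos = _column_arrays(row_a, match_row, row_b)
        bounds = _trim_bounds(match, params)
        if bounds is None:
            continue
        left, right = bounds
        columns = right - left
        identity = 100.0 * match[left:right].sum() / columns
        if columns <= params.final_min_length or identity <= params.final_min_identity:
            continue
        fa0 = pa0 + int(a_pos[left] if not a_gap[left] else a_pos[left] + 1)
        fa1 = pa0 + int(a_pos[right - 1]) + 1
        if reverse:
            rb_lo = int(b_pos[left] if not b_gap[left] else b_pos[left] + 1)
            rb_hi = int(b_pos[right - 1]) + 1
            fb0 = pb0 + (len(seq_b) - rb_hi)
            fb1 = pb0 + (len(seq_b) - rb_lo)
        else:
            fb0 = pb0 + int(b_pos[left] if not b_gap[left] else b_pos[left] + 1)
            fb1 = pb0 + int(b_pos[right - 1]) + 1
        seg_map = _segment_map_from_columns(
            match, a_gap, b_gap, a_pos, b_pos, left, right,
            pa0, pb0, len(seq_b), reverse,
        )
        copy_a = GenomicInterval(ca, fa0, fa1, "+")
        copy_b = GenomicInterval(cb, fb0, fb1, "+" if not reverse else "-")
        # canonical ordering for deduplication
        if (copy_b.chromosome, copy_b.start) < (copy_a.chromosome, copy_a.start):
            copy_a, copy_b = copy_b, copy_a
            seg_map = _invert_map(seg_map)
        ov = copy_a.overlap(copy_b)
        if ov > params.max_self_overlap * min(len(copy_a), len(copy_b)):
            continue
        out.append(
            SegmentalDuplication(
                copy_a, copy_b, identity, columns,
                "reverse" if reverse else "forward", seg_map,
            )
        )
    return _dedupe(out)


def _invert_map(seg_map: SegmentMap) -> SegmentMap:
    blocks = []
    for a0, b0, length, step in seg_map.blocks:
        if step == 1:
            blocks.append((b0, a0, length, 1))
        else:
            blocks.append((b0 - length + 1, a0 + length - 1, length, -1))
    blocks.sort()
    return SegmentMap(blocks)


def _dedupe(sds: list[SegmentalDuplication]) -> list[SegmentalDuplication]:
    sds = sorted(
        sds, key=lambda s: (-s.aligned_length, s.copy_a.chromosome, s.copy_a.start)
    )
    kept: list[SegmentalDuplication] = []
    for sd in sds:
        dup = False
        for other in kept:
            ra = sd.copy_a.overlap(other.copy_a)
            rb = sd.copy_b.overlap(other.copy_b)
            if (
                ra >= 0.8 * min(len(sd.copy_a), len(other.copy_a))
                and rb >= 0.8 * min(len(sd.copy_b), len(other.copy_b))
            ):
                dup = True
                break
        if not dup:
            kept.append(sd)
    kept.sort(key=lambda s: (s.copy_a.chromosome, s.copy_a.start, s.copy_b.start))
    return kept


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def detect_sds(
    genome: Genome | Mapping[str, str],
    repeats: Iterable[GenomicInterval],
    params: SDParams = SDParams(),
) -> list[SegmentalDuplication]:
    """Run the four-stage detector on one genome."""
    sequences = genome.sequences if isinstance(genome, Genome) else dict(genome)
    repeats = list(repeats)
    condensed, maps = remove_repeats(sequences, repeats)
    fragments = fragment(condensed, params.fragment_size)
    raws = pairwise_align(fragments, params)
    sds = reinsert_and_trim(raws, maps, sequences, repeats, params)
    for sd in sds:
        assert sd.aligned_length > params.final_min_length
        assert sd.identity > params.final_min_identity
    return sds


def sd_table(sds: Sequence[SegmentalDuplication]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.copy_a.chromosome, s.copy_a.start, s.copy_a.end,
                s.copy_b.chromosome, s.copy_b.start, s.copy_b.end,
                round(s.identity, 2), s.aligned_length, s.orientation,
            )
            for s in sds
        ],
        columns=[
            "chrA", "startA", "endA", "chrB", "startB", "endB",
            "identity", "aligned_length", "orientation",
        ],
    )


def density_track(
    sds: Sequence[SegmentalDuplication],
    sequences: Mapping[str, str],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """bp of SD coverage per fixed window per chromosome."""
    rows = []
    for chrom in sorted(sequences):
        n = len(sequences[chrom])
        cov = np.zeros(n, dtype=bool)
        for sd in sds:
            for iv in (sd.copy_a, sd.copy_b):
                if iv.chromosome == chrom:
                    cov[iv.start : iv.end] = True
        for start in range(0, n, window):
            rows.append(
                (chrom, start, min(n, start + window),
                 int(cov[start : start + window].sum()))
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "sd_bp"])
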