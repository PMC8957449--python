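"""Alignment parsing, filtering, and per-site evidence extraction.

Reads come either from a SAM/BAM file (via :mod:`pysam`) or from the built-in
simulator's truth-projected records.  Either way they are distilled into a
columnar :class:`ReadTable` and then into an :class:`EvidenceMap`: per-site
booleans for soft-clip topology (MS = matched-then-clipped, SM =
clipped-then-matched), strand, and the insert-size class of spanning pairs.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

CIGAR_OPS = set("MIDSHN=X")
#: CIGAR ops that consume reference bases.
REF_CONSUMING = set("MDN=X")
#: CIGAR ops that consume read (query) bases.
QUERY_CONSUMING = set("MIS=X")

#: pysam integer op codes -> op characters.
_PYSAM_OPS = "MIDNSHP=XB"

DEFAULT_MIN_MAPQ = 20
#: Soft clips shorter than this are treated as absent (dominated by base errors).
DEFAULT_MIN_CLIP = 5


@dataclass(frozen=True)
class AlignedRead:
    """One alignment record, reduced to the fields the caller needs."""

    query_name: str
    ref_name: str
    pos: int                       # 0-based leftmost reference coordinate
    mapq: int
    is_reverse: bool
    cigar: tuple[tuple[str, int], ...]
    mate_pos: int | None = None
    template_len: int | None = None
    is_paired: bool = False
    is_proper: bool = False
    is_mapped: bool = True
    mate_is_reverse: bool | None = None

    @property
    def is_orientation_anomalous(self) -> bool:
        """True when the read is "reversely mapped" in the SV-evidence sense.

        For a paired read with a known mate strand this means the pair maps
        on the same strand (the orientation anomaly that inversions and
        inverted duplications produce); for unpaired reads or unknown mates
        it falls back to the read's own reverse flag.
        """
        if self.is_paired and self.mate_is_reverse is not None:
            return self.is_reverse == self.mate_is_reverse
        return self.is_reverse

    def __post_init__(self) -> None:
        if self.is_mapped and self.pos < 0:
            raise ValueError("mapped read with negative position")
        for op, length in self.cigar:
            if op not in CIGAR_OPS:
                raise ValueError(f"unknown CIGAR op {op!r}")
            if length < 1:
                raise ValueError("CIGAR length must be >= 1")

    @property
    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_length


class ClipKind(str, Enum):
    MS = "MS"        # matched block then trailing soft clip
    SM = "SM"        # leading soft clip then matched block
    NONE = "NONE"
    BOTH = "BOTH"


@dataclass(frozen=True)
class ClipClass:
    """Soft-clip topology of one read.

    ``boundary_ref_pos`` is the reference coordinate of the matched/clipped
    junction: ``pos`` for SM, ``pos + reference_length`` for MS.  For BOTH the
    leading (SM) boundary is stored; both boundaries carry evidence and are
    attached separately by :func:`collect_evidence`.
    """

    kind: ClipKind
    clip_len: int = 0
    boundary_ref_pos: int | None = None


def classify_clip(
    cigar: Sequence[tuple[str, int]],
    pos: int = 0,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> ClipClass:
    """Classify the soft-clip structure of a CIGAR anchored at ``pos``.

    Raises ``ValueError`` if the CIGAR contains no aligned block.
    """
    ops = [op for op, _ in cigar]
    if not any(op in "M=X" for op in ops):
        raise ValueError("no aligned segment in CIGAR")
    # leading soft clip: first op after any hard clip
    lead = trail = 0
    core = list(cigar)
    while core and core[0][0] == "H":
        core.pop(0)
    while core and core[-1][0] == "H":
        core.pop()
    if core and core[0][0] == "S":
        lead = core[0][1]
    if core and core[-1][0] == "S" and len(core) > 1:
        trail = core[-1][1]
    lead_ok = lead >= min_clip
    trail_ok = trail >= min_clip
    ref_len = sum(n for op, n in cigar if op in REF_CONSUMING)
    if lead_ok and trail_ok:
        return ClipClass(ClipKind.BOTH, lead + trail, pos)
    if lead_ok:
        return ClipClass(ClipKind.SM, lead, pos)
    if trail_ok:
        return ClipClass(ClipKind.MS, trail, pos + ref_len)
    return ClipClass(ClipKind.NONE, 0, None)


@dataclass(frozen=True)
class InsertSizeModel:
    """Expected insert-size distribution with an equal-band tolerance.

    A pair distance d is EQUAL when ``mean - k*sd <= d <= mean + k*sd``,
    BELOW/ABOVE otherwise.
    """

    mean: float
    sd: float
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or self.k <= 0:
            raise ValueError("sd and k must be positive")

    @property
    def band(self) -> tuple[float, float]:
        return (self.mean - self.k * self.sd, self.mean + self.k * self.sd)

    def classify(self, dist: float) -> str:
        lo, hi = self.band
        if dist < lo:
            return "BELOW"
        if dist > hi:
            return "ABOVE"
        return "EQUAL"


#: sd floor avoiding a zero-width equal-band on degenerate (noise-free) data.
SD_FLOOR = 1.0
_MIN_PAIRS = 50


def estimate_insert_size(
    reads: "Iterable[AlignedRead] | ReadTable",
    max_sample: int = 100_000,
    k: float = 3.0,
    min_pairs: int = _MIN_PAIRS,
) -> InsertSizeModel:
    """Robust insert-size estimate (median / scaled MAD) over proper pairs.

    Uses ``|template_len|`` of proper pairs with positive template length so
    each pair is counted once.  Requires at least ``min_pairs`` pairs.
    """
    if isinstance(reads, ReadTable):
        sel = reads.is_mapped & reads.is_paired & reads.is_proper & (reads.tlen > 0)
        tlens = reads.tlen[sel][:max_sample].astype(float)
    else:
        vals: list[float] = []
        for r in reads:
            if (
                r.is_paired
                and r.is_proper
                and r.template_len is not None
                and r.template_len > 0
            ):
                vals.append(float(r.template_len))
                if len(vals) >= max_sample:
                    break
        tlens = np.asarray(vals)
    if tlens.size < min_pairs:
        raise ValueError(
            f"only {tlens.size} proper pairs found (need >= {min_pairs}); "
            "supply insert mean/sd explicitly in the configuration"
        )
    med = float(np.median(tlens))
    mad = float(np.median(np.abs(tlens - med)))
    sd = max(1.4826 * mad, SD_FLOOR)
    return InsertSizeModel(mean=med, sd=sd, k=k)


class ReadTable:
    """Columnar store of alignment records (one row per read).

    ``lead_clip``/``trail_clip`` are soft-clip lengths; ``end`` is the
    reference end (exclusive) of the aligned block; ``tlen`` is the signed
    template length (0 when unavailable).
    """

    __slots__ = (
        "pos", "end", "mapq", "is_reverse", "lead_clip", "trail_clip",
        "tlen", "is_paired", "is_proper", "is_mapped", "anom",
    )

    def __init__(self, **cols: np.ndarray) -> None:
        n = None
        for name in self.__slots__:
            arr = np.asarray(cols[name])
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("column length mismatch")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return int(self.pos.shape[0])

    def filter_mapq(self, min_mapq: int) -> "ReadTable":
        keep = ~self.is_mapped | (self.mapq >= min_mapq)
        keep &= self.is_mapped
        return ReadTable(**{name: getattr(self, name)[keep] for name in self.__slots__})


def reads_to_table(reads: Iterable[AlignedRead], min_clip: int = DEFAULT_MIN_CLIP) -> ReadTable:
    """Convert an iterable of :class:`AlignedRead` into a :class:`ReadTable`."""
    rows = list(reads)
    n = len(rows)
    pos = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    mapq = np.zeros(n, dtype=np.int32)
    is_reverse = np.zeros(n, dtype=bool)
    lead = np.zeros(n, dtype=np.int32)
    trail = np.zeros(n, dtype=np.int32)
    tlen = np.zeros(n, dtype=np.int64)
    paired = np.zeros(n, dtype=bool)
    proper = np.zeros(n, dtype=bool)
    mapped = np.zeros(n, dtype=bool)
    anom = np.zeros(n, dtype=bool)
    for i, r in enumerate(rows):
        pos[i] = r.pos
        end[i] = r.reference_end if r.is_mapped else r.pos
        mapq[i] = r.mapq
        is_reverse[i] = r.is_reverse
        mapped[i] = r.is_mapped
        paired[i] = r.is_paired
        proper[i] = r.is_proper
        tlen[i] = r.template_len or 0
        anom[i] = r.is_orientation_anomalous
        if r.is_mapped and r.cigar:
            cc = classify_clip(r.cigar, r.pos, min_clip=1)
            if cc.kind in (ClipKind.SM, ClipKind.BOTH):
                lead[i] = next(nn for op, nn in r.cigar if op != "H")
            if cc.kind in (ClipKind.MS, ClipKind.BOTH):
                trail[i] = next(nn for op, nn in reversed(r.cigar) if op != "H")
    return ReadTable(
        pos=pos, end=end, mapq=mapq, is_reverse=is_reverse,
        lead_clip=lead, trail_clip=trail, tlen=tlen,
        is_paired=paired, is_proper=proper, is_mapped=mapped, anom=anom,
    )


def read_alignments(path: str, min_mapq: int = DEFAULT_MIN_MAPQ) -> Iterator[AlignedRead]:
    """Stream filtered alignment records from a SAM/BAM file.

    Keeps records that are mapped, primary, non-supplementary, non-duplicate
    and have ``mapq >= min_mapq`` (inclusive); order follows the file.
    """
    import pysam

    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
                or rec.mapping_quality < min_mapq
            ):
                continue
            cigar = tuple(
                (_PYSAM_OPS[op], length) for op, length in (rec.cigartuples or ())
            )
            yield AlignedRead(
                query_name=rec.query_name or "",
                ref_name=rec.reference_name or "",
                pos=rec.reference_start,
                mapq=rec.mapping_quality,
                is_reverse=rec.is_reverse,
                cigar=cigar,
                mate_pos=(rec.next_reference_start
                          if rec.is_paired and not rec.mate_is_unmapped else None),
                template_len=rec.template_length if rec.is_paired else None,
                is_paired=rec.is_paired,
                is_proper=rec.is_proper_pair,
                is_mapped=True,
                mate_is_reverse=(rec.mate_is_reverse
                                 if rec.is_paired and not rec.mate_is_unmapped
                                 else None),
            )


def load_read_table(path: str, min_mapq: int = DEFAULT_MIN_MAPQ) -> ReadTable:
    """Read a SAM/BAM file straight into a filtered :class:`ReadTable`."""
    return reads_to_table(read_alignments(path, min_mapq=min_mapq))


@dataclass(frozen=True)
class SiteEvidence:
    """Distilled alignment evidence at one reference site."""

    site: int
    has_reverse: bool = False
    has_reverse_sm: bool = False
    has_reverse_ms: bool = False
    has_sm: bool = False
    has_ms: bool = False
    pair_dist_class: frozenset = field(default_factory=frozenset)
    n_reads: int = 0


class EvidenceMap:
    """Per-site evidence over a half-open region, backed by numpy arrays.

    Clip evidence (MS/SM and their reverse-strand variants) attaches only at
    the clip boundary coordinate; pair-distance evidence attaches to every
    site spanned by the pair's outer fragment interval.
    """

    def __init__(self, start: int, end: int) -> None:
        if end < start:
            raise ValueError("region end < start")
        self.start = start
        self.end = end
        L = end - start
        self.cov = np.zeros(L, dtype=np.int32)
        self.pair_cov = np.zeros(L, dtype=np.int32)
        self.rev = np.zeros(L, dtype=bool)
        self.rev_sm = np.zeros(L, dtype=bool)
        self.rev_ms = np.zeros(L, dtype=bool)
        self.sm = np.zeros(L, dtype=bool)
        self.ms = np.zeros(L, dtype=bool)
        self.below = np.zeros(L, dtype=bool)
        self.equal = np.zeros(L, dtype=bool)
        self.above = np.zeros(L, dtype=bool)

    # -- accessors ---------------------------------------------------------
    def _idx(self, site: int) -> int:
        if not (self.start <= site < self.end):
            raise KeyError(site)
        return site - self.start

    def get(self, site: int) -> SiteEvidence:
        i = self._idx(site)
        cls = set()
        if self.pair_cov[i] > 0:
            if self.below[i]:
                cls.add("BELOW")
            if self.equal[i]:
                cls.add("EQUAL")
            if self.above[i]:
                cls.add("ABOVE")
        return SiteEvidence(
            site=site,
            has_reverse=bool(self.rev[i]),
            has_reverse_sm=bool(self.rev_sm[i]),
            has_reverse_ms=bool(self.rev_ms[i]),
            has_sm=bool(self.sm[i]),
            has_ms=bool(self.ms[i]),
            pair_dist_class=frozenset(cls),
            n_reads=int(self.cov[i]),
        )

    def __getitem__(self, site: int) -> SiteEvidence:
        return self.get(site)

    def clip_sites(self) -> np.ndarray:
        """Sites (absolute coordinates) carrying any clip evidence."""
        return np.nonzero(self.sm | self.ms)[0] + self.start

    def merged_with(self, other: "EvidenceMap") -> "EvidenceMap":
        """Field-wise union of two maps over the same region."""
        if (self.start, self.end) != (other.start, other.end):
            raise ValueError("region mismatch")
        out = EvidenceMap(self.start, self.end)
        out.cov = self.cov + other.cov
        out.pair_cov = self.pair_cov + other.pair_cov
        for name in ("rev", "rev_sm", "rev_ms", "sm", "ms", "below", "equal", "above"):
            setattr(out, name, getattr(self, name) | getattr(other, name))
        return out


def _add_intervals(acc: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> None:
    """Accumulate +1 over [lo, hi) per interval via a difference array."""
    L = acc.shape[0]
    lo = np.clip(lo, 0, L)
    hi = np.clip(hi, 0, L)
    keep = hi > lo
    diff = np.zeros(L + 1, dtype=np.int64)
    np.add.at(diff, lo[keep], 1)
    np.add.at(diff, hi[keep], -1)
    acc += np.cumsum(diff[:-1]).astype(acc.dtype)


def _mark_intervals(mask: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> None:
    cnt = np.zeros(mask.shape[0], dtype=np.int32)
    _add_intervals(cnt, lo, hi)
    mask |= cnt > 0


def collect_evidence(
    reads: "Iterable[AlignedRead] | ReadTable",
    insert_model: InsertSizeModel,
    region: tuple[int, int],
    min_clip: int = DEFAULT_MIN_CLIP,
) -> EvidenceMap:
    """Aggregate per-site evidence over ``region`` from filtered reads.

    Empty regions and empty read sets yield an empty map, never an error.
    """
    start, end = region
    emap = EvidenceMap(start, end)
    if end == start:
        return emap
    tbl = reads if isinstance(reads, ReadTable) else reads_to_table(reads)
    m = tbl.is_mapped
    if not m.any():
        return emap
    pos = tbl.pos[m] - start
    rend = tbl.end[m] - start
    rev = tbl.anom[m]
    lead = tbl.lead_clip[m]
    trail = tbl.trail_clip[m]
    tlen = tbl.tlen[m]
    paired = tbl.is_paired[m]

    _add_intervals(emap.cov, pos, rend)

    L = end - start
    sm_mask = lead >= min_clip
    ms_mask = trail >= min_clip

    # An MS boundary (read end) lies one past the read's span; the clipped
    # read still informs that site, so count it toward n_reads there.
    ms_pts = rend[ms_mask]
    ms_pts = ms_pts[(ms_pts >= 0) & (ms_pts < L)]
    np.add.at(emap.cov, ms_pts, 1)

    def mark_points(mask: np.ndarray, pts: np.ndarray) -> None:
        pts = pts[(pts >= 0) & (pts < L)]
        mask[pts] = True

    mark_points(emap.sm, pos[sm_mask])
    mark_points(emap.ms, rend[ms_mask])
    mark_points(emap.rev_sm, pos[sm_mask & rev])
    mark_points(emap.rev_ms, rend[ms_mask & rev])
    # "reversely mapped" (orientation-anomalous) evidence covers the read's
    # span and its clip boundaries
    _mark_intervals(emap.rev, pos[rev], rend[rev])
    mark_points(emap.rev, rend[ms_mask & rev])

    # Pair-distance evidence: leftmost read of each mapped pair (tlen > 0).
    # A discordant pair localizes its breakpoint to within about one insert
    # length of each anchor, so attachment is capped at the equal-band upper
    # bound from either end of the outer span (otherwise a single pair whose
    # mates map hundreds of kb apart would blanket everything in between).
    psel = paired & (tlen > 0)
    plo = pos[psel]
    phi = plo + tlen[psel]
    lo_band, hi_band = insert_model.band
    cap = int(np.ceil(hi_band))
    d = tlen[psel].astype(float)

    def attach(mask_or_cov, sel):
        lo, hi = plo[sel], phi[sel]
        wide = (hi - lo) > cap
        fn = _add_intervals if mask_or_cov.dtype != bool else _mark_intervals
        fn(mask_or_cov, lo[~wide], hi[~wide])
        fn(mask_or_cov, lo[wide], lo[wide] + cap)
        fn(mask_or_cov, hi[wide] - cap, hi[wide])

    attach(emap.pair_cov, np.ones(plo.shape[0], dtype=bool))
    attach(emap.below, d < lo_band)
    attach(emap.above, d > hi_band)
    attach(emap.equal, (d >= lo_band) & (d <= hi_band))
    return emap
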