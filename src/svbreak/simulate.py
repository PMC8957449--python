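"""Synthetic SV benchmark generator.

Builds a random reference, implants the seven SV categories (insertion,
deletion, translocation, inversion, interspersed duplication, inverted
duplication, tandem duplication) into a donor genome with an exact
piecewise liftover, samples paired-end reads from the donor, and projects
every read back to reference coordinates deterministically — a read whose
fragment spans a donor junction becomes a soft-clipped record anchored on
its longer flank, reads inside inverted segments get the reverse flag, and
reads living entirely in novel inserted sequence come back unmapped.  The
projected records play the role an external aligner would play on real
data, with the advantage that CIGARs and positions follow exactly from the
simulated truth.

Bases are encoded 0..3 = A,C,G,T internally; complement is ``3 - code``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alignment_io import ReadTable
from .model import SVType, SV_TYPES

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MIN_GENOME = 10_000
#: shortest anchor flank that still produces a mapped (clipped) record.
MIN_ANCHOR = 20


def str_to_codes(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[ord(chr(b).lower())] = i
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return codes


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    genome_len: int = 1_000_000
    gc: float = 0.41                       # human-like GC content
    n_per_type: int = 20
    size_range: tuple[int, int] = (200, 2000)
    coverage: float = 30.0
    read_len: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 30.0
    base_error: float = 0.002
    confident_anchor: int = 70
    seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.genome_len < _MIN_GENOME:
            raise ValueError(f"genome_len must be >= {_MIN_GENOME}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        if self.n_per_type < 0:
            raise ValueError("n_per_type must be >= 0")
        if not (0 < self.confident_anchor <= self.read_len):
            raise ValueError("confident_anchor must be in (0, read_len]")


@dataclass(frozen=True)
class TruthRecord:
    """One implanted SV with its reference breakpoints.

    Breakpoint convention: DEL/INV/TDUP contribute their two segment
    boundaries; INS contributes its single insertion point; TRA/IDUP/INVDUP
    contribute the source-segment boundaries plus the distant insertion
    point (3 breakpoints).
    """

    svtype: SVType
    breakpoints: tuple[int, ...]
    size: int
    donor_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be sorted")


class Liftover:
    """Exact piecewise donor -> reference correspondence with strand flags.

    Each block maps donor interval ``[donor_start, donor_start + length)``
    onto reference interval ``[ref_start, ref_start + length)`` either
    forward (strand +1) or reverse-complemented (strand -1); novel blocks
    have no reference home (``ref_start == -1``).
    """

    def __init__(self, donor_starts, lengths, ref_starts, strands, novel):
        self.donor_starts = np.asarray(donor_starts, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.int64)
        self.ref_starts = np.asarray(ref_starts, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=np.int8)
        self.novel = np.asarray(novel, dtype=bool)

    @property
    def donor_len(self) -> int:
        return int(self.donor_starts[-1] + self.lengths[-1]) if len(self.lengths) else 0

    def block_of(self, d: int) -> int:
        i = int(np.searchsorted(self.donor_starts, d, side="right") - 1)
        if i < 0 or d >= self.donor_starts[i] + self.lengths[i]:
            raise IndexError(f"donor position {d} outside liftover")
        return i

    def map_position(self, d: int) -> tuple[int, bool] | None:
        """Reference position and reverse-strand flag for donor position d,
        or None inside novel sequence."""
        i = self.block_of(d)
        if self.novel[i]:
            return None
        off = d - int(self.donor_starts[i])
        if self.strands[i] > 0:
            return int(self.ref_starts[i]) + off, False
        return int(self.ref_starts[i] + self.lengths[i] - 1 - off), True


def generate_reference(genome_len: int, gc: float = 0.41, seed: int = 0) -> np.ndarray:
    """I.i.d. random reference at the given GC content (seeded)."""
    if genome_len < _MIN_GENOME:
        raise ValueError(f"genome_len must be >= {_MIN_GENOME}")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=genome_len, p=p).astype(np.uint8)


# ---------------------------------------------------------------------------
# SV implantation

def _place_footprints(config: SimConfig, rng: np.random.Generator):
    """Sample non-overlapping SV footprints with mutual spacing.

    Returns a list of placement dicts, one per SV.  Raises when the genome
    cannot host the requested load.
    """
    spacing = int(2 * config.insert_mean)
    lo_margin = spacing
    hi_margin = config.genome_len - spacing
    occupied: list[tuple[int, int]] = []

    def conflicts(a: int, b: int) -> bool:
        for x, y in occupied:
            if a < y + spacing and x < b + spacing:
                return True
        return False

    def place_interval(size: int, max_tries: int = 2000) -> tuple[int, int]:
        for _ in range(max_tries):
            a = int(rng.integers(lo_margin, hi_margin - size))
            if not conflicts(a, a + size):
                occupied.append((a, a + size))
                return a, a + size
        raise RuntimeError(
            "could not place SV footprints without overlap; "
            "use fewer or smaller SVs or a larger genome"
        )

    requests = [
        (t, int(rng.integers(config.size_range[0], config.size_range[1] + 1)))
        for t in SV_TYPES
        for _ in range(config.n_per_type)
    ]
    interval_load = sum(s for t, s in requests if t is not SVType.INS)
    if interval_load >= 0.2 * config.genome_len:
        raise ValueError("total SV footprint must stay below 20% of the genome; "
                         "use fewer or smaller SVs or a larger genome")

    order = rng.permutation(len(requests))
    placements = []
    for i in order:
        t, size = requests[i]
        if t is SVType.INS:
            c, _ = place_interval(1)
            placements.append({"svtype": t, "size": size, "point": c})
        elif t in (SVType.DEL, SVType.INV, SVType.TDUP):
            a, b = place_interval(size)
            placements.append({"svtype": t, "size": size, "interval": (a, b)})
        else:  # TRA / IDUP / INVDUP: source segment + distant insertion point
            a, b = place_interval(size)
            c, _ = place_interval(1)
            placements.append({"svtype": t, "size": size, "interval": (a, b), "point": c})
    return placements


def implant_svs(
    reference: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[TruthRecord], Liftover]:
    """Place and realize the seven SV categories in a donor genome.

    Returns the donor sequence (codes), the ground-truth records, and the
    exact donor->reference liftover.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    placements = _place_footprints(config, rng)
    return realize_svs(reference, placements, rng)


def realize_svs(
    reference: np.ndarray,
    placements: list[dict],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, list[TruthRecord], Liftover]:
    """Realize explicit SV placements in a donor genome.

    Each placement is a dict with ``svtype``, ``size``, and an ``interval``
    (source segment) and/or ``point`` (insertion site) as the type requires.
    Placements must be pairwise non-overlapping.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ref = np.asarray(reference, dtype=np.uint8)

    # edits keyed by the reference coordinate at which donor assembly acts
    edits = []    # (anchor, order, kind, payload, placement_index)
    for pi, pl in enumerate(placements):
        t = pl["svtype"]
        if t is SVType.INS:
            novel = rng.integers(0, 4, size=pl["size"]).astype(np.uint8)
            edits.append((pl["point"], 0, "INS", novel, pi))
        elif t is SVType.DEL:
            a, b = pl["interval"]
            edits.append((a, 0, "DEL", (a, b), pi))
        elif t is SVType.INV:
            a, b = pl["interval"]
            edits.append((a, 0, "INV", (a, b), pi))
        elif t is SVType.TDUP:
            a, b = pl["interval"]
            edits.append((a, 0, "TDUP", (a, b), pi))
        else:
            a, b = pl["interval"]
            c = pl["point"]
            if t is SVType.TRA:
                edits.append((a, 0, "DEL", (a, b), pi))
            strand = -1 if t is SVType.INVDUP else 1
            edits.append((c, 1, "COPY", (a, b, strand), pi))
    edits.sort(key=lambda e: (e[0], e[1]))

    blocks = []   # ('R', a, b, strand) | ('N', codes); + placement index or None
    cursor = 0
    donor_pos = 0
    spans: dict[int, list[int]] = {}

    def emit(block, pi=None):
        nonlocal donor_pos
        blocks.append(block)
        length = (block[2] - block[1]) if block[0] == "R" else len(block[1])
        if pi is not None:
            spans.setdefault(pi, [donor_pos, donor_pos])
            spans[pi][1] = donor_pos + length
        donor_pos += length

    for anchor, _order, kind, payload, pi in edits:
        if anchor > cursor:
            emit(("R", cursor, anchor, 1))
        if kind == "DEL":
            a, b = payload
            spans.setdefault(pi, [donor_pos, donor_pos])
            cursor = b
        elif kind == "INV":
            a, b = payload
            emit(("R", a, b, -1), pi)
            cursor = b
        elif kind == "TDUP":
            a, b = payload
            emit(("R", a, b, 1), pi)
            emit(("R", a, b, 1), pi)
            cursor = b
        elif kind == "INS":
            emit(("N", payload), pi)
            cursor = anchor
        elif kind == "COPY":
            a, b, strand = payload
            emit(("R", a, b, strand), pi)
            cursor = anchor
    if cursor < len(ref):
        emit(("R", cursor, len(ref), 1))

    # merge reference-collinear neighbours (e.g. a tandem-duplication copy
    # flowing into the resumed reference) so only true junctions exist
    merged: list = []
    for block in blocks:
        if (
            merged
            and merged[-1][0] == "R"
            and block[0] == "R"
            and merged[-1][3] == block[3]
            and (
                (block[3] > 0 and block[1] == merged[-1][2])
                or (block[3] < 0 and block[2] == merged[-1][1])
            )
        ):
            prev = merged.pop()
            if block[3] > 0:
                merged.append(("R", prev[1], block[2], 1))
            else:
                merged.append(("R", block[1], prev[2], -1))
        else:
            merged.append(block)
    blocks = merged

    # assemble donor + liftover
    donor_parts = []
    donor_starts, lengths, ref_starts, strands, novel = [], [], [], [], []
    d = 0
    for block in blocks:
        if block[0] == "R":
            _, a, b, st = block
            seg = ref[a:b] if st > 0 else revcomp(ref[a:b])
            donor_parts.append(seg)
            donor_starts.append(d)
            lengths.append(b - a)
            ref_starts.append(a)
            strands.append(st)
            novel.append(False)
            d += b - a
        else:
            seq = block[1]
            donor_parts.append(seq)
            donor_starts.append(d)
            lengths.append(len(seq))
            ref_starts.append(-1)
            strands.append(1)
            novel.append(True)
            d += len(seq)
    donor = np.concatenate(donor_parts) if donor_parts else np.empty(0, dtype=np.uint8)
    lift = Liftover(donor_starts, lengths, ref_starts, strands, novel)

    truths = []
    for pi, pl in enumerate(placements):
        t = pl["svtype"]
        if t is SVType.INS:
            bkps = (pl["point"],)
        elif t in (SVType.DEL, SVType.INV, SVType.TDUP):
            bkps = tuple(pl["interval"])
        else:
            a, b = pl["interval"]
            bkps = tuple(sorted((a, b, pl["point"])))
        span = tuple(spans.get(pi, [0, 0]))
        truths.append(TruthRecord(svtype=t, breakpoints=bkps,
                                  size=pl["size"], donor_span=span))
    truths.sort(key=lambda r: r.breakpoints[0])
    return donor, truths, lift


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class ReadSet:
    """Paired-end reads with their true donor coordinates.

    R1 is the forward read at the fragment start, R2 the reverse-complemented
    read at the fragment end (as sequenced).
    """

    start: np.ndarray        # fragment start on donor
    frag: np.ndarray         # fragment length
    r1: np.ndarray           # (n, read_len) base codes, as sequenced
    r2: np.ndarray
    read_len: int
    donor_len: int

    def __len__(self) -> int:
        return int(self.start.shape[0])


def simulate_reads(
    donor: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Sample paired-end reads uniformly from the donor at the configured
    coverage, with Normal fragment lengths and i.i.d. substitution errors."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    donor = np.asarray(donor, dtype=np.uint8)
    L = donor.shape[0]
    rl = config.read_len
    n = int(round(config.coverage * L / (2 * rl)))
    frag = np.rint(rng.normal(config.insert_mean, config.insert_sd, n)).astype(np.int64)
    frag = np.clip(frag, 2 * rl, L)
    start = (rng.random(n) * (L - frag + 1)).astype(np.int64)
    offs = np.arange(rl)
    r1 = donor[start[:, None] + offs]
    r2_fwd = donor[(start + frag - rl)[:, None] + offs]
    r2 = (3 - r2_fwd)[:, ::-1].copy()
    if config.base_error > 0:
        for arr in (r1, r2):
            mask = rng.random(arr.shape) < config.base_error
            shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            arr[mask] = (arr[mask] + shift) % 4
    return ReadSet(start=start, frag=frag, r1=r1, r2=r2, read_len=rl, donor_len=L)


# ---------------------------------------------------------------------------
# truth projection (deterministic aligner stand-in)

@dataclass
class ProjectedReads:
    """Reference-projected alignment records for a :class:`ReadSet`.

    Rows 0..n-1 are R1, rows n..2n-1 are R2 of the same pair index.
    """

    pos: np.ndarray
    end: np.ndarray
    mapq: np.ndarray
    is_reverse: np.ndarray
    lead_clip: np.ndarray
    trail_clip: np.ndarray
    tlen: np.ndarray
    is_proper: np.ndarray
    is_mapped: np.ndarray
    pair_id: np.ndarray
    is_read1: np.ndarray
    seqs: np.ndarray          # as-sequenced base codes, (2n, read_len)
    read_len: int
    chrom: str
    ref_len: int

    def __len__(self) -> int:
        return int(self.pos.shape[0])

    def read_table(self) -> ReadTable:
        n = len(self) // 2
        both = self.is_mapped[:n] & self.is_mapped[n:]
        same = self.is_reverse[:n] == self.is_reverse[n:]
        anom_pair = both & same
        anom = np.concatenate([anom_pair, anom_pair])
        return ReadTable(
            pos=self.pos, end=self.end, mapq=self.mapq,
            is_reverse=self.is_reverse, lead_clip=self.lead_clip,
            trail_clip=self.trail_clip, tlen=self.tlen,
            is_paired=np.ones(len(self), dtype=bool),
            is_proper=self.is_proper, is_mapped=self.is_mapped, anom=anom,
        )

    # -- SAM export --------------------------------------------------------
    def cigar_string(self, i: int) -> str:
        if not self.is_mapped[i]:
            return "*"
        lead = int(self.lead_clip[i])
        trail = int(self.trail_clip[i])
        m = self.read_len - lead - trail
        parts = []
        if lead:
            parts.append(f"{lead}S")
        parts.append(f"{m}M")
        if trail:
            parts.append(f"{trail}S")
        return "".join(parts)

    def to_sam(self, path: str) -> None:
        """Write coordinate-sorted SAM with a proper header."""
        # mapped records first in coordinate order, unmapped at the end
        mapped_first = np.lexsort((self.pos, ~self.is_mapped))
        n_pairs = len(self) // 2
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            fh.write(f"@SQ\tSN:{self.chrom}\tLN:{self.ref_len}\n")
            fh.write("@PG\tID:svbreak-sim\tPN:svbreak-sim\n")
            for i in mapped_first:
                i = int(i)
                mate = i + n_pairs if self.is_read1[i] else i - n_pairs
                flag = 1
                flag |= 2 if self.is_proper[i] else 0
                flag |= 4 if not self.is_mapped[i] else 0
                flag |= 8 if not self.is_mapped[mate] else 0
                flag |= 16 if self.is_reverse[i] else 0
                flag |= 32 if self.is_reverse[mate] else 0
                flag |= 64 if self.is_read1[i] else 128
                seq = self.seqs[i]
                if self.is_reverse[i]:
                    seq = (3 - seq)[::-1]
                rname = self.chrom if self.is_mapped[i] else "*"
                pos1 = int(self.pos[i]) + 1 if self.is_mapped[i] else 0
                mrname = "=" if self.is_mapped[mate] else "*"
                mpos1 = int(self.pos[mate]) + 1 if self.is_mapped[mate] else 0
                fh.write(
                    f"pair{int(self.pair_id[i])}\t{flag}\t{rname}\t{pos1}\t"
                    f"{int(self.mapq[i])}\t{self.cigar_string(i)}\t{mrname}\t"
                    f"{mpos1}\t{int(self.tlen[i])}\t{codes_to_str(seq)}\t"
                    f"{'I' * self.read_len}\n"
                )


def project_alignments(
    reads: ReadSet,
    liftover: Liftover,
    config: SimConfig,
    min_anchor: int = MIN_ANCHOR,
) -> ProjectedReads:
    """Map simulated reads through the liftover to reference coordinates.

    A read fitting inside one liftover block maps contiguously (all-M).  A
    read spanning one or more junctions is anchored on its longest
    reference-mapped flank (ties to the leftmost) and the remaining bases
    are soft-clipped on the appropriate side; if no flank reaches
    ``min_anchor`` matched bases (e.g. a read living inside novel inserted
    sequence) the record is emitted unmapped.
    """
    n = len(reads)
    rl = reads.read_len
    donor_s = np.concatenate([reads.start, reads.start + reads.frag - rl])
    donor_e = donor_s + rl
    donor_rev = np.concatenate([np.zeros(n, dtype=bool), np.ones(n, dtype=bool)])
    seqs = np.concatenate([reads.r1, reads.r2], axis=0)
    N = 2 * n

    ds, dl = liftover.donor_starts, liftover.lengths
    i0 = np.searchsorted(ds, donor_s, side="right") - 1
    i1 = np.searchsorted(ds, donor_e - 1, side="right") - 1

    pos = np.zeros(N, dtype=np.int64)
    end = np.zeros(N, dtype=np.int64)
    rev = np.zeros(N, dtype=bool)
    lead = np.zeros(N, dtype=np.int32)
    trail = np.zeros(N, dtype=np.int32)
    mapped = np.zeros(N, dtype=bool)

    simple = (i0 == i1) & ~liftover.novel[i0]
    b = i0[simple]
    off = donor_s[simple] - ds[b]
    fwd = liftover.strands[b] > 0
    p = np.where(
        fwd,
        liftover.ref_starts[b] + off,
        liftover.ref_starts[b] + dl[b] - (donor_e[simple] - ds[b]),
    )
    pos[simple] = p
    end[simple] = p + rl
    rev[simple] = donor_rev[simple] ^ ~fwd
    mapped[simple] = True

    hard = np.nonzero(~simple)[0]
    for i in hard:
        s, e = int(donor_s[i]), int(donor_e[i])
        pieces = []
        for j in range(int(i0[i]), int(i1[i]) + 1):
            lo = max(s, int(ds[j]))
            hi = min(e, int(ds[j] + dl[j]))
            if hi > lo and not liftover.novel[j]:
                pieces.append((hi - lo, lo, hi, j))
        if not pieces:
            continue
        best = max(pieces, key=lambda t: (t[0], -t[1]))
        plen, lo, hi, j = best
        if plen < min_anchor:
            continue
        offj = lo - int(ds[j])
        if liftover.strands[j] > 0:
            rp = int(liftover.ref_starts[j]) + offj
            ld, tr = lo - s, e - hi
            flip = False
        else:
            rp = int(liftover.ref_starts[j] + dl[j] - (hi - int(ds[j])))
            ld, tr = e - hi, lo - s
            flip = True
        pos[i] = rp
        end[i] = rp + plen
        lead[i] = ld
        trail[i] = tr
        rev[i] = bool(donor_rev[i]) ^ flip
        mapped[i] = True

    # template length from the reference-projected pair
    tlen = np.zeros(N, dtype=np.int64)
    proper = np.zeros(N, dtype=bool)
    m1, m2 = mapped[:n], mapped[n:]
    both = m1 & m2
    left = np.minimum(pos[:n], pos[n:])
    right = np.maximum(end[:n], end[n:])
    size = right - left
    r1_left = pos[:n] <= pos[n:]
    t1 = np.where(r1_left, size, -size)
    tlen[:n][both] = t1[both]
    tlen[n:][both] = -t1[both]
    opp = rev[:n] != rev[n:]
    proper_pair = both & opp & (size > 0) & (size < 5 * config.insert_mean)
    proper[:n] = proper_pair
    proper[n:] = proper_pair

    # Mapping-quality model: full-length alignments are confident (60); a
    # soft-clipped record whose matched block is shorter than
    # ``confident_anchor`` is the kind of short split anchor a real aligner
    # places ambiguously, so it gets a low quality and is removed by the
    # default mapq filter.  This is what makes split-read evidence genuinely
    # coverage-dependent.
    matched = rl - lead - trail
    clipped = (lead + trail) > 0
    confident = ~clipped | (matched >= config.confident_anchor)
    mapq = np.where(mapped & confident, 60,
                    np.where(mapped, 10, 0)).astype(np.int32)
    return ProjectedReads(
        pos=pos, end=end, mapq=mapq, is_reverse=rev,
        lead_clip=lead, trail_clip=trail, tlen=tlen,
        is_proper=proper, is_mapped=mapped,
        pair_id=np.concatenate([np.arange(n), np.arange(n)]),
        is_read1=np.concatenate([np.ones(n, dtype=bool), np.zeros(n, dtype=bool)]),
        seqs=seqs, read_len=rl, chrom=config.chrom,
        ref_len=0,  # filled by simulate_dataset / caller
    )


# ---------------------------------------------------------------------------
# file I/O

def write_fasta(path: str, name: str, codes: np.ndarray, width: int = 70) -> None:
    seq = codes_to_str(codes)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def write_fastq(reads: ReadSet, path_r1: str, path_r2: str) -> None:
    qual = "I" * reads.read_len
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for i in range(len(reads)):
            f1.write(f"@pair{i}/1\n{codes_to_str(reads.r1[i])}\n+\n{qual}\n")
            f2.write(f"@pair{i}/2\n{codes_to_str(reads.r2[i])}\n+\n{qual}\n")


def write_truth(records: list[TruthRecord], bed_path: str, tsv_path: str,
                chrom: str = "chr1") -> None:
    """One BED row per breakpoint; one TSV row per SV (lossless round-trip)."""
    with open(bed_path, "w") as fh:
        for r in records:
            for bp in r.breakpoints:
                fh.write(f"{chrom}\t{bp}\t{bp + 1}\t{r.svtype.name}\n")
    with open(tsv_path, "w") as fh:
        fh.write("svtype\tbreakpoints\tsize\tdonor_start\tdonor_end\n")
        for r in records:
            bps = ",".join(str(b) for b in r.breakpoints)
            fh.write(f"{r.svtype.name}\t{bps}\t{r.size}\t"
                     f"{r.donor_span[0]}\t{r.donor_span[1]}\n")


def read_truth_tsv(path: str) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            name, bps, size, d0, d1 = line.rstrip("\n").split("\t")
            records.append(TruthRecord(
                svtype=SVType[name],
                breakpoints=tuple(int(x) for x in bps.split(",")),
                size=int(size), donor_span=(int(d0), int(d1)),
            ))
    return records


# ---------------------------------------------------------------------------
# one-call dataset builder

@dataclass
class SimResult:
    config: SimConfig
    reference: np.ndarray
    donor: np.ndarray
    truths: list[TruthRecord]
    liftover: Liftover
    reads: ReadSet
    projected: ProjectedReads

    @property
    def truth_breakpoints(self) -> list[tuple[int, SVType]]:
        return [(bp, r.svtype) for r in self.truths for bp in r.breakpoints]


def simulate_dataset(config: SimConfig, out_dir: str | None = None) -> SimResult:
    """Reference -> donor -> reads -> projected alignments, fully seeded."""
    root = np.random.default_rng(config.seed)
    ref_seed, sv_seed, read_seed = (int(s) for s in root.integers(0, 2**31, 3))
    ref = generate_reference(config.genome_len, config.gc, seed=ref_seed)
    donor, truths, lift = implant_svs(ref, config, rng=np.random.default_rng(sv_seed))
    reads = simulate_reads(donor, config, rng=np.random.default_rng(read_seed))
    proj = project_alignments(reads, lift, config)
    proj.ref_len = config.genome_len
    result = SimResult(config=config, reference=ref, donor=donor, truths=truths,
                       liftover=lift, reads=reads, projected=proj)
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_fasta(d / "reference.fa", config.chrom, ref)
        write_fasta(d / "donor.fa", f"{config.chrom}_donor", donor)
        write_fastq(reads, d / "reads_R1.fastq", d / "reads_R2.fastq")
        proj.to_sam(d / "alignments.sam")
        write_truth(truths, d / "truth.bed", d / "truth.tsv", chrom=config.chrom)
    return result
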