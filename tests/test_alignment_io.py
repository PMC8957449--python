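"""Alignment filtering, clip classification, and evidence collection."""

import numpy as np
import pytest

from svbreak.alignment_io import (
    AlignedRead,
    ClipKind,
    InsertSizeModel,
    classify_clip,
    collect_evidence,
    estimate_insert_size,
    read_alignments,
    reads_to_table,
)


def make_read(pos=100, cigar=(("M", 100),), mapq=60, reverse=False, **kw):
    defaults = dict(query_name="r", ref_name="chr1", pos=pos, mapq=mapq,
                    is_reverse=reverse, cigar=tuple(cigar))
    defaults.update(kw)
    return AlignedRead(**defaults)


# ---------------------------------------------------------------------------
# clip classification

@pytest.mark.parametrize("cigar,pos,kind,clip_len,boundary", [
    ((("M", 70), ("S", 30)), 1000, ClipKind.MS, 30, 1070),
    ((("S", 30), ("M", 70)), 1000, ClipKind.SM, 30, 1000),
    ((("M", 100),), 1000, ClipKind.NONE, 0, None),
    ((("S", 10), ("M", 80), ("S", 10)), 50, ClipKind.BOTH, 20, 50),
    ((("S", 3), ("M", 97)), 10, ClipKind.NONE, 0, None),   # below min clip
    ((("H", 5), ("M", 70), ("S", 30)), 0, ClipKind.MS, 30, 70),
])
def test_classify_clip_cases(cigar, pos, kind, clip_len, boundary):
    cc = classify_clip(cigar, pos)
    assert (cc.kind, cc.clip_len, cc.boundary_ref_pos) == (kind, clip_len, boundary)


def test_classify_clip_requires_aligned_block():
    with pytest.raises(ValueError, match="no aligned segment"):
        classify_clip((("S", 50), ("S", 50)), 0)


def test_classify_clip_matches_bruteforce_walker():
    """MS boundary must equal pos + sum of reference-consuming op lengths,
    on 1000 random CIGARs, against an independent walker."""
    rng = np.random.default_rng(12345)
    ref_ops, any_ops = "MDN=X", "MIDN=X"
    for _ in range(1000):
        n_ops = int(rng.integers(1, 6))
        core = [(any_ops[rng.integers(len(any_ops))], int(rng.integers(1, 60)))
                for _ in range(n_ops)]
        if not any(op in "M=X" for op, _ in core):
            core.append(("M", int(rng.integers(1, 60))))
        lead = int(rng.integers(0, 40))
        trail = int(rng.integers(0, 40))
        cigar = ([("S", lead)] if lead else []) + core + ([("S", trail)] if trail else [])
        pos = int(rng.integers(0, 10000))
        cc = classify_clip(cigar, pos)
        # independent walker
        ref_len = sum(n for op, n in cigar if op in ref_ops)
        lead_ok, trail_ok = lead >= 5, trail >= 5
        if lead_ok and trail_ok:
            assert cc.kind is ClipKind.BOTH and cc.boundary_ref_pos == pos
        elif lead_ok:
            assert cc.kind is ClipKind.SM and cc.boundary_ref_pos == pos
        elif trail_ok:
            assert cc.kind is ClipKind.MS
            assert cc.boundary_ref_pos == pos + ref_len
        else:
            assert cc.kind is ClipKind.NONE


# ---------------------------------------------------------------------------
# SAM reading / mapq filter

SAM_TEMPLATE = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:10000
r1\t0\tchr1\t101\t0\t100M\t*\t0\t0\t{seq}\t{qual}
r2\t0\tchr1\t201\t30\t100M\t*\t0\t0\t{seq}\t{qual}
r3\t16\tchr1\t301\t60\t70M30S\t*\t0\t0\t{seq}\t{qual}
"""


@pytest.fixture()
def three_read_sam(tmp_path):
    path = tmp_path / "t.sam"
    path.write_text(SAM_TEMPLATE.format(seq="A" * 100, qual="I" * 100))
    return str(path)


def test_mapq_filter_threshold_and_boundary(three_read_sam):
    # mapqs are {0, 30, 60}: threshold 20 keeps 2; the boundary is inclusive
    reads = list(read_alignments(three_read_sam, min_mapq=20))
    assert len(reads) == 2
    assert [r.mapq for r in reads] == [30, 60]
    assert len(list(read_alignments(three_read_sam, min_mapq=30))) == 2
    assert len(list(read_alignments(three_read_sam, min_mapq=0))) == 3
    # fields survive the round trip
    r3 = [r for r in read_alignments(three_read_sam, min_mapq=0) if r.is_reverse]
    assert r3[0].pos == 300 and r3[0].cigar == (("M", 70), ("S", 30))


# ---------------------------------------------------------------------------
# insert-size estimation

def _pair(tlen, pos=0):
    return make_read(pos=pos, template_len=tlen, is_paired=True, is_proper=True,
                     mate_is_reverse=True)


def test_insert_size_median_and_floor():
    reads = [_pair(t) for t in (340, 350, 360) * 20]
    m = estimate_insert_size(reads, min_pairs=50)
    assert m.mean == 350
    degenerate = [_pair(350) for _ in range(60)]
    m2 = estimate_insert_size(degenerate, min_pairs=50)
    assert m2.mean == 350 and m2.sd == 1.0     # sd floor on zero spread


def test_insert_size_requires_pairs():
    unpaired = [make_read() for _ in range(100)]
    with pytest.raises(ValueError, match="supply insert mean/sd"):
        estimate_insert_size(unpaired)


# ---------------------------------------------------------------------------
# evidence collection

MODEL = InsertSizeModel(mean=350, sd=30, k=3)


def test_reverse_sm_read_marks_its_boundary():
    # an unpaired reverse read "30S70M" at 500: reverse status falls back to
    # the strand flag; SM evidence lands at the alignment start
    read = make_read(pos=500, cigar=(("S", 30), ("M", 70)), reverse=True)
    emap = collect_evidence([read], MODEL, (0, 1000))
    ev = emap.get(500)
    assert ev.has_reverse and ev.has_reverse_sm and ev.has_sm
    assert not ev.has_ms and not ev.has_reverse_ms
    assert ev.n_reads == 1


def test_uncovered_site_is_empty():
    read = make_read(pos=500)
    emap = collect_evidence([read], MODEL, (0, 1000))
    ev = emap.get(50)
    assert ev.n_reads == 0
    assert not any([ev.has_reverse, ev.has_sm, ev.has_ms])
    assert ev.pair_dist_class == frozenset()


def test_pair_distance_above_band():
    # |tlen| 850 with band [260, 440] -> ABOVE on sites near the anchors
    r1 = make_read(pos=1000, template_len=850, is_paired=True, mate_is_reverse=True)
    r2 = make_read(pos=1750, template_len=-850, is_paired=True, reverse=True,
                   mate_is_reverse=False)
    emap = collect_evidence([r1, r2], MODEL, (0, 3000))
    assert "ABOVE" in emap.get(1050).pair_dist_class
    assert "ABOVE" in emap.get(1800).pair_dist_class
    assert emap.get(2500).pair_dist_class == frozenset()


def test_evidence_additivity_over_read_sets():
    """Evidence of a concatenation equals the field-wise union/merge."""
    rng = np.random.default_rng(3)
    def random_reads(n, seed):
        r = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            pos = int(r.integers(0, 1900))
            kind = r.integers(3)
            cigar = ((("M", 100),), (("S", 30), ("M", 70)),
                     (("M", 70), ("S", 30)))[kind]
            out.append(make_read(pos=pos, cigar=cigar,
                                 reverse=bool(r.integers(2)),
                                 template_len=int(r.integers(200, 900)),
                                 is_paired=True, mate_is_reverse=False))
        return out
    A, B = random_reads(30, 1), random_reads(30, 2)
    merged = collect_evidence(A, MODEL, (0, 3000)).merged_with(
        collect_evidence(B, MODEL, (0, 3000)))
    combined = collect_evidence(A + B, MODEL, (0, 3000))
    for name in ("rev", "rev_sm", "rev_ms", "sm", "ms", "below", "equal", "above"):
        assert np.array_equal(getattr(merged, name), getattr(combined, name)), name
    assert np.array_equal(merged.cov, combined.cov)


def test_no_flags_outside_spans_and_boundaries():
    reads = [make_read(pos=100, cigar=(("M", 70), ("S", 30)))]
    emap = collect_evidence(reads, MODEL, (0, 1000))
    flagged = emap.cov > 0
    for name in ("rev", "sm", "ms", "below", "equal", "above"):
        assert not np.any(getattr(emap, name) & ~flagged)
    # the only evidence sites are the span [100,170) and the MS boundary 170
    assert set(np.nonzero(flagged)[0]) == set(range(100, 171))


def test_empty_region_is_not_an_error():
    emap = collect_evidence([], MODEL, (100, 100))
    assert emap.clip_sites().size == 0


def test_read_table_round_trip(small_sim):
    """Projected records survive SAM export and re-import."""
    tbl = small_sim.projected.read_table()
    keep = tbl.filter_mapq(20)
    assert len(keep) < len(tbl)
    assert keep.is_mapped.all()
    assert (keep.mapq >= 20).all()
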