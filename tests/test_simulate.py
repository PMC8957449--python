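"""Reference generation, SV implantation, read simulation and projection."""

import numpy as np
import pytest

from svbreak.alignment_io import load_read_table
from svbreak.model import SVType
from svbreak.simulate import (
    ReadSet,
    SimConfig,
    generate_reference,
    implant_svs,
    project_alignments,
    read_truth_tsv,
    realize_svs,
    simulate_dataset,
    simulate_reads,
    write_truth,
)


def test_reference_is_seeded_and_gc_controlled():
    a = generate_reference(50_000, 0.5, seed=3)
    b = generate_reference(50_000, 0.5, seed=3)
    assert np.array_equal(a, b)
    big = generate_reference(1_000_000, 0.5, seed=4)
    gc = np.isin(big, (1, 2)).mean()
    assert 0.49 <= gc <= 0.51
    with pytest.raises(ValueError):
        generate_reference(1000)


# ---------------------------------------------------------------------------
# SV semantics

REF = generate_reference(30_000, 0.5, seed=9)


def test_deletion_semantics():
    donor, truths, lift = realize_svs(REF, [
        {"svtype": SVType.DEL, "size": 500, "interval": (10_000, 10_500)}])
    assert len(donor) == len(REF) - 500
    assert truths[0].breakpoints == (10_000, 10_500)
    assert np.array_equal(donor, np.concatenate([REF[:10_000], REF[10_500:]]))


def test_inversion_semantics():
    donor, truths, lift = realize_svs(REF, [
        {"svtype": SVType.INV, "size": 300, "interval": (10_000, 10_300)}])
    assert len(donor) == len(REF)
    assert np.array_equal(donor[10_000:10_300], (3 - REF[10_000:10_300])[::-1])
    i = lift.block_of(10_100)
    assert lift.strands[i] == -1                  # segment marked reverse
    assert truths[0].breakpoints == (10_000, 10_300)


def test_tandem_duplication_semantics():
    donor, truths, _ = realize_svs(REF, [
        {"svtype": SVType.TDUP, "size": 400, "interval": (10_000, 10_400)}])
    assert len(donor) == len(REF) + 400
    expect = np.concatenate([REF[:10_400], REF[10_000:10_400], REF[10_400:]])
    assert np.array_equal(donor, expect)
    assert truths[0].breakpoints == (10_000, 10_400)


def test_insertion_and_interspersed_duplication_semantics():
    donor, truths, _ = realize_svs(
        REF, [{"svtype": SVType.INS, "size": 250, "point": 5_000}],
        rng=np.random.default_rng(0))
    assert len(donor) == len(REF) + 250
    assert truths[0].breakpoints == (5_000,)

    donor, truths, _ = realize_svs(REF, [
        {"svtype": SVType.IDUP, "size": 300, "interval": (10_000, 10_300),
         "point": 20_000}])
    assert len(donor) == len(REF) + 300
    assert np.array_equal(donor[20_000:20_300], REF[10_000:10_300])
    assert truths[0].breakpoints == (10_000, 10_300, 20_000)

    donor, truths, _ = realize_svs(REF, [
        {"svtype": SVType.INVDUP, "size": 300, "interval": (10_000, 10_300),
         "point": 20_000}])
    assert np.array_equal(donor[20_000:20_300], (3 - REF[10_000:10_300])[::-1])


def test_translocation_semantics():
    donor, truths, _ = realize_svs(REF, [
        {"svtype": SVType.TRA, "size": 400, "interval": (10_000, 10_400),
         "point": 20_000}])
    assert len(donor) == len(REF)                  # moved, not copied
    expect = np.concatenate([REF[:10_000], REF[10_400:20_000],
                             REF[10_000:10_400], REF[20_000:]])
    assert np.array_equal(donor, expect)
    assert truths[0].breakpoints == (10_000, 10_400, 20_000)


def test_footprint_overflow_is_an_error():
    cfg = SimConfig(genome_len=10_000, n_per_type=20)
    with pytest.raises(ValueError, match="20%"):
        implant_svs(REF[:10_000], cfg)


def test_liftover_is_exact(clean_sim):
    """Donor base equals strand-adjusted reference base at every non-novel
    position (block-wise exhaustive on a <=100 kb genome)."""
    ref, donor, lift = clean_sim.reference, clean_sim.donor, clean_sim.liftover
    for i in range(len(lift.lengths)):
        ds, ln = int(lift.donor_starts[i]), int(lift.lengths[i])
        if lift.novel[i]:
            continue
        rs = int(lift.ref_starts[i])
        seg = ref[rs:rs + ln]
        if lift.strands[i] < 0:
            seg = (3 - seg)[::-1]
        assert np.array_equal(donor[ds:ds + ln], seg)
    assert lift.donor_len == len(donor)


# ---------------------------------------------------------------------------
# reads

def test_read_count_follows_coverage_identity():
    donor = generate_reference(100_000, 0.5, seed=5)
    cfg = SimConfig(genome_len=100_000, coverage=10, read_len=100, n_per_type=0)
    reads = simulate_reads(donor, cfg, rng=np.random.default_rng(1))
    expect = 10 * 100_000 / 200
    assert abs(len(reads) - expect) / expect < 0.05


def test_error_free_reads_substring_match_donor(clean_sim):
    reads, donor = clean_sim.reads, clean_sim.donor
    rl = reads.read_len
    for i in range(0, len(reads), 997):
        s = int(reads.start[i])
        f = int(reads.frag[i])
        assert np.array_equal(reads.r1[i], donor[s:s + rl])
        r2fwd = (3 - reads.r2[i])[::-1]
        assert np.array_equal(r2fwd, donor[s + f - rl:s + f])


def test_fastq_is_deterministic(tmp_path):
    cfg = SimConfig(genome_len=100_000, n_per_type=1, coverage=5, seed=13)
    for d in ("a", "b"):
        simulate_dataset(cfg, out_dir=tmp_path / d)
    for name in ("reads_R1.fastq", "reads_R2.fastq", "reference.fa",
                 "alignments.sam", "truth.bed"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes(), name


# ---------------------------------------------------------------------------
# truth projection

def _single_del_setup():
    ref = generate_reference(30_000, 0.5, seed=2)
    donor, truths, lift = realize_svs(ref, [
        {"svtype": SVType.DEL, "size": 500, "interval": (10_000, 10_500)}])
    cfg = SimConfig(genome_len=30_000, n_per_type=0, coverage=1,
                    base_error=0.0, seed=1)
    return ref, donor, lift, cfg


def _manual_readset(donor, starts, frag, rl=100):
    starts = np.asarray(starts, dtype=np.int64)
    frag = np.asarray(frag, dtype=np.int64)
    offs = np.arange(rl)
    r1 = donor[starts[:, None] + offs]
    r2 = (3 - donor[(starts + frag - rl)[:, None] + offs])[:, ::-1].copy()
    return ReadSet(start=starts, frag=frag, r1=r1, r2=r2, read_len=rl,
                   donor_len=len(donor))


def test_unbroken_read_projects_full_match():
    ref, donor, lift, cfg = _single_del_setup()
    rs = _manual_readset(donor, [2_000], [300])
    pr = project_alignments(rs, lift, cfg)
    assert pr.is_mapped.all()
    assert pr.cigar_string(0) == "100M"
    assert pr.pos[0] == 2_000 and not pr.is_reverse[0]
    assert pr.is_proper[0]


def test_split_read_at_deletion_junction_is_70M30S():
    ref, donor, lift, cfg = _single_del_setup()
    # donor position 10_000 is the junction; read covers 70 bp left of it
    rs = _manual_readset(donor, [9_930], [300])
    pr = project_alignments(rs, lift, cfg)
    assert pr.cigar_string(0) == "70M30S"
    assert pr.pos[0] == 9_930 and pr.end[0] == 10_000    # MS boundary at bkp
    # mapq model: a 70 bp anchor is the confident minimum
    assert pr.mapq[0] == 60
    rs2 = _manual_readset(donor, [9_935], [300])
    pr2 = project_alignments(rs2, lift, cfg)
    assert pr2.cigar_string(0) == "65M35S"
    assert pr2.mapq[0] == 10                             # short anchor


def test_pair_spanning_deletion_has_inflated_template():
    ref, donor, lift, cfg = _single_del_setup()
    # fragment 350 fully straddling the 500 bp deletion
    rs = _manual_readset(donor, [9_800], [350])
    pr = project_alignments(rs, lift, cfg)
    assert pr.tlen[0] == 350 + 500                       # reference-projected
    assert pr.tlen[1] == -850


def test_read_inside_novel_sequence_is_unmapped():
    ref = generate_reference(30_000, 0.5, seed=2)
    donor, truths, lift = realize_svs(
        ref, [{"svtype": SVType.INS, "size": 600, "point": 10_000}],
        rng=np.random.default_rng(0))
    cfg = SimConfig(genome_len=30_000, n_per_type=0, coverage=1, seed=1)
    rs = _manual_readset(donor, [10_250], [300])         # fully inside novel
    pr = project_alignments(rs, lift, cfg)
    assert not pr.is_mapped[0]
    assert pr.mapq[0] == 0


def test_projected_match_blocks_are_reference_substrings(clean_sim):
    pr, ref = clean_sim.projected, clean_sim.reference
    rl = pr.read_len
    idx = np.nonzero(pr.is_mapped)[0][::31]
    for i in idx:
        i = int(i)
        seq = pr.seqs[i]
        if pr.is_reverse[i]:
            seq = (3 - seq)[::-1]
        sub = seq[int(pr.lead_clip[i]):rl - int(pr.trail_clip[i])]
        assert np.array_equal(sub, ref[int(pr.pos[i]):int(pr.end[i])])


def test_sam_export_parses_and_round_trips(tmp_path, small_sim):
    path = tmp_path / "aln.sam"
    small_sim.projected.to_sam(path)
    tbl = load_read_table(str(path), min_mapq=20)
    ref_tbl = small_sim.projected.read_table().filter_mapq(20)
    assert len(tbl) == len(ref_tbl)
    assert np.array_equal(np.sort(tbl.pos), np.sort(ref_tbl.pos))
    assert tbl.lead_clip.sum() == ref_tbl.lead_clip.sum()
    assert int(tbl.is_reverse.sum()) == int(ref_tbl.is_reverse.sum())


def test_breakpoints_have_nearby_clip_evidence():
    """At >=20x, essentially every truth breakpoint carries a soft-clipped
    record within +/-5 bp (statistical over seeds, not per-seed)."""
    hits = total = 0
    for seed in (5, 6):
        sim = simulate_dataset(SimConfig(genome_len=500_000, n_per_type=10,
                                         coverage=20, seed=seed))
        tbl = sim.projected.read_table()        # pre-filter: record existence
        sm = tbl.pos[tbl.lead_clip >= 5]
        ms = tbl.end[tbl.trail_clip >= 5]
        clip_sites = np.unique(np.concatenate([sm, ms]))
        for bp, _t in sim.truth_breakpoints:
            total += 1
            d = np.abs(clip_sites - bp).min()
            hits += d <= 5
    assert hits / total >= 0.99


# ---------------------------------------------------------------------------
# truth files

def test_truth_files_round_trip(tmp_path):
    recs = [
        __import__("svbreak.simulate", fromlist=["TruthRecord"]).TruthRecord(
            svtype=SVType.DEL, breakpoints=(10_000, 10_500), size=500,
            donor_span=(10_000, 10_000)),
    ]
    bed, tsv = tmp_path / "t.bed", tmp_path / "t.tsv"
    write_truth(recs, bed, tsv)
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == 2                       # one BED row per breakpoint
    assert lines[0].split("\t")[:4] == ["chr1", "10000", "10001", "DEL"]
    back = read_truth_tsv(tsv)
    assert back == recs

    write_truth([], tmp_path / "e.bed", tmp_path / "e.tsv")
    assert (tmp_path / "e.tsv").read_text().startswith("svtype\t")
    assert read_truth_tsv(tmp_path / "e.tsv") == []
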