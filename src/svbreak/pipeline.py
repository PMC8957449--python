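"""Glue between alignment evidence, feature encoding and the classifiers.

Feature vectors are built for *candidate* sites — every site carrying clip
evidence, plus a seeded sample of random background sites that supply
noise negatives for training — rather than for every base of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import (
    DEFAULT_MIN_CLIP,
    EvidenceMap,
    InsertSizeModel,
    ReadTable,
    collect_evidence,
    estimate_insert_size,
    load_read_table,
)
from .features import DEFAULT_NEIGHBOR_WINDOW, encode_sites
from .simulate import SimResult
from .train import LabeledSiteSet, label_sites

#: density of random background (noise) sites added to the candidate set.
DEFAULT_BACKGROUND_PER_MB = 1000


@dataclass
class ExtractResult:
    """Candidate sites and their feature rows for one sample/region."""

    sites: np.ndarray          # (n,) 0-based, strictly increasing
    matrix: np.ndarray         # (n, 12) raw ternary features
    emap: EvidenceMap
    insert_model: InsertSizeModel


def extract_candidates(
    reads: ReadTable,
    region: tuple[int, int],
    insert_model: InsertSizeModel | None = None,
    min_clip: int = DEFAULT_MIN_CLIP,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
    background_per_mb: float = DEFAULT_BACKGROUND_PER_MB,
    rng: np.random.Generator | None = None,
) -> ExtractResult:
    """Collect evidence, pick candidate sites, and encode their features."""
    if insert_model is None:
        insert_model = estimate_insert_size(reads)
    emap = collect_evidence(reads, insert_model, region, min_clip=min_clip)
    clip_sites = emap.clip_sites()
    start, end = region
    n_bg = int(round(background_per_mb * (end - start) / 1e6))
    if n_bg > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        bg = rng.choice(end - start, size=min(n_bg, end - start), replace=False) + start
        sites = np.union1d(clip_sites, bg)
    else:
        sites = clip_sites
    matrix = encode_sites(emap, sites, neighbor_window=neighbor_window)
    return ExtractResult(sites=sites, matrix=matrix, emap=emap,
                         insert_model=insert_model)


def extract_from_sam(
    path: str,
    region: tuple[int, int],
    min_mapq: int = 20,
    insert_model: InsertSizeModel | None = None,
    **kwargs,
) -> ExtractResult:
    """Convenience: SAM/BAM file -> candidate feature rows."""
    table = load_read_table(path, min_mapq=min_mapq)
    return extract_candidates(table, region, insert_model=insert_model, **kwargs)


def labeled_set_from_sim(
    sim: SimResult,
    group: int = 0,
    label_tolerance: int = 5,
    min_mapq: int = 20,
    background_per_mb: float = DEFAULT_BACKGROUND_PER_MB,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledSiteSet, ExtractResult]:
    """Run extraction on one simulated dataset and attach truth labels."""
    table = sim.projected.read_table().filter_mapq(min_mapq)
    ex = extract_candidates(
        table, (0, sim.config.genome_len),
        background_per_mb=background_per_mb, rng=rng,
    )
    labels = label_sites(ex.sites, sim.truth_breakpoints, tolerance=label_tolerance)
    siteset = LabeledSiteSet(
        matrix=ex.matrix, sites=ex.sites, labels=labels,
        groups=np.full(ex.sites.shape[0], group, dtype=np.int64),
    )
    return siteset, ex
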