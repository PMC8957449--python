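"""Ternary per-site feature encoding, 10000-row batching, and normalization.

Each candidate genome site is described by twelve features taking values in
{-1, 0, 1}:

====  =========================================================
RMR   a reversely mapped read attaches evidence at the site
RMSM  a reversely mapped read with SM clip topology at the site
RMMS  a reversely mapped read with MS clip topology at the site
MSM   a mapped read with SM topology at the site
MMS   a mapped read with MS topology at the site
MDS   spanning pair distance below the insert-size band
MDE   spanning pair distance inside the insert-size band
MDL   spanning pair distance above the insert-size band
PSM   previous breakpoint-candidate site shows SM
PMS   previous breakpoint-candidate site shows MS
NSM   next breakpoint-candidate site shows SM
NMS   next breakpoint-candidate site shows MS
====  =========================================================

Presence is 1.  For RMSM/RMMS the negative status is -1 when the site has
reads but lacks the pattern; for MDS/MDE/MDL it is -1 when spanning pairs
exist but the distance class does not.  A site with no informative reads is
*uncertain* and every affected feature is 0; a site with no reads at all is
the all-zero vector.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import EvidenceMap, SiteEvidence

FEATURE_NAMES = (
    "RMR", "RMSM", "RMMS", "MSM", "MMS",
    "MDS", "MDE", "MDL", "PSM", "PMS", "NSM", "NMS",
)
N_FEATURES = 12
BATCH_ROWS = 10_000
#: previous/next candidate sites are linked only within this many bp.
DEFAULT_NEIGHBOR_WINDOW = 1000


def encode_site(
    ev: SiteEvidence,
    prev_ev: SiteEvidence | None = None,
    next_ev: SiteEvidence | None = None,
) -> np.ndarray:
    """Encode one site's evidence into the 12-feature ternary vector.

    ``prev_ev``/``next_ev`` are the nearest breakpoint-candidate sites before
    and after the target site (or None when none exists within the linking
    window).
    """
    v = np.zeros(N_FEATURES, dtype=np.int8)
    if ev.n_reads == 0:
        return v
    v[0] = 1 if ev.has_reverse else 0
    v[1] = 1 if ev.has_reverse_sm else -1
    v[2] = 1 if ev.has_reverse_ms else -1
    v[3] = 1 if ev.has_sm else 0
    v[4] = 1 if ev.has_ms else 0
    if ev.pair_dist_class:
        v[5] = 1 if "BELOW" in ev.pair_dist_class else -1
        v[6] = 1 if "EQUAL" in ev.pair_dist_class else -1
        v[7] = 1 if "ABOVE" in ev.pair_dist_class else -1
    if prev_ev is not None:
        v[8] = 1 if prev_ev.has_sm else 0
        v[9] = 1 if prev_ev.has_ms else 0
    if next_ev is not None:
        v[10] = 1 if next_ev.has_sm else 0
        v[11] = 1 if next_ev.has_ms else 0
    return v


def encode_sites(
    emap: EvidenceMap,
    sites: np.ndarray,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> np.ndarray:
    """Vectorized encoding of many sites against one evidence map.

    Equivalent to calling :func:`encode_site` per site with previous/next
    breakpoint-candidate sites resolved within ``neighbor_window`` bp.
    """
    sites = np.asarray(sites, dtype=np.int64)
    idx = sites - emap.start
    if idx.size and (idx.min() < 0 or idx.max() >= emap.end - emap.start):
        raise ValueError("site outside evidence-map region")
    n = sites.shape[0]
    M = np.zeros((n, N_FEATURES), dtype=np.int8)
    has_reads = emap.cov[idx] > 0
    M[:, 0] = np.where(emap.rev[idx], 1, 0)
    M[:, 1] = np.where(emap.rev_sm[idx], 1, -1)
    M[:, 2] = np.where(emap.rev_ms[idx], 1, -1)
    M[:, 3] = np.where(emap.sm[idx], 1, 0)
    M[:, 4] = np.where(emap.ms[idx], 1, 0)
    has_pairs = emap.pair_cov[idx] > 0
    M[:, 5] = np.where(emap.below[idx], 1, -1) * has_pairs
    M[:, 6] = np.where(emap.equal[idx], 1, -1) * has_pairs
    M[:, 7] = np.where(emap.above[idx], 1, -1) * has_pairs

    cand = emap.clip_sites()
    if cand.size:
        # nearest candidate strictly before / strictly after each site
        ip = np.searchsorted(cand, sites, side="left") - 1
        prev_ok = (ip >= 0) & (sites - cand[np.clip(ip, 0, None)] <= neighbor_window)
        prev_sites = cand[np.clip(ip, 0, None)] - emap.start
        M[:, 8] = np.where(prev_ok & emap.sm[prev_sites], 1, 0)
        M[:, 9] = np.where(prev_ok & emap.ms[prev_sites], 1, 0)
        inx = np.searchsorted(cand, sites, side="right")
        next_ok = (inx < cand.size) & (
            cand[np.clip(inx, None, cand.size - 1)] - sites <= neighbor_window
        )
        next_sites = cand[np.clip(inx, None, cand.size - 1)] - emap.start
        M[:, 10] = np.where(next_ok & emap.sm[next_sites], 1, 0)
        M[:, 11] = np.where(next_ok & emap.ms[next_sites], 1, 0)
    M[~has_reads] = 0
    return M


def resolve_neighbors(
    emap: EvidenceMap,
    site: int,
    neighbor_window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> tuple[SiteEvidence | None, SiteEvidence | None]:
    """Nearest breakpoint-candidate sites strictly before/after ``site``."""
    cand = emap.clip_sites()
    prev_ev = next_ev = None
    before = cand[cand < site]
    if before.size and site - before[-1] <= neighbor_window:
        prev_ev = emap.get(int(before[-1]))
    after = cand[cand > site]
    if after.size and after[0] - site <= neighbor_window:
        next_ev = emap.get(int(after[0]))
    return prev_ev, next_ev


@dataclass
class FeatureBatch:
    """Up to 10000 feature rows (zero-padded to exactly 10000).

    ``sites`` holds the coordinates of the ``n_real`` leading real rows;
    padded rows are flagged out of calling via ``real_mask``.
    """

    matrix: np.ndarray          # (BATCH_ROWS, 12)
    sites: np.ndarray           # (n_real,)
    real_mask: np.ndarray       # (BATCH_ROWS,) bool

    @property
    def n_real(self) -> int:
        return int(self.real_mask.sum())


def build_batches(matrix: np.ndarray, sites: np.ndarray) -> list[FeatureBatch]:
    """Chunk site-ordered feature rows into 10000-row batches."""
    matrix = np.asarray(matrix)
    sites = np.asarray(sites, dtype=np.int64)
    if matrix.shape[0] != sites.shape[0]:
        raise ValueError("matrix/sites length mismatch")
    if sites.size and np.any(np.diff(sites) <= 0):
        raise ValueError("sites must be strictly increasing")
    out: list[FeatureBatch] = []
    for lo in range(0, matrix.shape[0], BATCH_ROWS):
        chunk = matrix[lo:lo + BATCH_ROWS]
        n = chunk.shape[0]
        full = np.zeros((BATCH_ROWS, N_FEATURES), dtype=float)
        full[:n] = chunk
        mask = np.zeros(BATCH_ROWS, dtype=bool)
        mask[:n] = True
        out.append(FeatureBatch(matrix=full, sites=sites[lo:lo + BATCH_ROWS], real_mask=mask))
    return out


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column center and scale (z-score; constant columns get scale 1)."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive")


def fit_normalization(batches: "list[FeatureBatch] | np.ndarray") -> NormalizationStats:
    """Fit per-column mean/std over real (non-padded) rows only."""
    if isinstance(batches, np.ndarray):
        rows = batches
    else:
        parts = [b.matrix[b.real_mask] for b in batches]
        rows = np.concatenate(parts) if parts else np.empty((0, N_FEATURES))
    if rows.shape[0] == 0:
        raise ValueError("no real rows to fit normalization on")
    center = rows.mean(axis=0)
    std = rows.std(axis=0)
    scale = np.where(std < 1e-12, 1.0, std)
    return NormalizationStats(center=center, scale=scale)


def apply_normalization(batch: FeatureBatch, stats: NormalizationStats) -> FeatureBatch:
    """Normalize a batch column-wise; padded rows are reset to zero."""
    if batch.matrix.shape[1] != stats.center.shape[0]:
        raise ValueError("column-count mismatch between batch and stats")
    M = (batch.matrix - stats.center) / stats.scale
    M[~batch.real_mask] = 0.0
    return FeatureBatch(matrix=M, sites=batch.sites, real_mask=batch.real_mask.copy())


def normalize_matrix(matrix: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Normalize a plain (n, 12) matrix of real rows."""
    if matrix.shape[1] != stats.center.shape[0]:
        raise ValueError("column-count mismatch between matrix and stats")
    return (np.asarray(matrix, dtype=float) - stats.center) / stats.scale


# ---------------------------------------------------------------------------
# feature-table I/O (gzipped TSV; pos is written 1-based)

def write_features(
    path: str,
    chrom: str,
    sites: np.ndarray,
    matrix: np.ndarray,
    labels: np.ndarray | None = None,
) -> None:
    df = pd.DataFrame(matrix, columns=list(FEATURE_NAMES))
    df.insert(0, "pos", np.asarray(sites) + 1)
    df.insert(0, "chrom", chrom)
    if labels is not None:
        df["label"] = labels
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False)


def read_features(path: str) -> tuple[str, np.ndarray, np.ndarray, np.ndarray | None]:
    """Read a feature TSV; returns (chrom, 0-based sites, matrix, labels-or-None)."""
    df = pd.read_csv(path, sep="\t")
    chrom = str(df["chrom"].iloc[0]) if len(df) else "chr1"
    sites = df["pos"].to_numpy(dtype=np.int64) - 1
    matrix = df[list(FEATURE_NAMES)].to_numpy(dtype=np.int8)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return chrom, sites, matrix, labels
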