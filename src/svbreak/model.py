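"""Seven one-vs-rest breakpoint classifiers and the largest-score call rule.

Each of the seven SV categories gets its own binary CNN: five 5x5 stride-1
convolutional stages (ReLU, Gaussian-initialized) with 2x2 pooling after
stages 1, 2 and 4, then three fully connected layers ending in a single
sigmoid score in [0, 1].  A site is scored on a sliding window of
consecutive feature rows centered on it; the site is called as the type
whose classifier returns the largest score, provided that score reaches the
threshold, and is a non-breakpoint otherwise.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from enum import IntEnum
from pathlib import Path

import numpy as np

from . import nn
from .features import FeatureBatch, NormalizationStats, N_FEATURES


class SVType(IntEnum):
    """The seven SV categories (stable order used for argmax tie-breaking)."""

    NONE = 0
    INS = 1
    DEL = 2
    TRA = 3
    INV = 4
    IDUP = 5       # interspersed duplication
    INVDUP = 6     # inverted duplication
    TDUP = 7       # tandem duplication


SV_TYPES: tuple[SVType, ...] = tuple(t for t in SVType if t is not SVType.NONE)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of one binary classifier.

    The layer plan (5 conv + 3 FC, 5x5 kernels, stride 1, 2x2 pooling, ReLU)
    is fixed; channel widths, the classification window, and the init spread
    are tunable.  ``init_sd=None`` uses a He-scaled Gaussian
    (sd = sqrt(2/fan_in)), which keeps activations from collapsing through
    five layers; a fixed sd may be forced instead.
    """

    window: int = 16
    conv_channels: tuple[int, ...] = (8, 16, 16, 32, 32)
    fc_sizes: tuple[int, ...] = (64, 32)
    kernel: int = 5
    stride: int = 1
    pool: int = 2
    pool_after: tuple[int, ...] = (0, 1, 3)
    init_sd: float | None = None
    score_threshold: float = 0.5

    @property
    def conv_layers(self) -> int:
        return len(self.conv_channels)

    @property
    def fc_layers(self) -> int:
        return len(self.fc_sizes) + 1

    def __post_init__(self) -> None:
        if self.conv_layers != 5 or self.fc_layers != 3:
            raise ValueError("architecture is fixed at 5 conv + 3 FC layers")
        if self.kernel != 5 or self.stride != 1 or self.pool != 2:
            raise ValueError("kernel 5x5, stride 1 and 2x2 pooling are fixed")
        min_window = self.pool ** len(self.pool_after)
        if self.window < max(min_window, self.kernel):
            raise ValueError(
                f"window {self.window} too small for the kernel/pool cascade; "
                f"minimal window is {max(min_window, self.kernel)}"
            )
        if not (0.0 < self.score_threshold < 1.0):
            raise ValueError("score_threshold must be in (0, 1)")


@dataclass(frozen=True)
class ScoreVector:
    """The seven per-type classifier scores for one site."""

    site: int
    scores: np.ndarray     # shape (7,), each in [0, 1]; index i -> SVType(i+1)


@dataclass(frozen=True)
class SVCall:
    """A typed breakpoint call (``pos`` is 1-based, user-facing)."""

    chrom: str
    pos: int
    svtype: SVType
    score: float


def build_model(config: ModelConfig, seed: int) -> nn.Network:
    """Construct one untrained binary classifier; same seed => same weights."""
    rng = np.random.default_rng(seed)
    layers: list = []
    cin = 2      # feature plane + center-row indicator plane
    h, w = config.window, N_FEATURES
    for i, cout in enumerate(config.conv_channels):
        layers.append(nn.Conv2D(cin, cout, config.kernel, rng, init_sd=config.init_sd))
        layers.append(nn.ReLU())
        if i in config.pool_after and (h >= 2 or w >= 2):
            layers.append(nn.MaxPool2())
            h = h // 2 if h >= 2 else h
            w = w // 2 if w >= 2 else w
        cin = cout
    layers.append(nn.Flatten())
    din = cin * h * w
    for dout in config.fc_sizes:
        layers.append(nn.Dense(din, dout, rng, init_sd=config.init_sd))
        layers.append(nn.ReLU())
        din = dout
    layers.append(nn.Dense(din, 1, rng, init_sd=config.init_sd))
    net = nn.Network(layers)
    net.stats_fingerprint = None
    return net


def build_windows(
    matrix: np.ndarray,
    window: int,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Sliding windows of consecutive rows centered on each row.

    Edge windows are clamped and zero-filled.  ``groups`` (e.g. a per-row
    genome id) prevents windows from crossing group boundaries.

    The result has two channels: the feature rows themselves, and a
    center-row indicator plane.  Pooling makes the convolutional stack
    partly translation-invariant, so without an explicit positional cue the
    classifier cannot distinguish "the breakpoint pattern is at the target
    row" from "it is a few rows away"; the indicator plane restores that
    distinction.

    Returns an array of shape (n, 2, window, n_features).
    """
    matrix = np.asarray(matrix, dtype=float)
    n, f = matrix.shape
    if groups is None:
        groups = np.zeros(n, dtype=np.int64)
    half = window // 2
    out = np.zeros((n, 2, window, f))
    out[:, 1, half, :] = 1.0
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        sub = matrix[idx]
        padded = np.pad(sub, ((half, window - half - 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(padded, window, axis=0)
        # win: (len(idx), f, window) -> (len(idx), window, f)
        out[idx, 0] = win.transpose(0, 2, 1)
    return out


def score_matrix(
    models: "dict[SVType, nn.Network] | list[nn.Network]",
    windows: np.ndarray,
) -> np.ndarray:
    """Score pre-built windows with all seven classifiers -> (n, 7)."""
    if isinstance(models, dict):
        ordered = [models[t] for t in SV_TYPES]
    else:
        ordered = list(models)
    if len(ordered) != len(SV_TYPES):
        raise ValueError("expected one classifier per SV type")
    fps = {getattr(m, "stats_fingerprint", None) for m in ordered}
    if len(fps) > 1:
        raise ValueError("classifiers were trained with different normalization stats")
    return np.stack([m.predict_scores(windows) for m in ordered], axis=1)


def score_sites(
    models: "dict[SVType, nn.Network] | list[nn.Network]",
    batch: FeatureBatch,
    window: int = 32,
) -> list[ScoreVector]:
    """Score every real (non-padded) row of a normalized batch."""
    real = batch.matrix[batch.real_mask]
    if real.shape[0] == 0:
        return []
    wins = build_windows(real, window)
    scores = score_matrix(models, wins)
    return [
        ScoreVector(site=int(s), scores=scores[i])
        for i, s in enumerate(batch.sites)
    ]


def call_breakpoints(
    scorevecs: list[ScoreVector],
    threshold: float = 0.5,
    chrom: str = "chr1",
) -> list[SVCall]:
    """Largest-score decision rule.

    For each site: if the maximum of the seven scores reaches ``threshold``
    the site is called as the argmax type (ties break to the lowest type
    index); otherwise the site is not a breakpoint.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    calls: list[SVCall] = []
    for sv in scorevecs:
        best = int(np.argmax(sv.scores))       # first max -> lowest type index
        score = float(sv.scores[best])
        if score >= threshold:
            calls.append(SVCall(chrom=chrom, pos=sv.site + 1,
                                svtype=SVType(best + 1), score=score))
    return calls


# ---------------------------------------------------------------------------
# model bundle on disk

@dataclass
class ModelBundle:
    """Seven trained classifiers + normalization stats + provenance manifest."""

    models: dict
    config: ModelConfig
    stats: NormalizationStats
    manifest: dict = field(default_factory=dict)

    def predict_scores(self, matrix: np.ndarray, groups: np.ndarray | None = None,
                       normalized: bool = False) -> np.ndarray:
        """(n, 12) raw feature rows -> (n, 7) per-type scores."""
        from .features import normalize_matrix

        M = matrix if normalized else normalize_matrix(matrix, self.stats)
        wins = build_windows(M, self.config.window, groups=groups)
        return score_matrix(self.models, wins)

    def call(self, sites: np.ndarray, matrix: np.ndarray,
             groups: np.ndarray | None = None, threshold: float | None = None,
             chrom: str = "chr1") -> list[SVCall]:
        scores = self.predict_scores(matrix, groups=groups)
        thr = self.config.score_threshold if threshold is None else threshold
        vecs = [ScoreVector(site=int(s), scores=scores[i])
                for i, s in enumerate(sites)]
        return call_breakpoints(vecs, threshold=thr, chrom=chrom)

    def save(self, out_dir: str) -> None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for t in SV_TYPES:
            weights = self.models[t].get_weights()
            np.savez(d / f"classifier_{t.name}.npz",
                     **{f"p{i}": w for i, w in enumerate(weights)})
        cfg = asdict(self.config)
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        (d / "stats.json").write_text(json.dumps(
            {"center": self.stats.center.tolist(),
             "scale": self.stats.scale.tolist()}, indent=2))
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str) -> "ModelBundle":
        d = Path(in_dir)
        cfg_raw = json.loads((d / "config.json").read_text())
        for key in ("conv_channels", "fc_sizes", "pool_after"):
            cfg_raw[key] = tuple(cfg_raw[key])
        config = ModelConfig(**cfg_raw)
        st = json.loads((d / "stats.json").read_text())
        stats = NormalizationStats(center=np.array(st["center"]),
                                   scale=np.array(st["scale"]))
        manifest = json.loads((d / "manifest.json").read_text())
        fingerprint = stats_fingerprint(stats)
        models = {}
        for t in SV_TYPES:
            net = build_model(config, seed=0)
            data = np.load(d / f"classifier_{t.name}.npz")
            net.set_weights([data[f"p{i}"] for i in range(len(data.files))])
            net.stats_fingerprint = fingerprint
            models[t] = net
        return cls(models=models, config=config, stats=stats, manifest=manifest)


def stats_fingerprint(stats: NormalizationStats) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(stats.center).tobytes())
    h.update(np.ascontiguousarray(stats.scale).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# call writers

def write_calls_bed(calls: list[SVCall], path: str) -> None:
    """BED (0-based half-open): chrom, start, end, svtype, score."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos - 1}\t{c.pos}\t{c.svtype.name}\t{c.score:.4f}\n")


def write_calls_vcf(calls: list[SVCall], path: str, contig: str = "chr1",
                    contig_len: int | None = None) -> None:
    """Minimal VCF 4.2 with single-breakend records and SVTYPE in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svbreak\n")
        if contig_len is not None:
            fh.write(f"##contig=<ID={contig},length={contig_len}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                 'Description="Structural variant type">\n')
        fh.write('##INFO=<ID=SCORE,Number=1,Type=Float,'
                 'Description="Winning classifier score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            fh.write(
                f"{c.chrom}\t{c.pos}\tbp{i}\tN\t<{c.svtype.name}>\t.\tPASS\t"
                f"SVTYPE={c.svtype.name};SCORE={c.score:.4f}\n"
            )


def read_calls_bed(path: str) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, _e, name, score = line.rstrip("\n").split("\t")[:5]
            calls.append(SVCall(chrom=chrom, pos=int(s) + 1,
                                svtype=SVType[name], score=float(score)))
    return calls


def read_calls_vcf(path: str) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
            calls.append(SVCall(chrom=fields[0], pos=int(fields[1]),
                                svtype=SVType[info["SVTYPE"]],
                                score=float(info.get("SCORE", 0.0))))
    return calls
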