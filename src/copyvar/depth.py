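"""Binned read-depth tracks on a reference genome.

Depth can come from direct read mapping (per-base or pre-binned TSV) or be
projected from contigs through filtered contig-to-reference alignment blocks.
Either way the downstream caller consumes a :class:`BinDepthTrack` whose
per-bin ``CN_index`` (bin depth / chromosome mean depth) is the copy-number
proxy.

Coordinates are 0-based half-open everywhere internally; 1-based closed
coordinates appear only at the ``show-coords`` / GFF3 parsing boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "BinDepthTrack",
    "AlignmentBlock",
    "bin_depth",
    "gc_correct",
    "filter_alignment_blocks",
    "project_contig_depth",
    "compute_cn_index",
    "read_depth_tsv",
    "read_coords",
    "read_paf",
]

DEFAULT_BIN_SIZE = 250


@dataclass
class BinDepthTrack:
    """Per-chromosome binned depth with its chromosome-mean normalisation.

    ``depths[i]`` is the mean per-base depth over bin ``i`` (bins are
    non-overlapping windows of ``bin_size``; a trailing partial bin is
    averaged over its actual length). ``cn_index`` is populated by
    :func:`compute_cn_index`.
    """

    chrom: str
    bin_size: int
    depths: np.ndarray
    chrom_length: int | None = None
    cn_index: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if (self.depths < 0).any():
            raise ValueError("bin depths must be non-negative")
        if self.chrom_length is None:
            self.chrom_length = len(self.depths) * self.bin_size
        n_expected = math.ceil(self.chrom_length / self.bin_size) if self.chrom_length else 0
        if len(self.depths) != n_expected:
            raise ValueError(
                f"{self.chrom}: {len(self.depths)} bins but chrom_length "
                f"{self.chrom_length} implies {n_expected}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.depths)

    @property
    def chrom_mean_depth(self) -> float:
        """Mean depth over all bins (``Average_depth_Chr``)."""
        return float(self.depths.mean()) if self.n_bins else 0.0

    def bin_bounds(self, i: int) -> tuple[int, int]:
        return i * self.bin_size, min((i + 1) * self.bin_size, self.chrom_length)

    def per_base(self) -> np.ndarray:
        """Expand to a per-base depth vector (bin value repeated)."""
        out = np.repeat(self.depths, self.bin_size)[: self.chrom_length]
        return out


@dataclass(frozen=True)
class AlignmentBlock:
    """One contig-to-reference alignment block (both intervals half-open)."""

    contig: str
    contig_start: int
    contig_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    identity: float = 1.0

    def __post_init__(self) -> None:
        if self.contig_end <= self.contig_start or self.ref_end <= self.ref_start:
            raise ValueError("alignment block intervals must have end > start")

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def contig_length(self) -> int:
        return self.contig_end - self.contig_start


def bin_depth(
    per_base_depth: np.ndarray,
    bin_size: int = DEFAULT_BIN_SIZE,
    chrom: str = "chr1",
) -> BinDepthTrack:
    """Bin a per-base depth vector into non-overlapping windows.

    Each bin's depth is the mean per-base depth over the window; the trailing
    partial window is averaged over its actual length.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    per_base_depth = np.asarray(per_base_depth, dtype=float)
    n = len(per_base_depth)
    if n == 0:
        return BinDepthTrack(chrom, bin_size, np.empty(0), chrom_length=0)
    n_bins = math.ceil(n / bin_size)
    sums = np.add.reduceat(per_base_depth, np.arange(0, n, bin_size))
    lengths = np.full(n_bins, bin_size, dtype=float)
    if n % bin_size:
        lengths[-1] = n % bin_size
    return BinDepthTrack(chrom, bin_size, sums / lengths, chrom_length=n)


def gc_correct(
    track: BinDepthTrack,
    gc_fraction: np.ndarray,
    min_stratum_size: int = 20,
) -> BinDepthTrack:
    """Median-ratio GC correction, one stratum per 1% GC.

    corrected = depth x global_median / stratum_median, computed over bins
    sharing the same rounded GC percentage. Strata with fewer than
    ``min_stratum_size`` bins (or zero median) are left uncorrected.
    """
    gc = np.asarray(gc_fraction, dtype=float)
    if len(gc) != track.n_bins:
        raise ValueError("gc_fraction length must equal the number of bins")
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc fractions must lie in [0, 1]")
    if track.n_bins == 0 or not track.depths.any():
        return track
    global_median = float(np.median(track.depths))
    strata = np.rint(gc * 100).astype(int)
    corrected = track.depths.copy()
    for s in np.unique(strata):
        mask = strata == s
        if mask.sum() < min_stratum_size:
            continue
        m = float(np.median(track.depths[mask]))
        if m > 0:
            corrected[mask] = track.depths[mask] * (global_median / m)
    return replace(track, depths=corrected, cn_index=None)


def _contained(inner: AlignmentBlock, outer: AlignmentBlock) -> bool:
    return inner.ref_start >= outer.ref_start and inner.ref_end <= outer.ref_end


def filter_alignment_blocks(
    blocks: list[AlignmentBlock],
    contained_rate: float = 0.8,
    keep_both_overlap_rate: float = 0.7,
    drop_short_rate: float = 0.2,
) -> list[AlignmentBlock]:
    """Resolve redundant alignment blocks on the reference.

    A block fully contained (reference coordinates) in another is dropped
    when its length rate (short/long) is below ``contained_rate``. For two
    partially overlapping blocks, both are kept when overlap/longer is at
    least ``keep_both_overlap_rate``; otherwise the shorter one is dropped
    when short/long is below ``drop_short_rate``. Applied as a left-to-right
    sweep per reference chromosome, so chains of overlaps resolve
    deterministically. Idempotent.
    """
    out: list[AlignmentBlock] = []
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    for chrom in sorted(by_chrom):
        chrom_blocks = sorted(
            by_chrom[chrom], key=lambda b: (b.ref_start, -b.ref_length)
        )
        kept: list[AlignmentBlock] = []
        for b in chrom_blocks:
            drop_b = False
            survivors: list[AlignmentBlock] = []
            for k in kept:
                if drop_b or k.ref_end <= b.ref_start or b.ref_end <= k.ref_start:
                    survivors.append(k)
                    continue
                short, long_ = sorted((k, b), key=lambda x: x.ref_length)
                rate = short.ref_length / long_.ref_length
                if _contained(b, k) or _contained(k, b):
                    if rate < contained_rate:
                        if short is b:
                            drop_b = True
                            survivors.append(k)
                        # short is k: drop k (omit from survivors)
                        else:
                            continue
                    else:
                        survivors.append(k)
                else:
                    overlap = min(k.ref_end, b.ref_end) - max(k.ref_start, b.ref_start)
                    if overlap / long_.ref_length >= keep_both_overlap_rate:
                        survivors.append(k)
                    elif rate < drop_short_rate:
                        if short is b:
                            drop_b = True
                            survivors.append(k)
                        else:
                            continue
                    else:
                        survivors.append(k)
            kept = survivors
            if not drop_b:
                kept.append(b)
        out.extend(sorted(kept, key=lambda b: b.ref_start))
    return out


def project_contig_depth(
    contig_tracks: dict[str, BinDepthTrack],
    blocks: list[AlignmentBlock],
    reference_layout: dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> dict[str, BinDepthTrack]:
    """Project contig depth onto the reference through alignment blocks.

    A contig base aligned to ``k`` reference regions contributes ``1/k`` of
    its depth to each; a reference base accumulates contributions from every
    contig aligned over it. Bases of the reference with no aligned contig get
    depth 0. ``reference_layout`` maps reference chromosome -> length (bp).
    """
    for b in blocks:
        if b.contig not in contig_tracks:
            raise KeyError(f"alignment block references unknown contig {b.contig!r}")

    # Per-contig-base alignment multiplicity k.
    multiplicity: dict[str, np.ndarray] = {}
    for name, track in contig_tracks.items():
        multiplicity[name] = np.zeros(track.chrom_length, dtype=float)
    for b in blocks:
        multiplicity[b.contig][b.contig_start : b.contig_end] += 1

    ref_acc = {
        chrom: np.zeros(length, dtype=float) for chrom, length in reference_layout.items()
    }
    for b in blocks:
        if b.ref_chrom not in ref_acc:
            raise KeyError(f"alignment block references unknown chromosome {b.ref_chrom!r}")
        ctrack = contig_tracks[b.contig]
        cdepth = ctrack.per_base()[b.contig_start : b.contig_end]
        k = multiplicity[b.contig][b.contig_start : b.contig_end]
        contrib = np.where(k > 0, cdepth / np.maximum(k, 1), 0.0)
        # Linear map of contig positions onto the reference interval.
        scale = b.ref_length / b.contig_length
        target = b.ref_start + np.floor(np.arange(b.contig_length) * scale).astype(int)
        np.add.at(ref_acc[b.ref_chrom], np.minimum(target, b.ref_end - 1), contrib)
    return {
        chrom: bin_depth(acc, bin_size=bin_size, chrom=chrom)
        for chrom, acc in ref_acc.items()
    }


def compute_cn_index(track: BinDepthTrack) -> BinDepthTrack:
    """Populate per-bin CN_index = bin depth / chromosome mean depth."""
    mean = track.chrom_mean_depth
    if mean <= 0:
        raise ValueError(
            f"{track.chrom}: chromosome mean depth is 0, CN_index undefined"
        )
    return replace(track, cn_index=track.depths / mean)


# ---------------------------------------------------------------------------
# Parsers


def read_depth_tsv(
    path, bin_size: int = DEFAULT_BIN_SIZE, binned: bool | None = None
) -> dict[str, BinDepthTrack]:
    """Read a depth TSV into tracks.

    Accepts per-base input (chrom, pos, depth; 0-based positions, absent
    positions depth 0) or pre-binned input (chrom, bin_start, depth with
    bin_start a multiple of ``bin_size``). When ``binned`` is None the
    format is taken from a ``bin_start`` header if present, else inferred:
    positions that are all multiples of ``bin_size`` are bin starts.
    Header lines are tolerated either way.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    header_pos_name = str(df.iloc[0, 1]).strip().lower() if len(df) else ""
    df = df[pd.to_numeric(df[1], errors="coerce").notna()]
    df.columns = ["chrom", "pos", "depth"][: len(df.columns)]
    df["pos"] = df["pos"].astype(int)
    df["depth"] = df["depth"].astype(float)
    if binned is None:
        if header_pos_name in ("bin_start", "pos", "position"):
            binned = header_pos_name == "bin_start"
        else:
            pos = df["pos"].to_numpy()
            binned = len(pos) > 1 and bool(np.all(pos % bin_size == 0))
    tracks = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        if binned:
            n_bins = int(sub["pos"].max()) // bin_size + 1
            depths = np.zeros(n_bins)
            depths[sub["pos"].to_numpy() // bin_size] = sub["depth"].to_numpy()
            tracks[str(chrom)] = BinDepthTrack(str(chrom), bin_size, depths)
        else:
            length = int(sub["pos"].max()) + 1
            per_base = np.zeros(length)
            per_base[sub["pos"].to_numpy()] = sub["depth"].to_numpy()
            tracks[str(chrom)] = bin_depth(per_base, bin_size=bin_size, chrom=str(chrom))
    return tracks


def read_coords(path) -> list[AlignmentBlock]:
    """Read nucmer ``show-coords -T``-style TSV into alignment blocks.

    Expected columns: S1 E1 S2 E2 LEN1 LEN2 %IDY REF CONTIG (1-based,
    closed, reference first). Header/separator lines are tolerated.
    """
    blocks = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            try:
                s1, e1, s2, e2 = (int(p) for p in parts[:4])
                idy = float(parts[6])
            except ValueError:
                continue
            blocks.append(
                AlignmentBlock(
                    contig=parts[8],
                    contig_start=min(s2, e2) - 1,
                    contig_end=max(s2, e2),
                    ref_chrom=parts[7],
                    ref_start=min(s1, e1) - 1,
                    ref_end=max(s1, e1),
                    identity=idy / 100.0,
                )
            )
    return blocks


def read_paf(path) -> list[AlignmentBlock]:
    """Read a PAF file into alignment blocks (query = contig, 0-based)."""
    blocks = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12 or not parts[2].isdigit():
                continue
            matches, aln_len = int(parts[9]), int(parts[10])
            blocks.append(
                AlignmentBlock(
                    contig=parts[0],
                    contig_start=int(parts[2]),
                    contig_end=int(parts[3]),
                    ref_chrom=parts[5],
                    ref_start=int(parts[7]),
                    ref_end=int(parts[8]),
                    identity=matches / aln_len if aln_len else 0.0,
                )
            )
    return blocks
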