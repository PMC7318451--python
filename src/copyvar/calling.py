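"""Read-depth CNV calling from a CN_index track.

Bins with CN_index below ``del_threshold`` (default 0.5) or at/above
``dup_threshold`` (default 1.5) seed deletion and duplication candidates;
adjacent same-type bins are linked, intervals are greedily extended while
their mean CN_index stays beyond a relaxed boundary threshold, nearby
same-type intervals are merged, and calls shorter than ``min_length``
(default 1000 bp) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depth import BinDepthTrack

__all__ = [
    "CandidateInterval",
    "CNVCall",
    "call_candidate_intervals",
    "extend_and_finalize",
    "call_cnvs",
    "calls_to_frame",
    "write_calls",
    "read_calls",
]

DEL = "DEL"
DUP = "DUP"


@dataclass(frozen=True)
class CandidateInterval:
    """A maximal run of same-type candidate bins (bin indices, half-open)."""

    chrom: str
    bin_start: int
    bin_end: int
    svtype: str
    mean_cn_index: float

    @property
    def n_bins(self) -> int:
        return self.bin_end - self.bin_start


@dataclass(frozen=True)
class CNVCall:
    """A finalized CNV interval on the reference (bp coordinates, half-open).

    ``cn`` is the integer copy-number estimate (half-up rounding of the mean
    CN_index); ``mean_cn_index`` keeps the raw depth ratio, which for
    deletions is the reported copy-number estimate.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    cn: int
    mean_cn_index: float
    n_bins: int
    source: str = "rd_caller"
    accession: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def call_candidate_intervals(
    track: BinDepthTrack,
    del_threshold: float = 0.5,
    dup_threshold: float = 1.5,
) -> list[CandidateInterval]:
    """Link adjacent same-type candidate bins into intervals.

    A bin is a DEL candidate when CN_index < ``del_threshold`` and a DUP
    candidate when CN_index >= ``dup_threshold`` (closed on the left).
    Single-bin runs are allowed at this stage.
    """
    if track.cn_index is None:
        raise ValueError("CN_index not populated; run compute_cn_index first")
    cn = track.cn_index
    labels = np.where(cn < del_threshold, 1, np.where(cn >= dup_threshold, 2, 0))
    out: list[CandidateInterval] = []
    i = 0
    while i < len(labels):
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append(
            CandidateInterval(
                chrom=track.chrom,
                bin_start=i,
                bin_end=j,
                svtype=DEL if labels[i] == 1 else DUP,
                mean_cn_index=float(cn[i:j].mean()),
            )
        )
        i = j
    return out


def extend_and_finalize(
    candidates: list[CandidateInterval],
    track: BinDepthTrack,
    min_length: int = 1000,
    del_threshold: float = 0.5,
    dup_threshold: float = 1.5,
    del_extend_threshold: float = 0.75,
    dup_extend_threshold: float = 1.25,
    source: str = "rd_caller",
) -> list[CNVCall]:
    """Extend candidate intervals, merge near neighbours, apply length cutoff.

    Extension is greedy and symmetric: a flanking bin is absorbed while its
    own CN_index stays below ``del_extend_threshold`` (deletions) or
    at/above ``dup_extend_threshold`` (duplications) — halfway back toward
    normal copy; each side stops at its first rejection. An interval-mean
    criterion would run away (a run of near-zero bins tolerates up to three
    times its width in normal flanking bins before the mean recovers), so
    the acceptance test is per bin. Extension never crosses a bin that
    seeded an opposite-type candidate.
    Two same-type intervals separated by at most one bin are merged when the
    merged mean still passes the *candidate* threshold. Calls shorter than
    ``min_length`` bp are dropped.
    """
    cn = track.cn_index
    if cn is None:
        raise ValueError("CN_index not populated; run compute_cn_index first")
    n = len(cn)

    claimed = np.zeros(n, dtype=int)  # 1 = DEL candidate bin, 2 = DUP
    for c in candidates:
        claimed[c.bin_start : c.bin_end] = 1 if c.svtype == DEL else 2

    def passes_ext(mean: float, svtype: str) -> bool:
        return mean < del_extend_threshold if svtype == DEL else mean >= dup_extend_threshold

    def passes_call(mean: float, svtype: str) -> bool:
        return mean < del_threshold if svtype == DEL else mean >= dup_threshold

    extended: list[tuple[int, int, str]] = []
    for c in candidates:
        lo, hi = c.bin_start, c.bin_end
        other = 2 if c.svtype == DEL else 1
        while lo > 0 and claimed[lo - 1] != other:
            if passes_ext(float(cn[lo - 1]), c.svtype):
                lo -= 1
            else:
                break
        while hi < n and claimed[hi] != other:
            if passes_ext(float(cn[hi]), c.svtype):
                hi += 1
            else:
                break
        extended.append((lo, hi, c.svtype))

    # Merge same-type intervals that overlap or sit <= 1 bin apart.
    merged: list[tuple[int, int, str]] = []
    for lo, hi, svtype in sorted(extended, key=lambda t: (t[2], t[0])):
        if merged and merged[-1][2] == svtype:
            plo, phi, _ = merged[-1]
            gap = lo - phi
            if gap < 0 or (
                gap <= 1 and passes_call(float(cn[plo:hi].mean()), svtype)
            ):
                merged[-1] = (plo, max(phi, hi), svtype)
                continue
        merged.append((lo, hi, svtype))

    calls: list[CNVCall] = []
    for lo, hi, svtype in merged:
        start = lo * track.bin_size
        end = min(hi * track.bin_size, track.chrom_length)
        if end - start < min_length:
            continue
        mean = float(cn[lo:hi].mean())
        calls.append(
            CNVCall(
                chrom=track.chrom,
                start=start,
                end=end,
                svtype=svtype,
                cn=_round_half_up(mean),
                mean_cn_index=mean,
                n_bins=hi - lo,
                source=source,
            )
        )
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.svtype))


def call_cnvs(track: BinDepthTrack, **kwargs) -> list[CNVCall]:
    """Candidate linking + extension + finalisation in one step."""
    cand_kwargs = {
        k: kwargs[k] for k in ("del_threshold", "dup_threshold") if k in kwargs
    }
    candidates = call_candidate_intervals(track, **cand_kwargs)
    return extend_and_finalize(candidates, track, **kwargs)


# ---------------------------------------------------------------------------
# Call table I/O (BED-like TSV)

_COLUMNS = ["chrom", "start", "end", "svtype", "cn", "mean_cn_index", "n_bins", "source"]


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    rows = [
        (c.chrom, c.start, c.end, c.svtype, c.cn, c.mean_cn_index, c.n_bins, c.source)
        for c in calls
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_calls(calls: list[CNVCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path) -> list[CNVCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CNVCall(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            svtype=str(r.svtype),
            cn=int(r.cn),
            mean_cn_index=float(r.mean_cn_index),
            n_bins=int(r.n_bins),
            source=str(r.source),
        )
        for r in df.itertuples()
    ]
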