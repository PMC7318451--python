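"""CNV call filtering, merging/integration, and accuracy scoring.

Three filter profiles mirror the evidence requirements of the three callers
feeding the pipeline: ``rd`` (read-depth calls), ``pe_sr_del`` (paired-end /
split-read deletion calls), and ``ctgref`` (contig-projection calls, with
stricter removal band and alignment-coverage requirements). Filtered calls
are merged within an accession and integrated across accessions into a core
CNV set; the weighted-accuracy statistic scores a called copy-number matrix
against a validation matrix with partial credit for duplications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import DEL, DUP, CNVCall
from .depth import BinDepthTrack

__all__ = [
    "CNVEvidence",
    "AccuracyTally",
    "FilterThresholds",
    "filter_calls",
    "merge_and_integrate",
    "weighted_accuracy",
    "evidence_from_track",
    "read_evidence_table",
    "breakpoint_support",
]

PROFILES = ("rd", "pe_sr_del", "ctgref")


@dataclass(frozen=True)
class CNVEvidence:
    """Read-level and coverage evidence attached to one CNV call.

    Split-read counts are taken within +/-500 bp of each breakpoint;
    discordant pairs require an insert size close to the interval length.
    Coverage fractions are over the CNV's bases: ``coverage`` (depth >= 1),
    ``dp10_cvrg`` (depth >= 10), ``dup_cvrg`` (CN_index >= 1.4) and
    ``algn_cvrg`` (covered by contig-reference alignment blocks).
    """

    split_reads_bp1: int = 0
    split_reads_bp2: int = 0
    discordant_pairs: int = 0
    coverage: float = 0.0
    dp10_cvrg: float = 0.0
    dup_cvrg: float = 0.0
    algn_cvrg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("coverage", "dp10_cvrg", "dup_cvrg", "algn_cvrg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.split_reads_bp1, self.split_reads_bp2, self.discordant_pairs) < 0:
            raise ValueError("evidence counts must be non-negative")

    @property
    def breakpoint_support(self) -> int:
        """Pooled split-read + discordant-pair support over both breakpoints."""
        return self.split_reads_bp1 + self.split_reads_bp2 + self.discordant_pairs


@dataclass(frozen=True)
class FilterThresholds:
    """Tunable cutoffs for :func:`filter_calls` (defaults per profile)."""

    min_support: int = 5
    del_max_coverage: float = 0.5
    del_max_dp10: float = 0.5
    dup_min_coverage: float = 0.8
    dup_min_dp10: float = 0.8
    dup_min_dup_cvrg: float = 0.5
    rd_remove_band: tuple[float, float] = (0.8, 1.4)
    ctgref_remove_band: tuple[float, float] = (0.4, 1.7)
    pe_sr_del_max_cn: float = 0.5
    ctgref_del_max_algn: float = 0.5
    ctgref_dup_min_algn: float = 0.9


def filter_calls(
    calls: list[CNVCall],
    evidence: dict[int, CNVEvidence] | list[CNVEvidence],
    profile: str,
    thresholds: FilterThresholds | None = None,
) -> list[CNVCall]:
    """Apply a caller-specific filter profile to CNV calls.

    ``evidence`` is indexed parallel to ``calls``. Profiles:

    rd
        Calls with a copy-number estimate inside the (0.8, 1.4) band are
        removed. A deletion passes with pooled breakpoint support >= 5 AND
        coverage <= 0.5 AND dp10_cvrg <= 0.5; a duplication with
        coverage >= 0.8 AND dp10_cvrg >= 0.8 AND dup_cvrg >= 0.5.
    pe_sr_del
        Deletions only (a duplication is a usage error): copy-number
        estimate < 0.5 plus the same deletion conditions as ``rd``.
    ctgref
        As ``rd`` but the removal band widens to (0.4, 1.7) and alignment
        coverage is additionally required: < 0.5 for deletions, >= 0.9 for
        duplications.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    t = thresholds or FilterThresholds()
    ev = list(evidence.values()) if isinstance(evidence, dict) else list(evidence)
    if len(ev) != len(calls):
        raise ValueError("one evidence record per call is required")

    kept = []
    for call, e in zip(calls, ev):
        cn_est = call.mean_cn_index
        if profile == "pe_sr_del":
            if call.svtype == DUP:
                raise ValueError("profile handles deletions only")
            if cn_est >= t.pe_sr_del_max_cn:
                continue
        else:
            lo, hi = t.rd_remove_band if profile == "rd" else t.ctgref_remove_band
            if lo < cn_est < hi:
                continue
        if call.svtype == DEL:
            ok = (
                e.breakpoint_support >= t.min_support
                and e.coverage <= t.del_max_coverage
                and e.dp10_cvrg <= t.del_max_dp10
            )
            if ok and profile == "ctgref":
                ok = e.algn_cvrg < t.ctgref_del_max_algn
        else:
            ok = (
                e.coverage >= t.dup_min_coverage
                and e.dp10_cvrg >= t.dup_min_dp10
                and e.dup_cvrg >= t.dup_min_dup_cvrg
            )
            if ok and profile == "ctgref":
                ok = e.algn_cvrg >= t.ctgref_dup_min_algn
        if ok:
            kept.append(call)
    return kept


def _reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return ov / max(a.length, b.length)


def _same_sv(a: CNVCall, b: CNVCall, min_reciprocal_overlap: float) -> bool:
    return (
        a.chrom == b.chrom
        and a.svtype == b.svtype
        and _reciprocal_overlap(a, b) >= min_reciprocal_overlap
    )


def _sweep_merge(
    calls: list[CNVCall], min_reciprocal_overlap: float
) -> list[tuple[CNVCall, list[CNVCall]]]:
    """Collapse same-SV calls; returns (union record, members) per cluster."""
    ordered = sorted(
        calls, key=lambda c: (c.chrom, c.svtype, c.start, c.end, c.source)
    )
    clusters: list[tuple[CNVCall, list[CNVCall]]] = []
    for c in ordered:
        merged = False
        if clusters:
            rep, members = clusters[-1]
            if _same_sv(rep, c, min_reciprocal_overlap):
                union = CNVCall(
                    chrom=rep.chrom,
                    start=min(rep.start, c.start),
                    end=max(rep.end, c.end),
                    svtype=rep.svtype,
                    cn=rep.cn,
                    mean_cn_index=rep.mean_cn_index,
                    n_bins=rep.n_bins,
                    source=",".join(
                        sorted(set(rep.source.split(",")) | set(c.source.split(",")))
                    ),
                    accession=rep.accession,
                )
                clusters[-1] = (union, members + [c])
                merged = True
        if not merged:
            clusters.append((c, [c]))
    return clusters


def merge_and_integrate(
    calls_by_accession: dict[str, list[CNVCall]],
    min_reciprocal_overlap: float = 0.5,
) -> tuple[dict[str, list[CNVCall]], pd.DataFrame]:
    """Merge calls within each accession, then integrate into a core CNV set.

    Within an accession, same-type calls with reciprocal overlap at or above
    ``min_reciprocal_overlap`` collapse to one record spanning their union
    and listing all contributing sources. Across accessions the merged
    records collapse again under the same criterion into core CNVs; the
    returned frame has one row per core CNV with a 0/1 presence column per
    accession. Output is independent of input ordering.
    """
    per_accession: dict[str, list[CNVCall]] = {}
    for acc in sorted(calls_by_accession):
        clusters = _sweep_merge(calls_by_accession[acc], min_reciprocal_overlap)
        per_accession[acc] = [
            CNVCall(
                chrom=rep.chrom,
                start=rep.start,
                end=rep.end,
                svtype=rep.svtype,
                cn=rep.cn,
                mean_cn_index=rep.mean_cn_index,
                n_bins=rep.n_bins,
                source=rep.source,
                accession=acc,
            )
            for rep, _ in clusters
        ]

    pooled = [c for acc_calls in per_accession.values() for c in acc_calls]
    core = _sweep_merge(pooled, min_reciprocal_overlap)
    accessions = sorted(per_accession)
    rows = []
    for rep, members in core:
        present = {m.accession for m in members}
        rows.append(
            [rep.chrom, rep.start, rep.end, rep.svtype]
            + [int(a in present) for a in accessions]
        )
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "svtype"] + accessions)
    frame = frame.sort_values(["chrom", "start", "end", "svtype"]).reset_index(drop=True)
    return per_accession, frame


@dataclass(frozen=True)
class AccuracyTally:
    """Weighted accuracy R_w = sum_t P_t * R_t over DUP / DEL / CN1 loci."""

    p_dup: float
    p_del: float
    p_cn1: float
    r_dup: float
    r_del: float
    r_cn1: float

    @property
    def r_weighted(self) -> float:
        return self.p_dup * self.r_dup + self.p_del * self.r_del + self.p_cn1 * self.r_cn1


def weighted_accuracy(called: np.ndarray, truth: np.ndarray) -> AccuracyTally:
    """Score a called copy-number matrix against validated copy numbers.

    Loci x accessions matrices, aligned. Each entry is typed by its truth
    value: DUP (CN >= 2), DEL (CN = 0) or CN1 (CN = 1). DEL and CN1 entries
    score 1 only on exact agreement. A DUP entry scores 0 when the called CN
    is <= 1, 1 on exact agreement, and otherwise partial credit
    CN_min / CN_maj of the (called, truth) pair.
    """
    called = np.asarray(called, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if called.shape != truth.shape:
        raise ValueError(f"shape mismatch: called {called.shape} vs truth {truth.shape}")
    flat_c, flat_t = called.ravel(), truth.ravel()
    n = len(flat_t)
    if n == 0:
        raise ValueError("empty matrices")

    is_dup = flat_t >= 2
    is_del = flat_t == 0
    is_cn1 = flat_t == 1

    def mean_credit(mask: np.ndarray, credit: np.ndarray) -> float:
        return float(credit[mask].mean()) if mask.any() else 0.0

    exact = (flat_c == flat_t).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        partial = np.minimum(flat_c, flat_t) / np.maximum(flat_c, flat_t)
    dup_credit = np.where(flat_c <= 1, 0.0, np.where(flat_c == flat_t, 1.0, partial))

    return AccuracyTally(
        p_dup=float(is_dup.mean()),
        p_del=float(is_del.mean()),
        p_cn1=float(is_cn1.mean()),
        r_dup=mean_credit(is_dup, dup_credit),
        r_del=mean_credit(is_del, exact),
        r_cn1=mean_credit(is_cn1, exact),
    )


# ---------------------------------------------------------------------------
# Evidence assembly helpers


def breakpoint_support(
    evidence_table: pd.DataFrame,
    chrom: str,
    pos: int,
    window: int = 500,
) -> tuple[int, int]:
    """(split_reads, discordant_pairs) within +/-``window`` bp of a breakpoint."""
    sub = evidence_table[
        (evidence_table["chrom"] == chrom)
        & (evidence_table["pos"] >= pos - window)
        & (evidence_table["pos"] <= pos + window)
    ]
    return int(sub["split_reads"].sum()), int(sub["discordant_pairs"].sum())


def evidence_from_track(
    call: CNVCall,
    track: BinDepthTrack,
    evidence_table: pd.DataFrame | None = None,
    alignment_mask: np.ndarray | None = None,
    window: int = 500,
    dup_cn_cutoff: float = 1.4,
) -> CNVEvidence:
    """Derive a :class:`CNVEvidence` record for a call from a depth track.

    Coverage fractions are computed at bin resolution over the call's span;
    split-read / discordant-pair counts come from ``evidence_table`` (chrom,
    pos, split_reads, discordant_pairs); ``alignment_mask`` is a per-base
    boolean of alignment-block coverage on the call's chromosome.
    """
    if track.cn_index is None:
        raise ValueError("CN_index not populated; run compute_cn_index first")
    b0 = call.start // track.bin_size
    b1 = max(b0 + 1, -(-call.end // track.bin_size))
    depths = track.depths[b0:b1]
    cn_idx = track.cn_index[b0:b1]
    sr1 = sr2 = dp = 0
    if evidence_table is not None:
        s1, d1 = breakpoint_support(evidence_table, call.chrom, call.start, window)
        s2, d2 = breakpoint_support(evidence_table, call.chrom, call.end, window)
        sr1, sr2, dp = s1, s2, d1 + d2
    algn = 0.0
    if alignment_mask is not None:
        algn = float(alignment_mask[call.start : call.end].mean())
    return CNVEvidence(
        split_reads_bp1=sr1,
        split_reads_bp2=sr2,
        discordant_pairs=dp,
        coverage=float((depths >= 1).mean()),
        dp10_cvrg=float((depths >= 10).mean()),
        dup_cvrg=float((cn_idx >= dup_cn_cutoff).mean()),
        algn_cvrg=algn,
    )


def read_evidence_table(path) -> pd.DataFrame:
    """Read a breakpoint-evidence TSV (chrom, pos, split_reads, discordant_pairs)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "split_reads", "discordant_pairs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    return df
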