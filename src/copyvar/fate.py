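"""Duplicate-gene evolution: Ka/Ks, age staging, fate, and copy expression.

Ka and Ks follow Nei & Gojobori's unweighted pathway method: synonymous and
nonsynonymous site counts come from per-position degeneracy enumeration
averaged over both sequences, observed differences are averaged over all
minimal substitution pathways between codons (pathways through stop codons
excluded), and proportions are Jukes-Cantor corrected,
d = -(3/4) ln(1 - (4/3) p). Divergence time is T = Ks / (2 mu) with
mu = 6.5e-9 synonymous substitutions per site per year (grass Adh rate),
and duplications are staged by Ks into six age classes. Pair fates are
classified from pseudogene flags and protein-domain multisets; copy-specific
variations split expression between the two copies of a pair.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "FateConfig",
    "DuplicatePair",
    "CopyExpression",
    "nei_gojobori_kaks",
    "jukes_cantor",
    "divergence_time_and_stage",
    "classify_gene_fate",
    "assign_parent_offspring",
    "find_csvs_and_split_expression",
    "build_fate_table",
    "STAGES",
]

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"

STAGES = ("I", "II", "III", "IV", "V", "VI")


@dataclass(frozen=True)
class FateConfig:
    """Parameters of the age/fate analysis.

    ``mu`` is the synonymous substitution rate per site per year;
    ``stage_bounds`` are the Ks upper bounds of stages II-V (stage I is
    Ks = 0 exactly, stage VI is everything above the last bound);
    ``min_cds_length`` excludes very short CDSs; ``dominance_fold`` is the
    major/minor expression ratio declaring copy dominance.
    """

    mu: float = 6.5e-9
    stage_bounds: tuple[float, ...] = (0.0072, 0.0313, 0.0879, 0.195)
    min_cds_length: int = 150
    dominance_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if list(self.stage_bounds) != sorted(self.stage_bounds) or len(
            set(self.stage_bounds)
        ) != len(self.stage_bounds):
            raise ValueError("stage bounds must be strictly increasing")


@dataclass
class DuplicatePair:
    """Two copies of a duplicated gene and everything derived from them."""

    pair_id: str
    cds_a: str
    cds_b: str
    pseudo_a: bool = False
    pseudo_b: bool = False
    domains_a: Counter | None = None
    domains_b: Counter | None = None
    domains_ref: Counter | None = None
    tandem: bool = False
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None
    t_years: float | None = None
    stage: str | None = None
    fate: str | None = None
    copy_fates: dict = field(default_factory=dict)
    parent: str | None = None


@dataclass
class CopyExpression:
    """Copy-specific expression split of one duplicate pair."""

    pair_id: str
    csv_sites: list
    count_a: int
    count_b: int

    @property
    def major(self) -> str | None:
        if self.count_a == self.count_b:
            return None
        return "A" if self.count_a > self.count_b else "B"

    @property
    def dominance(self) -> bool:
        hi, lo = max(self.count_a, self.count_b), min(self.count_a, self.count_b)
        return self.major is not None and hi > 2 * lo


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks


def _check_cds(cds: str, name: str, min_length: int = 0) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: length {len(cds)} is not a multiple of 3")
    if min_length and len(cds) < min_length:
        raise ValueError(f"{name}: CDS shorter than {min_length} bp")
    for i in range(0, len(cds), 3):
        if cds[i : i + 3] in _STOPS:
            raise ValueError(f"{name}: stop codon at nucleotide position {i}")
    return cds


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes its fraction of synonymous single-nucleotide
    changes; changes producing a stop codon count as nonsynonymous.
    """
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged with equal weights over all minimal substitution pathways;
    pathways passing through a stop codon are excluded (all-blocked codon
    pairs fall back to averaging over every pathway).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur, sd, nd = c1, 0.0, 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                return None
            sd += 1.0 if _CODON_TABLE[cur] == _CODON_TABLE[nxt] else 0.0
            nd += 0.0 if _CODON_TABLE[cur] == _CODON_TABLE[nxt] else 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # every path passes a stop; average over all of them
        valid = []
        for order in itertools.permutations(diff_pos):
            cur, sd, nd = c1, 0.0, 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                same = nxt not in _STOPS and cur not in _STOPS and (
                    _CODON_TABLE[cur] == _CODON_TABLE[nxt]
                )
                sd += 1.0 if same else 0.0
                nd += 0.0 if same else 1.0
                cur = nxt
            valid.append((sd, nd))
    return (
        sum(v[0] for v in valid) / len(valid),
        sum(v[1] for v in valid) / len(valid),
    )


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction, d = -(3/4) ln(1 - (4/3) p)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise ValueError(f"proportion {p} >= 3/4: correction saturated")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def nei_gojobori_kaks(
    cds_a: str, cds_b: str, min_length: int = 150
) -> tuple[float, float, float | None]:
    """Nei-Gojobori (Ka, Ks, Ka/Ks) for an aligned, gap-free codon pair.

    Site counts are averaged over the two sequences; differences are summed
    over codons with pathway averaging; both proportions are Jukes-Cantor
    corrected. The ratio is None when Ks = 0. Raises on saturation
    (p >= 3/4) or internal stop codons.
    """
    cds_a = _check_cds(cds_a, "cds_a", min_length)
    cds_b = _check_cds(cds_b, "cds_b", min_length)
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences must have equal length")
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = _codon_differences(ca, cb)
        sd += dsd
        nd += dnd
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = ka / ks if ks > 0 else None
    return ka, ks, ratio


# ---------------------------------------------------------------------------
# Age staging


def divergence_time_and_stage(
    ks: float, config: FateConfig = FateConfig()
) -> tuple[float, str]:
    """Divergence time T = Ks / (2 mu) in years and the age stage.

    Stage I is reserved for Ks = 0 exactly ("recent" duplications); stages
    II-V cover half-open intervals (lower, upper] over the configured Ks
    bounds and stage VI everything beyond the last bound.
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    t = ks / (2.0 * config.mu)
    if ks == 0:
        return t, "I"
    for bound, stage in zip(config.stage_bounds, STAGES[1:]):
        if ks <= bound:
            return t, stage
    return t, STAGES[-1]


# ---------------------------------------------------------------------------
# Fate classification


def _copy_fate(copy_domains: Counter, ref_domains: Counter) -> str:
    new_domain = any(copy_domains[d] > ref_domains.get(d, 0) for d in copy_domains)
    total_copy, total_ref = sum(copy_domains.values()), sum(ref_domains.values())
    if new_domain or total_copy > total_ref:
        return "Neo"
    if total_copy < total_ref:
        return "Sub"
    return "Non"


def classify_gene_fate(pair: DuplicatePair, neo_dominates: bool = True) -> str:
    """Classify a duplicate pair's fate from pseudogene flags and domains.

    Any pseudogene flag short-circuits to ``Gene-Psi`` (one copy) or
    ``Psi-Psi`` (both). Otherwise each copy's domain multiset is compared to
    the reference counterpart: a domain absent from the reference or a
    strictly larger multiset means neofunctionalization, a strictly smaller
    one subfunctionalization, equality means no detectable differentiation
    (``Non``) — an indeterminate outcome without expression evidence, kept
    per copy in ``pair.copy_fates``. When the copies disagree (one Neo, one
    Sub), the pair is labelled Neo by default.
    """
    if pair.pseudo_a and pair.pseudo_b:
        pair.fate = "Psi-Psi"
        return pair.fate
    if pair.pseudo_a or pair.pseudo_b:
        pair.fate = "Gene-Psi"
        return pair.fate
    if pair.domains_a is None or pair.domains_b is None or pair.domains_ref is None:
        pair.fate = "indeterminate"
        return pair.fate
    fa = _copy_fate(Counter(pair.domains_a), Counter(pair.domains_ref))
    fb = _copy_fate(Counter(pair.domains_b), Counter(pair.domains_ref))
    pair.copy_fates = {"A": fa, "B": fb}
    fates = {fa, fb}
    if "Neo" in fates and "Sub" in fates:
        pair.fate = "Neo" if neo_dominates else "Sub"
    elif "Neo" in fates:
        pair.fate = "Neo"
    elif "Sub" in fates:
        pair.fate = "Sub"
    else:
        pair.fate = "Non"
    return pair.fate


def assign_parent_offspring(
    pair: DuplicatePair,
    flanking_support: dict[str, dict[str, int]],
    min_flanking_genes: int = 2,
    min_accessions: int = 10,
) -> str:
    """Decide which copy sits in the ancestral collinearity block.

    ``flanking_support`` maps copy label ("A"/"B") -> {accession: number of
    the four flanking reference genes co-assembled with that copy}. A copy
    is *in the block* when at least ``min_flanking_genes`` flanking genes
    co-locate with it in more than ``min_accessions`` accessions. Exactly
    one qualifying copy becomes the parent; ties, no support, or a tandem
    pair are indistinguishable.
    """
    if pair.tandem:
        pair.parent = None
        return "indistinguishable"
    qualified = []
    for copy_label in ("A", "B"):
        support = flanking_support.get(copy_label, {})
        n_acc = sum(1 for v in support.values() if v >= min_flanking_genes)
        if n_acc > min_accessions:
            qualified.append(copy_label)
    if len(qualified) == 1:
        pair.parent = qualified[0]
        return f"{qualified[0]}-parent"
    pair.parent = None
    return "indistinguishable"


# ---------------------------------------------------------------------------
# Copy-specific expression


def _align_pair(cds_a: str, cds_b: str) -> tuple[str, str]:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    aln = aligner.align(cds_a, cds_b)[0]
    return str(aln[0]), str(aln[1])


def find_csvs_and_split_expression(
    pair: DuplicatePair,
    reads: list[str] | None = None,
    counts: tuple[int, int] | None = None,
) -> CopyExpression:
    """Find copy-specific variations (CSVs) and split expression by copy.

    The two CDSs are globally aligned; mismatch columns are CSV sites. Reads
    (exact sequences) are assigned to the copy whose CDS contains them as an
    exact substring; reads matching both copies carry no CSV and stay
    unassigned, reads matching neither (conflicting alleles or errors) are
    discarded. Precomputed per-copy counts may be passed instead of reads.
    Identical CDSs carry no CSV and the pair is excluded.
    """
    a, b = _align_pair(pair.cds_a.upper(), pair.cds_b.upper())
    csv_sites = [
        (i, x, y) for i, (x, y) in enumerate(zip(a, b)) if x != y
    ]
    if not csv_sites:
        raise ValueError(f"{pair.pair_id}: no CSVs; pair excluded")
    if counts is not None:
        count_a, count_b = counts
    else:
        count_a = count_b = 0
        for read in reads or []:
            read = read.upper()
            in_a = read in pair.cds_a.upper()
            in_b = read in pair.cds_b.upper()
            if in_a and not in_b:
                count_a += 1
            elif in_b and not in_a:
                count_b += 1
    return CopyExpression(pair.pair_id, csv_sites, count_a, count_b)


# ---------------------------------------------------------------------------
# Stage table


def build_fate_table(pairs: list[DuplicatePair]) -> pd.DataFrame:
    """Per-stage counts of non-pseudogenic duplicate pairs and their rates.

    Columns: duplicate pairs, non-differentiated pairs, differentiated
    pairs, rate of differentiated pairs (%), Neo pairs, Sub pairs, rate of
    Neo among differentiated pairs (%); rates are 100 x ratio rounded to two
    decimals (0.00 when the denominator is zero), plus a totals row.
    Pseudogenic or unstaged pairs are rejected.
    """
    counts = {s: Counter() for s in STAGES}
    for p in pairs:
        if p.fate in ("Gene-Psi", "Psi-Psi"):
            raise ValueError(f"{p.pair_id}: pseudogenic pairs are excluded")
        if p.stage not in counts or p.fate not in ("Neo", "Sub", "Non"):
            raise ValueError(f"{p.pair_id}: pair not staged/classified")
        counts[p.stage][p.fate] += 1
    return fate_table_from_counts(
        {s: (c["Non"], c["Neo"], c["Sub"]) for s, c in counts.items()}
    )


def fate_table_from_counts(
    stage_counts: dict[str, tuple[int, int, int]]
) -> pd.DataFrame:
    """Build the stage table from (non, neo, sub) counts per stage."""
    rows = []
    tot = np.zeros(3, dtype=int)
    for stage in STAGES:
        non, neo, sub = stage_counts.get(stage, (0, 0, 0))
        rows.append(_stage_row(stage, non, neo, sub))
        tot += (non, neo, sub)
    rows.append(_stage_row("Total", *tot))
    return pd.DataFrame(
        rows,
        columns=[
            "stage",
            "pairs",
            "non_differentiated",
            "differentiated",
            "differentiated_rate_pct",
            "neo",
            "sub",
            "neo_rate_pct",
        ],
    ).set_index("stage")


def _stage_row(stage: str, non: int, neo: int, sub: int):
    diff = neo + sub
    pairs = non + diff
    diff_rate = round(100.0 * diff / pairs, 2) if pairs else 0.0
    neo_rate = round(100.0 * neo / diff, 2) if diff else 0.0
    return (stage, pairs, non, diff, diff_rate, neo, sub, neo_rate)
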