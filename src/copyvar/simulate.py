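"""Synthetic genomes, depth tracks, expression matrices and CDS pairs.

Everything the pipeline consumes can be generated here with known ground
truth: reference/sample genome pairs differing by implanted deletions and
(tandem or dispersed) duplications, Poisson read-depth tracks whose
expectation scales with the true local copy number, breakpoint evidence
counts, dosage-responsive TPM matrices, and CDS pairs with controlled
numbers of synonymous and nonsynonymous substitutions. Fixed seeds give
byte-identical outputs.

Defaults emulate a short-read resequencing design at ~50x depth with
250 bp depth bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import DEL, DUP, CNVCall
from .depth import BinDepthTrack, compute_cn_index
from .fate import _CODON_TABLE, _STOPS, _check_cds

__all__ = [
    "CNVEvent",
    "SimConfig",
    "SimTruth",
    "simulate_genome_with_cnvs",
    "simulate_depth_track",
    "simulate_dosage_expression",
    "mutate_cds_pair",
    "random_cds",
    "match_calls_to_truth",
    "write_fasta",
    "write_truth_bed",
    "write_depth_tsv",
]

_BASES = np.array(list("ACGT"))
EDGE_MARGIN = 2000  # implants keep this distance from chromosome ends


@dataclass(frozen=True)
class CNVEvent:
    """One implanted event: a deletion (CN 0) or duplication (CN >= 2)."""

    svtype: str
    length: int
    copy_number: int
    tandem: bool = True

    def __post_init__(self) -> None:
        if self.svtype == DEL and self.copy_number != 0:
            raise ValueError("deletions are implanted homozygous (CN 0)")
        if self.svtype == DUP and self.copy_number < 2:
            raise ValueError("duplications need copy_number >= 2")


@dataclass(frozen=True)
class SimConfig:
    """Study design of one simulated sample."""

    genome_length: int = 300_000
    n_chromosomes: int = 1
    n_genes: int = 0
    cnv_events: tuple[CNVEvent, ...] = ()
    mean_depth: float = 50.0
    bin_size: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("genome_length and n_chromosomes must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for ev in self.cnv_events:
            if ev.length < self.bin_size:
                raise ValueError("event lengths must be at least one bin")

    @property
    def chrom_length(self) -> int:
        return self.genome_length // self.n_chromosomes


@dataclass
class SimTruth:
    """Ground truth of one simulated sample (reference coordinates)."""

    events: list  # (chrom, start, end, svtype, copy_number, tandem)
    gene_cn: dict = field(default_factory=dict)
    dosage_model: dict = field(default_factory=dict)  # gene -> (slope, sd, baseline)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_genome_with_cnvs(
    config: SimConfig,
) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Build a (reference, sample) genome pair differing by implanted CNVs.

    Events are placed uniformly at random, non-overlapping, at least 2 kb
    from chromosome ends. Deletions remove the segment from the sample;
    tandem duplications insert the extra copies adjacent to the source;
    dispersed duplications insert them at distant loci of the same
    chromosome. Truth records every event in reference coordinates.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chrom_length
    for ev in config.cnv_events:
        if ev.length + 2 * EDGE_MARGIN > L:
            raise ValueError(
                f"event of {ev.length} bp does not fit a {L} bp chromosome"
            )
    reference = {
        f"chr{i + 1}": _random_seq(rng, L) for i in range(config.n_chromosomes)
    }

    # Assign events to chromosomes round-robin, then place non-overlapping.
    events: list[tuple[str, int, int, CNVEvent]] = []
    per_chrom: dict[str, list[tuple[int, int, CNVEvent]]] = {
        c: [] for c in reference
    }
    chroms = sorted(reference)
    for idx, ev in enumerate(config.cnv_events):
        chrom = chroms[idx % len(chroms)]
        placed = False
        for _ in range(1000):
            start = int(rng.integers(EDGE_MARGIN, L - EDGE_MARGIN - ev.length))
            end = start + ev.length
            gap = 2 * config.bin_size  # keep implants separable by the caller
            if all(
                end + gap <= s or start >= e + gap for s, e, _ in per_chrom[chrom]
            ):
                per_chrom[chrom].append((start, end, ev))
                placed = True
                break
        if not placed:
            raise ValueError("could not place all events without overlap")

    sample: dict[str, str] = {}
    truth_events = []
    for chrom in chroms:
        ref_seq = reference[chrom]
        placements = sorted(per_chrom[chrom])
        pieces: list[str] = []
        cursor = 0
        inserts: list[tuple[int, str]] = []  # dispersed copies: (ref pos, seq)
        for start, end, ev in placements:
            pieces.append(ref_seq[cursor:start])
            segment = ref_seq[start:end]
            if ev.svtype == DEL:
                pass  # drop the segment
            elif ev.tandem:
                pieces.append(segment * ev.copy_number)
            else:
                pieces.append(segment)
                occupied = [(s, e) for s, e, _ in placements]
                for _ in range(ev.copy_number - 1):
                    for _ in range(1000):
                        pos = int(rng.integers(EDGE_MARGIN, L - EDGE_MARGIN))
                        if all(
                            not (s - ev.length < pos < e + ev.length)
                            for s, e in occupied
                        ):
                            inserts.append((pos, segment))
                            occupied.append((pos, pos))
                            break
                    else:
                        raise ValueError("could not place dispersed copy")
            cursor = end
            truth_events.append(
                (chrom, start, end, ev.svtype, ev.copy_number, ev.tandem)
            )
        pieces.append(ref_seq[cursor:])
        # splice dispersed insertions at their reference offsets
        assembled = "".join(pieces)
        if inserts:
            # insertion offsets are in reference coordinates; apply right-to-left
            out = assembled
            shift_map = sorted(inserts, key=lambda t: -t[0])
            for pos, seg in shift_map:
                adj = max(0, min(len(out), pos + _offset_at(placements, pos)))
                out = out[:adj] + seg + out[adj:]
            assembled = out
        sample[chrom] = assembled

    return reference, sample, SimTruth(events=sorted(truth_events))


def _offset_at(placements: list[tuple[int, int, CNVEvent]], pos: int) -> int:
    """Sample-vs-reference coordinate shift accumulated left of ``pos``."""
    shift = 0
    for start, end, ev in placements:
        if end <= pos:
            if ev.svtype == DEL:
                shift -= ev.length
            elif ev.tandem:
                shift += ev.length * (ev.copy_number - 1)
    return shift


def true_cn_per_base(truth: SimTruth, chrom: str, length: int) -> np.ndarray:
    """Per-base true copy number on the reference (1 outside events)."""
    cn = np.ones(length)
    for c, start, end, svtype, copy_number, _ in truth.events:
        if c == chrom:
            cn[start:end] = copy_number
    return cn


def simulate_depth_track(
    truth: SimTruth,
    config: SimConfig,
) -> tuple[dict[str, BinDepthTrack], pd.DataFrame]:
    """Poisson depth tracks on the reference plus breakpoint evidence.

    Bin depths are Poisson(mean_depth x true CN x bin_size) / bin_size, so
    the expectation outside events is ``mean_depth`` and scales linearly
    with the implanted copy number inside them. Each event breakpoint
    receives at least 5 split-read and discordant-pair counts within
    +/-500 bp. CN_index is populated on the returned tracks.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.chrom_length
    tracks: dict[str, BinDepthTrack] = {}
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for chrom in chroms:
        cn = true_cn_per_base(truth, chrom, L)
        n_bins = -(-L // config.bin_size)
        lam = np.add.reduceat(cn, np.arange(0, L, config.bin_size)) * config.mean_depth
        lengths = np.full(n_bins, config.bin_size, dtype=float)
        if L % config.bin_size:
            lengths[-1] = L % config.bin_size
        depths = rng.poisson(lam) / lengths
        tracks[chrom] = compute_cn_index(
            BinDepthTrack(chrom, config.bin_size, depths, chrom_length=L)
        )

    rows = []
    for chrom, start, end, svtype, _, _ in truth.events:
        for pos in (start, end):
            rows.append(
                (
                    chrom,
                    int(np.clip(pos + rng.integers(-100, 101), 0, L - 1)),
                    int(5 + rng.poisson(5)),
                    int(5 + rng.poisson(5)) if svtype == DEL else 0,
                )
            )
    evidence = pd.DataFrame(
        rows, columns=["chrom", "pos", "split_reads", "discordant_pairs"]
    )
    return tracks, evidence


def simulate_dosage_expression(
    cn: pd.DataFrame,
    dosage_model: dict[str, tuple[float, float, float]],
    seed: int = 0,
) -> pd.DataFrame:
    """TPM matrix from per-gene linear dosage models.

    ``dosage_model`` maps gene -> (slope, noise sd, baseline);
    TPM = max(0, baseline + slope x CN + Normal(0, sd)) per accession.
    """
    rng = np.random.default_rng(seed)
    tpm = pd.DataFrame(0.0, index=cn.index, columns=cn.columns)
    for gene in cn.index:
        slope, sd, baseline = dosage_model[gene]
        noise = rng.normal(0.0, sd, size=cn.shape[1]) if sd > 0 else 0.0
        tpm.loc[gene] = np.maximum(
            0.0, baseline + slope * cn.loc[gene].to_numpy(dtype=float) + noise
        )
    return tpm


# ---------------------------------------------------------------------------
# CDS pair fixtures


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A random in-frame CDS with no stop codons."""
    codons = [c for c in _CODON_TABLE if c not in _STOPS]
    return "".join(rng.choice(codons) for _ in range(n_codons))


def _single_site_changes(codon: str) -> list[tuple[str, bool]]:
    """All single-nucleotide, non-stop variants of a codon (variant, is_syn)."""
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            out.append((alt, _CODON_TABLE[alt] == _CODON_TABLE[codon]))
    return out


def mutate_cds_pair(
    cds: str,
    n_synonymous: int,
    n_nonsynonymous: int,
    seed: int = 0,
) -> tuple[str, str]:
    """Derive a CDS pair differing by exact substitution counts.

    Copy A is the input CDS; copy B carries exactly ``n_synonymous``
    synonymous and ``n_nonsynonymous`` nonsynonymous single-nucleotide
    substitutions, each in a distinct codon (so substitution classes stay
    exact by the codon table). Raises when the CDS has too few codons
    offering the requested change classes.
    """
    cds = _check_cds(cds, "cds", min_length=150)
    rng = np.random.default_rng(seed)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    syn_options: dict[int, list[str]] = {}
    non_options: dict[int, list[str]] = {}
    for i, codon in enumerate(codons):
        for alt, is_syn in _single_site_changes(codon):
            (syn_options if is_syn else non_options).setdefault(i, []).append(alt)

    order = rng.permutation(len(codons))
    chosen: dict[int, str] = {}
    need = [(n_synonymous, syn_options), (n_nonsynonymous, non_options)]
    for count, options in need:
        picked = 0
        for i in order:
            if picked == count:
                break
            if i in chosen or int(i) not in options:
                continue
            alts = options[int(i)]
            chosen[int(i)] = alts[int(rng.integers(len(alts)))]
            picked += 1
        if picked < count:
            raise ValueError(
                f"requested {count} substitutions but only {picked} codons available"
            )
    mutated = list(codons)
    for i, alt in chosen.items():
        mutated[i] = alt
    return cds, "".join(mutated)


# ---------------------------------------------------------------------------
# Truth matching and writers


def match_calls_to_truth(
    calls: list[CNVCall],
    truth: SimTruth,
    min_reciprocal_overlap: float = 0.5,
    min_truth_length: int = 0,
) -> tuple[float, float]:
    """(precision, recall) of calls against implanted events.

    A call matches a truth event of the same type on the same chromosome
    with reciprocal overlap >= ``min_reciprocal_overlap``. Truth events
    shorter than ``min_truth_length`` are ignored on both sides.
    """
    truths = [
        t for t in truth.events if t[2] - t[1] >= min_truth_length
    ]
    def overlaps(call: CNVCall, t) -> bool:
        chrom, start, end, svtype = t[0], t[1], t[2], t[3]
        if call.chrom != chrom or call.svtype != svtype:
            return False
        ov = min(call.end, end) - max(call.start, start)
        return ov > 0 and ov / max(call.length, end - start) >= min_reciprocal_overlap

    matched_truth = set()
    tp = 0
    for call in calls:
        hit = next(
            (i for i, t in enumerate(truths) if overlaps(call, t)), None
        )
        if hit is not None:
            tp += 1
            matched_truth.add(hit)
    precision = tp / len(calls) if calls else 1.0
    recall = len(matched_truth) / len(truths) if truths else 1.0
    return precision, recall


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth_bed(truth: SimTruth, path) -> None:
    pd.DataFrame(
        truth.events,
        columns=["chrom", "start", "end", "svtype", "copy_number", "tandem"],
    ).to_csv(path, sep="\t", index=False)


def write_depth_tsv(tracks: dict[str, BinDepthTrack], path) -> None:
    rows = []
    for chrom, track in sorted(tracks.items()):
        for i, d in enumerate(track.depths):
            rows.append((chrom, i * track.bin_size, d))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "depth"]).to_csv(
        path, sep="\t", index=False
    )
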