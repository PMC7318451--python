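"""Gene-level copy-number annotation and dosage-effect analysis.

CNV calls are lifted to integer gene copy numbers (a gene is CNV-impacted
when at least half of its body is covered by same-type calls), per-accession
vectors are merged into a population matrix with 0/1 duplication/deletion
genotype encodings, and the copy-number-vs-expression correlation is run
per gene after the selection filters: change fold >= 1.1, per-gene TPM
outlier removal at mean +/- 3 sd, >= 3 accessions per copy-number group,
removal of two-type genes whose smaller type is 0, and a population
differentiation cap V_ST <= 0.4. Significance is Pearson with
Benjamini-Hochberg adjustment at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import DEL, CNVCall
from .depth import BinDepthTrack

__all__ = [
    "GeneModel",
    "GeneCopyNumberMatrix",
    "DosageResult",
    "read_gene_models",
    "annotate_gene_copy_numbers",
    "build_population_matrix",
    "select_genes_for_correlation",
    "vst",
    "correlate_dosage",
    "expression_increase_rates",
    "tandem_flags",
]

TPM_EXPRESSED = 0.5


@dataclass(frozen=True)
class GeneModel:
    """A gene locus on the reference (half-open interval)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    is_transposon: bool = False
    cds_length: int | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: malformed interval")

    @property
    def length(self) -> int:
        return self.end - self.start


def read_gene_models(gff3_path) -> list[GeneModel]:
    """Read gene features from a GFF3 file.

    Transposon genes (a ``transposon`` note or TE-related biotype in the
    attributes) are flagged so the annotation step can exclude them.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        attrs = {k.lower(): ";".join(v).lower() for k, v in feat.attributes.items()}
        blob = " ".join(attrs.values())
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand or "+",
                is_transposon="transposon" in blob or "transposable" in blob,
            )
        )
    return genes


def annotate_gene_copy_numbers(
    calls: list[CNVCall],
    genes: list[GeneModel],
    track_by_chrom: dict[str, BinDepthTrack] | None = None,
    min_overlap: float = 0.5,
    rescue_min_coverage: float = 0.5,
    rescue_min_cn_index: float = 0.5,
) -> dict[str, int]:
    """Assign an integer copy number to every (non-transposon) gene.

    A gene takes a call's copy number when same-type calls cover at least
    ``min_overlap`` of its body (the call with the largest individual
    overlap supplies the CN); otherwise CN = 1. Genes landing at CN 0 are
    rescued back to 1 when the gene body's read coverage is >=
    ``rescue_min_coverage`` and its mean CN_index is >=
    ``rescue_min_cn_index`` (requires ``track_by_chrom``).
    """
    genes = [g for g in genes if not g.is_transposon]
    by_chrom: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)

    out: dict[str, int] = {}
    for g in genes:
        cn = 1
        best: tuple[int, CNVCall] | None = None
        cover_by_type: dict[str, int] = {}
        for c in by_chrom.get(g.chrom, []):
            ov = min(c.end, g.end) - max(c.start, g.start)
            if ov <= 0:
                continue
            cover_by_type[c.svtype] = cover_by_type.get(c.svtype, 0) + ov
            if best is None or ov > best[0]:
                best = (ov, c)
        if best is not None:
            svtype = best[1].svtype
            if cover_by_type.get(svtype, 0) / g.length >= min_overlap:
                cn = best[1].cn
        if cn == 0 and track_by_chrom is not None and g.chrom in track_by_chrom:
            track = track_by_chrom[g.chrom]
            if track.cn_index is not None:
                b0 = g.start // track.bin_size
                b1 = max(b0 + 1, -(-g.end // track.bin_size))
                depths = track.depths[b0:b1]
                cov = float((depths >= 1).mean())
                mean_ci = float(track.cn_index[b0:b1].mean())
                if cov >= rescue_min_coverage and mean_ci >= rescue_min_cn_index:
                    cn = 1
        out[g.gene_id] = max(0, int(cn))
    return out


@dataclass
class GeneCopyNumberMatrix:
    """Gene x accession integer copy numbers with 0/1 genotype encodings."""

    cn: pd.DataFrame  # genes x accessions, int

    def __post_init__(self) -> None:
        if (self.cn.to_numpy() < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.cn.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.cn.columns)

    def duplication_genotypes(self) -> pd.DataFrame:
        """1 where the accession carries a duplication (CN >= 2), else 0."""
        return (self.cn >= 2).astype(int)

    def deletion_genotypes(self) -> pd.DataFrame:
        """1 where the accession carries a deletion (CN = 0), else 0."""
        return (self.cn == 0).astype(int)

    def change_fold(self) -> pd.Series:
        """Per-gene max/min copy-number fold over positive CN values.

        Genes whose positive copy numbers are all equal (including all-0/1
        genes) get fold 1.0.
        """
        def fold(row: pd.Series) -> float:
            pos = row[row > 0]
            if pos.empty:
                return 1.0
            return float(pos.max() / pos.min())

        return self.cn.apply(fold, axis=1)


def build_population_matrix(
    vectors: dict[str, dict[str, int]],
    gene_universe: list[str] | None = None,
) -> GeneCopyNumberMatrix:
    """Merge per-accession gene CN vectors into the population matrix.

    Missing gene x accession entries default to the normal copy number 1.
    Duplicate accession identifiers are rejected.
    """
    accs = list(vectors)
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accession ids")
    if gene_universe is None:
        gene_universe = sorted({g for v in vectors.values() for g in v})
    cn = pd.DataFrame(1, index=gene_universe, columns=sorted(accs), dtype=int)
    for acc, vec in vectors.items():
        for gene, value in vec.items():
            cn.loc[gene, acc] = int(value)
    return GeneCopyNumberMatrix(cn)


def vst(values: np.ndarray, labels: np.ndarray) -> float:
    """Population differentiation of copy number, V_ST = (V_T - V_S) / V_T.

    ``V_T`` is the variance over all accessions and ``V_S`` the size-weighted
    mean of within-population variances (sample variances, ddof = 1). A zero
    total variance yields V_ST = 0 by definition. Clamped to [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pops = np.unique(labels)
    if len(pops) < 2:
        raise ValueError("V_ST needs at least two populations")
    for p in pops:
        if (labels == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than two members")
    v_t = float(np.var(values, ddof=1))
    if v_t == 0:
        return 0.0
    n = len(values)
    v_s = sum(
        (labels == p).sum() / n * float(np.var(values[labels == p], ddof=1))
        for p in pops
    )
    return float(min(1.0, max(0.0, (v_t - v_s) / v_t)))


def select_genes_for_correlation(
    matrix: GeneCopyNumberMatrix,
    tpm: pd.DataFrame,
    population_labels: dict[str, str] | None = None,
    min_fold: float = 1.1,
    outlier_sd: float = 3.0,
    min_replicates: int = 3,
    max_vst: float = 0.4,
    impacted_genes: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Select genes eligible for the dosage correlation and group their TPMs.

    Pipeline order: (1) gene must be CNV-impacted (``impacted_genes``;
    defaults to genes with any CN != 1) with CN change fold >= ``min_fold``;
    (2) per gene, (TPM, CN) pairs with TPM outside mean +/- ``outlier_sd``
    sd are dropped (one pass); (3) CN groups with fewer than
    ``min_replicates`` accessions are dropped, and genes left with < 2 CN
    groups are excluded; (4) genes with exactly two remaining CN types whose
    smaller type is 0 are discarded; (5) genes with V_ST > ``max_vst`` over
    ``population_labels`` are discarded (step skipped when labels are None).

    Returns gene -> DataFrame(accession, cn, tpm) for surviving genes.
    """
    shared = [a for a in matrix.accessions if a in tpm.columns]
    if not shared:
        raise ValueError("matrix and TPM table share no accessions")
    folds = matrix.change_fold()
    if impacted_genes is None:
        impacted_genes = {
            g for g in matrix.genes if (matrix.cn.loc[g, shared] != 1).any()
        }

    out: dict[str, pd.DataFrame] = {}
    for gene in matrix.genes:
        if gene not in impacted_genes or gene not in tpm.index:
            continue
        if folds[gene] < min_fold:
            continue
        df = pd.DataFrame(
            {
                "accession": shared,
                "cn": matrix.cn.loc[gene, shared].to_numpy(),
                "tpm": tpm.loc[gene, shared].to_numpy(dtype=float),
            }
        ).dropna(subset=["tpm"])
        if df.empty:
            continue
        mu, sd = df["tpm"].mean(), df["tpm"].std(ddof=1)
        if sd > 0:
            df = df[(df["tpm"] - mu).abs() <= outlier_sd * sd]
        counts = df["cn"].value_counts()
        df = df[df["cn"].isin(counts[counts >= min_replicates].index)]
        cn_types = sorted(df["cn"].unique())
        if len(cn_types) < 2:
            continue
        if len(cn_types) == 2 and cn_types[0] == 0:
            continue
        if population_labels is not None:
            lab = df["accession"].map(population_labels)
            if lab.isna().any():
                raise ValueError("population label missing for some accessions")
            if vst(df["cn"].to_numpy(), lab.to_numpy()) > max_vst:
                continue
        out[gene] = df.reset_index(drop=True)
    return out


@dataclass
class DosageResult:
    """Per-gene dosage correlation results with BH-adjusted classes."""

    table: pd.DataFrame = field(repr=False)  # gene, r, p, p_adj, class, anova_p

    def class_fractions(self) -> dict[str, float]:
        counts = self.table["class"].value_counts()
        n = len(self.table)
        return {
            c: float(counts.get(c, 0)) / n
            for c in ("positive", "negative", "non-significant")
        }


def correlate_dosage(
    grouped: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    method: str = "pearson",
    anova: bool = False,
) -> DosageResult:
    """Correlate copy number with expression per gene, BH-adjusted.

    ``grouped`` is the output of :func:`select_genes_for_correlation`. The
    coefficient is Pearson's r (``method="spearman"`` optional) with its
    t-test p-value; p-values are Benjamini-Hochberg adjusted across all
    tested genes and classes assigned at adjusted p < ``alpha``: positive
    (r > 0), negative (r < 0), else non-significant. Genes with zero CN or
    TPM variance after selection are skipped.
    """
    rows = []
    for gene, df in grouped.items():
        cn, tpm_vals = df["cn"].to_numpy(dtype=float), df["tpm"].to_numpy(dtype=float)
        if np.var(cn) == 0 or np.var(tpm_vals) == 0:
            continue
        if method == "pearson":
            r, p = stats.pearsonr(cn, tpm_vals)
        elif method == "spearman":
            r, p = stats.spearmanr(cn, tpm_vals)
        else:
            raise ValueError(f"unknown method {method!r}")
        a_p = np.nan
        if anova:
            groups = [g["tpm"].to_numpy() for _, g in df.groupby("cn")]
            if len(groups) >= 2:
                a_p = stats.f_oneway(*groups).pvalue
        rows.append((gene, float(r), float(p), a_p))
    table = pd.DataFrame(rows, columns=["gene", "r", "p", "anova_p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table["class"] = np.where(
            table["p_adj"] < alpha,
            np.where(table["r"] > 0, "positive", "negative"),
            "non-significant",
        )
    else:
        table["p_adj"] = []
        table["class"] = []
    cols = ["gene", "r", "p", "p_adj", "class", "anova_p"]
    return DosageResult(table[cols].set_index("gene", drop=False))


def expression_increase_rates(
    df: pd.DataFrame,
    denominator: str = "cn1",
) -> pd.DataFrame:
    """Expression increase per copy-number level for one gene.

    DupCN1(k) = 100 x (mean TPM at CN=k - mean TPM at CN=1) / mean TPM at
    CN=1; AddCN1(k) uses the CN=k-1 mean in the numerator but (by default)
    keeps the CN=1 mean as denominator (``denominator="previous"`` switches
    to mean TPM at CN=k-1). Requires a CN=1 group with nonzero mean TPM.
    """
    means = df.groupby("cn")["tpm"].mean()
    if 1 not in means.index:
        raise ValueError("gene has no CN=1 group")
    base = means[1]
    if base == 0:
        raise ValueError("mean TPM at CN=1 is 0; rates undefined")
    rows = []
    for k in sorted(means.index):
        if k <= 1:
            continue
        dup = 100.0 * (means[k] - base) / base
        add = np.nan
        if k - 1 in means.index:
            denom = base if denominator == "cn1" else means[k - 1]
            add = 100.0 * (means[k] - means[k - 1]) / denom if denom else np.nan
        rows.append((int(k), dup, add))
    return pd.DataFrame(rows, columns=["cn", "dup_cn1_pct", "add_cn1_pct"])


def tandem_flags(
    copy_positions: dict[str, list[tuple[str, int]]],
    max_distance: int = 25_000,
) -> dict[str, bool]:
    """Label duplicated genes tandem vs dispersed.

    ``copy_positions`` maps gene -> list of (chromosome, midpoint) for its
    copies; a gene is tandem when any two copies share a chromosome with
    midpoints within ``max_distance`` bp.
    """
    out = {}
    for gene, positions in copy_positions.items():
        tandem = False
        for i, (c1, p1) in enumerate(positions):
            for c2, p2 in positions[i + 1 :]:
                if c1 == c2 and abs(p1 - p2) <= max_distance:
                    tandem = True
        out[gene] = tandem
    return out
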