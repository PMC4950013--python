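"""Polygenic scores from GWAS summary statistics and hard-call genotypes.

The score follows the classic risk-profile recipe: keep SNPs passing a
liberal GWAS p-value threshold (strict ``p < PT``), prune them to a
quasi-independent set (greedy, ascending p, retaining a SNP only if its
pairwise r-squared with every already-retained SNP stays below the
threshold), align genotype dosages so the counted allele is the GWAS
effect allele, then average risk-allele counts weighted by the natural
log of each SNP's odds ratio:

    score_i = sum_j ln(OR_j) * dosage_ij / n_snps

Missing hard calls are mean-imputed per SNP by default (matching the
standard scoring convention) or dropped per sample in complete-case
mode.  Inputs are assumed post-QC; LD reference panels, imputation and
dosage (non-hard-call) data are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Strand-ambiguous (palindromic) allele pairs.
AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

SUMMARY_COLUMNS = ("snp_id", "effect_allele", "other_allele", "odds_ratio", "p_value")

DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "odds_ratio": "OR",
    "p_value": "P",
}


@dataclass(frozen=True)
class SummaryStatRecord:
    snp_id: str
    effect_allele: str
    other_allele: str
    odds_ratio: float
    p_value: float

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.snp_id}: odds ratio must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"{self.snp_id}: p-value outside [0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")


def records_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=SUMMARY_COLUMNS)


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    stats = stats.reset_index(drop=True)
    for col in SUMMARY_COLUMNS:
        if col not in stats.columns:
            raise ValueError(f"summary statistics lack column {col!r}")
    bad = stats.index[stats["odds_ratio"] <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive odds ratio at row {bad[0]} "
            f"(snp {stats.loc[bad[0], 'snp_id']!r})"
        )
    bad = stats.index[(stats["p_value"] < 0) | (stats["p_value"] > 1)]
    if len(bad):
        raise ValueError(
            f"p-value outside [0, 1] at row {bad[0]} "
            f"(snp {stats.loc[bad[0], 'snp_id']!r})"
        )
    bad = stats.index[stats["effect_allele"] == stats["other_allele"]]
    if len(bad):
        raise ValueError(
            f"identical alleles at row {bad[0]} "
            f"(snp {stats.loc[bad[0], 'snp_id']!r})"
        )
    dup = stats["snp_id"][stats["snp_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate snp_id {dup.iloc[0]!r}")
    return stats


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None, sep: str = "\t"
) -> pd.DataFrame:
    """Read and validate GWAS summary statistics.

    ``column_map`` maps the canonical names (snp_id, effect_allele,
    other_allele, odds_ratio, p_value) to the file's column headers;
    defaults are SNP/A1/A2/OR/P.  A ``beta`` entry may replace
    ``odds_ratio``, in which case the column is exponentiated.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    use_beta = False
    if column_map:
        for key, col in column_map.items():
            if key == "beta":
                use_beta = True
                cmap["odds_ratio"] = col
            elif key in cmap:
                cmap[key] = col
            else:
                raise KeyError(f"unknown column-map key {key!r}")
    raw = pd.read_csv(path, sep=sep)
    for canon, col in cmap.items():
        if col not in raw.columns:
            raise ValueError(f"file lacks column {col!r} (for {canon})")
    stats = pd.DataFrame(
        {
            "snp_id": raw[cmap["snp_id"]].astype(str),
            "effect_allele": raw[cmap["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[cmap["other_allele"]].astype(str).str.upper(),
            "odds_ratio": raw[cmap["odds_ratio"]].astype(float),
            "p_value": raw[cmap["p_value"]].astype(float),
        }
    )
    if use_beta:
        stats["odds_ratio"] = np.exp(stats["odds_ratio"])
    return validate_summary_stats(stats)


@dataclass
class GenotypeMatrix:
    """Hard-call dosages with per-SNP counted/alternative allele labels.

    ``dosages`` is samples x SNPs with values in {0, 1, 2} counted on
    ``counted_allele``; NaN marks missing calls.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    counted_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.counted_allele = np.asarray(self.counted_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        n, m = self.dosages.shape
        if n != self.sample_ids.size or m != self.snp_ids.size:
            raise ValueError("dosage matrix shape disagrees with id vectors")
        if self.counted_allele.size != m or self.alt_allele.size != m:
            raise ValueError("allele labels must match the SNP count")
        d = self.dosages
        ok = np.isnan(d) | ((d >= 0) & (d <= 2))
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise KeyError(f"SNPs absent from genotypes: {missing}")
        return np.array([lookup[s] for s in snp_ids], dtype=int)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.snp_index(snp_ids)
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            dosages=self.dosages[:, idx],
            counted_allele=self.counted_allele[idx],
            alt_allele=self.alt_allele[idx],
        )


@dataclass(frozen=True)
class PrunedSnpSet:
    retained: tuple[str, ...]
    r2_threshold: float
    audit: tuple[tuple[str, str, float], ...]  # (removed, retained partner, r2)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.audit), columns=["removed_snp", "retained_partner", "r2"]
        )


@dataclass(frozen=True)
class PolygenicScores:
    sample_ids: np.ndarray
    score: np.ndarray
    n_snps_used: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "score": self.score,
                "n_snps_used": self.n_snps_used,
            }
        )

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name="pgs")


def threshold_by_p(stats: pd.DataFrame, p_threshold: float) -> pd.DataFrame:
    """Keep records with p-value strictly below the threshold (PT)."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must be in (0, 1]")
    out = stats[stats["p_value"] < p_threshold]
    if out.empty:
        raise ValueError(f"no SNPs with p < {p_threshold}")
    return out.reset_index(drop=True)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation over pairwise-complete samples."""
    df = pd.DataFrame(dosages)
    r = df.corr(min_periods=2).to_numpy()
    return r * r


def ld_prune_greedy(
    genotypes: GenotypeMatrix, stats: pd.DataFrame, r2_threshold: float = 0.2
) -> PrunedSnpSet:
    """Greedy LD pruning: ascending p-value, strict r-squared < threshold.

    A SNP is retained iff its r-squared with every already-retained SNP
    is strictly below the threshold; ties on p break by snp_id so the
    result is deterministic.  Constant SNPs have undefined r-squared and
    never veto retention.  Returns an audit of every removal.
    """
    order = stats.sort_values(["p_value", "snp_id"], kind="mergesort")
    snp_ids = list(order["snp_id"])
    idx = genotypes.snp_index(snp_ids)  # raises listing missing ids
    r2 = _pairwise_r2(genotypes.dosages[:, idx])

    retained: list[int] = []
    audit: list[tuple[str, str, float]] = []
    for j in range(len(snp_ids)):
        blocker = None
        for i in retained:
            v = r2[i, j]
            if np.isfinite(v) and v >= r2_threshold:
                blocker = (snp_ids[j], snp_ids[i], float(v))
                break
        if blocker is None:
            retained.append(j)
        else:
            audit.append(blocker)
    return PrunedSnpSet(
        retained=tuple(snp_ids[j] for j in retained),
        r2_threshold=r2_threshold,
        audit=tuple(audit),
    )


def align_alleles(
    genotypes: GenotypeMatrix, stats: pd.DataFrame, strict: bool = True
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Re-count dosages on the GWAS effect allele.

    Per SNP either the counted allele already is the effect allele
    (no-op) or it is the other allele (dosage d -> 2 - d).  Any other
    allele configuration is an error.  Strand-ambiguous pairs (A/T and
    C/G) cannot be oriented without strand information; in strict mode
    they are dropped (from both outputs), otherwise kept as-is when the
    labels match directly.

    Returns the aligned genotypes and the summary-stat rows retained.
    """
    stats = stats.reset_index(drop=True)
    idx = genotypes.snp_index(list(stats["snp_id"]))
    dos = genotypes.dosages[:, idx].copy()
    counted = genotypes.counted_allele[idx].copy()
    alt = genotypes.alt_allele[idx].copy()

    keep = np.ones(len(stats), dtype=bool)
    for j, row in stats.iterrows():
        ea, oa = row["effect_allele"], row["other_allele"]
        pair = frozenset((ea, oa))
        geno_pair = frozenset((counted[j], alt[j]))
        if geno_pair != pair:
            raise ValueError(
                f"{row['snp_id']}: allele pair {sorted(geno_pair)} in genotypes "
                f"does not match {sorted(pair)} in summary statistics"
            )
        if pair in AMBIGUOUS_PAIRS and strict:
            keep[j] = False
            continue
        if counted[j] == ea:
            continue
        # counted allele is the other allele: complement the count
        dos[:, j] = 2.0 - dos[:, j]
        counted[j], alt[j] = ea, oa
    aligned = GenotypeMatrix(
        sample_ids=genotypes.sample_ids,
        snp_ids=np.asarray(list(stats["snp_id"]), dtype=object)[keep],
        dosages=dos[:, keep],
        counted_allele=counted[keep],
        alt_allele=alt[keep],
    )
    return aligned, stats[keep].reset_index(drop=True)


def compute_scores(
    genotypes: GenotypeMatrix,
    stats: pd.DataFrame,
    missing: str = "mean",
    divisor: str = "n_snps",
) -> PolygenicScores:
    """Average ln(OR)-weighted risk-allele counts per sample.

    ``genotypes`` must already be aligned (counted allele = effect
    allele) and restricted/orderable to the thresholded + pruned SNPs in
    ``stats``.  Missing calls are imputed to the per-SNP mean dosage
    (``missing='mean'``, the standard scoring convention) or excluded
    with per-sample renormalisation (``missing='complete'``).
    ``divisor`` is the SNP count ``n_snps`` (default) or the allele
    count ``n_alleles`` (= 2 * n_snps).
    """
    if missing not in ("mean", "complete"):
        raise ValueError("missing must be 'mean' or 'complete'")
    if divisor not in ("n_snps", "n_alleles"):
        raise ValueError("divisor must be 'n_snps' or 'n_alleles'")
    stats = stats.reset_index(drop=True)
    if stats.empty:
        raise ValueError("no SNPs to score")
    sub = genotypes.subset(list(stats["snp_id"]))
    mismatch = sub.counted_allele != stats["effect_allele"].to_numpy(dtype=object)
    if mismatch.any():
        bad = list(sub.snp_ids[mismatch])
        raise ValueError(f"genotypes not aligned to effect alleles for: {bad}")
    w = np.log(stats["odds_ratio"].to_numpy(dtype=float))
    dos = sub.dosages
    called = ~np.isnan(dos)
    if not called.any(axis=0).all():
        bad = list(sub.snp_ids[~called.any(axis=0)])
        raise ValueError(f"SNPs with no called genotypes: {bad}")

    scale = 2.0 if divisor == "n_alleles" else 1.0
    if missing == "mean":
        col_mean = np.nanmean(dos, axis=0)
        filled = np.where(called, dos, col_mean[None, :])
        total = filled @ w
        denom = np.full(sub.n_samples, scale * len(w))
    else:
        total = np.nansum(dos * w[None, :], axis=1)
        n_used = called.sum(axis=1)
        if (n_used == 0).any():
            bad = list(sub.sample_ids[n_used == 0])
            raise ValueError(f"samples with no called SNPs: {bad}")
        denom = scale * n_used.astype(float)
    return PolygenicScores(
        sample_ids=sub.sample_ids,
        score=total / denom,
        n_snps_used=len(w),
    )


# ---------------------------------------------------------------------------
# genotype I/O

def read_dosage_tsv(path, allele_table_path) -> GenotypeMatrix:
    """Dosage TSV (first column sample id, header SNP ids) plus a sidecar
    allele table with columns (snp_id, counted_allele, alt_allele)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    alleles = pd.read_csv(allele_table_path, sep="\t", dtype=str).set_index("snp_id")
    missing = [s for s in df.columns if s not in alleles.index]
    if missing:
        raise ValueError(f"SNPs without allele annotations: {missing}")
    al = alleles.loc[list(df.columns)]
    return GenotypeMatrix(
        sample_ids=df.index.astype(str).to_numpy(dtype=object),
        snp_ids=np.asarray(list(df.columns), dtype=object),
        dosages=df.to_numpy(dtype=float),
        counted_allele=al["counted_allele"].to_numpy(dtype=object),
        alt_allele=al["alt_allele"].to_numpy(dtype=object),
    )


def write_dosage_tsv(genotypes: GenotypeMatrix, path, allele_table_path) -> None:
    pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.snp_ids,
    ).to_csv(path, sep="\t")
    pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "counted_allele": genotypes.counted_allele,
            "alt_allele": genotypes.alt_allele,
        }
    ).to_csv(allele_table_path, sep="\t", index=False)


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid hard calls from a VCF; the counted allele is ALT.

    Multi-allelic records are rejected.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids, counted, alt, rows = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{var.ID or var.POS}: multi-allelic records unsupported")
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        counted.append(var.ALT[0])
        alt.append(var.REF)
        g = var.gt_types.astype(float)  # 0/1/2 = ALT count, 3 = unknown
        g[g == 3] = np.nan
        rows.append(g)
    if not rows:
        raise ValueError("VCF contains no variants")
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=np.asarray(snp_ids, dtype=object),
        dosages=np.column_stack(rows),
        counted_allele=np.asarray(counted, dtype=object),
        alt_allele=np.asarray(alt, dtype=object),
    )


def write_scores_tsv(scores: PolygenicScores, path) -> None:
    scores.to_frame().to_csv(path, sep="\t", index=False)
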