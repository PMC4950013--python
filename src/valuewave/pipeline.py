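"""End-to-end study driver: values + trait + polygenic score -> report.

Mirrors the full analysis: score the value survey (ipsatized type
means), score the trait scale, build the polygenic score (threshold,
align, prune, weighted average), join the three measures on sample ids
(inner join, logged), correlate each external variable (trait and
polygenic score) with the 10 value types in circular order, fit the
constrained sinusoid to each profile, and report each SFI with its
empirical p-value against a Monte-Carlo null calibration, plus the
trait-score Pearson correlation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from valuewave import polygenic, value_processing as vp
from valuewave.calibration import (
    CalibrationTable,
    DEFAULT_THRESHOLDS,
    NullSpec,
    calibrate,
    empirical_pvalue,
)
from valuewave.sine_fit import (
    DEFAULT_VALUE_ORDER,
    CorrelationProfile,
    SineFitResult,
    correlate_profile,
    fit_sine,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScaleFileSpec:
    """On-disk scale description: items, reverse keys, rating range."""

    label: str
    items: tuple[str, ...]
    reverse_keyed: tuple[str, ...]
    scale_range: tuple[float, float]

    @classmethod
    def from_json(cls, path) -> "ScaleFileSpec":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            label=d.get("label", "scale"),
            items=tuple(d["items"]),
            reverse_keyed=tuple(d.get("reverse_keyed", ())),
            scale_range=tuple(d["scale_range"]),
        )


@dataclass(frozen=True)
class StudyConfig:
    responses_path: str
    item_map_path: str
    scale_spec_path: str
    sumstats_path: str
    genotypes_path: str
    genotype_format: str = "dosage"  # "dosage" | "vcf"
    allele_table_path: str | None = None  # required for dosage format
    sumstats_column_map: dict | None = None
    p_threshold: float = 0.5
    r2_threshold: float = 0.2
    order: tuple[str, ...] = DEFAULT_VALUE_ORDER
    null: NullSpec = field(default_factory=lambda: NullSpec(n_samples=10_000))
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.genotype_format not in ("dosage", "vcf"):
            raise ValueError("genotype_format must be 'dosage' or 'vcf'")
        if self.genotype_format == "dosage" and not self.allele_table_path:
            raise ValueError("dosage format needs allele_table_path")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted ascending")

    def content_hash(self) -> str:
        d = asdict(self)
        d["null"] = asdict(self.null)
        d.pop("outdir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "null" in d:
            d["null"] = NullSpec(**d["null"])
        for key in ("order", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StudyReport:
    profiles: dict  # name -> CorrelationProfile
    fits: dict  # name -> SineFitResult
    pvalues: dict  # name -> (p, mc_se)
    trait_score_r: float
    trait_score_p: float
    n_joined: int
    n_snps_used: int
    calibration: CalibrationTable
    config_hash: str
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_joined": self.n_joined,
            "n_snps_used": self.n_snps_used,
            "trait_score_r": self.trait_score_r,
            "trait_score_p": self.trait_score_p,
            "profiles": {
                name: {
                    "labels": list(p.labels),
                    "r": [float(v) for v in p.y],
                }
                for name, p in self.profiles.items()
            },
            "fits": {name: f.to_dict() for name, f in self.fits.items()},
            "empirical_p": {
                name: {"p": p, "mc_se": se}
                for name, (p, se) in self.pvalues.items()
            },
            "calibration": self.calibration.to_frame().to_dict("records"),
        }


def _read_genotypes(config: StudyConfig) -> polygenic.GenotypeMatrix:
    if config.genotype_format == "vcf":
        return polygenic.read_vcf(config.genotypes_path)
    return polygenic.read_dosage_tsv(
        config.genotypes_path, config.allele_table_path
    )


def run_full_analysis(config: StudyConfig) -> StudyReport:
    """Run the whole study; write report files if an outdir is set."""
    responses = vp.read_responses(config.responses_path)
    item_map = vp.read_item_map(config.item_map_path)
    scale = ScaleFileSpec.from_json(config.scale_spec_path)

    centered = vp.ipsatize(responses)
    value_scores = vp.aggregate_value_types(centered, item_map)
    trait = vp.score_scale(
        responses,
        vp.ScaleSpec(
            item_ids=scale.items,
            reverse_keyed=frozenset(scale.reverse_keyed),
            label=scale.label,
        ),
        scale.scale_range,
    )

    stats = polygenic.read_summary_stats(
        config.sumstats_path, config.sumstats_column_map
    )
    genotypes = _read_genotypes(config)
    kept = polygenic.threshold_by_p(stats, config.p_threshold)
    aligned, kept = polygenic.align_alleles(genotypes, kept, strict=True)
    pruned = polygenic.ld_prune_greedy(aligned, kept, config.r2_threshold)
    kept = kept[kept["snp_id"].isin(pruned.retained)]
    scores = polygenic.compute_scores(aligned, kept)
    pgs = scores.to_series()

    common = value_scores.index.intersection(trait.index).intersection(
        pd.Index(pgs.index.astype(str))
    )
    logger.info(
        "joined %d samples (values %d, trait %d, genotypes %d)",
        len(common), len(value_scores), len(trait), len(pgs),
    )
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} samples carry all three measures; "
            "correlations undefined"
        )
    value_scores = value_scores.loc[common]
    # z-standardize the externals for reporting (correlations unchanged)
    t = trait.loc[common].astype(float)
    g = pgs.loc[common].astype(float)
    t = (t - t.mean()) / t.std(ddof=1)
    g = (g - g.mean()) / g.std(ddof=1)

    r, p_r = pearsonr(t.to_numpy(), g.to_numpy())

    profiles = {
        "trait": correlate_profile(value_scores, t, config.order),
        "pgs": correlate_profile(value_scores, g, config.order),
    }
    fits = {name: fit_sine(prof) for name, prof in profiles.items()}

    table = calibrate(config.null, config.thresholds)
    pvalues = {
        name: empirical_pvalue(fit.sfi, table) for name, fit in fits.items()
    }

    report = StudyReport(
        profiles=profiles,
        fits=fits,
        pvalues=pvalues,
        trait_score_r=float(r),
        trait_score_p=float(p_r),
        n_joined=int(len(common)),
        n_snps_used=scores.n_snps_used,
        calibration=table,
        config_hash=config.content_hash(),
        seed=config.seed,
    )
    if config.outdir:
        _write_report(report, config, scores, pruned)
    return report


def _write_report(report: StudyReport, config: StudyConfig,
                  scores: polygenic.PolygenicScores,
                  pruned: polygenic.PrunedSnpSet) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
    for name, prof in report.profiles.items():
        df = prof.to_frame()
        df["fitted"] = report.fits[name].fitted
        df.to_csv(out / f"profile_{name}.tsv", sep="\t", index=False)
    report.calibration.to_frame().to_csv(
        out / "calibration.tsv", sep="\t", index=False
    )
    polygenic.write_scores_tsv(scores, out / "polygenic_scores.tsv")
    pruned.audit_frame().to_csv(out / "prune_audit.tsv", sep="\t", index=False)


def refit_excluding(
    profile: CorrelationProfile, drop_label: str, **fit_kwargs
) -> SineFitResult:
    """Re-fit after removing one value type.

    The remaining K-1 points re-index contiguously to 1..K-1 and the
    frequency bounds rescale to the new K (the circle is treated as
    closing over the remaining values).
    """
    return fit_sine(profile.drop(drop_label), **fit_kwargs)
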