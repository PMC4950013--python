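"""Synthetic cohorts with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* ``gen_value_responses`` — survey ratings whose 56 items load on a
  two-dimensional circumplex: each item of a value type at angle theta
  scores loading*(cos(theta)*F1 + sin(theta)*F2) + noise on two latent
  participant factors, so inter-type correlations decay as the cosine
  of angular distance; latents are mapped affinely onto the -1..7
  rating grid and rounded.
* ``gen_external_trait`` — a trait whose population correlations with
  the 10 ipsatized value-type scores follow a prescribed sinusoid
  (weights solved through the observed value-score correlation matrix).
* ``gen_genotypes_with_trait`` — independent binomial hard-call
  genotypes with GWAS-style summary statistics and a trait constructed
  to have a target Pearson correlation with the resulting polygenic
  score (defaults emulate the reported score-trait correlation of 0.22,
  at cohort scale).

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from valuewave import polygenic
from valuewave.sine_fit import DEFAULT_VALUE_ORDER, SineParams, sine_model
from valuewave.value_processing import (
    VALUE_TYPE_ITEM_COUNTS,
    ValueItemMap,
    default_item_map,
)

#: Allele pairs that are unambiguous across strands.
_SAFE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))


def default_type_angles() -> dict[str, float]:
    """Equally spaced angles (radians) in the circular value order."""
    k = len(DEFAULT_VALUE_ORDER)
    return {
        vt: 2.0 * math.pi * i / k for i, vt in enumerate(DEFAULT_VALUE_ORDER)
    }


@dataclass(frozen=True)
class CircumplexSpec:
    """Generative model of circumplex-structured survey responses.

    ``loading`` and ``noise_sd`` set the item communality: two items of
    types separated by angle delta correlate
    loading^2*cos(delta) / (loading^2 + noise_sd^2) in the latent
    metric.  The defaults give moderate-to-good internal consistency
    per type, matching a typical value survey.  ``spread`` scales the
    latent (unit-variance) item score onto the -1..7 grid around the
    midpoint 3 before rounding and clamping.
    """

    type_angles: dict = field(default_factory=default_type_angles)
    items_per_type: dict = field(
        default_factory=lambda: dict(VALUE_TYPE_ITEM_COUNTS)
    )
    n_unassigned: int = 2
    loading: float = 1.0
    noise_sd: float = 1.3
    spread: float = 1.8
    n_participants: int = 81
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.loading <= 1:
            raise ValueError("loading must be in [0, 1]")
        angles = list(self.type_angles.values())
        if len(set(np.round(angles, 12))) != len(angles):
            raise ValueError("type angles must be distinct")

    def item_map(self) -> ValueItemMap:
        assignments: dict[str, str | None] = {}
        pos = 1
        for vt, k in self.items_per_type.items():
            for _ in range(k):
                assignments[f"svs{pos:02d}"] = vt
                pos += 1
        for _ in range(self.n_unassigned):
            assignments[f"svs{pos:02d}"] = None
            pos += 1
        return ValueItemMap(assignments)

    def latent_type_correlation(self, type_a: str, type_b: str) -> float:
        """Closed-form correlation of two *type mean* scores (continuous,
        pre-rounding, pre-ipsatization)."""
        l2 = self.loading**2
        s2 = self.noise_sd**2
        ka = self.items_per_type[type_a]
        kb = self.items_per_type[type_b]
        delta = self.type_angles[type_a] - self.type_angles[type_b]
        cov = l2 * math.cos(delta) if type_a != type_b else l2
        va = l2 + s2 / ka
        vb = l2 + s2 / kb
        if type_a == type_b:
            return 1.0
        return cov / math.sqrt(va * vb)


def gen_value_responses(spec: CircumplexSpec) -> pd.DataFrame:
    """Simulate the participants x items rating table.

    Items of a type share that type's angle on the circle; the two
    unassigned items are independent noise of the same marginal
    variance.  Continuous scores are standardized, scaled by ``spread``,
    shifted to the grid midpoint 3, rounded, and clamped to -1..7.
    """
    rng = np.random.default_rng(spec.seed)
    imap = spec.item_map()
    items = list(imap.assignments)
    n = spec.n_participants
    f = rng.standard_normal((n, 2))
    total_sd = math.sqrt(spec.loading**2 + spec.noise_sd**2)

    cols = {}
    for item in items:
        vt = imap.assignments[item]
        eps = rng.standard_normal(n)
        if vt is None:
            latent = total_sd * eps
        else:
            th = spec.type_angles[vt]
            latent = (
                spec.loading * (math.cos(th) * f[:, 0] + math.sin(th) * f[:, 1])
                + spec.noise_sd * eps
            )
        z = latent / total_sd
        ratings = np.clip(np.round(3.0 + spec.spread * z), -1, 7)
        cols[item] = ratings
    idx = pd.Index([f"p{i + 1:04d}" for i in range(n)], name="participant_id")
    return pd.DataFrame(cols, index=idx)


@dataclass(frozen=True)
class TraitSimSpec:
    """Target sinusoidal correlation profile for a simulated trait.

    ``target_sine`` gives the intended population correlation of the
    trait with the value type at position k as a + b*sin(c*k + d); the
    implied correlations must be feasible (|a| + |b| <= 1).
    ``residual_sd`` sets the scale of the trait's unexplained part (the
    achieved correlations do not depend on it).
    """

    target_sine: SineParams
    residual_sd: float = 1.0
    seed: int = 0
    max_residual: float = 0.05  # tolerated |target - achievable| per type

    def __post_init__(self):
        if abs(self.target_sine.a) + abs(self.target_sine.b) > 1:
            raise ValueError("infeasible target: |a| + |b| must be <= 1")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def gen_external_trait(
    value_scores: pd.DataFrame,
    spec: TraitSimSpec,
    order=DEFAULT_VALUE_ORDER,
) -> pd.Series:
    """Simulate a trait with a sinusoidal value-correlation profile.

    With Z the standardized value-type scores and R their sample
    correlation matrix, weights w are solved from R w ∝ rho (rho the
    target profile) so that corr(w'Z + residual, Z_k) equals the
    projection of rho onto the achievable space; if that projection
    misses any target correlation by more than ``max_residual`` (the
    targets are infeasible under the observed value covariance) an
    error reports the least-squares residual.
    """
    rng = np.random.default_rng(spec.seed)
    vs = value_scores[list(order)].astype(float)
    Z = (vs - vs.mean()) / vs.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    x = np.arange(1, len(order) + 1, dtype=float)
    rho = np.asarray(sine_model(x, spec.target_sine))

    u, *_ = np.linalg.lstsq(R, rho, rcond=None)
    rho_hat = R @ u
    resid = float(np.max(np.abs(rho_hat - rho)))
    v = float(rho @ u)  # = u' R u, implied R^2 of the trait on Z
    if v >= 1.0 or resid > spec.max_residual:
        raise ValueError(
            "target correlation profile infeasible under the observed "
            f"value-score covariance (implied R^2 = {v:.3f}, max "
            f"least-squares residual = {resid:.4f})"
        )
    alpha = spec.residual_sd / math.sqrt(1.0 - v)
    w = alpha * u
    noise = spec.residual_sd * rng.standard_normal(len(vs))
    trait = Z.to_numpy() @ w + noise
    return pd.Series(trait, index=vs.index, name="trait")


@dataclass(frozen=True)
class GenoSimSpec:
    """Genotype/summary-statistic/trait generator settings.

    Independent binomial SNPs by default; ``block_size`` > 1 turns on a
    Gaussian-copula AR(1) haplotype structure within consecutive blocks
    (correlation ``block_r``) solely to exercise LD pruning.  Effect
    sizes ln(OR) are normal(0, ``effect_sd``); p-values are assigned
    consistently with effect magnitude as the two-sided normal tail of
    ln(OR)/effect_sd.  The trait is built as
    z(score)*target_rho + sqrt(1 - target_rho^2)*noise from the
    polygenic score the pipeline itself would compute (threshold,
    align, prune, average), so the target is the population score-trait
    correlation.
    """

    n_samples: int = 81
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    target_rho: float = 0.22
    effect_sd: float = 0.05
    missing_rate: float = 0.0
    block_size: int = 1
    block_r: float = 0.0
    p_threshold: float = 0.5
    r2_threshold: float = 0.2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0.01, 0.5]")
        if not abs(self.target_rho) < 1:
            raise ValueError("|target_rho| must be < 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _draw_dosages(spec: GenoSimSpec, rng: np.random.Generator,
                  maf: np.ndarray) -> np.ndarray:
    n, m = spec.n_samples, spec.n_snps
    if spec.block_size <= 1 or spec.block_r == 0.0:
        return rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    # AR(1) Gaussian copula across SNPs within blocks, per haplotype
    dos = np.zeros((n, m))
    for _hap in range(2):
        z = np.empty((n, m))
        for j in range(m):
            e = rng.standard_normal(n)
            if j % spec.block_size == 0:
                z[:, j] = e
            else:
                z[:, j] = (
                    spec.block_r * z[:, j - 1]
                    + math.sqrt(1 - spec.block_r**2) * e
                )
        dos += (norm.cdf(z) < maf[None, :]).astype(float)
    return dos


def gen_genotypes_with_trait(
    spec: GenoSimSpec,
) -> tuple[polygenic.GenotypeMatrix, pd.DataFrame, pd.Series]:
    """Simulate genotypes, GWAS summary statistics, and a matched trait.

    Returns ``(genotypes, summary_stats, trait)``.  Half the SNPs are
    stored counted on the GWAS *other* allele so that allele alignment
    is exercised downstream; allele pairs avoid strand-ambiguous
    (palindromic) combinations.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_snps
    maf = rng.uniform(*spec.maf_range, size=m)
    dos_effect = _draw_dosages(spec, rng, maf)  # counted on effect allele

    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        dos_effect = np.where(mask, np.nan, dos_effect)

    if spec.effect_sd > 0:
        ln_or = rng.normal(0.0, spec.effect_sd, size=m)
        p = 2.0 * norm.sf(np.abs(ln_or) / spec.effect_sd)
    else:
        # all-null effects: every weight is ln(1) = 0, p carries no signal
        ln_or = np.zeros(m)
        p = rng.uniform(0.0, 1.0, size=m)
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    swap = rng.random(m) < 0.5
    eff = np.array([_SAFE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oth = np.array([_SAFE_PAIRS[i][1] for i in pair_idx], dtype=object)
    eff[swap], oth[swap] = oth[swap], eff[swap].copy()

    snp_ids = np.array([f"rs{j + 1:06d}" for j in range(m)], dtype=object)
    stats = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": eff,
            "other_allele": oth,
            "odds_ratio": np.exp(ln_or),
            "p_value": p,
        }
    )

    # store half the SNPs counted on the other allele (flip dosage + labels)
    flip = rng.random(m) < 0.5
    dosages = dos_effect.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    counted = np.where(flip, oth, eff).astype(object)
    alt = np.where(flip, eff, oth).astype(object)
    genotypes = polygenic.GenotypeMatrix(
        sample_ids=np.array([f"s{i + 1:05d}" for i in range(n)], dtype=object),
        snp_ids=snp_ids,
        dosages=dosages,
        counted_allele=counted,
        alt_allele=alt,
    )

    # compute the score exactly as the pipeline will, then mix the trait
    kept = polygenic.threshold_by_p(stats, spec.p_threshold)
    aligned, kept = polygenic.align_alleles(genotypes, kept, strict=True)
    pruned = polygenic.ld_prune_greedy(aligned, kept, spec.r2_threshold)
    kept = kept[kept["snp_id"].isin(pruned.retained)]
    scores = polygenic.compute_scores(aligned, kept)
    s = scores.score
    sd = s.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "polygenic score is constant (all effects zero?); "
            "score-trait correlation undefined"
        )
    z = (s - s.mean()) / sd
    trait = spec.target_rho * z + math.sqrt(
        1.0 - spec.target_rho**2
    ) * rng.standard_normal(n)
    return genotypes, stats, pd.Series(trait, index=genotypes.sample_ids, name="trait")


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic study cohort.

    One set of participants with survey responses (56 circumplex value
    items plus a keyed trait scale), genotypes with GWAS summary
    statistics, and both external variables carrying a planted
    sinusoidal correlation profile over the value circle.  The genotype
    samples are rank-matched on the polygenic score to the intended
    genetic liability so the score inherits the planted profile.
    Defaults follow the study scale: 81 participants, a profile
    amplitude of ~0.22 centred on zero with its trough at the openness
    values, and a score-liability link at the reported magnitude.
    """

    n_participants: int = 81
    circumplex: CircumplexSpec | None = None
    profile_sine: SineParams = SineParams(a=0.0, b=0.22, c=0.9 * 2 * math.pi / 10, d=1.6)
    scale_items: int = 10
    scale_range: tuple[int, int] = (1, 5)
    scale_loading: float = 0.8
    geno: GenoSimSpec | None = None
    seed: int = 0

    def resolved(self) -> tuple[CircumplexSpec, GenoSimSpec]:
        circ = self.circumplex or CircumplexSpec(
            n_participants=self.n_participants, seed=self.seed
        )
        geno = self.geno or GenoSimSpec(
            n_samples=self.n_participants, seed=self.seed + 1
        )
        if circ.n_participants != self.n_participants:
            raise ValueError("circumplex spec disagrees on participant count")
        if geno.n_samples != self.n_participants:
            raise ValueError("genotype spec disagrees on sample count")
        return circ, geno


@dataclass
class Cohort:
    responses: pd.DataFrame          # value items + scale items, one row per participant
    item_map: ValueItemMap
    scale_item_ids: tuple[str, ...]
    scale_reverse_keyed: tuple[str, ...]
    scale_range: tuple[int, int]
    genotypes: polygenic.GenotypeMatrix  # sample ids = participant ids
    summary_stats: pd.DataFrame
    value_scores: pd.DataFrame       # ipsatized type scores (convenience)
    liability: pd.Series             # the planted genetic liability


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate a coherent cohort for the full pipeline.

    Steps: circumplex value responses -> ipsatized type scores; a latent
    liability with the planted sinusoidal value-correlation profile; a
    keyed trait scale whose items load on that liability; genotypes and
    summary statistics whose polygenic score is rank-matched to the
    liability (so both the questionnaire trait and the score correlate
    sinusoidally with the value circle).
    """
    from valuewave import value_processing as vp

    circ, geno = spec.resolved()
    rng = np.random.default_rng(spec.seed + 2)

    responses = gen_value_responses(circ)
    imap = circ.item_map()
    value_scores = vp.aggregate_value_types(vp.ipsatize(responses), imap)

    # separate liability draws for the questionnaire trait and the
    # genetic score: both carry the planted sinusoidal profile, but they
    # share only the value-structured component (their residuals are
    # independent), which keeps the trait-score correlation moderate as
    # in a real cohort rather than near 1
    liability = gen_external_trait(
        value_scores, TraitSimSpec(spec.profile_sine, seed=spec.seed + 3)
    )
    scale_liability = gen_external_trait(
        value_scores, TraitSimSpec(spec.profile_sine, seed=spec.seed + 4)
    )
    z = (scale_liability - scale_liability.mean()) / scale_liability.std(ddof=1)

    # keyed trait scale: items load on the liability, half reverse-keyed
    lo, hi = spec.scale_range
    mid = 0.5 * (lo + hi)
    half_span = 0.5 * (hi - lo)
    lam = spec.scale_loading
    scale_ids, reverse = [], []
    scale_cols = {}
    for i in range(spec.scale_items):
        item = f"emo{i + 1:02d}"
        latent = lam * z.to_numpy() + math.sqrt(1 - lam**2) * rng.standard_normal(len(z))
        rating = np.clip(np.round(mid + 0.8 * half_span * latent), lo, hi)
        if i % 2 == 1:
            rating = lo + hi - rating
            reverse.append(item)
        scale_ids.append(item)
        scale_cols[item] = rating
    responses = pd.concat(
        [responses, pd.DataFrame(scale_cols, index=responses.index)], axis=1
    )

    genotypes, stats, _ = gen_genotypes_with_trait(geno)
    kept = polygenic.threshold_by_p(stats, geno.p_threshold)
    aligned, kept = polygenic.align_alleles(genotypes, kept, strict=True)
    pruned = polygenic.ld_prune_greedy(aligned, kept, geno.r2_threshold)
    kept = kept[kept["snp_id"].isin(pruned.retained)]
    score = polygenic.compute_scores(aligned, kept).score

    # rank-match genotype samples to the genetic liability: the sample
    # with the r-th smallest score becomes the participant with the r-th
    # smallest liability (preserves the score's marginal distribution)
    z_gene = liability.to_numpy()
    part_by_rank = value_scores.index.to_numpy()[np.argsort(z_gene, kind="stable")]
    sample_rank = np.argsort(np.argsort(score, kind="stable"), kind="stable")
    matched_ids = part_by_rank[sample_rank]
    genotypes = polygenic.GenotypeMatrix(
        sample_ids=matched_ids.astype(object),
        snp_ids=genotypes.snp_ids,
        dosages=genotypes.dosages,
        counted_allele=genotypes.counted_allele,
        alt_allele=genotypes.alt_allele,
    )
    return Cohort(
        responses=responses,
        item_map=imap,
        scale_item_ids=tuple(scale_ids),
        scale_reverse_keyed=tuple(reverse),
        scale_range=spec.scale_range,
        genotypes=genotypes,
        summary_stats=stats,
        value_scores=value_scores,
        liability=liability,
    )


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write a cohort in the exact formats the pipeline reads.

    Returns the dict of file paths (also usable as a StudyConfig seed).
    """
    import json
    from pathlib import Path

    from valuewave import value_processing as vp

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "responses_path": str(out / "responses.csv"),
        "item_map_path": str(out / "item_map.tsv"),
        "scale_spec_path": str(out / "scale_spec.json"),
        "sumstats_path": str(out / "sumstats.tsv"),
        "genotypes_path": str(out / "dosages.tsv"),
        "allele_table_path": str(out / "alleles.tsv"),
    }
    cohort.responses.to_csv(paths["responses_path"])
    vp.write_item_map(cohort.item_map, paths["item_map_path"])
    with open(paths["scale_spec_path"], "w") as fh:
        json.dump(
            {
                "label": "trait",
                "items": list(cohort.scale_item_ids),
                "reverse_keyed": list(cohort.scale_reverse_keyed),
                "scale_range": list(cohort.scale_range),
            },
            fh,
            indent=2,
        )
    cohort.summary_stats.rename(
        columns={"snp_id": "SNP", "effect_allele": "A1", "other_allele": "A2",
                 "odds_ratio": "OR", "p_value": "P"}
    ).to_csv(paths["sumstats_path"], sep="\t", index=False)
    polygenic.write_dosage_tsv(
        cohort.genotypes, paths["genotypes_path"], paths["allele_table_path"]
    )
    return paths
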