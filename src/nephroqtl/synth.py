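"""Synthetic two-cohort genotype / expression / trait generator.

Emulates the study design the rest of the package is built for: two kidney
cohorts (default 180 and 100 samples) genotyped on a shared variant panel with
block-structured linkage disequilibrium, expression with planted cis effects
plus covariate and hidden-factor structure, a quantitative trait driven
through one eGene (shared-causal vs distinct-causal colocalisation
scenarios), and two-sample MR summary statistics with configurable
pleiotropy.  Every planted quantity is recorded in a :class:`GroundTruth` so
downstream recovery can be scored without any external data.

Genome layout: all variants sit on one synthetic chromosome.  Each LD block
holds ``snps_per_block`` variants whose haplotypes share an equicorrelated
latent Gaussian (a threshold copula), so within-block genotype correlation is
close to ``within_block_r`` and variants in different blocks are independent.
Gene *g* is centred on block *g*; a 1 Mb cis window therefore spans the
gene's own block (where any planted causal variant lives) plus several
independent neighbouring blocks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

# layout constants (bp); one block spans SNP_SPACING * snps_per_block,
# blocks are separated so that a 1 Mb window covers a handful of them
SNP_SPACING = 5_000
BLOCK_STRIDE = 150_000
GENE_LENGTH = 10_000
CHROM = "1"


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Cohort sizes default to the two-study design (180 and 100).  Effects are
    in units of residual expression SD per alternate allele.  ``frac_egenes``
    defaults to 0.2, close to the one-in-five genes under detectable cis
    control that motivates the whole analysis.
    """

    seed: int = 0
    n_samples_study1: int = 180
    n_samples_study2: int = 100
    n_blocks: int = 50
    snps_per_block: int = 10
    within_block_r: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    n_genes: int = 50
    frac_egenes: float = 0.2
    effect_size_sd: float = 0.5
    fixed_effect_size: float | None = None
    n_hidden_factors: int = 2
    hidden_factor_sd: float = 0.5
    noise_sd: float = 1.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.2}
    )
    expression_scale: str = "tpm"  # "tpm" (2**latent) or "sd" (latent linear model)
    between_study_effect_jitter: float = 0.0

    def __post_init__(self):
        for name in (
            "n_samples_study1", "n_samples_study2", "n_blocks",
            "snps_per_block", "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must be in [0, 1)")
        if not (0 <= self.frac_egenes <= 1):
            raise ValueError("frac_egenes must be in [0, 1]")
        if self.n_genes > self.n_blocks:
            raise ValueError("n_genes may not exceed n_blocks (one gene per block)")
        if self.expression_scale not in ("tpm", "sd"):
            raise ValueError("expression_scale must be 'tpm' or 'sd'")

    @property
    def n_samples(self) -> int:
        return self.n_samples_study1 + self.n_samples_study2


@dataclass
class GroundTruth:
    """Planted quantities: one row of provenance per downstream claim."""

    planted_pairs: list  # of (gene_id, snp_id, beta)
    trait_model: dict | None = None  # driver_gene, causal_snp, effect, scenario
    mr_truth: dict | None = None  # theta, pleiotropy_mean, pleiotropy_sd, invalid_frac
    hidden_factors: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "planted_pairs": [
                {"gene": g, "snp": s, "beta": float(b)}
                for g, s, b in self.planted_pairs
            ],
            "trait_model": self.trait_model,
            "mr_truth": self.mr_truth,
        }
        return json.dumps(payload, indent=2)


def _variant_table(config: SimulationConfig) -> pd.DataFrame:
    ids, chroms, poss, blocks = [], [], [], []
    for b in range(config.n_blocks):
        start = 1 + b * BLOCK_STRIDE
        for j in range(config.snps_per_block):
            ids.append(f"rs{b:04d}_{j:02d}")
            chroms.append(CHROM)
            poss.append(start + j * SNP_SPACING)
            blocks.append(b)
    return pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": "A", "alt": "G", "block": blocks},
        index=pd.Index(ids, name="snp"),
    )


def gene_table(config: SimulationConfig) -> pd.DataFrame:
    """One gene per block, centred on the block's variants (1-based, inclusive)."""
    span = SNP_SPACING * (config.snps_per_block - 1)
    rows = {}
    for g in range(config.n_genes):
        block_start = 1 + g * BLOCK_STRIDE
        centre = block_start + span // 2
        rows[f"gene{g:04d}"] = (CHROM, centre - GENE_LENGTH // 2,
                                centre + GENE_LENGTH // 2)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "start", "end"]
    )
    out.index.name = "gene"
    return out


def _latent_rho(maf: float, target_r: float) -> float:
    """Latent Gaussian correlation giving allele-level correlation ``target_r``.

    For two alleles thresholded at the same frequency p, corr = (P11 - p^2) /
    (p (1 - p)) with P11 the bivariate-normal orthant probability; solved by
    bisection.  Genotypes (sums of two independent haplotypes) inherit the
    allele-level correlation.
    """
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def attained(rho):
        p11 = stats.multivariate_normal.cdf(
            [t, t], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - maf * maf) / denom - target_r

    from scipy.optimize import brentq

    return float(brentq(attained, 0.0, 1.0 - 1e-9, xtol=1e-6))


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw the shared variant panel and both cohorts' dosages.

    Haplotypes within a block share one allele frequency (tight LD implies
    similar frequencies) and come from an equicorrelated latent Gaussian
    thresholded at that frequency; the latent correlation is calibrated so
    the *genotype* pairwise correlation matches ``within_block_r``.
    Genotypes are in Hardy-Weinberg proportions by construction; variants in
    different blocks are independent.
    """
    if config.n_blocks * config.snps_per_block == 0:
        raise ValueError("degenerate config: zero variants")
    rng = np.random.default_rng([config.seed, 1])
    variants = _variant_table(config)
    n = config.n_samples
    block_mafs = rng.uniform(*config.maf_range, size=config.n_blocks)

    dosage = np.empty((n, len(variants)), dtype=np.int8)
    col = 0
    for b in range(config.n_blocks):
        m = config.snps_per_block
        maf = block_mafs[b]
        rho = _latent_rho(maf, config.within_block_r)
        threshold = stats.norm.ppf(maf)
        # two haplotypes per sample, shared block factor => equicorrelation rho
        shared = rng.standard_normal((2, n, 1))
        indiv = rng.standard_normal((2, n, m))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv
        alleles = (z < threshold).astype(np.int8)
        dosage[:, col:col + m] = alleles[0] + alleles[1]
        col += m

    study = np.array(
        ["S1"] * config.n_samples_study1 + ["S2"] * config.n_samples_study2
    )
    sample_ids = [f"{s}_{i:04d}" for i, s in enumerate(study)]
    samples = pd.DataFrame(
        {
            "study": study,
            "age": np.round(rng.normal(55, 10, size=n), 1),
            "sex": rng.integers(0, 2, size=n),
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    dosages = pd.DataFrame(dosage, index=samples.index, columns=variants.index)
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def simulate_expression(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Expression = intercept + planted beta * dosage + covariates + hidden factors + noise.

    The linear model lives on a latent scale where the residual SD is
    ``noise_sd`` and planted betas are in residual-SD units per allele.  With
    ``expression_scale='tpm'`` the returned matrix is ``2**latent`` (a
    positive, skewed, TPM-like quantity that exercises the full normalisation
    chain); with ``'sd'`` the latent values themselves are returned, so a
    plain regression recovers the planted beta without attenuation.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = gene_table(config)
    n = geno.n_samples
    g_ids = genes.index.to_numpy()

    n_egenes = int(round(config.frac_egenes * config.n_genes))
    egene_idx = rng.choice(config.n_genes, size=n_egenes, replace=False)
    planted = []
    dosage = geno.dosages.to_numpy(dtype=float)
    block_of = geno.variants["block"].to_numpy()

    cov = geno.samples
    age_c = cov["age"].to_numpy() - cov["age"].mean()
    sex = cov["sex"].to_numpy().astype(float)
    eff = config.covariate_effects

    factors = rng.standard_normal((n, config.n_hidden_factors))
    loadings = rng.standard_normal((config.n_hidden_factors, config.n_genes))
    # random sparse loadings: each factor touches ~half the genes
    loadings *= rng.random(loadings.shape) < 0.5

    latent = np.empty((config.n_genes, n))
    study2 = (geno.samples["study"] == "S2").to_numpy()
    for gi in range(config.n_genes):
        mu = rng.normal(5.0, 1.0)
        y = mu + eff.get("age", 0.0) * age_c + eff.get("sex", 0.0) * sex
        if config.n_hidden_factors:
            y = y + config.hidden_factor_sd * factors @ loadings[:, gi]
        if gi in egene_idx:
            snp_candidates = np.where(block_of == gi)[0]
            snp_i = rng.choice(snp_candidates)
            if config.fixed_effect_size is not None:
                beta = float(config.fixed_effect_size)
            else:
                beta = rng.normal(0.0, config.effect_size_sd)
            b = np.full(n, beta)
            if config.between_study_effect_jitter:
                b = b + study2 * rng.normal(0, config.between_study_effect_jitter)
            y = y + b * dosage[:, snp_i]
            planted.append((g_ids[gi], geno.variants.index[snp_i], beta))
        latent[gi] = y + rng.normal(0.0, config.noise_sd, size=n)

    if config.expression_scale == "tpm":
        values = np.exp2(latent)
        stage = "tpm"
    else:
        values = latent
        stage = "tpm"  # container stage tag; values are already model-scale
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes.index, columns=geno.dosages.index),
        genes=genes,
        stage=stage,
        batch=geno.samples["study"].rename("batch"),
    )
    truth = GroundTruth(
        planted_pairs=planted,
        hidden_factors=pd.DataFrame(
            factors, index=geno.dosages.index,
            columns=[f"factor{i}" for i in range(config.n_hidden_factors)],
        ),
    )
    return expr, truth


def _gwas_scan(trait: np.ndarray, dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised simple regression of the trait on each variant's dosage."""
    n = trait.shape[0]
    y = trait - trait.mean()
    g = dosage - dosage.mean(axis=0)
    gg = (g * g).sum(axis=0)
    gg = np.where(gg == 0, np.nan, gg)
    beta = (g * y[:, None]).sum(axis=0) / gg
    rss = (y * y).sum() - beta**2 * gg
    df = n - 2
    se = np.sqrt(np.maximum(rss, 0.0) / df / gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p


def simulate_trait(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    truth: GroundTruth,
    scenario: str,
    trait_effect: float = 1.0,
    trait_noise_sd: float = 1.0,
    r2_bound: float = 0.2,
    seed: int | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Quantitative trait plus GWAS summary statistics for one scenario.

    shared   -- trait driven by the driver eGene's expression, so trait and
                expression share the planted causal variant;
    distinct -- trait driven by a second variant inside the driver gene's cis
                window whose r^2 with the expression-causal variant is below
                ``r2_bound`` (drawn from a different LD block);
    null     -- pure noise.
    """
    if scenario not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario != "null" and not truth.planted_pairs:
        raise ValueError("no planted eGene available to drive the trait")
    rng = np.random.default_rng(
        [seed if seed is not None else 0, 3]
    )
    n = geno.n_samples
    dosage = geno.dosages.to_numpy(dtype=float)
    noise = rng.normal(0.0, trait_noise_sd, size=n)

    model: dict | None = None
    if scenario == "null":
        trait = noise
    else:
        # driver = planted eGene with the largest absolute effect
        gene_id, esnp, beta = max(truth.planted_pairs, key=lambda t: abs(t[2]))
        if scenario == "shared":
            e = expr.values.loc[gene_id].to_numpy(dtype=float)
            if expr.stage == "tpm":
                e = np.log2(e + 1.0)
            e = (e - e.mean()) / e.std()
            trait = trait_effect * e + noise
            model = {"driver_gene": gene_id, "causal_snp": esnp,
                     "effect": trait_effect, "scenario": "shared"}
        else:
            gstart, gend = expr.genes.loc[gene_id, ["start", "end"]]
            pos = geno.variants["pos"]
            in_window = (pos >= gstart - 1_000_000) & (pos <= gend + 1_000_000)
            esnp_block = geno.variants.loc[esnp, "block"]
            candidates = geno.variants.index[
                in_window & (geno.variants["block"] != esnp_block)
            ]
            e_dos = geno.dosages[esnp].to_numpy(dtype=float)
            ok = []
            for snp in candidates:
                d = geno.dosages[snp].to_numpy(dtype=float)
                if d.std() == 0:
                    continue
                r = np.corrcoef(e_dos, d)[0, 1]
                if r * r < r2_bound:
                    ok.append(snp)
            if not ok:
                raise ValueError(
                    f"no variant with r^2 < {r2_bound} available in the window"
                )
            tsnp = ok[rng.integers(len(ok))]
            trait = trait_effect * dosage[:, geno.dosages.columns.get_loc(tsnp)] + noise
            model = {"driver_gene": gene_id, "causal_snp": tsnp,
                     "eqtl_snp": esnp, "effect": trait_effect,
                     "scenario": "distinct"}
    truth.trait_model = model if model is not None else {"scenario": "null"}

    beta, se, p = _gwas_scan(trait, dosage)
    gwas = pd.DataFrame(
        {
            "snp": geno.variants.index,
            "chrom": geno.variants["chrom"].to_numpy(),
            "pos": geno.variants["pos"].to_numpy(),
            "effect_allele": geno.variants["alt"].to_numpy(),
            "other_allele": geno.variants["ref"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    ).set_index("snp")
    return pd.Series(trait, index=geno.dosages.index, name="trait"), gwas


def simulate_mr_summary(
    n_instruments: int,
    theta: float,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    se_x: float = 0.05,
    se_y: float = 0.05,
    seed: int = 0,
    invalid_frac: float = 1.0,
) -> pd.DataFrame:
    """Two-sample MR summary data with known causal effect ``theta``.

    True exposure effects are drawn N(0.4, 0.1^2) truncated at 0.1; observed
    exposure effects add N(0, se_x^2) noise; outcome effects are generated
    from the *observed* exposure effects (the standard NOME-satisfying
    shortcut) as ``beta_y = theta * beta_x + alpha + N(0, se_y^2)`` where the
    pleiotropic intercept ``alpha ~ N(pleiotropy_mean, pleiotropy_sd^2)`` hits
    the first ``invalid_frac`` share of instruments and is zero elsewhere.
    """
    if n_instruments < 1:
        raise ValueError("n_instruments must be >= 1")
    rng = np.random.default_rng([seed, 4])
    bx_true = np.maximum(rng.normal(0.4, 0.1, size=n_instruments), 0.1)
    bx = bx_true + rng.normal(0.0, se_x, size=n_instruments)
    alpha = np.zeros(n_instruments)
    n_invalid = int(round(invalid_frac * n_instruments))
    if n_invalid and (pleiotropy_mean != 0 or pleiotropy_sd != 0):
        alpha[:n_invalid] = rng.normal(pleiotropy_mean, pleiotropy_sd, n_invalid)
    by = theta * bx + alpha + rng.normal(0.0, se_y, size=n_instruments)
    out = pd.DataFrame(
        {
            "effect_allele": "G",
            "other_allele": "A",
            "beta_x": bx,
            "se_x": se_x,
            "beta_y": by,
            "se_y": se_y,
        },
        index=pd.Index([f"iv{j:03d}" for j in range(n_instruments)], name="snp"),
    )
    out.attrs["theta"] = theta
    out.attrs["pleiotropy_mean"] = pleiotropy_mean
    out.attrs["pleiotropy_sd"] = pleiotropy_sd
    out.attrs["invalid_frac"] = invalid_frac
    return out


def rtc_intervals(config: SimulationConfig) -> pd.DataFrame:
    """Recombination-coldspot-style intervals: the cis window of each gene.

    Emitted as 0-based half-open BED-like rows (chrom, start, end, name).
    """
    genes = gene_table(config)
    return pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.maximum(genes["start"] - 1_000_000 - 1, 0),
            "end": genes["end"] + 1_000_000,
            "name": ["ivl_" + g for g in genes.index],
        }
    ).reset_index(drop=True)


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    if "maf_range" in d:
        d = dict(d, maf_range=tuple(d["maf_range"]))
    return SimulationConfig(**d)
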