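"""Liability-threshold case-control simulator for gene-level rare-variant studies.

The generative model, per gene:

1. Variant sites get minor-allele frequencies drawn independently from
   Wright's stationary distribution, truncated to the rare-variant window
   (MAF < 0.5%), until the expected per-subject carriage probability is as
   close as possible to 1% per 500 coding base pairs.
2. Each variant gets a deleteriousness class ``D`` in {0,1,2,3} with marginal
   probabilities (0.26, 0.16, 0.36, 0.22) and a sign, +1 (risk increasing)
   with probability ``zeta``.
3. Per subject, carriage of each variant is Bernoulli in its frequency; a
   subject carrying several variants retains only the most deleterious one
   (first in gene order on ties). The latent trait is

       Z = delta * s * d + gamma * C + eps,

   with ``d`` the retained class (linear scenario) or its indicator
   (magnitude scenario), ``C ~ N(0,1)`` a covariate explaining ``Rsq`` of
   the trait variance (see ``SimulationConfig.gamma_sq`` for the scale
   convention), and ``eps ~ N(0, 1-gamma^2)``, so ``Var(Z) = 1`` for
   non-carriers.
4. A subject is a case iff ``Z`` exceeds the ``1-K`` quantile of ``N(0,1)``;
   subjects are generated until the case/control quotas are filled
   (retrospective ascertainment).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "WrightParams",
    "VariantSite",
    "GeneModel",
    "SimulationConfig",
    "Cohort",
    "sample_wright_frequency",
    "sample_wright_frequencies",
    "build_gene",
    "simulate_population",
    "simulate_cohort",
    "export_cohort",
]

#: Marginal distribution of the true deleteriousness class of a variant,
#: classes 0 (benign) through 3 (very deleterious).
DEFAULT_CLASS_PROBS = (0.26, 0.16, 0.36, 0.22)


class AscertainmentError(RuntimeError):
    """Raised when case/control quotas cannot be filled within the subject cap."""


@dataclass(frozen=True)
class WrightParams:
    """Hyper-priors for Wright's stationary allele-frequency distribution.

    The density is ``psi(p) ~ p**(beta1-1) * (1-p)**(beta2-1) * exp(sigma*(1-p))``
    truncated to ``[maf_lower, maf_upper)``.  ``beta1`` and ``beta2`` are drawn
    uniformly from their ranges per variant; ``sigma`` is 0 with probability
    ``sigma_zero_prob`` and otherwise uniform on ``sigma_range``.
    """

    beta1_range: tuple[float, float] = (0.001, 0.003)
    beta2_range: tuple[float, float] = (1.0, 5.0)
    sigma_zero_prob: float = 0.5
    sigma_range: tuple[float, float] = (0.0, 20.0)
    maf_upper: float = 0.005
    maf_lower: float = 1.0 / 20000.0
    grid_points: int = 512

    def __post_init__(self) -> None:
        for name in ("beta1_range", "beta2_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be ordered low <= high, got {(lo, hi)}")
        if not (0.0 < self.maf_lower < self.maf_upper <= 0.5):
            raise ValueError(
                f"need 0 < maf_lower < maf_upper <= 0.5, got "
                f"({self.maf_lower}, {self.maf_upper})"
            )
        if not 0.0 <= self.sigma_zero_prob <= 1.0:
            raise ValueError("sigma_zero_prob must be a probability")
        if self.grid_points < 2:
            raise ValueError("grid_points must be >= 2")


@dataclass(frozen=True)
class VariantSite:
    """One simulated variant: frequency, deleteriousness class, effect sign."""

    maf: float
    damage_class: int
    sign: int

    def __post_init__(self) -> None:
        if self.damage_class not in (0, 1, 2, 3):
            raise ValueError(f"damage_class must be in 0..3, got {self.damage_class}")
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")


@dataclass(frozen=True)
class GeneModel:
    """A simulated gene: CDS length plus its variant sites.

    ``target_carriage`` is the calibration target 0.01 * cds_length / 500; the
    realised expected carriage ``1 - prod(1 - maf_j)`` is the closest value
    achievable under the sequential stopping rule.
    """

    cds_length: float
    variants: tuple[VariantSite, ...]
    target_carriage: float

    @property
    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])

    @property
    def damage_classes(self) -> np.ndarray:
        return np.array([v.damage_class for v in self.variants], dtype=np.int64)

    @property
    def signs(self) -> np.ndarray:
        return np.array([v.sign for v in self.variants], dtype=np.int64)

    @property
    def expected_carriage(self) -> float:
        """Probability a subject carries at least one variant."""
        return 1.0 - float(np.prod(1.0 - self.mafs))


@dataclass(frozen=True)
class SimulationConfig:
    """All design parameters for one simulated case-control study."""

    n_cases: int = 1000
    n_controls: int = 1000
    prevalence: float = 0.1
    rsq: float = 0.0
    delta: float = 0.0
    zeta: float = 0.5
    cds_length: float = 1209.0
    scenario: str = "linear"
    #: scale on which ``rsq`` is stated: "binary" (fraction of observed
    #: binary-trait variance explained by the covariate, converted internally
    #: to a liability-scale coefficient) or "liability" (gamma^2 = rsq
    #: directly on the latent scale)
    rsq_scale: str = "binary"
    class_probs: tuple[float, float, float, float] = DEFAULT_CLASS_PROBS
    wright: WrightParams = field(default_factory=WrightParams)
    seed: int | None = None
    #: Safety cap on generated subjects during ascertainment, as a multiple of
    #: (n_cases + n_controls) / min(K, 1-K).
    ascertainment_cap_factor: float = 200.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not 0.0 <= self.rsq < 1.0:
            raise ValueError("rsq must be in [0, 1)")
        if not 0.0 <= self.zeta <= 1.0:
            raise ValueError("zeta must be a probability")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.scenario not in ("linear", "magnitude"):
            raise ValueError("scenario must be 'linear' or 'magnitude'")
        if self.rsq_scale not in ("binary", "liability"):
            raise ValueError("rsq_scale must be 'binary' or 'liability'")
        if not 0.0 <= self.gamma_sq < 1.0:
            raise ValueError(
                f"covariate coefficient out of range: rsq={self.rsq} on the "
                f"{self.rsq_scale} scale gives liability-scale gamma^2="
                f"{self.gamma_sq:.3f}; must be < 1"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def threshold(self) -> float:
        """Liability threshold: the (1-K) quantile of the null latent N(0,1)."""
        return float(stats.norm.ppf(1.0 - self.prevalence))

    @property
    def gamma_sq(self) -> float:
        """Fraction of latent variance carried by the covariate (gamma^2).

        On the liability scale this is ``rsq`` itself.  On the binary scale
        ``rsq`` is the squared correlation between the covariate and the
        observed 0/1 trait; for a threshold model with latent
        ``Z = gamma C + eps`` (unit variance) and threshold ``tau``,
        ``corr(y, C) = gamma phi(tau) / sqrt(K (1-K))``, so
        ``gamma^2 = rsq K (1-K) / phi(tau)^2``.
        """
        if self.rsq_scale == "liability":
            return self.rsq
        tau = stats.norm.ppf(1.0 - self.prevalence)
        return self.rsq * self.prevalence * (1.0 - self.prevalence) / stats.norm.pdf(tau) ** 2


@dataclass
class Cohort:
    """An ascertained case-control cohort for one gene.

    ``genotypes`` holds per-variant carriage indicators (subjects x variants);
    ``carriage`` is 1 for subjects carrying any variant; ``damage`` and
    ``sign`` describe the retained (most deleterious) variant, with
    ``damage = 0`` and ``sign = 0`` for non-carriers.
    """

    y: np.ndarray
    covariate: np.ndarray
    genotypes: np.ndarray
    carriage: np.ndarray
    damage: np.ndarray
    sign: np.ndarray
    gene: GeneModel

    @property
    def n_subjects(self) -> int:
        return int(self.y.shape[0])


def _wright_log_density(p: np.ndarray, beta1, beta2, sigma) -> np.ndarray:
    b1 = np.asarray(beta1)[..., None]
    b2 = np.asarray(beta2)[..., None]
    s = np.asarray(sigma)[..., None]
    return (b1 - 1.0) * np.log(p) + (b2 - 1.0) * np.log1p(-p) + s * (1.0 - p)


def sample_wright_frequencies(
    params: WrightParams,
    rng: np.random.Generator,
    size: int,
    *,
    beta1: float | None = None,
    beta2: float | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Draw ``size`` frequencies from Wright's distribution on the rare window.

    Each draw uses its own hyper-parameter draws unless fixed values are
    supplied.  Sampling is by normalized weights on a uniform grid of
    ``params.grid_points`` points spanning ``[maf_lower, maf_upper)``.
    """
    if params.maf_lower >= params.maf_upper:
        raise ValueError("degenerate grid: maf_lower >= maf_upper")
    b1 = (
        rng.uniform(*params.beta1_range, size=size)
        if beta1 is None
        else np.full(size, beta1)
    )
    b2 = (
        rng.uniform(*params.beta2_range, size=size)
        if beta2 is None
        else np.full(size, beta2)
    )
    if sigma is None:
        s = np.where(
            rng.random(size) < params.sigma_zero_prob,
            0.0,
            rng.uniform(*params.sigma_range, size=size),
        )
    else:
        s = np.full(size, sigma)
    # half-open grid: cell left edges, so every draw is < maf_upper
    grid = np.linspace(
        params.maf_lower, params.maf_upper, params.grid_points, endpoint=False
    )
    logw = _wright_log_density(grid, b1, b2, s)
    logw -= logw.max(axis=-1, keepdims=True)
    w = np.exp(logw)
    cdf = np.cumsum(w, axis=-1)
    cdf /= cdf[..., -1:]
    u = rng.random(size)
    idx = (cdf < u[:, None]).sum(axis=-1)
    return grid[idx]


def sample_wright_frequency(params: WrightParams, rng: np.random.Generator) -> float:
    """Draw one minor-allele frequency from the truncated Wright distribution."""
    return float(sample_wright_frequencies(params, rng, 1)[0])


def build_gene(
    cds_length: float,
    class_probs: Sequence[float] = DEFAULT_CLASS_PROBS,
    zeta: float = 0.5,
    params: WrightParams | None = None,
    rng: np.random.Generator | None = None,
) -> GeneModel:
    """Build a simulated gene calibrated to 1% carriage per 500 coding bp.

    Frequencies are drawn sequentially; each sampled frequency is the
    per-subject carriage probability of that variant, so expected gene
    carriage after j variants is ``1 - prod(1 - q_1..q_j)``.  Drawing stops at
    the first variant whose inclusion would move expected carriage farther
    from the target than leaving it out; that variant is discarded.  The first
    draw is always kept, so every gene has at least one variant.
    """
    if cds_length <= 0:
        raise ValueError("cds_length must be positive")
    params = params or WrightParams()
    rng = rng if rng is not None else np.random.default_rng()
    target = 0.01 * cds_length / 500.0

    mafs: list[float] = []
    miss_prob = 1.0  # prod(1 - q_j)
    while True:
        q = sample_wright_frequency(params, rng)
        current = 1.0 - miss_prob
        candidate = 1.0 - miss_prob * (1.0 - q)
        if mafs and abs(candidate - target) >= abs(current - target):
            break
        mafs.append(q)
        miss_prob *= 1.0 - q

    k = len(mafs)
    classes = rng.choice(4, size=k, p=np.asarray(class_probs, dtype=float))
    signs = np.where(rng.random(k) < zeta, 1, -1)
    variants = tuple(
        VariantSite(maf=m, damage_class=int(c), sign=int(s))
        for m, c, s in zip(mafs, classes, signs)
    )
    return GeneModel(cds_length=float(cds_length), variants=variants, target_carriage=target)


def _simulate_batch(
    config: SimulationConfig, gene: GeneModel, rng: np.random.Generator, n: int
):
    """Generate ``n`` unascertained subjects; returns (y, C, genotypes, damage, sign, Z)."""
    q = gene.mafs
    dmg = gene.damage_classes
    sgn = gene.signs

    genotypes = (rng.random((n, q.size)) < q).astype(np.int8)
    carried_any = genotypes.any(axis=1)
    # retained variant: carried variant with maximal damage class, first wins ties
    score = np.where(genotypes.astype(bool), dmg, -1)
    retained = np.argmax(score, axis=1)
    damage = np.where(carried_any, dmg[retained], 0)
    sign = np.where(carried_any, sgn[retained], 0)

    if config.scenario == "linear":
        d = damage.astype(float)
    else:  # magnitude: homogeneous effect size for any deleterious carriage
        d = (damage > 0).astype(float)

    gamma_sq = config.gamma_sq
    covariate = rng.standard_normal(n)
    eps = rng.standard_normal(n) * np.sqrt(1.0 - gamma_sq)
    z = config.delta * sign * d + np.sqrt(gamma_sq) * covariate + eps
    y = (z > config.threshold).astype(np.int8)
    return y, covariate, genotypes, damage, sign, z


def simulate_population(
    config: SimulationConfig,
    gene: GeneModel,
    rng: np.random.Generator,
    n_subjects: int,
) -> Cohort:
    """Simulate ``n_subjects`` subjects with no case-control ascertainment."""
    y, cov, geno, damage, sign, _ = _simulate_batch(config, gene, rng, n_subjects)
    return Cohort(
        y=y.astype(np.int64),
        covariate=cov,
        genotypes=geno,
        carriage=geno.any(axis=1).astype(np.int64),
        damage=damage.astype(np.int64),
        sign=sign.astype(np.int64),
        gene=gene,
    )


def simulate_cohort(
    config: SimulationConfig,
    gene: GeneModel,
    rng: np.random.Generator | None = None,
    batch_size: int = 8192,
) -> Cohort:
    """Simulate subjects until the case and control quotas are filled.

    Subjects are generated in fixed-size batches (vectorised but equivalent to
    one-at-a-time generation under the same draw order) and banked in
    generation order until ``n_cases`` cases and ``n_controls`` controls are
    collected; surplus subjects of a filled class are discarded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    need = {1: config.n_cases, 0: config.n_controls}
    k = min(config.prevalence, 1.0 - config.prevalence)
    cap = int(config.ascertainment_cap_factor * (config.n_cases + config.n_controls) / k)

    parts: list[tuple[np.ndarray, ...]] = []
    generated = 0
    while need[1] > 0 or need[0] > 0:
        if generated >= cap:
            raise AscertainmentError(
                f"ascertainment did not finish within the cap of {cap} generated "
                f"subjects (still need {need[1]} cases, {need[0]} controls)"
            )
        n = min(batch_size, cap - generated)
        y, cov, geno, damage, sign, _ = _simulate_batch(config, gene, rng, n)
        generated += n
        keep = np.zeros(n, dtype=bool)
        for cls in (1, 0):
            idx = np.flatnonzero(y == cls)[: need[cls]]
            keep[idx] = True
            need[cls] -= idx.size
        if keep.any():
            parts.append((y[keep], cov[keep], geno[keep], damage[keep], sign[keep]))

    y = np.concatenate([p[0] for p in parts]).astype(np.int64)
    cov = np.concatenate([p[1] for p in parts])
    geno = np.concatenate([p[2] for p in parts])
    damage = np.concatenate([p[3] for p in parts]).astype(np.int64)
    sign = np.concatenate([p[4] for p in parts]).astype(np.int64)
    return Cohort(
        y=y,
        covariate=cov,
        genotypes=geno,
        carriage=geno.any(axis=1).astype(np.int64),
        damage=damage,
        sign=sign,
        gene=gene,
    )


def export_cohort(cohort: Cohort, out_prefix: str) -> tuple[str, str]:
    """Write a cohort as a minimal VCF plus a phenotype/covariate TSV.

    Carriage is encoded as heterozygous genotype 0/1; INFO carries the
    simulated damage class (DMG) and effect sign (SGN).  Returns the two
    paths written: ``(vcf_path, pheno_path)``.
    """
    vcf_path = f"{out_prefix}.vcf"
    pheno_path = f"{out_prefix}.pheno.tsv"
    n, v = cohort.genotypes.shape
    sample_ids = [f"S{i:06d}" for i in range(n)]

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rvth-simulate\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=DMG,Number=1,Type=Integer,Description="Simulated damage class (0-3)">\n')
        fh.write('##INFO=<ID=SGN,Number=1,Type=Integer,Description="Simulated effect sign (+1/-1)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids) + "\n")
        for j, site in enumerate(cohort.gene.variants):
            gts = "\t".join("0/1" if g else "0/0" for g in cohort.genotypes[:, j])
            fh.write(
                f"1\t{j + 1}\tvar{j + 1:05d}\tA\tT\t.\tPASS\t"
                f"DMG={site.damage_class};SGN={site.sign}\tGT\t{gts}\n"
            )

    with open(pheno_path, "w") as fh:
        fh.write("sample_id\tstatus\tcovariate\n")
        for sid, status, c in zip(sample_ids, cohort.y, cohort.covariate):
            fh.write(f"{sid}\t{int(status)}\t{c:.17g}\n")
    return vcf_path, pheno_path
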