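"""Monte-Carlo size and power grids for the rare-variant tests.

Each grid cell fixes (delta, zeta, Rsq, CDS length, scenario); every
replicate draws a fresh gene (fresh Wright frequencies, damage classes and
signs), simulates an ascertained case-control cohort, runs the requested
tests and records whether each rejects at the nominal level.  Empirical size
is the rejection fraction at delta = 0; empirical power the same at
delta > 0.  Monte-Carlo uncertainty is the binomial standard error
``sqrt(est (1 - est) / n_sims)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import rv_tests
from .rv_tests import TestResult
from .simulate import SimulationConfig, build_gene, simulate_cohort

__all__ = [
    "GridSpec",
    "GridResult",
    "run_methods",
    "estimate_size",
    "estimate_power",
    "summarize",
]

logger = logging.getLogger(__name__)

ALL_METHODS = ("TH", "RCS", "RCS-C", "CA", "CA-P", "SK", "SK-R")


@dataclass(frozen=True)
class GridSpec:
    """The evaluation grid and Monte-Carlo settings."""

    deltas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
    zetas: tuple[float, ...] = (0.5, 0.8, 1.0)
    rsqs: tuple[float, ...] = (0.0, 0.15, 0.30)
    cds_lengths: tuple[float, ...] = (361.0, 1209.0, 4057.0)
    scenario: str = "linear"
    n_sims_power: int = 250
    n_sims_size: int = 25000
    alpha: float = 1e-3
    methods: tuple[str, ...] = ALL_METHODS
    #: resamples/permutations/bootstraps per test; None -> 10 / alpha, which
    #: places the resampling p-value floor a decade below alpha
    n_resamples: int | None = None

    def __post_init__(self) -> None:
        if not (self.deltas and self.zetas and self.rsqs and self.cds_lengths):
            raise ValueError("all grid lists must be non-empty")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def resolved_resamples(self) -> int:
        return self.n_resamples if self.n_resamples is not None else int(round(10 / self.alpha))


@dataclass(frozen=True)
class GridResult:
    """Empirical rejection fraction for one (cell, method) pair."""

    method: str
    delta: float
    zeta: float
    rsq: float
    cds_length: float
    scenario: str
    estimate: float
    mc_se: float
    n_sims: int
    alpha: float
    n_failures: int = 0


def run_methods(
    y: np.ndarray,
    covariates: np.ndarray | None,
    genotypes: np.ndarray,
    methods: Sequence[str],
    n_resamples: int,
    rng: np.random.Generator,
    *,
    on_error: str = "raise",
) -> list[TestResult | None]:
    """Run the requested tests on one dataset, sharing the null model fit.

    With ``on_error='none'`` a failing method yields ``None`` in its slot
    (and a logged traceback) instead of aborting the remaining methods.
    """
    carriage = np.asarray(genotypes).any(axis=1).astype(np.int64)
    null = None
    if {"TH", "RCS-C", "SK", "SK-R"} & set(methods):
        try:
            null = rv_tests.fit_null(y, covariates)
        except Exception:
            if on_error == "raise":
                raise
            logger.exception("null model fit failed; dependent methods will retry")
    out: list[TestResult | None] = []
    for method in methods:
        try:
            if method == "TH":
                res = rv_tests.th_test(y, covariates, carriage, n_resamples, rng, null=null)
            elif method == "RCS":
                res = rv_tests.rcs_test(y, carriage, None)
            elif method == "RCS-C":
                res = rv_tests.rcs_test(y, carriage, covariates, null=null)
            elif method == "CA":
                res = rv_tests.calpha_test(genotypes, y, "asymptotic")
            elif method == "CA-P":
                res = rv_tests.calpha_test(genotypes, y, "permutation", n_resamples, rng)
            elif method == "SK":
                res = rv_tests.skat_test(y, genotypes, covariates, mode="asymptotic", null=null)
            elif method == "SK-R":
                res = rv_tests.skat_test(
                    y, genotypes, covariates, mode="bootstrap", n_boot=n_resamples,
                    rng=rng, null=null,
                )
            else:  # pragma: no cover - guarded by GridSpec validation
                raise ValueError(f"unknown method {method}")
        except Exception:
            if on_error == "raise":
                raise
            logger.exception("method %s failed", method)
            res = None
        out.append(res)
    return out


def _run_cell(
    spec: GridSpec,
    template: SimulationConfig,
    delta: float,
    zeta: float,
    rsq: float,
    cds: float,
    n_sims: int,
    cell_seq: np.random.SeedSequence,
) -> tuple[list[GridResult], dict[str, np.ndarray]]:
    config = template.replace(
        delta=delta, zeta=zeta, rsq=rsq, cds_length=cds, scenario=spec.scenario
    )
    n_resamples = spec.resolved_resamples
    rejections = {m: 0 for m in spec.methods}
    failures = {m: 0 for m in spec.methods}
    pvals: dict[str, list[float]] = {m: [] for m in spec.methods}
    for child in cell_seq.spawn(n_sims):
        rng = np.random.default_rng(child)
        gene = build_gene(cds, config.class_probs, zeta, config.wright, rng)
        cohort = simulate_cohort(config, gene, rng)
        results = run_methods(
            cohort.y, cohort.covariate, cohort.genotypes, spec.methods,
            n_resamples, rng, on_error="none",
        )
        for method, res in zip(spec.methods, results):
            if res is None:
                failures[method] += 1
                pvals[method].append(np.nan)
            else:
                pvals[method].append(res.p_value)
                if res.p_value <= spec.alpha:
                    rejections[method] += 1
    out = []
    for method in spec.methods:
        n_ok = n_sims - failures[method]
        est = rejections[method] / n_ok if n_ok else np.nan
        se = float(np.sqrt(est * (1 - est) / n_ok)) if n_ok else np.nan
        out.append(
            GridResult(
                method=method, delta=delta, zeta=zeta, rsq=rsq, cds_length=cds,
                scenario=spec.scenario, estimate=est, mc_se=se, n_sims=n_ok,
                alpha=spec.alpha, n_failures=failures[method],
            )
        )
    return out, {m: np.asarray(v) for m, v in pvals.items()}


def _estimate(
    spec: GridSpec, template: SimulationConfig, master_seed: int, n_sims: int
) -> tuple[list[GridResult], dict]:
    cells = [
        (d, z, r, c)
        for d in spec.deltas
        for z in spec.zetas
        for r in spec.rsqs
        for c in spec.cds_lengths
    ]
    root = np.random.SeedSequence(master_seed)
    results: list[GridResult] = []
    pvalues: dict[tuple, dict[str, np.ndarray]] = {}
    for (d, z, r, c), cell_seq in zip(cells, root.spawn(len(cells))):
        res, pv = _run_cell(spec, template, d, z, r, c, n_sims, cell_seq)
        results.extend(res)
        pvalues[(d, z, r, c)] = pv
    return results, pvalues


def estimate_size(
    spec: GridSpec,
    template: SimulationConfig | None = None,
    master_seed: int = 0,
    *,
    return_pvalues: bool = False,
):
    """Empirical type-I error over the grid; requires all deltas to be 0.

    With ``return_pvalues`` also returns the per-cell raw p-values keyed by
    ``(delta, zeta, rsq, cds_length)`` then method tag.
    """
    if any(d != 0 for d in spec.deltas):
        raise ValueError("size estimation requires deltas = {0}")
    template = template or SimulationConfig()
    results, pvalues = _estimate(spec, template, master_seed, spec.n_sims_size)
    return (results, pvalues) if return_pvalues else results


def estimate_power(
    spec: GridSpec,
    template: SimulationConfig | None = None,
    master_seed: int = 0,
    *,
    return_pvalues: bool = False,
):
    """Empirical power over the grid at the spec's nominal level."""
    template = template or SimulationConfig()
    results, pvalues = _estimate(spec, template, master_seed, spec.n_sims_power)
    return (results, pvalues) if return_pvalues else results


def summarize(
    results: Iterable[GridResult], out: str | None = None
) -> pd.DataFrame:
    """Tidy one-row-per-(cell, method) table; optionally written as CSV.

    ``relative_size`` is the rejection fraction divided by the nominal level
    (the natural reading of a size run; under power runs it is power / alpha).
    """
    rows = list(results)
    if not rows:
        raise ValueError("no results to summarize")
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["relative_size"] = df["estimate"] / df["alpha"]
    if out is not None:
        df.to_csv(out, index=False)
    return df


def plot_power_curves(df: pd.DataFrame, out: str) -> None:
    """Optional convenience: power-vs-delta panels by (zeta, rsq), lines by method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = df.groupby(["zeta", "rsq"])
    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.2), squeeze=False, sharey=True)
    for ax, ((zeta, rsq), sub) in zip(axes.ravel(), panels):
        for (method, cds), line in sub.groupby(["method", "cds_length"]):
            line = line.sort_values("delta")
            ax.plot(line["delta"], line["estimate"], marker="o", ms=3,
                    label=f"{method} cds={cds:g}")
        ax.set_title(f"zeta={zeta:g}, Rsq={rsq:g}")
        ax.set_xlabel("delta (latent SD)")
    axes[0, 0].set_ylabel("empirical power")
    axes[0, 0].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
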