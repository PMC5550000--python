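"""Simulation-study harness: type-I error, power, ranking curves, filtering.

Reproduces the structure of the method's validation experiments on
synthetic data: empirical size of the tests on null phenotypes, power on
epistatic phenotypes evaluated at the causal variants, TPR-FPR ranking
curves (with pair-to-variant unrolling for exhaustive pairwise methods),
and the two-step filtering comparison in which variants are first ranked
by a marginal test and pairwise interactions are then tested among the
top-ranked set under Bonferroni correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .baselines import PairTestRecord, additive_scan, bonferroni, pairwise_scan
from .genotypes_io import GenotypeMatrix, Phenotype
from .simulate import SimulationDesign, simulate_epistatic, simulate_genotypes, simulate_null
from .testing import MapitScanner, mapit_scan

__all__ = ["EvalReport", "type1_study", "power_study", "tpr_fpr_curve",
           "two_step_filter"]


@dataclasses.dataclass
class EvalReport:
    """Results of one simulation study."""

    design: SimulationDesign
    replicates: int
    type1: dict = dataclasses.field(default_factory=dict)
    # (method, alpha) -> (mean rate, across-replicate s.d.)
    type1_reps: dict = dataclasses.field(default_factory=dict)
    # method -> array of per-replicate proportions per alpha
    power: dict = dataclasses.field(default_factory=dict)
    # (group, method, alpha) -> (rate, 1.96 * binomial s.e. band)
    flags: tuple[str, ...] = ()


def type1_study(design: SimulationDesign, replicates: int = 100,
                alphas=(0.05, 0.01, 0.001), methods=("normal", "davies"),
                variants_per_replicate: int | None = None,
                seed: int | None = None) -> EvalReport:
    """Empirical size of the tests on null (additive-only) phenotypes.

    One genotype panel is drawn from the design; ``replicates`` null
    phenotypes are simulated on it and a fixed random subset of
    ``variants_per_replicate`` variants is tested in each (all variants
    when None).  Both the normal and the exact mixture p-value are
    computed for every tested variant (the two tests reject largely
    different variants at moderate alpha, so the exact size cannot be
    recovered from a normal-test screen).  The method name ``"uniform"``
    injects uniform random p-values to validate the counting harness
    itself.

    Per method and alpha the report holds the mean and across-replicate
    standard deviation of the per-replicate rejection fraction.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    geno = simulate_genotypes(design.n, design.p, design.maf_range, rng)
    if variants_per_replicate is None:
        test_idx = np.arange(design.p)
    else:
        test_idx = np.sort(rng.choice(design.p, size=variants_per_replicate,
                                      replace=False))
    scan_methods = [m for m in methods if m != "uniform"]
    need_exact = any(m in ("davies", "hybrid") for m in scan_methods)
    scanner = (MapitScanner(geno.standardized, variants=test_idx,
                            exact_cache=need_exact)
               if scan_methods else None)

    alphas = tuple(alphas)
    reps = {m: np.zeros((replicates, len(alphas))) for m in methods}
    for r in range(replicates):
        y = simulate_null(geno, design, seed=rng)
        if scanner is not None:
            records = scanner.scan(y.y, mode="davies" if need_exact else "normal")
            p_norm = np.array([rec.p_normal for rec in records])
            p_exact = np.array([rec.p_final for rec in records])
        for m in methods:
            if m == "uniform":
                pv = rng.uniform(size=test_idx.size)
            elif m == "normal":
                pv = p_norm
            elif m in ("davies", "hybrid"):
                pv = p_exact
            else:
                raise ValueError(f"unknown method {m!r}")
            for a_i, alpha in enumerate(alphas):
                reps[m][r, a_i] = np.mean(pv < alpha)

    report = EvalReport(design=design, replicates=replicates)
    if replicates == 1:
        report.flags = ("single_replicate_sd_zero",)
    for m in methods:
        report.type1_reps[m] = reps[m]
        for a_i, alpha in enumerate(alphas):
            vals = reps[m][:, a_i]
            sd = float(vals.std(ddof=1)) if replicates > 1 else 0.0
            report.type1[(m, alpha)] = (float(vals.mean()), sd)
    return report


def power_study(design: SimulationDesign, replicates: int = 100,
                alpha: float = 0.05, methods=("hybrid",),
                seed: int | None = None) -> EvalReport:
    """Power to detect the interacting causal groups.

    Each replicate draws a fresh genotype panel and epistatic phenotype;
    only the causal group-1/group-2 variants are tested.  Power per group
    is the overall fraction of that group's tests significant at
    ``alpha``; the band is +/- 1.96 binomial standard errors over the
    pooled Bernoulli draws.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    hits = {(g, m): [] for g in ("group1", "group2") for m in methods}
    for _ in range(replicates):
        geno = simulate_genotypes(design.n, design.p, design.maf_range, rng)
        study = simulate_epistatic(geno, design, seed=rng)
        g1, g2, _ = study.causal_groups
        targets = np.concatenate([g1, g2])
        for m in methods:
            records = mapit_scan(geno.standardized, study.y.y, mode=m,
                                 variants=targets)
            pv = {rec.k: rec.p_final for rec in records}
            hits[("group1", m)].extend(pv[k] < alpha for k in g1)
            hits[("group2", m)].extend(pv[k] < alpha for k in g2)

    report = EvalReport(design=design, replicates=replicates)
    for (g, m), draws in hits.items():
        draws = np.asarray(draws, dtype=float)
        rate = float(draws.mean())
        band = 1.96 * float(np.sqrt(max(rate * (1 - rate), 1e-12) / draws.size))
        report.power[(g, m, alpha)] = (rate, band)
    return report


def tpr_fpr_curve(scores, truth, pairs=None):
    """Stepwise TPR-FPR curve over a ranked list of variants.

    ``scores`` are p-values (smaller = stronger); ``truth`` is a boolean
    causal mask over variants.  For pair-based methods pass ``pairs`` as
    the (i, j) list aligned with ``scores``: pairs are unrolled to their
    constituent variants in rank order and de-duplicated, so a top pair
    hitting one causal variant contributes one true and one false
    variant.
    """
    truth = np.asarray(truth, dtype=bool)
    n_true = int(truth.sum())
    n_false = int(truth.size - n_true)
    if n_true == 0:
        raise ValueError("empty truth set: TPR is undefined")
    order = np.argsort(np.asarray(scores), kind="stable")
    if pairs is None:
        ranked = list(order)
    else:
        ranked, seen = [], set()
        for idx in order:
            for v in pairs[idx]:
                if v not in seen:
                    seen.add(v)
                    ranked.append(v)
    curve = [(0.0, 0.0)]
    tp = fp = 0
    for v in ranked:
        if truth[v]:
            tp += 1
        else:
            fp += 1
        curve.append((fp / max(n_false, 1), tp / n_true))
    return curve


def two_step_filter(X, y, filter_method: str = "mapit", top_v: int = 100,
                    alpha: float = 0.05, covariates=None) -> list[PairTestRecord]:
    """Rank variants marginally, then test all pairs among the top set.

    ``filter_method`` is ``"mapit"`` (marginal epistasis hybrid scan) or
    ``"additive"`` (single-SNP linear model).  All top_v * (top_v - 1)/2
    pairs are tested with main-effect control and Bonferroni correction
    of ``alpha`` over the tested pair count; the significant pairs are
    returned (indices refer to the original variant numbering).  Ties at
    the top_v boundary break by variant index (stable sort).
    """
    Xs = X.standardized if isinstance(X, GenotypeMatrix) else np.asarray(X, float)
    yv = y.y if isinstance(y, Phenotype) else np.asarray(y, float)
    p = Xs.shape[1]
    if top_v > p:
        raise ValueError(f"top_v={top_v} exceeds p={p}")
    if filter_method == "mapit":
        records = mapit_scan(Xs, yv, mode="hybrid", covariates=covariates)
        pvals = np.array([r.p_final for r in records])
    elif filter_method == "additive":
        pvals = additive_scan(Xs, yv, covariates=covariates)
    else:
        raise ValueError(f"unknown filter_method {filter_method!r}")
    top = np.sort(np.argsort(pvals, kind="stable")[:top_v])
    pair_list = [(int(top[a]), int(top[b]))
                 for a in range(top_v) for b in range(a + 1, top_v)]
    tested = pairwise_scan(Xs, yv, pairs=pair_list, covariates=covariates)
    cut = bonferroni(alpha, len(pair_list))
    return [r for r in tested if r.p_value < cut]
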