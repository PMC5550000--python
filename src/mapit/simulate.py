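"""Synthetic GWAS simulation engine.

Emulates the null and power study designs used to validate the marginal
epistasis test: binomial genotypes at uniform allele frequencies,
phenotypes composed of additive, pairwise-epistatic, stratification, and
noise parts with *exactly* enforced variance shares.

Design of the epistatic phenotype: the causal variants split into three
disjoint groups of sizes (p1, p2, p3).  Groups 1 and 2 interact across
groups (never within), so the interaction design matrix W holds the
elementwise products x_i o x_j over the full cross product
group1 x group2; group 3 carries additive effects only.  With
broad-sense heritability H^2 and additive share rho, the realized sample
variances satisfy Var(X beta) = rho H^2, Var(W alpha) = (1 - rho) H^2,
and (for the stratified model) Var(Z u) equals the requested share --
exactly, by centering, sequentially orthogonalizing, and rescaling the
realized component vectors, so downstream recovery tests have analytic
truth.  The per-SNP interaction share of variance is then
(1 - rho) H^2 / p_group for each interacting group.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genotypes_io import GenotypeMatrix, Phenotype, standardize

__all__ = [
    "SimulationDesign",
    "SimulatedStudy",
    "scenario",
    "simulate_genotypes",
    "simulate_null",
    "simulate_epistatic",
]

_SCENARIOS = {
    "I": (10, 10, 980),
    "II": (10, 20, 970),
    "III": (10, 50, 940),
    "IV": (10, 100, 890),
}


def scenario(label: str) -> tuple[int, int, int]:
    """Causal-group sizes (p1, p2, p3) for the four canonical scenarios."""
    try:
        return _SCENARIOS[label]
    except KeyError:
        raise ValueError(f"unknown scenario {label!r}; expected one of I-IV") from None


@dataclasses.dataclass(frozen=True)
class SimulationDesign:
    """Settings for one simulated study.

    ``h2``: broad-sense heritability; ``rho``: additive share of h2;
    ``groups``: (p1, p2, p3) causal counts (p1/p2 interacting hubs and
    partners, p3 additive-only); ``model``: ``standard`` or
    ``stratified``; ``n_pcs``/``strat_var``: stratification settings
    (share of phenotypic variance carried by top genotype PCs);
    ``maf_range``: uniform allele-frequency range for genotype draws.
    """

    n: int
    p: int
    h2: float = 0.6
    rho: float = 0.8
    groups: tuple[int, int, int] = (10, 10, 980)
    model: str = "standard"
    n_pcs: int = 5
    strat_var: float = 0.10
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if sum(self.groups) > self.p:
            raise ValueError("causal groups exceed the number of variants")
        for name in ("h2", "rho", "strat_var"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.model not in ("standard", "stratified"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "standard" and self.strat_var != 0.0:
            object.__setattr__(self, "strat_var", 0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(d["groups"])
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        d = dict(d)
        for key in ("groups", "maf_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        import json
        import pathlib

        pathlib.Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SimulationDesign":
        import json
        import pathlib

        return cls.from_dict(json.loads(pathlib.Path(path).read_text()))


@dataclasses.dataclass(frozen=True)
class SimulatedStudy:
    """A genotype panel plus a phenotype with known causal architecture."""

    X: GenotypeMatrix
    y: Phenotype
    causal_groups: tuple[np.ndarray, np.ndarray, np.ndarray]
    interaction_pairs: list[tuple[int, int]]
    true_pve_per_snp: dict[str, float]


def simulate_genotypes(n: int, p: int, maf_range=(0.05, 0.5),
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Draw counts ~ Binomial(2, f_j), f_j ~ Uniform(maf_range), and
    standardize.  Constant columns are redrawn (bounded retries)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freq = rng.uniform(maf_range[0], maf_range[1], size=p)
    counts = rng.binomial(2, freq, size=(n, p)).astype(np.int8)
    for _ in range(100):
        sd = counts.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size == 0:
            break
        counts[:, bad] = rng.binomial(2, freq[bad], size=(n, bad.size)).astype(np.int8)
    else:
        raise RuntimeError("could not draw non-constant genotype columns")
    obs_freq = counts.mean(axis=0) / 2.0
    return GenotypeMatrix(
        counts=counts,
        standardized=standardize(counts),
        variant_ids=np.array([f"snp{j}" for j in range(p)]),
        chrom=np.ones(p, dtype=int),
        pos=np.arange(1, p + 1),
        sample_ids=np.array([f"sample{i}" for i in range(n)]),
        maf=np.minimum(obs_freq, 1.0 - obs_freq),
    )


def _pc_scores(Xs: np.ndarray, n_pcs: int) -> np.ndarray:
    Xc = Xs - Xs.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return Xc @ vt[:n_pcs].T


def _exact_mixture(parts: list[np.ndarray], shares: list[float]) -> np.ndarray:
    """Center, sequentially orthogonalize, and rescale components so each
    contributes exactly its requested share of unit total variance."""
    n = parts[0].size
    basis: list[np.ndarray] = []
    out = np.zeros(n)
    for part, share in zip(parts, shares):
        v = part - part.mean()
        for b in basis:
            v = v - b * float(b @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-12:
            if share > 0:
                raise ValueError("degenerate component with nonzero variance share")
            continue
        b = v / norm
        basis.append(b)
        out += b * np.sqrt(share * n)  # sample variance of b*sqrt(share*n) is share
    return out


def simulate_null(X: GenotypeMatrix, design: SimulationDesign,
                  seed: int | np.random.Generator | None = None) -> Phenotype:
    """Additive-only phenotype: y = [Zu] + X beta + eps, no interactions.

    The causal additive count is the total of ``design.groups``; realized
    variance shares are h2 (additive), strat_var (stratified model), and
    the remainder (noise), enforced exactly.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(design.seed if seed is None else seed))
    Xs = X.standardized
    n, p = Xs.shape
    n_causal = sum(design.groups)
    causal = rng.choice(p, size=n_causal, replace=False)
    beta = rng.standard_normal(n_causal)
    g_add = Xs[:, causal] @ beta
    eps = rng.standard_normal(n)

    parts, shares = [], []
    if design.model == "stratified" and design.strat_var > 0:
        Z = _pc_scores(Xs, design.n_pcs)
        u = rng.standard_normal(design.n_pcs)
        parts.append(Z @ u)
        shares.append(design.strat_var)
    parts.extend([g_add, eps])
    shares.extend([design.h2, 1.0 - design.h2 - design.strat_var])
    y = _exact_mixture(parts, shares)
    return Phenotype(y=y, sample_ids=X.sample_ids)


def simulate_epistatic(X: GenotypeMatrix, design: SimulationDesign,
                       seed: int | np.random.Generator | None = None) -> SimulatedStudy:
    """Phenotype with additive + pairwise-epistatic architecture.

    rho = 1 reduces to the null (additive-only) model.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(design.seed if seed is None else seed))
    Xs = X.standardized
    n, p = Xs.shape
    p1, p2, p3 = design.groups
    causal = rng.choice(p, size=p1 + p2 + p3, replace=False)
    g1, g2, g3 = causal[:p1], causal[p1:p1 + p2], causal[p1 + p2:]

    beta = rng.standard_normal(causal.size)
    g_add = Xs[:, causal] @ beta

    pairs = [(int(i), int(j)) for i in g1 for j in g2]
    epi_share = (1.0 - design.rho) * design.h2
    if epi_share > 0:
        # interaction columns from standardized genotypes, not re-standardized
        W = np.empty((n, len(pairs)))
        for c, (i, j) in enumerate(pairs):
            W[:, c] = Xs[:, i] * Xs[:, j]
        alpha = rng.standard_normal(len(pairs))
        g_epi = W @ alpha
    else:
        g_epi = np.zeros(n)
    eps = rng.standard_normal(n)

    parts, shares = [], []
    if design.model == "stratified" and design.strat_var > 0:
        Z = _pc_scores(Xs, design.n_pcs)
        parts.append(Z @ rng.standard_normal(design.n_pcs))
        shares.append(design.strat_var)
    parts.append(g_add)
    shares.append(design.rho * design.h2)
    if epi_share > 0:
        parts.append(g_epi)
        shares.append(epi_share)
    parts.append(eps)
    shares.append(1.0 - design.h2 - design.strat_var)
    y = _exact_mixture(parts, shares)

    true_pve = {"group1": epi_share / p1 if p1 else 0.0,
                "group2": epi_share / p2 if p2 else 0.0,
                "total_epistatic": epi_share}
    return SimulatedStudy(
        X=X,
        y=Phenotype(y=y, sample_ids=X.sample_ids),
        causal_groups=(g1, g2, g3),
        interaction_pairs=pairs,
        true_pve_per_snp=true_pve,
    )
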