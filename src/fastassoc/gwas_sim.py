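"""Synthetic GWAS studies: structured genotypes, liability-threshold phenotypes,
genotype-PC covariates.

The generator emulates the statistical structure of contest-style test data:

* **Genotypes** follow the Balding-Nichols model.  Each marker draws an
  ancestral allele frequency uniform on (0.05, 0.95); each of ``n_pops``
  populations draws its own frequency from a Beta distribution with that mean
  and variance ``fst * p * (1 - p)``; subjects, assigned round-robin to
  populations, draw dosages Binomial(2, population frequency).  Markers are
  independent given population (no LD), and no calls are missing.
* **Phenotypes** follow a liability-threshold model.  Per phenotype, a causal
  fraction is drawn uniform on [0, ``causal_frac``]; causal effects are
  Normal(0, ``effect_sd``) on standardized dosages.  The liability is the
  genetic score plus a per-population background effect
  (Normal(0, ``pop_effect_sd``)) plus standard normal noise, centered to mean
  zero; the binary phenotype is the indicator that liability exceeds zero.
* **Covariates** are the top principal-component scores of the standardized
  genotype matrix, which absorb the population-structure confounding the
  background effects induce.

A single seeded generator drives all draws, so a fixed seed yields a fully
deterministic study.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from fastassoc.plink_io import GenotypeStudy, MarkerInfo, SampleInfo, write_bed

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "sample_problem_dims",
    "sample_genotypes",
    "compute_pc_covariates",
    "simulate_phenotypes",
    "simulate_study",
    "write_study",
]

# contest-style problem-dimension ranges
_N_RANGE = (500, 1500)
_M_RANGE = (1000, 5000)
_P_CHOICES = (3, 50)
_C_CHOICES = (5, 10)


@dataclass
class SimConfig:
    """Study-generator parameters.

    ``causal_frac`` is the *upper bound* of the per-phenotype causal-marker
    fraction (each phenotype draws its own fraction uniformly from
    [0, causal_frac]); it may not exceed 0.05.  ``fst`` controls
    between-population allele-frequency divergence; ``effect_sd`` scales
    causal effects on standardized dosages; ``pop_effect_sd`` scales the
    population background on the liability.
    """

    n_subjects: int = 1000
    n_markers: int = 5000
    n_phenotypes: int = 1
    n_covariates: int = 5
    n_pops: int = 8
    fst: float = 0.05
    causal_frac: float = 0.05
    effect_sd: float = 0.5
    pop_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_markers", "n_phenotypes", "n_covariates", "n_pops"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0, 1)")
        if not (0.0 <= self.causal_frac <= 0.05):
            raise ValueError("causal_frac must be in [0, 0.05]")


@dataclass
class SimulatedStudy:
    """A genotype study plus simulated phenotypes, covariates and ground truth."""

    study: GenotypeStudy
    phenotypes: np.ndarray  # N x P, {0, 1}
    covariates: np.ndarray  # N x C PC scores
    causal_sets: list[dict]  # per phenotype: {"markers": indices, "effects": floats}
    liabilities: np.ndarray  # N x P, centered
    pop_labels: np.ndarray  # length N
    config: SimConfig = field(repr=False, default=None)


def sample_problem_dims(seed: int) -> tuple[int, int, int, int]:
    """Draw contest-style problem dimensions (N, P, M, C).

    N is uniform on [500, 1500], M on [1000, 5000]; P is 3 or 50 and C is 5
    or 10, each with equal probability.  A fixed seed gives a fixed tuple.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(_N_RANGE[0], _N_RANGE[1] + 1))
    p = int(rng.choice(_P_CHOICES))
    m = int(rng.integers(_M_RANGE[0], _M_RANGE[1] + 1))
    c = int(rng.choice(_C_CHOICES))
    return n, p, m, c


def _pop_assignments(n_subjects: int, n_pops: int) -> np.ndarray:
    return np.arange(n_subjects) % n_pops


def sample_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeStudy:
    """Draw a structured genotype study under the Balding-Nichols model."""
    rng = rng or np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_subjects, cfg.n_markers, cfg.n_pops
    labels = _pop_assignments(n, k)

    anc = rng.uniform(0.05, 0.95, size=m)
    # Beta with mean p and variance fst * p * (1 - p)
    scale = (1.0 - cfg.fst) / cfg.fst
    pop_freq = rng.beta(anc * scale, (1.0 - anc) * scale, size=(k, m))
    dosage = rng.binomial(2, pop_freq[labels, :]).astype(np.int8)

    width = len(str(m))
    markers = [
        MarkerInfo(chrom="1", id=f"snp{j + 1:0{width}d}", cm=0.0, bp=(j + 1) * 1000,
                   a1="A", a2="G")
        for j in range(m)
    ]
    samples = [
        SampleInfo(fid=f"F{i + 1:05d}", iid=f"I{i + 1:05d}", sex=1 + int(i % 2))
        for i in range(n)
    ]
    return GenotypeStudy(dosage=dosage, markers=markers, samples=samples)


def _standardize(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized dosages; zero-variance markers become zero columns.

    Returns (Z, polymorphic-mask)."""
    X = dosage.astype(np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    poly = sd > 0
    Z = np.zeros_like(X)
    Z[:, poly] = (X[:, poly] - mean[poly]) / sd[poly]
    return Z, poly


def compute_pc_covariates(study: GenotypeStudy, n_components: int) -> np.ndarray:
    """Top principal-component scores of the standardized genotype matrix.

    Markers are standardized to mean 0 / unit variance (monomorphic markers
    dropped); the returned N x C matrix holds the top left singular scores
    (U * S), computed from the eigendecomposition of Z Z', with a
    deterministic sign convention: each component's largest-magnitude marker
    loading is positive.
    """
    n, m = study.dosage.shape
    if n_components >= min(n, m):
        raise ValueError(f"C={n_components} must be < min(N, M) = {min(n, m)}")
    Z, poly = _standardize(study.dosage)
    Zp = Z[:, poly]
    K = Zp @ Zp.T
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:n_components]
    vals, vecs = vals[order], vecs[:, order]
    rank = int((vals > 1e-9 * max(vals[0], 1.0)).sum())
    if rank < n_components:
        raise ValueError(f"C={n_components} exceeds the genotype matrix rank {rank}")
    s = np.sqrt(vals)
    scores = vecs * s
    # sign convention via marker loadings v = Z'u / s
    loadings = Zp.T @ vecs / s
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)] < 0
    scores[:, flip] *= -1.0
    return scores


def simulate_phenotypes(
    study: GenotypeStudy,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    pop_labels: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict], np.ndarray]:
    """Draw liability-threshold binary phenotypes over the study's genotypes.

    Returns (phenotypes N x P, causal sets, liabilities N x P); the phenotype
    is exactly the indicator that the centered liability exceeds zero.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, m = study.dosage.shape
    labels = pop_labels if pop_labels is not None else _pop_assignments(n, cfg.n_pops)
    Z, _ = _standardize(study.dosage)

    phenos = np.empty((n, cfg.n_phenotypes), dtype=np.int8)
    liabs = np.empty((n, cfg.n_phenotypes))
    causal_sets: list[dict] = []
    for ph in range(cfg.n_phenotypes):
        frac = rng.uniform(0.0, cfg.causal_frac)
        n_causal = int(round(frac * m))
        causal = np.sort(rng.choice(m, size=n_causal, replace=False))
        effects = rng.normal(0.0, cfg.effect_sd, size=n_causal)
        genetic = Z[:, causal] @ effects if n_causal else np.zeros(n)
        pop_bg = rng.normal(0.0, cfg.pop_effect_sd, size=cfg.n_pops)[labels]
        liab = genetic + pop_bg + rng.standard_normal(n)
        liab -= liab.mean()
        liabs[:, ph] = liab
        phenos[:, ph] = (liab > 0.0).astype(np.int8)
        causal_sets.append(
            {"markers": causal.tolist(), "effects": effects.tolist()}
        )
    return phenos, causal_sets, liabs


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a complete synthetic study from one seeded RNG stream.

    Draw order: genotypes, then phenotypes; PC covariates are computed
    deterministically from the genotypes.
    """
    rng = np.random.default_rng(cfg.seed)
    study = sample_genotypes(cfg, rng)
    labels = _pop_assignments(cfg.n_subjects, cfg.n_pops)
    phenos, causal_sets, liabs = simulate_phenotypes(study, cfg, rng, labels)
    covars = compute_pc_covariates(study, cfg.n_covariates)
    return SimulatedStudy(
        study=study,
        phenotypes=phenos,
        covariates=covars,
        causal_sets=causal_sets,
        liabilities=liabs,
        pop_labels=labels,
        config=cfg,
    )


def write_study(sim: SimulatedStudy, prefix) -> None:
    """Write a simulated study as a PLINK fileset plus text sidecars.

    Emits ``prefix``.{bed,bim,fam}, ``prefix``.pheno and ``prefix``.covar in
    PLINK text format (FID IID V1 V2 ...; phenotypes coded 1=control,
    2=case), and ``prefix``.truth.json holding causal sets, effect sizes,
    population labels and the generator configuration.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_bed(sim.study, prefix)
    samples = sim.study.samples

    with open(prefix.parent / (prefix.name + ".pheno"), "w") as fh:
        p = sim.phenotypes.shape[1]
        fh.write("FID IID " + " ".join(f"PHENO{k + 1}" for k in range(p)) + "\n")
        for i, s in enumerate(samples):
            vals = " ".join(str(int(v) + 1) for v in sim.phenotypes[i])
            fh.write(f"{s.fid} {s.iid} {vals}\n")

    with open(prefix.parent / (prefix.name + ".covar"), "w") as fh:
        c = sim.covariates.shape[1]
        fh.write("FID IID " + " ".join(f"PC{k + 1}" for k in range(c)) + "\n")
        for i, s in enumerate(samples):
            vals = " ".join(f"{v:.8g}" for v in sim.covariates[i])
            fh.write(f"{s.fid} {s.iid} {vals}\n")

    truth = {
        "config": asdict(sim.config) if sim.config else None,
        "causal_sets": sim.causal_sets,
        "pop_labels": sim.pop_labels.tolist(),
    }
    with open(prefix.parent / (prefix.name + ".truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
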