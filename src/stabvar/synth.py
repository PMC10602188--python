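"""Synthetic variant-table generator with known ground truth.

Emulates the statistical structure of a curated monogenic-disease variant
database: pathogenic variants are on average more destabilizing (more
negative folding free-energy change, ΔΔG) and more buried (lower relative
solvent accessibility, RSA) than benign variants; the three simulated ΔΔG
predictor columns are mutually correlated; genes carry mixed significance
classes so the curation rules have both outcomes to exercise; allele
frequencies straddle the 0.01 filter boundary.

All randomness flows from :class:`GeneratorConfig.seed` through NumPy's
PCG64 generator (``numpy.random.default_rng``).  Each public operation
derives a child generator as ``default_rng([OFFSET, seed])`` with a fixed
per-operation offset, so the same config produces byte-identical output for
every operation independently of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "AMINO_ACIDS",
    "SIGNIFICANCE_CLASSES",
    "PREDICTORS",
    "FUNCTIONAL_CLASSES",
    "GaussianParams",
    "BetaParams",
    "LogUniformRange",
    "GeneratorConfig",
    "ConfigError",
    "generate_raw_table",
    "generate_annotated",
    "generate_sequences",
    "analytic_auc",
    "analytic_auc_rsa",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SIGNIFICANCE_CLASSES = (
    "benign",
    "likely_benign",
    "pathogenic",
    "likely_pathogenic",
    "vus",
    "conflicting",
)

#: Names of the simulated ΔΔG predictor columns.
PREDICTORS = ("ddg_p1", "ddg_p2", "ddg_p3")

#: Functional classes assigned to proteins (16 named groups + miscellaneous).
FUNCTIONAL_CLASSES = (
    "enzyme",
    "transport_translocation_cargo",
    "transcription_regulation",
    "structural_support",
    "scaffold",
    "receptor",
    "signaling",
    "regulatory",
    "dna_binding",
    "motor",
    "secretory",
    "adhesion",
    "chaperone",
    "membrane",
    "rna_binding",
    "antigen_antibody",
    "miscellaneous",
)

# Fixed offsets for per-operation child generators (documented contract).
_OFFSET_RAW = 11
_OFFSET_ANNOTATED = 23
_OFFSET_SEQUENCES = 37


class ConfigError(ValueError):
    """A GeneratorConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class GaussianParams:
    """Per-label ΔΔG distribution: one (mean, sd) per predictor, kcal/mol.

    Negative mean = destabilizing on average.  ``rho`` is the shared
    inter-predictor correlation in [0, 1], realized through a common latent
    factor weighted by sqrt(rho).
    """

    means: tuple[float, float, float]
    sds: tuple[float, float, float]
    rho: float = 0.6

    def validate(self, name: str) -> None:
        if len(self.means) != len(PREDICTORS) or len(self.sds) != len(PREDICTORS):
            raise ConfigError(f"{name}: need one (mean, sd) per predictor")
        if any(s <= 0 for s in self.sds):
            raise ConfigError(f"{name}.sds: standard deviations must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigError(f"{name}.rho: correlation must be in [0, 1]")


@dataclass(frozen=True)
class BetaParams:
    """Beta(a, b) distribution on [0, 1] for relative solvent accessibility."""

    a: float
    b: float

    def validate(self, name: str) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ConfigError(f"{name}: Beta shape parameters must be > 0")


@dataclass(frozen=True)
class LogUniformRange:
    """Allele frequencies drawn log-uniformly in [low, high] ⊂ (0, 1]."""

    low: float
    high: float

    def validate(self, name: str) -> None:
        if not (0 < self.low <= self.high <= 1):
            raise ConfigError(f"{name}: need 0 < low <= high <= 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=n))


def _default_class_mix() -> dict[str, float]:
    return {
        "benign": 0.15,
        "likely_benign": 0.10,
        "pathogenic": 0.25,
        "likely_pathogenic": 0.15,
        "vus": 0.30,
        "conflicting": 0.05,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic variant universe.

    Defaults: pathogenic ΔΔG ~ N(−1.5, 1.5²) and benign ~ N(−0.3, 1.0²)
    kcal/mol on each predictor (pathogenic substitutions destabilize more),
    inter-predictor correlation 0.6; RSA Beta(2, 5) for pathogenic (buried)
    vs Beta(4, 3) for benign (exposed); allele frequencies log-uniform with
    benign in [1e−3, 0.2] and pathogenic in [1e−6, 0.02] so both sides of
    the 0.01 population-frequency filter occur in both classes.
    """

    seed: int = 0
    n_genes: int = 50
    variants_per_gene: tuple[int, int] = (5, 40)
    class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    af_benign: LogUniformRange = LogUniformRange(1e-3, 0.2)
    af_pathogenic: LogUniformRange = LogUniformRange(1e-6, 0.02)
    ddg_pathogenic: GaussianParams = GaussianParams((-1.5, -1.5, -1.5), (1.5, 1.5, 1.5))
    ddg_benign: GaussianParams = GaussianParams((-0.3, -0.3, -0.3), (1.0, 1.0, 1.0))
    rsa_pathogenic: BetaParams = BetaParams(2.0, 5.0)
    rsa_benign: BetaParams = BetaParams(4.0, 3.0)
    #: Optional wild-type residue weighting, e.g. {"R": 5.0} for an
    #: Arg-heavy spectrum as seen in curated monogenic databases.
    aa_bias: dict[str, float] | None = None
    #: Dirichlet concentration for per-gene class-mix jitter; smaller values
    #: give more heterogeneous genes so the 10% curation rule fires both ways.
    gene_mix_concentration: float = 4.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes: must be >= 0")
        lo, hi = self.variants_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError("variants_per_gene: need 1 <= low <= high")
        if set(self.class_mix) - set(SIGNIFICANCE_CLASSES):
            raise ConfigError("class_mix: unknown significance class")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_mix: proportions sum to {total}, not 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ConfigError("class_mix: proportions must be >= 0")
        self.af_benign.validate("af_benign")
        self.af_pathogenic.validate("af_pathogenic")
        self.ddg_pathogenic.validate("ddg_pathogenic")
        self.ddg_benign.validate("ddg_benign")
        self.rsa_pathogenic.validate("rsa_pathogenic")
        self.rsa_benign.validate("rsa_benign")
        if self.aa_bias is not None:
            if set(self.aa_bias) - set(AMINO_ACIDS):
                raise ConfigError("aa_bias: non-canonical residue key")
            if any(w < 0 for w in self.aa_bias.values()) or sum(self.aa_bias.values()) <= 0:
                raise ConfigError("aa_bias: weights must be >= 0 with positive sum")
        if self.gene_mix_concentration <= 0:
            raise ConfigError("gene_mix_concentration: must be > 0")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _rng(config: GeneratorConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([offset, config.seed])


def _aa_weights(config: GeneratorConfig) -> np.ndarray:
    if config.aa_bias is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    w = np.array([config.aa_bias.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    return w / w.sum()


def _draw_residues(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    idx = rng.choice(len(AMINO_ACIDS), size=n, p=weights)
    return np.array(list(AMINO_ACIDS))[idx]


def _draw_mutants(rng: np.random.Generator, wt: np.ndarray) -> np.ndarray:
    """Uniform mutant residue distinct from wild type."""
    aa = np.array(list(AMINO_ACIDS))
    offs = rng.integers(1, len(AMINO_ACIDS), size=len(wt))
    wt_idx = np.searchsorted(aa, wt)
    return aa[(wt_idx + offs) % len(AMINO_ACIDS)]


def _draw_allele_freqs(
    config: GeneratorConfig, rng: np.random.Generator, clin_sig: np.ndarray
) -> np.ndarray:
    af = np.empty(len(clin_sig), dtype=float)
    benign_like = np.isin(clin_sig, ["benign", "likely_benign"])
    pathogenic_like = np.isin(clin_sig, ["pathogenic", "likely_pathogenic"])
    other = ~(benign_like | pathogenic_like)
    af[benign_like] = config.af_benign.sample(rng, int(benign_like.sum()))
    af[pathogenic_like] = config.af_pathogenic.sample(rng, int(pathogenic_like.sum()))
    # VUS / conflicting: a 50:50 mixture of the two class ranges.
    n_other = int(other.sum())
    pick = rng.random(n_other) < 0.5
    mix = np.where(
        pick,
        config.af_benign.sample(rng, n_other),
        config.af_pathogenic.sample(rng, n_other),
    )
    af[other] = mix
    return af


def generate_raw_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a pre-curation variant table (one row per variant).

    Columns: gene, protein_id, position, wt_aa, mut_aa, clin_sig,
    allele_freq.  Per-gene significance mixes are jittered around
    ``config.class_mix`` with a Dirichlet draw, so some genes clear the 10%
    definitive-fraction rule and others do not.
    """
    rng = _rng(config, _OFFSET_RAW)
    weights = _aa_weights(config)
    classes = list(SIGNIFICANCE_CLASSES)
    base = np.array([config.class_mix.get(c, 0.0) for c in classes])
    lo, hi = config.variants_per_gene

    frames = []
    for g in range(config.n_genes):
        n = int(rng.integers(lo, hi + 1))
        # Dirichlet jitter over the classes present in the base mix.
        alive = base > 0
        mix = np.zeros(len(classes))
        if alive.sum() == 1:
            mix[alive] = 1.0
        else:
            mix[alive] = rng.dirichlet(base[alive] * config.gene_mix_concentration)
        clin_sig = rng.choice(classes, size=n, p=mix)
        wt = _draw_residues(rng, n, weights)
        mut = _draw_mutants(rng, wt)
        frames.append(
            pd.DataFrame(
                {
                    "gene": f"GENE{g:04d}",
                    "protein_id": f"PROT{g:04d}",
                    "position": rng.integers(1, 1001, size=n),
                    "wt_aa": wt,
                    "mut_aa": mut,
                    "clin_sig": clin_sig,
                    "allele_freq": _draw_allele_freqs(config, rng, clin_sig),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene",
                "protein_id",
                "position",
                "wt_aa",
                "mut_aa",
                "clin_sig",
                "allele_freq",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def _correlated_ddg(
    rng: np.random.Generator, params: GaussianParams, n: int
) -> np.ndarray:
    """n × 3 ΔΔG draws via the common-factor construction.

    Each standardized column is sqrt(rho)·Z_common + sqrt(1−rho)·Z_i, giving
    pairwise Pearson correlation exactly rho between predictors.
    """
    common = rng.standard_normal(n)
    out = np.empty((n, len(PREDICTORS)))
    sr, si = np.sqrt(params.rho), np.sqrt(1.0 - params.rho)
    for j, (m, s) in enumerate(zip(params.means, params.sds)):
        z = sr * common + si * rng.standard_normal(n)
        out[:, j] = m + s * z
    return out


def generate_annotated(
    config: GeneratorConfig, n_benign: int, n_pathogenic: int
) -> pd.DataFrame:
    """Generate a curated-style table with ΔΔG, RSA and binary labels.

    Returns exactly ``n_benign + n_pathogenic`` rows; label 0 = benign,
    1 = pathogenic.  ΔΔG columns come from the label's correlated Gaussian,
    RSA from the label's Beta distribution.  A functional class is assigned
    per gene so stratified analyses have a grouping column.
    """
    if n_benign < 0 or n_pathogenic < 0:
        raise ConfigError("n_benign/n_pathogenic: must be >= 0")
    rng = _rng(config, _OFFSET_ANNOTATED)
    weights = _aa_weights(config)
    n = n_benign + n_pathogenic

    labels = np.concatenate([np.zeros(n_benign, int), np.ones(n_pathogenic, int)])
    ddg = np.empty((n, len(PREDICTORS)))
    ddg[labels == 0] = _correlated_ddg(rng, config.ddg_benign, n_benign)
    ddg[labels == 1] = _correlated_ddg(rng, config.ddg_pathogenic, n_pathogenic)
    rsa = np.empty(n)
    rsa[labels == 0] = rng.beta(config.rsa_benign.a, config.rsa_benign.b, n_benign)
    rsa[labels == 1] = rng.beta(
        config.rsa_pathogenic.a, config.rsa_pathogenic.b, n_pathogenic
    )

    n_genes = max(config.n_genes, 1)
    gene_idx = rng.integers(0, n_genes, size=n)
    gene_fc = rng.choice(len(FUNCTIONAL_CLASSES), size=n_genes)
    wt = _draw_residues(rng, n, weights)
    clin_sig = np.where(labels == 1, "pathogenic", "benign")

    df = pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in gene_idx],
            "protein_id": [f"PROT{i:04d}" for i in gene_idx],
            "position": rng.integers(1, 1001, size=n),
            "wt_aa": wt,
            "mut_aa": _draw_mutants(rng, wt),
            "clin_sig": clin_sig,
            "allele_freq": _draw_allele_freqs(config, rng, clin_sig),
            "ddg_p1": ddg[:, 0],
            "ddg_p2": ddg[:, 1],
            "ddg_p3": ddg[:, 2],
            "rsa": rsa,
            "label": labels,
            "functional_class": [FUNCTIONAL_CLASSES[gene_fc[i]] for i in gene_idx],
        }
    )
    return df


def analytic_auc(config: GeneratorConfig, predictor: str = "ddg_p1") -> float:
    """Closed-form AUC of one ΔΔG predictor under the config's Gaussians.

    With pathogenicity score = −ΔΔG, two-class Gaussian AUC is
    Φ((μ_b − μ_p) / sqrt(σ_b² + σ_p²)).
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"unknown predictor {predictor!r}")
    j = PREDICTORS.index(predictor)
    mu_p, sd_p = config.ddg_pathogenic.means[j], config.ddg_pathogenic.sds[j]
    mu_b, sd_b = config.ddg_benign.means[j], config.ddg_benign.sds[j]
    return float(norm.cdf((mu_b - mu_p) / np.hypot(sd_b, sd_p)))


def analytic_auc_rsa(config: GeneratorConfig, grid: int = 20001) -> float:
    """AUC of RSA as a pathogenicity score (lower RSA = more pathogenic).

    P(X_p < X_b) + 0.5·P(X_p = X_b) for independent Beta draws, evaluated
    by numerical quadrature (continuous distributions, so ties have measure
    zero).
    """
    from scipy.stats import beta as beta_dist

    x = np.linspace(0.0, 1.0, grid)
    fp = beta_dist.pdf(x, config.rsa_pathogenic.a, config.rsa_pathogenic.b)
    sb = beta_dist.sf(x, config.rsa_benign.a, config.rsa_benign.b)
    return float(np.trapezoid(fp * sb, x))


def generate_sequences(
    config: GeneratorConfig, n: int, min_len: int, max_len: int
) -> list[tuple[str, str]]:
    """Generate ``n`` random protein sequences as (id, sequence) pairs.

    Lengths are uniform in [min_len, max_len]; residues are drawn from the
    canonical 20 with ``aa_bias`` weighting if configured.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    rng = _rng(config, _OFFSET_SEQUENCES)
    weights = _aa_weights(config)
    records = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_draw_residues(rng, length, weights))
        records.append((f"SYN{i:04d}", seq))
    return records
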