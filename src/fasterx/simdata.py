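"""Synthetic datasets with the statistical structure of a faster-X study.

The generator produces a per-gene table (chromosome class, sex-bias
class, expression level, expression divergence and polymorphism, tissue
specificity, interaction degree), a gene-by-tissue expression matrix, a
protein-interaction edge list, replicated two-species log2 expression
measurements, and codon-aligned orthologous CDS pairs evolved under a
single-omega codon model — everything the downstream analysis consumes,
with no external data.

Generative structure: expression divergence is log-normal around a
linear predictor in level (negative coefficient), tau (positive) and
log interaction degree (negative), and is multiplied by
``x_mbg_inflation`` for genes that are both X-linked and male-biased;
``x_mbg_inflation = 1`` is the exchangeable null. Covariate
distributions depend on the sex-bias class only, so under the null
X-linked and autosomal genes of the same class are statistically
identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from . import _codon
from .codonevol import CodonSequencePair
from .exprprops import FBG, MBG, NBG, tissue_specificity

BIAS_CLASSES = (MBG, FBG, NBG)


@dataclass(frozen=True)
class LinearEffectModel:
    """Log-scale linear model for a positive per-gene response:
    log(response) = intercept + b_level*level + b_tau*tau
    + b_degree*log1p(degree) + noise_sd * eps."""

    intercept: float
    b_level: float
    b_tau: float
    b_degree: float
    noise_sd: float

    def sample(self, level, tau, degree, eps) -> float:
        mu = (
            self.intercept
            + self.b_level * level
            + self.b_tau * tau
            + self.b_degree * math.log1p(degree)
        )
        return math.exp(mu + self.noise_sd * eps)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a two-species Drosophila comparison at roughly the
    composition of the analyzed gene set (about 16% X-linked genes;
    bias-class proportions 20% MBG / 19% FBG / 61% NBG), with shallow
    divergence (mean t about 0.05 substitutions per codon), strong
    purifying selection (mean omega 0.1) and 25 tissues.
    """

    n_genes: int = 1000
    prop_x: float = 0.16
    bias_props: tuple = (0.20, 0.19, 0.61)  # MBG, FBG, NBG
    # true omega per (chromosome class, bias class): gamma(shape, mean/shape)
    omega_mean: dict = field(
        default_factory=lambda: {
            (c, b): 0.10 for c in ("X", "A") for b in BIAS_CLASSES
        }
    )
    omega_shape: float = 2.0
    kappa: float = 2.0
    t_log_mean: float = math.log(0.05)  # substitutions per codon
    t_log_sd: float = 0.4
    n_codons_log_mean: float = math.log(400.0)
    n_codons_log_sd: float = 0.4
    n_codons_min: int = 30
    n_codons_max: int = 2000
    n_tissues: int = 25
    # symmetric Dirichlet concentration per bias class; lower => higher tau
    tau_concentration: dict = field(
        default_factory=lambda: {MBG: 0.20, FBG: 0.35, NBG: 0.50}
    )
    level_mean: float = 5.0
    level_sd: float = 2.0
    divergence_model: LinearEffectModel = LinearEffectModel(
        intercept=-1.2, b_level=-0.12, b_tau=0.8, b_degree=-0.15, noise_sd=0.5
    )
    polymorphism_model: LinearEffectModel = LinearEffectModel(
        intercept=-1.6, b_level=-0.08, b_tau=0.4, b_degree=-0.10, noise_sd=0.4
    )
    x_mbg_inflation: float = 1.0  # 1.0 = null
    # mean interaction degree per bias class (negative binomial, given shape)
    degree_mean: dict = field(
        default_factory=lambda: {MBG: 5.0, FBG: 8.0, NBG: 10.0}
    )
    degree_shape: float = 2.0
    n_replicates: int = 2
    with_sequences: bool = True
    codon_freqs: np.ndarray | None = None  # default: uniform over 61
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.prop_x <= 1.0:
            raise ValueError("prop_x must lie in [0, 1]")
        if len(self.bias_props) != 3 or any(p < 0 or p > 1 for p in self.bias_props):
            raise ValueError("bias_props must be three fractions in [0, 1]")
        if abs(sum(self.bias_props) - 1.0) > 1e-12:
            raise ValueError("bias_props must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be strictly positive")
        if self.x_mbg_inflation < 0:
            raise ValueError("x_mbg_inflation must be >= 0")
        if any(a <= 0 for a in self.tau_concentration.values()):
            raise ValueError("tau_concentration values must be strictly positive")
        if any(m <= 0 for m in self.degree_mean.values()):
            raise ValueError("degree_mean values must be strictly positive")
        if self.n_tissues < 2:
            raise ValueError("n_tissues must be >= 2")
        if self.n_codons_min <= 0:
            raise ValueError("n_codons_min must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.omega_shape <= 0 or self.degree_shape <= 0:
            raise ValueError("distribution shape parameters must be positive")


@dataclass
class SyntheticDataset:
    gene_table: pd.DataFrame  # indexed by gene_id
    codon_pairs: dict  # gene_id -> CodonSequencePair
    tissue_matrix: pd.DataFrame  # genes x tissues
    interaction_edges: list  # unordered gene-id pairs
    measurements: pd.DataFrame  # gene_id, species, replicate, log2_signal
    config_echo: SimulationConfig
    seed_used: int


def largest_remainder_counts(n: int, proportions) -> list[int]:
    """Deterministic quota rounding: integer class counts summing to n,
    proportional to ``proportions`` (largest-remainder method; ties go
    to the earlier class)."""
    props = np.asarray(proportions, dtype=float)
    quotas = props * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def _gene_rng(master_seed: int, index: int, stream: int = 0) -> np.random.Generator:
    # per-gene substreams: adding genes never perturbs earlier genes.
    # stream 0 carries label-independent draws, stream 1 the class-
    # dependent ones, so a class relabel cannot shift the former.
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(index, stream))
    )


def chromosome_copy_accounting(
    chromosome_class: str, n_females: int, n_males: int
) -> dict:
    """Population chromosome-copy bookkeeping.

    Females carry two X copies, males one; autosomes are carried twice
    by everyone. Returns the chromosome's copy count relative to an
    autosome and the share of its copies residing in females. At an
    equal sex ratio the X:A ratio is exactly 3/4 and an X copy spends
    2/3 of its time in females.
    """
    if n_females < 1 or n_males < 1:
        raise ValueError("n_females and n_males must be >= 1")
    if chromosome_class == "X":
        x_copies = 2 * n_females + n_males
        a_copies = 2 * (n_females + n_males)
        return {
            "copy_ratio_vs_autosome": x_copies / a_copies,
            "fraction_in_females": 2 * n_females / x_copies,
        }
    if chromosome_class in ("A", "autosome"):
        return {
            "copy_ratio_vs_autosome": 1.0,
            "fraction_in_females": n_females / (n_females + n_males),
        }
    raise ValueError(f"unknown chromosome class {chromosome_class!r}")


def simulate_codon_pair(
    omega: float,
    kappa: float,
    t: float,
    codon_freqs,
    n_codons: int,
    seed,
    gene_id: str = "gene",
) -> CodonSequencePair:
    """Evolve a codon-aligned orthologous pair under the single-omega
    codon model.

    An ancestral sequence is drawn from ``codon_freqs`` (61 sense-codon
    probabilities, lexicographic order) and evolved along a single
    lineage of total length ``t`` expected substitutions per codon by
    sampling each descendant codon from the exact transition kernel
    expm(Q t); under reversibility this matches evolving both branches
    from a common ancestor at total divergence t. Stop codons are
    unreachable; the pair has no gaps and no internal stops.
    """
    freqs = np.asarray(codon_freqs, dtype=float)
    if freqs.shape != (_codon.N_SENSE,):
        raise ValueError(f"codon_freqs must have {_codon.N_SENSE} entries (sense codons only)")
    if np.any(freqs < 0):
        raise ValueError("codon_freqs must be nonnegative")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("codon_freqs must sum to 1 (within 1e-9)")
    if t < 0:
        raise ValueError("t must be >= 0")
    if n_codons <= 0:
        raise ValueError("n_codons must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    anc_idx = rng.choice(_codon.N_SENSE, size=n_codons, p=freqs)
    if t == 0:
        des_idx = anc_idx.copy()
    else:
        q = _codon.rate_matrix(kappa, omega, freqs)
        p = _codon.transition_probabilities(q, freqs, t)
        p = p / p.sum(axis=1, keepdims=True)
        u = rng.random(n_codons)
        cum = np.cumsum(p, axis=1)
        des_idx = (u[:, None] > cum[anc_idx]).sum(axis=1)
        des_idx = np.minimum(des_idx, _codon.N_SENSE - 1)
    seq_a = "".join(_codon.SENSE_CODONS[i] for i in anc_idx)
    seq_b = "".join(_codon.SENSE_CODONS[i] for i in des_idx)
    return CodonSequencePair(gene_id, seq_a, seq_b)


def _exact_sd_replicates(mean: float, sd: float, n: int) -> np.ndarray:
    """n replicate values with sample mean ``mean`` and sample SD
    exactly ``sd`` (deterministic alternating pattern)."""
    pattern = np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
    pattern -= pattern.mean()
    norm = math.sqrt((pattern**2).sum() / (n - 1))
    if norm == 0:
        return np.full(n, mean)
    return mean + sd * pattern / norm


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one synthetic dataset under ``config``.

    Class labels are assigned by deterministic largest-remainder quotas
    (X count first, then bias classes within each chromosome class), so
    configured proportions are exact at small n. All per-gene draws use
    per-gene substreams of the master seed. The interaction network is
    a configuration-model graph on the drawn degree sequence, simplified
    to remove self-loops and parallel edges; the gene table records the
    realized degree.
    """
    config.validate()
    n = config.n_genes
    gene_ids = [f"g{i:06d}" for i in range(n)]

    n_x = largest_remainder_counts(n, [config.prop_x, 1 - config.prop_x])[0]
    chrom = np.array(["X"] * n_x + ["A"] * (n - n_x))
    bias = np.empty(n, dtype=object)
    for cls, size, offset in (("X", n_x, 0), ("A", n - n_x, n_x)):
        counts = largest_remainder_counts(size, config.bias_props)
        labels = [b for b, c in zip(BIAS_CLASSES, counts) for _ in range(c)]
        bias[offset : offset + size] = labels

    level = np.empty(n)
    tau = np.empty(n)
    omega_true = np.empty(n)
    t_true = np.empty(n)
    n_codons = np.empty(n, dtype=int)
    drawn_degree = np.empty(n, dtype=int)
    eps_div = np.empty(n)
    eps_poly = np.empty(n)
    profiles = np.empty((n, config.n_tissues))
    seq_seeds = []

    for i in range(n):
        rng = _gene_rng(config.seed, i, stream=0)
        rng_cls = _gene_rng(config.seed, i, stream=1)
        b = bias[i]
        level[i] = rng.normal(config.level_mean, config.level_sd)
        t_true[i] = rng.lognormal(config.t_log_mean, config.t_log_sd)
        n_codons[i] = int(
            np.clip(
                round(rng.lognormal(config.n_codons_log_mean, config.n_codons_log_sd)),
                config.n_codons_min,
                config.n_codons_max,
            )
        )
        eps_div[i] = rng.normal()
        eps_poly[i] = rng.normal()
        seq_seeds.append(rng.integers(0, 2**31 - 1))

        alpha = config.tau_concentration[b]
        profile = rng_cls.dirichlet(np.full(config.n_tissues, alpha))
        profiles[i] = profile
        tau[i] = tissue_specificity(profile)
        mean_w = config.omega_mean[(chrom[i], b)]
        omega_true[i] = rng_cls.gamma(config.omega_shape, mean_w / config.omega_shape)
        mean_d = config.degree_mean[b]
        p_nb = config.degree_shape / (config.degree_shape + mean_d)
        drawn_degree[i] = rng_cls.negative_binomial(config.degree_shape, p_nb)

    # interaction network: configuration model on the drawn degrees,
    # simplified (self-loops and parallel edges dropped)
    deg_seq = drawn_degree.copy()
    if deg_seq.sum() % 2 == 1:
        j = int(np.argmax(deg_seq > 0))
        deg_seq[j] += 1
    graph_rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2**31,))
    )
    multigraph = nx.configuration_model(
        deg_seq.tolist(), seed=int(graph_rng.integers(0, 2**31 - 1))
    )
    graph = nx.Graph(multigraph)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    realized_degree = np.array([graph.degree(i) for i in range(n)])
    edges = sorted((gene_ids[min(u, v)], gene_ids[max(u, v)]) for u, v in graph.edges())

    divergence = np.empty(n)
    polymorphism = np.empty(n)
    for i in range(n):
        d = config.divergence_model.sample(
            level[i], tau[i], realized_degree[i], eps_div[i]
        )
        if chrom[i] == "X" and bias[i] == MBG:
            d *= config.x_mbg_inflation
        divergence[i] = d
        polymorphism[i] = config.polymorphism_model.sample(
            level[i], tau[i], realized_degree[i], eps_poly[i]
        )

    # replicated two-species log2 measurements consistent with the
    # gene-level summaries (species means level +/- divergence/2; within-
    # species spread constructed so the pooled SD equals polymorphism)
    rows = []
    for i in range(n):
        for sp, sign in ((1, +0.5), (2, -0.5)):
            mean_sp = level[i] + sign * divergence[i]
            reps = _exact_sd_replicates(mean_sp, polymorphism[i], config.n_replicates)
            for r, val in enumerate(reps, start=1):
                rows.append((gene_ids[i], sp, r, val))
    measurements = pd.DataFrame(
        rows, columns=["gene_id", "species", "replicate", "log2_signal"]
    )

    tissue_matrix = pd.DataFrame(
        profiles * np.exp2(level)[:, None],
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"tissue_{j+1}" for j in range(config.n_tissues)],
    )

    codon_pairs = {}
    if config.with_sequences:
        freqs = (
            np.full(_codon.N_SENSE, 1.0 / _codon.N_SENSE)
            if config.codon_freqs is None
            else np.asarray(config.codon_freqs, dtype=float)
        )
        for i in range(n):
            codon_pairs[gene_ids[i]] = simulate_codon_pair(
                omega_true[i],
                config.kappa,
                t_true[i],
                freqs,
                n_codons[i],
                int(seq_seeds[i]),
                gene_id=gene_ids[i],
            )

    gene_table = pd.DataFrame(
        {
            "chromosome": chrom,
            "bias_class": bias,
            "level": level,
            "tau": tau,
            "divergence": divergence,
            "polymorphism": polymorphism,
            "degree": realized_degree,
            "omega_true": omega_true,
            "t_true": t_true,
            "n_codons": n_codons,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticDataset(
        gene_table=gene_table,
        codon_pairs=codon_pairs,
        tissue_matrix=tissue_matrix,
        interaction_edges=edges,
        measurements=measurements,
        config_echo=config,
        seed_used=config.seed,
    )


def null_config(**overrides) -> SimulationConfig:
    """Convenience: the exchangeable-null configuration
    (x_mbg_inflation = 1) with optional field overrides."""
    overrides.setdefault("x_mbg_inflation", 1.0)
    return replace(SimulationConfig(), **overrides)
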