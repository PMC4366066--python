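"""Per-gene expression properties.

Level, between-species divergence and within-species polymorphism from
replicated log2 expression measurements in two species; the Yanai et al.
tissue-specificity index tau from a gene-by-tissue profile; and sex-bias
classification (MBG / FBG / NBG) from male vs female expression levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MBG = "MBG"
FBG = "FBG"
NBG = "NBG"

EXPRESSION_COLUMNS = ["gene_id", "species", "replicate", "log2_signal"]


@dataclass
class ExpressionSummary:
    gene_id: str
    level: float
    divergence: float
    polymorphism: float  # NaN when < 2 replicates per species
    tau: float = math.nan
    bias_class: str | None = None


def summarize_expression(measurements: pd.DataFrame, gene: str) -> ExpressionSummary:
    """Level, divergence and polymorphism for one gene.

    * level — unweighted mean of the two species' mean log2 signals;
    * divergence — absolute difference of the species means;
    * polymorphism — within-species SD of the log2 signal pooled across
      the two species by degrees of freedom (NaN, not 0, when either
      species has fewer than 2 replicates).
    """
    sub = measurements[measurements["gene_id"] == gene]
    by_species = {}
    for sp in (1, 2):
        vals = sub.loc[sub["species"] == sp, "log2_signal"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise ValueError(f"gene {gene!r} missing in species {sp}")
        by_species[sp] = vals
    m1, m2 = by_species[1].mean(), by_species[2].mean()
    level = 0.5 * (m1 + m2)
    divergence = abs(m1 - m2)
    n1, n2 = len(by_species[1]), len(by_species[2])
    if n1 >= 2 and n2 >= 2:
        ss = sum(((v - v.mean()) ** 2).sum() for v in by_species.values())
        polymorphism = math.sqrt(ss / (n1 + n2 - 2))
    else:
        polymorphism = math.nan
    return ExpressionSummary(gene, level, divergence, polymorphism)


def summarize_expression_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`summarize_expression` over every gene present in
    both species; returns a DataFrame indexed by gene_id with columns
    level, divergence, polymorphism."""
    g = measurements.groupby(["gene_id", "species"])["log2_signal"]
    means = g.mean().unstack("species")
    counts = g.size().unstack("species", fill_value=0)
    both = means.dropna(subset=[1, 2]).index
    means = means.loc[both]
    counts = counts.loc[both]
    level = means[[1, 2]].mean(axis=1)
    divergence = (means[1] - means[2]).abs()
    centered = measurements.set_index(["gene_id", "species"])["log2_signal"] - g.mean()
    ss = (centered**2).groupby("gene_id").sum().reindex(both)
    dof = counts[1] + counts[2] - 2
    poly = np.sqrt(ss / dof)
    poly[(counts[1] < 2) | (counts[2] < 2)] = np.nan
    out = pd.DataFrame(
        {"level": level, "divergence": divergence, "polymorphism": poly}
    )
    out.index.name = "gene_id"
    return out


def tissue_specificity(profile) -> float:
    """Tissue-specificity index tau (Yanai et al. 2005).

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1) over N >= 2 tissues;
    0 for a uniform profile, 1 for single-tissue expression, invariant
    to positive rescaling of the profile.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be 1-D with at least 2 tissues")
    if np.any(x < 0):
        raise ValueError("negative expression values in tissue profile")
    mx = x.max()
    if mx == 0:
        raise ValueError("all-zero tissue profile: tau undefined")
    return float((1.0 - x / mx).sum() / (len(x) - 1))


def tissue_specificity_table(tissue_matrix: pd.DataFrame) -> pd.Series:
    """Tau per gene for a gene-by-tissue matrix (rows = genes)."""
    x = tissue_matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative expression values in tissue matrix")
    mx = x.max(axis=1)
    tau = np.full(len(x), np.nan)
    ok = mx > 0
    n = x.shape[1]
    tau[ok] = (1.0 - x[ok] / mx[ok, None]).sum(axis=1) / (n - 1)
    return pd.Series(tau, index=tissue_matrix.index, name="tau")


def classify_sex_bias(
    male_level: float, female_level: float, log2_threshold: float = 1.0
) -> str:
    """MBG if male - female >= threshold (log2), FBG if female - male >=
    threshold, NBG otherwise. Default threshold 1 (2-fold)."""
    if not (math.isfinite(male_level) and math.isfinite(female_level)):
        raise ValueError("non-finite expression level")
    if log2_threshold <= 0:
        raise ValueError("log2_threshold must be positive")
    d = male_level - female_level
    if d >= log2_threshold:
        return MBG
    if -d >= log2_threshold:
        return FBG
    return NBG
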