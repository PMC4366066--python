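"""Shared codon-model machinery.

Builds the single-omega (Model-0 style) codon rate matrix of Goldman-Yang
form on the 61 sense codons of the standard genetic code, with F3x4
equilibrium frequencies, and exposes transition probabilities via
eigendecomposition of the symmetrized reversible generator.

Codon order everywhere is lexicographic over {A,C,G,T} triplets with the
three stop codons (TAA, TAG, TGA) removed.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

NUCS = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))

ALL_CODONS = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AMINO_ACIDS = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in _TABLE.stop_codons:
        return "*"
    return _TABLE.forward_table[codon]


def is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _build_static_tables():
    n = N_SENSE
    ndiff = np.zeros((n, n), dtype=np.int8)
    single_ts = np.zeros((n, n), dtype=bool)   # single-diff & transition
    single_tv = np.zeros((n, n), dtype=bool)   # single-diff & transversion
    nonsyn = np.zeros((n, n), dtype=bool)      # amino acids differ
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            d = sum(x != y for x, y in zip(ci, cj))
            ndiff[i, j] = d
            if d == 1:
                pos = next(k for k in range(3) if ci[k] != cj[k])
                if is_transition(ci[pos], cj[pos]):
                    single_ts[i, j] = True
                else:
                    single_tv[i, j] = True
            if AMINO_ACIDS[i] != AMINO_ACIDS[j]:
                nonsyn[i, j] = True
    return ndiff, single_ts, single_tv, nonsyn


NDIFF, SINGLE_TS, SINGLE_TV, NONSYN = _build_static_tables()
SINGLE_DIFF = SINGLE_TS | SINGLE_TV

# nucleotide composition of each sense codon, per position: (61, 3) indices
CODON_POS_NUC = np.array(
    [[_NUC_INDEX[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.intp
)

_FREQ_FLOOR = 1e-8  # numerical floor for codon frequencies


def f3x4_frequencies(
    pos_nuc_freqs: np.ndarray, third_position_only: bool = False
) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide frequencies.

    Parameters
    ----------
    pos_nuc_freqs : (3, 4) array
        Nucleotide frequencies (A, C, G, T) at codon positions 1-3; each
        row sums to 1.
    third_position_only : bool
        If True, use the third-position frequencies at all three positions
        (sensitivity variant for the ambiguous "average nucleotide
        frequencies at third codon positions" reading).

    Returns
    -------
    (61,) array of sense-codon frequencies summing to 1.
    """
    f = np.asarray(pos_nuc_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("pos_nuc_freqs must have shape (3, 4)")
    if third_position_only:
        f = np.tile(f[2], (3, 1))
    pi = (
        f[0, CODON_POS_NUC[:, 0]]
        * f[1, CODON_POS_NUC[:, 1]]
        * f[2, CODON_POS_NUC[:, 2]]
    )
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def count_position_nucleotides(codons: list[str]) -> np.ndarray:
    """(3, 4) nucleotide frequency table from a list of codons."""
    counts = np.zeros((3, 4), dtype=float)
    for codon in codons:
        for p, base in enumerate(codon):
            counts[p, _NUC_INDEX[base]] += 1.0
    if counts.sum() == 0:
        raise ValueError("no codons supplied")
    return counts / counts.sum(axis=1, keepdims=True)


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Single-omega codon generator, scaled to one expected substitution
    per codon per unit time.

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous] for codon
    pairs differing at a single position; 0 otherwise. Stop codons are
    outside the state space, hence unreachable.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,):
        raise ValueError(f"pi must have {N_SENSE} entries")
    q = np.zeros((N_SENSE, N_SENSE))
    q[SINGLE_TV] = 1.0
    q[SINGLE_TS] = kappa
    q[NONSYN & SINGLE_DIFF] *= omega
    q *= pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero total flux)")
    return q / scale


def transition_probabilities(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via eigendecomposition of the symmetrized
    reversible generator; falls back to scipy's scaling-and-squaring if
    the spectral reconstruction is ill-conditioned."""
    sqrt_pi = np.sqrt(pi)
    sym = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    try:
        lam, u = np.linalg.eigh(sym)
        inner = (u * np.exp(lam * t)) @ u.T
        p = (inner / sqrt_pi[:, None]) * sqrt_pi[None, :]
        rowsum = p.sum(axis=1)
        if not np.all(np.isfinite(p)) or np.max(np.abs(rowsum - 1.0)) > 1e-8:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        from scipy.linalg import expm

        p = expm(q * t)
    return np.clip(p, 0.0, None)


def flux_proportions(kappa: float, omega: float, pi: np.ndarray) -> tuple[float, float]:
    """Proportions (synonymous, nonsynonymous) of equilibrium substitution
    flux under the model."""
    q = rate_matrix(kappa, omega, pi)
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    flux = pi[:, None] * off
    total = flux.sum()
    syn = flux[~NONSYN].sum()
    return syn / total, 1.0 - syn / total
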