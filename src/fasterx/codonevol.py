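"""Pairwise coding-sequence divergence: QC, site filtering, and dN/dS.

Two estimators are provided for codon-aligned orthologous CDS pairs:

* :func:`ng86` — Nei-Gojobori (1986) counting of synonymous and
  nonsynonymous sites and differences with Jukes-Cantor multiple-hit
  correction; pathways through stop codons are excluded.
* :func:`gy94_ml` — maximum likelihood under a single-omega codon
  substitution model (one dN/dS ratio for all sites) with F3x4
  equilibrium frequencies estimated from the pair itself.

Plus the consensus-site quality filter (sites kept only when read depth
exceeds 7x and phred-scaled consensus quality exceeds Q = 40, both strict)
and the gene-level exclusion rules (internal stop codons, zero observed
synonymous changes, omega >= 9).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import _codon
from ._codon import (
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    STOP_CODONS,
    f3x4_frequencies,
    flux_proportions,
    rate_matrix,
    transition_probabilities,
    translate_codon,
)

MASK_CHAR = "N"

# optimizer bounds (natural scale)
T_BOUNDS = (1e-6, 10.0)
KAPPA_BOUNDS = (0.01, 100.0)
OMEGA_BOUNDS = (1e-4, 99.0)


@dataclass
class CodonSequencePair:
    """Two codon-aligned CDS sharing a gene ID.

    Sequences are nucleotide strings over {A, C, G, T, N, -} of equal
    length divisible by 3.
    """

    gene_id: str
    seq_a: str
    seq_b: str
    genetic_code: int = 1

    def __post_init__(self):
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"{self.gene_id}: aligned sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )

    def swapped(self) -> "CodonSequencePair":
        return CodonSequencePair(self.gene_id, self.seq_b, self.seq_a, self.genetic_code)


@dataclass
class QCReport:
    gene_id: str
    ok: bool
    internal_stop_a: bool = False
    internal_stop_b: bool = False
    length_error: bool = False
    ambiguous_codon_count: int = 0
    n_codons_usable: int = 0
    terminal_stop_trimmed: bool = False


@dataclass
class DivergenceEstimate:
    """Pairwise divergence estimate for one gene.

    dN and dS are substitutions per nonsynonymous / synonymous site;
    t is expected substitutions per codon. ``syn_differences`` carries
    the observed (pathway-averaged) synonymous difference count, used by
    the zero-synonymous-changes exclusion rule.
    """

    gene_id: str
    method: str  # "NG86" or "ML_M0"
    dN: float
    dS: float
    omega: float
    kappa: float
    t: float
    logL: float
    n_codons_used: int
    syn_differences: float | None = None
    reliable: bool = True


@dataclass
class FilterResult:
    kept: list = field(default_factory=list)
    excluded: dict = field(default_factory=dict)  # gene_id -> primary reason


# ---------------------------------------------------------------------------
# consensus site filter
# ---------------------------------------------------------------------------

def consensus_site_filter(
    depths,
    qualities,
    bases,
    min_depth: int = 7,
    min_quality: float = 40.0,
):
    """Mask consensus sites failing the depth/quality rule.

    A site is retained iff depth > min_depth AND quality > min_quality
    (both inequalities strict; a site at exactly the threshold is masked).

    Returns (masked base string, fraction of sites retained).
    """
    depths = np.asarray(depths)
    qualities = np.asarray(qualities, dtype=float)
    bases = list(bases)
    if not (len(depths) == len(qualities) == len(bases)):
        raise ValueError(
            f"length mismatch: depths={len(depths)}, qualities={len(qualities)}, "
            f"bases={len(bases)}"
        )
    keep = (depths > min_depth) & (qualities > min_quality)
    masked = "".join(b if k else MASK_CHAR for b, k in zip(bases, keep))
    frac = float(keep.mean()) if len(bases) else 0.0
    return masked, frac


# ---------------------------------------------------------------------------
# CDS validation
# ---------------------------------------------------------------------------

def _codons_of(seq: str):
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _is_ambiguous(codon: str) -> bool:
    return any(c not in "ACGT" for c in codon)


def validate_cds(pair: CodonSequencePair) -> QCReport:
    """QC a codon-aligned pair.

    A terminal stop codon (in either sequence) is permitted: the final
    codon column is trimmed. Internal stop codons are fatal for the gene.
    Codons containing N or '-' in either sequence are counted and excluded
    pairwise downstream.
    """
    rep = QCReport(gene_id=pair.gene_id, ok=False)
    if len(pair.seq_a) % 3 != 0:
        rep.length_error = True
        return rep
    ca, cb = _codons_of(pair.seq_a), _codons_of(pair.seq_b)
    if ca and (
        (not _is_ambiguous(ca[-1]) and ca[-1] in STOP_CODONS)
        or (not _is_ambiguous(cb[-1]) and cb[-1] in STOP_CODONS)
    ):
        ca, cb = ca[:-1], cb[:-1]
        rep.terminal_stop_trimmed = True
    usable = 0
    for a, b in zip(ca, cb):
        amb = _is_ambiguous(a) or _is_ambiguous(b)
        if amb:
            rep.ambiguous_codon_count += 1
            continue
        if a in STOP_CODONS:
            rep.internal_stop_a = True
        if b in STOP_CODONS:
            rep.internal_stop_b = True
        if a not in STOP_CODONS and b not in STOP_CODONS:
            usable += 1
    rep.n_codons_usable = usable
    rep.ok = not (rep.internal_stop_a or rep.internal_stop_b or rep.length_error)
    return rep


def usable_codon_pairs(pair: CodonSequencePair):
    """Trim the terminal stop column and drop ambiguous codon columns
    pairwise; returns a list of (codon_a, codon_b) over sense codons."""
    rep = validate_cds(pair)
    if rep.length_error:
        raise ValueError(f"{pair.gene_id}: length not divisible by 3")
    if not rep.ok:
        raise ValueError(f"{pair.gene_id}: internal stop codon; gene unusable")
    ca, cb = _codons_of(pair.seq_a), _codons_of(pair.seq_b)
    if rep.terminal_stop_trimmed:
        ca, cb = ca[:-1], cb[:-1]
    return [
        (a, b)
        for a, b in zip(ca, cb)
        if not (_is_ambiguous(a) or _is_ambiguous(b))
    ]


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Each position contributes one site, split by the fraction of
    synonymous changes among its non-stop single-nucleotide neighbours.
    """
    aa = translate_codon(codon)
    s = 0.0
    for p in range(3):
        syn = nonstop = 0
        for b in "ACGT":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut in STOP_CODONS:
                continue
            nonstop += 1
            if translate_codon(mut) == aa:
                syn += 1
        if nonstop:
            s += syn / nonstop
    return s, 3.0 - s


_SITE_CACHE = {c: _codon_site_counts(c) for c in SENSE_CODONS}
_PATH_CACHE: dict = {}


def _codon_diff_counts(a: str, b: str) -> tuple[float, float]:
    """Synonymous / nonsynonymous difference counts between two sense
    codons, averaged over all minimal mutational pathways that avoid stop
    codons. If every pathway passes through a stop, all pathways are used
    with stop transitions counted as nonsynonymous."""
    if a == b:
        return 0.0, 0.0
    key = (a, b) if a <= b else (b, a)
    cached = _PATH_CACHE.get(key)
    if cached is not None:
        return cached
    positions = [p for p in range(3) if a[p] != b[p]]
    valid = []
    all_paths = []
    for order in itertools.permutations(positions):
        cur = a
        syn = nonsyn = 0.0
        blocked = False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                nonsyn += 1.0
            elif translate_codon(cur) == translate_codon(nxt):
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        all_paths.append((syn, nonsyn))
        if not blocked:
            valid.append((syn, nonsyn))
    pool = valid if valid else all_paths
    sd = sum(p[0] for p in pool) / len(pool)
    nd = sum(p[1] for p in pool) / len(pool)
    _PATH_CACHE[key] = (sd, nd)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p == 0.0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: CodonSequencePair) -> DivergenceEstimate:
    """Nei-Gojobori (1986) counting estimate of dN and dS.

    Site counts are averaged over the two sequences; multi-hit codon
    differences are averaged over minimal mutational pathways (stop-codon
    pathways excluded); proportions are corrected with the Jukes-Cantor
    formula. dS is exactly 0 when no synonymous difference is observed;
    a corrected proportion >= 3/4 yields NaN for that distance class.
    """
    codons = usable_codon_pairs(pair)
    if not codons:
        raise ValueError(f"{pair.gene_id}: no usable codons")
    s_sites = n_sites = sd = nd = 0.0
    for a, b in codons:
        sa, na = _SITE_CACHE[a]
        sb, nb = _SITE_CACHE[b]
        s_sites += 0.5 * (sa + sb)
        n_sites += 0.5 * (na + nb)
        dsyn, dnon = _codon_diff_counts(a, b)
        sd += dsyn
        nd += dnon
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    omega = dn / ds if (ds and ds > 0 and not math.isnan(dn)) else math.nan
    n_codons = len(codons)
    t = math.nan
    if not (math.isnan(ds) or math.isnan(dn)):
        t = (s_sites * ds + n_sites * dn) / n_codons
    return DivergenceEstimate(
        gene_id=pair.gene_id,
        method="NG86",
        dN=dn,
        dS=ds,
        omega=omega,
        kappa=math.nan,
        t=t,
        logL=math.nan,
        n_codons_used=n_codons,
        syn_differences=sd,
    )


# ---------------------------------------------------------------------------
# single-omega ML (GY94 form, F3x4)
# ---------------------------------------------------------------------------

def _pair_counts(codons) -> np.ndarray:
    counts = np.zeros((N_SENSE, N_SENSE))
    for a, b in codons:
        counts[CODON_INDEX[a], CODON_INDEX[b]] += 1.0
    return counts


def _neg_loglik(log_params, counts, pi):
    t, kappa, omega = np.exp(log_params)
    q = rate_matrix(kappa, omega, pi)
    p = transition_probabilities(q, pi, t)
    joint = pi[:, None] * p
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.maximum(joint, 1e-300)), 0.0)
    return -ll.sum()


def gy94_ml(
    pair: CodonSequencePair,
    init: dict | None = None,
    third_position_only: bool = False,
) -> DivergenceEstimate:
    """Maximum-likelihood pairwise divergence under the single-omega codon
    model with F3x4 frequencies.

    The likelihood is maximized over (t, kappa, omega) by bounded
    multi-start local optimization in log-parameter space (starts:
    NG86-informed, neutral omega = 1, and omega = 0.1; plus ``init`` if
    given). dN and dS are decomposed from t via the model's equilibrium
    synonymous/nonsynonymous flux proportions (mutational-opportunity
    site definition). Estimates are invariant to swapping the sequences
    (reversibility).
    """
    codons = usable_codon_pairs(pair)
    if not codons:
        raise ValueError(f"{pair.gene_id}: no usable codons")
    counts = _pair_counts(codons)
    all_codons = [c for ab in codons for c in ab]
    pos_freqs = _codon.count_position_nucleotides(all_codons)
    pi = f3x4_frequencies(pos_freqs, third_position_only=third_position_only)

    counting = ng86(pair)
    p_diff = float(np.mean([a != b for a, b in codons]))
    t_rough = min(max(-math.log(max(1.0 - p_diff, 1e-6)), T_BOUNDS[0]), 5.0)
    starts = []
    if init is not None:
        starts.append((init.get("t", t_rough), init.get("kappa", 2.0), init.get("omega", 1.0)))
    t_ng = counting.t if not math.isnan(counting.t) else t_rough
    w_ng = counting.omega if not math.isnan(counting.omega) else 1.0
    starts.append((t_ng, 2.0, w_ng))
    starts.append((t_rough, 2.0, 1.0))
    starts.append((t_rough, 2.0, 0.1))

    lo = np.log([T_BOUNDS[0], KAPPA_BOUNDS[0], OMEGA_BOUNDS[0]])
    hi = np.log([T_BOUNDS[1], KAPPA_BOUNDS[1], OMEGA_BOUNDS[1]])
    best = None
    any_converged = False
    for t0, k0, w0 in starts:
        x0 = np.clip(np.log([max(t0, T_BOUNDS[0]), k0, max(w0, OMEGA_BOUNDS[0])]), lo, hi)
        res = minimize(
            _neg_loglik,
            x0,
            args=(counts, pi),
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best = res

    t_hat, k_hat, w_hat = np.exp(best.x)
    rho_s, rho_n = flux_proportions(k_hat, w_hat, pi)
    rho_s1, rho_n1 = flux_proportions(k_hat, 1.0, pi)
    ds = t_hat * rho_s / (3.0 * rho_s1)
    dn = t_hat * rho_n / (3.0 * rho_n1)
    at_floor = t_hat <= T_BOUNDS[0] * (1 + 1e-6)
    if at_floor:
        dn = ds = 0.0
    return DivergenceEstimate(
        gene_id=pair.gene_id,
        method="ML_M0",
        dN=dn,
        dS=ds,
        omega=w_hat,
        kappa=k_hat,
        t=t_hat,
        logL=-best.fun,
        n_codons_used=len(codons),
        syn_differences=counting.syn_differences,
        reliable=any_converged,
    )


# ---------------------------------------------------------------------------
# gene-level exclusion rules
# ---------------------------------------------------------------------------

REASON_INTERNAL_STOP = "internal_stop"
REASON_ZERO_SYNONYMOUS = "zero_synonymous_changes"
REASON_OMEGA_CAP = "omega_cap"


def apply_divergence_filters(
    estimates,
    qc_reports,
    omega_cap: float = 9.0,
) -> FilterResult:
    """Apply the gene exclusion rules, in order: (i) internal stop codon
    in either sequence, (ii) zero observed synonymous changes, (iii)
    omega >= omega_cap (inclusive). Each excluded gene carries exactly
    one primary reason — the first rule it trips."""
    qc_by_gene = {r.gene_id: r for r in qc_reports}
    result = FilterResult()
    for est in estimates:
        qc = qc_by_gene.get(est.gene_id)
        if qc is not None and (qc.internal_stop_a or qc.internal_stop_b or qc.length_error):
            result.excluded[est.gene_id] = REASON_INTERNAL_STOP
            continue
        syn = est.syn_differences
        zero_syn = (syn is not None and syn == 0.0) or (syn is None and est.dS == 0.0)
        if zero_syn:
            result.excluded[est.gene_id] = REASON_ZERO_SYNONYMOUS
            continue
        if not math.isnan(est.omega) and est.omega >= omega_cap:
            result.excluded[est.gene_id] = REASON_OMEGA_CAP
            continue
        result.kept.append(est.gene_id)
    return result
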