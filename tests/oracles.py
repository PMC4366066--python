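"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by exhaustive enumeration
or simulation, independently of the library's implementations.
"""

from itertools import combinations, permutations, product

import numpy as np
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def translate(codon: str) -> str:
    return "*" if codon in STOPS else str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# NG86 enumeration oracle
# ---------------------------------------------------------------------------

def ng86_sites(codon: str):
    """(synonymous, nonsynonymous) site counts for one sense codon by
    enumerating its nine single-nucleotide neighbours."""
    aa = translate(codon)
    s = n = 0.0
    for pos in range(3):
        outcomes = []
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOPS:
                continue
            outcomes.append(translate(mutant) == aa)
        if outcomes:
            frac_syn = sum(outcomes) / len(outcomes)
            s += frac_syn
            n += 1.0 - frac_syn
    return s, n


def ng86_differences(a: str, b: str):
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaging over all orders of the differing positions and
    discarding orders that pass through a stop codon (all orders used,
    stop steps counted nonsynonymous, if every order is blocked)."""
    diff_positions = [p for p in range(3) if a[p] != b[p]]
    if not diff_positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(diff_positions):
        cur, syn, non, hit_stop = a, 0.0, 0.0, False
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1 :]
            if nxt in STOPS:
                hit_stop = True
                non += 1.0
            elif translate(nxt) == translate(cur):
                syn += 1.0
            else:
                non += 1.0
            cur = nxt
        (blocked if hit_stop else clean).append((syn, non))
    pool = clean if clean else blocked + clean
    return (
        sum(p[0] for p in pool) / len(pool),
        sum(p[1] for p in pool) / len(pool),
    )


def ng86_counts(codons_a, codons_b):
    """Total (S sites, N sites, syn diffs, nonsyn diffs) for aligned
    sense-codon lists."""
    S = N = sd = nd = 0.0
    for x, y in zip(codons_a, codons_b):
        sx, nx = ng86_sites(x)
        sy, ny = ng86_sites(y)
        S += (sx + sy) / 2
        N += (nx + ny) / 2
        ds, dn = ng86_differences(x, y)
        sd += ds
        nd += dn
    return S, N, sd, nd


def random_sense_codons(rng, n):
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    sense = [c for c in sense if c not in STOPS]
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]


# ---------------------------------------------------------------------------
# exact-test enumeration oracles
# ---------------------------------------------------------------------------

def mann_whitney_exact(a, b):
    """(U of sample a, exact two-sided P) by enumerating all group
    assignments of the pooled sample. Requires no ties."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    def u_of(idx):
        rsum = sum(ranks[pooled[i]] for i in idx)
        return rsum - n1 * (n1 + 1) / 2
    u_obs = u_of(range(n1))
    dist = [u_of(c) for c in combinations(range(len(pooled)), n1)]
    m = len(dist)
    lo = sum(u <= u_obs for u in dist) / m
    hi = sum(u >= u_obs for u in dist) / m
    return u_obs, min(1.0, 2.0 * min(lo, hi))


def wilcoxon_exact(diffs):
    """(T = smaller rank sum, exact two-sided P) by enumerating all 2^n
    sign assignments of |differences|. Requires nonzero, untied |d|."""
    d = [x for x in diffs if x != 0]
    absd = sorted(abs(x) for x in d)
    rank = {v: r for r, v in enumerate(absd, start=1)}
    t_pos = sum(rank[abs(x)] for x in d if x > 0)
    t_neg = sum(rank[abs(x)] for x in d if x < 0)
    t_obs = min(t_pos, t_neg)
    n = len(d)
    dist = []
    for signs in product([1, -1], repeat=n):
        tp = sum(rank[abs(x)] for s, x in zip(signs, d) if s > 0)
        dist.append(tp)
    m = len(dist)
    lo = sum(t <= t_pos for t in dist) / m
    hi = sum(t >= t_pos for t in dist) / m
    return t_obs, min(1.0, 2.0 * min(lo, hi))


def mann_whitney_permutation_p(a, b, n_perm, seed):
    """Monte-Carlo two-sided permutation P for the Mann-Whitney U with
    arbitrary ties, using the midrank U statistic."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def u_stat(x_idx):
        ranks = rankdata(pooled)
        rsum = ranks[x_idx].sum()
        return rsum - n1 * (n1 + 1) / 2

    idx = np.arange(len(pooled))
    u_obs = u_stat(idx[:n1])
    mu = len(a) * len(b) / 2
    count = 0
    for _ in range(n_perm):
        rng.shuffle(idx)
        u = u_stat(idx[:n1])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / n_perm


def signflip_permutation_p(diffs, n_perm, seed):
    """Monte-Carlo two-sided sign-flip P for the signed-rank statistic."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    d = np.asarray([x for x in diffs if x != 0], float)
    ranks = rankdata(np.abs(d))
    mu = ranks.sum() / 2

    t_obs = ranks[d > 0].sum()
    count = 0
    for _ in range(n_perm):
        signs = rng.integers(0, 2, size=len(d)) * 2 - 1
        t = ranks[signs > 0].sum()
        if abs(t - mu) >= abs(t_obs - mu) - 1e-12:
            count += 1
    return count / n_perm
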