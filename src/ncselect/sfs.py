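"""Site-frequency-spectrum neutrality statistics.

Implements the classical summaries for a sample of n phased haplotypes:
segregating sites S, nucleotide diversity π, Watterson's θ_W, Tajima's D,
Fu & Li's outgroup-free D* and F* (minor-allele-singleton convention, with
the corrected variance constants), Fay & Wu's unnormalized H (polarized,
derived-allele counts), and diploid observed heterozygosity H_o.

π and H are computed in "total" units (mean pairwise differences over the
unit analysed); per-site values divide by the unit length L.  Statistics
that are undefined (S = 0, or no polarizable site for H) are returned as
NaN and flagged — never coerced to 0 — so window means are not biased.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .datamodel import HaplotypeBlock

__all__ = [
    "SfsConstants",
    "SfsSummary",
    "sfs_constants",
    "site_counts",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "fu_li_star",
    "fay_wu_h",
    "observed_heterozygosity",
    "sfs_summary",
]


@dataclass(frozen=True)
class SfsConstants:
    """Sample-size constants for the normalized neutrality tests."""

    n: int
    a1: float  # sum_{i<n} 1/i
    a2: float  # sum_{i<n} 1/i^2
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    cn: float
    dn: float
    u_dstar: float
    v_dstar: float
    u_fstar: float
    v_fstar: float


def _harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k))) if k > 1 else 0.0


@lru_cache(maxsize=None)
def sfs_count_covariance(n: int) -> np.ndarray:
    """θ²-coefficients of Cov(ξ_i, ξ_j) for the neutral-coalescent SFS.

    ξ_i is the number of sites at derived count i; the full covariance is
    Cov(ξ_i, ξ_j) = δ_ij θ/i + σ_ij θ², and this returns the (n−1)×(n−1)
    matrix σ (Fu 1995, Theorem 1 and 2).  It underlies the exact variance
    constants of the normalized neutrality tests.
    """
    a_n = _harmonic(n)

    def beta(i: int) -> float:
        return (2.0 * n / ((n - i + 1.0) * (n - i))) * (_harmonic(n + 1) - _harmonic(i)) - 2.0 / (n - i)

    s = np.zeros((n - 1, n - 1))
    for i in range(1, n):
        if 2 * i < n:
            s[i - 1, i - 1] = beta(i + 1)
        elif 2 * i == n:
            s[i - 1, i - 1] = 2.0 * (a_n - _harmonic(i)) / (n - i) - 1.0 / i**2
        else:
            s[i - 1, i - 1] = beta(i) - 1.0 / i**2
        for j in range(1, i):  # i > j
            if i + j < n:
                v = (beta(i + 1) - beta(i)) / 2.0
            elif i + j == n:
                v = (
                    (a_n - _harmonic(i)) / (n - i)
                    + (a_n - _harmonic(j)) / (n - j)
                    - (beta(i) + beta(j + 1)) / 2.0
                    - 1.0 / (i * j)
                )
            else:
                v = (beta(j) - beta(j + 1)) / 2.0 - 1.0 / (i * j)
            s[i - 1, j - 1] = s[j - 1, i - 1] = v
    return s


def _uv_constants(n: int, weights: np.ndarray) -> tuple[float, float]:
    """(u, v) with Var(Σ w_i ξ_i) = (u+v)a₁θ + v(a₁²+a₂)θ² exactly.

    The normalized statistic divides its numerator by sqrt(uS + vS²),
    whose expectation equals that variance.  Deriving u, v from the SFS
    covariance matrix avoids the typo-prone printed constants.
    """
    i = np.arange(1, n)
    a1 = _harmonic(n)
    a2 = float(np.sum(1.0 / i**2))
    alpha = float(np.sum(weights**2 / i))
    beta = float(weights @ sfs_count_covariance(n) @ weights)
    v = beta / (a1**2 + a2)
    u = alpha / a1 - v
    return u, v


def sfs_constants(n: int) -> SfsConstants:
    """All n-dependent constants for Tajima's D and Fu & Li's D*/F*.

    Tajima's e₁/e₂ use the classical closed forms; the star-statistic
    variance constants are derived exactly from the coalescent covariance
    of the SFS counts (several corrected printed forms circulate; the
    covariance route is unambiguous and reproduces the closed-form D*
    constants to machine precision).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    if n >= 4:
        an1 = a1 + 1.0 / n  # a_{n+1}
        cn = 2.0 * (n * a1 - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
        dn = (
            cn
            + (n - 2) / ((n - 1) ** 2)
            + (2.0 / (n - 1)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2) - 1.0 / n)
        )
        # D* numerator weights: (n/(n-1))·S − a₁·η_s
        w = np.full(n - 1, n / (n - 1.0))
        w[0] -= a1
        w[n - 2] -= a1
        u_dstar, v_dstar = _uv_constants(n, w)
        # F* numerator weights: π_total − ((n−1)/n)·η_s
        w = 2.0 * i * (n - i) / (n * (n - 1.0))
        w[0] -= (n - 1.0) / n
        w[n - 2] -= (n - 1.0) / n
        u_fstar, v_fstar = _uv_constants(n, w)
    else:
        cn = dn = u_dstar = v_dstar = u_fstar = v_fstar = math.nan
    return SfsConstants(n, a1, a2, b1, b2, c1, c2, e1, e2, cn, dn, u_dstar, v_dstar, u_fstar, v_fstar)


def site_counts(block: HaplotypeBlock) -> np.ndarray:
    """Derived (or ALT) allele counts at segregating sites only."""
    c = block.derived_counts()
    n = block.n_haplotypes
    return c[(c > 0) & (c < n)]


def _pi_total(counts: np.ndarray, n: int) -> float:
    # mean pairwise differences: sum over sites of 2 i (n-i) / (n (n-1))
    if counts.size == 0:
        return 0.0
    return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1.0)))


def nucleotide_diversity(block: HaplotypeBlock, L: float | None = None) -> float:
    """π: average pairwise nucleotide differences, per site when L is given.

    Uses the frequency identity π_total = Σ_sites 2p(1−p)·n/(n−1), which
    equals the direct average over all C(n,2) haplotype pairs.
    """
    if block.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    pi = _pi_total(site_counts(block), block.n_haplotypes)
    if L is None:
        return pi
    if L <= 0:
        raise ValueError("L must be positive")
    return pi / L


def watterson_theta(block: HaplotypeBlock, L: float | None = None) -> float:
    """θ_W = S / a₁ (per site when L is given)."""
    S = site_counts(block).size
    theta = S / sfs_constants(block.n_haplotypes).a1
    return theta if L is None else theta / L


def tajimas_d(block: HaplotypeBlock) -> float:
    """Tajima's D = (π_total − S/a₁) / sqrt(e₁S + e₂S(S−1)); NaN when S=0."""
    n = block.n_haplotypes
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = site_counts(block)
    S = counts.size
    if S == 0:
        return math.nan
    k = sfs_constants(n)
    num = _pi_total(counts, n) - S / k.a1
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:  # degenerate at n=2/3, where the test has no variance model
        return math.nan
    return num / math.sqrt(var)


def _minor_singletons(counts: np.ndarray, n: int) -> int:
    """η_s for the star statistics: sites whose minor allele is a singleton."""
    return int(np.sum((counts == 1) | (counts == n - 1)))


def fu_li_star(block: HaplotypeBlock) -> tuple[float, float]:
    """Fu & Li's outgroup-free (D*, F*); NaN when S=0 or n<4."""
    n = block.n_haplotypes
    counts = site_counts(block)
    S = counts.size
    if n < 4 or S == 0:
        return math.nan, math.nan
    k = sfs_constants(n)
    eta_s = _minor_singletons(counts, n)
    d_num = (n / (n - 1.0)) * S - k.a1 * eta_s
    d_star = d_num / math.sqrt(k.u_dstar * S + k.v_dstar * S**2)
    f_num = _pi_total(counts, n) - ((n - 1.0) / n) * eta_s
    f_star = f_num / math.sqrt(k.u_fstar * S + k.v_fstar * S**2)
    return d_star, f_star


def fay_wu_h(block: HaplotypeBlock) -> float:
    """Fay & Wu's unnormalized H = π_total − θ_H over polarized sites.

    θ_H = Σ_i 2 S_i i² / (n(n−1)) weights high-frequency derived alleles;
    sites with unknown ancestral state are excluded.  NaN when no
    polarized segregating site remains.
    """
    n = block.n_haplotypes
    c = block.derived_counts()
    mask = block.ancestral_known & (c > 0) & (c < n)
    counts = c[mask]
    if counts.size == 0:
        return math.nan
    pi = _pi_total(counts, n)
    theta_h = float(np.sum(2.0 * counts.astype(float) ** 2) / (n * (n - 1.0)))
    return pi - theta_h


def observed_heterozygosity(block: HaplotypeBlock) -> float:
    """H_o: mean over sites of the fraction of heterozygous diploid samples.

    Haplotypes 2i and 2i+1 form sample i; an odd haplotype count raises.
    """
    if block.n_haplotypes % 2:
        raise ValueError("observed heterozygosity requires diploid pairing (even n)")
    if block.n_sites == 0:
        return math.nan
    h1 = block.alleles[0::2, :]
    h2 = block.alleles[1::2, :]
    return float(np.mean(h1 != h2))


@dataclass
class SfsSummary:
    """One analysis unit's SFS summary (a window or a concatenated element)."""

    n: int
    L: float
    S: int
    eta_s: int
    pi_total: float
    pi_per_site: float
    theta_w: float
    tajima_d: float
    fu_li_d_star: float
    fu_li_f_star: float
    fay_wu_h: float
    n_unpolarized: int
    defined: bool  # False when S == 0


def sfs_summary(block: HaplotypeBlock, L: float) -> SfsSummary:
    """All statistics for one block, with L the unit length in bp."""
    if L <= 0:
        raise ValueError("L must be positive")
    n = block.n_haplotypes
    counts = site_counts(block)
    S = counts.size
    pi = _pi_total(counts, n)
    d_star, f_star = fu_li_star(block) if S else (math.nan, math.nan)
    return SfsSummary(
        n=n,
        L=L,
        S=S,
        eta_s=_minor_singletons(counts, n) if S else 0,
        pi_total=pi,
        pi_per_site=pi / L,
        theta_w=S / sfs_constants(n).a1,
        tajima_d=tajimas_d(block) if S else math.nan,
        fu_li_d_star=d_star,
        fu_li_f_star=f_star,
        fay_wu_h=fay_wu_h(block),
        n_unpolarized=int(np.sum(~block.ancestral_known)),
        defined=S > 0,
    )
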