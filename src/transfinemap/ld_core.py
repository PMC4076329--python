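"""Pairwise linkage disequilibrium from unphased genotypes.

Two-locus haplotype frequencies are estimated by maximum likelihood with an
EM algorithm (phase of double heterozygotes resolved by expected counts),
from which the standard LD coefficients r^2 and D' follow. Also provides the
exact Hardy-Weinberg test used as a pre-association QC gate (retention rule
p > 0.01) and proxy-set construction around an index SNP.

Estimation is complete-case per SNP pair; missing calls are never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateError, InputError
from .geno_io import GenotypeMatrix

__all__ = [
    "HapFreq2",
    "LDPair",
    "em_hapfreq2",
    "ld_stats",
    "r_squared",
    "pairwise_r2",
    "hwe_test",
    "hwe_flags",
    "proxy_set",
]

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class HapFreq2:
    """ML two-locus haplotype frequencies from unphased genotype pairs.

    Alleles are labelled from the effect-allele coding of the two genotype
    vectors: ``A``/``B`` are the counted alleles at the first/second SNP.
    """

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    n_used: int
    loglik: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])


@dataclass(frozen=True)
class LDPair:
    snp_a: str
    snp_b: str
    r2: float
    d_prime: float
    D: float


def _count_table(g_a: np.ndarray, g_b: np.ndarray) -> tuple[np.ndarray, int]:
    g_a = np.asarray(g_a, dtype=float)
    g_b = np.asarray(g_b, dtype=float)
    if g_a.shape != g_b.shape:
        raise InputError("genotype vectors must have the same length")
    ok = ~(np.isnan(g_a) | np.isnan(g_b))
    a = g_a[ok].astype(int)
    b = g_b[ok].astype(int)
    n = a.size
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (a, b), 1.0)
    return table, n


def _loglik(table: np.ndarray, f: np.ndarray) -> float:
    f_AB, f_Ab, f_aB, f_ab = f
    # genotype-pair probabilities under random union of haplotypes
    p = np.empty((3, 3))
    p[2, 2] = f_AB * f_AB
    p[2, 1] = 2 * f_AB * f_Ab
    p[2, 0] = f_Ab * f_Ab
    p[1, 2] = 2 * f_AB * f_aB
    p[1, 1] = 2 * f_AB * f_ab + 2 * f_Ab * f_aB
    p[1, 0] = 2 * f_Ab * f_ab
    p[0, 2] = f_aB * f_aB
    p[0, 1] = 2 * f_aB * f_ab
    p[0, 0] = f_ab * f_ab
    mask = table > 0
    with np.errstate(divide="ignore"):
        logp = np.log(p, where=mask, out=np.full_like(p, -np.inf))
    if np.any(mask & ~np.isfinite(logp)):
        return -np.inf
    return float(np.sum(table[mask] * logp[mask]))


def em_hapfreq2(g_a: np.ndarray, g_b: np.ndarray) -> HapFreq2:
    """EM estimate of the four two-locus haplotype frequencies.

    Starts from linkage equilibrium at the observed allele frequencies and
    iterates to convergence (max-abs frequency change < 1e-10, at most 1000
    iterations). Requires at least 2 complete genotype pairs and both SNPs
    polymorphic among them.
    """
    table, n = _count_table(g_a, g_b)
    if n < 2:
        raise InputError(f"need >= 2 complete genotype pairs, have {n}")
    pA = float((2 * table[2, :].sum() + table[1, :].sum()) / (2 * n))
    pB = float((2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n))
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise DegenerateError("monomorphic SNP: LD undefined")

    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    n_dh = table[1, 1]
    # fixed (phase-unambiguous) haplotype counts
    base = np.array(
        [
            2 * table[2, 2] + table[2, 1] + table[1, 2],
            2 * table[2, 0] + table[2, 1] + table[1, 0],
            2 * table[0, 2] + table[0, 1] + table[1, 2],
            2 * table[0, 0] + table[0, 1] + table[1, 0],
        ]
    )
    for _ in range(EM_MAX_ITER):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        q = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base + n_dh * np.array([q, 1 - q, 1 - q, q])
        f_new = counts / (2 * n)
        if np.max(np.abs(f_new - f)) < EM_TOL:
            f = f_new
            break
        f = f_new
    return HapFreq2(
        f_AB=float(f[0]),
        f_Ab=float(f[1]),
        f_aB=float(f[2]),
        f_ab=float(f[3]),
        n_used=n,
        loglik=_loglik(table, f),
    )


def ld_stats(h: HapFreq2, snp_a: str = "a", snp_b: str = "b") -> LDPair:
    """r^2, D' and signed D from two-locus haplotype frequencies."""
    pA = h.f_AB + h.f_Ab
    pB = h.f_AB + h.f_aB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise DegenerateError("monomorphic margin: LD undefined")
    D = h.f_AB - pA * pB
    r2 = min(D * D / denom, 1.0)
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    return LDPair(snp_a=snp_a, snp_b=snp_b, r2=float(r2), d_prime=float(min(d_prime, 1.0)), D=float(D))


def r_squared(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """EM-based r^2 between two genotype vectors."""
    return ld_stats(em_hapfreq2(g_a, g_b)).r2


def pairwise_r2(panel: GenotypeMatrix, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric r^2 matrix over the named SNPs (NaN where undefined)."""
    ids = snp_ids if snp_ids is not None else panel.snp_ids
    m = len(ids)
    out = np.ones((m, m))
    genos = [panel.genotype(s) for s in ids]
    for i in range(m):
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = r_squared(genos[i], genos[j])
            except DegenerateError:
                out[i, j] = out[j, i] = np.nan
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_het_probs(n_het_obs: int, n_rare: int, n_geno: int) -> np.ndarray:
    """Conditional distribution of heterozygote counts given allele counts.

    Wigginton-style recurrence over all heterozygote counts with the parity
    of the rare-allele count. Returns probabilities indexed by het count.
    """
    probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n_geno - n_rare) // (2 * n_geno)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: het -> het - 2
    het = mid
    while het > 1:
        hom_r = (n_rare - het) // 2
        hom_c = n_geno - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    # upward recurrence: het -> het + 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n_geno - het - hom_r
        probs[het + 2] = probs[het] * 4 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
    return probs / probs.sum()


def hwe_test(g: np.ndarray) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) that are no more likely than the observed count.
    """
    g = np.asarray(g, dtype=float)
    g = g[~np.isnan(g)].astype(int)
    if g.size < 1:
        raise InputError("need at least one complete genotype")
    n0 = int(np.sum(g == 0))
    n1 = int(np.sum(g == 1))
    n2 = int(np.sum(g == 2))
    return hwe_test_counts(n2, n1, n0)


def hwe_test_counts(n_hom_effect: int, n_het: int, n_hom_other: int) -> float:
    """Exact HWE p-value from genotype counts."""
    n_geno = n_hom_effect + n_het + n_hom_other
    if n_geno == 0:
        raise InputError("need at least one complete genotype")
    n_eff = 2 * n_hom_effect + n_het
    n_rare = min(n_eff, 2 * n_geno - n_eff)
    if n_rare == 0:
        return 1.0
    probs = _hwe_het_probs(n_het, n_rare, n_geno)
    p_obs = probs[n_het]
    p = float(np.sum(probs[probs <= p_obs * (1 + 1e-12)]))
    return min(1.0, p)


def hwe_flags(panel: GenotypeMatrix, p_threshold: float = 0.01) -> pd.DataFrame:
    """QC table flagging SNPs out of Hardy-Weinberg equilibrium.

    SNPs with exact-test p <= ``p_threshold`` are flagged (``hwe_pass`` False)
    but never silently dropped; monomorphic SNPs pass trivially (p = 1).
    """
    rows = []
    for snp_id in panel.snp_ids:
        p = hwe_test(panel.genotype(snp_id))
        rows.append({"snp_id": snp_id, "hwe_p": p, "hwe_pass": p > p_threshold})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proxy sets
# ---------------------------------------------------------------------------


def proxy_set(
    index_snp: str, panel: GenotypeMatrix, r2_threshold: float
) -> set[str]:
    """All panel SNPs with r^2 >= threshold to the index (index included).

    Monomorphic non-index SNPs are skipped (their LD to the index is
    undefined); a monomorphic index raises :class:`DegenerateError`.
    """
    if index_snp not in panel.snp_ids:
        raise InputError(f"index SNP {index_snp!r} not in panel")
    g_index = panel.genotype(index_snp)
    vals = g_index[~np.isnan(g_index)]
    if vals.size == 0 or np.all(vals == vals[0]):
        raise DegenerateError(f"index SNP {index_snp!r} is monomorphic")
    out = {index_snp}
    for snp_id in panel.snp_ids:
        if snp_id == index_snp:
            continue
        try:
            r2 = r_squared(g_index, panel.genotype(snp_id))
        except DegenerateError:
            continue
        if r2 >= r2_threshold:
            out.add(snp_id)
    return out
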