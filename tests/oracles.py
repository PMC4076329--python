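"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the two-locus
likelihood is maximised by grid search, and the exact Hardy-Weinberg
distribution is recomputed from the log-gamma closed form rather than by
recurrence.
"""

import numpy as np
from scipy.special import gammaln


def genotype_pair_probs(f):
    """3x3 genotype-pair probabilities from haplotype frequencies.

    ``f`` columns are (f_AB, f_Ab, f_aB, f_ab); rows of the result are
    indexed by (g_a, g_b) flattened row-major.
    """
    fAB, fAb, faB, fab = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    return np.stack(
        [
            fab**2,  # (0,0)
            2 * faB * fab,  # (0,1)
            faB**2,  # (0,2)
            2 * fAb * fab,  # (1,0)
            2 * fAB * fab + 2 * fAb * faB,  # (1,1)
            2 * fAB * faB,  # (1,2)
            fAb**2,  # (2,0)
            2 * fAB * fAb,  # (2,1)
            fAB**2,  # (2,2)
        ],
        axis=1,
    )


def _batch_loglik(table, f):
    p = genotype_pair_probs(np.clip(f, 0.0, 1.0))
    counts = np.asarray(table, dtype=float).reshape(-1)
    ll = np.zeros(len(f))
    for k, n in enumerate(counts):
        if n > 0:
            with np.errstate(divide="ignore"):
                ll += n * np.log(p[:, k])
    return ll


def _simplex_grid(step):
    k = int(round(1.0 / step))
    pts = []
    for a in range(k + 1):
        for b in range(k + 1 - a):
            for c in range(k + 1 - a - b):
                pts.append((a * step, b * step, c * step))
    pts = np.array(pts)
    return np.column_stack([pts, 1.0 - pts.sum(axis=1)])


def grid_max_loglik(table, coarse=0.01, fine=1e-3, radius=0.015):
    """Grid-search maximum of the two-locus likelihood at ~1e-3 resolution.

    A coarse sweep of the frequency simplex is refined locally around its
    best point at the fine resolution.
    """
    f = _simplex_grid(coarse)
    ll = _batch_loglik(table, f)
    best = f[int(np.argmax(ll)), :3]
    offs = np.arange(-radius, radius + fine / 2, fine)
    fine_pts = []
    for da in offs:
        for db in offs:
            for dc in offs:
                a, b, c = best[0] + da, best[1] + db, best[2] + dc
                if a >= -1e-12 and b >= -1e-12 and c >= -1e-12 and a + b + c <= 1 + 1e-12:
                    fine_pts.append((max(a, 0), max(b, 0), max(c, 0)))
    fine_pts = np.array(fine_pts)
    f2 = np.column_stack([fine_pts, np.maximum(1.0 - fine_pts.sum(axis=1), 0.0)])
    ll2 = _batch_loglik(table, f2)
    return float(max(ll.max(), ll2.max()))


def hwe_exact_p(n_hom_effect, n_het, n_hom_other):
    """Exact HWE p-value from the log-gamma closed-form distribution.

    P(n_het | allele counts) ~ C(N, n_aa, n_Aa, n_AA) * 2^n_het / C(2N, n_A);
    p sums the probabilities of all heterozygote counts no more likely than
    the observed one.
    """
    n = n_hom_effect + n_het + n_hom_other
    n_a = 2 * n_hom_effect + n_het
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = []
    for h in hets:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp.append(
            gammaln(n + 1)
            - gammaln(hom_r + 1)
            - gammaln(h + 1)
            - gammaln(hom_c + 1)
            + h * np.log(2.0)
            - (gammaln(2 * n + 1) - gammaln(n_rare + 1) - gammaln(2 * n - n_rare + 1))
        )
    probs = np.exp(np.array(logp))
    probs = probs / probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))
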