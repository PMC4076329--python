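"""Fixed-effect inverse-variance meta-analysis and Cochran's Q.

Panel-level or population-level estimates (beta, se) are combined with
weights w_i = 1/se_i^2; heterogeneity of per-allele effect sizes across
studies is tested with Cochran's Q against chi-square with k - 1 degrees of
freedom. Combination is associative: meta of metas equals the one-shot meta
over all inputs, so panels can be combined into populations and populations
into a trans-ethnic estimate, as done when two panels per country are
characterised separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError

__all__ = ["MetaResult", "fixed_effect_meta", "cochran_q"]


@dataclass(frozen=True)
class MetaResult:
    beta_combined: float
    se_combined: float
    z: float
    p: float
    q_stat: float | None
    q_df: int | None
    p_hetero: float | None
    k_studies: int


def fixed_effect_meta(estimates: Sequence[tuple[float, float]]) -> MetaResult:
    """Inverse-variance fixed-effect combination of (beta, se) pairs.

    p is the two-sided normal p-value of z = beta_combined / se_combined.
    Heterogeneity fields are filled when k >= 2.
    """
    if len(estimates) == 0:
        raise InputError("no estimates to combine")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if np.any(ses <= 0):
        raise InputError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    result = MetaResult(
        beta_combined=beta,
        se_combined=se,
        z=float(z),
        p=p,
        q_stat=None,
        q_df=None,
        p_hetero=None,
        k_studies=len(estimates),
    )
    if len(estimates) >= 2:
        q, p_het = cochran_q(estimates, result)
        result = MetaResult(
            beta_combined=beta,
            se_combined=se,
            z=float(z),
            p=p,
            q_stat=q,
            q_df=len(estimates) - 1,
            p_hetero=p_het,
            k_studies=len(estimates),
        )
    return result


def cochran_q(
    estimates: Sequence[tuple[float, float]], meta: MetaResult
) -> tuple[float, float]:
    """Cochran's Q heterogeneity statistic and its chi-square p-value."""
    if len(estimates) < 2:
        raise InputError("heterogeneity needs at least two studies")
    betas = np.array([b for b, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    w = 1.0 / ses**2
    q = float(np.sum(w * (betas - meta.beta_combined) ** 2))
    df = len(estimates) - 1
    p_het = float(stats.chi2.sf(q, df))
    return q, p_het
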