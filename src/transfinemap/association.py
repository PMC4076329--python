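"""Single-SNP association and pairwise conditional screening.

BMI association: ordinary least squares of rank-based inverse-normal
transformed (INT) BMI on additive genotype dosage, adjusted for age and
age-squared; the INT is applied separately within each sex using Blom scores
Phi^{-1}((r - 3/8)/(n + 1/4)). Type 2 diabetes: maximum-likelihood logistic
regression in an additive model adjusted for sex.

Significance of a single SNP uses the direction-consistency rule: nominal
p < 0.05 AND the effect must increase BMI / disease risk on the reference
risk allele established in European-descent populations.

The conditional screen fits pairs of SNPs jointly: a SNP is "less closely
correlated with the causal variant" (and excluded) when, against every other
SNP in the tested set, it drops below the Bonferroni-adjusted significance
level while the partner remains significant. Near-perfect proxies
(r^2 >= 0.99) are declared statistically indistinguishable rather than
contested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import ld_core
from .errors import DegenerateError, FitError, InputError, TransformError
from .geno_io import GenotypeMatrix, PhenotypeTable

__all__ = [
    "AssocResult",
    "ConditionalResult",
    "inverse_normal_transform",
    "linear_assoc",
    "logistic_assoc",
    "direction_significance",
    "pairwise_conditional",
    "exclusion_screen",
    "bonferroni_alpha",
    "INDISTINGUISHABLE_R2",
]

#: pairs at or above this r^2 are not contested in conditional analysis
INDISTINGUISHABLE_R2 = 0.99

BLOM_OFFSET = 3.0 / 8.0


def bonferroni_alpha(n_tested: int, family_alpha: float = 0.05) -> float:
    """Adjusted significance level for a conditional screen of n SNPs."""
    if n_tested < 1:
        raise InputError("need at least one tested SNP")
    return family_alpha / n_tested


@dataclass(frozen=True)
class AssocResult:
    """Per-SNP effect estimate on the analysis scale.

    ``beta`` is in z-score units for INT-BMI and log-OR units for type 2
    diabetes; ``eaf`` is the effect-allele frequency in the analysed samples.
    """

    snp_id: str
    trait: str
    effect_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    population: str = "all"
    other_allele: str = ""
    covariates_used: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise InputError(f"{self.snp_id}: se must be positive")
        if not (0 < self.p <= 1):
            raise InputError(f"{self.snp_id}: p must be in (0, 1]")


@dataclass(frozen=True)
class ConditionalResult:
    """Joint-model statistics for an (ordered) SNP pair.

    ``p_a_given_b`` is the Wald p of snp_a's genotype term with snp_b in the
    model, and vice versa. ``indistinguishable`` marks pairs too correlated
    to contest (r^2 >= 0.99 or identical SNPs); their p/beta fields are NaN.
    """

    snp_a: str
    snp_b: str
    p_a_given_b: float
    p_b_given_a: float
    beta_a_given_b: float
    beta_b_given_a: float
    n: int
    r2: float
    indistinguishable: bool = False


# ---------------------------------------------------------------------------
# inverse normal transform
# ---------------------------------------------------------------------------


def inverse_normal_transform(
    values: Sequence[float], group_labels: Sequence | None = None
) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform, applied within groups.

    Within each group, the value of rank r (average ranks for ties) among n
    non-missing values maps to Phi^{-1}((r - 3/8)/(n + 1/4)). Missing values
    stay missing. Groups with fewer than 2 non-missing values, or constant
    values, raise :class:`TransformError`.
    """
    vals = np.asarray(values, dtype=float)
    if group_labels is None:
        labels = np.zeros(vals.shape, dtype=int)
    else:
        labels = np.asarray(group_labels)
        if labels.shape != vals.shape:
            raise InputError("values and group_labels must have the same length")
    out = np.full(vals.shape, np.nan)
    for g in pd.unique(labels[~pd.isna(labels)]):
        mask = (labels == g) & ~np.isnan(vals)
        n = int(mask.sum())
        if n < 2:
            raise TransformError(f"group {g!r}: need >= 2 non-missing values, have {n}")
        v = vals[mask]
        if np.all(v == v[0]):
            raise TransformError(f"group {g!r}: constant values cannot be rank-transformed")
        ranks = stats.rankdata(v, method="average")
        out[mask] = stats.norm.ppf((ranks - BLOM_OFFSET) / (n + 0.25))
    return out


# ---------------------------------------------------------------------------
# regression helpers
# ---------------------------------------------------------------------------


def _covariate_columns(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = df["age"]
        elif cov in ("age2", "age_squared"):
            cols["age2"] = df["age"] ** 2
        elif cov == "sex":
            cols["sex"] = df["sex"]
        elif cov in df.columns:
            cols[cov] = df[cov]
        else:
            raise InputError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=df.index)


def _merged_frame(
    panel: GenotypeMatrix, pheno: PhenotypeTable, snp_ids: Sequence[str]
) -> pd.DataFrame:
    df = pheno.aligned_to(panel.samples)
    for s in snp_ids:
        df[f"g_{s}"] = panel.genotype(s)
    return df


def _int_bmi(df: pd.DataFrame, transform: str) -> pd.Series:
    if transform == "none":
        return df["bmi"]
    if transform != "blom":
        raise InputError(f"unknown transform {transform!r}")
    ok = ~(df["bmi"].isna() | df["sex"].isna())
    out = pd.Series(np.nan, index=df.index)
    out[ok] = inverse_normal_transform(df.loc[ok, "bmi"].values, df.loc[ok, "sex"].values)
    return out


def _population_label(df: pd.DataFrame) -> str:
    pops = df["population"].dropna().unique()
    return str(pops[0]) if len(pops) == 1 else "pooled"


def _check_polymorphic(g: np.ndarray, snp_id: str) -> None:
    vals = g[~np.isnan(g)]
    if vals.size == 0 or np.all(vals == vals[0]):
        raise DegenerateError(f"{snp_id} is monomorphic in the analysed samples")


def linear_assoc(
    snp_id: str,
    panel: GenotypeMatrix,
    pheno: PhenotypeTable,
    covariates: Sequence[str] = ("age", "age2"),
    transform: str = "blom",
) -> AssocResult:
    """OLS of INT-BMI on additive genotype plus covariates.

    ``transform='none'`` regresses raw BMI instead (used for exact-recovery
    checks on noiseless data). Complete-case per SNP; needs >= 10 complete
    cases and a polymorphic genotype.
    """
    df = _merged_frame(panel, pheno, [snp_id])
    y_all = _int_bmi(df, transform)
    X_cov = _covariate_columns(df, covariates)
    keep = ~(y_all.isna() | df[f"g_{snp_id}"].isna() | X_cov.isna().any(axis=1))
    n = int(keep.sum())
    if n < 10:
        raise InputError(f"{snp_id}: need >= 10 complete cases, have {n}")
    g = df.loc[keep, f"g_{snp_id}"].values
    _check_polymorphic(g, snp_id)
    X = sm.add_constant(
        pd.concat([df.loc[keep, [f"g_{snp_id}"]], X_cov.loc[keep]], axis=1),
        has_constant="add",
    )
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise InputError(f"{snp_id}: collinear covariates (rank-deficient design)")
    fit = sm.OLS(y_all[keep].values, X).fit()
    beta = float(fit.params[f"g_{snp_id}"])
    se = float(fit.bse[f"g_{snp_id}"])
    p = float(fit.pvalues[f"g_{snp_id}"])
    v = panel.variant(snp_id)
    return AssocResult(
        snp_id=snp_id,
        trait="bmi",
        effect_allele=v.effect_allele,
        other_allele=v.other_allele,
        eaf=float(np.mean(g) / 2),
        beta=beta,
        se=se,
        p=max(p, np.finfo(float).tiny),
        n=n,
        population=_population_label(df.loc[keep]),
        covariates_used=tuple(covariates),
    )


def logistic_assoc(
    snp_id: str,
    panel: GenotypeMatrix,
    pheno: PhenotypeTable,
    covariates: Sequence[str] = ("sex",),
) -> AssocResult:
    """Additive-model logistic regression of case/control status.

    ``beta`` is the log odds ratio per effect allele; Wald two-sided p.
    Requires >= 10 cases and >= 10 controls with complete data. Complete
    separation raises :class:`FitError`.
    """
    df = _merged_frame(panel, pheno, [snp_id])
    status = df["t2d"].map({"case": 1.0, "control": 0.0})
    X_cov = _covariate_columns(df, covariates)
    keep = ~(status.isna() | df[f"g_{snp_id}"].isna() | X_cov.isna().any(axis=1))
    y = status[keep].values
    n_case, n_ctrl = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_case < 10 or n_ctrl < 10:
        raise InputError(
            f"{snp_id}: need >= 10 cases and controls, have {n_case}/{n_ctrl}"
        )
    g = df.loc[keep, f"g_{snp_id}"].values
    _check_polymorphic(g, snp_id)
    X = sm.add_constant(
        pd.concat([df.loc[keep, [f"g_{snp_id}"]], X_cov.loc[keep]], axis=1),
        has_constant="add",
    )
    fit = _fit_logit(y, X, snp_id)
    beta = float(fit.params[f"g_{snp_id}"])
    se = float(fit.bse[f"g_{snp_id}"])
    p = float(fit.pvalues[f"g_{snp_id}"])
    v = panel.variant(snp_id)
    return AssocResult(
        snp_id=snp_id,
        trait="t2d",
        effect_allele=v.effect_allele,
        other_allele=v.other_allele,
        eaf=float(np.mean(g) / 2),
        beta=beta,
        se=se,
        p=max(p, np.finfo(float).tiny),
        n=n_case + n_ctrl,
        population=_population_label(df.loc[keep]),
        covariates_used=tuple(covariates),
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame, label: str):
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except (PerfectSeparationError, Exception) as exc:
        if "separation" in str(exc).lower() or isinstance(exc, PerfectSeparationError):
            raise FitError(f"{label}: complete separation in logistic fit") from exc
        # retry without warning escalation (benign overflow in irls steps)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc2:
            raise FitError(f"{label}: logistic fit failed: {exc2}") from exc2
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(fit.params) > 30):
        raise FitError(f"{label}: logistic fit did not converge (separation suspected)")
    return fit


def direction_significance(
    result: AssocResult, reference_risk_allele: str, alpha: float = 0.05
) -> str:
    """Apply the direction-consistency significance rule.

    Returns ``'significant'`` iff p < alpha AND the estimated effect implies
    BMI/disease-risk increase on the reference risk allele (the allele
    reported in European-descent populations); otherwise
    ``'not_significant'``.
    """
    if reference_risk_allele not in (result.effect_allele, result.other_allele):
        raise InputError(
            f"{result.snp_id}: reference allele {reference_risk_allele!r} is not "
            "one of this SNP's alleles"
        )
    if result.p >= alpha:
        return "not_significant"
    risk_increasing_on_reference = (
        result.beta > 0
        if result.effect_allele == reference_risk_allele
        else result.beta < 0
    )
    return "significant" if risk_increasing_on_reference else "not_significant"


# ---------------------------------------------------------------------------
# conditional analysis
# ---------------------------------------------------------------------------


def pairwise_conditional(
    snp_a: str,
    snp_b: str,
    panel: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str = "bmi",
    covariates: Sequence[str] | None = None,
    transform: str = "blom",
) -> ConditionalResult:
    """Fit the trait model with both SNPs' genotype terms included.

    Pairs with r^2 >= 0.99 (or identical SNPs) are returned as
    ``indistinguishable`` without fitting: conditional analysis cannot
    separate them with realistic sample sizes.
    """
    if covariates is None:
        covariates = ("age", "age2") if trait == "bmi" else ("sex",)
    if snp_a == snp_b:
        return ConditionalResult(
            snp_a, snp_b, np.nan, np.nan, np.nan, np.nan, 0, 1.0, indistinguishable=True
        )
    r2 = ld_core.r_squared(panel.genotype(snp_a), panel.genotype(snp_b))
    df = _merged_frame(panel, pheno, [snp_a, snp_b])
    if trait == "bmi":
        y_all = _int_bmi(df, transform)
    elif trait == "t2d":
        y_all = df["t2d"].map({"case": 1.0, "control": 0.0})
    else:
        raise InputError(f"unknown trait {trait!r}")
    X_cov = _covariate_columns(df, covariates)
    keep = ~(
        y_all.isna()
        | df[f"g_{snp_a}"].isna()
        | df[f"g_{snp_b}"].isna()
        | X_cov.isna().any(axis=1)
    )
    n = int(keep.sum())
    if r2 >= INDISTINGUISHABLE_R2:
        return ConditionalResult(
            snp_a, snp_b, np.nan, np.nan, np.nan, np.nan, n, float(r2), indistinguishable=True
        )
    _check_polymorphic(df.loc[keep, f"g_{snp_a}"].values, snp_a)
    _check_polymorphic(df.loc[keep, f"g_{snp_b}"].values, snp_b)
    X = sm.add_constant(
        pd.concat(
            [df.loc[keep, [f"g_{snp_a}", f"g_{snp_b}"]], X_cov.loc[keep]], axis=1
        ),
        has_constant="add",
    )
    if trait == "bmi":
        fit = sm.OLS(y_all[keep].values, X).fit()
    else:
        fit = _fit_logit(y_all[keep].values, X, f"{snp_a}+{snp_b}")
    return ConditionalResult(
        snp_a=snp_a,
        snp_b=snp_b,
        p_a_given_b=float(fit.pvalues[f"g_{snp_a}"]),
        p_b_given_a=float(fit.pvalues[f"g_{snp_b}"]),
        beta_a_given_b=float(fit.params[f"g_{snp_a}"]),
        beta_b_given_a=float(fit.params[f"g_{snp_b}"]),
        n=n,
        r2=float(r2),
    )


def _loses(
    results: dict[frozenset, ConditionalResult], snp: str, other: str, alpha: float
) -> bool:
    """True when ``snp`` drops out while ``other`` stays significant."""
    res = results[frozenset((snp, other))]
    if res.indistinguishable:
        return False
    if res.snp_a == snp:
        p_self, p_other = res.p_a_given_b, res.p_b_given_a
    else:
        p_self, p_other = res.p_b_given_a, res.p_a_given_b
    return p_self > alpha and p_other <= alpha


def exclusion_screen(
    cond_results: Iterable[ConditionalResult],
    alpha_adj: float | None = None,
    iterate: bool = False,
) -> list[str]:
    """SNPs less closely correlated with the causal variant than all others.

    A SNP is excluded when, against every other SNP in the set, its
    conditional p exceeds ``alpha_adj`` while the partner's does not.
    ``alpha_adj`` defaults to 0.05 divided by the number of SNPs screened
    (Bonferroni over the tested set, recomputed from the input). With
    ``iterate=True`` the screen is repeated on the surviving set until no
    further SNP is universally dominated (stepwise elimination).

    Requires a conditional result for every unordered pair; mutually
    indistinguishable pairs cannot dominate each other.
    """
    results: dict[frozenset, ConditionalResult] = {}
    snps: set[str] = set()
    for res in cond_results:
        snps.update((res.snp_a, res.snp_b))
        if res.snp_a != res.snp_b:
            results[frozenset((res.snp_a, res.snp_b))] = res
    snps = set(s for s in snps)
    missing = [
        (a, b)
        for a in sorted(snps)
        for b in sorted(snps)
        if a < b and frozenset((a, b)) not in results
    ]
    if missing:
        raise InputError(f"conditional results missing for pairs: {missing}")
    if alpha_adj is None:
        alpha_adj = bonferroni_alpha(len(snps))

    excluded: list[str] = []
    active = set(snps)
    while True:
        losers = sorted(
            s
            for s in active
            if all(_loses(results, s, o, alpha_adj) for o in active if o != s)
        )
        excluded.extend(losers)
        active -= set(losers)
        if not iterate or not losers or len(active) < 2:
            break
    return excluded
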