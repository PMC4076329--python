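"""Multi-SNP haplotype phasing, dosage association and phylogeny.

Phasing is a deterministic multilocus EM over haplotype frequencies with
exhaustive diplotype expansion (practical for up to ~12 SNPs; at the FTO-style
locus 7-9 SNPs are phased). Per-sample posterior probabilities over *ordered*
haplotype pairs are retained, so the expected copy number (haplotype dosage)
of every haplotype sums to exactly 2 per sample. Trait association of a
haplotype uses the same linear/logistic models as single-SNP analysis, with
the dosage in place of the genotype.

The haplotype phylogeny is rooted at the ancestral haplotype (all-ancestral
alleles) and built by greedy minimum-mutation attachment; haplotypes that are
more cheaply explained as a single crossover of two placed haplotypes are
re-labelled as recombinants with a breakpoint interval.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from . import meta as meta_mod
from .association import AssocResult, _covariate_columns, _fit_logit, _int_bmi
from .errors import DegenerateError, InputError
from .geno_io import GenotypeMatrix, PhenotypeTable, VariantRecord

import pandas as pd
import statsmodels.api as sm

__all__ = [
    "Haplotype",
    "HaplotypeSet",
    "PhylogenyNetwork",
    "PhyloEdge",
    "em_phase",
    "haplotype_dosage",
    "haplotype_assoc",
    "haplotype_assoc_meta",
    "build_phylogeny",
]

PHASE_TOL = 1e-8
PHASE_MAX_ITER = 5000
PRUNE_FREQ = 1e-4
#: haplotypes rarer than this across all populations are labelled "Low"
DEFAULT_FREQ_FLOOR = 0.004


@dataclass(frozen=True)
class Haplotype:
    """An ordered allele vector over a declared SNP list."""

    label: str
    alleles: tuple[str, ...]
    ancestral_flags: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if self.ancestral_flags is not None and len(self.ancestral_flags) != len(
            self.alleles
        ):
            raise InputError(f"{self.label}: ancestral_flags length mismatch")


@dataclass
class HaplotypeSet:
    """Haplotypes over a SNP list with frequencies and diplotype posteriors.

    ``freqs`` maps population label -> {haplotype label -> frequency};
    ``posterior`` (when phased from a panel) holds, per sample, a dict over
    ordered haplotype-label pairs summing to 1.
    """

    snp_list: list[VariantRecord]
    haplotypes: list[Haplotype]
    freqs: dict[str, dict[str, float]]
    samples: list[str] | None = None
    posterior: list[dict[tuple[str, str], float]] | None = None

    def __post_init__(self) -> None:
        m = len(self.snp_list)
        for h in self.haplotypes:
            if len(h.alleles) != m:
                raise InputError(f"{h.label}: allele vector length != SNP list length")
        labels = [h.label for h in self.haplotypes]
        if len(set(labels)) != len(labels):
            raise InputError("duplicate haplotype labels")
        for pop, fr in self.freqs.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-6:
                raise InputError(f"{pop}: haplotype frequencies sum to {total}, not 1")
        if self.posterior is not None:
            for i, post in enumerate(self.posterior):
                if abs(sum(post.values()) - 1.0) > 1e-9:
                    raise InputError(f"sample {i}: posterior does not sum to 1")

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.snp_list]

    def haplotype(self, label: str) -> Haplotype:
        for h in self.haplotypes:
            if h.label == label:
                return h
        raise KeyError(label)

    def max_freq(self, label: str) -> float:
        """Largest frequency of this haplotype across populations."""
        return max((fr.get(label, 0.0) for fr in self.freqs.values()), default=0.0)

    def by_alleles(self) -> dict[tuple[str, ...], str]:
        return {h.alleles: h.label for h in self.haplotypes}

    def subset(self, labels: list[str]) -> "HaplotypeSet":
        keep = set(labels)
        haps = [h for h in self.haplotypes if h.label in keep]
        freqs = {}
        for pop, fr in self.freqs.items():
            sub = {l: f for l, f in fr.items() if l in keep}
            total = sum(sub.values())
            if total > 0:  # populations lacking all kept haplotypes are dropped
                freqs[pop] = {l: f / total for l, f in sub.items()}
        return HaplotypeSet(snp_list=list(self.snp_list), haplotypes=haps, freqs=freqs)

    def relabelled(self, reference: "HaplotypeSet") -> "HaplotypeSet":
        """Rename haplotypes to the reference's labels where alleles match."""
        ref = reference.by_alleles()
        mapping = {h.label: ref.get(h.alleles, h.label) for h in self.haplotypes}
        haps = [
            Haplotype(mapping[h.label], h.alleles, h.ancestral_flags)
            for h in self.haplotypes
        ]
        freqs = {
            pop: {mapping[l]: f for l, f in fr.items()} for pop, fr in self.freqs.items()
        }
        posterior = None
        if self.posterior is not None:
            posterior = [
                {(mapping[a], mapping[b]): p for (a, b), p in post.items()}
                for post in self.posterior
            ]
        return HaplotypeSet(
            snp_list=list(self.snp_list),
            haplotypes=haps,
            freqs=freqs,
            samples=self.samples,
            posterior=posterior,
        )


# ---------------------------------------------------------------------------
# EM phasing
# ---------------------------------------------------------------------------


def _enumerate_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """Unordered haplotype pairs compatible with one multilocus genotype.

    Genotypes count copies of allele 1 per site. With h heterozygous sites
    there are 2^(h-1) distinct unordered resolutions (the first het site is
    pinned to break the mirror symmetry).
    """
    het = [i for i, g in enumerate(geno) if g == 1]
    base = [g // 2 for g in geno]  # 0 for g in {0,1}, 1 for g==2
    if not het:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    for bits in itertools.product((0, 1), repeat=len(het) - 1):
        h1 = list(base)
        h2 = list(base)
        h1[het[0]] = 1
        h2[het[0]] = 0
        for site, bit in zip(het[1:], bits):
            h1[site] = bit
            h2[site] = 1 - bit
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_phase(
    panel: GenotypeMatrix,
    snp_list: list[str] | None = None,
    population: str = "all",
    max_iter: int = PHASE_MAX_ITER,
    tol: float = PHASE_TOL,
    prune: float = PRUNE_FREQ,
) -> HaplotypeSet:
    """Maximum-likelihood haplotype frequencies by multilocus EM.

    Starts uniform over all haplotypes compatible with at least one observed
    genotype; EM iterates until the max-abs frequency change is below ``tol``
    (default 1e-8) or ``max_iter`` iterations. The log-likelihood is checked
    to be non-decreasing at every step. Haplotypes below ``prune`` frequency
    are removed after convergence and per-sample ordered-pair posteriors are
    recomputed from the pruned frequencies.

    Only samples complete at all listed SNPs are used (>= 20 required).
    """
    ids = snp_list if snp_list is not None else panel.snp_ids
    m = len(ids)
    if not (2 <= m <= 12):
        raise InputError(f"need 2..12 SNPs for exhaustive phasing, got {m}")
    sub = panel.subset(ids)
    calls = sub.calls
    complete = np.all(calls >= 0, axis=1)
    if not complete.any():
        raise InputError("no sample has complete genotypes at the listed SNPs")
    n_complete = int(complete.sum())
    if n_complete < 20:
        raise InputError(f"need >= 20 complete samples for phasing, have {n_complete}")
    samples = [s for s, ok in zip(sub.samples, complete) if ok]
    geno_rows = [tuple(int(g) for g in row) for row in calls[complete]]

    # collapse identical genotypes
    geno_counts: dict[tuple[int, ...], int] = {}
    for row in geno_rows:
        geno_counts[row] = geno_counts.get(row, 0) + 1
    genos = sorted(geno_counts)
    counts = np.array([geno_counts[g] for g in genos], dtype=float)
    pair_lists = [_enumerate_pairs(g) for g in genos]

    universe = sorted({h for pairs in pair_lists for pair in pairs for h in pair})
    hap_index = {h: k for k, h in enumerate(universe)}
    K = len(universe)
    # per genotype: indices of pair members + homozygosity multiplier
    pair_idx = [
        np.array([[hap_index[a], hap_index[b]] for a, b in pairs]) for pairs in pair_lists
    ]
    pair_mult = [
        np.array([1.0 if a == b else 2.0 for a, b in pairs]) for pairs in pair_lists
    ]

    freqs = np.full(K, 1.0 / K)
    n_hap = 2 * counts.sum()
    loglik_prev = -np.inf
    for _ in range(max_iter):
        new = np.zeros(K)
        loglik = 0.0
        for c, idx, mult in zip(counts, pair_idx, pair_mult):
            w = mult * freqs[idx[:, 0]] * freqs[idx[:, 1]]
            total = w.sum()
            if total <= 0:
                continue
            loglik += c * np.log(total)
            post = w / total
            np.add.at(new, idx[:, 0], c * post)
            np.add.at(new, idx[:, 1], c * post)
        if loglik < loglik_prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")  # pragma: no cover
        new /= n_hap
        delta = np.max(np.abs(new - freqs))
        freqs = new
        loglik_prev = loglik
        if delta < tol:
            break

    keep = freqs >= prune
    if not keep.any():  # pragma: no cover - cannot happen with valid input
        raise DegenerateError("all haplotypes pruned")
    freqs = np.where(keep, freqs, 0.0)
    freqs /= freqs.sum()

    # label surviving haplotypes by allele string, ordered by frequency
    order = np.argsort(-freqs, kind="stable")
    haplotypes: list[Haplotype] = []
    label_of: dict[int, str] = {}
    for k in order:
        if freqs[k] <= 0:
            continue
        alleles = tuple(
            v.effect_allele if bit else v.other_allele
            for v, bit in zip(sub.variants, universe[k])
        )
        label = "".join(alleles)
        label_of[k] = label
        haplotypes.append(Haplotype(label=label, alleles=alleles))

    posterior: list[dict[tuple[str, str], float]] = []
    post_of_geno: dict[tuple[int, ...], dict[tuple[str, str], float]] = {}
    for g, idx, mult in zip(genos, pair_idx, pair_mult):
        w = mult * freqs[idx[:, 0]] * freqs[idx[:, 1]]
        total = w.sum()
        post: dict[tuple[str, str], float] = {}
        if total > 0:
            for (k1, k2), wi in zip(idx, w):
                if wi <= 0:
                    continue
                l1, l2 = label_of[k1], label_of[k2]
                if l1 == l2:
                    post[(l1, l2)] = post.get((l1, l2), 0.0) + wi / total
                else:
                    post[(l1, l2)] = post.get((l1, l2), 0.0) + wi / (2 * total)
                    post[(l2, l1)] = post.get((l2, l1), 0.0) + wi / (2 * total)
        post_of_geno[g] = post
    for row in geno_rows:
        posterior.append(post_of_geno[row])

    freq_map = {label_of[k]: float(freqs[k]) for k in order if freqs[k] > 0}
    return HaplotypeSet(
        snp_list=list(sub.variants),
        haplotypes=haplotypes,
        freqs={population: freq_map},
        samples=samples,
        posterior=posterior,
    )


def haplotype_dosage(hs: HaplotypeSet, target_label: str) -> np.ndarray:
    """Posterior expected copy number of the target haplotype per sample."""
    if hs.posterior is None:
        raise InputError("haplotype set carries no per-sample posteriors")
    if target_label not in hs.labels:
        raise KeyError(target_label)
    out = np.zeros(len(hs.posterior))
    for i, post in enumerate(hs.posterior):
        d = 0.0
        for (l1, l2), p in post.items():
            d += p * ((l1 == target_label) + (l2 == target_label))
        out[i] = d
    return out


def haplotype_assoc(
    hs: HaplotypeSet,
    target_label: str,
    pheno: PhenotypeTable,
    trait: str = "bmi",
    covariates: tuple[str, ...] | None = None,
    transform: str = "blom",
) -> AssocResult:
    """Regression of the trait on the target haplotype's dosage.

    Linear model on INT-BMI (age, age^2) or logistic on T2D status (sex),
    mirroring the single-SNP analysis; the haplotype label plays the role of
    the effect allele. A near-constant dosage raises
    :class:`DegenerateError` (haplotype absent from this population).
    """
    if covariates is None:
        covariates = ("age", "age2") if trait == "bmi" else ("sex",)
    if hs.samples is None:
        raise InputError("haplotype set carries no sample information")
    dosage = haplotype_dosage(hs, target_label)
    if float(np.var(dosage)) < 1e-12:
        raise DegenerateError(
            f"haplotype {target_label!r} has (near-)zero dosage variance"
        )
    df = pheno.aligned_to(hs.samples)
    df["dosage"] = dosage
    X_cov = _covariate_columns(df, covariates)
    if trait == "bmi":
        y_all = _int_bmi(df, transform)
    elif trait == "t2d":
        y_all = df["t2d"].map({"case": 1.0, "control": 0.0})
    else:
        raise InputError(f"unknown trait {trait!r}")
    keep = ~(y_all.isna() | df["dosage"].isna() | X_cov.isna().any(axis=1))
    n = int(keep.sum())
    if n < 10:
        raise InputError(f"{target_label}: need >= 10 complete cases, have {n}")
    X = sm.add_constant(
        pd.concat([df.loc[keep, ["dosage"]], X_cov.loc[keep]], axis=1),
        has_constant="add",
    )
    if trait == "bmi":
        fit = sm.OLS(y_all[keep].values, X).fit()
    else:
        y = y_all[keep].values
        if min(np.sum(y == 1), np.sum(y == 0)) < 10:
            raise InputError(f"{target_label}: need >= 10 cases and controls")
        fit = _fit_logit(y, X, target_label)
    pops = df.loc[keep, "population"].dropna().unique()
    return AssocResult(
        snp_id=target_label,
        trait=trait,
        effect_allele=target_label,
        other_allele="other",
        eaf=float(np.mean(dosage[keep.values]) / 2),
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        p=max(float(fit.pvalues["dosage"]), np.finfo(float).tiny),
        n=n,
        population=str(pops[0]) if len(pops) == 1 else "pooled",
        covariates_used=tuple(covariates),
    )


def haplotype_assoc_meta(
    panels: dict[str, GenotypeMatrix],
    phenos: dict[str, PhenotypeTable],
    snp_list: list[str],
    target_alleles: tuple[str, ...],
    trait: str = "bmi",
) -> tuple[meta_mod.MetaResult, dict[str, AssocResult]]:
    """Per-population haplotype association combined by fixed-effect meta.

    Each population is phased separately; populations where the target
    haplotype is absent (degenerate dosage) are dropped with a warning, as
    with low-frequency haplotypes excluded from the combined estimate.
    """
    per_pop: dict[str, AssocResult] = {}
    for pop in sorted(panels):
        hs = em_phase(panels[pop], snp_list, population=pop)
        label = hs.by_alleles().get(tuple(target_alleles))
        if label is None:
            warnings.warn(f"{pop}: target haplotype absent; dropped from meta")
            continue
        try:
            per_pop[pop] = haplotype_assoc(hs, label, phenos[pop], trait=trait)
        except DegenerateError:
            warnings.warn(f"{pop}: target haplotype degenerate; dropped from meta")
    if not per_pop:
        raise InputError("target haplotype unusable in every population")
    combined = meta_mod.fixed_effect_meta(
        [(r.beta, r.se) for r in per_pop.values()]
    )
    return combined, per_pop


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhyloEdge:
    parent: str
    child: str
    kind: str  # "mutation" | "recombination"
    #: for mutation edges: tuple of differing SNP ids;
    #: for recombination edges: (second parent, breakpoint interval)
    detail: tuple

    def n_events(self) -> int:
        return len(self.detail) if self.kind == "mutation" else 1


@dataclass
class PhylogenyNetwork:
    """Ancestral-rooted haplotype network with mutation/recombination edges."""

    nodes: list[str]
    root: str
    edges: list[PhyloEdge]

    def edge_to(self, child: str) -> PhyloEdge:
        for e in self.edges:
            if e.child == child:
                return e
        raise KeyError(child)

    def total_events(self) -> int:
        return sum(e.n_events() for e in self.edges)

    def newick(self) -> str:
        """Bracket export for mutation-only trees."""
        if any(e.kind != "mutation" for e in self.edges):
            raise InputError("newick export only defined for mutation-only trees")
        children: dict[str, list[str]] = {}
        for e in self.edges:
            children.setdefault(e.parent, []).append(e.child)

        def fmt(node: str) -> str:
            kids = sorted(children.get(node, []))
            if not kids:
                return node
            return "(" + ",".join(fmt(k) for k in kids) + ")" + node

        return fmt(self.root) + ";"


def _hamming(a: tuple[str, ...], b: tuple[str, ...]) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def build_phylogeny(
    hs: HaplotypeSet,
    ancestral_label: str,
    freq_floor: float = DEFAULT_FREQ_FLOOR,
) -> PhylogenyNetwork:
    """Greedy minimum-mutation haplotype network rooted at the ancestor.

    Haplotypes below ``freq_floor`` (max frequency over populations) are
    excluded, except the root. Unplaced haplotypes are attached, closest
    first, to the placed node at the smallest Hamming distance (ties broken
    toward the higher-frequency parent, then the parent nearer the root,
    then lexicographic label). A multi-SNP mutation edge is re-labelled as a
    recombination when the child equals a single crossover of two placed
    haplotypes (1 implied event < number of substitutions); its detail names
    the second parent and the breakpoint interval of SNP ids.
    """
    if ancestral_label not in hs.labels:
        raise InputError(f"ancestral haplotype {ancestral_label!r} not in set")
    included = [
        h.label
        for h in hs.haplotypes
        if h.label == ancestral_label or hs.max_freq(h.label) >= freq_floor
    ]
    alleles = {h.label: h.alleles for h in hs.haplotypes}
    snp_ids = hs.snp_ids

    depth = {ancestral_label: 0}
    placed = [ancestral_label]
    edges: list[PhyloEdge] = []
    unplaced = [l for l in included if l != ancestral_label]
    while unplaced:
        best = None
        for child in unplaced:
            for parent in placed:
                diff = _hamming(alleles[child], alleles[parent])
                key = (
                    len(diff),
                    -hs.max_freq(parent),
                    depth[parent],
                    child,
                    parent,
                )
                if best is None or key < best[0]:
                    best = (key, child, parent, diff)
        _, child, parent, diff = best
        edges.append(
            PhyloEdge(
                parent=parent,
                child=child,
                kind="mutation",
                detail=tuple(snp_ids[i] for i in diff),
            )
        )
        depth[child] = depth[parent] + 1
        placed.append(child)
        unplaced.remove(child)

    # recombination re-labelling
    final_edges: list[PhyloEdge] = []
    for e in edges:
        if e.kind != "mutation" or len(e.detail) < 2:
            final_edges.append(e)
            continue
        child_alleles = alleles[e.child]
        best_rec = None
        candidates = [l for l in placed if l != e.child]
        for p1 in candidates:
            for p2 in candidates:
                if p1 == p2:
                    continue
                valid_i = [
                    i
                    for i in range(1, len(snp_ids))
                    if alleles[p1][:i] + alleles[p2][i:] == child_alleles
                ]
                if not valid_i:
                    continue
                key = (-max(hs.max_freq(p1), hs.max_freq(p2)), min(p1, p2))
                if best_rec is None or key < best_rec[0]:
                    interval = (snp_ids[min(valid_i) - 1], snp_ids[max(valid_i)])
                    major, minor = sorted(
                        (p1, p2), key=lambda l: (-hs.max_freq(l), l)
                    )
                    best_rec = (key, major, minor, interval)
        if best_rec is not None:
            _, major, minor, interval = best_rec
            final_edges.append(
                PhyloEdge(
                    parent=major,
                    child=e.child,
                    kind="recombination",
                    detail=(minor, interval),
                )
            )
        else:
            final_edges.append(e)
    return PhylogenyNetwork(nodes=list(placed), root=ancestral_label, edges=final_edges)


def network_to_frame(net: PhylogenyNetwork) -> pd.DataFrame:
    """Edge-list table (parent, child, kind, detail) for TSV export."""
    rows = []
    for e in net.edges:
        if e.kind == "mutation":
            detail = ",".join(e.detail)
        else:
            minor, interval = e.detail
            detail = f"second_parent={minor};breakpoint={interval[0]}..{interval[1]}"
        rows.append(
            {"parent": e.parent, "child": e.child, "kind": e.kind, "detail": detail}
        )
    return pd.DataFrame(rows, columns=["parent", "child", "kind", "detail"])
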