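"""Synthetic multi-population genotype panels with known ground truth.

Two generators are provided.

:func:`simulate_panel`
    Haplotype-architecture panels: two haplotypes per individual are drawn
    i.i.d. from a population-specific frequency table over the FTO-style
    haplotype classes (H1..H4 plus recombinant sub-haplotypes), genotypes at
    the core SNPs follow from the sampled diplotypes, and filler SNPs are
    created in tunable LD with their cluster's core SNP by per-haplotype
    allele switching with frequency-matched switch probabilities (haplotype
    correlation sqrt(r^2)), which keeps haplotype structure coherent for
    phasing. BMI is generated additively on a standardised scale from the
    number of H1 (risk-haplotype) copies; type 2 diabetes status is sampled
    from a logistic model on the same count.

:func:`simulate_clustered_panel`
    Panels with several mutually independent planted LD clusters (one core
    SNP plus proxies each), used to exercise index-SNP selection, cluster
    assignment, conditional screening and trans-ethnic filtering against an
    exact truth record.

All outputs are bitwise-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import ConfigError
from .geno_io import GenotypeMatrix, PhenotypeTable, VariantRecord
from .haplotype import Haplotype, HaplotypeSet

import pandas as pd

__all__ = [
    "PopulationConfig",
    "EffectConfig",
    "TruthRecord",
    "core_snps",
    "default_haplotypes",
    "population_presets",
    "simulate_panel",
    "simulate_clustered_panel",
]

#: the eight assayed SNPs defining the FTO-style haplotype classes, in
#: physical order; rs7206790 shows within-class recombination and is excluded
#: from haplotype definitions unless explicitly requested.
_CORE_SNPS = (
    # snp_id, pos, other_allele, effect_allele (BMI/T2D-risk-increasing)
    ("rs7206790", 53_798_000, "C", "G"),
    ("rs1421085", 53_801_000, "T", "C"),
    ("rs3751812", 53_818_000, "G", "T"),
    ("rs9939609", 53_820_500, "T", "A"),
    ("rs9941349", 53_822_700, "C", "T"),
    ("rs56137030", 53_825_500, "G", "A"),
    ("rs17817964", 53_828_100, "C", "T"),
    ("rs12149832", 53_842_900, "G", "A"),
)

RECOMBINANT_SNP = "rs7206790"

# haplotype class -> alleles at the 8 core SNPs (rs7206790 shown as its major
# allele) and per-population frequencies; "Low" rare classes are coded 0.002.
_LOW = 0.002
_HAPLOTYPES = {
    #        7206790 1421085 3751812 9939609 9941349 56137030 17817964 12149832
    "H1":   ("G", "C", "T", "A", "T", "A", "T", "A"),
    "H1-2": ("G", "C", "T", "A", "T", "G", "T", "A"),
    "H1-3": ("G", "C", "T", "A", "T", "A", "T", "G"),
    "H2-1": ("G", "T", "G", "A", "C", "A", "C", "G"),
    "H2":   ("G", "T", "G", "A", "C", "G", "C", "G"),
    "H2-2": ("C", "T", "G", "A", "T", "G", "C", "G"),
    "H3":   ("C", "T", "G", "T", "C", "G", "C", "G"),
    "H3-1": ("G", "C", "G", "T", "C", "G", "C", "G"),
    "H3-3": ("C", "T", "G", "T", "C", "G", "C", "A"),
    "H3-4": ("C", "T", "G", "T", "C", "G", "T", "G"),
    "H4":   ("C", "T", "G", "T", "T", "G", "C", "G"),
}
ANCESTRAL_LABEL = "H2"

_FREQS = {
    # population -> haplotype -> frequency as printed (None omitted, Low=0.002)
    "AFR": {"H1": 0.05, "H2-1": 0.01, "H2": 0.45, "H2-2": 0.03, "H3": 0.38,
            "H3-1": _LOW, "H4": 0.07},
    "EUR": {"H1": 0.41, "H1-2": 0.003, "H1-3": 0.01, "H3": 0.53, "H3-1": 0.02,
            "H3-3": 0.02, "H4": 0.01},
    "ASN": {"H1": 0.15, "H1-3": _LOW, "H3": 0.77, "H3-3": 0.01, "H3-4": 0.02,
            "H4": 0.03},
    "Japanese": {"H1": 0.18, "H1-3": 0.01, "H2": _LOW, "H3": 0.73, "H3-1": _LOW,
                 "H3-3": 0.01, "H3-4": 0.03, "H4": 0.03},
    "Vietnamese": {"H1": 0.18, "H1-3": 0.01, "H2": _LOW, "H2-2": _LOW,
                   "H3": 0.74, "H3-1": _LOW, "H3-3": 0.01, "H3-4": 0.01,
                   "H4": 0.05},
    "SriLankan": {"H1": 0.32, "H1-2": _LOW, "H1-3": _LOW, "H2": _LOW,
                  "H3": 0.54, "H3-1": 0.02, "H3-3": 0.04, "H4": 0.07},
}


def core_snps(include_recombinant: bool = True) -> list[VariantRecord]:
    """VariantRecords for the core assayed SNPs, in physical order."""
    records = [
        VariantRecord(snp_id=s, chrom="16", pos=pos, allele_a=other, allele_b=eff,
                      effect_allele=eff)
        for s, pos, other, eff in _CORE_SNPS
    ]
    if not include_recombinant:
        records = [v for v in records if v.snp_id != RECOMBINANT_SNP]
    return records


def default_haplotypes(include_rs7206790: bool = False) -> HaplotypeSet:
    """The FTO-style haplotype classes H1..H4 and their sub-haplotypes.

    By default the definitions cover the 7 non-recombinant core SNPs;
    rs7206790 recombines within haplotype classes, so when included its
    major allele is used. Frequencies are per population (1000 Genomes-style
    AFR/EUR/ASN plus the three Asian study populations), rare classes coded
    at 0.002 and each population normalised to sum to 1.
    """
    snps = core_snps(include_recombinant=include_rs7206790)
    skip = 0 if include_rs7206790 else 1
    ancestral = _HAPLOTYPES[ANCESTRAL_LABEL][skip:]
    haps = []
    for label, alleles in _HAPLOTYPES.items():
        cut = alleles[skip:]
        haps.append(
            Haplotype(
                label=label,
                alleles=cut,
                ancestral_flags=tuple(a == b for a, b in zip(cut, ancestral)),
            )
        )
    freqs = {}
    for pop, fr in _FREQS.items():
        total = sum(fr.values())
        freqs[pop] = {l: f / total for l, f in fr.items()}
    return HaplotypeSet(snp_list=snps, haplotypes=haps, freqs=freqs)


def population_presets() -> dict[str, dict[str, float]]:
    """Normalised per-population haplotype frequency tables."""
    return {pop: dict(fr) for pop, fr in default_haplotypes().freqs.items()}


@dataclass
class PopulationConfig:
    """Study conditions for one simulated population."""

    name: str
    n_samples: int
    hap_freqs: dict[str, float]
    snp_list: list[VariantRecord] = field(default_factory=lambda: core_snps(False))
    filler_snps: int = 0
    #: target r^2 of each filler to its cluster's core SNP; scalar or one
    #: value per filler
    filler_r2: float | list[float] = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")
        total = sum(self.hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"haplotype frequencies sum to {total}, not 1")
        r2s = self.filler_r2_list()
        if any(not (0 <= r <= 1) for r in r2s):
            raise ConfigError("filler_r2 must lie in [0, 1]")

    def filler_r2_list(self) -> list[float]:
        if isinstance(self.filler_r2, (int, float)):
            return [float(self.filler_r2)] * self.filler_snps
        if len(self.filler_r2) != self.filler_snps:
            raise ConfigError("filler_r2 list must have one value per filler")
        return [float(r) for r in self.filler_r2]


@dataclass
class EffectConfig:
    """Planted phenotype effects, per copy of the causal (H1) haplotype.

    ``bmi_beta_per_h1`` is on the standardised (z-score-like) BMI scale;
    ``t2d_log_or_per_h1`` is a log odds ratio. Defaults follow the combined
    Asian estimates for the H1 risk haplotype (beta 0.064, OR 1.221).
    """

    bmi_beta_per_h1: float = 0.064
    t2d_log_or_per_h1: float = float(np.log(1.221))
    baseline_prevalence: float = 0.3
    noise_sd: float = 1.0
    age_range: tuple[float, float] = (35.0, 74.0)
    sex_ratio: float = 0.5
    age_lin: float = 0.01
    age_quad: float = -0.0005

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0 < self.baseline_prevalence < 1):
            raise ConfigError("baseline_prevalence must be in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel."""

    diplotypes: list[tuple[str, str]]
    cluster_of: dict[str, str]  # snp_id -> core snp_id of its planted cluster
    causal_haplotype: str | None = None
    causal_snps: list[str] = field(default_factory=list)

    @property
    def causal_snp(self) -> str | None:
        return self.causal_snps[0] if self.causal_snps else None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"snp_id": s, "cluster": c} for s, c in sorted(self.cluster_of.items())]
        return pd.DataFrame(rows, columns=["snp_id", "cluster"])


def _ld_filler(bits: np.ndarray, target_r2: float, rng: np.random.Generator) -> np.ndarray:
    """Per-haplotype allele switching toward a target r^2, frequency-matched.

    Copying the core allele with asymmetric switch probabilities
    a = (1-rho)(1-p) for carriers and b = (1-rho)p for non-carriers keeps the
    filler's allele frequency equal to the core's (p) and gives haplotype
    correlation rho = sqrt(r^2) exactly, hence genotype r^2 ~ target at any
    frequency.
    """
    rho = float(np.sqrt(target_r2))
    p = float(bits.mean())
    if p <= 0.0 or p >= 1.0 or rho >= 1.0:
        return bits.copy()
    a = (1.0 - rho) * (1.0 - p)
    b = (1.0 - rho) * p
    u = rng.random(bits.shape)
    return np.where(bits == 1, (u >= a).astype(np.int8), (u < b).astype(np.int8))


def _phenotypes(
    rng: np.random.Generator,
    n: int,
    n_causal_copies: np.ndarray,
    eff: EffectConfig,
    name: str,
    bmi_beta: float | None = None,
    log_or: float | None = None,
) -> PhenotypeTable:
    bmi_beta = eff.bmi_beta_per_h1 if bmi_beta is None else bmi_beta
    log_or = eff.t2d_log_or_per_h1 if log_or is None else log_or
    age = rng.uniform(*eff.age_range, size=n)
    sex = np.where(rng.random(n) < eff.sex_ratio, 1, 2)
    noise = rng.normal(0.0, eff.noise_sd, size=n) if eff.noise_sd > 0 else np.zeros(n)
    latent = (
        eff.age_lin * (age - 50.0)
        + eff.age_quad * (age - 50.0) ** 2
        + bmi_beta * n_causal_copies
        + noise
    )
    bmi = 23.0 + latent
    p_case = expit(logit(eff.baseline_prevalence) + log_or * n_causal_copies)
    t2d = np.where(rng.random(n) < p_case, "case", "control")
    return PhenotypeTable(
        pd.DataFrame(
            {
                "sample_id": [f"{name}_{i:05d}" for i in range(n)],
                "sex": sex,
                "age": age,
                "bmi": bmi,
                "t2d": t2d,
                "population": name,
                "panel": name,
            }
        )
    )


def simulate_panel(
    pop_cfg: PopulationConfig,
    eff_cfg: EffectConfig | None = None,
    haplotypes: HaplotypeSet | None = None,
) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Simulate one population under the haplotype architecture.

    Each individual receives two haplotypes i.i.d. from ``hap_freqs``; core
    SNP genotypes count effect alleles implied by the diplotype; each filler
    SNP copies its core SNP's haplotype allele with a switching probability
    calibrated to the requested r^2. BMI and T2D follow additive models on
    the number of H1 copies.
    """
    eff_cfg = eff_cfg if eff_cfg is not None else EffectConfig()
    hs = haplotypes if haplotypes is not None else default_haplotypes()
    labels = sorted(pop_cfg.hap_freqs)
    unknown = [l for l in labels if l not in hs.labels]
    if unknown:
        raise ConfigError(f"haplotype labels not in set: {unknown}")
    snp_ids = [v.snp_id for v in pop_cfg.snp_list]
    hap_of = {l: hs.haplotype(l) for l in labels}
    col_of = {v.snp_id: i for i, v in enumerate(hs.snp_list)}
    missing_snp = [s for s in snp_ids if s not in col_of]
    if missing_snp:
        raise ConfigError(f"SNPs not covered by haplotype definitions: {missing_snp}")

    rng = np.random.default_rng(pop_cfg.seed)
    n = pop_cfg.n_samples
    probs = np.array([pop_cfg.hap_freqs[l] for l in labels])
    pick = rng.choice(len(labels), size=(n, 2), p=probs)
    diplotypes = [(labels[a], labels[b]) for a, b in pick]

    # haplotype-level allele indicators at core SNPs (1 = effect allele)
    hap_bits = np.zeros((len(labels), len(snp_ids)), dtype=np.int8)
    for k, l in enumerate(labels):
        for j, (s, v) in enumerate(zip(snp_ids, pop_cfg.snp_list)):
            hap_bits[k, j] = int(hap_of[l].alleles[col_of[s]] == v.effect_allele)
    bits = hap_bits[pick]  # n x 2 x m

    variants = list(pop_cfg.snp_list)
    cluster_of = {s: s for s in snp_ids}
    filler_cols = []
    r2s = pop_cfg.filler_r2_list()
    if pop_cfg.filler_snps:
        for j, v in enumerate(pop_cfg.snp_list):
            for k, r2 in enumerate(r2s):
                fb = _ld_filler(bits[:, :, j], r2, rng)
                filler_cols.append(fb.sum(axis=1))
                fid = f"{v.snp_id}_px{k + 1}"
                variants.append(
                    VariantRecord(
                        snp_id=fid,
                        chrom=v.chrom,
                        pos=v.pos + 17 * (k + 1),
                        allele_a="G",
                        allele_b="A",
                        effect_allele="A",
                    )
                )
                cluster_of[fid] = v.snp_id

    core_calls = bits.sum(axis=1)
    calls = (
        np.column_stack([core_calls] + [np.column_stack(filler_cols)])
        if filler_cols
        else core_calls
    )
    panel = GenotypeMatrix(
        variants=variants,
        samples=[f"{pop_cfg.name}_{i:05d}" for i in range(n)],
        calls=calls.astype(np.int8),
    )
    n_h1 = np.array([(a == "H1") + (b == "H1") for a, b in diplotypes], dtype=float)
    pheno = _phenotypes(rng, n, n_h1, eff_cfg, pop_cfg.name)
    truth = TruthRecord(
        diplotypes=diplotypes, cluster_of=cluster_of, causal_haplotype="H1"
    )
    return panel, pheno, truth


def simulate_clustered_panel(
    n_samples: int,
    n_clusters: int,
    proxies_per_cluster: int = 0,
    proxy_r2: float | list[float] = 0.95,
    mafs: float | list[float] = 0.3,
    causal_cluster: int | list[int] = 0,
    beta: float = 0.15,
    log_or: float = 0.0,
    eff_cfg: EffectConfig | None = None,
    name: str = "pop",
    chrom: str = "16",
    seed: int = 0,
) -> tuple[GenotypeMatrix, PhenotypeTable, TruthRecord]:
    """Panel with mutually independent planted LD clusters.

    Cluster ``c`` has a core SNP ``clu{c+1}`` (haplotype allele frequency
    ``mafs[c]``) plus proxies ``clu{c+1}_px{k}`` at per-proxy target r^2.
    The phenotype is driven additively by the causal clusters' core SNPs
    (``causal_cluster`` may be an index or a list of indices), each with the
    same effect size on the standardised BMI scale (and optionally a T2D
    log-OR); other clusters are null.
    """
    if n_samples < 2:
        raise ConfigError("n_samples must be >= 2")
    eff_cfg = eff_cfg if eff_cfg is not None else EffectConfig()
    maf_list = (
        [float(mafs)] * n_clusters if isinstance(mafs, (int, float)) else list(mafs)
    )
    if len(maf_list) != n_clusters:
        raise ConfigError("need one maf per cluster")
    r2_list = (
        [float(proxy_r2)] * proxies_per_cluster
        if isinstance(proxy_r2, (int, float))
        else [float(r) for r in proxy_r2]
    )
    if len(r2_list) != proxies_per_cluster:
        raise ConfigError("need one proxy_r2 per proxy")

    causal_set = (
        {int(causal_cluster)}
        if isinstance(causal_cluster, int)
        else {int(c) for c in causal_cluster}
    )
    bad = [c for c in causal_set if not (0 <= c < n_clusters)]
    if bad:
        raise ConfigError(f"causal cluster indices out of range: {bad}")

    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    cluster_of: dict[str, str] = {}
    causal_g = np.zeros(n_samples)
    for c in range(n_clusters):
        core_id = f"clu{c + 1}"
        pos0 = 53_700_000 + 10_000 * c
        hap = (rng.random((n_samples, 2)) < maf_list[c]).astype(np.int8)
        g = hap.sum(axis=1)
        variants.append(
            VariantRecord(core_id, chrom, pos0, "G", "A", "A")
        )
        cols.append(g)
        cluster_of[core_id] = core_id
        if c in causal_set:
            causal_g = causal_g + g.astype(float)
        for k, r2 in enumerate(r2_list):
            ph = _ld_filler(hap, r2, rng)
            pid = f"{core_id}_px{k + 1}"
            variants.append(
                VariantRecord(pid, chrom, pos0 + 17 * (k + 1), "G", "A", "A")
            )
            cols.append(ph.sum(axis=1))
            cluster_of[pid] = core_id

    panel = GenotypeMatrix(
        variants=variants,
        samples=[f"{name}_{i:05d}" for i in range(n_samples)],
        calls=np.column_stack(cols).astype(np.int8),
    )
    pheno = _phenotypes(
        rng, n_samples, causal_g, eff_cfg, name, bmi_beta=beta, log_or=log_or
    )
    truth = TruthRecord(
        diplotypes=[],
        cluster_of=cluster_of,
        causal_snps=[f"clu{c + 1}" for c in sorted(causal_set)],
    )
    return panel, pheno, truth
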