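"""Genotype, phenotype and summary-statistic I/O.

Containers
----------
:class:`VariantRecord`
    One biallelic SNP with a declared effect allele.
:class:`GenotypeMatrix`
    samples x variants matrix of unphased genotypes coded as counts of the
    effect allele (0/1/2, ``-1`` for missing).
:class:`PhenotypeTable`
    Per-sample phenotypes and covariates (sex, age, BMI, case/control status,
    population and panel labels) backed by a pandas DataFrame.

Formats
-------
VCF 4.x (GT field only, read through cyvcf2) and whitespace-delimited
PLINK-style ``.ped``/``.map`` text. Summary statistics travel as a TSV with a
fixed schema (see :func:`read_summary_stats`). Coordinates are 1-based in both
genotype dialects. Multi-allelic VCF records are rejected rather than split.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParseError, SchemaError

__all__ = [
    "MISSING",
    "VariantRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "read_summary_stats",
    "write_summary_stats",
    "read_phenotypes",
    "write_phenotypes",
]

#: Sentinel for a missing genotype call in :attr:`GenotypeMatrix.calls`.
MISSING: int = -1

_TOOL_TAG = "transfinemap"


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("transfinemap")
    except Exception:  # pragma: no cover - not installed
        return "0.0.0"


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP.

    ``effect_allele`` is the allele whose copies the genotype calls count; it
    must be one of ``allele_a``/``allele_b``. Positions are 1-based as in VCF.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    effect_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"{self.snp_id}: position must be >= 1, got {self.pos}")
        if self.effect_allele not in (self.allele_a, self.allele_b):
            raise InputError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is neither "
                f"{self.allele_a!r} nor {self.allele_b!r}"
            )

    @property
    def other_allele(self) -> str:
        return self.allele_a if self.effect_allele == self.allele_b else self.allele_b

    def flipped(self) -> "VariantRecord":
        """The same variant with the opposite effect allele."""
        return replace(self, effect_allele=self.other_allele)


@dataclass
class GenotypeMatrix:
    """Unphased genotypes for a panel of samples.

    ``calls[i, j]`` counts copies of ``variants[j].effect_allele`` carried by
    ``samples[i]`` (0, 1 or 2; :data:`MISSING` for no-calls).
    """

    variants: list[VariantRecord]
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise InputError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise InputError("genotype calls must be in {0, 1, 2} or missing")
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate snp_id in panel")
        if len(set(self.samples)) != len(self.samples):
            raise InputError("duplicate sample id in panel")
        self._index = {s: j for j, s in enumerate(ids)}

    # -- lookup ---------------------------------------------------------

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def variant(self, snp_id: str) -> VariantRecord:
        return self.variants[self._index[snp_id]]

    def genotype(self, snp_id: str) -> np.ndarray:
        """Effect-allele dosage vector for one SNP (float, NaN = missing)."""
        col = self.calls[:, self._index[snp_id]].astype(float)
        col[col == MISSING] = np.nan
        return col

    def positions(self) -> dict[str, int]:
        return {v.snp_id: v.pos for v in self.variants}

    # -- transforms -----------------------------------------------------

    def set_effect_allele(self, snp_id: str, allele: str) -> None:
        """Re-orient one SNP so calls count ``allele`` (flips g -> 2 - g)."""
        j = self._index[snp_id]
        v = self.variants[j]
        if allele == v.effect_allele:
            return
        if allele not in (v.allele_a, v.allele_b):
            raise InputError(f"{snp_id}: unknown allele {allele!r}")
        col = self.calls[:, j]
        nonmissing = col != MISSING
        col[nonmissing] = 2 - col[nonmissing]
        self.variants[j] = replace(v, effect_allele=allele)

    def subset(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(
            variants=[self.variants[j] for j in idx],
            samples=list(self.samples),
            calls=self.calls[:, idx].copy(),
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )


_T2D_LEVELS = ("case", "control", "unknown")
_PHENO_COLUMNS = ("sample_id", "sex", "age", "bmi", "t2d", "population", "panel")


@dataclass
class PhenotypeTable:
    """Per-sample phenotype and covariate table.

    Columns: sample_id, sex (1 = male, 2 = female), age (years), bmi
    (standardised synthetic scale or kg/m^2), t2d (case/control/unknown),
    population and panel labels. Missing numeric values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PHENO_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"phenotype table missing columns: {missing}")
        df = self.data.reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            raise InputError("duplicate sample_id in phenotype table")
        ages = df["age"].dropna()
        if (ages <= 0).any():
            raise InputError("ages must be positive where present")
        bad_sex = ~df["sex"].dropna().isin((1, 2))
        if bad_sex.any():
            raise InputError("sex must be coded 1/2")
        bad_t2d = ~df["t2d"].dropna().isin(_T2D_LEVELS)
        if bad_t2d.any():
            raise InputError(f"t2d must be one of {_T2D_LEVELS}")
        self.data = df

    def aligned_to(self, samples: Sequence[str]) -> pd.DataFrame:
        """Rows reindexed to the given sample order (NaN where absent)."""
        df = self.data.set_index("sample_id").reindex(samples)
        df.index.name = "sample_id"
        return df.reset_index()

    def populations(self) -> list[str]:
        return sorted(self.data["population"].dropna().unique())


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | os.PathLike, fmt: str = "vcf") -> GenotypeMatrix:
    """Read a genotype panel.

    ``fmt='vcf'``: VCF 4.x via cyvcf2; the effect allele defaults to ALT.
    ``fmt='plink_text'``: whitespace ``.ped``/``.map`` pair (pass either the
    ``.ped`` path or the shared prefix); alleles are inferred from the data
    (allele_a = lexicographically smaller) and the effect allele defaults to
    allele_b. Missing genotypes are preserved as missing.
    """
    if fmt == "vcf":
        return _read_vcf(Path(path))
    if fmt == "plink_text":
        return _read_plink_text(Path(path))
    raise InputError(f"unknown genotype format {fmt!r}")


def write_genotypes(matrix: GenotypeMatrix, path: str | os.PathLike, fmt: str = "vcf") -> None:
    """Write a panel so that :func:`read_genotypes` recovers it losslessly.

    VCF output places the effect allele in ALT (so a call of 2 is written
    ``1/1``); PLINK-text output writes a ``.ped``/``.map`` pair.
    """
    if fmt == "vcf":
        _write_vcf(matrix, Path(path))
    elif fmt == "plink_text":
        _write_plink_text(matrix, Path(path))
    else:
        raise InputError(f"unknown genotype format {fmt!r}")


def _validate_vcf_lines(path: Path) -> None:
    """Light structural pass so parse failures name the offending line."""
    n_fixed = 8  # sites-only VCF; 9+ when samples are present
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                n_cols = len(line.rstrip("\n").split("\t"))
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise ParseError(f"{path}: line {lineno}: data before #CHROM header")
            fields = line.rstrip("\n").split("\t")
            if len(fields) < n_fixed or len(fields) != n_cols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"fields, found {len(fields)}"
                )
        if not saw_header:
            raise ParseError(f"{path}: no #CHROM header line")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise InputError(f"no such file: {path}")
    _validate_vcf_lines(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib-level failure
        raise ParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{path}: {rec.ID or rec.POS}: multi-allelic records are not supported"
            )
        ref, alt = rec.REF, rec.ALT[0]
        variants.append(
            VariantRecord(
                snp_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=rec.CHROM,
                pos=rec.POS,
                allele_a=ref,
                allele_b=alt,
                effect_allele=alt,
            )
        )
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes if samples else []):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise FormatError(
                    f"{path}: {rec.ID or rec.POS}: non-diploid call for sample "
                    f"{samples[i]}"
                )
            if -1 in alleles:
                continue
            col[i] = int(alleles[0]) + int(alleles[1])
        cols.append(col)
    calls = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if matrix.samples:
        header_cols += ["FORMAT", *matrix.samples]
    contigs = list(dict.fromkeys(v.chrom for v in matrix.variants))
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={_TOOL_TAG} {_version()}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        *[f"##contig=<ID={c}>" for c in contigs],
        "\t".join(header_cols),
    ]
    for j, v in enumerate(matrix.variants):
        for allele in (v.allele_a, v.allele_b):
            if not allele or not allele.strip() or any(c.isspace() for c in allele):
                raise FormatError(f"{v.snp_id}: unencodable allele {allele!r}")
        ref, alt = v.other_allele, v.effect_allele
        row = f"{v.chrom}\t{v.pos}\t{v.snp_id}\t{ref}\t{alt}\t.\t.\t."
        if matrix.samples:
            gts = "\t".join(_GT_STRINGS[int(g)] for g in matrix.calls[:, j])
            row += "\tGT\t" + gts
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def _plink_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".ped":
        return path, path.with_suffix(".map")
    if path.suffix == ".map":
        return path.with_suffix(".ped"), path
    return path.with_suffix(".ped"), path.with_suffix(".map")


def _read_plink_text(path: Path) -> GenotypeMatrix:
    ped_path, map_path = _plink_paths(path)
    for p in (ped_path, map_path):
        if not p.exists():
            raise InputError(f"no such file: {p}")

    snps: list[tuple[str, str, int]] = []  # (snp_id, chrom, pos)
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 fields")
            chrom, snp_id, _cm, pos = parts
            snps.append((snp_id, chrom, int(pos)))

    m = len(snps)
    samples: list[str] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields, "
                    f"found {len(parts)}"
                )
            samples.append(parts[1])
            alleles = parts[6:]
            rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)])

    variants: list[VariantRecord] = []
    calls = np.full((len(samples), m), MISSING, dtype=np.int8)
    for j, (snp_id, chrom, pos) in enumerate(snps):
        observed = sorted(
            {a for row in rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise FormatError(f"{snp_id}: more than two alleles observed")
        if not observed:
            observed = ["N"]
        if len(observed) == 1:
            # monomorphic: only one allele recoverable from data
            observed = ["0", observed[0]]
        allele_a, allele_b = observed
        effect = allele_b
        for i, row in enumerate(rows):
            a1, a2 = row[j]
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = (a1 == effect) + (a2 == effect)
        variants.append(
            VariantRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                allele_a=allele_a,
                allele_b=allele_b,
                effect_allele=effect,
            )
        )
    return GenotypeMatrix(variants=variants, samples=samples, calls=calls)


def _write_plink_text(matrix: GenotypeMatrix, path: Path) -> None:
    ped_path, map_path = _plink_paths(Path(path))
    map_lines = [f"# {_TOOL_TAG} {_version()}"]
    for v in matrix.variants:
        for allele in (v.allele_a, v.allele_b):
            if not allele or any(c.isspace() for c in allele) or allele == "0":
                raise FormatError(f"{v.snp_id}: unencodable allele {allele!r}")
        map_lines.append(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos}")
    map_path.write_text("\n".join(map_lines) + "\n")

    ped_lines = []
    for i, sample in enumerate(matrix.samples):
        fields = [sample, sample, "0", "0", "0", "-9"]
        for j, v in enumerate(matrix.variants):
            g = int(matrix.calls[i, j])
            if g == MISSING:
                fields += ["0", "0"]
            else:
                fields += [v.other_allele] * (2 - g) + [v.effect_allele] * g
        ped_lines.append("\t".join(fields))
    ped_path.write_text("\n".join(ped_lines) + ("\n" if ped_lines else ""))


# ---------------------------------------------------------------------------
# summary statistics and phenotypes
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "population",
    "trait",
)


def read_summary_stats(path: str | os.PathLike) -> list:
    """Read per-SNP summary statistics from TSV into ``AssocResult`` rows.

    Betas are taken as-is on the analysis scale: z-score units for
    inverse-normal-transformed BMI, log-odds-ratios for type 2 diabetes.
    """
    from .association import AssocResult  # deferred: geno_io is lower level

    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if (df["se"] <= 0).any():
        bad = df.loc[df["se"] <= 0, "snp_id"].tolist()
        raise ValueError(f"{path}: non-positive se for {bad}")
    results = []
    for row in df.itertuples(index=False):
        results.append(
            AssocResult(
                snp_id=str(row.snp_id),
                trait=str(row.trait),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                p=float(row.p),
                n=int(row.n),
                population=str(row.population),
            )
        )
    return results


def write_summary_stats(results: Iterable, path: str | os.PathLike) -> None:
    rows = [
        {
            "snp_id": r.snp_id,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "p": r.p,
            "n": r.n,
            "population": r.population,
            "trait": r.trait,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    with open(path, "w") as fh:
        fh.write(f"# {_TOOL_TAG} {_version()}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_TOOL_TAG} {_version()}\n")
        pheno.data.to_csv(fh, sep="\t", index=False)
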