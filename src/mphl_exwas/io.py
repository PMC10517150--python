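"""Cohort I/O: genotype matrices, variant/phenotype tables and standard formats.

Conventions
-----------
* Variant ids are ``chrom:pos:ref:alt`` strings (GRCh38 style); the X
  chromosome is coded ``"23"``.
* Positions are 1-based (VCF convention); window arithmetic elsewhere uses
  closed intervals on 1-based coordinates.
* Dosages are alternate-allele counts in {0, 1, 2}; missing entries are NaN.
  Hemizygous (male X) columns are coded on the {0, 2} scale so that allele
  frequency and burden formulas are uniform across chromosomes.
* Multi-allelic VCF records are rejected; input must be pre-split.
* All readers reject out-of-domain values rather than silently coercing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "maf", "consequence", "impact", "score", "gene"]

IMPACT_LEVELS = ("high", "moderate", "none")


class TableValidationError(ValueError):
    """A table violated its documented schema."""


class VcfParseError(ValueError):
    """A VCF record could not be parsed under the package's conventions."""


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with missingness and hemizygosity.

    ``dosage`` is an (n_samples, n_variants) float array of alternate-allele
    counts with NaN marking missing genotypes.  ``is_hemizygous`` flags male-X
    columns, which carry dosages in {0, 2} only.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    is_hemizygous: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.is_hemizygous is None:
            self.is_hemizygous = np.zeros(len(self.variant_ids), dtype=bool)
        self.is_hemizygous = np.asarray(self.is_hemizygous, dtype=bool)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise TableValidationError("dosage shape does not match sample/variant ids")
        if self.is_hemizygous.shape != (m,):
            raise TableValidationError("is_hemizygous length does not match variants")
        if self.is_hemizygous.any():
            hemi = self.dosage[:, self.is_hemizygous]
            if np.nansum(hemi == 1) > 0:
                raise TableValidationError("hemizygous columns must not contain dosage 1")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset(self, samples: np.ndarray | None = None, variants: np.ndarray | None = None) -> "GenotypeMatrix":
        """Row/column subset by boolean mask or integer index array."""
        s_idx = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        v_idx = np.arange(self.n_variants) if variants is None else np.asarray(variants)
        if s_idx.dtype == bool:
            s_idx = np.flatnonzero(s_idx)
        if v_idx.dtype == bool:
            v_idx = np.flatnonzero(v_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in s_idx],
            variant_ids=[self.variant_ids[j] for j in v_idx],
            dosage=self.dosage[np.ix_(s_idx, v_idx)],
            is_hemizygous=self.is_hemizygous[v_idx],
        )

    def allele_frequency(self) -> np.ndarray:
        """Per-variant alternate-allele frequency on non-missing dosages.

        Hemizygous {0,2} columns and diploid columns share sum(dosage)/(2n).
        Monomorphic-missing columns return NaN.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        f = self.allele_frequency()
        return np.minimum(f, 1.0 - f)


def _split_variant_id(variant_id: str) -> tuple[str, int, str, str]:
    parts = variant_id.split(":")
    if len(parts) != 4:
        raise TableValidationError(f"malformed variant id {variant_id!r}; want chrom:pos:ref:alt")
    chrom, pos, ref, alt = parts
    return chrom, int(pos), ref, alt


def validate_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Check the variant-annotation table invariants and return it.

    Required columns: variant_id, chrom, pos, maf, consequence, impact,
    score, gene.  variant_id unique, maf in [0, 0.5], pos >= 1, score >= 0,
    impact in {high, moderate, none}.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise TableValidationError(f"variant table missing columns: {missing}")
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise TableValidationError(f"duplicate variant_id {dup!r}")
    if ((variants["maf"] < 0) | (variants["maf"] > 0.5)).any():
        raise TableValidationError("maf outside [0, 0.5]")
    if (variants["pos"] < 1).any():
        raise TableValidationError("pos must be >= 1")
    if (variants["score"] < 0).any():
        raise TableValidationError("deleteriousness score must be nonnegative")
    bad = set(variants["impact"]) - set(IMPACT_LEVELS)
    if bad:
        raise TableValidationError(f"unknown impact tiers: {sorted(bad)}")
    return variants


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write dosages as a VCF 4.2 file with GT fields.

    Coordinates, ref and alt alleles are taken from the ``chrom:pos:ref:alt``
    variant ids.  Hemizygous columns are written as haploid genotypes;
    diploid heterozygotes as 0/1 (unphased).  Records are emitted sorted by
    (chrom, pos).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    parsed = [_split_variant_id(v) for v in G.variant_ids]
    for chrom in dict.fromkeys(p[0] for p in parsed):
        header.contigs.add(chrom)
    for s in G.sample_ids:
        header.add_sample(s)
    order = sorted(range(len(parsed)), key=lambda j: (parsed[j][0], parsed[j][1]))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            chrom, pos, ref, alt = parsed[j]
            rec = out.new_record(contig=chrom, start=pos - 1, stop=pos - 1 + len(ref),
                                 alleles=(ref, alt), id=G.variant_ids[j])
            hemi = bool(G.is_hemizygous[j])
            col = G.dosage[:, j]
            for i, s in enumerate(G.sample_ids):
                d = col[i]
                if np.isnan(d):
                    gt = (None,) if hemi else (None, None)
                elif hemi:
                    gt = (int(d) // 2,)
                else:
                    gt = (0, 1) if d == 1 else (int(d) // 2,) * 2
                rec.samples[s]["GT"] = gt
            out.write(rec)


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a biallelic VCF into a GenotypeMatrix and a variant skeleton.

    Dosages are alternate-allele counts; ``./.`` becomes missing.  Haploid
    genotypes are read onto the {0, 2} hemizygous scale.  Multi-allelic
    records raise with an instruction to normalize first.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        variant_ids: list[str] = []
        rows = []
        cols: list[np.ndarray] = []
        hemi_flags: list[bool] = []
        for line_no, rec in enumerate(vf, start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise VcfParseError(
                    f"record {line_no} ({rec.chrom}:{rec.pos}) is not biallelic; "
                    "normalize/split multi-allelic sites before reading"
                )
            vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            dosages = np.empty(len(samples))
            ploidies = []
            for i, s in enumerate(samples):
                alleles = rec.samples[s].get("GT", (None,))
                known = [a for a in alleles if a is not None]
                if not known:
                    dosages[i] = np.nan
                    continue
                if any(a not in (0, 1) for a in known):
                    raise VcfParseError(f"record {line_no}: unexpected allele index in GT")
                ploidies.append(len(alleles))
                dosages[i] = sum(known) * (2 if len(alleles) == 1 else 1)
            hemi = bool(ploidies) and all(p == 1 for p in ploidies)
            variant_ids.append(vid)
            cols.append(dosages)
            hemi_flags.append(hemi)
            rows.append({"variant_id": vid, "chrom": rec.chrom, "pos": rec.pos,
                         "ref": rec.ref, "alt": rec.alts[0]})
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    G = GenotypeMatrix(samples, variant_ids, dosage, np.array(hemi_flags, dtype=bool))
    return G, pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])


# ---------------------------------------------------------------------------
# Tabular formats (headered TSV)
# ---------------------------------------------------------------------------

def read_visits(path: str | os.PathLike) -> pd.DataFrame:
    """Visit table: sample_id, visit_index, age, pattern (1-4)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    need = ["sample_id", "visit_index", "age", "pattern"]
    if list(df.columns[: len(need)]) != need:
        raise TableValidationError(f"visits file must have columns {need}")
    bad = df[~df["pattern"].isin([1, 2, 3, 4])]
    if len(bad):
        row = bad.index[0]
        raise TableValidationError(
            f"visits row {row}: pattern {bad['pattern'].iloc[0]!r} outside 1-4"
        )
    if df.duplicated(subset=["sample_id", "visit_index"]).any():
        dup = df[df.duplicated(subset=["sample_id", "visit_index"])].iloc[0]
        raise TableValidationError(
            f"duplicate (sample, visit) entry: ({dup['sample_id']}, {dup['visit_index']})"
        )
    return df


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    return validate_variant_table(df)


def read_kinship(path: str | os.PathLike) -> list[tuple[str, str, float]]:
    """Kinship pairs: sample_a, sample_b, kinship."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_a": str, "sample_b": str})
    if df.empty:
        return []
    if (df["kinship"] < 0).any() or (df["kinship"] > 0.5).any():
        raise TableValidationError("kinship coefficients must be in [0, 0.5]")
    return list(df[["sample_a", "sample_b", "kinship"]].itertuples(index=False, name=None))


def read_covariates(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise TableValidationError("covariate file must contain sample_id")
    return df


def read_lead_snps(path: str | os.PathLike) -> pd.DataFrame:
    """GWAS lead-SNP table: snp_id, chrom, pos, effect_allele, beta, p."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    need = {"snp_id", "chrom", "pos", "effect_allele", "beta", "p"}
    missing = need - set(df.columns)
    if missing:
        raise TableValidationError(f"lead-SNP table missing columns: {sorted(missing)}")
    if df["snp_id"].duplicated().any():
        raise TableValidationError("duplicate snp_id in lead-SNP table")
    if (df["pos"] < 1).any():
        raise TableValidationError("lead-SNP pos must be >= 1")
    return df


def read_gene_set(path: str | os.PathLike) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                out.add(sym)
    return out


def load_cohort(directory: str | os.PathLike) -> dict:
    """Load a written synthetic-cohort bundle and cross-validate references.

    Expects the files written by :func:`mphl_exwas.simulate.write_cohort`.
    Raises if any table references a sample or variant id absent from the
    genotype data.
    """
    d = os.fspath(directory)
    mats = []
    for name in sorted(os.listdir(d)):
        if name.startswith("genotypes.chr") and name.endswith(".vcf"):
            mats.append(read_vcf(os.path.join(d, name))[0])
    if not mats:
        raise TableValidationError(f"no genotypes.chr*.vcf files under {d}")
    samples = mats[0].sample_ids
    for g in mats[1:]:
        if g.sample_ids != samples:
            raise TableValidationError("per-chromosome VCFs disagree on sample roster")
    G = GenotypeMatrix(
        samples,
        [v for g in mats for v in g.variant_ids],
        np.concatenate([g.dosage for g in mats], axis=1),
        np.concatenate([g.is_hemizygous for g in mats]),
    )
    variants = read_annotations(os.path.join(d, "annotations.tsv"))
    visits = read_visits(os.path.join(d, "visits.tsv"))
    kinship = read_kinship(os.path.join(d, "kinship.tsv"))
    covariates = read_covariates(os.path.join(d, "covariates.tsv"))

    vset, sset = set(G.variant_ids), set(G.sample_ids)
    dangling = set(variants["variant_id"]) - vset
    if dangling:
        raise TableValidationError(f"annotations reference unknown variants: {sorted(dangling)[:3]}")
    for tbl, name in ((visits, "visits"), (covariates, "covariates")):
        miss = set(tbl["sample_id"]) - sset
        if miss:
            raise TableValidationError(f"{name} reference unknown samples: {sorted(miss)[:3]}")
    for a, b, _ in kinship:
        if a not in sset or b not in sset:
            raise TableValidationError(f"kinship pair ({a}, {b}) references unknown sample")
    return {"genotypes": G, "variants": variants, "visits": visits,
            "kinship": kinship, "covariates": covariates}
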