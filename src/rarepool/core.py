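"""Domain containers and plain-text I/O for gene-based rare-variant association.

The package works on a samples × variants matrix of minor-allele counts
(:class:`GenotypeMatrix`), a per-variant annotation table (a pandas DataFrame
with columns ``variant_id, chrom, pos, maf``), gene regions
(:class:`GeneRegion`), a gene → variant-index mapping (a plain dict, the
"gene index"), and a phenotype/covariate table (:class:`PhenotypeTable`).

All on-disk formats are tab-separated text:

* genotype matrix: header ``sample_id`` followed by variant ids, one row per
  sample, cells in {0, 1, 2};
* companion variant table: ``variant_id  chrom  pos``;
* gene regions: ``gene_name  chrom  start  end`` with 1-based, both-ends
  inclusive coordinates (a deliberate divergence from 0-based half-open BED);
* phenotypes: header with ``sample_id``, trait/covariate columns and an
  optional replicate column;
* association results: one row per (gene, test).

Minor-allele polarity is enforced at load time: any column whose alternate
allele frequency exceeds 0.5 is flipped so counts always tally the rarer
allele and sample MAFs lie in [0, 0.5].
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "maf"]
RESULT_COLUMNS = [
    "gene",
    "test",
    "n_variants_used",
    "statistic",
    "optimal_threshold",
    "n_permutations",
    "p_value",
]


class ParseError(ValueError):
    """A file did not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed data violate a container invariant."""


class JoinError(ValueError):
    """Sample identifiers do not align between two tables."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples × variants minor-allele counts.

    ``counts[j, i]`` is the number of minor-allele copies carried by sample
    ``j`` at variant ``i`` — the x_i regressed on in every pooled test.
    Entries are in {0, 1, 2}; missingness must be resolved at load time.
    """

    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples × variants array")
        if len(self.sample_ids) < 2:
            raise ValidationError("at least two samples are required")
        if counts.shape[0] != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {counts.shape[0]} count rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if counts.size and not np.isin(counts, (0, 1, 2)).all():
            bad = counts[~np.isin(counts, (0, 1, 2))].ravel()[:5]
            raise ValidationError(f"genotype counts must be in {{0,1,2}}; saw {bad}")
        self.counts = counts.astype(np.int8, copy=False)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]


@dataclasses.dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval, 1-based and inclusive at both ends."""

    gene_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_name}: start {self.start} > end {self.end}"
            )


@dataclasses.dataclass
class PhenotypeTable:
    """Phenotypes and covariates for the loaded samples.

    ``data`` holds one row per sample (per replicate when ``replicate_col``
    is set).  ``traits`` are quantitative outcomes, ``binary_traits`` are
    {0,1} outcomes, ``covariates`` (e.g. Age, Smoking) are adjustment
    variables.  ``adjusted_for`` records covariates already consumed by
    residualization.
    """

    data: pd.DataFrame
    traits: list[str] = dataclasses.field(default_factory=list)
    binary_traits: list[str] = dataclasses.field(default_factory=list)
    covariates: list[str] = dataclasses.field(default_factory=list)
    replicate_col: str | None = None
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        if "sample_id" not in cols:
            raise ValidationError("phenotype table needs a sample_id column")
        declared = [*self.traits, *self.binary_traits, *self.covariates]
        if self.replicate_col:
            declared.append(self.replicate_col)
        missing = [c for c in declared if c not in cols]
        if missing:
            raise ValidationError(f"declared columns absent from table: {missing}")
        for b in self.binary_traits:
            vals = pd.unique(self.data[b].dropna())
            if not set(np.asarray(vals, dtype=float)).issubset({0.0, 1.0}):
                raise ValidationError(
                    f"binary trait {b!r} contains values outside {{0,1}}: {sorted(vals)[:5]}"
                )

    @property
    def replicate_ids(self) -> list:
        if self.replicate_col is None:
            return [None]
        return sorted(pd.unique(self.data[self.replicate_col]))

    def replicate(self, rep) -> pd.DataFrame:
        """Rows of one replicate (or the whole table when unreplicated)."""
        if self.replicate_col is None:
            return self.data
        return self.data[self.data[self.replicate_col] == rep]

    def vector(self, column: str, rep=None, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """One column as a float vector, optionally aligned to ``sample_ids``."""
        frame = self.replicate(rep)
        if sample_ids is not None:
            frame = frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return frame[column].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def compute_maf(genotypes: GenotypeMatrix, variants: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fill the ``maf`` column of a variant table from the loaded samples.

    The minor-allele frequency of variant i is ``min(f_i, 1 - f_i)`` with
    ``f_i = sum_j counts[j, i] / (2 n)``, estimated from all loaded samples
    pooled (there is no external reference panel in this design).
    """
    n = genotypes.n_samples
    if n == 0:
        raise ValidationError("cannot compute allele frequencies with zero samples")
    f = genotypes.counts.sum(axis=0) / (2.0 * n)
    maf = np.minimum(f, 1.0 - f)
    if variants is None:
        variants = pd.DataFrame(
            {
                "variant_id": [f"V{i:06d}" for i in range(genotypes.n_variants)],
                "chrom": ".",
                "pos": np.arange(1, genotypes.n_variants + 1),
            }
        )
    if len(variants) != genotypes.n_variants:
        raise ValidationError(
            f"variant table has {len(variants)} rows for {genotypes.n_variants} columns"
        )
    out = variants.copy()
    out["maf"] = maf
    return out


def _fold_to_minor(counts: np.ndarray) -> np.ndarray:
    """Re-polarize columns so every column counts the minor allele."""
    counts = counts.astype(np.int8, copy=True)
    if counts.size:
        f = counts.sum(axis=0) / (2.0 * counts.shape[0])
        flip = f > 0.5
        if flip.any():
            counts[:, flip] = 2 - counts[:, flip]
            log.debug("folded %d columns to minor-allele counts", int(flip.sum()))
    return counts


# ---------------------------------------------------------------------------
# genotype readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(
    path,
    format: str = "matrix-tsv",
    variants_path=None,
    missing_policy: str = "error",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Load genotypes as minor-allele counts plus a variant table (maf unset).

    Parameters
    ----------
    format
        ``"matrix-tsv"`` (header ``sample_id`` + variant ids, cells in
        {0,1,2}, optional companion ``variants_path``) or ``"vcf-minimal"``
        (biallelic SNP records of an uncompressed VCF; FILTER is ignored).
    missing_policy
        ``"error"`` rejects missing genotypes; ``"zero"`` imputes them as
        homozygous major and logs the count.
    """
    if format == "matrix-tsv":
        gm, variants = _read_matrix_tsv(path, variants_path, missing_policy)
    elif format == "vcf-minimal":
        gm, variants = _read_vcf_minimal(path, missing_policy)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    variants["maf"] = np.nan
    return gm, variants


def _read_matrix_tsv(path, variants_path, missing_policy):
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pandas names the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first header field must be 'sample_id'")
    sample_ids = df["sample_id"].tolist()
    variant_ids = list(df.columns[1:])
    body = df.iloc[:, 1:]
    missing = body.isna() | body.isin([".", ""])
    values = body.mask(missing, "0")
    try:
        counts = values.to_numpy(dtype=np.int64, na_value=0)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-integer genotype cell ({exc})") from exc
    n_missing = int(missing.to_numpy().sum())
    if n_missing:
        if missing_policy == "zero":
            log.info("%s: imputed %d missing genotypes as 0", path, n_missing)
        else:
            raise ValidationError(
                f"{path}: {n_missing} missing genotypes and no imputation policy"
            )
    if counts.size and not np.isin(counts, (0, 1, 2)).all():
        rows, cols = np.nonzero(~np.isin(counts, (0, 1, 2)))
        raise ValidationError(
            f"{path}: genotype outside {{0,1,2}} at data line {rows[0] + 2}, "
            f"variant {variant_ids[cols[0]]}"
        )
    gm = GenotypeMatrix(sample_ids, _fold_to_minor(counts))
    if variants_path is not None:
        variants = read_variants(variants_path)
        if list(variants["variant_id"]) != variant_ids:
            vset = set(variants["variant_id"])
            missing_ids = [v for v in variant_ids if v not in vset]
            if missing_ids:
                raise ValidationError(
                    f"{variants_path}: variant ids absent from companion table: "
                    f"{missing_ids[:5]}"
                )
            variants = (
                variants.set_index("variant_id").loc[variant_ids].reset_index()
            )
    else:
        variants = pd.DataFrame(
            {"variant_id": variant_ids, "chrom": ".", "pos": np.arange(1, len(variant_ids) + 1)}
        )
    return gm, variants


def _read_vcf_minimal(path, missing_policy):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValidationError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} is not supported"
            )
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValidationError(
                f"{path}: non-SNP record at {rec.CHROM}:{rec.POS} is not supported"
            )
        gt = np.asarray(rec.gt_types, dtype=np.int64)  # 0/1/2 alt copies, 3 unknown
        unknown = gt == 3
        if unknown.any():
            if missing_policy == "zero":
                gt[unknown] = 0
                log.info(
                    "%s: imputed %d missing genotypes as 0 at %s:%d",
                    path, int(unknown.sum()), rec.CHROM, rec.POS,
                )
            else:
                raise ValidationError(
                    f"{path}: missing genotype at {rec.CHROM}:{rec.POS} "
                    "and no imputation policy"
                )
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        cols.append(gt)
    counts = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0), dtype=np.int64)
    gm = GenotypeMatrix(sample_ids, _fold_to_minor(counts))
    variants = pd.DataFrame({"variant_id": ids, "chrom": chroms, "pos": poss})
    if variants["variant_id"].duplicated().any():
        dups = variants.loc[variants["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValidationError(f"{path}: duplicate variant ids {dups[:5]}")
    return gm, variants


def write_genotypes(genotypes: GenotypeMatrix, variants: pd.DataFrame, path, variants_path=None) -> None:
    """Write the matrix-tsv dialect (and its companion variant table)."""
    df = pd.DataFrame(
        genotypes.counts, columns=list(variants["variant_id"]), dtype=np.int64
    )
    df.insert(0, "sample_id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    if variants_path is not None:
        write_variants(variants, variants_path)


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    need = {"variant_id", "chrom", "pos"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: variant table needs columns {sorted(need)}")
    if df["variant_id"].duplicated().any():
        dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValidationError(f"{path}: duplicate variant ids {dups[:5]}")
    df["pos"] = df["pos"].astype(np.int64)
    return df.reset_index(drop=True)


def write_variants(variants: pd.DataFrame, path) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in variants.columns]
    variants.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.10g")


# ---------------------------------------------------------------------------
# gene regions and the gene index
# ---------------------------------------------------------------------------


def read_regions(path) -> list[GeneRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "chrom": str})
    need = {"gene_name", "chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: gene region table needs columns {sorted(need)}")
    return [
        GeneRegion(r.gene_name, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_regions(regions: Sequence[GeneRegion], path) -> None:
    pd.DataFrame(
        {
            "gene_name": [r.gene_name for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)


def map_variants_to_genes(
    variants: pd.DataFrame, regions: Sequence[GeneRegion]
) -> dict[str, np.ndarray]:
    """Assign variants to genes by position: pos in [start, end] on the same chrom.

    Overlapping regions each receive the shared variants; genes with no
    variants are kept with an empty index (they are excluded per test later,
    not here).  The index lists are ascending, so the result is independent
    of the input ordering of regions.
    """
    if len(regions) == 0:
        raise ValidationError("no gene regions supplied")
    names = [r.gene_name for r in regions]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate gene names: {dups[:5]}")
    chrom = variants["chrom"].to_numpy(dtype=object)
    pos = variants["pos"].to_numpy(dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(variants["chrom"]) if len(variants) else []:
        idx = np.nonzero(chrom == c)[0]
        order = np.argsort(pos[idx], kind="stable")
        by_chrom[c] = (pos[idx][order], idx[order])
    index: dict[str, np.ndarray] = {}
    for r in regions:
        if r.chrom not in by_chrom:
            index[r.gene_name] = np.empty(0, dtype=np.int64)
            continue
        sorted_pos, orig = by_chrom[r.chrom]
        lo = np.searchsorted(sorted_pos, r.start, side="left")
        hi = np.searchsorted(sorted_pos, r.end, side="right")
        index[r.gene_name] = np.sort(orig[lo:hi])
    return index


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(
    path,
    traits: Sequence[str] = (),
    binary_traits: Sequence[str] = (),
    covariates: Sequence[str] = (),
    replicate_col: str | None = None,
    genotype_sample_ids: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Load a phenotype/covariate table and (optionally) validate the sample join."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    table = PhenotypeTable(
        df,
        traits=list(traits),
        binary_traits=list(binary_traits),
        covariates=list(covariates),
        replicate_col=replicate_col,
    )
    if genotype_sample_ids is not None:
        want = set(map(str, genotype_sample_ids))
        for rep in table.replicate_ids:
            have = set(table.replicate(rep)["sample_id"])
            extra = sorted(have - want)
            absent = sorted(want - have)
            if extra or absent:
                raise JoinError(
                    f"{path}: sample ids do not match genotypes"
                    + (f"; only in phenotypes: {extra[:5]}" if extra else "")
                    + (f"; only in genotypes: {absent[:5]}" if absent else "")
                )
    return table


def write_phenotypes(table: PhenotypeTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# results and truth files
# ---------------------------------------------------------------------------


def write_results(results: Iterable, path) -> None:
    """Write per-(gene, test) association results, sorted by gene then test.

    Not-testable results (a gene outside a test's universe) are skipped with
    a debug log line; downstream evaluation treats the absent row as
    not-testable.
    """
    rows = []
    for res in results:
        if not res.testable:
            log.debug("gene %s not testable by %s; omitted", res.gene_name, res.test_name)
            continue
        rows.append(
            {
                "gene": res.gene_name,
                "test": res.test_name,
                "n_variants_used": res.n_variants_used,
                "statistic": res.statistic,
                "optimal_threshold": res.optimal_threshold,
                "n_permutations": res.n_permutations,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["gene", "test"], kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "test": str})
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: results file lacks columns {missing}")
    return df


def write_truth(truth: Mapping[str, Sequence[tuple[str, float]]], path) -> None:
    """Write the causal-gene answer key: gene_name, variant_id, effect_size."""
    rows = [
        {"gene_name": g, "variant_id": v, "effect_size": e}
        for g in sorted(truth)
        for v, e in truth[g]
    ]
    pd.DataFrame(rows, columns=["gene_name", "variant_id", "effect_size"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_truth(path) -> dict[str, list[tuple[str, float]]]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "variant_id": str})
    out: dict[str, list[tuple[str, float]]] = {}
    for r in df.itertuples():
        out.setdefault(r.gene_name, []).append((r.variant_id, float(r.effect_size)))
    return out
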