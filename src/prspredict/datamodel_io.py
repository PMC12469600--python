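"""Core genotype data model, PLINK 1 binary I/O, a text dialect, and sex splitting.

The central container is :class:`GenotypeDataset`: an individuals x variants
matrix of minor-allele dosages (0/1/2, ``-1`` for missing) plus sample metadata
(sex, case/control phenotype) and variant metadata (id, chromosome, position,
minor/major alleles).

PLINK bed/bim/fam support is written against the published PLINK 1 binary
format (SNP-major, 2 bits per genotype).  On read the minor allele is
recomputed from the observed allele frequencies rather than trusting the A1
column of the .bim file; dosages always count minor alleles.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "FormatError",
    "ConsistencyError",
    "read_plink",
    "write_plink",
    "read_text",
    "write_text",
    "split_by_sex",
]

#: Sentinel for a missing genotype call in the dosage matrix.
MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_MODE_SNP_MAJOR = 0x01

# 2-bit bed codes -> dosage of the A1 allele (PLINK 1 binary spec).
_BED_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

_FAM_SEX = {"1": "male", "2": "female", "0": "unknown"}
_FAM_PHENO = {"2": "case", "1": "control", "0": "missing", "-9": "missing"}
_SEX_FAM = {"male": "1", "female": "2", "unknown": "0"}
_PHENO_FAM = {"case": "2", "control": "1", "missing": "-9"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ConsistencyError(ValueError):
    """Files or arrays that should agree do not."""


@dataclass
class GenotypeDataset:
    """Individuals x variants dosage matrix with sample and variant metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` int8 array of minor-allele dosages;
        entries are 0, 1, 2 or ``MISSING`` (-1).
    samples
        DataFrame with columns ``sample_id``, ``sex`` (male/female/unknown)
        and ``phenotype`` (case/control/missing), one row per matrix row.
    variants
        DataFrame with columns ``variant_id``, ``chromosome``, ``bp``,
        ``allele_minor``, ``allele_major``, one row per matrix column.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- basic interrogation -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def case_mask(self) -> np.ndarray:
        return (self.samples["phenotype"] == "case").to_numpy()

    def control_mask(self) -> np.ndarray:
        return (self.samples["phenotype"] == "control").to_numpy()

    def missing_mask(self) -> np.ndarray:
        """Boolean matrix marking missing genotype calls."""
        return self.genotypes == MISSING

    def validate(self) -> None:
        if self.genotypes.ndim != 2:
            raise ConsistencyError("genotype matrix must be 2-dimensional")
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ConsistencyError(
                f"sample table has {len(self.samples)} rows for {n} matrix rows"
            )
        if len(self.variants) != m:
            raise ConsistencyError(
                f"variant table has {len(self.variants)} rows for {m} matrix columns"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ConsistencyError("dosages must be 0, 1, 2 or missing (-1)")
        if self.samples["sample_id"].duplicated().any():
            raise ConsistencyError("duplicate sample_ids")
        if self.variants["variant_id"].duplicated().any():
            raise ConsistencyError("duplicate variant_ids")

    # -- subsetting ----------------------------------------------------------

    def subset_samples(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            genotypes=self.genotypes[mask, :].copy(),
            samples=self.samples.loc[mask].copy(),
            variants=self.variants.copy(),
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            genotypes=self.genotypes[:, mask].copy(),
            samples=self.samples.copy(),
            variants=self.variants.loc[mask].copy(),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.samples.equals(other.samples)
            and self.variants.equals(other.variants)
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------


def _read_fam(path: str | Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 6:
        raise FormatError(f"{path}: .fam needs 6 columns, found {fam.shape[1]}")
    sex = fam[4].map(_FAM_SEX)
    if sex.isna().any():
        raise FormatError(f"{path}: unrecognized sex code")
    pheno = fam[5].map(_FAM_PHENO)
    if pheno.isna().any():
        raise FormatError(f"{path}: unrecognized phenotype code")
    return pd.DataFrame(
        {"sample_id": fam[1].to_numpy(), "sex": sex.to_numpy(), "phenotype": pheno.to_numpy()}
    )


def _read_bim(path: str | Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] < 6:
        raise FormatError(f"{path}: .bim needs 6 columns, found {bim.shape[1]}")
    return pd.DataFrame(
        {
            "variant_id": bim[1].to_numpy(),
            "chromosome": bim[0].to_numpy(),
            "bp": bim[3].astype(np.int64).to_numpy(),
            # A1 provisionally minor; re-polarized from the data after decoding
            "allele_minor": bim[4].to_numpy(),
            "allele_major": bim[5].to_numpy(),
        }
    )


def _polarize_to_minor(dataset: GenotypeDataset) -> GenotypeDataset:
    """Flip dosages so they count the observed minor allele.

    A tie (frequency exactly 0.5) keeps the current A1 as minor.
    """
    G = dataset.genotypes
    miss = G == MISSING
    nonmiss = (~miss).sum(axis=0)
    dose = np.where(miss, 0, G).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(nonmiss > 0, dose / (2.0 * nonmiss), 0.0)
    flip = freq > 0.5
    if flip.any():
        Gf = G.copy()
        cols = np.where(flip)[0]
        block = Gf[:, cols]
        block = np.where(block == MISSING, MISSING, 2 - block).astype(np.int8)
        Gf[:, cols] = block
        variants = dataset.variants.copy()
        mn = variants.loc[flip, "allele_minor"].copy()
        variants.loc[flip, "allele_minor"] = variants.loc[flip, "allele_major"].to_numpy()
        variants.loc[flip, "allele_major"] = mn.to_numpy()
        return GenotypeDataset(Gf, dataset.samples, variants)
    return dataset


def read_plink(bed_path: str | Path, bim_path: str | Path | None = None,
               fam_path: str | Path | None = None) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeDataset`.

    ``bed_path`` may be the ``.bed`` file or a bare prefix; ``bim_path`` and
    ``fam_path`` default to the sibling files.  Dosages count the minor allele
    recomputed from the data.
    """
    bed_path = Path(bed_path)
    if bed_path.suffix != ".bed":
        prefix = bed_path
        bed_path = prefix.with_suffix(".bed")
        bim_path = bim_path or prefix.with_suffix(".bim")
        fam_path = fam_path or prefix.with_suffix(".fam")
    else:
        bim_path = bim_path or bed_path.with_suffix(".bim")
        fam_path = fam_path or bed_path.with_suffix(".fam")

    samples = _read_fam(fam_path)
    variants = _read_bim(bim_path)
    n, m = len(samples), len(variants)

    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes, not a PLINK .bed file")
    if raw[2] != _BED_MODE_SNP_MAJOR:
        raise FormatError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise ConsistencyError(
            f"{bed_path}: expected {bytes_per_variant * m} data bytes for "
            f"{n} samples x {m} variants, found {body.size}"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    G = _BED_CODE_TO_DOSAGE[codes[:, :n]].T.copy()

    return _polarize_to_minor(GenotypeDataset(G, samples, variants))


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``dataset`` as ``prefix``.bed/.bim/.fam (SNP-major)."""
    if dataset.n_variants == 0:
        raise ValueError("refusing to write a dataset with zero variants")
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")

    with open(fam_path, "w") as fh:
        for _, row in dataset.samples.iterrows():
            fh.write(
                f"{row.sample_id}\t{row.sample_id}\t0\t0\t"
                f"{_SEX_FAM[row.sex]}\t{_PHENO_FAM[row.phenotype]}\n"
            )
    with open(bim_path, "w") as fh:
        for _, row in dataset.variants.iterrows():
            fh.write(
                f"{row.chromosome}\t{row.variant_id}\t0\t{row.bp}\t"
                f"{row.allele_minor}\t{row.allele_major}\n"
            )

    n, m = dataset.n_samples, dataset.n_variants
    bytes_per_variant = (n + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        code_lut[dosage % 4] = code  # -1 -> index 3
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = code_lut[dataset.genotypes.T % 4]
    blocks = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        blocks |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_BED_MODE_SNP_MAJOR]))
        fh.write(blocks.tobytes())
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# Text dialect
# ---------------------------------------------------------------------------


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_text(path: str | Path) -> GenotypeDataset:
    """Read the tab-separated genotype dialect (gzip accepted).

    Layout: header ``sample_id sex phenotype <variant ids...>``; one row per
    individual with dosages 0/1/2 or ``NA``.  Variant coordinates are not part
    of the dialect: variants are placed on chromosome "1" at consecutive
    positions with alleles A (minor) / B (major).
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "sex", "phenotype"]:
            raise FormatError(f"{path}: bad header, expected sample_id/sex/phenotype first")
        variant_ids = header[3:]
        rows, meta = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + len(variant_ids):
                raise ConsistencyError(f"{path}: row width mismatch for {parts[0]!r}")
            meta.append(parts[:3])
            rows.append([MISSING if v == "NA" else np.int8(v) for v in parts[3:]])
    samples = pd.DataFrame(meta, columns=["sample_id", "sex", "phenotype"])
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": "1",
            "bp": np.arange(1, len(variant_ids) + 1, dtype=np.int64),
            "allele_minor": "A",
            "allele_major": "B",
        }
    )
    G = np.asarray(rows, dtype=np.int8).reshape(len(samples), len(variant_ids))
    return GenotypeDataset(G, samples, variants)


def write_text(dataset: GenotypeDataset, path: str | Path) -> Path:
    """Write the text dialect (gzip if the path ends in .gz)."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(["sample_id", "sex", "phenotype", *dataset.variant_ids]) + "\n")
        for i, row in enumerate(dataset.samples.itertuples(index=False)):
            vals = ["NA" if g == MISSING else str(int(g)) for g in dataset.genotypes[i]]
            fh.write("\t".join([row.sample_id, row.sex, row.phenotype, *vals]) + "\n")
    return path


# ---------------------------------------------------------------------------
# Sex split
# ---------------------------------------------------------------------------


def split_by_sex(dataset: GenotypeDataset) -> tuple[GenotypeDataset, GenotypeDataset]:
    """Split into (male, female) datasets sharing the full variant list.

    Unknown-sex samples are dropped from both outputs.  An empty stratum is
    returned as an empty dataset with a warning; the caller decides.
    """
    male = dataset.subset_samples((dataset.samples["sex"] == "male").to_numpy())
    female = dataset.subset_samples((dataset.samples["sex"] == "female").to_numpy())
    if male.n_samples == 0:
        warnings.warn("no male samples in dataset", stacklevel=2)
    if female.n_samples == 0:
        warnings.warn("no female samples in dataset", stacklevel=2)
    return male, female
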