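"""Genotype matrix I/O and locus filtering.

Reads multi-sample diploid VCFs into a :class:`GenotypeMatrix` (samples x loci
alt-allele dosages plus locus metadata) and applies the three locus filters used
throughout the analysis: biallelic-only, genotyping-quality, and
invariant-locus removal.

Coordinates are VCF-style 1-based inclusive everywhere in this module;
interval types elsewhere in the package (e.g. TE coverage gaps) are 0-based
half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF


class GenotypeError(ValueError):
    """Malformed or unsupported genotype data."""


class UnsupportedPloidyError(GenotypeError):
    """A GT call was not diploid."""


class VcfParseError(GenotypeError):
    """The VCF could not be parsed."""


LOCUS_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid genotype table.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample names.
    loci
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int),
        ``ref`` (str), ``alt`` (tuple of str), ``qual`` (float, NaN if
        missing), sorted by (chrom, pos) with no duplicate positions.
    gt
        ``(n_samples, n_loci, 2)`` integer allele indices; ``-1`` marks a
        missing allele call.
    populations
        Optional mapping sample id -> population label.

    Dosage semantics (count of the first ALT allele) are only meaningful for
    biallelic loci; multiallelic loci may be present before
    :func:`filter_biallelic` and keep their full per-allele encoding in ``gt``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    gt: np.ndarray
    populations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeError("duplicate sample ids")
        self.gt = np.asarray(self.gt, dtype=np.int16)
        if self.gt.shape != (self.n_samples, self.n_loci, 2):
            raise GenotypeError(
                f"gt shape {self.gt.shape} does not match "
                f"{self.n_samples} samples x {self.n_loci} loci"
            )
        if self.n_loci:
            key = list(zip(self.loci["chrom"], self.loci["pos"]))
            if len(set(key)) != len(key):
                raise GenotypeError("duplicate (chrom, pos) pairs")
            # sorted: each chromosome forms one contiguous run with increasing pos
            seen: set[str] = set()
            prev = None
            for c, _ in key:
                if c != prev:
                    if c in seen:
                        raise GenotypeError(f"chromosome {c!r} not contiguous")
                    seen.add(c)
                    prev = c
            for (c1, p1), (c2, p2) in zip(key, key[1:]):
                if c1 == c2 and p2 <= p1:
                    raise GenotypeError(f"positions not increasing on {c1!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def is_biallelic(self) -> np.ndarray:
        """Boolean mask: exactly one ALT allele at the locus."""
        return np.array([len(a) == 1 for a in self.loci["alt"]], dtype=bool)

    @property
    def dosages(self) -> np.ndarray:
        """(n_samples, n_loci) float array of first-ALT dosages; NaN = missing.

        Only meaningful for biallelic loci.
        """
        missing = (self.gt < 0).any(axis=2)
        dos = (self.gt == 1).sum(axis=2).astype(float)
        dos[missing] = np.nan
        return dos

    def population_of(self, sample: str) -> str | None:
        return (self.populations or {}).get(sample)

    def subset_loci(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            loci=self.loci.iloc[idx].reset_index(drop=True),
            gt=self.gt[:, idx, :],
        )

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        missing = [n for n in names if n not in self.sample_ids]
        if missing:
            raise GenotypeError(f"unknown samples: {missing}")
        idx = [self.sample_ids.index(n) for n in names]
        pops = None
        if self.populations is not None:
            pops = {n: self.populations[n] for n in names if n in self.populations}
        return replace(self, sample_ids=list(names), gt=self.gt[idx], populations=pops)


def read_vcf(path: str, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Unphased diploid GT fields are parsed to allele-index pairs; ``./.``
    becomes missing. QUAL is captured per locus (NaN when absent).
    Multiallelic records are retained with their full ALT lists.

    Raises
    ------
    UnsupportedPloidyError
        If any GT call is not diploid.
    VcfParseError
        If the file cannot be parsed as VCF.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    quals: list[float] = []
    gts: list[np.ndarray] = []
    try:
        for rec_no, v in enumerate(vcf, start=1):
            row = np.empty((len(samples), 2), dtype=np.int16)
            for i, call in enumerate(v.genotypes):
                alleles = call[:-1]  # last element is the phased flag
                if len(alleles) != 2:
                    raise UnsupportedPloidyError(
                        f"record {rec_no} ({v.CHROM}:{v.POS}) sample "
                        f"{samples[i]!r}: ploidy {len(alleles)} unsupported"
                    )
                row[i] = [a if a is not None and a >= 0 else -1 for a in alleles]
            chroms.append(v.CHROM)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(tuple(v.ALT))
            quals.append(float(v.QUAL) if v.QUAL is not None else np.nan)
            gts.append(row)
    except UnsupportedPloidyError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF {path!r} near record {len(chroms) + 1}: {exc}"
        ) from exc
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "qual": quals}
    )
    gt = (
        np.stack(gts, axis=1)
        if gts
        else np.empty((len(samples), 0, 2), dtype=np.int16)
    )
    return GenotypeMatrix(samples, loci, gt, populations=populations)


def write_vcf(matrix: GenotypeMatrix, path: str, source: str = "introkit") -> None:
    """Write a GenotypeMatrix as VCF 4.2 (unphased GT, QUAL populated)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(matrix.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j in range(matrix.n_loci):
            row = matrix.loci.iloc[j]
            qual = "." if np.isnan(row["qual"]) else f"{row['qual']:g}"
            calls = []
            for i in range(matrix.n_samples):
                a, b = matrix.gt[i, j]
                calls.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t"
                f"{','.join(row['alt'])}\t{qual}\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def filter_biallelic(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Keep only loci with exactly one REF and one ALT allele.

    Returns the filtered matrix and the number of removed loci.
    """
    mask = matrix.is_biallelic
    return matrix.subset_loci(mask), int((~mask).sum())


def filter_quality(matrix: GenotypeMatrix, min_qual: float = 500.0) -> GenotypeMatrix:
    """Keep loci with QUAL strictly greater than ``min_qual``.

    Loci with missing QUAL are dropped; if every locus lacks QUAL a warning is
    emitted and the result is empty.
    """
    qual = matrix.loci["qual"].to_numpy(dtype=float)
    if matrix.n_loci and np.isnan(qual).all():
        warnings.warn("all loci lack QUAL; quality filter removes everything")
    mask = np.zeros(matrix.n_loci, dtype=bool)
    finite = ~np.isnan(qual)
    mask[finite] = qual[finite] > min_qual
    return matrix.subset_loci(mask)


def drop_invariant(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Remove loci whose non-missing genotypes are identical across samples.

    A locus with all calls missing is vacuously invariant and is removed.
    Genotypes are compared as unordered allele pairs.
    """
    if matrix.n_loci == 0:
        return matrix
    g = np.sort(matrix.gt, axis=2)  # unordered genotype
    code = (g[:, :, 0].astype(np.int64) + 1) * 1024 + (g[:, :, 1] + 1)
    valid = (matrix.gt >= 0).all(axis=2)
    hi = np.where(valid, code, np.int64(-1)).max(axis=0)
    lo = np.where(valid, code, np.int64(1 << 40)).min(axis=0)
    variable = hi != lo  # all-missing loci give hi < lo -> invariant
    variable &= valid.any(axis=0)
    return matrix.subset_loci(variable)


@dataclass
class FilterReport:
    """Per-filter locus accounting."""

    rows: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.rows.append(
            {"filter": name, "loci_in": n_in, "loci_out": n_out, "removed": n_in - n_out}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["filter", "loci_in", "loci_out", "removed"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_filters(
    matrix: GenotypeMatrix,
    biallelic: bool = True,
    min_qual: float | None = 500.0,
    invariant: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard filter stack in order, with a locus-count report."""
    report = FilterReport()
    if biallelic:
        n_in = matrix.n_loci
        matrix, _ = filter_biallelic(matrix)
        report.add("biallelic", n_in, matrix.n_loci)
    if min_qual is not None:
        n_in = matrix.n_loci
        matrix = filter_quality(matrix, min_qual)
        report.add("quality", n_in, matrix.n_loci)
    if invariant:
        n_in = matrix.n_loci
        matrix = drop_invariant(matrix)
        report.add("invariant", n_in, matrix.n_loci)
    return matrix, report
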