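"""Outgroup-polarized ABBA-BABA D-statistics with block-jackknife Z-scores.

For an ordered quadruple (Outgroup, P1, P2, Test) — where P2 and the Test
population are the sister pair and P1 is the candidate gene-flow partner —
the allele carried by the outgroup defines the ancestral state, and per-site
derived-allele frequencies p1, p2, p3 weight the two discordant patterns

    abba_s = p1 (1 - p2) p3        baba_s = p1 p2 (1 - p3)

so that D = sum(abba - baba) / sum(abba + baba) equals the qpDstat
frequency-weighted statistic sum p1 (p3 - p2) / sum p1 (p2 + p3 - 2 p2 p3)
(the outgroup contributes derived frequency 0).  Under incomplete lineage
sorting alone the sister pair is exchangeable and E[D] = 0; a positive D
means the Test population shares an excess of derived alleles with P1 — the
signature of gene flow between them.  Uncertainty comes from a
delete-one-block jackknife over contiguous genomic blocks: Z = D / SE.

The frequency-weighted estimator coincides with integer ABBA/BABA pattern
counts when every population is a single haploid-coded (homozygous)
individual; tests exploit that identity as an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix


class DStatError(ValueError):
    pass


@dataclass
class DStatResult:
    """One Table-style row of the four-taxon test."""

    outgroup: str
    p1: str
    p2: str
    p3: str
    abba: float
    baba: float
    d: float
    se: float | None = None
    z: float | None = None
    n_snps: int = 0
    n_blocks: int | None = None

    def to_dict(self) -> dict:
        return {
            "Outgroup": self.outgroup,
            "Pop1": self.p1,
            "Pop2": self.p2,
            "Pop3": self.p3,
            "D": self.d,
            "Z": self.z,
            "ABBA": self.abba,
            "BABA": self.baba,
            "nSNPs": self.n_snps,
            "nBlocks": self.n_blocks,
        }


def _pop_derived_freq(
    dosages: np.ndarray, anc_is_alt: np.ndarray, rows: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean derived-allele frequency per locus and a completeness mask."""
    sub = dosages[rows, :]
    complete = ~np.isnan(sub).any(axis=0)
    freq = sub.mean(axis=0) / 2.0
    freq = np.where(anc_is_alt, 1.0 - freq, freq)
    return freq, complete


def polarize(
    matrix: GenotypeMatrix,
    p1_samples: list[str],
    p2_samples: list[str],
    p3_samples: list[str],
    outgroup_samples: list[str] | None = None,
    ancestral_alleles: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-site derived-allele frequencies polarized by the outgroup.

    The ancestral allele at a site is the allele carried by the outgroup
    sample(s); sites where the outgroup is heterozygous, polymorphic across
    outgroup individuals, or missing are dropped.  Alternatively
    ``ancestral_alleles`` supplies the ancestral allele index (0 = REF,
    1 = ALT) per locus directly, representing the reference-genome nucleotide
    at the SNP site.  Sites with missing data in any involved sample and
    sites with no derived variation (p1 = p2 = p3 = 0) are dropped.

    Returns a DataFrame with columns chrom, pos, p1, p2, p3.
    """
    if not matrix.is_biallelic.all():
        raise DStatError("matrix contains multiallelic loci; run filter_biallelic first")
    if (outgroup_samples is None) == (ancestral_alleles is None):
        raise DStatError("supply exactly one of outgroup_samples / ancestral_alleles")

    dosages = matrix.dosages
    n = matrix.n_loci
    if outgroup_samples is not None:
        idx = [matrix.sample_ids.index(s) for s in outgroup_samples]
        og = matrix.gt[idx, :, :]  # (n_og, L, 2)
        defined = (og >= 0).all(axis=(0, 2))
        first = og[0, :, 0]
        consistent = (og == first[None, :, None]).all(axis=(0, 2))
        ok = defined & consistent
        anc_is_alt = first == 1
    else:
        anc = np.asarray(ancestral_alleles)
        if anc.shape != (n,):
            raise DStatError("ancestral_alleles must have one entry per locus")
        ok = (anc == 0) | (anc == 1)
        anc_is_alt = anc == 1

    rows = {
        "p1": [matrix.sample_ids.index(s) for s in p1_samples],
        "p2": [matrix.sample_ids.index(s) for s in p2_samples],
        "p3": [matrix.sample_ids.index(s) for s in p3_samples],
    }
    freqs = {}
    for key, r in rows.items():
        f, complete = _pop_derived_freq(dosages, anc_is_alt, r)
        freqs[key] = f
        ok = ok & complete

    informative = ok & ~(
        (freqs["p1"] == 0) & (freqs["p2"] == 0) & (freqs["p3"] == 0)
    )
    if ok.sum() == 0 and n > 0:
        import warnings

        warnings.warn("no site has a defined outgroup ancestral allele")
    df = pd.DataFrame(
        {
            "chrom": matrix.loci["chrom"].to_numpy()[informative],
            "pos": matrix.loci["pos"].to_numpy()[informative],
            "p1": freqs["p1"][informative],
            "p2": freqs["p2"][informative],
            "p3": freqs["p3"][informative],
        }
    )
    return df


def assign_blocks(pf: pd.DataFrame, n_blocks: int = 50, by_chrom: bool = False) -> pd.DataFrame:
    """Attach contiguous jackknife block ids.

    Default: ``n_blocks`` equal-count contiguous blocks in genome order.
    ``by_chrom=True`` uses one block per chromosome instead.
    """
    pf = pf.copy()
    if by_chrom:
        codes, _ = pd.factorize(pf["chrom"])
        pf["block"] = codes
    else:
        m = len(pf)
        if m == 0:
            pf["block"] = np.array([], dtype=int)
        else:
            nb = min(n_blocks, m)
            pf["block"] = (np.arange(m) * nb) // m
    return pf


def site_patterns(pf: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted ABBA and BABA weights per site.

    abba_s = p1 (1-p2) p3 counts P1-Test derived sharing, baba_s =
    p1 p2 (1-p3) counts P1-P2 derived sharing; their difference is the
    qpDstat numerator p1 (p3 - p2).
    """
    p1 = pf["p1"].to_numpy(dtype=float)
    p2 = pf["p2"].to_numpy(dtype=float)
    p3 = pf["p3"].to_numpy(dtype=float)
    abba = p1 * (1.0 - p2) * p3
    baba = p1 * p2 * (1.0 - p3)
    return abba, baba


def dstat(
    pf: pd.DataFrame,
    labels: tuple[str, str, str, str] = ("outgroup", "P1", "P2", "P3"),
) -> DStatResult:
    """Point estimate of D from polarized frequencies (no SE/Z)."""
    abba, baba = site_patterns(pf)
    denom = float(abba.sum() + baba.sum())
    if denom <= 0:
        raise DStatError("ABBA + BABA sums to zero; D undefined")
    d = float(abba.sum() - baba.sum()) / denom
    og, l1, l2, l3 = labels
    return DStatResult(
        outgroup=og, p1=l1, p2=l2, p3=l3,
        abba=float(abba.sum()), baba=float(baba.sum()), d=d, n_snps=len(pf),
    )


def block_jackknife(pf: pd.DataFrame) -> tuple[float, float, int]:
    """Delete-one-block jackknife SE and Z for D.

    ``pf`` must carry a ``block`` column (see :func:`assign_blocks`).  Blocks
    whose sites carry zero ABBA+BABA weight are skipped.  Returns
    ``(se, z, n_blocks_used)``; a degenerate jackknife (all leave-one-out
    estimates identical) reports SE = 0 and Z = +/-inf (0 when D = 0).
    """
    if "block" not in pf.columns:
        raise DStatError("no block column; call assign_blocks first")
    abba, baba = site_patterns(pf)
    num_total = float((abba - baba).sum())
    den_total = float((abba + baba).sum())
    if den_total <= 0:
        raise DStatError("ABBA + BABA sums to zero; D undefined")
    d = num_total / den_total

    blocks = pf["block"].to_numpy()
    uniq = np.unique(blocks)
    num_b = np.array([float((abba - baba)[blocks == b].sum()) for b in uniq])
    den_b = np.array([float((abba + baba)[blocks == b].sum()) for b in uniq])
    keep = den_b > 0
    num_b, den_b = num_b[keep], den_b[keep]
    m = len(num_b)
    if m < 2:
        raise DStatError(f"need >= 2 informative jackknife blocks, got {m}")
    d_loo = (num_total - num_b) / (den_total - den_b)
    se = float(np.sqrt((m - 1) / m * ((d_loo - d_loo.mean()) ** 2).sum()))
    if se == 0.0:
        z = 0.0 if d == 0.0 else float(np.copysign(np.inf, d))
    else:
        z = d / se
    return se, z, m


def dstat_with_jackknife(
    pf: pd.DataFrame,
    labels: tuple[str, str, str, str] = ("outgroup", "P1", "P2", "P3"),
    n_blocks: int = 50,
) -> DStatResult:
    """D with jackknife SE/Z; assigns equal-count blocks if none present."""
    if "block" not in pf.columns:
        pf = assign_blocks(pf, n_blocks=n_blocks)
    res = dstat(pf, labels)
    res.se, res.z, res.n_blocks = block_jackknife(pf)
    return res


def _resolve_population(matrix: GenotypeMatrix, name: str) -> list[str]:
    pops = matrix.populations or {}
    members = [s for s, p in pops.items() if p == name and s in matrix.sample_ids]
    if members:
        return [s for s in matrix.sample_ids if s in members]  # preserve order
    if name in matrix.sample_ids:
        return [name]
    raise DStatError(f"unknown population or sample name {name!r}")


def qp_dstat_table(
    matrix: GenotypeMatrix,
    outgroup: str,
    trios: list[tuple[str, str, str]],
    n_blocks: int = 50,
) -> pd.DataFrame:
    """One D-statistic row per ordered trio (P1, P2, Test).

    Names may be population labels (resolved through the matrix's population
    mapping) or individual sample ids.  Columns mirror the classic qpDstat
    report: Outgroup, Pop1, Pop2, Pop3, D, Z, ABBA, BABA, nSNPs, nBlocks.
    """
    unknown = []
    for trio in trios:
        for name in trio:
            try:
                _resolve_population(matrix, name)
            except DStatError:
                unknown.append(name)
    if outgroup is not None:
        try:
            _resolve_population(matrix, outgroup)
        except DStatError:
            unknown.append(outgroup)
    if unknown:
        raise DStatError(f"unknown sample/population names: {sorted(set(unknown))}")

    og_samples = _resolve_population(matrix, outgroup)
    rows = []
    for p1, p2, p3 in trios:
        pf = polarize(
            matrix,
            _resolve_population(matrix, p1),
            _resolve_population(matrix, p2),
            _resolve_population(matrix, p3),
            outgroup_samples=og_samples,
        )
        pf = assign_blocks(pf, n_blocks=n_blocks)
        res = dstat_with_jackknife(pf, labels=(outgroup, p1, p2, p3))
        rows.append(res.to_dict())
    columns = ["Outgroup", "Pop1", "Pop2", "Pop3", "D", "Z", "ABBA", "BABA", "nSNPs", "nBlocks"]
    return pd.DataFrame(rows, columns=columns)
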