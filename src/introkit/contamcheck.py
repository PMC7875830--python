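"""Alignment mismatch-rate contamination QC.

A library contaminated with DNA from another sample or species maps with a
noticeably elevated substitution rate.  The statistic is the samtools-stats
style error rate: substitution mismatches divided by the total number of
reference-matching aligned bases (CIGAR M/=/X), summed over primary mapped
reads.  NM counts indel bases too, so inserted/deleted bases are subtracted
to leave substitutions only.  A cross-sample robust-outlier comparison then
flags suspect libraries; a genuinely admixed sample is expected NOT to be
flagged, which is what separates true introgression from a mixed library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam


class ContamError(ValueError):
    pass


@dataclass
class MismatchStats:
    sample_id: str
    mapped_bases: int
    mismatches: int
    n_reads: int = 0
    n_skipped_no_tag: int = 0

    @property
    def error_rate(self) -> float:
        if self.mapped_bases <= 0:
            raise ContamError(
                f"sample {self.sample_id!r} has no mapped bases; error rate undefined"
            )
        return self.mismatches / self.mapped_bases


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _mismatches_from_md(md: str) -> int:
    """Substitution count from an MD:Z tag (deleted runs ^XXX excluded)."""
    n = 0
    for num, deletion, sub in _MD_TOKEN.findall(md):
        if sub:
            n += 1
    return n


def mismatch_rate(sam_path: str, sample_id: str | None = None) -> MismatchStats:
    """Per-library mismatch statistics from a SAM/BAM file.

    Unmapped, secondary, supplementary and duplicate records are skipped.
    Substitutions come from NM minus inserted/deleted bases; when NM is
    absent the MD tag is parsed instead; reads with neither tag are skipped
    and counted in ``n_skipped_no_tag``.
    """
    stats = MismatchStats(sample_id=sample_id or sam_path, mapped_bases=0, mismatches=0)
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for read in fh:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
            ):
                continue
            cig = read.cigartuples or []
            aligned = sum(n for op, n in cig if op in (0, 7, 8))  # M, =, X
            indel = sum(n for op, n in cig if op in (1, 2))  # I, D
            if read.has_tag("NM"):
                sub = int(read.get_tag("NM")) - indel
            elif read.has_tag("MD"):
                sub = _mismatches_from_md(str(read.get_tag("MD")))
            else:
                stats.n_skipped_no_tag += 1
                continue
            stats.mapped_bases += aligned
            stats.mismatches += max(sub, 0)
            stats.n_reads += 1
    if stats.mapped_bases <= 0:
        raise ContamError(f"no mapped bases in {sam_path!r}; error rate undefined")
    return stats


def compare_samples(stats: list[MismatchStats], k_mad: float = 5.0) -> pd.DataFrame:
    """Cross-sample outlier report.

    Each sample gets a robust z-score (rate - median) / MAD; rates above
    median + ``k_mad`` * MAD are flagged as contamination-suspect.  When the
    MAD is zero (all rates equal), any rate above twice the median is
    flagged instead.
    """
    if len(stats) < 3:
        raise ContamError("need at least 3 samples to compare")
    rates = np.array([s.error_rate for s in stats])
    med = float(np.median(rates))
    mad = float(np.median(np.abs(rates - med)))
    if mad > 0:
        z = (rates - med) / mad
        flagged = rates > med + k_mad * mad
    else:
        z = np.where(rates == med, 0.0, np.inf * np.sign(rates - med))
        flagged = rates > 2 * med
    return pd.DataFrame(
        {
            "sample": [s.sample_id for s in stats],
            "mapped_bases": [s.mapped_bases for s in stats],
            "mismatches": [s.mismatches for s in stats],
            "error_rate": rates,
            "robust_z": z,
            "flagged": flagged,
        }
    )
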