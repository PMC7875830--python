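"""Synthetic data with known truth for every downstream stage.

The genotype generator emulates the population structure the analysis assumes:
two species diverged from a common ancestor under Balding-Nichols drift, a
distant outgroup fixed for the ancestral allele at every site (so sites are
polarizable), and one focal individual that carries a small introgressed
fraction of its loci from the other species.  Additional generators produce
SAM alignments with controlled mismatch rates (for the contamination check)
and TE reference sequences with planted read-coverage gaps (for diagnostic
primer design).

All randomness flows from ``numpy.random.Generator`` streams derived from the
config seed, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .genio import GenotypeMatrix

BASES = np.array(list("ACGT"))

POP_A = "speciesA"
POP_B = "speciesB"
POP_OUT = "outgroup"


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the two-species + outgroup + admixed-individual generator.

    ``F_A``/``F_B`` are the Balding-Nichols drift parameters of each species
    away from the shared ancestor (Fst-like, in (0,1)).  The ancestral derived
    allele frequency at each locus is Beta(a, b) with
    ``ancestral_freq_dist = (a, b)``.  The outgroup is fixed for the ancestral
    allele everywhere.  ``introgression_alpha`` is the per-locus probability
    that the focal (``recipient_sample``) individual draws its genotype from
    the ``donor`` species; ``tract_length`` switches to contiguous-tract
    introgression (whole tracts of that many loci introgress together).
    """

    n_loci: int = 10_000
    n_chrom: int = 21
    samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {POP_A: 3, POP_B: 5, POP_OUT: 1}
    )
    F_A: float = 0.2
    F_B: float = 0.2
    ancestral_freq_dist: tuple[float, float] = (1.0, 1.0)
    introgression_alpha: float = 0.0
    donor: str = POP_A
    recipient_sample: str = "B1"
    tract_length: int | None = None
    qual: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 0 or self.n_chrom < 1:
            raise SimulationError("n_loci must be >= 0 and n_chrom >= 1")
        for name, f in (("F_A", self.F_A), ("F_B", self.F_B)):
            if not (0.0 < f < 1.0):
                raise SimulationError(f"{name}={f} invalid: drift F must be in (0, 1)")
        if not (0.0 <= self.introgression_alpha <= 1.0):
            raise SimulationError("introgression_alpha must be in [0, 1]")
        a, b = self.ancestral_freq_dist
        if a <= 0 or b <= 0:
            raise SimulationError("ancestral Beta hyperparameters must be positive")
        if self.donor not in (POP_A, POP_B):
            raise SimulationError(f"donor must be {POP_A!r} or {POP_B!r}")
        for pop in (POP_A, POP_B, POP_OUT):
            if self.samples_per_pop.get(pop, 0) < (1 if pop != POP_OUT else 1):
                raise SimulationError(f"need at least one {pop} sample")

    @property
    def sample_ids(self) -> list[str]:
        ids = [f"A{i+1}" for i in range(self.samples_per_pop[POP_A])]
        ids += [f"B{i+1}" for i in range(self.samples_per_pop[POP_B])]
        ids += [f"OUT{i+1}" for i in range(self.samples_per_pop[POP_OUT])]
        return ids

    @property
    def populations(self) -> dict[str, str]:
        pops = {}
        for s in self.sample_ids:
            pops[s] = POP_A if s.startswith("A") else POP_B if s.startswith("B") else POP_OUT
        return pops


@dataclass
class FrequencySet:
    """Per-locus derived-allele frequencies for ancestor and both species."""

    p_anc: np.ndarray
    p_A: np.ndarray
    p_B: np.ndarray


@dataclass
class TruthRecord:
    """Per-locus introgression indicators for the focal individual."""

    indicators: np.ndarray  # 0/1 per locus
    seed: int

    @property
    def q_true(self) -> float:
        """Realized fraction of introgressed loci (mean of the indicators)."""
        return float(self.indicators.mean()) if self.indicators.size else 0.0


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    # descendant frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F); mean p, var p(1-p)F
    c = (1.0 - f) / f
    return rng.beta(p * c, (1.0 - p) * c)


def simulate_frequencies(config: SimulationConfig) -> FrequencySet:
    """Draw ancestral and per-species derived-allele frequencies.

    Ancestral ``p_l ~ Beta(a, b)`` i.i.d.; each species drifts independently
    under the Balding-Nichols model.  The outgroup needs no frequency: it is
    fixed for the ancestral allele (derived frequency 0).
    """
    rng = np.random.default_rng([0, config.seed])
    a, b = config.ancestral_freq_dist
    p_anc = rng.beta(a, b, size=config.n_loci)
    p_a = _balding_nichols(rng, p_anc, config.F_A)
    p_b = _balding_nichols(rng, p_anc, config.F_B)
    return FrequencySet(p_anc=p_anc, p_A=p_a, p_B=p_b)


def _locus_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_loci
    per = int(np.ceil(n / config.n_chrom)) if n else 1
    chrom_idx = np.arange(n) // per
    within = np.arange(n) % per
    ref = rng.integers(0, 4, size=n)
    alt = (ref + rng.integers(1, 4, size=n)) % 4
    return pd.DataFrame(
        {
            "chrom": [f"chr{i+1}" for i in chrom_idx],
            "pos": (within + 1) * 100,
            "ref": BASES[ref],
            "alt": [(x,) for x in BASES[alt]],
            "qual": float(config.qual),
        }
    )


def _introgression_mask(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_loci
    if config.introgression_alpha == 0.0:
        return np.zeros(n, dtype=bool)
    if config.tract_length is None:
        return rng.random(n) < config.introgression_alpha
    n_tracts = int(np.ceil(n / config.tract_length))
    tract_on = rng.random(n_tracts) < config.introgression_alpha
    return np.repeat(tract_on, config.tract_length)[:n]


def simulate_genotypes(
    freqs: FrequencySet, config: SimulationConfig
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Sample diploid dosages from the species frequencies.

    Each individual's dosage at locus *l* is Binomial(2, species frequency).
    For the recipient sample, a Bernoulli(``introgression_alpha``) mask (or
    contiguous tracts in tract mode) switches the sampling frequency to the
    donor species at masked loci.  Outgroup individuals are homozygous
    ancestral (dosage 0) everywhere.  REF is the ancestral allele, ALT the
    derived one.
    """
    rng = np.random.default_rng([1, config.seed])
    ids = config.sample_ids
    if config.recipient_sample not in ids:
        raise SimulationError(
            f"recipient_sample {config.recipient_sample!r} not among samples {ids}"
        )
    pops = config.populations
    n = config.n_loci
    loci = _locus_table(config, rng)

    pop_freq = {POP_A: freqs.p_A, POP_B: freqs.p_B}
    donor_freq = pop_freq[config.donor]
    mask = _introgression_mask(config, rng)

    dosage = np.zeros((len(ids), n), dtype=np.int16)
    for i, s in enumerate(ids):
        pop = pops[s]
        if pop == POP_OUT:
            continue  # fixed ancestral
        freq = pop_freq[pop]
        if s == config.recipient_sample:
            freq = np.where(mask, donor_freq, freq)
        dosage[i] = rng.binomial(2, freq)

    gt = np.zeros((len(ids), n, 2), dtype=np.int16)
    gt[:, :, 0] = (dosage == 2).astype(np.int16)
    gt[:, :, 1] = (dosage >= 1).astype(np.int16)
    matrix = GenotypeMatrix(ids, loci, gt, populations=pops)
    truth = TruthRecord(indicators=mask.astype(np.int8), seed=config.seed)
    return matrix, truth


def simulate_dataset(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Convenience: frequencies + genotypes in one call."""
    return simulate_genotypes(simulate_frequencies(config), config)


def write_sim_vcf(
    matrix: GenotypeMatrix, path: str, triallelic_loci: tuple[int, ...] = ()
) -> None:
    """Write the simulated matrix as VCF 4.2.

    ``triallelic_loci`` lists locus indices whose records are written with a
    second ALT allele (genotype calls unchanged), to exercise the
    biallelic-only filter with a known injected count.
    """
    from .genio import write_vcf

    if triallelic_loci:
        loci = matrix.loci.copy()
        alts = list(loci["alt"])
        for j in triallelic_loci:
            ref = loci.iloc[j]["ref"]
            used = {ref, *alts[j]}
            extra = next(b for b in "ACGT" if b not in used)
            alts[j] = tuple(alts[j]) + (extra,)
        loci["alt"] = alts
        matrix = GenotypeMatrix(
            matrix.sample_ids, loci, matrix.gt, populations=matrix.populations
        )
    write_vcf(matrix, path)


def write_truth_table(truth: TruthRecord, matrix: GenotypeMatrix, path: str) -> None:
    """TSV of locus_id, chrom, pos, introgressed 0/1 for the focal sample."""
    df = pd.DataFrame(
        {
            "locus_id": np.arange(matrix.n_loci),
            "chrom": matrix.loci["chrom"],
            "pos": matrix.loci["pos"],
            "introgressed": truth.indicators,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SAM simulation (contamination-check support)
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently at ``rate`` with a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _md_tag(ref_seg: np.ndarray, read: np.ndarray) -> tuple[str, int]:
    """MD string and NM count for an all-match alignment."""
    mism = np.flatnonzero(ref_seg != read)
    parts = []
    prev = 0
    for m in mism:
        parts.append(str(m - prev))
        parts.append(BASES[ref_seg[m]])
        prev = m + 1
    parts.append(str(len(read) - prev))
    return "".join(parts), len(mism)


def simulate_sam(
    n_reads: int,
    read_len: int,
    per_base_mismatch: float,
    contaminant_fraction: float = 0.0,
    contaminant_divergence: float = 0.0,
    seed: int = 0,
    ref_len: int = 1000,
    indel_rate: float = 0.0,
    sam_path: str | None = None,
    fasta_path: str | None = None,
    sample_id: str = "sim",
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Simulate an all-match alignment with controlled mismatch rate.

    Reads are copied from a random reference with i.i.d. substitutions at
    ``per_base_mismatch``; a ``contaminant_fraction`` of reads is instead
    copied from a second reference diverged by ``contaminant_divergence``
    (still aligned to the primary reference, so their extra divergence shows
    up as mismatches).  NM and MD are set from the actual substitutions; the
    CIGAR is all-match unless ``indel_rate`` > 0, in which case a read gains a
    single 1-bp insertion with that probability (NM then includes the
    inserted base, as in real aligner output).

    If ``sam_path``/``fasta_path`` are given the SAM and reference FASTA are
    written there as well.
    """
    for name, p in (
        ("per_base_mismatch", per_base_mismatch),
        ("contaminant_fraction", contaminant_fraction),
        ("contaminant_divergence", contaminant_divergence),
        ("indel_rate", indel_rate),
    ):
        if not (0.0 <= p <= 1.0):
            raise SimulationError(f"{name}={p} must be a probability in [0, 1]")
    if read_len > ref_len:
        raise SimulationError(f"read_len {read_len} exceeds reference length {ref_len}")

    rng = np.random.default_rng([2, seed])
    ref = _random_seq(rng, ref_len)
    contaminant = _mutate(rng, ref, contaminant_divergence)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": "ref1", "LN": ref_len}],
            "RG": [{"ID": sample_id, "SM": sample_id}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    starts = rng.integers(0, ref_len - read_len + 1, size=n_reads)
    is_contam = rng.random(n_reads) < contaminant_fraction
    has_ins = rng.random(n_reads) < indel_rate
    for r in range(n_reads):
        start = int(starts[r])
        template = contaminant if is_contam[r] else ref
        read = _mutate(rng, template[start : start + read_len], per_base_mismatch)
        ref_seg = ref[start : start + read_len]
        md, nm = _md_tag(ref_seg, read)
        seq = "".join(BASES[read])
        cigar = f"{read_len}M"
        if has_ins[r]:
            # single 1-bp insertion after the first half; consumes no reference
            mid = read_len // 2
            ins_base = BASES[int(rng.integers(0, 4))]
            seq = seq[:mid] + ins_base + seq[mid:]
            cigar = f"{mid}M1I{read_len - mid}M"
            nm += 1
        a = pysam.AlignedSegment(header)
        a.query_name = f"read{r}"
        a.query_sequence = seq
        a.flag = 0
        a.reference_id = 0
        a.reference_start = start
        a.mapping_quality = 60
        a.cigarstring = cigar
        a.set_tag("NM", nm, "i")
        a.set_tag("MD", md, "Z")
        a.set_tag("RG", sample_id, "Z")
        records.append(a)

    if fasta_path:
        with open(fasta_path, "w") as fh:
            fh.write(">ref1\n")
            s = "".join(BASES[ref])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    if sam_path:
        with pysam.AlignmentFile(sam_path, "w", header=header) as out:
            for a in records:
                out.write(a)
    return header, records


# ---------------------------------------------------------------------------
# TE coverage simulation (marker-design support)
# ---------------------------------------------------------------------------


def simulate_te_coverage(
    te_length: int,
    gaps: list[tuple[int, int]],
    depth: int,
    seed: int = 0,
    poisson_noise: bool = False,
    name: str = "TE1",
    te_class: str = "DNA",
    gc_content: float = 0.5,
):
    """Random TE reference plus a coverage track with planted zero-coverage gaps.

    ``gaps`` are 0-based half-open intervals within ``[0, te_length)``; they
    must not overlap.  Outside the gaps coverage is ``depth`` exactly, or
    Poisson(``depth``) when ``poisson_noise`` is set (but never 0, so planted
    gaps remain the only uncovered positions).
    """
    from .temarkers import CoverageTrack, TEReference

    if depth <= 0:
        raise SimulationError("depth must be positive")
    ivals = sorted((int(s), int(e)) for s, e in gaps)
    for s, e in ivals:
        if not (0 <= s < e <= te_length):
            raise SimulationError(f"gap ({s}, {e}) outside [0, {te_length})")
    for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
        if s2 < e1:
            raise SimulationError("gaps overlap")

    rng = np.random.default_rng([3, seed])
    weights = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    seq = "".join(rng.choice(list("AGCT"), size=te_length, p=weights))
    cov = np.full(te_length, depth, dtype=int)
    if poisson_noise:
        cov = rng.poisson(depth, size=te_length)
        cov = np.maximum(cov, 1)
    for s, e in ivals:
        cov[s:e] = 0
    return TEReference(name=name, te_class=te_class, sequence=seq), CoverageTrack(
        te_name=name, depth=cov
    )
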