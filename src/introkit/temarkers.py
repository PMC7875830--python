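"""Species-diagnostic TE marker (primer) design from coverage gaps.

A transposable-element consensus from the target species is used as a mapping
reference for reads of the *non*-target species; intervals of the TE left
uncovered by those reads are sequence unique to the target lineage.  PCR
primer pairs whose amplicon lies entirely inside such a coverage gap then
amplify the target species' TE but produce nothing from the non-target one —
a cheap presence/absence introgression assay.

Default physicochemical constraints (length 18-25 nt, GC 0.40-0.60, melting
temperature 50-62 degC by nearest-neighbor thermodynamics, pair dTm <= 3.5,
no homopolymer run of 5+, 3' G/C clamp optional and off by default) were
calibrated once against the 24-primer published stickleback TE panel shipped
in :data:`STICKLEBACK_TE_PRIMERS`, all of which pass them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as mt


class PrimerError(ValueError):
    pass


# Published diagnostic panel: 12 three-spined stickleback TEs (7 DNA
# transposons, 5 Gypsy-family retroelements), one primer pair each, with the
# reported PCR fragment lengths (nt).  Used as a regression set for the
# default design constraints.
STICKLEBACK_TE_PRIMERS: list[dict] = [
    {"te": "Ltr80", "class": "DNA", "fwd": "AGTTCCAGGGAGCTATGCTGGGT", "rev": "CGATGCCTCACGTCCAAAGAC", "product": 431},
    {"te": "Tcl5", "class": "DNA", "fwd": "GGACAACCATCTCTGCAGCAC", "rev": "GATGAGCAGTGCCTGGTTTCC", "product": 231},
    {"te": "Tcl7", "class": "DNA", "fwd": "GGTGTTTCAGATTCATGCAGCGA", "rev": "GTGCTGTCCAAAACAAGCAGTGC", "product": 496},
    {"te": "Tcl3", "class": "DNA", "fwd": "CCCTTTACTTTCAGTGCAGCA", "rev": "TTGCACAGTGCTCCTTGGGA", "product": 296},
    {"te": "hAT1", "class": "DNA", "fwd": "CACAGATGGAGCCCCTGCTA", "rev": "CCTCCTGATGGACCAAAAGC", "product": 321},
    {"te": "hAT3", "class": "DNA", "fwd": "AAGAGCAACACGGATCAGATGC", "rev": "CATTGAGAAGCCAATGGTGC", "product": 456},
    {"te": "hAT5", "class": "DNA", "fwd": "ACGTTGTGTTGATGTAGCTTGGT", "rev": "CCCTCCAAAAGGCTGTTCTC", "product": 296},
    {"te": "Gyp37_12", "class": "RNA", "fwd": "CCTCCTAGGCTTCCGTAGTT", "rev": "AACACAGACGGTGCCTTCTG", "product": 346},
    {"te": "Gyp13_5", "class": "RNA", "fwd": "CTGTGGCAGGAGCAGTCCATCTT", "rev": "CTTTGACCCGTTGGCACTCAAGG", "product": 296},
    {"te": "Gyp13_10", "class": "RNA", "fwd": "GGGTGAGTTCTGGAAAACCAGC", "rev": "GCGCTCATTAGTGGCCATGAGTG", "product": 461},
    {"te": "Gyp9_3F", "class": "RNA", "fwd": "ACCCAAATAGCTGTCCGCTT", "rev": "CAGTGCGTATCTTCGGGAACC", "product": 260},
    {"te": "Gyp9_4", "class": "RNA", "fwd": "GTTCCCGAAGGTACGCACTG", "rev": "TGGAGAGGTACGTTAGCCCCA", "product": 421},
]


@dataclass
class TEReference:
    name: str
    te_class: str  # "DNA" or "RNA"
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence or set(self.sequence) - set("ACGTN"):
            raise PrimerError("TE sequence must be non-empty over A/C/G/T/N")


@dataclass
class CoverageTrack:
    te_name: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=int)
        if (self.depth < 0).any():
            raise PrimerError("coverage depths must be non-negative")


@dataclass
class GapInterval:
    """0-based half-open uncovered interval on a TE reference."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PrimerError(f"invalid gap interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PrimerPair:
    te_name: str
    fwd_seq: str
    rev_seq: str  # reverse complement of the template
    fwd_start: int  # 0-based
    rev_end: int  # 0-based half-open
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float
    score: float

    @property
    def product_length(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 25
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (50.0, 62.0)
    max_tm_diff: float = 3.5
    max_homopolymer: int = 4  # longest run allowed
    gc_clamp: bool = False  # require 3' terminal G or C
    min_product: int = 200
    max_product: int = 500
    tm_method: str = "nn"
    target_product: int | None = None  # default: midpoint of product range
    weights: tuple[float, float, float] = (1.0, 10.0, 0.01)  # dTm, GC dev, product dev


@dataclass
class PrimerDesign:
    """Ranked candidate pairs plus per-constraint rejection accounting."""

    pairs: list[PrimerPair]
    rejections: dict[str, int] = field(default_factory=dict)


def coverage_gaps(
    track: CoverageTrack, max_depth: int = 0, min_length: int = 250
) -> list[GapInterval]:
    """Maximal runs of depth <= ``max_depth`` of length >= ``min_length``."""
    low = track.depth <= max_depth
    if not low.any():
        return []
    edges = np.diff(low.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if low[0]:
        starts.insert(0, 0)
    if low[-1]:
        ends.append(len(low))
    return [
        GapInterval(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_length
    ]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def tm_estimate(primer_seq: str, method: str = "nn") -> float:
    """Melting temperature in degC.

    ``wallace``: the 2(A+T) + 4(G+C) rule of thumb; ``nn``: nearest-neighbor
    thermodynamics with the standard unified parameter set at default salt
    and primer concentrations.
    """
    seq = primer_seq.upper()
    if len(seq) < 8:
        raise PrimerError("primer too short for a meaningful Tm (need >= 8 nt)")
    if set(seq) - set("ACGT"):
        raise PrimerError(f"ambiguous bases in primer {primer_seq!r}")
    if method == "wallace":
        return float(mt.Tm_Wallace(seq))
    if method == "nn":
        return float(mt.Tm_NN(seq))
    raise PrimerError(f"unknown Tm method {method!r}")


def _check_primer(seq: str, c: PrimerConstraints) -> tuple[float, float, list[str]]:
    """(tm, gc, failed-constraint names) for a single candidate."""
    failures = []
    gc = gc_fraction(seq)
    tm = tm_estimate(seq, c.tm_method)
    if not (c.gc_range[0] <= gc <= c.gc_range[1]):
        failures.append("GC content")
    if not (c.tm_range[0] <= tm <= c.tm_range[1]):
        failures.append("Tm")
    if max_homopolymer_run(seq) > c.max_homopolymer:
        failures.append("homopolymer")
    if c.gc_clamp and seq[-1] not in "GC":
        failures.append("3' clamp")
    return tm, gc, failures


def check_pair_constraints(
    fwd: str, rev: str, constraints: PrimerConstraints | None = None
) -> list[str]:
    """Names of default constraints violated by an existing primer pair."""
    c = constraints or PrimerConstraints()
    failures = []
    for seq in (fwd, rev):
        if not (c.min_len <= len(seq) <= c.max_len):
            failures.append("length")
        tm, gc, fail = _check_primer(seq, c)
        failures.extend(fail)
    if abs(tm_estimate(fwd, c.tm_method) - tm_estimate(rev, c.tm_method)) > c.max_tm_diff:
        failures.append("Tm difference")
    return sorted(set(failures))


def design_primers(
    te: TEReference,
    gap: GapInterval,
    constraints: PrimerConstraints | None = None,
    max_pairs: int = 20,
    step: int = 1,
) -> PrimerDesign:
    """Enumerate and rank primer pairs whose amplicon lies inside the gap.

    Forward primers start in the first part of the gap, reverse primers end
    in the last part, such that the product length falls in
    ``[min_product, max_product]``.  Candidates failing any single-primer
    constraint are counted per constraint in ``rejections``; surviving pairs
    are scored by w1 |dTm| + w2 (|GC_f - 0.5| + |GC_r - 0.5|) +
    w3 |product - target| and returned best-first (ties broken by
    coordinates).
    """
    c = constraints or PrimerConstraints()
    if gap.end > len(te.sequence):
        raise PrimerError("gap extends beyond the TE reference")
    rejections: dict[str, int] = {}
    if gap.length < c.min_product:
        rejections["product length"] = 1
        return PrimerDesign(pairs=[], rejections=rejections)

    seq = te.sequence
    target = c.target_product or (c.min_product + c.max_product) // 2
    w1, w2, w3 = c.weights

    def enumerate_candidates(kind: str) -> list[tuple[int, int, str, float, float]]:
        out = []
        if kind == "fwd":
            lo, hi = gap.start, gap.end - c.min_product
        else:
            lo, hi = gap.start + c.min_product, gap.end
        for anchor in range(lo, hi + 1, step):
            for ln in range(c.min_len, c.max_len + 1):
                if kind == "fwd":
                    s, e = anchor, anchor + ln
                else:
                    s, e = anchor - ln, anchor
                if s < gap.start or e > gap.end:
                    continue
                sub = seq[s:e]
                if "N" in sub:
                    rejections["ambiguous base"] = rejections.get("ambiguous base", 0) + 1
                    continue
                primer = sub if kind == "fwd" else str(Seq(sub).reverse_complement())
                tm, gc, failures = _check_primer(primer, c)
                if failures:
                    for fkey in failures:
                        rejections[fkey] = rejections.get(fkey, 0) + 1
                    continue
                out.append((s, e, primer, tm, gc))
        return out

    fwd_cands = enumerate_candidates("fwd")
    rev_cands = enumerate_candidates("rev")
    pairs: list[PrimerPair] = []
    for fs, fe, fseq, ftm, fgc in fwd_cands:
        for rs, re_, rseq, rtm, rgc in rev_cands:
            product = re_ - fs
            if not (c.min_product <= product <= c.max_product):
                rejections["product length"] = rejections.get("product length", 0) + 1
                continue
            if rs < fe:  # overlapping primers
                rejections["overlap"] = rejections.get("overlap", 0) + 1
                continue
            if abs(ftm - rtm) > c.max_tm_diff:
                rejections["Tm difference"] = rejections.get("Tm difference", 0) + 1
                continue
            score = (
                w1 * abs(ftm - rtm)
                + w2 * (abs(fgc - 0.5) + abs(rgc - 0.5))
                + w3 * abs(product - target)
            )
            pairs.append(
                PrimerPair(
                    te_name=te.name, fwd_seq=fseq, rev_seq=rseq,
                    fwd_start=fs, rev_end=re_, fwd_tm=ftm, rev_tm=rtm,
                    fwd_gc=fgc, rev_gc=rgc, score=score,
                )
            )
    pairs.sort(key=lambda p: (p.score, p.fwd_start, p.rev_end))
    return PrimerDesign(pairs=pairs[:max_pairs], rejections=rejections)


# ---------------------------------------------------------------------------
# In-silico PCR screening
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _match_positions(
    target: np.ndarray,
    site: str,
    max_mismatches: int,
    anchor: int,
    anchor_end: str = "tail",
) -> list[int]:
    """Start positions where ``site`` occurs with the 3'-anchored mismatch rule.

    ``anchor_end`` says which end of the plus-strand site corresponds to the
    primer's 3' terminus: ``tail`` for a forward primer, ``head`` for the
    plus-strand binding site of a reverse primer.
    """
    p = _encode(site)
    m = len(p)
    if len(target) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(target, m)
    mism = (windows != p[None, :]).sum(axis=1)
    ok = mism <= max_mismatches
    if anchor > 0:
        if anchor_end == "tail":
            ok &= (windows[:, m - anchor :] == p[None, m - anchor :]).all(axis=1)
        else:
            ok &= (windows[:, :anchor] == p[None, :anchor]).all(axis=1)
    return list(np.flatnonzero(ok))


def screen_primers_in_silico(
    primer_pairs: list[PrimerPair],
    genome: str | dict[str, str],
    max_mismatches: int = 0,
    anchor: int = 3,
    max_product: int = 2000,
) -> pd.DataFrame:
    """Predict PCR products of each primer pair against target sequences.

    ``genome`` is a FASTA path or a name->sequence dict.  A product is called
    when the forward primer binds the plus strand and the reverse primer's
    reverse complement binds downstream within ``max_product``; binding
    tolerates up to ``max_mismatches`` substitutions but the 3'-terminal
    ``anchor`` bases must match exactly.

    Returns a DataFrame (te, sequence, product_start, product_end,
    product_length), one row per predicted amplicon.
    """
    if isinstance(genome, (str,)):
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(genome, "fasta")}
    else:
        seqs = dict(genome)
    rows = []
    for pair in primer_pairs:
        rev_site = str(Seq(pair.rev_seq).reverse_complement())
        for name, s in seqs.items():
            enc = _encode(s)
            fwd_hits = _match_positions(enc, pair.fwd_seq, max_mismatches, anchor, "tail")
            # the reverse primer's 3' end faces upstream on the plus strand,
            # so its anchored bases are the *first* bases of the binding site
            rev_ends = [
                h + len(rev_site)
                for h in _match_positions(enc, rev_site, max_mismatches, anchor, "head")
            ]
            for fs in fwd_hits:
                for re_ in rev_ends:
                    length = re_ - fs
                    if len(pair.fwd_seq) + len(pair.rev_seq) <= length <= max_product:
                        rows.append(
                            {
                                "te": pair.te_name,
                                "sequence": name,
                                "product_start": fs,
                                "product_end": re_,
                                "product_length": length,
                            }
                        )
    return pd.DataFrame(
        rows, columns=["te", "sequence", "product_start", "product_end", "product_length"]
    )


def read_coverage_tsv(path: str, te_name: str, te_length: int | None = None) -> CoverageTrack:
    """Read samtools-depth style TSV (name, 1-based pos, depth) into a track."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "pos", "depth"])
    df = df[df["name"] == te_name]
    length = te_length or (int(df["pos"].max()) if len(df) else 0)
    depth = np.zeros(length, dtype=int)
    pos = df["pos"].to_numpy(dtype=int) - 1
    ok = (pos >= 0) & (pos < length)
    depth[pos[ok]] = df["depth"].to_numpy(dtype=int)[ok]
    return CoverageTrack(te_name=te_name, depth=depth)


def write_gaps_bed(gaps: list[GapInterval], te_name: str, path: str) -> None:
    """Write gaps as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in gaps:
            fh.write(f"{te_name}\t{g.start}\t{g.end}\n")


def primer_table(pairs: list[PrimerPair], te_class: str = "") -> pd.DataFrame:
    """Published-panel-style table: TE, class, F/R sequences, product length."""
    return pd.DataFrame(
        [
            {
                "te": p.te_name,
                "class": te_class,
                "fwd": p.fwd_seq,
                "rev": p.rev_seq,
                "product_length": p.product_length,
                "fwd_tm": round(p.fwd_tm, 2),
                "rev_tm": round(p.rev_tm, 2),
                "score": round(p.score, 4),
            }
            for p in pairs
        ]
    )
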