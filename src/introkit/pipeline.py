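"""Orchestration: simulate/load -> filter -> NJ -> admixture -> D-stat -> QC -> primers.

``run_pipeline`` executes the stages in dependency order from a single
:class:`RunConfig` (built in code or from a YAML file), writes every
intermediate artifact into the output directory, and returns a
:class:`RunReport` with one summary per executed stage.  All randomness
derives from the config seed, so a rerun with the same config produces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import abbababa, admixmc, contamcheck, distclust, genio, simdata, temarkers

FOCAL_POP = "focal"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, completed outputs are kept."""


@dataclass
class RunConfig:
    """Flat per-stage parameter blocks; exactly one genotype source.

    Either ``simulate`` (a :class:`~introkit.simdata.SimulationConfig` block)
    or ``inputs`` (paths to a VCF and optional SAMs / TE fasta+coverage)
    supplies the genotypes.
    """

    out_dir: str = "introkit_out"
    seed: int = 0
    simulate: dict | None = None
    sim_sam: dict | None = None
    sim_te: dict | None = None
    inputs: dict | None = None
    filter: dict = field(default_factory=dict)
    nj: dict = field(default_factory=dict)
    admixture: dict = field(default_factory=dict)
    dstat: dict = field(default_factory=dict)
    contam: dict = field(default_factory=dict)
    te: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError("exactly one of 'simulate' / 'inputs' must supply genotypes")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = yaml.safe_dump(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = ["introkit pipeline report", "=" * 30]
        for k, v in self.provenance.items():
            lines.append(f"{k}: {v}")
        for name, summ in self.stages.items():
            lines.append("")
            lines.append(f"[{name}]")
            for k, v in summ.items():
                lines.append(f"  {k}: {v}")
        if self.skipped:
            lines.append("")
            lines.append("skipped stages: " + ", ".join(self.skipped))
        return "\n".join(lines) + "\n"


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _load_populations(path: str) -> dict[str, str]:
    pops = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sample, pop = line.split()[:2]
                pops[sample] = pop
    return pops


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; see module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        provenance={"seed": config.seed, "config_digest": config.digest()}
    )

    # ------------------------------------------------------------------ data
    truth = None
    recipient = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_cfg = simdata.SimulationConfig(**sim_kwargs)
        matrix, truth = _sim_genotypes(sim_cfg)
        recipient = sim_cfg.recipient_sample
        simdata.write_sim_vcf(matrix, str(out / "genotypes.vcf"))
        simdata.write_truth_table(truth, matrix, str(out / "truth.tsv"))
        report.stages["simulate"] = {
            "n_loci": matrix.n_loci,
            "n_samples": matrix.n_samples,
            "q_true": round(truth.q_true, 6),
        }
    else:
        pops = None
        if config.inputs.get("populations"):
            pops = _load_populations(config.inputs["populations"])
        matrix = _read_vcf(config.inputs["vcf"], pops)
        report.stages["load"] = {
            "vcf": config.inputs["vcf"],
            "n_loci": matrix.n_loci,
            "n_samples": matrix.n_samples,
        }

    # ---------------------------------------------------------------- filter
    fcfg = config.filter
    matrix, freport = _filter(
        matrix,
        biallelic=fcfg.get("biallelic", True),
        min_qual=fcfg.get("min_qual", 500.0),
        invariant=fcfg.get("drop_invariant", True),
    )
    freport.write_tsv(str(out / "filter_report.tsv"))
    genio.write_vcf(matrix, str(out / "filtered.vcf"))
    report.stages["filter"] = {
        r["filter"]: f"{r['loci_in']} -> {r['loci_out']} (-{r['removed']})"
        for r in freport.rows
    }

    # -------------------------------------------------------------------- NJ
    if config.nj.get("enabled", True):
        dist, tree = _nj(matrix, config.nj.get("missing", "rescale"))
        dist.write_tsv(str(out / "distances.tsv"))
        distclust.write_newick(tree, str(out / "tree.nwk"))
        report.stages["nj"] = {"newick": tree.to_newick()}
    else:
        report.skipped.append("nj")

    # ------------------------------------------------------------- admixture
    if config.admixture.get("enabled", True):
        acfg = config.admixture
        res = _admixture(
            matrix,
            k=acfg.get("k", 2),
            model=acfg.get("model", "correlated"),
            burnin=acfg.get("burnin", 10_000),
            reps=acfg.get("reps", 20_000),
            thin=acfg.get("thin", 1),
            n_chains=acfg.get("n_chains", 1),
            seed=config.seed,
        )
        res.write_tsv(str(out / "admixture_q.tsv"))
        summ = {
            "K": res.model.k,
            "draws": res.q_trace.shape[0],
        }
        if recipient is not None and recipient in res.sample_ids:
            i = res.sample_ids.index(recipient)
            summ["focal_minor_ancestry"] = round(float(res.q_mean[i].min()), 4)
        if res.chain_disagreement is not None:
            summ["max_chain_dQ"] = round(res.chain_disagreement, 4)
        report.stages["admixture"] = summ
    else:
        report.skipped.append("admixture")

    # ----------------------------------------------------------------- dstat
    if config.dstat.get("enabled", True):
        table = _dstat(matrix, config, recipient)
        if table is not None:
            table.to_csv(str(out / "dstat.tsv"), sep="\t", index=False, float_format="%.6g")
            report.stages["dstat"] = {
                "rows": len(table),
                "D": [round(x, 4) for x in table["D"]],
                "Z": [round(x, 3) for x in table["Z"]],
            }
        else:
            report.skipped.append("dstat")
    else:
        report.skipped.append("dstat")

    # ---------------------------------------------------------------- contam
    sam_paths = _contam_inputs(config, out)
    if sam_paths:
        stats = [
            _mismatch(path, sample) for sample, path in sam_paths
        ]
        ctable = _compare(stats, config.contam.get("k_mad", 5.0))
        ctable.to_csv(str(out / "contam.tsv"), sep="\t", index=False, float_format="%.6g")
        report.stages["contam"] = {
            "rates": [round(r, 5) for r in ctable["error_rate"]],
            "flagged": list(ctable.loc[ctable["flagged"], "sample"]),
        }
    else:
        report.skipped.append("contam")

    # -------------------------------------------------------------- primers
    te_input = _te_inputs(config)
    if te_input is not None:
        te_ref, track = te_input
        tcfg = config.te
        gaps = temarkers.coverage_gaps(
            track,
            max_depth=tcfg.get("max_depth", 0),
            min_length=tcfg.get("min_gap", 250),
        )
        temarkers.write_gaps_bed(gaps, te_ref.name, str(out / "gaps.bed"))
        constraints = temarkers.PrimerConstraints(
            min_product=tcfg.get("min_product", 200),
            max_product=tcfg.get("max_product", 500),
        )
        all_pairs = []
        for gap in gaps:
            design = temarkers.design_primers(te_ref, gap, constraints, max_pairs=3)
            all_pairs.extend(design.pairs)
        temarkers.primer_table(all_pairs, te_ref.te_class).to_csv(
            str(out / "primers.tsv"), sep="\t", index=False
        )
        report.stages["te_markers"] = {
            "gaps": [(g.start, g.end) for g in gaps],
            "primer_pairs": len(all_pairs),
        }
    else:
        report.skipped.append("te_markers")

    (out / "summary.txt").write_text(report.summary_text())
    (out / "report.json").write_text(
        json.dumps(
            {"stages": report.stages, "skipped": report.skipped,
             "provenance": report.provenance},
            indent=2, default=str,
        )
    )
    return report


# stage wrappers: uniform error reporting with the failing stage's name
_sim_genotypes = _stage("simulate")(simdata.simulate_dataset)
_read_vcf = _stage("load")(genio.read_vcf)
_filter = _stage("filter")(genio.apply_filters)
_mismatch = _stage("contam")(contamcheck.mismatch_rate)
_compare = _stage("contam")(contamcheck.compare_samples)


@_stage("nj")
def _nj(matrix, missing):
    dist = distclust.euclidean_distances(matrix, missing=missing)
    return dist, distclust.neighbor_joining(dist)


@_stage("admixture")
def _admixture(matrix, k, model, burnin, reps, thin, n_chains, seed):
    # the admixture model is fitted to the ingroup samples only: a distant
    # monomorphic outgroup would otherwise capture one of the K clusters
    pops = matrix.populations or {}
    ingroup = [s for s in matrix.sample_ids if pops.get(s) != simdata.POP_OUT]
    if len(ingroup) >= 2 and len(ingroup) < matrix.n_samples:
        matrix = matrix.subset_samples(ingroup)
    model_obj = admixmc.AdmixtureModel(matrix, k=k, model=model)
    return model_obj.fit(
        burnin=burnin, reps=reps, thin=thin, seed=seed, n_chains=n_chains
    )


@_stage("dstat")
def _dstat(matrix, config: RunConfig, recipient: str | None):
    dcfg = config.dstat
    trios = [tuple(t) for t in dcfg.get("trios", [])]
    outgroup = dcfg.get("outgroup")
    if not trios and recipient is not None:
        # default design: donor species as P1, the recipient's conspecifics as
        # P2, the focal individual as the test population
        pops = dict(matrix.populations or {})
        pops[recipient] = FOCAL_POP
        matrix = genio.GenotypeMatrix(
            matrix.sample_ids, matrix.loci, matrix.gt, populations=pops
        )
        donor = (config.simulate or {}).get("donor", simdata.POP_A)
        other = simdata.POP_B if donor == simdata.POP_A else simdata.POP_A
        trios = [(donor, other, recipient)]
        outgroup = outgroup or simdata.POP_OUT
    if not trios or outgroup is None:
        return None
    return abbababa.qp_dstat_table(
        matrix, outgroup, trios, n_blocks=dcfg.get("n_blocks", 50)
    )


def _contam_inputs(config: RunConfig, out: Path) -> list[tuple[str, str]]:
    if config.inputs is not None:
        return [
            (Path(p).stem, p) for p in (config.inputs.get("sams") or [])
        ]
    if config.sim_sam is None:
        return []
    scfg = dict(config.sim_sam)
    n_samples = scfg.pop("n_samples", 8)
    contaminated = scfg.pop("contaminated_sample", None)
    cf = scfg.pop("contaminant_fraction", 0.1)
    paths = []
    sam_dir = out / "sam"
    sam_dir.mkdir(exist_ok=True)
    for i in range(n_samples):
        name = f"lib{i+1}"
        path = str(sam_dir / f"{name}.sam")
        simdata.simulate_sam(
            n_reads=scfg.get("n_reads", 2000),
            read_len=scfg.get("read_len", 100),
            per_base_mismatch=scfg.get("per_base_mismatch", 0.01),
            contaminant_fraction=cf if name == contaminated else 0.0,
            contaminant_divergence=scfg.get("contaminant_divergence", 0.05),
            seed=config.seed * 1000 + i,
            sam_path=path,
            sample_id=name,
        )
        paths.append((name, path))
    return paths


def _te_inputs(config: RunConfig):
    if config.inputs is not None:
        fasta = config.inputs.get("te_fasta")
        cov = config.inputs.get("te_coverage")
        if not fasta or not cov:
            return None
        from Bio import SeqIO

        rec = next(SeqIO.parse(fasta, "fasta"))
        te = temarkers.TEReference(
            name=rec.id, te_class=config.te.get("te_class", "DNA"), sequence=str(rec.seq)
        )
        track = temarkers.read_coverage_tsv(cov, rec.id, te_length=len(te.sequence))
        return te, track
    if config.sim_te is None:
        return None
    tcfg = dict(config.sim_te)
    tcfg.setdefault("seed", config.seed)
    return simdata.simulate_te_coverage(**tcfg)
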