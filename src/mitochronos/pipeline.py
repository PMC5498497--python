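"""End-to-end orchestration: collapse → diversity → mask → tree → date → skyline.

A single config (TOML file or PipelineConfig) drives the stages; every
intermediate artifact is persisted in the output directory and a JSON report
collects the machine-readable results plus provenance (input checksums,
parameters, wall time per stage). Reruns with an identical config reproduce
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
import tomllib
from dataclasses import dataclass, field

from . import clock_dating, codon_masking, diversity, mito_io, parsimony_tree, skyline

logger = logging.getLogger(__name__)

ALL_STAGES = ("collapse", "diversity", "mask", "tree", "date", "skyline")


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str
    genemap: str
    calibrations: str | None = None
    rules: str | None = None
    out_dir: str = "mitochronos_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 7
    strict_haplotypes: bool = True
    site_unit: str = "nt"  # 'nt' or 'codon' for the clock site count
    outgroup_btypes: tuple[str, ...] = ("river", "outgroup")
    constraints: list[list[str]] = field(default_factory=list)
    skyline_groups: int = 10
    skyline_iters: int = 500_000
    skyline_thin: int = 100
    generation_time: float = 6.0
    mp_n_starts: int = 3
    mp_spr_rounds: int = 3
    clock_n_starts: int = 5

    def validate(self) -> None:
        for path in (self.fasta, self.metadata, self.genemap):
            if not os.path.exists(path):
                raise FileNotFoundError(path)
        for path in (self.calibrations, self.rules):
            if path and not os.path.exists(path):
                raise FileNotFoundError(path)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.site_unit not in ("nt", "codon"):
            raise ValueError("site_unit must be 'nt' or 'codon'")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls(**{k: tuple(v) if k == "stages" else v for k, v in data.items()})
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the report dict.

    A stage failure raises, after the report so far (with the failing stage
    named) has been written to ``report.json``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in vars(config).items()},
        "inputs": {
            name: _sha256(path)
            for name, path in (
                ("fasta", config.fasta), ("metadata", config.metadata),
                ("genemap", config.genemap), ("calibrations", config.calibrations),
                ("rules", config.rules),
            )
            if path
        },
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            t0 = time.perf_counter()
            logger.info("stage %s starting", stage)
            _STAGE_FN[stage](config, state, report)
            report["stages"][stage] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:
        report["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_report(config, report)
        raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc
    _write_report(config, report)
    return report


def _write_report(config: PipelineConfig, report: dict) -> None:
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, float) and not math.isfinite(x):
        return str(x)
    try:
        return x.item()
    except AttributeError:
        return str(x)


def _load(config: PipelineConfig, state: dict) -> None:
    if "records" in state:
        return
    metadata = mito_io.read_metadata(config.metadata)
    records = mito_io.read_alignment(config.fasta, metadata)
    genemap = mito_io.GeneMap.from_tsv(config.genemap)
    by_id = {r.id: r for r in records}
    if genemap.reference_id not in by_id:
        raise ValueError(f"reference {genemap.reference_id!r} missing from alignment")
    state.update(
        records=records,
        genemap=genemap,
        reference=by_id[genemap.reference_id],
        ingroup=[r for r in records if r.btype == "swamp"] or records,
        outgroup_ids=[r.id for r in records if r.btype in config.outgroup_btypes],
    )


def _stage_collapse(config, state, report) -> None:
    _load(config, state)
    table = mito_io.collapse_haplotypes(
        state["ingroup"], state["reference"], state["genemap"],
        strict=config.strict_haplotypes,
    )
    if config.rules:
        rules = mito_io.read_rules(config.rules)
        for ht in table.haplotypes:
            ht.haplogroup = mito_io.assign_haplogroup(ht.variants, rules)
    table.to_tsv(os.path.join(config.out_dir, "haplotypes.tsv"))
    mito_io.variants_to_vcf(
        {h.ht_id: h.variants for h in table.haplotypes},
        state["genemap"].reference_id,
        os.path.join(config.out_dir, "variants.vcf"),
    )
    state["haplotypes"] = table
    report["haplotypes"] = {
        "n_sequences": table.n_members,
        "n_haplotypes": len(table),
        "haplogroups": sorted({h.haplogroup for h in table.haplotypes}),
    }


def _stage_diversity(config, state, report) -> None:
    _load(config, state)
    if "haplotypes" not in state:
        _stage_collapse(config, state, report)
    summary = diversity.summarize(state["ingroup"], state["haplotypes"])
    summary.to_frame().to_csv(
        os.path.join(config.out_dir, "diversity.tsv"), sep="\t", index=False
    )
    report["diversity"] = vars(summary)


def _stage_mask(config, state, report) -> None:
    _load(config, state)
    coding = codon_masking.extract_coding(state["records"], state["genemap"])
    ancestral = codon_masking.infer_ancestral(
        coding, outgroup_ids=state["outgroup_ids"] or [state["reference"].id]
    )
    masked, audit = codon_masking.mask_nonsynonymous(coding, ancestral)
    audit.to_csv(os.path.join(config.out_dir, "mask_audit.tsv"), sep="\t", index=False)
    masked_records = [
        mito_io.MitogenomeRecord(id=i, sequence=masked.sequences[i], btype="swamp")
        for i in masked.ids
    ]
    mito_io.write_alignment(
        masked_records, os.path.join(config.out_dir, "masked_coding.fa")
    )
    state["coding"], state["masked"], state["ancestral"] = coding, masked, ancestral
    report["masking"] = {
        "length_nt": masked.length_nt,
        "codon_count": masked.codon_count,
        "n_masked": int((audit["action"] == "masked").sum()) if len(audit) else 0,
        "n_retained": int((audit["action"] == "retained").sum()) if len(audit) else 0,
    }


def _stage_tree(config, state, report) -> None:
    if "masked" not in state:
        _stage_mask(config, state, report)
    if "haplotypes" not in state:
        _stage_collapse(config, state, report)
    # search on haplotype representatives plus the outgroups
    reps = [h.member_ids[0] for h in state["haplotypes"].haplotypes]
    keep = list(dict.fromkeys(reps + state["outgroup_ids"]))
    seqs = {i: state["masked"].sequences[i] for i in keep}
    constraints = [set(c) & set(keep) for c in config.constraints]
    # the ingroup/outgroup split is taken as known (it anchors the rooting)
    ingroup_reps = set(keep) - set(state["outgroup_ids"])
    if state["outgroup_ids"] and len(ingroup_reps) >= 2:
        constraints.append(ingroup_reps)
    constraints = [c for c in constraints if len(c) >= 2]
    tree = parsimony_tree.mp_search(
        seqs,
        constraints=constraints or None,
        outgroup_ids=state["outgroup_ids"],
        seed=config.seed,
        n_starts=config.mp_n_starts,
        max_spr_rounds=config.mp_spr_rounds,
    )
    parsimony_tree.assign_branch_mutations(tree, seqs, state["ancestral"].bases)
    ages = {r.id: r.tip_age for r in state["records"]}
    for leaf in tree.leaves():
        leaf.tip_age = ages.get(leaf.name, 0.0)
    with open(os.path.join(config.out_dir, "mp_tree.nwk"), "w") as fh:
        fh.write(tree.newick(lengths="k") + "\n")
    state["tree"] = tree
    report["tree"] = {
        "n_leaves": len(tree.leaves()),
        "parsimony_length": tree.parsimony_length,
        "tree_length_check": tree.tree_length,
    }


def _stage_date(config, state, report) -> None:
    if "tree" not in state:
        _stage_tree(config, state, report)
    if not config.calibrations:
        raise ValueError("dating requires a calibrations table")
    calibrations = clock_dating.Calibration.table_from_tsv(config.calibrations)
    # calibration targets may name any collapsed member; map to representatives
    member_to_rep = {}
    for h in state["haplotypes"].haplotypes:
        for m in h.member_ids:
            member_to_rep[m] = h.member_ids[0]
    leaf_names = set(state["tree"].leaf_names())
    for cal in calibrations:
        cal.target = sorted(
            {member_to_rep.get(t, t) for t in cal.target} & (leaf_names | set(cal.target))
        )
        cal.target = [t for t in cal.target if t in leaf_names]
        if not cal.target:
            raise ValueError("calibration target has no leaf in the tree")
    site_count = (
        state["masked"].codon_count if config.site_unit == "codon"
        else state["masked"].length_nt
    )
    fit = clock_dating.fit_clock(
        state["tree"], calibrations, site_count,
        n_starts=config.clock_n_starts, seed=config.seed,
    )
    with open(os.path.join(config.out_dir, "dated_tree.nwk"), "w") as fh:
        fh.write(state["tree"].newick(lengths="age") + "\n")
    swamp_reps = sorted(
        {member_to_rep[r.id] for r in state["ingroup"] if r.id in member_to_rep}
        & leaf_names
    )
    clades = {"ingroup_mrca": swamp_reps}
    ages = clock_dating.node_age_report(fit, clades)
    ages.to_csv(os.path.join(config.out_dir, "node_ages.tsv"), sep="\t", index=False)
    state["fit"], state["swamp_reps"] = fit, swamp_reps
    rate_ky = fit.rate
    report["clock"] = {
        "rate_per_site_per_ky": rate_ky,
        "rate_se": fit.rate_se,
        "site_count": site_count,
        "site_unit": config.site_unit,
        "loglik": fit.loglik,
        "ingroup_mrca_ky": float(ages["T_ky"].iloc[0]),
        "ingroup_mrca_se_ky": float(ages["SE_ky"].iloc[0]),
        "waiting_time_ky": clock_dating.waiting_time(rate_ky, site_count)
        if rate_ky > 0 else None,
    }


def _stage_skyline(config, state, report) -> None:
    if "fit" not in state:
        _stage_date(config, state, report)
    mrca = state["tree"].mrca(state["swamp_reps"])
    subtree = parsimony_tree.PhyloTree(mrca)
    gen = skyline.genealogy_from_tree(subtree)
    traj = skyline.run_skyline_mcmc(
        gen,
        m_groups=min(config.skyline_groups, gen.n_tips - 1),
        iters=config.skyline_iters,
        thin=config.skyline_thin,
        seed=config.seed,
        generation_time=config.generation_time,
    )
    traj.to_tsv(os.path.join(config.out_dir, "skyline.tsv"))
    try:
        traj.plot(os.path.join(config.out_dir, "skyline.png"))
    except Exception:  # plotting is best-effort
        logger.warning("skyline plot could not be written")
    report["skyline"] = {
        "n_tips": gen.n_tips,
        "tmrca_years": gen.span,
        "ess": traj.ess,
        "converged": traj.converged,
        "present_median_Nef": float(traj.median_Nef[0]),
    }


_STAGE_FN = {
    "collapse": _stage_collapse,
    "diversity": _stage_diversity,
    "mask": _stage_mask,
    "tree": _stage_tree,
    "date": _stage_date,
    "skyline": _stage_skyline,
}
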