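"""Stage orchestration: ingest -> non-clock run -> clock-rate prior ->
clock run -> hypothesis comparison -> ASR -> biogeography ->
morphometrics, driven by one configuration.

Stages communicate only through files in a run directory (no hidden
state), so any stage can be re-run, or swapped for outputs produced
elsewhere.  Every stage writes a ``provenance.json`` embedding the
configuration hash, seed and package version; a completed stage is a
no-op on re-run unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characters import (CombinedDataset, read_molecular_nexus,
                         read_morph_nexus, read_taxon_metadata,
                         recode_ordered_polymorphisms, write_morph_nexus,
                         write_taxon_metadata)
from .mcmc import (InferenceModel, RunConfig, diagnose, run_mcmcmc,
                   summarize_allcompat)
from .treemodel import TimeTree, derive_clock_rate_prior, study_calibrations

logger = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "nonclock", "clockprior", "clock",
          "compare", "asr", "biogeo", "morpho", "report")


class PipelineError(RuntimeError):
    pass


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path) -> dict:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return json.load(fh)


def _stage_dir(outdir, stage) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _write_provenance(stage_dir: Path, cfg: dict, stage: str, seed) -> None:
    (stage_dir / "provenance.json").write_text(json.dumps({
        "stage": stage, "config_hash": config_hash(cfg), "seed": seed,
        "version": __version__}, indent=1))


def _provenance_ok(stage_dir: Path, cfg: dict) -> bool:
    p = stage_dir / "provenance.json"
    if not p.exists():
        return False
    try:
        return json.loads(p.read_text())["config_hash"] == config_hash(cfg)
    except Exception:
        return False


def validate_provenance_chain(outdir, cfg: dict) -> dict:
    """Check every completed stage's recorded config hash against the
    current configuration."""
    out = {}
    for stage in STAGES:
        p = Path(outdir) / stage / "provenance.json"
        if p.exists():
            rec = json.loads(p.read_text())
            out[stage] = rec["config_hash"] == config_hash(cfg)
            if not out[stage]:
                logger.warning("stage %s provenance mismatch", stage)
    return out


def _require(outdir, stage, filename) -> Path:
    p = Path(outdir) / stage / filename
    if not p.exists():
        raise PipelineError(
            f"missing dependency {p}; run the '{stage}' stage first")
    return p


def _seed_for(cfg, stage) -> int:
    base = int(cfg.get("seed", 0))
    return int(np.random.SeedSequence(
        [base, STAGES.index(stage)]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Stage implementations


def _load_dataset(outdir, cfg) -> CombinedDataset:
    from .characters import concatenate
    ing = Path(outdir) / "ingest"
    morph = read_morph_nexus(_require(outdir, "ingest", "morph.nex"),
                             sidecar=str(ing / "morph_ordering.json"))
    taxa = read_taxon_metadata(_require(outdir, "ingest", "taxa.csv"))
    mol = None
    if (ing / "dna.nex").exists():
        mol = read_molecular_nexus(ing / "dna.nex")
    constraints = [(c["label"], frozenset(c["taxa"]))
                   for c in cfg.get("constraints", [])]
    return concatenate(morph, mol, taxa, constraints)


def stage_simulate(cfg, outdir, seed):
    from .simulate import SimulationConfig, simulate_dataset
    sd = _stage_dir(outdir, "simulate")
    scfg = SimulationConfig(seed=seed, **cfg.get("simulate", {}))
    data, tree, truth = simulate_dataset(scfg)
    write_morph_nexus(data.morph, sd / "morph.nex",
                      sd / "morph_ordering.json")
    write_taxon_metadata(data.taxa, sd / "taxa.csv")
    if data.mol is not None:
        _write_dna_nexus(data.mol, sd / "dna.nex")
    (sd / "true_tree.nwk").write_text(tree.to_newick() + "\n")
    truth = {k: v for k, v in truth.items() if k != "node_areas"} | {
        "node_areas": {"|".join(sorted(c)): a
                       for c, a in truth["node_areas"].items()}}
    (sd / "truth.json").write_text(json.dumps(truth, default=str, indent=1))
    return {"n_taxa": len(data.taxa)}


def _write_dna_nexus(mol, path):
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={mol.n_taxa} NCHAR={mol.n_sites};\n")
        fh.write("FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n")
        code = np.array(list("ACGT?"))
        for i, t in enumerate(mol.taxa):
            fh.write(f"{t}  {''.join(code[mol.sites[i]])}\n")
        fh.write(";\nEND;\n")


def stage_ingest(cfg, outdir, seed):
    sd = _stage_dir(outdir, "ingest")
    src = cfg.get("inputs", {})
    sim = Path(outdir) / "simulate"
    paths = {
        "morph.nex": src.get("morph", sim / "morph.nex"),
        "morph_ordering.json": src.get("ordering",
                                       sim / "morph_ordering.json"),
        "taxa.csv": src.get("taxa", sim / "taxa.csv"),
    }
    if src.get("dna") or (sim / "dna.nex").exists():
        paths["dna.nex"] = src.get("dna", sim / "dna.nex")
    for dest, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise PipelineError(f"input {p} not found; run 'simulate' or "
                                "point [inputs] at your data")
        (sd / dest).write_text(p.read_text())
    morph = read_morph_nexus(sd / "morph.nex",
                             sidecar=str(sd / "morph_ordering.json"))
    recoded = recode_ordered_polymorphisms(morph)
    write_morph_nexus(recoded, sd / "morph.nex", sd / "morph_ordering.json")
    data = _load_dataset(outdir, cfg)
    summary = {"n_taxa": len(data.taxa), "n_chars": data.morph.n_chars,
               "n_sites": data.mol.n_sites if data.mol else 0,
               "n_partitions": data.n_partitions,
               "n_recoded": int(recoded.recoded_flags.sum())}
    (sd / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _run_cfg(cfg, section, seed) -> RunConfig:
    c = dict(cfg.get(section, {}))
    c.setdefault("n_generations", 2000)
    c.setdefault("n_chains", 2)
    c.setdefault("sample_every", 20)
    return RunConfig(seed=seed, **c)


def _save_mcmc(sd, result, burnin_frac=0.25):
    for i, run in enumerate(result.runs):
        run.params.to_csv(sd / f"trace_run{i}.tsv", sep="\t", index=False)
    rep = diagnose(result)
    (sd / "diagnostics.json").write_text(
        json.dumps(rep.to_dict(), indent=1, default=float))
    trees = result.pooled_trees(burnin_frac)
    summary, support = summarize_allcompat(trees)
    (sd / "allcompat.nwk").write_text(summary.to_newick() + "\n")
    (sd / "support.json").write_text(json.dumps(
        {"|".join(sorted(c)): round(f, 4) for c, f in support.items()},
        indent=1))
    ages = {"root": summary.root.age}
    (sd / "summary.json").write_text(json.dumps({
        "root_age_mean": summary.root.age,
        "min_ess": rep.min_ess, "asdsf": rep.asdsf}, indent=1,
        default=float))
    return summary, rep


def stage_nonclock(cfg, outdir, seed):
    sd = _stage_dir(outdir, "nonclock")
    data = _load_dataset(outdir, cfg)
    model = InferenceModel(tree_prior="uniform",
                           morph_ascertainment="variable",
                           rho=float(cfg.get("rho", 1.0)))
    result = run_mcmcmc(data, model, _run_cfg(cfg, "nonclock", seed))
    summary, rep = _save_mcmc(sd, result)
    # mean substitution-unit root-to-tip path length per tip
    rows = {}
    for run in result.runs:
        n = len(run.trees)
        for tree, (_, prow) in zip(run.trees[n // 4:],
                                   run.params.iloc[n // 4:].iterrows()):
            rate = prow["clock_rate"]
            for tip in tree.tips:
                d, node = 0.0, tip
                while node.parent is not None:
                    d += (node.parent.age - node.age) * node.rate * rate
                    node = node.parent
                rows.setdefault(tip.name, []).append(d)
    pd.DataFrame({"name": list(rows),
                  "path_length": [float(np.mean(v)) for v in rows.values()]
                  }).to_csv(sd / "pathlengths.csv", index=False)
    return {"root_age": summary.root.age}


def stage_clockprior(cfg, outdir, seed):
    sd = _stage_dir(outdir, "clockprior")
    pl = pd.read_csv(_require(outdir, "nonclock", "pathlengths.csv"))
    taxa = read_taxon_metadata(_require(outdir, "ingest", "taxa.csv"))
    tip_ages = {t.name: (0.0 if t.extant else t.midpoint_age) for t in taxa}
    root_age = cfg.get("root_age_estimate")
    if root_age is None:
        root_age = max([t.age_window[1] for t in taxa if not t.extant]
                       + [1.0]) * 1.3
    fit = derive_clock_rate_prior(
        dict(zip(pl["name"], pl["path_length"])), tip_ages, float(root_age))
    fit.bic_table().to_csv(sd / "bic_table.tsv", sep="\t", index=False)
    (sd / "clock_prior.json").write_text(json.dumps({
        "best": fit.best, "params": fit.best_params,
        "root_age": float(root_age)}, indent=1))
    return {"best": fit.best}


def stage_clock(cfg, outdir, seed):
    sd = _stage_dir(outdir, "clock")
    data = _load_dataset(outdir, cfg)
    prior_file = Path(outdir) / "clockprior" / "clock_prior.json"
    clock_prior = ("exponential", 1.0)
    if prior_file.exists():
        cp = json.loads(prior_file.read_text())
        if cp["best"] == "lognormal":
            clock_prior = ("lognormal", cp["params"]["log_mean"],
                           cp["params"]["log_sd"])
    elif "clock_rate_prior" not in cfg:
        raise PipelineError("clock stage needs the clockprior stage or an "
                            "explicit clock_rate_prior in the config")
    if "clock_rate_prior" in cfg:
        clock_prior = tuple(cfg["clock_rate_prior"])
    calibrations = None
    if cfg.get("calibrations") == "study":
        prim = frozenset(cfg["primates_taxa"])
        eua = frozenset(cfg["euarchonta_taxa"])
        calibrations = study_calibrations(prim, eua)
    model = InferenceModel(tree_prior="fbd", rho=float(cfg.get("rho", 1.0)),
                           clock_rate_prior=clock_prior,
                           calibrations=calibrations)
    result = run_mcmcmc(data, model, _run_cfg(cfg, "clock", seed))
    summary, rep = _save_mcmc(sd, result)
    return {"root_age": summary.root.age, "asdsf": rep.asdsf}


def stage_compare(cfg, outdir, seed):
    from .comparison import (build_hypothesis_constraints, comparison_table,
                             stepping_stone_lnML)
    sd = _stage_dir(outdir, "compare")
    data = _load_dataset(outdir, cfg)
    tree = TimeTree.from_newick(
        _require(outdir, "clock", "allcompat.nwk").read_text())
    hcfg = cfg.get("hypotheses", {})
    focals = hcfg.get("focal_taxa", [])
    if not focals:
        (sd / "comparison.tsv").write_text("")
        return {"skipped": "no focal taxa configured"}
    reference = hcfg["reference_taxon"]
    crown = hcfg["crown_clade"]
    hypotheses = hcfg.get("list", ["H1", "H2"])
    backbone = tree.prune_taxa(focals)
    focal_ages = {f: data.record(f).midpoint_age for f in focals}
    morph_only = CombinedDataset(morph=data.morph, mol=None,
                                 taxa=data.taxa, constraints=[])
    model = InferenceModel(tree_prior="uniform", sample_topology=True,
                           relaxed_clock=False)
    estimates = {}
    sscfg = cfg.get("stepping_stone", {})
    for h in hypotheses:
        cons = build_hypothesis_constraints(backbone, h, focals, reference,
                                            crown)
        estimates[h] = stepping_stone_lnML(
            morph_only, model, cons, backbone, focal_ages,
            n_steps=int(sscfg.get("n_steps", 10)),
            samples_per_step=int(sscfg.get("samples_per_step", 200)),
            seed=seed + ["H1", "H2", "H3", "H4"].index(h))
    table = comparison_table(estimates)
    table.to_csv(sd / "comparison.tsv", sep="\t", index=False)
    (sd / "comparison.json").write_text(table.to_json(orient="records"))
    return {"hypotheses": hypotheses}


def stage_asr(cfg, outdir, seed):
    from .asr import (asr_morphology, call_best_states, count_branch_changes,
                      scored_characters)
    sd = _stage_dir(outdir, "asr")
    data = _load_dataset(outdir, cfg)
    tree = TimeTree.from_newick(
        _require(outdir, "clock", "allcompat.nwk").read_text())
    focals = cfg.get("hypotheses", {}).get("focal_taxa",
                                           tree.tip_names()[:1])
    chars = scored_characters(data.morph, [f for f in focals
                                           if f in data.morph.taxa])
    bl = tree.durations()
    probs = asr_morphology(tree, data.morph, bl, characters=chars)
    calls = {node: call_best_states(
        np.vstack([probs[node][j] for j in chars]))
        for node in probs}
    rows = []
    for node in probs:
        if node.parent is None or node.parent not in probs:
            continue
        n_changes = count_branch_changes(calls[node.parent], calls[node])
        clade = tree.clade_names(node)
        rows.append({"clade": "|".join(sorted(clade)[:4]),
                     "clade_size": len(clade),
                     "n_changes": n_changes})
    pd.DataFrame(rows).to_csv(sd / "branch_changes.tsv", sep="\t",
                              index=False)
    (sd / "summary.json").write_text(json.dumps(
        {"n_characters": int(len(chars))}, indent=1))
    return {"n_characters": int(len(chars))}


def stage_biogeo(cfg, outdir, seed):
    from .asr import areas_to_newick, asr_biogeography
    sd = _stage_dir(outdir, "biogeo")
    taxa = read_taxon_metadata(_require(outdir, "ingest", "taxa.csv"))
    tree = TimeTree.from_newick(
        _require(outdir, "clock", "allcompat.nwk").read_text())
    areas = {t.name: t.area for t in taxa if t.area}
    if not areas:
        (sd / "areas.tsv").write_text("")
        return {"skipped": "no area codings"}
    probs = asr_biogeography(tree, areas)
    from .characters import AREAS
    rows = []
    for clade, p in probs.items():
        best = int(np.argmax(p))
        rows.append({"clade_size": len(clade),
                     "clade": "|".join(sorted(clade)[:4]),
                     "best_area": AREAS[best],
                     "probability": float(p[best])})
    pd.DataFrame(rows).sort_values("clade_size").to_csv(
        sd / "areas.tsv", sep="\t", index=False)
    (sd / "areas.nwk").write_text(areas_to_newick(tree, probs) + "\n")
    return {"n_nodes": len(rows)}


def stage_morpho(cfg, outdir, seed):
    from .morphometrics import flag_outliers, morphometrics_pipeline
    sd = _stage_dir(outdir, "morpho")
    mcfg = dict(cfg.get("morpho", {}))
    mesh_paths = mcfg.pop("meshes", None)
    if mesh_paths:
        import trimesh
        meshes = [trimesh.load(p) for p in mesh_paths]
        labels = mcfg.pop("labels", list(range(len(meshes))))
    else:
        from .simulate import generate_tooth_meshes
        meshes, labels = generate_tooth_meshes(
            n_classes=int(mcfg.pop("n_classes", 2)),
            n_per_class=int(mcfg.pop("n_per_class", 6)),
            deformation=float(mcfg.pop("deformation", 0.15)),
            noise_sd=float(mcfg.pop("noise_sd", 0.01)), seed=seed)
    space, dist = morphometrics_pipeline(
        meshes, n_initial=int(mcfg.get("n_initial", 100)),
        n_final=int(mcfg.get("n_final", 200)), seed=seed)
    scores = pd.DataFrame(space.scores[:, :10],
                          columns=[f"PC{i+1}" for i in
                                   range(min(10, space.scores.shape[1]))])
    scores.insert(0, "label", list(labels))
    scores["outlier"] = flag_outliers(space.scores[:, :5], labels)
    scores.to_csv(sd / "scores.csv", index=False)
    space.scree_table().to_csv(sd / "scree.tsv", sep="\t", index=False)
    return {"pc1_variance": float(space.variance_fractions[0])}


def stage_report(cfg, outdir, seed):
    sd = _stage_dir(outdir, "report")
    lines = ["# Pipeline report", ""]
    clock = Path(outdir) / "clock" / "summary.json"
    if clock.exists():
        s = json.loads(clock.read_text())
        lines += ["## Dated tree",
                  f"- mean root age: {s['root_age_mean']:.2f} Ma",
                  f"- ASDSF: {s['asdsf']:.4f}, minESS: {s['min_ess']:.1f}",
                  ""]
    comp = Path(outdir) / "compare" / "comparison.tsv"
    if comp.exists() and comp.read_text().strip():
        lines += ["## Hypothesis comparison", "",
                  comp.read_text(), ""]
    else:
        lines += ["## Hypothesis comparison", "(not run)", ""]
    for stage, fname, title in [("asr", "branch_changes.tsv",
                                 "Character changes per branch"),
                                ("biogeo", "areas.tsv",
                                 "Biogeographic reconstruction"),
                                ("morpho", "scree.tsv",
                                 "Morphometric variance")]:
        p = Path(outdir) / stage / fname
        if p.exists() and p.read_text().strip():
            lines += [f"## {title}", "", p.read_text(), ""]
    chain = {k: v for k, v in
             validate_provenance_chain(outdir, cfg).items()
             if k != "report"}
    lines += ["## Provenance", "",
              "\n".join(f"- {k}: {'ok' if v else 'MISMATCH'}"
                        for k, v in chain.items()), ""]
    (sd / "report.md").write_text("\n".join(lines))
    return {"stages": list(chain)}


_STAGE_FN = {
    "simulate": stage_simulate, "ingest": stage_ingest,
    "nonclock": stage_nonclock, "clockprior": stage_clockprior,
    "clock": stage_clock, "compare": stage_compare, "asr": stage_asr,
    "biogeo": stage_biogeo, "morpho": stage_morpho, "report": stage_report,
}


def run_stage(cfg: dict, stage: str, outdir, force: bool = False) -> dict:
    """Run one pipeline stage; no-op when already complete for this
    configuration unless ``force``."""
    if stage not in _STAGE_FN:
        raise PipelineError(f"unknown stage {stage!r}; "
                            f"expected one of {STAGES}")
    sd = _stage_dir(outdir, stage)
    if not force and _provenance_ok(sd, cfg) and stage != "report":
        logger.info("stage %s already complete (config hash matches)", stage)
        return {"cached": True}
    seed = _seed_for(cfg, stage)
    out = _STAGE_FN[stage](cfg, outdir, seed)
    _write_provenance(sd, cfg, stage, seed)
    logger.info("stage %s: %s", stage, out)
    return out
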