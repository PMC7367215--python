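"""End-to-end orchestration from a YAML config with a run manifest.

Stages run in dependency order: simulate cohort → local AF panel →
ancestry (PCA, supervised admixture, representative selection, IBS/NJ
tree) → per-representative WGS VCFs → prioritization → QC and the share
partition → array concordance → SV intersection. Any stage failure aborts
with the stage name. Re-running with an identical config and seed
reproduces byte-identical outputs, and the manifest records a sha256 per
output (paths stored relative to the output directory so manifests from
identical runs hash identically).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__, ancestry, concordance, prioritize, qc, simulate, svmerge
from ._random import substream
from .cohort_af import build_panel


class ConfigError(ValueError):
    """Config failed validation before any stage ran."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


_RANGES = {
    ("cohort", "fst"): (0.0, 1.0, "open"),
    ("cohort", "missing_rate"): (0.0, 1.0, "half"),
    ("cohort", "known_fraction"): (0.0, 1.0, "closed"),
    ("cohort_af", "min_call_rate"): (0.0, 1.0, "closed"),
    ("wgs", "indel_fraction"): (0.0, 1.0, "closed"),
    ("wgs", "discordance_rate"): (0.0, 1.0, "half"),
    ("sv", "ro_min"): (0.0, 1.0, "closed"),
    ("sv", "db_fraction"): (0.0, 1.0, "closed"),
}


@dataclass
class RunConfig:
    raw: dict[str, Any]
    outdir: Path

    def section(self, name: str) -> dict[str, Any]:
        return dict(self.raw.get(name) or {})

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    def validate(self) -> None:
        for (sec, key), (lo, hi, kind) in _RANGES.items():
            val = self.section(sec).get(key)
            if val is None:
                continue
            ok = {
                "open": lo < val < hi,
                "half": lo <= val < hi,
                "closed": lo <= val <= hi,
            }[kind]
            if not ok:
                raise ConfigError(f"{sec}.{key}={val} outside its valid range")
        z = self.section("prioritize")
        if z.get("strong_z", 4.0) < z.get("weak_z", 1.96):
            raise ConfigError("prioritize.strong_z must be >= weak_z")
        for key, path in self.section("inputs").items():
            if path and not Path(path).exists():
                raise ConfigError(f"inputs.{key}: missing file {path}")


def load_config(path: str | Path, outdir: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(raw=raw, outdir=Path(outdir))
    cfg.validate()
    return cfg


def demo_config(outdir: str | Path) -> RunConfig:
    """The bundled laptop-scale demo configuration."""
    text = resources.files("popaf").joinpath("data/demo.yaml").read_text()
    cfg = RunConfig(raw=yaml.safe_load(text), outdir=Path(outdir))
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class _Manifest:
    outdir: Path
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, params: dict, outputs: list[Path]) -> None:
        self.stages.append({
            "name": name,
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p) for p in outputs},
        })


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the run manifest."""
    config.validate()
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    state: dict[str, Any] = {}

    def _stage(name: str, fn) -> None:
        try:
            params, outputs = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc
        manifest.add(name, params, outputs)

    _stage("simulate_cohort", lambda: _run_simulate(config, out, state))
    _stage("cohort_af", lambda: _run_cohort_af(config, out, state))
    _stage("reference_panels", lambda: _run_panels(config, out, state))
    _stage("ancestry", lambda: _run_ancestry(config, out, state))
    _stage("sample_vcfs", lambda: _run_vcfs(config, out, state))
    _stage("prioritize", lambda: _run_prioritize(config, out, state))
    _stage("qc", lambda: _run_qc(config, out, state))
    _stage("concordance", lambda: _run_concordance(config, out, state))
    _stage("svmerge", lambda: _run_svmerge(config, out, state))

    doc = {
        "popaf_version": __version__,
        "seed": config.seed,
        "config": config.raw,
        "stages": manifest.stages,
    }
    (out / "manifest.json").write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


# ------------------------------------------------------------------- stages

def _run_simulate(config: RunConfig, out: Path, state: dict):
    sec = config.section("cohort")
    alpha = sec.get("dirichlet_alpha")
    spec = simulate.CohortSpec(
        n_samples=int(sec.get("n_samples", 200)),
        n_loci=int(sec.get("n_loci", 20_000)),
        n_pops=int(sec.get("n_pops", 3)),
        fst=float(sec.get("fst", 0.1)),
        dirichlet_alpha=tuple(alpha) if alpha else None,
        missing_rate=float(sec.get("missing_rate", 0.01)),
        known_fraction=float(sec.get("known_fraction", 0.9725)),
        seed=config.seed,
    )
    gm, truth = simulate.simulate_cohort(spec)
    state["gm"], state["truth"] = gm, truth
    path = out / "cohort_genotypes.tsv"
    gm.to_tsv(path)
    return {"spec": sec, "seed": config.seed}, [path]


def _run_cohort_af(config: RunConfig, out: Path, state: dict):
    sec = config.section("cohort_af")
    rate = float(sec.get("min_call_rate", 0.95))
    panel = build_panel(state["gm"], sec.get("population", "LOCAL"), min_call_rate=rate)
    state["local_panel"] = panel
    tsv = out / "local_af.tsv"
    vcf = out / "local_af.sites.vcf"
    panel.to_tsv(tsv)
    panel.to_sites_vcf(vcf)
    return {"min_call_rate": rate, "n_loci": len(panel)}, [tsv, vcf]


def _run_panels(config: RunConfig, out: Path, state: dict):
    n_ref = int(config.section("panels").get("n_ref", 5000))
    panels = simulate.emit_reference_panels(state["truth"], n_ref=n_ref,
                                            out_dir=out / "ref_panels")
    state["ref_panels"] = panels
    files = sorted((out / "ref_panels").glob("*.tsv"))
    return {"n_ref": n_ref, "populations": list(panels)}, files


def _run_ancestry(config: RunConfig, out: Path, state: dict):
    sec = config.section("ancestry")
    gm, truth = state["gm"], state["truth"]
    d = int(sec.get("d", 2))
    model = ancestry.fit_pca(gm, d=d)
    coords = model.reference_coords
    m_sub = min(int(sec.get("admix_loci", 4000)), gm.n_loci)
    sub = np.sort(substream(config.seed, "pipeline", "admix_subsample").choice(
        gm.n_loci, size=m_sub, replace=False))
    f_full = ancestry.panel_F(list(state["ref_panels"].values()))
    q_hat = ancestry.supervised_admixture_batch(gm.genotypes[:, sub], f_full[:, sub])
    groups = [state["truth"].pop_names[k] for k in q_hat.argmax(axis=1)]
    reps = ancestry.select_representatives(coords, q_hat, groups, gm.sample_ids)
    state["q_hat"], state["reps"] = q_hat, reps
    state["rep_indices"] = [gm.sample_ids.index(r.sample_id) for r in reps.values()]

    coords_path = out / "pca_coords.tsv"
    import pandas as pd

    pd.DataFrame(coords, index=gm.sample_ids,
                 columns=[f"PC{i + 1}" for i in range(d)]).to_csv(coords_path, sep="\t")
    q_path = out / "admixture_q.tsv"
    pd.DataFrame(q_hat, index=gm.sample_ids, columns=truth.pop_names).to_csv(q_path, sep="\t")
    reps_path = out / "representatives.json"
    ancestry.representatives_json(reps, reps_path)

    n_tree = min(int(sec.get("tree_samples", 30)), gm.n_samples)
    pick = list(dict.fromkeys(
        state["rep_indices"]
        + list(substream(config.seed, "pipeline", "tree_subset").choice(
            gm.n_samples, size=n_tree, replace=False))
    ))[:n_tree]
    pick.sort()
    dmat = ancestry.ibs_distance(gm.genotypes[pick])
    tree = ancestry.neighbor_joining(dmat, [gm.sample_ids[i] for i in pick])
    tree_path = out / "ibs_nj.nwk"
    tree.to_newick_file(tree_path)
    return ({"d": d, "admix_loci": m_sub, "tree_samples": len(pick),
             "representatives": {g: r.sample_id for g, r in reps.items()}},
            [coords_path, q_path, reps_path, tree_path])


def _run_vcfs(config: RunConfig, out: Path, state: dict):
    sec = config.section("wgs")
    truth = state["truth"]
    vcf_dir = out / "wgs"
    vcf_dir.mkdir(exist_ok=True)
    samples = []
    paths = []
    for idx in state["rep_indices"]:
        sv = simulate.emit_sample_vcf(
            truth, idx, vcf_dir / f"S{idx + 1:04d}.vcf",
            extra_loci=int(sec.get("extra_loci", 2000)),
            indel_fraction=float(sec.get("indel_fraction", 0.2)),
            discordance_rate=float(sec.get("discordance_rate", 0.002)),
        )
        samples.append(sv)
        paths.append(sv.path)
    state["sample_vcfs"] = samples
    known_path = out / "known_sites.tsv"
    state["known"] = simulate.known_sites(truth, samples, out=known_path)
    patho_path = out / "pathogenicity.tsv"
    rates = simulate.PathoRates(**config.section("patho")) if config.section("patho") \
        else simulate.PathoRates()
    state["patho"] = simulate.emit_pathogenicity_table(
        truth.loci, rates=rates, seed=config.seed, out=patho_path)
    return ({"n_samples": len(samples), **sec}, paths + [known_path, patho_path])


def _run_prioritize(config: RunConfig, out: Path, state: dict):
    sec = config.section("prioritize")
    refs = list(state["ref_panels"].values())
    outputs = []
    summaries = {}
    for sv in state["sample_vcfs"]:
        annot_path = out / "wgs" / f"{sv.sample_id}.annot.vcf"
        variants = prioritize.annotate_vcf(
            sv.path, state["local_panel"], refs,
            patho=state["patho"], known_sites=state["known"], out=annot_path,
            mode=sec.get("mode", "global"),
            default_ref_an=float(sec.get("default_ref_an", prioritize.DEFAULT_REF_AN)),
            strong=float(sec.get("strong_z", 4.0)), weak=float(sec.get("weak_z", 1.96)),
        )
        summary = prioritize.summarize(variants,
                                       strong=float(sec.get("strong_z", 4.0)),
                                       weak=float(sec.get("weak_z", 1.96)))
        tsv = out / f"priority_{sv.sample_id}.tsv"
        summary.to_tsv(tsv)
        jpath = out / f"priority_{sv.sample_id}.json"
        summary.to_json(jpath)
        summaries[sv.sample_id] = summary
        outputs += [annot_path, tsv, jpath]
    state["summaries"] = summaries
    return dict(sec), outputs


def _run_qc(config: RunConfig, out: Path, state: dict):
    outputs = []
    for sv in state["sample_vcfs"]:
        rep = qc.sample_qc(sv.path, known_sites=state["known"])
        path = out / f"qc_{sv.sample_id}.json"
        rep.to_json(path)
        outputs.append(path)
    part = qc.share_partition([sv.path for sv in state["sample_vcfs"]],
                              [sv.sample_id for sv in state["sample_vcfs"]])
    part_path = out / "share_partition.tsv"
    part.to_tsv(part_path)
    state["share"] = part
    return {"n_samples": len(state["sample_vcfs"])}, outputs + [part_path]


def _run_concordance(config: RunConfig, out: Path, state: dict):
    gm = state["gm"]
    outputs = []
    for idx, sv in zip(state["rep_indices"], state["sample_vcfs"]):
        rep = concordance.concordance(gm, idx, sv.path)
        path = out / f"concordance_{sv.sample_id}.json"
        rep.to_json(path)
        outputs.append(path)
    return {}, outputs


def _run_svmerge(config: RunConfig, out: Path, state: dict):
    sec = config.section("sv")
    sim = simulate.simulate_sv_callsets(
        n_true=int(sec.get("n_true", 200)),
        genome_len=int(sec.get("genome_len", 10_000_000)),
        jitter_sd=float(sec.get("jitter_sd", 20.0)),
        sens_a=float(sec.get("sens_a", 0.9)),
        sens_b=float(sec.get("sens_b", 0.8)),
        db_fraction=float(sec.get("db_fraction", 0.865)),
        seed=config.seed,
    )
    calls_a = svmerge._calls_from_frame(sim.caller_a)
    calls_b = svmerge._calls_from_frame(sim.caller_b)
    db = svmerge._calls_from_frame(sim.database)
    ro = float(sec.get("ro_min", 0.5))
    merged = svmerge.intersect_callers(calls_a, calls_b, ro_min=ro)
    tallies = svmerge.classify_novelty(merged, db, ro_min=ro)
    tsv = out / "sv_merged.tsv"
    svmerge.write_sv_tsv(merged, tsv)
    jpath = out / "sv_summary.json"
    svmerge.summary_json(merged, tallies, jpath)
    vcf = out / "sv_merged.vcf"
    svmerge.write_sv_vcf(merged, vcf)
    return dict(sec), [tsv, jpath, vcf]
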