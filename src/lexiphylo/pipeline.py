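"""End-to-end orchestration: validate -> infer x runs -> combine -> summaries
-> innovations -> topology test -> contact, driven by one declarative config.

The config is a YAML mapping; see ``docs/methods.md`` for the schema.  Every
stage writes its outputs under ``output_dir`` and registers them (with SHA256
checksums) in ``manifest.json``, so a rerun with the same config and seed
reproduces identical files.  Downstream stages are gated on the effective
sample size of the combined run (default threshold 200) unless ``force``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import cognate_data as cd
from .contact import read_trait_table, weighted_mean_rates, fitch_asr, \
    transition_report
from .covarion import PriorConfig
from .innovations import innovation_posterior, list_innovations
from .mcmc import ChainConfig, MonophylyConstraint, PosteriorSample, \
    combine_runs, ess, run_chain
from .simulate import SimulationConfig, simulate_dataset
from .topology_test import discriminating_cognates, relative_likelihood_table
from .tree_summaries import majority_consensus, mcc_tree
from .trees import write_nexus_trees

__all__ = ["run_pipeline", "EssBelowThresholdError", "load_config"]

ESS_PARAMS = ("posterior", "clock_mean", "root_age")


class EssBelowThresholdError(RuntimeError):
    """Convergence gate failed; rerun longer or pass force=True."""


def load_config(path: str) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _constraints(entries) -> list[MonophylyConstraint]:
    out = []
    for e in entries or []:
        out.append(MonophylyConstraint(taxa=frozenset(e["taxa"]),
                                       polarity=e.get("polarity", "must_be_clade")))
    return out


def _chain_config(config: dict, seed: int) -> ChainConfig:
    return ChainConfig(
        generations=int(config.get("generations", 200_000)),
        sample_every=int(config.get("sample_every", 200)),
        seed=seed,
        burnin_fraction=float(config.get("burnin_fraction", 0.1)),
    )


def run_pipeline(config: dict[str, Any] | str,
                 output_dir: Optional[str] = None) -> dict[str, Any]:
    """Execute all configured stages; returns the manifest dictionary."""
    if isinstance(config, str):
        config = load_config(config)
    outdir = Path(output_dir or config.get("output_dir", "lexiphylo_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 1))
    n_runs = int(config.get("runs", 3))
    manifest: dict[str, Any] = {"seed": master_seed, "stages": [],
                                "config": {k: v for k, v in config.items()}}

    def register(stage: str, files: dict[str, Path], t0: float,
                 extra: Optional[dict] = None) -> None:
        manifest["stages"].append({
            "stage": stage,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in files.items()},
            **(extra or {}),
        })

    # ---------------------------------------------------------- stage: data
    t0 = time.perf_counter()
    data_cfg = config.get("data", {})
    trait_map = None
    if "simulate" in data_cfg:
        sim_kwargs = dict(data_cfg["simulate"])
        sim_kwargs.setdefault("seed", master_seed)
        if isinstance(sim_kwargs.get("covarion"), dict):
            from .covarion import CovarionParams
            sim_kwargs["covarion"] = CovarionParams(**sim_kwargs["covarion"])
        if "negrito_tips" in sim_kwargs:
            sim_kwargs["negrito_tips"] = frozenset(sim_kwargs["negrito_tips"])
        if "innovation_clades" in sim_kwargs:
            sim_kwargs["innovation_clades"] = tuple(
                (frozenset(clade), label)
                for clade, label in sim_kwargs["innovation_clades"])
        sim = simulate_dataset(SimulationConfig(**sim_kwargs))
        matrix = sim.matrix
        truth_path = outdir / "true_tree.nwk"
        truth_path.write_text(sim.tree.newick() + "\n", encoding="utf-8")
        data_path = outdir / "data.nex"
        cd.write_cognate_matrix(matrix, str(data_path))
        register("validate", {"data": data_path, "true_tree": truth_path}, t0,
                 {"n_doculects": matrix.n_doculects,
                  "n_cognates": matrix.n_cognates,
                  "n_meanings": matrix.n_meanings})
    else:
        data_path = Path(data_cfg["path"])
        matrix = cd.read_cognate_matrix(
            str(data_path), data_cfg.get("format", "nexus_binary"))
        if data_cfg.get("drop_subcognates", True):
            matrix = matrix.drop_subcognates()
        min_cog = int(data_cfg.get("min_cognates_per_doculect", 0))
        if min_cog:
            matrix, _ = matrix.filter_doculects(min_cog)
        register("validate", {"data": data_path}, t0,
                 {"n_doculects": matrix.n_doculects,
                  "n_cognates": matrix.n_cognates,
                  "n_meanings": matrix.n_meanings})

    scheme = cd.partition_by_meaning_size(
        matrix, int(config.get("partition_bin_width", 10)))
    priors = PriorConfig(**config.get("priors", {}))
    constraints = _constraints(config.get("constraints"))

    # --------------------------------------------------------- stage: infer
    runs: list[PosteriorSample] = []
    for k in range(n_runs):
        t0 = time.perf_counter()
        run_seed = master_seed + 1000 * (k + 1)  # fixed offsets per run
        sample = run_chain(matrix=matrix, scheme=scheme, priors=priors,
                           constraints=constraints,
                           config=_chain_config(config, run_seed))
        trace = outdir / f"run{k + 1}.trace.tsv"
        trees = outdir / f"run{k + 1}.trees.nex"
        sample.write_trace(str(trace))
        write_nexus_trees(sample.trees, str(trees))
        runs.append(sample)
        register(f"infer_run{k + 1}", {"trace": trace, "trees": trees}, t0,
                 {"seed": run_seed})

    # ------------------------------------------------------- stage: combine
    t0 = time.perf_counter()
    burnin = float(config.get("burnin_fraction", 0.1))
    combined = combine_runs(runs, burnin)
    trace = outdir / "combined.trace.tsv"
    combined.write_trace(str(trace))
    ess_values = {p: ess(combined.params[p].to_numpy()) for p in ESS_PARAMS}
    register("combine", {"trace": trace}, t0,
             {"n_runs": len(runs), "n_samples": len(combined),
              "ess": {k: round(v, 1) for k, v in ess_values.items()}})
    threshold = float(config.get("ess_threshold", 200))
    if min(ess_values.values()) < threshold and not config.get("force", False):
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str), encoding="utf-8")
        raise EssBelowThresholdError(
            f"ESS {ess_values} below threshold {threshold}; "
            "increase generations or set force: true")

    # ----------------------------------------------------- stage: summarize
    t0 = time.perf_counter()
    consensus = majority_consensus(combined.trees)
    mcc = mcc_tree(combined.trees)
    cons_path = outdir / "consensus.nwk"
    mcc_path = outdir / "mcc.nwk"
    cons_path.write_text(consensus.newick(annotate_rates=False) + "\n",
                         encoding="utf-8")
    mcc_path.write_text(mcc.newick() + "\n", encoding="utf-8")
    register("summarize", {"consensus": cons_path, "mcc": mcc_path}, t0)

    # --------------------------------------------------- stage: innovations
    if "innovations" in config:
        t0 = time.perf_counter()
        clade = frozenset(config["innovations"]["clade"])
        rng = np.random.default_rng(master_seed + 77)
        table = innovation_posterior(combined, matrix, clade, rng, scheme)
        listed = list_innovations(
            table, float(config["innovations"].get("threshold", 0.5)))
        path = outdir / "innovations.tsv"
        frame = table.probabilities.rename("innovation_pp").to_frame()
        frame["listed"] = frame.index.isin(listed.index)
        frame.to_csv(path, sep="\t")
        register("innovations", {"table": path}, t0,
                 {"n_listed": int(len(listed)),
                  "monophyly_fraction": table.monophyly_fraction})

    # ------------------------------------------------------ stage: topotest
    if "topotest" in config:
        t0 = time.perf_counter()
        tt = config["topotest"]
        traces = {}
        for label in ("a", "b"):
            cons = constraints + _constraints([tt[f"constraint_{label}"]])
            sub_runs = []
            for k in range(n_runs):
                run_seed = master_seed + 1000 * (k + 1) + (7 if label == "a" else 13)
                sub_runs.append(run_chain(
                    matrix=matrix, scheme=scheme, priors=priors,
                    constraints=cons, config=_chain_config(config, run_seed)))
            traces[label] = combine_runs(sub_runs, burnin).per_cognate
        table = discriminating_cognates(traces["a"], traces["b"],
                                        float(tt.get("mass", 0.5)))
        rel = relative_likelihood_table(traces["a"], traces["b"],
                                       float(tt.get("mass", 0.5)))
        path = outdir / "topotest.tsv"
        rel_path = outdir / "topotest_relative.tsv"
        table.to_csv(path, sep="\t", index=False)
        rel.to_csv(rel_path, sep="\t", index=False)
        register("topotest", {"table": path, "relative": rel_path}, t0,
                 {"n_support_a": int((table["support"] == "A").sum()),
                  "n_support_b": int((table["support"] == "B").sum())})

    # ------------------------------------------------------- stage: contact
    if "contact" in config:
        t0 = time.perf_counter()
        cc = config["contact"]
        if "trait_file" in cc:
            trait_map = read_trait_table(cc["trait_file"])
        else:
            trait_map = {d: ("negrito" if flag else "background")
                         for d, flag in cc["trait"].items()}
        asr, n_changes = fitch_asr(mcc, trait_map)
        transitions = transition_report(mcc, asr)
        rates = weighted_mean_rates(combined, trait_map)
        tr_path = outdir / "transitions.tsv"
        with open(tr_path, "w", encoding="utf-8") as fh:
            fh.write("min_age\tmax_age\tlanguages\n")
            for tr in transitions:
                fh.write(f"{tr.min_age:.1f}\t{tr.max_age:.1f}\t"
                         f"{', '.join(tr.descendants)}\n")
        rates_path = outdir / "category_rates.tsv"
        rates.to_csv(rates_path, sep="\t", index=False)
        register("contact", {"transitions": tr_path, "rates": rates_path}, t0,
                 {"n_transitions": len(transitions),
                  "n_changes": n_changes,
                  "p_transition_gt_background":
                       rates.attrs["p_transition_gt_background"]})

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str),
                             encoding="utf-8")
    return manifest
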