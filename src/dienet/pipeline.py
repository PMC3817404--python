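"""End-to-end orchestration: simulate → score → call → confirm → project.

``run_pipeline`` executes the whole analysis on a synthetic screen family
described by a YAML/dict config with planted ground truth, writing every
intermediate table plus a recovery report and a manifest of SHA-256
checksums. Reruns with an identical config are bit-identical (no
timestamps enter any output).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import competition as comp
from . import conservation as cons
from . import differential as diff
from . import io as dio
from . import scoring, signatures, simulate
from .errors import ConfigError

__all__ = ["load_config", "run_pipeline"]

DEFAULTS = {
    "alpha": 0.05,
    "B": 200,
    "n_perm": 1999,
    "presence_method": "mixture",
    "competition_level": 0.80,
    "orthology_f": 0.9,
    "max_competition_pairs": 200,
}


def load_config(path) -> dict:
    """Load and minimally validate a pipeline YAML config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return _fill_defaults(cfg)


def _fill_defaults(cfg: dict) -> dict:
    out = dict(DEFAULTS)
    out.update(cfg)
    if "simulate" not in out:
        raise ConfigError("config needs a 'simulate' section (ScreenSimConfig fields)")
    if "seed" not in out["simulate"]:
        raise ConfigError("simulate.seed is mandatory")
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full synthetic-screen pipeline and write all outputs.

    Stages: simulate screens and expression → per-line GARP/zGARP scoring
    → per-query dGARP calls with the expression presence filter → network
    assembly → competition-assay confirmation → orthology projection →
    high-confidence network → signature classification of a simulated
    cell-line panel → recovery report against the planted truth.

    Returns the report dict (also written as ``report.json``).
    """
    config = _fill_defaults(dict(config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.ScreenSimConfig(**config["simulate"])
    seed = int(sim_cfg.seed)
    alpha, B = float(config["alpha"]), int(config["B"])

    # --- simulate ---------------------------------------------------------
    screen = simulate.generate_screen(sim_cfg)
    expression, presence_truth = simulate.generate_expression(sim_cfg, screen.truth)
    dio.write_hairpin_map(screen.hairpin_map, outdir / "hairpins.tsv")
    if sim_cfg.noise_model == "multinomial":
        dio.write_count_table(screen.counts, outdir / "counts.tsv")
    dio.write_expression_table(expression, outdir / "expression.tsv")

    # --- score each line --------------------------------------------------
    normalized = scoring.normalize_counts(screen.counts)
    tables, sharps = {}, {}
    for i, line in enumerate(sim_cfg.lines):
        table, sharp = scoring.score_screen(
            screen.counts, screen.hairpin_map, line, B=B, seed=seed + 1000 + i
        )
        tables[line], sharps[line] = table, sharp
        dio.write_score_table(table, outdir / f"scores_{line}.tsv")
    qc = scoring.replicate_correlation(normalized)
    qc.to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)

    # --- differential calls per query --------------------------------------
    presence = diff.expression_presence(expression, method=config["presence_method"])
    all_records = []
    for i, query in enumerate(sim_cfg.queries):
        dgarp = diff.compute_dgarp(
            tables[query]["zgarp"], tables[simulate.PARENTAL]["zgarp"]
        )
        pvals = diff.dgarp_pvalues(
            sharps[query], sharps[simulate.PARENTAL], screen.hairpin_map,
            B=B, seed=seed + 2000 + i,
        )
        records = diff.call_ssl(
            dgarp, pvals.loc[dgarp.index],
            presence.loc[dgarp.index, query], query, alpha=alpha,
        )
        all_records.append(records)
        records.to_csv(outdir / f"records_{query}.tsv", sep="\t", index=False)

    network = diff.assemble_network(all_records)
    dio.write_edge_list(network.edges, outdir / "network.tsv")
    dio.write_sif(network.edges, outdir / "network.sif")

    # --- competition confirmation ------------------------------------------
    ssl_pairs = list(zip(network.edges["gene"], network.edges["query"]))
    ssl_pairs = ssl_pairs[: int(config["max_competition_pairs"])]
    confirmed_set: set = set()
    if ssl_pairs:
        comp_cfg = simulate.CompetitionSimConfig(pairs=ssl_pairs, seed=seed + 3000)
        wells = simulate.generate_competition(comp_cfg, screen.truth)
        wells.to_csv(outdir / "competition_wells.tsv", sep="\t", index=False)
        fitness, conf_rate = comp.score_competition(
            wells, level=float(config["competition_level"])
        )
        fitness.to_csv(outdir / "competition_fitness.tsv", sep="\t", index=False)
        confirmed_set = set(
            zip(fitness.loc[fitness["confirmed"], "query"],
                fitness.loc[fitness["confirmed"], "gene"])
        )
    else:
        conf_rate = float("nan")

    # --- conservation -------------------------------------------------------
    planted_pairs = [
        (q, g) for q in sim_cfg.queries for g in screen.truth.ssl_genes(q)
    ]
    conserved_set: set = set()
    if planted_pairs:
        orth_cfg = simulate.OrthologySimConfig(
            conserved_pairs=planted_pairs, seed=seed + 4000
        )
        groups, sims, gi = simulate.generate_orthology(orth_cfg)
        omap = cons.build_ortholog_map(
            groups, sims, mode="most_probable", f=float(config["orthology_f"])
        )
        preds, _rep = cons.project_interactions(
            pd.concat(all_records, ignore_index=True), omap, gi
        )
        nonred = cons.deduplicate_conserved(preds)
        nonred.to_csv(outdir / "conserved.tsv", sep="\t", index=False)
        edge_keys = set(zip(network.edges["query"], network.edges["gene"]))
        conserved_set = set(zip(nonred["query"], nonred["gene"])) & edge_keys
    hc = cons.merge_confidence(network, confirmed_set, conserved_set)
    dio.write_edge_list(hc.edges, outdir / "network_high_confidence.tsv")

    # --- signature classification -------------------------------------------
    records_all = pd.concat(all_records, ignore_index=True)
    query1 = sim_cfg.queries[0]
    profile = signatures.build_die_profile(records_all, query1, alpha=alpha)
    dio.write_gmt({f"DiE_{query1}": profile}, outdir / "profiles.gmt")
    panel_p = None
    if profile:
        panel_cfg = simulate.PanelSimConfig(seed=seed + 5000)
        universe = list(screen.truth.gene_class.index)
        ess_sets, labels = simulate.generate_cell_line_panel(
            panel_cfg, profile, universe
        )
        jacc, panel_p = signatures.classify_panel(
            profile, ess_sets, labels, n_perm=int(config["n_perm"]),
            seed=seed + 5001,
        )
        pd.DataFrame({"jaccard": jacc, "label": labels}).to_csv(
            outdir / "panel_jaccard.tsv", sep="\t"
        )

    # --- recovery report ------------------------------------------------------
    report = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_high_confidence_edges": hc.n_edges,
        "confirmation_rate_pct": conf_rate,
        "panel_mean_shift_p": panel_p,
        "per_query": {},
    }
    for query in sim_cfg.queries:
        truth_set = set(screen.truth.ssl_genes(query))
        called = set(
            records_all.loc[
                (records_all["query"] == query) & records_all["ssl_call"], "gene"
            ]
        )
        tp = len(called & truth_set)
        report["per_query"][query] = {
            "planted": len(truth_set),
            "called": len(called),
            "recall": tp / len(truth_set) if truth_set else None,
            "fdp": (len(called) - tp) / len(called) if called else 0.0,
        }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    manifest = {
        "config": config,
        "screen_config": asdict(sim_cfg),
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return report
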