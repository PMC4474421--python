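"""End-to-end discovery and validation runs with file outputs.

``run_discovery`` wires the network stages together: read the
compound-regulator and regulator-enzyme edge layers, filter the compound
layer, merge, rank regulator hub clusters and predict signed
compound-enzyme interactions.  ``run_validation`` computes, per
(cell line, gene) dataset, the relative fold-change table, the one-way
ANOVA and the Tukey HSD pairwise table.

Both are deterministic: identical inputs and configuration produce
byte-identical output files.  A JSON manifest echoing the configuration
and package version is written alongside the results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ArgumentError
from .io import read_interactions, write_network
from .network import (
    FilterConfig,
    build_network,
    filter_network,
    find_clusters,
    merge_networks,
    network_summary,
    predict_interactions,
)
from .qpcr import fold_change, read_expression
from .stats import anova_oneway, tukey_hsd


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run."""

    out_dir: str
    compound_regulator_edges: str | None = None
    regulator_enzyme_edges: str | None = None
    roles: str | None = None
    expression: str | None = None
    dialect: str = "tsv"
    min_compound_edges: int = 3
    drop_orphan_regulators: bool = True
    iterate_to_fixpoint: bool = False
    max_depth: int = 10
    fc_method: str = "ddct"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ArgumentError(f"alpha must be in (0, 1), got {self.alpha}")


def _write_manifest(cfg: RunConfig, out: Path, stage: str) -> None:
    manifest = {"stage": stage, "cypnet_version": __version__, "config": asdict(cfg)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_discovery(cfg: RunConfig) -> dict:
    """Build -> filter -> merge -> clusters -> predict; write TSV reports.

    Writes ``predictions.tsv``, ``clusters.tsv``, ``summary.tsv``,
    ``merged_network.sif`` and ``manifest.json`` to ``cfg.out_dir`` and
    returns the in-memory results.
    """
    if not (cfg.compound_regulator_edges and cfg.regulator_enzyme_edges and cfg.roles):
        raise ArgumentError(
            "discovery needs compound_regulator_edges, regulator_enzyme_edges "
            "and roles paths"
        )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cr_table = read_interactions(
        cfg.compound_regulator_edges, dialect=cfg.dialect, roles_path=cfg.roles
    )
    re_table = read_interactions(
        cfg.regulator_enzyme_edges, dialect=cfg.dialect, roles_path=cfg.roles
    )
    cr_net = build_network(cr_table, {"compound"}, {"regulator"})
    re_net = build_network(re_table, {"regulator"}, {"enzyme"})
    cr_net = filter_network(
        cr_net,
        FilterConfig(
            min_compound_edges=cfg.min_compound_edges,
            drop_orphan_regulators=cfg.drop_orphan_regulators,
            iterate_to_fixpoint=cfg.iterate_to_fixpoint,
        ),
    )
    merged = merge_networks(cr_net, re_net)
    clusters = find_clusters(merged)
    predictions = predict_interactions(merged, max_depth=cfg.max_depth)
    summary = network_summary(merged)

    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "hub": c.hub_id,
                "size": c.size,
                "compounds": ",".join(sorted(c.member_compound_ids)),
            }
            for c in clusters
        ],
        columns=["hub", "size", "compounds"],
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame([summary]).to_csv(out / "summary.tsv", sep="\t", index=False)
    write_network(merged, out / "merged_network.sif", dialect="sif")
    _write_manifest(cfg, out, "discovery")
    return {
        "network": merged,
        "clusters": clusters,
        "predictions": predictions,
        "summary": summary,
    }


def run_validation(cfg: RunConfig) -> dict:
    """Fold change + ANOVA + Tukey HSD per (cell line, gene) dataset.

    Writes ``anova.tsv`` (one row per dataset: F, degrees of freedom, p —
    full precision plus a 4-decimal rendering), ``fold_change.tsv``,
    ``tukey.tsv`` and ``manifest.json`` to ``cfg.out_dir``.
    """
    if not cfg.expression:
        raise ArgumentError("validation needs an expression file path")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    datasets = read_expression(cfg.expression)
    anova_rows, fc_rows, tukey_rows, results = [], [], [], {}
    for ds in datasets:
        fc = fold_change(ds, method=cfg.fc_method)
        anova = anova_oneway(fc)
        tukey = tukey_hsd(fc, alpha=cfg.alpha)
        results[(ds.cell_line, ds.gene)] = {
            "fold_change": fc,
            "anova": anova,
            "tukey": tukey,
        }
        anova_rows.append(
            {
                "cell_line": ds.cell_line,
                "gene": ds.gene,
                "F": anova.F,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p": anova.p,
                "F_4dp": f"{anova.F:.4f}",
                "p_4dp": f"{anova.p:.4f}",
            }
        )
        for _, row in fc.per_dose.iterrows():
            fc_rows.append(
                {"cell_line": ds.cell_line, "gene": ds.gene, **row.to_dict()}
            )
        for comp in tukey.comparisons:
            tukey_rows.append(
                {
                    "cell_line": ds.cell_line,
                    "gene": ds.gene,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "mean_difference": comp.mean_difference,
                    "q": comp.q,
                    "p_adjusted": comp.p_adjusted,
                    "significant": comp.significant,
                }
            )

    pd.DataFrame(anova_rows).to_csv(out / "anova.tsv", sep="\t", index=False)
    pd.DataFrame(fc_rows).to_csv(out / "fold_change.tsv", sep="\t", index=False)
    pd.DataFrame(tukey_rows).to_csv(out / "tukey.tsv", sep="\t", index=False)
    _write_manifest(cfg, out, "validation")
    return results
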