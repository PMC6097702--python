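"""End-to-end orchestration of the co-activation network analysis.

One call runs correlations -> thresholding (all p-levels) -> component
census -> small-world assessment -> centralities -> hub identification ->
stable hubs -> permutation centrality comparison -> edge comparison ->
behavior statistics, and writes every report as CSV with a manifest of
content hashes. One global seed expands into independent per-stage seed
streams, so disabling a stage never perturbs the others, and rerunning
with the same config, inputs and seed reproduces every artifact hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import centrality as ct
from . import edges as ed
from . import io as cio
from . import topology as tp
from .datatypes import AnalysisConfig, BehaviorTable, ExpressionMatrix
from .network import (
    CorrelationResult,
    ThresholdedNetwork,
    component_census,
    drop_regions,
    pearson_matrix,
    threshold,
)

__all__ = ["PipelineRun", "run_full", "matched_control_label"]


def matched_control_label(control: str) -> str:
    """Label of the control network restricted to the lesioned node set."""
    return f"{control}-nH"


@dataclass
class PipelineRun:
    """Outputs of one full analysis: artifact paths, hashes and a stage log."""

    config: AnalysisConfig
    outdir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    networks: dict[tuple[str, float], ThresholdedNetwork] = field(default_factory=dict)
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)
    hubsets: dict[tuple[str, float], set[str]] = field(default_factory=dict)
    stable_hubs: dict[str, set[str]] = field(default_factory=dict)

    def record(self, name: str, path: Path) -> None:
        self.artifacts[name] = path
        self.manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        payload = {
            "config": {
                "thresholds": list(self.config.thresholds),
                "n_resamples": self.config.n_resamples,
                "rng_seed": self.config.rng_seed,
                "hub_quantile": self.config.hub_quantile,
                "hub_min_metrics": self.config.hub_min_metrics,
                "z_cutoff": self.config.z_cutoff,
            },
            # file names only: the manifest must hash identically wherever
            # the output directory lives
            "artifacts": {k: v.name for k, v in self.artifacts.items()},
            "sha256": self.manifest,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _behavior_stats(
    table: BehaviorTable,
    n_resamples: int,
    rng_seed: int,
) -> pd.DataFrame:
    """F, pairwise t, KS and Cohen's d for one behavior table, one row per test."""
    labels = list(dict.fromkeys(table.df["group"]))
    samples = {g: table.sample(g) for g in labels}
    rows = []
    f_emp, f_p = bh.bootstrap_p(
        bh.f_statistic, [samples[g] for g in labels], n_resamples, rng_seed
    )
    rows.append(
        {
            "comparison": "all-groups",
            "statistic": "F",
            "value": f_emp,
            "p": f_p,
            "p_corrected": f_p,
            "method": "bootstrap one-way ANOVA",
        }
    )
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    for res in bh.pairwise_t_bootstrap(table, pairs, n_resamples, rng_seed):
        rows.append(
            {
                "comparison": f"{res.groups[0]} vs {res.groups[1]}",
                "statistic": "t",
                "value": res.value,
                "p": res.p,
                "p_corrected": res.p_corrected,
                "method": f"bootstrap Welch t, {res.correction}",
            }
        )
    for ga, gb in pairs:
        d_stat, d_p = bh.ks_two_sample(samples[ga], samples[gb])
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "statistic": "D",
                "value": d_stat,
                "p": d_p,
                "p_corrected": d_p,
                "method": "two-sample KS (asymptotic)",
            }
        )
        rows.append(
            {
                "comparison": f"{ga} vs {gb}",
                "statistic": "d",
                "value": bh.cohens_d(samples[ga], samples[gb]),
                "p": np.nan,
                "p_corrected": np.nan,
                "method": "Cohen's d (pooled SD)",
            }
        )
    return pd.DataFrame(rows)


def run_full(
    config: AnalysisConfig,
    expr_control: ExpressionMatrix,
    expr_lesion: ExpressionMatrix,
    behavior_tables: dict[str, BehaviorTable] | None = None,
    outdir: str | Path = "coactnet_out",
    n_nets_smallworld: int | None = None,
    n_permutations: int | None = None,
) -> PipelineRun:
    """Run the complete analysis for a control and a lesioned expression matrix.

    The control matrix is analyzed on its full region set and, in parallel,
    restricted to the lesioned group's node set (the matched-control
    network) for all direct comparisons. ``n_nets_smallworld`` and
    ``n_permutations`` default to ``config.n_resamples``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=config, outdir=outdir)
    n_nets = n_nets_smallworld or config.n_resamples
    n_perm = n_permutations or config.n_resamples

    control = expr_control.group_labels()[0]
    lesion = expr_lesion.group_labels()[0]
    matched = matched_control_label(control)

    # stage: correlations ------------------------------------------------
    expr_matched = drop_regions(expr_control)
    if set(expr_matched.regions) != set(expr_lesion.regions):
        expr_matched = expr_control.restrict(expr_lesion.regions)
    exprs = {control: expr_control, matched: expr_matched, lesion: expr_lesion}
    for label, expr in exprs.items():
        run.correlations[label] = pearson_matrix(expr)
        run.log.append(
            f"correlations[{label}]: {run.correlations[label].n_pairs} coefficients "
            f"from n={run.correlations[label].n} subjects"
        )

    # stage: thresholding and component census ---------------------------
    census_rows = []
    for label, corr in run.correlations.items():
        for level in config.thresholds:
            net = threshold(corr, level)
            run.networks[(label, level)] = net
            cc = component_census(net)
            census_rows.append(
                {
                    "network": label,
                    "level": level,
                    "n_nodes": net.n_nodes,
                    "n_edges": net.n_edges,
                    "n_components": cc.n_components,
                    "component_sizes": ";".join(map(str, cc.component_sizes)),
                    "n_isolates": cc.n_isolates,
                }
            )
            run.log.append(
                f"network[{label}@{level}]: {net.n_edges} edges, "
                f"{cc.n_components} components, {cc.n_isolates} isolates"
            )
            cio.write_network(
                net, outdir / f"network_{label}_p{level}.csv", format="edgelist"
            )
            run.record(
                f"network_{label}_p{level}", outdir / f"network_{label}_p{level}.csv"
            )
    census = pd.DataFrame(census_rows)
    census.to_csv(outdir / "network_census.csv", index=False)
    run.record("network_census", outdir / "network_census.csv")

    # per-stage independent seed streams
    seed_root = np.random.SeedSequence(config.rng_seed)
    sw_seed, perm_seed, behav_seed = seed_root.spawn(3)

    # stage: small-world assessment --------------------------------------
    ensembles: dict[str, tp.NullEnsemble] = {}
    streams = sw_seed.spawn(len(run.networks))
    for ((label, level), net), stream in zip(run.networks.items(), streams):
        ensembles[f"{label}@{level}"] = tp.rewire_null(
            net, n_nets=n_nets, rng_seed=np.random.default_rng(stream)
        )
    summary, comparisons = tp.smallworld_assessment(ensembles)
    summary.to_csv(outdir / "smallworld_summary.csv", index=False)
    comparisons.to_csv(outdir / "smallworld_comparisons.csv", index=False)
    run.record("smallworld_summary", outdir / "smallworld_summary.csv")
    run.record("smallworld_comparisons", outdir / "smallworld_comparisons.csv")
    for row in summary.itertuples(index=False):
        run.log.append(
            f"smallworld[{row.network}]: Leff ratio CI "
            f"[{row.leff_ci_lo:.3f}, {row.leff_ci_hi:.3f}], "
            f"small_world={row.small_world}"
        )

    # stage: centralities and hubs ---------------------------------------
    cent_rows = []
    for (label, level), net in run.networks.items():
        table = ct.centralities(net)
        run.hubsets[(label, level)] = ct.identify_hubs(
            table, config.hub_quantile, config.hub_min_metrics
        )
        for region in table.index:
            cent_rows.append(
                {
                    "network": label,
                    "level": level,
                    "region": region,
                    **{m: table.loc[region, m] for m in ct.METRICS},
                    "hub": region in run.hubsets[(label, level)],
                }
            )
    pd.DataFrame(cent_rows).to_csv(outdir / "centralities.csv", index=False)
    run.record("centralities", outdir / "centralities.csv")

    hub_rows = []
    for label in exprs:
        hubset = ct.stable_hubs(
            {level: run.hubsets[(label, level)] for level in config.thresholds}
        )
        run.stable_hubs[label] = hubset.stable
        run.log.append(f"stable_hubs[{label}]: {sorted(hubset.stable)}")
        for region, score in sorted(hubset.hub_score.items()):
            hub_rows.append(
                {
                    "network": label,
                    "region": region,
                    **{
                        f"hub_at_{level}": region in run.hubsets[(label, level)]
                        for level in config.thresholds
                    },
                    "hub_score": score,
                    "stable_hub": region in hubset.stable,
                }
            )
    pd.DataFrame(hub_rows).to_csv(outdir / "hubs.csv", index=False)
    run.record("hubs", outdir / "hubs.csv")

    # stage: permutation centrality comparison (matched control vs lesion)
    perm_frames = []
    for level, stream in zip(config.thresholds, perm_seed.spawn(len(config.thresholds))):
        result = ct.permutation_centrality_test(
            expr_matched,
            expr_lesion,
            level=level,
            n_permutations=n_perm,
            rng_seed=np.random.default_rng(stream),
        )
        frame = result.to_frame()
        frame.insert(0, "level", level)
        perm_frames.append(frame)
        n_sig = int((frame["p"] < 0.05).sum())
        run.log.append(
            f"permutation[{matched} vs {lesion}@{level}]: "
            f"{n_sig} significant (p<0.05) region-metric cells"
        )
    pd.concat(perm_frames).to_csv(outdir / "centrality_comparison.csv", index=False)
    run.record("centrality_comparison", outdir / "centrality_comparison.csv")

    # stage: edge comparison ----------------------------------------------
    edge_frames = []
    summary_rows = []
    for level in config.thresholds:
        netA = run.networks[(matched, level)]
        netB = run.networks[(lesion, level)]
        result = ed.edge_diff_zscores(
            netA,
            netB,
            z_cutoff=config.z_cutoff,
            labels=(matched, lesion),
        )
        counts = ed.classify_significant(
            result,
            run.hubsets[(matched, level)],
            run.hubsets[(lesion, level)],
            labels=(matched, lesion),
        )
        frame = result.cells.copy()
        frame.insert(0, "level", level)
        edge_frames.append(frame)
        summary_rows.append(
            {
                "level": level,
                "ks_D": result.ks_D,
                "ks_p": result.ks_p,
                **counts,
            }
        )
        run.log.append(
            f"edges[{matched} vs {lesion}@{level}]: KS D={result.ks_D:.4f} "
            f"(p={result.ks_p:.4f}); {counts['total']} significant cells, "
            f"{counts['owned_' + matched]} owned by {matched}"
        )
    pd.concat(edge_frames).to_csv(outdir / "edge_comparison.csv", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "edge_comparison_summary.csv", index=False)
    run.record("edge_comparison", outdir / "edge_comparison.csv")
    run.record("edge_comparison_summary", outdir / "edge_comparison_summary.csv")

    # stage: behavior statistics ------------------------------------------
    if behavior_tables:
        streams = behav_seed.spawn(len(behavior_tables))
        for (name, table), stream in zip(behavior_tables.items(), streams):
            seed = int(stream.generate_state(1)[0] % (2**31))
            stats_table = _behavior_stats(table, config.n_resamples, seed)
            stats_table.insert(0, "experiment", name)
            stats_table.to_csv(outdir / f"behavior_{name}.csv", index=False)
            run.record(f"behavior_{name}", outdir / f"behavior_{name}.csv")
            f_row = stats_table[stats_table["statistic"] == "F"].iloc[0]
            run.log.append(
                f"behavior[{name}]: F={f_row['value']:.3f} (bootstrap p={f_row['p']:.4f})"
            )

    run.write_manifest()
    run.record("manifest", outdir / "manifest.json")
    (outdir / "run.log").write_text("\n".join(run.log) + "\n")
    return run
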