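"""End-to-end analysis pipeline and its configuration.

Stage order mirrors the reference workflow: per-sample normalization ->
log2 -> PCA outlier screen -> univariate screen (t-test, BH at the
external total-test count, volcano selection, annotated subset) ->
autoscale -> PLS-DA with LOO cross-validation and permutation test ->
sparse local graphical model on annotated features -> seed-node module
extraction -> optional over-representation analysis -> clustered
z-score matrix for heatmap plotting.  Every artifact is a plain-text
table; a run log records each stage's input/output dimensions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from . import enrichment as enr
from . import io as uio
from . import network as netmod
from . import plsda as plsmod
from . import preprocess as prep
from . import univariate as uni
from .univariate import Thresholds

__all__ = ["PlsdaConfig", "NetworkConfig", "AnalysisConfig", "RunLog", "run_pipeline"]


@dataclass(frozen=True)
class PlsdaConfig:
    n_components: int = 3
    B: int = 2000
    feature_subset: str = "volcano_annotated"  # or "annotated", "all"

    def __post_init__(self):
        if self.feature_subset not in ("volcano_annotated", "annotated", "all"):
            raise ValueError(f"unknown feature_subset {self.feature_subset!r}")


@dataclass(frozen=True)
class NetworkConfig:
    lambda_method: str = "bic"
    symmetrize: str = "or"
    features: str = "annotated"  # or "all"
    module_seeds: tuple = ()
    module_mode: str = "component"


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one run needs; serializable to/from YAML."""

    input: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    outdir: str = "uromet_out"
    seed: int = 0
    normalization: str = "ones"
    pca_components: int = 2
    pca_alpha: float = 0.025
    thresholds: Thresholds = field(default_factory=Thresholds)
    plsda: PlsdaConfig = field(default_factory=PlsdaConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        def build(dc, data, where):
            names = {f.name: f for f in dataclasses.fields(dc)}
            unknown = set(data) - set(names)
            if unknown:
                raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
            kwargs = {}
            for key, val in data.items():
                ftype = names[key].type
                if key == "thresholds":
                    kwargs[key] = build(Thresholds, val or {}, key)
                elif key == "plsda":
                    kwargs[key] = build(PlsdaConfig, val or {}, key)
                elif key == "network":
                    if isinstance(val, dict) and "module_seeds" in val:
                        val = {**val, "module_seeds": tuple(val["module_seeds"] or ())}
                    kwargs[key] = build(NetworkConfig, val or {}, key)
                else:
                    kwargs[key] = val
            return dc(**kwargs)

        return build(cls, raw, "top level")

    def to_yaml(self, path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        with open(path, "w") as fh:
            yaml.safe_dump(plain(self), fh, sort_keys=False)


class RunLog:
    """Append-only log of pipeline stages with ISO timestamps."""

    def __init__(self, seed=None):
        self.records = []
        self.seed = seed

    def add(self, stage: str, message: str, n_samples=None, n_features=None):
        self.records.append(
            {
                "time": datetime.now(timezone.utc).isoformat(),
                "stage": stage,
                "message": message,
                "n_samples": n_samples,
                "n_features": n_features,
            }
        )

    def write(self, path):
        with open(path, "w") as fh:
            if self.seed is not None:
                fh.write(f"# seed: {self.seed}\n")
            for r in self.records:
                dims = ""
                if r["n_samples"] is not None:
                    dims = f" [{r['n_samples']} samples x {r['n_features']} features]"
                fh.write(f"{r['time']}\t{r['stage']}\t{r['message']}{dims}\n")


def _heatmap_export(M_log2, selected_ids, outdir):
    """Z-score the selected features and order rows/columns by average-
    linkage Euclidean hierarchical clustering; write matrix + orders."""
    idx = [M_log2.feature_ids.index(f) for f in selected_ids]
    sub = M_log2.select_features(idx)
    z = (sub.values - sub.values.mean(axis=0)) / sub.values.std(axis=0, ddof=1)
    row_order = np.arange(z.shape[0])
    col_order = np.arange(z.shape[1])
    if z.shape[0] > 2:
        row_order = leaves_list(average(pdist(z)))
    if z.shape[1] > 2:
        col_order = leaves_list(average(pdist(z.T)))
    zdf = pd.DataFrame(
        z[np.ix_(row_order, col_order)],
        index=[sub.sample_ids[i] for i in row_order],
        columns=[sub.feature_ids[j] for j in col_order],
    )
    zdf.index.name = "sample_id"
    zdf.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    pd.DataFrame(
        {"sample_id": zdf.index, "group": sub.y[row_order]}
    ).to_csv(outdir / "heatmap_row_order.tsv", sep="\t", index=False)
    pd.DataFrame({"feature_id": zdf.columns}).to_csv(
        outdir / "heatmap_col_order.tsv", sep="\t", index=False
    )


def run_pipeline(config: AnalysisConfig, matrix=None) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    ``matrix`` may be passed directly (an :class:`AbundanceMatrix`);
    otherwise ``config.input``/``config.metadata`` are read.  All
    artifacts land in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(seed=config.seed)

    if matrix is None:
        if config.input is None:
            raise ValueError("config.input required when no matrix is passed")
        matrix = uio.read_abundance(config.input, config.metadata)
    log.add("load", "input matrix", matrix.n_samples, matrix.n_features)

    M = prep.normalize_per_sample(matrix, config.normalization)
    log.add("normalize", f"policy={config.normalization}", M.n_samples, M.n_features)

    M_log2 = prep.log2_transform(M)
    M_log2, outliers = prep.pca_outlier_exclude(
        M_log2, n_components=config.pca_components, alpha=config.pca_alpha
    )
    keep = [s in set(M_log2.sample_ids) for s in M.sample_ids]
    M = M.select_samples(np.array(keep))
    pd.DataFrame(
        {
            "sample_id": list(matrix.sample_ids),
            "score_distance": outliers.score_distances,
            "excluded": [s in outliers.excluded_sample_ids for s in matrix.sample_ids],
        }
    ).to_csv(outdir / "outlier_report.tsv", sep="\t", index=False)
    log.add(
        "pca_exclude",
        f"excluded {len(outliers.excluded_sample_ids)} sample(s) "
        f"at alpha={config.pca_alpha}",
        M.n_samples,
        M.n_features,
    )

    thresholds = config.thresholds
    if thresholds.m_total is None:
        thresholds = dataclasses.replace(thresholds, m_total=M.n_features)
    results = uni.differential_analysis(M, thresholds)
    results.to_csv(outdir / "univariate.tsv", sep="\t", index=False)
    n_sel = int(results["selected"].sum())
    annotated = uni.annotated_subset(results)
    n_sel_known = int(annotated["selected"].sum())
    log.add(
        "univariate",
        f"{n_sel} volcano-selected ({n_sel_known} annotated), "
        f"m_total={thresholds.m_total}",
        M.n_samples,
        M.n_features,
    )

    # ---- PLS-DA on the configured feature subset ----------------------
    if config.plsda.feature_subset == "all":
        sel_ids = list(results["feature_id"])
    elif config.plsda.feature_subset == "annotated":
        sel_ids = list(annotated["feature_id"])
    else:
        sel_ids = list(annotated.loc[annotated["selected"], "feature_id"])
    perm = None
    loo_preds, loo_acc = None, None
    if len(sel_ids) >= 2:
        idx = [M_log2.feature_ids.index(f) for f in sel_ids]
        X = M_log2.select_features(idx).values
        k = min(config.plsda.n_components, len(sel_ids), M_log2.n_samples - 2)
        model = plsmod.fit_plsda(X, M_log2.y, n_components=k, scale=True)
        scores = pd.DataFrame(
            model.x_scores,
            index=list(M_log2.sample_ids),
            columns=[f"comp_{a + 1}" for a in range(k)],
        )
        scores.insert(0, "group", M_log2.y)
        scores.index.name = "sample_id"
        scores.to_csv(outdir / "plsda_scores.tsv", sep="\t")
        pd.DataFrame(
            model.x_loadings,
            index=sel_ids,
            columns=[f"comp_{a + 1}" for a in range(k)],
        ).rename_axis("feature_id").to_csv(outdir / "plsda_loadings.tsv", sep="\t")

        loo_preds, loo_acc = plsmod.loo_cv(X, M_log2.y, n_components=k)
        perm = plsmod.permutation_test(
            X, M_log2.y, n_components=k, B=config.plsda.B, seed=config.seed
        )
        pd.DataFrame({"permuted_stat": perm.permuted_stats}).to_csv(
            outdir / "plsda_permutations.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            {
                "observed_stat": [perm.observed_stat],
                "p_value": [perm.p_value],
                "B": [perm.B],
                "loo_accuracy": [loo_acc],
            }
        ).to_csv(outdir / "plsda_summary.tsv", sep="\t", index=False)
        log.add(
            "plsda",
            f"{k} components on {len(sel_ids)} features; "
            f"LOO accuracy {loo_acc:.3f}; permutation p {perm.p_value:.4g}",
            M_log2.n_samples,
            len(sel_ids),
        )
        _heatmap_export(M_log2, sel_ids, outdir)
    else:
        log.add("plsda", "skipped: fewer than 2 features in subset")

    # ---- sparse local graphical model ---------------------------------
    if config.network.features == "all":
        net_mask = np.ones(M_log2.n_features, dtype=bool)
    else:
        net_mask = M_log2.known_mask
    net = None
    modules = {}
    if net_mask.sum() >= 2 and M_log2.n_samples >= 10:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            M_net = prep.autoscale(M_log2.select_features(net_mask))
        net = netmod.build_networks(
            M_net.values,
            M_net.y,
            M_net.feature_ids,
            symmetrize=config.network.symmetrize,
            lambda_method=config.network.lambda_method,
            seed=config.seed,
        )
        rows = [(a, b, "common", w) for a, b, w in net.common_edges] + [
            (a, b, "diff", w) for a, b, w in net.diff_edges
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "layer", "weight"]).to_csv(
            outdir / "network_edges.tsv", sep="\t", index=False
        )
        netmod.export_network(net, "sif", outdir / "network.sif")
        netmod.export_network(net, "graphml", outdir / "network.graphml")
        log.add(
            "network",
            f"{len(net.common_edges)} common, {len(net.diff_edges)} differential edges",
            M_net.n_samples,
            M_net.n_features,
        )

        upreg = dict(
            zip(results["feature_id"], results["selected"] & (results["fold_change"] > 1))
        )
        for seed_node in config.network.module_seeds:
            mod = netmod.extract_module(
                net, seed_node, mode=config.network.module_mode, upregulated=upreg
            )
            modules[seed_node] = mod
            safe = seed_node.replace(" ", "_").replace("/", "_")
            netmod.export_network(mod, "sif", outdir / f"module_{safe}.sif")
            log.add("module", f"seed {seed_node}: {len(mod.nodes)} nodes")
    else:
        log.add("network", "skipped: too few annotated features or samples")

    # ---- enrichment ----------------------------------------------------
    ora_results = None
    if config.gmt is not None and net is not None:
        library = enr.read_gmt(config.gmt)
        universe = [f for f, m in zip(M_log2.feature_ids, net_mask) if m]
        if modules:
            query = sorted({n for mod in modules.values() for n in mod.nodes})
        else:
            query = [f for f in annotated.loc[annotated["selected"], "feature_id"]]
        query = [q for q in query if q in set(universe)]
        ora_results = enr.ora(query, universe, library)
        ora_results.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        log.add("enrichment", f"{len(ora_results)} sets tested on {len(query)} metabolites")

    log.write(outdir / "run_log.txt")
    return {
        "matrix": M,
        "outliers": outliers,
        "univariate": results,
        "selected_ids": sel_ids,
        "loo_accuracy": loo_acc,
        "permutation": perm,
        "network": net,
        "modules": modules,
        "enrichment": ora_results,
        "log": log,
    }
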