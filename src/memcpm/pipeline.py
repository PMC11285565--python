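"""End-to-end study pipeline over a synthetic cohort.

Stages, in dependency order: simulate -> motion exclusion -> CPM per
(group, scan, score) -> permutation significance + BH -> sex comparison ->
consensus edges + network summaries + intra-network heatmaps -> cross-sex
transfer -> segregation table -> report.

Every stage derives its random seed deterministically from the global seed
and its coordinates (stage, group, scan, score), so identical configs produce
byte-identical machine-readable outputs and any stage subset can be re-run
reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as coh
from .atlas import Atlas, synthetic_atlas
from .connectome import n_edges
from .consensus import (ConsensusEdgeTable, build_consensus, difference_map,
                        internetwork_counts, intranetwork_heatmap,
                        summarize_internetwork)
from .cpm import (CPMConfig, median_model, rho_distribution, run_cpm,
                  select_edges, transfer_model)
from .segregation import compare_segregation, format_table2, subject_ratios
from .stats import (bh_adjust, compare_group_performance, permutation_test,
                    rmse, spearman_rho)

log = logging.getLogger("memcpm")

_STAGE_CODES = {"simulate": 1, "cpm": 2, "permute": 3, "consensus": 4,
                "transfer": 5, "segregate": 6}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    The ``profile`` fixes the default counts: ``full`` uses the
    published protocol (268 nodes, 7 scans, 5 folds, 1,000 iterations, 1,000
    permutations); ``test`` is a desk-scale reduction of the same design.
    """

    profile: str = "test"
    seed: int = 0
    out_dir: str = "results/run"
    # cohort
    n_per_sex: int = 60
    n_nodes: int = 60
    planted_f_edges: int = 20
    planted_m_edges: int = 20
    effect_size: float = 0.5
    edge_noise_sd: float = 0.25
    score_noise_sd: float = 0.5
    write_matrices: bool = False
    # analysis grid
    groups: tuple[str, ...] = ("all", "F", "M")
    scans: tuple[str, ...] = ("REST1_AP", "FACENAME")
    scores: tuple[str, ...] = coh.SCORES
    # CPM
    k_folds: int = 5
    n_iterations: int = 20
    selection_alpha: float = 0.01
    covariates: tuple[str, ...] = ("ffd", "age", "ffd_x_age")
    model_mode: str = "combined"
    n_permutations: int = 50
    # consensus
    consensus_min_folds: int | None = None
    consensus_fraction: float = 0.4
    heatmap_networks: tuple[str, ...] = ("DMN",)
    # segregation
    segregation_networks: tuple[str, ...] = ("DMN", "VI", "VII", "VAs")
    segregation_denominator: str = "incident"
    segregation_welch: bool = False
    motion_threshold_mm: float = 0.3

    @classmethod
    def full_protocol(cls, **overrides) -> "RunConfig":
        base = dict(profile="full", n_per_sex=250, n_nodes=268,
                    scans=coh.SCANS, n_iterations=1000, n_permutations=1000)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("groups", "scans", "scores", "covariates",
                    "heatmap_networks", "segregation_networks"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("profile") == "full":
            return cls.full_protocol(**{k: v for k, v in raw.items()
                                         if k != "profile"})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def cpm_config(self, seed: int = 0) -> CPMConfig:
        return CPMConfig(k_folds=self.k_folds, n_iterations=self.n_iterations,
                         selection_alpha=self.selection_alpha,
                         covariates=self.covariates, model_mode=self.model_mode,
                         seed=seed)


def stage_seed(config: RunConfig, stage: str, *coords: str) -> int:
    """Deterministic sub-seed for a (stage, group, scan, score, ...) cell."""
    codes = [config.seed, _STAGE_CODES.get(stage, 99)]
    for c in coords:
        codes.append(int.from_bytes(hashlib.sha256(str(c).encode()).digest()[:4],
                                    "big"))
    ss = np.random.SeedSequence(codes)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineResult:
    """In-memory handles to everything a run produced."""

    config: RunConfig
    cohort: coh.Cohort
    performance: pd.DataFrame
    consensus: dict[tuple[str, str, str], ConsensusEdgeTable] = field(default_factory=dict)
    runs: dict[tuple[str, str, str], list] = field(default_factory=dict)
    transfer: pd.DataFrame | None = None
    segregation: pd.DataFrame | None = None
    out_dir: Path | None = None


def simulate_stage(config: RunConfig) -> coh.Cohort:
    """Generate the synthetic cohort with the configured planted structure."""
    atlas = synthetic_atlas(config.n_nodes)
    rng = np.random.default_rng(stage_seed(config, "simulate"))
    planted: dict[str, list] = {}
    if config.planted_f_edges > 0:
        pairs = coh.within_network_pairs(atlas, "DMN", config.planted_f_edges, rng)
        planted["F"] = [(i, j, config.effect_size) for i, j in pairs]
    if config.planted_m_edges > 0:
        pairs = coh.visual_block_pairs(atlas, config.planted_m_edges, rng)
        planted["M"] = [(i, j, config.effect_size) for i, j in pairs]
    spec = coh.GroundTruthSpec(
        n_female=config.n_per_sex, n_male=config.n_per_sex,
        planted_edges=planted, edge_noise_sd=config.edge_noise_sd,
        score_noise_sd=config.score_noise_sd, scans=tuple(config.scans),
        seed=stage_seed(config, "simulate", "draw"))
    return coh.generate_cohort(spec, atlas)


def _group_mask(cohort: coh.Cohort, group: str) -> np.ndarray:
    if group == "all":
        return np.ones(cohort.n_subjects, dtype=bool)
    if group in ("F", "M"):
        return cohort.sex_mask(group)
    raise ValueError(f"unknown group {group!r}")


def _model_inputs(cohort: coh.Cohort, group: str, scan: str, score: str):
    mask = _group_mask(cohort, group)
    X = cohort.edges[scan][mask]
    y = cohort.subjects.loc[mask, score].to_numpy(float)
    cov = {"ffd": cohort.subjects.loc[mask, f"ffd_{scan}"].to_numpy(float),
           "age": cohort.subjects.loc[mask, "age"].to_numpy(float)}
    return X, y, cov


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute every stage; write machine-readable outputs under ``out_dir``."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(
        {"config": config.to_dict(), "config_hash": config.config_hash()},
        indent=1, sort_keys=True))

    log.info("stage simulate: n=%d/sex, %d nodes", config.n_per_sex, config.n_nodes)
    cohort = simulate_stage(config)
    kept, excl_log = coh.apply_motion_exclusion(cohort.subjects,
                                                config.motion_threshold_mm)
    excl_log.to_csv(out / "motion_exclusions.csv", index=False)
    if len(kept) < len(cohort.subjects):
        keep_mask = cohort.subjects["id"].isin(kept["id"]).to_numpy()
        cohort = coh.Cohort(subjects=kept,
                            edges={s: W[keep_mask] for s, W in cohort.edges.items()},
                            atlas=cohort.atlas, ground_truth=cohort.ground_truth)
    coh.write_cohort(cohort, out / "cohort",
                     matrices="text" if config.write_matrices else "none")

    result = PipelineResult(config=config, cohort=cohort,
                            performance=pd.DataFrame(), out_dir=out)
    rows = []
    rho_dists: dict[tuple[str, str, str], np.ndarray] = {}
    for group in config.groups:
        for scan in config.scans:
            for score in config.scores:
                key = (group, scan, score)
                X, y, cov = _model_inputs(cohort, group, scan, score)
                cfg = config.cpm_config(stage_seed(config, "cpm", *key))
                log.info("stage cpm: %s/%s/%s (n=%d)", group, scan, score, len(y))
                runs = run_cpm(X, y, cov, cfg)
                med = median_model(runs)
                rho_dists[key] = rho_distribution(runs)
                perm = permutation_test(
                    X, y, cov, cfg, med.rho, config.n_permutations,
                    seed=stage_seed(config, "permute", *key))
                cons = build_consensus(runs, n_edges(cohort.atlas.n_nodes),
                                       config.consensus_min_folds,
                                       config.consensus_fraction)
                result.runs[key] = runs
                result.consensus[key] = cons
                rows.append({"group": group, "scan": scan, "score": score,
                             "rho_median": med.rho, "rmse_median": med.rmse,
                             "p_raw": perm.p,
                             "n_subjects": int(len(y)),
                             "n_sig_pos": int(cons.significant_pos.sum()),
                             "n_sig_neg": int(cons.significant_neg.sum())})
                _write_model_outputs(out, key, cohort, X, y, cov, cfg, runs,
                                     med, perm, cons)
    perf = pd.DataFrame(rows)
    for group in config.groups:
        idx = perf["group"] == group
        perf.loc[idx, "p_bh"] = bh_adjust(perf.loc[idx, "p_raw"].to_numpy())
    perf.to_csv(out / "performance.csv", index=False)
    result.performance = perf

    _sex_comparison(config, rho_dists, out)
    _difference_maps(config, result, cohort.atlas, out)
    _transfer_stage(config, cohort, result, out)
    _segregation_stage(config, cohort, result, out)
    report(out)
    return result


def _write_model_outputs(out, key, cohort, X, y, cov, cfg, runs, med, perm, cons):
    group, scan, score = key
    d = out / "models" / f"{group}_{scan}_{score}"
    d.mkdir(parents=True, exist_ok=True)
    summary = {
        "group": group, "scan": scan, "score": score,
        "config": {"k_folds": cfg.k_folds, "n_iterations": cfg.n_iterations,
                   "selection_alpha": cfg.selection_alpha,
                   "covariates": list(cfg.covariates),
                   "model_mode": cfg.model_mode, "seed": cfg.seed},
        "rho_median": None if not np.isfinite(med.rho) else round(med.rho, 10),
        "rmse_median": round(med.rmse, 10),
        "median_iteration": med.index,
        "perm_p": perm.p, "perm_p_display": perm.p_display,
        "rho_iterations": [None if not np.isfinite(v) else round(float(v), 10)
                           for v in rho_distribution(runs)],
        "n_significant_edges": {"positive": int(cons.significant_pos.sum()),
                                "negative": int(cons.significant_neg.sum())},
    }
    (d / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    # per-fold edge selections of the median iteration, with statistics
    from .connectome import edge_pairs
    i_all, j_all = edge_pairs(cohort.atlas.n_nodes)
    frames = []
    C = None
    if cov:
        from .cpm import _covariate_matrix
        C = _covariate_matrix(cov, cfg.covariates)
    for f, fm in enumerate(med.fold_models):
        train = med.fold_assignment != f
        sel = select_edges(X[train], y[train], None if C is None else C[train],
                           cfg.selection_alpha, keep_stats=True)
        for sign, idx in (("positive", sel.positive), ("negative", sel.negative)):
            if idx.size:
                frames.append(pd.DataFrame({
                    "fold": f, "node_i": i_all[idx], "node_j": j_all[idx],
                    "sign": sign, "statistic": np.round(sel.r[idx], 10),
                    "p": sel.p[idx]}))
    sel_df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["fold", "node_i", "node_j", "sign", "statistic", "p"])
    sel_df.to_csv(d / "median_model_edges.tsv", sep="\t", index=False)
    cons.to_frame(cohort.atlas).to_csv(d / "consensus_edges.tsv", sep="\t",
                                       index=False)
    for sign in ("positive", "negative"):
        summarize_internetwork(cons, cohort.atlas, sign).to_csv(
            d / f"internetwork_{sign}.csv")


def _sex_comparison(config, rho_dists, out):
    if not {"F", "M"} <= set(config.groups):
        return
    rows = []
    for scan in config.scans:
        for score in config.scores:
            rf = rho_dists[("F", scan, score)]
            rm = rho_dists[("M", scan, score)]
            rf = rf[np.isfinite(rf)]
            rm = rm[np.isfinite(rm)]
            if rf.size and rm.size:
                u, p = compare_group_performance(rf, rm)
                rows.append({"scan": scan, "score": score, "U": u, "p": p})
    pd.DataFrame(rows).to_csv(out / "sex_performance_comparison.csv", index=False)


def _difference_maps(config, result, atlas, out):
    if not {"F", "M"} <= set(config.groups):
        return
    d = out / "difference_maps"
    d.mkdir(exist_ok=True)
    for scan in config.scans:
        for score in config.scores:
            for sign in ("positive", "negative"):
                sf = summarize_internetwork(result.consensus[("F", scan, score)],
                                            atlas, sign)
                sm = summarize_internetwork(result.consensus[("M", scan, score)],
                                            atlas, sign)
                difference_map(sf, sm).to_csv(d / f"{scan}_{score}_{sign}_FminusM.csv")
    hm = out / "intranetwork"
    hm.mkdir(exist_ok=True)
    for nw in config.heatmap_networks:
        for group in ("F", "M"):
            for scan in config.scans:
                for score in config.scores:
                    h = intranetwork_heatmap(result.consensus[(group, scan, score)],
                                             atlas, nw)
                    h.to_frame().to_csv(hm / f"{group}_{scan}_{score}_{nw}.csv")
                    pd.DataFrame({"node": h.nodes, "sv": h.summed_vector}).to_csv(
                        hm / f"{group}_{scan}_{score}_{nw}_sv.csv", index=False)


def _transfer_stage(config, cohort, result, out):
    if not {"F", "M"} <= set(config.groups):
        return
    rows = []
    for src, tgt in (("F", "M"), ("M", "F")):
        for scan in config.scans:
            for score in config.scores:
                Xs, ys, cs = _model_inputs(cohort, src, scan, score)
                Xt, yt, _ = _model_inputs(cohort, tgt, scan, score)
                cfg = config.cpm_config(stage_seed(config, "transfer", src, scan, score))
                tr = transfer_model(Xs, ys, cs, Xt, yt, cfg)
                rows.append({"source": src, "target": tgt, "scan": scan,
                             "score": score, "rho_median": tr.rho_median,
                             "rmse_median": float(np.median(tr.rmse))})
    df = pd.DataFrame(rows)
    df.to_csv(out / "transfer.csv", index=False)
    result.transfer = df


def _segregation_stage(config, cohort, result, out):
    ratios = {}
    for sex in ("F", "M"):
        mask = cohort.sex_mask(sex)
        ratios[sex] = subject_ratios(
            {s: W[mask] for s, W in cohort.edges.items()}, cohort.atlas,
            config.segregation_networks, config.segregation_denominator)
    comp = compare_segregation(ratios["F"], ratios["M"],
                               networks=config.segregation_networks,
                               scans=tuple(config.scans),
                               welch=config.segregation_welch)
    flat = comp.table.copy()
    flat.columns = [f"{nw}_{fieldname}" for nw, fieldname in comp.table.columns]
    flat.to_csv(out / "segregation.csv")
    format_table2(comp, config.segregation_networks).to_csv(
        out / "segregation_table.csv")
    result.segregation = flat


def report(out_dir: str | Path) -> Path:
    """Render a human-readable summary (markdown + figures) from the
    machine-readable outputs of a completed (or partial) run."""
    out = Path(out_dir)
    lines = ["# Pipeline report", ""]
    missing = []
    perf_path = out / "performance.csv"
    if perf_path.exists():
        perf = pd.read_csv(perf_path)
        lines += ["## Model performance (median iteration)", "",
                  perf.to_string(index=False,
                                 float_format=lambda v: f"{v:.4f}"), ""]
        total_sig = int(perf[["n_sig_pos", "n_sig_neg"]].to_numpy().sum())
        if total_sig == 0:
            lines += ["No significant consensus edges at the configured "
                      "threshold.", ""]
        _performance_figure(perf, out)
    else:
        missing.append("performance.csv")
    for name, title in (("sex_performance_comparison.csv",
                         "Female vs male performance (rank-sum)"),
                        ("transfer.csv", "Cross-sex model transfer"),
                        ("segregation_table.csv",
                         "Network segregation (t, p; † fails BH)")):
        p = out / name
        if p.exists():
            df = pd.read_csv(p)
            lines += [f"## {title}", "", df.to_string(index=False), ""]
        else:
            missing.append(name)
    if missing:
        lines += ["## Missing stage outputs", ""] + [f"- {m}" for m in missing]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def _performance_figure(perf: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    labels = perf["group"] + "/" + perf["scan"] + "/" + perf["score"]
    ax.bar(np.arange(len(perf)), perf["rho_median"].fillna(0.0))
    ax.set_xticks(np.arange(len(perf)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("median out-of-fold Spearman rho")
    fig.tight_layout()
    fig.savefig(out / "performance.png", dpi=100)
    plt.close(fig)
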