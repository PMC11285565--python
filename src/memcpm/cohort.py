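"""Synthetic cohort generation with planted, sex-specific predictive edges.

The generator emulates the structure of an aging-cohort fMRI study: subjects
with sex, age, per-scan head-motion summaries (maximum mean frame-to-frame
displacement, FFD) and three bounded memory scores, plus one functional
connectome per subject per scan.  A latent standardized memory propensity
``z ~ N(0, 1)`` drives both the observed scores (monotone discretized
transforms of ``z`` plus score noise) and a designated set of "planted" edges
whose Fisher-z weights carry ``beta * z`` of linear signal, on top of a
structured baseline, optional motion/age confound leakage and i.i.d. edge
noise.  All remaining edges are baseline plus noise, so the generator has an
exact null.

Planted sets are sex-specific (e.g. within-DMN edges for female subjects,
visual-network edges for male subjects) so that sex-stratified predictive
models have disjoint recoverable ground truth.

For a planted edge with effect size ``beta`` and edge noise SD ``sigma``, the
population edge-score correlation against the continuous propensity is
``beta / sqrt(beta**2 + sigma**2)`` (sigma_z = 1); score discretization
attenuates this slightly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .atlas import Atlas
from .connectome import devectorize, edge_index_of, n_edges, vectorize

#: The seven fMRI scans: four resting-state runs (split by phase-encoding
#: direction) and three tasks.
SCANS: tuple[str, ...] = (
    "REST1_AP", "REST1_PA", "REST2_AP", "REST2_PA",
    "CARIT", "FACENAME", "VISMOTOR",
)

#: Memory outcomes and their maximum attainable integer scores:
#: face-name total recall (10 face-name pairs), RAVLT learning sum over
#: five 15-word trials (75), RAVLT immediate recall, sixth trial (15).
SCORE_MAX: dict[str, int] = {"fn_tr": 10, "ravlt_l": 75, "ravlt_ir": 15}
SCORES: tuple[str, ...] = tuple(SCORE_MAX)


@dataclass
class GroundTruthSpec:
    """Parameters of the simulated world.

    Effect sizes ``beta`` are in Fisher-z edge-weight units per standard
    deviation of the latent memory propensity; with edge noise SD ``sigma``
    the implied per-edge correlation is ``beta / sqrt(beta**2 + sigma**2)``.
    Defaults are desk-scale (200 subjects per sex) with no planted signal.
    """

    n_female: int = 200
    n_male: int = 200
    #: sex -> list of (node_i, node_j, beta)
    planted_edges: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    #: list of (node_i, node_j, gamma_motion, gamma_age): confound leakage in
    #: Fisher-z units per mm of FFD and per SD of age respectively.
    confound_edges: list[tuple[int, int, float, float]] = field(default_factory=list)
    baseline_mean: float = 0.25          # background Fisher-z level
    within_network_boost: float = 0.15   # added to within-network baseline
    edge_noise_sd: float = 0.25          # across-subject edge SD (Fisher-z)
    score_noise_sd: float = 0.5          # latent-score noise, SD units of z
    age_range: tuple[float, float] = (36.0, 100.0)
    age_mean: float = 57.0
    age_sd: float = 14.0
    ffd_mean: float = 0.12               # mm
    ffd_sd: float = 0.06                 # mm
    missing_motion_rate: float = 0.0
    scans: tuple[str, ...] = SCANS
    seed: int = 0

    def validate(self, atlas: Atlas) -> None:
        if self.n_female <= 0 or self.n_male <= 0:
            raise ValueError("subject counts must be positive")
        for sex, edges in self.planted_edges.items():
            if sex not in ("F", "M"):
                raise ValueError(f"planted-edge group must be F or M, got {sex!r}")
            seen = set()
            for i, j, beta in edges:
                if i == j:
                    raise ValueError(f"self-loop ({i},{i}) in planted edges")
                if not (0 <= i < atlas.n_nodes and 0 <= j < atlas.n_nodes):
                    raise ValueError(f"edge ({i},{j}) outside atlas of {atlas.n_nodes}")
                if not np.isfinite(beta):
                    raise ValueError("non-finite effect size")
                key = (min(i, j), max(i, j))
                if key in seen:
                    raise ValueError(f"duplicate planted edge {key}")
                seen.add(key)
        for i, j, gm, ga in self.confound_edges:
            if i == j or not (0 <= i < atlas.n_nodes and 0 <= j < atlas.n_nodes):
                raise ValueError(f"bad confound edge ({i},{j})")
            if not (np.isfinite(gm) and np.isfinite(ga)):
                raise ValueError("non-finite confound effect")


@dataclass
class Cohort:
    """A generated cohort: subject table + per-scan edge matrices."""

    subjects: pd.DataFrame
    #: scan -> (n_subjects, n_edges) array of Fisher-z edge weights, rows
    #: aligned with ``subjects``.
    edges: dict[str, np.ndarray]
    atlas: Atlas
    ground_truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def connectome(self, subject_id: str, scan: str) -> np.ndarray:
        row = self.subjects.index[self.subjects["id"] == subject_id]
        if len(row) != 1:
            raise KeyError(f"unknown subject {subject_id!r}")
        vec = self.edges[scan][int(row[0])]
        return devectorize(vec, self.atlas.n_nodes)

    def sex_mask(self, sex: str) -> np.ndarray:
        return (self.subjects["sex"] == sex).to_numpy()


def discretize_score(latent: np.ndarray, max_score: int,
                     slope: float = 1.0, offset: float = 0.5) -> np.ndarray:
    """Rank-preserving map of a latent normal score onto 0..max_score.

    A scaled logistic squashes the latent value into (0, 1) before scaling to
    the legal range and rounding; monotone, so Spearman relationships with the
    latent propensity are preserved up to rounding ties.  The positive offset
    reproduces the above-midpoint score means typical of healthy cohorts.
    """
    return np.rint(max_score * expit(slope * np.asarray(latent) + offset)).astype(int)


def generate_cohort(spec: GroundTruthSpec, atlas: Atlas) -> Cohort:
    """Draw a full synthetic cohort according to ``spec``.

    Bit-reproducible for a fixed ``spec.seed``.  Returns the cohort together
    with a ground-truth report (planted edges, latent propensities, realized
    within-sex edge-score correlations).
    """
    spec.validate(atlas)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_female + spec.n_male
    E = n_edges(atlas.n_nodes)

    sex = np.array(["F"] * spec.n_female + ["M"] * spec.n_male, dtype=object)
    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)

    lo, hi = spec.age_range
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), lo, hi)
    age_std = (age - age.mean()) / age.std()

    z = rng.standard_normal(n)  # latent memory propensity

    scores = {
        name: discretize_score(z + spec.score_noise_sd * rng.standard_normal(n), mx)
        for name, mx in SCORE_MAX.items()
    }

    ffd = {
        scan: np.abs(rng.normal(spec.ffd_mean, spec.ffd_sd, size=n))
        for scan in spec.scans
    }
    if spec.missing_motion_rate > 0:
        for scan in spec.scans:
            miss = rng.random(n) < spec.missing_motion_rate
            ffd[scan] = np.where(miss, np.nan, ffd[scan])

    baseline = _baseline_edge_vector(spec, atlas)
    planted_idx = {
        s: np.array([edge_index_of(i, j, atlas.n_nodes) for i, j, _ in edges], int)
        for s, edges in spec.planted_edges.items()
    }
    planted_beta = {
        s: np.array([b for _, _, b in edges], float)
        for s, edges in spec.planted_edges.items()
    }

    edges_by_scan: dict[str, np.ndarray] = {}
    for scan in spec.scans:
        W = baseline[None, :] + spec.edge_noise_sd * rng.standard_normal((n, E))
        for s in planted_idx:
            rows = np.flatnonzero(sex == s)
            W[np.ix_(rows, planted_idx[s])] += np.outer(z[rows], planted_beta[s])
        if spec.confound_edges:
            ffd_filled = np.nan_to_num(ffd[scan], nan=spec.ffd_mean)
            for i, j, gm, ga in spec.confound_edges:
                e = edge_index_of(i, j, atlas.n_nodes)
                W[:, e] += gm * ffd_filled + ga * age_std
        edges_by_scan[scan] = W

    subjects = pd.DataFrame({"id": ids, "sex": sex, "age": age})
    for scan in spec.scans:
        subjects[f"ffd_{scan}"] = ffd[scan]
    for name in SCORES:
        subjects[name] = scores[name]

    report = _ground_truth_report(spec, atlas, sex, z, scores, edges_by_scan,
                                  planted_idx)
    return Cohort(subjects=subjects, edges=edges_by_scan, atlas=atlas,
                  ground_truth=report)


def _baseline_edge_vector(spec: GroundTruthSpec, atlas: Atlas) -> np.ndarray:
    """Structured mean connectome: elevated within-network connectivity."""
    from .connectome import edge_pairs

    i, j = edge_pairs(atlas.n_nodes)
    within = atlas.labels[i] == atlas.labels[j]
    return np.where(within, spec.baseline_mean + spec.within_network_boost,
                    spec.baseline_mean).astype(float)


def _ground_truth_report(spec, atlas, sex, z, scores, edges_by_scan, planted_idx):
    realized: dict[str, dict] = {}
    for s, idx in planted_idx.items():
        rows = np.flatnonzero(sex == s)
        per_scan = {}
        for scan, W in edges_by_scan.items():
            per_score = {}
            for name in SCORES:
                y = scores[name][rows].astype(float)
                cors = _colwise_corr(W[np.ix_(rows, idx)], y)
                per_score[name] = float(np.mean(cors)) if idx.size else float("nan")
            zc = _colwise_corr(W[np.ix_(rows, idx)], z[rows])
            per_scan[scan] = {"vs_scores": per_score,
                              "vs_latent_mean": float(np.mean(zc)) if idx.size else None,
                              "vs_latent_per_edge": np.round(zc, 6).tolist()}
        realized[s] = per_scan
    return {
        "seed": spec.seed,
        "planted_edges": {s: [[int(i), int(j), float(b)] for i, j, b in e]
                          for s, e in spec.planted_edges.items()},
        "confound_edges": [[int(i), int(j), float(gm), float(ga)]
                           for i, j, gm, ga in spec.confound_edges],
        "edge_noise_sd": spec.edge_noise_sd,
        "score_noise_sd": spec.score_noise_sd,
        "latent_z": np.round(z, 6).tolist(),
        "realized_correlation": realized,
    }


def _colwise_corr(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc.T @ yc / denom, 0.0)
    return r


# -- time-series mode (for end-to-end connectome-builder tests) -------------

def generate_timeseries(matrix: np.ndarray, frames: int,
                        seed: int | np.random.Generator = 0,
                        psd_eps: float = 1e-10) -> tuple[np.ndarray, float]:
    """Sample node time series whose correlation targets a connectome.

    The Fisher-z connectome is mapped back to correlation space (tanh, unit
    diagonal) and projected to the nearest positive semidefinite correlation
    matrix (eigenvalue clipping followed by diagonal renormalization) before
    multivariate-normal sampling.  Returns ``(series, projection_distance)``
    where the distance is the Frobenius norm between the requested and the
    projected correlation matrix (0 when the target was already PSD).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) \
        else seed
    m = np.asarray(matrix, float)
    n = m.shape[0]
    if frames < 1:
        raise ValueError("frames must be positive")
    if frames < n + 1:
        warnings.warn(
            f"frames ({frames}) < n_nodes+1 ({n + 1}): empirical correlation "
            "will be rank-deficient", stacklevel=2)
    target = np.tanh(m)
    np.fill_diagonal(target, 1.0)
    proj = _nearest_psd_correlation(target, psd_eps)
    distance = float(np.linalg.norm(proj - target, "fro"))
    L = np.linalg.cholesky(proj + psd_eps * np.eye(n))
    series = L @ rng.standard_normal((n, frames))
    return series, distance


def psd_adjusted_target(matrix: np.ndarray,
                        psd_eps: float = 1e-10) -> tuple[np.ndarray, float]:
    """The correlation matrix :func:`generate_timeseries` actually samples
    from, with its Frobenius projection distance from the requested target."""
    m = np.asarray(matrix, float)
    target = np.tanh(m)
    np.fill_diagonal(target, 1.0)
    proj = _nearest_psd_correlation(target, psd_eps)
    return proj, float(np.linalg.norm(proj - target, "fro"))


def _nearest_psd_correlation(a: np.ndarray, eps: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    if vals.min() >= 0:
        return 0.5 * (a + a.T)
    vals = np.clip(vals, eps, None)
    b = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    np.fill_diagonal(b, 1.0)
    return 0.5 * (b + b.T)


# -- motion exclusion -------------------------------------------------------

def apply_motion_exclusion(subjects: pd.DataFrame, threshold_mm: float = 0.3,
                           ffd_columns: list[str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects whose maximum mean FFD exceeds ``threshold_mm`` on any scan.

    The comparison is strict (``> threshold``): a subject at exactly the
    threshold is kept.  Missing FFD values are treated as unverifiable motion
    and exclude the subject with reason ``"missing-motion"``.  Returns the
    filtered table and an exclusion log with one row per offending scan.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold must be positive")
    if ffd_columns is None:
        ffd_columns = [c for c in subjects.columns if c.startswith("ffd_")]
    log_rows = []
    drop = np.zeros(len(subjects), dtype=bool)
    for pos, (_, row) in enumerate(subjects.iterrows()):
        for col in ffd_columns:
            v = row[col]
            if pd.isna(v):
                log_rows.append({"id": row["id"], "scan": col.removeprefix("ffd_"),
                                 "ffd": np.nan, "reason": "missing-motion"})
                drop[pos] = True
            elif v > threshold_mm:
                log_rows.append({"id": row["id"], "scan": col.removeprefix("ffd_"),
                                 "ffd": float(v), "reason": "high-motion"})
                drop[pos] = True
    log = pd.DataFrame(log_rows, columns=["id", "scan", "ffd", "reason"])
    return subjects.loc[~drop].reset_index(drop=True), log


# -- on-disk round trip -----------------------------------------------------

def write_cohort(cohort: Cohort, outdir, matrices: str = "text") -> None:
    """Write subjects.csv, atlas.tsv, ground_truth.json and (optionally) one
    delimited matrix file per subject per scan with a manifest.csv."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    cohort.atlas.to_tsv(out / "atlas.tsv")
    (out / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth, indent=1, sort_keys=True))
    if matrices == "none":
        return
    mdir = out / "matrices"
    mdir.mkdir(exist_ok=True)
    rows = []
    for scan, W in cohort.edges.items():
        for r, sid in enumerate(cohort.subjects["id"]):
            path = mdir / f"{sid}_{scan}.txt"
            np.savetxt(path, devectorize(W[r], cohort.atlas.n_nodes), fmt="%.6f")
            rows.append({"subject_id": sid, "scan_label": scan,
                         "path": str(path.relative_to(out))})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_cohort(indir) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (text-matrix form)."""
    ind = Path(indir)
    subjects = pd.read_csv(ind / "subjects.csv")
    atlas = Atlas.from_tsv(ind / "atlas.tsv")
    gt_path = ind / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else {}
    manifest = pd.read_csv(ind / "manifest.csv")
    order = {sid: k for k, sid in enumerate(subjects["id"])}
    edges: dict[str, np.ndarray] = {}
    for scan, grp in manifest.groupby("scan_label"):
        W = np.empty((len(subjects), n_edges(atlas.n_nodes)))
        for _, row in grp.iterrows():
            m = np.loadtxt(ind / row["path"])
            W[order[row["subject_id"]]] = vectorize(m)
        edges[str(scan)] = W
    return Cohort(subjects=subjects, edges=edges, atlas=atlas,
                  ground_truth=ground_truth)


# -- convenience planted-edge constructors ----------------------------------

def within_network_pairs(atlas: Atlas, network: str,
                         k: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Sample ``k`` distinct within-network node pairs."""
    nodes = atlas.nodes_in(network)
    pairs = [(int(a), int(b)) for ai, a in enumerate(nodes) for b in nodes[ai + 1:]]
    if k > len(pairs):
        raise ValueError(f"{network} has only {len(pairs)} within edges, need {k}")
    sel = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[int(s)] for s in sel]


def visual_block_pairs(atlas: Atlas, k: int, rng: np.random.Generator,
                       networks: tuple[str, ...] = ("VII", "VAs"),
                       ) -> list[tuple[int, int]]:
    """Sample ``k`` distinct pairs within the union of visual networks
    (within- and between-network edges of the block)."""
    nodes = np.concatenate([atlas.nodes_in(nw) for nw in networks])
    nodes = np.sort(nodes)
    pairs = [(int(a), int(b)) for ai, a in enumerate(nodes) for b in nodes[ai + 1:]]
    if k > len(pairs):
        raise ValueError(f"visual block has only {len(pairs)} edges, need {k}")
    sel = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[int(s)] for s in sel]
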