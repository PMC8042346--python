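"""End-to-end orchestration: simulate -> metrics -> PCA -> clustering ->
group statistics -> lesion mapping -> longitudinal projection.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([global_seed, stage_index])``, so any stage can be
rerun in isolation and reproduce its output bit-for-bit.  A manifest records
the config, the seed and a SHA-256 checksum of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gmm, lesion, longitudinal, metrics, pca, stats, synthetic

STAGES = ("simulate", "metrics", "pca", "cluster", "stats", "lesions", "longitudinal")


@dataclass
class RunConfig:
    seed: int = 0
    n_patients: int = 122
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    cum_threshold: float = 0.70
    g_max: int = 10
    n_init: int = 10
    bic_tolerance: float = 10.0
    subtraction_criterion_pct: float = 50.0
    vlsm_min_lesion_count: int = 5
    vlsm_test: str = "brunner-munzel"
    vlsm_alpha: float = 0.05
    resel_left_denominator: str = "left"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Documented derivation of a per-stage seed (below 2**31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([global_seed, idx]).generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the enabled stages into ``out_dir`` and write the manifest.

    Stages read their prerequisites from disk, so a stage toggled off must
    have been produced by an earlier run in the same directory; a missing
    prerequisite raises an error naming it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def need(path: Path, stage: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs missing prerequisite {path.name}; "
                "run its producing stage first")
        return path

    def enabled_from(*names: str) -> bool:
        return any(config.stages[s] for s in names)

    cohort = None
    if config.stages["simulate"]:
        sim = synthetic.default_cohort_config(
            n_patients=config.n_patients, seed=stage_seed(config.seed, "simulate"))
        cohort = synthetic.generate_cohort(sim)
        synthetic.write_cohort(cohort, out / "cohort")
    elif enabled_from("metrics", "lesions"):
        need(out / "cohort" / "task_logs.jsonl", "metrics")
        cohort = synthetic.read_cohort(out / "cohort")

    if config.stages["metrics"]:
        table = metrics.build_feature_table(cohort)
        metrics.write_feature_table(table, out / "features.csv")
    if enabled_from("pca"):
        table = metrics.read_feature_table(need(out / "features.csv", "pca"))
        model = pca.fit_pca(table, cum_threshold=config.cum_threshold)
        model.to_json(out / "pca_model.json")
        pca.correlation_matrix(table).to_csv(out / "correlation.csv")
        pca.project(model, table).to_csv(out / "scores.csv")

    model = scores = None
    if enabled_from("cluster", "stats", "lesions", "longitudinal"):
        model = pca.PCModel.from_json(need(out / "pca_model.json", "cluster"))
        scores = pd.read_csv(need(out / "scores.csv", "cluster"), index_col=0)

    if config.stages["cluster"]:
        cands = gmm.fit_candidates(scores, seed=stage_seed(config.seed, "cluster"),
                                   g_range=range(1, config.g_max + 1),
                                   n_init=config.n_init)
        gmm.candidate_table(cands).to_csv(out / "candidates.csv", index=False)
        mixture = gmm.select_model(cands, bic_tolerance=config.bic_tolerance)
        pd.DataFrame({"patient_id": scores.index,
                      "cluster": mixture.labels + 1}).to_csv(
            out / "assignments.csv", index=False)
        gmm.cluster_summary(mixture, scores).to_csv(out / "cluster_summary.csv", index=False)
        _save_mixture(mixture, out / "mixture_model.json")

    mixture = assignments = None
    if enabled_from("stats", "lesions", "longitudinal"):
        mixture = _load_mixture(need(out / "mixture_model.json", "stats"), scores)
        assignments = pd.read_csv(need(out / "assignments.csv", "stats"),
                                  index_col="patient_id")["cluster"]

    if config.stages["stats"]:
        kw = stats.kruskal_wallis_by_pc(scores, assignments.to_numpy())
        pd.DataFrame([{"PC": pc_name, "H": r.statistic, "df": r.df, "p": r.p_value,
                       "r": r.effect_size_r, "n": r.n}
                      for pc_name, r in kw.items()]).to_csv(out / "kruskal_wallis.csv",
                                                            index=False)
        for pc_name, mat in stats.steel_dwass_by_pc(scores, assignments.to_numpy()).items():
            mat.to_csv(out / f"steel_dwass_{pc_name}.csv")

    if config.stages["lesions"]:
        _lesion_stage(cohort, scores, assignments, config, out)

    if config.stages["longitudinal"]:
        _longitudinal_stage(model, mixture, config, out)

    _write_manifest(config, out)
    return out


def _save_mixture(mixture: gmm.MixtureModel, path: Path) -> None:
    c = mixture.candidate
    payload = {"n_components": c.n_components, "family": c.family,
               "loglik": c.loglik, "n_params": c.n_params, "bic": c.bic,
               "icl": c.icl, "weights": c.weights.tolist(),
               "means": c.means.tolist(), "covariances": c.covariances.tolist(),
               "responsibilities": c.responsibilities.tolist()}
    path.write_text(json.dumps(payload))


def _load_mixture(path: Path, scores: pd.DataFrame) -> gmm.MixtureModel:
    d = json.loads(path.read_text())
    cand = gmm.MixtureCandidate(
        n_components=d["n_components"], family=d["family"], loglik=d["loglik"],
        n_params=d["n_params"], bic=d["bic"], icl=d["icl"], converged=True,
        weights=np.array(d["weights"]), means=np.array(d["means"]),
        covariances=np.array(d["covariances"]),
        responsibilities=np.array(d["responsibilities"]))
    return gmm.MixtureModel(cand)


def _lesion_stage(cohort, scores, assignments, config: RunConfig, out: Path) -> None:
    les_dir = out / "lesion_maps"
    les_dir.mkdir(exist_ok=True)
    vols = {p.patient_id: p.lesion for p in cohort.patients if p.lesion is not None}
    if not vols:
        raise FileNotFoundError("stage 'lesions' needs lesion volumes in the cohort")
    ids = [pid for pid in scores.index if pid in vols]
    all_vols = [vols[pid] for pid in ids]
    labels = assignments.loc[ids]

    lesion.save_volume(lesion.overlap_map(all_vols), les_dir / "overlap_all.nii.gz")
    by_cluster = {k: [vols[pid] for pid in ids if labels.loc[pid] == k]
                  for k in sorted(labels.unique())}
    maps = {}
    for k, group in by_cluster.items():
        if group:
            maps[f"c{k}"] = lesion.overlap_map(group)
            lesion.save_volume(maps[f"c{k}"], les_dir / f"overlap_c{k}.nii.gz")
    lesion.pairwise_cosine(maps).to_csv(out / "cosine_similarity.csv")

    atlas = lesion.build_toy_atlas(all_vols[0].shape)
    regions = []
    # subtype-isolating subtractions among the three most impaired clusters
    # (highest mean first-component score: severity loads positively on PC1
    # under the deterministic sign convention)
    pc1 = scores.columns[0]
    severity = scores.loc[ids].groupby(labels).mean()[pc1]
    ks = list(severity.sort_values(ascending=False).index[:3])
    if len(ks) == 3 and all(by_cluster[k] for k in ks):
        k1, k2, k3 = ks
        pooled23 = by_cluster[k2] + by_cluster[k3]
        combos = {f"c{k1}_vs_c{k2}+c{k3}": (by_cluster[k1], pooled23),
                  f"c{k2}_vs_c{k3}": (by_cluster[k2], by_cluster[k3]),
                  f"c{k3}_vs_c{k2}": (by_cluster[k3], by_cluster[k2])}
        for name, (a, b) in combos.items():
            diff, mask, _ = lesion.subtraction_map(a, b, config.subtraction_criterion_pct)
            lesion.save_volume(diff, les_dir / f"subtraction_{name}.nii.gz")
            summ = lesion.region_summary(np.where(mask, diff, 0.0), atlas)
            summ.insert(0, "contrast", name)
            regions.append(summ)
    if regions:
        pd.concat(regions).to_csv(out / "subtraction_regions.csv", index=False)

    vol_stack = [vols[pid] for pid in ids]
    results = lesion.vlsm_by_pc(vol_stack, scores.loc[ids],
                                min_lesion_count=config.vlsm_min_lesion_count,
                                test=config.vlsm_test, alpha=config.vlsm_alpha)
    for pc_name, res in results.items():
        lesion.save_volume(np.nan_to_num(res["p"], nan=1.0), les_dir / f"vlsm_p_{pc_name}.nii.gz")


def _longitudinal_stage(model, mixture, config: RunConfig, out: Path) -> None:
    """Simulated recovery cases: behavior morphs between subtype profiles and
    each timepoint is projected through the frozen models."""
    rng_seed = stage_seed(config.seed, "longitudinal")
    rng = np.random.default_rng(rng_seed)
    sim = synthetic.default_cohort_config()
    spec_by_id = {s.id: s for s in sim.subtypes}
    # canonical recovery contrasts: severe 1 -> 2 or 3; mild 2 -> 4, 3 -> 5
    paths = {"case1": (1, 2), "case2": (1, 3), "case3": (2, 4), "case4": (3, 5)}
    trajectories = []
    for case, (a, b) in paths.items():
        assessments = []
        for i, t in enumerate(np.linspace(0.0, 1.0, 4)):
            spec = synthetic.interpolate_specs(spec_by_id[a], spec_by_id[b], float(t))
            endo = synthetic.generate_endoat_log(spec, rng)
            exo = synthetic.generate_exoat_log(spec, rng)
            bit = synthetic.generate_bit_scores(spec, rng)
            feats = metrics.patient_features(endo, exo, bit)
            assessments.append((7.0 + 40.0 * i, feats))
        trajectories.append(longitudinal.build_trajectory(case, model, mixture, assessments))
    pd.concat([t.to_frame() for t in trajectories]).to_csv(out / "trajectories.csv", index=False)
    longitudinal.transition_table(trajectories, mixture.n_components).to_csv(
        out / "transitions.csv")


def _write_manifest(config: RunConfig, out: Path) -> None:
    artifacts = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            artifacts[str(path.relative_to(out))] = _sha256(path)
    manifest = {"config": dataclasses.asdict(config), "seed": config.seed,
                "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
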