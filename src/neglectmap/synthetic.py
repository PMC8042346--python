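"""Synthetic cohorts with known latent subtype structure.

Each subtype drives three data streams — endogenous-task selection logs,
exogenous-task reaction times/misses, and a binary lesion volume — so every
downstream stage (metrics, PCA, mixture clustering, lesion mapping,
longitudinal projection) can be tested against planted ground truth.

The generator emulates the statistical structure of neglect behavior, not its
psychophysics: a per-column probability that a target is never found, a
leftward reaction-time gradient, a reselection (spatial-working-memory
failure) rate, an initial-selection bias, and lesion probability elevated in
spherical foci.  Reaction-time noise is log-normal so times stay positive and
right-skewed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import math

import numpy as np
import pandas as pd
import yaml

from . import grid
from .metrics import BITScores, EndoATLog, ExoATLog, BIT_MAXIMA

CROSSING_STYLES = ("columnwise", "rowwise", "random")


@dataclass
class LesionFocus:
    """Spherical locus of elevated lesion probability (voxel coordinates)."""

    center: tuple[int, int, int]
    radius: float
    prob: float = 0.9


@dataclass
class SubtypeSpec:
    """Parameters of one latent neglect subtype.

    ``endo_miss_gradient`` / ``exo_miss_gradient`` give, per grid column
    left-to-right, the probability a target is never selected / a flash is
    missed.  ``rt_left_gradient`` is the additive slowing in ms per column of
    distance from the right edge.  ``reselect_prob`` is the probability that
    any emitted selection is a repeat of an already-selected target;
    ``reselect_space`` optionally restricts the repeated target's hemispace.
    ``start_position_dist`` is a categorical distribution over initial target
    indices.  ``prevalence`` is the mixing weight in the cohort.
    """

    id: int
    prevalence: float
    endo_miss_gradient: Sequence[float] = (0.0,) * grid.N_COLS
    reselect_prob: float = 0.0
    reselect_space: str | None = None  # None | "left" | "right"
    start_position_dist: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    crossing_style: str = "columnwise"
    rt_base: float = 500.0
    rt_left_gradient: float = 0.0
    rt_sd: float = 0.0
    patient_rt_sd: float = 0.0
    exo_miss_gradient: Sequence[float] = (0.0,) * grid.N_COLS
    bit_means: Sequence[float] = BIT_MAXIMA
    bit_sds: Sequence[float] = (2.0, 2.0, 3.0, 0.5, 1.0, 0.5)
    lesion_foci: list[LesionFocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.endo_miss_gradient) != grid.N_COLS or len(self.exo_miss_gradient) != grid.N_COLS:
            raise ValueError("miss gradients must have one probability per column")
        for p in (*self.endo_miss_gradient, *self.exo_miss_gradient,
                  self.reselect_prob, *self.start_position_dist.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.crossing_style not in CROSSING_STYLES:
            raise ValueError(f"crossing_style must be one of {CROSSING_STYLES}")
        if self.reselect_space not in (None, "left", "right"):
            raise ValueError("reselect_space must be None, 'left' or 'right'")
        if not self.rt_base > 0:
            raise ValueError("rt_base must be positive")
        if len(self.bit_means) != 6:
            raise ValueError("bit_means needs six subtest means")
        for m, hi in zip(self.bit_means, BIT_MAXIMA):
            if not 0 <= m <= hi:
                raise ValueError(f"BIT mean {m} outside 0..{hi}")
        if abs(sum(self.start_position_dist.values()) - 1.0) > 1e-9:
            raise ValueError("start_position_dist must sum to 1")


@dataclass
class SimulationConfig:
    """Cohort-level settings; the seed fully determines the output."""

    n_patients: int
    subtypes: list[SubtypeSpec]
    grid_shape: tuple[int, int] = (grid.N_ROWS, grid.N_COLS)
    volume_shape: tuple[int, int, int] = (24, 28, 24)
    background_lesion_prob: float = 0.02
    response_timeout_ms: float = 10_000.0
    generate_lesions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.grid_shape) != (grid.N_ROWS, grid.N_COLS):
            raise ValueError(f"grid must be {grid.N_ROWS}x{grid.N_COLS} (35 targets)")
        if not self.subtypes:
            raise ValueError("at least one subtype is required")
        total = sum(s.prevalence for s in self.subtypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences sum to {total}, expected 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


@dataclass
class Patient:
    patient_id: str
    subtype: int  # ground-truth latent label
    endo: EndoATLog
    exo: ExoATLog
    bit: BITScores
    lesion: np.ndarray | None = None
    timepoint: float | None = None


@dataclass
class CohortDataset:
    patients: list[Patient]
    config: SimulationConfig

    def truth_labels(self) -> pd.Series:
        return pd.Series({p.patient_id: p.subtype for p in self.patients},
                         name="subtype")


# ---------------------------------------------------------------------------
# generators

def generate_endoat_log(spec: SubtypeSpec, rng: np.random.Generator) -> EndoATLog:
    """Simulate one endogenous-task selection sequence."""
    miss = np.array([spec.endo_miss_gradient[grid.column_of(t)]
                     for t in range(1, grid.N_TARGETS + 1)])
    found = [t for t in range(1, grid.N_TARGETS + 1) if rng.random() >= miss[t - 1]]
    if not found:
        return EndoATLog([])

    # initial selection from the start distribution, restricted to found targets
    cand = [t for t in spec.start_position_dist if t in set(found)]
    if cand:
        w = np.array([spec.start_position_dist[t] for t in cand])
        start = int(rng.choice(cand, p=w / w.sum()))
    else:
        start = int(rng.choice(found))

    rest = [t for t in found if t != start]
    if spec.crossing_style == "columnwise":
        rest.sort(key=lambda t: (grid.column_of(t), grid.row_of(t)))
    elif spec.crossing_style == "rowwise":
        rest.sort(key=lambda t: (grid.row_of(t), grid.column_of(t)))
    else:
        rng.shuffle(rest)

    # each completed selection is followed by a geometric run of repeats, so
    # any emitted selection is a repeat with probability reselect_prob
    selections: list[int] = []
    selected: list[int] = []
    for t in [start] + rest:
        selections.append(t)
        selected.append(t)
        while rng.random() < spec.reselect_prob:
            pool = selected
            if spec.reselect_space == "left":
                pool = [x for x in selected if grid.hemispace(x) == grid.LEFT] or selected
            elif spec.reselect_space == "right":
                pool = [x for x in selected if grid.hemispace(x) == grid.RIGHT] or selected
            selections.append(int(rng.choice(pool)))
    return EndoATLog(selections)


def _lognormal_rt(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Log-normal draw with the requested mean and (approximate) SD."""
    if sd <= 0:
        return mean
    sigma2 = math.log1p((sd / mean) ** 2)
    return mean * math.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2)))


def generate_exoat_log(spec: SubtypeSpec, rng: np.random.Generator,
                       rt_base: float | None = None,
                       timeout_ms: float = 10_000.0) -> ExoATLog:
    """Simulate one exogenous-task run: 35 single-target flashes in random
    order, each missed per the column gradient or answered with
    RT = rt_base + gradient * (columns from the right edge), log-normal noise."""
    base = spec.rt_base if rt_base is None else rt_base
    order = rng.permutation(np.arange(1, grid.N_TARGETS + 1))
    trials: list[tuple[int, bool, float]] = []
    for t in order:
        t = int(t)
        col = grid.column_of(t)
        if rng.random() < spec.exo_miss_gradient[col]:
            trials.append((t, False, math.nan))
            continue
        mean = base + spec.rt_left_gradient * (grid.N_COLS - 1 - col)
        rt = _lognormal_rt(mean, spec.rt_sd, rng)
        if rt >= timeout_ms:
            trials.append((t, False, math.nan))
        else:
            trials.append((t, True, float(rt)))
    return ExoATLog(trials)


def generate_bit_scores(spec: SubtypeSpec, rng: np.random.Generator) -> BITScores:
    """Clipped, rounded normal draws around the subtype subtest means."""
    vals = []
    for mean, sd, hi in zip(spec.bit_means, spec.bit_sds, BIT_MAXIMA):
        v = int(round(rng.normal(mean, sd)))
        vals.append(int(np.clip(v, 0, hi)))
    return BITScores(*vals)


def generate_lesion_volume(spec: SubtypeSpec, volume_shape: tuple[int, int, int],
                           rng: np.random.Generator,
                           background_prob: float = 0.02) -> np.ndarray:
    """Binary lesion mask: Bernoulli background plus spherical foci."""
    vol = rng.random(volume_shape) < background_prob
    if spec.lesion_foci:
        ix = np.indices(volume_shape)
        for focus in spec.lesion_foci:
            c = np.array(focus.center).reshape(3, 1, 1, 1)
            dist2 = ((ix - c) ** 2).sum(axis=0)
            sphere = dist2 <= focus.radius ** 2
            hit = rng.random(volume_shape) < focus.prob
            vol |= sphere & hit
    return vol.astype(np.uint8)


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate the full cohort; bit-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    prevalences = np.array([s.prevalence for s in config.subtypes])
    assignments = rng.choice(len(config.subtypes), size=config.n_patients, p=prevalences)

    patients = []
    for i, k in enumerate(assignments):
        spec = config.subtypes[int(k)]
        rt_base = spec.rt_base
        if spec.patient_rt_sd > 0:
            rt_base = max(100.0, rng.normal(spec.rt_base, spec.patient_rt_sd))
        endo = generate_endoat_log(spec, rng)
        exo = generate_exoat_log(spec, rng, rt_base=rt_base,
                                 timeout_ms=config.response_timeout_ms)
        bit = generate_bit_scores(spec, rng)
        lesion = None
        if config.generate_lesions:
            lesion = generate_lesion_volume(spec, config.volume_shape, rng,
                                            config.background_lesion_prob)
        patients.append(Patient(patient_id=f"P{i:04d}", subtype=spec.id,
                                endo=endo, exo=exo, bit=bit, lesion=lesion))
    return CohortDataset(patients=patients, config=config)


# ---------------------------------------------------------------------------
# reference configurations

def default_cohort_config(n_patients: int = 122, seed: int = 0) -> SimulationConfig:
    """Six-subtype cohort mirroring the canonical neglect-subtype contrasts.

    Subtype 1: global slowing, bilateral misses, right-space reselection, very
    low BIT (low arousal/attention).  Subtype 2: strong left RT gradient and
    left-space misses (exogenous neglect).  Subtype 3: heavy bilateral
    reselection (spatial-working-memory deficit).  Subtypes 4/5: subtle left
    slowing with right vs left initial-selection bias.  Subtype 6: clean
    performance.  Prevalences follow the canonical 6/20/8/50/22/16 of 122
    split.  Lesion foci for subtypes 1-3 sit in distinct regions of the
    bundled toy atlas (perisylvian anterior, temporal, parietal).
    """
    z7 = (0.0,) * 7
    subtypes = [
        SubtypeSpec(
            id=1, prevalence=6 / 122,
            endo_miss_gradient=(0.7, 0.65, 0.6, 0.5, 0.45, 0.4, 0.4),
            reselect_prob=0.25, reselect_space="right",
            start_position_dist={7: 0.9, 14: 0.1}, crossing_style="random",
            rt_base=1500.0, rt_left_gradient=80.0, rt_sd=300.0, patient_rt_sd=120.0,
            exo_miss_gradient=(0.45, 0.4, 0.35, 0.3, 0.3, 0.25, 0.25),
            bit_means=(6, 7, 9, 1, 2, 1), bit_sds=(4, 4, 5, 0.8, 1.2, 0.7),
            lesion_foci=[LesionFocus((6, 16, 10), 3.5),
                         LesionFocus((7, 13, 9), 2.5)],
        ),
        SubtypeSpec(
            id=2, prevalence=20 / 122,
            endo_miss_gradient=(0.75, 0.55, 0.35, 0.15, 0.05, 0.0, 0.0),
            reselect_prob=0.05,
            start_position_dist={7: 0.9, 14: 0.1}, crossing_style="columnwise",
            rt_base=620.0, rt_left_gradient=150.0, rt_sd=140.0, patient_rt_sd=70.0,
            exo_miss_gradient=(0.45, 0.35, 0.25, 0.1, 0.05, 0.0, 0.0),
            bit_means=(25, 28, 38, 3, 6, 2), bit_sds=(3, 3, 4, 0.8, 1.2, 0.7),
            lesion_foci=[LesionFocus((10, 8, 8), 3.5),
                         LesionFocus((12, 12, 10), 2.5)],
        ),
        SubtypeSpec(
            id=3, prevalence=8 / 122,
            endo_miss_gradient=(0.3, 0.2, 0.1, 0.05, 0.0, 0.0, 0.0),
            reselect_prob=0.35,
            start_position_dist={7: 0.4, 14: 0.3, 4: 0.3}, crossing_style="random",
            rt_base=600.0, rt_left_gradient=50.0, rt_sd=110.0, patient_rt_sd=60.0,
            exo_miss_gradient=(0.25, 0.15, 0.1, 0.05, 0.0, 0.0, 0.0),
            bit_means=(31, 34, 45, 3, 7, 2), bit_sds=(3, 3, 4, 0.8, 1.2, 0.7),
            lesion_foci=[LesionFocus((14, 20, 14), 3.5),
                         LesionFocus((16, 17, 15), 2.5)],
        ),
        SubtypeSpec(
            id=4, prevalence=50 / 122,
            endo_miss_gradient=(0.08, 0.05, 0.03, 0.0, 0.0, 0.0, 0.0),
            reselect_prob=0.03,
            start_position_dist={35: 0.9, 28: 0.1}, crossing_style="rowwise",
            rt_base=520.0, rt_left_gradient=40.0, rt_sd=90.0, patient_rt_sd=40.0,
            exo_miss_gradient=(0.06, 0.04, 0.02, 0.0, 0.0, 0.0, 0.0),
            bit_means=(32, 35, 48, 3, 7, 2), bit_sds=(2, 2, 3, 0.6, 1.0, 0.6),
            lesion_foci=[LesionFocus((11, 14, 11), 2.0, prob=0.5)],
        ),
        SubtypeSpec(
            id=5, prevalence=22 / 122,
            endo_miss_gradient=(0.08, 0.05, 0.03, 0.0, 0.0, 0.0, 0.0),
            reselect_prob=0.03,
            start_position_dist={1: 0.9, 8: 0.1}, crossing_style="columnwise",
            rt_base=520.0, rt_left_gradient=40.0, rt_sd=90.0, patient_rt_sd=40.0,
            exo_miss_gradient=(0.06, 0.04, 0.02, 0.0, 0.0, 0.0, 0.0),
            bit_means=(33, 36, 49, 3, 7, 3), bit_sds=(2, 2, 3, 0.6, 1.0, 0.5),
            lesion_foci=[LesionFocus((11, 14, 11), 2.0, prob=0.5)],
        ),
        SubtypeSpec(
            id=6, prevalence=16 / 122,
            endo_miss_gradient=z7,
            reselect_prob=0.01,
            start_position_dist={1: 0.9, 2: 0.1}, crossing_style="columnwise",
            rt_base=450.0, rt_left_gradient=5.0, rt_sd=60.0, patient_rt_sd=35.0,
            exo_miss_gradient=z7,
            bit_means=(35, 39, 53, 4, 9, 3), bit_sds=(1, 1, 1, 0.3, 0.5, 0.3),
            lesion_foci=[],
        ),
    ]
    return SimulationConfig(n_patients=n_patients, subtypes=subtypes, seed=seed)


def interpolate_specs(a: SubtypeSpec, b: SubtypeSpec, t: float) -> SubtypeSpec:
    """Linear interpolation of the numeric fields of two subtypes (for
    simulating recovery paths that morph one behavioral profile into
    another); categorical fields switch at t = 0.5."""
    lerp = lambda x, y: (1 - t) * x + t * y
    near = b if t >= 0.5 else a
    start = dict(near.start_position_dist)
    return SubtypeSpec(
        id=near.id, prevalence=1.0,
        endo_miss_gradient=tuple(lerp(x, y) for x, y in
                                 zip(a.endo_miss_gradient, b.endo_miss_gradient)),
        reselect_prob=lerp(a.reselect_prob, b.reselect_prob),
        reselect_space=near.reselect_space,
        start_position_dist=start, crossing_style=near.crossing_style,
        rt_base=lerp(a.rt_base, b.rt_base),
        rt_left_gradient=lerp(a.rt_left_gradient, b.rt_left_gradient),
        rt_sd=lerp(a.rt_sd, b.rt_sd),
        patient_rt_sd=lerp(a.patient_rt_sd, b.patient_rt_sd),
        exo_miss_gradient=tuple(lerp(x, y) for x, y in
                                zip(a.exo_miss_gradient, b.exo_miss_gradient)),
        bit_means=tuple(lerp(x, y) for x, y in zip(a.bit_means, b.bit_means)),
        bit_sds=near.bit_sds, lesion_foci=list(near.lesion_foci),
    )


def latent_factor_features(n: int, seed: int, n_factors: int = 4,
                           loading: float = math.sqrt(0.75)) -> pd.DataFrame:
    """Synthetic 18-variable table with a planted latent-factor structure.

    The 18 variables are split into ``n_factors`` contiguous groups; each
    variable equals ``loading`` times its group's latent factor plus
    independent unique noise of complementary variance.  This is a harness for
    component-retention behavior, not a behavioral cohort: values are on an
    arbitrary standardized scale.
    """
    from .metrics import FEATURE_COLUMNS

    rng = np.random.default_rng(seed)
    p = len(FEATURE_COLUMNS)
    sizes = [p // n_factors + (1 if i < p % n_factors else 0) for i in range(n_factors)]
    factors = rng.standard_normal((n, n_factors))
    unique_sd = math.sqrt(max(0.0, 1.0 - loading ** 2))
    cols = []
    f = 0
    for k, g in enumerate(sizes):
        for _ in range(g):
            cols.append(loading * factors[:, k] + unique_sd * rng.standard_normal(n))
            f += 1
    data = np.column_stack(cols)
    return pd.DataFrame(data, columns=FEATURE_COLUMNS,
                        index=[f"S{i:04d}" for i in range(n)])


# ---------------------------------------------------------------------------
# on-disk cohort format

def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    """BIT/demographics CSV, JSON-lines task logs, NIfTI lesions, truth CSV,
    config YAML."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bit_rows = []
    with open(out / "task_logs.jsonl", "w") as fh:
        for p in cohort.patients:
            bit_rows.append({"patient_id": p.patient_id, **p.bit.as_dict()})
            rec = {
                "patient_id": p.patient_id,
                "endo": p.endo.selections,
                "exo": [[t, bool(r), None if math.isnan(rt) else rt]
                        for t, r, rt in p.exo.trials],
                "timepoint": p.timepoint,
            }
            fh.write(json.dumps(rec) + "\n")
    pd.DataFrame(bit_rows).to_csv(out / "bit_scores.csv", index=False)
    cohort.truth_labels().rename_axis("patient_id").to_frame().to_csv(out / "truth.csv")

    lesion_dir = out / "lesions"
    for p in cohort.patients:
        if p.lesion is not None:
            lesion_dir.mkdir(exist_ok=True)
            img = nib.Nifti1Image(p.lesion.astype(np.uint8), affine=np.eye(4))
            nib.save(img, lesion_dir / f"{p.patient_id}.nii.gz")

    cfg = dataclasses.asdict(cohort.config)
    for st in cfg["subtypes"]:
        st["endo_miss_gradient"] = list(st["endo_miss_gradient"])
        st["exo_miss_gradient"] = list(st["exo_miss_gradient"])
        st["bit_means"] = list(st["bit_means"])
        st["bit_sds"] = list(st["bit_sds"])
        st["lesion_foci"] = [{"center": list(f["center"]), "radius": f["radius"],
                              "prob": f["prob"]} for f in st["lesion_foci"]]
    cfg["grid_shape"] = list(cfg["grid_shape"])
    cfg["volume_shape"] = list(cfg["volume_shape"])
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))


def read_cohort(in_dir: str | Path) -> CohortDataset:
    import nibabel as nib

    src = Path(in_dir)
    cfg = config_from_yaml(src / "config.yaml")
    bit = pd.read_csv(src / "bit_scores.csv").set_index("patient_id")
    truth = pd.read_csv(src / "truth.csv").set_index("patient_id")["subtype"]

    patients = []
    with open(src / "task_logs.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            pid = rec["patient_id"]
            b = bit.loc[pid]
            trials = [(int(t), bool(r), math.nan if rt is None else float(rt))
                      for t, r, rt in rec["exo"]]
            lesion = None
            lpath = src / "lesions" / f"{pid}.nii.gz"
            if lpath.exists():
                lesion = np.asarray(nib.load(lpath).dataobj).astype(np.uint8)
            patients.append(Patient(
                patient_id=pid, subtype=int(truth.loc[pid]),
                endo=EndoATLog([int(s) for s in rec["endo"]]),
                exo=ExoATLog(trials),
                bit=BITScores(int(b["BIT_Line"]), int(b["BIT_Letter"]),
                              int(b["BIT_Star"]), int(b["BIT_Copy"]),
                              int(b["BIT_Bisect"]), int(b["BIT_Draw"])),
                lesion=lesion, timepoint=rec.get("timepoint")))
    return CohortDataset(patients=patients, config=cfg)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    cfg = yaml.safe_load(Path(path).read_text())
    subtypes = []
    for st in cfg.pop("subtypes"):
        st["lesion_foci"] = [LesionFocus(tuple(f["center"]), f["radius"], f["prob"])
                             for f in st.get("lesion_foci", [])]
        st["endo_miss_gradient"] = tuple(st["endo_miss_gradient"])
        st["exo_miss_gradient"] = tuple(st["exo_miss_gradient"])
        st["bit_means"] = tuple(st["bit_means"])
        st["bit_sds"] = tuple(st["bit_sds"])
        st["start_position_dist"] = {int(k): v for k, v in st["start_position_dist"].items()}
        subtypes.append(SubtypeSpec(**st))
    cfg["grid_shape"] = tuple(cfg["grid_shape"])
    cfg["volume_shape"] = tuple(cfg["volume_shape"])
    return SimulationConfig(subtypes=subtypes, **cfg)
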