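"""Lesion-map analyses: group overlap, cluster subtraction, region summaries,
cosine similarity between maps, and voxel-based lesion-symptom mapping (VLSM).

All volumes in an analysis must share one voxel grid (registration to a
common template is upstream and out of scope).  Overlap maps are the percent
of a group lesioned per voxel; subtraction maps are percentage-point
differences thresholded at a >=50-point criterion, which guards against
overestimating loci when groups are small.  VLSM compares, at every voxel
lesioned in at least ``min_lesion_count`` patients, the behavioral score of
lesioned vs spared patients (Brunner-Munzel by default; Welch t available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats as sps


def load_volume(path: str | Path) -> np.ndarray:
    """Binary lesion mask from NIfTI; any nonzero voxel counts as lesioned."""
    data = np.asarray(nib.load(path).dataobj)
    return (data != 0).astype(np.uint8)


def save_volume(data: np.ndarray, path: str | Path,
                affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, np.float32),
                          affine=np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def _stack(volumes) -> np.ndarray:
    vols = [np.asarray(v) for v in volumes]
    if not vols:
        raise ValueError("empty group: no lesion volumes")
    shape = vols[0].shape
    for v in vols:
        if v.shape != shape:
            raise ValueError(f"volume shapes differ: {v.shape} vs {shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("lesion volumes must be binary")
    return np.stack(vols).astype(float)


def overlap_map(volumes) -> np.ndarray:
    """Per-voxel percent of the group lesioned there, in [0, 100]."""
    stack = _stack(volumes)
    return 100.0 * stack.mean(axis=0)


def subtraction_map(group_a, group_b, criterion_pct: float = 50.0):
    """overlap(A) - overlap(B) with one-sided >=criterion masks both ways.

    Returns ``(diff, mask_a_over_b, mask_b_over_a)``; the difference map is
    antisymmetric in the two groups.
    """
    diff = overlap_map(group_a) - overlap_map(group_b)
    return diff, (diff >= criterion_pct), (-diff >= criterion_pct)


def cosine_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Cosine of the angle between two maps flattened over voxels, in [0, 1]
    for non-negative maps; 0 (with a warning) if either map is empty."""
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share the voxel grid")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity of an empty map is reported as 0")
        return 0.0
    return float(a @ b / (na * nb))


def pairwise_cosine(maps: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(maps)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out.loc[a, b] = out.loc[b, a] = cosine_similarity(maps[a], maps[b])
    return out


# ---------------------------------------------------------------------------
# region atlas

@dataclass
class RegionAtlas:
    """Integer label volume plus a label -> region-name table."""

    labels: np.ndarray
    names: dict[int, str]

    def to_files(self, nii_path: str | Path, tsv_path: str | Path) -> None:
        save_volume(self.labels, nii_path)
        pd.DataFrame({"label": list(self.names), "region": list(self.names.values())}
                     ).to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, nii_path: str | Path, tsv_path: str | Path) -> "RegionAtlas":
        labels = np.asarray(nib.load(nii_path).dataobj).astype(int)
        tab = pd.read_csv(tsv_path, sep="\t")
        return cls(labels, dict(zip(tab["label"], tab["region"])))


TOY_REGIONS = ("insula", "IFGop", "IFGorb", "STG", "MTG", "SMG", "SLF",
               "Rolandic_op", "SPL", "IPL", "AG", "SOG", "PrCUN")


def build_toy_atlas(shape: tuple[int, int, int] = (24, 28, 24)) -> RegionAtlas:
    """Box-parcel atlas with perisylvian/temporal/parietal region names, for
    tests and synthetic cohorts; label 0 is unlabeled background."""
    labels = np.zeros(shape, int)
    nx, ny, nz = shape
    x3, y4, z3 = nx // 3, ny // 4, nz // 3
    boxes = {
        "insula": (slice(x3 - 4, x3 + 2), slice(2 * y4 - 2, 2 * y4 + 6), slice(z3, 2 * z3)),
        "IFGop": (slice(0, x3 - 4), slice(2 * y4 + 2, 3 * y4 + 2), slice(z3, 2 * z3)),
        "IFGorb": (slice(0, x3 - 4), slice(3 * y4 + 2, ny), slice(z3, 2 * z3)),
        "STG": (slice(x3 - 4, x3 + 4), slice(0, y4 + 2), slice(0, z3)),
        "MTG": (slice(x3 + 4, 2 * x3), slice(0, y4 + 2), slice(0, z3)),
        "SMG": (slice(x3 + 2, 2 * x3), slice(y4 + 2, 2 * y4 + 2), slice(z3, 2 * z3)),
        "SLF": (slice(x3 - 2, 2 * x3 + 2), slice(y4, 2 * y4 + 4), slice(2 * z3 - 3, 2 * z3 + 2)),
        "Rolandic_op": (slice(x3 - 2, x3 + 6), slice(2 * y4 + 4, 3 * y4), slice(0, z3)),
        "SPL": (slice(2 * x3, nx), slice(2 * y4, 3 * y4 + 2), slice(2 * z3, nz)),
        "IPL": (slice(2 * x3, nx), slice(y4 + 2, 2 * y4), slice(2 * z3, nz)),
        "AG": (slice(2 * x3 - 4, nx), slice(2 * y4 + 2, 3 * y4 + 2), slice(z3, 2 * z3)),
        "SOG": (slice(2 * x3, nx), slice(0, y4), slice(z3, 2 * z3)),
        "PrCUN": (slice(2 * x3, nx), slice(3 * y4, ny), slice(z3, 2 * z3)),
    }
    names: dict[int, str] = {}
    for lab, (region, box) in enumerate(boxes.items(), start=1):
        region_mask = np.zeros(shape, bool)
        region_mask[box] = True
        labels[region_mask & (labels == 0)] = lab
        names[lab] = region
    return RegionAtlas(labels, names)


def region_summary(value_map: np.ndarray, atlas: RegionAtlas,
                   dominant_pct: float = 50.0) -> pd.DataFrame:
    """Per-region maximum and mean of a map, flagged dominant when the
    maximum reaches ``dominant_pct``."""
    value_map = np.asarray(value_map, float)
    if value_map.shape != atlas.labels.shape:
        raise ValueError("map and atlas must share the voxel grid")
    rows = []
    for lab, region in atlas.names.items():
        vox = value_map[atlas.labels == lab]
        if vox.size == 0:
            continue
        mx, mn = float(vox.max()), float(vox.mean())
        rows.append({"region": region, "max_pct": mx, "mean_pct": mn,
                     "dominant": mx >= dominant_pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VLSM

def vlsm(volumes, scores: np.ndarray, min_lesion_count: int = 5,
         test: str = "brunner-munzel", alpha: float = 0.05,
         n_permutations: int = 0, seed: int = 0) -> dict[str, np.ndarray]:
    """Mass-univariate lesion-symptom mapping of one behavioral score.

    At each voxel lesioned in >= ``min_lesion_count`` patients (and spared in
    at least 2), compare the score between lesioned and spared patients.
    Returns ``stat``, ``p``, ``tested`` (mask) and ``significant`` (p < alpha)
    volumes; untested voxels hold NaN.  Optional max-statistic permutation
    familywise correction adds ``p_fwer``.
    """
    if test not in ("brunner-munzel", "welch"):
        raise ValueError("test must be 'brunner-munzel' or 'welch'")
    stack = _stack(volumes).astype(bool)
    scores = np.asarray(scores, float)
    if stack.shape[0] != scores.shape[0]:
        raise ValueError("one score per patient is required")
    shape = stack.shape[1:]
    lesion_counts = stack.sum(axis=0)
    tested = (lesion_counts >= min_lesion_count) & (lesion_counts <= stack.shape[0] - 2)

    stat = np.full(shape, np.nan)
    pmap = np.full(shape, np.nan)
    idx = np.argwhere(tested)

    def _voxel_stat(lesioned_mask) -> tuple[float, float]:
        a, b = scores[lesioned_mask], scores[~lesioned_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if test == "brunner-munzel":
                res = sps.brunnermunzel(a, b)
            else:
                res = sps.ttest_ind(a, b, equal_var=False)
        s = float(res.statistic)
        p = float(res.pvalue)
        if not np.isfinite(s):
            return np.nan, np.nan
        return s, p

    for v in idx:
        mask = stack[(slice(None), *v)]
        stat[tuple(v)], pmap[tuple(v)] = _voxel_stat(mask)

    out = {"stat": stat, "p": pmap, "tested": tested,
           "significant": np.where(np.isnan(pmap), False, pmap < alpha)}

    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        observed = np.abs(stat[tested])
        max_null = np.empty(n_permutations)
        for b in range(n_permutations):
            perm = rng.permutation(scores)
            vals = []
            for v in idx:
                mask = stack[(slice(None), *v)]
                a, c = perm[mask], perm[~mask]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if test == "brunner-munzel":
                        s = sps.brunnermunzel(a, c).statistic
                    else:
                        s = sps.ttest_ind(a, c, equal_var=False).statistic
                vals.append(abs(s) if np.isfinite(s) else 0.0)
            max_null[b] = max(vals) if vals else 0.0
        p_fwer = np.full(shape, np.nan)
        flat = np.full(observed.shape, np.nan)
        for i, o in enumerate(observed):
            flat[i] = (1 + np.sum(max_null >= o)) / (1 + n_permutations)
        p_fwer[tested] = flat
        out["p_fwer"] = p_fwer
    return out


def vlsm_by_pc(volumes, score_table: pd.DataFrame, **kwargs) -> dict[str, dict[str, np.ndarray]]:
    """VLSM for every PC column of a score table."""
    return {col: vlsm(volumes, score_table[col].to_numpy(float), **kwargs)
            for col in score_table.columns}
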