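"""Segmentation scoring against ground truth and replicate benchmarks.

Unsupervised labels are arbitrary, so predicted and true regions are
first matched one-to-one by maximising total voxel overlap (Hungarian
assignment on the contingency table).  Region agreement is scored with
Dice and Jaccard overlap (empty-vs-empty defined as 1) and with the mean
percent error of region-average TACs.  ``benchmark`` runs the phantom
protocol: per noise replicate it rebuilds the phantom, runs each
clustering method under both voxel representations (raw TACs or FPC
scores) on the three sphere-vs-surrounding-background two-class tasks
and on the five-class whole-image task, and tabulates replicate mean and
SD scores.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import fpca
from .io import LabelVolume, TACTable, ValidationError
from .phantom import PhantomSpec, build_phantom
from .segment import MRFConfig, baseline_cluster, radfit_segment

__all__ = [
    "match_labels",
    "dice",
    "jaccard",
    "generalized_dice",
    "mean_percent_error",
    "evaluate_segmentation",
    "benchmark",
    "two_class_task_mask",
]


def match_labels(pred: LabelVolume, truth: LabelVolume) -> dict:
    """Optimal one-to-one predicted-to-true label assignment.

    Maximises total overlap over the contingency table; predicted labels
    left unmatched (when counts differ) map to None.  Label 0 is outside
    the matching.
    """
    if pred.shape != truth.shape:
        raise ValidationError("label volumes differ in shape")
    p, t = pred.labels, truth.labels
    pl = np.unique(p[p > 0])
    tl = np.unique(t[t > 0])
    cont = np.zeros((pl.size, tl.size), dtype=np.int64)
    for i, a in enumerate(pl):
        ta = t[p == a]
        for j, b in enumerate(tl):
            cont[i, j] = int((ta == b).sum())
    ri, ci = linear_sum_assignment(-cont)
    mapping = {int(a): None for a in pl}
    for i, j in zip(ri, ci):
        mapping[int(pl[i])] = int(tl[j])
    return mapping


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b|/(|a|+|b|); both empty -> 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a&b|/|a|b|; both empty -> 1."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def generalized_dice(pred: LabelVolume, truth: LabelVolume, mapping: dict
                     ) -> float:
    """Overlap-weighted multi-class Dice: sum of intersections over sizes."""
    inter = 0
    size = 0
    for a, b in mapping.items():
        pa = pred.labels == a
        if b is None:
            size += int(pa.sum())
            continue
        tb = truth.labels == b
        inter += int((pa & tb).sum())
        size += int(pa.sum()) + int(tb.sum())
    if size == 0:
        return 1.0
    return 2.0 * inter / size


def mean_percent_error(pred_mean_tac: np.ndarray, true_mean_tac: np.ndarray,
                       eps: float = 1e-9) -> float:
    """Mean over frames of 100*|pred - true|/true.

    Frames where the true value is <= eps (e.g. pre-injection) are
    excluded with a warning; an error is raised if none remain.
    """
    pred = np.asarray(pred_mean_tac, dtype=float)
    true = np.asarray(true_mean_tac, dtype=float)
    if pred.shape != true.shape:
        raise ValidationError("TACs differ in length")
    ok = true > eps
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} frames with true TAC <= eps")
    if not np.any(ok):
        raise ValidationError("no frames with positive true TAC")
    return float(np.mean(100.0 * np.abs(pred[ok] - true[ok]) / true[ok]))


def evaluate_segmentation(pred: LabelVolume, truth: LabelVolume,
                          img=None) -> pd.DataFrame:
    """Per-region Dice/Jaccard (+ TAC percent error when an image is given).

    Rows are true labels; adds a summary row with the generalized Dice.
    """
    mapping = match_labels(pred, truth)
    inv = {b: a for a, b in mapping.items() if b is not None}
    rows = []
    for b in np.unique(truth.labels[truth.labels > 0]):
        b = int(b)
        tb = truth.labels == b
        pa = pred.labels == inv[b] if b in inv else np.zeros_like(tb)
        row = {"region": b, "dice": dice(pa, tb), "jaccard": jaccard(pa, tb)}
        if img is not None and pa.any():
            row["mpe"] = mean_percent_error(
                img.values[pa].mean(axis=0), img.values[tb].mean(axis=0)
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["generalized_dice"] = generalized_dice(pred, truth, mapping)
    return df


# --------------------------------------------------------------------------
# phantom benchmark
# --------------------------------------------------------------------------

def two_class_task_mask(spec: PhantomSpec, truth: LabelVolume,
                        sphere_index: int, box_factor: float = 2.0):
    """Analysis mask for one sphere-vs-surrounding-background task.

    A cube of ``box_factor`` times the sphere diameter centred on the
    sphere, restricted to sphere + background voxels (other regions that
    would leak into the box are excluded).
    """
    sph = spec.spheres[sphere_index]
    half = box_factor * sph.diameter_mm / 2.0 / spec.spacing_mm
    lo = np.maximum(np.floor(np.asarray(sph.center) - half).astype(int), 0)
    hi = np.minimum(np.ceil(np.asarray(sph.center) + half).astype(int) + 1,
                    np.asarray(spec.grid_shape))
    box = np.zeros(spec.grid_shape, dtype=bool)
    box[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    lab = truth.labels
    mask = box & ((lab == 0) | (lab == sphere_index + 1))
    return mask, lab == sphere_index + 1


def _cluster(method, scores, mask, k, seed):
    if method == "radfit":
        cfg = MRFConfig(k=k, seed=seed)
        return radfit_segment(scores, mask, cfg).labels
    return baseline_cluster(scores, method, k, seed=seed,
                            mask_shape=mask.shape)


def _representation(img, mask, representation, var_threshold=0.85):
    tacs = img.tacs(mask)
    if representation == "fpc":
        model = fpca.fit_fpca(tacs, img.schedule, var_threshold=var_threshold)
        return fpca.transform(model, tacs)
    if representation == "tac":
        return fpca.FPCScores(scores=tacs.values.copy(), coords=tacs.coords)
    raise ValidationError(f"unknown representation {representation!r}")


#: sphere indices of the 13-mm two-class tasks in the default layout
TWO_CLASS_SPHERES = {"low": 0, "medium": 1, "high": 2}

#: five-class grouping: background(+nothing), blood, low/medium/high spheres
def _five_class_truth(spec: PhantomSpec, truth: LabelVolume) -> LabelVolume:
    lab = truth.labels
    out = np.zeros_like(lab)
    preset_class = {"low": 2, "medium": 3, "high": 4}
    for i, sph in enumerate(spec.spheres, start=1):
        out[lab == i] = preset_class[sph.preset]
    out[lab == len(spec.spheres) + 1] = 5
    out[out == 0] = 1   # background as an explicit class
    return LabelVolume(labels=out)


def benchmark(spec: PhantomSpec, methods=("hierarchical", "spectral",
                                          "kmeans", "radfit"),
              representations=("tac", "fpc"), replicates: int = 10,
              seed: int = 0, include_five_class: bool = False,
              five_class_methods=("kmeans", "radfit")) -> pd.DataFrame:
    """Replicate-averaged segmentation benchmark on the sphere phantom.

    Replicates vary only the noise seed.  Returns a tidy table with one
    row per (task, representation, method): mean and SD Dice/Jaccard
    over replicates, plus mean TAC percent error; five-class rows report
    the low/medium/high sphere-class Dice and the generalized Dice.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    cells: dict = {}

    for r in range(replicates):
        rep_spec = replace(spec, seed=seed + 1000 * r)
        img, truth = build_phantom(rep_spec)

        for name, si in TWO_CLASS_SPHERES.items():
            mask, sphere = two_class_task_mask(rep_spec, truth, si)
            task_truth = LabelVolume(labels=(sphere & mask).astype(np.int32))
            for rep in representations:
                scores = _representation(img, mask, rep)
                for method in methods:
                    key = (name, rep, method)
                    try:
                        pred = _cluster(method, scores, mask, 2, rep_spec.seed)
                        mapping = match_labels(pred, task_truth)
                        inv = {b: a for a, b in mapping.items() if b is not None}
                        pa = (pred.labels == inv.get(1, -1))
                        row = {
                            "dice": dice(pa, task_truth.labels == 1),
                            "jaccard": jaccard(pa, task_truth.labels == 1),
                            "mpe": mean_percent_error(
                                img.values[pa].mean(axis=0),
                                img.values[task_truth.labels == 1].mean(axis=0),
                            ) if pa.any() else np.nan,
                        }
                    except Exception as exc:
                        warnings.warn(f"{key} failed on replicate {r}: {exc}")
                        row = {"dice": np.nan, "jaccard": np.nan, "mpe": np.nan}
                    cells.setdefault(key, []).append(row)

        if include_five_class:
            truth5 = _five_class_truth(rep_spec, truth)
            full_mask = np.ones(rep_spec.grid_shape, dtype=bool)
            for rep in representations:
                scores = _representation(img, full_mask, rep)
                for method in five_class_methods:
                    key = ("five_class", rep, method)
                    try:
                        pred = _cluster(method, scores, full_mask, 5,
                                        rep_spec.seed)
                        mapping = match_labels(pred, truth5)
                        inv = {b: a for a, b in mapping.items()
                               if b is not None}
                        row = {"gdice": generalized_dice(pred, truth5, mapping)}
                        for cls, cname in ((2, "low"), (3, "medium"),
                                           (4, "high"), (5, "blood")):
                            pa = pred.labels == inv.get(cls, -1)
                            row[f"dice_{cname}"] = dice(pa, truth5.labels == cls)
                    except Exception as exc:
                        warnings.warn(f"{key} failed on replicate {r}: {exc}")
                        row = {"gdice": np.nan}
                    cells.setdefault(key, []).append(row)

    rows = []
    for (task, rep, method), reps in cells.items():
        df = pd.DataFrame(reps)
        row = {"task": task, "representation": rep, "method": method,
               "replicates": len(reps)}
        for col in df.columns:
            row[f"{col}_mean"] = float(df[col].mean())
            row[f"{col}_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
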