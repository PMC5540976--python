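"""Preference-replicability index: do training-data voxel preferences generalize?

For each cross-validation fold, the training and test contrast vectors
(one signed t-contrast per voxel, reference minus anti-reference
condition) are compared over each preference-defined voxel set by a
cosine-type statistic:

    index = <t_train, t_test> / (||t_train|| * ||t_test||)

Unlike a Pearson correlation there is *no* mean-centering: the regression
intercept is pinned at the origin, so a positive index requires the signs
of the per-voxel contrasts to replicate.  The index lies in [-1, 1], is
symmetric about 0 under the null of no replicability, and is expected to
be *negative* for a voxel set whose training-data preference was pure
noise (such voxels revert toward the true contrast in test data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PatternDataset
from .decoding import FoldPlan, make_folds
from .errors import InvalidParameterError, UndefinedIndexError
from .geometry import LABEL_PAIRS
from .preference import label_voxel_preferences, reference_condition_index, signed_contrast


def replicability_index(t_train: np.ndarray, t_test: np.ndarray) -> float:
    """Normalized inner product of train/test t-vectors (no centering)."""
    u = np.asarray(t_train, dtype=float)
    v = np.asarray(t_test, dtype=float)
    if u.shape != v.shape:
        raise InvalidParameterError("train and test vectors must share voxel ordering")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedIndexError("zero-norm t-vector: index undefined")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class ReplicabilityResult:
    """Fold-averaged indices per subject x orientation set x ROI.

    ``per_subject`` columns: subject, kind, set_label, roi, index,
    n_folds_used.  ROI names: "combined", "patch1".."patch4",
    "band0".."band2".
    """

    per_subject: pd.DataFrame

    def group_table(self, n_boot: int = 10000, seed=0) -> pd.DataFrame:
        """Group mean, bootstrap CI95 and one-sided p per (set, ROI) cell."""
        rows = []
        for (kind, set_label, roi), grp in self.per_subject.groupby(
            ["kind", "set_label", "roi"], sort=False
        ):
            vals = grp["index"].dropna().to_numpy()
            row = dict(kind=kind, set_label=set_label, roi=roi, n_subjects=len(vals))
            if len(vals) >= 2:
                bt = bootstrap_group_test(vals, n_boot=n_boot, seed=seed)
                row.update(mean_index=bt.mean, ci_low=bt.ci_low, ci_high=bt.ci_high,
                           p_one_sided=bt.p)
            else:
                row.update(mean_index=np.nan, ci_low=np.nan, ci_high=np.nan,
                           p_one_sided=np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


def _roi_masks(dataset: PatternDataset) -> dict[str, np.ndarray]:
    masks = {"combined": np.ones(dataset.n_voxels, dtype=bool)}
    for pid in sorted({p.patch_id for p in dataset.patches}):
        masks[f"patch{pid}"] = dataset.roi_mask(patch_id=pid)
    for band in sorted(dataset.voxels["ecc_band"].unique()):
        masks[f"band{band}"] = dataset.roi_mask(band=band)
    return masks


def _contrast_vector(dataset, subject, kind, subruns, ref_idx, method):
    """Signed per-voxel contrast over the given subruns.

    ``mean_difference``: plain mean of per-subrun t-differences (default
    reading for pattern-level data, where patterns already are t-values).
    ``tstat``: one-sample t across the per-(run, subrun) differences —
    the contrast-t-map reading; requires >= 2 contributing subruns.
    """
    if method == "mean_difference":
        return signed_contrast(dataset, subject, kind, subruns, ref_idx)
    if method != "tstat":
        raise InvalidParameterError(f"unknown contrast method {method!r}")
    ik = dataset.kind_index(kind)
    block = dataset.t[subject, ik][:, tuple(subruns)]
    diff = (block[..., 0, :] - block[..., 1, :]).reshape(-1, dataset.n_voxels)
    sign = np.where(ref_idx == 0, 1.0, -1.0)
    diff = sign * diff
    m = diff.mean(axis=0)
    if diff.shape[0] < 2:
        raise InvalidParameterError("tstat contrast requires >= 2 (run, subrun) samples")
    se = diff.std(axis=0, ddof=1) / np.sqrt(diff.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, m / se, 0.0)


def crossval_replicability(
    dataset: PatternDataset,
    folds: list[FoldPlan] | None = None,
    kinds=None,
    method: str = "mean_difference",
) -> ReplicabilityResult:
    """Fold-averaged replicability index per subject, orientation set and ROI.

    Per fold, voxel sets (reference- vs anti-preferring) come from the
    training subruns only; the index compares the training contrast vector
    with the held-out test contrast vector over each set intersected with
    each ROI.  Folds with an empty set or a zero-norm vector are excluded
    from the average (never imputed); a cell with no usable fold is NaN.
    """
    folds = folds or make_folds(dataset.n_subruns)
    kinds = kinds or dataset.kinds
    rows = []
    for subject in range(dataset.n_subjects):
        for kind in kinds:
            ref_idx = reference_condition_index(dataset, kind)
            names = LABEL_PAIRS[kind]
            masks = _roi_masks(dataset)
            acc: dict[tuple[str, str], list[float]] = {}
            for plan in folds:
                labels = label_voxel_preferences(dataset, subject, kind, plan.train_subruns)
                c_train = _contrast_vector(
                    dataset, subject, kind, plan.train_subruns, ref_idx, method)
                c_test = _contrast_vector(
                    dataset, subject, kind, (plan.test_subrun,), ref_idx, "mean_difference"
                    if method == "mean_difference" else method)
                for sign, set_label in zip((1, -1), names):
                    in_set = labels.label == sign
                    for roi, mask in masks.items():
                        sel = in_set & mask
                        if not sel.any():
                            continue
                        try:
                            idx = replicability_index(c_train[sel], c_test[sel])
                        except UndefinedIndexError:
                            continue
                        acc.setdefault((set_label, roi), []).append(idx)
            for (set_label, roi) in [(s, r) for s in names for r in masks]:
                vals = acc.get((set_label, roi), [])
                rows.append(dict(
                    subject=subject, kind=kind, set_label=set_label, roi=roi,
                    index=float(np.mean(vals)) if vals else np.nan,
                    n_folds_used=len(vals),
                ))
    return ReplicabilityResult(per_subject=pd.DataFrame(rows))


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    p: float
    n_boot: int


def bootstrap_group_test(values, n_boot: int = 10000, seed=0) -> BootstrapResult:
    """Participant bootstrap: percentile CI95 and one-sided p for mean > 0.

    Subjects are resampled with replacement; the add-one estimator
    p = (1 + #{resampled means < 0} + 0.5 * #{resampled means == 0})
    / (n_boot + 1) avoids p = 0.  Resampled means exactly at zero carry
    half weight so the estimator stays centered at 0.5 under a symmetric
    null even when the values have an atom at a balanced split; for
    continuous data this coincides with counting means <= 0.
    Deterministic given ``seed``.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InvalidParameterError("need >= 2 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    p = (1 + np.sum(means < 0) + 0.5 * np.sum(means == 0)) / (n_boot + 1)
    return BootstrapResult(
        mean=float(vals.mean()), ci_low=float(lo), ci_high=float(hi), p=float(p),
        n_boot=n_boot,
    )


def roi_effect_anova(
    result: ReplicabilityResult, factor: str, kinds=None
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of the index across ROI levels, per set.

    ``factor`` is "quarterfield" (levels patch1..4) or "eccentricity"
    (levels band0..2); subjects are the observations within each level.
    With both factors this yields the 4 orientation sets x 2 factors = 8
    tests of the ROI-effect analysis.
    """
    prefix = {"quarterfield": "patch", "eccentricity": "band"}.get(factor)
    if prefix is None:
        raise InvalidParameterError(f"unknown factor {factor!r}")
    df = result.per_subject
    df = df[df["roi"].str.startswith(prefix)]
    rows = []
    for (kind, set_label), grp in df.groupby(["kind", "set_label"], sort=False):
        groups = [g["index"].dropna().to_numpy() for _, g in grp.groupby("roi")]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            raise InvalidParameterError(
                f"need >= 2 factor levels with >= 2 subjects each for {set_label}"
            )
        f, p = stats.f_oneway(*groups)
        rows.append(dict(kind=kind, set_label=set_label, factor=factor,
                         F=float(f), p=float(p), n_levels=len(groups)))
    return pd.DataFrame(rows)
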