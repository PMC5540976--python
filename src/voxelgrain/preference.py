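"""Voxel orientation-preference labeling and group preference summaries.

A voxel's preference is the sign of its mean training t-difference between
the patch-relative reference condition (radial for gratings, vertical for
spirals) and the orthogonal condition.  Labels are always derived from
training subruns only, so a preference that is mere noise cannot
replicate into test data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PatternDataset
from .errors import DegenerateDataError, InvalidFoldError
from .geometry import LABEL_PAIRS, condition_label_map, stimulus_pair


def reference_condition_index(dataset: PatternDataset, kind: str) -> np.ndarray:
    """Per-voxel index (0/1) of the condition carrying the reference label.

    For gratings the reference is the patch-relative *radial* condition;
    for spirals the *vertical* one.  Constant within a patch, varying
    across patches.
    """
    pair = stimulus_pair(kind)
    ref_label = LABEL_PAIRS[kind][0]
    conditions = dataset.conditions(kind)
    per_patch = {}
    for p in dataset.patches:
        cmap = condition_label_map(pair, p, dataset.annulus)
        (ref_variant,) = [v for v, lab in cmap.items() if lab == ref_label]
        per_patch[p.patch_id] = conditions.index(ref_variant)
    return dataset.voxels["patch_id"].map(per_patch).to_numpy()


@dataclass
class PreferenceLabels:
    """Per-voxel signed training contrast and preference label for one fold.

    ``delta_t`` is the mean training t-difference, reference minus
    anti-reference condition; ``label`` is +1 (reference-preferring),
    -1 (anti-preferring) or 0 (exact tie, excluded from both sets).
    """

    kind: str
    delta_t: np.ndarray
    label: np.ndarray
    train_subruns: tuple[int, ...]
    ref_condition: np.ndarray  # per-voxel index of the reference condition

    @property
    def label_names(self) -> tuple[str, str]:
        return LABEL_PAIRS[self.kind]


def signed_contrast(
    dataset: PatternDataset, subject: int, kind: str, subruns, ref_idx=None
) -> np.ndarray:
    """Mean reference-minus-anti t-difference over the given subruns (both runs)."""
    subruns = tuple(subruns)
    if len(subruns) == 0:
        raise InvalidFoldError("empty training set")
    ik = dataset.kind_index(kind)
    if ref_idx is None:
        ref_idx = reference_condition_index(dataset, kind)
    block = dataset.t[subject, ik][:, subruns]  # (runs, subruns, conditions, voxels)
    diff = block[..., 0, :] - block[..., 1, :]  # condition0 - condition1
    sign = np.where(ref_idx == 0, 1.0, -1.0)
    return sign * diff.mean(axis=(0, 1))


def label_voxel_preferences(
    dataset: PatternDataset, subject: int, kind: str, train_subruns
) -> PreferenceLabels:
    """Label every voxel from training subruns only (one cross-validation fold)."""
    ref_idx = reference_condition_index(dataset, kind)
    delta = signed_contrast(dataset, subject, kind, train_subruns, ref_idx)
    label = np.sign(delta).astype(np.int8)
    return PreferenceLabels(
        kind=kind,
        delta_t=delta,
        label=label,
        train_subruns=tuple(train_subruns),
        ref_condition=ref_idx,
    )


def split_voxel_sets(labels: PreferenceLabels) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint voxel index sets (reference-preferring, anti-preferring).

    Either set may be empty; callers record such folds as missing rather
    than imputing.
    """
    ref = np.flatnonzero(labels.label > 0)
    anti = np.flatnonzero(labels.label < 0)
    return ref, anti


@dataclass
class PreferenceSummary:
    """Fig-2-style group summary of voxel preferences for one stimulus kind."""

    kind: str
    per_subject: pd.DataFrame  # subject, n_ref, n_anti, pct_ref, pct_anti, mean_contrast
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    pooled_pct_ref: float  # voxel-pooled across subjects
    subject_mean_pct_ref: float  # subjects weighted equally
    mean_contrast_psc: float  # mean reference-minus-anti response, %-signal-change
    ttest_statistic: float
    ttest_p: float

    @property
    def label_names(self):
        return LABEL_PAIRS[self.kind]


def preference_proportions(
    dataset: PatternDataset, kind: str, bins: int = 41, hist_range: float | None = None
) -> PreferenceSummary:
    """Pooled preference histogram, per-subject proportions and the group test.

    Uses all subruns (no cross-validation: this mirrors the descriptive
    histogram/proportion analysis, not the decoding one).  The group test
    is a two-sided one-sample t-test across subjects of the within-subject
    percentage-point difference (reference% minus anti%), subject as
    random effect.  The mean %-signal-change contrast comes from the
    simulator's noise-free amplitude channel when present, else from the
    measured t-contrast (whose units are pattern units).
    """
    if dataset.n_subjects < 2:
        raise DegenerateDataError("group test requires >= 2 subjects")
    all_subruns = range(dataset.n_subruns)
    ref_idx = reference_condition_index(dataset, kind)
    rows, deltas = [], []
    for s in range(dataset.n_subjects):
        delta = signed_contrast(dataset, s, kind, all_subruns, ref_idx)
        labeled = delta != 0
        n_ref = int(np.sum(delta > 0))
        n_anti = int(np.sum(delta < 0))
        if n_ref + n_anti == 0:
            import warnings

            warnings.warn(f"subject {s}: zero labeled voxels, dropped from group test")
            continue
        pct_ref = 100.0 * n_ref / (n_ref + n_anti)
        if dataset.amplitudes is not None:
            ik = dataset.kind_index(kind)
            amp = dataset.amplitudes[s, ik]
            sign = np.where(ref_idx == 0, 1.0, -1.0)
            contrast = float(np.mean(sign * (amp[0] - amp[1])))
        else:
            contrast = float(np.mean(delta))
        rows.append(
            dict(subject=s, n_ref=n_ref, n_anti=n_anti, pct_ref=pct_ref,
                 pct_anti=100.0 - pct_ref, mean_contrast=contrast)
        )
        deltas.append(delta[labeled])
    per_subject = pd.DataFrame(rows)
    pooled = np.concatenate(deltas)
    if hist_range is None:
        hist_range = float(np.max(np.abs(pooled))) or 1.0
    counts, edges = np.histogram(pooled, bins=bins, range=(-hist_range, hist_range))
    diffs = per_subject["pct_ref"] - per_subject["pct_anti"]
    if np.isclose(diffs.std(ddof=1), 0.0):
        # zero between-subject variance: descriptive summary still valid,
        # the group test is undefined
        import warnings

        warnings.warn("degenerate group test: zero variance of %-point differences")
        tt_statistic, tt_p = np.nan, np.nan
    else:
        tt = stats.ttest_1samp(diffs, 0.0)
        tt_statistic, tt_p = float(tt.statistic), float(tt.pvalue)
    return PreferenceSummary(
        kind=kind,
        per_subject=per_subject,
        hist_counts=counts,
        hist_edges=edges,
        pooled_pct_ref=100.0 * float(np.mean(pooled > 0)),
        subject_mean_pct_ref=float(per_subject["pct_ref"].mean()),
        mean_contrast_psc=float(per_subject["mean_contrast"].mean()),
        ttest_statistic=tt_statistic,
        ttest_p=tt_p,
    )
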