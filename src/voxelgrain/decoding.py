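"""Cross-validated linear SVM decoding of stimulus condition from t-patterns.

Cross-validation is four-fold over the subrun index: fold k holds out
subrun k of *both* runs as test data (4 test patterns: 2 conditions x 2
runs) and trains on the remaining 6 subruns (12 patterns).  Voxel
preference labels, when a preferred-set selection is requested, are
recomputed inside every fold from that fold's training subruns only —
there is no test leakage by construction.

The classifier is a linear two-class maximum-margin SVM with fixed cost
C = 1 and no feature scaling (inputs are t-values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .datasets import PatternDataset
from .errors import InvalidParameterError
from .geometry import LABEL_PAIRS
from .groupstats import wilcoxon_signed_rank
from .preference import label_voxel_preferences, split_voxel_sets

SELECTIONS = ("all", "prefA", "prefB")  # prefA = radial/vertical, prefB = tangential/horizontal

#: In-plane grid axis shift directions (dy, dx) for the flat 2D sheet.
GRID_DIRECTIONS = ((0, 1), (0, -1), (1, 0), (-1, 0))


@dataclass(frozen=True)
class FoldPlan:
    """One cross-validation fold over the subrun index."""

    fold: int
    test_subrun: int
    train_subruns: tuple[int, ...]


def make_folds(n_subruns: int = 4) -> list[FoldPlan]:
    """The four-fold subrun-index plan (generalizes, with a warning, to other counts)."""
    if n_subruns < 2:
        raise InvalidParameterError("need at least 2 subruns to cross-validate")
    if n_subruns != 4:
        warnings.warn(f"generalized {n_subruns}-fold subrun plan (canonical design has 4)")
    return [
        FoldPlan(fold=k, test_subrun=k,
                 train_subruns=tuple(s for s in range(n_subruns) if s != k))
        for k in range(n_subruns)
    ]


@dataclass(frozen=True)
class ShiftSpec:
    """Spatial shift of test patterns, in voxels along a grid axis.

    Allowed magnitudes are 0, 0.5, 1, 2, 3 voxels (0, 1, 2, 4, 6 mm at
    2-mm voxels).  A half-voxel shift is realized by interpolation: the
    average of two adjacent voxels.
    """

    magnitude: float
    voxel_mm: float = 2.0

    ALLOWED = (0.0, 0.5, 1.0, 2.0, 3.0)

    def __post_init__(self):
        if self.magnitude not in self.ALLOWED:
            raise InvalidParameterError(
                f"shift magnitude {self.magnitude} not in {self.ALLOWED}"
            )

    @property
    def mm(self) -> float:
        return self.magnitude * self.voxel_mm


def shift_mm_to_voxels(mm: float, voxel_mm: float = 2.0) -> ShiftSpec:
    return ShiftSpec(magnitude=mm / voxel_mm, voxel_mm=voxel_mm)


def _shift_index_map(grid_shape, magnitude: float, direction):
    """(valid, src_a, src_b, w) flat per-patch index arrays for one shift.

    Target voxel i takes value w*pattern[src_a[i]] + (1-w)*pattern[src_b[i]];
    voxels whose source falls outside the grid are excluded from ``valid``.
    """
    dy, dx = direction
    if (dy, dx) not in GRID_DIRECTIONS:
        raise InvalidParameterError(f"direction {direction} is not a grid axis")
    ny, nx = grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    lo = int(np.floor(magnitude))
    hi = int(np.ceil(magnitude))
    w = 1.0 - (magnitude - lo)
    ya, xa = yy + dy * lo, xx + dx * lo
    yb, xb = yy + dy * hi, xx + dx * hi
    valid = (ya >= 0) & (ya < ny) & (xa >= 0) & (xa < nx) \
        & (yb >= 0) & (yb < ny) & (xb >= 0) & (xb < nx)
    src_a = (ya * nx + xa)[valid]
    src_b = (yb * nx + xb)[valid]
    return valid.ravel(), src_a, src_b, w


def shift_patterns(
    patterns: np.ndarray,
    dataset: PatternDataset,
    shift: ShiftSpec,
    direction,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift patterns on each patch's voxel grid; drop out-of-grid voxels.

    ``patterns`` is (..., n_voxels) in the dataset's voxel order.  Returns
    (shifted patterns over the retained voxels, retained voxel indices).
    Training-side views must be restricted to the same retained indices so
    that train and test see identical voxel sets (symmetric dropping, no
    zero-padding).
    """
    valid, src_a, src_b, w = _shift_index_map(dataset.grid_shape, shift.magnitude, direction)
    nv_patch = dataset.grid_shape[0] * dataset.grid_shape[1]
    n_patches = dataset.n_voxels // nv_patch
    keep_idx, out = [], []
    for p in range(n_patches):
        base = p * nv_patch
        keep_idx.append(base + np.flatnonzero(valid))
        block = patterns[..., base:base + nv_patch]
        out.append(w * block[..., src_a] + (1.0 - w) * block[..., src_b])
    return np.concatenate(out, axis=-1), np.concatenate(keep_idx)


def _classifier():
    return SVC(kernel="linear", C=1.0)


def _fold_patterns(dataset, subject, kind, plan):
    """(train X, train y, test X, test y) raw pattern matrices for one fold."""
    ik = dataset.kind_index(kind)
    block = dataset.t[subject, ik]  # (runs, subruns, conditions, voxels)
    tr = block[:, plan.train_subruns]  # (runs, 3, 2, V)
    te = block[:, plan.test_subrun]  # (runs, 2, V)
    nv = block.shape[-1]
    Xtr = tr.reshape(-1, nv)
    ytr = np.broadcast_to(np.arange(2)[None, None, :], tr.shape[:3]).ravel()
    Xte = te.reshape(-1, nv)
    yte = np.broadcast_to(np.arange(2)[None, :], te.shape[:2]).ravel()
    return Xtr, ytr, Xte, yte


def _selection_mask(dataset, subject, kind, plan, selection):
    if selection == "all":
        return np.ones(dataset.n_voxels, dtype=bool)
    labels = label_voxel_preferences(dataset, subject, kind, plan.train_subruns)
    ref, anti = split_voxel_sets(labels)
    idx = ref if selection == "prefA" else anti
    mask = np.zeros(dataset.n_voxels, dtype=bool)
    mask[idx] = True
    return mask


@dataclass
class DecodingResult:
    """Per-fold accuracies plus group-level summaries.

    ``per_fold`` columns: subject, kind, selection, shift_mm, direction,
    fold, n_test, accuracy (NaN where a fold was skipped for an empty
    voxel selection).
    """

    per_fold: pd.DataFrame

    def per_subject(self) -> pd.DataFrame:
        """Mean accuracy per subject (directions averaged within subject first)."""
        by_dir = (
            self.per_fold.groupby(
                ["subject", "kind", "selection", "shift_mm", "direction"], dropna=False
            )["accuracy"].mean().reset_index()
        )
        return (
            by_dir.groupby(["subject", "kind", "selection", "shift_mm"])["accuracy"]
            .mean().reset_index()
        )

    def group_summary(self, chance: float = 0.5) -> pd.DataFrame:
        """Mean accuracy and one-sided signed-rank test vs chance per cell."""
        rows = []
        for (kind, sel, shift), grp in self.per_subject().groupby(
            ["kind", "selection", "shift_mm"]
        ):
            acc = grp["accuracy"].dropna().to_numpy()
            row = dict(kind=kind, selection=sel, shift_mm=shift,
                       n_subjects=len(acc), mean_accuracy=np.nan, p_vs_chance=np.nan)
            if len(acc):
                row["mean_accuracy"] = float(acc.mean())
                try:
                    res = wilcoxon_signed_rank(acc, mu=chance, alternative="greater")
                    row["p_vs_chance"] = res.p
                except Exception:
                    pass
            rows.append(row)
        return pd.DataFrame(rows)

    def paired_selection_test(self, kind: str, sel_a: str = "prefA", sel_b: str = "prefB",
                              shift_mm: float = 0.0):
        """Two-sided signed-rank test between two voxel selections."""
        ps = self.per_subject()
        a = ps.query("kind == @kind and selection == @sel_a and shift_mm == @shift_mm")
        b = ps.query("kind == @kind and selection == @sel_b and shift_mm == @shift_mm")
        merged = a.merge(b, on="subject", suffixes=("_a", "_b")).dropna()
        return wilcoxon_signed_rank(
            merged["accuracy_a"].to_numpy() - merged["accuracy_b"].to_numpy(),
            mu=0.0, alternative="two-sided",
        )


def _decode_fold(dataset, subject, kind, plan, selection, shift=None, direction=None):
    """Accuracy of one fold, or NaN for an empty voxel selection."""
    mask = _selection_mask(dataset, subject, kind, plan, selection)
    if not mask.any():
        return np.nan, 0
    Xtr, ytr, Xte, yte = _fold_patterns(dataset, subject, kind, plan)
    if shift is not None and shift.magnitude > 0:
        Xte, keep = shift_patterns(Xte, dataset, shift, direction)
        sel = mask[keep]
        if not sel.any():
            return np.nan, 0
        Xtr = Xtr[:, keep][:, sel]
        Xte = Xte[:, sel]
    else:
        Xtr = Xtr[:, mask]
        Xte = Xte[:, mask]
    clf = _classifier()
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    return float(np.mean(pred == yte)), len(yte)


def train_test_decode(
    dataset: PatternDataset,
    folds: list[FoldPlan] | None = None,
    selections=("all",),
    kinds=None,
    shifts=(0.0,),
    directions=GRID_DIRECTIONS,
) -> DecodingResult:
    """Cross-validated decoding accuracy per subject/kind/selection/shift.

    ``shifts`` are magnitudes in mm (0, 1, 2, 4, 6 at 2-mm voxels); shifted
    test accuracies are recorded per direction and averaged within subject
    by :meth:`DecodingResult.per_subject`.
    """
    if isinstance(selections, str):
        selections = (selections,)
    folds = folds or make_folds(dataset.n_subruns)
    kinds = kinds or dataset.kinds
    voxel_mm = 2.0
    rows = []
    for subject in range(dataset.n_subjects):
        for kind in kinds:
            for sel in selections:
                if sel not in SELECTIONS:
                    raise InvalidParameterError(f"unknown selection {sel!r}")
                for mm in shifts:
                    spec = shift_mm_to_voxels(mm, voxel_mm)
                    dirs = [None] if spec.magnitude == 0 else list(directions)
                    for d in dirs:
                        for plan in folds:
                            acc, n = _decode_fold(
                                dataset, subject, kind, plan, sel,
                                shift=spec if spec.magnitude > 0 else None, direction=d,
                            )
                            rows.append(dict(
                                subject=subject, kind=kind, selection=sel, shift_mm=mm,
                                direction="none" if d is None else f"{d[0]},{d[1]}",
                                fold=plan.fold, n_test=n, accuracy=acc,
                            ))
    return DecodingResult(per_fold=pd.DataFrame(rows))


def shift_decoding_curve(
    dataset: PatternDataset,
    folds=None,
    selections=("all", "prefA", "prefB"),
    shifts_mm=(0.0, 1.0, 2.0, 4.0, 6.0),
    kinds=None,
) -> DecodingResult:
    """Decoding accuracy as a function of test-pattern shift magnitude."""
    return train_test_decode(
        dataset, folds=folds, selections=selections, kinds=kinds, shifts=shifts_mm
    )
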