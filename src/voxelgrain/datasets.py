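"""PatternDataset: t-value patterns indexed by (subject, kind, run, subrun, condition, voxel).

This is the universal currency of the pipeline.  Voxels are stored
patch-major: for each quarterfield patch in ``patches`` order, a row-major
(ny, nx) grid where the y axis runs along eccentricity (row 0 = fovea-most)
and the x axis along polar angle.  That layout is what the spatial-shift
analysis relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import DEFAULT_ANNULUS, AnnulusSpec, PatchSpec, quarterfield_patches

CONDITION_ORDER = {"grating": ("plus45", "minus45"), "spiral": ("clockwise", "anticlockwise")}


@dataclass
class PatternDataset:
    """t-patterns plus voxel metadata.

    Attributes
    ----------
    t : ndarray, shape (n_subjects, n_kinds, n_runs, n_subruns, n_conditions, n_voxels)
    voxels : DataFrame with columns patch_id, ecc_band, x, y, polar, ecc
    kinds : tuple of stimulus kinds, matching axis 1 of ``t``
    grid_shape : (ny, nx) voxel grid of each patch
    amplitudes : optional noise-free per-voxel response amplitudes in
        %-signal-change, shape (n_subjects, n_kinds, n_conditions, n_voxels);
        present when the simulator generated the data (the "%-signal-change
        channel" used by preference summaries).
    """

    t: np.ndarray
    voxels: pd.DataFrame
    kinds: tuple[str, ...]
    grid_shape: tuple[int, int]
    patches: list[PatchSpec]
    amplitudes: np.ndarray | None = None
    baseline: float = 2.0
    annulus: AnnulusSpec = DEFAULT_ANNULUS

    def __post_init__(self):
        if self.t.ndim != 6:
            raise InvalidParameterError("t must be 6-dimensional")
        if len(self.kinds) != self.t.shape[1]:
            raise InvalidParameterError("kinds length must match t axis 1")
        if self.t.shape[-1] != len(self.voxels):
            raise InvalidParameterError("voxel metadata must match t axis 5")
        if not np.all(np.isfinite(self.t)):
            raise InvalidParameterError("t-patterns must be finite")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.t.shape[0]

    @property
    def n_runs(self) -> int:
        return self.t.shape[2]

    @property
    def n_subruns(self) -> int:
        return self.t.shape[3]

    @property
    def n_voxels(self) -> int:
        return self.t.shape[-1]

    def kind_index(self, kind: str) -> int:
        return self.kinds.index(kind)

    def conditions(self, kind: str) -> tuple[str, str]:
        return CONDITION_ORDER[kind]

    def roi_mask(self, patch_id: int | None = None, band: int | None = None) -> np.ndarray:
        """Boolean voxel mask for a quarterfield patch and/or eccentricity band."""
        mask = np.ones(self.n_voxels, dtype=bool)
        if patch_id is not None:
            mask &= (self.voxels["patch_id"] == patch_id).to_numpy()
        if band is not None:
            mask &= (self.voxels["ecc_band"] == band).to_numpy()
        return mask

    # -- serialization -----------------------------------------------------
    def tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (subject, kind, run, subrun, condition, voxel)."""
        ns, nk, nr, nsub, nc, nv = self.t.shape
        idx = pd.MultiIndex.from_product(
            [range(ns), list(self.kinds), range(nr), range(nsub), range(nc), range(nv)],
            names=["subject", "stimulus_kind", "run", "subrun", "condition_idx", "voxel"],
        )
        df = pd.DataFrame({"t_value": self.t.ravel()}, index=idx).reset_index()
        df["condition"] = [
            CONDITION_ORDER[k][c] for k, c in zip(df["stimulus_kind"], df["condition_idx"])
        ]
        meta = self.voxels.reset_index(drop=True)
        for col in ("patch_id", "ecc_band", "x", "y"):
            df[col] = meta[col].to_numpy()[df["voxel"].to_numpy()]
        return df.drop(columns=["condition_idx"])[
            ["subject", "stimulus_kind", "run", "subrun", "condition",
             "patch_id", "ecc_band", "x", "y", "voxel", "t_value"]
        ]

    def to_tsv(self, path) -> None:
        self.tidy().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, grid_shape=None, patches=None, baseline: float = 2.0):
        """Rebuild a dataset from the tidy TSV format (amplitude channel is not stored)."""
        df = pd.read_csv(path, sep="\t")
        kinds = tuple(sorted(df["stimulus_kind"].unique(), key=["grating", "spiral"].index))
        subjects = np.sort(df["subject"].unique())
        runs = np.sort(df["run"].unique())
        subruns = np.sort(df["subrun"].unique())
        voxels = np.sort(df["voxel"].unique())
        shape = (len(subjects), len(kinds), len(runs), len(subruns), 2, len(voxels))
        t = np.full(shape, np.nan)
        cond_idx = np.array(
            [CONDITION_ORDER[k].index(c) for k, c in zip(df["stimulus_kind"], df["condition"])]
        )
        t[
            df["subject"].map({s: i for i, s in enumerate(subjects)}),
            df["stimulus_kind"].map({k: i for i, k in enumerate(kinds)}),
            df["run"].map({r: i for i, r in enumerate(runs)}),
            df["subrun"].map({s: i for i, s in enumerate(subruns)}),
            cond_idx,
            df["voxel"].map({v: i for i, v in enumerate(voxels)}),
        ] = df["t_value"]
        meta = (
            df.drop_duplicates("voxel")
            .sort_values("voxel")[["patch_id", "ecc_band", "x", "y"]]
            .reset_index(drop=True)
        )
        meta["polar"] = np.nan
        meta["ecc"] = np.nan
        if grid_shape is None:
            ny = int(meta.groupby("patch_id")["y"].max().iloc[0]) + 1
            nx = int(meta.groupby("patch_id")["x"].max().iloc[0]) + 1
            grid_shape = (ny, nx)
        return cls(
            t=t,
            voxels=meta,
            kinds=kinds,
            grid_shape=grid_shape,
            patches=patches or quarterfield_patches(),
            baseline=baseline,
        )

    def to_nifti(self, outdir, voxel_mm: float = 2.0) -> None:
        """Export mean per-condition t-volumes and an integer ROI label mask.

        The four patch grids are laid side by side (with a one-voxel gap) in
        a single synthetic axial slab; this is a convenience volume for
        viewing in standard tools, not an anatomical reconstruction.
        """
        import pathlib

        import nibabel as nib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ny, nx = self.grid_shape
        n_patch = len({p.patch_id for p in self.patches})
        vol_shape = (n_patch * (nx + 1) - 1, ny, 1)
        affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])

        def blank():
            return np.zeros(vol_shape, dtype=float)

        label = blank()
        xs = self.voxels["x"].to_numpy()
        ys = self.voxels["y"].to_numpy()
        pids = self.voxels["patch_id"].to_numpy()
        gx = (pids - 1) * (nx + 1) + xs
        label[gx, ys, 0] = pids
        nib.save(nib.Nifti1Image(label.astype(np.int16), affine), outdir / "roi_labels.nii")
        mean_t = self.t.mean(axis=(0, 2, 3))  # kinds x conditions x voxels
        for ik, kind in enumerate(self.kinds):
            for ic, cond in enumerate(CONDITION_ORDER[kind]):
                vol = blank()
                vol[gx, ys, 0] = mean_t[ik, ic]
                nib.save(
                    nib.Nifti1Image(vol, affine), outdir / f"mean_t_{kind}_{cond}.nii"
                )
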