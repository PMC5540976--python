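"""Synthetic V1 generator: orientation maps, coarse biases, gain field, noise.

Each quarterfield ROI patch is modeled as a flat square cortical sheet of
orientation columns.  A stimulus drives each column according to a
double-angle cosine response with three additive components inside one
bracket, so amplitudes read directly in %-signal-change of baseline:

    R(x) = baseline * (1 + a_col * cos 2(pref(x) - stim(x))
                         + a_rad * cos 2(stim(x) - radial(x))
                         + a_vert * cos 2 stim(x))

* ``a_col`` — fine-grained columnar tuning (sub-millimetre preference map);
* ``a_rad`` — coarse radial bias (stronger response to radial orientations);
* ``a_vert`` — coarse vertical bias.

Voxels (2-mm squares) average columns through a strictly positive
log-normal gain field, which can therefore rescale but never invert the
sign of a between-condition contrast — the property that makes locally
intermingled *opposite* preferences a signature of fine-grained pattern
information rather than of the gain field.

Three named scenarios realize the competing accounts:
``coarse_only`` (a_col = 0: any apparent opposite preference is noise),
``fine_only`` (no coarse biases) and ``mixed`` (both, the realistic case).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm as _glm
from .datasets import CONDITION_ORDER, PatternDataset
from .errors import InvalidParameterError
from .geometry import (
    AnnulusSpec,
    DEFAULT_ANNULUS,
    PatchSpec,
    StimulusSpec,
    local_stimulus_orientation,
    quarterfield_patches,
    stimulus_pair,
)


@dataclass(frozen=True)
class NeuralMapParams:
    """Columnar map geometry and response amplitudes.

    Amplitudes are fractions of ``baseline`` (itself in %-signal-change).
    Defaults reproduce published group effect sizes at 3T: a mean
    radial-minus-tangential voxel contrast of 2*baseline*a_rad = 0.04 %SC
    and a vertical bias of 0.032 %SC on a ~2 %SC response, with columnar
    tuning strong at the neural scale but heavily attenuated by 2-mm voxel
    averaging.
    """

    columns_per_patch: int = 64
    column_pitch: float = 0.25  # mm
    columnar_period: float = 0.8  # mm
    a_col: float = 0.6
    a_rad: float = 0.01
    a_vert: float = 0.008
    baseline: float = 2.0  # %-signal-change

    def __post_init__(self):
        if self.baseline <= 0:
            raise InvalidParameterError("baseline must be positive")
        if min(self.a_col, self.a_rad, self.a_vert) < 0:
            raise InvalidParameterError("amplitudes must be >= 0")
        if self.a_col + self.a_rad + self.a_vert >= 1:
            raise InvalidParameterError("a_col + a_rad + a_vert must stay below 1")
        if self.columnar_period <= 2 * self.column_pitch:
            raise InvalidParameterError(
                "columnar_period must exceed twice the column pitch (resolvable map)"
            )
        if self.columns_per_patch < 2 or self.column_pitch <= 0:
            raise InvalidParameterError("invalid column grid")


@dataclass(frozen=True)
class GainFieldParams:
    """Strictly positive voxel gain field (log-normal)."""

    distribution: str = "lognormal"
    sigma_log: float = 0.4
    smoothness_mm: float = 0.0  # 0 = i.i.d. across voxels

    def __post_init__(self):
        if self.distribution != "lognormal":
            raise InvalidParameterError("only the lognormal gain field is implemented")
        if self.sigma_log < 0 or self.smoothness_mm < 0:
            raise InvalidParameterError("gain parameters must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Measurement and between-subject variability.

    ``sigma_pattern`` is the additive per-voxel per-subrun noise SD, in the
    pattern units of the chosen fidelity mode; ``sigma_subject`` is the
    relative SD of the per-subject multiplicative jitter on the response
    amplitudes (a_col, a_rad, a_vert).
    """

    sigma_pattern: float = 0.5
    sigma_subject: float = 0.2

    def __post_init__(self):
        if self.sigma_pattern < 0 or self.sigma_subject < 0:
            raise InvalidParameterError("noise SDs must be >= 0")


@dataclass(frozen=True)
class Scenario:
    """Full simulator parameter bundle.

    ``name`` must be consistent with the amplitudes: ``coarse_only``
    requires a_col = 0 and ``fine_only`` requires a_rad = a_vert = 0.
    """

    name: str
    map: NeuralMapParams = NeuralMapParams()
    gain: GainFieldParams = GainFieldParams()
    noise: NoiseParams = NoiseParams()
    design: _glm.BlockDesign = _glm.BlockDesign()
    n_subjects: int = 18
    seed: int | None = None
    kinds: tuple[str, ...] = ("grating", "spiral")
    mode: str = "pattern"  # "pattern" | "timeseries"
    voxel_mm: float = 2.0
    annulus: AnnulusSpec = DEFAULT_ANNULUS

    def __post_init__(self):
        if self.name not in ("coarse_only", "fine_only", "mixed"):
            raise InvalidParameterError(f"unknown scenario name {self.name!r}")
        if self.name == "coarse_only" and self.map.a_col != 0:
            raise InvalidParameterError("coarse_only requires a_col = 0")
        if self.name == "fine_only" and (self.map.a_rad != 0 or self.map.a_vert != 0):
            raise InvalidParameterError("fine_only requires a_rad = a_vert = 0")
        if self.mode not in ("pattern", "timeseries"):
            raise InvalidParameterError(f"unknown fidelity mode {self.mode!r}")
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        cpv = self.voxel_mm / self.map.column_pitch
        if abs(cpv - round(cpv)) > 1e-9 or self.map.columns_per_patch % round(cpv):
            raise InvalidParameterError(
                "voxel width must be an integer number of column pitches that "
                "divides columns_per_patch (footprints must tile the sheet)"
            )


def _scenario(name, seed, **overrides) -> Scenario:
    mp = overrides.pop("map", NeuralMapParams())
    if name == "coarse_only":
        mp = replace(mp, a_col=0.0)
    elif name == "fine_only":
        mp = replace(mp, a_rad=0.0, a_vert=0.0)
    return Scenario(name=name, map=mp, seed=seed, **overrides)


def coarse_only_scenario(seed: int | None = None, **overrides) -> Scenario:
    """Voxel-gain-field world: coarse biases only, no columnar term."""
    return _scenario("coarse_only", seed, **overrides)


def fine_only_scenario(seed: int | None = None, **overrides) -> Scenario:
    """Pure fine-grained world: columnar term only, no coarse biases."""
    return _scenario("fine_only", seed, **overrides)


def mixed_scenario(seed: int | None = None, **overrides) -> Scenario:
    """Realistic world: columnar tuning plus coarse radial and vertical biases."""
    return _scenario("mixed", seed, **overrides)


@dataclass
class CorticalPatchMap:
    """Columnar orientation-preference map of one patch plus retinotopy.

    ``pref`` holds per-column preferred orientations in [0, 180) degrees;
    ``polar`` and ``ecc`` give each column's visual-field coordinates under
    the patch's retinotopic placement (polar angle linear across the sheet,
    eccentricity log-spaced, approximating cortical magnification).
    """

    patch: PatchSpec
    pref: np.ndarray
    polar: np.ndarray
    ecc: np.ndarray


def _column_coordinates(patch: PatchSpec, n: int, annulus: AnnulusSpec):
    lo, hi = patch.polar_range
    polar_1d = lo + (np.arange(n) + 0.5) / n * (hi - lo)
    ratio = annulus.r_outer / annulus.r_inner
    ecc_1d = annulus.r_inner * ratio ** ((np.arange(n) + 0.5) / n)
    polar = np.broadcast_to(polar_1d[None, :], (n, n)).copy()
    ecc = np.broadcast_to(ecc_1d[:, None], (n, n)).copy()
    return polar, ecc


def generate_orientation_map(
    params: NeuralMapParams,
    seed,
    patch: PatchSpec | None = None,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
) -> CorticalPatchMap:
    """Pinwheel-like columnar preference map by band-pass complex noise.

    A white complex Gaussian field is band-pass filtered around spatial
    frequency 1/columnar_period; the preference is half the argument of the
    filtered field, which makes the marginal preference distribution
    exactly uniform on [0, 180) and concentrates the power of the
    double-angle field exp(2i*pref) near the requested period.
    Deterministic given ``seed``.
    """
    if params.columnar_period <= 2 * params.column_pitch:
        raise InvalidParameterError("unresolvable columnar period")
    rng = np.random.default_rng(seed)
    n = params.columns_per_patch
    if patch is None:
        patch = quarterfield_patches(annulus)[0]
    z = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    k = np.fft.fftfreq(n, d=params.column_pitch)
    kk = np.hypot(*np.meshgrid(k, k, indexing="ij"))
    k0 = 1.0 / params.columnar_period
    bandwidth = k0 / 3.0
    filt = np.exp(-0.5 * ((kk - k0) / bandwidth) ** 2)
    filt[kk == 0] = 0.0
    zf = np.fft.ifft2(np.fft.fft2(z) * filt)
    pref = np.degrees(np.angle(zf)) / 2.0 % 180.0
    polar, ecc = _column_coordinates(patch, n, annulus)
    return CorticalPatchMap(patch=patch, pref=pref, polar=polar, ecc=ecc)


def columnar_response(
    cmap: CorticalPatchMap,
    stim: StimulusSpec,
    params: NeuralMapParams,
    annulus: AnnulusSpec = DEFAULT_ANNULUS,
    amplitude_scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Per-column response in %-signal-change (the pre-gain neural pattern).

    ``amplitude_scale`` multiplies (a_col, a_rad, a_vert), e.g. for
    per-subject jitter; the summed modulation is clipped below 1 so the
    response stays strictly positive.
    """
    theta_stim = np.radians(local_stimulus_orientation(stim, cmap.polar, cmap.ecc, annulus))
    theta_pref = np.radians(cmap.pref)
    theta_rad = np.radians(cmap.polar % 180.0)
    s_col, s_rad, s_vert = amplitude_scale
    modulation = (
        params.a_col * s_col * np.cos(2 * (theta_pref - theta_stim))
        + params.a_rad * s_rad * np.cos(2 * (theta_stim - theta_rad))
        + params.a_vert * s_vert * np.cos(2 * theta_stim)
    )
    return params.baseline * (1.0 + np.clip(modulation, -0.999, None))


@dataclass
class VoxelGrid:
    """Square voxel footprints tiling the cortical sheets of all patches.

    ``gain`` has shape (n_patches, ny, nx); footprints are
    ``columns_per_voxel`` x ``columns_per_voxel`` non-overlapping blocks.
    """

    voxel_mm: float
    columns_per_voxel: int
    shape: tuple[int, int]  # (ny, nx) voxels per patch
    gain: np.ndarray
    patch_ids: tuple[int, ...]

    def __post_init__(self):
        if np.any(self.gain <= 0):
            raise InvalidParameterError("every voxel gain must be strictly positive")


def make_voxel_grid(
    map_params: NeuralMapParams,
    gain_params: GainFieldParams,
    rng: np.random.Generator,
    patch_ids=(1, 2, 3, 4),
    voxel_mm: float = 2.0,
) -> VoxelGrid:
    """Draw a gain field and lay out the voxel grid over every patch sheet."""
    cpv = int(round(voxel_mm / map_params.column_pitch))
    n_vox = map_params.columns_per_patch // cpv
    log_gain = rng.normal(0.0, 1.0, size=(len(patch_ids), n_vox, n_vox))
    if gain_params.smoothness_mm > 0:
        from scipy import ndimage

        sigma_vox = gain_params.smoothness_mm / voxel_mm
        log_gain = ndimage.gaussian_filter(log_gain, sigma=(0, sigma_vox, sigma_vox))
        sd = log_gain.std()
        if sd > 0:
            log_gain = log_gain / sd
    gain = np.exp(gain_params.sigma_log * log_gain)
    return VoxelGrid(
        voxel_mm=voxel_mm,
        columns_per_voxel=cpv,
        shape=(n_vox, n_vox),
        gain=gain,
        patch_ids=tuple(patch_ids),
    )


def sample_voxels(responses: np.ndarray, grid: VoxelGrid, patch_index: int = 0) -> np.ndarray:
    """Voxel amplitudes: gain times the footprint mean of the column responses.

    Because every gain is strictly positive, the sign of any
    between-condition contrast equals the sign of the footprint-mean neural
    contrast — the gain field can never invert it.
    """
    cpv = grid.columns_per_voxel
    ny, nx = grid.shape
    if responses.shape != (ny * cpv, nx * cpv):
        raise InvalidParameterError(
            f"response field {responses.shape} does not cover the {ny}x{nx} voxel grid"
        )
    if cpv < 1:
        raise InvalidParameterError("empty voxel footprint")
    means = responses.reshape(ny, cpv, nx, cpv).mean(axis=(1, 3))
    return grid.gain[patch_index] * means


def _voxel_metadata(grid: VoxelGrid, patches: list[PatchSpec], annulus: AnnulusSpec):
    """Voxel table: patch, grid coordinates, visual-field center, ecc band."""
    ny, nx = grid.shape
    band_bounds = np.geomspace(annulus.r_inner, annulus.r_outer, 4)
    rows = []
    for p in patches:
        lo, hi = p.polar_range
        ratio = annulus.r_outer / annulus.r_inner
        for y in range(ny):
            f = (y + 0.5) / ny
            ecc = annulus.r_inner * ratio ** f
            band = min(int(np.searchsorted(band_bounds, ecc, side="right")) - 1, 2)
            for x in range(nx):
                polar = lo + (x + 0.5) / nx * (hi - lo)
                rows.append(
                    dict(patch_id=p.patch_id, ecc_band=band, x=x, y=y, polar=polar, ecc=ecc)
                )
    return pd.DataFrame(rows)


def _subject_amplitudes(scenario: Scenario, sub_ss: np.random.SeedSequence):
    """Per-subject maps, gain grid and noise-free voxel amplitude channel."""
    map_ss, gain_ss, jitter_ss, *run_ss = sub_ss.spawn(3 + scenario.design.n_runs * len(scenario.kinds))
    patches = quarterfield_patches(scenario.annulus)
    maps = [
        generate_orientation_map(scenario.map, child, patch=p, annulus=scenario.annulus)
        for p, child in zip(patches, map_ss.spawn(len(patches)))
    ]
    grid = make_voxel_grid(
        scenario.map,
        scenario.gain,
        np.random.default_rng(gain_ss),
        patch_ids=tuple(p.patch_id for p in patches),
        voxel_mm=scenario.voxel_mm,
    )
    jit_rng = np.random.default_rng(jitter_ss)
    scale = tuple(np.clip(jit_rng.normal(1.0, scenario.noise.sigma_subject, 3), 0.0, None))
    amps = {}
    for kind in scenario.kinds:
        per_cond = []
        for stim in stimulus_pair(kind):
            vox = [
                sample_voxels(
                    columnar_response(m, stim, scenario.map, scenario.annulus, scale),
                    grid,
                    i,
                )
                for i, m in enumerate(maps)
            ]
            per_cond.append(np.concatenate([v.ravel() for v in vox]))
        amps[kind] = np.stack(per_cond)  # (conditions, voxels)
    return patches, grid, amps, run_ss


def generate_timeseries(
    design: _glm.BlockDesign,
    amplitudes: np.ndarray,
    noise: NoiseParams,
    seed,
    hrf: _glm.HrfParams = _glm.HrfParams(),
) -> np.ndarray:
    """BOLD time series of one run: condition boxcars x HRF plus white noise.

    ``amplitudes`` has shape (conditions, voxels) in %-signal-change; the
    block order honors the alternation rule of the design.  Returns
    (volumes, voxels).
    """
    amplitudes = np.atleast_2d(amplitudes)
    if amplitudes.shape[0] != design.conditions:
        raise InvalidParameterError("amplitudes must have one row per condition")
    kernel = _glm.boynton_hrf(hrf, dt=design.tr)
    n = design.volumes_per_run
    series = np.zeros((n, amplitudes.shape[1]))
    for cond in range(design.conditions):
        box = np.zeros(n)
        for sub in range(design.subruns_per_run):
            box += _glm._boxcar(design, sub, cond)
        reg = np.convolve(box, kernel)[:n]
        series += np.outer(reg, amplitudes[cond])
    rng = np.random.default_rng(seed)
    if noise.sigma_pattern > 0:
        series = series + rng.normal(0.0, noise.sigma_pattern, size=series.shape)
    return series


def generate_dataset(scenario: Scenario) -> PatternDataset:
    """Simulate the full experiment for every subject of a scenario.

    Pattern-level mode (default): each of the 2 runs x 4 subruns x 2
    conditions patterns is the noise-free voxel amplitude plus i.i.d.
    Gaussian noise, standing in for a per-subrun GLM t-pattern.
    Timeseries mode synthesizes BOLD runs and pushes them through the GLM
    module, yielding genuine per-subrun t-patterns.

    Seeding is hierarchical (master -> subject -> run), so adding subjects
    never perturbs existing ones; identical scenarios give bit-identical
    datasets.
    """
    if scenario.seed is None:
        raise InvalidParameterError("a stochastic scenario requires a seed")
    master = np.random.SeedSequence(scenario.seed)
    subject_ss = master.spawn(scenario.n_subjects)
    design = scenario.design
    nk, nr, nsub, nc = len(scenario.kinds), design.n_runs, design.subruns_per_run, design.conditions
    t = None
    amp_channel = None
    voxels = patches = None
    for s, sub_ss in enumerate(subject_ss):
        patches, grid, amps, run_ss = _subject_amplitudes(scenario, sub_ss)
        if t is None:
            nv = next(iter(amps.values())).shape[1]
            t = np.empty((scenario.n_subjects, nk, nr, nsub, nc, nv))
            amp_channel = np.empty((scenario.n_subjects, nk, nc, nv))
            voxels = _voxel_metadata(grid, patches, scenario.annulus)
        for ik, kind in enumerate(scenario.kinds):
            amp_channel[s, ik] = amps[kind]
            for run in range(nr):
                rs = run_ss[ik * nr + run]
                if scenario.mode == "pattern":
                    rng = np.random.default_rng(rs)
                    noise = rng.normal(
                        0.0, scenario.noise.sigma_pattern, size=(nsub, nc, t.shape[-1])
                    ) if scenario.noise.sigma_pattern > 0 else 0.0
                    t[s, ik, run] = amps[kind][None, :, :] + noise
                else:
                    series = generate_timeseries(design, amps[kind], scenario.noise, rs)
                    X, labels = _glm.build_design_matrix(design)
                    tvals = _glm.fit_tpatterns(series, X, labels, n_task=nc * nsub)
                    # rows are cond-major (cond0_subrun0..3, cond1_subrun0..3)
                    t[s, ik, run] = tvals.reshape(nc, nsub, -1).transpose(1, 0, 2)
    return PatternDataset(
        t=t,
        voxels=voxels,
        kinds=tuple(scenario.kinds),
        grid_shape=grid.shape,
        patches=patches,
        amplitudes=amp_channel,
        baseline=scenario.map.baseline,
        annulus=scenario.annulus,
    )
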