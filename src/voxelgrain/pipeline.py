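"""End-to-end orchestration: simulate -> patterns -> preference -> decoding
-> replicability -> group statistics, with TSV/figure reports.

Everything is bit-reproducible given the master seed: the simulator uses
hierarchical seeding and the bootstrap seed is derived from the master
seed.  Report TSVs use a fixed float format so byte-identical reruns can
be asserted.  No multiple-testing correction is applied anywhere by
default, mirroring uncorrected per-ROI reporting; a Bonferroni switch
exists for the ROI tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate
from .datasets import PatternDataset
from .decoding import make_folds, train_test_decode
from .errors import ConfigurationError
from .preference import preference_proportions
from .replicability import crossval_replicability, roi_effect_anova

log = logging.getLogger("voxelgrain")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run."""

    scenario_name: str = "mixed"
    seed: int | None = None
    n_subjects: int = 18
    kinds: tuple[str, ...] = ("grating", "spiral")
    mode: str = "pattern"
    map_params: dict = field(default_factory=dict)
    gain_params: dict = field(default_factory=dict)
    noise_params: dict = field(default_factory=dict)
    selections: tuple[str, ...] = ("all", "prefA", "prefB")
    shifts_mm: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0)
    n_boot: int = 10000
    bonferroni: bool = False
    write_dataset: bool = False
    write_figures: bool = True

    def scenario(self) -> simulate.Scenario:
        if self.seed is None:
            raise ConfigurationError("a master seed is mandatory for stochastic runs")
        factory = {
            "coarse_only": simulate.coarse_only_scenario,
            "fine_only": simulate.fine_only_scenario,
            "mixed": simulate.mixed_scenario,
        }[self.scenario_name]
        return factory(
            seed=self.seed,
            n_subjects=self.n_subjects,
            kinds=tuple(self.kinds),
            mode=self.mode,
            map=simulate.NeuralMapParams(**self.map_params),
            gain=simulate.GainFieldParams(**self.gain_params),
            noise=simulate.NoiseParams(**self.noise_params),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kinds", "selections", "shifts_mm"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("kinds", "selections", "shifts_mm"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    log.info("wrote %s (%d rows)", path.name, len(df))


def _bar_figure(df, x, y, err_lo=None, err_hi=None, title="", path=None):
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(max(4, 0.5 * len(df)), 3.2))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    xs = np.arange(len(df))
    ax.bar(xs, df[y], color="#777777")
    if err_lo is not None:
        ax.errorbar(xs, df[y], yerr=[df[y] - df[err_lo], df[err_hi] - df[y]],
                    fmt="none", ecolor="black", capsize=2)
    ax.set_xticks(xs)
    ax.set_xticklabels(df[x], rotation=60, ha="right", fontsize=6)
    ax.set_ylabel(y)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every analysis stage and write the result bundle to ``outdir``.

    Returns the in-memory results: dataset, preference summaries, decoding
    result, replicability result and group tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    current = "setup"
    try:
        config.to_yaml(outdir / "config_resolved.yaml")
        stages = []

        def stage(name):
            nonlocal current
            current = name
            stages.append((name, time.perf_counter()))
            log.info("stage: %s", name)

        stage("simulate")
        scenario = config.scenario()
        dataset = simulate.generate_dataset(scenario)
        results["dataset"] = dataset
        log.info("dataset: %d subjects, %d voxels, kinds=%s",
                 dataset.n_subjects, dataset.n_voxels, dataset.kinds)
        if config.write_dataset:
            dataset.to_tsv(outdir / "dataset.tsv")

        stage("preference")
        pref_rows = []
        for kind in dataset.kinds:
            summ = preference_proportions(dataset, kind)
            results[f"preference_{kind}"] = summ
            _write(summ.per_subject.assign(kind=kind), outdir / f"preference_{kind}.tsv")
            hist = pd.DataFrame({
                "bin_low": summ.hist_edges[:-1], "bin_high": summ.hist_edges[1:],
                "count": summ.hist_counts,
            })
            _write(hist, outdir / f"preference_histogram_{kind}.tsv")
            pref_rows.append(dict(
                kind=kind, label_ref=summ.label_names[0], label_anti=summ.label_names[1],
                pooled_pct_ref=summ.pooled_pct_ref,
                subject_mean_pct_ref=summ.subject_mean_pct_ref,
                mean_contrast_psc=summ.mean_contrast_psc,
                ttest_statistic=summ.ttest_statistic, ttest_p=summ.ttest_p,
            ))
        _write(pd.DataFrame(pref_rows), outdir / "preference_group.tsv")

        stage("decoding")
        folds = make_folds(dataset.n_subruns)
        dec = train_test_decode(
            dataset, folds=folds, selections=config.selections, shifts=config.shifts_mm
        )
        results["decoding"] = dec
        _write(dec.per_fold, outdir / "decoding_per_fold.tsv")
        _write(dec.per_subject(), outdir / "decoding_per_subject.tsv")
        group = dec.group_summary()
        if config.bonferroni:
            group["p_vs_chance_corrected"] = np.minimum(group["p_vs_chance"] * len(group), 1.0)
        _write(group, outdir / "decoding_group.tsv")

        stage("replicability")
        rep = crossval_replicability(dataset, folds=folds)
        results["replicability"] = rep
        table = rep.group_table(n_boot=config.n_boot, seed=(config.seed or 0) + 10_000)
        if config.bonferroni:
            table["p_corrected"] = np.minimum(table["p_one_sided"] * len(table), 1.0)
        results["replicability_group"] = table
        _write(rep.per_subject, outdir / "replicability_per_subject.tsv")
        _write(table, outdir / "replicability_group.tsv")
        anova_rows = []
        for factor in ("quarterfield", "eccentricity"):
            try:
                anova_rows.append(roi_effect_anova(rep, factor))
            except Exception as exc:
                log.warning("ANOVA (%s) skipped: %s", factor, exc)
        if anova_rows:
            anova = pd.concat(anova_rows, ignore_index=True)
            results["anova"] = anova
            _write(anova, outdir / "replicability_anova.tsv")

        if config.write_figures:
            stage("figures")
            for kind in dataset.kinds:
                summ = results[f"preference_{kind}"]
                hist = pd.DataFrame({
                    "bin": np.round(
                        (summ.hist_edges[:-1] + summ.hist_edges[1:]) / 2, 3),
                    "count": summ.hist_counts})
                _bar_figure(hist, "bin", "count",
                            title=f"{kind}: pooled preference contrast",
                            path=outdir / f"fig_preference_hist_{kind}.png")
            gs = group.assign(cell=group["kind"].str[:4] + "/" + group["selection"]
                              + "@" + group["shift_mm"].astype(str))
            _bar_figure(gs, "cell", "mean_accuracy", title="decoding accuracy",
                        path=outdir / "fig_decoding.png")
            tb = table.assign(cell=table["kind"].str[:4] + "/" + table["set_label"]
                              + "/" + table["roi"])
            _bar_figure(tb, "cell", "mean_index", "ci_low", "ci_high",
                        title="preference replicability",
                        path=outdir / "fig_replicability.png")

        timings = {name: (stages[i + 1][1] if i + 1 < len(stages) else time.perf_counter()) - t0
                   for i, (name, t0) in enumerate(stages)}
        with open(outdir / "timings.json", "w") as fh:
            json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=1)
    except Exception as exc:
        log.error("stage %s failed: %s", current, exc)
        raise type(exc)(f"[{current}] {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return results
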