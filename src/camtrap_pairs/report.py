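"""Pipeline orchestration: raw tables to ratio tables, tests and figures.

``run_pipeline`` wires the stages together — ingest, event building,
effort, encounter rates at every aggregation level, mixed-model fits with
multiplicity-adjusted certification contrasts, the biomass proxy, the
hunting-sign comparison, the threshold sensitivity table and the
habituation check — and writes every table with a reproducibility header
(config hash + seed).  Inputs are either the three CSV paths of a real
survey or, when paths are absent, a synthetic survey drawn from the
default community.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

from . import events as ev_mod
from . import inference, paired_tests, rates, synthetic
from .ingest import DEFAULT_MASS_EDGES, load_deployments, load_photos, load_traits

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

RATIO_LEVELS = ("all", "body_mass_class", "iucn", "taxon")


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on; hashable for reproducibility."""

    photos_path: str | None = None
    deployments_path: str | None = None
    traits_path: str | None = None
    outdir: str = "camtrap_pairs_out"
    seed: int = 0
    threshold_minutes: float = 10.0
    anchor: str = "last_photo"
    mass_edges: tuple = DEFAULT_MASS_EDGES
    transform: str = "identity"
    covariate_candidates: tuple = ()
    include_indet: bool = False
    n_mc: int = 100_000
    habituation_window: int = paired_tests.DEFAULT_HABITUATION_WINDOW
    sensitivity_thresholds: tuple = ev_mod.DEFAULT_SENSITIVITY_THRESHOLDS
    make_figures: bool = True
    # generator overrides, only used when no input paths are given
    design: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mass_edges", "covariate_candidates", "sensitivity_thresholds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    disposition: dict
    effort: ev_mod.EffortTable
    rate_tables: dict  # level -> camera-level rate table
    concession_rates: pd.DataFrame  # species level, concession unit
    fits: dict  # level -> LMMFit
    contrasts: dict  # level -> ContrastSet
    biomass: pd.DataFrame
    hunting_signs: pd.DataFrame
    hunting_test: paired_tests.WilcoxonResult
    sensitivity: pd.DataFrame
    habituation: paired_tests.HabituationResult
    outputs: dict  # name -> written path

    def ratio_table(self, level: str) -> pd.DataFrame:
        return self.contrasts[level].table


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, index=False)


def _load_or_simulate(config: RunConfig):
    if config.photos_path:
        traits = load_traits(config.traits_path, edges=config.mass_edges)
        deployments = load_deployments(config.deployments_path)
        photos, disp = load_photos(
            config.photos_path, traits, include_indet=config.include_indet
        )
        return photos, deployments, traits, disp.as_dict()
    design = synthetic.SimDesign(seed=config.seed, **config.design)
    photos, deployments, traits_raw = synthetic.simulate_dataset(
        synthetic.default_community(), design
    )
    traits = load_traits(traits_raw, edges=config.mass_edges)
    photos, disp = load_photos(photos, traits, include_indet=config.include_indet)
    return photos, deployments, traits, disp.as_dict()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the result bundle to ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    photos, deployments, traits, disposition = _stage("ingest")(_load_or_simulate)(config)

    events = _stage("events")(ev_mod.build_events)(
        photos, threshold_minutes=config.threshold_minutes, anchor=config.anchor
    )
    effort = _stage("effort")(ev_mod.compute_effort)(deployments, photos)
    sensitivity = _stage("sensitivity")(ev_mod.sensitivity_table)(
        photos, traits, thresholds=config.sensitivity_thresholds, anchor=config.anchor
    )

    rate_tables, fits, contrasts = {}, {}, {}
    for level in RATIO_LEVELS:
        tab = _stage(f"rates[{level}]")(rates.encounter_rate)(
            events, effort, traits, level=level, unit="camera"
        )
        rate_tables[level] = tab
        spec = inference.LMMSpec(
            transform=config.transform,
            group_col=None if level == "all" else "group_label",
        )
        fit = _stage(f"fit[{level}]")(inference.fit_lmm)(tab, spec)
        fits[level] = fit
        contrasts[level] = _stage(f"contrasts[{level}]")(inference.certification_ratios)(
            fit, n_mc=config.n_mc, seed=config.seed
        )

    concession_rates = _stage("rates[species]")(rates.encounter_rate)(
        events, effort, traits, level="species", unit="concession"
    )
    biomass = _stage("biomass")(rates.biomass_proxy)(concession_rates, traits)

    hunting = _stage("hunting_signs")(paired_tests.hunting_sign_pairs)(deployments)
    hunting_test = _stage("hunting_test")(paired_tests.wilcoxon_signed_rank)(
        hunting["certified"], hunting["noncert"]
    )
    daily = _stage("habituation")(paired_tests.daily_observation_counts)(events, deployments)
    habituation = _stage("habituation")(paired_tests.habituation_test)(
        daily, window_days=config.habituation_window
    )

    # --- outputs -----------------------------------------------------------
    _write_csv(events, outdir / "events.csv", config)
    outputs["events"] = outdir / "events.csv"
    _write_csv(effort.camera, outdir / "effort_camera.csv", config)
    _write_csv(effort.concession, outdir / "effort_concession.csv", config)
    outputs["effort"] = outdir / "effort_camera.csv"
    _write_csv(sensitivity, outdir / "sensitivity.csv", config)
    outputs["sensitivity"] = outdir / "sensitivity.csv"
    for level in RATIO_LEVELS:
        _write_csv(rate_tables[level], outdir / f"rates_{level}.csv", config)
        _write_csv(contrasts[level].table, outdir / f"ratios_{level}.csv", config)
        outputs[f"ratios_{level}"] = outdir / f"ratios_{level}.csv"
    _write_csv(concession_rates, outdir / "rates_species_concession.csv", config)
    _write_csv(biomass, outdir / "biomass.csv", config)
    outputs["biomass"] = outdir / "biomass.csv"
    _write_csv(hunting, outdir / "hunting_signs.csv", config)

    summary = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "disposition": disposition,
        "n_events": int(len(events)),
        "total_camera_days": float(effort.concession["camera_days"].sum()),
        "fits": {lvl: fits[lvl].summary_dict() for lvl in RATIO_LEVELS},
        "ratios": {
            lvl: {
                str(r["group"]): {
                    "ratio": None if pd.isna(r["ratio"]) else float(r["ratio"]),
                    "p_adj": float(r["p_adj"]),
                }
                for _, r in contrasts[lvl].table.iterrows()
            }
            for lvl in RATIO_LEVELS
        },
        "hunting_signs": {
            "W": hunting_test.statistic,
            "p": hunting_test.p_value,
            "method": hunting_test.method,
        },
        "habituation": dataclasses.asdict(habituation),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    outputs["summary"] = outdir / "summary.json"

    if config.make_figures:
        _figures(outdir, config, rate_tables, hunting, outputs)

    return PipelineResult(
        config=config,
        disposition=disposition,
        effort=effort,
        rate_tables=rate_tables,
        concession_rates=concession_rates,
        fits=fits,
        contrasts=contrasts,
        biomass=biomass,
        hunting_signs=hunting,
        hunting_test=hunting_test,
        sensitivity=sensitivity,
        habituation=habituation,
        outputs=outputs,
    )


def _paired_boxplot(ax, conc_rates: pd.DataFrame, title: str) -> None:
    """Paired boxplot of per-concession rates, certified vs not."""
    cert = conc_rates.loc[conc_rates["certified"], "encounter_rate"]
    non = conc_rates.loc[~conc_rates["certified"], "encounter_rate"]
    ax.boxplot([non, cert], tick_labels=["non-FSC", "FSC"])
    piv = conc_rates.pivot_table(
        index="pair_id", columns="certified", values="encounter_rate"
    )
    for _, row in piv.iterrows():
        ax.plot([1, 2], [row.get(False, np.nan), row.get(True, np.nan)],
                color="grey", alpha=0.6, lw=0.8)
    ax.set_title(title, fontsize=9)
    ax.set_ylabel("obs / camera-day", fontsize=8)


def _figures(outdir, config, rate_tables, hunting, outputs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for level in RATIO_LEVELS:
            tab = rate_tables[level]
            conc = tab.groupby(
                ["concession_id", "pair_id", "certified", "group_label"], as_index=False
            ).apply(
                lambda g: pd.Series(
                    {"encounter_rate": g["weighted_count"].sum() / g["effort_days"].sum()}
                ),
                include_groups=False,
            )
            groups = list(dict.fromkeys(tab["group_label"]))
            fig, axes = plt.subplots(
                1, len(groups), figsize=(2.4 * len(groups), 3.0), squeeze=False
            )
            for ax, g in zip(axes[0], groups):
                _paired_boxplot(ax, conc[conc["group_label"] == g], str(g))
            fig.tight_layout()
            path = Path(outdir) / f"fig_rates_{level}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            outputs[f"fig_{level}"] = path

        fig, ax = plt.subplots(figsize=(3, 3))
        ax.boxplot(
            [hunting["noncert"], hunting["certified"]], tick_labels=["non-FSC", "FSC"]
        )
        for _, row in hunting.iterrows():
            ax.plot([1, 2], [row["noncert"], row["certified"]], color="grey", alpha=0.6, lw=0.8)
        ax.set_ylabel("prop. cameras with hunting signs", fontsize=8)
        fig.tight_layout()
        path = Path(outdir) / "fig_hunting_signs.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        outputs["fig_hunting"] = path
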