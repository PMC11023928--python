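"""Synthetic camera-trap surveys with a paired-concession design.

The generator emulates a blocked before-the-fact ("BACI-style") certification
comparison: pairs of logging concessions, one certified and one not, each
holding a systematic grid of cameras deployed for a fixed window.  Species
detections arrive as independent Poisson processes whose rates carry
log-normal heterogeneity at the pair, concession and camera level:

    rate(camera c, species s) = base_rate_s * multiplier_s^[certified]
                                * exp(u_pair + u_concession + u_camera)

with ``u ~ Normal(0, sd^2)`` on the log scale.  Each detection event emits a
short burst of photos; cameras also take a status photo on a fixed schedule
so that downtime can be recovered from the photo stream alone, and a subset
of cameras suffers a single terminal outage.

Two entry points are provided.  :func:`simulate_events` returns the event
table directly (fast path for replicate studies); :func:`simulate_dataset`
expands events into photo-level records and is the input of record for the
ingest stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import assign_body_mass_class

__all__ = [
    "SpeciesSpec",
    "SimDesign",
    "default_community",
    "simulate_events",
    "simulate_dataset",
]

IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD")
TAXA = ("elephants", "primates", "ungulates", "carnivores", "pangolins", "rodents", "other")

_SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One species of the simulated community.

    ``base_rate`` is the expected number of independent detections per
    camera-day in a non-certified concession.  ``group_size_mean`` is the
    mean of a shifted-Poisson group-size distribution (``1 + Poisson(mean-1)``),
    so group sizes are positive integers with mean >= 1.
    ``certification_multiplier`` scales the rate in certified concessions.
    """

    name: str
    mean_body_mass: float  # kg, mean across sexes
    iucn: str
    taxon: str
    base_rate: float
    group_size_mean: float = 1.0
    certification_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.base_rate) or self.base_rate < 0:
            raise ValueError(f"base_rate must be finite and >= 0, got {self.base_rate}")
        if not np.isfinite(self.certification_multiplier) or self.certification_multiplier < 0:
            raise ValueError("certification_multiplier must be finite and >= 0")
        if self.mean_body_mass <= 0:
            raise ValueError("mean_body_mass must be > 0")
        if self.group_size_mean < 1:
            raise ValueError("group_size_mean must be >= 1")
        if self.iucn not in IUCN_CATEGORIES:
            raise ValueError(f"iucn must be one of {IUCN_CATEGORIES}")
        if self.taxon not in TAXA:
            raise ValueError(f"taxon must be one of {TAXA}")


@dataclass(frozen=True)
class SimDesign:
    """Survey design parameters.

    Defaults mirror the field design the package targets: 7 concession
    pairs, 28-36 cameras per concession on 1-km grids, 2-3 month
    deployments, three-photo bursts and a 12-h status photo.  Standard
    deviations are on the log-rate scale.  Downtime is a single terminal
    outage: an affected camera stops taking any photos ``downtime_days``
    before its scheduled retrieval, and the outage is recoverable only
    through the status-photo schedule (its recorded downtime stays 0, as a
    field team would not know the camera died until retrieval).
    """

    n_pairs: int = 7
    cameras_per_concession: tuple[int, int] = (28, 36)
    deployment_days: int = 80
    downtime_prob: float = 0.10
    downtime_days_mean: float = 8.0
    sd_pair: float = 0.40
    sd_concession: float = 0.25
    sd_camera: float = 0.50
    burst_size: int = 3
    status_photo_interval_h: float = 12.0
    seed: int = 0
    start_date: str = "2019-06-01"
    # per-camera standardized geographic covariates and their log-rate slopes
    covariate_effects: dict = field(default_factory=dict)
    # hunting-sign counts per camera approach (Poisson means)
    hunting_sign_mean_certified: float = 0.25
    hunting_sign_mean_noncert: float = 0.90

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.deployment_days <= 0:
            raise ValueError("deployment_days must be positive")
        lo, hi = self.cameras_per_concession
        if not (1 <= lo <= hi):
            raise ValueError("cameras_per_concession must be an increasing positive range")
        for name in ("sd_pair", "sd_concession", "sd_camera"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.downtime_prob <= 1:
            raise ValueError("downtime_prob must be a probability")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")
        if self.status_photo_interval_h <= 0:
            raise ValueError("status_photo_interval_h must be positive")

    def replace(self, **kwargs) -> "SimDesign":
        return dataclasses.replace(self, **kwargs)


GEO_COVARIATES = ("elevation", "dist_roads", "dist_rivers", "dist_settlements", "dist_protected")

VISIBILITY_CLASSES = ("0-10 m", "11-20 m", ">20 m")
SLOPE_CLASSES = ("0-5 deg", "5-20 deg", ">20 deg")
TRAIL_TYPES = ("elephant path", "skidder trail", "wildlife trail", "none")

# Certification multipliers by body-mass class: the headline effect grows
# with body mass, with no effect below 10 kg.
CLASS_MULTIPLIERS = {
    "0-1 kg": 1.0,
    "1-10 kg": 1.0,
    "10-30 kg": 3.5,
    "30-100 kg": 2.5,
    ">100 kg": 2.7,
}


def _community_rows():
    # name, mass kg, IUCN, taxon, base rate (det/cam-day, non-certified), mean group size
    return [
        # < 1 kg
        ("rats and mice", 0.060, "LC", "rodents", 0.40, 1.0),
        ("shrews", 0.015, "LC", "rodents", 0.06, 1.0),
        ("squirrels", 0.50, "LC", "rodents", 0.18, 1.0),
        # 1-10 kg
        ("brush-tailed porcupine", 3.0, "LC", "rodents", 0.16, 1.1),
        ("blue duiker", 4.5, "LC", "ungulates", 0.45, 1.2),
        ("white-bellied pangolin", 2.5, "EN", "pangolins", 0.012, 1.0),
        ("black-bellied pangolin", 1.2, "VU", "pangolins", 0.004, 1.0),
        ("long-nosed mongoose", 1.0, "LC", "carnivores", 0.05, 1.5),
        ("marsh mongoose", 3.3, "LC", "carnivores", 0.03, 1.0),
        ("servaline genet", 2.0, "LC", "carnivores", 0.04, 1.0),
        ("tree hyrax", 2.5, "LC", "other", 0.010, 1.0),
        ("putty-nosed monkey", 4.2, "NT", "primates", 0.03, 2.0),
        # 10-30 kg
        ("bay duiker", 20.0, "NT", "ungulates", 0.09, 1.1),
        ("peters's duiker", 18.0, "LC", "ungulates", 0.07, 1.1),
        ("water chevrotain", 11.0, "LC", "ungulates", 0.03, 1.0),
        ("giant pangolin", 30.0, "EN", "pangolins", 0.005, 1.0),
        ("african golden cat", 11.0, "VU", "carnivores", 0.010, 1.0),
        ("mandrill", 20.0, "VU", "primates", 0.02, 4.0),
        # 30-100 kg
        ("central chimpanzee", 45.0, "EN", "primates", 0.025, 2.2),
        ("leopard", 55.0, "VU", "carnivores", 0.012, 1.0),
        ("red river hog", 70.0, "LC", "ungulates", 0.04, 3.0),
        ("yellow-backed duiker", 60.0, "NT", "ungulates", 0.03, 1.0),
        ("sitatunga", 80.0, "LC", "ungulates", 0.010, 1.0),
        ("aardvark", 50.0, "LC", "other", 0.004, 1.0),
        # > 100 kg
        ("forest elephant", 2800.0, "CR", "elephants", 0.020, 1.6),
        ("western lowland gorilla", 130.0, "CR", "primates", 0.020, 2.5),
        ("forest buffalo", 300.0, "NT", "ungulates", 0.008, 2.0),
    ]


def default_community() -> list[SpeciesSpec]:
    """A deterministic 27-species community spanning all body-mass classes,
    all six analysable taxa plus 'other', and five IUCN categories.

    Base rates are heavy-tailed (a few common duikers and rodents, many rare
    species).  Certification multipliers follow :data:`CLASS_MULTIPLIERS`:
    no effect below 10 kg and a 2.5-3.5x effect above, which makes the
    pooled group-size-weighted community ratio come out near 1.5-1.6.
    """
    out = []
    for name, mass, iucn, taxon, rate, gmean in _community_rows():
        mult = CLASS_MULTIPLIERS[assign_body_mass_class(mass)]
        out.append(
            SpeciesSpec(
                name=name,
                mean_body_mass=mass,
                iucn=iucn,
                taxon=taxon,
                base_rate=rate,
                group_size_mean=gmean,
                certification_multiplier=mult,
            )
        )
    return out


def traits_table(species: list[SpeciesSpec]) -> pd.DataFrame:
    """Species-trait table (one row per species) in the ingest schema."""
    return pd.DataFrame(
        {
            "species_label": [s.name for s in species],
            "mean_body_mass": [s.mean_body_mass for s in species],
            "iucn": [s.iucn for s in species],
            "taxon": [s.taxon for s in species],
        }
    )


def _layout(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Camera/deployment layout with covariates and downtime draws."""
    lo, hi = design.cameras_per_concession
    start = pd.Timestamp(design.start_date)
    end = start + pd.Timedelta(days=design.deployment_days)
    rows = []
    for p in range(1, design.n_pairs + 1):
        for certified in (True, False):
            conc = f"P{p}{'F' if certified else 'N'}"
            n_cam = int(rng.integers(lo, hi + 1))
            for k in range(1, n_cam + 1):
                rows.append((f"{conc}-{k:02d}", conc, f"P{p}", certified))
    df = pd.DataFrame(rows, columns=["camera_id", "concession_id", "pair_id", "certified"])
    n = len(df)
    df["start"] = start
    df["end"] = end
    # terminal outages: camera dies downtime_days before scheduled retrieval
    dead = rng.random(n) < design.downtime_prob
    dt = np.where(dead, rng.poisson(design.downtime_days_mean, n), 0)
    dt = np.minimum(dt, design.deployment_days)
    df["true_active_days"] = design.deployment_days - dt.astype(float)
    # recorded downtime is 0: outages are recovered via the status-photo rule
    df["downtime_days"] = 0.0
    df["visibility_class"] = rng.choice(VISIBILITY_CLASSES, n, p=[0.45, 0.35, 0.20])
    df["slope_class"] = rng.choice(SLOPE_CLASSES, n, p=[0.55, 0.35, 0.10])
    df["fruiting_tree_30m"] = rng.random(n) < 0.25
    df["water_50m"] = rng.random(n) < 0.20
    df["trail_type"] = rng.choice(TRAIL_TYPES, n, p=[0.08, 0.12, 0.30, 0.50])
    sign_mean = np.where(
        df["certified"], design.hunting_sign_mean_certified, design.hunting_sign_mean_noncert
    )
    df["hunting_signs"] = rng.poisson(sign_mean)
    for cov in GEO_COVARIATES:
        df[cov] = rng.normal(size=n)
    return df


def _log_rate_offsets(deployments: pd.DataFrame, design: SimDesign, rng: np.random.Generator) -> np.ndarray:
    pair_u = {p: rng.normal(0.0, design.sd_pair) for p in deployments["pair_id"].unique()}
    conc_u = {c: rng.normal(0.0, design.sd_concession) for c in deployments["concession_id"].unique()}
    cam_u = rng.normal(0.0, design.sd_camera, len(deployments))
    off = (
        deployments["pair_id"].map(pair_u).to_numpy()
        + deployments["concession_id"].map(conc_u).to_numpy()
        + cam_u
    )
    for cov, slope in design.covariate_effects.items():
        off = off + slope * deployments[cov].to_numpy()
    return off


def simulate_events(
    species: list[SpeciesSpec],
    design: SimDesign,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw detection events directly (no photo expansion).

    Returns ``(events, deployments, traits)``.  Events carry camera_id,
    species_label, start_time, end_time, group_size and n_photos, matching
    the schema produced by the event-building stage, so the rate and
    inference stages accept them unchanged.  ``deployments`` includes the
    generator-truth ``true_active_days`` column.
    """
    if not species:
        raise ValueError("species list must not be empty")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    deployments = _layout(design, rng)
    offsets = _log_rate_offsets(deployments, design, rng)
    active = deployments["true_active_days"].to_numpy()
    certified = deployments["certified"].to_numpy()

    base = np.array([s.base_rate for s in species])
    mult = np.array([s.certification_multiplier for s in species])
    gmean = np.array([s.group_size_mean for s in species])
    names = np.array([s.name for s in species], dtype=object)

    # expected events: (n_cameras, n_species)
    lam = np.exp(offsets)[:, None] * active[:, None] * base[None, :]
    lam[certified] *= mult[None, :]
    counts = rng.poisson(lam)

    cam_idx, sp_idx = np.nonzero(counts)
    reps = counts[cam_idx, sp_idx]
    cam_rep = np.repeat(cam_idx, reps)
    sp_rep = np.repeat(sp_idx, reps)
    n_ev = len(cam_rep)

    t_days = rng.random(n_ev) * active[cam_rep]
    group = 1 + rng.poisson(np.maximum(gmean[sp_rep] - 1.0, 0.0))
    start = deployments["start"].iloc[0]
    start_times = start + pd.to_timedelta(np.round(t_days * _SECONDS_PER_DAY), unit="s")
    burst_span = pd.Timedelta(seconds=1.5 * (design.burst_size - 1))

    events = pd.DataFrame(
        {
            "camera_id": deployments["camera_id"].to_numpy()[cam_rep],
            "species_label": names[sp_rep],
            "start_time": start_times,
            "end_time": start_times + burst_span,
            "group_size": group.astype(int),
            "n_photos": design.burst_size,
        }
    )
    events = events.sort_values(["camera_id", "species_label", "start_time"], kind="mergesort")
    events = events.reset_index(drop=True)
    return events, deployments, traits_table(species)


def simulate_dataset(
    species: list[SpeciesSpec],
    design: SimDesign,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full photo-level survey.

    Returns ``(photos, deployments, traits)`` — valid, uncleaned inputs for
    the ingest stage.  Each event becomes ``burst_size`` photos 1.5 s apart;
    per-photo individual counts are between 1 and the event's group size with
    the maximum attained at least once, so downstream group-size recovery
    (max count within an event) is exact.  Status photos are emitted on the
    camera's schedule until its (possibly truncated) active window ends.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    events, deployments, traits = simulate_events(species, design, rng)

    b = design.burst_size
    n_ev = len(events)
    if n_ev:
        ev_start = events["start_time"].to_numpy()
        offs = pd.to_timedelta(np.tile(np.arange(b) * 1.5, n_ev), unit="s")
        ts = np.repeat(ev_start, b) + offs.to_numpy()
        g = events["group_size"].to_numpy()
        counts = rng.integers(1, np.repeat(g, b) + 1)
        # force the max to be attained once per burst
        pos = rng.integers(0, b, n_ev) + np.arange(n_ev) * b
        counts[pos] = g
        animal = pd.DataFrame(
            {
                "camera_id": np.repeat(events["camera_id"].to_numpy(), b),
                "timestamp": ts,
                "species_label": np.repeat(events["species_label"].to_numpy(), b),
                "n_individuals": counts,
                "is_status_photo": False,
            }
        )
    else:
        animal = pd.DataFrame(
            columns=["camera_id", "timestamp", "species_label", "n_individuals", "is_status_photo"]
        )

    # status photos: every interval from deployment start while the camera is alive
    step_days = design.status_photo_interval_h / 24.0
    frames = [animal] if len(animal) else []
    for cam, start, active in zip(
        deployments["camera_id"], deployments["start"], deployments["true_active_days"]
    ):
        k = int(np.floor(active / step_days))
        times = start + pd.to_timedelta(np.arange(1, k + 1) * step_days, unit="D")
        frames.append(
            pd.DataFrame(
                {
                    "camera_id": cam,
                    "timestamp": times,
                    "species_label": "",
                    "n_individuals": 0,
                    "is_status_photo": True,
                }
            )
        )
    photos = pd.concat(frames, ignore_index=True)
    photos = photos.sort_values(["camera_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    photos["n_individuals"] = photos["n_individuals"].astype(int)
    photos["is_status_photo"] = photos["is_status_photo"].astype(bool)
    return photos, deployments, traits
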