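"""Reading and validation of photo, deployment and species-trait tables.

The ingest stage applies the survey's labelling conventions before any
analysis: classes that are not wild mammals (humans, birds, bats, reptiles,
domestic dogs) are excluded; photos that could not be identified to species
("indet") are dropped from every rate computation; small mammals are pooled
into three morphological groups (squirrels; rats and mice; shrews) because
species identification from photos is unreliable at that size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MASS_EDGES",
    "EXCLUDED_CLASSES",
    "SMALL_MAMMAL_GROUPS",
    "assign_body_mass_class",
    "mass_class_labels",
    "load_photos",
    "load_deployments",
    "load_traits",
]

#: labels dropped from all analyses (non-target classes), matched after
#: lower-casing and stripping
EXCLUDED_CLASSES = frozenset(
    {
        "human", "humans",
        "bird", "birds",
        "bat", "bats",
        "reptile", "reptiles",
        "domestic dog", "domestic dogs",
    }
)

#: pooled small-mammal identification groups
SMALL_MAMMAL_GROUPS = frozenset({"squirrels", "rats and mice", "shrews"})

INDET_LABEL = "indet"

#: interior class edges in kg; intervals are half-open (lower, upper]
DEFAULT_MASS_EDGES = (1.0, 10.0, 30.0, 100.0)

IUCN_CATEGORIES = ("CR", "EN", "VU", "NT", "LC", "DD")
TAXA = ("elephants", "primates", "ungulates", "carnivores", "pangolins", "rodents", "other")

PHOTO_COLUMNS = ("camera_id", "timestamp", "species_label", "n_individuals", "is_status_photo")
DEPLOYMENT_COLUMNS = ("camera_id", "concession_id", "pair_id", "certified", "start", "end", "downtime_days")
TRAIT_COLUMNS = ("species_label", "mean_body_mass", "iucn", "taxon")


def mass_class_labels(edges=DEFAULT_MASS_EDGES) -> list[str]:
    """Ordered class labels implied by ``edges`` (kg)."""
    e = [_fmt_kg(x) for x in edges]
    labels = [f"0-{e[0]} kg"]
    labels += [f"{a}-{b} kg" for a, b in zip(e[:-1], e[1:])]
    labels.append(f">{e[-1]} kg")
    return labels


def _fmt_kg(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def assign_body_mass_class(mass_kg, edges=DEFAULT_MASS_EDGES):
    """Map body mass (kg) to its class label.

    Intervals are half-open ``(lower, upper]``, so a 30 kg species falls in
    "10-30 kg" and anything above the last edge in ">100 kg" (with default
    edges).  Accepts a scalar or an array; masses must be positive and
    ``edges`` strictly increasing.
    """
    edges = tuple(float(e) for e in edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0:
        raise ValueError("edges must be positive and strictly increasing")
    arr = np.asarray(mass_kg, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("mass must be positive and finite")
    labels = np.array(mass_class_labels(edges), dtype=object)
    # (lower, upper]: left side of searchsorted gives the half-open convention
    idx = np.searchsorted(np.asarray(edges), arr, side="left")
    if arr.ndim == 0:
        return str(labels[int(idx)])
    return labels[idx]


def _read_table(src, parse_dates=()):
    if isinstance(src, pd.DataFrame):
        df = src.copy()
    else:
        df = pd.read_csv(src, comment="#")
    for col in parse_dates:
        if col in df.columns and not pd.api.types.is_datetime64_any_dtype(df[col]):
            try:
                df[col] = pd.to_datetime(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"unparseable {col!r} values: {exc}") from exc
    return df


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required columns: {missing}")


def _norm_label(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip().str.lower()


def load_traits(src, edges=DEFAULT_MASS_EDGES) -> pd.DataFrame:
    """Load and validate the species-trait table; adds ``body_mass_class``."""
    df = _read_table(src)
    _require(df, TRAIT_COLUMNS, "traits")
    df["species_label"] = _norm_label(df["species_label"])
    if df["species_label"].duplicated().any():
        dups = sorted(df.loc[df["species_label"].duplicated(), "species_label"].unique())
        raise ValueError(f"duplicate trait rows for species: {dups}")
    if (df["mean_body_mass"] <= 0).any() or df["mean_body_mass"].isna().any():
        raise ValueError("mean_body_mass must be positive for every species")
    bad = ~df["iucn"].isin(IUCN_CATEGORIES)
    if bad.any():
        raise ValueError(f"unknown IUCN categories: {sorted(df.loc[bad, 'iucn'].unique())}")
    bad = ~df["taxon"].isin(TAXA)
    if bad.any():
        raise ValueError(f"unknown taxa: {sorted(df.loc[bad, 'taxon'].unique())}")
    df["body_mass_class"] = assign_body_mass_class(df["mean_body_mass"].to_numpy(), edges)
    return df


def load_deployments(src) -> pd.DataFrame:
    """Load and validate the deployment/metadata table."""
    df = _read_table(src, parse_dates=("start", "end"))
    _require(df, DEPLOYMENT_COLUMNS, "deployments")
    if df["camera_id"].duplicated().any():
        raise ValueError("duplicate camera_id rows in deployments")
    if not (df["end"] > df["start"]).all():
        bad = df.loc[~(df["end"] > df["start"]), "camera_id"].tolist()
        raise ValueError(f"deployment end must be after start for cameras: {bad}")
    span = (df["end"] - df["start"]).dt.total_seconds() / 86400.0
    if (df["downtime_days"] < 0).any() or (df["downtime_days"] > span).any():
        raise ValueError("downtime_days must be within [0, deployment span]")
    df["certified"] = df["certified"].astype(bool)
    return df


def _load_aliases(aliases) -> dict[str, str]:
    if aliases is None:
        return {}
    if isinstance(aliases, dict):
        return {str(k).strip().lower(): str(v).strip().lower() for k, v in aliases.items()}
    adf = _read_table(aliases)
    _require(adf, ("alias", "species_label"), "alias")
    return dict(
        zip(_norm_label(adf["alias"]), _norm_label(adf["species_label"]))
    )


@dataclass
class Disposition:
    """Row counts by fate during photo ingest; partitions the animal rows."""

    total_animal: int = 0
    retained: int = 0
    excluded_class: int = 0
    indet: int = 0
    unknown_label: int = 0
    status: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def load_photos(
    src,
    traits: pd.DataFrame,
    aliases=None,
    strict: bool = True,
    include_indet: bool = False,
):
    """Load, relabel and filter the photo table.

    Returns ``(photos, disposition)``.  Status photos are kept (flagged) for
    effort computation; excluded classes and (by default) "indet" records
    are dropped.  Any remaining species label without a trait row is a hard
    error in strict mode, otherwise dropped with a warning.
    """
    df = _read_table(src, parse_dates=("timestamp",))
    _require(df, PHOTO_COLUMNS, "photos")
    disp = Disposition()
    if df.empty:
        warnings.warn("photo table is empty", stacklevel=2)
        return df, disp

    df["species_label"] = _norm_label(df["species_label"])
    alias_map = _load_aliases(aliases)
    if alias_map:
        df["species_label"] = df["species_label"].replace(alias_map)
    df["is_status_photo"] = df["is_status_photo"].astype(bool)

    status = df["is_status_photo"]
    disp.status = int(status.sum())
    animal = df[~status]
    disp.total_animal = len(animal)

    excl = animal["species_label"].isin(EXCLUDED_CLASSES)
    disp.excluded_class = int(excl.sum())
    animal = animal[~excl]

    indet = animal["species_label"].eq(INDET_LABEL)
    disp.indet = int(indet.sum())
    if not include_indet:
        animal = animal[~indet]
    known = set(traits["species_label"])
    if include_indet:
        known = known | {INDET_LABEL}
    unknown = ~animal["species_label"].isin(known)
    if unknown.any():
        offenders = sorted(animal.loc[unknown, "species_label"].unique())
        if strict:
            raise ValueError(f"species labels without a trait row: {offenders}")
        warnings.warn(f"dropping labels without a trait row: {offenders}", stacklevel=2)
        disp.unknown_label = int(unknown.sum())
        animal = animal[~unknown]

    if (animal["n_individuals"] < 1).any():
        bad = animal.loc[animal["n_individuals"] < 1]
        raise ValueError(
            f"{len(bad)} non-status animal photos have n_individuals < 1"
        )
    disp.retained = len(animal)
    logger.info("photo ingest disposition: %s", disp.as_dict())

    out = pd.concat([animal, df[status]], ignore_index=True)
    out = out.sort_values(["camera_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    out["n_individuals"] = out["n_individuals"].astype(int)
    return out, disp
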