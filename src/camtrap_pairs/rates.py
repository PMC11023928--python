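"""Encounter rates, aggregations and the relative-biomass proxy.

The encounter rate is the group-size-weighted number of independent
detections divided by sampling effort, reported as observations per
camera-trap day.  Rates are additive over disjoint species sets, so class-,
category- and taxon-level rates are sums of member-species rates.  The
biomass proxy weights each species' rate by its mean body mass; it ranks
concessions on a common scale but cannot be interpreted as true biomass.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .events import EffortTable
from .ingest import mass_class_labels

__all__ = ["GROUPING_LEVELS", "encounter_rate", "biomass_proxy"]

GROUPING_LEVELS = ("all", "species", "body_mass_class", "iucn", "taxon")

#: taxa omitted from the taxon-level analysis (retained everywhere else)
TAXON_ANALYSIS_EXCLUDED = ("other",)


def _group_map(traits: pd.DataFrame, level: str) -> pd.Series:
    """species_label -> group label for the requested aggregation level."""
    t = traits.set_index("species_label")
    if level == "all":
        return pd.Series("all", index=t.index)
    if level == "species":
        return pd.Series(t.index, index=t.index)
    if level == "body_mass_class":
        return t["body_mass_class"]
    if level == "iucn":
        return t["iucn"]
    if level == "taxon":
        keep = ~t["taxon"].isin(TAXON_ANALYSIS_EXCLUDED)
        return t.loc[keep, "taxon"]
    raise ValueError(f"unknown grouping level {level!r}; expected one of {GROUPING_LEVELS}")


def _label_universe(traits: pd.DataFrame, level: str) -> list[str]:
    if level == "all":
        return ["all"]
    if level == "species":
        return sorted(traits["species_label"])
    if level == "body_mass_class":
        present = set(traits["body_mass_class"])
        return [c for c in mass_class_labels() if c in present] or sorted(present)
    if level == "iucn":
        order = ("CR", "EN", "VU", "NT", "LC", "DD")
        present = set(traits["iucn"])
        return [c for c in order if c in present]
    if level == "taxon":
        present = set(traits["taxon"]) - set(TAXON_ANALYSIS_EXCLUDED)
        return sorted(present)
    raise ValueError(f"unknown grouping level {level!r}")


def encounter_rate(
    events: pd.DataFrame,
    effort: EffortTable,
    traits: pd.DataFrame,
    level: str = "species",
    unit: str = "camera",
) -> pd.DataFrame:
    """Group-size-weighted encounter rates at a given aggregation level.

    Parameters
    ----------
    events
        Detection-event table.
    effort
        Output of :func:`camtrap_pairs.events.compute_effort`.
    traits
        Trait table with ``body_mass_class`` (from :func:`load_traits` or
        the generator plus class assignment).
    level
        One of ``all, species, body_mass_class, iucn, taxon``.  The taxon
        level silently omits species whose taxon is in
        :data:`TAXON_ANALYSIS_EXCLUDED`.
    unit
        ``"camera"`` gives one row per camera x group (model input, rate =
        weighted count / camera active days; zero-effort cameras are
        dropped with a warning).  ``"concession"`` divides pooled weighted
        counts by the concession's total camera-days.

    Returns a tidy frame with zero-filled rows for every unit x group
    combination, so absences count as rate 0.
    """
    gmap = _group_map(traits, level)
    labels = _label_universe(traits, level)

    ev = events.copy()
    known = ev["species_label"].isin(gmap.index)
    if level != "taxon" and not known.all():
        missing = sorted(ev.loc[~known, "species_label"].unique())
        raise ValueError(f"events contain species without trait rows: {missing}")
    ev = ev[known]
    ev["group_label"] = ev["species_label"].map(gmap)

    if unit == "camera":
        frame = effort.camera.rename(columns={"active_days": "effort_days"})
        zero = frame["effort_days"] <= 0
        if zero.any():
            warnings.warn(
                f"dropping {int(zero.sum())} zero-effort cameras from rate table",
                stacklevel=2,
            )
            frame = frame[~zero]
        key = "camera_id"
    elif unit == "concession":
        frame = effort.concession.rename(columns={"camera_days": "effort_days"})
        zero = frame["effort_days"] <= 0
        if zero.any():
            warnings.warn("dropping zero-effort concessions from rate table", stacklevel=2)
            frame = frame[~zero]
        key = "concession_id"
        cam_to_conc = effort.camera.set_index("camera_id")["concession_id"]
        ev = ev.assign(concession_id=ev["camera_id"].map(cam_to_conc))
    else:
        raise ValueError("unit must be 'camera' or 'concession'")

    w = (
        ev.groupby([key, "group_label"], sort=False)["group_size"]
        .sum()
        .rename("weighted_count")
    )
    grid = pd.MultiIndex.from_product([frame[key], labels], names=[key, "group_label"])
    counts = w.reindex(grid, fill_value=0).reset_index()
    out = counts.merge(frame, on=key, how="left")
    out["weighted_count"] = out["weighted_count"].astype(float)
    out["encounter_rate"] = out["weighted_count"] / out["effort_days"]
    out["grouping_level"] = level
    cols = [key, "concession_id", "pair_id", "certified", "grouping_level", "group_label",
            "weighted_count", "effort_days", "encounter_rate"]
    cols = list(dict.fromkeys(c for c in cols if c in out.columns))
    return out[cols]


def biomass_proxy(
    species_rates: pd.DataFrame,
    traits: pd.DataFrame,
    literal_effort_division: bool = False,
) -> pd.DataFrame:
    """Relative faunal biomass per concession.

    The index is ``sum_s rate_s * mass_s`` in kg per camera-trap day:
    encounter rates already carry the division by effort, so multiplying by
    body mass yields a per-effort biomass flow.  ``literal_effort_division``
    divides by effort a second time (an alternative reading of the same
    recipe, off by default); the two orderings give identical concession
    rankings whenever efforts are equal.
    """
    if not (species_rates["grouping_level"] == "species").all():
        raise ValueError("biomass_proxy expects a species-level rate table")
    mass = traits.set_index("species_label")["mean_body_mass"]
    missing = set(species_rates["group_label"]) - set(mass.index)
    if missing:
        raise ValueError(f"species without body mass: {sorted(missing)}")
    df = species_rates.copy()
    df["term"] = df["encounter_rate"] * df["group_label"].map(mass).astype(float)
    if literal_effort_division:
        df["term"] = df["term"] / df["effort_days"]
    keys = [c for c in ("concession_id", "pair_id", "certified") if c in df.columns]
    out = df.groupby(keys, as_index=False)["term"].sum()
    return out.rename(columns={"term": "biomass_index"})
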