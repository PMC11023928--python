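import numpy as np
import pandas as pd
import pytest

import camtrap_pairs as cp

T0 = pd.Timestamp("2019-06-01 06:00:00")


def photo_row(camera="C1", minutes=0.0, species="blue duiker", n=1, status=False):
    return {
        "camera_id": camera,
        "timestamp": T0 + pd.Timedelta(minutes=minutes),
        "species_label": species,
        "n_individuals": n,
        "is_status_photo": status,
    }


def photo_frame(rows):
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def community():
    return cp.default_community()


@pytest.fixture(scope="session")
def traits(community):
    from camtrap_pairs.synthetic import traits_table

    return cp.load_traits(traits_table(community))


@pytest.fixture(scope="session")
def small_design():
    return cp.SimDesign(
        n_pairs=2, cameras_per_concession=(5, 5), deployment_days=30, seed=11
    )


@pytest.fixture(scope="session")
def small_survey(community, small_design):
    photos, deployments, traits_raw = cp.simulate_dataset(community, small_design)
    return photos, deployments, cp.load_traits(traits_raw)


def truth_effort(deployments):
    """EffortTable built from the generator's true active days."""
    from camtrap_pairs.events import EffortTable

    cam = deployments[["camera_id", "concession_id", "pair_id", "certified"]].copy()
    cam["active_days"] = deployments["true_active_days"].to_numpy()
    conc = (
        cam.groupby(["concession_id", "pair_id", "certified"], as_index=False)["active_days"]
        .sum()
        .rename(columns={"active_days": "camera_days"})
    )
    return EffortTable(camera=cam, concession=conc)


def balanced_rate_table(n_pairs=4, n_cameras=3, effect=0.3, sd=0.15, seed=1, groups=None):
    """Balanced camera-level rate table with known certification effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_pairs):
        for ci, cert in enumerate((True, False)):
            conc = f"P{p}c{ci}"
            for k in range(n_cameras):
                cam = f"{conc}k{k}"
                for g in groups or ["all"]:
                    rows.append(
                        dict(
                            encounter_rate=1.0 + (effect if cert else 0.0) + rng.normal(0, sd),
                            certified=cert,
                            pair_id=f"P{p}",
                            concession_id=conc,
                            camera_id=cam,
                            group_label=g,
                        )
                    )
    return pd.DataFrame(rows)
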