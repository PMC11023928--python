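import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import camtrap_pairs as cp
from camtrap_pairs.events import build_events, compute_effort, sensitivity_table

from conftest import T0, photo_frame, photo_row


def brute_force_cluster(minutes, threshold):
    """Single-linkage clustering of photo times: number of clusters."""
    order = np.argsort(minutes, kind="stable")
    t = np.asarray(minutes, dtype=float)[order]
    n = len(t)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(t[i] - t[j]) < threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


@pytest.mark.parametrize(
    "minutes, expected_events, expected_photos",
    [
        ([0, 5, 9], 1, [3]),
        ([0, 10], 2, [1, 1]),  # exactly at threshold => separate detections
        ([0, 6, 12], 1, [3]),  # chained gaps below threshold
        ([0, 9.999, 19.0], 1, [3]),
        ([0, 15, 16, 40], 3, [1, 2, 1]),
    ],
)
def test_build_events_chaining(minutes, expected_events, expected_photos):
    photos = photo_frame([photo_row(minutes=m) for m in minutes])
    ev = build_events(photos, threshold_minutes=10)
    assert len(ev) == expected_events
    assert ev["n_photos"].tolist() == expected_photos


def test_group_size_is_max_count_within_event():
    photos = photo_frame(
        [photo_row(minutes=m, n=n) for m, n in zip([0, 2, 4], [2, 5, 3])]
    )
    ev = build_events(photos)
    assert len(ev) == 1
    assert ev["group_size"].iloc[0] == 5


def test_species_and_cameras_never_merge():
    photos = photo_frame(
        [
            photo_row(minutes=0),
            photo_row(minutes=1, species="red river hog"),
            photo_row(minutes=2, camera="C2"),
        ]
    )
    ev = build_events(photos)
    assert len(ev) == 3


def test_status_photos_never_seed_events():
    photos = photo_frame(
        [photo_row(minutes=0), photo_row(minutes=5, species="", n=0, status=True)]
    )
    ev = build_events(photos)
    assert len(ev) == 1 and ev["n_photos"].iloc[0] == 1


def test_duplicate_rows_collapse_with_warning():
    photos = photo_frame([photo_row(minutes=0), photo_row(minutes=0)])
    with pytest.warns(UserWarning, match="duplicate"):
        ev = build_events(photos)
    assert len(ev) == 1 and ev["n_photos"].iloc[0] == 1


def test_anchor_modes_differ_on_long_chains():
    photos = photo_frame([photo_row(minutes=m) for m in [0, 6, 12, 18]])
    assert len(build_events(photos, anchor="last_photo")) == 1
    ev = build_events(photos, anchor="event_start")
    assert len(ev) == 2 and ev["n_photos"].tolist() == [2, 2]


def test_invalid_arguments():
    photos = photo_frame([photo_row()])
    with pytest.raises(ValueError):
        build_events(photos, threshold_minutes=-1)
    with pytest.raises(ValueError):
        build_events(photos, anchor="nearest")


def test_photo_conservation_and_permutation_invariance(small_survey, traits):
    photos_raw, _, _ = small_survey
    photos, _ = cp.load_photos(photos_raw, traits)
    ev = build_events(photos)
    n_animal = int((~photos["is_status_photo"]).sum())
    assert ev["n_photos"].sum() == n_animal
    shuffled = photos.sample(frac=1, random_state=0).reset_index(drop=True)
    ev2 = build_events(shuffled)
    pd.testing.assert_frame_equal(
        ev.sort_values(list(ev.columns)).reset_index(drop=True),
        ev2.sort_values(list(ev.columns)).reset_index(drop=True),
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    gaps=hst.lists(
        hst.one_of(
            hst.floats(min_value=0.1, max_value=25.0),
            hst.just(10.0),  # force boundary hits
        ),
        min_size=0,
        max_size=40,
    )
)
def test_event_count_matches_bruteforce_oracle(gaps):
    minutes = np.cumsum([0.0] + gaps)
    photos = photo_frame([photo_row(minutes=m) for m in minutes])
    ev = build_events(photos, threshold_minutes=10)
    # the oracle compares the stored nanosecond timestamps, exactly as the
    # implementation does
    ns = photos["timestamp"].astype("int64").to_numpy()
    assert len(ev) == brute_force_cluster(ns, 10 * 60 * 1_000_000_000)


def test_event_counts_non_increasing_in_threshold(small_survey, traits):
    photos_raw, _, _ = small_survey
    photos, _ = cp.load_photos(photos_raw, traits)
    counts = [
        len(build_events(photos, threshold_minutes=t)) for t in (10, 30, 60, 1440)
    ]
    assert counts == sorted(counts, reverse=True)


def test_sensitivity_table_shape_and_monotonicity(small_survey, traits):
    photos_raw, _, _ = small_survey
    photos, _ = cp.load_photos(photos_raw, traits)
    tab = sensitivity_table(photos, traits)
    assert set(tab["threshold_minutes"]) == {10, 30, 60, 1440}
    totals = tab.groupby("threshold_minutes")["n_events"].sum()
    assert totals.loc[1440] <= totals.loc[10]
    # proportions sum to 1 within each threshold
    sums = tab.groupby("threshold_minutes")["proportion"].sum()
    assert np.allclose(sums, 1.0)
    with pytest.raises(ValueError):
        sensitivity_table(photos, traits, thresholds=())


def test_sensitivity_single_photo(traits):
    photos = photo_frame([photo_row()])
    tab = sensitivity_table(photos, traits)
    assert (tab["n_events"] == 1).all() and len(tab) == 4


def make_deployment(camera="C1", days=30, downtime=0.0):
    return pd.DataFrame(
        [
            {
                "camera_id": camera,
                "concession_id": "P1F",
                "pair_id": "P1",
                "certified": True,
                "start": T0,
                "end": T0 + pd.Timedelta(days=days),
                "downtime_days": downtime,
            }
        ]
    )


def test_effort_subtracts_recorded_downtime():
    dep = make_deployment(days=30, downtime=4.0)
    # status photos every 12 h to the scheduled end
    photos = photo_frame(
        [photo_row(minutes=m * 720, species="", n=0, status=True) for m in range(1, 61)]
    )
    eff = compute_effort(dep, photos)
    assert eff.camera["active_days"].iloc[0] == pytest.approx(26.0)


def test_effort_truncates_at_last_photo_plus_grace():
    dep = make_deployment(days=30)
    photos = photo_frame(
        [photo_row(minutes=m * 720, species="", n=0, status=True) for m in range(1, 25)]
    )  # last status photo at day 12.0
    eff = compute_effort(dep, photos)
    assert eff.camera["active_days"].iloc[0] == pytest.approx(12.5)


def test_effort_zero_photo_camera_warns_and_unknown_camera_errors():
    dep = make_deployment()
    with pytest.warns(UserWarning, match="no photos"):
        eff = compute_effort(dep, photo_frame([photo_row()]).iloc[:0])
    assert eff.camera["active_days"].iloc[0] == 0.0
    with pytest.raises(ValueError, match="no deployment record"):
        compute_effort(dep, photo_frame([photo_row(camera="C9")]))


def test_effort_concession_totals_are_camera_sums(small_survey):
    photos_raw, deployments, traits = small_survey
    photos, _ = cp.load_photos(photos_raw, traits)
    eff = compute_effort(deployments, photos)
    merged = eff.camera.groupby("concession_id")["active_days"].sum()
    for _, row in eff.concession.iterrows():
        assert row["camera_days"] == pytest.approx(merged[row["concession_id"]])
    span = (deployments["end"] - deployments["start"]).dt.days.max()
    assert (eff.camera["active_days"] <= span + 1e-9).all()
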