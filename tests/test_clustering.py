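"""Within-country clustering: partition correctness against a brute-force
oracle, the cluster-count heuristic, and conservative disaggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import plumlite as pl
from plumlite.spatial_clustering import (
    InfeasibleDeltaError,
    cell_features,
    _zscore,
    membership_frame,
)


def wcss(X, labels):
    tot = 0.0
    for j in np.unique(labels):
        grp = X[labels == j]
        tot += ((grp - grp.mean(axis=0)) ** 2).sum()
    return tot


@pytest.fixture(scope="module")
def one_country():
    world, anchors = pl.generate_world(1, 8, 2, seed=3)
    return world, anchors


def test_singleton_clustering_has_zero_variance(one_country):
    world, anchors = one_country
    cls = pl.cluster_country(world, anchors, "C00", k=8, seed=0)
    assert len(cls) == 8
    assert all(len(c.cell_ids) == 1 for c in cls)
    X = _zscore(cell_features(world, anchors, world.country_cells("C00")))
    labels = np.empty(8, dtype=int)
    for c in cls:
        for cid in c.cell_ids:
            labels[cid] = c.index
    assert wcss(X, labels) == pytest.approx(0.0, abs=1e-12)


def test_single_cluster_centroid_is_feature_mean(one_country):
    world, anchors = one_country
    (cl,) = pl.cluster_country(world, anchors, "C00", k=1, seed=0)
    X = _zscore(cell_features(world, anchors, world.country_cells("C00")))
    np.testing.assert_allclose(cl.centroid, X.mean(axis=0), atol=1e-9)
    # aggregates equal country totals
    rows = world.country_cells("C00")
    assert cl.area_ha == pytest.approx(rows.area_ha.sum())
    for cls_name in world.cover_classes:
        want = float((rows[f"cover_{cls_name}"] * rows.area_ha).sum())
        assert cl.areas[cls_name] == pytest.approx(want, rel=1e-9)


def test_kmeans_matches_exhaustive_two_partition_oracle(one_country):
    world, anchors = one_country
    cls = pl.cluster_country(world, anchors, "C00", k=2, seed=0)
    X = _zscore(cell_features(world, anchors, world.country_cells("C00")))
    labels = np.empty(8, dtype=int)
    for c in cls:
        for cid in c.cell_ids:
            labels[cid] = c.index
    got = wcss(X, labels)
    best = np.inf
    for mask in range(1, 2**7):  # all 2-partitions up to symmetry
        lab = np.array([(mask >> i) & 1 for i in range(8)])
        best = min(best, wcss(X, lab))
    assert got <= best * (1 + 1e-9)


def test_invalid_k_rejected(one_country):
    world, anchors = one_country
    with pytest.raises(ValueError):
        pl.cluster_country(world, anchors, "C00", k=9, seed=0)
    with pytest.raises(ValueError):
        pl.cluster_country(world, anchors, "C00", k=0, seed=0)


def test_clustering_invariant_to_cell_ordering(one_country):
    world, anchors = one_country
    a = membership_frame(pl.cluster_country(world, anchors, "C00", k=3, seed=4))
    shuffled = world.cells_table.sample(frac=1.0, random_state=9)
    world2 = pl.WorldGrid(
        resolution_deg=world.resolution_deg, crops=world.crops,
        cells_table=shuffled, countries=world.countries, fpus=world.fpus,
    )
    b = membership_frame(pl.cluster_country(world2, anchors, "C00", k=3, seed=4))
    pd.testing.assert_frame_equal(
        a.sort_values("cell_id").reset_index(drop=True),
        b.sort_values("cell_id").reset_index(drop=True),
    )


class TestChooseK:
    def test_single_cell_country(self):
        world, anchors = pl.generate_world(1, 1, 2, seed=0)
        assert pl.choose_k(world, anchors, "C00") == 1

    def test_zero_variance_country_collapses_to_one(self):
        world, anchors = pl.generate_world(1, 100, 2, seed=0)
        # homogenise: identical anchors and covers everywhere
        anchors.yields[:] = anchors.yields[0]
        t = world.cells_table
        for c in world.cover_classes:
            t[f"cover_{c}"] = t[f"cover_{c}"].iloc[0]
        assert pl.choose_k(world, anchors, "C00") == 1

    def test_heterogeneous_country_gets_more_clusters(self):
        world, anchors = pl.generate_world(1, 100, 2, seed=0)
        assert pl.choose_k(world, anchors, "C00") > 1


class TestDisaggregate:
    def test_zero_delta_changes_nothing(self, one_country):
        world, anchors = one_country
        (cl,) = pl.cluster_country(world, anchors, "C00", k=1, seed=0)
        before = world.country_cells("C00").copy()
        out = pl.disaggregate(world, cl, {c: 0.0 for c in world.crops})
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), before.reset_index(drop=True)
        )

    def test_expansion_proportional_to_available_natural(self):
        """Cells with 30/70 ha available natural split +10 ha as +3/+7."""
        crops = ("cereals_c3",)
        rows = []
        for i, nat in enumerate((30.0, 70.0)):
            area = 100.0
            rows.append({
                "cell_id": i, "lat": 0.25, "lon": 0.25 + 0.5 * i, "area_ha": area,
                "country_id": "X", "fpu_id": "X-F0", "protected_fraction": 0.0,
                "aridity_index": 0.2, "cover_cereals_c3": 0.2, "cover_pasture": 0.0,
                "cover_forest": nat / (2 * area), "cover_other_natural": nat / (2 * area),
                "cover_urban": 0.8 - nat / area,
            })
        table = pd.DataFrame(rows)
        world = pl.WorldGrid(resolution_deg=0.5, crops=crops, cells_table=table,
                             countries=[], fpus=[])
        anchors = pl.YieldAnchorSet(
            crops=crops, yields=np.full((2, 2, 3, 2), 1.0),
            irrigation_requirement=np.zeros((2, 2)), runoff=np.zeros(2),
        )
        (cl,) = pl.cluster_country(world, anchors, "X", k=1, seed=0)
        out = pl.disaggregate(world, cl, {"cereals_c3": 10.0})
        gained = (out.cover_cereals_c3.to_numpy() - table.cover_cereals_c3.to_numpy()) * 100.0
        np.testing.assert_allclose(gained, [3.0, 7.0], atol=1e-9)

    def test_random_deltas_conserve_cluster_totals(self, one_country):
        world, anchors = one_country
        cls = pl.cluster_country(world, anchors, "C00", k=2, seed=0)
        rng = np.random.default_rng(8)
        for cl in cls:
            scale = 0.02 * cl.area_ha
            deltas = {c: float(rng.uniform(-scale, scale)) for c in world.crops}
            deltas["pasture"] = float(rng.uniform(-0.5, 0.5) * cl.areas["pasture"])
            before = world.cells_table[world.cells_table.cell_id.isin(cl.cell_ids)]
            out = pl.disaggregate(world, cl, deltas)
            area = out.area_ha.to_numpy()
            for c, d in deltas.items():
                got = ((out[f"cover_{c}"].to_numpy()
                        - before[f"cover_{c}"].to_numpy()) * area).sum()
                assert got == pytest.approx(d, abs=1e-9 * max(1.0, cl.area_ha))
            cov = out[[f"cover_{c}" for c in world.cover_classes]].to_numpy()
            np.testing.assert_allclose(cov.sum(axis=1), 1.0, atol=1e-9)
            assert (cov >= -1e-12).all() and (cov <= 1 + 1e-12).all()

    def test_infeasible_expansion_names_cluster(self, one_country):
        world, anchors = one_country
        (cl,) = pl.cluster_country(world, anchors, "C00", k=1, seed=0)
        with pytest.raises(InfeasibleDeltaError, match="C00"):
            pl.disaggregate(world, cl, {"cereals_c3": 10 * cl.area_ha})
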