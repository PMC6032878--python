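"""Within-country clustering of grid cells and cluster-to-cell mapping.

Similar (not necessarily contiguous) cells are grouped by K-means on
z-scored features — per-crop anchor yields and land-cover fractions — so
the country optimiser can work on a handful of clusters instead of every
cell.  Cluster land-use changes are mapped back to member cells in
proportion to each cell's available natural area (expansion) or its current
area of the shrinking class (contraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .commodities import NATURAL_CLASSES, URBAN, land_uses
from .grid import WorldGrid, YieldAnchorSet

#: Scale factor of the cluster-count heuristic.
K_WEIGHT = 2.0


class InfeasibleDeltaError(ValueError):
    """A cluster-level change cannot be realised on its member cells."""


@dataclass
class Cluster:
    """Aggregate of similar cells within one country."""

    country_id: str
    index: int
    cell_ids: np.ndarray
    centroid: np.ndarray
    area_ha: float
    areas: dict[str, float]  # per land-cover class, ha
    protected_ha: float
    mean_anchors: np.ndarray  # (n_land_uses, 3, 2), area-weighted, t/ha
    mean_irrigation_requirement: np.ndarray  # (n_land_uses,) km3/ha/yr
    available_water: float = 0.0  # km3/yr, filled from the water budget
    mean_irrigation_cost_index: float = 1.0
    cell_areas_ha: np.ndarray | None = None  # member cell areas
    cell_protected_ha: np.ndarray | None = None  # member protected areas

    def reserved_ha(self, min_natural_fraction: float) -> float:
        """Natural area that must be preserved: per-cell maximum of the
        protected area and the minimum-natural-fraction reserve."""
        if self.cell_areas_ha is None:
            return max(self.protected_ha, min_natural_fraction * self.area_ha)
        return float(
            np.maximum(self.cell_protected_ha, min_natural_fraction * self.cell_areas_ha).sum()
        )


def cell_features(world: WorldGrid, anchors: YieldAnchorSet, rows: pd.DataFrame) -> np.ndarray:
    """Feature matrix for clustering: anchor yields (rain-fed and irrigated
    at 200 kgN/ha, all land uses) plus cover fractions."""
    idx = rows.index.to_numpy()
    feats = [anchors.yields[idx, :, 1, 0], anchors.yields[idx, :, 1, 1]]
    feats.append(world.cover_matrix(rows))
    return np.column_stack(feats)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def choose_k(world: WorldGrid, anchors: YieldAnchorSet, country_id: str,
             weight: float = K_WEIGHT) -> int:
    """Cluster count heuristic: grows with country size and heterogeneity.

    ``k = clamp(ceil(weight * sqrt(n_cells) * cv), 1, n_cells)`` where cv is
    the mean coefficient of variation of the clustering features; a
    perfectly homogeneous country collapses to a single cluster.
    """
    rows = world.country_cells(country_id)
    n = len(rows)
    if n == 0:
        raise ValueError(f"country {country_id} has no cells")
    X = cell_features(world, anchors, rows)
    mu = np.abs(X.mean(axis=0))
    sd = X.std(axis=0)
    cv = float(np.mean(np.divide(sd, mu, out=np.zeros_like(sd), where=mu > 0)))
    return int(np.clip(np.ceil(weight * np.sqrt(n) * cv), 1, n))


def cluster_country(
    world: WorldGrid,
    anchors: YieldAnchorSet,
    country_id: str,
    k: int,
    seed: int = 0,
) -> list[Cluster]:
    """K-means clustering of a country's cells on standardised features.

    Deterministic under a fixed seed; cells are canonically sorted by id
    before clustering so the result is invariant to input ordering.
    """
    rows = world.country_cells(country_id).sort_values("cell_id")
    n = len(rows)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}] for country {country_id}")
    X = _zscore(cell_features(world, anchors, rows))
    if k == n:
        labels = np.arange(n)
        centroids = X
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        labels = km.labels_
        centroids = km.cluster_centers_
    # relabel by first-member cell id for a canonical order
    order = sorted(range(k), key=lambda j: int(rows.cell_id.to_numpy()[labels == j].min()))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    centroids = centroids[order]

    clusters = []
    idx_all = rows.index.to_numpy()
    area = rows.area_ha.to_numpy()
    cov = world.cover_matrix(rows)
    classes = world.cover_classes
    for j in range(k):
        sel = labels == j
        idx = idx_all[sel]
        a = area[sel]
        areas = {cls: float((cov[sel, ci] * a).sum()) for ci, cls in enumerate(classes)}
        w = a / a.sum()
        mean_anchors = np.einsum("c,cluw->luw", w, world_anchor_block(anchors, idx))
        mean_req = np.einsum("c,cl->l", w, anchors.irrigation_requirement[idx])
        clusters.append(
            Cluster(
                country_id=country_id,
                index=j,
                cell_ids=rows.cell_id.to_numpy()[sel],
                centroid=centroids[j],
                area_ha=float(a.sum()),
                areas=areas,
                protected_ha=float((rows.protected_fraction.to_numpy()[sel] * a).sum()),
                cell_areas_ha=a.copy(),
                cell_protected_ha=(rows.protected_fraction.to_numpy()[sel] * a).copy(),
                mean_anchors=mean_anchors,
                mean_irrigation_requirement=mean_req,
                mean_irrigation_cost_index=float(
                    (w * (0.5 + rows.aridity_index.to_numpy()[sel])).sum()
                ),
            )
        )
    return clusters


def world_anchor_block(anchors: YieldAnchorSet, idx: np.ndarray) -> np.ndarray:
    return anchors.yields[idx]


def membership_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tidy cell -> cluster mapping."""
    rows = []
    for cl in clusters:
        for cid in cl.cell_ids:
            rows.append({"cell_id": int(cid), "country_id": cl.country_id, "cluster": cl.index})
    return pd.DataFrame(rows)


def disaggregate(
    world: WorldGrid,
    cluster: Cluster,
    deltas: dict[str, float],
    min_natural_fraction: float = 0.0,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Map cluster-level land-use changes (ha per class) back to cells.

    Expansion of an agricultural class is allocated in proportion to each
    member cell's available natural area (unprotected forest + other
    natural above the minimum-natural reserve); contraction in proportion
    to the cell's current area of the shrinking class.  The expansion is
    debited from each cell's forest and other natural cover in equal parts
    (falling back proportionally where one class runs out); contraction is
    credited back to other natural vegetation.

    Returns the member rows of the cell table with updated cover fractions.
    Cell totals conserve the cluster delta to ``tol`` and no fraction
    leaves [0, 1].
    """
    rows = world.cells_table[world.cells_table.cell_id.isin(cluster.cell_ids)].copy()
    area = rows.area_ha.to_numpy()
    ag_classes = [c for c in world.cover_classes if c not in NATURAL_CLASSES + (URBAN,)]

    forest = rows["cover_forest"].to_numpy() * area
    othernat = rows["cover_other_natural"].to_numpy() * area
    reserved = np.maximum(
        rows.protected_fraction.to_numpy() * area, min_natural_fraction * area
    )
    available = np.maximum(forest + othernat - reserved, 0.0)

    expand_total = sum(max(0.0, d) for d in deltas.values())
    contract_total = sum(max(0.0, -d) for d in deltas.values())
    net_expand = expand_total - contract_total
    if net_expand > available.sum() + tol:
        raise InfeasibleDeltaError(
            f"cluster {cluster.country_id}/{cluster.index}: net expansion "
            f"{net_expand:.3f} ha exceeds available natural {available.sum():.3f} ha"
        )

    changes = {cls: np.zeros(len(rows)) for cls in world.cover_classes}
    freed = np.zeros(len(rows))
    for cls, d in deltas.items():
        if cls not in ag_classes:
            raise ValueError(f"deltas must address agricultural classes, got {cls}")
        if d < -tol:
            cur = rows[f"cover_{cls}"].to_numpy() * area
            if cur.sum() < -d - tol:
                raise InfeasibleDeltaError(
                    f"cluster {cluster.country_id}/{cluster.index}: contraction of "
                    f"{cls} by {-d:.3f} ha exceeds current {cur.sum():.3f} ha"
                )
            w = cur / cur.sum() if cur.sum() > 0 else np.zeros(len(rows))
            changes[cls] += d * w
            freed -= d * w
    # expansion weighted by what each cell can supply: available natural
    # plus agricultural area freed by the contracting classes
    capacity = available + freed
    for cls, d in deltas.items():
        if d > tol:
            if capacity.sum() <= 0:
                raise InfeasibleDeltaError(
                    f"cluster {cluster.country_id}/{cluster.index}: expansion of "
                    f"{cls} with no available land in member cells"
                )
            changes[cls] += d * capacity / capacity.sum()

    net_ag = sum(changes[c] for c in ag_classes)
    # debit expansion equally from forest and other natural, credit
    # contraction to other natural
    gain = np.maximum(net_ag, 0.0)
    loss = np.maximum(-net_ag, 0.0)
    unprot_forest = np.maximum(forest - np.minimum(reserved, forest), 0.0)
    unprot_other = np.maximum(available - unprot_forest, 0.0)
    take_forest = np.minimum(gain / 2.0, unprot_forest)
    take_other = np.minimum(gain - take_forest, unprot_other)
    take_forest = gain - take_other  # remainder falls back to forest
    changes["forest"] -= take_forest
    changes["other_natural"] -= take_other
    changes["other_natural"] += loss

    out = rows.copy()
    for cls in world.cover_classes:
        frac = rows[f"cover_{cls}"].to_numpy() + changes[cls] / area
        if (frac < -tol).any() or (frac > 1 + tol).any():
            raise InfeasibleDeltaError(
                f"cluster {cluster.country_id}/{cluster.index}: cover fraction for "
                f"{cls} leaves [0, 1]"
            )
        out[f"cover_{cls}"] = np.clip(frac, 0.0, 1.0)
    return out
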