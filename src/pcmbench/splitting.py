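"""Compound clustering and cluster-atomic train/validation/test splitting.

Chemical-series bias is controlled by splitting at the level of fingerprint
clusters rather than records: K-means (k = 100 by default, Euclidean on the
0/1 vectors) groups similar compounds, and whole clusters are assigned to
training/validation/test at 80/10/10 so that no similar molecules straddle
a split boundary.  Clustering is computed once per dataset; each of the 10
folds redraws only the cluster-to-set assignment with a fold-derived seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from pcmbench.core_data import BioactivityRecord, Dataset
from pcmbench.seeding import derive_seed, rng_for

logger = logging.getLogger(__name__)

SETS = ("train", "val", "test")
DEFAULT_FRACTIONS = (0.80, 0.10, 0.10)


@dataclass
class FoldSplit:
    """Cluster map and record-set assignment for one fold.

    Set membership is defined at the record level through the compound's
    cluster, so one protein may (and typically does) appear in all three
    sets; cluster atomicity means all records of one compound cluster land
    in one set.
    """

    fold_index: int
    cluster_of: dict[str, int]
    set_of_cluster: dict[int, str]

    def set_of(self, record: BioactivityRecord) -> str:
        return self.set_of_cluster[self.cluster_of[record.compound_id]]

    def split_records(
        self, records: list[BioactivityRecord]
    ) -> dict[str, list[BioactivityRecord]]:
        out: dict[str, list[BioactivityRecord]] = {s: [] for s in SETS}
        for rec in records:
            out[self.set_of(rec)].append(rec)
        return out


def cluster_compounds(
    fingerprints: dict[str, np.ndarray], k: int = 100, seed: int = 0
) -> dict[str, int]:
    """K-means cluster labels for every compound, Euclidean on the bit vectors.

    If fewer than ``k`` distinct fingerprints exist, ``k`` is lowered to
    that number with a warning.  Identical fingerprints always share a
    label.  Deterministic given the seed.
    """
    if not fingerprints:
        raise ValueError("no fingerprints to cluster")
    ids = sorted(fingerprints)
    X = np.stack([fingerprints[c] for c in ids]).astype(np.float64)
    distinct = np.unique(X, axis=0)
    n_distinct = len(distinct)
    if n_distinct < k:
        logger.warning(
            "only %d distinct fingerprints; lowering k from %d", n_distinct, k
        )
        k = n_distinct
    km = KMeans(n_clusters=k, n_init=4, random_state=derive_seed(seed, "kmeans"))
    # fit on distinct vectors so duplicates cannot split across clusters,
    # then assign every compound to its vector's cluster
    km.fit(distinct)
    labels = km.predict(X)
    return {cid: int(lab) for cid, lab in zip(ids, labels)}


def assign_clusters(
    cluster_of: dict[str, int],
    record_cluster_sizes: dict[int, int],
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    seed: int = 0,
    fold_index: int = 0,
    set_names: tuple[str, ...] = SETS,
) -> FoldSplit:
    """Assign whole clusters to the split sets near the target fractions.

    ``record_cluster_sizes`` gives the number of *records* per cluster (the
    quantity the 80/10/10 targets refer to).  Clusters are visited in a
    seeded random order and greedily placed into the set whose deficit
    relative to its target is largest (ties break by set order), so
    different folds draw genuinely different assignments while record
    fractions stay close to the targets.  Atomicity is guaranteed by
    construction; each set is non-empty whenever there are at least as
    many clusters as sets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != len(set_names):
        raise ValueError("one fraction per set required")
    clusters = sorted(record_cluster_sizes)
    if len(clusters) < len(set_names):
        raise ValueError(
            f"need >= {len(set_names)} clusters to form {len(set_names)} sets, "
            f"got {len(clusters)}"
        )
    rng = rng_for(seed, "assign", fold_index)
    perm = list(rng.permutation(clusters))
    total = sum(record_cluster_sizes.values())
    targets = {s: f * total for s, f in zip(set_names, fractions)}
    filled = {s: 0.0 for s in set_names}
    set_of_cluster: dict[int, str] = {}
    for c in perm:
        deficits = {s: targets[s] - filled[s] for s in set_names}
        best = max(set_names, key=lambda s: deficits[s])
        set_of_cluster[c] = best
        filled[best] += record_cluster_sizes[c]
    # guarantee non-emptiness: move the smallest cluster of the fullest set
    for s in set_names:
        if not any(v == s for v in set_of_cluster.values()):
            counts = {
                t: sum(1 for v in set_of_cluster.values() if v == t)
                for t in set_names
            }
            donor_set = max(set_names, key=lambda t: counts[t])
            donor = min(
                (c for c, v in set_of_cluster.items() if v == donor_set),
                key=lambda c: record_cluster_sizes[c],
            )
            set_of_cluster[donor] = s
    realized = {
        s: sum(record_cluster_sizes[c] for c, v in set_of_cluster.items() if v == s)
        / total
        for s in set_names
    }
    for s, f in zip(set_names, fractions):
        if abs(realized[s] - f) > 0.05:
            logger.warning(
                "fold %d: %s fraction %.3f deviates from target %.2f "
                "(cluster atomicity)",
                fold_index,
                s,
                realized[s],
                f,
            )
    return FoldSplit(
        fold_index=fold_index, cluster_of=dict(cluster_of), set_of_cluster=set_of_cluster
    )


def _record_cluster_sizes(
    dataset: Dataset, cluster_of: dict[str, int]
) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for rec in dataset.records:
        c = cluster_of[rec.compound_id]
        sizes[c] = sizes.get(c, 0) + 1
    return sizes


def make_folds(
    dataset: Dataset,
    n_folds: int = 10,
    k: int = 100,
    seed: int = 0,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    cluster_of: dict[str, int] | None = None,
) -> list[FoldSplit]:
    """n_folds cluster-atomic splits sharing one clustering.

    Fold seeds are derived deterministically from the master seed, so folds
    differ only in their cluster-to-set assignment.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if cluster_of is None:
        cluster_of = cluster_compounds(dataset.fingerprints, k=k, seed=seed)
    sizes = _record_cluster_sizes(dataset, cluster_of)
    return [
        assign_clusters(cluster_of, sizes, fractions=fractions, seed=seed, fold_index=i)
        for i in range(n_folds)
    ]
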