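"""The four balancing x clustering schemas and resampling-round accounting.

A *resampling round* is one pass oversampling every eligible protein within
one split set (or one pooled set).  Over a complete 10-fold run the four
strategies execute:

- ``no_resampling`` — cluster, split; the original imbalance is kept
  (0 rounds).
- ``resampling_after_clustering`` — cluster, split, then balance train,
  validation and test independently per fold (3 x 10 = 30 rounds); every
  retained protein ends at exactly 50% actives in every set.
- ``resampling_before_clustering`` — balance the whole dataset once
  (1 round), then cluster the augmented compound set and split; the global
  per-protein ratio is 50% but per-set ratios drift.
- ``semi_resampling`` — reuse the ``no_resampling`` folds, keep the test
  set untouched, pool train+val, balance the pool (1 round per fold = 10
  rounds), re-cluster the pooled compounds and re-split train:val at 8:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from pcmbench.core_data import BioactivityRecord, Dataset
from pcmbench.resampling import ResampleReport, SmoteConfig, resample_protein
from pcmbench.seeding import derive_seed, rng_for
from pcmbench.splitting import (
    SETS,
    FoldSplit,
    assign_clusters,
    cluster_compounds,
    make_folds,
)

logger = logging.getLogger(__name__)


class StrategyName(str, Enum):
    no_resampling = "no_resampling"
    resampling_after_clustering = "resampling_after_clustering"
    resampling_before_clustering = "resampling_before_clustering"
    semi_resampling = "semi_resampling"


@dataclass
class StrategyRun:
    """Materialized train/val/test record sets for one strategy and fold."""

    strategy: StrategyName
    fold_index: int
    train: list[BioactivityRecord]
    val: list[BioactivityRecord]
    test: list[BioactivityRecord]
    fingerprints: dict[str, np.ndarray]
    cluster_of: dict[str, int]
    rounds_ledger: list[tuple[int, str]] = field(default_factory=list)
    reports: list[ResampleReport] = field(default_factory=list)

    def records_of(self, set_name: str) -> list[BioactivityRecord]:
        return {"train": self.train, "val": self.val, "test": self.test}[set_name]


def _resample_set(
    records: list[BioactivityRecord],
    fingerprints: dict[str, np.ndarray],
    smote: SmoteConfig,
    seed_tags: tuple,
    id_prefix: str,
) -> tuple[list[BioactivityRecord], dict[str, np.ndarray], dict[str, str], list[ResampleReport]]:
    """One resampling round: balance every eligible protein in one record set.

    Discarded proteins are removed from the returned set (only from the set
    being resampled; they stay put elsewhere).
    """
    by_protein: dict[str, list[BioactivityRecord]] = {}
    for rec in records:
        by_protein.setdefault(rec.protein_id, []).append(rec)
    out_records: list[BioactivityRecord] = []
    new_fps: dict[str, np.ndarray] = {}
    parent_of: dict[str, str] = {}
    reports: list[ResampleReport] = []
    for pid in sorted(by_protein):
        rng = rng_for(seed_tags[0], *seed_tags[1:], pid)
        recs, fps, parents, report = resample_protein(
            by_protein[pid],
            fingerprints,
            smote,
            rng=rng,
            synthetic_id_prefix=id_prefix,
        )
        reports.append(report)
        if report.discarded:
            continue
        out_records.extend(recs)
        new_fps.update(fps)
        parent_of.update(parents)
    return out_records, new_fps, parent_of, reports


def run_strategy(
    dataset: Dataset,
    strategy: StrategyName | str,
    n_folds: int = 10,
    seed: int = 0,
    k_clusters: int = 100,
    smote: SmoteConfig | None = None,
) -> list[StrategyRun]:
    """Materialize all folds of one balancing strategy.

    The base clustering and fold assignments depend only on the dataset and
    master seed, never on the strategy, so ``semi_resampling`` reuses
    (and ``no_resampling`` shares) identical splits — in particular their
    test sets are record-identical at equal seeds.
    """
    strategy = StrategyName(strategy)
    if smote is None:
        smote = SmoteConfig(seed=seed)

    base_cluster_of = cluster_compounds(dataset.fingerprints, k=k_clusters, seed=seed)
    base_folds = make_folds(
        dataset, n_folds=n_folds, seed=seed, cluster_of=base_cluster_of
    )

    if strategy is StrategyName.no_resampling:
        return [
            _plain_run(dataset, strategy, fold, base_cluster_of)
            for fold in base_folds
        ]
    if strategy is StrategyName.resampling_after_clustering:
        return [
            _after_clustering_run(dataset, fold, base_cluster_of, smote, seed)
            for fold in base_folds
        ]
    if strategy is StrategyName.resampling_before_clustering:
        return _before_clustering_runs(dataset, n_folds, seed, k_clusters, smote)
    if strategy is StrategyName.semi_resampling:
        return [
            _semi_run(dataset, fold, base_cluster_of, smote, seed, k_clusters)
            for fold in base_folds
        ]
    raise ValueError(f"unknown strategy {strategy!r}")


def _plain_run(
    dataset: Dataset,
    strategy: StrategyName,
    fold: FoldSplit,
    cluster_of: dict[str, int],
) -> StrategyRun:
    parts = fold.split_records(dataset.records)
    return StrategyRun(
        strategy=strategy,
        fold_index=fold.fold_index,
        train=parts["train"],
        val=parts["val"],
        test=parts["test"],
        fingerprints=dict(dataset.fingerprints),
        cluster_of=dict(cluster_of),
        rounds_ledger=[],
    )


def _after_clustering_run(
    dataset: Dataset,
    fold: FoldSplit,
    cluster_of: dict[str, int],
    smote: SmoteConfig,
    seed: int,
) -> StrategyRun:
    parts = fold.split_records(dataset.records)
    fingerprints = dict(dataset.fingerprints)
    clusters = dict(cluster_of)
    ledger: list[tuple[int, str]] = []
    reports: list[ResampleReport] = []
    out: dict[str, list[BioactivityRecord]] = {}
    for set_name in SETS:  # fixed order: train, val, test
        recs, fps, parents, reps = _resample_set(
            parts[set_name],
            fingerprints,
            smote,
            seed_tags=(seed, "after", fold.fold_index, set_name),
            id_prefix=f"S{fold.fold_index}{set_name[0]}",
        )
        fingerprints.update(fps)
        # synthetic compounds inherit the cluster of their parent v_i,
        # which lies in the same set: atomicity is preserved
        for cid, parent in parents.items():
            clusters[cid] = clusters[parent]
        out[set_name] = recs
        reports.extend(reps)
        ledger.append((fold.fold_index, set_name))
    return StrategyRun(
        strategy=StrategyName.resampling_after_clustering,
        fold_index=fold.fold_index,
        train=out["train"],
        val=out["val"],
        test=out["test"],
        fingerprints=fingerprints,
        cluster_of=clusters,
        rounds_ledger=ledger,
        reports=reports,
    )


def _before_clustering_runs(
    dataset: Dataset,
    n_folds: int,
    seed: int,
    k_clusters: int,
    smote: SmoteConfig,
) -> list[StrategyRun]:
    # one global round before any clustering; the single ledger entry is
    # attached to fold 0 (it is shared by all folds)
    recs, fps, _parents, reports = _resample_set(
        dataset.records,
        dataset.fingerprints,
        smote,
        seed_tags=(seed, "before", "all"),
        id_prefix="Sg",
    )
    fingerprints = {**dataset.fingerprints, **fps}
    used = {r.compound_id for r in recs}
    augmented = Dataset(
        records=recs,
        fingerprints={c: fingerprints[c] for c in used},
        sequences=dataset.sequences,
    )
    cluster_of = cluster_compounds(
        augmented.fingerprints, k=k_clusters, seed=derive_seed(seed, "before-cluster")
    )
    folds = make_folds(augmented, n_folds=n_folds, seed=seed, cluster_of=cluster_of)
    runs = []
    for fold in folds:
        run = _plain_run(
            augmented, StrategyName.resampling_before_clustering, fold, cluster_of
        )
        if fold.fold_index == 0:
            run.rounds_ledger = [(-1, "all")]
            run.reports = reports
        runs.append(run)
    return runs


def _semi_run(
    dataset: Dataset,
    fold: FoldSplit,
    cluster_of: dict[str, int],
    smote: SmoteConfig,
    seed: int,
    k_clusters: int,
) -> StrategyRun:
    parts = fold.split_records(dataset.records)
    pool = parts["train"] + parts["val"]
    recs, fps, _parents, reports = _resample_set(
        pool,
        dataset.fingerprints,
        smote,
        seed_tags=(seed, "semi", fold.fold_index),
        id_prefix=f"S{fold.fold_index}p",
    )
    fingerprints = {**dataset.fingerprints, **fps}
    pool_fps = {r.compound_id: fingerprints[r.compound_id] for r in recs}
    new_clusters = cluster_compounds(
        pool_fps,
        k=k_clusters,
        seed=derive_seed(seed, "semi-recluster", fold.fold_index),
    )
    # namespace the re-clustering away from the base labels kept by test
    offset = max(cluster_of.values()) + 1
    merged = dict(cluster_of)
    merged.update({c: lab + offset for c, lab in new_clusters.items()})
    sizes: dict[int, int] = {}
    for r in recs:
        c = merged[r.compound_id]
        sizes[c] = sizes.get(c, 0) + 1
    resplit = assign_clusters(
        merged,
        sizes,
        fractions=(8 / 9, 1 / 9),
        seed=derive_seed(seed, "semi-resplit"),
        fold_index=fold.fold_index,
        set_names=("train", "val"),
    )
    out = {"train": [], "val": []}
    for r in recs:
        out[resplit.set_of_cluster[merged[r.compound_id]]].append(r)
    return StrategyRun(
        strategy=StrategyName.semi_resampling,
        fold_index=fold.fold_index,
        train=out["train"],
        val=out["val"],
        test=parts["test"],
        fingerprints=fingerprints,
        cluster_of=merged,
        rounds_ledger=[(fold.fold_index, "train+val")],
        reports=reports,
    )


def count_rounds(runs: list[StrategyRun]) -> int:
    """Total resampling rounds executed across the folds of one strategy."""
    strategies = {run.strategy for run in runs}
    if len(strategies) > 1:
        raise ValueError(f"runs mix strategies {sorted(s.value for s in strategies)}")
    return sum(len(run.rounds_ledger) for run in runs)
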