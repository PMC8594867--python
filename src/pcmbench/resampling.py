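"""Per-protein SMOTE oversampling with eligibility and discard accounting.

Each protein's activity data is balanced separately: the minority class is
oversampled with SMOTE until it equals the majority count, so the
protein-level active ratio is exactly 1/2.  A protein is discarded from
the set being resampled when SMOTE is inapplicable: its records are
single-class, or the minority class has fewer than k_neighbors + 1 members
(each minority point needs k distinct minority neighbours besides itself).

Synthetic points are interpolated between a minority point and one of its
k nearest minority neighbours (Euclidean distance, ties by compound id);
by default they are then binarized at 0.5 so every stored fingerprint
remains a valid 881-bit vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from pcmbench.core_data import BioactivityRecord
from pcmbench.seeding import rng_for


@dataclass
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = 0
    binarize_synthetic: bool = True

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class ResampleReport:
    protein_id: str
    n_active_before: int
    n_inactive_before: int
    n_synthetic_added: int
    discarded: bool
    discard_reason: str  # single_class | minority_too_small | none

    def __post_init__(self) -> None:
        if self.discarded and self.n_synthetic_added != 0:
            raise ValueError("a discarded protein adds no synthetic records")


def _minority_neighbours(vectors: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours within the minority set, self excluded."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(vectors)
    _, idx = nn.kneighbors(vectors)
    m = len(vectors)
    out = np.empty((m, k), dtype=int)
    for i in range(m):
        row = [j for j in idx[i] if j != i][:k]
        while len(row) < k:  # only when duplicate vectors displaced self
            row.append(row[-1])
        out[i] = row
    return out


def _interpolate(
    vectors: np.ndarray,
    n_needed: int,
    config: SmoteConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n_needed SMOTE points; returns (points, base index of each v_i)."""
    neighbours = _minority_neighbours(vectors, config.k_neighbors)
    m = len(vectors)
    base = rng.integers(0, m, size=n_needed)
    pick = rng.integers(0, config.k_neighbors, size=n_needed)
    u = rng.random(n_needed)
    vi = vectors[base]
    vj = vectors[neighbours[base, pick]]
    synth = vi + u[:, None] * (vj - vi)
    if config.binarize_synthetic:
        synth = (synth >= 0.5).astype(np.float64)
    return synth, base


def smote_points(
    minority_vectors: np.ndarray,
    n_needed: int,
    config: SmoteConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Interpolate ``n_needed`` synthetic minority vectors.

    Each synthetic point is ``v_i + u * (v_j - v_i)`` with u ~ Uniform[0,1],
    where v_j is one of the k nearest minority neighbours of a uniformly
    chosen v_i (the point itself excluded).  Binarization, when enabled,
    rounds each coordinate to {0, 1} at 0.5.  Deterministic given the seed.
    """
    minority_vectors = np.asarray(minority_vectors, dtype=np.float64)
    if n_needed < 0:
        raise ValueError("n_needed must be >= 0")
    if len(minority_vectors) < config.k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors + 1 = {config.k_neighbors + 1} "
            f"minority vectors, got {len(minority_vectors)}"
        )
    if n_needed == 0:
        return np.empty((0, minority_vectors.shape[1]))
    if rng is None:
        rng = rng_for(config.seed, "smote")
    synth, _ = _interpolate(minority_vectors, n_needed, config, rng)
    return synth


def resample_protein(
    records: list[BioactivityRecord],
    fingerprints: dict[str, np.ndarray],
    config: SmoteConfig,
    rng: np.random.Generator | None = None,
    synthetic_id_prefix: str = "S",
) -> tuple[list[BioactivityRecord], dict[str, np.ndarray], dict[str, str], ResampleReport]:
    """Balance one protein's records to an exact 50% active ratio.

    Returns the (possibly augmented) record list, the new synthetic
    fingerprints, a map synthetic compound_id -> parent compound_id (the
    v_i whose cluster the synthetic compound inherits), and the report.
    Original records are never modified or removed here; ineligible
    proteins come back unchanged with ``discarded=True`` and the caller
    decides removal.
    """
    pids = {r.protein_id for r in records}
    if len(pids) != 1:
        raise ValueError(f"records span proteins {sorted(pids)}")
    protein_id = pids.pop()
    actives = [r for r in records if r.label == 1]
    inactives = [r for r in records if r.label == 0]
    n_act, n_inact = len(actives), len(inactives)

    def report(discarded: bool, reason: str, added: int = 0) -> ResampleReport:
        return ResampleReport(
            protein_id=protein_id,
            n_active_before=n_act,
            n_inactive_before=n_inact,
            n_synthetic_added=added,
            discarded=discarded,
            discard_reason=reason,
        )

    if n_act == 0 or n_inact == 0:
        return records, {}, {}, report(True, "single_class")
    if n_act == n_inact:
        return records, {}, {}, report(False, "none", 0)
    minority, majority = (actives, inactives) if n_act < n_inact else (inactives, actives)
    if len(minority) < config.k_neighbors + 1:
        return records, {}, {}, report(True, "minority_too_small")

    n_needed = len(majority) - len(minority)
    minority_ids = sorted(r.compound_id for r in minority)  # tie-break order
    vectors = np.stack([fingerprints[c] for c in minority_ids]).astype(np.float64)
    if rng is None:
        rng = rng_for(config.seed, "resample", protein_id)
    synth, base = _interpolate(vectors, n_needed, config, rng)

    label = minority[0].label
    new_records = list(records)
    new_fps: dict[str, np.ndarray] = {}
    parent_of: dict[str, str] = {}
    for i in range(n_needed):
        cid = f"{synthetic_id_prefix}:{protein_id}:{i:05d}"
        new_fps[cid] = synth[i].astype(np.int8 if config.binarize_synthetic else float)
        parent_of[cid] = minority_ids[base[i]]
        new_records.append(
            BioactivityRecord(
                compound_id=cid, protein_id=protein_id, label=label, synthetic=True
            )
        )
    return new_records, new_fps, parent_of, report(False, "none", n_needed)
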