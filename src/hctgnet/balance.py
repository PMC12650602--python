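"""SMOTE class balancing, applied to the training split only.

The Synthetic Minority Over-sampling Technique generates new minority-class
beats by linear interpolation between an existing beat and one of its *k*
nearest same-class neighbours (Euclidean distance in the 188-dimensional
normalised beat space):  ``x_new = x + lam * (x_neighbour - x)`` with
``lam ~ U[0, 1]``.  Original rows are preserved verbatim; synthetic rows are
appended.  The default target policy equalises every class to the majority
count.

Balancing a dataset tagged as a validation or test split is refused: the
whole point of holding those splits out is an unbiased evaluation, so the
resampling contract is train-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .preprocess import BeatDataset
from .wfdb_io import CLASSES


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE parameters: neighbourhood size, per-class targets, seed."""

    k_neighbors: int = 5
    target_counts: tuple[int, ...] | str = "equalize"
    seed: int = 0

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not (self.target_counts == "equalize"
                or (len(self.target_counts) == len(CLASSES)
                    and all(int(t) >= 0 for t in self.target_counts))):
            raise ValueError("target_counts must be 'equalize' or 5 counts")


def smote_interpolate(x: np.ndarray, x_neighbor: np.ndarray,
                      lam: float) -> np.ndarray:
    """Point on the segment between two beats: ``x + lam * (x_neighbor - x)``."""
    x = np.asarray(x, dtype=float)
    x_neighbor = np.asarray(x_neighbor, dtype=float)
    if x.shape != x_neighbor.shape:
        raise ValueError(
            f"length mismatch: {x.shape} vs {x_neighbor.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    return x + lam * (x_neighbor - x)


def smote_oversample(dataset: BeatDataset,
                     config: SmoteConfig = SmoteConfig()) -> BeatDataset:
    """Oversample minority classes to the target counts.

    Deterministic given ``config.seed``.  Classes with a single sample fall
    back to replication (recorded as a provenance warning); classes with
    fewer than ``k_neighbors + 1`` samples use every available same-class
    neighbour.  Raises if the dataset is tagged as a val/test split or if a
    target is below the current count.
    """
    role = dataset.role
    if role in ("val", "test"):
        raise ValueError(
            f"refusing to balance a dataset tagged as the {role!r} split: "
            "resampling is applied to the training set only")
    counts = dataset.class_counts
    if config.target_counts == "equalize":
        targets = np.full(len(CLASSES), counts.max(), dtype=int)
    else:
        targets = np.asarray(config.target_counts, dtype=int)
    for cls, have, want in zip(CLASSES, counts, targets):
        if have and want < have:
            raise ValueError(
                f"target count {want} for class {cls} below current {have}")

    rng = np.random.default_rng(config.seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    warnings: list[str] = []
    for ci, cls in enumerate(CLASSES):
        need = int(targets[ci] - counts[ci])
        if need <= 0 or counts[ci] == 0:
            if need > 0 and counts[ci] == 0:
                warnings.append(f"class {cls} absent; cannot oversample")
            continue
        rows = dataset.beats[dataset.labels == cls].astype(float)
        if len(rows) < 2:
            # cannot interpolate: replicate the lone sample
            warnings.append(f"class {cls} has {len(rows)} sample(s); "
                            "fell back to replication")
            reps = np.repeat(rows, need, axis=0)
            new_rows.extend(reps)
            new_labels.extend([cls] * need)
            continue
        k = min(config.k_neighbors, len(rows) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(rows)
        # drop the self-neighbour in column 0
        neighbor_idx = nn.kneighbors(rows, return_distance=False)[:, 1:]
        base = rng.integers(0, len(rows), size=need)
        pick = rng.integers(0, k, size=need)
        lams = rng.uniform(0.0, 1.0, size=need)
        for b, p, lam in zip(base, pick, lams):
            new_rows.append(smote_interpolate(rows[b],
                                              rows[neighbor_idx[b, p]], lam))
        new_labels.extend([cls] * need)

    if new_rows:
        beats = np.concatenate([dataset.beats,
                                np.asarray(new_rows, dtype=np.float32)])
        labels = np.concatenate([dataset.labels,
                                 np.asarray(new_labels, dtype="U1")])
    else:
        beats, labels = dataset.beats, dataset.labels
    prov = [dict(s) for s in dataset.provenance]
    prov.append({"step": "smote", "k_neighbors": config.k_neighbors,
                 "targets": [int(x) for x in targets], "seed": config.seed,
                 "n_synthetic": len(new_rows), "warnings": warnings})
    return BeatDataset(beats, labels, prov)
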