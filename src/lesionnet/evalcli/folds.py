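"""Seeded stratified k-fold splitting (scikit-learn backed)."""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold


def stratified_kfold(labels: Sequence[int], k: int, seed: int
                     ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Disjoint (train_indices, val_indices) pairs with per-fold class
    proportions within one sample of the global proportions."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValueError(f"classes {small.tolist()} have fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), va.copy()) for tr, va in skf.split(np.zeros(len(labels)), labels)]
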