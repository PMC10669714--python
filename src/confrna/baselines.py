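"""Reference classifiers used as sanity baselines and protocol stubs.

These are intentionally simple: the nearest-centroid k-mer-frequency
classifier certifies that a synthetic dataset carries learnable signal
(any competent model should beat it), and the majority-class stub gives
closed-form expected accuracies for cross-validation protocol tests.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .representation import build_vocab
from .sequence_io import LabeledDataset, SequenceRecord

__all__ = ["KmerCentroidClassifier", "MajorityClassClassifier"]


def _kmer_frequencies(seq: str, k: int, lut: dict[str, int]) -> np.ndarray:
    vec = np.zeros(len(lut))
    for i in range(len(seq) - k + 1):
        vec[lut[seq[i:i + k]]] += 1.0
    total = vec.sum()
    return vec / total if total else vec


class KmerCentroidClassifier:
    """Nearest centroid over L1-normalized k-mer frequency vectors."""

    def __init__(self, k: int = 2):
        self.k = k
        self._lut = build_vocab(k).token_to_index
        self.families: list[str] = []
        self.centroids: np.ndarray | None = None

    def _featurize(self, records) -> np.ndarray:
        return np.stack([_kmer_frequencies(r.residues, self.k, self._lut) for r in records])

    def fit(self, records, families=None) -> "KmerCentroidClassifier":
        records = list(records)
        self.families = list(families) if families is not None else sorted(
            {r.family for r in records}
        )
        feats = self._featurize(records)
        labels = np.array([self.families.index(r.family) for r in records])
        self.centroids = np.stack([
            feats[labels == i].mean(axis=0) for i in range(len(self.families))
        ])
        return self

    def predict(self, records) -> list[str]:
        feats = self._featurize(list(records))
        dists = ((feats[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=-1)
        return [self.families[i] for i in dists.argmin(axis=1)]

    def accuracy(self, records) -> float:
        records = list(records)
        pred = self.predict(records)
        return float(np.mean([p == r.family for p, r in zip(pred, records)]))


class MajorityClassClassifier:
    """Predicts the most frequent training family, ties broken by order."""

    def __init__(self):
        self.majority: str | None = None

    def fit(self, records, families=None) -> "MajorityClassClassifier":
        counts = Counter(r.family for r in records)
        top = max(counts.values())
        order = families if families is not None else counts.keys()
        self.majority = next(f for f in order if counts.get(f, 0) == top)
        return self

    def predict(self, records) -> list[str]:
        return [self.majority for _ in records]
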