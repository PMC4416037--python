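"""Synthetic feature tables with the structure the analysis assumes.

The generator emulates an untargeted metabolite-profiling study of a handful
of animals per class: log-normal abundances (so the log-transform step is
meaningful), hundreds of features, an optional shared equicorrelation among
features, and a small planted set of class-discriminative features whose
log-scale means shift by a configurable number of standard deviations in
specific classes.  Defaults mirror a five-class design of ~5 animals each
with one class of 4 (24 samples), exercising unbalanced leave-one-out folds.

It does not attempt chromatography artifacts, missingness, batch effects or
technique-specific intensity distributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .preprocess import FeatureTable

DEFAULT_CLASSES = (
    "fearful-neophobic-alert",
    "interested-stressed",
    "outgoing-neophilic-alert",
    "subdued-uninterested-calm",
    "indistinct",
)


class SyntheticSpecError(ValueError):
    pass


@dataclasses.dataclass
class SyntheticSpec:
    """Generator parameters.

    ``informative`` maps a feature index to its per-class mean shifts in
    units of ``base_log_sd``.  ``feature_correlation`` is an equicorrelation
    rho shared by all feature pairs on the log scale.
    """

    n_features: int = 200
    class_names: tuple = DEFAULT_CLASSES
    samples_per_class: tuple = (5, 5, 5, 5, 4)
    informative: dict = dataclasses.field(default_factory=dict)
    base_log_mean: float = 5.0
    base_log_sd: float = 1.0
    feature_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1:
            raise SyntheticSpecError("n_features must be >= 1")
        if len(self.class_names) != len(self.samples_per_class):
            raise SyntheticSpecError("class_names and samples_per_class differ")
        if len(self.class_names) < 2:
            raise SyntheticSpecError("need at least 2 classes")
        if any(s < 1 for s in self.samples_per_class):
            raise SyntheticSpecError("every class needs at least one sample")
        if not (0 <= self.feature_correlation < 1):
            raise SyntheticSpecError("feature_correlation must be in [0, 1)")
        if self.base_log_sd <= 0:
            raise SyntheticSpecError("base_log_sd must be positive")
        K = len(self.class_names)
        for j, shifts in self.informative.items():
            if not (0 <= int(j) < self.n_features):
                raise SyntheticSpecError(f"informative index {j} out of range")
            if len(shifts) != K:
                raise SyntheticSpecError(
                    f"feature {j}: need one shift per class ({K})"
                )
            if not np.all(np.isfinite(np.asarray(shifts, dtype=float))):
                raise SyntheticSpecError(f"feature {j}: shifts must be finite")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_class))


def planted_shifts(
    n_informative: int = 10, shift: float = 2.5, n_classes: int = 5
) -> dict:
    """Convenience pattern: informative feature ``i`` is shifted by ``shift``
    SD in class ``i mod n_classes`` and unshifted elsewhere."""
    out = {}
    for i in range(n_informative):
        s = [0.0] * n_classes
        s[i % n_classes] = float(shift)
        out[i] = tuple(s)
    return out


def generate(spec: SyntheticSpec):
    """Draw a raw feature table and its ground truth.

    Log-scale values are Gaussian with mean ``base_log_mean``, SD
    ``base_log_sd`` and pairwise feature correlation ``rho`` (one shared
    standard-normal factor per sample); planted shifts are added on the log
    scale, then everything is exponentiated to positive raw abundances.
    Identical seeds give bit-identical output.

    Returns ``(FeatureTable, ground_truth_dict)``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, K = spec.n_samples, spec.n_features, len(spec.class_names)
    rho = spec.feature_correlation

    labels = []
    class_idx = []
    for k, (name, size) in enumerate(zip(spec.class_names, spec.samples_per_class)):
        labels.extend([name] * size)
        class_idx.extend([k] * size)
    class_idx = np.asarray(class_idx)

    z = rng.standard_normal((n, p))
    if rho > 0:
        shared = rng.standard_normal((n, 1))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z
    logv = spec.base_log_mean + spec.base_log_sd * z
    for j, shifts in spec.informative.items():
        shifts = np.asarray(shifts, dtype=float)
        logv[:, int(j)] += spec.base_log_sd * shifts[class_idx]

    sample_ids = [f"animal_{i + 1:02d}" for i in range(n)]
    names = [f"feat_{j + 1:04d}" for j in range(p)]
    # alternate technique tags so downstream tables exercise both labels
    meta = pd.DataFrame(
        {"technique": ["GC-MS" if j % 2 == 0 else "LC-MS" for j in range(p)]},
        index=names,
    )
    table = FeatureTable(sample_ids, labels, np.exp(logv), meta, "raw")
    truth = {
        "informative": sorted(int(j) for j in spec.informative),
        "shifts": {str(int(j)): list(map(float, s)) for j, s in spec.informative.items()},
        "informative_names": [names[int(j)] for j in sorted(spec.informative)],
        "seed": int(spec.seed),
        "n_samples": n,
        "n_features": p,
        "class_names": list(spec.class_names),
        "samples_per_class": list(map(int, spec.samples_per_class)),
        "base_log_mean": float(spec.base_log_mean),
        "base_log_sd": float(spec.base_log_sd),
        "feature_correlation": float(rho),
    }
    return table, truth
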