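"""Training objectives and the out-of-distribution score.

The supervised branch minimises a class-frequency-weighted cross-entropy

    L_S = -(1/|D_K|) sum_i sum_c w_c y_ic log p(y_ic | x_i)

with w_c = 1/freq(c) computed on the labelled subset D_K, which counteracts
the heavy neoplastic : non-neoplastic imbalance (about 0.83 : 0.17 at the
full-data scale).  The jigsaw branch minimises the same form over the P+1
pseudo-labels with w_0 = 1/(1-s) and w_p = P/s for scrambled indices, the
inverses of the batch-assembly frequencies.  The total loss is
L_total = L_S + lambda * L_U.

At inference, an out-of-distribution score

    kappa = KL[U || p(y|x)] + w_0 * (-log p_jigsaw(0 | x))

combines the divergence of the class posterior from uniform with the jigsaw
cross-entropy of the (always unscrambled) test image; the baseline variant
uses the KL term alone.  Both terms are exposed so their opposing movements
can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "ClassWeights",
    "JigsawWeights",
    "LossReport",
    "OODScore",
    "compute_class_weights",
    "supervised_loss",
    "jigsaw_loss",
    "total_loss",
    "kl_from_uniform",
    "ood_score",
    "ood_scores_batch",
]

# probabilities are clamped to at least EPS inside every log
EPS = 1e-12


class DegenerateClassError(ValueError):
    """Raised when a class required for weighting has no samples."""


@dataclass(frozen=True)
class ClassWeights:
    """Inverse-frequency class weights, w_c = 1 / freq(c)."""

    weights: np.ndarray
    source_counts: np.ndarray


@dataclass(frozen=True)
class JigsawWeights:
    """Inverse-frequency pseudo-label weights for the jigsaw loss.

    freq = ((1-s), s/P, ..., s/P)  =>  w_0 = 1/(1-s), w_p = P/s.
    """

    weights: np.ndarray
    s: float
    P: int

    @classmethod
    def from_ratio(cls, s: float, P: int) -> "JigsawWeights":
        if not 0 < s < 1:
            raise ValueError(f"s must be in (0, 1) for finite weights, got {s}")
        if P < 1:
            raise ValueError(f"P must be >= 1, got {P}")
        w = np.full(P + 1, P / s, dtype=float)
        w[0] = 1.0 / (1.0 - s)
        return cls(weights=w, s=float(s), P=int(P))

    @property
    def w0(self) -> float:
        return float(self.weights[0])


@dataclass(frozen=True)
class LossReport:
    L_S: float
    L_U: float
    lam: float
    L_total: float


@dataclass(frozen=True)
class OODScore:
    kappa: float
    kl_term: float
    jigsaw_term: float
    mode: str


def compute_class_weights(labels, n_classes: int = 2) -> ClassWeights:
    """Inverse relative-frequency weights from a labelled sample.

    Every class must be present; a balanced two-class set yields (2, 2).
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=n_classes)
    if (counts == 0).any():
        missing = np.flatnonzero(counts == 0).tolist()
        raise DegenerateClassError(f"classes {missing} have no samples")
    freq = counts / counts.sum()
    return ClassWeights(weights=1.0 / freq, source_counts=counts)


def _weighted_ce(probs: np.ndarray, labels: np.ndarray, weights: np.ndarray) -> float:
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs and labels length mismatch")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label outside probability-vector support")
    p_true = np.clip(probs[np.arange(len(labels)), labels], EPS, None)
    return float(np.mean(weights[labels] * -np.log(p_true)))


def supervised_loss(probs, labels, weights: ClassWeights) -> float:
    """Weighted cross-entropy over the two lesion classes (mean over samples)."""
    return _weighted_ce(probs, labels, np.asarray(weights.weights))


def jigsaw_loss(probs, pseudo_labels, weights: JigsawWeights) -> float:
    """Weighted cross-entropy over the P+1 jigsaw pseudo-labels."""
    return _weighted_ce(probs, pseudo_labels, np.asarray(weights.weights))


def total_loss(L_S: float, L_U: float, lam: float) -> LossReport:
    """L_total = L_S + lambda * L_U."""
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if not (np.isfinite(L_S) and np.isfinite(L_U) and np.isfinite(lam)):
        raise ValueError("loss terms must be finite")
    return LossReport(L_S=float(L_S), L_U=float(L_U), lam=float(lam),
                      L_total=float(L_S + lam * L_U))


def kl_from_uniform(probs) -> float:
    """KL[U || p] = sum_y (1/C) log((1/C) / p_y), natural log, eps-clamped.

    Zero iff ``probs`` is the uniform distribution; large when the prediction
    is confidently peaked, i.e. for typical in-distribution samples.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a single probability vector")
    if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probs must be non-negative and sum to 1")
    c = len(p)
    u = 1.0 / c
    return float(np.sum(u * np.log(u / np.clip(p, EPS, None))))


def ood_score(
    class_probs,
    jigsaw_probs,
    jigsaw_weights: JigsawWeights,
    mode: str = "ssl",
) -> OODScore:
    """Out-of-distribution score for one unscrambled test image.

    baseline: kappa = KL[U || p(y|x)]
    ssl:      kappa = KL[U || p(y|x)] + w_0 * (-log p_jigsaw(0|x))

    The jigsaw term is the pseudo-label-0 cross-entropy, the only label
    available at test time since test images are never scrambled.
    """
    if mode not in ("baseline", "ssl"):
        raise ValueError(f"mode must be 'baseline' or 'ssl', got {mode!r}")
    kl = kl_from_uniform(class_probs)
    if mode == "baseline":
        return OODScore(kappa=kl, kl_term=kl, jigsaw_term=0.0, mode=mode)
    jp = np.asarray(jigsaw_probs, dtype=float)
    if jp.ndim != 1 or (jp < -1e-9).any() or abs(jp.sum() - 1.0) > 1e-6:
        raise ValueError("jigsaw_probs must be a probability vector")
    jig = jigsaw_weights.w0 * -np.log(np.clip(jp[0], EPS, None))
    return OODScore(kappa=kl + jig, kl_term=kl, jigsaw_term=float(jig), mode=mode)


def ood_scores_batch(class_probs, jigsaw_probs, jigsaw_weights, mode="ssl"):
    """Vectorised per-sample OOD scores; returns (kappa, kl_term, jigsaw_term)."""
    cp = np.atleast_2d(np.asarray(class_probs, dtype=float))
    c = cp.shape[1]
    u = 1.0 / c
    kl = (u * np.log(u / np.clip(cp, EPS, None))).sum(axis=1)
    if mode == "baseline":
        jig = np.zeros(len(cp))
    else:
        jp = np.atleast_2d(np.asarray(jigsaw_probs, dtype=float))
        jig = jigsaw_weights.w0 * -np.log(np.clip(jp[:, 0], EPS, None))
    return kl + jig, kl, jig
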