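"""Confounder-aware triplet sampling and the triplet margin loss.

For each anchor sample i and each of the c known confounders, omega
triplets (i, j, j') are drawn: the positive j shares the anchor's label but
comes from a different confounder stratum; the negative j' carries a
different label (any stratum).  The loss is a hinge on squared Euclidean
distances in latent space,

    (1 / (omega * c)) * sum_i sum_(i,j,j') max(||z_i - z_j||^2
                                               - ||z_i - z_j'||^2 + alpha, 0),

averaged over anchors.  Minimizing it pulls same-label samples from
different batches together while pushing differently labelled samples at
least `alpha` further away — the mechanism that strips supplier signal out
of the embedding while keeping the disease signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import SampleAnnotations

__all__ = ["Triplet", "TripletSet", "BatchTriplets", "sample_triplets",
           "sample_batch_triplets", "triplet_margin_loss"]


@dataclass(frozen=True)
class Triplet:
    i: int
    j: int
    j_prime: int
    confounder_index: int


@dataclass
class TripletSet:
    triplets: list[Triplet]
    omega: int
    c: int
    alpha: float = 1.0
    #: anchors for which the different-confounder constraint had to be dropped
    relaxed_anchors: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.triplets)

    def by_anchor(self) -> dict[int, list[Triplet]]:
        out: dict[int, list[Triplet]] = {}
        for t in self.triplets:
            out.setdefault(t.i, []).append(t)
        return out

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.array([t.i for t in self.triplets], dtype=np.intp)
        j = np.array([t.j for t in self.triplets], dtype=np.intp)
        jp = np.array([t.j_prime for t in self.triplets], dtype=np.intp)
        return i, j, jp


@dataclass
class BatchTriplets:
    """Flat triplet index arrays for one mini-batch."""

    i: np.ndarray
    j: np.ndarray
    j_prime: np.ndarray
    n_anchors: int


def _draw_triplets(labels: np.ndarray, conf: np.ndarray, omega: int,
                   rng: np.random.Generator, alpha: float,
                   warn: bool = True) -> TripletSet:
    n, c = conf.shape
    triplets: list[Triplet] = []
    relaxed: list[int] = []
    for i in range(n):
        same = np.flatnonzero(labels == labels[i])
        same = same[same != i]
        neg = np.flatnonzero(labels != labels[i])
        if len(neg) == 0 or len(same) == 0:
            continue
        for cc in range(c):
            pos = same[conf[same, cc] != conf[i, cc]]
            if len(pos) == 0:
                # degenerate stratum: fall back to same-label positives
                pos = same
                relaxed.append(i)
            pj = rng.choice(pos, size=omega, replace=True)
            nj = rng.choice(neg, size=omega, replace=True)
            triplets.extend(
                Triplet(i, int(a), int(b), cc) for a, b in zip(pj, nj)
            )
    if relaxed and warn:
        warnings.warn(
            f"{len(relaxed)} anchor/confounder pairs had no same-label sample "
            "in a different confounder stratum; constraint relaxed",
            stacklevel=3,
        )
    return TripletSet(triplets=triplets, omega=omega, c=c, alpha=alpha,
                      relaxed_anchors=relaxed)


def sample_triplets(annotations: SampleAnnotations, omega: int = 16,
                    seed: int = 0, alpha: float = 1.0) -> TripletSet:
    """Draw omega triplets per anchor per confounder over a whole cohort."""
    labels = annotations.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("triplet sampling requires at least two label classes")
    conf = annotations.confounder_codes()
    if conf.shape[1] < 1:
        raise ValueError("at least one confounder column is required")
    rng = np.random.default_rng(seed)
    return _draw_triplets(labels, conf, omega, rng, alpha)


def sample_batch_triplets(labels: np.ndarray, conf: np.ndarray, omega: int,
                          rng: np.random.Generator) -> BatchTriplets | None:
    """In-batch triplet draw used during training; None if single-class."""
    if len(np.unique(labels)) < 2:
        return None
    tset = _draw_triplets(labels, conf, omega, rng, alpha=1.0, warn=False)
    if not tset.triplets:
        return None
    i, j, jp = tset.arrays()
    return BatchTriplets(i=i, j=j, j_prime=jp,
                         n_anchors=len(np.unique(i)))


def triplet_margin_loss(z: np.ndarray, tset: TripletSet) -> float:
    """Hinge loss over the listed triplets, averaged over anchors.

    Scaling is 1 / (omega * c * n_anchors) so the value is comparable
    across batch sizes.
    """
    z = np.asarray(z, dtype=np.float64)
    if not tset.triplets:
        return 0.0
    i, j, jp = tset.arrays()
    if i.max() >= z.shape[0] or j.max() >= z.shape[0] or jp.max() >= z.shape[0]:
        raise IndexError("triplet index outside the provided latent matrix")
    d_pos = ((z[i] - z[j]) ** 2).sum(axis=1)
    d_neg = ((z[i] - z[jp]) ** 2).sum(axis=1)
    hinge = np.maximum(d_pos - d_neg + tset.alpha, 0.0)
    n_anchors = len(np.unique(i))
    return float(hinge.sum() / (tset.omega * tset.c * n_anchors))
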