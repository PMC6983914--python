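"""Permutation-tested spatial correlograms.

Three analyses over 1-m distance classes (half-open bins ``[k, k+1)``,
co-located pairs in the first class):

* :func:`moran_identity_correlogram` — spatial autocorrelation of genet
  *identity* among ramets.  Each sample is encoded as the centered
  one-hot vector of its genet; per distance class k,
  ``I_k = (N / W_k) * sum_{ordered pairs in k} <z_i, z_j> / sum_i <z_i, z_i>``
  (a join-count-equivalent multivariate Moran's I).
* :func:`mantel_correlogram` — spatial dependence of a genetic distance
  matrix (e.g. among ramets of one genet).  The per-class statistic is
  the normalized cross-product between centered genetic *similarities*
  (negated centered distances, so positive values mean genetically
  similar pairs at that distance) and the class-membership indicator.
* :func:`genet_correlogram` — the Mantel form applied to one
  representative ramet per genet (the member nearest the genet
  centroid).

Inference is purely permutational: one permutation of the coordinate
rows yields one full correlogram (preserving cross-class dependence),
p-values are two-sided ``(b + 1) / (n_perm + 1)`` with
``b = #{perm : |I| >= |I_obs|}``, and the reported envelope is the
2.5/97.5 percentile band of the permuted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .model import DistanceMatrix, GenetAssignment, SampleSheet


@dataclass
class PairClasses:
    """Unordered sample pairs binned into geographic distance classes."""

    i: np.ndarray  # pair first index
    j: np.ndarray  # pair second index
    cls: np.ndarray  # distance class per pair, -1 = beyond max distance
    n_classes: int
    bin_width: float
    counts: np.ndarray  # pairs per class

    def edges(self) -> list[tuple[float, float]]:
        return [(k * self.bin_width, (k + 1) * self.bin_width) for k in range(self.n_classes)]


@dataclass
class Correlogram:
    table: pd.DataFrame  # class_lo, class_hi, n_pairs, I, env_lo, env_hi, p, significant, excluded
    statistic: str
    n_perm: int

    def significant_classes(self) -> list[int]:
        t = self.table
        return t.index[t["significant"] & ~t["excluded"]].tolist()


def bin_pairs(
    sheet: SampleSheet,
    bin_width: float = 1.0,
    max_dist: float = 18.0,
    min_pairs: int = 2,
) -> PairClasses:
    """Bin all unordered sample pairs by Euclidean distance.

    Classes are half-open ``[k*w, (k+1)*w)`` for k = 0..max_dist/w - 1;
    pairs at or beyond ``max_dist`` get class -1.  ``min_pairs`` is
    carried by the correlogram functions (classes under it are excluded
    from testing but still reported).
    """
    n = sheet.n_samples
    iu = np.triu_indices(n, k=1)
    d = pdist(sheet.xy)
    cls = np.floor(d / bin_width).astype(int)
    n_classes = int(np.ceil(max_dist / bin_width))
    cls[d >= max_dist] = -1
    counts = np.bincount(cls[cls >= 0], minlength=n_classes)
    return PairClasses(iu[0], iu[1], cls, n_classes, bin_width, counts)


def _permutation_correlogram(
    pair_value,  # callable (perm | None) -> per-pair values aligned with pairs
    pc: PairClasses,
    scale: np.ndarray,  # per-class divisor turning class sums into I
    n_perm: int,
    rng: np.random.Generator,
    n_samples: int,
    min_pairs: int,
    alpha: float,
    statistic: str,
) -> Correlogram:
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation null", stacklevel=3)
    keep = pc.cls >= 0
    ci, cj, cc = pc.i[keep], pc.j[keep], pc.cls[keep]

    def class_I(perm: np.ndarray | None) -> np.ndarray:
        vals = pair_value(perm)
        sums = np.bincount(cc, weights=vals, minlength=pc.n_classes)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(pc.counts > 0, sums / scale, np.nan)

    obs = class_I(None)
    perm_I = np.empty((n_perm, pc.n_classes))
    for b in range(n_perm):
        perm_I[b] = class_I(rng.permutation(n_samples))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        env_lo = np.nanpercentile(perm_I, 2.5, axis=0)
        env_hi = np.nanpercentile(perm_I, 97.5, axis=0)
        b_ge = np.sum(np.abs(perm_I) >= np.abs(obs)[None, :], axis=0)
    p = (b_ge + 1) / (n_perm + 1)
    excluded = pc.counts < min_pairs
    significant = (p < alpha) & ~excluded & ~np.isnan(obs)
    edges = pc.edges()
    table = pd.DataFrame(
        {
            "class_lo": [e[0] for e in edges],
            "class_hi": [e[1] for e in edges],
            "n_pairs": pc.counts,
            "I": obs,
            "env_lo": env_lo,
            "env_hi": env_hi,
            "p": p,
            "significant": significant,
            "excluded": excluded,
        }
    )
    return Correlogram(table, statistic, n_perm)


def moran_identity_correlogram(
    sheet: SampleSheet,
    assignment: GenetAssignment,
    n_perm: int = 1000,
    rng=None,
    bin_width: float = 1.0,
    max_dist: float = 18.0,
    min_pairs: int = 2,
    alpha: float = 0.05,
) -> Correlogram:
    """Moran's I of same-genet identity per geographic distance class."""
    if sheet.samples != assignment.samples:
        raise ValueError("sample sheet and assignment sample order differ")
    if assignment.n_genets < 2:
        raise ValueError("identity correlogram undefined with a single genet (zero variance)")
    rng = np.random.default_rng(rng)
    n = sheet.n_samples
    G = assignment.n_genets
    Z = np.zeros((n, G))
    Z[np.arange(n), assignment.genet_ids - 1] = 1.0
    Z -= Z.mean(axis=0, keepdims=True)
    cross = Z @ Z.T  # <z_i, z_j>
    denom = float(np.einsum("ij,ij->", Z, Z))  # sum_i <z_i, z_i>

    pc = bin_pairs(sheet, bin_width, max_dist, min_pairs)
    keep = pc.cls >= 0
    ci, cj = pc.i[keep], pc.j[keep]

    def pair_value(perm):
        if perm is None:
            return cross[ci, cj]
        return cross[perm[ci], perm[cj]]

    # I_k = (N / 2 n_k) * (2 * class sum) / denom = N * class_sum / (n_k * denom)
    scale = pc.counts * denom / n
    return _permutation_correlogram(
        pair_value, pc, scale, n_perm, rng, n, min_pairs, alpha, "moran_identity"
    )


def mantel_correlogram(
    sheet: SampleSheet,
    genetic: DistanceMatrix,
    n_perm: int = 1000,
    rng=None,
    bin_width: float = 1.0,
    max_dist: float = 18.0,
    min_pairs: int = 2,
    alpha: float = 0.05,
) -> Correlogram:
    """Mantel correlogram of a genetic distance matrix over distance classes.

    Positive I at a class means pairs in that class are genetically more
    similar than average.  Constant genetic distances leave the statistic
    undefined (flagged as an error).
    """
    if sheet.samples != list(genetic.ids):
        raise ValueError("sample sheet and distance matrix sample order differ")
    if sheet.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(rng)
    n = sheet.n_samples
    gvals = genetic.values
    iu = np.triu_indices(n, k=1)
    flat = gvals[iu]
    if np.allclose(flat, flat[0]):
        raise ValueError("genetic distances are constant; correlogram undefined")
    sim = -(gvals - flat.mean())  # similarity: positive where closer than average
    sd = flat.std()

    pc = bin_pairs(sheet, bin_width, max_dist, min_pairs)
    keep = pc.cls >= 0
    ci, cj = pc.i[keep], pc.j[keep]

    def pair_value(perm):
        if perm is None:
            return sim[ci, cj]
        return sim[perm[ci], perm[cj]]

    # normalized cross-product: class mean similarity in sd units
    scale = pc.counts * sd
    return _permutation_correlogram(
        pair_value, pc, scale, n_perm, rng, n, min_pairs, alpha, "mantel"
    )


def genet_representatives(
    sheet: SampleSheet, assignment: GenetAssignment
) -> tuple[list[int], SampleSheet]:
    """One sample per genet: the member nearest the genet's centroid
    (ties broken by lowest sample id).  Returns (sample indices, sheet)."""
    if sheet.samples != assignment.samples:
        raise ValueError("sample sheet and assignment sample order differ")
    reps = []
    for g in range(1, assignment.n_genets + 1):
        members = assignment.members(g)
        centroid = sheet.xy[members].mean(axis=0)
        dist = np.linalg.norm(sheet.xy[members] - centroid, axis=1)
        best = min(
            zip(dist, [sheet.samples[i] for i in members], members),
            key=lambda t: (t[0], t[1]),
        )[2]
        reps.append(best)
    return reps, sheet.subset(reps)


def genet_correlogram(
    rep_sheet: SampleSheet,
    rep_genetic: DistanceMatrix,
    n_perm: int = 1000,
    rng=None,
    bin_width: float = 1.0,
    max_dist: float = 18.0,
    min_pairs: int = 2,
    alpha: float = 0.05,
) -> Correlogram:
    """Mantel correlogram at the genet level (one representative each)."""
    if rep_sheet.n_samples < 3:
        raise ValueError("need at least 3 genets for a genet-level correlogram")
    return mantel_correlogram(
        rep_sheet, rep_genetic, n_perm, rng, bin_width, max_dist, min_pairs, alpha
    )
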