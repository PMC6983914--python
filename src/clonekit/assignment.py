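"""Genet-assignment threshold selection and clustering.

Ramets are clustered into genets by cutting an agglomerative clustering
of the pairwise genetic distance matrix at a threshold ``t``:

* ``single`` linkage: two ramets share a genet iff they are connected in
  the graph of pairs with ``d <= t`` (a ramet joins a genet as soon as it
  is within ``t`` of *any* member);
* ``complete`` linkage: the conservative farthest-neighbour rule, in
  which every within-genet pair must satisfy the threshold.

Three threshold estimators are provided, mirroring the three common
practices for clonal data:

``plateau``
    Exploits the bimodality of the pairwise distance histogram (a
    within-genet mode from somatic mutation/genotyping error, and a
    between-genet mode).  The threshold is the top of the longest window
    between the two modes over which the genet count is constant.
``gap``
    The largest gap between consecutive agglomeration merge distances.
``sexual``
    Simulates sexually produced offspring from observed genotypes and
    takes the minimum distance among them: anything closer than the
    closest plausible seed pair is treated as clonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .distances import pairwise_matrix
from .model import DistanceMatrix, GenetAssignment, GenotypeTable

_LINKAGES = ("single", "complete")


@dataclass
class ThresholdDiagnostics:
    """Everything needed to audit a threshold choice."""

    method: str  # plateau | gap | sexual
    threshold: float
    histogram: np.ndarray | None = None  # pair counts per integer distance bin
    curve_t: np.ndarray | None = None  # integer thresholds scanned
    curve_n_genets: np.ndarray | None = None
    low_mode: int | None = None
    high_mode: int | None = None
    valley: int | None = None
    plateau_run: tuple[int, int] | None = None  # inclusive (t_first, t_last)
    extras: dict = field(default_factory=dict)


def _check_linkage(linkage: str) -> None:
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")


def linkage_tree(dm: DistanceMatrix, linkage: str = "single") -> np.ndarray:
    """scipy linkage matrix for the distance matrix."""
    _check_linkage(linkage)
    if dm.n < 2:
        raise ValueError("need at least 2 samples")
    return scipy_linkage(squareform(dm.values, checks=False), method=linkage)


def genet_count_curve(
    dm: DistanceMatrix, linkage: str = "single"
) -> tuple[np.ndarray, np.ndarray]:
    """Number of genets at every integer threshold t = 0..max distance.

    Returns ``(t, n_genets)``.  ``n_genets(t)`` equals ``N`` minus the
    number of dendrogram merges at height <= t, which for single linkage
    coincides with the number of connected components of the graph
    ``{d_ij <= t}``.
    """
    Z = linkage_tree(dm, linkage)
    heights = np.sort(Z[:, 2])
    t = np.arange(0, int(np.floor(dm.max())) + 1)
    n = dm.n - np.searchsorted(heights, t, side="right")
    return t, n


def assign_genets(
    dm: DistanceMatrix, threshold: float, linkage: str = "single"
) -> GenetAssignment:
    """Cluster ramets into genets at the given distance threshold.

    Membership uses ``d <= threshold`` (a threshold that is itself an
    attained distance merges that pair).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    _check_linkage(linkage)
    Z = linkage_tree(dm, linkage)
    labels = fcluster(Z, t=threshold, criterion="distance")
    return GenetAssignment.from_labels(dm.ids, labels, linkage=linkage, threshold=threshold)


def _peak_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Local maxima of a histogram, collapsing flat tops.

    Returns (leftmost_bin, height) for each run of equal counts that is
    strictly higher than both flanking runs (array edges count as lower).
    Zero-height runs are never peaks.
    """
    peaks = []
    i = 0
    m = len(counts)
    while i < m:
        j = i
        while j + 1 < m and counts[j + 1] == counts[i]:
            j += 1
        left_lower = i == 0 or counts[i - 1] < counts[i]
        right_lower = j == m - 1 or counts[j + 1] < counts[i]
        if counts[i] > 0 and left_lower and right_lower:
            peaks.append((i, int(counts[i])))
        i = j + 1
    return peaks


def plateau_threshold(dm: DistanceMatrix, linkage: str = "single") -> ThresholdDiagnostics:
    """Between-modes plateau threshold from the bimodal distance histogram.

    The histogram (bin width 1) must show at least two peaks.  The two
    highest peaks (ties -> leftmost) are located, the deepest valley
    between them splits the histogram into a within-genet and a
    between-genet segment, and the modes are the argmax bins of each
    segment.  Among maximal runs of integer thresholds strictly between
    the modes over which the genet count is constant, the longest run
    (ties -> the lower run) is the plateau; the threshold is its maximum.
    """
    counts = dm.histogram()
    peaks = _peak_runs(counts)
    if len(peaks) < 2:
        raise ValueError(
            "distance distribution is unimodal: no between-genet mode detected; "
            "choose a threshold manually"
        )
    # primary peak = global maximum; secondary = the local maximum with the
    # greatest topographic prominence relative to it, so the deepest valley
    # separates the two modes (raw peak height alone would confuse jagged
    # sub-peaks of one mode with genuine bimodality)
    p1 = min(peaks, key=lambda p: (-p[1], p[0]))[0]
    best = None  # (prominence, -index proxy for leftmost, index)
    for q, hq in peaks:
        if q == p1:
            continue
        lo, hi = sorted((q, p1))
        if hi - lo < 2:
            continue
        prominence = hq - int(counts[lo + 1 : hi].min())
        if prominence > 0 and (best is None or (prominence, -q) > (best[0], -best[2])):
            best = (prominence, None, q)
    if best is None:
        raise ValueError(
            "distance distribution is unimodal: no between-genet mode detected; "
            "choose a threshold manually"
        )
    lo_peak, hi_peak = sorted((p1, best[2]))
    between = counts[lo_peak + 1 : hi_peak]
    valley = lo_peak + 1 + int(np.argmin(between))  # ties -> leftmost
    low_mode = int(np.argmax(counts[: valley + 1]))
    high_mode = valley + 1 + int(np.argmax(counts[valley + 1 :]))

    t, n = genet_count_curve(dm, linkage)
    inside = (t > low_mode) & (t < high_mode)
    ti, ni = t[inside], n[inside]
    if len(ti) == 0:
        raise ValueError("no integer thresholds strictly between the two modes")
    # maximal runs of constant genet count
    runs: list[tuple[int, int]] = []
    start = 0
    for k in range(1, len(ti) + 1):
        if k == len(ti) or ni[k] != ni[start]:
            runs.append((int(ti[start]), int(ti[k - 1])))
            start = k
    best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))  # longest; ties -> lower run
    threshold = best[1]
    return ThresholdDiagnostics(
        method="plateau",
        threshold=float(threshold),
        histogram=counts,
        curve_t=t,
        curve_n_genets=n,
        low_mode=low_mode,
        high_mode=high_mode,
        valley=valley,
        plateau_run=best,
        extras={"linkage": linkage, "n_genets_at_threshold": int(ni[ti == threshold][0])},
    )


def gap_threshold(
    dm: DistanceMatrix, linkage: str = "single", fraction: float = 0.5
) -> ThresholdDiagnostics:
    """Largest gap between consecutive distinct merge distances.

    The putative thresholds are the distinct agglomeration merge heights;
    the threshold is placed ``fraction`` of the way into the widest gap
    between consecutive values (ties -> the lowest gap).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    Z = linkage_tree(dm, linkage)
    merges = np.unique(Z[:, 2])
    if len(merges) < 2:
        raise ValueError("fewer than 2 distinct merge distances; gap undefined")
    gaps = np.diff(merges)
    k = int(np.argmax(gaps))  # ties -> first (lowest) maximal gap
    threshold = merges[k] + fraction * gaps[k]
    t, n = genet_count_curve(dm, linkage)
    return ThresholdDiagnostics(
        method="gap",
        threshold=float(threshold),
        histogram=dm.histogram(),
        curve_t=t,
        curve_n_genets=n,
        extras={
            "linkage": linkage,
            "gap_low": float(merges[k]),
            "gap_high": float(merges[k + 1]),
            "fraction": fraction,
        },
    )


def sexual_threshold(
    parents: GenotypeTable,
    n_sim: int = 1000,
    selfing_fraction: float = 0.5,
    model: str = "iam",
    rng: np.random.Generator | None = None,
) -> ThresholdDiagnostics:
    """Minimum distance among simulated sexually produced offspring.

    Offspring are generated by Mendelian segregation from random parent
    pairs drawn from ``parents`` (a ``selfing_fraction`` of them selfed),
    and the threshold is the smallest pairwise distance among offspring:
    observed pairs closer than any simulated seed pair are taken as
    clonal.  The defaults (1000 offspring, half selfed) are recorded in
    the diagnostics.
    """
    from .sim import simulate_offspring  # deferred: sim depends on model only

    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    if not 0 <= selfing_fraction <= 1:
        raise ValueError("selfing_fraction must be in [0, 1]")
    if parents.n_samples < 2 and selfing_fraction < 1:
        raise ValueError("need >= 2 parents for outcrossing")
    rng = np.random.default_rng(rng)

    rows = []
    n_parents = parents.n_samples
    for k in range(n_sim):
        if n_parents == 1 or rng.random() < selfing_fraction:
            ia = ib = int(rng.integers(n_parents))
            mode = "self"
        else:
            ia, ib = rng.choice(n_parents, size=2, replace=False)
            mode = "outcross"
        off = simulate_offspring(
            parents.calls[int(ia)], parents.calls[int(ib)], 1, mode=mode, rng=rng
        )
        rows.append(off[0])
    offspring = GenotypeTable(
        [f"off{k}" for k in range(n_sim)], parents.loci, np.array(rows)
    )
    dm = pairwise_matrix(offspring, model=model)
    threshold = float(dm.condensed().min())
    return ThresholdDiagnostics(
        method="sexual",
        threshold=threshold,
        extras={
            "n_sim": n_sim,
            "selfing_fraction": selfing_fraction,
            "model": model,
            "offspring_distance_max": float(dm.max()),
        },
    )
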