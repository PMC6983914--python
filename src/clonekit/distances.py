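"""Pairwise genetic distances between multilocus genotypes.

Three models:

``iam``
    Infinite-allele model.  Per locus the distance between two diploid
    calls is ``2 - |multiset intersection of the two allele pairs|``,
    i.e. the number of allele copies that cannot be matched (0, 1 or 2).
    Summed over loci where both calls are present.
``stepwise``
    Stepwise mutation model for SSR repeat scores.  Per locus the
    distance is the minimum over the two possible allele pairings of the
    summed squared repeat-count differences.
``dissimilarity``
    The IAM count, optionally divided by ``2 x loci compared`` to give a
    relative dissimilarity in [0, 1].

Missing data are handled by pairwise-complete deletion: a locus where
either call is missing is skipped for that pair and the per-pair count of
loci actually compared is recorded.  Counts are *not* rescaled for the
integer models, so distances stay raw mismatch counts.
"""

from __future__ import annotations

import numpy as np

from .model import MISSING, Dataset, DistanceMatrix, GenotypeTable


def _matched_copies(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Size of the multiset intersection of 2-element allele multisets.

    ``a`` and ``b`` are (..., 2) arrays of allele codes.  For two-element
    multisets the intersection size is ``min(#a-copies found in b,
    #b-copies found in a)``.
    """
    a1, a2 = a[..., 0], a[..., 1]
    b1, b2 = b[..., 0], b[..., 1]
    a_in_b = ((a1 == b1) | (a1 == b2)).astype(np.int8) + ((a2 == b1) | (a2 == b2)).astype(np.int8)
    b_in_a = ((b1 == a1) | (b1 == a2)).astype(np.int8) + ((b2 == a1) | (b2 == a2)).astype(np.int8)
    return np.minimum(a_in_b, b_in_a)


def iam_distance(calls_a: np.ndarray, calls_b: np.ndarray) -> int:
    """IAM distance between two samples' call vectors, shape (n_loci, 2)."""
    d, n = _iam_pair(np.asarray(calls_a), np.asarray(calls_b))
    if n == 0:
        raise ValueError("no shared non-missing loci between the two samples")
    return int(d)


def _iam_pair(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[int, int]:
    present = (calls_a[..., 0] != MISSING) & (calls_b[..., 0] != MISSING)
    per_locus = 2 - _matched_copies(calls_a, calls_b)
    return int(per_locus[present].sum()), int(present.sum())


def stepwise_distance(calls_a: np.ndarray, calls_b: np.ndarray) -> int:
    """Stepwise (squared repeat difference, best pairing) distance."""
    calls_a = np.asarray(calls_a, dtype=np.int64)
    calls_b = np.asarray(calls_b, dtype=np.int64)
    present = (calls_a[..., 0] != MISSING) & (calls_b[..., 0] != MISSING)
    if not present.any():
        raise ValueError("no shared non-missing loci between the two samples")
    a1, a2 = calls_a[..., 0], calls_a[..., 1]
    b1, b2 = calls_b[..., 0], calls_b[..., 1]
    p1 = (a1 - b1) ** 2 + (a2 - b2) ** 2
    p2 = (a1 - b2) ** 2 + (a2 - b1) ** 2
    return int(np.minimum(p1, p2)[present].sum())


def dissimilarity(calls_a: np.ndarray, calls_b: np.ndarray, relative: bool = False) -> float:
    """Allelic dissimilarity: IAM count, or fraction of allele copies differing."""
    d, n = _iam_pair(np.asarray(calls_a), np.asarray(calls_b))
    if n == 0:
        raise ValueError("no shared non-missing loci between the two samples")
    return d / (2 * n) if relative else float(d)


def pairwise_matrix(
    data: Dataset | GenotypeTable,
    model: str = "iam",
    sample_idx=None,
    locus_idx=None,
    relative: bool = False,
) -> DistanceMatrix:
    """All-pairs distance matrix under the given model.

    For ``model="dissimilarity"`` the ``relative`` flag selects the
    per-locus-scaled form (the default absolute form equals ``iam``).
    Raises if any pair shares no non-missing locus.
    """
    gt = data.genotypes if isinstance(data, Dataset) else data
    if sample_idx is not None or locus_idx is not None:
        gt = gt.subset(sample_idx, locus_idx)
    n = gt.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    calls = gt.calls
    present = calls[:, :, 0] != MISSING

    vals = np.zeros((n, n), dtype=float)
    comp = np.zeros((n, n), dtype=np.int32)

    biallelic_snp = all(lc.kind.value == "snp" and lc.is_biallelic for lc in gt.loci)
    if model in ("iam", "dissimilarity") and biallelic_snp:
        # fast path: for biallelic loci the IAM distance equals |dosage diff|
        dos = calls.sum(axis=2).astype(np.int16)  # -2 where missing, else 0/1/2
        for i in range(n - 1):
            both = present[i] & present[i + 1 :]
            d = np.abs(dos[i] - dos[i + 1 :], dtype=np.int16)
            row = np.where(both, d, 0).sum(axis=1)
            vals[i, i + 1 :] = row
            comp[i, i + 1 :] = both.sum(axis=1)
    elif model in ("iam", "dissimilarity"):
        for i in range(n - 1):
            both = present[i] & present[i + 1 :]
            d = 2 - _matched_copies(calls[i][None, :, :], calls[i + 1 :])
            vals[i, i + 1 :] = np.where(both, d, 0).sum(axis=1)
            comp[i, i + 1 :] = both.sum(axis=1)
    elif model == "stepwise":
        c = calls.astype(np.int64)
        a1, a2 = c[:, :, 0], c[:, :, 1]
        for i in range(n - 1):
            both = present[i] & present[i + 1 :]
            p1 = (a1[i] - a1[i + 1 :]) ** 2 + (a2[i] - a2[i + 1 :]) ** 2
            p2 = (a1[i] - a2[i + 1 :]) ** 2 + (a2[i] - a1[i + 1 :]) ** 2
            vals[i, i + 1 :] = np.where(both, np.minimum(p1, p2), 0).sum(axis=1)
            comp[i, i + 1 :] = both.sum(axis=1)
    else:
        raise ValueError(f"unknown distance model: {model!r}")

    vals = vals + vals.T
    comp = comp + comp.T
    np.fill_diagonal(comp, gt.n_loci)

    iu = np.triu_indices(n, k=1)
    if (comp[iu] == 0).any():
        i, j = next(zip(*[idx[comp[iu] == 0] for idx in iu]))
        raise ValueError(
            f"samples {gt.samples[int(i)]!r} and {gt.samples[int(j)]!r} share no "
            "non-missing loci; distance undefined"
        )

    tag = model
    if model == "dissimilarity" and relative:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = vals / (2.0 * comp)
        np.fill_diagonal(vals, 0.0)
        tag = "dissimilarity_relative"
    return DistanceMatrix(gt.samples, vals, tag, comp)


def distance_histogram(dm: DistanceMatrix) -> np.ndarray:
    """Pair counts per integer distance bin (width 1); diagnostic helper."""
    return dm.histogram()
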