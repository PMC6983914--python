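"""Clonal diversity indices and genet-size statistics.

Clonal richness G/N, Simpson's diversity D = 1 - sum(q_g^2) over genet
frequencies q_g (the probability that two ramets drawn at random belong
to different genets; the plain uncorrected form), and the Gini
coefficient of genet-size inequality computed as the mean absolute
difference form sum_ij |x_i - x_j| / (2 n^2 xbar) with no small-sample
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, Dataset, GenetAssignment, GenotypeTable


def clonal_richness(assignment: GenetAssignment) -> float:
    """G/N: number of genets over number of samples (biased but standard)."""
    if assignment.n_samples == 0:
        raise ValueError("empty assignment")
    return assignment.n_genets / assignment.n_samples


def simpson_d(assignment: GenetAssignment, unbiased: bool = False) -> float:
    """Simpson's D = 1 - sum(q_g^2).

    ``unbiased=True`` applies the N/(N-1) correction; the plain form is
    the default and the one reported by the pipeline.
    """
    n = assignment.n_samples
    if n == 0:
        raise ValueError("empty assignment")
    q = assignment.sizes() / n
    d = 1.0 - float(np.sum(q**2))
    if unbiased:
        if n < 2:
            raise ValueError("unbiased D needs N >= 2")
        d *= n / (n - 1)
    return d


def gini(sizes) -> float:
    """Gini coefficient of a size vector (mean-absolute-difference form)."""
    x = np.asarray(sizes, dtype=float)
    if len(x) == 0 or (x < 0).any():
        raise ValueError("sizes must be a non-empty non-negative vector")
    if x.sum() == 0:
        raise ValueError("sizes sum to zero")
    n = len(x)
    mad = np.abs(x[:, None] - x[None, :]).sum()
    return float(mad / (2 * n**2 * x.mean()))


@dataclass
class DiversityStats:
    n_samples: int
    n_genets: int
    richness: float
    simpson_d: float
    gini: float
    sizes: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_genets": self.n_genets,
            "richness": self.richness,
            "simpson_d": self.simpson_d,
            "gini": self.gini,
            "genet_sizes": self.sizes.tolist(),
        }


def diversity_stats(assignment: GenetAssignment) -> DiversityStats:
    sizes = assignment.sizes()
    return DiversityStats(
        n_samples=assignment.n_samples,
        n_genets=assignment.n_genets,
        richness=clonal_richness(assignment),
        simpson_d=simpson_d(assignment),
        gini=gini(sizes),
        sizes=sizes,
    )


def within_genet_variation(
    data: Dataset | GenotypeTable, assignment: GenetAssignment, top_k: int = 8
) -> pd.DataFrame:
    """Genetic variation inside each of the ``top_k`` largest genets.

    Per genet: the number of polymorphic loci (>= 2 distinct non-missing
    genotypes among members), the average number of distinct genotypes
    per locus and the average number of distinct alleles per locus, both
    averaged over loci with at least one non-missing member call.
    """
    gt = data.genotypes if isinstance(data, Dataset) else data
    if gt.samples != assignment.samples:
        raise ValueError("assignment samples do not match genotype table")
    rows = []
    for g in range(1, min(top_k, assignment.n_genets) + 1):
        members = assignment.members(g)
        calls = gt.calls[members]  # (k, m, 2)
        n_poly = 0
        geno_counts, allele_counts = [], []
        for j in range(gt.n_loci):
            col = calls[:, j, :]
            ok = col[:, 0] != MISSING
            if not ok.any():
                continue
            genos = {tuple(c) for c in col[ok]}
            alleles = {int(a) for c in col[ok] for a in c}
            geno_counts.append(len(genos))
            allele_counts.append(len(alleles))
            if len(genos) >= 2:
                n_poly += 1
        rows.append(
            {
                "genet": g,
                "n_ramets": len(members),
                "n_polymorphic_loci": n_poly,
                "mean_genotypes_per_locus": float(np.mean(geno_counts)) if geno_counts else np.nan,
                "mean_alleles_per_locus": float(np.mean(allele_counts)) if allele_counts else np.nan,
            }
        )
    return pd.DataFrame(rows)
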