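"""Locus and sample selection from genotype + depth tables.

The selection rules for reduced-representation SNP data:

1. keep only contigs carrying a single biallelic SNP;
2. keep loci with sufficient read depth (``depth >= d``) in strictly
   more than ``min_sample_fraction_at_depth`` of samples *and* minor
   allele frequency strictly above ``min_maf`` (computed from allele
   counts over all non-missing calls, before any sample exclusion — no
   second estimation pass is performed);
3. drop samples genotyped (non-missing call with ``depth >= d``) at
   fewer than ``min_locus_fraction_per_sample`` of the selected loci.

After selection, calls with depth below ``d`` at surviving loci are
treated as missing in all downstream distance computations
(:func:`apply_depth_mask`): depth-gated genotyping is the point of the
rule, not a property of the raw call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MISSING, Dataset, GenotypeTable, Locus, LocusKind


@dataclass
class FilterParams:
    min_depth: int = 10
    min_sample_fraction_at_depth: float = 0.90  # strict >
    min_maf: float = 0.01  # strict >
    min_locus_fraction_per_sample: float = 0.90  # samples below are dropped (strict <)

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("min_sample_fraction_at_depth", "min_locus_fraction_per_sample"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.min_maf < 1:
            raise ValueError("min_maf must be in [0, 1)")


@dataclass
class FilterReport:
    """Stage counts plus the first failing rule for every excluded item."""

    n_loci_input: int = 0
    n_loci_single_snp: int = 0
    n_loci_depth: int = 0
    n_loci_maf: int = 0
    n_samples_input: int = 0
    n_samples_retained: int = 0
    locus_fail_reason: dict[str, str] = field(default_factory=dict)
    sample_fail_reason: dict[str, str] = field(default_factory=dict)
    params: FilterParams | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("loci_input", self.n_loci_input),
            ("loci_single_biallelic_snp", self.n_loci_single_snp),
            ("loci_depth_pass", self.n_loci_depth),
            ("loci_maf_pass", self.n_loci_maf),
            ("samples_input", self.n_samples_input),
            ("samples_retained", self.n_samples_retained),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def select_single_snp_contigs(loci: list[Locus]) -> np.ndarray:
    """Indices of SNP loci that are the only SNP on their contig and
    strictly biallelic."""
    return np.array(
        [
            j
            for j, lc in enumerate(loci)
            if lc.kind == LocusKind.SNP and lc.snp_count_on_contig == 1 and lc.is_biallelic
        ],
        dtype=int,
    )


def minor_allele_frequencies(gt: GenotypeTable) -> np.ndarray:
    """Per-locus MAF from allele counts over non-missing calls.

    For a biallelic locus this is the minority allele's frequency; for a
    multi-allelic (SSR) locus, the frequency of the second most frequent
    allele.  Loci with no non-missing calls get MAF 0.
    """
    maf = np.zeros(gt.n_loci)
    for j, lc in enumerate(gt.loci):
        col = gt.calls[:, j, :].ravel()
        col = col[col != MISSING]
        if len(col) == 0:
            continue
        counts = np.sort(np.bincount(col - col.min()))[::-1]
        counts = counts[counts > 0]
        if len(counts) < 2:
            maf[j] = 0.0
        else:
            maf[j] = counts[1] / counts.sum()
    return maf


def filter_loci(
    data: Dataset, params: FilterParams | None = None
) -> tuple[np.ndarray, FilterReport]:
    """Locus selection.  Returns (indices of surviving loci, report)."""
    params = params or FilterParams()
    gt = data.genotypes
    report = FilterReport(
        n_loci_input=gt.n_loci, n_samples_input=gt.n_samples, params=params
    )
    is_snp = any(lc.kind == LocusKind.SNP for lc in gt.loci)

    if is_snp:
        keep = select_single_snp_contigs(gt.loci)
        kept = set(keep.tolist())
        for j, lc in enumerate(gt.loci):
            if j not in kept:
                if lc.kind == LocusKind.SNP and lc.snp_count_on_contig != 1:
                    report.locus_fail_reason[lc.id] = "multi_snp_contig"
                else:
                    report.locus_fail_reason[lc.id] = "not_biallelic"
    else:
        keep = np.arange(gt.n_loci)
    report.n_loci_single_snp = len(keep)

    if data.depths is not None:
        d = data.depths.depths[:, keep]
        frac = (d >= params.min_depth).mean(axis=0)
        ok = frac > params.min_sample_fraction_at_depth  # strict, as printed
        for j in keep[~ok]:
            report.locus_fail_reason[gt.loci[j].id] = "depth"
        keep = keep[ok]
    elif is_snp:
        raise ValueError("depth table required for SNP locus filtering")
    report.n_loci_depth = len(keep)

    maf = minor_allele_frequencies(gt)[keep]
    ok = maf > params.min_maf  # strict
    for j in keep[~ok]:
        report.locus_fail_reason[gt.loci[j].id] = "maf"
    keep = keep[ok]
    report.n_loci_maf = len(keep)
    if len(keep) == 0:
        import warnings

        warnings.warn("no loci survive filtering", stacklevel=2)
    return keep, report


def filter_samples(
    data: Dataset,
    selected_loci: np.ndarray,
    params: FilterParams | None = None,
    report: FilterReport | None = None,
) -> tuple[np.ndarray, FilterReport]:
    """Drop samples genotyped at too few selected loci.

    A sample counts as genotyped at a locus when the call is non-missing
    and (if depths are available) the depth is >= min_depth.
    Returns (indices of retained samples, report).
    """
    params = params or FilterParams()
    if report is None:
        report = FilterReport(
            n_loci_input=data.genotypes.n_loci,
            n_samples_input=data.genotypes.n_samples,
            params=params,
        )
    gt = data.genotypes
    sel = np.asarray(selected_loci)
    called = gt.calls[:, sel, 0] != MISSING
    if data.depths is not None:
        called &= data.depths.depths[:, sel] >= params.min_depth
    frac = called.mean(axis=1) if len(sel) else np.zeros(gt.n_samples)
    ok = frac >= params.min_locus_fraction_per_sample  # drop strictly below
    for i in np.flatnonzero(~ok):
        report.sample_fail_reason[gt.samples[i]] = "low_coverage"
    report.n_samples_retained = int(ok.sum())
    return np.flatnonzero(ok), report


def apply_depth_mask(data: Dataset, min_depth: int) -> GenotypeTable:
    """Copy of the genotype table with calls below min_depth set missing."""
    gt = data.genotypes.copy()
    if data.depths is not None:
        low = data.depths.depths < min_depth
        gt.calls[low] = MISSING
    return gt


def run_filters(
    data: Dataset, params: FilterParams | None = None
) -> tuple[Dataset, GenotypeTable, FilterReport]:
    """Full selection: loci, then samples, then the depth mask.

    Returns (filtered dataset, depth-masked genotypes ready for distance
    computation, report).
    """
    params = params or FilterParams()
    loci_idx, report = filter_loci(data, params)
    sample_idx, report = filter_samples(data, loci_idx, params, report)
    filtered = data.subset(sample_idx, loci_idx)
    masked = apply_depth_mask(filtered, params.min_depth)
    return filtered, masked, report


def depth_sensitivity(
    data: Dataset,
    depths: tuple[int, ...] = (5, 10, 15, 20, 30),
    params: FilterParams | None = None,
    linkage: str = "single",
    model: str = "iam",
) -> pd.DataFrame:
    """Re-run filtering -> distances -> plateau threshold -> assignment ->
    diversity at several minimum-depth criteria.

    One row per depth with the locus count, chosen threshold, genet
    count, clonal richness G/N, Simpson's D and the Gini coefficient.
    Rows where the threshold search fails (e.g. too few loci leave a
    unimodal distance distribution) carry NaNs past the locus count.
    """
    from dataclasses import replace

    from .assignment import assign_genets, plateau_threshold
    from .distances import pairwise_matrix
    from .diversity import clonal_richness, gini, simpson_d

    params = params or FilterParams()
    rows = []
    for d in depths:
        p = replace(params, min_depth=int(d))
        _, masked, report = run_filters(data, p)
        row = {
            "min_depth": int(d),
            "n_loci": report.n_loci_maf,
            "n_samples": report.n_samples_retained,
            "threshold": np.nan,
            "n_genets": np.nan,
            "richness": np.nan,
            "simpson_d": np.nan,
            "gini": np.nan,
        }
        try:
            dm = pairwise_matrix(masked, model=model)
            diag = plateau_threshold(dm, linkage)
            assignment = assign_genets(dm, diag.threshold, linkage)
            row.update(
                threshold=diag.threshold,
                n_genets=assignment.n_genets,
                richness=clonal_richness(assignment),
                simpson_d=simpson_d(assignment),
                gini=gini(assignment.sizes()),
            )
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)
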