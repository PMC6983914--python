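"""Core domain types shared by every pipeline stage.

The central objects are a :class:`GenotypeTable` of unordered diploid
allele pairs (samples x loci), an aligned :class:`DepthTable` of read
depths, a :class:`SampleSheet` of map coordinates, and the pipeline's
main output, a :class:`GenetAssignment` mapping each sampled ramet to a
size-ranked genet.

Allele encoding
---------------
Calls are stored as an ``(n_samples, n_loci, 2)`` integer array with the
two alleles of each call sorted ascending (phase is never used by any
distance model here).  For SNP loci the stored integers index into
``Locus.alleles`` (0 = REF, 1 = ALT); for SSR loci they are the repeat
scores themselves.  ``MISSING`` (-1) in both slots marks a missing call.
Missing is a first-class state distinct from "depth 0": depth-based
exclusion is applied explicitly by the filtering stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

MISSING: int = -1


class LocusKind(str, Enum):
    SNP = "snp"
    SSR = "ssr"


@dataclass(frozen=True)
class Locus:
    """One scored marker: a biallelic SNP on a contig, or an SSR locus."""

    id: str
    kind: LocusKind
    contig: str = ""
    position: int = 1  # 1-based, VCF convention
    alleles: tuple = ()
    snp_count_on_contig: int = 1

    def __post_init__(self) -> None:
        if self.kind == LocusKind.SSR:
            if any((not isinstance(a, (int, np.integer))) or a <= 0 for a in self.alleles):
                raise ValueError(f"SSR locus {self.id}: repeat scores must be positive integers")
        if self.position < 1:
            raise ValueError(f"locus {self.id}: position must be 1-based (>= 1)")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alleles) == 2


def canonical_calls(calls: np.ndarray) -> np.ndarray:
    """Sort each allele pair ascending and force both slots of half-missing
    calls to MISSING (a call is all-or-nothing)."""
    calls = np.asarray(calls)
    out = np.sort(calls, axis=-1)
    half = (out[..., 0] == MISSING) | (out[..., 1] == MISSING)
    out[half] = MISSING
    return out


@dataclass
class GenotypeTable:
    """Diploid calls for samples x loci.  See module docstring for encoding."""

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray  # (n_samples, n_loci, 2) int16

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.loci = list(self.loci)
        self.calls = canonical_calls(np.asarray(self.calls, dtype=np.int16))
        n, m = len(self.samples), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with {n} samples x {m} loci"
            )
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        ids = [lc.id for lc in self.loci]
        if len(set(ids)) != m:
            raise ValueError("duplicate locus ids")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_samples, n_loci); True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def missing_fraction_per_sample(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def missing_fraction_per_locus(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def subset(
        self,
        sample_idx: Sequence[int] | None = None,
        locus_idx: Sequence[int] | None = None,
    ) -> "GenotypeTable":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeTable(
            samples=[self.samples[i] for i in si],
            loci=[self.loci[j] for j in li],
            calls=self.calls[np.ix_(si, li)].copy(),
        )

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(list(self.samples), list(self.loci), self.calls.copy())


@dataclass
class DepthTable:
    """Read depth per sample x locus, aligned with a GenotypeTable."""

    samples: list[str]
    locus_ids: list[str]
    depths: np.ndarray  # (n_samples, n_loci) int32, >= 0

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.locus_ids = list(self.locus_ids)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.depths.shape != (len(self.samples), len(self.locus_ids)):
            raise ValueError("depth matrix shape inconsistent with ids")
        if (self.depths < 0).any():
            raise ValueError("negative read depth")

    def subset(self, sample_idx=None, locus_idx=None) -> "DepthTable":
        si = np.arange(len(self.samples)) if sample_idx is None else np.asarray(sample_idx)
        li = np.arange(len(self.locus_ids)) if locus_idx is None else np.asarray(locus_idx)
        return DepthTable(
            [self.samples[i] for i in si],
            [self.locus_ids[j] for j in li],
            self.depths[np.ix_(si, li)].copy(),
        )


@dataclass
class SampleSheet:
    """Sample map coordinates in metres, with an optional group label."""

    samples: list[str]
    xy: np.ndarray  # (n, 2) float
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.samples), 2)
        if not np.isfinite(self.xy).all():
            raise ValueError("non-finite coordinates")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids in sample sheet")
        if self.group is not None and len(self.group) != len(self.samples):
            raise ValueError("group labels inconsistent with samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, sample_idx: Sequence[int]) -> "SampleSheet":
        si = np.asarray(sample_idx)
        return SampleSheet(
            [self.samples[i] for i in si],
            self.xy[si].copy(),
            None if self.group is None else [self.group[i] for i in si],
        )


@dataclass
class Dataset:
    """Genotypes + (optional) depths + coordinates with one shared sample order."""

    genotypes: GenotypeTable
    depths: DepthTable | None = None
    sheet: SampleSheet | None = None

    def __post_init__(self) -> None:
        if self.depths is not None:
            if self.depths.samples != self.genotypes.samples:
                raise ValueError("depth table sample order differs from genotypes")
            if self.depths.locus_ids != [lc.id for lc in self.genotypes.loci]:
                raise ValueError("depth table locus order differs from genotypes")
        if self.sheet is not None and self.sheet.samples != self.genotypes.samples:
            missing = set(self.genotypes.samples) - set(self.sheet.samples)
            if missing:
                raise ValueError(f"samples absent from coordinates: {sorted(missing)[:5]}")
            # same set, different order: realign
            order = [self.sheet.samples.index(s) for s in self.genotypes.samples]
            self.sheet = self.sheet.subset(order)

    def subset(self, sample_idx=None, locus_idx=None) -> "Dataset":
        return Dataset(
            self.genotypes.subset(sample_idx, locus_idx),
            None if self.depths is None else self.depths.subset(sample_idx, locus_idx),
            self.sheet
            if (self.sheet is None or sample_idx is None)
            else self.sheet.subset(sample_idx),
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances with per-pair locus counts."""

    ids: list[str]
    values: np.ndarray  # (n, n), zero diagonal
    model: str  # iam | stepwise | dissimilarity
    n_compared: np.ndarray | None = None  # (n, n) loci compared per pair

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix not square / inconsistent with ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValueError("distance matrix diagonal not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def max(self) -> float:
        return float(self.values.max()) if self.n > 1 else 0.0

    def histogram(self) -> np.ndarray:
        """Pair counts per integer distance bin (width 1), bins 0..floor(max)."""
        d = self.condensed()
        return np.bincount(np.floor(d).astype(int), minlength=int(np.floor(self.max())) + 1)

    def subset(self, idx: Sequence[int]) -> "DistanceMatrix":
        idx = np.asarray(idx)
        return DistanceMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)].copy(),
            self.model,
            None if self.n_compared is None else self.n_compared[np.ix_(idx, idx)].copy(),
        )


@dataclass
class GenetAssignment:
    """sample -> genet, with genet ids 1..G ranked by descending size.

    Rank ties (equal sizes) are broken by the smallest member sample id so
    the labelling is reproducible.
    """

    samples: list[str]
    genet_ids: np.ndarray  # (n,) int, values in 1..G
    linkage: str = ""
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.genet_ids = np.asarray(self.genet_ids, dtype=int)
        if self.genet_ids.shape != (len(self.samples),):
            raise ValueError("genet ids inconsistent with samples")
        uniq = np.unique(self.genet_ids)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("genet ids must be contiguous 1..G")

    @classmethod
    def from_labels(
        cls,
        samples: Sequence[str],
        labels: Iterable,
        linkage: str = "",
        threshold: float | None = None,
    ) -> "GenetAssignment":
        """Relabel arbitrary cluster labels into size-ranked genet ids."""
        samples = list(samples)
        labels = np.asarray(list(labels))
        uniq, inv = np.unique(labels, return_inverse=True)
        sizes = np.bincount(inv)
        # smallest member sample id per cluster, for deterministic tie-break
        first_member = {}
        for k in range(len(uniq)):
            members = [samples[i] for i in np.flatnonzero(inv == k)]
            first_member[k] = min(members)
        order = sorted(range(len(uniq)), key=lambda k: (-sizes[k], first_member[k]))
        rank = np.empty(len(uniq), dtype=int)
        rank[order] = np.arange(1, len(uniq) + 1)
        return cls(samples, rank[inv], linkage=linkage, threshold=threshold)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genets(self) -> int:
        return int(self.genet_ids.max()) if len(self.samples) else 0

    def sizes(self) -> np.ndarray:
        """Genet sizes indexed by rank (element 0 = genet 1 = largest)."""
        return np.bincount(self.genet_ids, minlength=self.n_genets + 1)[1:]

    def members(self, genet_id: int) -> list[int]:
        return list(np.flatnonzero(self.genet_ids == genet_id))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.samples, self.genet_ids.tolist()))


@dataclass
class SimTruth:
    """Generator-side truth: genet membership, pedigree, lineage, mutations."""

    samples: list[str]
    true_genet: np.ndarray  # (n,) int labels (arbitrary but consistent)
    pedigree: list[tuple[str, str, str]] = field(default_factory=list)
    # (parent_genet, offspring_genet, mode) with mode in {outcross, self}
    lineage_parent: dict[str, str] = field(default_factory=dict)  # ramet -> mother ramet
    mutations: list[tuple[str, str]] = field(default_factory=list)  # (sample, locus)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_genet = np.asarray(self.true_genet, dtype=int)
        if self.true_genet.shape != (len(self.samples),):
            raise ValueError("truth labels inconsistent with samples")

    @property
    def n_genets(self) -> int:
        return len(np.unique(self.true_genet))

    def as_assignment(self) -> GenetAssignment:
        return GenetAssignment.from_labels(self.samples, self.true_genet, linkage="truth")
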