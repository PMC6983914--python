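"""Spatially explicit synthetic clonal populations with known truth.

The generator emulates a pseudo-annual rhizomatous herb sampled on a
regular grid: founder genets arise from seeds, spread clonally by
rhizome steps (each ramet lives one season and is replaced by daughter
ramets at rhizome tips), and are sampled as the nearest ramet within a
capture radius of each grid point.  Genotypes are diploid biallelic SNPs
(or SSR repeat scores) that accumulate somatic mutations along the
clonal lineage and per-sample genotyping noise (allele dropout, random
allele errors, missing calls); read depths follow a negative binomial
with per-locus amplification bias.

Two calibrated presets reproduce the two study designs used to exercise
the genet-assignment pipeline:

* :func:`make_validation_preset` — clonal replicates of two unrelated
  founders plus one half-sib seed family (15 genets, ~264 loci), the
  hardest case for genet distinction;
* :func:`make_main_plot_preset` — a 20 x 20 m grid population with 61
  genets of strongly unequal size (the dominant genet holds about one
  third of the 372 sampled ramets) at 363 loci.

Every operation is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    MISSING,
    Dataset,
    DepthTable,
    GenotypeTable,
    Locus,
    LocusKind,
    SampleSheet,
    SimTruth,
)

_NUCS = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Tunable study conditions.  Lengths in metres, rates per call or per
    locus per ramet-generation as noted."""

    n_loci: int = 363
    maf_range: tuple[float, float] = (0.05, 0.5)  # founder minor-allele freq, uniform
    n_founder_genets: int = 61
    n_outcross_offspring: int = 13  # half-sib family size (validation design)
    years: int = 8
    daughters_mean: float = 1.2  # Poisson mean daughters per ramet per year
    mothers_persist: bool = False  # pseudo-annual: mothers die each year
    rhizome_step_mean: float = 0.451  # m
    rhizome_step_sd: float = 0.215  # m
    arena: tuple[float, float] = (20.0, 20.0)  # m
    grid_interval: float = 1.0  # m
    grid_capture_radius: float = 0.5  # m
    somatic_mutation_rate: float = 1e-4  # per locus per lineage edge
    allele_dropout_rate: float = 1e-3  # per call (heterozygotes only)
    random_error_rate: float = 5e-4  # per call
    missing_rate: float = 1e-3  # per call; keeps missing data < 0.2 %
    depth_mean: float = 45.0
    depth_dispersion: float = 8.0  # negative-binomial size parameter
    depth_locus_bias_sd: float = 0.35  # log-sd of per-locus bias factor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("somatic_mutation_rate", "allele_dropout_rate",
                     "random_error_rate", "missing_rate"):
            r = getattr(self, name)
            if not 0 <= r <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        lo, hi = self.maf_range
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be positive")
        if self.rhizome_step_mean <= 0:
            raise ValueError("rhizome_step_mean must be positive")


@dataclass
class Lineage:
    """Clonal ramet forest: ``parent[i] == -1`` marks a founder ramet.
    Ramet ids are array indices; a daughter's index always exceeds its
    mother's, so genotype propagation is a single forward pass."""

    parent: np.ndarray  # (n,) int
    genet: np.ndarray  # (n,) int founder-genet label
    year: np.ndarray  # (n,) int
    xy: np.ndarray  # (n, 2) float
    alive: np.ndarray  # (n,) bool, ramets alive in the final year

    def __post_init__(self) -> None:
        n = len(self.parent)
        if (np.asarray(self.parent) >= np.arange(n)).any():
            raise ValueError("lineage is not topologically ordered (parent >= child id)")

    @property
    def n_ramets(self) -> int:
        return len(self.parent)


def _rng(rng) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def make_snp_loci(n_loci: int, rng) -> list[Locus]:
    """One biallelic SNP per contig, with random REF/ALT nucleotides."""
    rng = _rng(rng)
    loci = []
    for j in range(n_loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            Locus(
                id=f"L{j:04d}",
                kind=LocusKind.SNP,
                contig=f"contig{j:05d}",
                position=int(rng.integers(1, 5000)),
                alleles=(str(_NUCS[ref]), str(_NUCS[alt])),
                snp_count_on_contig=1,
            )
        )
    return loci


def make_ssr_loci(n_loci: int, rng, allele_range: tuple[int, int] = (2, 12)) -> list[Locus]:
    """SSR loci with 2..12 alleles (consecutive repeat scores)."""
    rng = _rng(rng)
    loci = []
    for j in range(n_loci):
        k = int(rng.integers(allele_range[0], allele_range[1] + 1))
        start = int(rng.integers(5, 30))
        loci.append(
            Locus(
                id=f"ssr{j:02d}",
                kind=LocusKind.SSR,
                alleles=tuple(range(start, start + k)),
            )
        )
    return loci


def simulate_founders(
    n: int,
    n_loci: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    rng=None,
    loci: list[Locus] | None = None,
) -> GenotypeTable:
    """Independent founder genotypes under Hardy-Weinberg equilibrium.

    For SNP loci one minor-allele frequency per locus is drawn uniformly
    from ``maf_range`` and each founder receives two Bernoulli(p) allele
    copies.  For pre-built SSR loci, allele frequencies are symmetric
    Dirichlet draws over the locus allele set.
    """
    if n < 1:
        raise ValueError("need at least one founder")
    lo, hi = maf_range
    if not (0 <= lo <= hi <= 0.5):
        raise ValueError("degenerate minor-allele-frequency specification")
    rng = _rng(rng)
    if loci is None:
        loci = make_snp_loci(n_loci, rng)
    n_loci = len(loci)
    calls = np.zeros((n, n_loci, 2), dtype=np.int16)
    for j, lc in enumerate(loci):
        if lc.kind == LocusKind.SNP:
            p = rng.uniform(lo, hi)
            calls[:, j, :] = (rng.random((n, 2)) < p).astype(np.int16)
        else:
            freqs = rng.dirichlet(np.ones(len(lc.alleles)))
            draws = rng.choice(len(lc.alleles), size=(n, 2), p=freqs)
            calls[:, j, :] = np.asarray(lc.alleles, dtype=np.int16)[draws]
    return GenotypeTable([f"F{i:03d}" for i in range(n)], loci, calls)


def simulate_offspring(
    parent_a: np.ndarray,
    parent_b: np.ndarray | None,
    n_off: int,
    mode: str = "outcross",
    rng=None,
) -> np.ndarray:
    """Mendelian offspring calls from two parent call vectors (n_loci, 2).

    Per locus one allele is sampled uniformly from each parent's pair;
    ``mode="self"`` draws both gametes from ``parent_a``.  A locus missing
    in either contributing parent is missing in the offspring.
    Returns an (n_off, n_loci, 2) call array.
    """
    if mode not in ("outcross", "self"):
        raise ValueError("mode must be 'outcross' or 'self'")
    parent_a = np.asarray(parent_a)
    if mode == "self" or parent_b is None:
        parent_b = parent_a
    parent_b = np.asarray(parent_b)
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents differ in locus set")
    rng = _rng(rng)
    m = parent_a.shape[0]
    ga = parent_a[np.arange(m), rng.integers(0, 2, size=(n_off, m))]
    gb = parent_b[np.arange(m), rng.integers(0, 2, size=(n_off, m))]
    out = np.stack([ga, gb], axis=-1).astype(np.int16)
    miss = (parent_a[:, 0] == MISSING) | (parent_b[:, 0] == MISSING)
    out[:, miss, :] = MISSING
    return np.sort(out, axis=-1)


def offspring_table(
    parents: GenotypeTable, a: str, b: str | None, n_off: int, mode: str = "outcross", rng=None
) -> GenotypeTable:
    """GenotypeTable wrapper around :func:`simulate_offspring`."""
    ia = parents.samples.index(a)
    calls_b = None if b is None else parents.calls[parents.samples.index(b)]
    off = simulate_offspring(parents.calls[ia], calls_b, n_off, mode=mode, rng=rng)
    return GenotypeTable([f"{a}x{b or a}_{k}" for k in range(n_off)], parents.loci, off)


def _step_lengths(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """Rhizome step lengths: normal truncated to positive by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def simulate_clonal_spread(
    founder_positions: np.ndarray, config: SimConfig, rng=None
) -> Lineage:
    """Pseudo-annual clonal growth from founder seed positions.

    Each year every living ramet produces ``k ~ Poisson(daughters_mean)``
    daughter ramets, each displaced by an independent rhizome step
    (length truncated-normal, direction uniform); mothers die unless
    ``mothers_persist``.  Ramets stepping outside the arena are clipped
    to the boundary.
    """
    if config.years < 0:
        raise ValueError("years must be >= 0")
    rng = _rng(rng)
    pos = np.atleast_2d(np.asarray(founder_positions, dtype=float))
    g = len(pos)
    parent = [-1] * g
    genet = list(range(g))
    year = [0] * g
    xy = [tuple(p) for p in pos]
    alive = list(range(g))  # indices of currently living ramets

    for yr in range(1, config.years + 1):
        new_alive: list[int] = []
        for ridx in alive:
            k = int(rng.poisson(config.daughters_mean))
            if k == 0:
                continue
            steps = _step_lengths(k, config.rhizome_step_mean, config.rhizome_step_sd, rng)
            theta = rng.uniform(0, 2 * np.pi, size=k)
            for s, th in zip(steps, theta):
                x = float(np.clip(xy[ridx][0] + s * np.cos(th), 0, config.arena[0]))
                y = float(np.clip(xy[ridx][1] + s * np.sin(th), 0, config.arena[1]))
                parent.append(ridx)
                genet.append(genet[ridx])
                year.append(yr)
                xy.append((x, y))
                new_alive.append(len(parent) - 1)
        alive = (alive + new_alive) if config.mothers_persist else new_alive

    alive_mask = np.zeros(len(parent), dtype=bool)
    alive_mask[alive] = True
    return Lineage(
        parent=np.array(parent, dtype=int),
        genet=np.array(genet, dtype=int),
        year=np.array(year, dtype=int),
        xy=np.array(xy, dtype=float).reshape(len(parent), 2),
        alive=alive_mask,
    )


def sample_grid(
    xy: np.ndarray,
    grid_interval: float,
    capture_radius: float,
    arena: tuple[float, float],
    ramet_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest ramet within the capture radius of each grid point.

    Grid points are visited in row-major order; each physical ramet is
    selected at most once; equidistant candidates are broken by lowest
    ramet id.  Returns ``(selected ramet ids, grid point coords)`` for
    the grid points that captured a ramet.
    """
    if capture_radius <= 0:
        raise ValueError("capture_radius must be positive")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    ids = np.arange(len(xy)) if ramet_ids is None else np.asarray(ramet_ids)
    gx = np.arange(0, arena[0] + 1e-9, grid_interval)
    gy = np.arange(0, arena[1] + 1e-9, grid_interval)
    points = np.array([(x, y) for y in gy for x in gx])
    if len(xy) == 0:
        return np.array([], dtype=int), np.empty((0, 2))
    tree = cKDTree(xy)
    taken: set[int] = set()
    sel_ids, sel_pts = [], []
    for pt in points:
        cand = tree.query_ball_point(pt, capture_radius)
        cand = [c for c in cand if c not in taken]
        if not cand:
            continue
        d = np.linalg.norm(xy[cand] - pt, axis=1)
        # nearest; ties by lowest ramet id
        best = min(zip(d, ids[cand], cand), key=lambda t: (t[0], t[1]))[2]
        taken.add(best)
        sel_ids.append(ids[best])
        sel_pts.append(pt)
    return np.array(sel_ids, dtype=int), np.array(sel_pts).reshape(-1, 2)


def _mutate_call(call: np.ndarray, locus: Locus, rng) -> np.ndarray:
    """One somatic mutation: substitute one allele copy.  SNP -> the other
    allele; SSR -> +/-1 repeat with a reflecting bound at 1 repeat."""
    call = call.copy()
    slot = int(rng.integers(0, 2))
    if locus.kind == LocusKind.SNP:
        call[slot] = 1 - call[slot]
    else:
        step = 1 if rng.random() < 0.5 else -1
        if call[slot] + step < 1:
            step = 1
        call[slot] += step
    return np.sort(call)


def mutate_and_corrupt(
    founders: GenotypeTable,
    lineage: Lineage,
    config: SimConfig,
    rng=None,
    sample_ramets: np.ndarray | None = None,
    sample_names: list[str] | None = None,
) -> tuple[GenotypeTable, dict]:
    """Propagate founder genotypes down the clonal lineage and corrupt them.

    Somatic mutations arise on lineage edges at ``somatic_mutation_rate``
    per locus per edge and are inherited by all clonal descendants.
    After propagation, the sampled ramets' calls are independently hit by
    allele dropout (heterozygote to homozygote), random allele error and
    missingness — per-sample noise that is not heritable.

    ``founders.calls`` must have one row per founder genet label used in
    ``lineage.genet``.  Returns the sampled table and an event log.
    """
    rng = _rng(rng)
    loci = founders.loci
    m = len(loci)
    n_r = lineage.n_ramets
    geno = np.empty((n_r, m, 2), dtype=np.int16)
    mut_events: list[tuple[int, str]] = []
    mu = config.somatic_mutation_rate
    for i in range(n_r):
        src = founders.calls[lineage.genet[i]] if lineage.parent[i] < 0 else geno[lineage.parent[i]]
        row = src.copy()
        # mutations ride lineage edges only; founder ramets carry the seed MLG
        if mu > 0 and lineage.parent[i] >= 0:
            n_mut = rng.binomial(m, mu)
            if n_mut:
                for j in rng.choice(m, size=n_mut, replace=False):
                    row[j] = _mutate_call(row[j], loci[j], rng)
                    mut_events.append((i, loci[j].id))
        geno[i] = row

    sel = np.arange(n_r) if sample_ramets is None else np.asarray(sample_ramets)
    calls = geno[sel].copy()
    n = len(sel)

    het = calls[:, :, 0] != calls[:, :, 1]
    drop = het & (rng.random((n, m)) < config.allele_dropout_rate)
    keep_slot = rng.integers(0, 2, size=(n, m))
    kept = np.take_along_axis(calls, keep_slot[:, :, None], axis=2)[:, :, 0]
    calls[drop, 0] = kept[drop]
    calls[drop, 1] = kept[drop]

    err = rng.random((n, m)) < config.random_error_rate
    if err.any():
        for i, j in zip(*np.nonzero(err)):
            if calls[i, j, 0] == MISSING:
                continue
            lc = loci[j]
            slot = int(rng.integers(0, 2))
            if lc.kind == LocusKind.SNP:
                calls[i, j, slot] = 1 - calls[i, j, slot]
            else:
                calls[i, j, slot] = int(rng.choice(np.asarray(lc.alleles)))
            calls[i, j] = np.sort(calls[i, j])

    miss = rng.random((n, m)) < config.missing_rate
    calls[miss] = MISSING

    names = sample_names or [f"r{int(r):04d}" for r in sel]
    table = GenotypeTable(names, loci, calls)
    log = {
        "somatic_mutations": mut_events,
        "n_dropout": int(drop.sum()),
        "n_random_error": int(err.sum()),
        "n_missing": int(miss.sum()),
    }
    return table, log


def simulate_depths(
    n_samples: int,
    n_loci: int,
    depth_mean: float = 45.0,
    depth_dispersion: float = 8.0,
    rng=None,
    locus_bias_sd: float = 0.35,
) -> np.ndarray:
    """Negative-binomial read depths with a per-locus amplification bias.

    A multiplicative bias factor is drawn once per locus (lognormal, unit
    mean); each cell is NB with mean ``depth_mean * bias`` and size
    ``depth_dispersion``, emulating restriction-fragment bias in reduced-
    representation sequencing.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    if depth_dispersion <= 0:
        raise ValueError("depth_dispersion must be positive")
    rng = _rng(rng)
    bias = rng.lognormal(mean=-0.5 * locus_bias_sd**2, sigma=locus_bias_sd, size=n_loci)
    mu = depth_mean * bias[None, :]
    size = depth_dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, np.broadcast_to(p, (n_samples, n_loci))).astype(np.int32)


# ---------------------------------------------------------------------------
# calibrated presets
# ---------------------------------------------------------------------------

#: Genet sizes for the main-plot preset: 61 genets over 372 samples, the
#: dominant genet holding 126 samples (33.9 %) and 30 singletons.
MAIN_PLOT_SIZES: tuple[int, ...] = (
    126, 33, 25, 20, 16, 13, 11, 10, 9, 8, 7,
    6, 6, 5, 5, 4, 4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2, 2,
) + (1,) * 30


def _finalize_dataset(
    names: list[str],
    loci: list[Locus],
    founders_by_genet: GenotypeTable,
    lineage: Lineage,
    sampled: np.ndarray,
    xy: np.ndarray,
    config: SimConfig,
    rng,
) -> tuple[Dataset, dict]:
    gt, log = mutate_and_corrupt(
        founders_by_genet, lineage, config, rng, sample_ramets=sampled, sample_names=names
    )
    depths = simulate_depths(
        len(names),
        len(loci),
        config.depth_mean,
        config.depth_dispersion,
        rng,
        config.depth_locus_bias_sd,
    )
    ds = Dataset(
        gt,
        DepthTable(names, [lc.id for lc in loci], depths),
        SampleSheet(names, xy),
    )
    return ds, log


def make_validation_preset(
    rng=None, config: SimConfig | None = None, n_clonal: tuple[int, int] = (8, 7)
) -> tuple[Dataset, SimTruth]:
    """Two unrelated founder genets with clonal replicates plus a half-sib
    family of 13 outcrossed offspring: 15 genets in total.

    Somatic mutation and genotyping noise are tuned so within-genet
    distances stay in the low single digits at ~264 biallelic loci while
    half-sib offspring remain tens of mismatches from their mother and
    from each other.
    """
    rng = _rng(rng)
    if config is None:
        config = SimConfig(n_loci=264, years=4)
    n_off = config.n_outcross_offspring
    loci = make_snp_loci(config.n_loci, rng)
    # founders: the two focal genets plus unrelated sires for the family
    pool = simulate_founders(2 + n_off, config.n_loci, config.maf_range, rng, loci=loci)
    founder_a, founder_b = pool.calls[0], pool.calls[1]
    offspring = np.concatenate(
        [
            simulate_offspring(founder_a, pool.calls[2 + k], 1, "outcross", rng)
            for k in range(n_off)
        ]
    )
    genet_calls = np.concatenate([pool.calls[:2], offspring])  # 15 genet genotypes
    genet_table = GenotypeTable(
        [f"G{k:02d}" for k in range(2 + n_off)], loci, genet_calls
    )

    n_a, n_b = n_clonal
    parent, genet, xy = [], [], []
    for g, (n_g, origin) in enumerate([(n_a, (3.0, 3.0)), (n_b, (16.0, 16.0))]):
        base = len(parent)
        for i in range(n_g):
            parent.append(-1 if i == 0 else base + i - 1)  # clonal chain
            genet.append(g)
            xy.append((origin[0] + 0.8 * i, origin[1] + 0.3 * (i % 3)))
    for k in range(n_off):
        parent.append(-1)
        genet.append(2 + k)
        xy.append((1.0 + 1.4 * k, 10.0))
    n_total = len(parent)
    lineage = Lineage(
        parent=np.array(parent),
        genet=np.array(genet),
        year=np.zeros(n_total, dtype=int),
        xy=np.array(xy),
        alive=np.ones(n_total, dtype=bool),
    )
    names = [f"v{idx:03d}" for idx in range(n_total)]
    ds, log = _finalize_dataset(
        names, loci, genet_table, lineage, np.arange(n_total), np.array(xy), config, rng
    )
    truth = SimTruth(
        samples=names,
        true_genet=np.array(genet),
        pedigree=[("G00", f"G{2 + k:02d}", "outcross") for k in range(n_off)],
        lineage_parent={
            names[i]: names[parent[i]] for i in range(n_total) if parent[i] >= 0
        },
        mutations=[(names[i], lid) for i, lid in log["somatic_mutations"]],
        manifest={
            "preset": "validation_family",
            "config": asdict(config),
            "n_genets_true": 2 + n_off,
            "note": (
                "composition assumed as 2 clonal founder genets + 13 half-sib "
                "offspring; only the total of 15 genets is fixed by the study design"
            ),
            "corruption": {k: v for k, v in log.items() if k != "somatic_mutations"},
        },
    )
    return ds, truth


def _grow_patches(sizes: np.ndarray, n_side: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Region-grow genet patches on an n_side x n_side grid.

    Multi-ramet genets expand from random seed cells into free 4-neighbour
    cells (claim probability proportional to remaining quota, so large
    genets form wide compact patches); a boxed-in genet jumps to the
    nearest free cell.  Singletons are then placed on random free cells.

    Returns ``(genet label per cell (-1 = unsampled), parent cell per
    cell (-1 = patch seed))``, flat row-major indexing.
    """
    n_cells = n_side * n_side
    label = np.full(n_cells, -1, dtype=int)
    parent = np.full(n_cells, -1, dtype=int)
    multi = np.flatnonzero(sizes > 1)
    singles = np.flatnonzero(sizes == 1)

    seeds = rng.choice(n_cells, size=len(multi), replace=False)
    members: dict[int, list[int]] = {}
    remaining = {}
    for g, cell in zip(multi, seeds):
        label[cell] = g
        members[g] = [int(cell)]
        remaining[g] = int(sizes[g]) - 1

    def neighbours(cell: int) -> list[int]:
        r, c = divmod(cell, n_side)
        out = []
        if r > 0:
            out.append(cell - n_side)
        if r < n_side - 1:
            out.append(cell + n_side)
        if c > 0:
            out.append(cell - 1)
        if c < n_side - 1:
            out.append(cell + 1)
        return out

    active = [g for g in multi if remaining[g] > 0]
    while active:
        quotas = np.array([remaining[g] for g in active], dtype=float)
        g = active[rng.choice(len(active), p=quotas / quotas.sum())]
        edges = [
            (mem, nb)
            for mem in members[g]
            for nb in neighbours(mem)
            if label[nb] == -1
        ]
        if edges:
            mem, cell = edges[rng.integers(len(edges))]
        else:  # boxed in: rhizome jump to the nearest free cell
            free = np.flatnonzero(label == -1)
            mcells = np.array(members[g])
            mr, mc = divmod(mcells, n_side)
            fr, fc = divmod(free, n_side)
            d2 = (fr[:, None] - mr[None, :]) ** 2 + (fc[:, None] - mc[None, :]) ** 2
            k_free, k_mem = np.unravel_index(np.argmin(d2), d2.shape)
            cell, mem = int(free[k_free]), int(mcells[k_mem])
        label[cell] = g
        parent[cell] = mem
        members[g].append(int(cell))
        remaining[g] -= 1
        if remaining[g] == 0:
            active.remove(g)

    free = np.flatnonzero(label == -1)
    placed = rng.choice(free, size=len(singles), replace=False)
    for g, cell in zip(singles, placed):
        label[cell] = g
    return label, parent


def make_main_plot_preset(
    rng=None, config: SimConfig | None = None
) -> tuple[Dataset, SimTruth]:
    """Grid-sampled population mirroring the 20 x 20 m study plot: 372
    ramets at 1-m grid points, 363 biallelic loci, 61 genets with a
    heavily skewed size distribution (:data:`MAIN_PLOT_SIZES`)."""
    rng = _rng(rng)
    if config is None:
        config = SimConfig()
    sizes = np.array(MAIN_PLOT_SIZES, dtype=int)
    n_side = int(round(config.arena[0] / config.grid_interval)) + 1  # 21
    loci = make_snp_loci(config.n_loci, rng)
    founders = simulate_founders(len(sizes), config.n_loci, config.maf_range, rng, loci=loci)

    label, cell_parent = _grow_patches(sizes, n_side, rng)
    occupied = np.flatnonzero(label >= 0)
    # lineage over occupied cells, topologically ordered (seeds first)
    order: list[int] = []
    pos_in_order: dict[int, int] = {}
    pending = [int(c) for c in occupied]
    while pending:
        rest = []
        for c in pending:
            p = cell_parent[c]
            if p < 0 or p in pos_in_order:
                pos_in_order[c] = len(order)
                order.append(c)
            else:
                rest.append(c)
        pending = rest
    cells = np.array(order)
    parent = np.array(
        [-1 if cell_parent[c] < 0 else pos_in_order[cell_parent[c]] for c in cells]
    )
    rows, cols = np.divmod(cells, n_side)
    xy = np.column_stack([cols, rows]).astype(float) * config.grid_interval
    lineage = Lineage(
        parent=parent,
        genet=label[cells],
        year=np.zeros(len(cells), dtype=int),
        xy=xy,
        alive=np.ones(len(cells), dtype=bool),
    )
    # sample names in row-major grid order for readability
    grid_order = np.argsort(cells)
    names_by_lineage = [""] * len(cells)
    for rank, li in enumerate(grid_order):
        r, c = divmod(int(cells[li]), n_side)
        names_by_lineage[li] = f"s{r:02d}x{c:02d}"
    ds, log = _finalize_dataset(
        names_by_lineage, loci, founders, lineage, np.arange(len(cells)), xy, config, rng
    )
    truth = SimTruth(
        samples=names_by_lineage,
        true_genet=label[cells],
        lineage_parent={
            names_by_lineage[i]: names_by_lineage[parent[i]]
            for i in range(len(cells))
            if parent[i] >= 0
        },
        mutations=[(names_by_lineage[i], lid) for i, lid in log["somatic_mutations"]],
        manifest={
            "preset": "main_plot",
            "config": asdict(config),
            "n_genets_true": len(sizes),
            "genet_sizes": sizes.tolist(),
            "corruption": {k: v for k, v in log.items() if k != "somatic_mutations"},
        },
    )
    return ds, truth
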