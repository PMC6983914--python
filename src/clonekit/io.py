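"""Readers and writers for the standard formats the pipeline touches.

SNP genotypes travel as VCF (GT + per-sample DP); SSR genotypes,
coordinates, assignments, distance matrices and correlograms as CSV.
Loading never silently drops anything: multi-allelic records are loaded
and flagged (their exclusion is the filtering stage's job), and id
mismatches raise with the offending ids.  All writers round-trip
exactly.
"""

from __future__ import annotations

import csv
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    Dataset,
    DepthTable,
    DistanceMatrix,
    GenetAssignment,
    GenotypeTable,
    Locus,
    LocusKind,
    SampleSheet,
)


def read_vcf(path) -> tuple[GenotypeTable, DepthTable]:
    """Load diploid GT + DP from a VCF.

    Records with more than one ALT allele are retained with their full
    allele list (the Locus is simply not biallelic; filtering excludes
    it later).  ``snp_count_on_contig`` is the number of records sharing
    the record's CHROM within this file.  Missing genotypes become
    MISSING calls; missing DP becomes depth 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[Locus] = []
    gt_rows, dp_rows = [], []
    ids_seen: set[str] = set()
    contigs: list[str] = []
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        if vid in ids_seen:
            raise ValueError(f"duplicate record id in VCF: {vid}")
        ids_seen.add(vid)
        alleles = tuple([var.REF] + list(var.ALT))
        row = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for i, g in enumerate(var.genotypes):
            if len(g) != 3:  # [allele, allele, phased] for diploids
                raise ValueError(f"non-diploid genotype at {vid}, sample {samples[i]}")
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                row[i] = (a, b)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            depth = np.zeros(len(samples), dtype=np.int32)
        else:
            depth = np.asarray(dp, dtype=float).reshape(len(samples))
            depth = np.where(np.isfinite(depth) & (depth >= 0), depth, 0).astype(np.int32)
        loci.append(
            Locus(
                id=vid,
                kind=LocusKind.SNP,
                contig=var.CHROM,
                position=var.POS,
                alleles=alleles,
            )
        )
        contigs.append(var.CHROM)
        gt_rows.append(row)
        dp_rows.append(depth)
    if not loci:
        raise ValueError(f"no records in VCF {path}")
    counts = Counter(contigs)
    loci = [
        Locus(
            id=lc.id,
            kind=lc.kind,
            contig=lc.contig,
            position=lc.position,
            alleles=lc.alleles,
            snp_count_on_contig=counts[lc.contig],
        )
        for lc in loci
    ]
    calls = np.stack(gt_rows, axis=1)  # (n_samples, n_loci, 2)
    depths = np.stack(dp_rows, axis=1)
    gt = GenotypeTable(samples, loci, calls)
    return gt, DepthTable(samples, [lc.id for lc in loci], depths)


def write_vcf(path, gt: GenotypeTable, depths: DepthTable | None = None) -> None:
    """Write SNP genotypes (GT:DP) as an uncompressed VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for contig in dict.fromkeys(lc.contig for lc in gt.loci):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.samples)
            + "\n"
        )
        for j, lc in enumerate(gt.loci):
            ref, alt = lc.alleles[0], ",".join(map(str, lc.alleles[1:]))
            cells = []
            for i in range(gt.n_samples):
                a, b = gt.calls[i, j]
                g = "./." if a == MISSING else f"{a}/{b}"
                d = 0 if depths is None else int(depths.depths[i, j])
                cells.append(f"{g}:{d}")
            fh.write(
                f"{lc.contig}\t{lc.position}\t{lc.id}\t{ref}\t{alt}\t.\t.\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_ssr_table(path) -> GenotypeTable:
    """Load SSR repeat scores from CSV: column ``sample`` then two columns
    per locus (``<locus>_1``, ``<locus>_2``); 0 or blank = missing."""
    df = pd.read_csv(path, dtype={0: str})
    cols = list(df.columns[1:])
    if len(cols) % 2:
        raise ValueError(f"odd number of allele columns ({len(cols)}) in {path}")
    samples = df.iloc[:, 0].tolist()
    n, m = len(samples), len(cols) // 2
    calls = np.full((n, m, 2), MISSING, dtype=np.int16)
    loci = []
    for j in range(m):
        pair = df[cols[2 * j : 2 * j + 2]].to_numpy()
        pair = np.where(pd.isna(pair), 0, pair)
        try:
            pair = pair.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-integer repeat score in columns {cols[2*j:2*j+2]}") from exc
        if not np.all(pair == np.floor(pair)):
            raise ValueError(f"non-integer repeat score in columns {cols[2*j:2*j+2]}")
        pair = pair.astype(np.int16)
        ok = (pair > 0).all(axis=1)
        calls[ok, j, :] = pair[ok]
        observed = sorted({int(v) for v in pair[ok].ravel()})
        name = cols[2 * j].rsplit("_", 1)[0]
        loci.append(Locus(id=name, kind=LocusKind.SSR, alleles=tuple(observed) or (1,)))
    return GenotypeTable(samples, loci, calls)


def write_ssr_table(path, gt: GenotypeTable) -> None:
    cols: dict[str, list] = {"sample": gt.samples}
    for j, lc in enumerate(gt.loci):
        a = gt.calls[:, j, 0].astype(object)
        b = gt.calls[:, j, 1].astype(object)
        a[gt.calls[:, j, 0] == MISSING] = 0
        b[gt.calls[:, j, 1] == MISSING] = 0
        cols[f"{lc.id}_1"] = list(a)
        cols[f"{lc.id}_2"] = list(b)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_coords(path) -> SampleSheet:
    """CSV with header ``sample,x,y[,group]``."""
    df = pd.read_csv(path, dtype={"sample": str})
    for col in ("sample", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinate file {path} lacks column {col!r}")
    dup = df["sample"][df["sample"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids in {path}: {sorted(set(dup))[:5]}")
    group = df["group"].astype(str).tolist() if "group" in df.columns else None
    return SampleSheet(df["sample"].tolist(), df[["x", "y"]].to_numpy(float), group)


def write_coords(path, sheet: SampleSheet) -> None:
    df = pd.DataFrame({"sample": sheet.samples, "x": sheet.xy[:, 0], "y": sheet.xy[:, 1]})
    if sheet.group is not None:
        df["group"] = sheet.group
    df.to_csv(path, index=False)


def check_ids_match(gt: GenotypeTable, sheet: SampleSheet) -> None:
    """Every genotyped sample must have a coordinate row."""
    missing = [s for s in gt.samples if s not in set(sheet.samples)]
    if missing:
        raise ValueError(f"samples missing from coordinates: {missing[:10]}")


def write_assignment(path, assignment: GenetAssignment, sheet: SampleSheet | None = None) -> None:
    """Assignment CSV: sample, x, y, genet (rank id), genet_size."""
    sizes = assignment.sizes()
    rows = []
    for i, s in enumerate(assignment.samples):
        g = int(assignment.genet_ids[i])
        x, y = ("", "")
        if sheet is not None:
            k = sheet.samples.index(s)
            x, y = sheet.xy[k]
        rows.append({"sample": s, "x": x, "y": y, "genet": g, "genet_size": int(sizes[g - 1])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment(path) -> GenetAssignment:
    df = pd.read_csv(path, dtype={"sample": str})
    return GenetAssignment.from_labels(df["sample"].tolist(), df["genet"].tolist())


def write_matrix(path, dm: DistanceMatrix) -> None:
    """Square CSV with id header row/column; the model tag rides in a
    leading comment line."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# model={dm.model}\n")
        w = csv.writer(fh)
        w.writerow(["id"] + dm.ids)
        for i, sid in enumerate(dm.ids):
            w.writerow([sid] + [repr(float(v)) for v in dm.values[i]])


def read_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        model = "iam"
        if first.startswith("#"):
            model = first.split("model=", 1)[-1]
            df = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(float), model)


def write_truth(path, truth) -> None:
    pd.DataFrame({"sample": truth.samples, "true_genet": truth.true_genet}).to_csv(
        path, index=False
    )


def write_correlogram(path, corr) -> None:
    corr.table.to_csv(path, index_label="class")


def write_dataset(outdir, ds: Dataset, prefix: str = "data") -> dict[str, str]:
    """Persist a dataset (VCF or SSR CSV + coords) and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if all(lc.kind == LocusKind.SNP for lc in ds.genotypes.loci):
        p = outdir / f"{prefix}.vcf"
        write_vcf(p, ds.genotypes, ds.depths)
        paths["vcf"] = str(p)
    else:
        p = outdir / f"{prefix}_ssr.csv"
        write_ssr_table(p, ds.genotypes)
        paths["ssr"] = str(p)
    if ds.sheet is not None:
        p = outdir / f"{prefix}_coords.csv"
        write_coords(p, ds.sheet)
        paths["coords"] = str(p)
    return paths
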