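"""Readers and writers for the pipeline's on-disk formats.

Canonical interchange is TSV:

* genotypes — one row per variant with columns ``variant_id``,
  ``chrom``, ``pos``, ``maf`` followed by one dosage column per sample
  (``maf`` may be omitted; it is then recomputed from the dosages);
* expression — samples in rows (first column ``sample_id``), probes in
  columns; probe annotation travels separately as BED;
* covariates — samples in rows, covariates in columns.

BED is 0-based half-open on disk and converted to 1-based inclusive
coordinates on read, once, at this boundary. A minimal VCF reader
(GT or DS) and writer (DS field) are provided for genotypes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_expression",
    "read_annotation",
    "write_annotation",
    "read_covariates",
    "align_samples",
    "write_study",
    "read_study",
]

PathLike = Union[str, Path]

GENO_META = ["variant_id", "chrom", "pos", "maf"]


def read_genotypes(path: PathLike, format: str = "tsv") -> GenotypeMatrix:
    """Load a genotype matrix from TSV or VCF (GT or DS dosages)."""
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"genotype TSV must carry columns {sorted(required)}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id {dup!r}")
    meta_cols = [c for c in GENO_META if c in df.columns]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise ValueError("genotype TSV has no sample columns")
    variants = df.set_index("variant_id")[[c for c in meta_cols if c != "variant_id"]]
    dosages = df.set_index("variant_id")[sample_cols].T.astype(float)
    bad = ~(((dosages >= 0) & (dosages <= 2)) | dosages.isna())
    if bad.any().any():
        variant = bad.any(axis=0).idxmax()
        line = int(np.flatnonzero(df["variant_id"] == variant)[0]) + 2
        raise ValueError(f"dosage out of [0, 2] for {variant!r} (line {line})")
    return GenotypeMatrix(dosages, variants)


def _read_genotypes_vcf(path: PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, genotypes-only

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for i, rec in enumerate(vcf):
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds_field = rec.format("DS")
        except KeyError:
            ds_field = None
        if ds_field is not None:
            ds = np.asarray(ds_field, dtype=float).reshape(-1)
        else:
            gts = np.asarray(rec.genotypes, dtype=object)
            ds = np.array(
                [g[0] + g[1] if g[0] >= 0 and g[1] >= 0 else np.nan for g in gts],
                dtype=float,
            )
        if np.nanmin(ds) < 0 or np.nanmax(ds) > 2:
            raise ValueError(f"dosage out of [0, 2] in VCF record {i + 1} ({vid})")
        ids.append(vid)
        chroms.append(str(rec.CHROM))
        poss.append(int(rec.POS))
        rows.append(ds)
    if not ids:
        raise ValueError("empty VCF")
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss}, index=pd.Index(ids))
    return GenotypeMatrix(dosages, variants)


def write_genotypes(geno: GenotypeMatrix, path: PathLike) -> None:
    out = geno.variants[["chrom", "pos", "maf"]].copy()
    out = pd.concat([out, geno.dosages.T], axis=1)
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t", index=True)


def write_vcf(geno: GenotypeMatrix, path: PathLike) -> None:
    """Minimal VCF 4.2 with a DS (dosage) FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for vid in geno.variant_ids:
            meta = geno.variants.loc[vid]
            ds = geno.dosages[vid]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tDS\t"
                + "\t".join(f"{v:g}" for v in ds)
                + "\n"
            )


def read_expression(
    path: PathLike, annotation: Optional[pd.DataFrame] = None
) -> Union[pd.DataFrame, ExpressionMatrix]:
    """Load expression TSV; with annotation, return an ExpressionMatrix.

    Probes missing from the annotation are dropped with a warning
    (they cannot enter a positional scan).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"duplicate sample id {df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r}")
    if annotation is None:
        return df
    unannotated = df.columns.difference(annotation.index)
    if len(unannotated):
        logger.warning(
            "dropping %d probes without annotation (e.g. %s)",
            len(unannotated),
            list(unannotated)[:3],
        )
        df = df[df.columns.intersection(annotation.index)]
    return ExpressionMatrix(df, annotation.loc[df.columns])


def read_annotation(path: PathLike) -> pd.DataFrame:
    """Read probe annotation BED (chrom, start, end, probe_id, gene).

    On-disk coordinates are 0-based half-open; returned ``start``/``end``
    are 1-based inclusive.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "probe_id", "gene"],
        dtype={"chrom": str},
    )
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValueError(f"duplicate probe id {dup!r}")
    if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
        raise ValueError("malformed BED interval")
    df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    return df.set_index("probe_id")


def write_annotation(probes: pd.DataFrame, path: PathLike) -> None:
    out = probes.reset_index()
    idcol = out.columns[0]
    bed = pd.DataFrame(
        {
            "chrom": out["chrom"],
            "start": out["start"] - 1,
            "end": out["end"],
            "probe_id": out[idcol],
            "gene": out.get("gene", out[idcol]),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_covariates(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate sample id in covariates")
    return df


def align_samples(
    geno: GenotypeMatrix,
    expr: ExpressionMatrix,
    covariates: Optional[pd.DataFrame] = None,
) -> Tuple[GenotypeMatrix, ExpressionMatrix, Optional[pd.DataFrame]]:
    """Restrict all inputs to the shared sample set, genotype order."""
    common = geno.samples.intersection(expr.samples)
    if covariates is not None:
        common = common.intersection(covariates.index)
    common = [s for s in geno.samples if s in set(common)]
    if not common:
        raise ValueError("no samples shared between genotypes and expression")
    dropped = len(geno.samples) + len(expr.samples) - 2 * len(common)
    if dropped:
        logger.warning("dropped %d unshared sample entries", dropped)
    geno2 = GenotypeMatrix(geno.dosages.loc[common], geno.variants.copy())
    expr2 = ExpressionMatrix(expr.values.loc[common], expr.probes.copy())
    cov2 = None if covariates is None else covariates.loc[common]
    return geno2, expr2, cov2


def write_study(study, outdir: PathLike) -> None:
    """Write a simulated study (genotypes, expression, BED, truth) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genotypes(study.genotypes, outdir / "genotypes.tsv")
    vals = study.expression.values.copy()
    vals.index.name = "sample_id"
    vals.to_csv(outdir / "expression.tsv", sep="\t")
    write_annotation(study.expression.probes, outdir / "annotation.bed")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_study(outdir: PathLike):
    """Round-trip counterpart of :func:`write_study`."""
    from .simulate import StudyDataset

    outdir = Path(outdir)
    geno = read_genotypes(outdir / "genotypes.tsv")
    annot = read_annotation(outdir / "annotation.bed")
    expr = read_expression(outdir / "expression.tsv", annot)
    truth = pd.read_csv(outdir / "truth.tsv", sep="\t", keep_default_na=False)
    return StudyDataset(genotypes=geno, expression=expr, truth=truth)
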