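"""Readers and writers for the interchange formats of the pipeline.

Genotypes travel as VCF v4.2 or HapMap text; phenotypes, network edges,
rank tables and count matrices as TSV; annotation as GFF3 (1-based
closed intervals, only features of type ``gene`` are used).  Dosages
are always re-oriented on read so they count the minor allele.  The
printed locus table of the source study ships as package data and
loads through :func:`load_table2`.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (GenotypeMatrix, validate_annotation,
                         validate_network, validate_phenotypes,
                         validate_ranks)
from .errors import ParseError
from .simulate import CountMatrix

log = logging.getLogger(__name__)

_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
_HET_TO_IUPAC = {frozenset(v): k for k, v in _IUPAC_HET.items()}


def _parse_chrom(raw: str) -> int:
    s = str(raw)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError as exc:
        raise ParseError(f"non-numeric chromosome {raw!r}") from exc


def _orient_minor(dosages: np.ndarray, ref: np.ndarray, alt: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip ALT-count dosages so they count the minor allele."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    flip = freq > 0.5
    dosages = dosages.copy()
    dosages[:, flip] = 2.0 - dosages[:, flip]
    minor = np.where(flip, ref, alt)
    major = np.where(flip, alt, ref)
    return dosages, major, minor


# ------------------------------------------------------------- genotypes

def read_genotypes(path: str | Path, dialect: str = "vcf") -> GenotypeMatrix:
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "hapmap":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, doses, seen = [], [], set()
    for i, var in enumerate(vcf, start=1):
        if len(var.ALT) != 1:
            raise ParseError(f"multiallelic site {var.ID or var.POS}",
                             str(path), i)
        snp_id = var.ID or f"Chr{var.CHROM}pos{var.POS}.1"
        if snp_id in seen:
            raise ValueError(f"duplicated marker ID {snp_id!r}")
        seen.add(snp_id)
        gt = np.array([g[:2] for g in var.genotypes], dtype=float)
        gt[gt < 0] = np.nan
        doses.append(gt.sum(axis=1))
        rows.append((snp_id, _parse_chrom(var.CHROM), var.POS,
                     var.REF, var.ALT[0]))
    if not rows:
        raise ParseError("no variant records", str(path))
    dosages = np.column_stack(doses)
    ref = np.array([r[3] for r in rows])
    alt = np.array([r[4] for r in rows])
    dosages, major, minor = _orient_minor(dosages, ref, alt)
    markers = pd.DataFrame({
        "snp_id": [r[0] for r in rows],
        "chrom": [r[1] for r in rows],
        "pos": [r[2] for r in rows],
        "major": major, "minor": minor,
    })
    order = np.lexsort((markers["pos"], markers["chrom"]))
    return GenotypeMatrix(samples=samples, dosages=dosages[:, order],
                          markers=markers.iloc[order].reset_index(drop=True))


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """VCF v4.2 with the *major* allele as REF and minor as ALT."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, m in geno.markers.iterrows():
            gts = [code.get(d, "./.") if np.isfinite(d) else "./."
                   for d in geno.dosages[:, j]]
            fh.write(f"{m['chrom']}\t{m['pos']}\t{m['snp_id']}\t{m['major']}\t"
                     f"{m['minor']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def _read_hapmap(path: str | Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 12 or header[0] not in ("rs#", "rs"):
            raise ParseError("not a HapMap header", str(path), 1)
        samples = header[11:]
        rows, doses, seen = [], [], set()
        for i, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(header):
                raise ParseError(f"expected {len(header)} fields, got {len(f)}",
                                 str(path), i)
            snp_id, alleles = f[0], f[1].split("/")
            if len(alleles) != 2:
                raise ParseError(f"marker {snp_id}: need two alleles",
                                 str(path), i)
            if snp_id in seen:
                raise ValueError(f"duplicated marker ID {snp_id!r}")
            seen.add(snp_id)
            a1, a2 = alleles
            row = np.full(len(samples), np.nan)
            for k, call in enumerate(f[11:]):
                call = call.strip().upper()
                if call in ("N", "NN", "", "-", "--"):
                    continue
                if len(call) == 1 and call in _IUPAC_HET:
                    row[k] = 1.0
                else:
                    pair = call if len(call) == 2 else call * 2
                    row[k] = sum(1.0 for c in pair if c == a2)
                    if any(c not in (a1, a2) for c in pair):
                        raise ParseError(
                            f"marker {snp_id}: genotype {call!r} outside "
                            f"alleles {a1}/{a2}", str(path), i)
            doses.append(row)
            rows.append((snp_id, _parse_chrom(f[2]), int(f[3]), a1, a2))
    dosages = np.column_stack(doses)
    a1 = np.array([r[3] for r in rows])
    a2 = np.array([r[4] for r in rows])
    dosages, major, minor = _orient_minor(dosages, a1, a2)
    markers = pd.DataFrame({
        "snp_id": [r[0] for r in rows],
        "chrom": [r[1] for r in rows],
        "pos": [r[2] for r in rows],
        "major": major, "minor": minor,
    })
    order = np.lexsort((markers["pos"], markers["chrom"]))
    return GenotypeMatrix(samples=samples, dosages=dosages[:, order],
                          markers=markers.iloc[order].reset_index(drop=True))


def write_hapmap(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
            "protLSID", "assayLSID", "panelLSID", "QCcode"]
    with open(path, "w") as fh:
        fh.write("\t".join(meta + geno.samples) + "\n")
        for j, m in geno.markers.iterrows():
            calls = []
            for d in geno.dosages[:, j]:
                if not np.isfinite(d):
                    calls.append("N")
                elif d == 0:
                    calls.append(m["major"])
                elif d == 2:
                    calls.append(m["minor"])
                else:
                    calls.append(_HET_TO_IUPAC.get(
                        frozenset((m["major"], m["minor"])), "N"))
            fh.write("\t".join([m["snp_id"], f"{m['major']}/{m['minor']}",
                                str(m["chrom"]), str(m["pos"]), "+", "NA",
                                "NA", "NA", "NA", "NA", "NA"] + calls) + "\n")


# ------------------------------------------------------------ flat tables

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(df).to_csv(path, sep="\t", index=False)


def read_network(path: str | Path) -> pd.DataFrame:
    return validate_network(pd.read_csv(path, sep="\t"))


def write_network(df: pd.DataFrame, path: str | Path) -> None:
    validate_network(df).to_csv(path, sep="\t", index=False)


def read_ranks(path: str | Path) -> pd.DataFrame:
    return validate_ranks(pd.read_csv(path, sep="\t"))


def write_ranks(df: pd.DataFrame, path: str | Path) -> None:
    validate_ranks(df).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, samplesheet: str | Path) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    sheet = pd.read_csv(samplesheet, sep="\t")
    need = {"sample_id", "condition", "time", "replicate"}
    if not need <= set(sheet.columns):
        raise ValueError(f"sample sheet missing columns: {need - set(sheet.columns)}")
    counts = counts[sheet["sample_id"].tolist()]
    return CountMatrix(counts=counts, samples=sheet)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 samplesheet_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.samples.to_csv(samplesheet_path, sep="\t", index=False)


# -------------------------------------------------------------- annotation

def read_annotation(path: str | Path) -> pd.DataFrame:
    """Gene features from GFF3; other feature types are counted and ignored."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    rows = []
    n_other = 0
    for feat in db.all_features():
        if feat.featuretype != "gene":
            n_other += 1
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"gene_id": gid, "chrom": _parse_chrom(feat.seqid),
                     "start": feat.start, "end": feat.end,
                     "strand": feat.strand})
    if n_other:
        log.info("annotation: ignored %d non-gene features", n_other)
    return validate_annotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot = validate_annotation(annot)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in annot.iterrows():
            fh.write(f"Chr{r['chrom']}\thntgwas\tgene\t{r['start']}\t"
                     f"{r['end']}\t.\t{r['strand']}\t.\tID={r['gene_id']}\n")


# ------------------------------------------------------------ study fixture

def load_table2() -> pd.DataFrame:
    """The study's printed cMTA table (57 loci rows) as a DataFrame.

    Columns: trait, locus_id, experiment, treatment, snp_name, chrom,
    pos, p_value, alleles (major:minor), allelic_effect,
    favorable_allele, n_genes (NaN where unreported).
    """
    with resources.files("hntgwas.data").joinpath("table2_cmtas.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
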