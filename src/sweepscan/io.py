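"""Reading phased VCFs and gene annotations; writing result tables.

All internal coordinates are 0-based half-open. VCF positions (1-based)
and GFF3 intervals (1-based inclusive) are converted on the way in; BED
is kept as-is.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GeneInterval, HaplotypeMatrix

logger = logging.getLogger(__name__)


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping sample name to population label."""
    popmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"{path}: empty population map")
    return popmap


def read_phased_vcf(
    path: str | Path,
    popmap: dict[str, str] | str | Path,
) -> tuple[list[HaplotypeMatrix], dict[str, int]]:
    """Load phased diploid genotypes into one HaplotypeMatrix per chromosome.

    Sites that are multi-allelic, unphased, or carry missing genotypes are
    excluded; the returned counter reports how many of each were dropped.
    Every VCF sample must appear in the population map.

    Returns
    -------
    (matrices, exclusions)
        ``matrices`` holds one HaplotypeMatrix per chromosome in file
        order; ``exclusions`` counts dropped sites by reason
        (``multiallelic``, ``unphased``, ``missing``).
    """
    from cyvcf2 import VCF

    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(
            f"sample(s) {', '.join(absent)} in VCF but missing from popmap"
        )
    hap_pop = np.array([popmap[s] for s in samples for _ in range(2)])

    exclusions = {"multiallelic": 0, "unphased": 0, "missing": 0}
    per_chrom: dict[str, tuple[list[int], list[np.ndarray]]] = {}

    for var in vcf:
        if len(var.ALT) != 1:
            exclusions["multiallelic"] += 1
            continue
        gts = var.genotype.array()  # (n_samples, 3): a0, a1, phased flag
        a0, a1, phased = gts[:, 0], gts[:, 1], gts[:, 2]
        if np.any((a0 < 0) | (a1 < 0)):
            exclusions["missing"] += 1
            continue
        # homozygous genotypes are phase-unambiguous even when written with "/"
        het = a0 != a1
        if np.any(het & (phased == 0)):
            exclusions["unphased"] += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.uint8)
        col[0::2] = a0
        col[1::2] = a1
        chrom = var.CHROM
        if chrom not in per_chrom:
            per_chrom[chrom] = ([], [])
        positions, cols = per_chrom[chrom]
        pos0 = var.POS - 1  # VCF is 1-based
        if positions and pos0 <= positions[-1]:
            if pos0 == positions[-1]:
                continue  # duplicate coordinate: keep first record
            raise ValueError(f"{path}: positions out of order on {chrom}")
        positions.append(pos0)
        cols.append(col)

    matrices = []
    for chrom, (positions, cols) in per_chrom.items():
        if not positions:
            logger.warning("chromosome %s: zero retained sites", chrom)
            alleles = np.empty((hap_pop.size, 0), dtype=np.uint8)
        else:
            alleles = np.column_stack(cols)
        matrices.append(
            HaplotypeMatrix(
                chrom=chrom,
                positions=np.array(positions, dtype=np.int64),
                alleles=alleles,
                hap_pop=hap_pop,
            )
        )
    return matrices, exclusions


def write_phased_vcf(
    hm: HaplotypeMatrix,
    path: str | Path,
    sample_prefix: str = "S",
) -> list[str]:
    """Write a HaplotypeMatrix as a minimal phased VCF (one ALT per site).

    Consecutive haplotype row pairs (2i, 2i+1) become diploid sample i.
    Returns the generated sample names (used to emit a matching popmap).
    """
    if hm.n_haplotypes % 2:
        raise ValueError("need an even number of haplotype rows")
    n_samples = hm.n_haplotypes // 2
    names = [f"{sample_prefix}{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hm.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(hm.n_sites):
            col = hm.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
            )
            fh.write(
                f"{hm.chrom}\t{hm.positions[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return names


def write_popmap(names: list[str], labels: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, label in zip(names, labels, strict=True):
            fh.write(f"{name}\t{label}\n")


def read_genes(path: str | Path, fmt: str | None = None) -> list[GeneInterval]:
    """Read gene intervals from BED4 or GFF3.

    BED is already 0-based half-open; GFF3 gene features are converted
    from 1-based inclusive (start-1, end). Format is inferred from the
    file suffix unless given explicitly.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    gene_id = fields[3] if len(fields) > 3 else f"interval_{lineno}"
                    gene = GeneInterval(chrom, start, end, gene_id)
                else:
                    if len(fields) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    if fields[2].lower() != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("ID") or attrs.get("gene_id")
                    if not gene_id:
                        raise ValueError("gene feature without ID attribute")
                    gene = GeneInterval(
                        fields[0],
                        int(fields[3]) - 1,
                        int(fields[4]),
                        gene_id,
                        attrs.get("Name"),
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
            if gene.gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene.gene_id!r}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _format_value(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, bool) or isinstance(v, np.bool_):
        return "True" if v else "False"
    if isinstance(v, float) or isinstance(v, np.floating):
        if math.isnan(v):
            return "NA"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        return f"{v:.6g}"
    return str(v)


_SORT_KEYS = ("chrom", "start", "pos", "gene_id", "site", "breed", "category")


def write_table(records: list, path: str | Path, record_type=None) -> pd.DataFrame:
    """Write a homogeneous list of dataclass records as TSV.

    A header row is always emitted; for an empty list the column names are
    taken from ``record_type`` (a dataclass) when given. Floats use 6
    significant digits; rows are sorted deterministically by the record's
    positional fields (chrom, then start/pos where present).
    """
    if records:
        if not all(type(r) is type(records[0]) for r in records):
            raise ValueError("records must be homogeneous")
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows)
        sort_cols = [c for c in _SORT_KEYS if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    elif record_type is not None:
        df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(record_type)])
    else:
        df = pd.DataFrame()
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_value(v) for v in row) + "\n")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by write_table back into a DataFrame."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
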