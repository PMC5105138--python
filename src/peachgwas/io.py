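"""File formats: VCF v4.2 (GT:GQ), phenotype/group TSV, BED, newick, JSON.

Internal coordinates are 0-based half-open; VCF positions are written and
read as 1-based, converted only here.  Multi-allelic VCF records are
dropped with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, Region
from .simdata import TruthSet

logger = logging.getLogger(__name__)

_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
_GT_PARSE = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".": MISSING, ".|.": MISSING,
}


def write_vcf(G: GenotypeMatrix, path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a plain-text VCF v4.2 with GT (and GQ when present)."""
    path = Path(path)
    fmt = "GT:GQ" if G.gq is not None else "GT"
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=peachgwas\n")
        if chrom_lengths:
            for name, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if G.gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, G.samples)) + "\n")
        for j in range(G.n_variants):
            cells = []
            for i in range(G.n_samples):
                gt = _GT_STRINGS[int(G.genotypes[i, j])]
                if G.gq is not None:
                    cells.append(f"{gt}:{int(G.gq[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{G.chrom[j]}\t{int(G.pos[j]) + 1}\t.\t{G.ref[j]}\t{G.alt[j]}\t.\tPASS\t.\t"
                f"{fmt}\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path, subpop: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF via cyvcf2; multi-allelic records are dropped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = np.array(vcf.samples)
    chroms, poss, refs, alts, geno_cols, gq_cols = [], [], [], [], [], []
    n_multi = 0
    has_gq = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS - 1)  # to 0-based
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        g = rec.gt_types.astype(np.int8)  # 0,1,2, 3=unknown with gts012
        g[g == 3] = MISSING
        geno_cols.append(g)
        try:
            gq = rec.format("GQ")
        except Exception:
            gq = None
        if gq is not None:
            has_gq = True
            gq_cols.append(np.asarray(gq).reshape(-1).astype(np.int16))
        else:
            gq_cols.append(None)
    if n_multi:
        logger.info("read_vcf: dropped %d multi-allelic records", n_multi)
    genotypes = np.column_stack(geno_cols) if geno_cols else np.zeros((len(samples), 0), np.int8)
    gq_matrix = None
    if has_gq:
        filled = [c if c is not None else np.full(len(samples), 99, np.int16) for c in gq_cols]
        gq_matrix = np.column_stack(filled)
    labels = None
    if subpop is not None:
        labels = np.array([subpop.get(str(s), "unknown") for s in samples])
    return GenotypeMatrix(
        genotypes=genotypes,
        chrom=np.array(chroms),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs),
        alt=np.array(alts),
        samples=samples,
        subpop=labels,
        gq=gq_matrix,
    )


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    """Phenotype TSV: sample_id plus one column per trait; missing as NA."""
    pheno.to_csv(path, sep="\t", na_rep="NA", index=True, index_label="sample_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])


def write_groups(samples, labels, path: str | Path) -> None:
    pd.DataFrame({"sample_id": samples, "group": labels}).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


def write_truth(truth: TruthSet, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> TruthSet:
    return TruthSet.from_json(Path(path).read_text())


def write_bed(regions: list[Region], path: str | Path, extra_cols: bool = True) -> None:
    """BED (0-based half-open) with optional label/score columns."""
    with Path(path).open("w") as fh:
        for r in regions:
            if extra_cols:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{r.score:.6g}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path: str | Path) -> list[Region]:
    regions = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        label = parts[3] if len(parts) > 3 else ""
        score = float(parts[4]) if len(parts) > 4 else float("nan")
        regions.append(Region(chrom, start, end, score, label))
    return regions


def write_matrix_tsv(M: np.ndarray, labels, path: str | Path) -> None:
    """Square matrix (kinship, distance) as TSV with sample-id headers."""
    pd.DataFrame(M, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), df.index.to_numpy()
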