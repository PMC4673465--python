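"""Readers and writers for phased VCF panels, genotype tables, sample labels
and gene-region files.

All tabular files are tab-separated UTF-8 with a header line. VCF handling is
deliberately minimal: biallelic SNPs, GT field only; phased panels require the
``|`` separator in every genotype.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GeneRegion, GenotypeMatrix, HaplotypePanel, SnpMap


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a sample_id -> population table (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "population"} <= set(df.columns):
        raise ValueError("labels file needs 'sample_id' and 'population' columns")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in labels file")
    return dict(zip(df["sample_id"], df["population"]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(labels), "population": list(labels.values())}) \
        .to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[GeneRegion]:
    """Read gene regions (name, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    return [GeneRegion(r["name"], str(r["chrom"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


def write_regions(regions: Sequence[GeneRegion], path: str | Path) -> None:
    pd.DataFrame([{"name": r.name, "chrom": r.chrom, "start": r.start, "end": r.end}
                  for r in regions]).to_csv(path, sep="\t", index=False)


def _labels_for(sample_ids: Sequence[str], labels: Mapping[str, str]) -> list[str]:
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing[:5]}")
    return [labels[s] for s in sample_ids]


def read_haplotype_panel(path: str | Path, labels_path: str | Path) -> HaplotypePanel:
    """Read a phased VCF (GT with '|' separators) into a HaplotypePanel.

    Raises on the first unphased or missing genotype, naming the record, and
    on any sample absent from the labels file.
    """
    labels = read_labels(labels_path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    populations = _labels_for(sample_ids, labels)
    rows: list[np.ndarray] = []
    records: list[dict] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        gts = np.asarray(v.genotypes, dtype=object)
        col = np.empty(2 * len(sample_ids), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a0, a1, phased = int(gt[0]), int(gt[1]), bool(gt[2])
            if a0 < 0 or a1 < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} ({sample_ids[i]})")
            if not phased:
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} ({sample_ids[i]})")
            col[2 * i] = a0
            col[2 * i + 1] = a1
        rows.append(col)
        records.append({"snp_id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM,
                        "pos": v.POS, "allele0": v.REF, "allele1": v.ALT[0]})
    vcf.close()
    snp_map = SnpMap(pd.DataFrame(records))
    return HaplotypePanel(np.column_stack(rows), sample_ids, populations, snp_map)


def read_genotype_matrix(path: str | Path, labels_path: str | Path) -> GenotypeMatrix:
    """Read a VCF into an unphased GenotypeMatrix; missing GT becomes -1."""
    labels = read_labels(labels_path)
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    populations = _labels_for(sample_ids, labels)
    cols: list[np.ndarray] = []
    records: list[dict] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"non-biallelic record at {v.CHROM}:{v.POS}")
        col = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = int(gt[0]), int(gt[1])
            col[i] = MISSING if (a0 < 0 or a1 < 0) else a0 + a1
        cols.append(col)
        records.append({"snp_id": v.ID or f"{v.CHROM}:{v.POS}", "chrom": v.CHROM,
                        "pos": v.POS, "allele0": v.REF, "allele1": v.ALT[0]})
    vcf.close()
    return GenotypeMatrix(np.column_stack(cols), sample_ids, populations,
                          SnpMap(pd.DataFrame(records)))


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _vcf_body(snp_map: SnpMap, sample_ids: Sequence[str], gt_strings: np.ndarray) -> str:
    buf = _io.StringIO()
    buf.write(_VCF_HEADER)
    for chrom in dict.fromkeys(snp_map.chroms):
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(sample_ids) + "\n")
    t = snp_map.table
    for j in range(len(snp_map)):
        buf.write(f"{t.chrom[j]}\t{t.pos[j]}\t{t.snp_id[j]}\t{t.allele0[j]}\t"
                  f"{t.allele1[j]}\t.\tPASS\t.\tGT\t" + "\t".join(gt_strings[j]) + "\n")
    return buf.getvalue()


def write_haplotype_panel(panel: HaplotypePanel, path: str | Path,
                          labels_path: str | Path | None = None) -> None:
    """Write a panel as a phased VCF (and optionally its labels file)."""
    h = panel.values
    gt = np.empty((panel.n_markers, panel.n_samples), dtype=object)
    for i in range(panel.n_samples):
        a, b = h[2 * i], h[2 * i + 1]
        col = np.char.add(np.char.add(a.astype("U1"), "|"), b.astype("U1"))
        gt[:, i] = col
    Path(path).write_text(_vcf_body(panel.snp_map, panel.sample_ids, gt))
    if labels_path is not None:
        write_labels(dict(zip(panel.sample_ids, panel.populations)), labels_path)


def write_genotype_matrix(g: GenotypeMatrix, path: str | Path,
                          labels_path: str | Path | None = None) -> None:
    """Write genotypes as an unphased VCF; missing entries become './.'."""
    codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    gt = np.empty((g.n_markers, g.n_samples), dtype=object)
    for i in range(g.n_samples):
        gt[:, i] = [codes[int(x)] for x in g.values[i]]
    Path(path).write_text(_vcf_body(g.snp_map, g.sample_ids, gt))
    if labels_path is not None:
        write_labels(dict(zip(g.sample_ids, g.populations)), labels_path)
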