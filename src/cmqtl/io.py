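"""Readers and writers for the pipeline's on-disk formats.

Tables are TSV with a single header row. Genotypes are minimal VCFv4.2
(CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + per-donor GT) written as
plain text and read back through cyvcf2; the variant annotation travels as
a separate TSV (variant_id, gene, impact), as produced by an upstream
functional annotator. GRMs are written GCTA-style: a lower-triangle table
plus an ID file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from cmqtl.genotypes import GenotypeSet

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_vcf(g: GenotypeSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, g.donors)) + "\n")
        for j, (vid, row) in enumerate(g.variants.iterrows()):
            gts = [
                _GT_CODE.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            ]
            filt = row.get("filter", "PASS") or "PASS"
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t{row['alt']}"
                f"\t.\t{filt}\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path, annotation: pd.DataFrame | None = None) -> GenotypeSet:
    """Load a VCF (GT field) into a GenotypeSet via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    donors = np.array(vcf.samples)
    records, dosage_rows = [], []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        records.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": alt,
                "filter": var.FILTER or "PASS",  # cyvcf2 reports PASS as None
            }
        )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types.astype(float)
        dose = np.where(gt == 3, 2.0, gt)
        dose[gt == 2] = np.nan
        dosage_rows.append(dose)
    variants = pd.DataFrame(records).set_index("id")
    dosages = np.column_stack(dosage_rows) if dosage_rows else np.empty((len(donors), 0))
    if annotation is None:
        annotation = pd.DataFrame(
            {"gene": "", "impact": "MODIFIER"}, index=variants.index
        )
    else:
        annotation = annotation.reindex(variants.index)
        annotation["gene"] = annotation["gene"].fillna("")
        annotation["impact"] = annotation["impact"].fillna("MODIFIER")
    return GenotypeSet(
        donors=donors,
        variants=variants[["chrom", "pos", "ref", "alt", "filter"]],
        dosages=dosages,
        annotation=annotation,
    )


def write_annotation(g: GenotypeSet, path: str | Path) -> None:
    ann = g.annotation.copy()
    ann.index.name = "variant_id"
    ann.reset_index().to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


def write_grm(grm: pd.DataFrame, prefix: str | Path) -> None:
    """Lower-triangle GRM text (i, j, value) plus .id file, GCTA-like."""
    prefix = Path(prefix)
    ids = pd.DataFrame({"fid": grm.index, "iid": grm.index})
    ids.to_csv(prefix.with_suffix(".grm.id"), sep="\t", index=False, header=False)
    with prefix.with_suffix(".grm.tsv").open("w") as fh:
        a = grm.to_numpy()
        for i in range(len(grm)):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{a[i, j]:.10g}\n")


def read_grm(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    ids = pd.read_csv(prefix.with_suffix(".grm.id"), sep="\t", header=None)[1]
    tri = pd.read_csv(prefix.with_suffix(".grm.tsv"), sep="\t", header=None)
    n = len(ids)
    a = np.zeros((n, n))
    a[tri[0] - 1, tri[1] - 1] = tri[2]
    a = a + np.tril(a, -1).T
    return pd.DataFrame(a, index=ids.to_numpy(), columns=ids.to_numpy())


def write_bed_regions(regions, path: str | Path) -> None:
    """0-based half-open exclusion intervals (long-range LD)."""
    with Path(path).open("w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed_regions(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, *_ = line.split("\t")
        out.append((chrom, int(start), int(end)))
    return out
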