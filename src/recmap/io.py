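"""Genotype file I/O: multi-sample VCF v4.2 (GT only) and PLINK-style
PED/MAP text pairs.

Writers emit plain uncompressed text; the VCF reader is backed by pysam so
anything a standard toolchain produces can be loaded, while PED/MAP parsing
is a small bespoke reader (the text format is trivial and no installed
library exposes one)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .mapping import GenotypeMatrix
from .prioritize import VariantRecord

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _vcf_header(sample_ids: list[str], contigs: dict[str, int] | None) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=recmap"]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids)
    )
    return "\n".join(lines)


def write_vcf_matrix(gm: GenotypeMatrix, path, contigs: dict[str, int] | None = None) -> None:
    """Write a genotype matrix as a multi-sample VCF (GT field only)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(gm.sample_ids, contigs) + "\n")
        markers = gm.markers.reset_index(drop=True)
        for j, row in markers.iterrows():
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_vcf_variants(
    variants: list[VariantRecord], sample_ids: list[str], path,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a variant-record callset as a multi-sample VCF."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(sample_ids, contigs) + "\n")
        for v in variants:
            gts = "\t".join(_GT_STRINGS[int(v.genotypes.get(s, -1))] for s in sample_ids)
            fh.write(f"{v.chrom}\t{v.pos}\tvar_{v.chrom}_{v.pos}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def _gt_code(gt: tuple | None) -> int:
    if gt is None or any(a is None for a in gt):
        return -1
    return int(sum(1 for a in gt if a != 0))


def read_vcf_matrix(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix (first ALT allele)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows, genos = [], []
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            rows.append((rec.chrom, rec.pos, rec.id or f"var_{rec.chrom}_{rec.pos}",
                         rec.ref, alt))
            genos.append([_gt_code(rec.samples[s].get("GT")) for s in samples])
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return GenotypeMatrix(
        sample_ids=samples,
        markers=markers,
        genotypes=np.array(genos, dtype=np.int8).T.copy(),
    )


def read_vcf_variants(path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF into VariantRecords; returns (variants,
    sample ids)."""
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        out = []
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "N"
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    genotypes={s: _gt_code(rec.samples[s].get("GT")) for s in samples},
                )
            )
    return out, samples


# --------------------------------------------------------------------------
# PED / MAP
# --------------------------------------------------------------------------


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path,
                  phenotypes: dict[str, int] | None = None) -> None:
    """PED/MAP pair with actual ref/alt bases as the two alleles.

    Genotype 0 -> ref/ref, 1 -> ref/alt, 2 -> alt/alt, missing -> 0 0.
    The MAP cM column is left 0 (positions carry the information).
    """
    markers = gm.markers.reset_index(drop=True)
    with open(map_path, "w") as fh:
        for _, row in markers.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    phenotypes = phenotypes or {}
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.sample_ids):
            fields = ["FAM1", s, "0", "0", "0", str(phenotypes.get(s, 0))]
            for j in range(len(markers)):
                g = int(gm.genotypes[i, j])
                ref, alt = markers.loc[j, "ref"], markers.loc[j, "alt"]
                pair = {0: (ref, ref), 1: (ref, alt), 2: (alt, alt), -1: ("0", "0")}[g]
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def read_ped_map(ped_path, map_path, ref_alt: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a PED/MAP pair written by :func:`write_ped_map`.

    PLINK text files do not carry the ref/alt assignment.  If ``ref_alt`` (a
    frame with columns id, ref, alt) is supplied it fixes the coding;
    otherwise the lexicographically smaller observed allele is taken as ref,
    which round-trips matrices whose markers are written ref < alt and
    polymorphic in the written cohort.
    """
    markers = pd.read_csv(
        map_path, sep="\t", header=None, names=["chrom", "id", "cm", "pos"],
        dtype={"chrom": str},
    )
    n_markers = len(markers)
    sample_ids, rows = [], []
    with open(ped_path) as fh:
        for line in fh:
            f = line.split()
            if len(f) != 6 + 2 * n_markers:
                raise ValueError("PED column count does not match MAP")
            sample_ids.append(f[1])
            rows.append(f[6:])
    alleles = np.array(rows).reshape(len(sample_ids), n_markers, 2)
    ref = np.empty(n_markers, dtype=object)
    alt = np.empty(n_markers, dtype=object)
    genotypes = np.zeros((len(sample_ids), n_markers), dtype=np.int8)
    fixed = None
    if ref_alt is not None:
        fixed = ref_alt.set_index("id")
    for j in range(n_markers):
        col = alleles[:, j, :]
        if fixed is not None:
            row = fixed.loc[markers.loc[j, "id"]]
            ref[j], alt[j] = row["ref"], row["alt"]
        else:
            observed = sorted(set(col.ravel()) - {"0"})
            if not observed:
                ref[j], alt[j] = "A", "C"
            elif len(observed) == 1:
                ref[j], alt[j] = observed[0], "."
            else:
                ref[j], alt[j] = observed[0], observed[1]
        is_missing = (col == "0").any(axis=1)
        genotypes[:, j] = np.where(is_missing, -1, (col == alt[j]).sum(axis=1))
    out_markers = pd.DataFrame(
        {"chrom": markers["chrom"], "pos": markers["pos"], "id": markers["id"],
         "ref": ref, "alt": alt}
    )
    return GenotypeMatrix(sample_ids=sample_ids, markers=out_markers, genotypes=genotypes)


def write_truth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
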