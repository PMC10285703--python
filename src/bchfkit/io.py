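"""File formats: PLINK .bed/.bim/.fam, VCF, and TSV tables.

The PLINK codec is written here directly (the 2-bit SNP-major layout):
in the .bim file A1 is the alternative allele and A2 the reference, so the
stored per-SNP dosage is the 0/1/2 count of the alternative allele.
Positions are 1-based throughout.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GRM, GenotypeMatrix

__all__ = [
    "write_plink",
    "read_plink",
    "write_vcf",
    "read_vcf",
    "write_grm",
    "read_grm",
    "write_frequency_panel",
    "read_frequency_panel",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, A1 = alt: 00 hom A1 (dosage 2), 10 het, 11 hom A2 (0), 01 missing
_ENC = {2: 0b00, 1: 0b10, 0: 0b11}
_DEC = np.full(4, np.nan)
_DEC[0b00], _DEC[0b10], _DEC[0b11] = 2.0, 1.0, 0.0


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write .bed/.bim/.fam; requires raw 0/1/2 alt-count coding."""
    if matrix.coding != "alt_count":
        raise ValueError("PLINK export requires raw 0/1/2 alt-count coding")
    prefix = Path(prefix)
    panel = matrix.panel
    bim = pd.DataFrame(
        {
            "chrom": panel["chrom"],
            "snp": [f"{c}:{p}" for c, p in zip(panel["chrom"], panel["pos"])],
            "cm": 0,
            "pos": panel["pos"],
            "a1": panel["alt"],
            "a2": panel["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": matrix.ids, "iid": matrix.ids, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = matrix.n_individuals
    codes = matrix.codes
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        two_bit = np.where(
            np.isnan(codes), 0b01, np.select([codes == 2, codes == 1], [0b00, 0b10], default=0b11)
        ).astype(np.uint8)
        padded = np.zeros((n_bytes * 4, matrix.n_loci), dtype=np.uint8)
        padded[:n] = two_bit
        padded[n:] = 0b01
        shaped = padded.reshape(n_bytes, 4, matrix.n_loci)
        packed = (
            shaped[:, 0, :]
            | (shaped[:, 1, :] << 2)
            | (shaped[:, 2, :] << 4)
            | (shaped[:, 3, :] << 6)
        )
        fh.write(packed.T.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    body = raw[3:].reshape(m, n_bytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts) & 0b11  # (m, n_bytes, 4)
    two_bit = two_bit.reshape(m, n_bytes * 4)[:, :n]
    codes = _DEC[two_bit].T.astype(np.float32)
    panel = pd.DataFrame(
        {"chrom": bim["chrom"], "pos": bim["pos"], "ref": bim["a2"], "alt": bim["a1"]}
    )
    return GenotypeMatrix(ids=fam["iid"].astype(str).to_numpy(), panel=panel, codes=codes, coding="alt_count")


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    if matrix.coding != "alt_count":
        raise ValueError("VCF export requires raw 0/1/2 alt-count coding")
    gt = {2.0: "1/1", 1.0: "0/1", 0.0: "0/0"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(matrix.panel["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(map(str, matrix.ids)) + "\n")
        for j, row in enumerate(matrix.panel.itertuples(index=False)):
            calls = "\t".join(gt.get(float(v), "./.") if not np.isnan(v) else "./." for v in matrix.codes[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.chrom}:{row.pos}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.asarray(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        types = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        rows.append(np.select([types == 0, types == 1, types == 3], [0.0, 1.0, 2.0], default=np.nan))
    codes = np.array(rows, dtype=np.float32).T if rows else np.empty((len(ids), 0), dtype=np.float32)
    panel = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    try:
        panel["chrom"] = panel["chrom"].astype(int)
    except (TypeError, ValueError):
        pass
    return GenotypeMatrix(ids=ids, panel=panel, codes=codes, coding="alt_count")


def write_grm(grm: GRM, path: str | Path) -> None:
    frame = pd.DataFrame(grm.matrix, index=grm.ids, columns=grm.ids)
    frame.attrs["scale"] = grm.scale
    with open(path, "w") as fh:
        fh.write(f"# scale={grm.scale!r}\n")
        frame.to_csv(fh, sep="\t")


def read_grm(path: str | Path) -> GRM:
    with open(path) as fh:
        first = fh.readline()
        scale = float(first.split("=", 1)[1]) if first.startswith("# scale=") else float("nan")
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return GRM(ids=frame.index.to_numpy().astype(str), matrix=frame.to_numpy(), scale=scale)


def write_frequency_panel(panel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_frequency_panel(path: str | Path):
    from .ancestry import BreedReferencePanel

    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "pos", "ref", "alt"]
    breeds = [c for c in df.columns if c not in meta_cols]
    return BreedReferencePanel(breeds=breeds, freqs=df[breeds].to_numpy().T, panel=df[meta_cols].copy())
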