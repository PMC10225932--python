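"""Tab-separated readers/writers for the pipeline's tables.

Everything is plain TSV with a header row so intermediate files are
inspectable and diffable. Depth profiles use a long format
(individual_id, site_class in {mt, auto}, position, depth); local ancestry
and genotypes are wide matrices with marker metadata columns first.
Genotype dosages can also be written as an uncompressed VCF with a DS
FORMAT field.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .copynumber import DepthProfile
from .simulate import GenotypeMatrix, LocalAncestryMatrix


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_depths(profiles: list[DepthProfile], path) -> None:
    frames = []
    for p in profiles:
        L = p.n_sites
        frames.append(pd.DataFrame({
            "individual_id": p.individual_id,
            "site_class": np.repeat(["mt", "auto"], L),
            "position": np.tile(np.arange(1, L + 1), 2),
            "depth": np.concatenate([p.mt_depths, p.auto_depths]),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depths(path) -> list[DepthProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for ind, grp in df.groupby("individual_id", sort=True):
        mt = grp[grp["site_class"] == "mt"].sort_values("position")["depth"].to_numpy()
        auto = grp[grp["site_class"] == "auto"].sort_values("position")["depth"].to_numpy()
        profiles.append(DepthProfile(str(ind), mt, auto))
    return profiles


def write_local_ancestry(local: LocalAncestryMatrix, path) -> None:
    meta = local.markers[["chrom", "pos", "gpos"]].copy()
    counts = pd.DataFrame(local.counts.T, columns=local.individual_ids)
    pd.concat([meta.reset_index(drop=True), counts], axis=1).to_csv(
        path, sep="\t", index=False)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    meta = g.variants.reset_index(drop=True)
    dos = pd.DataFrame(g.dosages.T, columns=g.individual_ids)
    pd.concat([meta, dos], axis=1).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt", "effect_allele", "freq"]
    ids = np.array([c for c in df.columns if c not in meta_cols])
    return GenotypeMatrix(ids, df[meta_cols].copy(), df[ids].to_numpy(dtype=float).T)


def write_genotypes_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with per-sample DS (dosage) entries, uncompressed."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        chroms = pd.unique(g.variants["chrom"])
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        samples = "\t".join(str(s) for s in g.individual_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, row in g.variants.reset_index(drop=True).iterrows():
            ds = "\t".join(f"{d:.3f}" for d in g.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{row['ref']}\t{row['alt']}\t.\t.\t.\tDS\t{ds}\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a DS-field VCF (as written by :func:`write_genotypes_vcf`) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).ravel()
        rows.append(ds)
        meta.append({"variant_id": var.ID, "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0], "effect_allele": var.ALT[0],
                     "freq": float(ds.mean() / 2.0)})
    return GenotypeMatrix(ids, pd.DataFrame(meta), np.array(rows).T)


def write_prs_weights(weights: pd.DataFrame, path) -> None:
    weights[["variant_id", "effect_allele", "weight"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_prs_weights(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["variant_id", "effect_allele", "weight"])
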