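"""Readers and writers for the standard formats the pipeline touches.

Genotypes travel as HapMap text (with a companion genetic-map TSV) or
VCF (genetic positions in a CM INFO field); phenotypes as long-format
CSV; gene models as GFF3 (parsed with gffutils); LD decay, expression
matrices and result tables as TSV. Dosages are always oriented to the
minor allele (heterozygote = 1), so HapMap and VCF encodings of the
same panel load to identical matrices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

_HAPMAP_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def _orient_minor(dosages: np.ndarray, alleles: list) -> tuple[np.ndarray, list]:
    """Flip markers so dosage counts the minor allele."""
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosages, axis=0) / 2.0
    flip = p > 0.5
    out = dosages.copy()
    out[:, flip] = 2.0 - out[:, flip]
    alleles = [
        (a[1], a[0]) if f else tuple(a) for a, f in zip(alleles, flip)
    ]
    return out, alleles


# ---------------------------------------------------------------- genetic map

def write_map(geno: GenotypeMatrix, path: str) -> None:
    geno.marker_frame().to_csv(path, sep="\t", index=False)


def read_map(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -------------------------------------------------------------------- HapMap

def write_hapmap(geno: GenotypeMatrix, path: str, map_path: str | None = None) -> None:
    """Write HapMap-format text; cM positions go to the companion map TSV."""
    alleles = geno.alleles or [("A", "G")] * geno.n_markers
    with open(path, "w") as fh:
        fh.write("\t".join(_HAPMAP_COLS + list(geno.genotype_ids)) + "\n")
        for j in range(geno.n_markers):
            major, minor = alleles[j]
            calls = []
            for d in geno.dosages[:, j]:
                if np.isnan(d):
                    calls.append("NN")
                elif d == 0:
                    calls.append(major + major)
                elif d == 1:
                    calls.append(major + minor)
                else:
                    calls.append(minor + minor)
            row = [
                geno.marker_ids[j], f"{major}/{minor}", str(geno.chrom[j]),
                str(int(geno.bp[j])), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ] + calls
            fh.write("\t".join(row) + "\n")
    if map_path:
        write_map(geno, map_path)


def read_hapmap(path: str, map_path: str | None = None) -> GenotypeMatrix:
    """Parse HapMap text into a minor-allele dosage matrix.

    Non-biallelic sites are dropped with a logged count. Genetic (cM)
    positions come from the companion map TSV when given, else default
    to 1 cM per Mb.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    sample_cols = df.columns[11:].tolist()
    keep_rows, dosage_rows, alleles = [], [], []
    n_dropped = 0
    for i, row in df.iterrows():
        pair = str(row.iloc[1]).split("/")
        if len(pair) != 2 or pair[0] == pair[1]:
            n_dropped += 1
            continue
        major, minor = pair
        calls = row.iloc[11:].astype(str).to_numpy()
        d = np.full(len(calls), np.nan)
        for k, call in enumerate(calls):
            if call in ("NN", "NA", "--", ""):
                continue
            d[k] = sum(1 for b in call if b == minor)
            if any(b not in (major, minor) for b in call):
                raise ValueError(f"malformed genotype {call!r} at line {i + 2}")
        keep_rows.append(i)
        dosage_rows.append(d)
        alleles.append((major, minor))
    if n_dropped:
        log.info("read_hapmap: dropped %d non-biallelic sites", n_dropped)
    if not keep_rows:
        raise ValueError("no biallelic sites parsed from HapMap file")
    sub = df.loc[keep_rows]
    dosages = np.array(dosage_rows).T
    dosages, alleles = _orient_minor(dosages, alleles)
    bp = sub.iloc[:, 3].astype(np.int64).to_numpy()
    chrom = sub.iloc[:, 2].astype(str).to_numpy()
    marker_ids = sub.iloc[:, 0].tolist()
    cm = bp / 1e6
    if map_path:
        m = read_map(map_path).set_index("marker")
        cm = m.reindex(marker_ids)["cm"].to_numpy(dtype=float)
    order = np.lexsort((bp, chrom))
    return GenotypeMatrix(
        dosages=dosages[:, order],
        genotype_ids=sample_cols,
        marker_ids=[marker_ids[i] for i in order],
        chrom=chrom[order],
        cm=cm[order],
        bp=bp[order],
        alleles=[alleles[i] for i in order],
    )


# ----------------------------------------------------------------------- VCF

def write_vcf(geno: GenotypeMatrix, path: str) -> None:
    """Write diploid GT records; REF=major, ALT=minor, cM in INFO/CM."""
    alleles = geno.alleles or [("A", "G")] * geno.n_markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.genotype_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(geno.n_markers):
            major, minor = alleles[j]
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in geno.dosages[:, j]
            ]
            fh.write(
                f"{geno.chrom[j]}\t{int(geno.bp[j])}\t{geno.marker_ids[j]}\t"
                f"{major}\t{minor}\t.\tPASS\tCM={geno.cm[j]:.6f}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read diploid GT calls into a minor-allele dosage matrix.

    Non-biallelic sites are dropped with a logged count; missing calls
    (./.) become NaN. Genetic positions come from INFO/CM when present,
    else default to 1 cM per Mb.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, chrom, bp, cm, ids, alleles = [], [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        g = np.array([a[:2] for a in v.genotypes], dtype=float)
        g[g < 0] = np.nan
        rows.append(g.sum(axis=1))
        chrom.append(v.CHROM)
        bp.append(v.POS)
        c = v.INFO.get("CM")
        cm.append(float(c) if c is not None else v.POS / 1e6)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        alleles.append((v.REF, v.ALT[0]))
    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic sites", n_dropped)
    if not rows:
        raise ValueError("no biallelic sites parsed from VCF")
    dosages = np.array(rows).T
    dosages, alleles = _orient_minor(dosages, alleles)
    chrom = np.array(chrom)
    bp = np.array(bp, dtype=np.int64)
    cm = np.array(cm, dtype=float)
    order = np.lexsort((bp, chrom))
    return GenotypeMatrix(
        dosages=dosages[:, order],
        genotype_ids=samples,
        marker_ids=[ids[i] for i in order],
        chrom=chrom[order],
        cm=cm[order],
        bp=bp[order],
        alleles=[alleles[i] for i in order],
    )


def read_genotypes(path: str, fmt: str = "auto", map_path: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'hapmap', 'vcf' or 'auto' (by extension)."""
    if fmt == "auto":
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "hapmap"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "hapmap":
        return read_hapmap(path, map_path=map_path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(pheno, path: str) -> None:
    pheno.data.to_csv(path, index=False)


def read_phenotypes(path: str):
    from .simulate import PlotPhenotypes

    df = pd.read_csv(path, comment="#")
    return PlotPhenotypes(data=df)


# --------------------------------------------------------------- other TSVs

def read_ld_decay(path: str) -> dict[str, float]:
    """Per-chromosome LD-decay distances (cM): TSV with chrom, ld_decay_cm."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    chrom_col = cols.get("chrom") or df.columns[0]
    val_col = cols.get("ld_decay_cm") or df.columns[1]
    return dict(zip(df[chrom_col].astype(str), df[val_col].astype(float)))


def read_expression(values_path: str, meta_path: str):
    """Expression TSV (gene x condition TPM) plus condition metadata TSV."""
    from .genes import ExpressionProfile

    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionProfile(values=values, meta=meta)


def read_gff3_genes(path: str) -> pd.DataFrame:
    """Gene models from GFF3: gene_id, chrom, start, end, strand, description."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for g in db.features_of_type("gene"):
        desc = ""
        for key in ("description", "Note", "product", "Name"):
            if key in g.attributes:
                desc = g.attributes[key][0]
                break
        rows.append(
            {
                "gene_id": g.id,
                "chrom": g.seqid,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "description": desc,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "description"]
    )


def write_hotspot_bed(hotspots, path: str) -> None:
    """Physical spans of hotspots as BED (0-based half-open intervals)."""
    with open(path, "w") as fh:
        for h in hotspots:
            bps = h.members["bp"]
            if bps.empty:
                continue
            fh.write(f"{h.chrom}\t{int(bps.min()) - 1}\t{int(bps.max())}\t{h.id}\n")
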