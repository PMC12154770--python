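"""Text-format IO: founder VCF, sync/TSV pool counts, metadata and results.

All formats are plain text so a full simulated experiment can be written,
inspected and re-read without any binary tooling: founder genotypes as a
haploid-coded VCF plus a climate CSV, pooled counts in PoPoolation2-style
sync format (A:T:C:G:N:del per sample) or a simple per-sample TSV, and tidy
TSV/CSV outputs for every downstream table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FounderPanel
from .poolfreq import AccessionFrequencyTable, FrequencyTable, PoolSample

logger = logging.getLogger(__name__)

__all__ = [
    "write_founder_vcf",
    "read_founder_vcf",
    "write_climate_csv",
    "read_climate_csv",
    "write_sync",
    "read_sync",
    "write_sample_tsv",
    "read_sample_tsv",
    "write_metadata_csv",
    "read_metadata_csv",
    "write_census_csv",
    "write_freq_tsv",
    "write_accfreq_tsv",
]

_REF, _ALT = "A", "T"
_SYNC_ORDER = "ATCGN"  # + del


def write_founder_vcf(panel: FounderPanel, path: str | Path) -> None:
    """Founder genotypes as a VCF with haploid-coded homozygous GT calls.

    Dosage 0 -> GT "0", 1 -> "1", missing -> ".", residual heterozygotes
    (dosage 0.5) -> "0/1".  REF/ALT bases are placeholders (A/T): only the
    biallelic dosage matters downstream.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.snp_chrom):
            length = int(panel.snp_pos[panel.snp_chrom == chrom].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.accession_ids) + "\n"
        )
        code = {0.0: "0", 1.0: "1", 0.5: "0/1"}
        for s in range(panel.n_snps):
            gts = [
                "." if np.isnan(g) else code[float(g)]
                for g in panel.genotypes[:, s]
            ]
            fh.write(
                f"{panel.snp_chrom[s]}\t{panel.snp_pos[s]}\tsnp{s}\t{_REF}\t{_ALT}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_founder_vcf(
    vcf_path: str | Path,
    climate_csv: str | Path | None = None,
    start_freq: np.ndarray | None = None,
) -> FounderPanel:
    """Read a founder panel from VCF (+ optional accession climate CSV)."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    accession_ids = list(vcf.samples)
    chroms, pos, rows = [], [], []
    for v in vcf:
        chroms.append(v.CHROM)
        pos.append(v.POS)
        dos = []
        for g in v.genotypes:
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            dos.append(np.nan if not alleles else float(np.mean(alleles)))
        rows.append(dos)
    geno = np.asarray(rows, float).T  # accessions x SNPs
    if climate_csv is not None:
        z = read_climate_csv(climate_csv).loc[accession_ids]
    else:
        z = pd.DataFrame(index=accession_ids)
    n = len(accession_ids)
    sf = np.full(n, 1.0 / n) if start_freq is None else np.asarray(start_freq, float)
    return FounderPanel(
        accession_ids=accession_ids,
        genotypes=geno,
        snp_chrom=np.asarray(chroms),
        snp_pos=np.asarray(pos, int),
        z_origin=z,
        start_freq=sf,
    )


def write_climate_csv(z: pd.DataFrame, path: str | Path, index_name: str = "id") -> None:
    z.rename_axis(index_name).to_csv(path)


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sync(
    samples: list[PoolSample],
    panel: FounderPanel,
    path: str | Path,
) -> None:
    """PoPoolation2-style sync file: chrom, pos, ref, A:T:C:G:N:del columns."""
    with Path(path).open("w") as fh:
        for s in range(panel.n_snps):
            cols = [str(panel.snp_chrom[s]), str(panel.snp_pos[s]), _REF]
            for sample in samples:
                counts = {b: 0 for b in _SYNC_ORDER}
                counts[_REF] = int(sample.ref_count[s])
                counts[_ALT] = int(sample.alt_count[s])
                cols.append(":".join(str(counts[b]) for b in _SYNC_ORDER) + ":0")
            fh.write("\t".join(cols) + "\n")


def read_sync(
    path: str | Path,
    sample_ids: list[str],
    metadata: pd.DataFrame | None = None,
) -> list[PoolSample]:
    """Read sync counts, collapsing multi-allelic sites to ref vs top alt.

    The most frequent non-reference base (summed over samples) becomes the
    alt allele; reads supporting other bases are dropped and the number of
    affected sites is logged.
    """
    chroms, pos, refs, per_sample = [], [], [], []
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            chroms.append(parts[0])
            pos.append(int(parts[1]))
            refs.append(parts[2])
            per_sample.append(
                [list(map(int, c.split(":"))) for c in parts[3 : 3 + len(sample_ids)]]
            )
    counts = np.asarray(per_sample)  # (snps, samples, 6)
    base_idx = {b: i for i, b in enumerate(_SYNC_ORDER)}
    n_multi = 0
    ref_counts = np.zeros(counts.shape[:2], int)
    alt_counts = np.zeros(counts.shape[:2], int)
    for s, ref in enumerate(refs):
        ri = base_idx.get(ref.upper(), 0)
        totals = counts[s].sum(axis=0)
        order = np.argsort(totals)[::-1]
        alt_i = next(i for i in order if i != ri)
        others = [i for i in range(6) if i not in (ri, alt_i)]
        if counts[s][:, others].sum() > 0:
            n_multi += 1
        ref_counts[s] = counts[s][:, ri]
        alt_counts[s] = counts[s][:, alt_i]
    if n_multi:
        logger.info("collapsed %d multi-allelic sync sites to ref vs top alt", n_multi)
    out = []
    for j, sid in enumerate(sample_ids):
        meta = {}
        if metadata is not None and sid in metadata.index:
            row = metadata.loc[sid]
            meta = {k: row[k] for k in ("garden", "replicate", "generation", "flowers")
                    if k in row.index}
        out.append(PoolSample(sample_id=sid, ref_count=ref_counts[:, j],
                              alt_count=alt_counts[:, j], **meta))
    return out


def write_sample_tsv(sample: PoolSample, panel: FounderPanel, path: str | Path) -> None:
    pd.DataFrame({
        "chrom": panel.snp_chrom, "pos": panel.snp_pos,
        "ref_count": sample.ref_count, "alt_count": sample.alt_count,
    }).to_csv(path, sep="\t", index=False)


def read_sample_tsv(path: str | Path, sample_id: str, **metadata) -> PoolSample:
    df = pd.read_csv(path, sep="\t")
    return PoolSample(sample_id=sample_id, ref_count=df.ref_count.to_numpy(),
                      alt_count=df.alt_count.to_numpy(), **metadata)


def write_metadata_csv(samples: list[PoolSample], path: str | Path) -> None:
    pd.DataFrame([s.metadata() for s in samples]).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("sample_id")


def write_census_csv(census: dict[str, np.ndarray], path: str | Path) -> None:
    """Census counts, one row per garden x replicate x generation."""
    rows = []
    for gid, arr in census.items():
        for r in range(arr.shape[0]):
            for t in range(arr.shape[1]):
                rows.append({"garden": gid, "replicate": r, "generation": t,
                             "census": int(arr[r, t])})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_freq_tsv(
    table: FrequencyTable, panel: FounderPanel, path: str | Path
) -> None:
    """Long-format allele frequencies: sample_id, chrom, pos, freq, depth."""
    frames = []
    for i, sid in enumerate(table.sample_ids):
        frames.append(pd.DataFrame({
            "sample_id": sid, "chrom": panel.snp_chrom, "pos": panel.snp_pos,
            "freq": table.freq[i], "depth": table.depth[i],
        }))
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_accfreq_tsv(table: AccessionFrequencyTable, path: str | Path) -> None:
    long = (
        table.to_frame()
        .rename_axis("sample_id")
        .reset_index()
        .melt(id_vars="sample_id", var_name="accession_id", value_name="freq")
    )
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")
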