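"""VCF reading/writing helpers shared across modules.

Reading goes through pysam; writing of simulated single-sample files is
plain text with a fixed 4.2 header so that identical inputs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_allele(seq: str) -> str:
    """Complement an allele sequence base-by-base (no reversal: array strand
    flips complement each base in place)."""
    return "".join(COMPLEMENT.get(b, "N") for b in seq)


def read_vcf_records(path: str | Path) -> pd.DataFrame:
    """Load VCF records into a DataFrame.

    Columns: chrom, pos, ref, alt, gt (alt-allele count, -1 if no/partial
    call), n_alt (number of ALT alleles in the record — >1 flags an unsplit
    multiallelic record, whose alt column holds the first ALT).
    """
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            alt = alts[0] if alts else "."
            gt = -1
            if samples:
                call = rec.samples[samples[0]].get("GT")
                if call is not None and None not in call:
                    gt = sum(1 for a in call if a and a > 0)
            rows.append((rec.chrom, rec.pos, rec.ref, alt, gt, len(alts)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt", "n_alt"])


def _contigs(chroms: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(str(c), None)
    return list(seen)


def write_sample_vcf(records: pd.DataFrame, sample_id: str, path: str | Path) -> None:
    """Write a single-sample VCF 4.2.

    ``records`` needs columns chrom, pos, ref, alt, gt with gt in {1,2}
    (0/1 or 1/1 calls); records are written in the given order.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popaf simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in _contigs(records["chrom"]):
            fh.write(f"##contig=<ID={chrom},length=250000000>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for rec in records.itertuples(index=False):
            gt_str = "0/1" if rec.gt == 1 else "1/1"
            fh.write(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gt_str}\n")


def complement_vcf(path_in: str | Path, path_out: str | Path) -> None:
    """Rewrite a VCF with every REF/ALT base complemented (whole-file strand
    flip); header and genotypes are untouched."""
    with open(path_in) as src, open(path_out, "w") as dst:
        for line in src:
            if line.startswith("#"):
                dst.write(line)
                continue
            f = line.rstrip("\n").split("\t")
            f[3] = revcomp_allele(f[3])
            f[4] = ",".join(revcomp_allele(a) for a in f[4].split(","))
            dst.write("\t".join(f) + "\n")


def read_sites(path: str | Path) -> set[tuple]:
    """Read a known-sites set keyed by (chrom,pos,ref,alt).

    Accepts a TSV with those four columns or a sites-VCF.
    """
    path = Path(path)
    head = path.open().readline()
    if head.startswith("##fileformat=VCF"):
        df = read_vcf_records(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["pos"] = df["pos"].astype(int)
    return set(zip(df["chrom"].astype(str), df["pos"], df["ref"], df["alt"]))


def write_sites(keys: Iterable[tuple], path: str | Path) -> None:
    df = pd.DataFrame(sorted(keys), columns=["chrom", "pos", "ref", "alt"])
    df.to_csv(path, sep="\t", index=False)
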