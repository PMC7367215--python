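"""Array-cohort genotype container and local allele-frequency panels.

The array cohort provides the *breadth*: hundreds of thousands to millions
of genotyped loci over many samples. This module holds the samples-by-loci
genotype matrix, computes per-locus alt-allele frequencies (AF) and allele
numbers (AN) with missing genotypes excluded, and writes the result as a
local AF panel usable as an annotation source (TSV or sites-VCF with
``AF``/``AN`` INFO keys).

AF is the alt-allele frequency relative to the declared ref/alt pair in the
panel's own strand convention; strand reconciliation against other data
sets is the concordance module's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype code for a missing call (codes 0/1/2 count alt alleles)
MISSING: int = -1

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


class InputError(ValueError):
    """Raised for structurally invalid inputs (empty matrix, bad codes...)."""


def _check_locus_frame(loci: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in LOCUS_COLUMNS if c not in loci.columns]
    if missing_cols:
        raise InputError(f"locus table lacks columns: {missing_cols}")
    keys = list(zip(loci["chrom"], loci["pos"], loci["ref"], loci["alt"]))
    if len(set(keys)) != len(keys):
        raise InputError("locus keys (chrom,pos,ref,alt) are not unique")
    return loci.reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Samples × biallelic loci, codes {0,1,2,MISSING} counting alt alleles."""

    sample_ids: list[str]
    loci: pd.DataFrame  # columns chrom, pos (1-based), ref, alt
    genotypes: np.ndarray  # int8, shape (n_samples, n_loci)

    def __post_init__(self) -> None:
        self.loci = _check_locus_frame(self.loci)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.loci)):
            raise InputError(
                f"genotype shape {self.genotypes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise InputError(f"{int(bad.sum())} genotype codes outside {{0,1,2,{MISSING}}}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_keys(self) -> list[tuple]:
        return list(zip(self.loci["chrom"], self.loci["pos"], self.loci["ref"], self.loci["alt"]))

    def sample_row(self, sample: str | int) -> np.ndarray:
        idx = sample if isinstance(sample, (int, np.integer)) else self.sample_ids.index(sample)
        return self.genotypes[int(idx)]

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write a samples×loci TSV, loci as ``chrom:pos:ref:alt`` columns."""
        cols = [f"{c}:{p}:{r}:{a}" for c, p, r, a in self.locus_keys()]
        df = pd.DataFrame(self.genotypes, index=self.sample_ids, columns=cols)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        parts = [c.split(":") for c in df.columns]
        loci = pd.DataFrame(parts, columns=LOCUS_COLUMNS)
        loci["pos"] = loci["pos"].astype(int)
        return cls(list(df.index.astype(str)), loci, df.to_numpy(dtype=np.int8))

    @classmethod
    def from_plink(cls, ped_path: str | Path, map_path: str | Path) -> "GenotypeMatrix":
        """Read PLINK text ped/map.

        ped alleles are unordered and carry no ref/alt designation; the major
        allele is taken as ref and the minor as alt (ties broken
        alphabetically). ``0`` alleles are missing.
        """
        mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                         names=["chrom", "id", "cm", "pos"], dtype={"chrom": str})
        n_loci = len(mp)
        sample_ids: list[str] = []
        allele_rows: list[list[str]] = []
        with open(ped_path) as fh:
            for line in fh:
                f = line.split()
                if not f:
                    continue
                if len(f) != 6 + 2 * n_loci:
                    raise InputError(
                        f"ped row for {f[1] if len(f) > 1 else '?'} has "
                        f"{len(f) - 6} allele fields, expected {2 * n_loci}"
                    )
                sample_ids.append(f[1])
                allele_rows.append(f[6:])
        alleles = np.array(allele_rows, dtype="U8").reshape(len(sample_ids), n_loci, 2)
        refs, alts = [], []
        geno = np.full((len(sample_ids), n_loci), MISSING, dtype=np.int8)
        for m in range(n_loci):
            col = alleles[:, m, :]
            called = col[col != "0"]
            uniq, counts = np.unique(called, return_counts=True)
            if len(uniq) > 2:
                raise InputError(f"locus {mp['id'][m]} has >2 alleles in ped")
            if len(uniq) == 0:
                refs.append("N")
                alts.append("N")
                continue
            order = np.lexsort((uniq, -counts))  # major first, ties alphabetical
            ref = uniq[order[0]]
            alt = uniq[order[1]] if len(uniq) == 2 else "N"
            refs.append(ref)
            alts.append(alt)
            full = (col != "0").all(axis=1)
            geno[full, m] = (col[full] == alt).sum(axis=1)
        loci = pd.DataFrame({"chrom": mp["chrom"].astype(str), "pos": mp["pos"].astype(int),
                             "ref": refs, "alt": alts})
        return cls(sample_ids, loci, geno)


@dataclass
class AFPanel:
    """Per-locus allele frequency + allele number for one named population."""

    population: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns chrom, pos, ref, alt, af, an

    def __post_init__(self) -> None:
        if len(self.records):
            self.records = _check_locus_frame(self.records)
            af = self.records["af"].to_numpy(float)
            an = self.records["an"].to_numpy(float)
            if ((af < 0) | (af > 1)).any():
                raise InputError("panel af outside [0,1]")
            if (an < 0).any():
                raise InputError("panel an negative")

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self) -> dict[tuple, tuple[float, float]]:
        """Map (chrom,pos,ref,alt) → (af, an)."""
        r = self.records
        return {
            (c, p, rf, al): (float(f), float(n))
            for c, p, rf, al, f, n in zip(r["chrom"], r["pos"], r["ref"], r["alt"], r["af"], r["an"])
        }

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, population: str | None = None) -> "AFPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        df["pos"] = df["pos"].astype(int)
        name = population or Path(path).stem
        return cls(name, df)

    def to_sites_vcf(self, path: str | Path) -> None:
        """Write the panel as a sites-only VCF with AF/AN INFO keys."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##source=popaf cohort_af panel population={self.population}\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">\n')
            fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Called allele number">\n')
            for chrom in pd.unique(self.records["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for rec in self.records.itertuples(index=False):
                fh.write(
                    f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t"
                    f"AF={rec.af:.6g};AN={int(rec.an)}\n"
                )


# ---------------------------------------------------------------- operations

def locus_af(genotypes: Sequence[int] | np.ndarray) -> tuple[float, int]:
    """Alt-allele frequency and allele number at one locus.

    Missing genotypes are excluded from numerator and denominator:
    af = (#alt alleles) / (2 · #called samples), an = 2 · #called.
    """
    g = np.asarray(genotypes)
    called = g != MISSING
    an = 2 * int(called.sum())
    if an == 0:
        raise InputError("all genotypes missing at locus")
    af = float(g[called].sum()) / an
    return af, an


def build_panel(
    g: GenotypeMatrix, population: str, min_call_rate: float = 0.95
) -> AFPanel:
    """Compute the cohort AF panel from the array genotype matrix.

    Loci whose call rate falls below ``min_call_rate`` (or with zero calls)
    are dropped; the dropped count is logged. Output is sorted by
    (chrom, pos).
    """
    if g.n_samples == 0 or g.n_loci == 0:
        raise InputError("empty genotype matrix")
    geno = g.genotypes
    called = geno != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / g.n_samples
    keep = (n_called > 0) & (call_rate >= min_call_rate)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_panel: dropped %d/%d loci below call rate %.3g",
                    n_dropped, g.n_loci, min_call_rate)
    alt_counts = np.where(called, geno, 0).sum(axis=0)
    an = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(an > 0, alt_counts / np.maximum(an, 1), np.nan)
    rec = g.loci.loc[keep, LOCUS_COLUMNS].copy()
    rec["af"] = af[keep]
    rec["an"] = an[keep]
    rec = rec.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return AFPanel(population, rec)


def combine_panels(panels: Iterable[AFPanel], name: str = "combined") -> AFPanel:
    """Pool several reference panels into one by allele-count-weighted AF.

    At each locus the pooled AF is Σ af_i·an_i / Σ an_i over the panels that
    carry the locus, and the pooled AN is Σ an_i.
    """
    frames = []
    for p in panels:
        df = p.records[LOCUS_COLUMNS + ["af", "an"]].copy()
        df["ac"] = df["af"] * df["an"]
        frames.append(df)
    if not frames:
        raise InputError("no panels to combine")
    allrec = pd.concat(frames, ignore_index=True)
    grouped = allrec.groupby(LOCUS_COLUMNS, sort=False, as_index=False).agg(
        ac=("ac", "sum"), an=("an", "sum")
    )
    grouped["af"] = np.where(grouped["an"] > 0, grouped["ac"] / grouped["an"].clip(lower=1), 0.0)
    out = grouped[LOCUS_COLUMNS + ["af", "an"]].sort_values(
        ["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return AFPanel(name, out)
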