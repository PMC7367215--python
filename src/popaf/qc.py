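"""Per-sample variant QC metrics and the multi-sample share partition.

Sanity metrics for a called genome: SNP/indel composition, the Het:Hom
ratio (≈2:1 in outbred populations, depressed by consanguinity), the Ti/Tv
ratio (≈2.05 genome-wide in human; 0.5 for random substitutions, so a
strong caller-quality signal) split by known/novel status, and the exact
presence/absence partition of variants across a set of samples.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .cohort_af import InputError
from .vcfio import read_vcf_records

TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_variant(ref: str, alt: str) -> str:
    """SNP iff both alleles are single bases; else insertion/deletion by
    ALT-vs-REF length."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "insertion" if len(alt) > len(ref) else "deletion"


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    return {ref, alt} in TRANSITIONS


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


@dataclass
class SampleQCReport:
    sample: str
    total_variants: int
    n_snp: int
    n_indel: int
    n_het: int
    n_hom: int
    het_fraction: float
    hom_fraction: float
    het_hom_ratio: float
    titv_all: float
    titv_known: float
    titv_novel: float
    n_known: int
    n_novel: int
    n_rejected_multiallelic: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _titv(snps: pd.DataFrame) -> float:
    if not len(snps):
        return float("nan")
    ti = sum(is_transition(r, a) for r, a in zip(snps["ref"], snps["alt"]))
    return _ratio(ti, len(snps) - ti)


def sample_qc(vcf: str | Path, known_sites: set[tuple] | None = None,
              het_hom_over: str = "all") -> SampleQCReport:
    """Compute the per-sample QC report.

    Het counts genotype 0/1, Hom counts 1/1 (phase-insensitive; half-calls
    are treated as missing and excluded from the Het/Hom denominators).
    Ti/Tv is computed over SNPs only, overall and split by known/novel
    status — exact (chrom,pos,ref,alt) membership in ``known_sites``.
    ``het_hom_over`` selects the Het/Hom denominator: all biallelic
    variant records (default) or ``"snp"`` for SNPs only.
    """
    df = read_vcf_records(vcf)
    if len(df) and (df["gt"] == -1).all():
        raise InputError(f"{vcf}: no usable GT field")
    multi = df["n_alt"] > 1
    n_multi = int(multi.sum())
    df = df[~multi].copy()
    known = known_sites or set()
    df["key"] = list(zip(df["chrom"].astype(str), df["pos"], df["ref"], df["alt"]))
    df["is_known"] = [k in known for k in df["key"]]
    df["vtype"] = [classify_variant(r, a) for r, a in zip(df["ref"], df["alt"])]
    snp = df[df["vtype"] == "SNP"]
    hh = snp if het_hom_over == "snp" else df
    hh = hh[hh["gt"] > 0]
    n_het = int((hh["gt"] == 1).sum())
    n_hom = int((hh["gt"] == 2).sum())
    n_known = int(df["is_known"].sum())
    return SampleQCReport(
        sample=Path(vcf).stem,
        total_variants=len(df),
        n_snp=len(snp),
        n_indel=len(df) - len(snp),
        n_het=n_het,
        n_hom=n_hom,
        het_fraction=_ratio(n_het, n_het + n_hom),
        hom_fraction=_ratio(n_hom, n_het + n_hom),
        het_hom_ratio=_ratio(n_het, n_hom),
        titv_all=_titv(snp),
        titv_known=_titv(snp[snp["is_known"]]),
        titv_novel=_titv(snp[~snp["is_known"]]),
        n_known=n_known,
        n_novel=len(df) - n_known,
        n_rejected_multiallelic=n_multi,
    )


@dataclass
class SharePartition:
    """Counts over the 2^S - 1 nonempty presence subsets of S samples.

    ``subset_counts`` is keyed by bitmask over ``sample_ids`` order (bit i
    set = variant present in sample i).
    """

    sample_ids: list[str]
    subset_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_union(self) -> int:
        return sum(self.subset_counts.values())

    @property
    def shared_all(self) -> int:
        full = (1 << len(self.sample_ids)) - 1
        return self.subset_counts.get(full, 0)

    @property
    def distinct_per_sample(self) -> dict[str, int]:
        return {
            sid: self.subset_counts.get(1 << i, 0)
            for i, sid in enumerate(self.sample_ids)
        }

    def sample_total(self, sample: str) -> int:
        i = self.sample_ids.index(sample)
        return sum(c for mask, c in self.subset_counts.items() if mask >> i & 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mask in sorted(self.subset_counts):
            members = [s for i, s in enumerate(self.sample_ids) if mask >> i & 1]
            rows.append((mask, ",".join(members), self.subset_counts[mask]))
        return pd.DataFrame(rows, columns=["bitmask", "samples", "count"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def share_partition(vcfs: Sequence[str | Path],
                    sample_ids: Sequence[str] | None = None) -> SharePartition:
    """Partition the union of variants by their presence subset.

    Variants are keyed by (chrom,pos,ref,alt); every member of the union
    lands in exactly one subset cell, so the cells sum to the union size.
    """
    ids = list(sample_ids) if sample_ids else [Path(p).stem for p in vcfs]
    if len(ids) != len(vcfs):
        raise InputError("sample_ids length must match vcfs")
    masks: dict[tuple, int] = {}
    for i, path in enumerate(vcfs):
        df = read_vcf_records(path)
        for key in zip(df["chrom"].astype(str), df["pos"], df["ref"], df["alt"]):
            masks[key] = masks.get(key, 0) | (1 << i)
    counts: dict[int, int] = {}
    for mask in masks.values():
        counts[mask] = counts.get(mask, 0) + 1
    return SharePartition(sample_ids=ids, subset_counts=counts)


def pairwise_shared(part: SharePartition) -> dict[tuple[str, str], int]:
    """Convenience: variants present in both members of each sample pair."""
    out = {}
    for (i, a), (j, b) in combinations(enumerate(part.sample_ids), 2):
        out[(a, b)] = sum(
            c for mask, c in part.subset_counts.items()
            if mask >> i & 1 and mask >> j & 1
        )
    return out
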