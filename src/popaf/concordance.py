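"""Array-vs-WGS genotype concordance with the standard filter cascade.

Array genotypes validate sequencing calls only after removing loci where
the comparison is ill-defined: missing array calls, indels, multiallelic
records, palindromic (A/T, C/G) variants whose strand cannot be inferred
from the alleles ("strand confusion"), and loci whose allele pairs cannot
be reconciled even after complementing and/or swapping ref/alt. The
remaining intersection with the WGS SNV calls is compared genotype by
genotype (allele-level comparison available as a flag) and reported as a
percentage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .cohort_af import MISSING, GenotypeMatrix, InputError
from .vcfio import read_vcf_records, revcomp_allele

PALINDROMIC = ({"A", "T"}, {"C", "G"})

RECONCILE_CATEGORIES = ("match", "flip_match", "swap_match", "flip_swap_match", "unresolved")


def is_palindromic(ref: str, alt: str) -> bool:
    """A/T and C/G pairs are their own reverse complement, so array strand
    cannot be resolved from the alleles alone."""
    return {ref, alt} in PALINDROMIC


def reconcile_alleles(array: tuple[str, str], wgs: tuple[str, str]) -> str:
    """Classify how the WGS allele pair maps onto the array pair.

    Categories are tried in priority order: exact match; complement
    (flip_match); ref/alt exchanged (swap_match, genotypes recode
    g -> 2 - g); complement plus exchange (flip_swap_match); unresolved.
    """
    a_ref, a_alt = array
    w_ref, w_alt = wgs
    if (w_ref, w_alt) == (a_ref, a_alt):
        return "match"
    if (revcomp_allele(w_ref), revcomp_allele(w_alt)) == (a_ref, a_alt):
        return "flip_match"
    if (w_alt, w_ref) == (a_ref, a_alt):
        return "swap_match"
    if (revcomp_allele(w_alt), revcomp_allele(w_ref)) == (a_ref, a_alt):
        return "flip_swap_match"
    return "unresolved"


@dataclass
class ConcordanceReport:
    sample: str
    n_array_loci: int
    dropped_missing: int
    dropped_indel: int
    dropped_multiallelic: int
    dropped_palindromic: int
    dropped_unresolved_strand: int
    absent_from_vcf: int
    n_compared: int
    n_agree: int
    n_strand_flipped: int
    concordance_pct: float | None
    status: str = "ok"  # "undefined" when nothing was comparable

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def concordance(
    array: GenotypeMatrix,
    sample: str | int,
    wgs_vcf: str | Path,
    allele_level: bool = False,
) -> ConcordanceReport:
    """Compare one sample's array genotypes with its WGS calls.

    The filter cascade runs in order (missing → indel → multiallelic →
    palindromic → allele reconciliation); every array locus lands in
    exactly one of dropped_*, compared, or absent_from_vcf. Array loci
    absent from the VCF are excluded rather than assumed hom-ref
    (intersection semantics). With ``allele_level`` the agreement is
    counted over the 2 alleles per genotype instead of whole genotypes.
    """
    g = array.sample_row(sample)
    sample_name = array.sample_ids[sample] if isinstance(sample, (int, np.integer)) else sample
    wgs = read_vcf_records(wgs_vcf)
    by_pos: dict[tuple, list] = {}
    for rec in wgs.itertuples(index=False):
        by_pos.setdefault((str(rec.chrom), int(rec.pos)), []).append(rec)

    drops = dict.fromkeys(
        ("missing", "indel", "multiallelic", "palindromic", "unresolved_strand"), 0)
    absent = 0
    n_cmp = 0
    n_agree = 0
    n_flip = 0
    for m, locus in enumerate(array.loci.itertuples(index=False)):
        a_ref, a_alt = locus.ref, locus.alt
        if g[m] == MISSING:
            drops["missing"] += 1
            continue
        if len(a_ref) != 1 or len(a_alt) != 1:
            drops["indel"] += 1
            continue
        if is_palindromic(a_ref, a_alt):
            drops["palindromic"] += 1
            continue
        recs = by_pos.get((str(locus.chrom), int(locus.pos)))
        if not recs:
            absent += 1
            continue
        if len(recs) > 1 or recs[0].n_alt > 1:
            drops["multiallelic"] += 1
            continue
        rec = recs[0]
        if len(rec.ref) != 1 or len(rec.alt) != 1:
            drops["indel"] += 1
            continue
        cat = reconcile_alleles((a_ref, a_alt), (rec.ref, rec.alt))
        if cat == "unresolved":
            drops["unresolved_strand"] += 1
            continue
        wgs_g = rec.gt
        if wgs_g < 0:
            drops["missing"] += 1
            continue
        if cat in ("swap_match", "flip_swap_match"):
            wgs_g = 2 - wgs_g
        if cat in ("flip_match", "flip_swap_match"):
            n_flip += 1
        if allele_level:
            n_cmp += 2
            n_agree += 2 - abs(int(g[m]) - wgs_g)
        else:
            n_cmp += 1
            n_agree += int(int(g[m]) == wgs_g)
    pct = 100.0 * n_agree / n_cmp if n_cmp else None
    return ConcordanceReport(
        sample=sample_name,
        n_array_loci=array.n_loci,
        dropped_missing=drops["missing"],
        dropped_indel=drops["indel"],
        dropped_multiallelic=drops["multiallelic"],
        dropped_palindromic=drops["palindromic"],
        dropped_unresolved_strand=drops["unresolved_strand"],
        absent_from_vcf=absent,
        n_compared=n_cmp,
        n_agree=n_agree,
        n_strand_flipped=n_flip,
        concordance_pct=pct,
        status="ok" if n_cmp else "undefined",
    )
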