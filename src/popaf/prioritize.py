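"""Z-score variant prioritization against local and reference AF panels.

A variant's local (array-derived) allele frequency p1 with allele number n1
is compared with a reference-population frequency p2, n2 through the pooled
two-proportion statistic

    pbar = (p1 n1 + p2 n2) / (n1 + n2)
    z    = (p1 - p2) / sqrt( pbar (1 - pbar) (1/n1 + 1/n2) )

with n counted in alleles. Positive z means the variant is more common
locally than in the reference; strongly negative z marks variants rare in
the local population, which deserve extra scrutiny. Cutpoints |z| >= 1.96
and |z| >= 4 define the rarity tiers, ties at a threshold falling into the
tail.

The statistic is used comparatively (to rank and tier variants), not
inferentially, so no continuity correction is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .cohort_af import AFPanel, InputError, combine_panels
from .qc import classify_variant

logger = logging.getLogger(__name__)

#: default reference allele number when a panel lacks AN
#: (125,748 diploid samples — a gnomAD-exome-sized aggregate)
DEFAULT_REF_AN = 2 * 125_748

STRONG_Z = 4.0
WEAK_Z = 1.96

TIERS = ("rare_strong", "rare", "neutral", "common", "common_strong", "unscored")


def zscore(p1, n1, p2, n2):
    """Pooled two-proportion Z statistic (vectorized).

    Degenerate pooled proportions (pbar of 0 or 1, where both samples are
    fixed for the same allele) give z = 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 <= 0).any() or (n2 <= 0).any():
        raise InputError("allele numbers must be positive")
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    var = pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    return z if z.ndim else float(z)


def tier_from_z(z: float | None, strong: float = STRONG_Z, weak: float = WEAK_Z) -> str:
    """Map a governing z to its rarity tier; None means unscored."""
    if z is None:
        return "unscored"
    if z <= -strong:
        return "rare_strong"
    if z <= -weak:
        return "rare"
    if z >= strong:
        return "common_strong"
    if z >= weak:
        return "common"
    return "neutral"


@dataclass(frozen=True)
class AFComparison:
    """One local-vs-reference frequency comparison."""

    ref_pop: str
    local_af: float
    local_an: float
    ref_af: float
    ref_an: float
    z: float


def governing_z(comparisons: Sequence[AFComparison], mode: str = "global") -> float | None:
    """Collapse per-population comparisons into the governing z.

    ``global``: expects a single comparison against the combined panel.
    ``strictest_vs_all``: the variant counts as deviating only if it
    deviates in the same direction from *every* reference population; the
    governing z is then the per-population z of minimum magnitude, else 0.
    """
    if not comparisons:
        return None
    zs = [c.z for c in comparisons]
    if mode == "global":
        if len(zs) != 1:
            raise InputError("global mode expects a single combined comparison")
        return zs[0]
    if mode == "strictest_vs_all":
        signs = {np.sign(z) for z in zs}
        if len(signs) > 1 or signs == {0.0}:
            return 0.0
        return min(zs, key=abs)
    raise InputError(f"unknown aggregation mode: {mode}")


@dataclass
class AnnotatedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gt: int
    variant_type: str  # SNP / insertion / deletion
    comparisons: list[AFComparison] = field(default_factory=list)
    z_gov: float | None = None
    tier: str = "unscored"
    novelty: str = "novel"
    clinvar_class: str = "benign"
    sift_deleterious: bool = False
    polyphen_deleterious: bool = False
    protein_altering: bool = False

    @property
    def scored(self) -> bool:
        return self.tier != "unscored"

    @property
    def clinvar_non_benign(self) -> bool:
        return self.clinvar_class in ("non_benign", "pathogenic_or_risk")

    @property
    def clinvar_pathogenic_or_risk(self) -> bool:
        return self.clinvar_class == "pathogenic_or_risk"

    @property
    def sift_or_polyphen_deleterious(self) -> bool:
        return self.sift_deleterious or self.polyphen_deleterious


# category name -> (membership attribute or None for all scored, tail threshold)
SUMMARY_CATEGORIES: dict[str, tuple[str | None, float]] = {
    "local_af": (None, STRONG_Z),
    "clinvar_non_benign": ("clinvar_non_benign", WEAK_Z),
    "clinvar_pathogenic_or_risk": ("clinvar_pathogenic_or_risk", WEAK_Z),
    "sift_deleterious": ("sift_deleterious", WEAK_Z),
    "sift_or_polyphen_deleterious": ("sift_or_polyphen_deleterious", WEAK_Z),
    "protein_altering": ("protein_altering", WEAK_Z),
}


@dataclass
class PrioritySummary:
    """Tier-by-pathogenicity crosstab over the scored variants.

    For each annotation category the three cells are the count of scored
    category members (``all``), those with z <= -t (``z_le``) and those with
    z >= t (``z_ge``); t is 4 for the bare local-AF category and 1.96 for
    annotation categories.
    """

    cells: dict[str, dict[str, int]]
    n_unscored: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat, c in self.cells.items():
            _, t = SUMMARY_CATEGORIES[cat]
            rows.append((cat, t, c["all"], c["z_le"], c["z_ge"]))
        return pd.DataFrame(rows, columns=["category", "threshold", "all", "z_le", "z_ge"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"cells": self.cells, "n_unscored": self.n_unscored}, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def summarize(variants: Iterable[AnnotatedVariant],
              strong: float = STRONG_Z, weak: float = WEAK_Z) -> PrioritySummary:
    """Tally the summary table from an annotated variant stream."""
    cells = {cat: {"all": 0, "z_le": 0, "z_ge": 0} for cat in SUMMARY_CATEGORIES}
    n_unscored = 0
    for v in variants:
        if not v.scored:
            n_unscored += 1
            continue
        z = v.z_gov
        for cat, (attr, _t) in SUMMARY_CATEGORIES.items():
            t = strong if cat == "local_af" else weak
            if attr is not None and not getattr(v, attr):
                continue
            cells[cat]["all"] += 1
            if z <= -t:
                cells[cat]["z_le"] += 1
            elif z >= t:
                cells[cat]["z_ge"] += 1
    return PrioritySummary(cells=cells, n_unscored=n_unscored)


# ----------------------------------------------------------- VCF annotation

_INFO_LINES = [
    ("LOCAL_AF", "1", "Float", "Local (array-cohort) alt allele frequency"),
    ("LOCAL_AN", "1", "Integer", "Local allele number"),
    ("Z_GOV", "1", "Float", "Governing two-proportion Z score"),
    ("TIER", "1", "String", "Rarity tier from the governing Z"),
    ("NOVEL", "0", "Flag", "Absent from the known-sites set"),
    ("CLNCLASS", "1", "String", "ClinVar-style class"),
    ("SIFT_DEL", "0", "Flag", "SIFT deleterious"),
    ("POLYPHEN_DEL", "0", "Flag", "PolyPhen deleterious"),
    ("PROT_ALT", "0", "Flag", "Protein altering"),
]


def _patho_lookup(patho: pd.DataFrame | None) -> dict[tuple, tuple]:
    if patho is None or not len(patho):
        return {}
    return {
        (str(r.chrom), int(r.pos), r.ref, r.alt):
            (r.clinvar_class, bool(r.sift_deleterious), bool(r.polyphen_deleterious),
             bool(r.protein_altering))
        for r in patho.itertuples(index=False)
    }


def _panel_lookup_checked(panel: AFPanel) -> dict[tuple, tuple[float, float]]:
    lut = panel.lookup()
    if len(lut) != len(panel):
        raise InputError(f"panel {panel.population} has colliding locus keys")
    return lut


def annotate_vcf(
    vcf: str | Path,
    local: AFPanel,
    refs: Sequence[AFPanel],
    patho: pd.DataFrame | None = None,
    known_sites: set[tuple] | None = None,
    out: str | Path | None = None,
    mode: str = "global",
    default_ref_an: float = DEFAULT_REF_AN,
    strong: float = STRONG_Z,
    weak: float = WEAK_Z,
) -> list[AnnotatedVariant]:
    """Annotate a sample VCF with AFs, Z-scores, tier, novelty and flags.

    Variants absent from the local panel are tier ``unscored``. In
    ``global`` mode the reference panels are pooled into one combined panel
    before scoring; ``strictest_vs_all`` scores against each population and
    keeps the least extreme z when all agree in sign.
    """
    local_lut = _panel_lookup_checked(local)
    if mode == "global" and len(refs) > 1:
        score_panels = [combine_panels(refs)]
    else:
        score_panels = list(refs)
    ref_luts = [(p.population, _panel_lookup_checked(p)) for p in score_panels]
    patho_lut = _patho_lookup(patho)
    known = known_sites or set()

    out_vf = None
    with pysam.VariantFile(str(vcf)) as vf:
        header = vf.header.copy()
        for key, num, typ, desc in _INFO_LINES:
            header.info.add(key, num, typ, desc)
        for pop, _ in ref_luts:
            header.info.add(f"REF_AF_{pop}", "1", "Float", f"Reference AF ({pop})")
            header.info.add(f"Z_{pop}", "1", "Float", f"Z score vs {pop}")
        if out is not None:
            out_vf = pysam.VariantFile(str(out), "w", header=header)
        samples = list(vf.header.samples)
        annotated: list[AnnotatedVariant] = []
        n_skipped = 0
        try:
            for rec in vf:
                alts = rec.alts or ()
                if len(alts) != 1 or rec.ref is None:
                    n_skipped += 1
                    logger.warning("skipping malformed/multiallelic record at %s:%s",
                                   rec.chrom, rec.pos)
                    continue
                key = (str(rec.chrom), int(rec.pos), rec.ref, alts[0])
                gt = -1
                if samples:
                    call = rec.samples[samples[0]].get("GT")
                    if call is not None and None not in call:
                        gt = sum(1 for a in call if a and a > 0)
                var = AnnotatedVariant(
                    chrom=key[0], pos=key[1], ref=key[2], alt=key[3], gt=gt,
                    variant_type=classify_variant(key[2], key[3]),
                )
                var.novelty = "known" if key in known else "novel"
                if key in patho_lut:
                    (var.clinvar_class, var.sift_deleterious,
                     var.polyphen_deleterious, var.protein_altering) = patho_lut[key]
                hit = local_lut.get(key)
                if hit is not None:
                    p1, n1 = hit
                    for pop, lut in ref_luts:
                        ref_hit = lut.get(key)
                        if ref_hit is None:
                            continue
                        p2, n2 = ref_hit
                        if not np.isfinite(n2) or n2 <= 0:
                            n2 = default_ref_an
                        var.comparisons.append(AFComparison(
                            ref_pop=pop, local_af=p1, local_an=n1,
                            ref_af=p2, ref_an=n2, z=float(zscore(p1, n1, p2, n2)),
                        ))
                    var.z_gov = governing_z(var.comparisons, mode=mode)
                    var.tier = tier_from_z(var.z_gov, strong=strong, weak=weak)
                annotated.append(var)
                if out_vf is not None:
                    orec = out_vf.new_record(
                        contig=key[0], start=rec.start, stop=rec.stop,
                        alleles=rec.alleles, id=rec.id, qual=rec.qual,
                        filter=list(rec.filter) or None,
                    )
                    for s in samples:
                        orec.samples[s]["GT"] = rec.samples[s].get("GT")
                    if hit is not None:
                        orec.info["LOCAL_AF"] = float(hit[0])
                        orec.info["LOCAL_AN"] = int(hit[1])
                    for comp in var.comparisons:
                        orec.info[f"REF_AF_{comp.ref_pop}"] = comp.ref_af
                        orec.info[f"Z_{comp.ref_pop}"] = comp.z
                    if var.z_gov is not None:
                        orec.info["Z_GOV"] = float(var.z_gov)
                    orec.info["TIER"] = var.tier
                    if var.novelty == "novel":
                        orec.info["NOVEL"] = True
                    orec.info["CLNCLASS"] = var.clinvar_class
                    if var.sift_deleterious:
                        orec.info["SIFT_DEL"] = True
                    if var.polyphen_deleterious:
                        orec.info["POLYPHEN_DEL"] = True
                    if var.protein_altering:
                        orec.info["PROT_ALT"] = True
                    out_vf.write(orec)
        finally:
            if out_vf is not None:
                out_vf.close()
    if n_skipped:
        logger.warning("annotate_vcf: skipped %d malformed records", n_skipped)
    return annotated
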