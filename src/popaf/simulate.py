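"""Synthetic admixed cohorts with known ground truth.

The generator stands in for a controlled-access study cohort: an array-
genotyped population of admixed individuals, per-sample whole-genome variant
calls at the array loci plus WGS-only extras, reference allele-frequency
panels for the ancestral populations, a known-sites set, per-locus
pathogenicity flags and two-caller structural-variant call sets.

Model
-----
Per locus m an ancestral allele frequency p_m is drawn uniformly on
(0.05, 0.95) — array loci are ascertained to be polymorphic, so frequencies
are bounded away from the edges. Population AFs follow the Balding–Nichols
F-model: f_km ~ Beta(p_m(1-c)/c, (1-p_m)(1-c)/c) with divergence c playing
the role of Fst. Per-sample admixture proportions q_i are Dirichlet(alpha),
and genotypes are g_im ~ Binomial(2, Σ_k q_ik f_km): exactly the likelihood
supervised admixture estimation assumes. Loci are independent (no linkage
disequilibrium).

All randomness derives from one global seed through named substreams, so
adding an output never perturbs existing draws and every artifact is
byte-identical across runs with the same spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._random import substream
from .cohort_af import MISSING, AFPanel, GenotypeMatrix
from .vcfio import write_sample_vcf, write_sites

BASES = np.array(["A", "C", "G", "T"])

_F_CLIP = 1e-6  # keep population AFs strictly inside (0,1)


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate an admixed national cohort genotyped on a dense array:
    1,000 samples, three ancestral components with moderate divergence,
    admixture proportions uniform on the simplex (a gradient continuum
    rather than discrete clusters), ~97% of loci present in the known-sites
    set and a 1% array missing rate.
    """

    n_samples: int = 1000
    n_loci: int = 100_000
    n_pops: int = 3
    fst: float = 0.1
    dirichlet_alpha: tuple[float, ...] | None = None
    missing_rate: float = 0.01
    known_fraction: float = 0.9725
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_loci < 1:
            raise ParameterError("n_samples and n_loci must be >= 1")
        if self.n_pops < 1:
            raise ParameterError("n_pops must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ParameterError("fst must be in (0,1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterError("missing_rate must be in [0,1)")
        if not 0.0 <= self.known_fraction <= 1.0:
            raise ParameterError("known_fraction must be in [0,1]")
        if self.dirichlet_alpha is not None:
            if len(self.dirichlet_alpha) != self.n_pops:
                raise ParameterError("dirichlet_alpha length must equal n_pops")
            if any(a <= 0 for a in self.dirichlet_alpha):
                raise ParameterError("dirichlet_alpha entries must be positive")

    @property
    def alpha(self) -> np.ndarray:
        if self.dirichlet_alpha is None:
            return np.ones(self.n_pops)
        return np.asarray(self.dirichlet_alpha, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would not."""

    spec: CohortSpec
    loci: pd.DataFrame  # chrom, pos, ref, alt
    ancestral_af: np.ndarray  # (M,)
    pop_af: np.ndarray  # F, (K, M)
    admixture: np.ndarray  # Q, (N, K) rows on the simplex
    true_genotypes: np.ndarray  # (N, M) codes 0/1/2, no missingness
    known_mask: np.ndarray  # (M,) bool: locus in the known-sites set
    pop_names: list[str] = field(default_factory=list)
    true_svs: pd.DataFrame | None = None

    @property
    def expected_af(self) -> np.ndarray:
        """E[sample AF] per locus: mean admixture times population AFs."""
        return self.admixture.mean(axis=0) @ self.pop_af


def _draw_loci(spec: CohortSpec) -> pd.DataFrame:
    rng = substream(spec.seed, "loci")
    m = spec.n_loci
    chrom_idx = (np.arange(m) * 22) // m + 1
    spacing = rng.integers(200, 2000, size=m)
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, 23):
        sel = chrom_idx == c
        pos[sel] = np.cumsum(spacing[sel])
    ref_i = rng.integers(0, 4, size=m)
    alt_off = rng.integers(1, 4, size=m)
    alt_i = (ref_i + alt_off) % 4
    return pd.DataFrame({
        "chrom": chrom_idx.astype(str),
        "pos": pos,
        "ref": BASES[ref_i],
        "alt": BASES[alt_i],
    })


def simulate_cohort(spec: CohortSpec) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw a full cohort; returns the observed matrix and the ground truth.

    The observed :class:`GenotypeMatrix` has missingness applied; the truth
    keeps the complete genotypes.
    """
    n, m, k, c = spec.n_samples, spec.n_loci, spec.n_pops, spec.fst
    p_anc = substream(spec.seed, "ancestral").uniform(0.05, 0.95, size=m)
    shape = (1.0 - c) / c
    f = substream(spec.seed, "popaf").beta(p_anc * shape, (1.0 - p_anc) * shape, size=(k, m))
    f = np.clip(f, _F_CLIP, 1.0 - _F_CLIP)
    q = substream(spec.seed, "admixture").dirichlet(spec.alpha, size=n)
    dose = q @ f  # (N, M) per-sample alt-allele probability
    g = substream(spec.seed, "genotypes").binomial(2, dose).astype(np.int8)
    observed = g.copy()
    if spec.missing_rate > 0:
        miss = substream(spec.seed, "missing").random((n, m)) < spec.missing_rate
        observed[miss] = MISSING
    known = substream(spec.seed, "known").random(m) < spec.known_fraction
    loci = _draw_loci(spec)
    truth = GroundTruth(
        spec=spec,
        loci=loci,
        ancestral_af=p_anc,
        pop_af=f,
        admixture=q,
        true_genotypes=g,
        known_mask=known,
        pop_names=[f"POP{i + 1}" for i in range(k)],
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(sample_ids, loci.copy(), observed)
    return gm, truth


# ------------------------------------------------------------- sample VCFs

@dataclass
class SampleVCF:
    """An emitted per-sample VCF plus the record-level ground truth."""

    sample_id: str
    path: Path | None
    records: pd.DataFrame
    # columns: chrom, pos, ref, alt, gt, known (bool), is_extra (bool),
    #          corrupted (bool)


def _extra_records(
    truth: GroundTruth, sample_index: int, extra_loci: int, indel_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    if extra_loci == 0:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "gt", "known"])
    max_pos = truth.loci.groupby("chrom")["pos"].max().to_dict()
    chroms = rng.integers(1, 23, size=extra_loci).astype(str)
    rows = []
    offsets: dict[str, int] = {}
    gts = rng.choice([1, 2], size=extra_loci, p=[0.6, 0.4])
    is_indel = rng.random(extra_loci) < indel_fraction
    known = rng.random(extra_loci) < truth.spec.known_fraction
    ref_b = rng.integers(0, 4, size=extra_loci)
    alt_off = rng.integers(1, 4, size=extra_loci)
    tail_len = rng.integers(1, 4, size=extra_loci)
    tail_b = rng.integers(0, 4, size=(extra_loci, 3))
    ins_flag = rng.random(extra_loci) < 0.5
    step = rng.integers(500, 5000, size=extra_loci)
    for i in range(extra_loci):
        ch = chroms[i]
        offsets[ch] = offsets.get(ch, int(max_pos.get(ch, 0)) + 1000) + int(step[i])
        ref = BASES[ref_b[i]]
        alt = BASES[(ref_b[i] + alt_off[i]) % 4]
        if is_indel[i]:
            tail = "".join(BASES[tail_b[i, : tail_len[i]]])
            if ins_flag[i]:
                alt = ref + tail  # insertion
            else:
                ref, alt = ref + tail, ref  # deletion
        rows.append((ch, offsets[ch], ref, alt, int(gts[i]), bool(known[i])))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gt", "known"])


def emit_sample_vcf(
    truth: GroundTruth,
    sample_index: int,
    out: str | Path | None,
    extra_loci: int = 0,
    indel_fraction: float = 0.2,
    discordance_rate: float = 0.0,
) -> SampleVCF:
    """Write one sample's WGS-style VCF.

    The file holds the sample's true genotypes at its non-hom-ref array loci
    plus ``extra_loci`` WGS-only variants, of which ``indel_fraction`` are
    indels. ``discordance_rate`` corrupts that fraction of the emitted
    array-locus genotypes by flipping het<->hom-alt, producing calls that
    disagree with the array while remaining comparable.
    """
    if not 0 <= sample_index < truth.spec.n_samples:
        raise ParameterError(f"sample_index {sample_index} outside cohort")
    g = truth.true_genotypes[sample_index]
    carrier = g > 0
    arr = truth.loci.loc[carrier, ["chrom", "pos", "ref", "alt"]].copy()
    arr["gt"] = g[carrier].astype(int)
    arr["known"] = truth.known_mask[carrier]
    arr["is_extra"] = False
    arr["corrupted"] = False
    rng = substream(truth.spec.seed, "vcf", sample_index)
    if discordance_rate > 0:
        flip = rng.random(len(arr)) < discordance_rate
        arr.loc[flip, "gt"] = 3 - arr.loc[flip, "gt"]  # 1<->2
        arr.loc[flip, "corrupted"] = True
    extras = _extra_records(truth, sample_index, extra_loci, indel_fraction, rng)
    if len(extras):
        extras["is_extra"] = True
        extras["corrupted"] = False
        rec = pd.concat([arr, extras], ignore_index=True)
    else:
        rec = arr.reset_index(drop=True)
    order = np.lexsort((rec["pos"].to_numpy(), rec["chrom"].astype(int).to_numpy()))
    rec = rec.iloc[order].reset_index(drop=True)
    sample_id = f"S{sample_index + 1:04d}"
    path = None
    if out is not None:
        path = Path(out)
        write_sample_vcf(rec, sample_id, path)
    return SampleVCF(sample_id=sample_id, path=path, records=rec)


def known_sites(truth: GroundTruth, samples: Sequence[SampleVCF] = (),
                out: str | Path | None = None) -> set[tuple]:
    """Union of known array loci and known WGS-only extras, as key tuples."""
    keys = {
        (str(c), int(p), r, a)
        for c, p, r, a in truth.loci.loc[truth.known_mask, ["chrom", "pos", "ref", "alt"]]
        .itertuples(index=False)
    }
    for sv in samples:
        ex = sv.records[sv.records["is_extra"] & sv.records["known"]]
        keys.update((str(c), int(p), r, a) for c, p, r, a in
                    ex[["chrom", "pos", "ref", "alt"]].itertuples(index=False))
    if out is not None:
        write_sites(keys, out)
    return keys


# --------------------------------------------------------- reference panels

def emit_reference_panels(
    truth: GroundTruth,
    n_ref: int | Sequence[int] = 5000,
    out_dir: str | Path | None = None,
    exact: bool = False,
) -> dict[str, AFPanel]:
    """One AF panel per ancestral population.

    Panel AF is a binomial resample of size 2·n_ref around the true
    population AF (``exact=True`` skips the resampling — the infinite-panel
    limit); AN is 2·n_ref.
    """
    k = truth.spec.n_pops
    sizes = [int(n_ref)] * k if np.isscalar(n_ref) else [int(x) for x in n_ref]
    if len(sizes) != k:
        raise ParameterError("n_ref must be scalar or one count per population")
    panels: dict[str, AFPanel] = {}
    for ki, pop in enumerate(truth.pop_names):
        an = 2 * sizes[ki]
        if exact:
            af = truth.pop_af[ki].copy()
        else:
            rng = substream(truth.spec.seed, "refpanel", pop)
            af = rng.binomial(an, truth.pop_af[ki]) / an
        rec = truth.loci.copy()
        rec["af"] = af
        rec["an"] = an
        panel = AFPanel(pop, rec)
        panels[pop] = panel
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            panel.to_tsv(out_dir / f"{pop}_af.tsv")
    return panels


# -------------------------------------------------------------- SV callsets

SV_TYPES = ("DEL", "INV", "INS")
_SV_TYPE_P = (0.70, 0.15, 0.15)


@dataclass
class SVSim:
    truth: pd.DataFrame  # chrom, start, end, type, size, sv_id
    caller_a: pd.DataFrame  # + caller, sv_id
    caller_b: pd.DataFrame
    database: pd.DataFrame


def simulate_sv_callsets(
    n_true: int = 200,
    genome_len: int = 10_000_000,
    jitter_sd: float = 20.0,
    sens_a: float = 0.9,
    sens_b: float = 0.8,
    db_fraction: float = 0.865,
    seed: int = 0,
) -> SVSim:
    """Simulate two caller outputs and a background database.

    True SVs (DEL/INV/INS) are placed without overlap on one contig; each
    caller reports a true SV with its sensitivity, with Gaussian breakpoint
    jitter; the database holds ``db_fraction`` of the true SVs (and nothing
    else), so novelty ground truth is exact. Coordinates are 0-based
    half-open; insertions are points (end == start) with a stored size.
    """
    if n_true < 1:
        raise ParameterError("n_true must be >= 1")
    rng = substream(seed, "sv")
    types = rng.choice(SV_TYPES, size=n_true, p=_SV_TYPE_P)
    sizes = np.where(
        types == "INS",
        rng.integers(50, 1000, size=n_true),
        rng.integers(100, 10_000, size=n_true),
    )
    span = np.where(types == "INS", 0, sizes)
    gaps_needed = int(span.sum()) + n_true * 200
    if gaps_needed >= genome_len:
        raise ParameterError("genome_len too small for requested SVs")
    slack = genome_len - gaps_needed
    gaps = rng.multinomial(slack, np.ones(n_true) / n_true) + 200
    starts = np.cumsum(gaps + np.concatenate([[0], span[:-1]]))
    ends = starts + span
    truth = pd.DataFrame({
        "chrom": "1", "start": starts, "end": ends, "type": types,
        "size": sizes, "sv_id": np.arange(n_true),
    })

    def _call(sens: float, caller: str) -> pd.DataFrame:
        crng = substream(seed, "sv", caller)
        hit = crng.random(n_true) < sens
        df = truth[hit].copy()
        if jitter_sd > 0 and len(df):
            j1 = np.rint(crng.normal(0, jitter_sd, size=len(df))).astype(int)
            j2 = np.rint(crng.normal(0, jitter_sd, size=len(df))).astype(int)
            ins = (df["type"] == "INS").to_numpy()
            start = np.maximum(df["start"].to_numpy() + j1, 0)
            end = df["end"].to_numpy() + np.where(ins, j1, j2)
            end = np.maximum(end, start + np.where(ins, 0, 1))
            df["start"], df["end"] = start, np.where(ins, start, end)
            df.loc[~ins, "size"] = df.loc[~ins, "end"] - df.loc[~ins, "start"]
            sz_jit = np.rint(crng.normal(0, jitter_sd, size=int(ins.sum()))).astype(int)
            df.loc[ins, "size"] = np.maximum(df.loc[ins, "size"].to_numpy() + sz_jit, 1)
        df["caller"] = caller
        return df.reset_index(drop=True)

    call_a = _call(sens_a, "callerA")
    call_b = _call(sens_b, "callerB")
    in_db = substream(seed, "sv", "db").random(n_true) < db_fraction
    db = truth[in_db].copy().reset_index(drop=True)
    db["caller"] = "database"
    return SVSim(truth=truth, caller_a=call_a, caller_b=call_b, database=db)


# ------------------------------------------------------ pathogenicity table

@dataclass(frozen=True)
class PathoRates:
    """Per-flag probabilities, as fractions of annotated loci.

    Defaults are the orders of magnitude seen when clinical databases
    annotate ~7e5 array loci: a few e-4 ClinVar non-benign, ~1e-3 algorithmic
    deleteriousness, ~7e-3 protein altering.
    """

    clinvar_non_benign: float = 3e-4
    clinvar_pathogenic: float = 6e-5
    sift_deleterious: float = 1.2e-3
    polyphen_deleterious: float = 1.2e-3
    protein_altering: float = 7.5e-3

    def __post_init__(self) -> None:
        for name in ("clinvar_non_benign", "clinvar_pathogenic", "sift_deleterious",
                     "polyphen_deleterious", "protein_altering"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be a probability")
        if self.clinvar_pathogenic > self.clinvar_non_benign:
            raise ParameterError("clinvar_pathogenic cannot exceed clinvar_non_benign")


def emit_pathogenicity_table(
    loci: pd.DataFrame,
    rates: PathoRates = PathoRates(),
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Per-locus pathogenicity flags keyed by (chrom,pos,ref,alt).

    ``clinvar_class`` is drawn hierarchically: pathogenic_or_risk with its
    rate, otherwise non_benign, otherwise benign (pathogenic records count
    as non-benign downstream). The three boolean flags are independent
    Bernoulli draws.
    """
    rng = substream(seed, "patho")
    m = len(loci)
    u = rng.random(m)
    cls = np.where(
        u < rates.clinvar_pathogenic, "pathogenic_or_risk",
        np.where(u < rates.clinvar_non_benign, "non_benign", "benign"),
    )
    df = loci[["chrom", "pos", "ref", "alt"]].copy()
    df["clinvar_class"] = cls
    df["sift_deleterious"] = rng.random(m) < rates.sift_deleterious
    df["polyphen_deleterious"] = rng.random(m) < rates.polyphen_deleterious
    df["protein_altering"] = rng.random(m) < rates.protein_altering
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df
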