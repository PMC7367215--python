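"""Two-caller structural-variant intersection and novelty classification.

Structural variant callers disagree on exact breakpoints, so consensus is
defined by reciprocal overlap: two same-type intervals on the same
chromosome match when each covers at least ``ro_min`` of the other (0.5 by
default — the community convention for database comparison). Insertions are
point events with no span, so they match by breakpoint proximity plus size
ratio instead. Only calls made by both callers survive; consensus calls are
then classified known/novel against a background SV database under the same
criterion.

Coordinates are 0-based half-open internally; readers accept 1-based
inclusive input with a dialect flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort_af import InputError

SV_COLUMNS = ["chrom", "start", "end", "type", "size", "caller"]


@dataclass(frozen=True)
class SVCall:
    chrom: str
    start: int  # 0-based half-open; end == start for insertions
    end: int
    type: str  # DEL / INV / INS
    size: int
    caller: str = ""
    sv_id: int | None = None  # simulation truth id, when known

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError(f"SV end < start at {self.chrom}:{self.start}")
        if self.size <= 0:
            raise InputError(f"SV size must be positive at {self.chrom}:{self.start}")
        if self.type in ("DEL", "INV") and self.size != self.end - self.start:
            raise InputError(f"{self.type} size must equal span at {self.chrom}:{self.start}")


@dataclass
class MergedSV:
    chrom: str
    start: int  # consensus = union of the two supports
    end: int
    type: str
    size: int
    support_a: SVCall
    support_b: SVCall
    novelty: str = "novel"


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 for disjoint or zero length."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def _calls_from_frame(df: pd.DataFrame, one_based: bool = False) -> list[SVCall]:
    bad = []
    calls = []
    for i, rec in enumerate(df.itertuples(index=False)):
        start = int(rec.start) - (1 if one_based else 0)
        end = int(rec.end)
        size = int(getattr(rec, "size", 0) or (end - start))
        try:
            calls.append(SVCall(
                chrom=str(rec.chrom), start=start, end=end, type=str(rec.type),
                size=size, caller=str(getattr(rec, "caller", "")),
                sv_id=int(rec.sv_id) if hasattr(rec, "sv_id") else None,
            ))
        except InputError as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise InputError("malformed SV rows:\n" + "\n".join(bad))
    return calls


def read_sv_tsv(path: str | Path, one_based: bool = False) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return _calls_from_frame(df, one_based=one_based)


def write_sv_tsv(calls: Iterable[SVCall | MergedSV], path: str | Path) -> None:
    rows = []
    for c in calls:
        caller = getattr(c, "caller", None)
        if caller is None:
            caller = f"{c.support_a.caller}+{c.support_b.caller}"
        rows.append((c.chrom, c.start, c.end, c.type, c.size, caller,
                     getattr(c, "novelty", "")))
    pd.DataFrame(rows, columns=SV_COLUMNS + ["novelty"]).to_csv(path, sep="\t", index=False)


def _pair_score(a: SVCall, b: SVCall, ro_min: float, ins_window: int,
                ins_size_ratio: float) -> float | None:
    """Match quality in [0,1], or None when the pair does not match."""
    if a.chrom != b.chrom or a.type != b.type:
        return None
    if a.type == "INS":
        if abs(a.start - b.start) > ins_window:
            return None
        ratio = min(a.size, b.size) / max(a.size, b.size)
        if ratio < ins_size_ratio:
            return None
        return ratio - abs(a.start - b.start) / (ins_window + 1) * 1e-6
    ro = reciprocal_overlap((a.start, a.end), (b.start, b.end))
    return ro if ro >= ro_min else None


def intersect_callers(
    a: Sequence[SVCall],
    b: Sequence[SVCall],
    ro_min: float = 0.5,
    ins_window: int = 100,
    ins_size_ratio: float = 0.5,
) -> list[MergedSV]:
    """One-to-one greedy intersection of two call sets.

    Candidate pairs are ranked by descending match score (reciprocal
    overlap, or size ratio for insertions), ties broken by smaller start
    then input order; each call supports at most one consensus. Unmatched
    calls are discarded.
    """
    candidates = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            s = _pair_score(ca, cb, ro_min, ins_window, ins_size_ratio)
            if s is not None:
                candidates.append((-s, min(ca.start, cb.start), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    merged: list[MergedSV] = []
    for _s, _st, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ca, cb = a[i], b[j]
        start = min(ca.start, cb.start)
        end = max(ca.end, cb.end)
        size = end - start if ca.type != "INS" else int(round((ca.size + cb.size) / 2))
        merged.append(MergedSV(chrom=ca.chrom, start=start, end=end, type=ca.type,
                               size=max(size, 1), support_a=ca, support_b=cb))
    merged.sort(key=lambda m: (m.chrom, m.start, m.end))
    return merged


def classify_novelty(
    merged: Sequence[MergedSV],
    db: Sequence[SVCall],
    ro_min: float = 0.5,
    ins_window: int = 100,
    ins_size_ratio: float = 0.5,
) -> pd.DataFrame:
    """Mark each consensus SV known/novel against the background database.

    Known iff some same-chromosome same-type database record matches under
    the intersection criterion (reciprocal overlap, or the insertion rule).
    Returns the per-type known/novel tally; ``merged`` novelty fields are
    set in place.
    """
    for m in merged:
        probe = SVCall(chrom=m.chrom, start=m.start, end=m.end, type=m.type,
                       size=m.size if m.type == "INS" else max(m.end - m.start, 1),
                       caller="consensus")
        m.novelty = "novel"
        for rec in db:
            if _pair_score(probe, rec, ro_min, ins_window, ins_size_ratio) is not None:
                m.novelty = "known"
                break
    rows = []
    for t in sorted({m.type for m in merged}):
        sub = [m for m in merged if m.type == t]
        n_known = sum(m.novelty == "known" for m in sub)
        rows.append((t, n_known, len(sub) - n_known, len(sub)))
    return pd.DataFrame(rows, columns=["type", "known", "novel", "total"])


def summary_json(merged: Sequence[MergedSV], tallies: pd.DataFrame,
                 path: str | Path | None = None) -> str:
    n_novel = sum(m.novelty == "novel" for m in merged)
    payload = json.dumps({
        "n_merged": len(merged),
        "n_novel": n_novel,
        "novel_pct": 100.0 * n_novel / len(merged) if merged else None,
        "by_type": tallies.to_dict(orient="records"),
    }, indent=2)
    if path is not None:
        Path(path).write_text(payload + "\n")
    return payload


def write_sv_vcf(merged: Sequence[MergedSV], path: str | Path) -> None:
    """Symbolic-ALT VCF 4.2 writer (<DEL>/<INV>/<INS>) with END/SVLEN."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popaf svmerge\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##INFO=<ID=NOVEL,Number=0,Type=Flag,Description="Absent from background DB">\n')
        for chrom in dict.fromkeys(m.chrom for m in merged):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in merged:
            svlen = -m.size if m.type == "DEL" else m.size
            info = f"END={m.end};SVTYPE={m.type};SVLEN={svlen}"
            if m.novelty == "novel":
                info += ";NOVEL"
            # POS anchors the base preceding the event (symbolic-ALT convention)
            fh.write(f"{m.chrom}\t{max(m.start, 1)}\t.\tN\t<{m.type}>\t.\tPASS\t{info}\n")
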