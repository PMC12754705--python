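"""Significance calling, LD clumping into independent loci, and novelty.

A variant is called significant if it satisfies any of:

1a. 1df interaction p <= 5e-9 and genome-wide interaction FDR < 0.05;
1b. 1df interaction p <= 0.05/m_G with FDR < 0.05 computed over the m_G
    variants whose marginal (exposure-free) p is <= 1e-5;
2.  2df joint p <= 5e-9 and genome-wide 2df FDR < 0.05.

FDR is Benjamini-Hochberg step-up q-values.  Significant variants are
clumped greedily: the most significant unassigned variant leads a locus
and absorbs every unassigned variant on the same chromosome within the
window (lead +/- 500 kb) or in LD with it (r^2 >= 0.1); loci are then
labelled known if any member lies within 1 Mb of a catalog entry on the
same chromosome, else novel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .meta import MetaResult
from .sumstats import KnownLocusCatalog, MarginalStat, VariantKey

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaSettings",
    "SignificanceFlags",
    "Locus",
    "bh_fdr",
    "flag_significant",
    "clump",
    "classify_novel",
]


@dataclass
class AlphaSettings:
    """Significance thresholds for locus discovery."""

    genomewide_p: float = 5e-9
    fdr_q: float = 0.05
    mg_marginal_p: float = 1e-5
    bonferroni_alpha: float = 0.05


@dataclass
class SignificanceFlags:
    """Per-variant significance decisions and q-values."""

    key: VariantKey
    pass_1df_genomewide: bool = False
    pass_1df_mg: bool = False
    pass_2df: bool = False
    fdr_gxe: float = 1.0
    fdr_gxe_mg: float = float("nan")
    fdr_2df: float = 1.0

    @property
    def significant(self) -> bool:
        return self.pass_1df_genomewide or self.pass_1df_mg or self.pass_2df


@dataclass
class Locus:
    """A clumped region led by its most significant variant."""

    lead: VariantKey
    lead_p: float
    members: list[VariantKey] = field(default_factory=list)
    chrom: str = ""
    start: int = 0
    end: int = 0
    novelty: str = "unclassified"
    matched_entry: tuple[str, int, str] | None = None

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input.

    q(i) = min over k with rank(k) >= rank(i) of m * p(k) / rank(k),
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def flag_significant(
    meta: list[MetaResult],
    marginal: list[MarginalStat] | None = None,
    alpha: AlphaSettings | None = None,
    use_gc: bool = True,
) -> list[SignificanceFlags]:
    """Apply the three significance rules to meta-analysis records.

    ``marginal`` supplies the exposure-free p-values used to define the
    m_G subset for rule 1b; without it rule 1b is vacuously false.
    GC-corrected p-values are used when present and ``use_gc`` is set.
    """
    alpha = alpha or AlphaSettings()

    def p1(r: MetaResult) -> float:
        if use_gc and r.p_1df_gc is not None:
            return r.p_1df_gc
        return r.p_1df

    def p2(r: MetaResult) -> float:
        if use_gc and r.p_2df_gc is not None:
            return r.p_2df_gc
        return r.p_2df

    p_1df = np.array([p1(r) for r in meta])
    p_2df = np.array([p2(r) for r in meta])
    q_1df = bh_fdr(p_1df)
    q_2df = bh_fdr(p_2df)

    # rule 1b operates on the subset of variants marginally suggestive
    marginal_p: dict[tuple, float] = {}
    if marginal:
        for m in marginal:
            marginal_p[(m.key.chrom, m.key.pos, m.key.ea, m.key.oa)] = m.p
    in_subset = np.array(
        [
            marginal_p.get(
                (r.key.chrom, r.key.pos, r.key.ea, r.key.oa), np.inf
            )
            <= alpha.mg_marginal_p
            for r in meta
        ]
    )
    m_g = int(in_subset.sum())
    q_mg = np.full(len(meta), np.nan)
    if m_g > 0:
        q_mg[in_subset] = bh_fdr(p_1df[in_subset])

    flags = []
    for i, r in enumerate(meta):
        f = SignificanceFlags(
            key=r.key,
            fdr_gxe=float(q_1df[i]),
            fdr_gxe_mg=float(q_mg[i]),
            fdr_2df=float(q_2df[i]),
        )
        f.pass_1df_genomewide = (
            p_1df[i] <= alpha.genomewide_p and q_1df[i] < alpha.fdr_q
        )
        if m_g > 0 and in_subset[i]:
            f.pass_1df_mg = (
                p_1df[i] <= alpha.bonferroni_alpha / m_g
                and q_mg[i] < alpha.fdr_q
            )
        f.pass_2df = p_2df[i] <= alpha.genomewide_p and q_2df[i] < alpha.fdr_q
        flags.append(f)
    return flags


def clump(
    significant: list[tuple[VariantKey, float]],
    ld_lookup: Callable[[VariantKey, VariantKey], float] | None = None,
    window_bp: int = 500_000,
    r2_max: float = 0.1,
    transitive: bool = False,
    background: list[VariantKey] | None = None,
) -> list[Locus]:
    """Greedy clumping of significant variants into independent loci.

    ``significant`` pairs each variant with its relevant p-value;
    ``ld_lookup(a, b)`` returns the signed correlation r between two
    variants (missing LD is treated as r = 0 with a warning).  The most
    significant unassigned variant leads a locus and absorbs unassigned
    variants on the same chromosome within ``window_bp`` of the lead or
    with r^2 >= ``r2_max`` to the lead.  ``background`` variants (not
    themselves significant) can be absorbed as members but never lead.
    With ``transitive=True`` absorption chains through members instead of
    measuring only from the lead.  Ties on p break by (chromosome,
    position).  Output is invariant to input order.
    """

    def _r2(a: VariantKey, b: VariantKey) -> float:
        if ld_lookup is None:
            return 0.0
        r = ld_lookup(a, b)
        if r is None or not np.isfinite(r):
            logger.warning("missing LD for %s-%s; treating r2 as 0", a.label(), b.label())
            return 0.0
        return float(r) ** 2

    def _chrom_sort(c: str):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    pending = sorted(
        significant, key=lambda kp: (kp[1], _chrom_sort(kp[0].chrom), kp[0].pos)
    )
    candidates = [k for k, _ in pending] + list(background or [])
    assigned: set[tuple] = set()
    loci: list[Locus] = []
    for lead, lead_p in pending:
        lead_id = (lead.chrom, lead.pos, lead.ea, lead.oa)
        if lead_id in assigned:
            continue
        assigned.add(lead_id)
        members = [lead]
        frontier = [lead]
        while frontier:
            anchors = frontier if transitive else [lead]
            frontier = []
            for cand in candidates:
                cid = (cand.chrom, cand.pos, cand.ea, cand.oa)
                if cid in assigned or cand.chrom != lead.chrom:
                    continue
                for anchor in anchors:
                    near = abs(cand.pos - anchor.pos) <= window_bp
                    linked = _r2(anchor, cand) >= r2_max
                    if near or linked:
                        assigned.add(cid)
                        members.append(cand)
                        frontier.append(cand)
                        break
            if not transitive:
                break
        members.sort(key=lambda k: k.pos)
        loci.append(
            Locus(
                lead=lead,
                lead_p=lead_p,
                members=members,
                chrom=lead.chrom,
                start=members[0].pos,
                end=members[-1].pos,
            )
        )
    loci.sort(key=lambda L: (_chrom_sort(L.chrom), L.start))
    return loci


def classify_novel(
    loci: list[Locus],
    catalog: KnownLocusCatalog,
    margin_bp: int = 1_000_000,
) -> list[Locus]:
    """Label each locus known or novel against a catalog.

    A locus is known iff any member lies within ``margin_bp`` of any
    catalog entry on the same chromosome.  Labels are set in place and the
    list returned for chaining.
    """
    for locus in loci:
        locus.novelty = "novel"
        locus.matched_entry = None
        for chrom, pos, trait in catalog.entries:
            if str(chrom) != str(locus.chrom):
                continue
            for member in locus.members:
                if abs(member.pos - pos) <= margin_bp:
                    locus.novelty = "known"
                    locus.matched_entry = (str(chrom), pos, trait)
                    break
            if locus.novelty == "known":
                break
    return loci
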