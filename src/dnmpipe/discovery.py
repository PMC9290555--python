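"""Candidate DNM discovery: Mendelian-violation scan and stringent filters.

A candidate is a site where both parents are homozygous reference and the
child is heterozygous. Six filters separate high-confidence DNMs from
genotyping error, the dominant failure mode for this configuration:

1. read depth within [depth_min, depth_max] for every trio member,
2. genotype quality strictly above gq_min for every member,
3. alternate allele seen on both strands in the child (ADF, ADR > 0),
4. zero alternate reads in either parent,
5. alternate allele absent from cohort samples not descended from the
   trio's parents (descendants may legitimately inherit the DNM),
6. child allelic balance alt/(ref+alt) strictly above allelic_balance_min.

All verdicts are always evaluated and recorded — no short-circuiting — so
the filter attrition table is complete for every candidate.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Iterator, Optional, Sequence

from scipy import stats

from .model import (
    FILTER_NAMES,
    MUTATION_CLASSES,
    CandidateMutation,
    FilterConfig,
    GenotypeCall,
    Pedigree,
    SiteGenotypes,
)

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def classify_mutation(ref: str, alt: str) -> str:
    """Strand-collapsed substitution class with the reference base as A or C.

    The 12 ordered base pairs map 2-to-1 onto the six classes: a purine
    reference (G or T... strictly, G) and its pyrimidine partner are folded
    by complementing both bases, so e.g. G>A reports as C>T.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in ("G", "T"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def scan_mendelian_violations(
    sites: Iterable[SiteGenotypes],
    trio: tuple[str, str, str],
    ped: Pedigree,
    counters: Optional[dict] = None,
) -> Iterator[CandidateMutation]:
    """Yield candidate DNMs for one trio from a cohort site stream.

    ``trio`` is (proband, father, mother). Sites where any trio member's
    genotype is missing are counted and skipped, never emitted. Cohort
    samples outside the couple's descendant closure that carry the
    alternate allele are tallied per candidate for filter 5.
    """
    proband, father, mother = trio
    exempt = ped.descendants_of_couple(father, mother) | {father, mother}
    if counters is None:
        counters = {}
    counters.setdefault("missing_genotype", 0)
    counters.setdefault("candidates", 0)
    for site in sites:
        try:
            child_c = site.calls[proband]
            father_c = site.calls[father]
            mother_c = site.calls[mother]
        except KeyError as exc:
            raise ValueError(f"trio member {exc} absent from site calls") from exc
        if "missing" in (child_c.gt, father_c.gt, mother_c.gt):
            counters["missing_genotype"] += 1
            continue
        if not (father_c.gt == "hom_ref" and mother_c.gt == "hom_ref" and child_c.gt == "het"):
            continue
        carriers = sum(
            1
            for sample, call in site.calls.items()
            if sample not in exempt
            and sample != proband
            and call.gt in ("het", "hom_alt")
        )
        counters["candidates"] += 1
        yield CandidateMutation(
            trio=proband,
            chrom=site.chrom,
            pos=site.pos,
            ref=site.ref,
            alt=site.alt,
            child_call=child_c,
            father_call=father_c,
            mother_call=mother_c,
            nondescendant_carriers=carriers,
        )


def _depth_verdict(call: GenotypeCall, cfg: FilterConfig) -> str:
    if call.dp is None:
        return "unevaluable"
    return "pass" if cfg.depth_min <= call.dp <= cfg.depth_max else "fail"


def _gq_verdict(call: GenotypeCall, cfg: FilterConfig) -> str:
    if call.gq is None:
        return "unevaluable"
    return "pass" if call.gq > cfg.gq_min else "fail"


def _combine(verdicts: Sequence[str]) -> str:
    if "fail" in verdicts:
        return "fail"
    if "unevaluable" in verdicts:
        return "unevaluable"
    return "pass"


def apply_stringent_filters(cand: CandidateMutation, cfg: FilterConfig) -> CandidateMutation:
    """Fill every filter verdict on ``cand`` and set its status.

    Evaluation is order-independent; verdicts are ``pass``, ``fail`` or
    ``unevaluable`` (required evidence absent). Status is high_confidence
    iff all six verdicts pass.
    """
    members = (cand.child_call, cand.father_call, cand.mother_call)
    v: dict[str, str] = {}
    v["depth"] = _combine([_depth_verdict(c, cfg) for c in members])
    v["genotype_quality"] = _combine([_gq_verdict(c, cfg) for c in members])

    if not cfg.require_both_strands:
        v["both_strands"] = "pass"
    elif cand.child_call.adf is None or cand.child_call.adr is None:
        v["both_strands"] = "unevaluable"
        log.warning(
            "candidate %s:%d lacks strand allelic depths; rejected", cand.chrom, cand.pos
        )
    else:
        v["both_strands"] = (
            "pass" if cand.child_call.adf > 0 and cand.child_call.adr > 0 else "fail"
        )

    parent_ads = [cand.father_call.ad_alt, cand.mother_call.ad_alt]
    if any(ad is None for ad in parent_ads):
        v["parent_alt_reads"] = "unevaluable"
    else:
        v["parent_alt_reads"] = (
            "pass" if all(ad <= cfg.parent_alt_reads_max for ad in parent_ads) else "fail"
        )

    if not cfg.check_nondescendants:
        v["nondescendant_absence"] = "pass"
    else:
        v["nondescendant_absence"] = "pass" if cand.nondescendant_carriers == 0 else "fail"

    ab = cand.child_call.allelic_balance
    if ab is None:
        v["allelic_balance"] = "unevaluable"
    else:
        v["allelic_balance"] = "pass" if ab > cfg.allelic_balance_min else "fail"

    cand.filter_verdicts = v
    cand.status = (
        "high_confidence" if all(v[name] == "pass" for name in FILTER_NAMES) else "rejected"
    )
    return cand


def discover_dnms(
    sites: Iterable[SiteGenotypes],
    trio: tuple[str, str, str],
    ped: Pedigree,
    cfg: Optional[FilterConfig] = None,
    counters: Optional[dict] = None,
) -> list[CandidateMutation]:
    """Scan + filter convenience wrapper; returns all candidates with verdicts."""
    cfg = cfg or FilterConfig()
    return [
        apply_stringent_filters(c, cfg)
        for c in scan_mendelian_violations(sites, trio, ped, counters=counters)
    ]


def spectrum_counts(
    mutations: Sequence[CandidateMutation] | Sequence[str],
) -> tuple[dict[str, int], float]:
    """Counts over the six substitution classes plus the Ts/Tv ratio.

    Accepts CandidateMutation objects or raw class labels. Transitions are
    A>G and C>T; the ratio is NaN for an empty input or when there are no
    transversions.
    """
    counts = {c: 0 for c in MUTATION_CLASSES}
    for m in mutations:
        label = m if isinstance(m, str) else m.mutation_class
        if label not in counts:
            raise ValueError(f"unknown mutation class {label!r}")
        counts[label] += 1
    ts = counts["A>G"] + counts["C>T"]
    tv = sum(counts.values()) - ts
    tstv = ts / tv if tv > 0 else math.nan
    return counts, tstv


def compare_spectra(
    counts_a: dict[str, int], counts_b: dict[str, int]
) -> tuple[dict[str, float], float]:
    """Chi-square comparison of two mutation spectra.

    Per class: a 2x2 test of (class vs rest) x (cohort a vs b), without
    continuity correction. Globally: a 2x6 contingency chi-square. Returns
    (per-class p-values, global p-value).
    """
    a = [counts_a.get(c, 0) for c in MUTATION_CLASSES]
    b = [counts_b.get(c, 0) for c in MUTATION_CLASSES]
    tot_a, tot_b = sum(a), sum(b)
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both spectra must have positive totals")
    per_class: dict[str, float] = {}
    for cls, ka, kb in zip(MUTATION_CLASSES, a, b):
        table = [[ka, tot_a - ka], [kb, tot_b - kb]]
        if ka == 0 and kb == 0:
            per_class[cls] = 1.0
            continue
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
        per_class[cls] = float(p)
    # classes absent from both cohorts carry no information for the global test
    keep = [j for j in range(len(a)) if a[j] + b[j] > 0]
    table = [[a[j] for j in keep], [b[j] for j in keep]]
    if len(keep) < 2:
        return per_class, 1.0
    _, global_p, _, _ = stats.chi2_contingency(table, correction=False)
    return per_class, float(global_p)
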