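"""Callability estimation and mutation-rate conversion.

The stringent DNM filters reject some true mutations; uncorrected counts
therefore underestimate the rate. The correction estimates, per trio, the
probability C that a true DNM site would survive all filters in all three
members, decomposed as C = C_child * C_father * C_mother under
independence. Each component is the fraction of *informative* sites
surviving that member's subset of the filters:

* child: sites where one parent is homozygous reference and the other
  homozygous alternate — the child is then a confident heterozygote, the
  same call a DNM requires (C_c = N_het,filtered / N_het,all);
* father/mother: that parent's confident homozygous-reference calls at
  cohort-polymorphic sites, filtered on depth, quality and zero alternate
  reads — the call a DNM requires of a parent.

The per-trio rate is n_mutations / (2 * C * G) with G the haploid genome
span surviving coverage filters; confidence intervals assume Poisson
variance in the mutation count.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

from .model import (
    FilterConfig,
    SiteGenotypes,
    TrioCallability,
    TrioRecord,
)


class CallabilityError(RuntimeError):
    """Raised when informative sites are insufficient for estimation."""


def _child_site_pass(call, cfg: FilterConfig) -> bool:
    if call.gt != "het":
        return False
    if call.dp is None or not (cfg.depth_min <= call.dp <= cfg.depth_max):
        return False
    if call.gq is None or not (call.gq > cfg.gq_min):
        return False
    if cfg.require_both_strands:
        if call.adf is None or call.adr is None or call.adf <= 0 or call.adr <= 0:
            return False
    ab = call.allelic_balance
    if ab is None or not (ab > cfg.allelic_balance_min):
        return False
    return True


def _parent_site_pass(call, cfg: FilterConfig) -> bool:
    if call.gt != "hom_ref":
        return False
    if call.dp is None or not (cfg.depth_min <= call.dp <= cfg.depth_max):
        return False
    if call.gq is None or not (call.gq > cfg.gq_min):
        return False
    if call.ad_alt is None or call.ad_alt > cfg.parent_alt_reads_max:
        return False
    return True


def estimate_member_callability(
    sites: Iterable[SiteGenotypes],
    trio: tuple[str, str, str],
    member: str,
    cfg: Optional[FilterConfig] = None,
) -> tuple[int, int, float]:
    """(n_pass, n_informative, C) for one trio member.

    ``member`` is ``child``, ``father`` or ``mother``. For the child,
    informative sites are parental homozygous-reference x homozygous-
    alternate crosses; passing requires the child's het call to survive the
    child-specific filters (depth, GQ, both strands, allelic balance). For
    a parent, informative sites are that parent's homozygous-reference
    calls at sites carrying the alternate in some cohort sample; passing
    requires depth, GQ and zero alternate reads.
    """
    cfg = cfg or FilterConfig()
    proband, father, mother = trio
    n_pass = n_info = 0
    if member == "child":
        for site in sites:
            fgt = site.calls[father].gt
            mgt = site.calls[mother].gt
            if {fgt, mgt} != {"hom_ref", "hom_alt"}:
                continue
            n_info += 1
            if _child_site_pass(site.calls[proband], cfg):
                n_pass += 1
    elif member in ("father", "mother"):
        target = father if member == "father" else mother
        for site in sites:
            call = site.calls[target]
            if call.gt != "hom_ref":
                continue
            if not any(
                c.gt in ("het", "hom_alt") for s, c in site.calls.items() if s != target
            ):
                continue
            n_info += 1
            if _parent_site_pass(call, cfg):
                n_pass += 1
    else:
        raise ValueError(f"member must be child/father/mother, got {member!r}")
    if n_info == 0:
        raise CallabilityError(
            f"no informative sites for {member} of trio {proband} (insufficient data)"
        )
    return n_pass, n_info, n_pass / n_info


def estimate_trio_callability(
    sites: Sequence[SiteGenotypes],
    trio: tuple[str, str, str],
    cfg: Optional[FilterConfig] = None,
) -> TrioCallability:
    """All three member callabilities from one (materialized) site stream."""
    pc, ic, cc = estimate_member_callability(sites, trio, "child", cfg)
    pf, if_, cf = estimate_member_callability(sites, trio, "father", cfg)
    pm, im, cm = estimate_member_callability(sites, trio, "mother", cfg)
    return TrioCallability(
        c_child=cc if cc > 0 else 1e-12,
        c_father=cf if cf > 0 else 1e-12,
        c_mother=cm if cm > 0 else 1e-12,
        n_pass_child=pc,
        n_informative_child=ic,
        n_pass_father=pf,
        n_informative_father=if_,
        n_pass_mother=pm,
        n_informative_mother=im,
    )


def compute_trio_rate(n_mut: int, C: float, haploid_span_bp: float) -> float:
    """Per-bp per-generation rate: n_mut / (2 * C * G)."""
    if not (0.0 < C <= 1.0):
        raise ValueError(f"callability C={C} outside (0, 1]")
    if haploid_span_bp <= 0:
        raise ValueError("haploid span must be > 0")
    return n_mut / (2.0 * C * haploid_span_bp)


from .model import RateEstimate  # noqa: E402  (public return type)


def aggregate_rate(
    trios: Sequence[TrioRecord], ci_z: float = 1.96, method: str = "mean"
) -> RateEstimate:
    """Cohort per-generation rate with a Poisson confidence interval.

    The point estimate is the unweighted mean of per-trio rates (``method=
    'mean'``) or the pooled ratio sum(N) / sum(2*C*G) (``'pooled'``). The
    interval applies the relative Poisson factor (1 +/- z/sqrt(N_total)) to
    the point estimate; the pooled estimate and its Wald interval
    (N +/- z*sqrt(N)) / sum(2*C*G) are reported alongside.
    """
    if not trios:
        raise ValueError("need at least one trio")
    if method not in ("mean", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    n_tot = sum(t.n_mutations for t in trios)
    denom = sum(t.callable_diploid_sites for t in trios)
    per_trio = [t.rate for t in trios]
    pooled = n_tot / denom
    point = sum(per_trio) / len(per_trio) if method == "mean" else pooled
    if n_tot > 0:
        rel = ci_z / math.sqrt(n_tot)
        lo, hi = point * (1 - rel), point * (1 + rel)
        pooled_lo = (n_tot - ci_z * math.sqrt(n_tot)) / denom
        pooled_hi = (n_tot + ci_z * math.sqrt(n_tot)) / denom
    else:
        lo = pooled_lo = 0.0
        hi = pooled_hi = ci_z**2 / denom
    return RateEstimate(
        rate_per_bp_per_gen=point,
        ci_low=max(lo, 0.0),
        ci_high=hi,
        n_mutations_total=n_tot,
        callable_diploid_sites=denom,
        pooled_rate=pooled,
        pooled_ci=(max(pooled_lo, 0.0), pooled_hi),
    )


def per_year_rate(est: RateEstimate, mean_parental_age: float) -> RateEstimate:
    """Convert a per-generation estimate to per-year by the mean parental age.

    The divisor is the mean over *all* recorded parental ages, both sexes.
    """
    if mean_parental_age <= 0:
        raise ValueError("mean parental age must be > 0")
    a = mean_parental_age
    return RateEstimate(
        rate_per_bp_per_gen=est.rate_per_bp_per_gen / a,
        ci_low=est.ci_low / a,
        ci_high=est.ci_high / a,
        n_mutations_total=est.n_mutations_total,
        callable_diploid_sites=est.callable_diploid_sites,
        rate_per_bp_per_year=est.rate_per_bp_per_gen / a,
        mean_parental_age=a,
        pooled_rate=None if est.pooled_rate is None else est.pooled_rate / a,
        pooled_ci=None
        if est.pooled_ci is None
        else (est.pooled_ci[0] / a, est.pooled_ci[1] / a),
    )


def subset_rate(
    n_subset: int, C: float, subset_span_bp: float, ci_z: float = 1.96
) -> RateEstimate:
    """Rate restricted to a genomic subset (e.g. CpG sites).

    The caller supplies the subset's callable haploid span; this module
    does not enumerate subset sites. The interval is Wald-Poisson on the
    subset count.
    """
    rate = compute_trio_rate(n_subset, C, subset_span_bp)
    denom = 2.0 * C * subset_span_bp
    half = ci_z * math.sqrt(n_subset) / denom
    return RateEstimate(
        rate_per_bp_per_gen=rate,
        ci_low=max(rate - half, 0.0),
        ci_high=rate + half,
        n_mutations_total=n_subset,
        callable_diploid_sites=denom,
    )


def mean_parental_age(trios: Sequence[TrioRecord]) -> float:
    """Mean over every recorded parental age (both sexes pooled)."""
    ages = [
        a
        for t in trios
        for a in (t.paternal_age, t.maternal_age)
        if a is not None
    ]
    if not ages:
        raise ValueError("no recorded parental ages")
    return sum(ages) / len(ages)
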