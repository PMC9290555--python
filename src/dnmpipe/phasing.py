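"""Parent-of-origin assignment for DNMs and male-bias quantification.

Transmission phasing exploits a third generation: in a 50 kb window around
the DNM, sites where the carrier's parents are opposite homozygotes label
the carrier's two haplotypes as paternal or maternal. Grandoffspring reveal
which haplotype the carrier transmitted; a DNM co-transmitted with the
paternal block is paternal, one transmitted opposite it is maternal, and a
DNM *not* transmitted is assigned to the parent of the non-transmitted
block. Windows distinguished by fewer than two informative sites, or
showing multiple mismatches between blocks (recombination), are left
undetermined — never guessed.

Read-based phasing is consumed as an externally produced table and merged;
mutations phased inconsistently by the two routes are dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

from scipy import stats

from .model import CandidateMutation, Pedigree, PhaseAssignment, SiteGenotypes

log = logging.getLogger(__name__)

#: tolerated block mismatches before a window is declared recombinant
MAX_MISMATCHES = 1


def _index_sites(sites: Iterable[SiteGenotypes]) -> dict[tuple[str, int], SiteGenotypes]:
    return {(s.chrom, s.pos): s for s in sites}


def _carrier_transmission(
    site_window: Sequence[SiteGenotypes],
    carrier: str,
    father: str,
    mother: str,
    grandoffspring: str,
    other_parent: Optional[str],
) -> tuple[Optional[str], int, int]:
    """Which of the carrier's haplotype blocks went to one grandoffspring.

    Returns (block, n_votes, n_mismatches); block is paternal/maternal or
    None when indeterminate (too few informative sites or recombination).
    """
    votes: list[str] = []
    for site in site_window:
        f, m, c = site.calls[father].gt, site.calls[mother].gt, site.calls[carrier].gt
        if {f, m} != {"hom_ref", "hom_alt"} or c != "het":
            continue
        alt_origin = "paternal" if f == "hom_alt" else "maternal"
        g = site.calls[grandoffspring].gt
        o = site.calls[other_parent].gt if other_parent else "hom_ref"
        if g == "missing" or o == "het" or o == "missing":
            continue  # cannot attribute the grandoffspring's alleles
        if o == "hom_ref":
            passed_alt = g in ("het", "hom_alt")
        else:  # other parent hom_alt contributes one alt
            passed_alt = g == "hom_alt"
        if passed_alt:
            votes.append(alt_origin)
        else:
            votes.append("maternal" if alt_origin == "paternal" else "paternal")
    if len(votes) < 2:
        return None, len(votes), 0
    counts = Counter(votes)
    block, top = counts.most_common(1)[0]
    mismatches = len(votes) - top
    if mismatches > MAX_MISMATCHES:
        return None, len(votes), mismatches
    return block, len(votes), mismatches


def transmission_phase(
    dnm: CandidateMutation,
    cohort_sites: Iterable[SiteGenotypes],
    ped: Pedigree,
    window_bp: int = 50_000,
) -> PhaseAssignment:
    """Phase one DNM by transmission to the third generation.

    The window is centered on the DNM (+/- window_bp / 2). Each genotyped
    grandoffspring gives an independent assignment; assignments must agree,
    otherwise the mutation is left undetermined with the conflict flagged.
    """
    carrier = dnm.trio
    if carrier not in ped.parent_map:
        raise ValueError(f"DNM carrier {carrier!r} has no parents in the pedigree")
    father, mother = ped.parent_map[carrier]
    offspring = ped.children_of(carrier)
    half = window_bp / 2

    index = _index_sites(cohort_sites)
    window = sorted(
        (
            s
            for (chrom, pos), s in index.items()
            if chrom == dnm.chrom and pos != dnm.pos and abs(pos - dnm.pos) <= half
        ),
        key=lambda s: s.pos,
    )
    dnm_site = index.get((dnm.chrom, dnm.pos))

    if not offspring:
        return PhaseAssignment(
            trio=carrier, chrom=dnm.chrom, pos=dnm.pos, source="transmission",
            parent="undetermined", reason="no genotyped third generation",
        )

    per_g: list[tuple[str, int]] = []
    n_votes_max = 0
    for g in offspring:
        gf, gm = ped.parent_map.get(g, (None, None))
        other = None
        if gf is not None:
            other = gm if gf == carrier else gf
        block, n_votes, _ = _carrier_transmission(window, carrier, father, mother, g, other)
        n_votes_max = max(n_votes_max, n_votes)
        if block is None:
            continue
        if dnm_site is None or dnm_site.calls[g].gt == "missing":
            continue
        carries = dnm_site.calls[g].gt in ("het", "hom_alt")
        if carries:
            assigned = block
        else:
            assigned = "maternal" if block == "paternal" else "paternal"
        per_g.append((assigned, n_votes))

    if not per_g:
        return PhaseAssignment(
            trio=carrier, chrom=dnm.chrom, pos=dnm.pos, source="transmission",
            parent="undetermined", n_informative_sites=n_votes_max,
            reason="fewer than two informative sites or recombination",
        )
    parents = {a for a, _ in per_g}
    if len(parents) > 1:
        return PhaseAssignment(
            trio=carrier, chrom=dnm.chrom, pos=dnm.pos, source="transmission",
            parent="undetermined", n_informative_sites=max(n for _, n in per_g),
            conflict_flag=True, reason="grandoffspring disagree",
        )
    return PhaseAssignment(
        trio=carrier, chrom=dnm.chrom, pos=dnm.pos, source="transmission",
        parent=parents.pop(), n_informative_sites=max(n for _, n in per_g),
    )


def combine_phase(
    transmission: Sequence[PhaseAssignment],
    read_based: Sequence[PhaseAssignment],
) -> list[PhaseAssignment]:
    """Merge transmission and read-based assignments.

    Determined assignments are unioned; mutations determined by both routes
    must agree, otherwise they are omitted entirely (and logged). Output is
    deterministic, ordered by (chrom, pos).
    """
    merged: dict[tuple, PhaseAssignment] = {}
    for source in (transmission, read_based):
        seen: set[tuple] = set()
        for a in source:
            if a.key in seen:
                raise ValueError(f"duplicate key {a.key} within one phase source")
            seen.add(a.key)
    dropped = []
    by_key: dict[tuple, list[PhaseAssignment]] = {}
    for a in list(transmission) + list(read_based):
        if a.parent == "undetermined":
            continue
        by_key.setdefault(a.key, []).append(a)
    for key, assigns in by_key.items():
        parents = {a.parent for a in assigns}
        if len(parents) > 1:
            dropped.append(key)
            log.warning("phase conflict at %s; mutation omitted", key)
            continue
        a = assigns[0]
        merged[key] = PhaseAssignment(
            trio=a.trio, chrom=a.chrom, pos=a.pos,
            source="combined" if len(assigns) > 1 else a.source,
            parent=a.parent,
            n_informative_sites=max(x.n_informative_sites for x in assigns),
        )
    return sorted(merged.values(), key=lambda a: (a.chrom, a.pos, a.trio))


def male_bias_summary(
    assignments: Sequence[PhaseAssignment],
) -> tuple[int, int, float, float]:
    """(n_paternal, n_maternal, fraction_paternal, two-sided binomial p).

    The exact test is against equal paternal/maternal origin (p = 0.5).
    """
    n_pat = sum(1 for a in assignments if a.parent == "paternal")
    n_mat = sum(1 for a in assignments if a.parent == "maternal")
    n = n_pat + n_mat
    if n == 0:
        raise ValueError("no determined assignments")
    p = stats.binomtest(n_pat, n, 0.5, alternative="two-sided").pvalue
    return n_pat, n_mat, n_pat / n, float(p)


def transmission_tally(
    dnms: Sequence[CandidateMutation],
    ped: Pedigree,
    cohort_sites: Iterable[SiteGenotypes],
) -> tuple[int, int]:
    """Transmission of DNMs to the third generation.

    Returns (n_transmitted, n_opportunities) over every (DNM x genotyped
    grandoffspring-of-carrier) pair; Mendelian expectation is 50%.
    """
    index = _index_sites(cohort_sites)
    n_trans = n_opp = 0
    for dnm in dnms:
        site = index.get((dnm.chrom, dnm.pos))
        if site is None:
            continue
        for g in ped.children_of(dnm.trio):
            call = site.calls.get(g)
            if call is None or call.gt == "missing":
                continue
            n_opp += 1
            if call.gt in ("het", "hom_alt"):
                n_trans += 1
    return n_trans, n_opp
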