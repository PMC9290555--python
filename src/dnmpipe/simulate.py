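"""Synthetic data generators for every pipeline stage.

Three generators cover the pipeline's inputs without any sequencing data:

* ``simulate_trio_cohort`` — a multi-trio genotype cohort (VCF + PED +
  truth table) with DNMs planted at an age-dependent per-bp rate,
  background polymorphic sites for callability estimation, and
  depth/quality/dropout noise producing realistic filter attrition;
* ``simulate_reference_dnms`` — a large phased-DNM cohort (a synthetic
  surrogate for a reference-species dataset) whose per-class counts follow
  linear-in-age Poisson means, for the spectrum machinery;
* ``make_table1_fixture`` — the 11-trio summary table of the cat study
  (counts, ages, callability, haploid spans), the fixture driving the
  rate and regression stages.

All generators are pure functions of (config, seed): identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MUTATION_CLASSES,
    CandidateMutation,
    GenotypeCall,
    Pedigree,
    SiteGenotypes,
)

# ---------------------------------------------------------------------------
# Trio summary fixture (printed study values, used as input data)

_TABLE1_TSV = """\
proband	paternal_age	maternal_age	mutations	mean_depth	callability	haploid_size_mb	rate
679	.	.	22	47.8	0.644	1493	1.14
955	3.9	4.4	21	38.8	0.714	1655	0.89
956	3.9	4.4	7	37.0	0.620	1611	0.35
957	12.0	1.4	29	42.7	0.751	1674	1.15
959	4.8	3.3	20	39.5	0.671	1609	0.93
960	4.8	3.3	24	38.2	0.695	1643	1.05
962	3.4	2.1	20	42.0	0.723	1880	0.74
963	2.3	2.8	17	40.6	0.711	1923	0.62
967	1.7	2.7	17	39.4	0.719	2070	0.57
969	3.9	1.6	27	39.7	0.676	1952	1.02
098	6.1	3.1	29	42.5	0.729	2018	0.99
"""


def make_table1_fixture(path: Optional[str] = None) -> pd.DataFrame:
    """The 11-trio cat study summary table (rate column on the 1e-8 scale).

    One trio (679) has unrecorded parental ages; it is excluded from age
    regressions but included in rate aggregation.
    """
    df = pd.read_csv(
        _io.StringIO(_TABLE1_TSV), sep="\t", dtype={"proband": str}, na_values=["."]
    )
    if path is not None:
        from .io import write_trio_table

        write_trio_table(df, path)
    return df


# ---------------------------------------------------------------------------
# Reference phased-DNM cohort (spectrum surrogate)

#: illustrative class proportions used to split default totals; config, not
#: an empirical claim about any particular dataset
_CLASS_PROPS = {
    "A>C": 0.065,
    "A>G": 0.27,
    "A>T": 0.06,
    "C>A": 0.08,
    "C>G": 0.095,
    "C>T": 0.43,
}


def default_class_coefficients(
    parent: str,
    intercept_total: Optional[float] = None,
    slope_total: Optional[float] = None,
) -> dict[str, tuple[float, float]]:
    """Per-class (beta0, beta1) defaults for the reference simulator.

    Totals default to a paternal slope of 1.51 mutations/year with
    intercept 7, and a maternal slope of 0.37/year with intercept 2.5,
    split across classes by a fixed illustrative spectrum.
    """
    if parent == "paternal":
        b0 = 7.0 if intercept_total is None else intercept_total
        b1 = 1.51 if slope_total is None else slope_total
    elif parent == "maternal":
        b0 = 2.5 if intercept_total is None else intercept_total
        b1 = 0.37 if slope_total is None else slope_total
    else:
        raise ValueError(f"unknown parent {parent!r}")
    return {c: (b0 * p, b1 * p) for c, p in _CLASS_PROPS.items()}


@dataclass
class ReferenceSimConfig:
    """Generative model for the surrogate reference cohort.

    Parental ages are normal, centered near 30 years (father slightly
    older), truncated to [16, 55]. Per-proband, per-parent, per-class
    counts are Poisson with mean beta0_c + beta1_c * age.
    """

    n_probands: int = 2000
    paternal_coef: dict[str, tuple[float, float]] = field(
        default_factory=lambda: default_class_coefficients("paternal")
    )
    maternal_coef: dict[str, tuple[float, float]] = field(
        default_factory=lambda: default_class_coefficients("maternal")
    )
    father_age_mean: float = 31.0
    father_age_sd: float = 4.5
    mother_age_mean: float = 29.2
    mother_age_sd: float = 4.2
    age_min: float = 16.0
    age_max: float = 55.0
    phased_fraction: float = 1.0

    def __post_init__(self) -> None:
        for coefs in (self.paternal_coef, self.maternal_coef):
            for cls, (b0, b1) in coefs.items():
                if b0 + b1 * self.age_min < 0 or b0 + b1 * self.age_max < 0:
                    raise ValueError(f"negative Poisson mean for class {cls} in age range")
        if not (0.0 <= self.phased_fraction <= 1.0):
            raise ValueError("phased_fraction must be in [0, 1]")


def simulate_reference_dnms(
    cfg: ReferenceSimConfig, seed: int, path: Optional[str] = None
) -> pd.DataFrame:
    """One row per simulated mutation: proband, class, parent, ages.

    A ``phased_fraction`` below 1 masks the parent of a random subset of
    rows to ``unknown``, mimicking incompletely phased real cohorts.
    Deterministic given (cfg, seed).
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_probands
    fa = np.clip(
        rng.normal(cfg.father_age_mean, cfg.father_age_sd, n), cfg.age_min, cfg.age_max
    )
    ma = np.clip(
        rng.normal(cfg.mother_age_mean, cfg.mother_age_sd, n), cfg.age_min, cfg.age_max
    )
    rows: list[tuple] = []
    for parent, coefs, ages in (
        ("paternal", cfg.paternal_coef, fa),
        ("maternal", cfg.maternal_coef, ma),
    ):
        for cls in MUTATION_CLASSES:
            b0, b1 = coefs[cls]
            lam = np.maximum(b0 + b1 * ages, 0.0)
            counts = rng.poisson(lam)
            for i in np.nonzero(counts)[0]:
                rows.extend([(f"p{i:05d}", cls, parent, fa[i], ma[i])] * counts[i])
    df = pd.DataFrame(
        rows, columns=["proband", "class", "parent", "father_age", "mother_age"]
    )
    df = df.sort_values(["proband", "class", "parent"], kind="stable").reset_index(drop=True)
    if cfg.phased_fraction < 1.0:
        mask = rng.random(len(df)) >= cfg.phased_fraction
        df.loc[mask, "parent"] = "unknown"
    # ensure every proband appears for downstream zero-count handling
    universe = pd.DataFrame({"proband": [f"p{i:05d}" for i in range(n)], "father_age": fa, "mother_age": ma})
    df.attrs["probands"] = universe
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return df


# ---------------------------------------------------------------------------
# Trio genotype cohort

@dataclass
class CohortSimConfig:
    """Generative model for a multi-trio genotype cohort.

    The per-trio DNM count is Poisson with mean 2 * span * (beta_N +
    beta_p * paternal_age) — the identity-link rate model run forwards.
    Depth is negative-binomial around ``mean_depth`` (or constant when
    ``depth_dispersion`` is None); genotype quality is a deterministic
    function of depth and call correctness plus optional noise; per-member
    ``dropout`` independently degrades a site's evidence so it fails the
    stringent filters, generating the filter attrition that callability
    correction must undo.
    """

    n_trios: int = 11
    genome_span_bp: int = 1_800_000_000
    beta_N: float = 5.4e-9
    beta_p: float = 6.4e-10
    father_age_range: tuple[float, float] = (1.7, 12.0)
    mother_age_range: tuple[float, float] = (1.4, 4.4)
    mean_depth: float = 40.0
    depth_dispersion: Optional[float] = 30.0
    gq_noise_sd: float = 0.0
    genotype_error_rate: float = 0.0
    dropout: tuple[float, float, float] = (0.0, 0.0, 0.0)  # child, father, mother
    n_background_sites: int = 2000
    paternal_origin_fraction: float = 0.75
    even_allele_split: bool = False
    chrom: str = "1"

    def __post_init__(self) -> None:
        for p in (*self.dropout, self.genotype_error_rate, self.paternal_origin_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        lo, hi = self.father_age_range
        if self.beta_N + self.beta_p * hi < 0 or self.beta_N + self.beta_p * lo < 0:
            raise ValueError("negative mutation rate inside the age range")


@dataclass
class TrioCohortSim:
    """In-memory simulated cohort plus its ground truth."""

    sites: list[SiteGenotypes]
    ped: Pedigree
    truth: pd.DataFrame  # trio, chrom, pos, ref, alt, parent
    samples: list[str]
    config: CohortSimConfig

    def trios(self) -> list[tuple[str, str, str]]:
        return self.ped.trios()

    def write_vcf(self, path: str) -> None:
        write_cohort_vcf(self.sites, self.samples, path)

    def write_ped(self, path: str) -> None:
        from .io import write_pedigree

        write_pedigree(self.ped, path)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _mendelian_child(rng, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """Child genotype codes from parents' (0/1/2 alt-dosage) codes."""
    def gamete(par):
        g = np.where(par == 1, rng.integers(0, 2, size=par.shape), par // 2)
        return g.astype(np.int64)

    return gamete(father) + gamete(mother)


def simulate_trio_cohort(cfg: CohortSimConfig, seed: int) -> TrioCohortSim:
    """Generate a trio cohort with planted DNMs and background variation.

    Background polymorphic sites exist so that callability can be
    *estimated* from the cohort itself; the genome span is an accounting
    parameter and is not enumerated site by site.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_trios
    samples: list[str] = []
    for i in range(n):
        samples += [f"F{i:02d}", f"M{i:02d}", f"C{i:02d}"]
    n_samples = len(samples)
    child_cols = np.arange(2, n_samples, 3)
    father_cols = np.arange(0, n_samples, 3)
    mother_cols = np.arange(1, n_samples, 3)

    fa = rng.uniform(*cfg.father_age_range, size=n)
    ma = rng.uniform(*cfg.mother_age_range, size=n)

    # --- plant DNMs per trio at the age-dependent rate
    mu = cfg.beta_N + cfg.beta_p * fa
    n_dnm = rng.poisson(2.0 * cfg.genome_span_bp * mu)
    total_dnm = int(n_dnm.sum())

    n_sites = cfg.n_background_sites + total_dnm
    pos = np.sort(rng.choice(cfg.genome_span_bp - 1, size=n_sites, replace=False)) + 1
    dnm_idx = np.sort(rng.choice(n_sites, size=total_dnm, replace=False))
    is_dnm = np.zeros(n_sites, dtype=bool)
    is_dnm[dnm_idx] = True
    dnm_trio = np.repeat(np.arange(n), n_dnm)
    order = rng.permutation(total_dnm)
    dnm_trio = dnm_trio[order]

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4

    # --- genotype codes (alt dosage)
    gt = np.zeros((n_sites, n_samples), dtype=np.int64)
    bg = ~is_dnm
    n_bg = int(bg.sum())
    # founder genotypes iid: hom_ref .45 / het .20 / hom_alt .35
    founder_draw = rng.random((n_bg, n_samples))
    founder_gt = np.select([founder_draw < 0.45, founder_draw < 0.65], [0, 1], default=2)
    for i in range(n):
        f, m, c = father_cols[i], mother_cols[i], child_cols[i]
        founder_gt[:, c] = _mendelian_child(rng, founder_gt[:, f], founder_gt[:, m])
    gt[bg] = founder_gt
    gt[dnm_idx, child_cols[dnm_trio]] = 1  # everyone else hom-ref at DNM sites

    true_gt = gt.copy()
    # --- genotype errors
    if cfg.genotype_error_rate > 0:
        err = rng.random(gt.shape) < cfg.genotype_error_rate
        shift = rng.integers(1, 3, size=gt.shape)
        gt = np.where(err, (gt + shift) % 3, gt)
        correct = ~err
    else:
        correct = np.ones(gt.shape, dtype=bool)

    # --- depth
    if cfg.depth_dispersion is None:
        dp = np.full(gt.shape, int(round(cfg.mean_depth)), dtype=np.int64)
    else:
        k = cfg.depth_dispersion
        lam = rng.gamma(k, cfg.mean_depth / k, size=gt.shape)
        dp = rng.poisson(lam)

    # --- allelic depths
    if cfg.even_allele_split:
        het_alt = dp // 2
        alt = np.where(gt == 1, het_alt, 0)
        alt = np.where(gt == 2, dp, alt)
        adf = alt // 2
    else:
        alt = np.where(gt == 1, rng.binomial(np.maximum(dp, 0), 0.5), 0)
        alt = np.where(gt == 2, dp, alt)
        adf = rng.binomial(alt, 0.5)
    adr = alt - adf

    # --- genotype quality: deterministic in depth and correctness (+ noise)
    gq = np.where(correct, np.minimum(99, (2.5 * dp).astype(np.int64)), 25)
    if cfg.gq_noise_sd > 0:
        gq = gq + rng.normal(0.0, cfg.gq_noise_sd, size=gq.shape).round().astype(np.int64)
    gq = np.clip(gq, 0, 99)

    # --- per-member dropout: degrade evidence so the site fails filters
    for cols, p in zip((child_cols, father_cols, mother_cols), cfg.dropout):
        if p <= 0:
            continue
        drop = rng.random((n_sites, len(cols))) < p
        mode = rng.random((n_sites, len(cols))) < 0.5
        sub_dp = dp[:, cols]
        sub_gq = gq[:, cols]
        dp[:, cols] = np.where(drop & mode, 8, sub_dp)
        gq[:, cols] = np.where(drop & ~mode, 40, sub_gq)

    dnm_parent = np.where(
        rng.random(total_dnm) < cfg.paternal_origin_fraction, "paternal", "maternal"
    )

    sites: list[SiteGenotypes] = []
    for s in range(n_sites):
        calls = {}
        for j, sample in enumerate(samples):
            code = gt[s, j]
            calls[sample] = GenotypeCall(
                gt=("hom_ref", "het", "hom_alt")[code],
                dp=int(dp[s, j]),
                gq=int(gq[s, j]),
                ad_ref=int(dp[s, j] - alt[s, j]),
                ad_alt=int(alt[s, j]),
                adf=int(adf[s, j]),
                adr=int(adr[s, j]),
            )
        sites.append(
            SiteGenotypes(
                chrom=cfg.chrom,
                pos=int(pos[s]),
                ref=str(bases[ref_i[s]]),
                alt=str(bases[alt_i[s]]),
                calls=calls,
            )
        )

    individuals = list(samples)
    parent_map = {f"C{i:02d}": (f"F{i:02d}", f"M{i:02d}") for i in range(n)}
    ages = {f"C{i:02d}": (float(fa[i]), float(ma[i])) for i in range(n)}
    sex = {}
    for i in range(n):
        sex[f"F{i:02d}"] = "male"
        sex[f"M{i:02d}"] = "female"
        sex[f"C{i:02d}"] = "unknown"
    ped = Pedigree(individuals=individuals, parent_map=parent_map, ages=ages, sex=sex)

    truth = pd.DataFrame(
        {
            "trio": [f"C{t:02d}" for t in dnm_trio],
            "chrom": cfg.chrom,
            "pos": pos[dnm_idx],
            "ref": bases[ref_i[dnm_idx]],
            "alt": bases[alt_i[dnm_idx]],
            "parent": dnm_parent,
        }
    ).sort_values("pos", kind="stable").reset_index(drop=True)
    return TrioCohortSim(sites=sites, ped=ped, truth=truth, samples=samples, config=cfg)


def write_cohort_vcf(
    sites: Sequence[SiteGenotypes], samples: Sequence[str], path: str
) -> None:
    """Write sites as an uncompressed VCF 4.2 with GT:DP:GQ:AD:ADF:ADR."""
    gt_codes = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    chroms = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward allelic depths">\n')
        fh.write('##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for s in sites:
            cols = [s.chrom, str(s.pos), ".", s.ref, s.alt, ".", "PASS", ".", "GT:DP:GQ:AD:ADF:ADR"]
            for sample in samples:
                c = s.calls[sample]
                adf_ref = (c.dp or 0) - (c.ad_alt or 0)  # ref strand split not modeled
                cols.append(
                    f"{gt_codes[c.gt]}:{c.dp}:{c.gq}:{c.ad_ref},{c.ad_alt}:"
                    f"{adf_ref},{c.adf}:0,{c.adr}"
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Three-generation phasing scenario

def simulate_phasing_case(
    seed: int,
    n_informative: int = 8,
    origin: str = "paternal",
    transmitted: bool = True,
    recombinant_sites: int = 0,
    n_grandoffspring: int = 1,
    window_bp: int = 50_000,
    dnm_pos: int = 1_000_000,
) -> tuple[CandidateMutation, list[SiteGenotypes], Pedigree, str]:
    """A 3-generation pedigree window with a DNM of known parental origin.

    The carrier P (child of F x M, mated to founder O) bears a DNM on the
    haplotype inherited from ``origin``. Informative sites (F and M
    opposite homozygotes) label P's haplotypes inside the window; each
    grandoffspring receives either the DNM haplotype (``transmitted``) or
    the other one. ``recombinant_sites`` flips the transmitted block at
    that many informative sites to emulate recombination inside the window.
    Returns (dnm, sites, pedigree, true_origin).
    """
    rng = np.random.default_rng(seed)
    if origin not in ("paternal", "maternal"):
        raise ValueError("origin must be paternal or maternal")
    g_ids = [f"G{j}" for j in range(n_grandoffspring)]
    ped = Pedigree(
        individuals=["F", "M", "O", "P"] + g_ids,
        parent_map={"P": ("F", "M"), **{g: ("P", "O") for g in g_ids}},
        ages={"P": (5.0, 4.0)},
        sex={"F": "male", "M": "female", "P": "male", "O": "female"},
    )
    evid = dict(dp=40, gq=99, ad_ref=20, ad_alt=20, adf=10, adr=10)
    hom_ref = GenotypeCall(gt="hom_ref", dp=40, gq=99, ad_ref=40, ad_alt=0, adf=0, adr=0)
    hom_alt = GenotypeCall(gt="hom_alt", dp=40, gq=99, ad_ref=0, ad_alt=40, adf=20, adr=20)
    het = GenotypeCall(gt="het", **evid)

    candidates = np.arange(-window_bp // 2 + 1, window_bp // 2)
    candidates = candidates[candidates != 0]
    offsets = rng.choice(candidates, size=n_informative, replace=False)
    sites: list[SiteGenotypes] = []
    transmitted_block = origin if transmitted else (
        "maternal" if origin == "paternal" else "paternal"
    )
    recomb = set(rng.choice(len(offsets), size=min(recombinant_sites, len(offsets)), replace=False))
    for k, off in enumerate(sorted(offsets)):
        alt_origin = "paternal" if rng.random() < 0.5 else "maternal"
        f_call, m_call = (hom_alt, hom_ref) if alt_origin == "paternal" else (hom_ref, hom_alt)
        block_here = transmitted_block
        if k in recomb:
            block_here = "maternal" if block_here == "paternal" else "paternal"
        passed_alt = block_here == alt_origin
        calls = {"F": f_call, "M": m_call, "O": hom_ref, "P": het}
        for g in g_ids:
            calls[g] = het if passed_alt else hom_ref
        sites.append(
            SiteGenotypes(chrom="1", pos=int(dnm_pos + off), ref="A", alt="G", calls=calls)
        )
    # the DNM site itself: P het, everyone in generations 1-2 hom-ref
    dnm_calls = {"F": hom_ref, "M": hom_ref, "O": hom_ref, "P": het}
    for g in g_ids:
        dnm_calls[g] = het if transmitted else hom_ref
    sites.append(SiteGenotypes(chrom="1", pos=dnm_pos, ref="C", alt="T", calls=dnm_calls))
    sites.sort(key=lambda s: s.pos)
    dnm = CandidateMutation(
        trio="P", chrom="1", pos=dnm_pos, ref="C", alt="T",
        child_call=het, father_call=hom_ref, mother_call=hom_ref,
    )
    return dnm, sites, ped, origin
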