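"""Readers and writers for the pipeline's on-disk formats.

VCF 4.x genotype input (via cyvcf2), 6-column PED pedigrees with two
optional parental-age columns, and the tab-separated tables that cross
stage boundaries: the trio summary table, the candidate/high-confidence DNM
tables, and the phase table. Coordinates are 1-based throughout, inherited
from VCF.
"""

from __future__ import annotations

import logging
from typing import Iterator, Optional, Sequence

import pandas as pd

from .model import (
    FILTER_NAMES,
    CandidateMutation,
    GenotypeCall,
    Pedigree,
    PedigreeError,
    PhaseAssignment,
    SiteGenotypes,
    TrioCallability,
    TrioRecord,
)

log = logging.getLogger(__name__)

#: chromosome names excluded by the default autosome filter
NON_AUTOSOMES = {"x", "y", "mt", "m", "chrx", "chry", "chrm", "chrmt"}

_BASES = {"A", "C", "G", "T"}


def _fmt_int(value) -> Optional[int]:
    """htslib encodes missing integer FORMAT values as large negatives."""
    if value is None:
        return None
    v = int(value)
    return v if v >= 0 else None


def read_vcf_cohort(
    path: str,
    samples: Optional[Sequence[str]] = None,
    autosomes: Optional[set[str]] = None,
    drop_nonpass: bool = True,
    counters: Optional[dict] = None,
) -> Iterator[SiteGenotypes]:
    """Stream autosomal biallelic SNV sites from a cohort VCF.

    Multi-allelic records, indels, non-autosomes and (by default) records
    whose FILTER column is not PASS are skipped, with per-reason counts
    accumulated in ``counters`` when supplied. Missing FORMAT values surface
    as None / genotype ``missing``, never as zero.

    Raises a configuration error if a requested sample is absent from the
    VCF header, and a parse error naming the record index on malformed rows.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    header_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in header_samples]
        if missing:
            raise ValueError(
                f"samples absent from VCF header: {missing} (configuration error)"
            )
        vcf.set_samples(list(samples))
    use_samples = list(vcf.samples)
    if counters is None:
        counters = {}
    for key in ("multiallelic", "indel", "non_autosome", "nonpass", "emitted"):
        counters.setdefault(key, 0)
    gt_names = {0: "hom_ref", 1: "het", 2: "hom_alt", 3: "missing"}

    for idx, var in enumerate(vcf):
        try:
            if len(var.ALT) != 1:
                counters["multiallelic"] += 1
                continue
            ref, alt = var.REF.upper(), var.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                counters["indel"] += 1
                continue
            chrom = var.CHROM
            if not is_autosome(chrom, autosomes):
                counters["non_autosome"] += 1
                continue
            if drop_nonpass and var.FILTER is not None:
                counters["nonpass"] += 1
                continue
            gts = var.gt_types

            def fmt(tag):
                try:
                    return var.format(tag)
                except KeyError:  # field absent from this VCF's header
                    return None

            dp = fmt("DP")
            gq = fmt("GQ")
            ad = fmt("AD")
            adf = fmt("ADF")
            adr = fmt("ADR")
            calls = {}
            for i, sample in enumerate(use_samples):
                calls[sample] = GenotypeCall(
                    gt=gt_names[int(gts[i])],
                    dp=_fmt_int(dp[i][0]) if dp is not None else None,
                    gq=_fmt_int(gq[i][0]) if gq is not None else None,
                    ad_ref=_fmt_int(ad[i][0]) if ad is not None else None,
                    ad_alt=_fmt_int(ad[i][1]) if ad is not None and ad.shape[1] > 1 else None,
                    adf=_fmt_int(adf[i][-1]) if adf is not None else None,
                    adr=_fmt_int(adr[i][-1]) if adr is not None else None,
                )
            counters["emitted"] += 1
            yield SiteGenotypes(chrom=chrom, pos=var.POS, ref=ref, alt=alt, calls=calls)
        except (ValueError, KeyError):
            raise
        except Exception as exc:  # htslib-level failures
            raise ValueError(f"malformed VCF record #{idx + 1} in {path}: {exc}") from exc

    if counters["multiallelic"]:
        log.info("skipped %d multi-allelic records", counters["multiallelic"])


def is_autosome(chrom: str, autosomes: Optional[set[str]] = None) -> bool:
    """True if ``chrom`` passes the autosome filter.

    With an explicit ``autosomes`` set, membership decides; otherwise
    everything not named like X/Y/MT is accepted. The sex/mito name list is
    configuration, not inference — reference genomes differ.
    """
    if autosomes is not None:
        return chrom in autosomes
    return chrom.lower() not in NON_AUTOSOMES


_AGE_MISSING = {"", ".", "-", "na", "nan", "none", "—"}


def _parse_age(tok: str) -> Optional[float]:
    if tok.strip().lower() in _AGE_MISSING:
        return None
    return float(tok)


def read_pedigree(path: str) -> Pedigree:
    """Read a PED file (FID IID FATHER MOTHER SEX PHENO [father_age mother_age]).

    ``0`` marks a missing parent. Children with exactly one known parent are
    rejected (a trio design needs both or neither). Validation (existence of
    parents, acyclicity, positive ages) happens in the Pedigree constructor.
    """
    individuals: list[str] = []
    parent_map: dict[str, tuple[str, str]] = {}
    ages: dict[str, tuple[Optional[float], Optional[float]]] = {}
    sex: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) < 6:
                raise PedigreeError(f"{path}:{ln}: expected >= 6 PED columns")
            _, iid, father, mother, sx, _ = tok[:6]
            if iid in individuals:
                raise PedigreeError(f"{path}:{ln}: duplicated individual {iid!r}")
            individuals.append(iid)
            sex[iid] = {"1": "male", "2": "female"}.get(sx, "unknown")
            if (father == "0") != (mother == "0"):
                raise PedigreeError(f"{path}:{ln}: {iid!r} has exactly one parent")
            if father != "0":
                parent_map[iid] = (father, mother)
            if len(tok) >= 8:
                ages[iid] = (_parse_age(tok[6]), _parse_age(tok[7]))
    return Pedigree(individuals=individuals, parent_map=parent_map, ages=ages, sex=sex)


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#FID\tIID\tFATHER\tMOTHER\tSEX\tPHENO\tFATHER_AGE\tMOTHER_AGE\n")
        for iid in ped.individuals:
            father, mother = ped.parent_map.get(iid, ("0", "0"))
            sx = {"male": "1", "female": "2"}.get(ped.sex.get(iid, "unknown"), "0")
            fa, ma = ped.ages.get(iid, (None, None))
            fh.write(
                "\t".join(
                    [
                        "FAM",
                        iid,
                        father,
                        mother,
                        sx,
                        "0",
                        "." if fa is None else f"{fa:.12g}",
                        "." if ma is None else f"{ma:.12g}",
                    ]
                )
                + "\n"
            )


TRIO_TABLE_COLUMNS = [
    "proband",
    "paternal_age",
    "maternal_age",
    "mutations",
    "mean_depth",
    "callability",
    "haploid_size_mb",
    "rate",
]


def read_trio_table(path: str) -> pd.DataFrame:
    """Read a trio summary table (one row per trio, rate on the 1e-8 scale)."""
    df = pd.read_csv(path, sep="\t", dtype={"proband": str}, na_values=["."])
    missing = [c for c in TRIO_TABLE_COLUMNS if c not in df.columns and c != "rate"]
    if missing:
        raise ValueError(f"trio table {path} lacks columns {missing}")
    return df


def write_trio_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%g", na_rep=".")


def trio_records_from_table(df: pd.DataFrame) -> list[TrioRecord]:
    """Build TrioRecords from a summary table.

    Only the product callability C is available in the table, so it is
    stored as the child component with the parent components at 1.
    """
    records = []
    for row in df.itertuples(index=False):
        records.append(
            TrioRecord(
                proband=str(row.proband),
                paternal_age=None if pd.isna(row.paternal_age) else float(row.paternal_age),
                maternal_age=None if pd.isna(row.maternal_age) else float(row.maternal_age),
                n_mutations=int(row.mutations),
                callability=TrioCallability(
                    c_child=float(row.callability), c_father=1.0, c_mother=1.0
                ),
                haploid_span_bp=int(round(float(row.haploid_size_mb) * 1e6)),
                mean_depth=None if pd.isna(row.mean_depth) else float(row.mean_depth),
            )
        )
    return records


def candidates_to_frame(cands: Sequence[CandidateMutation]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {
            "trio": c.trio,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "class": c.mutation_class,
            "status": c.status,
        }
        for name in FILTER_NAMES:
            row[f"filter_{name}"] = c.filter_verdicts.get(name, "not_evaluated")
        rows.append(row)
    return pd.DataFrame(rows)


def write_dnm_table(cands: Sequence[CandidateMutation], path: str) -> None:
    """High-confidence DNM table: trio, chrom, pos, ref, alt, class."""
    df = candidates_to_frame(cands)
    if len(df):
        df = df[df["status"] == "high_confidence"]
        df = df[["trio", "chrom", "pos", "ref", "alt", "class"]]
    df.to_csv(path, sep="\t", index=False)


def read_dnm_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"trio": str, "chrom": str})


def write_phase_table(assignments: Sequence[PhaseAssignment], path: str) -> None:
    pd.DataFrame(
        [
            {
                "trio": a.trio,
                "chrom": a.chrom,
                "pos": a.pos,
                "source": a.source,
                "parent": a.parent,
                "n_informative_sites": a.n_informative_sites,
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def read_phase_table(path: str, source: str = "read_based") -> list[PhaseAssignment]:
    """Read a phase table, e.g. one produced by an external read-backed phaser.

    Expected columns: trio, chrom, pos, parent [, source, n_informative_sites].
    """
    df = pd.read_csv(path, sep="\t", dtype={"trio": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PhaseAssignment(
                trio=str(row.trio),
                chrom=str(row.chrom),
                pos=int(row.pos),
                source=getattr(row, "source", source),
                parent=str(row.parent),
                n_informative_sites=int(getattr(row, "n_informative_sites", 0)),
            )
        )
    return out
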