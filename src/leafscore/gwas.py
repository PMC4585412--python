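"""Post-GWAS summarisation: SNP filtering, thresholds, locus clumping.

This module never runs an association model; it post-processes a per-SNP
summary table (chromosome, position, p-value, minor allele frequency,
minor-allele accession count, optionally trait and growth stage):

* SNPs are kept when MAF ≥ 0.05 and at least 6 accessions carry the minor
  allele (both bounds inclusive);
* genome-wide p-value thresholds follow the effective-marker Bonferroni
  rule — suggestive 1/N and significant 0.05/N for N effective independent
  markers, so significant/suggestive = 0.05 exactly;
* associated SNPs are clumped into loci: within a chromosome, a maximal
  run of SNPs in which every adjacent pair is less than 300 kb apart; a
  locus spans its member extremes and is represented by its lead SNP
  (smallest p-value, ties to the smaller position);
* loci detected for different traits, or by the same trait at different
  growth stages, are cross-referenced by interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SNP_COLUMNS",
    "Thresholds",
    "Locus",
    "filter_snps",
    "thresholds",
    "clump_loci",
    "loci_table",
    "cross_trait_overlap",
    "read_snp_table",
]

#: Required columns of a SNP summary table.
SNP_COLUMNS = ("chrom", "pos", "pvalue")


class Thresholds(NamedTuple):
    suggestive: float  # 1/N
    significant: float  # 0.05/N


@dataclass
class Locus:
    """A clumped chromosomal region of associated SNPs."""

    chrom: str
    start: int  # position of the first member (bp, 1-based)
    end: int  # position of the last member
    members: pd.DataFrame  # member SNP rows, sorted by position
    lead: pd.Series  # member with minimal p-value (tie: smaller position)

    @property
    def n_snps(self) -> int:
        return len(self.members)

    def overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and not (
            self.end < other.start or other.end < self.start
        )


def _check_columns(df: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table lacks columns: {missing}")


def filter_snps(
    records: pd.DataFrame, maf_min: float = 0.05, mac_min: int = 6
) -> pd.DataFrame:
    """Keep SNPs with MAF ≥ ``maf_min`` and minor-allele count ≥ ``mac_min``."""
    _check_columns(records, ("maf", "mac"))
    keep = (records["maf"] >= maf_min) & (records["mac"] >= mac_min)
    return records.loc[keep].reset_index(drop=True)


def thresholds(n_eff: float) -> Thresholds:
    """Bonferroni thresholds (suggestive 1/N, significant 0.05/N)."""
    if n_eff < 1:
        raise ValueError("effective marker count must be >= 1")
    return Thresholds(suggestive=1.0 / n_eff, significant=0.05 / n_eff)


def clump_loci(records: pd.DataFrame, gap_bp: int = 300_000) -> list[Locus]:
    """Clump associated SNPs into loci by the adjacent-gap rule.

    Within each chromosome (loci never span chromosomes), SNPs sorted by
    position belong to one locus while every adjacent pair is less than
    ``gap_bp`` apart; a gap of ``gap_bp`` or more starts a new locus.
    Every input SNP belongs to exactly one locus.
    """
    _check_columns(records, SNP_COLUMNS)
    loci: list[Locus] = []
    if len(records) == 0:
        return loci
    snps = records.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for chrom, group in snps.groupby("chrom", sort=True):
        pos = group["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp) + 1
        for chunk in np.split(np.arange(len(group)), breaks):
            members = group.iloc[chunk].reset_index(drop=True)
            lead_idx = members.sort_values(
                ["pvalue", "pos"], kind="mergesort"
            ).index[0]
            loci.append(
                Locus(
                    chrom=str(chrom),
                    start=int(members["pos"].iloc[0]),
                    end=int(members["pos"].iloc[-1]),
                    members=members,
                    lead=members.loc[lead_idx],
                )
            )
    return loci


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    """Flatten loci into a summary table (one row per locus)."""
    rows = []
    for locus in loci:
        row = {
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "n_snps": locus.n_snps,
            "lead_pos": int(locus.lead["pos"]),
            "lead_p": float(locus.lead["pvalue"]),
        }
        for extra in ("trait", "stage"):
            if extra in locus.members.columns:
                row[extra] = locus.members[extra].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def cross_trait_overlap(
    loci_by_group: dict[Hashable, list[Locus]]
) -> pd.DataFrame:
    """Cross-reference loci detected by different (trait, stage) groups.

    For every locus, lists the groups whose loci overlap its interval
    (including its own group).  Returns one row per locus with the
    overlapping group keys and their count.
    """
    flat = [
        (group, locus)
        for group, loci in loci_by_group.items()
        for locus in loci
    ]
    rows = []
    for group, locus in flat:
        hits = sorted(
            {str(g) for g, other in flat if locus.overlaps(other)}
        )
        rows.append(
            {
                "group": str(group),
                "chrom": locus.chrom,
                "start": locus.start,
                "end": locus.end,
                "n_overlapping_groups": len(hits),
                "overlapping_groups": ";".join(hits),
            }
        )
    return pd.DataFrame(rows)


def read_snp_table(path) -> pd.DataFrame:
    """Read a tab-delimited SNP summary table and validate its columns."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, SNP_COLUMNS)
    return df
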