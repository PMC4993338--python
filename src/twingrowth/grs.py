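"""Un-weighted 7-SNP genetic risk score (GRS) for shorter telomere length.

The score is the plain sum of risk-allele dosages over seven SNPs previously
associated with leukocyte telomere length (rs2736100, rs2281929, rs11125529,
rs10936599, rs7675998, rs9420907, rs8105767), giving a 0-14 range; it is
centered on its sample mean before entering any model.  The risk-allele map
ships with PLACEHOLDER alleles and coordinates: the true effect alleles were
not published in the available study text, so real-data use requires editing
the map from the source GWAS.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .simulate import GRS_SNPS


@dataclass(frozen=True)
class RiskAllele:
    rsid: str
    risk_allele: str
    other_allele: str
    source: str  # "genotyped" or "imputed"
    chrom: str = "1"
    pos: int = 1

    def __post_init__(self) -> None:
        for a in (self.risk_allele, self.other_allele):
            if a not in ("A", "C", "G", "T"):
                raise ValueError(f"{self.rsid}: allele {a!r} is not a single base")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele are identical")
        if self.source not in ("genotyped", "imputed"):
            raise ValueError(f"{self.rsid}: source must be genotyped/imputed")


class RiskAlleleMap:
    """The seven SNPs of the score, keyed by rsID."""

    def __init__(self, entries: list[RiskAllele]):
        if len(entries) != 7:
            raise ValueError(f"risk-allele map needs exactly 7 SNPs, got {len(entries)}")
        rsids = [e.rsid for e in entries]
        if len(set(rsids)) != 7:
            raise ValueError("rsIDs must be unique")
        self._entries = {e.rsid: e for e in entries}

    def __getitem__(self, rsid: str) -> RiskAllele:
        return self._entries[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._entries

    @property
    def rsids(self) -> list[str]:
        return list(self._entries)

    @classmethod
    def from_yaml(cls, path) -> "RiskAlleleMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls([RiskAllele(rsid=rsid, **fields) for rsid, fields in raw.items()])

    def to_yaml(self, path) -> None:
        raw = {
            e.rsid: {
                "risk_allele": e.risk_allele,
                "other_allele": e.other_allele,
                "source": e.source,
                "chrom": e.chrom,
                "pos": e.pos,
            }
            for e in self._entries.values()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_risk_allele_map() -> RiskAlleleMap:
    """Shipped map with placeholder alleles (edit before real-data use)."""
    ref = importlib.resources.files("twingrowth") / "profiles" / "risk_alleles.yaml"
    with importlib.resources.as_file(ref) as path:
        return RiskAlleleMap.from_yaml(path)


def compute_grs(
    genotypes: pd.DataFrame,
    allele_map: RiskAlleleMap | None = None,
    missing: str = "strict",
) -> pd.Series:
    """Per-individual risk-allele count over the 7 SNPs (range 0-14).

    ``missing='strict'`` sets the score to NaN for any individual with a
    missing dosage (complete-case, the default); ``missing='mean'`` imputes
    each missing dosage with that SNP's sample mean.
    """
    allele_map = allele_map or default_risk_allele_map()
    snp_cols = [c for c in genotypes.columns if c != "individual_id"]
    unmatched = [c for c in snp_cols if c not in allele_map]
    if unmatched:
        raise ValueError(f"genotype columns not in the risk-allele map: {unmatched}")
    absent = [r for r in allele_map.rsids if r not in snp_cols]
    if absent:
        raise ValueError(f"genotype table missing SNPs: {absent}")
    if missing not in ("strict", "mean"):
        raise ValueError("missing must be 'strict' or 'mean'")

    dos = genotypes[allele_map.rsids].astype(float)
    valid = dos.notna()
    if ((dos < 0) | (dos > 2)).any().any():
        raise ValueError("dosages must lie in [0, 2]")
    if missing == "mean":
        dos = dos.fillna(dos.mean())
        score = dos.sum(axis=1)
    else:
        score = dos.sum(axis=1).where(valid.all(axis=1))
    score.name = "grs"
    score.index = pd.Index(genotypes["individual_id"], name="individual_id")
    return score


def center_grs(scores: pd.Series) -> pd.Series:
    """Center scores on their mean over non-missing entries (mean becomes 0)."""
    if scores.notna().sum() == 0:
        raise ValueError("all GRS values are missing; cannot center")
    return scores - scores.mean()


def read_genotypes_vcf(path, allele_map: RiskAlleleMap | None = None) -> pd.DataFrame:
    """Read risk-allele dosages for the 7 score SNPs from a VCF (v4.2, GT).

    Handles the risk allele being either REF or ALT; multi-allelic sites and
    sites whose alleles do not match the map are rejected.  Missing genotypes
    become NaN dosages.
    """
    from cyvcf2 import VCF

    allele_map = allele_map or default_risk_allele_map()
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in allele_map:
            continue
        if len(variant.ALT) != 1:
            raise ValueError(f"{rsid}: multi-allelic sites are not supported")
        entry = allele_map[rsid]
        ref, alt = variant.REF, variant.ALT[0]
        if entry.risk_allele == alt:
            count_alt = True
        elif entry.risk_allele == ref:
            count_alt = False
        else:
            raise ValueError(
                f"{rsid}: risk allele {entry.risk_allele} matches neither "
                f"REF ({ref}) nor ALT ({alt})"
            )
        dose = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                n_alt = sum(a > 0 for a in alleles)
                dose[i] = n_alt if count_alt else 2 - n_alt
        dosages[rsid] = dose
    absent = [r for r in allele_map.rsids if r not in dosages]
    if absent:
        raise ValueError(f"VCF missing SNPs: {absent}")
    out = pd.DataFrame({"individual_id": samples})
    for rsid in allele_map.rsids:
        out[rsid] = dosages[rsid]
    return out


def write_genotypes_vcf(
    genotypes: pd.DataFrame, path, allele_map: RiskAlleleMap | None = None
) -> None:
    """Write hard-call dosages as a minimal VCF v4.2 with GT genotypes.

    The risk allele is written as ALT and the map's other allele as REF, so a
    dosage of d becomes a genotype with d ALT alleles.
    """
    allele_map = allele_map or default_risk_allele_map()
    snp_cols = [c for c in genotypes.columns if c != "individual_id"]
    absent = [r for r in allele_map.rsids if r not in snp_cols]
    if absent:
        raise ValueError(f"genotype table missing SNPs: {absent}")
    samples = list(genotypes["individual_id"])
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    entries = sorted(
        (allele_map[r] for r in allele_map.rsids),
        key=lambda e: (str(e.chrom), int(e.pos)),
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(e.chrom for e in entries):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for e in entries:
            dos = genotypes[e.rsid].to_numpy()
            gts = []
            for d in dos:
                if pd.isna(d):
                    gts.append("./.")
                else:
                    d = int(round(float(d)))
                    if d not in gt_strings:
                        raise ValueError(f"{e.rsid}: dosage {d} is not a hard call")
                    gts.append(gt_strings[d])
            fh.write(
                f"{e.chrom}\t{e.pos}\t{e.rsid}\t{e.other_allele}\t{e.risk_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
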