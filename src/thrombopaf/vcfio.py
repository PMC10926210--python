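"""Optional VCF import: GT fields to risk-allele counts.

The risk allele at each site follows the panel coding rule unless an
explicit allele is given:

- ``minor_allele_risk``: the ALT allele is the risk allele (count of ALT).
- ``major_allele_risk``: the REF allele is the risk allele (2 - ALT count).
  This presumes the reference allele is the major allele at the site, as it
  is for the panel's major-allele-risk SNPs; pass ``risk_alleles`` to
  override where that does not hold.
- ``abo_deletion``: the non-deletion (G) allele is the risk allele; the
  allele with the shorter sequence is taken to be the O deletion.

Missing genotypes (``./.``) become NaN. Requires cyvcf2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import CodingRule, Panel

__all__ = ["read_vcf_genotypes"]


def _risk_allele_index(variant, rule: CodingRule, override: str | None) -> int:
    """0 for REF, 1.. for ALT alleles."""
    alleles = [variant.REF] + list(variant.ALT)
    if override is not None:
        if override not in alleles:
            raise ValueError(
                f"risk allele {override!r} not among alleles {alleles} "
                f"at {variant.ID or variant.POS}"
            )
        return alleles.index(override)
    if rule is CodingRule.minor_allele_risk:
        return 1
    if rule is CodingRule.major_allele_risk:
        return 0
    # abo_deletion: risk allele is the longer (non-deletion) sequence
    lengths = [len(a) for a in alleles]
    return int(np.argmax(lengths))


def read_vcf_genotypes(
    path,
    panel: Panel,
    risk_alleles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read per-individual risk-allele counts for panel SNPs from a VCF.

    Sites are matched by VCF ID against ``panel`` snp_ids. Returns a
    DataFrame indexed by VCF sample name with one 0/1/2/NaN column per
    panel SNP found; panel SNPs absent from the file give all-NaN columns.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "VCF import requires cyvcf2 (install thrombopaf[vcf])"
        ) from exc

    risk_alleles = risk_alleles or {}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    counts = {s.snp_id: np.full(len(samples), np.nan) for s in panel}
    wanted = {s.snp_id: s for s in panel}
    for variant in vcf:
        snp = wanted.get(variant.ID)
        if snp is None:
            continue
        ridx = _risk_allele_index(
            variant, snp.coding_rule, risk_alleles.get(snp.snp_id)
        )
        out = np.zeros(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a = [x for x in gt[:-1]]
            if any(x < 0 for x in a):
                out[i] = np.nan
            else:
                out[i] = sum(1 for x in a if x == ridx)
        counts[snp.snp_id] = out
    vcf.close()
    return pd.DataFrame(counts, index=pd.Index(samples, name="sample"))
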