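"""SNP panel definitions and carrier-coding rules.

A *panel* is an ordered list of :class:`SnpDef` entries describing the loci
under study: the identifier, the gene label, how the risk allele is defined
(minor allele, major allele, or the ABO O-deletion convention where the G
allele marks non-O blood type), the population risk-allele frequency used by
the simulator, and per-sex simulation log hazard ratios.

The packaged default panel (17 prothrombotic loci with subcohort allele
frequencies from a Norwegian population-based case-cohort study of venous
thromboembolism) is returned by :func:`default_panel`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "CodingRule",
    "SnpDef",
    "Panel",
    "load_panel",
    "default_panel",
    "CUMULATIVE_6SNP_ORDER",
]

#: Fixed published order of the 6-SNP cumulative model (descending individual
#: PAF in the total population, with F2 rs1799963 force-included last).
CUMULATIVE_6SNP_ORDER = (
    "rs8176719",  # ABO
    "rs2036914",  # F11
    "rs2289252",  # F11
    "rs6025",     # FVL (factor V Leiden)
    "rs2066865",  # FGG
    "rs1799963",  # F2 (prothrombin G20210A)
)


class CodingRule(str, enum.Enum):
    """How the risk allele at a site is defined.

    ``minor_allele_risk``
        The minor (alternate) allele is the risk allele.
    ``major_allele_risk``
        The major allele is the risk allele; carrier = >=1 major allele.
    ``abo_deletion``
        ABO rs8176719: the G (non-deletion) allele marks non-O blood type
        and is the risk allele; homozygous deletion (blood type O) is the
        reference group.
    """

    minor_allele_risk = "minor_allele_risk"
    major_allele_risk = "major_allele_risk"
    abo_deletion = "abo_deletion"


@dataclass(frozen=True)
class SnpDef:
    """One panel entry.

    Parameters
    ----------
    snp_id
        rs identifier, unique within a panel.
    gene
        Gene label used in reports (e.g. ``"FVL"`` for rs6025).
    coding_rule
        Risk-allele convention, see :class:`CodingRule`.
    risk_allele_freq
        Population risk-allele frequency ``q`` in [0, 1]; simulation
        parameter (Hardy-Weinberg genotype draws).
    log_hr_female, log_hr_male
        Per-sex log hazard ratios (carrier vs noncarrier) used by the
        cohort simulator.
    """

    snp_id: str
    gene: str
    coding_rule: CodingRule = CodingRule.minor_allele_risk
    risk_allele_freq: float = 0.0
    log_hr_female: float = 0.0
    log_hr_male: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ValueError(
                f"{self.snp_id}: risk_allele_freq must be in [0, 1], "
                f"got {self.risk_allele_freq}"
            )
        object.__setattr__(self, "coding_rule", CodingRule(self.coding_rule))

    def log_hr(self, sex: str) -> float:
        if sex == "female":
            return self.log_hr_female
        if sex == "male":
            return self.log_hr_male
        raise ValueError(f"unknown sex {sex!r}")


class Panel(list):
    """An ordered list of :class:`SnpDef` with unique ``snp_id``."""

    def __init__(self, snps: Iterable[SnpDef] = ()):  # noqa: D107
        super().__init__(snps)
        seen = set()
        for snp in self:
            if not isinstance(snp, SnpDef):
                raise TypeError("Panel entries must be SnpDef")
            if snp.snp_id in seen:
                raise ValueError(f"duplicate snp_id {snp.snp_id!r} in panel")
            seen.add(snp.snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self]

    def get(self, snp_id: str) -> SnpDef:
        for snp in self:
            if snp.snp_id == snp_id:
                return snp
        raise KeyError(f"snp_id {snp_id!r} not in panel")

    def subset(self, snp_ids: Sequence[str]) -> "Panel":
        return Panel(self.get(s) for s in snp_ids)


def load_panel(source) -> Panel:
    """Load a panel from a YAML file path, file object, or parsed mapping.

    The document must contain a top-level ``panel:`` list whose entries
    mirror :class:`SnpDef` field names.
    """
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = source
    if not isinstance(doc, dict) or "panel" not in doc:
        raise ValueError("panel document must contain a top-level 'panel' list")
    return Panel(SnpDef(**entry) for entry in doc["panel"])


def default_panel() -> Panel:
    """The packaged 17-SNP prothrombotic panel."""
    ref = resources.files("thrombopaf.data").joinpath("panel_17snp.yaml")
    with ref.open() as fh:
        return load_panel(fh)
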