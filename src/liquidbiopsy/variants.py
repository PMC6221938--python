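"""Somatic variant filter-and-prioritize cascade.

Reduces a patient's annotated somatic SNV list to a single trackable
target for plasma ddPCR:

1. keep rare non-synonymous SNVs (population allele frequency below a
   cutoff, default 0.01, in the consulted databases);
2. drop variants below a tumor VAF floor (default 20%, inclusive — a
   variant at exactly the floor survives);
3. rank survivors by tier: disease-associated gene > cancer census gene >
   high predicted pathogenicity; ties broken by descending CADD PHRED,
   then genomic coordinate.

All predicates are pure and per-record, so the survivor set is order-
independent and the cascade idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

from .genome import chrom_sort_key


class Consequence(str, Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Sift(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class Tier(str, Enum):
    NET_GENE = "NET_gene"
    COSMIC_CENSUS = "cosmic_census"
    PATHOGENICITY = "pathogenicity"
    NONE = "none"


#: Ranking order of tiers, best first.
TIER_ORDER = (Tier.NET_GENE, Tier.COSMIC_CENSUS, Tier.PATHOGENICITY, Tier.NONE)

_POP_AF_FIELDS = ("af_dbsnp", "af_exac", "af_1000g")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic SNV.

    Population AFs and CADD may be ``None`` (absent from the databases /
    unscored); SIFT uses an explicit MISSING level.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    vaf_tumor: Optional[float] = None
    af_dbsnp: Optional[float] = None
    af_exac: Optional[float] = None
    af_1000g: Optional[float] = None
    cadd_phred: Optional[float] = None
    sift: Sift = Sift.MISSING
    in_net_genes: bool = False
    in_cosmic_census: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for name in ("vaf_tumor", *_POP_AF_FIELDS):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")
        object.__setattr__(self, "consequence", Consequence(self.consequence))
        object.__setattr__(self, "sift", Sift(self.sift))

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def population_afs(self) -> tuple[Optional[float], ...]:
        return tuple(getattr(self, f) for f in _POP_AF_FIELDS)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and modes of the cascade; defaults follow the workflow."""

    max_af: float = 0.01
    min_vaf: float = 0.20
    cadd_min: float = 20.0
    #: require rarity in all databases (strictest) or in any one of them
    af_require_all: bool = True
    #: how CADD and SIFT combine for the pathogenicity tier
    pathogenicity_rule: str = "cadd"  # "cadd" | "cadd_and_sift" | "cadd_or_sift"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_af <= 1.0:
            raise ValueError("max_af must lie in (0, 1]")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")
        if self.cadd_min < 0:
            raise ValueError("cadd_min must be >= 0")
        if self.pathogenicity_rule not in ("cadd", "cadd_and_sift", "cadd_or_sift"):
            raise ValueError(f"unknown pathogenicity_rule {self.pathogenicity_rule!r}")


@dataclass
class SelectionResult:
    survivors: list[VariantRecord]
    target: Optional[VariantRecord]
    tier: Tier
    ranked: list[tuple[VariantRecord, Tier]]
    audit: dict[str, str]  # variant key -> "pass" or removing clause

    def to_dict(self) -> dict:
        return {
            "target": None if self.target is None else self.target.key,
            "target_gene": None if self.target is None else self.target.gene,
            "tier": self.tier.value,
            "n_survivors": len(self.survivors),
            "survivors": [v.key for v in self.survivors],
            "audit": self.audit,
        }


# ---------------------------------------------------------------------------
# filters


def _is_rare(record: VariantRecord, af_threshold: float, require_all: bool) -> bool:
    afs = [af for af in record.population_afs if af is not None]
    if not afs:
        return True  # absent from every database: treated as rare
    if require_all:
        return all(af < af_threshold for af in afs)
    return any(af < af_threshold for af in afs)


def filter_rare_nonsynonymous(
    variants: Sequence[VariantRecord],
    af_threshold: float = 0.01,
    require_all: bool = True,
) -> list[VariantRecord]:
    """Keep non-synonymous SNVs that are rare in the population databases.

    A record passes if its consequence is non-synonymous and every
    (``require_all=True``, default) or any non-missing population AF is
    below ``af_threshold``. Records missing from all databases pass the
    rarity clause. Input order is preserved.
    """
    if not 0.0 < af_threshold <= 1.0:
        raise ValueError("af_threshold must lie in (0, 1]")
    return [
        v
        for v in variants
        if v.consequence == Consequence.NONSYNONYMOUS
        and _is_rare(v, af_threshold, require_all)
    ]


def filter_min_vaf(
    variants: Sequence[VariantRecord], min_vaf: float = 0.20
) -> list[VariantRecord]:
    """Keep records with tumor VAF at or above ``min_vaf`` (inclusive).

    A missing tumor VAF indicates malformed caller output and is an error.
    """
    if not 0.0 <= min_vaf <= 1.0:
        raise ValueError("min_vaf must lie in [0, 1]")
    for v in variants:
        if v.vaf_tumor is None:
            raise ValueError(f"variant {v.key} has no tumor VAF")
    return [v for v in variants if v.vaf_tumor >= min_vaf]


# ---------------------------------------------------------------------------
# prioritization


def _is_pathogenic(record: VariantRecord, cadd_min: float, rule: str) -> bool:
    cadd_hit = record.cadd_phred is not None and record.cadd_phred >= cadd_min
    sift_hit = record.sift == Sift.DELETERIOUS
    if rule == "cadd":
        return cadd_hit
    if rule == "cadd_and_sift":
        return cadd_hit and sift_hit
    return cadd_hit or sift_hit


def assign_tier(
    record: VariantRecord, cadd_min: float = 20.0, pathogenicity_rule: str = "cadd"
) -> Tier:
    if record.in_net_genes:
        return Tier.NET_GENE
    if record.in_cosmic_census:
        return Tier.COSMIC_CENSUS
    if _is_pathogenic(record, cadd_min, pathogenicity_rule):
        return Tier.PATHOGENICITY
    return Tier.NONE


def _rank_key(item: tuple[VariantRecord, Tier]) -> tuple:
    record, tier = item
    cadd = record.cadd_phred if record.cadd_phred is not None else float("-inf")
    return (TIER_ORDER.index(tier), -cadd, chrom_sort_key(record.chrom), record.pos)


def prioritize(
    variants: Sequence[VariantRecord],
    cadd_min: float = 20.0,
    pathogenicity_rule: str = "cadd",
) -> list[tuple[VariantRecord, Tier]]:
    """Rank variants by tier, then descending CADD, then coordinate.

    Tier order is disease gene > census gene > pathogenicity; variants
    matching no tier rank last with :attr:`Tier.NONE`. The sort is total
    and deterministic.
    """
    if cadd_min < 0:
        raise ValueError("cadd_min must be >= 0")
    tiered = [(v, assign_tier(v, cadd_min, pathogenicity_rule)) for v in variants]
    return sorted(tiered, key=_rank_key)


def select_target(
    variants: Sequence[VariantRecord], config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Run the full cascade and pick the single ddPCR target.

    The target is the top-ranked survivor with a non-NONE tier; if every
    survivor is tierless the top survivor is taken anyway; an empty
    survivor set yields ``target=None`` (no trackable variant). The audit
    maps each input variant to "pass" or the clause that removed it.
    """
    audit: dict[str, str] = {}

    rare = filter_rare_nonsynonymous(variants, config.max_af, config.af_require_all)
    rare_keys = {v.key for v in rare}
    for v in variants:
        if v.key not in rare_keys:
            audit[v.key] = (
                "consequence_not_nonsynonymous"
                if v.consequence != Consequence.NONSYNONYMOUS
                else "population_af_too_high"
            )

    survivors = filter_min_vaf(rare, config.min_vaf)
    survivor_keys = {v.key for v in survivors}
    for v in rare:
        if v.key not in survivor_keys:
            audit[v.key] = "vaf_below_minimum"
    for v in survivors:
        audit[v.key] = "pass"

    ranked = prioritize(survivors, config.cadd_min, config.pathogenicity_rule)
    target: Optional[VariantRecord] = None
    tier = Tier.NONE
    if ranked:
        target, tier = ranked[0]
    return SelectionResult(
        survivors=survivors, target=target, tier=tier, ranked=ranked, audit=audit
    )


# ---------------------------------------------------------------------------
# gene sets


def load_gene_set(path) -> frozenset[str]:
    """Read a newline-delimited gene list (blank lines and # comments skipped)."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return frozenset(genes)


def default_net_genes() -> frozenset[str]:
    """The packaged neuroendocrine-tumor gene list (editable, overridable)."""
    text = resources.files("liquidbiopsy").joinpath("data/net_genes.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def annotate_gene_sets(
    variants: Iterable[VariantRecord],
    net_genes: Optional[frozenset[str]] = None,
    cosmic_genes: Optional[frozenset[str]] = None,
) -> list[VariantRecord]:
    """Set the gene-set membership flags from explicit gene lists."""
    if net_genes is None:
        net_genes = default_net_genes()
    cosmic = cosmic_genes or frozenset()
    return [
        replace(v, in_net_genes=v.gene in net_genes, in_cosmic_census=v.gene in cosmic)
        for v in variants
    ]
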