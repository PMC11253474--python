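"""Site filtering and parental-origin orientation of allele counts.

Every downstream statistic is computed on biallelic counts whose two
alleles have, where possible, been assigned to the parents of the mapping
population.  Orientation sources, in order of precedence:

* resequenced parents (Pr/Pd for MBS, P for QTL-seq): a parent sample that
  is homozygous for one allele assigns that allele to that parent; with
  both parents present only sites where the parents are homozygous for
  *different* alleles are kept (inter-parent polymorphisms);
* a declared match between the reference genome and one parent (``-r``);
* neither: the site is emitted unoriented and the SNP-index falls back to
  the most-abundant-allele convention (values >= 0.5).

W samples (Wr/Wd) never orient; they only veto alleles that existed before
mutagenesis (``--parental-filter``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .variant_io import SampleRoleMap, VariantRecord

#: EMS lesions alkylate G, so the canonical read-out is G->A on one strand
#: and C->T on the other; both (REF,ALT) pairs pass the --EMS filter.
EMS_PAIRS = frozenset({("G", "A"), ("C", "T")})

DNA = frozenset("ACGT")


class FilterConfigError(ValueError):
    """Contradictory or invalid filter configuration."""


@dataclass
class FilterConfig:
    """Variant filters and orientation hints for one analysis run.

    ``reference_matches`` declares which parent the reference genome
    corresponds to: ``"D"`` or ``"R"`` in MBS mode, ``"P"`` in QTL mode,
    or ``None``.  ``mutant_bulk`` only labels which bulk carries the mutant
    phenotype; it does not alter any computation.
    """

    ems_only: bool = False
    exclude_indels: bool = False
    parental_filter: bool = False
    reference_matches: str | None = None
    mutant_bulk: str | None = None
    w_min_depth: int = 1
    parent_homo_frac: float = 0.9
    parent_min_depth: int = 4

    def validate(self, roles: SampleRoleMap) -> None:
        if self.parental_filter and not roles.w_samples:
            raise FilterConfigError(
                "--parental-filter requires a Wr or Wd sample in -d"
            )
        if self.reference_matches is not None:
            valid = ("D", "R") if roles.mode == "mbs" else ("P",)
            if self.reference_matches not in valid:
                raise FilterConfigError(
                    f"-r {self.reference_matches!r} is not valid for "
                    f"{roles.mode} (choose from {', '.join(valid)})"
                )
        if roles.mode == "mbs" and self.reference_matches is not None:
            # declaring a reference parent contradicts resequencing data for
            # that same parent only if both are present AND disagree per site;
            # per-site disagreement is resolved in favour of the parents.
            pass
        if self.mutant_bulk is not None and self.mutant_bulk not in roles.roles:
            raise FilterConfigError(
                f"-m {self.mutant_bulk!r} does not name an assigned sample"
            )
        if self.w_min_depth < 1:
            raise FilterConfigError("--w-min-depth must be >= 1")


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str | None = None


KEEP = FilterDecision(True)


def _variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "substitution"
    return "insertion" if len(alt) > len(ref) else "deletion"


def apply_filters(
    record: VariantRecord, roles: SampleRoleMap, cfg: FilterConfig
) -> FilterDecision:
    """Pure keep/drop decision with a machine-readable reason code.

    Reasons: ``matches-reference`` (no ALT allele), ``non-biallelic``,
    ``indel``, ``non-EMS-type``, ``present-in-W-sample``.
    """
    if len(record.alts) == 0:
        return FilterDecision(False, "matches-reference")
    if len(record.alts) > 1:
        return FilterDecision(False, "non-biallelic")
    alt = record.alts[0]
    vclass = _variant_class(record.ref, alt)
    if cfg.exclude_indels and vclass != "substitution":
        return FilterDecision(False, "indel")
    if cfg.ems_only and vclass == "substitution":
        if (record.ref.upper(), alt.upper()) not in EMS_PAIRS:
            return FilterDecision(False, "non-EMS-type")
    if cfg.parental_filter:
        for w in roles.w_samples:
            ad = record.depths.get(w)
            if ad is not None and len(ad) >= 2 and ad[1] >= cfg.w_min_depth:
                return FilterDecision(False, "present-in-W-sample")
    return KEEP


@dataclass(frozen=True)
class OrientedSiteCounts:
    """Biallelic per-bulk counts after parental-origin orientation.

    ``alleles`` is (allele A, allele B); when oriented, allele A is the one
    inherited from the recessive parent (MBS) or from parent P (QTL), and
    ``counts[bulk] = (A reads, B reads)``.  Unoriented sites keep the
    (REF, ALT) order and set ``oriented=False``.
    """

    chrom: str
    pos: int
    alleles: tuple[str, str]
    oriented: bool
    variant_class: str
    counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class Rejection:
    reason: str


def _homozygous_allele(
    ad: tuple[int, ...], frac: float, min_depth: int
) -> int | None:
    """Index (0=REF, 1=ALT) of the allele a parent is homozygous for."""
    total = ad[0] + ad[1]
    if total < min_depth:
        return None
    for i in (0, 1):
        if ad[i] >= frac * total:
            return i
    return None


def orient_site(
    record: VariantRecord, roles: SampleRoleMap, cfg: FilterConfig
) -> OrientedSiteCounts | Rejection:
    """Assign the two alleles of a biallelic site to parental origins.

    Returns :class:`Rejection` with reason ``parents-not-informative`` when
    parent samples are present but cannot assign the alleles (not
    homozygous, or both parents homozygous for the same allele), or
    ``zero-depth-in-bulk`` / ``zero-depth-in-required-bulk`` when an
    analyzed bulk has no reads at the site.
    """
    if not record.is_biallelic:
        return Rejection("non-biallelic")
    alt = record.alts[0]
    tracked: int | None = None  # 0=REF first, 1=ALT first

    if roles.mode == "mbs":
        a_r = a_d = None
        if "Pr" in roles:
            a_r = _homozygous_allele(
                record.depths["Pr"], cfg.parent_homo_frac, cfg.parent_min_depth
            )
        if "Pd" in roles:
            a_d = _homozygous_allele(
                record.depths["Pd"], cfg.parent_homo_frac, cfg.parent_min_depth
            )
        if "Pr" in roles and "Pd" in roles:
            # only inter-parent polymorphisms are informative
            if a_r is None or a_d is None or a_r == a_d:
                return Rejection("parents-not-informative")
            tracked = a_r
        elif "Pr" in roles:
            if a_r is None:
                return Rejection("parents-not-informative")
            tracked = a_r
        elif "Pd" in roles:
            if a_d is None:
                return Rejection("parents-not-informative")
            tracked = 1 - a_d
        elif cfg.reference_matches == "D":
            tracked = 1  # reference is the dominant parent: ALT is recessive
        elif cfg.reference_matches == "R":
            tracked = 0
        required = ("R",)
    else:  # qtl
        if "P" in roles:
            a_p = _homozygous_allele(
                record.depths["P"], cfg.parent_homo_frac, cfg.parent_min_depth
            )
            if a_p is None:
                return Rejection("parents-not-informative")
            tracked = a_p
        elif cfg.reference_matches == "P":
            tracked = 0
        required = ("H", "L")

    counts: dict[str, tuple[int, int]] = {}
    for bulk in roles.bulks:
        ad = record.depths[bulk]
        pair = (ad[0], ad[1])
        if pair[0] + pair[1] == 0:
            reason = (
                "zero-depth-in-required-bulk" if bulk in required else "zero-depth-in-bulk"
            )
            return Rejection(reason)
        if tracked == 1:
            pair = (pair[1], pair[0])
        counts[bulk] = pair

    if tracked is None:
        alleles = (record.ref, alt)
        oriented = False
    else:
        alleles = (record.ref, alt) if tracked == 0 else (alt, record.ref)
        oriented = True
    return OrientedSiteCounts(
        chrom=record.chrom,
        pos=record.pos,
        alleles=alleles,
        oriented=oriented,
        variant_class=_variant_class(record.ref, alt),
        counts=counts,
    )
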