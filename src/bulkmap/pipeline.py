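"""Site-by-site analysis pipeline shared by the mbs and qtl commands."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

from . import PROGRAM
from .allele_model import (
    FilterConfig,
    OrientedSiteCounts,
    Rejection,
    apply_filters,
    orient_site,
)
from .bsa_statistics import site_statistics
from .variant_io import ResultHeader, SampleRoleMap, Source, VcfReader

logger = logging.getLogger(PROGRAM)


@dataclass
class RunCounters:
    n_sites: int = 0
    n_emitted: int = 0
    dropped: Counter = field(default_factory=Counter)


def result_columns(roles: SampleRoleMap, cfg: FilterConfig) -> list[tuple[str, str]]:
    """Column contract of the mbs/qtl results table for a given design."""
    mode = roles.mode
    top, bottom = ("D", "R") if mode == "mbs" else ("H", "L")
    tracked = (
        "allele inherited from the recessive parent"
        if mode == "mbs"
        else "allele inherited from parent P"
    )
    cols = [
        ("CHROM", "chromosome identifier"),
        ("POS", "1-based position"),
        ("REF", "reference allele"),
        ("ALT", "alternate allele"),
        ("ORIENTED", f"1 if allele A is the {tracked}, 0 if unoriented"),
    ]
    for b in roles.bulks:
        cols.append((f"{b}_A", f"{b}-bulk reads for allele A ({tracked} when oriented, REF otherwise)"))
        cols.append((f"{b}_B", f"{b}-bulk reads for the other allele"))
    for b in roles.bulks:
        cols.append(
            (
                f"SNPIDX_{b}",
                f"SNP-index in the {b} bulk "
                "(frequency of allele A; most-abundant allele when unoriented)",
            )
        )
    if top in roles.bulks and bottom in roles.bulks:
        cols += [
            ("DELTA", f"delta SNP-index, {top} minus {bottom} (absolute value when unoriented)"),
            ("PVALUE", "two-tailed Fisher exact test p-value on the 2x2 allele-count table"),
            ("GSTAT", "G statistic (likelihood-ratio) on the 2x2 allele-count table"),
            ("ED", "per-marker Euclidean distance between bulk allele-frequency vectors"),
        ]
    return cols


def analyze_stream(
    source: Source,
    roles: SampleRoleMap,
    cfg: FilterConfig,
    strict: bool = False,
) -> tuple[ResultHeader, Iterator[dict], RunCounters]:
    """Stream VCF records through filtering, orientation and statistics.

    Returns the result header (without a provenance line; the caller adds
    its own step), a lazy row iterator, and mutable run counters that are
    complete once the iterator is exhausted.  Input site order is
    preserved.
    """
    cfg.validate(roles)
    reader = VcfReader(source, roles, strict=strict)
    counters = RunCounters()
    header = ResultHeader(columns=result_columns(roles, cfg))

    def rows() -> Iterator[dict]:
        for rec in reader:
            counters.n_sites += 1
            decision = apply_filters(rec, roles, cfg)
            if not decision.keep:
                counters.dropped[decision.reason] += 1
                continue
            site = orient_site(rec, roles, cfg)
            if isinstance(site, Rejection):
                counters.dropped[site.reason] += 1
                continue
            row = site_to_row(site, rec.ref, rec.alts[0], roles.mode)
            counters.n_emitted += 1
            yield row
        counters.dropped["unparsed-input-line"] += reader.n_skipped

    return header, rows(), counters


def site_to_row(site: OrientedSiteCounts, ref: str, alt: str, mode: str) -> dict:
    row: dict = {
        "CHROM": site.chrom,
        "POS": site.pos,
        "REF": ref,
        "ALT": alt,
        "ORIENTED": 1 if site.oriented else 0,
    }
    for bulk, (a, b) in site.counts.items():
        row[f"{bulk}_A"] = a
        row[f"{bulk}_B"] = b
    row.update(site_statistics(site.counts, site.oriented, mode))
    return row
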