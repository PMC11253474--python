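"""Variant filters and parental-origin orientation."""

import pytest
from hypothesis import given, settings, strategies as st

from bulkmap.allele_model import (
    FilterConfig,
    FilterConfigError,
    OrientedSiteCounts,
    Rejection,
    apply_filters,
    orient_site,
)
from bulkmap.bsa_statistics import snp_index
from bulkmap.variant_io import VariantRecord, parse_role_assignment


def record(ref="G", alt="A", alts=None, **depths):
    alts = alts if alts is not None else (alt,)
    return VariantRecord(
        chrom="chr1", pos=100, ref=ref, alts=tuple(alts),
        depths={k: tuple(v) for k, v in depths.items()},
    )


class TestFilters:
    @pytest.mark.parametrize(
        "ref, alt, cfg_kw, keep, reason",
        [
            ("G", "A", dict(ems_only=True), True, None),
            ("C", "T", dict(ems_only=True), True, None),
            ("A", "C", dict(ems_only=True), False, "non-EMS-type"),
            ("A", "G", dict(ems_only=True), False, "non-EMS-type"),
            ("G", "GA", dict(exclude_indels=True), False, "indel"),
            ("GA", "G", dict(exclude_indels=True), False, "indel"),
            ("G", "GA", dict(), True, None),
        ],
    )
    def test_type_filters(self, ref, alt, cfg_kw, keep, reason):
        roles = parse_role_assignment("R", "mbs")
        dec = apply_filters(
            record(ref, alt, R=(5, 5)), roles, FilterConfig(**cfg_kw)
        )
        assert dec.keep is keep and dec.reason == reason

    def test_multiallelic_dropped(self):
        roles = parse_role_assignment("R", "mbs")
        rec = record(alts=("A", "T"), R=(5, 3, 2))
        assert apply_filters(rec, roles, FilterConfig()).reason == "non-biallelic"

    def test_monomorphic_dropped_as_reference_match(self):
        roles = parse_role_assignment("R", "mbs")
        rec = record(alts=(), R=(10,))
        assert apply_filters(rec, roles, FilterConfig()).reason == "matches-reference"

    def test_parental_filter_discards_w_alleles(self):
        roles = parse_role_assignment("R,Wr", "mbs")
        cfg = FilterConfig(parental_filter=True)
        seen = record(R=(2, 18), Wr=(10, 1))
        absent = record(R=(2, 18), Wr=(11, 0))
        assert apply_filters(seen, roles, cfg).reason == "present-in-W-sample"
        assert apply_filters(absent, roles, cfg).keep

    def test_w_min_depth_relaxes_parental_filter(self):
        roles = parse_role_assignment("R,Wr", "mbs")
        rec = record(R=(2, 18), Wr=(10, 2))
        assert not apply_filters(rec, roles, FilterConfig(parental_filter=True)).keep
        assert apply_filters(
            rec, roles, FilterConfig(parental_filter=True, w_min_depth=3)
        ).keep

    def test_filter_idempotence(self):
        roles = parse_role_assignment("R,Wr", "mbs")
        cfg = FilterConfig(ems_only=True, parental_filter=True)
        rec = record("A", "C", R=(5, 5), Wr=(9, 0))
        first = apply_filters(rec, roles, cfg)
        assert apply_filters(rec, roles, cfg) == first

    def test_parental_filter_needs_w_sample(self):
        roles = parse_role_assignment("R,D", "mbs")
        with pytest.raises(FilterConfigError):
            FilterConfig(parental_filter=True).validate(roles)


class TestOrientation:
    def test_homozygous_parents_assign_alleles(self):
        roles = parse_role_assignment("R,Pr,Pd", "mbs")
        rec = record(R=(2, 18), Pr=(0, 20), Pd=(20, 0))
        site = orient_site(rec, roles, FilterConfig())
        assert isinstance(site, OrientedSiteCounts) and site.oriented
        assert site.counts["R"] == (18, 2)  # recessive-parent allele first

    def test_reference_match_dominant(self):
        roles = parse_role_assignment("R", "mbs")
        rec = record(R=(3, 17))
        site = orient_site(rec, roles, FilterConfig(reference_matches="D"))
        assert site.oriented and site.counts["R"] == (17, 3)

    def test_unoriented_most_abundant_convention(self):
        roles = parse_role_assignment("R", "mbs")
        site = orient_site(record(R=(7, 3)), roles, FilterConfig())
        assert not site.oriented
        assert snp_index(*site.counts["R"], oriented=False) == pytest.approx(0.7)

    def test_parents_sharing_allele_rejected(self):
        roles = parse_role_assignment("R,Pr,Pd", "mbs")
        rec = record(R=(2, 18), Pr=(20, 0), Pd=(20, 0))
        site = orient_site(rec, roles, FilterConfig())
        assert isinstance(site, Rejection)
        assert site.reason == "parents-not-informative"

    def test_heterozygous_parent_rejected(self):
        roles = parse_role_assignment("R,Pr", "mbs")
        rec = record(R=(2, 18), Pr=(10, 10))
        assert orient_site(rec, roles, FilterConfig()).reason == "parents-not-informative"

    def test_zero_depth_required_bulk_rejected(self):
        roles = parse_role_assignment("R", "mbs")
        rec = record(R=(0, 0))
        assert orient_site(rec, roles, FilterConfig()).reason == "zero-depth-in-required-bulk"

    def test_qtl_parent_orientation(self):
        roles = parse_role_assignment("H,L,P", "qtl")
        rec = record(H=(1, 19), L=(15, 5), P=(0, 30))
        site = orient_site(rec, roles, FilterConfig())
        assert site.oriented
        assert site.counts["H"] == (19, 1) and site.counts["L"] == (5, 15)

    @settings(deadline=None, derandomize=True)
    @given(
        r=st.tuples(st.integers(0, 200), st.integers(0, 200)).filter(lambda t: sum(t) > 0),
        d=st.tuples(st.integers(0, 200), st.integers(0, 200)).filter(lambda t: sum(t) > 0),
    )
    def test_depth_conserved_and_parent_swap_complements(self, r, d):
        """Orientation permutes but never changes counts; swapping Pr and Pd
        maps the recessive-allele count to its complement."""
        roles = parse_role_assignment("R,D,Pr,Pd", "mbs")
        rec = record(R=r, D=d, Pr=(0, 30), Pd=(30, 0))
        swapped = record(R=r, D=d, Pr=(30, 0), Pd=(0, 30))
        site = orient_site(rec, roles, FilterConfig())
        other = orient_site(swapped, roles, FilterConfig())
        for bulk, ad in (("R", r), ("D", d)):
            assert sum(site.counts[bulk]) == sum(ad)
            a, b = site.counts[bulk]
            assert other.counts[bulk] == (b, a)
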