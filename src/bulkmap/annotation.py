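"""Functional-effect annotation of candidate mutations.

Genes are indexed per chromosome in a position-sorted structure that is
queried by binary search; each variant inside a user-selected interval is
classified per transcript isoform.  Substitutions in the CDS are
translated on the coding strand (standard genetic code) and labelled
synonymous, missense, nonsense or nonstop; intronic substitutions report
their distance to the flanking exons and are flagged when they fall near a
donor or acceptor splice site; 5'-UTR substitutions are checked for
premature ATG creation; indels are checked for frameshifts, and deletions
for partial or complete disruption of one or more genes.  Intergenic
variants report the identity of and distance to the nearest flanking
genes.
"""

from __future__ import annotations

import bisect
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from . import PROGRAM

logger = logging.getLogger(PROGRAM)

#: closed effect taxonomy; every emitted label belongs to this set
EFFECT_LABELS = frozenset(
    {
        "synonymous",
        "missense",
        "nonsense",
        "nonstop",
        "frameshift",
        "in-frame-indel",
        "splice-site",
        "premature-start-gain",
        "gene-disruption",
        "intergenic",
        "intron",
        "5-utr",
        "3-utr",
        "noncoding",
    }
)

STOP = "*"


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    """VCF REF allele disagrees with the genome FASTA: wrong genome build."""


@dataclass
class Transcript:
    id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # start, end, phase
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    non_canonical: bool = False

    @property
    def start(self) -> int:
        spans = self.exons or [(s, e) for s, e, _ in self.cds]
        return min(s for s, *_ in spans)

    @property
    def end(self) -> int:
        spans = self.exons or [(s, e) for s, e, _ in self.cds]
        return max(e for _, e, *_ in spans)

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    def cds_segments_in_translation_order(self) -> list[tuple[int, int, int]]:
        return sorted(self.cds, key=lambda t: t[0], reverse=self.strand == "-")


@dataclass
class Gene:
    id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenicContext:
    genes: list[Gene]


@dataclass
class IntergenicContext:
    left: tuple[Gene, int] | None  # (gene, distance from gene end to position)
    right: tuple[Gene, int] | None

    @property
    def nearest(self) -> list[tuple[str, int]]:
        out = []
        if self.left:
            out.append((self.left[0].id, self.left[1]))
        if self.right:
            out.append((self.right[0].id, self.right[1]))
        return out


class GenomeAnnotation:
    """Binary-searchable, per-chromosome index of gene models."""

    def __init__(self, genes: Iterable[Gene]):
        self._genes: dict[str, list[Gene]] = {}
        for g in genes:
            self._genes.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        self._pmax_end: dict[str, list[int]] = {}
        self._pmax_idx: dict[str, list[int]] = {}
        for chrom, glist in self._genes.items():
            glist.sort(key=lambda g: (g.start, g.end, g.id))
            self._starts[chrom] = [g.start for g in glist]
            pmax, pidx = [], []
            best, best_i = -1, -1
            for i, g in enumerate(glist):
                if g.end > best:
                    best, best_i = g.end, i
                pmax.append(best)
                pidx.append(best_i)
            self._pmax_end[chrom] = pmax
            self._pmax_idx[chrom] = pidx

    # -- construction -------------------------------------------------------

    @classmethod
    def from_gff3(cls, source: str | Path) -> "GenomeAnnotation":
        """Load gene/mRNA/exon/CDS/UTR features from GFF3 (path or text)."""
        data = str(source)
        from_string = "\n" in data or data.lstrip().startswith("##gff")
        db = gffutils.create_db(
            data,
            ":memory:",
            from_string=from_string,
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes: list[Gene] = []
        for gf in db.features_of_type("gene"):
            gene = Gene(
                id=gf.id,
                chrom=gf.seqid,
                start=gf.start,
                end=gf.end,
                strand=gf.strand,
                biotype=gf.attributes.get("biotype", ["protein_coding"])[0],
            )
            for tf in db.children(gf, level=1):
                if tf.featuretype not in ("mRNA", "transcript"):
                    continue
                tr = Transcript(id=tf.id, strand=tf.strand)
                for child in db.children(tf, level=1):
                    span = (child.start, child.end)
                    if child.featuretype == "exon":
                        tr.exons.append(span)
                    elif child.featuretype == "CDS":
                        phase = 0 if child.frame in (None, ".") else int(child.frame)
                        tr.cds.append((child.start, child.end, phase))
                    elif child.featuretype in ("five_prime_UTR", "five_prime_utr"):
                        tr.utr5.append(span)
                    elif child.featuretype in ("three_prime_UTR", "three_prime_utr"):
                        tr.utr3.append(span)
                tr.exons.sort()
                tr.cds.sort()
                tr.utr5.sort()
                tr.utr3.sort()
                if tr.cds:
                    first = tr.cds_segments_in_translation_order()[0]
                    total = sum(e - s + 1 for s, e, _ in tr.cds)
                    if (total - first[2]) % 3 != 0:
                        tr.non_canonical = True
                        logger.warning(
                            "transcript %s: CDS length %d (phase %d) not a "
                            "multiple of 3; flagged non-canonical",
                            tr.id, total, first[2],
                        )
                gene.transcripts.append(tr)
            genes.append(gene)
        return cls(genes)

    # -- queries ------------------------------------------------------------

    def chromosomes(self) -> list[str]:
        return list(self._genes)

    def genes(self, chrom: str) -> list[Gene]:
        return self._genes.get(chrom, [])

    def locate(self, chrom: str, pos: int) -> GenicContext | IntergenicContext:
        """Binary search over sorted gene spans.

        An unknown chromosome yields an intergenic context with no
        neighbours.
        """
        glist = self._genes.get(chrom)
        if not glist:
            return IntergenicContext(None, None)
        starts = self._starts[chrom]
        pmax = self._pmax_end[chrom]
        i = bisect.bisect_right(starts, pos) - 1
        hits: list[Gene] = []
        j = i
        while j >= 0 and pmax[j] >= pos:
            g = glist[j]
            if g.start <= pos <= g.end:
                hits.append(g)
            j -= 1
        if hits:
            hits.reverse()
            return GenicContext(hits)
        left = None
        if i >= 0:
            lg = glist[self._pmax_idx[chrom][i]]
            left = (lg, pos - lg.end)
        right = None
        if i + 1 < len(glist):
            rg = glist[i + 1]
            right = (rg, rg.start - pos)
        return IntergenicContext(left, right)

    def overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """All genes intersecting [start, end]."""
        return [
            g
            for g in self._genes.get(chrom, [])
            if g.start <= end and g.end >= start
        ]


@dataclass
class VariantEffect:
    """Per-isoform functional classification of one candidate mutation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region: str  # intergenic | 5-utr | CDS | intron | 3-utr | genic
    effect: str  # member of EFFECT_LABELS
    gene_id: str = ""
    transcript_id: str = ""
    aa_ref: str = ""
    aa_alt: str = ""
    codon_number: int | None = None
    distance: int | None = None
    nearest: list[tuple[str, int]] = field(default_factory=list)
    note: str = ""

    def to_row(self) -> dict:
        return {
            "CHROM": self.chrom,
            "POS": self.pos,
            "REF": self.ref,
            "ALT": self.alt,
            "REGION": self.region,
            "EFFECT": self.effect,
            "GENE": self.gene_id,
            "TRANSCRIPT": self.transcript_id,
            "AA_REF": self.aa_ref,
            "AA_ALT": self.aa_alt,
            "CODON": self.codon_number,
            "DISTANCE": self.distance,
            "NEAREST": ";".join(f"{g}:{d}" for g, d in self.nearest),
            "NOTE": self.note,
        }


ANNOTATION_COLUMNS = [
    ("CHROM", "chromosome identifier"),
    ("POS", "1-based position of the variant"),
    ("REF", "reference allele"),
    ("ALT", "mutant allele"),
    ("REGION", "intergenic, 5-utr, CDS, intron, 3-utr or genic"),
    ("EFFECT", "functional effect label"),
    ("GENE", "affected gene"),
    ("TRANSCRIPT", "affected transcript isoform"),
    ("AA_REF", "reference amino acid (CDS substitutions)"),
    ("AA_ALT", "mutant amino acid (CDS substitutions)"),
    ("CODON", "1-based codon number within the CDS"),
    ("DISTANCE", "distance in bp to the relevant landmark (exon, gene or start codon)"),
    ("NEAREST", "nearest flanking genes as id:distance pairs (intergenic variants)"),
    ("NOTE", "free-text detail"),
]


# ---------------------------------------------------------------------------
# sequence helpers


def _check_reference(genome: Mapping[str, str], chrom: str, pos: int, ref: str) -> None:
    seq = genome.get(chrom)
    if seq is None:
        raise AnnotationError(f"chromosome {chrom!r} absent from genome FASTA")
    if pos < 1 or pos + len(ref) - 1 > len(seq):
        raise AnnotationError(f"{chrom}:{pos} outside sequence bounds")
    observed = seq[pos - 1 : pos - 1 + len(ref)].upper()
    if observed != ref.upper():
        raise ReferenceMismatchError(
            f"{chrom}:{pos} REF={ref} but genome has {observed}; "
            "annotation and VCF likely use different genome builds"
        )


def _in_spans(pos: int, spans: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in spans)


def _cds_index(tr: Transcript, pos: int) -> int | None:
    """0-based index of a genomic position within the spliced CDS (coding strand)."""
    segs = sorted((s, e) for s, e, _ in tr.cds)
    off = 0
    plus_idx = None
    for s, e in segs:
        if s <= pos <= e:
            plus_idx = off + (pos - s)
            break
        off += e - s + 1
    if plus_idx is None:
        return None
    total = sum(e - s + 1 for s, e in segs)
    return plus_idx if tr.strand == "+" else total - 1 - plus_idx


def _cds_sequence(tr: Transcript, seq: str) -> str:
    segs = sorted((s, e) for s, e, _ in tr.cds)
    cds = "".join(seq[s - 1 : e] for s, e in segs)
    if tr.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# substitution classification


def classify_substitution(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    ann: GenomeAnnotation,
    genome: Mapping[str, str],
    splice_window: int = 10,
) -> list[VariantEffect]:
    """Classify a single-base substitution against every overlapping isoform."""
    _check_reference(genome, chrom, pos, ref)
    ctx = ann.locate(chrom, pos)
    base = dict(chrom=chrom, pos=pos, ref=ref, alt=alt)
    if isinstance(ctx, IntergenicContext):
        return [
            VariantEffect(
                **base, region="intergenic", effect="intergenic", nearest=ctx.nearest
            )
        ]
    effects: list[VariantEffect] = []
    seq = genome[chrom]
    for gene in ctx.genes:
        if not gene.transcripts:
            effects.append(
                VariantEffect(
                    **base, region="genic", effect="noncoding",
                    gene_id=gene.id, note=f"gene biotype {gene.biotype}, no transcript model",
                )
            )
            continue
        for tr in gene.transcripts:
            effects.append(
                _substitution_effect_for_transcript(
                    base, gene, tr, seq, splice_window
                )
            )
    return effects


def _substitution_effect_for_transcript(
    base: dict, gene: Gene, tr: Transcript, seq: str, splice_window: int
) -> VariantEffect:
    pos, ref, alt = base["pos"], base["ref"], base["alt"]
    if not tr.coding and not tr.exons:
        return VariantEffect(
            **base, region="genic", effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id,
            note=f"gene biotype {gene.biotype}",
        )
    if not (tr.start <= pos <= tr.end):
        return VariantEffect(
            **base, region="genic", effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id,
            note="outside this isoform",
        )
    if tr.coding and _in_spans(pos, [(s, e) for s, e, _ in tr.cds]):
        return _cds_substitution(base, gene, tr, seq)
    if _in_spans(pos, tr.utr5):
        return _utr5_substitution(base, gene, tr, seq)
    if _in_spans(pos, tr.utr3):
        return VariantEffect(
            **base, region="3-utr", effect="3-utr",
            gene_id=gene.id, transcript_id=tr.id,
        )
    if _in_spans(pos, tr.exons):
        region = "genic" if tr.coding else "genic"
        return VariantEffect(
            **base, region=region, effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id,
            note="exonic, outside annotated CDS/UTR",
        )
    return _intron_substitution(base, gene, tr, splice_window)


def _cds_substitution(base: dict, gene: Gene, tr: Transcript, seq: str) -> VariantEffect:
    pos, ref, alt = base["pos"], base["ref"], base["alt"]
    idx = _cds_index(tr, pos)
    cds = _cds_sequence(tr, seq)
    first_phase = tr.cds_segments_in_translation_order()[0][2]
    ref_c = ref if tr.strand == "+" else str(Seq(ref).reverse_complement())
    alt_c = alt if tr.strand == "+" else str(Seq(alt).reverse_complement())
    eff_idx = idx - first_phase
    if eff_idx < 0 or tr.non_canonical and eff_idx // 3 * 3 + 3 > len(cds):
        return VariantEffect(
            **base, region="CDS", effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id,
            note="non-canonical CDS; codon not resolvable",
        )
    ci = eff_idx // 3
    start = first_phase + ci * 3
    codon_ref = cds[start : start + 3]
    if len(codon_ref) < 3:
        return VariantEffect(
            **base, region="CDS", effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id, note="truncated terminal codon",
        )
    within = eff_idx % 3
    if codon_ref[within].upper() != ref_c.upper():
        raise ReferenceMismatchError(
            f"{base['chrom']}:{pos} CDS base {codon_ref[within]} != REF {ref_c} "
            f"in transcript {tr.id}"
        )
    codon_alt = codon_ref[:within] + alt_c + codon_ref[within + 1 :]
    aa_ref = _translate_codon(codon_ref)
    aa_alt = _translate_codon(codon_alt)
    if aa_ref == STOP and aa_alt != STOP:
        effect, note = "nonstop", "stop codon lost; translation continues into the 3'-UTR"
    elif aa_alt == STOP and aa_ref != STOP:
        effect, note = "nonsense", "premature stop codon"
    elif aa_ref == aa_alt:
        effect, note = "synonymous", ""
    else:
        effect, note = "missense", ""
    return VariantEffect(
        **base, region="CDS", effect=effect,
        gene_id=gene.id, transcript_id=tr.id,
        aa_ref=aa_ref, aa_alt=aa_alt, codon_number=ci + 1, note=note,
    )


def _intron_substitution(
    base: dict, gene: Gene, tr: Transcript, splice_window: int
) -> VariantEffect:
    pos = base["pos"]
    prev_ends = [e for _, e in tr.exons if e < pos]
    next_starts = [s for s, _ in tr.exons if s > pos]
    d_left = pos - max(prev_ends) if prev_ends else None
    d_right = min(next_starts) - pos if next_starts else None
    candidates = [d for d in (d_left, d_right) if d is not None]
    dist = min(candidates) if candidates else None
    if dist is not None and dist <= splice_window:
        # genomic-left boundary is the donor on + strand, acceptor on -
        near_left = d_left is not None and d_left == dist
        site = ("donor" if near_left else "acceptor") if tr.strand == "+" else (
            "acceptor" if near_left else "donor"
        )
        return VariantEffect(
            **base, region="intron", effect="splice-site",
            gene_id=gene.id, transcript_id=tr.id, distance=dist,
            note=f"{dist} nt from a {site} splice site",
        )
    return VariantEffect(
        **base, region="intron", effect="intron",
        gene_id=gene.id, transcript_id=tr.id, distance=dist,
    )


def _utr5_substitution(base: dict, gene: Gene, tr: Transcript, seq: str) -> VariantEffect:
    pos, alt = base["pos"], base["alt"]
    # scan the three transcript-strand trinucleotides covering the base
    lo = max(pos - 3, 0)
    original = seq[lo : pos + 2]
    mutated = seq[lo : pos - 1] + alt + seq[pos : pos + 2]
    if tr.strand == "-":
        original = str(Seq(original).reverse_complement())
        mutated = str(Seq(mutated).reverse_complement())
    gained = any(
        mutated[i : i + 3] == "ATG" and original[i : i + 3] != "ATG"
        for i in range(0, max(len(mutated) - 2, 0))
    )
    if tr.coding:
        segs = tr.cds_segments_in_translation_order()
        tss = segs[0][0] if tr.strand == "+" else segs[0][1]
        dist = abs(tss - pos)
    else:
        dist = None
    if gained:
        return VariantEffect(
            **base, region="5-utr", effect="premature-start-gain",
            gene_id=gene.id, transcript_id=tr.id, distance=dist,
            note="creates an upstream ATG",
        )
    return VariantEffect(
        **base, region="5-utr", effect="5-utr",
        gene_id=gene.id, transcript_id=tr.id, distance=dist,
    )


# ---------------------------------------------------------------------------
# indel classification


def classify_indel(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    ann: GenomeAnnotation,
    genome: Mapping[str, str],
    splice_window: int = 10,
) -> list[VariantEffect]:
    """Classify a VCF-anchored insertion or deletion.

    Deletions that extend beyond a gene's boundary are reported as partial
    gene disruptions; deletions that span an entire gene, as complete
    disruptions (one row per disrupted gene).  Indels contained within a
    CDS are frameshifts unless the length change is a multiple of 3.
    """
    _check_reference(genome, chrom, pos, ref)
    base = dict(chrom=chrom, pos=pos, ref=ref, alt=alt)
    net = len(alt) - len(ref)
    if net == 0:
        raise AnnotationError("not an indel (equal allele lengths)")
    if net < 0:
        span = (pos + len(alt), pos + len(ref) - 1)  # deleted bases
    else:
        span = (pos, pos + len(ref) - 1)  # insertion anchored here
    genes = ann.overlapping(chrom, span[0], span[1])
    if not genes:
        ctx = ann.locate(chrom, pos)
        nearest = ctx.nearest if isinstance(ctx, IntergenicContext) else []
        return [
            VariantEffect(
                **base, region="intergenic", effect="intergenic", nearest=nearest
            )
        ]
    effects: list[VariantEffect] = []
    for gene in genes:
        if net < 0 and span[0] <= gene.start and span[1] >= gene.end:
            effects.append(
                VariantEffect(
                    **base, region="genic", effect="gene-disruption",
                    gene_id=gene.id, note="complete deletion of the gene",
                )
            )
            continue
        if net < 0 and (span[0] < gene.start or span[1] > gene.end):
            effects.append(
                VariantEffect(
                    **base, region="genic", effect="gene-disruption",
                    gene_id=gene.id, note="partial deletion of the gene",
                )
            )
            continue
        for tr in gene.transcripts or [None]:
            if tr is None:
                effects.append(
                    VariantEffect(
                        **base, region="genic", effect="noncoding",
                        gene_id=gene.id, note="no transcript model",
                    )
                )
                continue
            effects.append(
                _indel_effect_for_transcript(base, gene, tr, span, net, splice_window)
            )
    return effects


def _spans_overlap(span: tuple[int, int], spans: Sequence[tuple[int, int]]) -> bool:
    return any(s <= span[1] and e >= span[0] for s, e in spans)


def _indel_effect_for_transcript(
    base: dict,
    gene: Gene,
    tr: Transcript,
    span: tuple[int, int],
    net: int,
    splice_window: int,
) -> VariantEffect:
    cds_spans = [(s, e) for s, e, _ in tr.cds]
    if tr.coding and _spans_overlap(span, cds_spans):
        effect = "in-frame-indel" if net % 3 == 0 else "frameshift"
        return VariantEffect(
            **base, region="CDS", effect=effect,
            gene_id=gene.id, transcript_id=tr.id,
            note=f"{'insertion' if net > 0 else 'deletion'} of {abs(net)} bp",
        )
    if _spans_overlap(span, tr.utr5):
        return VariantEffect(
            **base, region="5-utr", effect="5-utr",
            gene_id=gene.id, transcript_id=tr.id,
        )
    if _spans_overlap(span, tr.utr3):
        return VariantEffect(
            **base, region="3-utr", effect="3-utr",
            gene_id=gene.id, transcript_id=tr.id,
        )
    if _spans_overlap(span, tr.exons):
        return VariantEffect(
            **base, region="genic", effect="noncoding",
            gene_id=gene.id, transcript_id=tr.id,
            note="exonic, outside annotated CDS/UTR",
        )
    # intronic indel: use the span's midpoint for splice distance
    mid = (span[0] + span[1]) // 2
    fake = dict(base)
    fake["pos"] = mid
    eff = _intron_substitution(fake, gene, tr, splice_window)
    eff.pos = base["pos"]
    return eff


# ---------------------------------------------------------------------------
# interval report


def annotate_interval(
    variants: Iterable[Mapping],
    region: tuple[str, int, int],
    ann: GenomeAnnotation,
    genome: Mapping[str, str],
    splice_window: int = 10,
) -> list[VariantEffect]:
    """One effect row per variant x isoform inside the selected interval.

    ``variants`` are mappings with CHROM/POS/REF/ALT keys (result rows or
    parsed VCF records).  Output is deterministically ordered by position,
    gene and isoform; no variant in the region is silently dropped.
    """
    chrom, start, end = region
    if chrom not in genome:
        raise AnnotationError(f"region chromosome {chrom!r} absent from genome FASTA")
    if start > end:
        raise AnnotationError("malformed region: start > end")
    out: list[VariantEffect] = []
    for v in variants:
        if str(v["CHROM"]) != chrom:
            continue
        pos = int(v["POS"])
        if not (start <= pos <= end):
            continue
        ref, alt = str(v["REF"]), str(v["ALT"])
        if len(ref) == len(alt) == 1:
            effs = classify_substitution(
                chrom, pos, ref, alt, ann, genome, splice_window
            )
        else:
            effs = classify_indel(chrom, pos, ref, alt, ann, genome, splice_window)
        out.extend(effs)
    out.sort(key=lambda e: (e.pos, e.gene_id, e.transcript_id))
    return out


def load_genome(fasta: str | Path) -> dict[str, str]:
    """Read a (multi-)FASTA into a chromosome -> sequence mapping."""
    from Bio import SeqIO

    handle = fasta
    if isinstance(fasta, str) and "\n" in fasta:
        handle = io.StringIO(fasta)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
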