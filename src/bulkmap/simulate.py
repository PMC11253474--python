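"""Synthetic genomes, annotations and mapping-population VCFs.

Everything the pipeline consumes can be generated here with known truth:

* :func:`simulate_mbs_vcf` emulates an F2 bulked-segregant experiment.
  Individuals are simulated as haplotype mosaics along each chromosome
  under a Haldane (no-interference) crossover model at a configurable
  cM/Mb rate; the recessive bulk contains individuals selected homozygous
  for the causal allele, so the expected recessive-parent allele frequency
  at a marker with recombination fraction r to the causal locus is 1 - r
  (and (1 + r)/3 in the dominant-phenotype bulk).  Read depths per sample
  are Poisson around the design mean; allele counts are binomial in the
  pooled genotype frequency.

* :func:`simulate_toy_genome` builds a small genome with multi-exon,
  UTR-bearing genes on both strands plus a list of planted variants whose
  functional-effect labels are known by construction, covering the full
  effect taxonomy of the annotation module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# bulk-sequencing simulator


@dataclass
class SimulationDesign:
    """Parameters of a simulated F2 mapping-by-sequencing experiment."""

    n_chromosomes: int = 5
    chromosome_length: int = 20_000_000
    markers_per_chromosome: int = 1000
    causal_chromosome: int = 1  # 1-based chromosome index
    causal_position: int = 10_000_000
    bulk_size: int = 30  # individuals in the recessive bulk
    dominant_bulk_size: int | None = None  # defaults to bulk_size
    mean_depth: float = 50.0
    cm_per_mb: float = 4.0
    population: str = "F2-isogenic"
    selection: str = "two-bulk"  # or "recessive-bulk"
    error_rate: float = 0.0  # per-read allele flip probability
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.causal_chromosome <= self.n_chromosomes):
            raise ValueError("causal chromosome outside the genome")
        if not (1 <= self.causal_position <= self.chromosome_length):
            raise ValueError("causal position outside its chromosome")
        if self.bulk_size < 1 or self.mean_depth <= 0:
            raise ValueError("bulk size >= 1 and positive depth required")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error rate must lie in [0, 0.5)")


def _haldane_r(dist_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Recombination fraction from physical distance via the Haldane map."""
    morgans = np.abs(dist_bp) / 1e6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def _gamete_states(
    rng: np.random.Generator,
    positions: np.ndarray,
    causal_idx: int | None,
    causal_states: np.ndarray,
    cm_per_mb: float,
) -> np.ndarray:
    """Simulate gamete haplotypes (1 = recessive-parent allele) at markers.

    Crossovers between adjacent loci occur independently with the Haldane
    step probability, which makes the haplotype a Markov chain along the
    chromosome; conditioning on the causal-locus state is then exact.
    """
    n_gametes = causal_states.shape[0]
    steps = _haldane_r(np.diff(positions), cm_per_mb)
    switches = rng.random((n_gametes, steps.size)) < steps
    parity = np.cumsum(switches, axis=1) % 2
    parity = np.concatenate([np.zeros((n_gametes, 1), dtype=int), parity], axis=1)
    if causal_idx is None:
        anchor = rng.integers(0, 2, size=(n_gametes, 1))
        return (anchor + parity) % 2
    # re-anchor the parity at the causal locus
    rel = (parity - parity[:, [causal_idx]]) % 2
    return (causal_states[:, None] + rel) % 2


def _bulk_frequencies(
    rng: np.random.Generator,
    positions: np.ndarray,
    causal_idx: int | None,
    bulk: str,
    n_ind: int,
    cm_per_mb: float,
) -> np.ndarray:
    """Pooled recessive-allele frequency per marker for one bulk."""
    if bulk == "R":
        causal = np.ones(2 * n_ind, dtype=int)  # selected homozygous aa
    else:
        # dominant-phenotype F2: AA with prob 1/3, Aa with prob 2/3
        het = rng.random(n_ind) < (2.0 / 3.0)
        causal = np.zeros((n_ind, 2), dtype=int)
        causal[het, 0] = 1
        causal = causal.reshape(-1)
    states = _gamete_states(rng, positions, causal_idx, causal, cm_per_mb)
    return states.mean(axis=0)


def expected_af(
    positions: Sequence[int],
    causal_position: int | None,
    bulk: str,
    cm_per_mb: float = 4.0,
) -> np.ndarray:
    """Expected recessive-parent allele frequency at each marker.

    Recessive (homozygote-selected) bulk: 1 - r; dominant bulk: (1 + r)/3;
    unlinked chromosomes (``causal_position=None``): 0.5 everywhere.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if causal_position is None:
        return np.full(pos.shape, 0.5)
    r = _haldane_r(pos - causal_position, cm_per_mb)
    if bulk == "R":
        return 1.0 - r
    return (1.0 + r) / 3.0


_BASES = np.array(list("ACGT"))


def simulate_mbs_vcf(
    design: SimulationDesign,
    samples: Sequence[str] = ("R", "D", "Pr", "Pd"),
) -> tuple[str, dict]:
    """Generate a multi-sample VCF with AD fields plus a truth record.

    Returns ``(vcf_text, truth)``; the truth dict stores the causal locus
    and the per-marker expected recessive-allele frequencies per bulk.
    Fixed seed implies byte-identical output.
    """
    design.validate()
    if design.selection == "recessive-bulk":
        samples = tuple(s for s in samples if s != "D")
    rng = np.random.default_rng(design.seed)
    n_d = design.dominant_bulk_size or design.bulk_size
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=bulkmap-simulate(seed={design.seed})",
    ]
    for c in range(1, design.n_chromosomes + 1):
        lines.append(f"##contig=<ID=chr{c},length={design.chromosome_length}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    truth: dict = {
        "causal_chromosome": f"chr{design.causal_chromosome}",
        "causal_position": design.causal_position,
        "chromosomes": {},
    }
    e = design.error_rate
    for c in range(1, design.n_chromosomes + 1):
        chrom = f"chr{c}"
        m = design.markers_per_chromosome
        positions = np.sort(
            rng.choice(design.chromosome_length, size=m, replace=False) + 1
        )
        causal = c == design.causal_chromosome
        if causal:
            ci = int(np.searchsorted(positions, design.causal_position))
            positions_full = np.insert(positions, ci, design.causal_position)
        else:
            ci = None
            positions_full = positions
        freqs: dict[str, np.ndarray] = {}
        if "R" in samples:
            f = _bulk_frequencies(rng, positions_full, ci, "R", design.bulk_size, design.cm_per_mb)
            freqs["R"] = np.delete(f, ci) if causal else f
        if "D" in samples:
            f = _bulk_frequencies(rng, positions_full, ci, "D", n_d, design.cm_per_mb)
            freqs["D"] = np.delete(f, ci) if causal else f
        ref_i = rng.integers(0, 4, size=m)
        alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
        depth: dict[str, np.ndarray] = {}
        alt_reads: dict[str, np.ndarray] = {}
        for s in samples:
            d = rng.poisson(design.mean_depth, size=m)
            if s in ("R", "D"):
                f_eff = freqs[s] * (1 - e) + (1 - freqs[s]) * e
            elif s == "Pr":
                f_eff = np.full(m, 1.0 - e)
            else:  # Pd (or any reference-parent sample)
                f_eff = np.full(m, e)
            k = rng.binomial(d, f_eff)
            depth[s] = d
            alt_reads[s] = k
        cp = design.causal_position if causal else None
        truth["chromosomes"][chrom] = {
            "positions": positions.tolist(),
            "expected_af_R": expected_af(positions, cp, "R", design.cm_per_mb).tolist(),
            "expected_af_D": expected_af(positions, cp, "D", design.cm_per_mb).tolist(),
        }
        refs = _BASES[ref_i]
        alts = _BASES[alt_i]
        for j in range(m):
            ads = "\t".join(
                f"{depth[s][j] - alt_reads[s][j]},{alt_reads[s][j]}" for s in samples
            )
            lines.append(
                f"{chrom}\t{positions[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tAD\t{ads}"
            )
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# toy genome with planted variant effects


SAFE_CODONS = np.array(["GCA", "GAA", "TCT", "CTT", "GGA", "ACT", "CCA", "GTT"])

_UTR5 = "TTCATCTTC"  # holds ATC: one substitution away from an upstream ATG
_CDS1 = "ATGGCTGCTTGGGAACT"  # M A A W E + 2 bases of a split Leu codon
_INTRON = "GT" + "T" * 12 + "AG"
_UTR3 = "CTTCCTTCGATC"


@dataclass
class ToyGenome:
    fasta: str
    gff3: str
    sequences: dict[str, str]
    variants: list[dict] = field(default_factory=list)

    def truth_json(self) -> str:
        return json.dumps(self.variants, indent=1)


def _wrap_fasta(name: str, seq: str, width: int = 60) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


def _gene_parts(rng: np.random.Generator) -> tuple[str, dict]:
    fill = "".join(rng.choice(SAFE_CODONS, size=6))
    cds2 = "G" + fill + "TAA"
    exon1 = _UTR5 + _CDS1
    exon2 = cds2 + _UTR3
    seq = exon1 + _INTRON + exon2
    layout = {
        "exon1_len": len(exon1),
        "intron_len": len(_INTRON),
        "exon2_len": len(exon2),
        "cds2_len": len(cds2),
    }
    return seq, layout


def _gene_features(gene_id: str, chrom: str, s: int, layout: dict, two_isoforms: bool):
    """GFF3 feature tuples (type, start, end, strand, phase, attrs) for one gene."""
    e1 = s + layout["exon1_len"] - 1
    i_end = e1 + layout["intron_len"]
    e2s = i_end + 1
    e2e = e2s + layout["exon2_len"] - 1
    cds1_s, cds1_e = s + len(_UTR5), e1
    cds2_s, cds2_e = e2s, e2s + layout["cds2_len"] - 1
    feats = [("gene", s, e2e, 0, {"ID": gene_id})]
    iso_specs = [(f"{gene_id}.1", s)]
    if two_isoforms:
        iso_specs.append((f"{gene_id}.2", s + 3))  # shorter 5'-UTR
    for iso_id, iso_start in iso_specs:
        feats.append(("mRNA", iso_start, e2e, 0, {"ID": iso_id, "Parent": gene_id}))
        feats.append(("exon", iso_start, e1, 0, {"Parent": iso_id}))
        feats.append(("exon", e2s, e2e, 0, {"Parent": iso_id}))
        feats.append(("five_prime_UTR", iso_start, cds1_s - 1, 0, {"Parent": iso_id}))
        len1 = cds1_e - cds1_s + 1
        feats.append(("CDS", cds1_s, cds1_e, 0, {"Parent": iso_id}))
        feats.append(("CDS", cds2_s, cds2_e, (3 - len1 % 3) % 3, {"Parent": iso_id}))
        feats.append(("three_prime_UTR", cds2_e + 1, e2e, 0, {"Parent": iso_id}))
    return feats, (cds1_s, cds1_e, cds2_s, cds2_e, e1, e2s, e2e)


def _planted_substitutions(gene_id: str, s: int, coords) -> list[dict]:
    cds1_s, _, cds2_s, cds2_e, e1, _, _ = coords
    return [
        dict(pos=s + 5, ref="C", alt="G", expected_effect="premature-start-gain",
             gene=gene_id, kind="substitution"),
        dict(pos=cds1_s + 5, ref="T", alt="C", expected_effect="synonymous",
             gene=gene_id, kind="substitution"),
        dict(pos=cds1_s + 7, ref="C", alt="A", expected_effect="missense",
             gene=gene_id, kind="substitution"),
        dict(pos=cds1_s + 11, ref="G", alt="A", expected_effect="nonsense",
             gene=gene_id, kind="substitution"),
        dict(pos=e1 + 1, ref="G", alt="A", expected_effect="splice-site",
             gene=gene_id, kind="substitution"),
        dict(pos=cds2_e - 2, ref="T", alt="C", expected_effect="nonstop",
             gene=gene_id, kind="substitution"),
    ]


def simulate_toy_genome(n_genes: int = 5, seed: int = 0) -> ToyGenome:
    """Two-chromosome toy genome with planted variants of known effect.

    chrA carries ``n_genes`` plus-strand genes (the first with two
    isoforms); chrB is the exact reverse complement of chrA with mirrored
    minus-strand gene models, providing a metamorphic twin of every
    planted substitution.  Deletion variants (frameshift, in-frame,
    partial and complete gene disruption) are planted on chrA only.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    gap = 300
    margin = 200
    seq_parts: list[str] = []
    cursor = 1
    features: list[tuple] = []  # (type, start, end, strand, phase, attrs)
    planted: list[dict] = []
    gene_spans: list[tuple[int, int]] = []

    seq_parts.append("".join(rng.choice(list("ACGT"), size=margin)))
    cursor += margin
    for i in range(n_genes):
        gseq, layout = _gene_parts(rng)
        gene_id = f"geneA{i + 1:02d}"
        feats, coords = _gene_features(gene_id, "chrA", cursor, layout, two_isoforms=(i == 0))
        features.extend(("chrA",) + f for f in feats)
        planted.extend(
            dict(chrom="chrA", **p) for p in _planted_substitutions(gene_id, cursor, coords)
        )
        gene_spans.append((cursor, cursor + len(gseq) - 1))
        seq_parts.append(gseq)
        cursor += len(gseq)
        seq_parts.append("".join(rng.choice(list("ACGT"), size=gap)))
        cursor += gap
    chr_a = "".join(seq_parts)

    # intergenic substitution midway through the first gap
    ig_pos = gene_spans[0][1] + gap // 2
    planted.append(
        dict(chrom="chrA", pos=ig_pos, ref=chr_a[ig_pos - 1],
             alt="A" if chr_a[ig_pos - 1] != "A" else "C",
             expected_effect="intergenic", gene="", kind="substitution")
    )
    # CDS deletions in gene 1 (exon 2 interior)
    g1s, _ = gene_spans[0]
    cds2_s = g1s + len(_UTR5 + _CDS1) + len(_INTRON)
    fs_anchor = cds2_s + 1
    planted.append(
        dict(chrom="chrA", pos=fs_anchor, ref=chr_a[fs_anchor - 1 : fs_anchor + 1],
             alt=chr_a[fs_anchor - 1], expected_effect="frameshift",
             gene="geneA01", kind="deletion")
    )
    if_anchor = cds2_s + 4
    planted.append(
        dict(chrom="chrA", pos=if_anchor, ref=chr_a[if_anchor - 1 : if_anchor + 3],
             alt=chr_a[if_anchor - 1], expected_effect="in-frame-indel",
             gene="geneA01", kind="deletion")
    )
    # gene-scale deletions on the last (complete) and first (partial) genes
    ps, pe = gene_spans[0]
    part_anchor = pe - 10
    planted.append(
        dict(chrom="chrA", pos=part_anchor,
             ref=chr_a[part_anchor - 1 : pe + 40], alt=chr_a[part_anchor - 1],
             expected_effect="gene-disruption", gene="geneA01",
             kind="deletion", disruption="partial")
    )
    qs, qe = gene_spans[-1]
    comp_anchor = qs - 11
    planted.append(
        dict(chrom="chrA", pos=comp_anchor,
             ref=chr_a[comp_anchor - 1 : qe + 10], alt=chr_a[comp_anchor - 1],
             expected_effect="gene-disruption", gene=f"geneA{n_genes:02d}",
             kind="deletion", disruption="complete")
    )

    # mirror chromosome: reverse complement with minus-strand gene models.
    # The mirror preserves segment lengths and translation order, so CDS
    # phases carry over unchanged.
    length = len(chr_a)
    chr_b = _revcomp(chr_a)
    mirrored: list[tuple] = []
    for chrom, ftype, fs, fe, phase, attrs in features:
        ms, me = length - fe + 1, length - fs + 1
        mattrs = {k: (v + "_m" if k in ("ID", "Parent") else v) for k, v in attrs.items()}
        mirrored.append(("chrB", ftype, ms, me, "-", phase, mattrs))
    for p in list(planted):
        if p["kind"] != "substitution":
            continue
        mp = length - p["pos"] + 1
        planted.append(
            dict(chrom="chrB", pos=mp, ref=p["ref"].translate(COMPLEMENT),
                 alt=p["alt"].translate(COMPLEMENT),
                 expected_effect=p["expected_effect"],
                 gene=(p["gene"] + "_m") if p["gene"] else "", kind="substitution")
        )

    gff_lines = ["##gff-version 3"]
    all_feats = [
        (chrom, ftype, fs, fe, "+", phase, attrs)
        for chrom, ftype, fs, fe, phase, attrs in features
    ] + mirrored
    for chrom, ftype, fs, fe, strand, phase, attrs in all_feats:
        col8 = str(phase) if ftype == "CDS" else "."
        attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
        gff_lines.append(
            f"{chrom}\tbulkmap\t{ftype}\t{fs}\t{fe}\t.\t{strand}\t{col8}\t{attr_s}"
        )
    fasta = _wrap_fasta("chrA", chr_a) + _wrap_fasta("chrB", chr_b)
    return ToyGenome(
        fasta=fasta,
        gff3="\n".join(gff_lines) + "\n",
        sequences={"chrA": chr_a, "chrB": chr_b},
        variants=planted,
    )
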