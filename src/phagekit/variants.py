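"""Whole-genome pairwise comparison of near-identical phage genomes.

Two assemblies that differ by a few hundred substitutions and a couple of
small indels are compared by anchoring on shared unique k-mers, chaining
the anchors colinearly, and closing the small inter-anchor gaps with an
optimal global alignment. Every mismatch column becomes a SNP; unaligned
runs become indels. SNPs are then classified against the CDS annotation
(intergenic / synonymous / non-synonymous under the bacterial genetic
code, table 11) and SNPs falling inside homopolymer tracts of six or more
identical nucleotides — the classic pyrosequencing trouble spots — are
flagged and excluded from the reported totals.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field
from itertools import groupby
from pathlib import Path

from Bio import Align
from Bio.Data import CodonTable

from .seqio import Feature, GenomeRecord

_TABLE11 = CodonTable.unambiguous_dna_by_id[11].forward_table
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class AlignmentError(ValueError):
    """Sequences could not be anchored/aligned."""


@dataclass(frozen=True)
class Block:
    """A gapless aligned segment (mismatches allowed, no indels)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int

    def __post_init__(self) -> None:
        if self.a_end - self.a_start != self.b_end - self.b_start:
            raise ValueError("gapless block must have equal spans")


@dataclass(frozen=True)
class IndelRegion:
    """A maximal unaligned run: present in exactly one genome."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def kind(self) -> str:
        return "deletion_in_b" if self.a_end > self.a_start else "insertion_in_b"

    @property
    def length(self) -> int:
        return max(self.a_end - self.a_start, self.b_end - self.b_start)


@dataclass
class PairwiseAlignment:
    blocks: list[Block]
    indels: list[IndelRegion]
    structural: list[IndelRegion] = field(default_factory=list)

    def identity(self, seq_a: str, seq_b: str) -> tuple[float, float]:
        """(percent identity over aligned columns, percent of A aligned)."""
        matches = columns = 0
        for blk in self.blocks:
            a = seq_a[blk.a_start:blk.a_end]
            b = seq_b[blk.b_start:blk.b_end]
            columns += len(a)
            matches += sum(x == y for x, y in zip(a, b))
        if columns == 0:
            return 0.0, 0.0
        return 100.0 * matches / columns, 100.0 * columns / len(seq_a)


@dataclass
class Snp:
    pos_a: int  # 0-based
    pos_b: int
    allele_a: str
    allele_b: str
    klass: str | None = None  # intergenic | synonymous | nonsynonymous | discordant
    locus_tag: str | None = None
    in_homopolymer: bool = False


@dataclass(frozen=True)
class HomopolymerTract:
    base: str
    start: int  # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Anchor alignment
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _lis_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates (anchors sorted by A)."""
    tails: list[int] = []  # b-values of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, b) in enumerate(anchors):
        j = bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            tails_idx.append(i)
        else:
            tails[j] = b
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i >= 0:
        chain.append(anchors[i])
        i = parent[i]
    chain.reverse()
    return chain


def _gap_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _align_gap(a: str, b: str, a_off: int, b_off: int,
               blocks: list[Block], indels: list[IndelRegion]) -> None:
    """Optimally align two gap segments and append blocks/indels."""
    if not a and not b:
        return
    if not a:
        indels.append(IndelRegion(a_off, a_off, b_off, b_off + len(b)))
        return
    if not b:
        indels.append(IndelRegion(a_off, a_off + len(a), b_off, b_off))
        return
    aln = _gap_aligner().align(a, b)[0]
    seg_a, seg_b = aln.aligned
    prev_a, prev_b = 0, 0
    for (sa, ea), (sb, eb) in zip(seg_a, seg_b):
        if sa > prev_a:
            indels.append(IndelRegion(a_off + prev_a, a_off + sa,
                                      b_off + prev_b, b_off + prev_b))
        if sb > prev_b:
            indels.append(IndelRegion(a_off + prev_a, a_off + prev_a,
                                      b_off + prev_b, b_off + sb))
        blocks.append(Block(a_off + sa, a_off + ea, b_off + sb, b_off + eb))
        prev_a, prev_b = ea, eb
    if len(a) > prev_a:
        indels.append(IndelRegion(a_off + prev_a, a_off + len(a),
                                  b_off + prev_b, b_off + prev_b))
    if len(b) > prev_b:
        indels.append(IndelRegion(a_off + prev_a, a_off + prev_a,
                                  b_off + prev_b, b_off + len(b)))


def anchor_align(seq_a: str, seq_b: str, k: int = 21,
                 max_gap: int = 20_000) -> PairwiseAlignment:
    """Colinear alignment of two near-identical genomes via unique k-mer anchors.

    k-mers unique in both sequences are chained (longest strictly
    increasing chain in both coordinates); inter-anchor gaps up to
    ``max_gap`` are closed by optimal global alignment with affine gaps
    (match +1 / mismatch -2 / open -5 / extend -1); larger gaps are
    reported as structural differences.
    """
    if len(seq_a) < 2 * k or len(seq_b) < 2 * k:
        raise AlignmentError("sequences shorter than 2k")
    ka = _unique_kmers(seq_a, k)
    kb = _unique_kmers(seq_b, k)
    shared = [(pa, kb[km]) for km, pa in ka.items() if km in kb]
    if not shared:
        raise AlignmentError("sequences too diverged: no unique shared k-mers")
    shared.sort()
    chain = _lis_chain(shared)

    # merge same-diagonal anchors into maximal gapless blocks; trim anchors
    # that overlap the previous block after a diagonal shift (small indel)
    merged: list[tuple[int, int, int]] = []  # (a_start, b_start, length)
    for pa, pb in chain:
        ln = k
        if merged:
            a0, b0, pln = merged[-1]
            if pa - a0 == pb - b0:
                # same diagonal: extend across the gapless span
                merged[-1] = (a0, b0, pa - a0 + k)
                continue
            trim = max(a0 + pln - pa, b0 + pln - pb, 0)
            pa, pb, ln = pa + trim, pb + trim, ln - trim
            if ln <= 0:
                continue
        merged.append((pa, pb, ln))

    blocks: list[Block] = []
    indels: list[IndelRegion] = []
    structural: list[IndelRegion] = []
    prev_a = prev_b = 0
    for a0, b0, ln in merged:
        ga, gb = seq_a[prev_a:a0], seq_b[prev_b:b0]
        if max(len(ga), len(gb)) > max_gap:
            structural.append(IndelRegion(prev_a, a0, prev_b, b0))
        else:
            _align_gap(ga, gb, prev_a, prev_b, blocks, indels)
        blocks.append(Block(a0, a0 + ln, b0, b0 + ln))
        prev_a, prev_b = a0 + ln, b0 + ln
    ga, gb = seq_a[prev_a:], seq_b[prev_b:]
    if max(len(ga), len(gb)) > max_gap:
        structural.append(IndelRegion(prev_a, len(seq_a), prev_b, len(seq_b)))
    else:
        _align_gap(ga, gb, prev_a, prev_b, blocks, indels)
    blocks.sort(key=lambda blk: blk.a_start)
    indels.sort(key=lambda iv: iv.a_start)
    return PairwiseAlignment(blocks=blocks, indels=indels, structural=structural)


# ---------------------------------------------------------------------------
# Variant calling
# ---------------------------------------------------------------------------

def call_variants(alignment: PairwiseAlignment, seq_a: str, seq_b: str
                  ) -> tuple[list[Snp], list[IndelRegion]]:
    """One SNP per mismatch column; indels from unaligned runs.

    Columns involving N are skipped. Adjacent indel regions (split only by
    alignment bookkeeping) are merged.
    """
    snps: list[Snp] = []
    for blk in alignment.blocks:
        a = seq_a[blk.a_start:blk.a_end]
        b = seq_b[blk.b_start:blk.b_end]
        if a == b:
            continue
        for i, (x, y) in enumerate(zip(a, b)):
            if x != y and x != "N" and y != "N":
                snps.append(Snp(pos_a=blk.a_start + i, pos_b=blk.b_start + i,
                                allele_a=x, allele_b=y))
    snps.sort(key=lambda s: s.pos_a)

    merged: list[IndelRegion] = []
    for iv in sorted(alignment.indels + alignment.structural,
                     key=lambda iv: (iv.a_start, iv.b_start)):
        if merged and merged[-1].a_end >= iv.a_start and merged[-1].b_end >= iv.b_start:
            last = merged.pop()
            iv = IndelRegion(last.a_start, max(last.a_end, iv.a_end),
                             last.b_start, max(last.b_end, iv.b_end))
        merged.append(iv)
    return snps, merged


# ---------------------------------------------------------------------------
# Homopolymers
# ---------------------------------------------------------------------------

def scan_homopolymers(sequence: str, min_len: int = 6) -> list[HomopolymerTract]:
    """All maximal runs of a single A/C/G/T base of length >= min_len."""
    if not sequence:
        raise ValueError("empty sequence")
    out = []
    pos = 0
    for base, grp in groupby(sequence):
        ln = sum(1 for _ in grp)
        if ln >= min_len and base in "ACGT":
            out.append(HomopolymerTract(base=base, start=pos, end=pos + ln))
        pos += ln
    return out


def filter_homopolymer_snps(
    snps: list[Snp],
    tracts_a: list[HomopolymerTract],
    tracts_b: list[HomopolymerTract],
) -> tuple[list[Snp], list[Snp]]:
    """Split SNPs into (kept, excluded) by tract membership in either genome."""
    in_a = {p for t in tracts_a for p in range(t.start, t.end)}
    in_b = {p for t in tracts_b for p in range(t.start, t.end)}
    kept, excluded = [], []
    for s in snps:
        s.in_homopolymer = s.pos_a in in_a or s.pos_b in in_b
        (excluded if s.in_homopolymer else kept).append(s)
    return kept, excluded


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _cds_at(features: list[Feature], pos: int) -> Feature | None:
    for f in features:
        if f.type == "CDS" and f.contains0(pos):
            return f
    return None


def _codon_at(seq: str, f: Feature, pos: int) -> tuple[str, int]:
    """(codon in coding orientation, within-codon index) for genome position pos."""
    s, e = f.slice0()
    if f.strand == "+":
        ci = (pos - s) // 3
        p0 = s + 3 * ci
        codon = seq[p0:p0 + 3]
        return codon, (pos - s) % 3
    ci = (e - 1 - pos) // 3
    p0 = e - 3 * ci
    codon = "".join(_COMP[seq[p0 - 1 - j]] for j in range(3))
    return codon, (e - 1 - pos) % 3


def _aa(codon: str) -> str:
    return _TABLE11.get(codon, "*")


def classify_snps(
    snps: list[Snp],
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
) -> tuple[list[Snp], int]:
    """Assign intergenic/synonymous/nonsynonymous classes in place.

    A SNP inside a CDS is classified by extracting the codon covering it
    from each genome (through that genome's own annotation and strand) and
    comparing the encoded amino acids under table 11 — so adjacent SNPs in
    one codon are judged jointly at codon level. A SNP coding in one genome
    but intergenic in the other is flagged "discordant" and not counted.
    Returns (snps, number of distinct proteins with >= 1 non-synonymous SNP).
    """
    cds_a = genome_a.cds
    cds_b = genome_b.cds
    affected: set[str] = set()
    for s in snps:
        fa = _cds_at(cds_a, s.pos_a)
        fb = _cds_at(cds_b, s.pos_b)
        if fa is None and fb is None:
            s.klass = "intergenic"
            continue
        if fa is None or fb is None:
            s.klass = "discordant"
            continue
        codon_a, _ = _codon_at(genome_a.sequence, fa, s.pos_a)
        codon_b, _ = _codon_at(genome_b.sequence, fb, s.pos_b)
        s.locus_tag = fa.locus_tag
        if _aa(codon_a) == _aa(codon_b):
            s.klass = "synonymous"
        else:
            s.klass = "nonsynonymous"
            affected.add(fa.locus_tag)
    return snps, len(affected)


# ---------------------------------------------------------------------------
# End-to-end comparison and reports
# ---------------------------------------------------------------------------

def compare_genomes(genome_a: GenomeRecord, genome_b: GenomeRecord,
                    k: int = 21, min_tract: int = 6) -> dict:
    """Full pipeline: align, call, filter homopolymer SNPs, classify.

    Returns a dict with the alignment, kept/excluded SNP lists, indels, and
    a summary with both pre- and post-filter totals.
    """
    aln = anchor_align(genome_a.sequence, genome_b.sequence, k=k)
    snps, indels = call_variants(aln, genome_a.sequence, genome_b.sequence)
    tracts_a = scan_homopolymers(genome_a.sequence, min_tract)
    tracts_b = scan_homopolymers(genome_b.sequence, min_tract)
    kept, excluded = filter_homopolymer_snps(snps, tracts_a, tracts_b)
    kept, n_proteins = classify_snps(kept, genome_a, genome_b)
    ident, cov = aln.identity(genome_a.sequence, genome_b.sequence)
    counts = {"intergenic": 0, "synonymous": 0, "nonsynonymous": 0, "discordant": 0}
    for s in kept:
        counts[s.klass] += 1
    summary = {
        "snps_total_prefilter": len(snps),
        "snps_kept": len(kept),
        "snps_excluded_homopolymer": len(excluded),
        "indel_regions": len(indels),
        "identity_percent": round(ident, 2),
        "aligned_percent": round(cov, 2),
        "proteins_with_nonsynonymous": n_proteins,
        **counts,
    }
    return {"alignment": aln, "snps": kept, "excluded": excluded,
            "indels": indels, "tracts_a": tracts_a, "tracts_b": tracts_b,
            "summary": summary}


def write_snp_tsv(snps: list[Snp], path: str | Path,
                  chrom_a: str = "A", chrom_b: str = "B") -> None:
    """VCF-like TSV report (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tPOS_B\tCLASS\tLOCUS\tHP_FLAG\n")
        for s in snps:
            fh.write(f"{chrom_a}\t{s.pos_a + 1}\t{s.allele_a}\t{s.allele_b}\t"
                     f"{s.pos_b + 1}\t{s.klass or '.'}\t{s.locus_tag or '.'}\t"
                     f"{int(s.in_homopolymer)}\n")


def write_tract_bed(tracts: list[HomopolymerTract], chrom: str,
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(f"{chrom}\t{t.start}\t{t.end}\t{t.base}x{t.length}\n")


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
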