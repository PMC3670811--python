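"""Synthetic phage genomes with known ground truth.

Everything downstream (terminal-repeat detection, digestion, SNP calling,
proteome comparison) is exercised on genomes built here, so the generator
emulates the salient features of an N4-like phage genome: ~69 kb of
AT-rich (~34.6% G+C) sequence densely packed with non-overlapping CDSs on
both strands, a ~2 kb direct terminal repeat at the 3' end, homopolymer
tracts, and pairs of genomes separated by a known set of intergenic /
synonymous / non-synonymous substitutions and small indels.

Determinism: every public operation takes a seed and derives independent
per-stage streams from it; identical spec + seed gives byte-identical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .seqio import Feature, GenomeRecord, reverse_complement

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


class SpecError(ValueError):
    """Invalid generator specification."""


class CapacityError(ValueError):
    """The genome cannot host the requested features or events."""


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    homopolymers: optional (length, base) tracts planted in intergenic
    space, e.g. ``[(12, "A")]`` to exercise the >=6 nt rule with the
    longest tract the study phages carry.
    """

    length: int
    gc: float
    n_cds: int
    dtr_length: int = 0
    seed: int = 0
    homopolymers: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise SpecError(f"genome length must be >= 1000 (got {self.length})")
        if not 0.0 < self.gc < 1.0:
            raise SpecError(f"gc must be in (0,1) (got {self.gc})")
        if self.n_cds < 0 or self.dtr_length < 0:
            raise SpecError("n_cds and dtr_length must be non-negative")
        if self.dtr_length >= self.length / 2:
            raise SpecError(
                f"dtr_length {self.dtr_length} must be < length/2 ({self.length / 2:.0f})"
            )
        for ln, base in self.homopolymers:
            if ln < 6 or base not in "ACGT":
                raise SpecError(f"homopolymer tract ({ln},{base}) invalid")


@dataclass(frozen=True)
class DivergenceSpec:
    """Counts of substitution/indel events to plant between a genome pair."""

    n_intergenic: int
    n_synonymous: int
    n_nonsynonymous: int
    n_indels: int
    seed: int = 0
    n_in_homopolymer: int = 0  # extra intergenic SNPs planted inside tracts
    cds_deletion: bool = False  # make one indel a whole-CDS deletion

    def __post_init__(self) -> None:
        for name in ("n_intergenic", "n_synonymous", "n_nonsynonymous",
                     "n_indels", "n_in_homopolymer"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.cds_deletion and self.n_indels < 1:
            raise SpecError("cds_deletion requires n_indels >= 1")


@dataclass(frozen=True)
class PlantedSub:
    pos_a: int  # 0-based, genome A, plus strand
    ref: str
    alt: str
    klass: str  # intergenic | synonymous | nonsynonymous
    in_homopolymer: bool
    locus_tag: str | None = None


@dataclass(frozen=True)
class PlantedIndel:
    pos_a: int  # 0-based position in A where the event anchors
    length: int
    kind: str  # "ins" (present in B only) | "del" (absent from B)
    sequence: str


@dataclass
class GroundTruth:
    """Everything planted into a synthetic genome (pair), for verification."""

    substitutions: list[PlantedSub] = field(default_factory=list)
    indels: list[PlantedIndel] = field(default_factory=list)
    dtr: tuple[int, int] | None = None  # 0-based half-open interval
    homopolymer_tracts: list[tuple[str, int, int]] = field(default_factory=list)

    def counts(self) -> dict:
        out = {"intergenic": 0, "synonymous": 0, "nonsynonymous": 0}
        for s in self.substitutions:
            if not s.in_homopolymer:
                out[s.klass] += 1
        out["in_homopolymer"] = sum(s.in_homopolymer for s in self.substitutions)
        out["indels"] = len(self.indels)
        return out

    def affected_proteins(self) -> int:
        return len({s.locus_tag for s in self.substitutions
                    if s.klass == "nonsynonymous" and not s.in_homopolymer})


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

_GAP_MIN = 50
_CDS_MIN = 300


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    """A codon drawn from the per-base model, conditioned on not being a stop."""
    while True:
        c = "".join(_random_bases(rng, 3, gc))
        if c not in _STOPS:
            return c


def _codon_gc_expectation(gc: float) -> float:
    """Expected GC fraction of a codon conditioned on not being a stop."""
    from itertools import product

    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    num = den = 0.0
    for codon in product("ACGT", repeat=3):
        c = "".join(codon)
        if c in _STOPS:
            continue
        w = p[c[0]] * p[c[1]] * p[c[2]]
        den += w
        num += w * (c.count("G") + c.count("C")) / 3
    return num / den


def _coding_gc(target: float) -> float:
    """Per-base GC that makes stop-free codons hit the target GC on average."""
    lo, hi = 0.01, 0.99
    for _ in range(50):
        mid = (lo + hi) / 2
        if _codon_gc_expectation(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _coding_sequence(rng: np.random.Generator, n_bp: int, gc: float) -> str:
    """ATG + stop-free body + one stop codon, n_bp total (multiple of 3)."""
    n_codons = n_bp // 3
    body = [_random_codon(rng, gc) for _ in range(n_codons - 2)]
    stop = rng.choice(["TAA", "TAG", "TGA"])
    return "ATG" + "".join(body) + str(stop)


def _layout(rng: np.random.Generator, spec: GenomeSpec) -> tuple[list[tuple[int, int]], list[int]]:
    """CDS intervals (0-based half-open) and gap widths; CDSs stay out of the DTR."""
    usable = spec.length - spec.dtr_length
    n = spec.n_cds
    hp_space = sum(ln + 4 for ln, _ in spec.homopolymers)
    need = n * _CDS_MIN + (n + 1) * _GAP_MIN + hp_space
    if usable < need:
        raise CapacityError(
            f"{usable} bp cannot host {n} CDSs (needs >= {need} bp)"
        )
    extra = usable - need
    cds_extra = int(extra * 0.85) // 3
    gap_extra = extra - cds_extra * 3
    cds_len = np.full(n, _CDS_MIN)
    if n:
        cds_len += 3 * rng.multinomial(cds_extra, np.full(n, 1 / n))
    gaps = np.full(n + 1, _GAP_MIN)
    gaps += rng.multinomial(gap_extra, np.full(n + 1, 1 / (n + 1)))
    # reserve room for homopolymer plantings in the widest gaps
    intervals = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        intervals.append((pos, pos + int(cds_len[i])))
        pos += int(cds_len[i])
    return intervals, [int(g) for g in gaps]


def _build_once(spec: GenomeSpec, seed: int) -> tuple[str, list[Feature], list[tuple[str, int, int]]]:
    rng = np.random.default_rng(seed)
    seq = _random_bases(rng, spec.length, spec.gc)
    intervals, gaps = _layout(rng, spec)
    gc_coding = _coding_gc(spec.gc)
    features = []
    for i, (s, e) in enumerate(intervals):
        strand = "+" if i % 2 == 0 else "-"
        coding = _coding_sequence(rng, e - s, gc_coding)
        insert = coding if strand == "+" else reverse_complement(coding)
        seq[s:e] = list(insert)
        features.append(Feature(type="CDS", locus_tag=f"SYN_{i + 1:04d}",
                                start=s + 1, end=e, strand=strand))
    # plant homopolymer tracts into the widest gaps, away from CDS edges
    tracts: list[tuple[str, int, int]] = []
    if spec.homopolymers:
        gap_iv = _gap_intervals(intervals, spec.length - spec.dtr_length)
        gap_iv.sort(key=lambda iv: iv[0] - iv[1])  # widest first
        for (ln, base), (gs, ge) in zip(spec.homopolymers, gap_iv):
            if ge - gs < ln + 6:
                raise CapacityError(f"no intergenic gap can host a {ln} bp tract")
            start = gs + (ge - gs - ln) // 2
            seq[start:start + ln] = base
            other = "T" if base != "T" else "A"
            seq[start - 1] = other
            seq[start + ln] = other
            tracts.append((base, start, start + ln))
    return "".join(seq), features, tracts


def _gap_intervals(cds_intervals: list[tuple[int, int]], end: int) -> list[tuple[int, int]]:
    gaps, pos = [], 0
    for s, e in cds_intervals:
        if s > pos:
            gaps.append((pos, s))
        pos = e
    if end > pos:
        gaps.append((pos, end))
    return gaps


def make_genome(spec: GenomeSpec, id: str = "synthetic") -> tuple[GenomeRecord, GroundTruth]:
    """Build one genome to spec; realized GC within 0.5 pp of target.

    The last ``dtr_length`` bases are recorded as the terminal-repeat unit
    (the non-redundant representation carries the repeat once, at the 3'
    end, as assembled phage genomes with direct terminal repeats do).
    """
    master = np.random.default_rng(spec.seed)
    for _ in range(25):
        sub_seed = int(master.integers(0, 2**31 - 1))
        seq, features, tracts = _build_once(spec, sub_seed)
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        if abs(gc - 100.0 * spec.gc) <= 0.5:
            break
    else:
        raise CapacityError("could not realize target GC within 0.5 pp in 25 tries")
    record = GenomeRecord(id=id, sequence=seq, features=features)
    truth = GroundTruth(
        dtr=(spec.length - spec.dtr_length, spec.length) if spec.dtr_length else None,
        homopolymer_tracts=tracts,
    )
    return record, truth


def make_redundant_form(genome: GenomeRecord | str, dtr_length: int) -> str:
    """Terminally redundant form: the 3'-terminal repeat copied to the 5' end."""
    seq = genome.sequence if isinstance(genome, GenomeRecord) else genome
    if dtr_length > len(seq):
        raise ValueError(f"dtr_length {dtr_length} exceeds genome length {len(seq)}")
    if dtr_length == 0:
        return seq
    return seq[-dtr_length:] + seq


# ---------------------------------------------------------------------------
# Planted divergence
# ---------------------------------------------------------------------------

def _run_length_at(seq, pos: int, base: str) -> int:
    """Length of the maximal run of `base` covering pos (0 if seq[pos] != base)."""
    if seq[pos] != base:
        return 0
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    n = len(seq)
    while j + 1 < n and seq[j + 1] == base:
        j += 1
    return j - i + 1


def _in_tract_after(seq_a, seq_b, pos: int, min_len: int = 6) -> bool:
    """Would a SNP at pos sit inside a >=min_len homopolymer in either genome?"""
    return (_run_length_at(seq_a, pos, seq_a[pos]) >= min_len
            or _run_length_at(seq_b, pos, seq_b[pos]) >= min_len)


def _codon_positions(f: Feature, codon_idx: int) -> list[int]:
    """Plus-strand 0-based genome positions of codon codon_idx, 5'->3' in coding order."""
    s, e = f.slice0()
    if f.strand == "+":
        p = s + 3 * codon_idx
        return [p, p + 1, p + 2]
    p = e - 3 * codon_idx
    return [p - 1, p - 2, p - 3]


def _synonyms(codon: str) -> list[tuple[int, str]]:
    """Single-base changes preserving the encoded amino acid (table 11)."""
    aa = _TABLE11.forward_table.get(codon)
    out = []
    if aa is None:
        return out
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _TABLE11.forward_table.get(alt) == aa:
                out.append((i, alt))
    return out


def _nonsynonyms(codon: str) -> list[tuple[int, str]]:
    aa = _TABLE11.forward_table.get(codon)
    out = []
    if aa is None:
        return out
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _TABLE11.forward_table.get(alt) != aa:
                out.append((i, alt))
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def diverge_pair(
    genome: GenomeRecord,
    spec: DivergenceSpec,
    truth_a: GroundTruth | None = None,
    id: str | None = None,
) -> tuple[GenomeRecord, GroundTruth]:
    """Create a second genome differing from the first by exactly the planted events.

    Substitution classes are guaranteed by construction (codons checked
    against the genetic code when planting) and plantings never overlap:
    each codon is used once, intergenic sites keep >= 30 bp separation from
    indels, and — except for the dedicated in-homopolymer plantings — no
    SNP lands inside a >=6 nt homopolymer tract of either genome.
    """
    if (spec.n_synonymous or spec.n_nonsynonymous) and not genome.cds:
        raise CapacityError("coding substitutions requested but genome has no CDS")
    rng = np.random.default_rng(spec.seed)
    seq_a = genome.sequence
    seq_b = list(seq_a)
    truth = GroundTruth(
        dtr=truth_a.dtr if truth_a else None,
        homopolymer_tracts=list(truth_a.homopolymer_tracts) if truth_a else [],
    )
    used: set[int] = set()

    cds_list = genome.cds
    in_cds = np.zeros(len(seq_a), dtype=bool)
    for f in cds_list:
        s, e = f.slice0()
        in_cds[s:e] = True

    # --- coding substitutions -------------------------------------------
    def plant_coding(n: int, klass: str, candidates_fn) -> None:
        planted, attempts = 0, 0
        max_attempts = 200 * n + 1000
        while planted < n:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not plant {n} {klass} substitutions "
                    f"(placed {planted}); genome too small or too constrained"
                )
            f = cds_list[int(rng.integers(len(cds_list)))]
            n_codons = f.length // 3
            if n_codons < 4:
                continue
            ci = int(rng.integers(1, n_codons - 1))  # skip start & stop codons
            positions = _codon_positions(f, ci)
            if any(p in used for p in positions):
                continue
            codon = "".join(
                seq_a[p] if f.strand == "+" else _COMP[seq_a[p]] for p in positions
            )
            cands = candidates_fn(codon)
            if not cands:
                continue
            i, alt_codon = cands[int(rng.integers(len(cands)))]
            pos = positions[i]
            alt_base = alt_codon[i] if f.strand == "+" else _COMP[alt_codon[i]]
            seq_b[pos] = alt_base
            if _in_tract_after(seq_a, seq_b, pos):
                seq_b[pos] = seq_a[pos]
                continue
            used.update(positions)
            truth.substitutions.append(PlantedSub(
                pos_a=pos, ref=seq_a[pos], alt=alt_base, klass=klass,
                in_homopolymer=False, locus_tag=f.locus_tag))
            planted += 1

    plant_coding(spec.n_synonymous, "synonymous", _synonyms)
    plant_coding(spec.n_nonsynonymous, "nonsynonymous", _nonsynonyms)

    # --- intergenic substitutions ---------------------------------------
    intergenic_pos = np.flatnonzero(~in_cds)
    if len(intergenic_pos) < 10 * (spec.n_intergenic + 1) and spec.n_intergenic:
        raise CapacityError("too little intergenic space for requested substitutions")

    def plant_intergenic(n: int, inside_tract: bool) -> None:
        planted, attempts = 0, 0
        max_attempts = 500 * n + 1000
        tract_positions = [
            (base, s, e) for base, s, e in truth.homopolymer_tracts
        ]
        while planted < n:
            attempts += 1
            if attempts > max_attempts:
                raise CapacityError(
                    f"could not plant {n} intergenic substitutions (placed {planted})"
                )
            if inside_tract:
                if not tract_positions:
                    raise CapacityError(
                        "in-homopolymer plantings requested but no tract was planted"
                    )
                base, s, e = tract_positions[int(rng.integers(len(tract_positions)))]
                pos = int(rng.integers(s + 1, e - 1))
            else:
                pos = int(intergenic_pos[int(rng.integers(len(intergenic_pos)))])
            if pos in used:
                continue
            ref = seq_a[pos]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(3))]
            seq_b[pos] = alt
            in_tract = _in_tract_after(seq_a, seq_b, pos)
            if in_tract != inside_tract:
                seq_b[pos] = ref
                continue
            used.add(pos)
            truth.substitutions.append(PlantedSub(
                pos_a=pos, ref=ref, alt=alt, klass="intergenic",
                in_homopolymer=inside_tract))
            planted += 1

    plant_intergenic(spec.n_intergenic, inside_tract=False)
    plant_intergenic(spec.n_in_homopolymer, inside_tract=True)

    # --- indels ----------------------------------------------------------
    events: list[PlantedIndel] = []
    n_small = spec.n_indels - (1 if spec.cds_deletion else 0)
    gap_iv = _gap_intervals([f.slice0() for f in cds_list], len(seq_a))
    wide = [(s, e) for s, e in gap_iv if e - s >= 90]
    if spec.n_indels and not wide and n_small:
        raise CapacityError("no intergenic gap wide enough for indel planting")
    attempts = 0
    while len(events) < n_small:
        attempts += 1
        if attempts > 200 * spec.n_indels + 100:
            raise CapacityError("could not place requested indels")
        s, e = wide[int(rng.integers(len(wide)))]
        pos = int(rng.integers(s + 30, e - 30))
        if any(abs(pos - u) < 30 for u in used):
            continue
        length = int(rng.integers(1, 11))
        kind = "del" if rng.random() < 0.5 else "ins"
        if kind == "del":
            seqn = seq_a[pos:pos + length]
        else:
            seqn = "".join(_random_bases(rng, length, 0.5))
        events.append(PlantedIndel(pos_a=pos, length=length, kind=kind, sequence=seqn))
        used.update(range(pos - 15, pos + length + 15))
    if spec.cds_deletion:
        # the deleted CDS must not carry any planted substitution
        for _ in range(20 * len(cds_list)):
            f = cds_list[int(rng.integers(len(cds_list)))]
            s, e = f.slice0()
            if not any(s <= u < e for u in used):
                break
        else:
            raise CapacityError("no CDS free of planted events to delete")
        events.append(PlantedIndel(pos_a=s, length=e - s, kind="del",
                                   sequence=seq_a[s:e]))
    truth.indels = sorted(events, key=lambda ev: ev.pos_a)

    # apply indels right-to-left so earlier coordinates stay valid
    deleted_cds: set[str] = set()
    for ev in sorted(events, key=lambda ev: -ev.pos_a):
        if ev.kind == "del":
            if ev.length >= _CDS_MIN:
                for f in cds_list:
                    if f.slice0() == (ev.pos_a, ev.pos_a + ev.length):
                        deleted_cds.add(f.locus_tag)
            del seq_b[ev.pos_a:ev.pos_a + ev.length]
        else:
            seq_b[ev.pos_a:ev.pos_a] = list(ev.sequence)

    # shift B's annotation across the indels
    def shift(p0: int) -> int:
        d = 0
        for ev in events:
            if ev.pos_a <= p0:
                d += ev.length if ev.kind == "ins" else -ev.length
        return p0 + d

    features_b = []
    for f in genome.features:
        if f.locus_tag in deleted_cds:
            continue
        s, e = f.slice0()
        features_b.append(Feature(type=f.type, locus_tag=f.locus_tag,
                                  start=shift(s) + 1, end=shift(e - 1) + 1,
                                  strand=f.strand))
    record_b = GenomeRecord(id=id or f"{genome.id}_sibling",
                            sequence="".join(seq_b), features=features_b)
    return record_b, truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    start: int  # 0-based source position (for verification only)


def simulate_reads(
    sequence: str,
    coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Read]:
    """Uniformly positioned fixed-length reads at the requested fold coverage."""
    if read_length > len(sequence):
        raise ValueError("read_length exceeds sequence length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * len(sequence) / read_length))
    if n_reads == 0:
        warnings.warn("requested coverage yields zero reads", stacklevel=2)
        return []
    starts = rng.integers(0, len(sequence) - read_length + 1, size=n_reads)
    reads = []
    for i, s in enumerate(starts):
        s = int(s)
        bases = list(sequence[s:s + read_length])
        if error_rate > 0:
            n_err = rng.binomial(read_length, error_rate)
            for p in rng.choice(read_length, size=n_err, replace=False):
                alts = [b for b in "ACGT" if b != bases[p]]
                bases[p] = alts[int(rng.integers(3))]
        reads.append(Read(id=f"read_{i}", sequence="".join(bases), start=s))
    return reads


def write_fastq(reads: list[Read], path: str | Path, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        reads.append(Read(id=lines[i][1:].split()[0], sequence=lines[i + 1], start=-1))
    return reads


def write_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    """Truth table as TSV (1-based positions in reports)."""
    with open(path, "w") as fh:
        fh.write("type\tpos\tref\talt\tclass\tin_homopolymer\tlocus\n")
        for s in truth.substitutions:
            fh.write(f"snp\t{s.pos_a + 1}\t{s.ref}\t{s.alt}\t{s.klass}\t"
                     f"{int(s.in_homopolymer)}\t{s.locus_tag or '.'}\n")
        for ev in truth.indels:
            fh.write(f"{ev.kind}\t{ev.pos_a + 1}\t{ev.sequence}\t.\tindel\t0\t.\n")
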