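"""Sequence I/O, genome statistics, CDS translation and protein masses.

Standard-format handling (FASTA, GenBank flat files) is delegated to
Biopython; this module adds the light-weight in-memory containers the rest
of the package works with and the genome-level statistics used throughout
(length, G+C mol%, CDS count, predicted protein mass).

Coordinate convention: GenBank files use 1-based inclusive coordinates;
`Feature` stores them the same way at the boundary, and every function that
slices a sequence converts to Python 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParam import ProteinAnalysis

VALID_BASES = set("ACGTN")
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: average mass of one water molecule in Da, added once per peptide chain
WATER_DA = 18.0153


class ParseError(ValueError):
    """Raised for malformed or unsupported input files."""


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated cleanly."""


@dataclass(frozen=True)
class Feature:
    """An annotated feature in 1-based inclusive genome coordinates."""

    type: str  # "CDS", "tRNA", "repeat_region", "other"
    locus_tag: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"feature {self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_tag}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def slice0(self) -> tuple[int, int]:
        """0-based half-open interval on the forward strand."""
        return self.start - 1, self.end

    def contains0(self, pos: int) -> bool:
        """True if 0-based position lies inside the feature."""
        return self.start - 1 <= pos < self.end


@dataclass
class GenomeRecord:
    """A genome: identifier, uppercase nucleotide sequence and features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(f"record {self.id}: non-IUPAC characters {sorted(bad)!r}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"feature {f.locus_tag} extends past sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.type == "CDS"]

    def feature_sequence(self, feature: Feature) -> str:
        """Feature sequence in coding orientation (minus strand reverse-complemented)."""
        s, e = feature.slice0()
        seq = self.sequence[s:e]
        if feature.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA / GenBank
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read all records from a FASTA file, in file order."""
    records = [
        GenomeRecord(id=r.id, sequence=str(r.seq))
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord] | GenomeRecord, path: str | Path) -> None:
    if isinstance(records, GenomeRecord):
        records = [records]
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "repeat_region": "repeat_region"}


def read_genbank_features(path: str | Path) -> GenomeRecord:
    """Read a GenBank flat file into a GenomeRecord with typed features.

    ``complement()`` locations become strand "-". ``join()`` (compound)
    locations are not supported and raise :class:`ParseError`.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(rec.seq) == 0:
        raise ParseError(f"{path}: record has no ORIGIN sequence")
    features: list[Feature] = []
    for f in rec.features:
        if f.type == "source":
            continue
        if isinstance(f.location, CompoundLocation):
            raise ParseError(
                f"{path}: join() locations are not supported "
                f"(feature at {f.location})"
            )
        ftype = _FEATURE_TYPES.get(f.type, "other")
        tag = f.qualifiers.get("locus_tag", [f"{ftype}_{int(f.location.start)+1}"])[0]
        features.append(
            Feature(
                type=ftype,
                locus_tag=tag,
                start=int(f.location.start) + 1,
                end=int(f.location.end),
                strand="-" if f.location.strand == -1 else "+",
            )
        )
    return GenomeRecord(id=rec.id, sequence=str(rec.seq), features=features)


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a minimal GenBank flat file (sequence + CDS/tRNA features)."""
    from Bio.SeqFeature import SeqFeature, SimpleLocation

    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="", annotations={"molecule_type": "DNA"})
    for f in record.features:
        loc = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        rec.features.append(
            SeqFeature(loc, type=f.type, qualifiers={"locus_tag": [f.locus_tag]})
        )
    SeqIO.write(rec, str(path), "genbank")


# ---------------------------------------------------------------------------
# Statistics, translation, mass
# ---------------------------------------------------------------------------

def genome_stats(record: GenomeRecord) -> dict:
    """Length, G+C mol% (1 decimal, N excluded from the denominator), CDS count."""
    seq = record.sequence
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return {
        "length": len(seq),
        "gc_percent": round(100.0 * gc / acgt, 1),
        "n_cds": len(record.cds),
    }


def translate_cds(record: GenomeRecord, feature: Feature, table: int = 11) -> str:
    """Translate a CDS feature with the bacterial/phage code (table 11).

    Minus-strand features are reverse-complemented first. Alternative start
    codons (GTG, TTG) are rendered as M. A single trailing stop is removed;
    an internal stop raises :class:`TranslationError`.
    """
    nt = record.feature_sequence(feature)
    if len(nt) % 3 != 0:
        raise TranslationError(
            f"CDS {feature.locus_tag}: length {len(nt)} not divisible by 3"
        )
    prot = str(Seq(nt).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise TranslationError(
            f"CDS {feature.locus_tag}: internal stop codon at aa {prot.index('*') + 1}"
        )
    # table-11 alternative initiators read as M
    if prot and nt[:3] in ("GTG", "TTG", "ATG"):
        prot = "M" + prot[1:]
    return prot


def protein_mass(protein: str, kda: bool = True) -> float:
    """Average molecular mass of a protein from its sequence.

    Uses average (not monoisotopic) residue masses plus one water, the
    convention of standard protein-stats tools. Returns kDa by default.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    bad = set(protein) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)!r}")
    mass_da = ProteinAnalysis(protein).molecular_weight()
    return mass_da / 1000.0 if kda else mass_da


def proteome_of(record: GenomeRecord, table: int = 11) -> list[tuple[str, str]]:
    """(locus_tag, protein) for every translatable CDS of a genome."""
    out = []
    for f in record.cds:
        try:
            out.append((f.locus_tag, translate_cds(record, f, table=table)))
        except TranslationError:
            continue
    return out
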