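"""In-silico restriction digestion and genome-topology inference.

The physical structure of a phage chromosome can be read off a restriction
gel: a fixed linear molecule cut at n sites gives n + 1 fragments, whereas
a circle — or a population of circularly permuted linear molecules — gives
n stoichiometric fragments. Cohesive (cos) ends betray themselves when
heating a digest separates the annealed terminal junction fragment into
its two halves. This module provides the digestion arithmetic and the
interpretation logic for both diagnostics.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_revcomp(site: str) -> str:
    return site.translate(_IUPAC_COMP)[::-1]


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str  # IUPAC recognition sequence
    cut_offset: int = 0  # bp from site start, top strand

    def __post_init__(self) -> None:
        bad = set(self.site) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC character(s) {sorted(bad)!r}")
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: site must be >= 4 bp")
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside site")

    @property
    def palindromic(self) -> bool:
        return _iupac_revcomp(self.site) == self.site

    def pattern(self) -> re.Pattern:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in self.site))


#: enzymes used in the study's digestion experiments, runnable out of the box
ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in [
        Enzyme("SalI", "GTCGAC", 1),
        Enzyme("ClaI", "ATCGAT", 2),
        Enzyme("NruI", "TCGCGA", 3),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("HindIII", "AAGCTT", 1),
        Enzyme("XhoI", "CTCGAG", 1),
        Enzyme("NheI", "GCTAGC", 1),
        Enzyme("PauI", "GCGCGC", 1),
        Enzyme("XmnI", "GAANNNNTTC", 5),
        Enzyme("HpaII", "CCGG", 1),
        Enzyme("Van91I", "CCANNNNNTGG", 7),
        Enzyme("OliI", "CACNNNNGTG", 5),
    ]
}


@dataclass
class DigestResult:
    enzyme: str
    topology: str  # "linear" | "circular"
    fragments: list[int]  # bp, descending

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def total(self) -> int:
        return sum(self.fragments)


@dataclass
class TopologyCall:
    verdict: str  # linear_fixed | circular_or_permuted | ambiguous
    evidence: list[dict] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)


def find_sites(sequence: str, enzyme: Enzyme) -> list[int]:
    """0-based start positions of recognition sites on the top strand.

    Palindromic sites are counted once; for non-palindromic sites the
    reverse-complement pattern is searched on the top strand as well.
    Site positions overlapping an N in the sequence never match.
    """
    sequence = sequence.upper()
    pats = [enzyme.pattern()]
    if not enzyme.palindromic:
        rc = _iupac_revcomp(enzyme.site)
        pats.append(re.compile("".join(f"[{IUPAC[c]}]" for c in rc)))
    hits: set[int] = set()
    for pat in pats:
        pos = 0
        while True:
            m = pat.search(sequence, pos)
            if m is None:
                break
            hits.add(m.start())
            pos = m.start() + 1  # overlapping matches
    return sorted(hits)


def digest(sequence: str, enzyme: Enzyme, topology: str = "linear") -> DigestResult:
    """Fragment lengths from a complete digest under the assumed topology.

    Linear: n sites -> n + 1 fragments, split at site start + cut offset.
    Circular: n >= 1 sites -> n fragments (the wrap-around fragment joined);
    an uncut circle is reported as one full-length fragment.
    """
    if topology not in ("linear", "circular"):
        raise ValueError("topology must be 'linear' or 'circular'")
    n = len(sequence)
    cuts = sorted({min(p + enzyme.cut_offset, n) for p in find_sites(sequence, enzyme)})
    if topology == "linear":
        bounds = [0] + cuts + [n]
        fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    else:
        if not cuts:
            fragments = [n]
        else:
            fragments = [b - a for a, b in zip(cuts, cuts[1:])]
            fragments.append(n - cuts[-1] + cuts[0])  # wrap-around
            fragments = [f for f in fragments if f > 0]
    fragments.sort(reverse=True)
    return DigestResult(enzyme=enzyme.name, topology=topology, fragments=fragments)


def double_digest(sequence: str, enzyme_a: Enzyme, enzyme_b: Enzyme,
                  topology: str = "linear") -> DigestResult:
    """Complete digestion with two enzymes simultaneously."""
    n = len(sequence)
    cuts = sorted(
        {min(p + e.cut_offset, n) for e in (enzyme_a, enzyme_b)
         for p in find_sites(sequence, e)}
    )
    name = f"{enzyme_a.name}+{enzyme_b.name}"
    if topology == "linear":
        bounds = [0] + cuts + [n]
        fragments = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
    else:
        if not cuts:
            fragments = [n]
        else:
            fragments = [b - a for a, b in zip(cuts, cuts[1:])]
            fragments.append(n - cuts[-1] + cuts[0])
            fragments = [f for f in fragments if f > 0]
    fragments.sort(reverse=True)
    return DigestResult(enzyme=name, topology=topology, fragments=fragments)


def infer_topology(evidence: list[tuple[int, int]]) -> TopologyCall:
    """Interpret (n_sites, n_observed_fragments) rows from digestion gels.

    A fixed linear genome shows n + 1 fragments for every enzyme with n
    sites; a circle or circularly permuted population shows max(n, 1).
    Mixed evidence is reported as ambiguous with the conflicting rows.
    """
    rows = []
    informative = False
    n_linear = n_circular = 0
    for n_sites, n_obs in evidence:
        if n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        row = {
            "n_sites": n_sites,
            "expected_linear": n_sites + 1,
            "expected_circular": max(n_sites, 1),
            "observed": n_obs,
        }
        rows.append(row)
        if n_sites >= 1:
            informative = True
            if n_obs == n_sites + 1:
                n_linear += 1
            elif n_obs == max(n_sites, 1):
                n_circular += 1
    if not informative:
        raise ValueError("uninformative digest set: no enzyme with >= 1 site")
    informative_rows = [r for r in rows if r["n_sites"] >= 1]
    if n_linear == len(informative_rows):
        verdict = "linear_fixed"
        conflicts = []
    elif n_circular == len(informative_rows):
        verdict = "circular_or_permuted"
        conflicts = []
    else:
        verdict = "ambiguous"
        majority_linear = n_linear >= n_circular
        conflicts = [r for r in informative_rows
                     if (r["observed"] == r["expected_linear"]) != majority_linear]
    return TopologyCall(verdict=verdict, evidence=rows, conflicts=conflicts)


def cos_test(
    unheated: list[int],
    heated: list[int],
    tolerance: float = 0.02,
) -> dict:
    """Diagnose cohesive ends from a heated vs unheated digest pair.

    Heating melts the annealed cos junction: exactly one unheated fragment
    disappears and is replaced by two fragments summing to it. Identical
    patterns (within the gel-resolution tolerance) mean no cos ends; any
    other difference is uninterpretable.
    """
    if not unheated or not heated:
        raise ValueError("both fragment patterns must be non-empty")

    def close(a: int, b: int) -> bool:
        return abs(a - b) <= tolerance * max(a, b)

    un = sorted(unheated, reverse=True)
    he = sorted(heated, reverse=True)
    un_left, he_left = list(un), list(he)
    for f in un:
        for g in he_left:
            if close(f, g):
                un_left.remove(f)
                he_left.remove(g)
                break
    if not un_left and not he_left:
        return {"cos_present": False, "split_fragment": None}
    if len(un_left) == 1 and len(he_left) == 2:
        parent, (c1, c2) = un_left[0], he_left
        if close(parent, c1 + c2):
            return {"cos_present": True, "split_fragment": (parent, c1, c2)}
    raise ValueError(
        f"uninterpretable pattern: unmatched unheated {un_left}, heated {he_left}"
    )


def fragment_counter(result: DigestResult) -> Counter:
    return Counter(result.fragments)
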