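"""Proteome-level comparison and distance-based phylogenetics.

Relatedness between phage genomes is summarized at the protein level:
every protein of one genome is locally aligned (Smith-Waterman, BLOSUM62,
affine gaps, Karlin-Altschul E-values) against the proteins of another.
Two summary statistics follow: API, the average percent identity of best
hits passing the display cutoffs (E <= 1e-5, identity >= 35%), and the
mean BLAST score ratio (BSR) — each protein's best cross-genome score
divided by its self-score — whose complement (1 - mean BSR) serves as a
proteome distance. Neighbor joining turns the distance matrix into a
dendrogram; bootstrap resampling (alignment columns, or proteins for BSR
trees) attaches support values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

# gapped BLOSUM62 statistics for gap open 11 / extend 1
LAMBDA = 0.267
K_PARAM = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinSet:
    """A genome's proteome: (locus_tag, sequence) pairs with unique tags."""

    genome_id: str
    proteins: list[tuple[str, str]]

    def __post_init__(self) -> None:
        tags = [t for t, _ in self.proteins]
        if len(set(tags)) != len(tags):
            raise ValueError(f"{self.genome_id}: duplicate locus tags")
        for tag, seq in self.proteins:
            if not seq:
                raise ValueError(f"{self.genome_id}/{tag}: empty sequence")
            bad = set(seq) - set(_AA)
            if bad:
                raise ValueError(f"{self.genome_id}/{tag}: non-standard {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    score: float  # raw Smith-Waterman score
    bits: float
    identity: float  # % over aligned residue pairs (gaps excluded)
    e_value: float
    aligned_columns: int


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _local_aligner()


def sw_score(p: str, q: str) -> float:
    """Raw local-alignment score (BLOSUM62, gap open 11 / extend 1)."""
    return float(_ALIGNER.score(p, q))


def align_proteins(p: str, q: str, query: str = "query",
                   subject: str = "subject") -> Hit:
    """Best local alignment of two proteins with BLAST-style statistics.

    E = K * m * n * exp(-lambda * S) with the standard gapped BLOSUM62
    constants; bits = (lambda * S - ln K) / ln 2.
    """
    if not p or not q:
        raise ValueError("empty protein sequence")
    aln = _ALIGNER.align(p, q)[0]
    score = float(aln.score)
    seg_p, seg_q = aln.aligned
    matches = columns = 0
    for (sp, ep), (sq, _) in zip(seg_p, seg_q):
        for off in range(ep - sp):
            columns += 1
            if p[sp + off] == q[sq + off]:
                matches += 1
    identity = 100.0 * matches / columns if columns else 0.0
    bits = (LAMBDA * score - math.log(K_PARAM)) / math.log(2)
    e_value = K_PARAM * len(p) * len(q) * math.exp(-LAMBDA * score)
    return Hit(query=query, subject=subject, score=score, bits=bits,
               identity=identity, e_value=e_value, aligned_columns=columns)


def best_hits(a: ProteinSet, b: ProteinSet, max_e: float = 1e-5,
              min_id: float = 35.0) -> list[Hit]:
    """For each protein of A, its best-scoring hit in B passing both cutoffs.

    The best hit is selected by raw score; the cutoffs then decide whether
    it is reported (the display convention of comparative genome maps).
    """
    if not a.proteins or not b.proteins:
        raise ValueError("both protein sets must be non-empty")
    hits = []
    for tag_a, p in a.proteins:
        best_score, best_tag, best_q = -1.0, None, None
        for tag_b, q in b.proteins:
            s = sw_score(p, q)
            if s > best_score:
                best_score, best_tag, best_q = s, tag_b, q
        hit = align_proteins(p, best_q, query=tag_a, subject=best_tag)
        if hit.e_value <= max_e and hit.identity >= min_id:
            hits.append(hit)
    return hits


def api(a: ProteinSet, b: ProteinSet, max_e: float = 1e-5,
        min_id: float = 35.0, reciprocal: bool = False) -> float:
    """Average percent identity of best hits passing the cutoffs.

    Unidirectional (query A -> reference B) by default; ``reciprocal``
    averages both directions.
    """
    hits = best_hits(a, b, max_e=max_e, min_id=min_id)
    if reciprocal:
        hits = hits + best_hits(b, a, max_e=max_e, min_id=min_id)
    if not hits:
        raise ValueError("API undefined: no hit passes the cutoffs")
    return float(np.mean([h.identity for h in hits]))


def _bsr_one_direction(a: ProteinSet, b: ProteinSet, max_e: float) -> float:
    ratios = []
    for tag_a, p in a.proteins:
        self_score = sw_score(p, p)
        best = 0.0
        for _, q in b.proteins:
            best = max(best, sw_score(p, q))
        e = K_PARAM * len(p) * len(p) * math.exp(-LAMBDA * best)
        ratios.append(best / self_score if best > 0 and e <= max_e else 0.0)
    return float(np.mean(ratios))


def mean_bsr(a: ProteinSet, b: ProteinSet, max_e: float = 1e-5) -> float:
    """Mean BLAST score ratio, symmetrized over both proteomes.

    Per protein: best cross-genome score / self score, 0 when no hit
    passes the E-value cutoff. The means over A's and B's proteins are
    averaged, giving a value in [0, 1].
    """
    return 0.5 * (_bsr_one_direction(a, b, max_e) + _bsr_one_direction(b, a, max_e))


def bsr_distance_matrix(sets: Sequence[ProteinSet],
                        max_e: float = 1e-5) -> tuple[list[str], np.ndarray]:
    """Symmetric distance matrix D = 1 - mean BSR over all genome pairs."""
    n = len(sets)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - mean_bsr(sets[i], sets[j], max_e=max_e)
            dist[i, j] = dist[j, i] = max(0.0, d)
    return [s.genome_id for s in sets], dist


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(names: Sequence[str], dist: np.ndarray) -> TreeNode:
    """Canonical neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lowest (i, j) index pair.
    Negative branch-length estimates are clamped to zero (with a warning).
    The returned tree is unrooted, represented with a trifurcating root
    (the final three lineages joined at a star center), so tip-to-tip
    path lengths reproduce an additive input matrix exactly.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if dist.shape != (n, n):
        raise ValueError("matrix shape does not match taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.diag(dist).any():
        raise ValueError("distance matrix must have zero diagonal")
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")

    nodes: list[TreeNode] = [TreeNode(name=str(nm)) for nm in names]
    D = dist.copy()
    active = list(range(n))
    clamped = False

    def join(i_loc: int, j_loc: int) -> None:
        nonlocal D, active, clamped
        m = len(active)
        r = D.sum(axis=0)
        dij = D[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[active[i_loc]], nodes[active[j_loc]]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        # distances from the new node to the others
        du = 0.5 * (D[i_loc, :] + D[j_loc, :] - dij)
        keep = [x for x in range(m) if x not in (i_loc, j_loc)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = newD[:-1, -1] = du[keep]
        D = newD
        nodes.append(parent)
        active = [active[x] for x in keep] + [len(nodes) - 1]

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=0)
        best, bi, bj = math.inf, -1, -1
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best - 1e-12:
                    best, bi, bj = q, i, j
        join(bi, bj)

    # star-join the final three lineages
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    if any(x < 0 for x in lens):
        clamped = True
        lens = [max(x, 0.0) for x in lens]
    root = TreeNode()
    for loc, ln in zip(active, lens):
        nodes[loc].length = float(ln)
        root.append(nodes[loc])
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as canonical tip sets."""
    tips = frozenset(t.name for t in tree.tips())
    first = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(tips) - 2:
            if first in side:
                side = tips - side
            parts.add(side)
    return parts


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_supports(
    names: Sequence[str],
    n_units: int,
    matrix_fn: Callable[[np.ndarray], np.ndarray],
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """Bootstrap a distance tree by resampling its underlying units.

    ``matrix_fn(indices)`` must return the distance matrix computed from
    the resampled units (alignment columns, or proteins in BSR mode).
    Support = fraction of replicate trees containing each internal
    bipartition of the tree built from the full data; supports (as
    percentages) are written onto the internal node names.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    full = nj_tree(names, matrix_fn(np.arange(n_units)))
    if len(names) < 4:
        warnings.warn("fewer than 4 taxa: no internal bipartitions to support",
                      stacklevel=2)
        return full, {}
    target = tree_bipartitions(full)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_units, size=n_units)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = nj_tree(names, matrix_fn(idx))
        rep_parts = tree_bipartitions(rep)
        for bp in target:
            if bp in rep_parts:
                counts[bp] += 1
    supports = {bp: c / n_replicates for bp, c in counts.items()}
    tips = frozenset(names)
    first = min(tips)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(tips) - 2:
            canon = tips - side if first in side else side
            node.name = str(int(round(100 * supports[canon])))
    return full, supports


def msa_p_distance(msa: list[tuple[str, str]],
                   indices: np.ndarray | None = None) -> np.ndarray:
    """p-distance matrix from an MSA, ignoring columns with a gap in a pair."""
    seqs = [s for _, s in msa]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("MSA rows must have equal length")
    cols = np.array([list(s) for s in seqs])
    if indices is not None:
        cols = cols[:, np.asarray(indices)]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (cols[i] != "-") & (cols[j] != "-")
            tot = int(ok.sum())
            diff = int(((cols[i] != cols[j]) & ok).sum())
            D[i, j] = D[j, i] = diff / tot if tot else 1.0
    return D


def bootstrap_msa_tree(msa: list[tuple[str, str]], n_replicates: int = 1000,
                       seed: int = 0) -> tuple[TreeNode, dict]:
    """NJ tree from an MSA with column-resampling bootstrap supports."""
    names = [n for n, _ in msa]
    L = len(msa[0][1])
    return bootstrap_supports(
        names, L, lambda idx: msa_p_distance(msa, idx),
        n_replicates=n_replicates, seed=seed)


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

_GAP_OPEN = -10.0
_GAP_EXTEND = -1.0


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _profile(rows: list[str]) -> np.ndarray:
    """Columns x 20 residue-frequency profile (gaps contribute nothing)."""
    L = len(rows[0])
    prof = np.zeros((L, len(_AA)))
    idx = {c: i for i, c in enumerate(_AA)}
    for row in rows:
        for j, c in enumerate(row):
            if c != "-":
                prof[j, idx[c]] += 1
    return prof / len(rows)


_B62 = np.zeros((len(_AA), len(_AA)))
for _i, _x in enumerate(_AA):
    for _j, _y in enumerate(_AA):
        _B62[_i, _j] = _BLOSUM62[_x][_y]


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> list[str]:
    """Global profile-profile alignment (affine gaps, mean BLOSUM62 score)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ _B62 @ pb.T  # column-pair scores
    la, lb = S.shape
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (A column unmatched)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = _GAP_OPEN + (i - 1) * _GAP_EXTEND
    for j in range(1, lb + 1):
        Y[0, j] = _GAP_OPEN + (j - 1) * _GAP_EXTEND
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) \
                + S[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] + _GAP_OPEN, X[i - 1, j] + _GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + _GAP_OPEN, Y[i, j - 1] + _GAP_EXTEND)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    cols: list[tuple[int, int]] = []  # (-1 = gap)
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i - 1, j - 1))
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            cols.append((i - 1, -1))
            if not math.isclose(X[i, j], X[i - 1, j] + _GAP_EXTEND,
                                rel_tol=0, abs_tol=1e-9):
                state = 0
            i -= 1
        else:
            cols.append((-1, j - 1))
            if not math.isclose(Y[i, j], Y[i, j - 1] + _GAP_EXTEND,
                                rel_tol=0, abs_tol=1e-9):
                state = 0
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    cols.reverse()
    out_a = ["".join(r[ca] if ca >= 0 else "-" for ca, _ in cols) for r in rows_a]
    out_b = ["".join(r[cb] if cb >= 0 else "-" for _, cb in cols) for r in rows_b]
    return out_a + out_b


def msa_progressive(proteins: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Guide-tree progressive multiple alignment.

    The guide tree is NJ on pairwise k-mer distances; profiles are merged
    by global profile-profile alignment under mean BLOSUM62 scores with
    affine gaps. Returns rows in input order.
    """
    if len(proteins) < 2:
        raise ValueError("need >= 2 sequences")
    names = [n for n, _ in proteins]
    seqs = {n: s for n, s in proteins}
    if len(proteins) == 2:
        rows = _align_profiles([proteins[0][1]], [proteins[1][1]])
        aligned = dict(zip(names, rows))
        return [(n, aligned[n]) for n in names]
    n = len(proteins)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(proteins[i][1], proteins[j][1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        guide = nj_tree(names, D)

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_tip():
            return [node.name], [seqs[node.name]]
        child_results = [merge(c) for c in node.children]
        nm, rows = child_results[0]
        for nm2, rows2 in child_results[1:]:
            rows = _align_profiles(rows, rows2)
            nm = nm + nm2
        return nm, rows

    order, rows = merge(guide)
    aligned = dict(zip(order, rows))
    return [(nm, aligned[nm]) for nm in names]


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
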