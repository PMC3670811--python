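"""Direct-terminal-repeat detection from read-depth doubling.

A linear phage genome with a direct terminal repeat (DTR) is assembled in
its non-redundant form, with the repeat present once. Reads sequenced from
the physical, terminally redundant molecule then pile up two-fold over the
repeat region: every repeat-derived read has two equally good placements
and is counted at both. `map_reads` reproduces this deliberately (multi-
mapped reads are counted at every best position); `detect_dtr` turns the
resulting step in coverage into a repeat call.

The redundant genome length is simply non-redundant length + repeat
length, exposed as `redundant_length` because it is the headline number a
termini analysis reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthgen import Read


@dataclass
class DepthProfile:
    """Per-base read depth over a reference."""

    reference_id: str
    depth: np.ndarray  # one non-negative int per reference position

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("depth values must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class DtrCall:
    """A detected terminal repeat: interval, length, and depth fold-change."""

    start: int  # 0-based half-open on the reference
    end: int
    fold: float  # repeat median depth / interior median depth
    terminus: str  # "5'" or "3'"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TerminalMotif:
    end: str  # "5'" or "3'"
    unit: str
    motif: str  # unit + f(unit); always 2x unit length
    arrangement: str  # direct | reverse | reverse_complement
    position: int  # 0-based start of the motif on the sequence


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def map_reads(
    reads: list[Read],
    reference: str,
    k: int = 31,
    min_identity: float = 0.9,
    reference_id: str = "ref",
) -> DepthProfile:
    """Place each read by k-mer seeding and count depth at every best position.

    Seeds are taken at offsets 0, k, 2k, ... so a read with scattered errors
    still finds its origin. A read is placed wherever its match fraction is
    maximal and >= min_identity; ambiguous reads (e.g. from a terminal
    repeat) contribute depth at all of their best positions — the signal
    DTR detection relies on.
    """
    if reads and k > min(len(r.sequence) for r in reads):
        raise ValueError("seed length k exceeds read length")
    index: dict[str, list[int]] = {}
    for i in range(len(reference) - k + 1):
        index.setdefault(reference[i:i + k], []).append(i)
    depth = np.zeros(len(reference), dtype=np.int64)
    ref = reference
    n_ref = len(ref)
    for read in reads:
        seq = read.sequence
        L = len(seq)
        candidates: set[int] = set()
        for off in range(0, L - k + 1, k):
            for p in index.get(seq[off:off + k], ()):
                start = p - off
                if 0 <= start <= n_ref - L:
                    candidates.add(start)
        if not candidates:
            continue
        best, best_pos = -1, []
        for start in candidates:
            window = ref[start:start + L]
            m = L if window == seq else sum(a == b for a, b in zip(seq, window))
            if m > best:
                best, best_pos = m, [start]
            elif m == best:
                best_pos.append(start)
        if best >= min_identity * L:
            for start in best_pos:
                depth[start:start + L] += 1
    return DepthProfile(reference_id=reference_id, depth=depth)


# ---------------------------------------------------------------------------
# DTR detection
# ---------------------------------------------------------------------------

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad:pad + len(x)]


def _step_refine(depth: np.ndarray, guess: int, radius: int) -> int:
    """Matched-filter changepoint: maximize |mean right - mean left| near guess.

    Exact on a clean step (the contrast is uniquely maximal at the step)
    and well-behaved on the gradual coverage ramps real pileups show.
    """
    n = len(depth)
    h = radius
    lo = max(h, guess - radius)
    hi = min(n - h, guess + radius + 1)
    if hi <= lo:
        return guess
    c = np.concatenate([[0], np.cumsum(depth, dtype=float)])
    b = np.arange(lo, hi)
    contrast = np.abs((c[b + h] - c[b]) - (c[b] - c[b - h])) / h
    return int(lo + np.argmax(contrast))


def _walk_to_baseline(depth: np.ndarray, start: int, interior: float,
                      direction: int, window: int = 150,
                      max_steps: int = 1000) -> int:
    """Walk from start toward the genome interior side of a boundary until the
    mean depth just outside returns to the interior baseline.

    Removes the half-ramp bias a matched filter has on gradual coverage
    ramps; on a clean step the first window already sits at baseline, so the
    position is left untouched.
    """
    c = np.concatenate([[0], np.cumsum(depth, dtype=float)])
    n = len(depth)
    pos = start
    for _ in range(max_steps):
        if direction < 0:
            lo, hi = max(0, pos - window), pos
        else:
            lo, hi = pos, min(n, pos + window)
        if hi <= lo:
            break
        if (c[hi] - c[lo]) / (hi - lo) <= 1.1 * interior:
            break
        pos += direction
        if pos <= 0 or pos >= n:
            break
    return pos


def detect_dtr(
    profile: DepthProfile,
    min_length: int = 100,
    fold_min: float = 1.75,
    refine_radius: int | None = None,
    smooth_window: int = 201,
) -> DtrCall | None:
    """Call a terminal repeat from a doubled-depth terminal run.

    The interior median is taken over the central 50% of positions.
    fold_min sets the detection threshold: a repeat is called at a terminus
    where the smoothed depth reaches fold_min x interior within the outer
    quarter of the genome. The end-of-contig coverage ramp (about one read
    length wide, where depth has not yet built up) is skipped when locating
    the elevated region; the inner boundary is then placed where the
    standardized excess coverage of the terminal region over the interior
    baseline is maximal — a changepoint statistic that is exact on a clean
    step and integrates over local coverage dips — and nudged back to the
    interior baseline to undo the half-ramp bias of gradual boundaries.
    The reported fold is the measured median of the run's established core
    over the interior median: a noisy estimate of the true copy ratio at
    moderate coverage, reported rather than re-thresholded. Runs shorter
    than min_length or longer than half the genome return None.
    """
    depth = profile.depth
    n = len(depth)
    if n < 10 * min_length:
        raise ValueError(f"profile length {n} < 10 x min_length")
    if not depth.any():
        raise ValueError("no coverage")
    interior = float(np.median(depth[n // 4: n - n // 4]))
    if interior == 0:
        raise ValueError("no interior coverage")
    threshold = fold_min * interior
    w = min(smooth_window, max(1, n // 50))
    sm = _smooth(depth, w)
    skip_limit = n // 4  # the detection seed must sit near a terminus
    limit = n // 2  # a terminal repeat cannot exceed half the genome
    c = np.concatenate([[0], np.cumsum(depth, dtype=float)])

    candidates: list[tuple[str, int, int, int]] = []  # (terminus, s, e, inner0)
    # 3' end: skip the outer ramp to the first threshold crossing, then put
    # the boundary at the maximum of the standardized excess statistic
    # S(b) = (sum depth[b:j] - interior*(j-b)) / sqrt(j-b)
    j = n
    while j > n - skip_limit and sm[j - 1] < threshold:
        j -= 1
    if j > n - skip_limit:
        b = np.arange(n - limit, j)
        span = j - b
        score = (c[j] - c[b] - interior * span) / np.sqrt(span)
        s = int(b[np.argmax(score)])
        candidates.append(("3'", s, n, j))
    # 5' end, mirrored
    i = 0
    while i < skip_limit and sm[i] < threshold:
        i += 1
    if i < skip_limit:
        b = np.arange(i + 1, limit + 1)
        span = b - i
        score = (c[b] - c[i] - interior * span) / np.sqrt(span)
        e = int(b[np.argmax(score)])
        candidates.append(("5'", 0, e, i))

    best = None
    for terminus, s, e, inner0 in candidates:
        if best is None or e - s > best[2] - best[1]:
            best = (terminus, s, e, inner0)
    if best is None:
        return None
    terminus, s, e, inner0 = best

    # the outer coverage ramp width estimates the boundary blur (about one
    # read length); it bounds the baseline walk and trims the fold estimate
    ramp = (n - inner0) if terminus == "3'" else inner0
    cap = max(ramp // 2, w // 2)
    if terminus == "3'":
        s = _walk_to_baseline(depth, s, interior, direction=-1, max_steps=cap)
        core_lo, core_hi = min(s + cap, n), inner0
        core = depth[core_lo:core_hi] if core_hi > core_lo else depth[s:e]
    else:
        e = _walk_to_baseline(depth, e, interior, direction=+1, max_steps=cap)
        core_lo, core_hi = inner0, max(e - cap, 0)
        core = depth[core_lo:core_hi] if core_hi > core_lo else depth[s:e]
    if e - s < min_length or e - s >= n // 2 or len(core) == 0:
        return None
    fold = float(np.median(core)) / interior
    if fold <= 1.0:
        return None
    return DtrCall(start=s, end=e, fold=fold, terminus=terminus)


def redundant_length(non_redundant_length: int, dtr_length: int) -> int:
    """Terminally redundant genome length = non-redundant length + repeat length."""
    if non_redundant_length <= 0:
        raise ValueError("non_redundant_length must be positive")
    if dtr_length < 0:
        raise ValueError("dtr_length must be non-negative")
    return non_redundant_length + dtr_length


# ---------------------------------------------------------------------------
# Terminal motifs
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


_ARRANGEMENTS = {
    "direct": lambda u: u,
    "reverse": lambda u: u[::-1],
    "reverse_complement": _revcomp,
}


def find_terminal_motif(
    sequence: str,
    min_unit: int = 4,
    window: int = 50,
) -> list[TerminalMotif]:
    """Longest u + f(u) motif within each terminal window, per arrangement.

    f is the identity (a tandem direct repeat), string reversal (the
    palindrome-style GATAGG|GGATAG arrangement seen at N4-like termini),
    or reverse complement (an inverted repeat proper). Homopolymeric units
    are excluded. Returns one motif per (end, arrangement) at most, longest
    unit first.
    """
    if window > len(sequence):
        raise ValueError("window exceeds sequence length")
    out: list[TerminalMotif] = []
    for end_label, region, offset in (
        ("5'", sequence[:window], 0),
        ("3'", sequence[-window:], len(sequence) - window),
    ):
        for name, f in _ARRANGEMENTS.items():
            best: TerminalMotif | None = None
            for ulen in range(min_unit, window // 2 + 1):
                for i in range(0, window - 2 * ulen + 1):
                    u = region[i:i + ulen]
                    if len(set(u)) == 1:
                        continue
                    if region[i + ulen:i + 2 * ulen] == f(u):
                        cand = TerminalMotif(
                            end=end_label, unit=u, motif=region[i:i + 2 * ulen],
                            arrangement=name, position=offset + i)
                        if best is None or len(cand.unit) > len(best.unit):
                            best = cand
            if best is not None:
                out.append(best)
    out.sort(key=lambda m: -len(m.unit))
    return out


# ---------------------------------------------------------------------------
# Depth I/O
# ---------------------------------------------------------------------------

def read_depth_tsv(path: str | Path, reference_id: str = "ref") -> DepthProfile:
    """2-column TSV (1-based position, depth) -> DepthProfile."""
    pos, dep = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            pos.append(int(a))
            dep.append(int(b))
    if not pos:
        raise ValueError(f"{path}: empty depth file")
    depth = np.zeros(max(pos), dtype=np.int64)
    depth[np.asarray(pos) - 1] = dep
    return DepthProfile(reference_id=reference_id, depth=depth)


def write_dtr_bed(call: DtrCall, reference_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{reference_id}\t{call.start}\t{call.end}\t"
                 f"DTR_{call.terminus}\t{call.fold:.2f}\n")
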