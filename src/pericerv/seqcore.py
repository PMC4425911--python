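"""Core sequence-comparison primitives.

Pairwise global alignment, percent identity, highlighter-style difference
tracks, Kimura-2-parameter distances and tandem-segment decomposition, plus
thin FASTA/FASTQ helpers.  These primitives underlie every other stage of the
pipeline: the in-silico PCR mapping, the recombination scan and the distance
phylogenetics all reduce to the operations defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq

DNA = frozenset("ACGTN")
GAP = "-"

# Scoring used whenever an alignment has to be inferred.  A gap of length L
# costs open + extend*L.  Fixed here (and surfaced in config) because the
# comparisons in this pipeline need to be bit-reproducible.
DEFAULT_SCORING = {"match": 2, "mismatch": -3, "gap_open": -5, "gap_extend": -2}

_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """Distance formula log-domain violated (sequences too diverged)."""


def revcomp(seq: str) -> str:
    """Reverse complement (gap and N aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PairwiseAlignment:
    """A gapped pair of sequences on a common coordinate frame."""

    seq_a: str
    seq_b: str
    score: float = 0.0
    scoring: dict = field(default_factory=lambda: dict(DEFAULT_SCORING))

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped sequences must have equal length")

    def degap(self) -> tuple[str, str]:
        return self.seq_a.replace(GAP, ""), self.seq_b.replace(GAP, "")

    def columns(self) -> Iterator[tuple[str, str]]:
        return zip(self.seq_a, self.seq_b)


@dataclass
class DiffTrack:
    """Highlighter-style mismatch ticks of a query against a master sequence.

    ``ticks`` hold (master-frame position, query base) substitutions;
    ``deletions`` hold half-open master-frame spans absent from the query.
    """

    master: str
    ticks: list[tuple[int, str]]
    deletions: list[tuple[int, int]]


def _validate_seq(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    s = seq.upper()
    bad = set(s) - DNA
    if bad:
        raise ValueError(f"{name} contains non-ACGTN symbols: {sorted(bad)}")
    return s


def _aligner(scoring: dict) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring["match"]
    aligner.mismatch_score = scoring["mismatch"]
    # Biopython charges open_gap_score on the first gapped position, so a
    # length-L gap costs open + extend*L under our convention.
    aligner.open_gap_score = scoring["gap_open"] + scoring["gap_extend"]
    aligner.extend_gap_score = scoring["gap_extend"]
    return aligner


def global_align(a: str, b: str, scoring: dict | None = None) -> PairwiseAlignment:
    """Optimal global alignment of ``a`` and ``b`` under affine gap costs.

    The first optimal traceback reported by the aligner is used, which is
    deterministic for fixed inputs and scoring.
    """
    scoring = dict(DEFAULT_SCORING, **(scoring or {}))
    a = _validate_seq(a, "a")
    b = _validate_seq(b, "b")
    aligner = _aligner(scoring)
    aln = aligner.align(a, b)[0]
    ga, gb = _gapped_strings(aln, a, b)
    return PairwiseAlignment(ga, gb, score=float(aln.score), scoring=scoring)


def _gapped_strings(aln, a: str, b: str) -> tuple[str, str]:
    """Rebuild gapped strings from a Bio.Align coordinate path."""
    coords = aln.coordinates
    ga: list[str] = []
    gb: list[str] = []
    for k in range(coords.shape[1] - 1):
        i0, i1 = int(coords[0, k]), int(coords[0, k + 1])
        j0, j1 = int(coords[1, k]), int(coords[1, k + 1])
        if i1 > i0 and j1 > j0:
            ga.append(a[i0:i1])
            gb.append(b[j0:j1])
        elif i1 > i0:
            ga.append(a[i0:i1])
            gb.append(GAP * (i1 - i0))
        else:
            ga.append(GAP * (j1 - j0))
            gb.append(b[j0:j1])
    return "".join(ga), "".join(gb)


def percent_identity(
    aln: PairwiseAlignment, gap_policy: str = "exclude_gap_columns"
) -> float:
    """Fraction of identical columns, as a percentage rounded to 0.1%.

    ``exclude_gap_columns`` drops columns containing a gap from the
    denominator; ``count_gaps_as_mismatch`` keeps them as differences.
    N never counts as a match.
    """
    if gap_policy not in ("exclude_gap_columns", "count_gaps_as_mismatch"):
        raise ValueError(f"unknown gap_policy: {gap_policy}")
    matches = 0
    denom = 0
    for x, y in aln.columns():
        gap_col = GAP in (x, y)
        if gap_col and gap_policy == "exclude_gap_columns":
            continue
        denom += 1
        if not gap_col and x == y and x != "N":
            matches += 1
    if denom == 0:
        raise ZeroDivisionError("no comparable columns under this gap policy")
    return round(100.0 * matches / denom, 1)


def highlighter_diff(master: str, query: str) -> DiffTrack:
    """Differences of ``query`` relative to ``master`` in master coordinates.

    Substitutions become ticks labelled with the query base; runs of master
    positions missing from the query become deletion spans (rendered as the
    gray boxes of a highlighter plot).  Query insertions have no master-frame
    coordinate and are not reported.
    """
    aln = global_align(master, query)
    ticks: list[tuple[int, str]] = []
    deletions: list[tuple[int, int]] = []
    pos = 0  # master-frame position
    del_start: int | None = None
    for x, y in aln.columns():
        if x == GAP:
            continue  # insertion in query, no master coordinate
        if y == GAP:
            if del_start is None:
                del_start = pos
        else:
            if del_start is not None:
                deletions.append((del_start, pos))
                del_start = None
            if x != y:
                ticks.append((pos, y))
        pos += 1
    if del_start is not None:
        deletions.append((del_start, pos))
    return DiffTrack(master="master", ticks=ticks, deletions=deletions)


def k2p_distance(a: str, b: str) -> float:
    """Kimura-2-parameter distance in substitutions per site.

    d = -(1/2) ln((1 - 2p - q) sqrt(1 - 2q)) with p, q the transition and
    transversion proportions over comparable (non-gap, non-N) columns.
    """
    a = a.upper()
    b = b.upper()
    if len(a) != len(b):
        raise ValueError("k2p_distance expects equal-length (aligned) sequences")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ZeroDivisionError("no comparable columns")
    p = ts / n
    q = tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P undefined: 1-2p-q={w1:.4f}, 1-2q={w2:.4f} (saturated)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def tandem_segments(monomer: str, unit: int) -> tuple[list[str], np.ndarray]:
    """Split ``monomer`` into ``unit``-length segments and score periodicity.

    Returns the segments (last one possibly shorter) and the matrix of
    pairwise percent identities between equal-length segments, the evidence
    for (or against) a tandem higher-order structure.
    """
    if unit < 1:
        raise ValueError("unit must be >= 1")
    if unit > len(monomer):
        raise ValueError("unit exceeds monomer length")
    monomer = monomer.upper()
    segments = [monomer[i : i + unit] for i in range(0, len(monomer), unit)]
    n = len(segments)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = segments[i], segments[j]
            m = min(len(si), len(sj))
            if m == 0:
                continue
            frac = sum(si[k] == sj[k] for k in range(m)) / m
            ident[i, j] = ident[j, i] = round(100.0 * frac, 1)
    return segments, ident


# --- FASTA / FASTQ helpers -------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    """Write sequences to FASTA, wrapped at 60 columns."""
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file (Phred+33; qualities are ignored downstream)."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def difftrack_to_tsv(track: DiffTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tstart\tend\tbase\n")
        for pos, base in track.ticks:
            fh.write(f"substitution\t{pos}\t{pos + 1}\t{base}\n")
        for s, e in track.deletions:
            fh.write(f"deletion\t{s}\t{e}\t.\n")


_TICK_COLORS = {"A": "green", "T": "red", "G": "orange", "C": "deepskyblue"}


def plot_difftrack(track: DiffTrack, length: int, path) -> None:
    """Render a one-row tick plot of a difference track (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 1.2))
    for s, e in track.deletions:
        ax.axvspan(s, e, color="0.8", lw=0)
    for pos, base in track.ticks:
        ax.vlines(pos, 0.2, 0.8, color=_TICK_COLORS.get(base, "black"), lw=0.8)
    ax.set_xlim(0, length)
    ax.set_yticks([])
    ax.set_xlabel("master position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
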