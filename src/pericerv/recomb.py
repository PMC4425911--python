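"""Sliding-window parental match-fraction recombination scan.

Given a multiple alignment of a query and two or more candidate parental
proviruses, the scan computes, in each window, the fraction of comparable
columns at which the query equals each parent.  Runs of best-parent
assignment delimit putative crossovers; each switch is localized to the
interval between the last informative column favoring the left parent and
the first favoring the right parent, and tested for significance with a
two-sided Fisher exact test on informative sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

GAP = "-"


@dataclass
class ParentalPanel:
    """Gapped query + parent sequences on one coordinate frame."""

    query_name: str
    sequences: dict[str, str]  # name -> gapped sequence (query included)

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("all panel sequences must share one gapped length")
        if self.query_name not in self.sequences:
            raise ValueError("query missing from panel")
        if len(self.sequences) < 3:
            raise ValueError("panel needs the query and at least two parents")

    @property
    def length(self) -> int:
        return len(self.sequences[self.query_name])

    @property
    def parents(self) -> list[str]:
        return [n for n in self.sequences if n != self.query_name]

    def arrays(self) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        q = np.frombuffer(self.sequences[self.query_name].upper().encode(), dtype=np.uint8)
        ps = {
            n: np.frombuffer(self.sequences[n].upper().encode(), dtype=np.uint8)
            for n in self.parents
        }
        return q, ps


@dataclass
class MatchProfile:
    centers: np.ndarray                 # alignment-column window centers
    fractions: dict[str, np.ndarray]    # parent -> per-window match fraction
    window: int
    step: int
    low_coverage: np.ndarray            # windows with <50% comparable columns
    panel: ParentalPanel | None = None


@dataclass
class BreakpointCall:
    left_parent: str
    right_parent: str
    interval: tuple[int, int]  # alignment columns bracketing the crossover
    p_value: float = float("nan")


def window_match_fractions(
    panel: ParentalPanel, window: int = 200, step: int = 10
) -> MatchProfile:
    """Per-window query/parent match fractions over the alignment.

    A column is comparable for a parent when neither the query nor that
    parent is gapped there; windows where fewer than half the columns are
    comparable (for any parent) are flagged low-coverage.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > panel.length:
        raise ValueError("window exceeds alignment length")
    q, parents = panel.arrays()
    gap = ord(GAP)
    n_windows = (panel.length - window) // step + 1
    starts = np.arange(n_windows) * step
    centers = starts + window // 2

    fractions: dict[str, np.ndarray] = {}
    low = np.zeros(n_windows, dtype=bool)
    for name, p in parents.items():
        comparable = (q != gap) & (p != gap)
        match = comparable & (q == p)
        ccum = np.concatenate([[0], np.cumsum(comparable)])
        mcum = np.concatenate([[0], np.cumsum(match)])
        ncomp = ccum[starts + window] - ccum[starts]
        nmatch = mcum[starts + window] - mcum[starts]
        with np.errstate(invalid="ignore"):
            frac = np.where(ncomp > 0, nmatch / np.maximum(ncomp, 1), np.nan)
        fractions[name] = frac
        low |= ncomp < window / 2
    return MatchProfile(
        centers=centers, fractions=fractions, window=window, step=step,
        low_coverage=low, panel=panel,
    )


def _informative_columns(panel: ParentalPanel, left: str, right: str):
    """Columns where the query matches exactly one of the two parents.

    Returns (columns, favors_left boolean array).
    """
    q, parents = panel.arrays()
    gap = ord(GAP)
    a, b = parents[left], parents[right]
    ok = (q != gap) & (a != gap) & (b != gap)
    qa = ok & (q == a) & (q != b)
    qb = ok & (q == b) & (q != a)
    cols = np.nonzero(qa | qb)[0]
    return cols, qa[cols]


def call_breakpoints(profile: MatchProfile, min_delta: float = 0.02) -> list[BreakpointCall]:
    """Parent-switch calls from a match profile.

    Best-parent runs are computed per window; a switch between runs is
    called when the winning margin exceeds ``min_delta`` on both sides, and
    is then refined to the informative-column interval bracketing the
    crossover.
    """
    names = sorted(profile.fractions)
    if len(names) < 2:
        raise ValueError("at least two parents required")
    mat = np.vstack([profile.fractions[n] for n in names])  # parents x windows
    order = np.argsort(-mat, axis=0)
    best_idx = order[0]
    best = mat[best_idx, np.arange(mat.shape[1])]
    second = mat[order[1], np.arange(mat.shape[1])]
    margin = best - second

    # contiguous best-parent runs; a switch needs convincing support
    # (margin above min_delta somewhere) within the run on each side, since
    # the transition windows themselves straddle the crossover and are
    # near-ties by construction
    runs: list[tuple[int, int, int]] = []  # (best parent index, start, end)
    start = 0
    for w in range(1, mat.shape[1] + 1):
        if w == mat.shape[1] or best_idx[w] != best_idx[start]:
            runs.append((int(best_idx[start]), start, w))
            start = w

    calls: list[BreakpointCall] = []
    for (pi, ls, le), (qi, rs, re) in zip(runs, runs[1:]):
        if margin[ls:le].max() <= min_delta or margin[rs:re].max() <= min_delta:
            continue
        left = names[pi]
        right = names[qi]
        interval = (int(profile.centers[le - 1]), int(profile.centers[rs]))
        if profile.panel is not None:
            interval = _refine_interval(
                profile.panel, left, right, interval, profile.window
            )
        calls.append(BreakpointCall(left_parent=left, right_parent=right, interval=interval))
    return calls


def _refine_interval(panel, left, right, coarse, window) -> tuple[int, int]:
    """Narrow a window-level switch to bracketing informative columns."""
    cols, favors_left = _informative_columns(panel, left, right)
    lo = coarse[0] - window
    hi = coarse[1] + window
    sel = (cols >= lo) & (cols <= hi)
    cols, favors_left = cols[sel], favors_left[sel]
    if cols.size == 0:
        return coarse
    # choose the split minimizing misassigned informative sites
    left_cum = np.concatenate([[0], np.cumsum(favors_left)])
    n_left = left_cum[-1]
    k = np.arange(cols.size + 1)
    # right-favoring sites left of the split + left-favoring sites right of it
    mis = (k - left_cum) + (n_left - left_cum)
    split = int(np.argmin(mis))
    last_left = int(cols[split - 1]) if split > 0 else coarse[0]
    first_right = int(cols[split]) if split < cols.size else coarse[1]
    return (last_left, first_right)


def breakpoint_significance(panel: ParentalPanel, call: BreakpointCall) -> float:
    """Two-sided Fisher exact p-value for a parent switch.

    Informative columns (query matches exactly one of the two parents) are
    tabulated left vs right of the breakpoint interval midpoint against the
    parent they favor; independence is rejected when the favored parent
    changes across the breakpoint.
    """
    cols, favors_left = _informative_columns(panel, call.left_parent, call.right_parent)
    if cols.size == 0:
        raise ValueError("no informative columns for this parent pair")
    mid = sum(call.interval) / 2.0
    left_side = cols < mid
    table = [
        [int((left_side & favors_left).sum()), int((left_side & ~favors_left).sum())],
        [int((~left_side & favors_left).sum()), int((~left_side & ~favors_left).sum())],
    ]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def verify_flank_similarity(
    panel: ParentalPanel, call: BreakpointCall, flank_width: int = 500
) -> dict[str, float]:
    """Query/assigned-parent identity within ``flank_width`` of the crossover.

    Returns identities (fractions over comparable columns) for the left and
    right flank against their respective assigned parents; flanks truncated
    at the alignment edge trigger a warning.
    """
    q, parents = panel.arrays()
    gap = ord(GAP)
    mid = int(sum(call.interval) // 2)
    lo, hi = mid - flank_width, mid + flank_width
    if lo < 0 or hi > panel.length:
        warnings.warn("flank extends past the alignment; truncated")
        lo, hi = max(lo, 0), min(hi, panel.length)
    out = {}
    for side, name, (s, e) in (
        ("left", call.left_parent, (lo, mid)),
        ("right", call.right_parent, (mid, hi)),
    ):
        p = parents[name]
        qs, ps = q[s:e], p[s:e]
        ok = (qs != gap) & (ps != gap)
        out[side] = float((qs[ok] == ps[ok]).mean()) if ok.any() else float("nan")
    return out


def profile_to_tsv(profile: MatchProfile, path) -> None:
    names = sorted(profile.fractions)
    with open(path, "w") as fh:
        fh.write("center\t" + "\t".join(names) + "\tlow_coverage\n")
        for i, c in enumerate(profile.centers):
            vals = "\t".join(f"{profile.fractions[n][i]:.4f}" for n in names)
            fh.write(f"{int(c)}\t{vals}\t{int(profile.low_coverage[i])}\n")


def plot_profile(profile: MatchProfile, calls: list[BreakpointCall], path) -> None:
    """Two-track match-fraction plot with arrows at called crossovers."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    for name in sorted(profile.fractions):
        ax.plot(profile.centers, profile.fractions[name], label=name, lw=1.2)
    for call in calls:
        mid = sum(call.interval) / 2
        ax.annotate(
            "", xy=(mid, 1.0), xytext=(mid, 1.08),
            arrowprops=dict(arrowstyle="->", color="black"),
        )
    ax.set_xlabel("alignment column")
    ax.set_ylabel("match fraction")
    ax.set_ylim(0, 1.1)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
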