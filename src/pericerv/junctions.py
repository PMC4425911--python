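"""Junction-read screen for 5'-truncated pericentromeric proviruses.

A read is integration-junction evidence when it contains, contiguously and
in order: at least ``min_flank`` terminal bases of the pericentromeric flank,
the full 13-bp junction motif (ACATATACCCAGT by default), and at least
``min_provirus`` leading bases of the provirus body, with no more than
``max_mismatch`` substitutions in total across the three segments.  Reads
are screened in both orientations.  Evidence is then filtered against a
decoy/reference set and clustered into loci, which pass only with at least
``min_locations`` unique hit locations in every required sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import revcomp


@dataclass(frozen=True)
class JunctionModel:
    """Three-segment junction signature of one provirus locus (variant)."""

    id: str
    flank: str
    junction: str = "ACATATACCCAGT"
    provirus: str = ""
    min_flank: int = 20
    min_provirus: int = 20
    max_mismatch: int = 1
    target: str = ""     # locus group (e.g. chromosome) used for clustering
    signature: str = ""  # private-substitution signature of this variant

    def __post_init__(self):
        if len(self.flank) < self.min_flank:
            raise ValueError(f"model {self.id}: flank shorter than min_flank")
        if len(self.provirus) < self.min_provirus:
            raise ValueError(f"model {self.id}: provirus shorter than min_provirus")
        if not self.junction:
            raise ValueError(f"model {self.id}: junction must be non-empty")

    @property
    def core(self) -> str:
        """The minimal diagnostic window: flank tail + junction + provirus head."""
        return (
            self.flank[len(self.flank) - self.min_flank:]
            + self.junction
            + self.provirus[: self.min_provirus]
        )


@dataclass(frozen=True)
class JunctionHit:
    read: str
    model: str
    strand: str           # "-" when the match is on the reverse complement
    flank_offset: int     # offsets of the three segments in the oriented read
    junction_offset: int
    provirus_offset: int
    mismatches: int


@dataclass
class LocusCluster:
    """Evidence for one locus group, aggregated across samples."""

    id: str
    signatures: set = field(default_factory=set)
    hits_per_sample: dict = field(default_factory=dict)
    unique_locations_per_sample: dict = field(default_factory=dict)
    unique_locations: int = 0
    passed: bool = False


def _hamming_leq(a: str, b: str, budget: int) -> int:
    """Mismatch count if <= budget, else -1 (early exit)."""
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return -1
    return mism


def _candidate_starts(seq: str, junction: str, min_flank: int, budget: int) -> list[int]:
    """Candidate core-start offsets in ``seq``.

    For a budget of at most one substitution, any admissible placement puts
    the junction in the read with <= 1 mismatch, so one of its two halves is
    exact (pigeonhole); seeding on the halves is therefore lossless.  Larger
    budgets fall back to scanning every offset.
    """
    if budget > 1:
        return list(range(len(seq)))
    half = len(junction) // 2
    seeds = ((junction[:half], 0), (junction[half:], half))
    starts: set[int] = set()
    for seed, off in seeds:
        pos = seq.find(seed)
        while pos != -1:
            start = pos - off - min_flank
            if start >= 0:
                starts.add(start)
            pos = seq.find(seed, pos + 1)
    return sorted(starts)


def _best_placement(seq: str, model: JunctionModel) -> tuple[int, int] | None:
    core = model.core
    if len(seq) < len(core):
        return None
    best: tuple[int, int] | None = None
    for start in _candidate_starts(seq, model.junction, model.min_flank, model.max_mismatch):
        if start + len(core) > len(seq):
            continue
        mism = _hamming_leq(seq[start: start + len(core)], core, model.max_mismatch)
        if mism >= 0 and (best is None or mism < best[1]):
            best = (start, mism)
            if mism == 0:
                break
    return best


def screen_read(read: str, model: JunctionModel, read_id: str = "read") -> JunctionHit | None:
    """Classify one read against one junction model.

    Returns the best-scoring placement over both orientations, or None.
    Reads shorter than the diagnostic window are classified None.  Offsets
    are reported in the oriented read (the reverse complement for "-" hits).
    """
    read = read.upper()
    fwd = _best_placement(read, model)
    rc = revcomp(read)
    rev = _best_placement(rc, model)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[1] <= rev[1]):
        start, mism, strand = fwd[0], fwd[1], "+"
    else:
        start, mism, strand = rev[0], rev[1], "-"
    return JunctionHit(
        read=read_id,
        model=model.id,
        strand=strand,
        flank_offset=start,
        junction_offset=start + model.min_flank,
        provirus_offset=start + model.min_flank + len(model.junction),
        mismatches=mism,
    )


def screen_library(
    reads: list[tuple[str, str]], models: list[JunctionModel]
) -> list[JunctionHit]:
    """Screen every read against every model, both strands.

    Output is ordered by read order, then model id.  Reads are pre-filtered
    by exact junction half-seeds before the mismatch-counted comparison, so
    libraries dominated by non-junction reads screen quickly.
    """
    models = sorted(models, key=lambda m: m.id)
    # group models by (junction, min_flank, budget) to share seed scans
    hits: list[JunctionHit] = []
    for read_id, seq in reads:
        seq = seq.upper()
        rc = revcomp(seq)
        seed_cache: dict[tuple, tuple[list[int], list[int]]] = {}
        for model in models:
            key = (model.junction, model.min_flank, model.max_mismatch)
            if key not in seed_cache:
                seed_cache[key] = (
                    _candidate_starts(seq, model.junction, model.min_flank, model.max_mismatch),
                    _candidate_starts(rc, model.junction, model.min_flank, model.max_mismatch),
                )
            fstarts, rstarts = seed_cache[key]
            if not fstarts and not rstarts:
                continue
            hit = screen_read(seq, model, read_id=read_id)
            if hit is not None:
                hits.append(hit)
    return hits


def _read_matches_decoy(read: str, decoy: np.ndarray, max_mismatch: int) -> bool:
    L = len(read)
    n = len(decoy) - L + 1
    if n <= 0:
        return False
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    mism = np.zeros(n, dtype=np.int32)
    for i in range(L):
        mism += decoy[i: n + i] != r[i]
        # mismatch counts only grow with i, so an exceeded budget is final
        if i % 16 == 15 and mism.min() > max_mismatch:
            return False
    return bool((mism <= max_mismatch).any())


def exclude_reference_hits(
    hits: list[JunctionHit],
    reads: dict[str, str],
    decoys: dict[str, str],
    max_mismatch: int = 1,
) -> list[JunctionHit]:
    """Drop hits whose read matches a decoy/reference sequence end-to-end.

    A read is excluded when it is contained in any decoy, in either
    orientation, with at most ``max_mismatch`` substitutions.
    """
    if not decoys:
        raise ValueError("decoy set must be non-empty")
    if not hits:
        return []
    enc = {
        name: np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for name, seq in decoys.items()
    }
    verdict: dict[str, bool] = {}
    kept = []
    for hit in hits:
        if hit.read not in verdict:
            seq = reads[hit.read].upper()
            rc = revcomp(seq)
            verdict[hit.read] = any(
                _read_matches_decoy(seq, d, max_mismatch)
                or _read_matches_decoy(rc, d, max_mismatch)
                for d in enc.values()
            )
        if not verdict[hit.read]:
            kept.append(hit)
    return kept


def cluster_and_support(
    hits: list[JunctionHit],
    models: list[JunctionModel],
    samples: dict[str, str],
    min_locations: int = 3,
    require_all_samples: bool = True,
    location_mode: str = "signature",
) -> list[LocusCluster]:
    """Group junction evidence into locus clusters and apply the support rule.

    Each read is assigned to the model it matches with fewest mismatches;
    reads tied between models carrying different variant signatures are
    ambiguous and excluded from unique-location counts.  A "unique hit
    location" is a distinct variant signature (``location_mode="signature"``,
    the default: copies are told apart by their private substitutions) or a
    distinct junction offset within reads (``location_mode="read_start"``).
    A cluster passes when its unique-location count reaches
    ``min_locations`` in every sample (or any sample when
    ``require_all_samples`` is false).
    """
    if location_mode not in ("signature", "read_start"):
        raise ValueError(f"unknown location_mode: {location_mode}")
    by_model = {m.id: m for m in models}
    all_samples = sorted(set(samples.values()))
    if not all_samples:
        raise ValueError("at least one sample label is required")

    per_read: dict[str, list[JunctionHit]] = {}
    for hit in hits:
        if hit.read not in samples:
            raise KeyError(f"read {hit.read!r} has no sample label")
        per_read.setdefault(hit.read, []).append(hit)

    clusters: dict[str, LocusCluster] = {}
    for read_id, read_hits in per_read.items():
        best_mm = min(h.mismatches for h in read_hits)
        best = [h for h in read_hits if h.mismatches == best_mm]
        sigs = {by_model[h.model].signature for h in best}
        targets = {by_model[h.model].target for h in best}
        if len(sigs) > 1 or len(targets) > 1:
            continue  # ambiguous assignment
        hit = best[0]
        model = by_model[hit.model]
        sample = samples[read_id]
        cl = clusters.setdefault(model.target, LocusCluster(id=model.target))
        location = (
            model.signature if location_mode == "signature" else hit.junction_offset
        )
        cl.signatures.add(model.signature)
        cl.hits_per_sample.setdefault(sample, []).append(hit)
        cl.unique_locations_per_sample.setdefault(sample, set()).add(location)

    out = []
    for target in sorted(clusters):
        cl = clusters[target]
        counts = {
            s: len(cl.unique_locations_per_sample.get(s, set())) for s in all_samples
        }
        cl.unique_locations_per_sample = counts
        if require_all_samples:
            cl.unique_locations = min(counts.values())
        else:
            cl.unique_locations = max(counts.values())
        cl.passed = cl.unique_locations >= min_locations
        out.append(cl)
    return out


def hits_to_tsv(hits: list[JunctionHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tmodel\tstrand\tflank_offset\tjunction_offset\tprovirus_offset\tmismatches\n")
        for h in hits:
            fh.write(
                f"{h.read}\t{h.model}\t{h.strand}\t{h.flank_offset}\t"
                f"{h.junction_offset}\t{h.provirus_offset}\t{h.mismatches}\n"
            )
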