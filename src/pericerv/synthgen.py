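"""Synthetic pericentromeric genomes with planted provirus loci.

The generator emulates the structures this pipeline is built to detect:

* two 384-bp centromeric repeat families (eight 48-bp segments each) at about
  71.8% mutual identity, standing in for CER:D22Z3 and pCER:D22Z8;
* full-length HERV-K (HML-2)-style proviruses (LTR-gag-pro-pol-env-LTR)
  flanked by a GAATTC target-site duplication inside CER arrays (the K111
  configuration);
* 5'-truncated proviruses lacking the 5'LTR and gag, missing the last 9 bp of
  the 3'LTR (ACCCCTTCA), joined to their pCER flank through the diagnostic
  13-bp junction ACATATACCCAGT, with no target-site duplication (the K222
  configuration);
* single-crossover recombinants between the two;
* multi-copy placement across nine chromosomes with 0-3 private substitutions
  per copy around the integration junction (the "chromosome-specific
  variants" that make copies distinguishable);
* short-read sampling with a substitution error rate, and qPCR cycle
  thresholds from a log-linear standard-curve model.

Every stochastic step is driven by a single integer seed and the generator
emits a ground-truth table sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pcr import load_primer_panel
from .seqcore import revcomp

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

JUNCTION_13BP = "ACATATACCCAGT"
TSD_K111 = "GAATTC"
LTR3_LOST_9BP = "ACCCCTTCA"
# the 3'LTR/pCER boundary carries the binding site of the junction-specific
# reverse primer (K222LTR-pCER-D22Z8R); its reverse complement is split
# between the trimmed LTR end and the first bases of the pCER monomer
_LTR3_END_MOTIF = "AGGGGCAACCC"
_PCER_START_MOTIF = "TATGTGAGGGA"

DEFAULT_CHROMOSOMES = ["1", "7", "12", "13", "14", "15", "18", "21", "22"]
# single copy on 1/18/21/22, several on 7/12/13/14/15
DEFAULT_K222_COPIES = {
    "1": 1, "7": 3, "12": 2, "13": 4, "14": 3, "15": 3, "18": 1, "21": 1, "22": 1,
}
DEFAULT_K111_COPIES = {c: 1 for c in DEFAULT_CHROMOSOMES}

# provirus feature layout (half-open spans on the full-length template)
FEATURE_SPANS = {
    "LTR5": (0, 968),
    "gag": (968, 3068),
    "pro": (3068, 4068),
    "pol": (4068, 6768),
    "env": (6768, 8768),
    "LTR3": (8768, 9736),
}

# primer footprints planted on the full-length provirus (top-strand start).
# Positions follow the primer naming where possible; the qPCR/junction assay
# primers are placed so the documented product sizes come out exactly
# (K222F+K222bR -> 171 bp, K222F+3460R -> 464 bp, P9+KLTR116-94R -> 422 bp).
_PROVIRUS_PLANTS = [
    ("KLTR116-94R", 93),
    ("982R", 982),
    ("1965F", 1965),
    ("1968R", 2010),
    ("2499R", 2499),
    ("2641F", 2641),
    ("K222P", 3108),
    ("K222bR", 3167),
    ("K222R", 3195),
    ("3170F", 3230),
    ("3460R", 3460),
    ("3500R", 3500),
    ("4080F", 4080),
    ("4734R", 4734),
    ("5359F", 5359),
    ("5388R", 5388),
    ("6586F", 6586),
    ("6609R", 6615),
    ("7320R", 7320),
    ("7972F", 7972),
    ("K111F", 8100),
    ("K111P", 8130),
    ("K111R", 8180),
]
_CER_PLANTS = [("P1", 20), ("P9", 84), ("P2", 150)]
_PCER_PLANTS = [("K222F", 349)]


# ---------------------------------------------------------------------------
# low-level mutation helpers

def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


_CODE_LUT = np.zeros(256, dtype=np.uint8)
for b, i in _B2I.items():
    _CODE_LUT[ord(b)] = i
_BASE_LUT = np.frombuffer("ACGT".encode(), dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate``, uniformly among the
    three alternative bases. Substitution-only by design (no indels)."""
    if rate <= 0:
        return seq
    codes = _CODE_LUT[_seq_to_codes(seq)].copy()
    mask = rng.random(len(codes)) < rate
    if mask.any():
        shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
    return _BASE_LUT[codes].tobytes().decode()


def plant(seq: str, pos: int, motif: str) -> str:
    """Overwrite ``seq[pos:pos+len(motif)]`` with ``motif``."""
    if pos < 0 or pos + len(motif) > len(seq):
        raise ValueError("plant out of range")
    return seq[:pos] + motif + seq[pos + len(motif):]


def identity_fraction(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError("equal lengths required")
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# repeat families

@dataclass(frozen=True)
class RepeatFamily:
    """A tandem repeat monomer built from fixed-length segment variants."""

    name: str
    segments: tuple[str, ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.segments:
            raise ValueError("family needs at least one segment")

    @property
    def segment(self) -> str:
        return self.segments[0]

    @property
    def segments_per_monomer(self) -> int:
        return len(self.segments)

    @property
    def monomer(self) -> str:
        return "".join(self.segments)

    def array(self, n_monomers: int) -> str:
        return self.monomer * n_monomers

    def with_plant(self, pos: int, motif: str) -> "RepeatFamily":
        """Return a copy whose monomer carries ``motif`` at ``pos``."""
        mono = plant(self.monomer, pos, motif)
        unit = len(self.segment)
        segs = tuple(mono[i: i + unit] for i in range(0, len(mono), unit))
        return replace(self, segments=segs)


def make_repeat_family(
    name: str,
    segment_length: int = 48,
    n_segments: int = 8,
    seed: int = 0,
    segment_divergence: float = 0.08,
) -> RepeatFamily:
    """Random repeat family: one canonical segment plus diverged variants.

    The monomer is the tandem concatenation of ``n_segments`` variants of a
    single ``segment_length``-bp unit; with the defaults that is the 384-bp
    (8 x 48 bp) organization of the CER repeat class.
    """
    if segment_length < 1 or n_segments < 1:
        raise ValueError("segment_length and n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    canonical = random_dna(rng, segment_length)
    segments = [canonical]
    for _ in range(n_segments - 1):
        segments.append(mutate(canonical, segment_divergence, rng))
    return RepeatFamily(name=name, segments=tuple(segments))


def diverge_family(
    parent: RepeatFamily, target_identity: float, seed: int = 0, name: str | None = None
) -> RepeatFamily:
    """Derive a sister family at ``target_identity`` expected identity.

    Each monomer site substitutes independently with probability
    (1 - target_identity); the realized identity is recorded in metadata.
    """
    if not (0.0 < target_identity <= 1.0):
        raise ValueError("target_identity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    child_mono = mutate(parent.monomer, 1.0 - target_identity, rng)
    unit = len(parent.segment)
    segs = tuple(child_mono[i: i + unit] for i in range(0, len(child_mono), unit))
    fam = RepeatFamily(
        name=name or f"{parent.name}_div",
        segments=segs,
        metadata={
            "parent": parent.name,
            "target_identity": target_identity,
            "realized_identity": identity_fraction(parent.monomer, child_mono),
        },
    )
    return fam


# ---------------------------------------------------------------------------
# provirus templates

@dataclass(frozen=True)
class ProvirusTemplate:
    """An integrated provirus plus its integration-site bookkeeping.

    ``tsd_5``/``tsd_3`` are the target-site-duplication copies emitted
    immediately outside the provirus on each side (identical and non-empty
    for a clean integration; asymmetric only for recombinant loci).
    ``junction_5`` is the flank-provirus boundary motif on the 5' side and
    ``ltr3_trim`` the number of bases missing from the 3'LTR end.
    """

    name: str
    features: tuple[tuple[str, str], ...]
    tsd_5: str = ""
    tsd_3: str = ""
    flank_family_5: str = ""
    flank_family_3: str = ""
    junction_5: str = ""
    ltr3_trim: int = 0

    def __post_init__(self):
        if not self.features:
            raise ValueError("template features must be non-empty")
        names = [n for n, _ in self.features]
        if self.junction_5 and ("LTR5" in names or "gag" in names):
            raise ValueError(
                "junction-bearing (5'-truncated) templates must lack LTR5 and gag"
            )
        if self.ltr3_trim:
            ltr3 = dict(self.features).get("LTR3")
            if ltr3 is None or self.ltr3_trim >= len(ltr3):
                raise ValueError("ltr3_trim must be smaller than the LTR3 length")

    @property
    def tsd(self) -> str:
        return self.tsd_5 if self.tsd_5 == self.tsd_3 else ""

    def feature(self, name: str) -> str:
        return dict(self.features)[name]

    def has_feature(self, name: str) -> bool:
        return name in dict(self.features)


@dataclass(frozen=True)
class RecombinantSpec:
    parent_5: str
    parent_3: str
    breakpoint: int  # alignment column; columns < breakpoint come from parent_5


def build_provirus_locus(
    template: ProvirusTemplate,
    families: dict[str, RepeatFamily],
    flank_monomers: int = 2,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Assemble one integration locus and its 0-based half-open feature map.

    Layout: 5' flank array, tsd_5, junction_5, provirus features in order
    (3'LTR trimmed by ``ltr3_trim``), tsd_3, 3' flank array.  Empty elements
    are omitted; the coordinate map tiles the construct without gaps.
    """
    try:
        fam5 = families[template.flank_family_5]
        fam3 = families[template.flank_family_3]
    except KeyError as exc:
        raise KeyError(f"unknown flank family: {exc.args[0]}") from exc

    parts: list[tuple[str, str]] = []
    if flank_monomers:
        parts.append(("flank5", fam5.array(flank_monomers)))
    if template.tsd_5:
        parts.append(("tsd5", template.tsd_5))
    if template.junction_5:
        parts.append(("junction5", template.junction_5))
    for fname, fseq in template.features:
        if fname == "LTR3" and template.ltr3_trim:
            fseq = fseq[: len(fseq) - template.ltr3_trim]
        parts.append((fname, fseq))
    if template.tsd_3:
        parts.append(("tsd3", template.tsd_3))
    if flank_monomers:
        parts.append(("flank3", fam3.array(flank_monomers)))

    seq_parts: list[str] = []
    coord_map: list[tuple[str, int, int]] = []
    pos = 0
    for fname, fseq in parts:
        coord_map.append((fname, pos, pos + len(fseq)))
        seq_parts.append(fseq)
        pos += len(fseq)
    return "".join(seq_parts), coord_map


def build_recombinant(
    spec: RecombinantSpec, alignment: dict[str, str]
) -> tuple[str, int]:
    """Column-wise single-crossover chimera of two aligned parents.

    Columns before ``spec.breakpoint`` take the 5' parent's allele, the rest
    the 3' parent's.  Returns the degapped chimera and the true breakpoint
    projected to its (degapped) coordinates - the ground truth consumed by
    the recombination-scan checks.
    """
    for p in (spec.parent_5, spec.parent_3):
        if p not in alignment:
            raise KeyError(f"parent {p!r} missing from alignment")
    a = alignment[spec.parent_5]
    b = alignment[spec.parent_3]
    if len(a) != len(b):
        raise ValueError("aligned parents must have equal gapped length")
    if not (0 <= spec.breakpoint <= len(a)):
        raise ValueError("breakpoint outside alignment")
    chimera_cols = a[: spec.breakpoint] + b[spec.breakpoint:]
    out_break = len(chimera_cols[: spec.breakpoint].replace("-", ""))
    return chimera_cols.replace("-", ""), out_break


# ---------------------------------------------------------------------------
# default templates: the study system

def default_primer_seqs() -> dict[str, str]:
    return {p.name: p.seq for p in load_primer_panel()}


def build_default_templates(seed: int = 0) -> dict:
    """Repeat families and provirus templates with the panel's binding sites.

    Returns a dict with ``families`` (CER_D22Z3, pCER_D22Z8) and
    ``templates`` (K111, K222 and the K222_K111 recombinant).  Primer
    footprints from the assay panel are planted at fixed coordinates so the
    documented amplicon sizes are reproduced by in-silico PCR.
    """
    primers = default_primer_seqs()
    rng = np.random.default_rng(seed)

    cer = make_repeat_family("CER_D22Z3", 48, 8, seed=int(rng.integers(2**31)))
    for name, pos in _CER_PLANTS:
        # P1/P9 forward, P2 reverse
        motif = primers[name] if name != "P2" else revcomp(primers[name])
        cer = cer.with_plant(pos, motif)

    pcer = diverge_family(cer, 0.718, seed=int(rng.integers(2**31)), name="pCER_D22Z8")
    pcer = pcer.with_plant(0, _PCER_START_MOTIF)
    for name, pos in _PCER_PLANTS:
        pcer = pcer.with_plant(pos, primers[name])

    # full-length provirus body; the two LTRs start identical and then each
    # accumulates ~1% substitutions, giving the molecular-clock signal
    ltr5 = random_dna(rng, FEATURE_SPANS["LTR5"][1] - FEATURE_SPANS["LTR5"][0])
    ltr5 = plant(ltr5, len(ltr5) - 20, _LTR3_END_MOTIF + LTR3_LOST_9BP)
    ltr3 = mutate(ltr5, 0.01, rng)
    ltr5_div = mutate(ltr5, 0.01, rng)
    ltr3 = plant(ltr3, len(ltr3) - 20, _LTR3_END_MOTIF + LTR3_LOST_9BP)

    body = {"LTR5": ltr5_div, "LTR3": ltr3}
    for fname in ("gag", "pro", "pol", "env"):
        s, e = FEATURE_SPANS[fname]
        body[fname] = random_dna(rng, e - s)

    def plant_provirus_primers(feats: dict[str, str]) -> dict[str, str]:
        feats = dict(feats)
        for pname, pos in _PROVIRUS_PLANTS:
            seq = primers[pname]
            motif = revcomp(seq) if pname.endswith("R") else seq
            for fname, (s, e) in FEATURE_SPANS.items():
                if fname in feats and s <= pos and pos + len(motif) <= e:
                    feats[fname] = plant(feats[fname], pos - s, motif)
                    break
        return feats

    k111_feats = plant_provirus_primers(body)
    k111 = ProvirusTemplate(
        name="K111",
        features=tuple((f, k111_feats[f]) for f in ("LTR5", "gag", "pro", "pol", "env", "LTR3")),
        tsd_5=TSD_K111,
        tsd_3=TSD_K111,
        flank_family_5="CER_D22Z3",
        flank_family_3="CER_D22Z3",
    )

    # K222 body: ~99% identical to K111 in the shared genes, 5'-truncated,
    # 3'LTR missing its last 9 bp, no TSD, pCER flanks
    k222_feats = {f: mutate(k111_feats[f], 0.01, rng) for f in ("pro", "pol", "env", "LTR3")}
    k222_feats = plant_provirus_primers(k222_feats)
    k222_feats["LTR3"] = plant(
        k222_feats["LTR3"], len(k222_feats["LTR3"]) - 20, _LTR3_END_MOTIF + LTR3_LOST_9BP
    )
    k222 = ProvirusTemplate(
        name="K222",
        features=tuple((f, k222_feats[f]) for f in ("pro", "pol", "env", "LTR3")),
        flank_family_5="pCER_D22Z8",
        flank_family_3="pCER_D22Z8",
        junction_5=JUNCTION_13BP,
        ltr3_trim=len(LTR3_LOST_9BP),
    )

    # single-crossover product: K222 5' half, K111 3'LTR + TSD + CER flank
    rec = ProvirusTemplate(
        name="K222_K111",
        features=tuple(
            [(f, k222_feats[f]) for f in ("pro", "pol", "env")] + [("LTR3", k111_feats["LTR3"])]
        ),
        tsd_3=TSD_K111,
        flank_family_5="pCER_D22Z8",
        flank_family_3="CER_D22Z3",
        junction_5=JUNCTION_13BP,
    )

    return {
        "families": {"CER_D22Z3": cer, "pCER_D22Z8": pcer},
        "templates": {"K111": k111, "K222": k222, "K222_K111": rec},
        "primers": primers,
    }


# ---------------------------------------------------------------------------
# genome assembly

TRUTH_COLUMNS = [
    "locus_id", "chromosome", "start", "end", "template", "strand",
    "junction_pos", "private_subs",
]


@dataclass
class SimulatedGenome:
    chromosomes: dict[str, str]
    truth: pd.DataFrame
    seed: int
    families: dict[str, RepeatFamily] = field(default_factory=dict)
    templates: dict[str, ProvirusTemplate] = field(default_factory=dict)

    def to_fasta(self, path) -> None:
        from .seqcore import write_fasta

        write_fasta(path, {f"chr{c}": s for c, s in self.chromosomes.items()})


def _apply_private_subs(
    construct: str, junction_pos: int, n_subs: int, rng: np.random.Generator,
    window_left: int = 20, window_right: int = 20,
) -> tuple[str, str]:
    """Plant ``n_subs`` locus-private substitutions near the junction.

    Eligible sites are the ``window_left`` flank bases immediately 5' of the
    junction and ``window_right`` provirus bases immediately 3' of it - the
    window a junction-spanning read screen inspects - so each copy's variant
    signature is visible to the screen; the 13-bp junction motif itself is
    kept intact.  Returns the mutated construct and the signature string
    "off:B;..." with offsets relative to the junction start.
    """
    jl = len(JUNCTION_13BP)
    eligible = list(range(junction_pos - window_left, junction_pos)) + list(
        range(junction_pos + jl, junction_pos + jl + window_right)
    )
    chosen = sorted(rng.choice(len(eligible), size=n_subs, replace=False))
    sig_parts = []
    out = list(construct)
    for idx in chosen:
        pos = eligible[idx]
        old = out[pos]
        new = BASES[(_B2I[old] + int(rng.integers(1, 4))) % 4]
        out[pos] = new
        sig_parts.append(f"{pos - junction_pos}:{new}")
    return "".join(out), ";".join(sig_parts)


def simulate_genome(
    seed: int = 0,
    k222_copies: dict[str, int] | None = None,
    k111_copies: dict[str, int] | None = None,
    flank_monomers: int = 2,
    spacer_monomers: int = 2,
    max_private_subs: int = 3,
    templates: dict | None = None,
) -> SimulatedGenome:
    """Multi-chromosome genome of repeat arrays with planted provirus loci.

    Chromosomes are CER monomer arrays interrupted by integration-locus
    constructs; each junction-bearing copy carries 0..``max_private_subs``
    private substitutions around its junction.  The truth table records each
    locus' coordinates, template, junction position and private-substitution
    signature.
    """
    rng = np.random.default_rng(seed)
    tpl = templates or build_default_templates(seed=int(rng.integers(2**31)))
    families = tpl["families"]
    k222_copies = DEFAULT_K222_COPIES if k222_copies is None else k222_copies
    k111_copies = DEFAULT_K111_COPIES if k111_copies is None else k111_copies
    chrom_labels = sorted(set(k222_copies) | set(k111_copies), key=lambda c: (len(c), c))

    spacer = families["CER_D22Z3"].array(spacer_monomers)
    chromosomes: dict[str, str] = {}
    truth_rows = []
    counter = 0
    for chrom in chrom_labels:
        plan = ["K111"] * k111_copies.get(chrom, 0) + ["K222"] * k222_copies.get(chrom, 0)
        rng.shuffle(plan)
        parts = [spacer]
        pos = len(spacer)
        for tname in plan:
            template = tpl["templates"][tname]
            construct, cmap = build_provirus_locus(template, families, flank_monomers)
            jpos = -1
            sig = ""
            spans = dict((n, (s, e)) for n, s, e in cmap)
            if "junction5" in spans:
                jpos = spans["junction5"][0]
                n_subs = int(rng.integers(0, max_private_subs + 1))
                if n_subs:
                    construct, sig = _apply_private_subs(construct, jpos, n_subs, rng)
            truth_rows.append({
                "locus_id": f"{tname}_chr{chrom}_{counter}",
                "chromosome": chrom,
                "start": pos,
                "end": pos + len(construct),
                "template": tname,
                "strand": "+",
                "junction_pos": (pos + jpos) if jpos >= 0 else -1,
                "private_subs": sig,
            })
            counter += 1
            parts.append(construct)
            parts.append(spacer)
            pos += len(construct) + len(spacer)
        chromosomes[chrom] = "".join(parts)

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedGenome(
        chromosomes=chromosomes, truth=truth, seed=seed,
        families=families, templates=tpl["templates"],
    )


def junction_models(
    genome: SimulatedGenome,
    flank_context: int = 60,
    provirus_context: int = 60,
    min_flank: int = 20,
    min_provirus: int = 20,
    max_mismatch: int = 1,
):
    """Per-locus junction models extracted from the genome itself.

    One model per junction-bearing locus, carrying the locus' own private
    substitutions; this mirrors building the screening targets from the
    per-chromosome sequences obtained by PCR.
    """
    from .junctions import JunctionModel

    models = []
    jl = len(JUNCTION_13BP)
    for row in genome.truth.itertuples():
        if row.junction_pos < 0:
            continue
        chrom = genome.chromosomes[row.chromosome]
        j = row.junction_pos
        models.append(
            JunctionModel(
                id=row.locus_id,
                flank=chrom[j - flank_context: j],
                junction=chrom[j: j + jl],
                provirus=chrom[j + jl: j + jl + provirus_context],
                min_flank=min_flank,
                min_provirus=min_provirus,
                max_mismatch=max_mismatch,
                target=row.chromosome,
                signature=row.private_subs,
            )
        )
    return models


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class ReadLibrary:
    reads: list[tuple[str, str]]
    truth: pd.DataFrame  # read, chromosome, start, end, strand

    def to_fastq(self, path) -> None:
        from .seqcore import write_fastq

        write_fastq(path, self.reads)


def simulate_reads(
    genome: SimulatedGenome,
    read_length: int = 100,
    depth: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
    sample: str = "S",
) -> ReadLibrary:
    """Uniform error-prone read sampling with per-read ground truth.

    Per chromosome, round(depth * L / read_length) reads are drawn with
    uniform start positions and random strand; errors are substitutions only,
    uniform over the three alternative bases.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must lie in [0, 1)")
    shortest = min(len(s) for s in genome.chromosomes.values())
    if read_length > shortest:
        raise ValueError("read_length exceeds the shortest chromosome")

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    idx = 0
    for chrom in sorted(genome.chromosomes, key=lambda c: (len(c), c)):
        seq = genome.chromosomes[chrom]
        n = int(round(depth * len(seq) / read_length))
        starts = rng.integers(0, len(seq) - read_length + 1, size=n)
        strands = rng.integers(0, 2, size=n)
        for s, st in zip(starts, strands):
            s = int(s)
            frag = seq[s: s + read_length]
            if st:
                frag = revcomp(frag)
            if error_rate > 0:
                frag = mutate(frag, error_rate, rng)
            rid = f"{sample}_read{idx}"
            reads.append((rid, frag))
            truth_rows.append({
                "read": rid, "chromosome": chrom, "start": s,
                "end": s + read_length, "strand": "-" if st else "+",
            })
            idx += 1
    return ReadLibrary(reads=reads, truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# qPCR readout simulation

@dataclass(frozen=True)
class QpcrSimModel:
    """Log-linear qPCR response: Ct = intercept + slope*log10(copies) + noise."""

    intercept: float = 40.0
    slope: float = -3.3219280948873626  # -1/log10(2): 100% efficiency
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("slope must be negative")


def simulate_qpcr(
    model: QpcrSimModel, copies_per_genome: dict[str, float], replicates: int = 3
) -> pd.DataFrame:
    """Ct table (target, replicate, ct) from the standard-curve model."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for target, copies in copies_per_genome.items():
        if copies <= 0:
            raise ValueError(f"copies must be > 0 for target {target!r}")
    rng = np.random.default_rng(model.seed)
    rows = []
    for target in copies_per_genome:
        copies = copies_per_genome[target]
        base_ct = model.intercept + model.slope * np.log10(copies)
        noise = rng.normal(0.0, model.noise_sd, size=replicates) if model.noise_sd > 0 else np.zeros(replicates)
        for r in range(replicates):
            rows.append({"target": target, "replicate": r + 1, "ct": float(base_ct + noise[r])})
    return pd.DataFrame(rows)
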