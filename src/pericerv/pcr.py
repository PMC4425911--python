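"""In-silico PCR: primer-site finding, amplicon prediction, genotyping.

Binding sites are located by mismatch-tolerant (Hamming) scanning of both
template strands; amplicons are enumerated for every convergent primer pair
up to a product-size cap and reported smallest-first, mirroring the bias of
real PCR toward the shortest product.  A genotyping panel reduces amplicon
predictions to a presence/absence matrix per template.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .seqcore import revcomp

_VALID_ROLES = {"forward", "reverse", "probe"}


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    role: str

    def __post_init__(self):
        if len(self.seq) < 10:
            raise ValueError(f"primer {self.name}: length must be >= 10")
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"primer {self.name}: alphabet must be ACGT")
        if self.role not in _VALID_ROLES:
            raise ValueError(f"primer {self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class AmpliconPrediction:
    template: str
    fwd: str
    rev: str
    start: int  # 0-based half-open on the template top strand
    end: int
    mismatches: tuple[int, int]  # (fwd, rev)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Assay:
    name: str
    fwd: Primer
    rev: Primer
    min_size: int = 0
    max_size: int = 10**9


def load_primer_panel(path=None) -> list[Primer]:
    """Load a primer panel from YAML (the packaged assay panel by default)."""
    if path is None:
        text = (resources.files("pericerv") / "data" / "primer_panel.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return [Primer(p["name"].strip(), p["seq"].strip(), p["role"]) for p in doc["primers"]]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _hamming_scan(template: np.ndarray, probe: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (position, mismatches) where ``probe`` fits within budget."""
    L = len(probe)
    n = len(template) - L + 1
    if n <= 0:
        return []
    p = _encode(probe)
    mism = np.zeros(n, dtype=np.int32)
    for i in range(L):
        mism += template[i: n + i] != p[i]
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(h), int(mism[h])) for h in hits]


def find_primer_sites(
    template: str, primer: Primer, max_mismatch: int = 1
) -> list[tuple[int, str, int]]:
    """Binding footprints of ``primer`` on the template top strand.

    Strand "+" means the primer binds in its role-appropriate orientation
    (a forward primer matches the top strand directly; a reverse primer's
    reverse complement matches the top strand).  Strand "-" is the opposite
    orientation.  Returns (position, strand, mismatches) sorted by position.
    """
    if not template:
        raise ValueError("template must be non-empty")
    t = _encode(template.upper())
    if primer.role == "reverse":
        plus_probe, minus_probe = revcomp(primer.seq), primer.seq
    else:
        plus_probe, minus_probe = primer.seq, revcomp(primer.seq)
    out = [(pos, "+", mm) for pos, mm in _hamming_scan(t, plus_probe, max_mismatch)]
    out += [(pos, "-", mm) for pos, mm in _hamming_scan(t, minus_probe, max_mismatch)]
    out.sort(key=lambda h: (h[0], h[1]))
    return out


def predict_amplicons(
    template: str,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 1,
    max_product: int = 15000,
    template_name: str = "template",
) -> list[AmpliconPrediction]:
    """Products of a primer pair on ``template``, smallest first.

    A product spans from the 5' end of the left-landing primer through the
    5' end of the right-landing primer, including both footprints.  Both
    template orientations are considered; coordinates are always reported on
    the top strand.
    """
    fsites = find_primer_sites(template, fwd, max_mismatch)
    rsites = find_primer_sites(template, rev, max_mismatch)
    out: list[AmpliconPrediction] = []
    # fwd on top strand, rev converging from the right
    f_plus = [(p, m) for p, s, m in fsites if s == "+"]
    r_plus = [(p, m) for p, s, m in rsites if s == "+"]
    for fp, fm in f_plus:
        for rp, rm in r_plus:
            end = rp + len(rev.seq)
            if rp >= fp and end - fp <= max_product:
                out.append(AmpliconPrediction(template_name, fwd.name, rev.name, fp, end, (fm, rm)))
    # the mirrored configuration: product read off the bottom strand
    f_minus = [(p, m) for p, s, m in fsites if s == "-"]
    r_minus = [(p, m) for p, s, m in rsites if s == "-"]
    for rp, rm in r_minus:
        for fp, fm in f_minus:
            end = fp + len(fwd.seq)
            if fp >= rp and end - rp <= max_product:
                out.append(AmpliconPrediction(template_name, fwd.name, rev.name, rp, end, (fm, rm)))
    out.sort(key=lambda a: (a.length, a.start))
    return out


def genotype_panel(
    templates: dict[str, str],
    assays: list[Assay],
    max_mismatch: int = 1,
    max_product: int = 15000,
):
    """Presence/absence matrix: templates x assays.

    "present" means at least one predicted amplicon falls inside the assay's
    expected size range.
    """
    import pandas as pd

    if not templates:
        raise ValueError("template panel must be non-empty")
    names = [a.name for a in assays]
    if len(set(names)) != len(names):
        raise ValueError("assay names must be unique")
    rows = {}
    for tname, tseq in templates.items():
        row = {}
        for assay in assays:
            if not tseq:
                row[assay.name] = False
                continue
            amps = predict_amplicons(
                tseq, assay.fwd, assay.rev, max_mismatch, max_product, template_name=tname
            )
            row[assay.name] = any(
                assay.min_size <= a.length <= assay.max_size for a in amps
            )
        rows[tname] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)
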