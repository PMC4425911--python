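"""qPCR quantitation and ChIP enrichment analysis.

Absolute copy numbers come from a standard curve (Ct regressed on
log10 copies of serial dilutions); targets are normalized to the single-copy
gene TOP3A; the copy number of the older provirus lineage is obtained by
subtraction, because one assay detects both lineages while a second is
specific for the younger one.  ChIP enrichment is the classic 2^dCt fold vs
the IgG control with a two-sample two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    slope: float      # Ct per log10(copies); negative
    intercept: float  # Ct at 1 copy
    r2: float

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency; 1.0 means perfect doubling per cycle."""
        return 10 ** (-1.0 / self.slope) - 1.0


@dataclass
class CopyEstimate:
    target: str
    copies: float
    normalizer_copies: float
    relative: float
    replicate_sd: float = 0.0
    floored: bool = False  # subtraction estimate clipped at zero


@dataclass
class ChIPResult:
    antibody: str
    delta_ct: float  # mean(Ct IgG) - mean(Ct antibody)
    fold: float      # 2 ** delta_ct
    p_value: float
    stars: str
    n: tuple[int, int]


def fit_standard_curve(dilutions: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares line of Ct on log10(known copies).

    Needs at least three distinct dilution points with positive copy counts.
    """
    if len(dilutions) < 3:
        raise ValueError("at least 3 dilution points are required")
    copies = np.array([c for c, _ in dilutions], dtype=float)
    cts = np.array([ct for _, ct in dilutions], dtype=float)
    if (copies <= 0).any():
        raise ValueError("dilution copy counts must be > 0")
    x = np.log10(copies)
    if np.allclose(x, x[0]):
        raise ValueError("dilution series has zero variance in copies")
    res = stats.linregress(x, cts)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue**2))


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10**((ct - intercept) / slope)."""
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def copy_number_report(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    combined_assay: str = "K111K222",
    specific_assay: str = "K222",
    normalizer: str = "TOP3A",
    subtraction_target: str = "K111",
) -> dict[str, CopyEstimate]:
    """Per-target relative copy numbers including the subtraction estimate.

    ``ct_table`` needs columns ``target`` and ``ct``; replicate Cts are
    averaged before conversion.  The combined assay detects both provirus
    lineages, the specific assay only the younger one, so
    ``subtraction_target`` copies = combined - specific, floored at zero
    (with a flag) when noise crosses zero.  All copy numbers are divided by
    the normalizer's to give copies per genome.
    """
    targets = set(ct_table["target"])
    for required in (combined_assay, specific_assay, normalizer):
        if required not in targets:
            raise ValueError(f"ct_table lacks required assay {required!r}")

    def mean_sd(name):
        cts = ct_table.loc[ct_table["target"] == name, "ct"].to_numpy(dtype=float)
        return float(cts.mean()), float(cts.std(ddof=1)) if len(cts) > 1 else 0.0

    def curve_for(name):
        try:
            return curves[name]
        except KeyError as exc:
            raise ValueError(f"no standard curve for assay {name!r}") from exc

    abs_copies = {}
    sds = {}
    for name in (combined_assay, specific_assay, normalizer):
        m, sd = mean_sd(name)
        abs_copies[name] = ct_to_copies(m, curve_for(name))
        sds[name] = sd

    norm = abs_copies[normalizer]
    out: dict[str, CopyEstimate] = {}
    out[specific_assay] = CopyEstimate(
        target=specific_assay,
        copies=abs_copies[specific_assay],
        normalizer_copies=norm,
        relative=abs_copies[specific_assay] / norm,
        replicate_sd=sds[specific_assay],
    )
    diff = abs_copies[combined_assay] - abs_copies[specific_assay]
    floored = diff < 0
    diff = max(diff, 0.0)
    out[subtraction_target] = CopyEstimate(
        target=subtraction_target,
        copies=diff,
        normalizer_copies=norm,
        relative=diff / norm,
        replicate_sd=float(np.hypot(sds[combined_assay], sds[specific_assay])),
        floored=floored,
    )
    return out


_STAR_LEVELS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


def chip_fold_enrichment(
    ct_ab, ct_igg, antibody: str = "antibody"
) -> ChIPResult:
    """Fold enrichment of an immunoprecipitated fraction over IgG.

    fold = 2**(mean Ct IgG - mean Ct antibody); the p-value is a two-sample
    two-tailed t-test across replicates (reported as NaN with fewer than two
    replicates in either group).
    """
    ab = np.asarray(ct_ab, dtype=float)
    igg = np.asarray(ct_igg, dtype=float)
    if ab.size < 1 or igg.size < 1:
        raise ValueError("at least one replicate per group is required")
    delta = float(igg.mean() - ab.mean())
    fold = float(2.0 ** delta)
    if ab.size >= 2 and igg.size >= 2:
        p = float(stats.ttest_ind(ab, igg).pvalue)
        if np.isnan(p):  # zero variance in both groups
            p = 1.0 if np.isclose(ab.mean(), igg.mean()) else 0.0
    else:
        p = float("nan")
    stars = "n.s."
    for level, symbol in _STAR_LEVELS:
        if p < level:
            stars = symbol
            break
    return ChIPResult(
        antibody=antibody, delta_ct=delta, fold=fold, p_value=p, stars=stars,
        n=(int(ab.size), int(igg.size)),
    )
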