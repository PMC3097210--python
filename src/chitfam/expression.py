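"""qPCR statistics: primer efficiency, relative quantification (2^-ddCt),
and ANOVA with Fisher's LSD compact letter display.

Relative quantification follows the 2^-ddCt method. In ``normalized`` mode
dCt = Ct(target) - Ct(reference) within a sample, ddCt subtracts the
calibrator sample's dCt, and fold change = 2^-ddCt; the relative expression
value (REV) 2^-dCt is the target/reference quantity ratio. ``total_rna``
mode drops the reference term (ddCt from target Ct alone vs the
calibrator) for experiments where no reference gene is stable across
conditions and input RNA is standardized by careful quantification instead.

Group comparisons: values are rescaled to [0,1] by the per-set maximum,
arcsine-square-root transformed, submitted to one-way ANOVA, and separated
by Fisher's LSD at alpha using the pooled error term. Samples sharing a
letter are not significantly different.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CtRecord",
    "DilutionSeries",
    "ExpressionResult",
    "primer_efficiency",
    "relative_expression",
    "replicate_folds",
    "lsd_letters",
    "lsd_significance_matrix",
]


@dataclass(frozen=True)
class CtRecord:
    sample: str  # stage or tissue label
    gene: str  # target or reference name
    replicate: int
    ct: float  # threshold cycles (technical replicates already averaged)

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class DilutionSeries:
    log10_input: tuple[float, ...]
    ct: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.log10_input) != len(self.ct):
            raise ValueError("dilution series arrays differ in length")
        if len(self.ct) < 3:
            raise ValueError("dilution series needs >= 3 points")


@dataclass(frozen=True)
class ExpressionResult:
    sample: str
    gene: str
    delta_ct: float | None  # None in total_rna mode
    delta_delta_ct: float
    fold_change: float  # 2^-ddCt
    rev: float | None  # 2^-dCt, target/reference quantity ratio
    letter: str | None = None


MIN_EFFICIENCY = 0.9


def primer_efficiency(series: DilutionSeries) -> tuple[float, float, bool]:
    """Amplification efficiency from a standard curve.

    Least-squares slope m of Ct against log10 input; E = 10^(-1/m) - 1
    (E = 1 is perfect doubling, slope -3.3219). Returns (efficiency,
    slope, accepted) where accepted means E >= 0.9.
    """
    x = np.asarray(series.log10_input, dtype=float)
    y = np.asarray(series.ct, dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero-variance dilution series")
    slope = float(stats.linregress(x, y).slope)
    if slope == 0:
        raise ValueError("flat standard curve; efficiency undefined")
    eff = 10.0 ** (-1.0 / slope) - 1.0
    return eff, slope, eff >= MIN_EFFICIENCY


def _mean_ct(records: Sequence[CtRecord], sample: str, gene: str) -> float:
    vals = [r.ct for r in records if r.sample == sample and r.gene == gene]
    if not vals:
        raise KeyError((sample, gene))
    return float(np.mean(vals))


def relative_expression(
    records: Sequence[CtRecord],
    reference_gene: str | None,
    calibrator: str,
    mode: str = "normalized",
) -> list[ExpressionResult]:
    """2^-ddCt relative expression for every (sample, target) pair.

    normalized: dCt = mean Ct(target) - mean Ct(reference) per sample;
    ddCt = dCt(sample) - dCt(calibrator). total_rna: ddCt = mean Ct(target,
    sample) - mean Ct(target, calibrator), no reference term (for runs where
    input RNA quantity is the normalizer).
    """
    if mode not in ("normalized", "total_rna"):
        raise ValueError(f"unknown mode {mode!r}")
    samples = sorted({r.sample for r in records})
    genes = sorted({r.gene for r in records})
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent from data")
    targets = [g for g in genes if g != reference_gene] if mode == "normalized" else genes
    if mode == "normalized":
        if reference_gene is None:
            raise ValueError("normalized mode requires a reference gene")
        ref_ct = {}
        for s in samples:
            try:
                ref_ct[s] = _mean_ct(records, s, reference_gene)
            except KeyError:
                raise ValueError(
                    f"sample {s!r} lacks reference-gene ({reference_gene}) records"
                )
    out: list[ExpressionResult] = []
    for gene in targets:
        per_sample_ct = {}
        for s in samples:
            try:
                per_sample_ct[s] = _mean_ct(records, s, gene)
            except KeyError:
                continue
        if calibrator not in per_sample_ct:
            continue
        if mode == "normalized":
            dct = {s: per_sample_ct[s] - ref_ct[s] for s in per_sample_ct}
            dct_cal = dct[calibrator]
            for s in sorted(per_sample_ct):
                ddct = dct[s] - dct_cal
                out.append(
                    ExpressionResult(
                        sample=s,
                        gene=gene,
                        delta_ct=dct[s],
                        delta_delta_ct=ddct,
                        fold_change=2.0 ** (-ddct),
                        rev=2.0 ** (-dct[s]),
                    )
                )
        else:
            cal_ct = per_sample_ct[calibrator]
            for s in sorted(per_sample_ct):
                ddct = per_sample_ct[s] - cal_ct
                out.append(
                    ExpressionResult(
                        sample=s,
                        gene=gene,
                        delta_ct=None,
                        delta_delta_ct=ddct,
                        fold_change=2.0 ** (-ddct),
                        rev=None,
                    )
                )
    return out


def replicate_folds(
    records: Sequence[CtRecord],
    gene: str,
    reference_gene: str | None,
    calibrator: str,
    mode: str = "normalized",
) -> dict[str, list[float]]:
    """Per-biological-replicate fold changes for one target gene, suitable
    as input to ``lsd_letters``. Replicates are paired by index; the
    calibrator term uses the calibrator sample's replicate-mean Ct."""
    samples = sorted({r.sample for r in records})
    by_key: dict[tuple[str, str, int], float] = {
        (r.sample, r.gene, r.replicate): r.ct for r in records
    }
    cal_target = _mean_ct(records, calibrator, gene)
    if mode == "normalized":
        cal_ref = _mean_ct(records, calibrator, reference_gene)
        cal_dct = cal_target - cal_ref
    out: dict[str, list[float]] = {}
    for s in samples:
        reps = sorted(r.replicate for r in records if r.sample == s and r.gene == gene)
        vals = []
        for rep in reps:
            ct_t = by_key[(s, gene, rep)]
            if mode == "normalized":
                ct_r = by_key.get((s, reference_gene, rep))
                if ct_r is None:
                    raise ValueError(
                        f"sample {s!r} replicate {rep}: missing reference Ct"
                    )
                ddct = (ct_t - ct_r) - cal_dct
            else:
                ddct = ct_t - cal_target
            vals.append(2.0 ** (-ddct))
        if vals:
            out[s] = vals
    return out


def arcsine_sqrt(x: float) -> float:
    """Variance-stabilizing transform for proportions: asin(sqrt(x)).
    0 -> 0, 1 -> pi/2."""
    if not 0.0 <= x <= 1.0:
        raise ValueError("arcsine-sqrt transform requires values in [0, 1]")
    return math.asin(math.sqrt(x))


def _anova_mse(groups: Sequence[Sequence[float]]) -> tuple[float, int]:
    """Pooled within-group mean square (ANOVA error term) and its df."""
    sse = 0.0
    df = 0
    for g in groups:
        m = float(np.mean(g))
        sse += sum((v - m) ** 2 for v in g)
        df += len(g) - 1
    if df == 0:
        raise ValueError("no residual degrees of freedom")
    return sse / df, df


def lsd_significance_matrix(
    values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    rescale: bool = True,
) -> dict[tuple[str, str], bool]:
    """Pairwise Fisher's-LSD significance (True = significantly different)
    after arcsine-sqrt transform of max-rescaled values."""
    names = sorted(values)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for name in names:
        if len(values[name]) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    transformed = _transform(values, rescale)
    mse, df = _anova_mse([transformed[n] for n in names])
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    sig: dict[tuple[str, str], bool] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ga, gb = transformed[a], transformed[b]
            if mse == 0:
                different = float(np.mean(ga)) != float(np.mean(gb))
            else:
                lsd = tcrit * math.sqrt(mse * (1 / len(ga) + 1 / len(gb)))
                different = abs(float(np.mean(ga)) - float(np.mean(gb))) > lsd
            sig[(a, b)] = sig[(b, a)] = different
    return sig


def _transform(values: Mapping[str, Sequence[float]], rescale: bool) -> dict[str, list[float]]:
    if rescale:
        top = max(max(v) for v in values.values())
        if top <= 0:
            raise ValueError("values must contain a positive maximum")
        scale = 1.0 / top
    else:
        scale = 1.0
    return {
        n: [arcsine_sqrt(min(1.0, v * scale)) for v in vs]
        for n, vs in values.items()
    }


def lsd_letters(
    values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    rescale: bool = True,
) -> dict[str, str]:
    """Compact letter display from pairwise Fisher's LSD.

    Samples sharing a letter are not significantly different at alpha.
    Letters are ordered by decreasing group mean (a = highest).
    """
    sig = lsd_significance_matrix(values, alpha=alpha, rescale=rescale)
    names = sorted(values)
    # insert-and-absorb: start with one letter covering everything, split on
    # each significant pair, drop sets absorbed by a superset
    letter_sets: list[set[str]] = [set(names)]
    for (a, b), different in sorted(sig.items()):
        if not different or a > b:
            continue
        new_sets: list[set[str]] = []
        for ls in letter_sets:
            if a in ls and b in ls:
                new_sets.append(ls - {a})
                new_sets.append(ls - {b})
            else:
                new_sets.append(ls)
        letter_sets = [
            s for s in new_sets
            if s and not any(s < t for t in new_sets)
        ]
        # de-duplicate while preserving order
        seen: list[set[str]] = []
        for s in letter_sets:
            if s not in seen:
                seen.append(s)
        letter_sets = seen
    means = {n: float(np.mean(values[n])) for n in names}
    letter_sets.sort(key=lambda s: -max(means[n] for n in s))
    labels = string.ascii_lowercase
    if len(letter_sets) > len(labels):
        raise ValueError("too many letter groups for a compact display")
    out = {n: "" for n in names}
    for k, ls in enumerate(letter_sets):
        for n in sorted(ls):
            out[n] += labels[k]
    return {n: "".join(sorted(v)) for n, v in out.items()}
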