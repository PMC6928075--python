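"""Diagnostic-test statistics for marker concordance.

Every marker (or marker panel) is evaluated against the reference assay by
cross-tabulating reference species against assigned category.  From the
confusion matrix we compute overall concordance, per-species sensitivity
S = TP/(TP+FN), specificity E = TN/(TN+FP), and the positive likelihood ratio
LR+ = S/(1-E) computed after adding 0.5 to all four cells so it stays finite
when specificity is 1.  95% confidence intervals for S and E are exact
(Clopper-Pearson) binomial; the LR+ interval uses the standard log method on
the corrected counts.

Panels are compared with an exact Wilcoxon signed-rank test on paired
per-species correct-assignment percentages.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import SPECIES_ORDER, SpeciesCall, expand_group

__all__ = [
    "ConfusionError",
    "DiagnosticStats",
    "confusion_matrix",
    "concordance",
    "diagnostic_stats",
    "heatmap_matrix",
    "wilcoxon_signed_rank",
    "load_confusion_fixture",
    "CONFUSION_FIXTURES",
]

logger = logging.getLogger(__name__)

#: Packaged confusion-count fixtures. Marginal totals and most cells are the
#: re-assignment tallies reported for the study's 253 (mono-locus mac-1/16S,
#: after excluding 40 DUI individuals and 5 amplification failures) or 258
#: (ITS/COI and the multi-locus panels) individuals. Cells not individually
#: reported (mac-1: the 11 trossulus and 21 galloprovincialis errors, and one
#: error each from edulis and chilensis placed to match the printed 0.99
#: specificity) are reconstructed and should be treated as plausible fill-in,
#: not observed data.
CONFUSION_FIXTURES = ("mac1", "16S", "ITS", "COI", "panel4", "panel5")


class ConfusionError(ValueError):
    """Invalid confusion-matrix input."""


def _call_label(call) -> str:
    return call.species if isinstance(call, SpeciesCall) else str(call)


def confusion_matrix(
    reference: Sequence[str],
    assigned: Sequence,
    ids: Sequence[str] | None = None,
    group_aware: bool = False,
) -> pd.DataFrame:
    """Cross-tabulate reference species against assigned categories.

    ``assigned`` entries may be species names, group calls ("E/G/Ch"), hybrid
    calls, "unassigned", or :class:`SpeciesCall`.  With ``group_aware=True`` a
    group call containing the reference species is counted on the diagonal
    (correct exclusion bookkeeping for ITS/COI); otherwise group calls are
    tabulated as their own category.  Pairs with a missing entry (None) are
    dropped and reported via logging.
    """
    if len(reference) != len(assigned):
        raise ConfusionError("reference and assigned must cover the same individuals")
    if ids is not None:
        if len(ids) != len(reference):
            raise ConfusionError("ids length mismatch")
        if len(set(ids)) != len(ids):
            raise ConfusionError("duplicate ids in confusion input")
    pairs = []
    dropped = 0
    for ref, asg in zip(reference, assigned):
        lab = None if asg is None else _call_label(asg)
        if ref is None or lab is None:
            dropped += 1
            continue
        if group_aware and "/" in lab and not lab.startswith("hybrid("):
            lab = ref if ref in expand_group(lab) else lab
        pairs.append((ref, lab))
    if dropped:
        logger.info("confusion_matrix: dropped %d individuals missing a call", dropped)
    if not pairs:
        raise ConfusionError("no complete (reference, assigned) pairs")
    df = pd.DataFrame(pairs, columns=["reference", "assigned"])
    table = pd.crosstab(df["reference"], df["assigned"])
    rows = [s for s in SPECIES_ORDER if s in table.index] + sorted(
        set(table.index) - set(SPECIES_ORDER)
    )
    extra_cols = sorted(set(table.columns) - set(SPECIES_ORDER) - {"unassigned"})
    cols = [s for s in SPECIES_ORDER if s in table.columns] + extra_cols + ["unassigned"]
    table = table.reindex(index=rows, columns=cols, fill_value=0)
    table.index.name = "reference"
    table.columns.name = "assigned"
    return table.astype(int)


def _diagonal(matrix: pd.DataFrame) -> int:
    return int(
        sum(matrix.loc[sp, sp] for sp in matrix.index if sp in matrix.columns)
    )


def concordance(matrix: pd.DataFrame) -> float:
    """Overall percent agreement, 100*trace/total, to one decimal.

    Unassigned individuals never count as agreement.
    """
    total = int(matrix.to_numpy().sum())
    if total == 0:
        raise ConfusionError("empty confusion matrix")
    return round(100.0 * _diagonal(matrix) / total, 1)


def _clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


@dataclass(frozen=True)
class DiagnosticStats:
    species: str
    sensitivity: float
    specificity: float
    lr_plus: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    lr_plus_ci: tuple[float, float]
    tp: int
    fn: int
    fp: int
    tn: int


def diagnostic_stats(matrix: pd.DataFrame, species: str, level: float = 0.95) -> DiagnosticStats:
    """Sensitivity, specificity and continuity-corrected LR+ for one species.

    Negatives are all individuals of the other species; unassigned and
    group-category assignments count as not-assigned-to-``species`` (so they
    are errors for the species' own row but correct exclusions elsewhere).
    """
    if species not in matrix.index:
        raise ConfusionError(f"species {species!r} not in confusion matrix rows")
    total = int(matrix.to_numpy().sum())
    row = int(matrix.loc[species].sum())
    col = int(matrix[species].sum()) if species in matrix.columns else 0
    tp = int(matrix.loc[species, species]) if species in matrix.columns else 0
    fn = row - tp
    fp = col - tp
    tn = total - row - fp
    if tp + fn == 0:
        raise ConfusionError(f"sensitivity undefined: no {species} individuals sampled")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp) if tn + fp else float("nan")
    # +0.5 continuity correction on all four cells keeps LR+ finite at E=1.
    tp_c, fn_c, fp_c, tn_c = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
    sens_c = tp_c / (tp_c + fn_c)
    spec_c = tn_c / (tn_c + fp_c)
    lr = sens_c / (1.0 - spec_c)
    se_log = np.sqrt(1 / tp_c - 1 / (tp_c + fn_c) + 1 / fp_c - 1 / (fp_c + tn_c))
    z = stats.norm.ppf(0.5 + level / 2)
    lr_ci = (float(lr * np.exp(-z * se_log)), float(lr * np.exp(z * se_log)))
    return DiagnosticStats(
        species=species,
        sensitivity=sens,
        specificity=spec,
        lr_plus=float(lr),
        sensitivity_ci=_clopper_pearson(tp, tp + fn, level),
        specificity_ci=_clopper_pearson(tn, tn + fp, level),
        lr_plus_ci=lr_ci,
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
    )


def heatmap_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-normalized percentages (each row sums to 100); plotting payload."""
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ConfusionError("heatmap_matrix requires positive row totals")
    return matrix.div(totals, axis=0) * 100.0


def _exact_signed_rank_p(d: np.ndarray, w_plus: float, alternative: str) -> float:
    # Exact null distribution of W+ over all 2^n sign assignments, by dynamic
    # programming on doubled (hence integer, tie-averaged) ranks.
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)
    counts = np.zeros(r2.sum() + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    if alternative == "less":
        return float(min(1.0, cdf))
    if alternative == "greater":
        return float(min(1.0, sf))
    return float(min(1.0, 2 * min(cdf, sf)))


def wilcoxon_signed_rank(
    paired_values_a: Sequence[float],
    paired_values_b: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 25,
) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired values; exact p for small n.

    Zero differences are dropped (standard convention); an all-tie input
    returns (0.0, 1.0).  For up to ``exact_limit`` nonzero pairs the p-value
    comes from the exact permutation distribution of the signed-rank statistic
    (valid with tied ranks); larger samples use the normal approximation.
    Returns (W+, p).
    """
    a = np.asarray(paired_values_a, dtype=float)
    b = np.asarray(paired_values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfusionError("paired vectors must be one-dimensional and equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= exact_limit:
        return w_plus, _exact_signed_rank_p(d, w_plus, alternative)
    res = stats.wilcoxon(d, alternative=alternative, method="approx")
    return w_plus, float(res.pvalue)


def load_confusion_fixture(name: str) -> pd.DataFrame:
    """Load a packaged confusion-count fixture by name.

    Names: 'mac1', '16S', 'ITS', 'COI', 'panel4' (four markers, Me15-16
    excluded) and 'panel5' (all five).  See the module docstring for which
    cells are reported tallies and which are reconstructed fill-in.
    """
    if name not in CONFUSION_FIXTURES:
        raise ConfusionError(f"unknown fixture {name!r}; choose from {CONFUSION_FIXTURES}")
    ref = importlib.resources.files("mytilus_id") / "data" / "confusion" / f"{name}.csv"
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, index_col="reference")
    df.index.name = "reference"
    df.columns.name = "assigned"
    return df.astype(int)
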