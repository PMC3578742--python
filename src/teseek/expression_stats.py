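"""Expression and count statistics: Pfaffl ratios, t tests, Fisher exact.

The Pfaffl method gives efficiency-corrected relative expression from qPCR
cycle thresholds: ratio = E_target^dCt_target / E_ref^dCt_ref, with
dCt = mean Ct(calibrator) - mean Ct(sample) and E the amplification
efficiency per cycle (2.0 = perfect doubling). Normalizing to a reference
gene (e.g. beta-actin) and calibrating on the wildtype group makes the
wildtype fold change exactly 1.

Group comparisons use the classic pooled-variance two-sample t test (Welch
available behind a flag), and transgenic-count comparisons use the exact
two-sided Fisher test under the probability-mass rule: the p value sums the
hypergeometric probabilities of every table with the observed margins whose
probability does not exceed the observed table's. Probabilities are
accumulated in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_TIE_REL_TOL = 1e-7


@dataclass(frozen=True)
class ExpressionMeasurement:
    """Replicate Ct values for one gene in one genotype group."""

    gene: str
    group: str                  # wt | het | hom
    ct_values: tuple[float, ...]
    efficiency: float = 2.0

    def __post_init__(self):
        if self.group not in ("wt", "het", "hom"):
            raise ValueError(f"bad group {self.group!r}")
        if not self.ct_values:
            raise ValueError("need at least one Ct replicate")
        if any(ct <= 0 for ct in self.ct_values):
            raise ValueError("Ct values must be positive")
        if not 1.0 <= self.efficiency <= 2.2:
            raise ValueError("efficiency must lie in [1, 2.2]")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values))


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero table")


# ---------------------------------------------------------------------------
# Pfaffl relative expression
# ---------------------------------------------------------------------------

def pfaffl_ratio(e_target: float, dct_target: float,
                 e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected fold change E_t^dCt_t / E_r^dCt_r."""
    if e_target <= 0 or e_ref <= 0:
        raise ValueError("amplification efficiencies must be positive")
    return e_target ** dct_target / e_ref ** dct_ref


def relative_expression(measurements: Sequence[ExpressionMeasurement],
                        target_gene: str, reference_gene: str,
                        calibrator_group: str = "wt") -> dict[str, float]:
    """Per-group fold change of ``target_gene`` normalized to
    ``reference_gene``, calibrated so ``calibrator_group`` equals 1."""
    by = {(m.gene, m.group): m for m in measurements}
    try:
        cal_t = by[(target_gene, calibrator_group)]
        cal_r = by[(reference_gene, calibrator_group)]
    except KeyError as exc:
        raise ValueError(f"missing calibrator measurement: {exc}") from exc
    out: dict[str, float] = {}
    for group in ("wt", "het", "hom"):
        mt = by.get((target_gene, group))
        mr = by.get((reference_gene, group))
        if mt is None or mr is None:
            continue
        dct_t = cal_t.mean_ct - mt.mean_ct
        dct_r = cal_r.mean_ct - mr.mean_ct
        out[group] = pfaffl_ratio(mt.efficiency, dct_t, mr.efficiency, dct_r)
    return out


def read_ct_table(path: str | Path) -> list[ExpressionMeasurement]:
    """TSV with columns gene, group, replicate, Ct (one row per replicate);
    optional efficiency column (constant per gene/group)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "group", "Ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    out = []
    for (gene, group), sub in df.groupby(["gene", "group"], sort=False):
        eff = float(sub["efficiency"].iloc[0]) if "efficiency" in sub else 2.0
        out.append(ExpressionMeasurement(str(gene), str(group),
                                         tuple(float(x) for x in sub["Ct"]),
                                         eff))
    return out


# ---------------------------------------------------------------------------
# Two-sample t test
# ---------------------------------------------------------------------------

def student_t_test(group_a: Sequence[float], group_b: Sequence[float],
                   welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test (pooled variance by default).

    Degenerate zero-variance inputs follow a documented convention:
    equal means => (0, 1); unequal means => (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Exact two-sided Fisher test
# ---------------------------------------------------------------------------

_lgamma = math.lgamma


def _log_comb(n: int, k: int) -> float:
    return _lgamma(n + 1) - _lgamma(k + 1) - _lgamma(n - k + 1)


def _log_hypergeom(k: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = k) for the table (k, r1-k; c1-k, r2-c1+k) given margins."""
    n = r1 + r2
    return (_log_comb(r1, k) + _log_comb(r2, c1 - k) - _log_comb(n, c1))


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Exact conditional two-sided p under the probability-mass rule.

    Sums hypergeometric probabilities of every table sharing the observed
    margins whose probability is <= the observed table's (up to a small
    relative tolerance for floating-point ties); log-space evaluation keeps
    extreme tables stable.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    log_obs = _log_hypergeom(a, r1, r2, c1)
    cutoff = log_obs + math.log1p(_TIE_REL_TOL)
    total = -math.inf
    for k in range(k_lo, k_hi + 1):
        lp = _log_hypergeom(k, r1, r2, c1)
        if lp <= cutoff:
            total = np.logaddexp(total, lp)
    return float(min(1.0, math.exp(total)))


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

def expression_report(measurements: Sequence[ExpressionMeasurement],
                      target_genes: Sequence[str], reference_gene: str,
                      path: str | Path,
                      calibrator_group: str = "wt") -> pd.DataFrame:
    """Fold changes per gene/group plus t tests of each mutant group's Ct
    values against wildtype; written as TSV and returned as a DataFrame."""
    by = {(m.gene, m.group): m for m in measurements}
    rows = []
    for gene in target_genes:
        folds = relative_expression(measurements, gene, reference_gene,
                                    calibrator_group)
        wt = by.get((gene, "wt"))
        for group, fold in folds.items():
            t = p = float("nan")
            if group != "wt" and wt is not None and len(wt.ct_values) >= 2:
                m = by[(gene, group)]
                if len(m.ct_values) >= 2:
                    t, p = student_t_test(m.ct_values, wt.ct_values)
            rows.append({"gene": gene, "group": group, "fold_change": fold,
                         "t": t, "p": p})
    df = pd.DataFrame(rows, columns=["gene", "group", "fold_change", "t", "p"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
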