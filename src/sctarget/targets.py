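"""Target-gene prioritization: candidate intersection and survival filtering.

Candidates are the intersection of differentially expressed genes with the
top genes of a metastasis-associated expression program.  Each candidate is
then scored on a cohort: expression is dichotomized at the median, the
high/low groups are compared by Kaplan-Meier/log-rank and univariate Cox
(Breslow ties), and a gene passes when it is hazardous (HR > 1, log-rank
p < 0.05) and up-regulated in tumors (log fold change > 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "intersect_candidates",
    "dichotomize",
    "km_curve",
    "logrank_test",
    "cox_univariate",
    "deg_filter",
    "rank_targets",
]


def intersect_candidates(deg_genes, program_top_genes) -> list[str]:
    """Exact, case-sensitive set intersection, returned sorted."""
    a, b = set(deg_genes), set(program_top_genes)
    if not a or not b:
        raise ValueError("both gene lists must be non-empty")
    return sorted(a & b)


def dichotomize(values, rule="median") -> np.ndarray:
    """Split values into 'high' (> cutoff) and 'low' (<= cutoff) groups.

    ``rule`` is 'median' or an explicit numeric cutoff; ties go to 'low'.
    Constant vectors are rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values")
    if np.ptp(v) == 0:
        raise ValueError("constant values cannot be dichotomized")
    cutoff = float(np.median(v)) if rule == "median" else float(rule)
    return np.where(v > cutoff, "high", "low")


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    t = table.copy()
    if (t["time"] <= 0).any():
        raise ValueError("times must be > 0")
    if not set(np.unique(t["event"])) <= {0, 1}:
        raise ValueError("event must be 0/1")
    return t


def km_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time (time, n_at_risk, n_events,
    survival); S(0) = 1 is implicit, censored subjects leave the risk set
    after their recorded time.
    """
    t = _check_table(table).sort_values("time")
    times = np.unique(t.loc[t["event"] == 1, "time"].to_numpy())
    rows = []
    s = 1.0
    all_t = t["time"].to_numpy()
    all_e = t["event"].to_numpy()
    for ti in times:
        at_risk = int((all_t >= ti).sum())
        d = int(((all_t == ti) & (all_e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((ti, at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_survival_at(curve: pd.DataFrame, t: float) -> float:
    """Evaluate a km_curve step function at time ``t``."""
    past = curve[curve["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(table: pd.DataFrame, group_col: str = "group") -> tuple[float, float]:
    """Two-group 1-df log-rank test over pooled event times.

    Returns (chi2, p); p = 1 when there are no events at all.
    """
    t = _check_table(table)
    groups = np.unique(t[group_col])
    if len(groups) != 2:
        raise ValueError("exactly 2 groups required")
    if (t.groupby(group_col).size() < 1).any():
        raise ValueError("both groups need >= 1 subject")
    times = np.unique(t.loc[t["event"] == 1, "time"].to_numpy())
    if times.size == 0:
        return 0.0, 1.0
    g1 = (t[group_col] == groups[0]).to_numpy()
    tt = t["time"].to_numpy()
    ee = t["event"].to_numpy()
    O1 = E1 = V = 0.0
    for ti in times:
        risk = tt >= ti
        n = risk.sum()
        n1 = (risk & g1).sum()
        d = int(((tt == ti) & (ee == 1)).sum())
        d1 = int(((tt == ti) & (ee == 1) & g1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = (O1 - E1) ** 2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    beta: float
    se: float
    converged: bool
    separated: bool = False


def cox_univariate(table: pd.DataFrame, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards fit for a binary/numeric covariate.

    Newton-Raphson on the partial likelihood with Breslow tie handling;
    HR = exp(beta) with a Wald 95% CI from the observed information.
    Monotone likelihood (complete separation) is flagged with an infinite CI
    bound rather than an error.
    """
    t = _check_table(table)
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != len(t):
        raise ValueError("covariate length must match table")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    if len(np.unique(x)) == 2:
        levels_events = [t["event"][x == v].sum() for v in np.unique(x)]
        if min(levels_events) < 1:
            raise ValueError("both covariate levels need >= 1 event")

    order = np.argsort(-t["time"].to_numpy(), kind="mergesort")
    tt = t["time"].to_numpy()[order]
    ee = t["event"].to_numpy()[order]
    xx = x[order]

    def newton(beta: float) -> tuple[float, float, float, bool]:
        for _ in range(50):
            w = np.exp(beta * xx)
            s0 = np.cumsum(w)
            s1 = np.cumsum(w * xx)
            s2 = np.cumsum(w * xx * xx)
            # risk set at event time tt[i] = all subjects with time >= tt[i];
            # with descending sort that is the prefix up to the last index
            # sharing tt[i]
            last = np.searchsorted(-tt, -tt, side="right") - 1
            ev = ee == 1
            r0, r1, r2 = s0[last][ev], s1[last][ev], s2[last][ev]
            U = float(np.sum(xx[ev] - r1 / r0))
            I = float(np.sum(r2 / r0 - (r1 / r0) ** 2))
            if I <= 0:
                return beta, np.inf, U, False
            step = U / I
            beta += step
            if abs(step) < 1e-8:
                return beta, 1.0 / np.sqrt(I), U, True
        return beta, 1.0 / np.sqrt(I), U, False

    beta, se, _, converged = newton(0.0)
    separated = not np.isfinite(se) or abs(beta) > 50
    if separated:
        hr = np.exp(np.sign(beta) * np.inf) if beta else 1.0
        lo, hi = (0.0, np.inf)
        return CoxResult(hr=float(hr), ci_low=lo, ci_high=hi, p=np.nan, beta=beta,
                         se=np.inf, converged=converged, separated=True)
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    return CoxResult(
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p=p,
        beta=float(beta),
        se=float(se),
        converged=converged,
    )


def deg_filter(deg_table: pd.DataFrame, padj_max: float = 0.01, min_abs_log_fc: float = 1.0) -> list[str]:
    """Generic DEG-list predicate: adjusted p < padj_max and |log2 FC| > min_abs_log_fc."""
    hit = deg_table[
        (deg_table["adjusted_p"] < padj_max) & (deg_table["log_fc"].abs() > min_abs_log_fc)
    ]
    return list(hit["gene_id"])


def rank_targets(
    candidates,
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    tumor_vs_normal_log_fc: pd.Series,
    deg_genes=None,
    program_genes=None,
    logrank_alpha: float = 0.05,
) -> pd.DataFrame:
    """Score each candidate gene on a bulk-like cohort and flag the passers.

    ``expression`` is subjects x genes aligned (by row order) with
    ``survival`` (columns time, event).  Per gene: expression is dichotomized
    at the median, log-rank and univariate Cox are run on high vs low, and
    ``pass`` requires membership in both input lists, HR > 1, log-rank
    p < ``logrank_alpha`` and tumor-vs-normal log FC > 0.  Sorted by
    log-rank p.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be non-empty")
    deg_genes = set(deg_genes) if deg_genes is not None else set(candidates)
    program_genes = set(program_genes) if program_genes is not None else set(candidates)
    rows = []
    for gene in candidates:
        rec = {
            "gene_id": gene,
            "in_deg": gene in deg_genes,
            "in_program": gene in program_genes,
            "km_logrank_p": np.nan,
            "cox_hr": np.nan,
            "cox_ci_low": np.nan,
            "cox_ci_high": np.nan,
            "tumor_vs_normal_log_fc": float(tumor_vs_normal_log_fc.get(gene, np.nan)),
            "pass": False,
        }
        if gene in expression.columns:
            try:
                groups = dichotomize(expression[gene].to_numpy())
            except ValueError:
                rows.append(rec)
                continue
            tab = survival.copy()
            tab["group"] = groups
            _, p = logrank_test(tab)
            cox = cox_univariate(tab, (groups == "high").astype(float))
            rec.update(
                km_logrank_p=p,
                cox_hr=cox.hr,
                cox_ci_low=cox.ci_low,
                cox_ci_high=cox.ci_high,
            )
            rec["pass"] = bool(
                rec["in_deg"]
                and rec["in_program"]
                and np.isfinite(cox.hr)
                and cox.hr > 1
                and p < logrank_alpha
                and rec["tumor_vs_normal_log_fc"] > 0
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out.sort_values("km_logrank_p", kind="mergesort").reset_index(drop=True)
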