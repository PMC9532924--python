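"""Responder labeling and group-comparison statistics.

Subjects are labeled from their seizure diary: the reduction fraction is
(baseline - followup)/baseline, and responder tiers are inclusive at the
1.0 / 0.8 / 0.5 thresholds (R100, R80, R50); anything below 50 % reduction
is NR50. The binary analysis label is R50 vs NR50.

Group comparisons mirror routine clinical reporting: Mann-Whitney U for
continuous covariates, chi-square or Fisher's exact for nominal ones, and
— for the synchronization features — Mann-Whitney per band with
Benjamini-Hochberg FDR correction applied within each metric across the
five tested bands (the combined beta band is extracted as a model feature
but excluded from testing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .recording import TESTED_BANDS
from .simulate import SeizureDiary

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class ResponderLabel:
    """Finest responder tier plus the raw reduction fraction."""

    category: str  # R100 | R80 | R50 | NR50
    reduction_fraction: float

    @property
    def responder(self) -> bool:
        """Binary analysis label: R50-level responder or better."""
        return self.category != "NR50"


def label_responder(diary: SeizureDiary) -> ResponderLabel:
    """Label a subject from the seizure diary (thresholds inclusive)."""
    if diary.baseline_freq <= 0:
        raise ValueError("baseline seizure frequency must be positive")
    reduction = (diary.baseline_freq - diary.followup_freq) / diary.baseline_freq
    if reduction >= 1.0:
        category = "R100"
    elif reduction >= 0.8:
        category = "R80"
    elif reduction >= 0.5:
        category = "R50"
    else:
        category = "NR50"
    return ResponderLabel(category=category, reduction_fraction=float(reduction))


def ks_normality(values: np.ndarray) -> float:
    """One-sample KS p-value against a normal with the sample mean/SD.

    Note the Lilliefors caveat: estimating the parameters from the same
    sample makes this p-value conservative relative to a true composite
    normality test; it is used here only as a descriptive screen.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input has no distribution to test")
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def mann_whitney_u(x, y, two_sided: bool = True) -> tuple[float, float]:
    """Mann-Whitney U with exact enumeration for small samples.

    Exact when the pooled sample size is <= 12 and tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided" if two_sided else "greater",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_or_fisher(table) -> tuple[str, float]:
    """Chi-square (no continuity correction) or Fisher's exact for a 2 x k table.

    Fisher's exact is used for 2 x 2 tables with any expected cell count
    below 5; larger sparse tables fall back to chi-square with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("need a 2 x k contingency table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    expected = sps.contingency.expected_freq(t)
    if (expected < 5).any():
        if t.shape == (2, 2):
            return "fisher", float(sps.fisher_exact(t).pvalue)
        warnings.warn(
            "expected cell count < 5 in a 2 x k (k > 2) table; "
            "chi-square may be unreliable", stacklevel=2)
    res = sps.chi2_contingency(t, correction=False)
    return "chi_square", float(res.pvalue)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GroupComparisonResult:
    """One row of a group-comparison report."""

    variable: str
    band: str | None
    group_summary: dict
    test: str
    statistic: float | None
    p_raw: float
    p_adjusted: float | None
    significant: bool


def compare_sync_by_group(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    metric: str,
    bands=TESTED_BANDS,
    alpha: float = ALPHA_DEFAULT,
) -> list[GroupComparisonResult]:
    """Per-band responder vs non-responder comparison of one metric.

    Mann-Whitney per band; BH-FDR across the tested bands of this metric
    (one FDR family per metric). ``feature_table`` columns are named
    ``{metric}_{band}``; ``labels`` is boolean (True = responder).
    Emits mean +/- SD per group per band.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    raw_p, rows = [], []
    for band in bands:
        col = f"{metric}_{band}"
        v = feature_table[col].to_numpy(dtype=float)
        r, nr = v[labels], v[~labels]
        U, p = mann_whitney_u(r, nr)
        raw_p.append(p)
        rows.append((band, U, p, r, nr))
    adj = fdr_bh(raw_p)
    out = []
    for (band, U, p, r, nr), pa in zip(rows, adj):
        out.append(GroupComparisonResult(
            variable=metric, band=band,
            group_summary={
                "responder_mean": float(r.mean()), "responder_sd": float(r.std(ddof=1)),
                "nonresponder_mean": float(nr.mean()), "nonresponder_sd": float(nr.std(ddof=1)),
            },
            test="mann_whitney_u", statistic=U, p_raw=p,
            p_adjusted=float(pa), significant=bool(pa < alpha),
        ))
    return out


def compare_sync_all_metrics(
    feature_table: pd.DataFrame,
    labels: np.ndarray,
    metrics=("plv", "pli", "wpli"),
    bands=TESTED_BANDS,
    alpha: float = ALPHA_DEFAULT,
) -> pd.DataFrame:
    """Band x metric comparison table (per-metric FDR families)."""
    rows = []
    for m in metrics:
        for r in compare_sync_by_group(feature_table, labels, m, bands, alpha):
            rows.append({
                "metric": m, "band": r.band,
                **r.group_summary,
                "U": r.statistic, "p_raw": r.p_raw, "p_fdr": r.p_adjusted,
                "significant": r.significant,
            })
    return pd.DataFrame(rows)


CONTINUOUS_CLINICAL = (
    "seizure_frequency", "bmi", "diastolic_pressure", "pulse_pressure",
    "age_onset", "epilepsy_duration", "age_implantation",
    "n_asm_baseline", "n_asm_historical",
)
BINARY_CLINICAL = ("gender", "prior_surgery", "benzodiazepine_use")
CATEGORICAL_CLINICAL = {
    "etiology": ("structural", "genetic", "autoimmune", "unknown"),
    "syndrome": ("infantile_spasms", "LGS", "EOEE", "unclassified"),
    "mri": ("local", "multifocal", "negative"),
}
MULTIHOT_CLINICAL = {"seizure_types": ("generalized", "focal", "spasms", "multiple")}


def compare_clinical_by_group(
    clinical_table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
) -> list[GroupComparisonResult]:
    """Baseline-covariate comparison between responders and non-responders.

    Continuous covariates use Mann-Whitney; nominal ones use chi-square or
    Fisher's exact on the 2 x k group-by-category counts. No multiplicity
    correction is applied (descriptive baseline table). Degenerate
    single-category variables are skipped with a warning.
    """
    labels = np.asarray(labels, dtype=bool)
    results: list[GroupComparisonResult] = []

    for var in CONTINUOUS_CLINICAL:
        if var not in clinical_table:
            continue
        v = clinical_table[var].to_numpy(dtype=float)
        r, nr = v[labels], v[~labels]
        U, p = mann_whitney_u(r, nr)
        results.append(GroupComparisonResult(
            variable=var, band=None,
            group_summary={
                "responder_mean": float(r.mean()), "responder_sd": float(r.std(ddof=1)),
                "nonresponder_mean": float(nr.mean()), "nonresponder_sd": float(nr.std(ddof=1)),
            },
            test="mann_whitney_u", statistic=U, p_raw=p, p_adjusted=None,
            significant=bool(p < alpha)))

    def nominal(var: str, table: np.ndarray, counts: dict) -> None:
        informative = [j for j in range(table.shape[1]) if table[:, j].sum() > 0]
        if len(informative) < 2:
            warnings.warn(f"{var}: fewer than two observed categories; skipped", stacklevel=2)
            return
        test, p = chi_square_or_fisher(table[:, informative])
        results.append(GroupComparisonResult(
            variable=var, band=None, group_summary=counts, test=test,
            statistic=None, p_raw=p, p_adjusted=None, significant=bool(p < alpha)))

    for var in BINARY_CLINICAL:
        if var not in clinical_table:
            continue
        v = clinical_table[var]
        if var == "gender":
            pos = (v.astype(str).str.lower() == "male").to_numpy()
        else:
            pos = v.astype(bool).to_numpy()
        table = np.array([
            [int(pos[labels].sum()), int((~pos[labels]).sum())],
            [int(pos[~labels].sum()), int((~pos[~labels]).sum())],
        ])
        nominal(var, table, {"responder": table[0].tolist(), "nonresponder": table[1].tolist()})

    for var, cats in CATEGORICAL_CLINICAL.items():
        if var not in clinical_table:
            continue
        v = clinical_table[var].astype(str)
        table = np.array([
            [int((v[labels] == c).sum()) for c in cats],
            [int((v[~labels] == c).sum()) for c in cats],
        ])
        nominal(var, table, {"categories": list(cats),
                             "responder": table[0].tolist(),
                             "nonresponder": table[1].tolist()})

    for var, cats in MULTIHOT_CLINICAL.items():
        if var not in clinical_table:
            continue
        sets = clinical_table[var].map(
            lambda s: set(s.split("|")) if isinstance(s, str) else set(s))
        table = np.array([
            [int(sum(c in s for s in sets[labels])) for c in cats],
            [int(sum(c in s for s in sets[~labels])) for c in cats],
        ])
        # categories are non-exclusive; the 2 x k test treats type counts
        # as independent tallies, matching descriptive clinical tables
        nominal(var, table, {"categories": list(cats),
                             "responder": table[0].tolist(),
                             "nonresponder": table[1].tolist()})
    return results
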