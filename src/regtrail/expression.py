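"""Two-group differential expression scores and RIF regulator statistics.

The differential-expression scores cover the standard effect-size measures
(log fold change on log-scale input, z-score, signal-to-noise ratio), the
classical location tests (Welch t, paired t, Wilcoxon rank-sum and
signed-rank, both reported as z-like statistics), and a shrinkage t-statistic
that stabilizes per-gene variances by shrinking them toward the median
variance across genes — the regularization of choice for small sample sizes.

The regulatory impact factors RIF1 and RIF2 quantify, for each regulator,
how strongly its co-expression with a set of differentially expressed (DE)
genes changes between two conditions. With e1j/e2j the mean expression of DE
gene j in case/control, r1ij/r2ij the within-group Pearson correlations of
regulator i with gene j, and PIFj = 0.5 (e1j + e2j)(e1j - e2j):

    RIF1_i = (1/n_de) * sum_j PIFj * (r1ij - r2ij)^2
    RIF2_i = (1/n_de) * sum_j [ (e1j * r1ij)^2 - (e2j * r2ij)^2 ]

Both columns are z-standardized across regulators. A regulator whose mean
within-group correlation with the DE genes is positive is called activating,
otherwise repressing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InputError, NumericalError
from .io import ExpressionMatrix

DE_METHODS = (
    "log2_fold_change", "zscore", "snr", "t_independent", "t_dependent",
    "wilcoxon_ranksum", "wilcoxon_signed", "shrinkage_t",
)


@dataclass(frozen=True)
class GroupDesign:
    case_samples: tuple[str, ...]
    control_samples: tuple[str, ...]
    paired: bool = False

    def __post_init__(self):
        if set(self.case_samples) & set(self.control_samples):
            raise InputError("case and control samples must be disjoint")
        if not self.case_samples or not self.control_samples:
            raise InputError("both groups must be non-empty")
        if self.paired and len(self.case_samples) != len(self.control_samples):
            raise InputError("paired design requires equally sized groups")

    @classmethod
    def from_matrix(cls, expr: ExpressionMatrix, paired: bool = False) -> "GroupDesign":
        if expr.groups is None:
            raise InputError("expression matrix carries no group assignment")
        case = tuple(s for s in expr.sample_ids if expr.groups.get(s) == "case")
        control = tuple(s for s in expr.sample_ids if expr.groups.get(s) == "control")
        return cls(case, control, paired)


@dataclass
class DEScoreTable:
    """Per-gene differential expression scores, one row per gene."""

    table: pd.DataFrame  # columns: gene_id, score, note
    method: str

    def scores(self) -> pd.Series:
        return self.table.set_index("gene_id")["score"]


def _split(expr: ExpressionMatrix, design: GroupDesign) -> tuple[np.ndarray, np.ndarray]:
    missing = (set(design.case_samples) | set(design.control_samples)) - set(expr.sample_ids)
    if missing:
        raise InputError(f"design samples not in matrix: {sorted(missing)}")
    case = expr.values[list(design.case_samples)].to_numpy(float)
    control = expr.values[list(design.control_samples)].to_numpy(float)
    return case, control


def _pooled_var(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    n1, n2 = case.shape[1], control.shape[1]
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    return ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)


def _shrinkage_t(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """t with per-gene pooled variances shrunk toward their median.

    The shrinkage weight is the usual plug-in optimum
    lambda* = min(1, sum_g Var^(v_g) / sum_g (v_g - v_median)^2), with the
    variance of each empirical variance estimated by the standard unbiased
    moment estimator applied to the pooled within-group centered data.
    """
    n1, n2 = case.shape[1], control.shape[1]
    v = _pooled_var(case, control)
    v_median = np.median(v)
    # centered observations pooled across groups
    z = np.concatenate(
        [case - case.mean(axis=1, keepdims=True),
         control - control.mean(axis=1, keepdims=True)], axis=1
    )
    n = n1 + n2
    w = z ** 2
    w_bar = w.mean(axis=1)
    var_of_v = n / (n - 1) ** 3 * ((w - w_bar[:, None]) ** 2).sum(axis=1)
    denom = ((v - v_median) ** 2).sum()
    lam = 1.0 if denom == 0 else min(1.0, var_of_v.sum() / denom)
    v_star = lam * v_median + (1 - lam) * v
    se = np.sqrt(v_star * (1 / n1 + 1 / n2))
    diff = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return diff / se


def _ranksum_z(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Wilcoxon rank-sum statistic standardized with tie-corrected variance."""
    n1, n2 = case.shape[1], control.shape[1]
    n = n1 + n2
    out = np.empty(case.shape[0])
    for g in range(case.shape[0]):
        combined = np.concatenate([case[g], control[g]])
        ranks = stats.rankdata(combined)
        w = ranks[:n1].sum()
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n - 1) * n)
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        out[g] = 0.0 if var == 0 else (w - mu) / np.sqrt(var)
    return out


def _signed_rank_z(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Signed-rank z on paired differences; zero differences are dropped."""
    out = np.empty(case.shape[0])
    for g in range(case.shape[0]):
        d = case[g] - control[g]
        d = d[d != 0]
        if d.size == 0:
            out[g] = 0.0
            continue
        ranks = stats.rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        m = d.size
        mu = m * (m + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - ((tie_counts ** 3 - tie_counts).sum()) / 48.0
        out[g] = 0.0 if var <= 0 else (w_plus - mu) / np.sqrt(var)
    return out


def de_score(expr: ExpressionMatrix, design: GroupDesign, method: str) -> DEScoreTable:
    """Per-gene two-group differential-expression scores.

    Genes whose score is undefined (zero pooled spread for ``zscore``/``snr``)
    are reported with a NaN score and an explanatory note rather than being
    dropped. Fold change assumes log-scale input, so it is the plain mean
    difference.
    """
    if method not in DE_METHODS:
        raise InputError(f"unknown DE method {method!r}; choose from {DE_METHODS}")
    case, control = _split(expr, design)
    n1, n2 = case.shape[1], control.shape[1]
    if method in ("zscore", "snr", "t_independent", "shrinkage_t") and min(n1, n2) < 2:
        raise InputError(f"{method} requires >= 2 samples per group")
    if method in ("t_dependent", "wilcoxon_signed") and not design.paired:
        raise InputError(f"{method} requires a paired design")

    diff = case.mean(axis=1) - control.mean(axis=1)
    notes = np.full(case.shape[0], "", dtype=object)

    if method == "log2_fold_change":
        score = diff
    elif method == "zscore":
        sd = np.sqrt(_pooled_var(case, control))
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(sd > 0, diff / sd, np.nan)
        notes[sd == 0] = "undefined: zero pooled standard deviation"
    elif method == "snr":
        denom = case.std(axis=1, ddof=1) + control.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(denom > 0, diff / denom, np.nan)
        notes[denom == 0] = "undefined: zero within-group spread"
    elif method == "t_independent":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = stats.ttest_ind(case, control, axis=1, equal_var=False).statistic
        score = np.where(np.isfinite(score), score, np.nan)
        notes[~np.isfinite(score)] = "undefined: zero variance in both groups"
    elif method == "t_dependent":
        with np.errstate(divide="ignore", invalid="ignore"):
            score = stats.ttest_rel(case, control, axis=1).statistic
        bad = ~np.isfinite(score)
        d = case - control
        same = (d.std(axis=1, ddof=1) == 0) & (d.mean(axis=1) == 0)
        score = np.where(same, 0.0, score)
        notes[bad & ~same] = "undefined: constant nonzero paired differences"
    elif method == "wilcoxon_ranksum":
        score = _ranksum_z(case, control)
    elif method == "wilcoxon_signed":
        score = _signed_rank_z(case, control)
    else:  # shrinkage_t
        score = _shrinkage_t(case, control)
        bad = ~np.isfinite(score)
        score = np.where(bad & (diff == 0), 0.0, score)
        notes[~np.isfinite(score)] = "undefined: zero shrunk variance"

    table = pd.DataFrame(
        {"gene_id": expr.gene_ids, "score": score, "note": notes}
    )
    return DEScoreTable(table, method)


def select_regulated(
    scores: DEScoreTable,
    mode: str = "upper_tail",
    cutoff: float | None = None,
    top_k: int | None = None,
) -> list[str]:
    """Select up- or down-regulated genes by score cutoff or top-k.

    ``upper_tail`` keeps scores strictly above the cutoff (or the k largest),
    ``lower_tail`` the mirror image. Ties in top-k selection break by gene ID
    so the result is deterministic. Undefined (NaN) scores never qualify.
    """
    if mode not in ("upper_tail", "lower_tail"):
        raise InputError(f"unknown selection mode {mode!r}")
    if (cutoff is None) == (top_k is None):
        raise InputError("give exactly one of cutoff or top_k")
    tbl = scores.table.dropna(subset=["score"])
    if top_k is not None:
        if top_k < 1:
            raise InputError("top_k must be >= 1")
        ascending = mode == "lower_tail"
        ordered = tbl.sort_values(
            ["score", "gene_id"], ascending=[ascending, True]
        )
        selected = ordered["gene_id"].head(top_k).tolist()
    else:
        if mode == "upper_tail":
            selected = tbl.loc[tbl["score"] > cutoff, "gene_id"].tolist()
        else:
            selected = tbl.loc[tbl["score"] < cutoff, "gene_id"].tolist()
    if not selected:
        raise InputError(
            "selection is empty; relax the cutoff or reduce top_k"
        )
    return selected


@dataclass(frozen=True)
class RIFResult:
    regulator: str
    rif1_raw: float
    rif2_raw: float
    rif1_z: float
    rif2_z: float
    n_de: int
    direction: str  # activating | repressing


def _zstandardize(x: np.ndarray) -> np.ndarray:
    if x.size < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def rif_scores(
    expr: ExpressionMatrix,
    design: GroupDesign,
    regulators,
    de_genes,
) -> list[RIFResult]:
    """Regulatory impact factors for each regulator against a DE gene set.

    Within-group Pearson correlations require at least 3 samples per group.
    Regulators with zero variance in either group are skipped with a warning;
    z-standardization is over the reported regulators only.
    """
    regulators = list(dict.fromkeys(regulators))
    de_genes = list(dict.fromkeys(de_genes))
    if not de_genes:
        raise InputError("no DE genes supplied")
    gene_set = set(expr.gene_ids)
    missing_r = [r for r in regulators if r not in gene_set]
    if missing_r:
        raise InputError(f"regulators not in expression matrix: {missing_r[:10]}")
    missing_g = [g for g in de_genes if g not in gene_set]
    if missing_g:
        raise InputError(f"DE genes not in expression matrix: {missing_g[:10]}")
    case, control = _split(expr, design)
    if case.shape[1] < 3 or control.shape[1] < 3:
        raise InputError("RIF needs >= 3 samples per group for correlations")

    idx = {g: i for i, g in enumerate(expr.gene_ids)}
    gi = [idx[g] for g in de_genes]
    e1 = case[gi].mean(axis=1)
    e2 = control[gi].mean(axis=1)
    pif = 0.5 * (e1 + e2) * (e1 - e2)

    def _corr(block: np.ndarray, rows_a: list[int], rows_b: list[int]) -> np.ndarray:
        a = block[rows_a]
        b = block[rows_b]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac ** 2).sum(axis=1))[:, None] * np.sqrt((bc ** 2).sum(axis=1))[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ac @ bc.T) / denom

    kept: list[str] = []
    ri = []
    for r in regulators:
        row = idx[r]
        if case[row].std() == 0 or control[row].std() == 0:
            warnings.warn(
                f"regulator {r} has zero variance in a group; skipped", stacklevel=2
            )
            continue
        kept.append(r)
        ri.append(row)
    if not kept:
        raise NumericalError("no regulator with nonzero variance in both groups")

    r1 = _corr(case, ri, gi)      # regulators x de genes
    r2 = _corr(control, ri, gi)
    # a DE gene constant within a group has undefined correlation; treat as 0
    r1 = np.nan_to_num(r1, nan=0.0)
    r2 = np.nan_to_num(r2, nan=0.0)

    n_de = len(de_genes)
    rif1 = (pif[None, :] * (r1 - r2) ** 2).mean(axis=1)
    rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)
    rif1_z = _zstandardize(rif1)
    rif2_z = _zstandardize(rif2)
    mean_corr = ((r1 + r2) / 2.0).mean(axis=1)

    return [
        RIFResult(
            reg, float(rif1[i]), float(rif2[i]), float(rif1_z[i]), float(rif2_z[i]),
            n_de, "activating" if mean_corr[i] > 0 else "repressing",
        )
        for i, reg in enumerate(kept)
    ]
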