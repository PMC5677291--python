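"""Classifier evaluation and feature statistics.

Within-subject leave-one-out cross-validation over the epoch feature
table, (C, gamma) grid search for the kernel ELM, confusion matrices in
row-percentage form, and the one-way ANOVA / Tukey HSD statistics used
to compare features across the three stress sessions.

The LOOCV protocol holds out one epoch at a time within each subject
(170 folds per subject for default-length sessions); features are
re-standardized on each training fold so no test statistics leak in.
Grid-search model selection deliberately reuses the same LOOCV that
reports accuracy — the protocol being replicated selects hyperparameters
on the evaluation folds, which is optimistic; a nested variant is
available for honest generalization estimates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .features import FEATURE_SETS, META_COLUMNS
from .kelm import KERNELS
from .signals import SESSIONS

log = logging.getLogger(__name__)

#: The standard 15-point decade grid used for both C and gamma.
PAPER_GRID = tuple(10.0 ** k for k in range(-8, 7))
#: C grid with one extra decade (1e7), where the integrated feature set's
#: reported optimum lies.
EXTENDED_C_GRID = PAPER_GRID + (1e7,)


def feature_set_slice(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Subset the table to one feature set: HRV (15), SC (6), SKT (3), IT (24)."""
    if which not in FEATURE_SETS:
        raise InvalidArgumentError(
            f"unknown feature set {which!r}; choose from {sorted(FEATURE_SETS)}")
    return table[META_COLUMNS + FEATURE_SETS[which]]


@dataclass
class ConfusionMatrix:
    """5x5 session-classification counts (rows true, columns predicted)."""

    counts: np.ndarray
    labels: tuple = SESSIONS

    @property
    def percent(self) -> np.ndarray:
        """Row-normalized view in percent; rows sum to 100."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / sums
        return np.where(sums > 0, out, 0.0)

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent (trace over total)."""
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else np.nan

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.percent if percent else self.counts
        return pd.DataFrame(data, index=self.labels, columns=self.labels)


@dataclass
class LOOCVResult:
    confusion: ConfusionMatrix
    per_subject_accuracy: dict
    n_folds: int
    excluded_folds: int = 0

    @property
    def mean_accuracy(self) -> float:
        """Epoch-weighted cohort accuracy in percent."""
        return self.confusion.accuracy

    @property
    def subject_mean_accuracy(self) -> float:
        """Subject-weighted cohort accuracy in percent."""
        return float(np.mean(list(self.per_subject_accuracy.values())))


def _split_xy(table: pd.DataFrame, feature_cols):
    X = table[feature_cols].to_numpy(dtype=float)
    y = table["session"].to_numpy()
    return X, y


def _fold_standardize(X: np.ndarray, train_idx: np.ndarray):
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def _loocv_correct_grid(X: np.ndarray, y: np.ndarray, C_grid, gamma_grid,
                        kernel: str = "rbf",
                        standardize_folds: bool = True) -> np.ndarray:
    """Boolean array (n_folds, nC, ngamma): fold correctness per cell.

    Distances are recomputed per fold (standardization uses training rows
    only) but shared across all grid cells, and each kernel matrix is
    shared across the C axis, which makes the full grid cheap.
    """
    n = X.shape[0]
    classes, y_idx = np.unique(y, return_inverse=True)
    T_full = np.eye(len(classes))[y_idx]
    correct = np.zeros((n, len(C_grid), len(gamma_grid)), dtype=bool)
    for i in range(n):
        tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Xs = _fold_standardize(X, tr) if standardize_folds else X
        Xtr, xq = Xs[tr], Xs[i:i + 1]
        T = T_full[tr]
        if kernel == "rbf":
            sq_tr = np.sum(Xtr ** 2, axis=1)
            D2 = np.maximum(sq_tr[:, None] + sq_tr[None, :]
                            - 2.0 * Xtr @ Xtr.T, 0.0)
            d2q = np.maximum(np.sum(xq ** 2) + sq_tr - 2.0 * (Xtr @ xq[0]), 0.0)
        for gi, gamma in enumerate(gamma_grid):
            if kernel == "rbf":
                omega = np.exp(-gamma * D2)
                kq = np.exp(-gamma * d2q)
            else:
                omega = KERNELS[kernel](Xtr, Xtr, gamma)
                kq = KERNELS[kernel](xq, Xtr, gamma)[0]
            for ci, C in enumerate(C_grid):
                try:
                    alpha = np.linalg.solve(
                        np.eye(n - 1) / C + omega, T)
                except np.linalg.LinAlgError:
                    alpha, *_ = np.linalg.lstsq(
                        np.eye(n - 1) / C + omega, T, rcond=None)
                pred = int(np.argmax(kq @ alpha))
                correct[i, ci, gi] = (pred == y_idx[i])
    return correct


def loocv(table: pd.DataFrame, C: float = 1e3, gamma: float = 0.1,
          kernel: str = "rbf", feature_set: str = "IT",
          standardize_folds: bool = True) -> LOOCVResult:
    """Within-subject LOOCV of a kernel ELM at fixed hyperparameters.

    Each subject contributes one fold per epoch row; confusion counts are
    pooled over subjects, so the percent view is the epoch-weighted
    cohort matrix. Per-subject accuracies are also returned for the
    subject-weighted summary.
    """
    cols = FEATURE_SETS[feature_set]
    labels = list(SESSIONS)
    lab_index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    per_subject = {}
    n_folds = excluded = 0
    for subject, sub in table.groupby("subject", sort=True):
        X, y = _split_xy(sub, cols)
        classes = np.unique(y)
        if X.shape[0] < 2 or len(classes) < 2:
            log.warning("subject %s skipped: too few rows/classes", subject)
            continue
        sub_correct = 0
        n = X.shape[0]
        for i in range(n):
            tr = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            if len(np.unique(y[tr])) < len(classes):
                excluded += 1
                log.warning("fold %d of %s excluded: class missing in "
                            "training split", i, subject)
                continue
            Xs = _fold_standardize(X, tr) if standardize_folds else X
            omega = KERNELS[kernel](Xs[tr], Xs[tr], gamma)
            yc, y_idx = np.unique(y[tr], return_inverse=True)
            T = np.eye(len(yc))[y_idx]
            alpha = np.linalg.solve(np.eye(n - 1) / C + omega, T)
            kq = KERNELS[kernel](Xs[i:i + 1], Xs[tr], gamma)
            pred = yc[int(np.argmax(kq @ alpha))]
            counts[lab_index[y[i]], lab_index[pred]] += 1
            n_folds += 1
            sub_correct += int(pred == y[i])
        per_subject[subject] = 100.0 * sub_correct / n
    return LOOCVResult(ConfusionMatrix(counts, tuple(labels)), per_subject,
                       n_folds, excluded)


@dataclass
class GridResult:
    C_grid: tuple
    gamma_grid: tuple
    accuracy: np.ndarray          # percent, shape (nC, ngamma)
    best_C: float = field(init=False)
    best_gamma: float = field(init=False)

    def __post_init__(self) -> None:
        best = np.max(self.accuracy)
        # ties resolve to the smallest C, then the smallest gamma
        ci, gi = np.argwhere(self.accuracy == best)[0]
        self.best_C = self.C_grid[ci]
        self.best_gamma = self.gamma_grid[gi]

    @property
    def best_accuracy(self) -> float:
        return float(np.max(self.accuracy))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, C in enumerate(self.C_grid):
            for gi, g in enumerate(self.gamma_grid):
                rows.append({"C": C, "gamma": g,
                             "accuracy": self.accuracy[ci, gi]})
        return pd.DataFrame(rows)


def grid_search(table: pd.DataFrame, C_grid=PAPER_GRID,
                gamma_grid=PAPER_GRID, feature_set: str = "IT",
                kernel: str = "rbf",
                standardize_folds: bool = True) -> GridResult:
    """Mean within-subject LOOCV accuracy over a (C, gamma) grid.

    The returned surface is the subject-mean accuracy in percent for
    every grid cell; the argmax is the selected operating point.
    """
    C_grid = tuple(sorted(C_grid))
    gamma_grid = tuple(sorted(gamma_grid))
    if not C_grid or not gamma_grid:
        raise InvalidArgumentError("grids must be non-empty")
    cols = FEATURE_SETS[feature_set]
    per_subject = []
    for _, sub in table.groupby("subject", sort=True):
        X, y = _split_xy(sub, cols)
        correct = _loocv_correct_grid(X, y, C_grid, gamma_grid, kernel,
                                      standardize_folds)
        per_subject.append(correct.mean(axis=0) * 100.0)
    return GridResult(C_grid, gamma_grid,
                      np.mean(per_subject, axis=0))


# ---------------------------------------------------------------------------
# Feature statistics across the three stress sessions.

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    infinite: bool = False


@dataclass
class TukeyResult:
    pairs: list                  # dicts: i, j, mean_diff, q, p_adj
    ms_within: float
    df_within: int


def one_way_anova(groups) -> AnovaResult:
    """Classic one-way ANOVA decomposition.

    F is the between-group mean square over the within-group mean square;
    degenerate data (zero within-group variance, unequal means) reports
    an infinite-capped F with a flag rather than dividing by zero.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise InvalidArgumentError("need >= 2 groups with >= 2 values each")
    n_tot = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    dfb = len(groups) - 1
    dfw = n_tot - len(groups)
    msb = ss_between / dfb
    msw = ss_within / dfw
    if msw == 0:
        if msb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0)
        return AnovaResult(np.inf, dfb, dfw, 0.0, infinite=True)
    F = msb / msw
    return AnovaResult(float(F), dfb, dfw, float(stats.f.sf(F, dfb, dfw)))


def tukey_hsd(groups) -> TukeyResult:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Requires equal group sizes. The q statistic for groups i, j is
    ``|mean_i - mean_j| / sqrt(MS_within / n)`` and adjusted p-values come
    from the studentized range distribution with k groups and the ANOVA
    within degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = {g.size for g in groups}
    if len(sizes) != 1:
        raise InvalidArgumentError(
            "Tukey's HSD requires equal group sizes")
    n = groups[0].size
    k = len(groups)
    anova = one_way_anova(groups)
    msw = sum(np.sum((g - g.mean()) ** 2) for g in groups) / anova.df_within
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            if msw > 0:
                q = abs(diff) / np.sqrt(msw / n)
                p = float(stats.studentized_range.sf(q, k, anova.df_within))
            else:
                q, p = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
            pairs.append({"i": i, "j": j, "mean_diff": float(diff),
                          "q": float(q), "p_adj": p})
    return TukeyResult(pairs, float(msw), anova.df_within)


def anova_table(table: pd.DataFrame, feature: str,
                sessions=("MIS-S", "MOS-S", "SES-S")) -> AnovaResult:
    """One-way ANOVA of one feature across the given sessions (pooled epochs)."""
    groups = [table.loc[table["session"] == s, feature].to_numpy()
              for s in sessions]
    return one_way_anova(groups)


# ---------------------------------------------------------------------------
# Questionnaire summaries.

def _round_half_up(x: float, decimals: int) -> float:
    f = 10.0 ** decimals
    return float(np.floor(np.abs(x) * f + 0.5) / f * np.sign(x))


def questionnaire_stats(csv_path=None) -> pd.DataFrame:
    """Means and sample SDs of the packaged questionnaire-score table.

    The fixture holds each subject's age and per-session state-anxiety
    (STAI Y-1) and visual-analogue stress (VAS) scores. Returns a frame
    with raw ``mean``/``sd`` rows and half-up-rounded ``mean_1dp`` /
    ``sd_2dp`` report rows.
    """
    if csv_path is None:
        from importlib.resources import files
        csv_path = files("stresskit.data") / "questionnaire_scores.csv"
    df = pd.read_csv(csv_path)
    num = df.select_dtypes("number")
    if num.empty:
        raise InvalidArgumentError("no numeric columns in questionnaire CSV")
    out = pd.DataFrame({
        "mean": num.mean(),
        "sd": num.std(ddof=1),
    }).T
    out.loc["mean_1dp"] = [_round_half_up(v, 1) for v in out.loc["mean"]]
    out.loc["sd_2dp"] = [_round_half_up(v, 2) for v in out.loc["sd"]]
    return out
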