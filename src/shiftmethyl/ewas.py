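"""Paired epigenome-wide analysis with a group-specific vacation-effect model.

For each probe *j* the methylation value of sample *i* is modelled as

    y_i = (1 - h_i) * b_swd + h_i * b_ctrl
        + (1 - h_i) * v_i * b_vac_swd + h_i * v_i * b_vac_ctrl
        + D_i . b_D + e_i

where ``h_i`` is 1 for a control subject and 0 for an SWD subject, ``v_i``
is 1 for a vacation sample and 0 for a work sample, and ``D_i`` holds
nuisance covariates (age continuous; sex, plate, alcohol, smoking as
reference-coded indicators).  Coefficients are estimated by ordinary least
squares with iid Gaussian errors — deliberately *without* a subject-level
pairing term; the simulator's ``subject_intercept_sd`` knob exists to
quantify the consequence of that assumption.

Four null hypotheses are tested per probe with nested-model variance-ratio
(F) tests:

* ``swd``   — no vacation effect in the SWD group (drop the SWD x vacation
  column; 1 df),
* ``ctrl``  — no vacation effect in the control group (1 df),
* ``either``— no effect in either group (drop both columns; joint 2-df test),
* ``both``  — the union null "no effect in at least one group", evaluated by
  the intersection-union construction ``p_both = max(p_swd, p_ctrl)``.

P-values are adjusted per hypothesis family across probes with the
Benjamini-Hochberg step-up procedure.  A positive vacation-minus-work
coefficient means methylation was *gained* on vacation, i.e. the probe was
hypomethylated during work.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ContractError, DesignError, FitError

logger = logging.getLogger(__name__)

GROUP_SWD = "swd"
GROUP_CONTROL = "control"
PERIOD_WORK = "work"
PERIOD_VACATION = "vacation"

HYPO_AT_WORK = "hypo_at_work"
HYPER_AT_WORK = "hyper_at_work"
NO_DIRECTION = "none"

#: Fixed leading columns of every design matrix, in order.
BASE_COLUMNS = ("intercept_swd", "intercept_ctrl", "vacation_swd", "vacation_ctrl")

HYPOTHESES = ("swd", "ctrl", "either", "both")

_RSS_TOL = 1e-12


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignMatrix:
    """A full-rank design matrix with named columns.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_columns)
    columns : tuple of str
        Column names; the first four are always :data:`BASE_COLUMNS`.
    rank : int
        Numerical rank (equals ``len(columns)`` after pruning).
    dropped : tuple of str
        Nuisance columns pruned for being constant or collinear.
    """

    values: np.ndarray
    columns: tuple
    rank: int
    dropped: tuple = ()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def drop_columns(self, names: Sequence[str]) -> "DesignMatrix":
        """Return a sub-design with the named columns removed (nested model)."""
        idx = [self.column_index(n) for n in names]
        keep = [i for i in range(len(self.columns)) if i not in idx]
        values = self.values[:, keep]
        return DesignMatrix(
            values=values,
            columns=tuple(self.columns[i] for i in keep),
            rank=int(np.linalg.matrix_rank(values)),
            dropped=self.dropped,
        )


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series)


def build_design(sheet: pd.DataFrame, covariates: Sequence[str] = ()) -> DesignMatrix:
    """Build the group-specific vacation design matrix from a sample sheet.

    Parameters
    ----------
    sheet : DataFrame
        One row per sample, with at least ``group`` (``swd``/``control``) and
        ``period`` (``work``/``vacation``) columns plus any requested
        covariates.  Row order defines sample order.
    covariates : sequence of str
        Nuisance covariate columns.  Numeric columns enter as-is; categorical
        columns are reference-coded with the lexicographically first level as
        reference.  Constant or collinear columns are pruned with a warning.

    Raises
    ------
    DesignError
        If a group x period cell is empty or a covariate column is missing.
    """
    for required in ("group", "period"):
        if required not in sheet.columns:
            raise DesignError(f"sample sheet lacks required column {required!r}")
    group = sheet["group"].astype(str)
    period = sheet["period"].astype(str)
    bad_group = sorted(set(group) - {GROUP_SWD, GROUP_CONTROL})
    if bad_group:
        raise DesignError(f"unknown group labels: {bad_group}")
    bad_period = sorted(set(period) - {PERIOD_WORK, PERIOD_VACATION})
    if bad_period:
        raise DesignError(f"unknown period labels: {bad_period}")
    for g in (GROUP_SWD, GROUP_CONTROL):
        for p in (PERIOD_WORK, PERIOD_VACATION):
            if not ((group == g) & (period == p)).any():
                raise DesignError(f"empty design cell: group={g!r}, period={p!r}")

    h = (group == GROUP_CONTROL).to_numpy(dtype=float)
    v = (period == PERIOD_VACATION).to_numpy(dtype=float)
    cols = [1.0 - h, h, (1.0 - h) * v, h * v]
    names = list(BASE_COLUMNS)

    candidates: list[tuple[str, np.ndarray]] = []
    for cov in covariates:
        if cov not in sheet.columns:
            raise DesignError(f"covariate column {cov!r} missing from sample sheet")
        series = sheet[cov]
        if series.isna().any():
            raise DesignError(f"covariate {cov!r} contains missing values")
        if _is_numeric(series):
            candidates.append((cov, series.to_numpy(dtype=float)))
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) == 1:
                # single-level factor carries no contrast at all
                candidates.append((f"{cov}[{levels[0]}]", np.ones(len(series))))
                continue
            for level in levels[1:]:  # first level is the reference
                candidates.append(
                    (f"{cov}[{level}]", (series.astype(str) == level).to_numpy(dtype=float))
                )

    X = np.column_stack(cols)
    rank = int(np.linalg.matrix_rank(X))
    dropped: list[str] = []
    for name, col in candidates:
        if np.ptp(col) == 0:
            logger.warning("design column %r is constant; pruned", name)
            dropped.append(name)
            continue
        trial = np.column_stack([X, col])
        trial_rank = int(np.linalg.matrix_rank(trial))
        if trial_rank <= rank:
            logger.warning("design column %r is collinear; pruned", name)
            dropped.append(name)
            continue
        X, rank = trial, trial_rank
        names.append(name)

    return DesignMatrix(values=X, columns=tuple(names), rank=rank, dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# per-probe fitting and testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeFit:
    """An OLS fit of one probe: coefficients, RSS and residual df."""

    coefficients: np.ndarray
    columns: tuple
    rss: float
    df_resid: int
    rank: int

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.columns.index(name)])


def fit_probe(y: np.ndarray, X: DesignMatrix) -> ProbeFit:
    """Fit one probe by ordinary least squares.

    Raises
    ------
    ContractError
        If ``y`` does not match the design's sample count or is non-finite.
    FitError
        If no residual degrees of freedom remain.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.n_samples:
        raise ContractError(
            f"y has length {y.shape[0] if y.ndim == 1 else y.shape}, design has "
            f"{X.n_samples} samples"
        )
    if not np.all(np.isfinite(y)):
        raise ContractError("y contains non-finite values; handle missing values upstream")
    df_resid = X.n_samples - X.rank
    if df_resid <= 0:
        raise FitError(f"no residual degrees of freedom (n={X.n_samples}, rank={X.rank})")
    beta, _, _, _ = np.linalg.lstsq(X.values, y, rcond=None)
    resid = y - X.values @ beta
    rss = float(resid @ resid)
    return ProbeFit(coefficients=beta, columns=X.columns, rss=rss, df_resid=df_resid, rank=X.rank)


def f_test(fit_full: ProbeFit, fit_null: ProbeFit) -> float:
    """Variance-ratio test of a null model nested inside a full model.

    ``F = ((RSS_null - RSS_full)/ddf) / (RSS_full/df_full)`` with the p-value
    from the upper tail of the F distribution.

    Raises
    ------
    ContractError
        If the null model is not nested in the full model.
    """
    ddf = fit_null.df_resid - fit_full.df_resid
    if ddf <= 0:
        raise ContractError("null model is not nested in the full model (no df difference)")
    if fit_null.rss < fit_full.rss - max(_RSS_TOL, _RSS_TOL * fit_full.rss):
        raise ContractError("null RSS is below full RSS; models are not nested")
    if fit_full.rss <= 0.0:
        warnings.warn("full model fits exactly (RSS=0); F test degenerate", stacklevel=2)
        return 0.0 if fit_null.rss > _RSS_TOL else 1.0
    num = max(fit_null.rss - fit_full.rss, 0.0) / ddf
    den = fit_full.rss / fit_full.df_resid
    return float(stats.f.sf(num / den, ddf, fit_full.df_resid))


def test_probe_hypotheses(y: np.ndarray, X: DesignMatrix) -> tuple:
    """Return ``(p_swd, p_ctrl, p_either, p_both)`` for one probe.

    ``p_swd``/``p_ctrl`` drop one vacation column each (1-df F tests),
    ``p_either`` drops both (2-df joint test), and ``p_both`` is the
    intersection-union ``max(p_swd, p_ctrl)``.
    """
    fit_full = fit_probe(y, X)
    p_swd = f_test(fit_full, fit_probe(y, X.drop_columns(["vacation_swd"])))
    p_ctrl = f_test(fit_full, fit_probe(y, X.drop_columns(["vacation_ctrl"])))
    p_either = f_test(fit_full, fit_probe(y, X.drop_columns(["vacation_swd", "vacation_ctrl"])))
    return p_swd, p_ctrl, p_either, max(p_swd, p_ctrl)


def classify_direction(beta_vw: float) -> str:
    """Label a vacation-minus-work coefficient.

    A positive coefficient means methylation was gained on vacation, so the
    probe was hypomethylated during work; a negative coefficient the mirror
    image; exactly zero is unclassified.
    """
    if not np.isfinite(beta_vw):
        raise ContractError("direction undefined for non-finite coefficient")
    if beta_vw > 0:
        return HYPO_AT_WORK
    if beta_vw < 0:
        return HYPER_AT_WORK
    return NO_DIRECTION


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, monotone).

    Raises
    ------
    ContractError
        If any p-value lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ContractError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# percentage reporting rules
# ---------------------------------------------------------------------------

_EPS = 1e-9


def percent_one_decimal(numerator: float, denominator: float):
    """Percentage truncated (not rounded) to one decimal place.

    This is the convention used for the headline DMP fractions in
    :func:`summarize_ewas` (e.g. 28,419/433,479 reports as 6.5, not 6.6).
    Returns ``None`` for an empty denominator.
    """
    if denominator == 0:
        return None
    return math.floor(1000.0 * numerator / denominator + _EPS) / 10.0


def percent_integer(numerator: float, denominator: float):
    """Percentage rounded half-up to an integer; ``None`` if denominator is 0."""
    if denominator == 0:
        return None
    return int(math.floor(100.0 * numerator / denominator + 0.5 + _EPS))


# ---------------------------------------------------------------------------
# cohort-level scan
# ---------------------------------------------------------------------------

#: Output columns of :func:`run_ewas`, in order.
RESULT_COLUMNS = (
    "mean_swd", "mean_ctrl", "beta_vacation_swd", "beta_vacation_ctrl",
    "p_swd", "p_ctrl", "p_either", "p_both",
    "q_swd", "q_ctrl", "q_either", "q_both",
    "direction_swd", "direction_ctrl", "dmp_swd", "dmp_ctrl",
)


def _residual_ss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y against design X (via QR)."""
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def _empty_result() -> pd.DataFrame:
    table = pd.DataFrame({c: pd.Series(dtype=float) for c in RESULT_COLUMNS})
    for c in ("direction_swd", "direction_ctrl"):
        table[c] = table[c].astype(object)
    for c in ("dmp_swd", "dmp_ctrl"):
        table[c] = table[c].astype(bool)
    table.index.name = "probe_id"
    return table


def run_ewas(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = (),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan every probe of a methylome matrix with the four-hypothesis model.

    Parameters
    ----------
    matrix : DataFrame, probes x samples
        M-values (or beta-values, at the caller's discretion) with probe ids
        as index and sample ids as columns.
    sheet : DataFrame
        Sample sheet whose ``sample_id`` column (or index) matches the matrix
        columns one-to-one.
    covariates : sequence of str
        Nuisance covariates passed to :func:`build_design`.
    alpha : float
        Unadjusted significance threshold defining the per-group DMP flags.

    Returns
    -------
    DataFrame
        One row per retained probe with :data:`RESULT_COLUMNS`.  Probes with
        zero variance, or with too few complete observations after removing
        missing values, are skipped (aggregated in a log message).  BH
        q-values are computed within each hypothesis family across the
        retained probes.

    Raises
    ------
    AlignmentError
        If matrix columns and sheet samples do not match one-to-one.
    """
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    sheet_ids = list(sheet.index.astype(str))
    matrix_ids = list(matrix.columns.astype(str))
    missing_in_sheet = sorted(set(matrix_ids) - set(sheet_ids))
    missing_in_matrix = sorted(set(sheet_ids) - set(matrix_ids))
    if missing_in_sheet or missing_in_matrix or len(sheet_ids) != len(set(sheet_ids)):
        raise AlignmentError(
            "matrix/sheet sample mismatch; "
            f"matrix-only={missing_in_sheet}, sheet-only={missing_in_matrix}"
        )
    sheet = sheet.loc[matrix_ids]

    design = build_design(sheet, covariates)
    if matrix.shape[0] == 0:
        return _empty_result()

    Y = matrix.to_numpy(dtype=float).T  # samples x probes
    probe_ids = matrix.index.to_numpy()

    complete = np.all(np.isfinite(Y), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN probes
        span = np.nanmax(Y, axis=0) - np.nanmin(Y, axis=0)
    nonconstant = np.nan_to_num(span) > 0
    vec_mask = complete & nonconstant

    n_probes = Y.shape[1]
    p_swd = np.full(n_probes, np.nan)
    p_ctrl = np.full(n_probes, np.nan)
    p_either = np.full(n_probes, np.nan)
    betas = np.full((n_probes, len(design.columns)), np.nan)
    skipped: dict[str, int] = {"zero_variance": 0, "too_few_observations": 0}

    if vec_mask.any():
        Yv = Y[:, vec_mask]
        X = design.values
        i_vs = design.column_index("vacation_swd")
        i_vc = design.column_index("vacation_ctrl")
        rss_full = _residual_ss(X, Yv)
        rss_no_swd = _residual_ss(np.delete(X, i_vs, axis=1), Yv)
        rss_no_ctrl = _residual_ss(np.delete(X, i_vc, axis=1), Yv)
        rss_no_both = _residual_ss(np.delete(X, [i_vs, i_vc], axis=1), Yv)
        df_full = design.n_samples - design.rank
        if df_full <= 0:
            raise FitError(f"no residual degrees of freedom (rank={design.rank})")
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = rss_full / df_full
            f1 = np.maximum(rss_no_swd - rss_full, 0.0) / scale
            f2 = np.maximum(rss_no_ctrl - rss_full, 0.0) / scale
            f3 = (np.maximum(rss_no_both - rss_full, 0.0) / 2.0) / scale
        p_swd[vec_mask] = stats.f.sf(f1, 1, df_full)
        p_ctrl[vec_mask] = stats.f.sf(f2, 1, df_full)
        p_either[vec_mask] = stats.f.sf(f3, 2, df_full)
        coef, _, _, _ = np.linalg.lstsq(X, Yv, rcond=None)
        betas[vec_mask] = coef.T

    skipped["zero_variance"] = int((complete & ~nonconstant).sum())

    # probes with missing values: complete-case refit, one at a time
    for j in np.nonzero(~complete)[0]:
        y = Y[:, j]
        keep = np.isfinite(y)
        if not keep.any() or np.ptp(y[keep]) == 0:
            skipped["zero_variance"] += 1
            continue
        sub_sheet = sheet.loc[np.asarray(keep)]
        try:
            sub_design = build_design(sub_sheet, covariates)
        except DesignError:
            skipped["too_few_observations"] += 1
            continue
        if keep.sum() < sub_design.rank + 2:
            skipped["too_few_observations"] += 1
            continue
        try:
            ps, pc, pe, _ = test_probe_hypotheses(y[keep], sub_design)
        except FitError:
            skipped["too_few_observations"] += 1
            continue
        p_swd[j], p_ctrl[j], p_either[j] = ps, pc, pe
        fit = fit_probe(y[keep], sub_design)
        for name in BASE_COLUMNS:
            betas[j, design.column_index(name)] = fit.coef(name)

    retained = np.isfinite(p_swd)
    n_skipped = int((~retained).sum())
    if n_skipped:
        logger.info(
            "skipped %d/%d probes (%s)", n_skipped, n_probes,
            ", ".join(f"{k}={v}" for k, v in skipped.items() if v),
        )

    idx = probe_ids[retained]
    table = pd.DataFrame(index=pd.Index(idx, name="probe_id"))
    table["mean_swd"] = betas[retained, design.column_index("intercept_swd")]
    table["mean_ctrl"] = betas[retained, design.column_index("intercept_ctrl")]
    table["beta_vacation_swd"] = betas[retained, design.column_index("vacation_swd")]
    table["beta_vacation_ctrl"] = betas[retained, design.column_index("vacation_ctrl")]
    table["p_swd"] = p_swd[retained]
    table["p_ctrl"] = p_ctrl[retained]
    table["p_either"] = p_either[retained]
    table["p_both"] = np.maximum(p_swd[retained], p_ctrl[retained])
    for hyp in HYPOTHESES:
        table[f"q_{hyp}"] = bh_adjust(table[f"p_{hyp}"].to_numpy())
    table["direction_swd"] = [classify_direction(b) for b in table["beta_vacation_swd"]]
    table["direction_ctrl"] = [classify_direction(b) for b in table["beta_vacation_ctrl"]]
    table["dmp_swd"] = table["p_swd"] < alpha
    table["dmp_ctrl"] = table["p_ctrl"] < alpha
    return table[list(RESULT_COLUMNS)]


def summarize_ewas(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Headline per-group counts and percentages from an EWAS result table.

    For each group reports the probe count, the DMP count and percentage
    (one decimal, truncated), the count/percentage of probes hypomethylated
    during work overall (integer percent, rounded), and the count/percentage
    hypomethylated among DMPs.  Percentages with an empty denominator are
    reported as ``None``.
    """
    if table.shape[0] == 0:
        raise ContractError("cannot summarize an empty result table")
    summary: dict = {"alpha": alpha, "n_probes": int(table.shape[0])}
    for group, p_col, d_col in (
        (GROUP_SWD, "p_swd", "direction_swd"),
        (GROUP_CONTROL, "p_ctrl", "direction_ctrl"),
    ):
        n = int(table.shape[0])
        dmp = table[p_col] < alpha
        hypo = table[d_col] == HYPO_AT_WORK
        n_dmp = int(dmp.sum())
        n_hypo = int(hypo.sum())
        n_hypo_dmp = int((dmp & hypo).sum())
        summary[group] = {
            "n_probes": n,
            "n_dmp": n_dmp,
            "pct_dmp": percent_one_decimal(n_dmp, n),
            "n_hypo": n_hypo,
            "pct_hypo": percent_integer(n_hypo, n),
            "n_hypo_dmp": n_hypo_dmp,
            "pct_hypo_dmp": percent_integer(n_hypo_dmp, n_dmp),
        }
    return summary


def qq_points(p: Sequence[float]) -> tuple:
    """Expected vs observed -log10 p-values for a quantile-quantile plot.

    The k-th smallest observed p is paired with the uniform quantile
    ``(k - 0.5) / n``; both are returned on the -log10 scale.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ContractError("qq_points requires at least one p-value")
    observed = np.sort(p)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return -np.log10(expected), -np.log10(observed)
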