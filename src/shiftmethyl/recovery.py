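"""Post-hoc recovery statistics and global profile embedding.

Change scores are differences of the work measurement minus the vacation
measurement, for both questionnaire symptoms and per-probe M-values, so a
positive symptom change means more symptoms while working and a negative
methylation change means methylation was gained on vacation.  Spearman
correlations between the two changes are computed across SWD subjects, with
an exact permutation p-value for very small n and the t approximation
otherwise.  A one-way work-period ANOVA compares groups at single probes,
and a t-SNE embedding gives per-sample 2-D coordinates of global profiles.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .ewas import bh_adjust

logger = logging.getLogger(__name__)

RECOVERY_LABELS = ("poor", "recovered", "well")

#: Below this many pairs the Spearman p-value is computed by exact
#: enumeration of all rank permutations; at or above it, by the t
#: approximation (safe for cohort-scale n).
EXACT_PERMUTATION_MAX_N = 10


# ---------------------------------------------------------------------------
# change scores
# ---------------------------------------------------------------------------

def change_symptoms(a_work, b_work, a_vacation, b_vacation):
    """``(A + B)_work - (A + B)_vacation``; ``None`` if any answer is missing."""
    values = (a_work, b_work, a_vacation, b_vacation)
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return None
    return int(a_work + b_work) - int(a_vacation + b_vacation)


def subject_symptom_scores(sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-subject symptom answers and change score from a paired sheet.

    Subjects missing any answer are excluded with a log entry.  Columns:
    ``group, a_work, b_work, a_vacation, b_vacation, change_symptoms``.
    """
    rows = {}
    for subject, sub in sheet.groupby("subject", sort=False):
        by_period = sub.set_index(sub["period"].astype(str))
        if not {"work", "vacation"}.issubset(by_period.index):
            logger.info("subject %s lacks a paired sample; excluded", subject)
            continue
        record = {
            "group": str(sub["group"].iloc[0]),
            "a_work": by_period.loc["work", "answer_a"],
            "b_work": by_period.loc["work", "answer_b"],
            "a_vacation": by_period.loc["vacation", "answer_a"],
            "b_vacation": by_period.loc["vacation", "answer_b"],
        }
        score = change_symptoms(
            record["a_work"], record["b_work"],
            record["a_vacation"], record["b_vacation"],
        )
        if score is None:
            logger.info("subject %s has missing answers; excluded", subject)
            continue
        record["change_symptoms"] = score
        rows[subject] = record
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject"
    return out


def methylation_change(matrix: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe ``M_work - M_vacation`` for every paired subject.

    Returns a probes x subjects DataFrame; subjects without both periods are
    skipped.
    """
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    cols = {}
    for subject, sub in sheet.groupby("subject", sort=False):
        periods = dict(zip(sub["period"].astype(str), sub.index.astype(str)))
        if not {"work", "vacation"}.issubset(periods):
            continue
        cols[subject] = matrix[periods["work"]] - matrix[periods["vacation"]]
    return pd.DataFrame(cols, index=matrix.index)


def assign_recovery_groups(
    scores: pd.Series,
    thresholds: tuple | None = None,
) -> pd.Series:
    """Label change scores as poor / recovered / well.

    With explicit ``thresholds=(lo, hi)``: score <= lo is poor, score <= hi
    is recovered, above hi is well (ties always fall to the lower group).
    Without thresholds the 1/3 and 2/3 quantiles of the scores are used; a
    higher change score means better recovery.  If all scores are identical
    in tertile mode, everyone is labelled ``recovered`` with a warning.
    """
    if thresholds is None:
        if scores.size < 3:
            raise ContractError("tertile mode needs at least 3 subjects")
        if scores.nunique() == 1:
            logger.warning("all change scores identical; single recovery group")
            return pd.Series("recovered", index=scores.index)
        lo, hi = np.quantile(scores.to_numpy(dtype=float), [1 / 3, 2 / 3])
    else:
        lo, hi = thresholds
        if not lo <= hi:
            raise ContractError("recovery thresholds must satisfy lo <= hi")
    labels = np.where(scores <= lo, "poor", np.where(scores <= hi, "recovered", "well"))
    return pd.Series(labels, index=scores.index)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple:
    """Spearman r with a two-sided exact permutation p (small n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    zx = rx - rx.mean()
    zy = ry - ry.mean()
    denom = math.sqrt(float(zx @ zx) * float(zy @ zy))
    r_obs = float(zx @ zy) / denom
    n = x.size
    perms = np.array(list(itertools.permutations(range(n))))
    r_perm = (zy[perms] @ zx) / denom
    p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return r_obs, p


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Spearman correlation with an n-appropriate two-sided p-value.

    Uses exact permutation enumeration below
    :data:`EXACT_PERMUTATION_MAX_N` pairs and the t approximation otherwise.
    Returns ``(nan, nan)`` when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("spearman needs two equal-length vectors")
    if x.size < 3:
        raise ContractError("spearman needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    if x.size < EXACT_PERMUTATION_MAX_N:
        return _spearman_exact(x, y)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlate_recovery(
    changes: pd.DataFrame,
    scores: pd.Series,
    probes: Iterable[str] | None = None,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Correlate per-probe methylation change with symptom change.

    Parameters
    ----------
    changes : DataFrame, probes x subjects
        Output of :func:`methylation_change` restricted to the subjects of
        interest (typically SWD only).
    scores : Series
        ``change_symptoms`` per subject.
    probes : iterable of str, optional
        Probe subset (e.g. the DMPs of a pathway); defaults to all rows.
    annotation : DataFrame, optional
        If given, a ``gene`` column is joined from its semicolon gene lists.

    Returns
    -------
    DataFrame with columns ``probe_id, gene, n, r, p, q`` sorted by p;
    BH adjustment runs across the tested probe set.  Probes with zero
    variance in either vector get missing r/p/q.
    """
    subjects = [s for s in changes.columns if s in scores.index]
    if len(subjects) < 4:
        raise ContractError(f"need >= 4 subjects with both scores, have {len(subjects)}")
    y = scores.loc[subjects].to_numpy(dtype=float)
    probe_list = list(changes.index if probes is None else probes)
    gene_of = {}
    if annotation is not None:
        from .pathways import probe_gene_map
        gene_of = {p: ";".join(g) for p, g in probe_gene_map(annotation).items()}
    rows = []
    for pid in probe_list:
        x = changes.loc[pid, subjects].to_numpy(dtype=float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() >= 4:
            r, p = spearman(x[mask], y[mask])
        else:
            r, p = float("nan"), float("nan")
        rows.append({
            "probe_id": pid,
            "gene": gene_of.get(str(pid), ""),
            "n": int(mask.sum()),
            "r": r,
            "p": p,
        })
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out.sort_values(["p", "probe_id"], kind="mergesort", na_position="last").reset_index(drop=True)


# ---------------------------------------------------------------------------
# work-period ANOVA
# ---------------------------------------------------------------------------

def work_period_anova(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    probes: Iterable[str] | None = None,
    grouping: str = "group",
    labels: pd.Series | None = None,
) -> pd.DataFrame:
    """One-way ANOVA of work-period methylation across a grouping factor.

    ``grouping`` names a sample-sheet column (default ``group``: SWD vs
    control); alternatively pass per-subject ``labels`` (e.g. recovery
    groups, with controls keeping their sheet label) to build the factor.
    Returns ``probe_id, F, p, q, note`` with BH across tested probes.
    Probes where any group degenerates get a missing entry and a note.
    """
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    work = sheet[sheet["period"].astype(str) == "work"]
    if labels is not None:
        factor = work["subject"].map(labels).fillna(work[grouping].astype(str))
    else:
        if grouping not in work.columns:
            raise ContractError(f"sample sheet lacks grouping column {grouping!r}")
        factor = work[grouping].astype(str)
    level_counts = factor.value_counts()
    if len(level_counts) < 2:
        raise ContractError("ANOVA needs at least 2 groups")
    if (level_counts < 2).any():
        small = level_counts[level_counts < 2].index.tolist()
        raise ContractError(f"groups with fewer than 2 work samples: {small}")
    sample_ids = list(work.index.astype(str))
    probe_list = list(matrix.index if probes is None else probes)
    rows = []
    for pid in probe_list:
        values = matrix.loc[pid, sample_ids].to_numpy(dtype=float)
        groups = [values[(factor == level).to_numpy()] for level in level_counts.index]
        groups = [g[np.isfinite(g)] for g in groups]
        if any(g.size < 2 for g in groups):
            rows.append({"probe_id": pid, "F": np.nan, "p": np.nan,
                         "note": "group with <2 observations"})
            continue
        grand = np.concatenate(groups)
        ssb = sum(g.size * (g.mean() - grand.mean()) ** 2 for g in groups)
        ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
        df_b = len(groups) - 1
        df_w = grand.size - len(groups)
        if ssw <= 0.0:
            rows.append({"probe_id": pid, "F": np.nan, "p": np.nan,
                         "note": "zero within-group variance"})
            continue
        F = (ssb / df_b) / (ssw / df_w)
        rows.append({"probe_id": pid, "F": float(F),
                     "p": float(stats.f.sf(F, df_b, df_w)), "note": ""})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# global profile embedding
# ---------------------------------------------------------------------------

def embed_global_profiles(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    perplexity: float = 10.0,
    iterations: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE coordinates of every sample's global methylation profile.

    Requires ``n_samples > 3 * perplexity``.  Deterministic given the seed
    (PCA initialisation).  Probes with any missing value are dropped before
    embedding.  The output carries subject/group/period so paired samples
    can be connected downstream.
    """
    if "sample_id" in sheet.columns:
        sheet = sheet.set_index("sample_id")
    n_samples = matrix.shape[1]
    if n_samples <= 3 * perplexity:
        raise ContractError(
            f"perplexity {perplexity} too large for {n_samples} samples; "
            f"use a value below {n_samples / 3:.1f}"
        )
    from sklearn.manifold import TSNE

    X = matrix.to_numpy(dtype=float).T
    finite = np.all(np.isfinite(X), axis=0)
    X = X[:, finite]
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max(int(iterations), 250),
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    ids = list(matrix.columns.astype(str))
    meta = sheet.loc[ids]
    return pd.DataFrame({
        "sample_id": ids,
        "subject": meta["subject"].to_list(),
        "group": meta["group"].astype(str).to_list(),
        "period": meta["period"].astype(str).to_list(),
        "x": coords[:, 0],
        "y": coords[:, 1],
    })


def summarize_recovery(results: pd.DataFrame, alpha: float = 0.05, n_top: int = 5) -> dict:
    """Counts of recovery-correlated probes below alpha, with top hits."""
    if results.shape[0] == 0:
        return {"alpha": alpha, "n_tested": 0, "n_p_below": 0, "n_q_below": 0, "top": []}
    tested = results["p"].notna()
    below_p = results.loc[tested & (results["p"] < alpha)]
    below_q = results.loc[tested & (results["q"] < alpha)]
    top = results.loc[tested].nsmallest(n_top, "p")
    return {
        "alpha": alpha,
        "n_tested": int(tested.sum()),
        "n_p_below": int(below_p.shape[0]),
        "n_q_below": int(below_q.shape[0]),
        "top": [
            {
                "probe_id": str(row.probe_id),
                "gene": str(row.gene),
                "r": float(row.r),
                "p": float(row.p),
                "q": float(row.q),
            }
            for row in top.itertuples()
        ],
    }
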