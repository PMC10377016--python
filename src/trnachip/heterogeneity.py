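"""Cross-tumour heterogeneity statistics.

Tumours differ widely in which individual tRNA genes carry H3K27ac, yet the
summed activity of a tRNA family is far more consistent — rank correlations
between tumour pairs rise as signal is aggregated from genes to isoacceptor
families to isotypes (family-level buffering). This module computes those
pairwise Spearman correlations at each hierarchy level, per-sample signal
totals and their fold range, a binary active/inactive classification, and
primary-vs-metastatic group comparisons (Student's t with optional
Benjamini–Hochberg adjustment).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FamilyLevel
from .families import AggregatedMatrix, aggregate
from .quantify import SignalMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Rank correlation
# ---------------------------------------------------------------------------

def spearman(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
) -> tuple[float, int]:
    """Spearman rank correlation on pairwise-complete observations.

    Ties receive average ranks. Returns ``(rho, n_complete)``. Raises if
    fewer than 3 complete pairs remain; a zero-variance ranked vector gives
    ``rho = nan`` (undefined, reported as missing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >=3 complete pairs for Spearman, got {n}")
    xs, ys = x[ok], y[ok]
    if np.unique(xs).size == 1 or np.unique(ys).size == 1:
        log.warning("spearman: zero variance in a ranked vector; rho undefined")
        return float("nan"), n
    rho = stats.spearmanr(xs, ys).statistic
    return float(rho), n


def _to_frame(matrix: SignalMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, SignalMatrix) else matrix


def correlation_hierarchy(
    matrix: SignalMatrix | pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    levels: Sequence[FamilyLevel | str] = ("gene", "isoacceptor", "isotype"),
) -> pd.DataFrame:
    """Pairwise Spearman rho between samples at each hierarchy level.

    The matrix is aggregated once per level (missing cells omitted from the
    family sums) and rho is computed per sample pair on pairwise-complete
    rows. ``pairs=None`` uses all unordered column pairs. Returns a long
    table (sample_a, sample_b, level, rho, n).
    """
    frame = _to_frame(matrix)
    if pairs is None:
        pairs = list(itertools.combinations(frame.columns, 2))
    rows = []
    for level in levels:
        lvl = FamilyLevel.coerce(level)
        agg = aggregate(frame, lvl, missing_policy="omit")
        for a, b in pairs:
            rho, n = spearman(agg.values[a], agg.values[b])
            rows.append(
                {"sample_a": a, "sample_b": b, "level": lvl.name, "rho": rho, "n": n}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample totals and activity classification
# ---------------------------------------------------------------------------

@dataclass
class SampleTotals:
    totals: pd.Series
    fold_range: float
    max_sample: str
    min_sample: str


def sample_totals(matrix: SignalMatrix | pd.DataFrame) -> SampleTotals:
    """Per-sample total signal over non-missing cells, and the max/min fold
    range across samples (e.g. the strongest tumour being several-fold
    stronger than the weakest)."""
    frame = _to_frame(matrix)
    if frame.isna().all().any():
        bad = list(frame.columns[frame.isna().all()])
        raise ValueError(f"sample(s) with no non-missing cells: {bad}")
    totals = frame.sum(skipna=True)
    min_sample, max_sample = totals.idxmin(), totals.idxmax()
    if totals[min_sample] == 0:
        log.warning("sample_totals: minimum total is 0; fold range is infinite")
        fold = float("inf")
    else:
        fold = float(totals[max_sample] / totals[min_sample])
    return SampleTotals(totals=totals, fold_range=fold,
                        max_sample=str(max_sample), min_sample=str(min_sample))


@dataclass
class ActivityMatrix:
    """Units × samples boolean activity calls (pd.NA where signal missing)."""

    values: pd.DataFrame
    rule: str


def classify_activity(
    matrix: SignalMatrix | pd.DataFrame,
    rule: Literal["per_sample_median", "global_quantile", "fixed_threshold"] = "per_sample_median",
    q: float | None = None,
    tau: float | None = None,
) -> ActivityMatrix:
    """Binarize signal into relatively active / inactive loci.

    ``per_sample_median`` (default) marks a cell active when it is >= its
    sample's median across genes — ties at the median count as active, so an
    even-length column of distinct values is split exactly in half.
    ``global_quantile`` thresholds at the q-quantile of all non-missing
    values; ``fixed_threshold`` at tau. Cells with missing signal stay
    undefined; an all-missing sample column is left entirely undefined.
    """
    frame = _to_frame(matrix)
    arr = frame.to_numpy(dtype=float)
    if rule == "per_sample_median":
        with np.errstate(all="ignore"):
            med = np.nanmedian(np.where(np.isnan(arr), np.nan, arr), axis=0)
        thresh = np.broadcast_to(med, arr.shape)
        rule_desc = "per_sample_median"
    elif rule == "global_quantile":
        if q is None or not (0 < q < 1):
            raise ValueError("global_quantile needs q in (0, 1)")
        thresh = np.full(arr.shape, np.nanquantile(arr, q))
        rule_desc = f"global_quantile(q={q})"
    elif rule == "fixed_threshold":
        if tau is None or tau < 0:
            raise ValueError("fixed_threshold needs tau >= 0")
        thresh = np.full(arr.shape, tau)
        rule_desc = f"fixed_threshold(tau={tau})"
    else:
        raise ValueError(f"unknown activity rule {rule!r}")
    calls = pd.DataFrame(
        arr >= thresh, index=frame.index, columns=frame.columns
    ).astype("boolean")
    calls = calls.mask(frame.isna())
    return ActivityMatrix(values=calls, rule=rule_desc)


# ---------------------------------------------------------------------------
# Group profiles and comparisons
# ---------------------------------------------------------------------------

def _resolve_groups(
    matrix_cols: Sequence[str],
    groups: Mapping[str, Iterable[str]] | Mapping[str, str],
) -> dict[str, list[str]]:
    """Accept either {label: [sample_ids]} or {sample_id: label}."""
    vals = list(groups.values())
    if vals and isinstance(vals[0], str):
        out: dict[str, list[str]] = {}
        for sample, label in groups.items():  # type: ignore[assignment]
            out.setdefault(str(label), []).append(str(sample))
    else:
        out = {str(k): [str(s) for s in v] for k, v in groups.items()}
    known = set(matrix_cols)
    for label, samples in out.items():
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ValueError(f"group {label!r} references unknown samples {unknown}")
    return out


def group_average_profile(
    matrix: SignalMatrix | pd.DataFrame,
    groups: Mapping[str, Iterable[str]] | Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene mean signal per sample group (e.g. primary vs metastatic).

    Returns ``(means, effective_n)``; means are over non-missing cells only.
    """
    frame = _to_frame(matrix)
    resolved = _resolve_groups(frame.columns, groups)
    means = pd.DataFrame(index=frame.index)
    eff_n = pd.DataFrame(index=frame.index)
    for label, samples in resolved.items():
        sub = frame[samples]
        means[label] = sub.mean(axis=1, skipna=True)
        eff_n[label] = sub.notna().sum(axis=1)
    return means, eff_n


def fdr_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (NaN-tolerant)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def compare_groups(
    matrix: SignalMatrix | pd.DataFrame,
    groups: Mapping[str, Iterable[str]] | Mapping[str, str],
    test: Literal["student_t", "welch"] = "student_t",
    adjust: Literal["none", "benjamini_hochberg"] = "benjamini_hochberg",
) -> pd.DataFrame:
    """Two-group per-unit comparison with Student's t-test.

    The default is the classical equal-variance two-sample t-test with a
    two-sided p; ``welch`` relaxes the equal-variance assumption. Units with
    fewer than 2 non-missing values in either group are reported missing
    with a reason; two identical constant groups give t = 0, p = 1. The
    adjusted q-value (Benjamini–Hochberg over the tested units) is reported
    alongside the raw p, which remains the primary output.
    """
    frame = _to_frame(matrix)
    resolved = _resolve_groups(frame.columns, groups)
    if len(resolved) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(resolved)}")
    (label_a, cols_a), (label_b, cols_b) = resolved.items()
    equal_var = test == "student_t"
    if test not in {"student_t", "welch"}:
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for unit in frame.index:
        a = frame.loc[unit, cols_a].to_numpy(dtype=float)
        b = frame.loc[unit, cols_b].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        row = {
            "unit": unit,
            f"mean_{label_a}": a.mean() if a.size else np.nan,
            f"mean_{label_b}": b.mean() if b.size else np.nan,
            "n_a": a.size, "n_b": b.size,
            "t": np.nan, "p": np.nan, "reason": None,
        }
        if a.size < 2 or b.size < 2:
            row["reason"] = "insufficient n"
        elif a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
            row["t"], row["p"] = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=equal_var)
            row["t"], row["p"] = float(res.statistic), float(res.pvalue)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("unit")
    if adjust == "benjamini_hochberg":
        table["q"] = fdr_bh(table["p"].to_numpy())
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


# ---------------------------------------------------------------------------
# Heat-map rendering
# ---------------------------------------------------------------------------

def plot_heatmap(
    matrix: SignalMatrix | AggregatedMatrix | pd.DataFrame,
    path: str,
    log_scale: bool = True,
    missing_color: str = "0.6",
    title: str | None = None,
) -> None:
    """Render a units × samples heat map; missing cells are drawn grey."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(matrix, (SignalMatrix, AggregatedMatrix)):
        frame = matrix.values
    else:
        frame = matrix
    data = frame.to_numpy(dtype=float)
    if log_scale:
        with np.errstate(divide="ignore"):
            data = np.log1p(data)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * frame.shape[1]), max(4, 0.02 * frame.shape[0]))
    )
    cmap = plt.get_cmap("coolwarm").copy()
    cmap.set_bad(missing_color)
    im = ax.imshow(np.ma.masked_invalid(data), aspect="auto", cmap=cmap,
                   interpolation="nearest")
    ax.set_xticks(range(frame.shape[1]))
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("sample")
    ax.set_ylabel(f"{frame.shape[0]} units")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log1p signal" if log_scale else "signal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
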