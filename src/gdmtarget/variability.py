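"""Observer-variability experiment logic and summary statistics.

The registration chain is manual in clinical practice, so its output
varies within one observer (intra) and between observers (inter).  The
experiment design: each of two observers repeats the triple registration
three times per patient.  Intra-observer variability compares the three
repeats of one observer pairwise ({(1,2),(1,3),(2,3)} → 3 comparisons per
observer, 6 per patient); inter-observer variability compares every repeat
of observer 1 with every repeat of observer 2 (3×3 → 9 per patient).

This module also ships, as packaged CSV fixtures, the published DICE and
average-Hausdorff values of such an experiment on five clinical patients
(plus a twelve-row PTV comparison table for seven patients), and the
summary statistics computed on them: per-row and grand means, pooled
means, group tests, coverage margins and histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ComparisonRecord

__all__ = [
    "ObserverRun",
    "SummaryTable",
    "load_intra_observer_table",
    "load_inter_observer_table",
    "load_ptv_comparison_table",
    "ptv_table_values",
    "enumerate_intra_pairs",
    "enumerate_inter_pairs",
    "summarize",
    "pooled_mean",
    "pooled_sd",
    "group_test",
    "margin_for_coverage",
    "histogram_report",
]

DICE_DECIMALS = 2
HAVE_DECIMALS = 1
DICE_BIN_WIDTH = 0.05
HAVE_BIN_WIDTH_MM = 0.25


@dataclass(frozen=True)
class ObserverRun:
    """One repetition of the registration chain by one observer."""

    patient_id: int
    observer_id: int
    repeat_id: int
    series_id: str = ""
    deformation: object = None
    itv: object = None

    def __post_init__(self) -> None:
        if self.observer_id not in (1, 2):
            raise ValueError(f"observer_id must be 1 or 2, got {self.observer_id}")
        if self.repeat_id not in (1, 2, 3):
            raise ValueError(f"repeat_id must be 1..3, got {self.repeat_id}")


def _data_path(name: str) -> Path:
    return Path(resources.files("gdmtarget.data") / name)


def load_intra_observer_table() -> pd.DataFrame:
    """Published intra-observer DICE / H-AVE values (2 observers × 3 repeat
    pairs × 5 patients = 30 comparisons)."""
    return pd.read_csv(_data_path("intra_observer.csv"))


def load_inter_observer_table() -> pd.DataFrame:
    """Published inter-observer DICE / H-AVE values (3 × 3 repeat pairs × 5
    patients = 45 comparisons)."""
    return pd.read_csv(_data_path("inter_observer.csv"))


def load_ptv_comparison_table() -> pd.DataFrame:
    """Published per-patient DICE values for the twelve PTV-pair comparisons
    (wide layout, one patient per column, NA where a structure variant was
    not available for that patient)."""
    return pd.read_csv(_data_path("ptv_comparisons.csv"))


def ptv_table_values(df: pd.DataFrame, rows=None) -> np.ndarray:
    """Flatten the per-patient values of selected rows, dropping NAs."""
    sub = df if rows is None else df[rows]
    cols = [c for c in sub.columns if c.startswith("p") and c[1:].isdigit()]
    return sub[cols].to_numpy(dtype=float).ravel()[
        ~np.isnan(sub[cols].to_numpy(dtype=float).ravel())
    ]


# ---------------------------------------------------------------------------
# Pairing schemes
# ---------------------------------------------------------------------------

def enumerate_intra_pairs(runs: list[ObserverRun]) -> list[tuple[ObserverRun, ObserverRun]]:
    """The 3 unordered repeat pairs of one observer on one patient."""
    if len(runs) != 3:
        raise ValueError(f"intra-observer scheme needs exactly 3 repeats, got {len(runs)}")
    if len({r.patient_id for r in runs}) != 1 or len({r.observer_id for r in runs}) != 1:
        raise ValueError("intra-observer runs must share patient and observer")
    if sorted(r.repeat_id for r in runs) != [1, 2, 3]:
        raise ValueError("intra-observer runs must be repeats 1, 2, 3")
    by_rep = {r.repeat_id: r for r in runs}
    return [(by_rep[i], by_rep[j]) for i, j in combinations((1, 2, 3), 2)]


def enumerate_inter_pairs(runs: list[ObserverRun]) -> list[tuple[ObserverRun, ObserverRun]]:
    """All 3×3 cross-observer repeat pairs on one patient."""
    if len({r.patient_id for r in runs}) != 1:
        raise ValueError("inter-observer runs must share the patient")
    obs1 = {r.repeat_id: r for r in runs if r.observer_id == 1}
    obs2 = {r.repeat_id: r for r in runs if r.observer_id == 2}
    if sorted(obs1) != [1, 2, 3] or sorted(obs2) != [1, 2, 3]:
        raise ValueError(
            "inter-observer scheme needs repeats 1..3 from both observers, got "
            f"observer 1: {sorted(obs1)}, observer 2: {sorted(obs2)}"
        )
    return [(obs1[i], obs2[j]) for i, j in product((1, 2, 3), repeat=2)]


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _sample_sd(values: np.ndarray) -> float | None:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else None


@dataclass
class SummaryTable:
    """Mean/SD summary of grouped comparison records."""

    rows: pd.DataFrame  # columns: group, n, mean_dice, sd_dice, mean_have, sd_have
    mean_dice: float
    mean_have: float

    def display(self) -> pd.DataFrame:
        """Rounded for display: DICE to 2 decimals, H-AVE to 1 (as printed)."""
        out = self.rows.copy()
        for c in ("mean_dice", "sd_dice"):
            out[c] = out[c].round(DICE_DECIMALS)
        for c in ("mean_have", "sd_have"):
            out[c] = out[c].round(HAVE_DECIMALS)
        return out


def summarize(records: list[ComparisonRecord] | pd.DataFrame, group_by=None) -> SummaryTable:
    """Arithmetic mean and sample SD (n−1) per group plus grand means.

    ``records`` is either a list of :class:`ComparisonRecord` or a
    DataFrame with ``dice`` and ``h_ave_mm`` columns; ``group_by`` names
    the grouping columns (``None`` → one overall group).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.as_dict() for r in records])
    if df.empty:
        raise ValueError("no records to summarize")
    if group_by:
        grouped = df.groupby(group_by, sort=True)
    else:
        grouped = [("all", df)]
    rows = []
    for key, g in grouped:
        dice_v = g["dice"].to_numpy(dtype=float)
        have_v = g["h_ave_mm"].to_numpy(dtype=float)
        rows.append(
            {
                "group": key,
                "n": len(g),
                "mean_dice": float(dice_v.mean()),
                "sd_dice": _sample_sd(dice_v),
                "mean_have": float(have_v.mean()),
                "sd_have": _sample_sd(have_v),
            }
        )
    return SummaryTable(
        rows=pd.DataFrame(rows),
        mean_dice=float(df["dice"].mean()),
        mean_have=float(df["h_ave_mm"].mean()),
    )


def pooled_mean(values: np.ndarray) -> float:
    """Mean over all individual values (pooled, not mean-of-row-means)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty selection")
    return float(values.mean())


def pooled_sd(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("pooled SD needs at least 2 values")
    return float(np.std(values, ddof=1))


def group_test(values_a, values_b, mode: str = "welch") -> tuple[float, float]:
    """Two-sided t-test between two groups (alpha 0.05 convention).

    ``welch`` for unequal-size group comparisons, ``paired`` for matched
    designs (requires equal lengths).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if mode == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif mode == "paired":
        if len(a) != len(b):
            raise ValueError(
                f"paired test requires equal lengths, got {len(a)} and {len(b)}"
            )
        res = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'welch' or 'paired'")
    return float(res.statistic), float(res.pvalue)


def margin_for_coverage(h_ave_values, coverage_fraction: float = 0.95) -> float:
    """Smallest margin m (mm) such that ≥ fraction of H-AVE values are ≤ m.

    The inclusive empirical quantile; with fraction 1.0 this is the sample
    maximum.  Monotone non-decreasing in the fraction.
    """
    v = np.sort(np.asarray(h_ave_values, dtype=float))
    if v.size == 0:
        raise ValueError("need at least one H-AVE value")
    if not 0 < coverage_fraction <= 1:
        raise ValueError(f"coverage fraction must be in (0, 1], got {coverage_fraction}")
    k = int(np.ceil(coverage_fraction * v.size)) - 1
    return float(v[k])


def histogram_report(
    values,
    kind: str = "differential",
    metric: str = "dice",
    plot_path: str | Path | None = None,
    label: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Binned counts (and optional plot) of DICE or H-AVE values.

    DICE bins are 0.05 wide on [0, 1]; H-AVE bins 0.25 mm from 0 to the
    sample maximum.  ``cumulative`` returns running counts (monotone,
    ending at the record count).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to histogram")
    if metric == "dice":
        edges = np.arange(0.0, 1.0 + DICE_BIN_WIDTH / 2, DICE_BIN_WIDTH)
        xlabel = "DICE"
    elif metric == "h_ave":
        top = np.ceil(v.max() / HAVE_BIN_WIDTH_MM) * HAVE_BIN_WIDTH_MM
        edges = np.arange(0.0, top + HAVE_BIN_WIDTH_MM / 2, HAVE_BIN_WIDTH_MM)
        xlabel = "H-AVE [mm]"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    counts, edges = np.histogram(v, bins=edges)
    if kind == "cumulative":
        counts = np.cumsum(counts)
    elif kind != "differential":
        raise ValueError(f"unknown histogram kind {kind!r}")

    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", edgecolor="k")
        ax.set_xlabel(xlabel)
        ax.set_ylabel("cumulative count" if kind == "cumulative" else "count")
        if label:
            ax.set_title(label)
        fig.tight_layout()
        Path(plot_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return counts, edges
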