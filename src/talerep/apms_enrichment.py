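"""Replicate-level enrichment statistics for AP-MS intensity matrices.

Input is a protein x sample matrix of linear-scale label-free
intensities (e.g. MaxLFQ output) with each sample labeled bait or
control. Per protein, the statistic is the mean log2 bait minus mean
log2 control intensity with a two-sided two-sample t-test; a protein is
called significant when p < alpha (default 0.05, matching the study's
cut-off over three biological replicates) AND its fold change is
positive. Welch's unequal-variance t is the default for robustness at
n = 3; a pooled-variance (classic Student) mode is available for literal
replication. No multiple-testing correction is applied unless
Benjamini–Hochberg is requested.

Missing values (NaN) are handled either by exclusion — a tested protein
must be fully quantified in bait and have >= 2 control observations — or
by imputation from a per-sample downshifted normal (mean - 1.8 sd, width
0.3 sd of that sample's observed log2 intensities), the convention used
by mainstream proteomics suites; imputation requires a seed and is
deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05
IMPUTE_SHIFT_SD = 1.8
IMPUTE_WIDTH_SD = 0.3

CONDITIONS = ("bait", "control")


@dataclass
class IntensityMatrix:
    """Protein x sample intensities plus the sample -> condition design."""

    data: pd.DataFrame  # index: protein ids; columns: sample ids; NaN = missing
    design: pd.Series  # sample id -> "bait" | "control"

    def __post_init__(self) -> None:
        self.design = self.design.reindex(self.data.columns)
        if self.design.isna().any():
            missing = list(self.design[self.design.isna()].index)
            raise ValueError(f"samples without condition labels: {missing}")
        bad = set(self.design.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("intensities must be positive where present")

    @property
    def bait_samples(self) -> list[str]:
        return list(self.design[self.design == "bait"].index)

    @property
    def control_samples(self) -> list[str]:
        return list(self.design[self.design == "control"].index)


def read_intensity_matrix(matrix_path: str | Path, design_path: str | Path) -> IntensityMatrix:
    """Read a TSV matrix (first column protein id) plus a sample->condition TSV."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    design = pd.Series(
        design_df.iloc[:, 1].to_numpy(), index=design_df.iloc[:, 0].astype(str)
    )
    return IntensityMatrix(data=data, design=design)


def _impute_downshifted(
    log2_data: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill NaNs per sample from N(mean - 1.8 sd, (0.3 sd)^2) of observed values."""
    out = log2_data.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_missing = out[col].isna().sum()
        if n_missing == 0:
            continue
        if observed.size < 2:
            raise ValueError(
                f"sample {col!r} has too few observed intensities to impute from"
            )
        mu = observed.mean() - IMPUTE_SHIFT_SD * observed.std(ddof=1)
        sd = IMPUTE_WIDTH_SD * observed.std(ddof=1)
        out.loc[out[col].isna(), col] = rng.normal(mu, sd, size=n_missing)
    return out


def _t_test(bait: np.ndarray, control: np.ndarray, equal_var: bool) -> tuple[float, bool]:
    """Two-sided p-value with explicit handling of the zero-variance case."""
    if bait.std(ddof=1) == 0 and control.std(ddof=1) == 0:
        # degenerate: no within-group variation; identical means carry no
        # evidence (p = 1), different means are unambiguous (p = 0)
        return (1.0 if bait.mean() == control.mean() else 0.0), True
    res = stats.ttest_ind(bait, control, equal_var=equal_var)
    return float(res.pvalue), False


def compare(
    matrix: IntensityMatrix,
    alpha: float = DEFAULT_ALPHA,
    impute: bool = False,
    seed: int | None = None,
    equal_var: bool = False,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-protein log2 fold change and t-test of bait vs control.

    Returns a DataFrame indexed like the matrix with columns ``log2fc``,
    ``p_value``, ``n_bait``, ``n_control``, ``tested``, ``zero_variance``
    and ``significant``; when ``bh`` is set an additional ``q_value``
    column carries Benjamini–Hochberg adjusted p-values (the significance
    flag then gates on q). Untested proteins (failed missing-value rules)
    keep NaN statistics. Deterministic given matrix and seed.
    """
    bait_cols = matrix.bait_samples
    ctrl_cols = matrix.control_samples
    if len(bait_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    log2_data = np.log2(matrix.data.astype(float))
    if impute:
        if seed is None:
            raise ValueError("imputation requires a seed")
        log2_data = _impute_downshifted(log2_data, np.random.default_rng(seed))

    rows = []
    for protein, row in log2_data.iterrows():
        bait = row[bait_cols].dropna().to_numpy(dtype=float)
        ctrl = row[ctrl_cols].dropna().to_numpy(dtype=float)
        # exclusion rule (no imputation): full bait quantification and at
        # least two control observations
        tested = len(bait) == len(bait_cols) and len(ctrl) >= 2 if not impute else True
        if not tested:
            rows.append((protein, np.nan, np.nan, len(bait), len(ctrl), False, False))
            continue
        log2fc = float(bait.mean() - ctrl.mean())
        p, zero_var = _t_test(bait, ctrl, equal_var=equal_var)
        rows.append((protein, log2fc, p, len(bait), len(ctrl), True, zero_var))
    out = pd.DataFrame(
        rows,
        columns=["protein_id", "log2fc", "p_value", "n_bait", "n_control", "tested", "zero_variance"],
    ).set_index("protein_id")
    crit = out["p_value"]
    if bh:
        tested_mask = out["tested"] & out["p_value"].notna()
        q = pd.Series(np.nan, index=out.index)
        if tested_mask.any():
            q.loc[tested_mask] = stats.false_discovery_control(
                out.loc[tested_mask, "p_value"].to_numpy(), method="bh"
            )
        out["q_value"] = q
        crit = out["q_value"]
    out["significant"] = (
        out["tested"]
        & (crit < alpha)
        & (out["log2fc"] > 0)
        & (out["n_bait"] >= 2)
        & (out["n_control"] >= 2)
    )
    out.attrs["alpha"] = alpha
    out.attrs["impute"] = impute
    out.attrs["equal_var"] = equal_var
    out.attrs["n_excluded"] = int((~out["tested"]).sum())
    return out


def volcano_table(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Ranked table: p ascending, then log2fc descending; adds -log10 p.

    Keeps every input protein (untested rows sort last).
    """
    df = stats_df.reset_index()
    df["neg_log10_p"] = -np.log10(df["p_value"])
    df = df.sort_values(
        ["p_value", "log2fc"],
        ascending=[True, False],
        na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    cols = ["protein_id", "log2fc", "neg_log10_p", "p_value", "significant"]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra]
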