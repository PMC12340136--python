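"""Spectral-count differential enrichment and the volcano statistic.

The quantification unit is the PSM (peptide-spectrum match): one
identified spectrum of a peptide from a protein in one sample.  For a
two-group design (here, vehicle-control vs. treated hearts, four
biological replicates each) the per-protein statistic is

    x = log2(treated PSM total / control PSM total)

with a zero group total replaced by a 0.1 pseudocount, and

    y = -log(p)   (log10 by default, natural log selectable)

where p comes from a two-sided two-sample t test on the per-sample
counts.  A protein is flagged significant when x >= x_min and
y >= y_min (defaults 2 and 1.3: at least fourfold enrichment in the
treated direction at 95% confidence).

Identification acceptance upstream of counting: peptide probability
strictly > 90%, protein probability strictly > 99.9%, and at least two
retained PSMs per protein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PSM_COLUMNS = [
    "protein_id",
    "sample_id",
    "group",
    "peptide_probability",
    "protein_probability",
]

GROUP_LABELS = ("control", "treated")


@dataclass(frozen=True)
class GroupDesign:
    """Sample-to-group assignment for the two-group comparison."""

    sample_ids_control: tuple[str, ...]
    sample_ids_treated: tuple[str, ...]

    def __post_init__(self) -> None:
        ctrl, trt = set(self.sample_ids_control), set(self.sample_ids_treated)
        if not ctrl or not trt:
            raise ValueError("each group needs at least one sample")
        if len(ctrl) != len(self.sample_ids_control) or len(trt) != len(
            self.sample_ids_treated
        ):
            raise ValueError("duplicate sample ids within a group")
        overlap = ctrl & trt
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")

    @property
    def all_samples(self) -> tuple[str, ...]:
        return tuple(self.sample_ids_control) + tuple(self.sample_ids_treated)


def validate_psm_table(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PSM_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"PSM table missing columns: {missing}")
    return records


def filter_identifications(
    records: pd.DataFrame,
    peptide_prob_min: float = 0.90,
    protein_prob_min: float = 0.999,
    min_psms: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identification-acceptance filters to a PSM table.

    Retains rows with peptide_probability strictly greater than
    ``peptide_prob_min`` AND protein_probability strictly greater than
    ``protein_prob_min``, then drops every protein whose retained PSM
    total (across all samples) is below ``min_psms``.

    Returns ``(filtered_table, rejection_log)``.  The log has one row
    per rejection event: malformed rows, probability-filtered rows (one
    summary row per protein), and proteins dropped by the PSM-count
    floor.  Nothing is silently discarded.
    """
    if not 0 <= peptide_prob_min <= 1 or not 0 <= protein_prob_min <= 1:
        raise ValueError("probability thresholds must lie in [0, 1]")
    if min_psms < 1:
        raise ValueError("min_psms must be >= 1")
    validate_psm_table(records)

    log_rows: list[dict] = []
    if records.empty:
        log_rows.append(
            {"protein_id": "", "reason": "empty_input", "n_rows": 0}
        )
        return records.copy(), pd.DataFrame(log_rows)

    pep = pd.to_numeric(records["peptide_probability"], errors="coerce")
    prot = pd.to_numeric(records["protein_probability"], errors="coerce")
    malformed = (
        pep.isna() | prot.isna() | (pep < 0) | (pep > 1) | (prot < 0) | (prot > 1)
    )
    for protein_id, n in (
        records.loc[malformed, "protein_id"].value_counts().sort_index().items()
    ):
        log_rows.append(
            {"protein_id": protein_id, "reason": "malformed_probability", "n_rows": int(n)}
        )

    ok = ~malformed & (pep > peptide_prob_min) & (prot > protein_prob_min)
    prob_rejected = ~malformed & ~ok
    for protein_id, n in (
        records.loc[prob_rejected, "protein_id"].value_counts().sort_index().items()
    ):
        log_rows.append(
            {"protein_id": protein_id, "reason": "probability_filter", "n_rows": int(n)}
        )

    retained = records.loc[ok]
    counts = retained["protein_id"].value_counts()
    low = counts[counts < min_psms]
    for protein_id, n in low.sort_index().items():
        log_rows.append(
            {"protein_id": protein_id, "reason": "min_psms", "n_rows": int(n)}
        )
    keep = retained["protein_id"].map(counts) >= min_psms
    filtered = retained.loc[keep].reset_index(drop=True)
    return filtered, pd.DataFrame(log_rows, columns=["protein_id", "reason", "n_rows"])


def aggregate_counts(records: pd.DataFrame, design: GroupDesign) -> pd.DataFrame:
    """Per-protein per-sample PSM count matrix, zero-filled.

    Columns are ordered control samples then treated samples; each cell
    is the number of PSM rows for that (protein, sample).
    """
    validate_psm_table(records)
    samples = design.all_samples
    if records.empty:
        return pd.DataFrame(columns=list(samples), dtype=int)
    unknown = sorted(set(records["sample_id"]) - set(samples))
    if unknown:
        raise ValueError(f"sample ids not in design: {unknown}")
    mat = (
        records.groupby(["protein_id", "sample_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(samples), fill_value=0)
        .astype(int)
    )
    mat.columns.name = None
    mat.index.name = "protein_id"
    return mat


def _two_sample_p(
    treated: np.ndarray, control: np.ndarray, test: str
) -> float:
    """Two-sided two-sample t-test p-value with explicit degenerate handling.

    All values identical across both groups -> p = 1.  Both group
    variances zero but means differing -> p = 0 (to be capped on the y
    scale).  Otherwise scipy's Student (pooled) or Welch test.
    """
    var_t = float(np.var(treated, ddof=1))
    var_c = float(np.var(control, ddof=1))
    if var_t == 0.0 and var_c == 0.0:
        return 1.0 if float(np.mean(treated)) == float(np.mean(control)) else 0.0
    with warnings.catch_warnings():
        # near-identical counts trip scipy's precision-loss warning; the
        # fully degenerate cases are already handled above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated, control, equal_var=(test == "student"))
    return float(res.pvalue)


def compute_enrichment(
    counts: pd.DataFrame,
    design: GroupDesign,
    pseudocount: float = 0.1,
    log_base_y: str = "log10",
    y_cap: float = 16.0,
    test: str = "student",
) -> pd.DataFrame:
    """Per-protein volcano coordinates from a count matrix.

    Group totals are summed per protein; a zero total is replaced by
    ``pseudocount`` (applied to totals only, never to the per-sample
    counts fed to the t test).  Proteins with zero PSMs in both groups
    are excluded (undefined ratio) and reported in the
    ``excluded_proteins`` attribute of the returned frame (``.attrs``).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if log_base_y not in ("log10", "ln"):
        raise ValueError("log_base_y must be 'log10' or 'ln'")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    if len(design.sample_ids_control) < 2 or len(design.sample_ids_treated) < 2:
        raise ValueError("need >= 2 samples per group for the t test")
    missing = [s for s in design.all_samples if s not in counts.columns]
    if missing:
        raise ValueError(f"count matrix lacks design samples: {missing}")

    log_fn = math.log10 if log_base_y == "log10" else math.log
    ctrl_cols = list(design.sample_ids_control)
    trt_cols = list(design.sample_ids_treated)

    rows: list[dict] = []
    excluded: list[str] = []
    for protein_id, row in counts.iterrows():
        c = row[ctrl_cols].to_numpy(dtype=float)
        t = row[trt_cols].to_numpy(dtype=float)
        total_c, total_t = float(c.sum()), float(t.sum())
        if total_c == 0.0 and total_t == 0.0:
            excluded.append(str(protein_id))
            continue
        adj_c = total_c if total_c > 0 else pseudocount
        adj_t = total_t if total_t > 0 else pseudocount
        x = math.log2(adj_t / adj_c)
        p = _two_sample_p(t, c, test)
        y = y_cap if p <= 0.0 else min(-log_fn(p), y_cap)
        rows.append(
            {
                "protein_id": protein_id,
                "control_total": int(total_c),
                "treated_total": int(total_t),
                "control_adjusted": adj_c,
                "treated_adjusted": adj_t,
                "x_log2_enrichment": x,
                "p_value": p,
                "y_neglogp": y,
                "significant": False,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "control_total",
            "treated_total",
            "control_adjusted",
            "treated_adjusted",
            "x_log2_enrichment",
            "p_value",
            "y_neglogp",
            "significant",
        ],
    )
    out.attrs["excluded_proteins"] = excluded
    return out


def classify_volcano(
    rows: pd.DataFrame, x_min: float = 2.0, y_min: float = 1.3
) -> pd.DataFrame:
    """Set the significance flag: x >= x_min AND y >= y_min, both inclusive.

    One-directional (treated-enriched, the upper-right quadrant);
    depleted proteins are never flagged.  Summary counts live in
    ``.attrs['summary']``.
    """
    out = rows.copy()
    out["significant"] = (out["x_log2_enrichment"] >= x_min) & (
        out["y_neglogp"] >= y_min
    )
    out.attrs["summary"] = {
        "n_proteins": int(len(out)),
        "n_significant": int(out["significant"].sum()),
    }
    return out


def run_enrichment(
    records: pd.DataFrame,
    design: GroupDesign,
    peptide_prob_min: float = 0.90,
    protein_prob_min: float = 0.999,
    min_psms: int = 2,
    pseudocount: float = 0.1,
    x_min: float = 2.0,
    y_min: float = 1.3,
    log_base_y: str = "log10",
    y_cap: float = 16.0,
    test: str = "student",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: filter -> aggregate -> enrichment -> volcano flags.

    Returns ``(volcano_table, rejection_log)``.
    """
    filtered, log = filter_identifications(
        records, peptide_prob_min, protein_prob_min, min_psms
    )
    counts = aggregate_counts(filtered, design)
    rows = compute_enrichment(
        counts, design, pseudocount=pseudocount, log_base_y=log_base_y,
        y_cap=y_cap, test=test,
    )
    return classify_volcano(rows, x_min=x_min, y_min=y_min), log
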