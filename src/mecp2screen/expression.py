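"""Stringent microarray differential-expression screen.

Mirrors the triplicate wild-type vs knockout design: a detection-call
prefilter produces two candidate lists (probes detected in at least two
knockout samples are candidates for up-in-KO, probes detected in at
least two wild-type samples for down-in-KO), intensities are quantile
normalized and log2 transformed, each probe gets an unpaired t test, and
a probe passes if it clears the significance criterion (raw P < 0.005 or
Benjamini-Hochberg q < 0.05, computed within its prefiltered list) and a
linear fold-change gate (> 1.2 or > 1.5) in the direction its list is
screening for.  Passing probes are collapsed many-to-one onto genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

Mode = Literal["fdr", "rawp"]

DETECTED = ("present", "marginal")
CALL_VALUES = ("present", "marginal", "absent")


def detection_prefilter(
    calls: pd.DataFrame,
    groups: pd.Series,
    target_group: str,
    min_detected: int = 2,
) -> list[str]:
    """Probes called present or marginal in >= min_detected target-group samples.

    ``calls`` is probes x samples with values in {present, marginal,
    absent}; ``groups`` maps sample_id -> group label.  In a full run the
    KO-filtered list holds the up-in-KO candidates and the WT-filtered
    list the down-in-KO candidates.
    """
    samples = groups.index[groups == target_group]
    if len(samples) == 0:
        raise ValueError(f"no samples in group {target_group!r}")
    if min_detected > len(samples):
        raise ValueError(
            f"min_detected={min_detected} exceeds group size {len(samples)} for {target_group!r}"
        )
    sub = calls[samples]
    bad = set(np.unique(sub.to_numpy())) - set(CALL_VALUES)
    if bad:
        raise ValueError(f"unknown detection-call values: {sorted(bad)}")
    n_det = sub.isin(DETECTED).sum(axis=1)
    return calls.index[n_det >= min_detected].tolist()


def fallback_detection_calls(matrix: pd.DataFrame, background_quantile: float = 0.25) -> pd.DataFrame:
    """Rule-based calls for matrices without vendor detection calls.

    A probe is called present in a sample iff its intensity exceeds that
    sample's background quantile; there is no marginal call.
    """
    thresh = matrix.quantile(background_quantile, axis=0)
    return pd.DataFrame(
        np.where(matrix.to_numpy() > thresh.to_numpy(), "present", "absent"),
        index=matrix.index,
        columns=matrix.columns,
    )


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Across-sample quantile normalization (rank -> mean of sorted values)."""
    arr = matrix.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="mergesort")
    ranks = np.empty_like(order)
    rows = np.arange(arr.shape[0])
    for j in range(arr.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    return pd.DataFrame(mean_sorted[ranks], index=matrix.index, columns=matrix.columns)


def normalize_log2(matrix: pd.DataFrame, method: str = "quantile_log2") -> pd.DataFrame:
    """Normalize raw intensities and move to log2 scale.

    quantile_log2: across-sample quantile normalization of the raw
    intensities followed by log2 (a simplified stand-in for full
    microarray preprocessing).  passthrough: the matrix is already on
    log2 scale and is returned unchanged.
    """
    if method == "passthrough":
        return matrix
    if method != "quantile_log2":
        raise ValueError(f"unknown normalization method {method!r}")
    if (matrix.to_numpy() <= 0).any():
        raise ValueError("quantile_log2 requires strictly positive raw intensities")
    if len(matrix) < 2:
        # a one-row matrix carries no rank information; log2 only
        return np.log2(matrix)
    return np.log2(quantile_normalize(matrix))


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class ExpressionScreenResult:
    """Probe-level screen output plus the collapsed gene-level verdicts."""

    probes: pd.DataFrame
    mode: Mode
    fc_cutoff: float
    untestable: list[str] = field(default_factory=list)
    genes: Optional[pd.DataFrame] = None
    unannotated: list[str] = field(default_factory=list)

    @property
    def passing_probes(self) -> pd.DataFrame:
        return self.probes[self.probes["passes"]]


def differential_expression(
    log2_matrix: pd.DataFrame,
    groups: pd.Series,
    mode: Mode = "rawp",
    p_cutoff: float = 0.005,
    q_cutoff: float = 0.05,
    fc_cutoff: float = 1.2,
    ko_prefiltered: Optional[Iterable[str]] = None,
    wt_prefiltered: Optional[Iterable[str]] = None,
    equal_var: bool = True,
    group_labels: tuple[str, str] = ("WT", "KO"),
) -> ExpressionScreenResult:
    """Per-probe unpaired t test with direction-aware pass flags.

    The two-sided t statistic compares KO vs WT log2 intensities
    (equal-variance Student by default, Welch with equal_var=False).
    BH q-values are computed within each prefiltered list separately.
    A probe passes iff the mode criterion holds (q < q_cutoff under
    "fdr", p < p_cutoff under "rawp"), its linear fold change exceeds
    fc_cutoff, and its direction matches the list it was prefiltered
    into (up-in-KO candidates come from the KO-detected list, down-in-KO
    candidates from the WT-detected list).  Probes with zero variance in
    both groups are untestable and excluded with a warning.
    """
    wt_label, ko_label = group_labels
    wt_samples = groups.index[groups == wt_label]
    ko_samples = groups.index[groups == ko_label]
    if len(wt_samples) < 2 or len(ko_samples) < 2:
        raise ValueError("need >= 2 samples per group for the t test")
    if ko_prefiltered is None:
        ko_prefiltered = log2_matrix.index
    if wt_prefiltered is None:
        wt_prefiltered = log2_matrix.index
    ko_set = pd.Index(ko_prefiltered)
    wt_set = pd.Index(wt_prefiltered)

    wt = log2_matrix[wt_samples].to_numpy(dtype=float)
    ko = log2_matrix[ko_samples].to_numpy(dtype=float)
    mean_wt = wt.mean(axis=1)
    mean_ko = ko.mean(axis=1)
    diff = mean_ko - mean_wt

    untestable_mask = (wt.var(axis=1) == 0) & (ko.var(axis=1) == 0)
    untestable = log2_matrix.index[untestable_mask].tolist()
    if untestable:
        logger.warning(
            "%d probes with zero within-group variance in both groups are untestable "
            "and were excluded", len(untestable),
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p_val = stats.ttest_ind(ko, wt, axis=1, equal_var=equal_var)

    df = pd.DataFrame(
        {
            "mean_log2_WT": mean_wt,
            "mean_log2_KO": mean_ko,
            "log2_diff": diff,
            "fold_change": np.exp2(np.abs(diff)),
            "direction": np.where(diff >= 0, "up_in_KO", "down_in_KO"),
            "t_statistic": t_stat,
            "p_value": p_val,
        },
        index=log2_matrix.index.rename("probe_id"),
    )
    df.loc[df["log2_diff"] == 0, "direction"] = "none"
    df = df[~untestable_mask]

    # BH within each direction-specific prefiltered list
    df["bh_q_up"] = np.nan
    df["bh_q_down"] = np.nan
    in_ko = df.index.isin(ko_set)
    in_wt = df.index.isin(wt_set)
    df.loc[in_ko, "bh_q_up"] = bh_qvalues(df.loc[in_ko, "p_value"].to_numpy())
    df.loc[in_wt, "bh_q_down"] = bh_qvalues(df.loc[in_wt, "p_value"].to_numpy())

    if mode == "rawp":
        sig_up = df["p_value"] < p_cutoff
        sig_down = df["p_value"] < p_cutoff
    elif mode == "fdr":
        sig_up = df["bh_q_up"] < q_cutoff
        sig_down = df["bh_q_down"] < q_cutoff
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fc_ok = df["fold_change"] > fc_cutoff
    df["passes_up"] = in_ko & (df["direction"] == "up_in_KO") & sig_up.fillna(False) & fc_ok
    df["passes_down"] = in_wt & (df["direction"] == "down_in_KO") & sig_down.fillna(False) & fc_ok
    df["passes"] = df["passes_up"] | df["passes_down"]
    return ExpressionScreenResult(probes=df, mode=mode, fc_cutoff=fc_cutoff, untestable=untestable)


def collapse_probes_to_genes(
    result: ExpressionScreenResult, probe_gene_map: pd.Series
) -> ExpressionScreenResult:
    """Collapse passing probes onto genes (any-probe-passes rule).

    A gene is differentially expressed iff at least one of its probes
    passes; its direction, fold and statistics are taken from its
    smallest-p passing probe.  Genes whose passing probes disagree in
    direction are flagged discordant but kept.  Passing probes missing
    from the map are reported as unannotated and excluded.
    """
    passing = result.passing_probes
    mapped = passing.index.intersection(probe_gene_map.index)
    unannotated = passing.index.difference(probe_gene_map.index).tolist()
    if unannotated:
        logger.warning("%d passing probes have no gene annotation", len(unannotated))
    sub = passing.loc[mapped].copy()
    sub["gene_id"] = probe_gene_map.loc[mapped].to_numpy()
    rows = []
    for gene_id, grp in sub.groupby("gene_id", sort=True):
        best = grp.sort_values(["p_value", "fold_change"], ascending=[True, False]).iloc[0]
        rows.append(
            {
                "gene_id": gene_id,
                "n_passing_probes": len(grp),
                "representative_probe": best.name,
                "direction": best["direction"],
                "fold_change": best["fold_change"],
                "p_value": best["p_value"],
                "discordant": grp["direction"].nunique() > 1,
            }
        )
    genes = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_passing_probes", "representative_probe",
            "direction", "fold_change", "p_value", "discordant",
        ],
    ).set_index("gene_id")
    result.genes = genes
    result.unannotated = unannotated
    return result


def read_expression_tsv(path) -> pd.DataFrame:
    """Probes x samples matrix from TSV with probe_id as first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path) -> pd.Series:
    """sample_id -> group Series from a two-column TSV (sample_id, group)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_probe_map(path) -> pd.Series:
    """probe_id -> gene_id Series from a two-column TSV."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]
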