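"""Comparative-Ct (delta-delta-Ct) relative quantification and qChIP-PCR
standard curves.

Each qPCR measurement yields a cycle threshold (Ct) for a target gene
and for a reference gene (Gapdh by default) in the same sample.  With
the comparative-Ct model (amplification efficiency fixed at 2), the
target's abundance relative to a calibrator genotype is

    dCt  = Ct_target - Ct_reference          (per sample)
    ddCt = dCt_sample - mean(dCt_calibrator)
    fold = 2 ** (-ddCt)

Validation experiments compare littermate pairs of wild-type and
knockout cultures: per pair, technical-replicate dCt values are
compared with one-tailed Student t tests and tallied as significantly
increased / reduced / no change in the knockout, the shape of the
paper-style concordance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ["sample_id", "genotype", "gene", "reference_gene", "ct_target", "ct_reference", "replicate"]


def read_ct_table(path) -> pd.DataFrame:
    """Ct TSV with columns sample_id, genotype, gene, reference_gene,
    ct_target, ct_reference, replicate."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return df


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    bad = records["ct_reference"].isna() | ~np.isfinite(records["ct_reference"])
    if bad.any():
        logger.warning(
            "rejecting %d Ct records with missing reference Ct (samples: %s)",
            int(bad.sum()), sorted(records.loc[bad, "sample_id"].unique()),
        )
        records = records[~bad]
    if ((records["ct_target"] <= 0) | (records["ct_reference"] <= 0)).any():
        raise ValueError("Ct values must be finite and positive")
    return records


def delta_delta_ct(
    records: pd.DataFrame,
    calibrator: str = "WT",
    average_technical: bool = True,
) -> pd.DataFrame:
    """Per-sample fold change relative to the calibrator genotype.

    Technical replicates are averaged to one dCt per sample first
    (default), then ddCt is taken against the mean calibrator dCt and
    fold = 2**(-ddCt).  Records lacking a reference Ct are rejected with
    a message.  Returns a DataFrame with sample_id, genotype, gene,
    dct, ddct, fold.
    """
    records = _validate_ct(records)
    if not (records["genotype"] == calibrator).any():
        raise ValueError(f"no records for calibrator genotype {calibrator!r}")
    recs = records.copy()
    recs["dct"] = recs["ct_target"] - recs["ct_reference"]
    keys = ["sample_id", "genotype", "gene"]
    if average_technical:
        per_sample = recs.groupby(keys, sort=True, as_index=False)["dct"].mean()
    else:
        per_sample = recs[keys + ["dct", "replicate"]].copy()
    out = []
    for gene, grp in per_sample.groupby("gene", sort=True):
        cal = grp.loc[grp["genotype"] == calibrator, "dct"]
        if cal.empty:
            raise ValueError(f"gene {gene!r}: calibrator group {calibrator!r} has no samples")
        ddct = grp["dct"] - cal.mean()
        g = grp.copy()
        g["ddct"] = ddct
        g["fold"] = np.exp2(-ddct)
        out.append(g)
    return pd.concat(out, ignore_index=True)


def replicate_concordance(
    records: pd.DataFrame,
    microarray_direction: dict[str, str] | pd.Series,
    alpha: float = 0.05,
    pair_column: str = "pair",
    calibrator: str = "WT",
) -> pd.DataFrame:
    """Table-style tally of per-pair significance calls for each gene.

    For every biological replicate pair, technical-replicate dCt values
    of the knockout sample are compared with those of the calibrator
    sample by one-tailed Student t tests in each direction (a lower dCt
    means more transcript).  A pair counts as "increased" if the
    increase-tail p < alpha, else "reduced" if the decrease-tail
    p < alpha, else "no change"; a pair with fewer than two technical
    replicates on either side is untestable and counted as no change
    with a warning.  Concordance is the count of pairs agreeing with the
    microarray direction ("up_in_KO"/"down_in_KO").

    ``records`` needs a pair identifier column (default "pair").
    Returns one row per gene: increased, reduced, no_change, n_pairs,
    microarray_direction, concordant.
    """
    records = _validate_ct(records)
    if pair_column not in records.columns:
        raise ValueError(f"Ct table lacks the {pair_column!r} pair identifier column")
    direction = pd.Series(microarray_direction)
    recs = records.copy()
    recs["dct"] = recs["ct_target"] - recs["ct_reference"]
    rows = []
    for gene, gene_grp in recs.groupby("gene", sort=True):
        inc = red = none = 0
        pairs = sorted(gene_grp[pair_column].unique())
        for pair in pairs:
            pg = gene_grp[gene_grp[pair_column] == pair]
            cal = pg.loc[pg["genotype"] == calibrator, "dct"].to_numpy()
            ko = pg.loc[pg["genotype"] != calibrator, "dct"].to_numpy()
            if len(cal) < 2 or len(ko) < 2:
                logger.warning(
                    "gene %s pair %s: <2 technical replicates, untestable; counted as no change",
                    gene, pair,
                )
                none += 1
                continue
            # increase in KO means KO dCt below calibrator dCt
            t, _p = stats.ttest_ind(ko, cal, equal_var=True)
            p_inc = stats.ttest_ind(ko, cal, equal_var=True, alternative="less").pvalue
            p_red = stats.ttest_ind(ko, cal, equal_var=True, alternative="greater").pvalue
            if p_inc < alpha:
                inc += 1
            elif p_red < alpha:
                red += 1
            else:
                none += 1
        md = direction.get(gene, "unknown")
        concordant = inc if md == "up_in_KO" else (red if md == "down_in_KO" else 0)
        rows.append(
            {
                "gene": gene,
                "microarray_direction": md,
                "increased": inc,
                "reduced": red,
                "no_change": none,
                "n_pairs": len(pairs),
                "concordant": concordant,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class StandardCurve:
    """Least-squares line Ct = slope * log10(quantity_pg) + intercept.

    ``efficiency`` is the per-cycle amplification factor minus one
    implied by the slope (10**(-1/slope) - 1; 1.0 at a perfect slope of
    -log2(10) = -3.3219).
    """

    log10_quantity: np.ndarray
    ct: np.ndarray
    slope: float
    intercept: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(quantity_pg: np.ndarray, ct: np.ndarray) -> StandardCurve:
    """Fit the dilution-series line on log10 picogram quantities."""
    q = np.asarray(quantity_pg, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if q.size < 3:
        raise ValueError("a standard curve needs at least 3 points")
    if np.any(q <= 0):
        raise ValueError("quantities must be positive picogram values")
    lq = np.log10(q)
    if np.ptp(lq) == 0:
        raise ValueError("degenerate standard curve: all quantities equal")
    slope, intercept = np.polyfit(lq, ct, 1)
    if slope >= 0:
        raise ValueError(f"standard curve slope must be negative, got {slope:.3g}")
    return StandardCurve(lq, ct, float(slope), float(intercept))


def standard_curve_quantify(curve: StandardCurve, unknown_ct: float) -> tuple[float, bool]:
    """Invert the curve: picograms for an observed Ct.

    Returns (quantity_pg, extrapolated) where the flag marks an unknown
    outside the fitted Ct range of the curve points.
    """
    q = 10 ** ((unknown_ct - curve.intercept) / curve.slope)
    lo, hi = float(np.min(curve.ct)), float(np.max(curve.ct))
    extrapolated = not (lo <= unknown_ct <= hi)
    if extrapolated:
        logger.warning("Ct %.3f outside the standard curve range [%.3f, %.3f]", unknown_ct, lo, hi)
    return float(q), extrapolated
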