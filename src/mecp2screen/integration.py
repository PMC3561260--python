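"""Intersection of the expression screen with the binding decile lists.

A candidate target gene is one that is both differentially expressed and
in the top decile of input-subtracted binding score for at least one of
the three gene windows.  The same gene may surface in more than one
window; duplicates are reported rather than collapsed, and per-window,
union, and duplicate counts are all exposed so any counting convention
can be read off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .annotation import WINDOW_NAMES

logger = logging.getLogger(__name__)


@dataclass
class TargetSet:
    """Per-window target tables plus union and duplicate bookkeeping.

    Each per-window table carries the gene's binding score and rank in
    that window and its expression direction/fold/p; ordering is by
    descending binding score with gene_id tie-break.
    """

    per_window: dict[str, pd.DataFrame]
    union: list[str]
    duplicates: list[str]
    venn: dict[str, dict[str, int]] = field(default_factory=dict)

    def window_genes(self, window: str) -> list[str]:
        return self.per_window[window]["gene_id"].tolist()


def intersect_targets(de_genes: pd.DataFrame, quant: pd.DataFrame) -> TargetSet:
    """Intersect the gene-level DE list with each window's top-decile set.

    ``de_genes`` is the collapsed gene table (indexed by gene_id, with
    direction/fold_change/p_value); ``quant`` is the long window
    quantification table with top_decile flags.  Matching is exact,
    case-sensitive string equality on gene_id.
    """
    if de_genes.index.has_duplicates:
        dupes = de_genes.index[de_genes.index.duplicated()].unique().tolist()
        raise ValueError(f"gene-level DE list has duplicate gene_ids: {dupes[:10]}")
    de_ids = set(de_genes.index)
    if not de_ids:
        logger.warning("empty differential-expression gene list; all target sets empty")
    per_window: dict[str, pd.DataFrame] = {}
    venn: dict[str, dict[str, int]] = {}
    seen: dict[str, int] = {}
    for name in WINDOW_NAMES:
        top = quant[(quant["window"] == name) & quant["top_decile"]]
        if top.empty:
            logger.warning("window %s: empty top-decile ranking", name)
        hits = top[top["gene_id"].isin(de_ids)].copy()
        hits = hits.sort_values(["score", "gene_id"], ascending=[False, True], kind="mergesort")
        table = pd.DataFrame(
            {
                "gene_id": hits["gene_id"].to_numpy(),
                "binding_score": hits["score"].to_numpy(),
                "binding_rank": hits["rank"].to_numpy(),
            }
        )
        for col in ("direction", "fold_change", "p_value"):
            table[col] = de_genes.loc[table["gene_id"], col].to_numpy() if len(table) else []
        per_window[name] = table
        venn[name] = {
            "n_de": len(de_ids),
            "n_top": len(top),
            "n_intersection": len(table),
        }
        for g in table["gene_id"]:
            seen[g] = seen.get(g, 0) + 1
    union = sorted(seen)
    duplicates = sorted(g for g, n in seen.items() if n >= 2)
    return TargetSet(per_window=per_window, union=union, duplicates=duplicates, venn=venn)


def direction_by_region_summary(targets: TargetSet) -> pd.DataFrame:
    """Counts of up_in_KO vs down_in_KO targets per window."""
    rows = []
    for name in WINDOW_NAMES:
        table = targets.per_window.get(name, pd.DataFrame(columns=["direction"]))
        counts = table["direction"].value_counts() if len(table) else pd.Series(dtype=int)
        rows.append(
            {
                "window": name,
                "up_in_KO": int(counts.get("up_in_KO", 0)),
                "down_in_KO": int(counts.get("down_in_KO", 0)),
            }
        )
    return pd.DataFrame(rows).set_index("window")


def write_targets(targets: TargetSet, outdir: str | Path) -> None:
    """Write per-window target TSVs, the union TSV, and the Venn JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in targets.per_window.items():
        table.to_csv(outdir / f"targets_{name}.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"gene_id": targets.union}).to_csv(outdir / "targets_union.tsv", sep="\t", index=False)
    summary = {
        "venn": targets.venn,
        "union_size": len(targets.union),
        "duplicates": targets.duplicates,
    }
    (outdir / "venn_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
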