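"""Synthetic data with planted truth for every pipeline stage.

The generators emulate the study design the pipeline was built for:
diffuse (non-peaky) ChIP enrichment concentrated in chosen gene windows
over a uniform genomic background, a triplicate wild-type vs knockout
expression matrix with a small set of modest planted effects and
detection calls, and comparative-Ct tables for littermate pairs
consistent with the planted fold changes.  Everything is deterministic
given (seed, config): a single master seed spawns independent
substreams per component.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, GeneWindows, derive_windows
from .coverage import Library

_SUBSTREAMS = {"genome": 0, "chip": 1, "expression": 2, "qpcr": 3, "picks": 4}


def _rng_for(seed: int, component: str) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return np.random.default_rng(children[_SUBSTREAMS[component]])


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic screen.

    Defaults are the screen's reference conditions: 1000 genes on 5
    chromosomes, 30 reads/kb of uniform background in both libraries,
    50 genes (5%) with 5-fold enrichment in their TSS window, 30 of
    those also carrying a 1.5-fold expression effect measured in
    triplicate with 2 probes per gene, and 4 qPCR littermate pairs in
    technical triplicate.
    """

    n_genes: int = 1000
    n_chroms: int = 5
    gene_length_range: tuple[int, int] = (2000, 8000)
    spacing: int = 2000
    margin: int = 5000
    flank_bp: int = 2000

    background_reads_per_kb: float = 30.0
    fragment_len: int = 300
    read_len: int = 76
    n_enriched_tss: int = 50
    enrichment_fold: float = 5.0

    probes_per_gene: int = 2
    n_per_group: int = 3
    n_de_planted: int = 30
    log2_effect: float = 0.585  # 1.5-fold
    noise_sd: float = 0.1
    detection_rate: float = 0.95
    expressed_fraction: float = 0.6

    n_qpcr_genes: int = 9
    ct_noise_sd: float = 0.05
    n_pairs: int = 4
    n_technical: int = 3


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated screen."""

    seed: int
    enrichment: dict[str, dict[str, float]]  # gene -> window -> fold (>1 only)
    expression_effects: dict[str, float]     # gene -> planted log2 effect (KO - WT)
    expressed_genes: list[str]
    probe_map: dict[str, str]                # probe -> gene
    qpcr_folds: dict[str, float]             # gene -> planted linear fold in KO

    @property
    def enriched_genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {"tss": [], "body": [], "tes": []}
        for gene, per_window in self.enrichment.items():
            for window in per_window:
                out[window].append(gene)
        return {k: sorted(v) for k, v in out.items()}

    @property
    def de_genes(self) -> list[str]:
        return sorted(g for g, eff in self.expression_effects.items() if eff != 0)

    def joint_truth(self, window: str = "tss") -> set[str]:
        """Genes planted both as enriched in *window* and as DE."""
        return set(self.enriched_genes[window]) & set(self.de_genes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def simulate_genome(
    n_genes: int,
    n_chroms: int = 5,
    gene_length_range: tuple[int, int] = (2000, 8000),
    spacing: int = 2000,
    seed: int = 0,
    margin: int = 5000,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping genes with random strands packed onto chromosomes.

    Genes are laid out left to right with jittered spacing; chromosome
    sizes are taken from the packing plus a margin so no default window
    is clipped.  Deterministic given the seed.
    """
    if n_chroms <= 0 or spacing <= 0 or margin <= 0:
        raise ValueError("n_chroms, spacing and margin must be positive")
    lo, hi = gene_length_range
    if not 0 < lo <= hi:
        raise ValueError(f"bad gene_length_range {gene_length_range}")
    if n_genes < 0:
        raise ValueError("n_genes must be nonnegative")
    rng = _rng_for(seed, "genome")
    width = len(str(max(n_genes - 1, 0)))
    genes: list[GeneModel] = []
    sizes: dict[str, int] = {}
    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0) for c in range(n_chroms)]
    gid = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = margin
        for _ in range(per_chrom[c]):
            length = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{gid:0{width}d}", chrom, pos, pos + length, strand))
            gid += 1
            pos += length + int(rng.integers(spacing // 2, spacing * 3 // 2 + 1))
        sizes[chrom] = pos + margin
    return genes, sizes


def _place_fragments(
    rng: np.random.Generator,
    chrom: str,
    lo: int,
    hi: int,
    n: int,
    fragment_len: int,
    read_len: int,
) -> pd.DataFrame:
    """n fragments whose full extent lies in [lo, hi); returns read intervals.

    The 5' end is uniform over positions keeping the fragment inside the
    region, strand chosen at random; the stored read is the first
    read_len bases from the 5' end.
    """
    if hi - lo < fragment_len or n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    plus = rng.random(n) < 0.5
    start5 = rng.integers(lo, hi - fragment_len + 1, size=n)  # + strand 5' end
    rs = np.where(plus, start5, start5 + fragment_len - read_len)
    re_ = rs + read_len
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": rs.astype(np.int64),
            "end": re_.astype(np.int64),
            "strand": np.where(plus, "+", "-"),
        }
    )


def simulate_chip_reads(
    genes: Sequence[GeneModel],
    sizes: Mapping[str, int],
    enrichment: Mapping[str, Mapping[str, float]],
    background_reads_per_kb: float = 30.0,
    fragment_len: int = 300,
    read_len: int = 76,
    seed: int = 0,
    flank_bp: int = 2000,
) -> tuple[Library, Library]:
    """A ChIP library and a matched input library.

    Both carry uniform Poisson background at ``background_reads_per_kb``;
    the ChIP library additionally multiplies read density by the planted
    fold inside each enriched gene window (extra fragments placed
    uniformly within the window).  Returns (chip, input) Libraries with
    total_mapped set to the generated read counts.
    """
    if background_reads_per_kb <= 0 or fragment_len <= 0 or read_len <= 0:
        raise ValueError("rates and lengths must be positive")
    if read_len > fragment_len:
        raise ValueError("read_len cannot exceed fragment_len")
    rng = _rng_for(seed, "chip")
    rate_per_bp = background_reads_per_kb / 1000.0
    windows = {gw.gene_id: gw for gw in derive_windows(genes, dict(sizes), flank_bp)}

    frames = {"chip": [], "input": []}
    for chrom in sorted(sizes):
        clen = sizes[chrom]
        for label in ("chip", "input"):
            n_bg = int(rng.poisson(rate_per_bp * clen))
            frames[label].append(_place_fragments(rng, chrom, 0, clen, n_bg, fragment_len, read_len))
    for gene_id in sorted(enrichment):
        gw = windows.get(gene_id)
        if gw is None:
            raise KeyError(f"enrichment planted for unknown gene {gene_id!r}")
        for window_name, fold in sorted(enrichment[gene_id].items()):
            if fold < 1:
                raise ValueError(f"enrichment fold must be >= 1, got {fold} for {gene_id}")
            iv = gw.window(window_name)
            if iv is None or fold == 1:
                continue
            n_extra = int(rng.poisson(rate_per_bp * len(iv) * (fold - 1.0)))
            frames["chip"].append(
                _place_fragments(rng, iv.chrom, iv.start, iv.end, n_extra, fragment_len, read_len)
            )
    chip_df = pd.concat(frames["chip"], ignore_index=True)
    input_df = pd.concat(frames["input"], ignore_index=True)
    return Library("chip", chip_df), Library("input", input_df)


def simulate_expression(
    gene_ids: Sequence[str],
    planted_effects: Mapping[str, float],
    probes_per_gene: int = 2,
    n_per_group: int = 3,
    noise_sd: float = 0.1,
    detection_rate: float = 0.95,
    expressed_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Triplicate-design log2 expression matrix with detection calls.

    Per probe: log2 intensity = gene baseline + group effect (planted
    genes only, added to KO samples) + Gaussian noise.  A configurable
    fraction of genes is expressed (planted genes always are); expressed
    probes are called present with probability ``detection_rate`` (a
    small share marginal), unexpressed probes sit at a low baseline and
    are mostly absent.  Returns (matrix, calls, probe_map, groups,
    expressed_genes); the matrix is on log2 scale.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not set(planted_effects) <= set(gene_ids):
        raise ValueError("planted effects reference unknown genes")
    rng = _rng_for(seed, "expression")
    genes = list(gene_ids)
    samples = [f"WT_{i + 1}" for i in range(n_per_group)] + [f"KO_{i + 1}" for i in range(n_per_group)]
    groups = pd.Series(["WT"] * n_per_group + ["KO"] * n_per_group, index=samples, name="group")

    expressed = {g: (rng.random() < expressed_fraction) or (g in planted_effects) for g in genes}
    probe_ids, probe_gene, rows, call_rows = [], [], [], []
    ko_mask = (groups == "KO").to_numpy()
    for g in genes:
        base = rng.normal(8.0, 1.5) if expressed[g] else rng.normal(4.0, 0.5)
        effect = planted_effects.get(g, 0.0)
        for p in range(probes_per_gene):
            probe_offset = rng.normal(0.0, 0.3)
            mu = base + probe_offset
            vals = mu + np.where(ko_mask, effect, 0.0) + rng.normal(0.0, noise_sd, len(samples))
            probe_ids.append(f"{g}_p{p + 1}")
            probe_gene.append(g)
            rows.append(vals)
            if expressed[g]:
                u = rng.random(len(samples))
                call = np.where(u < detection_rate, "present",
                                np.where(u < detection_rate + (1 - detection_rate) / 2, "marginal", "absent"))
            else:
                call = np.where(rng.random(len(samples)) < 0.1, "marginal", "absent")
            call_rows.append(call)
    matrix = pd.DataFrame(np.array(rows), index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    calls = pd.DataFrame(np.array(call_rows), index=matrix.index, columns=samples)
    probe_map = pd.Series(probe_gene, index=matrix.index, name="gene_id")
    expressed_genes = sorted(g for g in genes if expressed[g])
    return matrix, calls, probe_map, groups, expressed_genes


def simulate_qpcr(
    folds: Mapping[str, float],
    ct_noise_sd: float = 0.05,
    n_pairs: int = 4,
    n_technical: int = 3,
    seed: int = 0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Comparative-Ct records for littermate pairs matching planted folds.

    Per gene the wild-type dCt baseline is drawn once; knockout target
    Ct is shifted by -log2(fold).  All Ct values carry Gaussian noise of
    sd ``ct_noise_sd``.  Columns match the Ct-table schema plus a
    ``pair`` column identifying the biological replicate pair.
    """
    if any(f <= 0 for f in folds.values()):
        raise ValueError("planted folds must be positive")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be nonnegative")
    rng = _rng_for(seed, "qpcr")
    rows = []
    for gene in sorted(folds):
        fold = folds[gene]
        dct0 = rng.uniform(4.0, 8.0)
        for pair in range(1, n_pairs + 1):
            for genotype in ("WT", "KO"):
                shift = -np.log2(fold) if genotype == "KO" else 0.0
                for rep in range(1, n_technical + 1):
                    ct_ref = reference_ct + rng.normal(0.0, ct_noise_sd)
                    ct_tgt = reference_ct + dct0 + shift + rng.normal(0.0, ct_noise_sd)
                    rows.append(
                        {
                            "sample_id": f"pair{pair}_{genotype}",
                            "genotype": genotype,
                            "gene": gene,
                            "reference_gene": "Gapdh",
                            "ct_target": round(ct_tgt, 4),
                            "ct_reference": round(ct_ref, 4),
                            "replicate": rep,
                            "pair": pair,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class SyntheticScreen:
    """All inputs of one synthetic end-to-end screen plus its truth."""

    genes: list[GeneModel]
    sizes: dict[str, int]
    chip: Library
    input: Library
    matrix: pd.DataFrame
    calls: pd.DataFrame
    probe_map: pd.Series
    groups: pd.Series
    ct_records: pd.DataFrame
    truth: SyntheticTruth
    config: SimConfig = field(default_factory=SimConfig)


def simulate_screen(seed: int, config: Optional[SimConfig] = None) -> SyntheticScreen:
    """Generate a complete coherent screen from one master seed.

    The first ``n_enriched_tss`` genes (by deterministic draw) get
    ``enrichment_fold`` TSS enrichment; the first ``n_de_planted`` of
    those also get the planted expression effect, alternating up/down
    in the knockout.  The qPCR panel is the first ``n_qpcr_genes`` of
    the jointly planted genes with folds implied by their expression
    effect.
    """
    cfg = config or SimConfig()
    genes, sizes = simulate_genome(
        cfg.n_genes, cfg.n_chroms, cfg.gene_length_range, cfg.spacing, seed, cfg.margin
    )
    picker = _rng_for(seed, "picks")
    gene_ids = [g.gene_id for g in genes]
    enriched = sorted(picker.choice(gene_ids, size=cfg.n_enriched_tss, replace=False).tolist())
    enrichment = {g: {"tss": cfg.enrichment_fold} for g in enriched}
    de_genes = enriched[: cfg.n_de_planted]
    effects = {g: (cfg.log2_effect if i % 2 == 0 else -cfg.log2_effect) for i, g in enumerate(de_genes)}

    chip, input_lib = simulate_chip_reads(
        genes, sizes, enrichment, cfg.background_reads_per_kb,
        cfg.fragment_len, cfg.read_len, seed, cfg.flank_bp,
    )
    matrix, calls, probe_map, groups, expressed = simulate_expression(
        gene_ids, effects, cfg.probes_per_gene, cfg.n_per_group,
        cfg.noise_sd, cfg.detection_rate, cfg.expressed_fraction, seed,
    )
    qpcr_genes = de_genes[: cfg.n_qpcr_genes]
    qpcr_folds = {g: float(2.0 ** effects[g]) for g in qpcr_genes}
    ct_records = simulate_qpcr(qpcr_folds, cfg.ct_noise_sd, cfg.n_pairs, cfg.n_technical, seed)

    truth = SyntheticTruth(
        seed=seed,
        enrichment=enrichment,
        expression_effects=effects,
        expressed_genes=expressed,
        probe_map=probe_map.to_dict(),
        qpcr_folds=qpcr_folds,
    )
    return SyntheticScreen(
        genes=genes, sizes=sizes, chip=chip, input=input_lib, matrix=matrix,
        calls=calls, probe_map=probe_map, groups=groups, ct_records=ct_records,
        truth=truth, config=cfg,
    )


def write_screen(screen: SyntheticScreen, outdir: str | Path) -> None:
    """Write all standard-format files of a simulated screen.

    genes.gtf, sizes.tsv, chip.bed, input.bed, expr.tsv (log2), calls.tsv,
    samples.tsv, probes.tsv, ct.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genes.gtf", "w") as fh:
        for g in screen.genes:
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )
    with open(outdir / "sizes.tsv", "w") as fh:
        for chrom in sorted(screen.sizes):
            fh.write(f"{chrom}\t{screen.sizes[chrom]}\n")
    for label, lib in (("chip", screen.chip), ("input", screen.input)):
        lib.reads.assign(name=".", score=0)[
            ["chrom", "start", "end", "name", "score", "strand"]
        ].to_csv(outdir / f"{label}.bed", sep="\t", header=False, index=False)
    screen.matrix.round(4).to_csv(outdir / "expr.tsv", sep="\t")
    screen.calls.to_csv(outdir / "calls.tsv", sep="\t")
    screen.groups.rename_axis("sample_id").to_frame().to_csv(outdir / "samples.tsv", sep="\t")
    screen.probe_map.rename_axis("probe_id").to_frame().to_csv(outdir / "probes.tsv", sep="\t")
    screen.ct_records.to_csv(outdir / "ct.tsv", sep="\t", index=False)
    screen.truth.to_json(outdir / "truth.json")
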