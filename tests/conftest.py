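import numpy as np
import pandas as pd
import pytest

from mecp2screen import Library, SimConfig, simulate_screen
from mecp2screen.annotation import WINDOW_NAMES


@pytest.fixture(scope="session")
def default_screen():
    """One full synthetic screen at the reference conditions (seed 1)."""
    return simulate_screen(1)


@pytest.fixture(scope="session")
def screen_result(default_screen):
    from mecp2screen import run_screen

    return run_screen(default_screen)


def brute_force_counts(lib: Library, windows, fragment_extension_bp, assignment):
    """Independent per-read/per-window double loop used as counting oracle."""
    rows = []
    for gw in windows:
        for name in WINDOW_NAMES:
            iv = gw.window(name)
            if iv is None:
                continue
            n = 0
            for read in lib.reads.itertuples(index=False):
                if read.chrom != iv.chrom:
                    continue
                s, e = read.start, read.end
                if fragment_extension_bp > 0:
                    if read.strand == "+":
                        e = s + fragment_extension_bp
                    else:
                        s = max(e - fragment_extension_bp, 0)
                if assignment == "midpoint":
                    mid = (s + e) // 2
                    hit = iv.start <= mid < iv.end
                else:
                    hit = s < iv.end and e > iv.start
                n += hit
            rows.append((gw.gene_id, name, n))
    return pd.DataFrame(rows, columns=["gene_id", "window", "count"])


def random_counting_instance(rng: np.random.Generator):
    """A tiny random instance: <= 5 windows (1-2 genes), <= 50 reads."""
    from mecp2screen import GeneModel, derive_windows

    sizes = {"c1": 40_000, "c2": 30_000}
    n_genes = int(rng.integers(1, 3))
    genes = []
    for i in range(n_genes):
        chrom = "c1" if rng.random() < 0.7 else "c2"
        start = int(rng.integers(0, 20_000))
        length = int(rng.integers(500, 8_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i}", chrom, start, start + length, strand))
    flank = int(rng.integers(100, 3_000))
    windows = derive_windows(genes, sizes, flank)
    if n_genes == 2 and rng.random() < 0.5:  # trim to <= 5 windows
        windows[1] = type(windows[1])(windows[1].gene_id, windows[1].tss, None, None)
    n_reads = int(rng.integers(0, 51))
    reads = []
    for _ in range(n_reads):
        chrom = "c1" if rng.random() < 0.8 else "c2"
        s = int(rng.integers(0, sizes[chrom] - 100))
        reads.append((chrom, s, s + 76, "+" if rng.random() < 0.5 else "-"))
    df = pd.DataFrame(reads, columns=["chrom", "start", "end", "strand"])
    lib = Library("chip", df, total_mapped=max(len(df), 1))
    ext = int(rng.choice([0, 150, 200, 400]))
    return lib, windows, ext
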