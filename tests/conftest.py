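from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from chipforge.containers import NOCALL
from chipforge.probedesign import VariantSite

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_sites_frame() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "toy_sites.tsv", sep="\t", keep_default_na=False)


def site_from_row(row) -> VariantSite:
    """Build a VariantSite from a toy-table row (10 samples per site)."""
    genotypes = np.array(
        [0] * row.n_aa + [1] * row.n_ab + [2] * row.n_bb + [NOCALL] * row.n_nn,
        dtype=np.int8,
    )
    return VariantSite(
        contig=row.contig,
        pos=int(row.pos),
        ref=row.ref,
        alt=row.alt,
        depth=int(row.depth),
        ref_reads=int(row.ref_reads),
        alt_reads=int(row.alt_reads),
        other_reads=int(row.other_reads),
        qual=float(row.qual),
        genotypes=genotypes,
    )


@pytest.fixture(scope="session")
def toy_sites(toy_sites_frame):
    return [site_from_row(row) for row in toy_sites_frame.itertuples()]


def weir_cockerham_fst(d1: np.ndarray, d2: np.ndarray) -> float:
    """Two-population Weir-Cockerham theta (ratio of averages).

    Independent oracle for the population simulator's differentiation
    parameter; operates directly on dosage matrices (loci x samples).
    """
    r = 2
    n1, n2 = d1.shape[1], d2.shape[1]
    p1, p2 = d1.mean(axis=1) / 2, d2.mean(axis=1) / 2
    h1, h2 = (d1 == 1).mean(axis=1), (d2 == 1).mean(axis=1)
    n_bar = (n1 + n2) / 2
    nc = (2 * n_bar - (n1**2 + n2**2) / (2 * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (2 * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (2 * n_bar)
    a = n_bar / nc * (
        s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
    )
    b = n_bar / (n_bar - 1) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a.sum() / (a + b + c).sum())
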