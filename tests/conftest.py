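from __future__ import annotations

import numpy as np
import pytest

from ligatyper import DesignParams, SampleTruth, Variant, builtin_panel_hl32
from ligatyper.design import assign_layout
from ligatyper.panel import Panel


@pytest.fixture(scope="session")
def hl32() -> Panel:
    return builtin_panel_hl32()


_BASES = "ACGT"


def random_panel(rng: np.random.Generator, n_variants: int | None = None) -> Panel:
    """A random valid bi-/tri-allelic panel with a first-fit layout."""
    n = int(n_variants or rng.integers(3, 13))
    genes = [f"GENE{g}" for g in range(1, int(rng.integers(2, 5)) + 1)]
    variants = []
    for i in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        ref = _BASES[int(rng.integers(4))]
        kind = rng.random()
        if kind < 0.2:  # deletion
            alt = ("-",)
        else:
            alt = (_BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4],)
        variants.append(
            Variant(
                gene=gene,
                chromosome="1",
                name=f"c.{100 + i}{ref}>{alt[0]}" if alt[0] != "-" else f"c.{100 + i}del{ref}",
                ref_allele=ref,
                alt_alleles=alt,
                inheritance="AR",
            )
        )
    layout = assign_layout(variants, DesignParams())
    return Panel(name="random", variants=variants, layout=layout)


def random_truth(
    rng: np.random.Generator, panel: Panel, sample_id: str = "S1"
) -> SampleTruth:
    g: dict[str, str | float] = {}
    for v in panel.variants:
        r = rng.random()
        if r < 0.25:
            g[v.name] = 1.0 if v.is_mitochondrial else "het"
        elif r < 0.4:
            g[v.name] = 1.0 if v.is_mitochondrial else "hom_alt"
    return SampleTruth(sample_id, g)
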