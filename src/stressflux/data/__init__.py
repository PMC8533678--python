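"""Reference tallies from the palladium stress experiment the pipeline models.

These are the published summary numbers of the study system (counts of DE
genes, the top-20 fold-change tables, and the per-condition flux-category
tallies for palladium and ten biocides). They are *inputs* for worked
examples and consistency checks — nothing in the pipeline computes from
them; the pipeline recomputes such quantities from raw data.
"""

from importlib import resources

import pandas as pd

from ..dge import DETable

__all__ = [
    "PD_N_MAPPED_GENES",
    "PD_N_UP",
    "PD_N_DOWN",
    "top_regulated_table",
    "flux_category_table",
]

#: genes mapped in the palladium RNA-seq experiment
PD_N_MAPPED_GENES = 3898
#: significantly up- / down-regulated genes (raw p < 0.05)
PD_N_UP = 411
PD_N_DOWN = 298


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def top_regulated_table() -> DETable:
    """The published top-20 up- and down-regulated genes as a DETable.

    p-values were not printed per gene; every listed gene was significant, so
    a placeholder p = 1e-3 below any usual α is used, with log2fc derived
    from the signed fold change.
    """
    import numpy as np

    raw = _read("top_regulated_pd.tsv").set_index("gene")
    fc = raw["fold_change_signed"].astype(float)
    frame = pd.DataFrame(
        {
            "log2fc": np.sign(fc) * np.log2(fc.abs()),
            "fold_change_signed": fc,
            "p_value": 1e-3,
            "status": raw["direction"],
        },
        index=raw.index,
    )
    return DETable(frame)


def flux_category_table() -> pd.DataFrame:
    """Published per-condition flux-category tallies (palladium + 10 biocides).

    The no-flux count was published for palladium only; it is NaN for the
    biocide conditions.
    """
    return _read("flux_categories.tsv").set_index("condition")
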