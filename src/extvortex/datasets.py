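"""Packaged reference tables and dataset accounting helpers.

``study_populations_synthetic.csv`` is a synthetic stand-in population
summary (not real monitoring data): 35 populations of 32 species whose
class composition — 25 avian populations, 8 mammalian populations of 5
species, 2 reptilian — matches the taxonomic structure of the published
extirpation dataset the pipeline targets, so accounting code can be
exercised without a download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_study_population_table", "class_composition"]


def load_study_population_table() -> pd.DataFrame:
    """Synthetic population summary table (ID, Binomial, Class)."""
    with resources.files("extvortex.data").joinpath(
        "study_populations_synthetic.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def class_composition(table: pd.DataFrame) -> pd.DataFrame:
    """Per-class population counts and percentage shares.

    Shares are percentages of populations (rows), rounded to two decimals
    for reporting.
    """
    counts = table.groupby("Class").agg(
        n_populations=("ID", "size"), n_species=("Binomial", "nunique")
    )
    counts["share_pct"] = (100.0 * counts["n_populations"] / len(table)).round(2)
    return counts.reset_index().sort_values("n_populations", ascending=False,
                                            ignore_index=True)
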