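"""Bundled reference tables.

Two small published summary tables from a continental-scale comparison of
Quaternary fossil occurrences with the modern climatic niches of Nearctic
turtles.  They serve as worked-example inputs for the aggregation
arithmetic in :mod:`paleoniche.fossils` (count-weighted pooling of
per-species percentages and of per-variable MESS deviation means).
"""

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fossil_niche_summary() -> pd.DataFrame:
    """Per-species fossil counts and the percentages of fossils falling
    within the species' realized and potential niches."""
    return _read("fossil_niche_summary.csv")


def load_fossil_mess_deviations() -> pd.DataFrame:
    """Per-variable MESS deviation summaries (N, mean, most-negative) for
    fossils that fell outside the niche on at least one variable, split by
    overall within/outside potential-niche status."""
    return _read("fossil_mess_deviations.csv")
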